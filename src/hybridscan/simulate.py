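"""Multispecies-coalescent simulation of phased multilocus datasets.

This module generates the synthetic study systems every downstream stage is
tested against: diploid specimens sampled from a small radiation of closely
related species with incomplete lineage sorting, optionally with first
generation (F1) hybrids and with continuous or pulse introgression between
species pairs, plus an outgroup.

The genealogical engine is msprime (structured coalescent, one independent
genealogy per unlinked locus) and sequences evolve under Jukes-Cantor on a
discrete genome, so multiple hits at a site are possible and closed-form JC
expectations apply.  Units are explicit throughout: times in generations,
population sizes are diploid effective sizes N (a pair of lineages in a
population coalesces at rate 1/(2N)), mutation and migration rates are per
generation.

Reproducibility contract: a single root seed; every locus draws its ancestry
and mutation seeds from a counter-keyed substream, so locus i is reproducible
in isolation and outputs are bit-identical across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MigrationPulse",
    "ContinuousMigration",
    "SpeciesJoin",
    "SpeciesTreeModel",
    "HybridSpec",
    "SimulationConfig",
    "Genealogy",
    "PhasedAlignment",
    "SyntheticDataset",
    "simulate_gene_tree",
    "mutate_alignment",
    "simulate_dataset",
    "make_f1_hybrid",
    "write_dataset",
    "three_species_model",
    "two_species_model",
]

SATURATION_GUARD = 0.75  # expected substitutions per site over the whole tree


class ModelError(ValueError):
    """Structural error in a species-tree model or simulation config."""


@dataclass(frozen=True)
class MigrationPulse:
    """Instantaneous admixture: at ``time`` generations ago a fraction
    ``proportion`` of the ``recipient`` population's lineages derive from
    ``donor`` (forward-time wording)."""

    donor: str
    recipient: str
    proportion: float
    time: float


@dataclass(frozen=True)
class ContinuousMigration:
    """Continuous gene flow ``donor`` -> ``recipient`` (forward time) at
    ``rate`` per generation per lineage, active on [start, end) generations
    ago."""

    donor: str
    recipient: str
    rate: float
    start: float
    end: float


@dataclass(frozen=True)
class SpeciesJoin:
    """Rootward merge of two populations into a named ancestor at ``time``."""

    time: float
    derived: tuple[str, str]
    ancestral: str


@dataclass
class SpeciesTreeModel:
    """Rooted species tree with per-branch diploid effective sizes.

    ``joins`` are ordered rootward; divergence times must strictly increase
    along every tip-to-root path.  ``pop_sizes`` must name every tip species
    and every ancestral population introduced by a join.
    """

    species: list[str]
    pop_sizes: dict[str, float]
    joins: list[SpeciesJoin] = field(default_factory=list)
    migration: list[MigrationPulse | ContinuousMigration] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ModelError("duplicate species names")
        names = set(self.species)
        parent_time: dict[str, float] = {}
        for j in self.joins:
            for d in j.derived:
                if d not in names:
                    raise ModelError(
                        f"join at t={j.time} merges unknown population {d!r}"
                    )
                parent_time[d] = j.time
            if j.ancestral in names:
                raise ModelError(f"ancestral population {j.ancestral!r} reused")
            names.add(j.ancestral)
        # strict rootward increase of divergence times
        for j in self.joins:
            for d in j.derived:
                for j2 in self.joins:
                    if d == j2.ancestral and j.time <= j2.time:
                        raise ModelError(
                            f"divergence times not strictly increasing rootward "
                            f"at branch {d!r}"
                        )
        if len(self.joins) != len(self.species) - 1:
            raise ModelError(
                "model must coalesce to a single root "
                f"({len(self.joins)} joins for {len(self.species)} species)"
            )
        for name in names:
            if self.pop_sizes.get(name, 0) <= 0:
                raise ModelError(f"pop_sizes must be > 0 for population {name!r}")
        for mig in self.migration:
            if mig.donor == mig.recipient:
                raise ModelError("migration donor and recipient must differ")
            for p in (mig.donor, mig.recipient):
                if p not in names:
                    raise ModelError(f"migration names unknown population {p!r}")
            if isinstance(mig, MigrationPulse):
                if not (0 <= mig.proportion < 1):
                    raise ModelError("migration proportion must be in [0, 1)")
            else:
                if not (0 <= mig.rate < 1):
                    raise ModelError("migration rate must be in [0, 1)")
                if mig.end <= mig.start:
                    raise ModelError("migration window must have end > start")

    @property
    def populations(self) -> list[str]:
        return list(self.species) + [j.ancestral for j in self.joins]

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name in self.populations:
            dem.add_population(name=name, initial_size=self.pop_sizes[name])
        for j in self.joins:
            dem.add_population_split(
                time=j.time, derived=list(j.derived), ancestral=j.ancestral
            )
        for mig in self.migration:
            if isinstance(mig, MigrationPulse):
                # forward donor->recipient == backward recipient->donor
                dem.add_mass_migration(
                    time=mig.time,
                    source=mig.recipient,
                    dest=mig.donor,
                    proportion=mig.proportion,
                )
            else:
                dem.add_migration_rate_change(
                    time=mig.start,
                    rate=mig.rate,
                    source=mig.recipient,
                    dest=mig.donor,
                )
                dem.add_migration_rate_change(
                    time=mig.end, rate=0.0, source=mig.recipient, dest=mig.donor
                )
        dem.sort_events()
        return dem


@dataclass(frozen=True)
class HybridSpec:
    """A planted first-generation hybrid: haplotype 0 is a fresh lineage from
    ``parent_a``'s gene pool, haplotype 1 from ``parent_b``'s."""

    specimen: str
    parent_a: str
    parent_b: str
    generation: str = "F1"

    def __post_init__(self) -> None:
        if self.parent_a == self.parent_b:
            raise ModelError("invalid hybrid: parents must be distinct species")
        if self.generation != "F1":
            raise ModelError("only F1 hybrids are supported")


@dataclass
class SimulationConfig:
    species_model: SpeciesTreeModel
    n_specimens_per_species: dict[str, int] | int
    n_loci: int
    locus_length: int
    mutation_rate: float
    hybrids: list[HybridSpec] = field(default_factory=list)
    outgroup: str | None = None
    seed: int = 1
    missing_prob: float = 0.0  # per-specimen per-locus dropout
    pool_reserve_per_species: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ModelError("n_loci must be >= 1")
        if self.locus_length < 1:
            raise ModelError("locus_length must be >= 1")
        if self.mutation_rate <= 0:
            raise ModelError("mutation_rate must be > 0")
        if not 0 <= self.missing_prob < 1:
            raise ModelError("missing_prob must be in [0, 1)")
        tips = set(self.species_model.species)
        for h in self.hybrids:
            if h.parent_a not in tips or h.parent_b not in tips:
                raise ModelError(f"hybrid {h.specimen!r} parents must be tip species")
        if self.outgroup is not None and self.outgroup not in tips:
            raise ModelError(f"outgroup {self.outgroup!r} is not a tip species")

    def counts(self) -> dict[str, int]:
        if isinstance(self.n_specimens_per_species, int):
            return {s: self.n_specimens_per_species for s in self.species_model.species}
        return dict(self.n_specimens_per_species)


@dataclass(frozen=True)
class Specimen:
    """Registry entry.  ``haplotype_pops`` gives the sampling population of
    (h0, h1); they differ only for hybrids."""

    specimen: str
    species: str  # putative species label used by downstream analyses
    role: str  # reference | query | outgroup
    haplotype_pops: tuple[str, str]
    is_hybrid: bool = False
    parent_a: str | None = None
    parent_b: str | None = None


def _locus_seeds(root_seed: int, locus: int) -> tuple[int, int]:
    """Counter-derived (ancestry, mutation) seeds for one locus."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(int(locus),))
    a, b = ss.generate_state(2, dtype=np.uint32)
    # msprime seeds must be >= 1
    return int(a % (2**31 - 1)) + 1, int(b % (2**31 - 1)) + 1


@dataclass
class Genealogy:
    """One locus genealogy: a (possibly mutated) tree sequence plus the
    mapping from sample node -> haplotype label ``{specimen}_h{0,1}``."""

    ts: "msprime.TreeSequence"
    labels: dict[int, str]  # sample node id -> tip label
    locus: str = "locus"

    def newick(self) -> str:
        return self.ts.first().as_newick(node_labels=self.labels)

    def tmrca(self) -> float:
        tree = self.ts.first()
        return tree.time(tree.root)

    def total_branch_length(self) -> float:
        return self.ts.first().total_branch_length


def _sample_sets_for(
    specimens: list[Specimen],
) -> tuple[list[msprime.SampleSet], dict[int, str]]:
    sets, labels = [], {}
    node = 0
    for sp in specimens:
        for h, pop in enumerate(sp.haplotype_pops):
            sets.append(msprime.SampleSet(1, population=pop, ploidy=1))
            labels[node] = f"{sp.specimen}_h{h}"
            node += 1
    return sets, labels


def simulate_gene_tree(
    model: SpeciesTreeModel,
    sample_map: dict[str, str],
    seed: int,
    ploidy: int = 2,
) -> Genealogy:
    """Simulate one genealogy for diploid (or haploid) specimens.

    ``sample_map`` maps specimen id -> species; every species must be a tip of
    the model.  Lineages coalesce only within populations at rate k(k-1)/2 /
    (2N), populations merge rootward at the model's divergence times, and
    migration moves single lineages between populations at the configured
    rates.
    """
    tips = set(model.species)
    for spec, species in sample_map.items():
        if species not in tips:
            raise ModelError(f"specimen {spec!r} sampled from non-tip {species!r}")
    if ploidy not in (1, 2):
        raise ModelError("ploidy must be 1 or 2")
    specimens = [
        Specimen(s, sp, "reference", (sp, sp) if ploidy == 2 else (sp,))
        for s, sp in sample_map.items()
    ]
    sets, labels = [], {}
    node = 0
    for sp in specimens:
        for h, pop in enumerate(sp.haplotype_pops):
            sets.append(msprime.SampleSet(1, population=pop, ploidy=1))
            labels[node] = f"{sp.specimen}_h{h}" if ploidy == 2 else sp.specimen
            node += 1
    try:
        ts = msprime.sim_ancestry(
            samples=sets,
            demography=model.to_demography(),
            sequence_length=1,
            ploidy=2,  # time scale: diploid N
            random_seed=seed,
        )
    except Exception as exc:  # pragma: no cover - msprime names the branch
        raise ModelError(f"unreachable coalescence: {exc}") from exc
    return Genealogy(ts=ts, labels=labels)


def mutate_alignment(
    genealogy: Genealogy, length: int, mu: float, seed: int
) -> "PhasedAlignment":
    """Throw Jukes-Cantor mutations on a genealogy and emit one sequence per
    haplotype tip.  Loci whose expected substitutions per site over the whole
    tree exceed the saturation guard are flagged, not rejected."""
    ts = genealogy.ts
    if ts.sequence_length != length:
        # re-lay the genealogy over the requested length (same topology/times)
        tables = ts.dump_tables()
        tables.sequence_length = float(length)
        tables.edges.clear()
        for e in ts.edges():
            tables.edges.add_row(
                left=0.0, right=float(length), parent=e.parent, child=e.child
            )
        ts = tables.tree_sequence()
    mts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.JC69(), random_seed=seed
    )
    saturated = mu * genealogy.total_branch_length() >= SATURATION_GUARD
    ref = "A" * length
    seqs = {}
    order = [u for u in ts.samples()]
    for node, aln in zip(order, mts.alignments(reference_sequence=ref)):
        seqs[genealogy.labels[int(node)]] = aln
    return PhasedAlignment(
        locus=genealogy.locus, length=length, sequences=seqs, saturated=saturated
    )


@dataclass
class PhasedAlignment:
    """Per-locus phased alignment: tip name ``{specimen}_h0/h1`` -> sequence."""

    locus: str
    length: int
    sequences: dict[str, str]
    saturated: bool = False

    def haplotypes_of(self, specimen: str) -> tuple[str | None, str | None]:
        return (
            self.sequences.get(f"{specimen}_h0"),
            self.sequences.get(f"{specimen}_h1"),
        )


@dataclass
class SyntheticDataset:
    """The simulated study system.

    ``alignments`` are materialised lazily from the stored mutated tree
    sequences; the genotype matrix is extracted from the same variants, and a
    consistency test guarantees both views agree.  Reserve lineages (extra
    coalescent samples kept aside per species) are hidden from every output
    until :func:`make_f1_hybrid` promotes them into a new specimen.
    """

    config: SimulationConfig
    specimens: list[Specimen]
    loci: list[Genealogy]  # mutated tree sequences
    reserve_nodes: dict[str, list[int]]  # species -> unused reserve sample nodes
    missing_mask: np.ndarray  # bool (n_specimens, n_loci) specimen dropout
    _alignments: list[PhasedAlignment] | None = None

    # -- views -------------------------------------------------------------
    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen for s in self.specimens]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.specimens:
            rows.append(
                {
                    "specimen": s.specimen,
                    "species": s.species,
                    "role": s.role,
                    "is_hybrid": s.is_hybrid,
                    "parent_a": s.parent_a or "",
                    "parent_b": s.parent_b or "",
                }
            )
        return pd.DataFrame(rows)

    def species_map(self):
        from .genotypes import SpeciesMap

        return SpeciesMap(
            species={s.specimen: s.species for s in self.specimens},
            roles={s.specimen: s.role for s in self.specimens},
        )

    @property
    def alignments(self) -> list[PhasedAlignment]:
        if self._alignments is None:
            self._alignments = [self._materialise_alignment(i) for i in range(len(self.loci))]
        return self._alignments

    def _materialise_alignment(self, i: int) -> PhasedAlignment:
        g = self.loci[i]
        mts = g.ts
        length = int(mts.sequence_length)
        ref = "A" * length
        seqs_by_node = {}
        for node, aln in zip(mts.samples(), mts.alignments(reference_sequence=ref)):
            seqs_by_node[int(node)] = aln
        sequences = {}
        node_of = {lab: n for n, lab in g.labels.items()}
        for si, s in enumerate(self.specimens):
            if self.missing_mask[si, i]:
                continue
            for h in (0, 1):
                lab = f"{s.specimen}_h{h}"
                sequences[lab] = seqs_by_node[node_of[lab]]
        sat = self.config.mutation_rate * g.total_branch_length() >= SATURATION_GUARD
        return PhasedAlignment(
            locus=g.locus, length=length, sequences=sequences, saturated=sat
        )

    # -- genotypes ---------------------------------------------------------
    def genotype_matrix(self):
        """Biallelic SNP matrix extracted from the simulated variants.

        Applies the same rules as ``genotypes_from_alignments``: only columns
        with exactly two segregating nucleotides among non-missing haplotypes
        are emitted, the reference allele is the majority allele (ties broken
        alphabetically), and a specimen is heterozygous iff its two haplotypes
        differ.
        """
        from .genotypes import GenotypeMatrix

        spec_ids = self.specimen_ids
        n_spec = len(spec_ids)
        calls_cols: list[np.ndarray] = []
        sites_rows: list[tuple[str, int, str, str]] = []
        skipped_multi = 0
        for li, g in enumerate(self.loci):
            mts = g.ts
            node_of = {lab: n for n, lab in g.labels.items()}
            idx = np.array(
                [
                    [node_of[f"{s.specimen}_h0"], node_of[f"{s.specimen}_h1"]]
                    for s in self.specimens
                ]
            )
            present = ~self.missing_mask[:, li]
            hap_nodes = idx[present].reshape(-1)
            sample_order = {int(n): i for i, n in enumerate(mts.samples())}
            hap_rows = np.array([sample_order[int(n)] for n in hap_nodes])
            if len(hap_rows) == 0:
                continue
            pres_idx = np.flatnonzero(present)
            for var in mts.variants():
                allele_arr = np.asarray(var.alleles, dtype="U1")
                bases = allele_arr[var.genotypes[hap_rows]]
                uniq, counts = np.unique(bases, return_counts=True)
                if len(uniq) < 2:
                    continue
                if len(uniq) > 2:
                    skipped_multi += 1
                    continue
                # majority allele is ref; tie broken alphabetically (uniq sorted)
                ref, alt = (uniq[0], uniq[1]) if counts[0] >= counts[1] else (uniq[1], uniq[0])
                a, b = bases[0::2], bases[1::2]
                gcall = np.where(a != b, 1, np.where(a == alt, 2, 0)).astype(np.int8)
                col = np.full(n_spec, -1, dtype=np.int8)
                col[pres_idx] = gcall
                calls_cols.append(col)
                sites_rows.append((g.locus, int(var.site.position) + 1, str(ref), str(alt)))
        if calls_cols:
            calls = np.stack(calls_cols, axis=1)
        else:
            calls = np.zeros((n_spec, 0), dtype=np.int8)
        sites = pd.DataFrame(
            sites_rows, columns=["locus", "pos", "ref", "alt"]
        )
        gm = GenotypeMatrix(specimens=spec_ids, sites=sites, calls=calls)
        gm.n_skipped_multiallelic = skipped_multi
        gm.loci_lengths = {g.locus: int(g.ts.sequence_length) for g in self.loci}
        return gm

    def true_trees(self) -> dict[str, str]:
        out = {}
        for g in self.loci:
            out[g.locus] = g.newick()
        return out


def _build_registry(config: SimulationConfig) -> list[Specimen]:
    counts = config.counts()
    specimens: list[Specimen] = []
    for species in config.species_model.species:
        role = "outgroup" if species == config.outgroup else "reference"
        for k in range(counts.get(species, 0)):
            specimens.append(
                Specimen(f"{species}_{k + 1}", species, role, (species, species))
            )
    for h in config.hybrids:
        specimens.append(
            Specimen(
                h.specimen,
                h.parent_a,  # putative species assignment for group analyses
                "query",
                (h.parent_a, h.parent_b),
                is_hybrid=True,
                parent_a=h.parent_a,
                parent_b=h.parent_b,
            )
        )
    if len({s.specimen for s in specimens}) != len(specimens):
        raise ModelError("duplicate specimen ids")
    return specimens


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate ``n_loci`` unlinked loci for the configured specimens.

    Deterministic for a fixed ``config.seed``.  Reserve lineages per species
    (``pool_reserve_per_species``) are simulated jointly so that a later
    :func:`make_f1_hybrid` can add a specimen without changing anyone else's
    sequences.
    """
    specimens = _build_registry(config)
    model = config.species_model
    dem = model.to_demography()
    sets, labels = _sample_sets_for(specimens)
    node = len(labels)
    reserve_nodes: dict[str, list[int]] = {s: [] for s in model.species}
    for species in model.species:
        for r in range(config.pool_reserve_per_species):
            sets.append(msprime.SampleSet(1, population=species, ploidy=1))
            labels[node] = f"__pool__{species}_{r}"
            reserve_nodes[species].append(node)
            node += 1

    loci: list[Genealogy] = []
    seeds = [_locus_seeds(config.seed, i) for i in range(config.n_loci)]
    for i in range(config.n_loci):
        s_anc, s_mut = seeds[i]
        ts = msprime.sim_ancestry(
            samples=sets,
            demography=dem,
            sequence_length=config.locus_length,
            ploidy=2,
            random_seed=s_anc,
        )
        mts = msprime.sim_mutations(
            ts, rate=config.mutation_rate, model=msprime.JC69(), random_seed=s_mut
        )
        loci.append(Genealogy(ts=mts, labels=dict(labels), locus=f"locus_{i:04d}"))

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(10**6,))
    )
    mask = rng.random((len(specimens), config.n_loci)) < config.missing_prob
    return SyntheticDataset(
        config=config,
        specimens=specimens,
        loci=loci,
        reserve_nodes={k: list(v) for k, v in reserve_nodes.items()},
        missing_mask=mask,
    )


def make_f1_hybrid(
    dataset: SyntheticDataset, parent_a: str, parent_b: str, new_id: str
) -> SyntheticDataset:
    """Return a new dataset with one extra F1 specimen.

    Haplotype 0 is an unused reserve lineage from ``parent_a``'s gene pool and
    haplotype 1 from ``parent_b``'s — independent coalescent samples simulated
    jointly with the base dataset, not copies of existing specimens.  All
    pre-existing specimens' sequences are bit-identical before and after.
    """
    if parent_a == parent_b:
        raise ModelError("invalid hybrid: parents must be distinct species")
    for p in (parent_a, parent_b):
        if p not in dataset.reserve_nodes:
            raise ModelError(f"unknown parent species {p!r}")
        if not dataset.reserve_nodes[p]:
            raise ModelError(
                f"no reserve lineages left for {p!r}; simulate with "
                "pool_reserve_per_species > 0"
            )
    if new_id in dataset.specimen_ids:
        raise ModelError(f"specimen id {new_id!r} already present")
    reserves = {k: list(v) for k, v in dataset.reserve_nodes.items()}
    node_a = reserves[parent_a].pop(0)
    node_b = reserves[parent_b].pop(0)
    new_specimen = Specimen(
        new_id,
        parent_a,
        "query",
        (parent_a, parent_b),
        is_hybrid=True,
        parent_a=parent_a,
        parent_b=parent_b,
    )
    loci = []
    for g in dataset.loci:
        labels = dict(g.labels)
        labels[node_a] = f"{new_id}_h0"
        labels[node_b] = f"{new_id}_h1"
        loci.append(Genealogy(ts=g.ts, labels=labels, locus=g.locus))
    mask = np.vstack([dataset.missing_mask, np.zeros((1, len(loci)), dtype=bool)])
    return SyntheticDataset(
        config=dataset.config,
        specimens=list(dataset.specimens) + [new_specimen],
        loci=loci,
        reserve_nodes=reserves,
        missing_mask=mask,
    )


# ---------------------------------------------------------------------------
# disk output

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per locus, true trees (newick), genotypes (VCF v4.2),
    alignment-length sidecar, species map and truth table (TSV)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .genotypes import write_vcf

    outdir = Path(outdir)
    fasta_dir = outdir / "alignments"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    lengths = []
    for aln in dataset.alignments:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(aln.sequences.items())
        ]
        SeqIO.write(recs, fasta_dir / f"{aln.locus}.fasta", "fasta")
        lengths.append((aln.locus, aln.length))
    pd.DataFrame(lengths, columns=["locus", "alignment_length"]).to_csv(
        outdir / "locus_lengths.tsv", sep="\t", index=False
    )
    trees_path = outdir / "true_trees.nwk"
    with open(trees_path, "w") as fh:
        for locus, nwk in dataset.true_trees().items():
            fh.write(nwk + "\n")
    gm = dataset.genotype_matrix()
    vcf_path = outdir / "genotypes.vcf"
    write_vcf(gm, vcf_path)
    dataset.species_map().to_tsv(outdir / "species_map.tsv")
    dataset.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "alignments": fasta_dir,
        "trees": trees_path,
        "vcf": vcf_path,
        "species_map": outdir / "species_map.tsv",
        "truth": outdir / "truth.tsv",
        "locus_lengths": outdir / "locus_lengths.tsv",
    }


# ---------------------------------------------------------------------------
# config (de)serialisation — flat YAML-friendly dicts

def model_from_dict(d: dict) -> SpeciesTreeModel:
    migs = []
    for m in d.get("migration", []) or []:
        kind = m.get("type", "pulse")
        if kind == "pulse":
            migs.append(
                MigrationPulse(m["donor"], m["recipient"], float(m["proportion"]),
                               float(m["time"]))
            )
        elif kind == "continuous":
            migs.append(
                ContinuousMigration(m["donor"], m["recipient"], float(m["rate"]),
                                    float(m["start"]), float(m["end"]))
            )
        else:
            raise ModelError(f"unknown migration type {kind!r}")
    joins = [
        SpeciesJoin(float(j["time"]), tuple(j["derived"]), j["ancestral"])
        for j in d.get("joins", [])
    ]
    return SpeciesTreeModel(
        species=list(d["species"]),
        pop_sizes={k: float(v) for k, v in d["pop_sizes"].items()},
        joins=joins,
        migration=migs,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    hybrids = [
        HybridSpec(h["specimen"], h["parent_a"], h["parent_b"],
                   h.get("generation", "F1"))
        for h in d.get("hybrids", []) or []
    ]
    n_spec = d["n_specimens_per_species"]
    if isinstance(n_spec, dict):
        n_spec = {k: int(v) for k, v in n_spec.items()}
    else:
        n_spec = int(n_spec)
    return SimulationConfig(
        species_model=model_from_dict(d["species_tree"]),
        n_specimens_per_species=n_spec,
        n_loci=int(d["n_loci"]),
        locus_length=int(d["locus_length"]),
        mutation_rate=float(d["mutation_rate"]),
        hybrids=hybrids,
        outgroup=d.get("outgroup"),
        seed=int(d.get("seed", 1)),
        missing_prob=float(d.get("missing_prob", 0.0)),
        pool_reserve_per_species=int(d.get("pool_reserve_per_species", 0)),
    )


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# convenience model builders (the standard study conditions; see docs/methods)

def two_species_model(
    t_split: float, n: float = 10_000, migration=None
) -> SpeciesTreeModel:
    return SpeciesTreeModel(
        species=["A", "B"],
        pop_sizes={"A": n, "B": n, "AB": n},
        joins=[SpeciesJoin(t_split, ("A", "B"), "AB")],
        migration=list(migration or []),
    )


def three_species_model(
    t1: float = 40_000,
    t2: float = 80_000,
    t_out: float = 400_000,
    n: float = 10_000,
    migration=None,
    names: tuple[str, str, str, str] = ("P1", "P2", "P3", "OUT"),
) -> SpeciesTreeModel:
    """(((P1,P2),P3),OUT) with one diploid size everywhere — the radiation-like
    regime with appreciable incomplete lineage sorting used throughout the
    test-suite."""
    p1, p2, p3, out = names
    return SpeciesTreeModel(
        species=[p1, p2, p3, out],
        pop_sizes={
            p1: n, p2: n, p3: n, out: n,
            "anc12": n, "anc123": n, "root": n,
        },
        joins=[
            SpeciesJoin(t1, (p1, p2), "anc12"),
            SpeciesJoin(t2, ("anc12", p3), "anc123"),
            SpeciesJoin(t_out, ("anc123", out), "root"),
        ],
        migration=list(migration or []),
    )
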