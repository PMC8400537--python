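"""Phased-allele placement in gene trees: the core hybrid diagnostic.

Each diploid specimen contributes two phased allele tips (``{specimen}_h0`` /
``{specimen}_h1``) to every rooted per-locus gene tree.  For a query
specimen, each allele is assigned to the species whose reference tips it
nests among: walking rootward from the allele tip, the first ancestor whose
subtree holds at least ``min_reference_tips`` reference tips (the query's own
tips excluded) decides — if a fraction >= ``purity`` of those tips belong to
one species (and clade support clears the optional threshold) the allele is
assigned there, otherwise it is "unsupported".

A locus is *monospecific* when both alleles land in the same species and
*heterospecific* when they land in different species; a high heterospecific
fraction with a balanced split between two parents is the signature of a
first-generation hybrid, whose every locus carries one haplotype per parent.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import SpeciesMap

__all__ = [
    "PlacementParams",
    "GeneTree",
    "AlleleAssignment",
    "LocusClassification",
    "PlacementSummary",
    "F1Diagnosis",
    "load_gene_trees",
    "assign_allele",
    "classify_locus",
    "summarize_placements",
    "f1_test",
    "nj_gene_tree",
    "round_pct",
]


class GeneTreeError(ValueError):
    pass


def round_pct(x: float, ndigits: int = 1) -> float:
    """Half-up rounding of a percentage (Python's round() is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PlacementParams:
    min_reference_tips: int = 2
    purity: float = 0.90
    min_support: float = 0.0  # 0 disables the support filter


def _split_tip(label: str) -> tuple[str, int | None]:
    """'spec_h0' -> ('spec', 0); bare 'spec' -> ('spec', None)."""
    if len(label) > 3 and label[-3:-1] == "_h" and label[-1] in "01":
        return label[:-3], int(label[-1])
    return label, None


@dataclass
class GeneTree:
    locus: str
    alignment_length: int
    tree: dendropy.Tree
    saturated_pairs: int = 0
    _index_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.alignment_length <= 0:
            raise GeneTreeError(f"{self.locus}: alignment_length must be > 0")

    def tip_specimens(self) -> set[str]:
        return {_split_tip(lf.taxon.label)[0] for lf in self.tree.leaf_node_iter()}

    def find_allele_tip(self, specimen: str, allele: int):
        want = f"{specimen}_h{allele}"
        bare = None
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == want:
                return lf
            if lf.taxon.label == specimen:
                bare = lf
        return bare  # homozygous/unphased tip stands for both alleles

    def _index(self, species_map: SpeciesMap):
        """Per-node reference-tip composition, computed once per species map:
        node -> (total reference tips, {species: count}, {specimen: count})."""
        key = id(species_map)
        if key in self._index_cache:
            return self._index_cache[key]
        idx = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                spec, _ = _split_tip(node.taxon.label)
                if (
                    spec in species_map.species
                    and species_map.roles.get(spec) == "reference"
                ):
                    sp = species_map.species_of(spec)
                    idx[node] = (1, {sp: 1}, {spec: 1})
                else:
                    idx[node] = (0, {}, {})
            else:
                tot, spc, spec_c = 0, {}, {}
                for ch in node.child_nodes():
                    t, s, c = idx[ch]
                    tot += t
                    for k, v in s.items():
                        spc[k] = spc.get(k, 0) + v
                    for k, v in c.items():
                        spec_c[k] = spec_c.get(k, 0) + v
                idx[node] = (tot, spc, spec_c)
        self._index_cache.clear()  # hold at most one map's index
        self._index_cache[key] = idx
        return idx


@dataclass(frozen=True)
class AlleleAssignment:
    locus: str
    specimen: str
    allele: int
    assigned: str  # species name | "unsupported" | "missing"
    reason: str = ""  # unsupported cause: purity | support | no_reference_clade
    clade_size: int = 0  # reference tips in the deciding clade
    clade_composition: tuple = ()  # ((species, count), ...) sorted by count
    support: float | None = None

    @property
    def is_assigned(self) -> bool:
        return self.assigned not in ("unsupported", "missing")


def assign_allele(
    gene_tree: GeneTree,
    specimen: str,
    allele: int,
    species_map: SpeciesMap,
    params: PlacementParams = PlacementParams(),
) -> AlleleAssignment:
    """Assign one phased allele of a query specimen to a reference species."""
    tip = gene_tree.find_allele_tip(specimen, allele)
    if tip is None:
        return AlleleAssignment(gene_tree.locus, specimen, allele, "missing")
    idx = gene_tree._index(species_map)
    query_is_ref = (
        specimen in species_map.species
        and species_map.roles.get(specimen) == "reference"
    )
    node = tip.parent_node
    while node is not None:
        tot, spc, spec_c = idx[node]
        excl = spec_c.get(specimen, 0) if query_is_ref else 0
        n_ref = tot - excl
        if n_ref >= params.min_reference_tips:
            comp = dict(spc)
            if query_is_ref and specimen in spec_c:
                sp_q = species_map.species_of(specimen)
                comp[sp_q] = comp.get(sp_q, 0) - spec_c[specimen]
                if comp[sp_q] <= 0:
                    comp.pop(sp_q, None)
            ordered = tuple(sorted(comp.items(), key=lambda kv: (-kv[1], kv[0])))
            best_sp, best_n = ordered[0]
            support = _node_support(node)
            if best_n / n_ref >= params.purity:
                if params.min_support > 0 and (
                    support is None or support < params.min_support
                ):
                    return AlleleAssignment(
                        gene_tree.locus, specimen, allele, "unsupported",
                        reason="support", clade_size=n_ref,
                        clade_composition=ordered, support=support,
                    )
                return AlleleAssignment(
                    gene_tree.locus, specimen, allele, best_sp,
                    clade_size=n_ref, clade_composition=ordered, support=support,
                )
            return AlleleAssignment(
                gene_tree.locus, specimen, allele, "unsupported",
                reason="purity", clade_size=n_ref,
                clade_composition=ordered, support=support,
            )
        node = node.parent_node
    return AlleleAssignment(
        gene_tree.locus, specimen, allele, "unsupported", reason="no_reference_clade"
    )


def _node_support(node) -> float | None:
    label = getattr(node, "label", None)
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


@dataclass(frozen=True)
class LocusClassification:
    locus: str
    specimen: str
    category: str  # monospecific | heterospecific | missing_unsupported
    species: tuple[str, ...] = ()


def classify_locus(
    gene_tree: GeneTree,
    specimen: str,
    species_map: SpeciesMap,
    params: PlacementParams = PlacementParams(),
) -> tuple[LocusClassification, tuple[AlleleAssignment, AlleleAssignment]]:
    a0 = assign_allele(gene_tree, specimen, 0, species_map, params)
    a1 = assign_allele(gene_tree, specimen, 1, species_map, params)
    if a0.is_assigned and a1.is_assigned:
        if a0.assigned == a1.assigned:
            cls = LocusClassification(
                gene_tree.locus, specimen, "monospecific", (a0.assigned,)
            )
        else:
            pair = tuple(sorted((a0.assigned, a1.assigned)))
            cls = LocusClassification(
                gene_tree.locus, specimen, "heterospecific", pair
            )
    else:
        cls = LocusClassification(gene_tree.locus, specimen, "missing_unsupported")
    return cls, (a0, a1)


@dataclass
class PlacementSummary:
    """Per-specimen aggregation shaped like a per-species allele-count table:
    assigned-allele counts and percentages per species (percentages over
    assigned alleles only), plus mono/heterospecific locus counts and
    percentages over classified loci."""

    specimen: str
    species_counts: dict[str, int]
    missing_unsupported: int
    monospecific: int
    heterospecific: int

    @property
    def n_assigned(self) -> int:
        return sum(self.species_counts.values())

    @property
    def n_classified(self) -> int:
        return self.monospecific + self.heterospecific

    @property
    def species_pct(self) -> dict[str, float]:
        tot = self.n_assigned
        if tot == 0:
            return {sp: float("nan") for sp in self.species_counts}
        return {
            sp: round_pct(100.0 * n / tot) for sp, n in self.species_counts.items()
        }

    @property
    def monospecific_pct(self) -> float:
        n = self.n_classified
        return float("nan") if n == 0 else round_pct(100.0 * self.monospecific / n)

    @property
    def heterospecific_pct(self) -> float:
        n = self.n_classified
        return float("nan") if n == 0 else round_pct(100.0 * self.heterospecific / n)

    @property
    def heterospecific_fraction(self) -> float:
        n = self.n_classified
        return float("nan") if n == 0 else self.heterospecific / n

    @property
    def defined(self) -> bool:
        return self.n_assigned > 0

    @classmethod
    def from_counts(
        cls,
        specimen: str,
        species_counts: dict[str, int],
        missing_unsupported: int,
        monospecific: int,
        heterospecific: int,
    ) -> "PlacementSummary":
        return cls(specimen, dict(species_counts), missing_unsupported,
                   monospecific, heterospecific)


def summarize_placements(
    classifications: list[LocusClassification],
    assignments: list[AlleleAssignment],
) -> PlacementSummary:
    """Aggregate one specimen's per-locus results into a summary table row."""
    specs = {a.specimen for a in assignments} | {c.specimen for c in classifications}
    if len(specs) != 1:
        raise GeneTreeError(f"summary expects one specimen, got {sorted(specs)}")
    (specimen,) = specs
    counts: dict[str, int] = {}
    missing = 0
    for a in assignments:
        if a.is_assigned:
            counts[a.assigned] = counts.get(a.assigned, 0) + 1
        else:
            missing += 1
    mono = sum(1 for c in classifications if c.category == "monospecific")
    het = sum(1 for c in classifications if c.category == "heterospecific")
    return PlacementSummary(specimen, counts, missing, mono, het)


@dataclass(frozen=True)
class F1Diagnosis:
    specimen: str
    parents: tuple[str, str]
    count_a: int
    count_b: int
    heterospecific_fraction: float
    balance_p: float | None
    verdict: str  # consistent-with-F1 | skewed | not-hybrid | insufficient data


def f1_test(
    summary: PlacementSummary,
    parents: tuple[str, str] | None = None,
    alpha: float = 0.05,
    min_alleles: int = 10,
    min_heterospecific_fraction: float = 0.2,
    min_minor_share: float = 0.1,
) -> F1Diagnosis:
    """Test the F1 expectation that assigned alleles split evenly between two
    parental species.

    Verdict rule table (pure function of the recorded statistics):

    ======================================  =====================
    condition                               verdict
    ======================================  =====================
    count_a + count_b < min_alleles         insufficient data
    minor-parent share < min_minor_share    not-hybrid
    heterospecific fraction < threshold     not-hybrid
    exact binomial two-sided p >= alpha     consistent-with-F1
    otherwise                               skewed
    ======================================  =====================
    """
    if parents is None:
        top = sorted(summary.species_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(top) < 2:
            top = top + [("", 0)]
        parents = (top[0][0], top[1][0])
    ca = summary.species_counts.get(parents[0], 0)
    cb = summary.species_counts.get(parents[1], 0)
    n = ca + cb
    frac = summary.heterospecific_fraction
    if n < min_alleles:
        return F1Diagnosis(summary.specimen, parents, ca, cb, frac, None,
                           "insufficient data")
    p = float(sps.binomtest(ca, n, 0.5).pvalue)
    minor = min(ca, cb) / n
    if minor < min_minor_share or (
        not math.isnan(frac) and frac < min_heterospecific_fraction
    ):
        verdict = "not-hybrid"
    elif p >= alpha:
        verdict = "consistent-with-F1"
    else:
        verdict = "skewed"
    return F1Diagnosis(summary.specimen, parents, ca, cb, frac, p, verdict)


# ---------------------------------------------------------------------------
# tree input

def load_gene_trees(
    source,
    lengths: dict[str, int] | str | Path,
    min_alignment_length: int = 900,
    species_map: SpeciesMap | None = None,
) -> tuple[list[GeneTree], int]:
    """Load rooted Newick gene trees and apply the locus-length filter.

    ``source`` is a directory of ``<locus>.nwk`` files, a list of files, or a
    single multi-tree file; ``lengths`` maps locus -> alignment length (dict
    or a two-column TSV sidecar).  Only trees whose alignment is strictly
    longer than ``min_alignment_length`` are retained ("more than" semantics:
    at a 900 bp threshold a 901 bp locus is kept and a 900 bp locus dropped).
    Returns (trees, n_excluded).
    """
    if isinstance(lengths, (str, Path)):
        df = pd.read_csv(lengths, sep="\t")
        lengths = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    entries: list[tuple[str, dendropy.Tree]] = []
    src = Path(source) if isinstance(source, (str, Path)) else None
    if src is not None and src.is_dir():
        files = sorted(src.glob("*.nwk")) + sorted(src.glob("*.tre")) + sorted(
            src.glob("*.newick")
        )
        for f in files:
            t = dendropy.Tree.get(path=str(f), schema="newick", preserve_underscores=True)
            entries.append((f.stem, t))
    elif src is not None:
        trees = dendropy.TreeList.get(path=str(src), schema="newick", preserve_underscores=True)
        for i, t in enumerate(trees):
            label = t.label or f"locus_{i:04d}"
            entries.append((label, t))
    else:
        for f in source:
            f = Path(f)
            t = dendropy.Tree.get(path=str(f), schema="newick", preserve_underscores=True)
            entries.append((f.stem, t))

    out, excluded = [], 0
    for locus, tree in entries:
        if locus not in lengths:
            raise GeneTreeError(f"no alignment length for locus {locus!r}")
        if species_map is not None:
            for lf in tree.leaf_node_iter():
                spec, _ = _split_tip(lf.taxon.label)
                if spec not in species_map.species:
                    raise GeneTreeError(
                        f"{locus}: tip {lf.taxon.label!r} does not map to a "
                        "known specimen"
                    )
        if lengths[locus] > min_alignment_length:
            tree.is_rooted = True
            out.append(GeneTree(locus, int(lengths[locus]), tree))
        else:
            excluded += 1
    return out, excluded


# ---------------------------------------------------------------------------
# plumbing: neighbor-joining trees so the synthetic pipeline runs end-to-end

_P_SATURATION = 0.74  # JC undefined at p >= 0.75; cap just below


def _jc_distance_matrix(names, mat, missing):
    """Pairwise Jukes-Cantor distances; (distances, n_capped).

    One-hot encodes the alignment so match counts and shared-coverage counts
    are two matrix products; missing characters simply contribute no one-hot
    bit.
    """
    n = len(names)
    onehot = np.stack(
        [((mat == b) & ~missing) for b in b"ACGT"], axis=1
    )  # (n, 4, L)
    flat = onehot.reshape(n, -1).astype(np.float64)
    matches = flat @ flat.T
    cov = (~missing).astype(np.float64)
    shared = cov @ cov.T  # positions covered in both sequences
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(shared > 0, 1.0 - matches / shared, 0.0)
    np.fill_diagonal(p, 0.0)
    capped = int((np.triu(p, 1) >= _P_SATURATION).sum())
    p = np.minimum(p, _P_SATURATION)
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    d = (d + d.T) / 2.0  # exact symmetry for the DistanceMatrix validator
    np.fill_diagonal(d, 0.0)
    return d.astype(float), capped


def nj_gene_tree(
    alignment,
    species_map: SpeciesMap,
    locus: str | None = None,
) -> GeneTree:
    """Neighbor-joining tree on Jukes-Cantor distances, rooted on the
    configured outgroup tips.

    NJ recovers additive distance matrices exactly, so on well-separated
    species it is adequate plumbing for placement; real analyses may import
    externally estimated trees instead.  Saturated pairwise distances
    (p >= 3/4, JC undefined) are capped and counted.  Alignments without any
    outgroup tip are rejected — midpoint rooting could silently flip
    nestings.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    names = sorted(alignment.sequences)
    if len(names) < 3:
        raise GeneTreeError(f"{alignment.locus}: NJ needs >= 3 sequences")
    mat = np.stack(
        [np.frombuffer(alignment.sequences[n].upper().encode(), dtype=np.uint8)
         for n in names]
    )
    missing = (mat == ord("N")) | (mat == ord("-")) | (mat == ord("?"))
    d, capped = _jc_distance_matrix(names, mat, missing)
    nwk = io.StringIO()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        skt = _nj(DistanceMatrix(d, ids=names))
        skt.write(nwk)
    tree = dendropy.Tree.get(data=nwk.getvalue(), schema="newick", preserve_underscores=True)

    og_tips = [
        n for n in names
        if _split_tip(n)[0] in species_map.species
        and species_map.roles.get(_split_tip(n)[0]) == "outgroup"
    ]
    if not og_tips:
        raise GeneTreeError(
            f"{alignment.locus}: no outgroup tip present; cannot root"
        )
    _root_on_outgroup(tree, og_tips)
    gt = GeneTree(
        locus or alignment.locus, alignment.length, tree, saturated_pairs=capped
    )
    return gt


def _root_on_outgroup(tree: dendropy.Tree, og_tips: list[str]) -> None:
    def split_edge(edge):
        half = (edge.length or 0.0) / 2.0
        tree.reroot_at_edge(
            edge, length1=half, length2=half, update_bipartitions=False
        )

    taxa = [tree.taxon_namespace.get_taxon(t) for t in og_tips]
    taxa = [t for t in taxa if t is not None]
    first = tree.find_node_with_taxon_label(og_tips[0])
    split_edge(first.edge)
    if len(taxa) > 1:
        mrca = tree.mrca(taxa=taxa)
        if mrca is not tree.seed_node and mrca.edge.tail_node is not None:
            split_edge(mrca.edge)
    tree.is_rooted = True
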