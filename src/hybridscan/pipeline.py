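"""End-to-end orchestration: simulate (or ingest) -> filter -> heterozygosity
-> pi/FST -> trio D tests -> allele placement -> consolidated hybrid-evidence
report.

Every stage consumes only files written by the previous stage, so a run can
be restarted or individual stages rerun from the command line.  The combined
hybrid verdict joins the three lines of evidence the placement approach
rests on: an observed-heterozygosity outlier (leave-one-out z above a
threshold), an elevated heterospecific-locus fraction (above a multiple of
the background across reference specimens), and a parental allele balance
that an exact binomial test does not reject — each threshold explicit in the
run configuration and overridable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dstats, heterozygosity, placement, popgen
from .genotypes import (
    SpeciesMap,
    filter_sites,
    filter_specimens,
    read_vcf,
    write_vcf,
)
from .simulate import config_from_dict, simulate_dataset, write_dataset

__all__ = ["RunConfig", "EvidenceReport", "run"]


class PipelineError(RuntimeError):
    pass


_DEFAULTS = {
    "filters": {"min_depth": 8, "max_missing": 0.8, "specimen_max_missing": 0.2},
    "placement": {
        "min_alignment_length": 900,
        "min_reference_tips": 2,
        "purity": 0.90,
        "min_support": 0.0,
    },
    "het": {"z_threshold": 3.0},
    "verdict": {
        "z_threshold": 3.0,
        "het_factor": 3.0,
        "het_floor": 0.1,
        "alpha": 0.05,
        "min_alleles": 10,
    },
    "dstats": {"enabled": True},
}


@dataclass
class RunConfig:
    out: Path
    seed: int = 1
    simulation: dict | None = None  # simulate.config_from_dict schema
    inputs: dict | None = None  # vcf, species_map, alignments|trees(+locus_lengths)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out = Path(self.out)
        if (self.simulation is None) == (self.inputs is None):
            raise PipelineError(
                "exactly one of 'simulation' or 'inputs' must be configured"
            )
        if self.inputs is not None:
            required = ["vcf", "species_map"]
            if "trees" in self.inputs or "alignments" in self.inputs:
                required.append("locus_lengths")
            for key in required:
                if key not in self.inputs:
                    raise PipelineError(f"inputs missing required key {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise PipelineError(f"input file missing: {self.inputs[key]}")
        merged = {k: dict(v) for k, v in _DEFAULTS.items()}
        for k, v in self.params.items():
            merged.setdefault(k, {}).update(v)
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            out=d["out"],
            seed=int(d.get("seed", 1)),
            simulation=d.get("simulation"),
            inputs=d.get("inputs"),
            params={
                k: v
                for k, v in d.items()
                if k in ("filters", "placement", "het", "verdict", "dstats")
            },
        )


@dataclass
class EvidenceReport:
    path: Path
    data: dict

    @property
    def specimens(self) -> pd.DataFrame:
        return pd.DataFrame(self.data["specimens"])

    def flagged_hybrids(self) -> list[str]:
        return [
            s["specimen"] for s in self.data["specimens"] if s["combined_hybrid_flag"]
        ]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if math.isnan(x) else x
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def run(config: RunConfig) -> EvidenceReport:
    """Execute the full pipeline; deterministic for a fixed seed on simulated
    inputs.  Raises with the failing stage named; intermediate artifacts are
    always rewritten, never silently reused."""
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # -- stage 1: obtain inputs -------------------------------------------
    if config.simulation is not None:
        log.append("simulate")
        sim_cfg = config_from_dict({**config.simulation, "seed": config.seed})
        try:
            dataset = simulate_dataset(sim_cfg)
            paths = write_dataset(dataset, out / "simulated")
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
        inputs = {
            "vcf": paths["vcf"],
            "species_map": paths["species_map"],
            "alignments": paths["alignments"],
            "locus_lengths": paths["locus_lengths"],
        }
    else:
        inputs = {k: Path(v) for k, v in config.inputs.items()}

    species_map = SpeciesMap.from_tsv(inputs["species_map"])

    # -- stage 2: genotype filtering --------------------------------------
    log.append("genotypes")
    f = config.params["filters"]
    try:
        gm = read_vcf(inputs["vcf"])
        gm = filter_sites(gm, min_depth=f["min_depth"], max_missing=f["max_missing"])
        gm, removal = filter_specimens(
            gm, max_missing_fraction=f["specimen_max_missing"]
        )
        write_vcf(gm, out / "filtered.vcf")
        with open(out / "filter_report.json", "w") as fh:
            json.dump(
                _jsonable(
                    {
                        "n_sites_kept": gm.n_sites,
                        "n_specimens_kept": gm.n_specimens,
                        "n_skipped_multiallelic": gm.n_skipped_multiallelic,
                        "n_skipped_indel": gm.n_skipped_indel,
                        **removal,
                    }
                ),
                fh,
                indent=2,
            )
    except Exception as exc:
        raise PipelineError(f"stage 'genotypes' failed: {exc}") from exc

    # -- stage 3: heterozygosity ------------------------------------------
    log.append("heterozygosity")
    try:
        gm = read_vcf(out / "filtered.vcf")
        het = heterozygosity.het_table(gm, species_map)
        het_scan = heterozygosity.het_outlier_scan(
            het, z_threshold=config.params["het"]["z_threshold"]
        )
        het_scan.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'heterozygosity' failed: {exc}") from exc

    # -- stage 4: pi and FST ----------------------------------------------
    log.append("popgen")
    try:
        ref_groups = [
            g
            for g in species_map.reference_species
            if any(s in gm.specimens for s in species_map.members(g))
        ]
        pi_rows = []
        for g in ref_groups:
            r = popgen.group_pi(gm, species_map, g)
            pi_rows.append(
                {"group": g, "mean_pi": r.mean, "sd_pi": r.sd, "n_sites": r.n_sites}
            )
        pi_df = pd.DataFrame(pi_rows)
        pi_df.to_csv(out / "pi.tsv", sep="\t", index=False)
        fst_df = popgen.pairwise_fst_table(gm, species_map, ref_groups)
        fst_df.to_csv(out / "fst.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'popgen' failed: {exc}") from exc

    # -- stage 5: trio D statistics ---------------------------------------
    log.append("dstats")
    trio_df = pd.DataFrame()
    try:
        og = species_map.with_role("outgroup")
        if config.params["dstats"]["enabled"] and og and len(ref_groups) >= 3:
            trio_df = dstats.all_trios(gm, species_map, f4_seed=config.seed)
            trio_df.to_csv(out / "dstats.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'dstats' failed: {exc}") from exc

    # -- stage 6: allele placement ----------------------------------------
    log.append("placement")
    p = config.params["placement"]
    pl_params = placement.PlacementParams(
        min_reference_tips=int(p["min_reference_tips"]),
        purity=float(p["purity"]),
        min_support=float(p["min_support"]),
    )
    try:
        trees, n_trees_excluded = _obtain_gene_trees(inputs, species_map, p)
        queries = [s for s in gm.specimens if species_map.roles.get(s) != "outgroup"]
        summaries, f1_rows, assign_rows, class_rows = {}, [], [], []
        for q in queries:
            classifications, assignments = [], []
            for gt in trees:
                if q not in gt.tip_specimens():
                    continue
                cls, (a0, a1) = placement.classify_locus(gt, q, species_map, pl_params)
                classifications.append(cls)
                assignments.extend([a0, a1])
            if not assignments:
                continue
            summ = placement.summarize_placements(classifications, assignments)
            summaries[q] = summ
            diag = placement.f1_test(
                summ,
                alpha=config.params["verdict"]["alpha"],
                min_alleles=config.params["verdict"]["min_alleles"],
            )
            f1_rows.append(
                {
                    "specimen": q,
                    "parent_a": diag.parents[0],
                    "parent_b": diag.parents[1],
                    "count_a": diag.count_a,
                    "count_b": diag.count_b,
                    "heterospecific_fraction": diag.heterospecific_fraction,
                    "balance_p": diag.balance_p,
                    "verdict": diag.verdict,
                }
            )
            for a in assignments:
                assign_rows.append(
                    {
                        "locus": a.locus,
                        "specimen": a.specimen,
                        "allele": a.allele,
                        "assigned": a.assigned,
                        "reason": a.reason,
                        "clade_size": a.clade_size,
                    }
                )
            for c in classifications:
                class_rows.append(
                    {
                        "locus": c.locus,
                        "specimen": c.specimen,
                        "category": c.category,
                        "species": "|".join(c.species),
                    }
                )
        pd.DataFrame(assign_rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
        pd.DataFrame(class_rows).to_csv(
            out / "classifications.tsv", sep="\t", index=False
        )
        pd.DataFrame(f1_rows).to_csv(out / "f1_diagnosis.tsv", sep="\t", index=False)
        summ_rows = []
        for q, s in summaries.items():
            row = {
                "specimen": q,
                "n_assigned": s.n_assigned,
                "missing_unsupported": s.missing_unsupported,
                "monospecific": s.monospecific,
                "heterospecific": s.heterospecific,
                "monospecific_pct": s.monospecific_pct,
                "heterospecific_pct": s.heterospecific_pct,
            }
            for sp, n in sorted(s.species_counts.items()):
                row[f"alleles_{sp}"] = n
                row[f"pct_{sp}"] = s.species_pct[sp]
            summ_rows.append(row)
        pd.DataFrame(summ_rows).to_csv(
            out / "placement_summary.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError(f"stage 'placement' failed: {exc}") from exc

    # -- stage 7: evidence report -----------------------------------------
    log.append("evidence")
    v = config.params["verdict"]
    het_by_spec = {r["specimen"]: dict(r) for _, r in het_scan.iterrows()}
    ref_fracs = [
        summaries[q].heterospecific_fraction
        for q in summaries
        if species_map.roles.get(q) == "reference"
        and not math.isnan(summaries[q].heterospecific_fraction)
    ]
    background = float(np.median(ref_fracs)) if ref_fracs else 0.0
    het_cutoff = max(background * v["het_factor"], v["het_floor"])
    f1_by_spec = {r["specimen"]: r for r in f1_rows}
    spec_rows = []
    for s in gm.specimens:
        if species_map.roles.get(s) == "outgroup":
            continue
        hrow = het_by_spec.get(s, {})
        summ = summaries.get(s)
        diag = f1_by_spec.get(s, {})
        z = float(hrow.get("z", float("nan")))
        frac = summ.heterospecific_fraction if summ else float("nan")
        balance_p = diag.get("balance_p")
        gate_z = not math.isnan(z) and z > v["z_threshold"]
        gate_frac = not math.isnan(frac) and frac > het_cutoff
        gate_balance = (
            balance_p is not None
            and not (isinstance(balance_p, float) and math.isnan(balance_p))
            and balance_p >= v["alpha"]
        )
        spec_rows.append(
            {
                "specimen": s,
                "species": species_map.species_of(s),
                "role": species_map.roles.get(s),
                "h_obs": float(hrow.get("h_obs", float("nan"))),
                "het_z": z,
                "heterospecific_fraction": frac,
                "f1_verdict": diag.get("verdict", ""),
                "balance_p": balance_p,
                "gate_het_z": gate_z,
                "gate_heterospecific": gate_frac,
                "gate_balance": gate_balance,
                "combined_hybrid_flag": gate_z and gate_frac and gate_balance,
            }
        )
    report = {
        "provenance": {
            "package": "hybridscan",
            "version": __version__,
            "seed": config.seed,
            "filters": config.params["filters"],
            "placement": config.params["placement"],
            "verdict": {**v, "heterospecific_cutoff": het_cutoff},
            "stages": log,
        },
        "filter_report": {
            **json.load(open(out / "filter_report.json")),
            "n_gene_trees_used": len(trees),
            "n_gene_trees_excluded_by_length": n_trees_excluded,
        },
        "specimens": spec_rows,
        "pi": pi_df.to_dict(orient="records"),
        "fst": fst_df.to_dict(orient="records"),
        "trios": trio_df.to_dict(orient="records") if len(trio_df) else [],
    }
    report = _jsonable(report)
    report_path = out / "evidence.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_summary(out / "report.txt", report)
    return EvidenceReport(path=report_path, data=report)


def _obtain_gene_trees(inputs: dict, species_map: SpeciesMap, p: dict):
    """Load externally built trees if provided, else neighbor-joining trees
    from the phased alignments.  Returns (trees, n_excluded_by_length)."""
    min_len = int(p["min_alignment_length"])
    if "trees" in inputs:
        return placement.load_gene_trees(
            inputs["trees"],
            inputs["locus_lengths"],
            min_alignment_length=min_len,
            species_map=species_map,
        )
    if "alignments" not in inputs:
        raise PipelineError("placement needs 'trees' or 'alignments' inputs")
    from Bio import SeqIO

    from .simulate import PhasedAlignment

    lengths = pd.read_csv(inputs["locus_lengths"], sep="\t")
    lengths = dict(zip(lengths.iloc[:, 0].astype(str), lengths.iloc[:, 1].astype(int)))
    trees, excluded = [], 0
    for fasta in sorted(Path(inputs["alignments"]).glob("*.fasta")):
        locus = fasta.stem
        if lengths.get(locus, 0) <= min_len:
            excluded += 1
            continue
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        aln = PhasedAlignment(locus=locus, length=lengths[locus], sequences=seqs)
        trees.append(placement.nj_gene_tree(aln, species_map))
    return trees, excluded


def _write_text_summary(path: Path, report: dict) -> None:
    lines = ["hybridscan evidence report", "=" * 26, ""]
    lines.append(f"seed: {report['provenance']['seed']}")
    fr = report["filter_report"]
    lines.append(
        f"sites kept: {fr['n_sites_kept']}  specimens kept: {fr['n_specimens_kept']}"
    )
    lines.append("")
    lines.append(
        f"{'specimen':<16}{'species':<14}{'H_obs':>8}{'z':>8}"
        f"{'het.frac':>10}{'balance_p':>11}  verdict"
    )
    for s in report["specimens"]:
        h = "--" if s["h_obs"] is None else f"{s['h_obs']:.4f}"
        z = "--" if s["het_z"] is None else f"{s['het_z']:.2f}"
        fq = (
            "--"
            if s["heterospecific_fraction"] is None
            else f"{s['heterospecific_fraction']:.3f}"
        )
        bp = "--" if s["balance_p"] is None else f"{s['balance_p']:.3g}"
        flag = "  << HYBRID" if s["combined_hybrid_flag"] else ""
        lines.append(
            f"{s['specimen']:<16}{s['species']:<14}{h:>8}{z:>8}"
            f"{fq:>10}{bp:>11}  {s['f1_verdict']}{flag}"
        )
    lines.append("")
    if report["trios"]:
        lines.append("trio tests (D / f4 / Dmin):")
        for t in report["trios"]:
            d = "--" if t["D"] is None else f"{t['D']:+.3f}"
            z = "--" if t["Z"] is None else f"{t['Z']:.2f}"
            f4 = "--" if t["f4_clamped"] is None else f"{t['f4_clamped']:.3f}"
            dm = "--" if t["Dmin"] is None else f"{t['Dmin']:.3f}"
            pb = "--" if t["p_BH"] is None else f"{t['p_BH']:.3g}"
            lines.append(
                f"  ({t['P1']},{t['P2']};{t['P3']}) D={d} Z={z} f4={f4} "
                f"Dmin={dm} p_BH={pb}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
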