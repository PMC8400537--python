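"""Biallelic SNP genotype matrices and the study's vcftools-equivalent filters.

The central container is :class:`GenotypeMatrix`: specimens x sites with calls
coded 0 (hom-ref), 1 (het), 2 (hom-alt), -1 (missing) and an optional read
depth surrogate.  Filters replicate the semantics of
``--minDP 8 --remove-indels --min-alleles 2 --max-alleles 2 --max-missing 0.8``.

A note on ``--max-missing``: despite its name the vcftools value is the
*required called fraction* — 0.8 keeps sites at which at least 80% of
specimens have a genotype.  That reading is adopted verbatim here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SpeciesMap",
    "genotypes_from_alignments",
    "filter_sites",
    "filter_specimens",
    "read_vcf",
    "write_vcf",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    specimens: list[str]
    sites: pd.DataFrame  # columns: locus, pos (1-based), ref, alt
    calls: np.ndarray  # int8, shape (n_specimens, n_sites)
    depth: np.ndarray | None = None  # same shape; None means unlimited
    n_skipped_multiallelic: int = 0
    n_skipped_indel: int = 0
    loci_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.specimens), len(self.sites)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.specimens)} specimens x {len(self.sites)} sites"
            )
        if self.depth is not None and self.depth.shape != self.calls.shape:
            raise GenotypeError("depth shape must match calls")
        dup = self.sites.duplicated(subset=["locus", "pos"])
        if dup.any():
            raise GenotypeError("duplicate (locus, pos) sites")

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def specimen_index(self, specimen: str) -> int:
        try:
            return self.specimens.index(specimen)
        except ValueError:
            raise GenotypeError(f"unknown specimen {specimen!r}") from None

    def site_called_fraction(self) -> np.ndarray:
        if self.n_specimens == 0:
            return np.zeros(self.n_sites)
        return (self.calls != MISSING).mean(axis=0)

    def specimen_missing_fraction(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_specimens)
        return (self.calls == MISSING).mean(axis=1)

    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            specimens=list(self.specimens),
            sites=self.sites.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            depth=None if self.depth is None else self.depth[:, keep],
            loci_lengths=dict(self.loci_lengths),
        )

    def take_specimens(self, keep_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.specimen_index(s) for s in keep_ids]
        return GenotypeMatrix(
            specimens=list(keep_ids),
            sites=self.sites.copy().reset_index(drop=True),
            calls=self.calls[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
            loci_lengths=dict(self.loci_lengths),
        )

    def alt_allele_counts(self, specimen_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele count) per site for a specimen set."""
        sub = self.calls[specimen_idx, :]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)  # 0/1/2 alt alleles per call
        return alt.astype(float), 2.0 * called.sum(axis=0)


@dataclass
class SpeciesMap:
    """Specimen -> species label plus an analysis role per specimen
    (``reference`` specimens anchor placements, ``query`` specimens are the
    hybrid candidates, ``outgroup`` roots trees and polarises D-statistics)."""

    species: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    VALID_ROLES = ("reference", "query", "outgroup")

    def __post_init__(self) -> None:
        for s in self.species:
            role = self.roles.setdefault(s, "reference")
            if role not in self.VALID_ROLES:
                raise GenotypeError(f"invalid role {role!r} for specimen {s!r}")

    def members(self, species: str) -> list[str]:
        return [s for s, sp in self.species.items() if sp == species]

    def analysis_members(self, species: str) -> list[str]:
        """Group members usable for allele-frequency statistics: hybrid
        candidates (role ``query``) carry mixed ancestry and are excluded so
        they cannot contaminate the frequencies of their putative species."""
        return [
            s
            for s in self.members(species)
            if self.roles.get(s) != "query"
        ]

    def species_of(self, specimen: str) -> str:
        try:
            return self.species[specimen]
        except KeyError:
            raise GenotypeError(f"unknown specimen {specimen!r}") from None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, sp in self.species.items():
            out.setdefault(sp, []).append(s)
        return out

    def with_role(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    @property
    def reference_species(self) -> list[str]:
        seen = []
        for s, r in self.roles.items():
            if r == "reference" and self.species[s] not in seen:
                seen.append(self.species[s])
        return seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "specimen" not in cols or "species" not in cols:
            raise GenotypeError(
                f"{path}: species map needs 'specimen' and 'species' columns"
            )
        roles = {}
        if "role" in cols:
            roles = dict(zip(df["specimen"], df["role"].fillna("reference")))
        return cls(species=dict(zip(df["specimen"], df["species"])), roles=roles)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "specimen": list(self.species),
                "species": [self.species[s] for s in self.species],
                "role": [self.roles[s] for s in self.species],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# construction from phased alignments

def genotypes_from_alignments(alignments) -> GenotypeMatrix:
    """In-silico genotyping of phased per-locus alignments.

    Emits exactly the columns at which the non-missing haplotypes carry two
    distinct nucleotides; columns with three or more alleles are skipped and
    counted (mirroring ``--max-alleles 2``).  The reference allele is the
    majority allele, ties broken alphabetically; a specimen is heterozygous
    iff its two haplotypes differ, and missing whenever either haplotype is
    absent or carries an N/gap at the column.
    """
    alignments = list(alignments)
    specimens: list[str] = []
    for aln in alignments:
        for name in aln.sequences:
            if not (name.endswith("_h0") or name.endswith("_h1")):
                raise GenotypeError(
                    f"{aln.locus}: tip {name!r} is not named '<specimen>_h0/_h1'"
                )
            spec = name[:-3]
            if spec not in specimens:
                specimens.append(spec)
    n_spec = len(specimens)
    spec_idx = {s: i for i, s in enumerate(specimens)}

    calls_cols, sites_rows = [], []
    skipped_multi = 0
    loci_lengths = {}
    for aln in alignments:
        loci_lengths[aln.locus] = aln.length
        # (2*n_spec, L) byte matrix; absent haplotypes become 'N'
        mat = np.full((2 * n_spec, aln.length), ord("N"), dtype=np.uint8)
        for name, seq in aln.sequences.items():
            spec = name[:-3]
            h = int(name[-1])
            if len(seq) != aln.length:
                raise GenotypeError(
                    f"{aln.locus}: sequence {name} length {len(seq)} != {aln.length}"
                )
            mat[2 * spec_idx[spec] + h] = np.frombuffer(
                seq.upper().encode(), dtype=np.uint8
            )
        missing = (
            (mat == ord("N")) | (mat == ord("-")) | (mat == ord("?"))
        )
        bases = b"ACGT"
        counts = np.stack([((mat == b) & ~missing).sum(axis=0) for b in bases])
        n_alleles = (counts > 0).sum(axis=0)
        skipped_multi += int((n_alleles > 2).sum())
        for col in np.flatnonzero(n_alleles == 2):
            present = counts[:, col] > 0
            ai = np.flatnonzero(present)
            # majority -> ref; argmax ties break toward the alphabetically
            # first base because the base axis is ACGT-ordered
            ref_i = ai[np.argmax(counts[ai, col])]
            alt_i = ai[ai != ref_i][0]
            ref, alt = chr(bases[ref_i]), chr(bases[alt_i])
            colv = mat[:, col]
            colm = missing[:, col]
            a, b = colv[0::2], colv[1::2]
            am, bm = colm[0::2], colm[1::2]
            call = np.where(
                am | bm,
                MISSING,
                np.where(a != b, HET, np.where(a == bases[alt_i], HOM_ALT, HOM_REF)),
            ).astype(np.int8)
            calls_cols.append(call)
            sites_rows.append((aln.locus, col + 1, ref, alt))

    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols
        else np.zeros((n_spec, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        specimens=specimens,
        sites=pd.DataFrame(sites_rows, columns=["locus", "pos", "ref", "alt"]),
        calls=calls,
        loci_lengths=loci_lengths,
    )
    gm.n_skipped_multiallelic = skipped_multi
    return gm


# ---------------------------------------------------------------------------
# filters

def filter_sites(
    gm: GenotypeMatrix,
    min_depth: float = 8,
    max_missing: float = 0.8,
) -> GenotypeMatrix:
    """Depth-mask then drop under-called sites, vcftools style.

    Calls with depth < ``min_depth`` are set missing first (no-op when the
    matrix carries no depth field).  A site is kept iff its called fraction is
    >= ``max_missing`` — vcftools ``--max-missing 0.8`` semantics.  Site order
    is preserved and retained genotype calls are never altered except by the
    depth mask.
    """
    if not 0 <= max_missing <= 1:
        raise GenotypeError("max_missing must be in [0, 1]")
    calls = gm.calls.copy()
    if gm.depth is not None:
        calls[gm.depth < min_depth] = MISSING
    masked = GenotypeMatrix(
        specimens=list(gm.specimens),
        sites=gm.sites.reset_index(drop=True),
        calls=calls,
        depth=gm.depth,
        loci_lengths=dict(gm.loci_lengths),
    )
    keep = masked.site_called_fraction() >= max_missing
    out = masked.take_sites(keep)
    out.n_skipped_multiallelic = gm.n_skipped_multiallelic
    return out


def filter_specimens(
    gm: GenotypeMatrix, max_missing_fraction: float = 0.2
) -> tuple[GenotypeMatrix, dict]:
    """Drop specimens missing more than the threshold, then re-drop positions
    missing in more than the same fraction of the survivors.

    Order matters and follows the study protocol: specimens first, so a site
    rescued by removing a bad specimen is retained.  Returns the surviving
    matrix and a removal report.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise GenotypeError("max_missing_fraction must be in [0, 1]")
    frac = gm.specimen_missing_fraction()
    keep_specs = [s for s, f in zip(gm.specimens, frac) if f <= max_missing_fraction]
    removed = [s for s in gm.specimens if s not in keep_specs]
    if not keep_specs:
        raise GenotypeError(
            f"all {gm.n_specimens} specimens exceed missing fraction "
            f"{max_missing_fraction}; nothing left"
        )
    sub = gm.take_specimens(keep_specs)
    site_missing = 1.0 - sub.site_called_fraction()
    keep_sites = site_missing <= max_missing_fraction
    out = sub.take_sites(keep_sites)
    report = {
        "specimens_removed": removed,
        "n_sites_removed": int((~keep_sites).sum()),
        "threshold": max_missing_fraction,
    }
    return out, report


# ---------------------------------------------------------------------------
# VCF I/O (GT and DP on the biallelic SNP subset)

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT (+DP when present) for biallelic SNP records; multiallelic and
    indel records are skipped and counted."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise GenotypeError(f"cannot parse VCF {path}: {exc}") from exc
    specimens = list(vcf.samples)
    calls_cols, depth_cols, sites_rows = [], [], []
    n_multi = n_indel = 0
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            n_indel += 1
            continue
        gt = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        col = np.select(
            [gt == 0, gt == 1, gt == 3], [HOM_REF, HET, HOM_ALT], default=MISSING
        ).astype(np.int8)
        calls_cols.append(col)
        try:
            d = v.format("DP")
        except KeyError:  # DP not declared in this file's header
            d = None
        if d is not None:
            any_depth = True
            d = d.reshape(-1).astype(np.int64)
            d[d < 0] = -1  # htslib encodes missing as INT32_MIN
            depth_cols.append(d.astype(np.int32))
        else:
            depth_cols.append(np.full(len(specimens), -1, dtype=np.int32))
        sites_rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            inner = line[line.index("<") + 1 : line.rindex(">")]
            kv = dict(p.split("=", 1) for p in inner.split(","))
            if "ID" in kv and "length" in kv:
                lengths[kv["ID"]] = int(kv["length"])
    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols
        else np.zeros((len(specimens), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        specimens=specimens,
        sites=pd.DataFrame(sites_rows, columns=["locus", "pos", "ref", "alt"]),
        calls=calls,
        depth=np.stack(depth_cols, axis=1).astype(float) if any_depth else None,
        loci_lengths=lengths,
    )
    gm.n_skipped_multiallelic = n_multi
    gm.n_skipped_indel = n_indel
    return gm


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with one pseudo-contig per locus."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridscan\n")
        loci = list(dict.fromkeys(gm.sites["locus"]))
        for locus in loci:
            sub = gm.sites[gm.sites["locus"] == locus]
            length = gm.loci_lengths.get(locus, int(sub["pos"].max()) if len(sub) else 1)
            fh.write(f"##contig=<ID={locus},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fmt = "GT"
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fmt = "GT:DP"
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.specimens)
            + "\n"
        )
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            fields = [
                str(row["locus"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(gm.n_specimens):
                g = _GT_STR[int(gm.calls[i, j])]
                if gm.depth is not None:
                    d = int(gm.depth[i, j])
                    g = f"{g}:{d if d >= 0 else '.'}"
                fields.append(g)
            fh.write("\t".join(fields) + "\n")
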