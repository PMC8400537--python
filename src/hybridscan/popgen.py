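"""Nucleotide diversity (pi) and Weir-Cockerham weighted FST between groups.

Both statistics are computed per SNP site and averaged, matching the
vcftools conventions used for target-capture SNP matrices: per-site pi is
the sample-size-corrected mean pairwise difference 2j(n-j)/(n(n-1)) and is
*not* divided by locus length, and pairwise FST is the Weir & Cockerham
(1984) estimator with the weighted mean ratio sum(a)/sum(a+b+c) alongside the
mean and SD of per-site ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import HET, MISSING, GenotypeMatrix, SpeciesMap

__all__ = ["PiResult", "FstResult", "site_pi", "group_pi", "weir_cockerham_fst",
           "pairwise_fst_table"]


class PopgenError(ValueError):
    pass


@dataclass
class PiResult:
    group: str
    per_site: np.ndarray  # pi at each retained site
    n_sites: int
    n_skipped: int  # sites with < 2 called alleles in the group

    @property
    def mean(self) -> float:
        return float(self.per_site.mean()) if self.n_sites else float("nan")

    @property
    def sd(self) -> float:
        return float(self.per_site.std(ddof=1)) if self.n_sites > 1 else float("nan")


@dataclass
class FstResult:
    group_a: str
    group_b: str
    a: np.ndarray  # per-site among-population variance component
    b: np.ndarray  # per-site among-individual component
    c: np.ndarray  # per-site within-individual component
    n_sites_used: int
    n_skipped: int

    @property
    def weighted(self) -> float | None:
        denom = (self.a + self.b + self.c).sum()
        if self.n_sites_used == 0 or denom == 0:
            return None
        return float(self.a.sum() / denom)

    @property
    def per_site_ratio(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        ok = denom != 0
        return self.a[ok] / denom[ok]

    @property
    def mean_of_ratios(self) -> float:
        r = self.per_site_ratio
        return float(r.mean()) if len(r) else float("nan")

    @property
    def sd_of_ratios(self) -> float:
        r = self.per_site_ratio
        return float(r.std(ddof=1)) if len(r) > 1 else float("nan")


def site_pi(alt_count: float, n_alleles: float) -> float:
    """Per-site pi for one group: 2 j (n-j) / (n (n-1))."""
    n, j = float(n_alleles), float(alt_count)
    if n < 2:
        raise PopgenError("site_pi needs >= 2 called alleles")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def group_pi(gm: GenotypeMatrix, species_map: SpeciesMap, group: str) -> PiResult:
    """Mean and SD of per-site pi over all sites with >= 2 called alleles."""
    members = [s for s in species_map.analysis_members(group) if s in gm.specimens]
    if not members:
        raise PopgenError(f"group {group!r} has no specimens in the matrix")
    idx = np.array([gm.specimen_index(s) for s in members])
    alt, n = gm.alt_allele_counts(idx)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    return PiResult(
        group=group,
        per_site=pi[ok],
        n_sites=int(ok.sum()),
        n_skipped=int((~ok).sum()),
    )


def _wc_components(
    gm: GenotypeMatrix, groups_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) a, b, c for r populations of diploids,
    with per-site sample sizes (missing calls excluded).  Returns (a, b, c,
    usable-mask)."""
    r = len(groups_idx)
    n_i, p_i, h_i = [], [], []
    for idx in groups_idx:
        sub = gm.calls[idx, :]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)  # individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == HET) & called).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)  # (r, sites)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    n_tot = n_i.sum(axis=0)
    nbar = n_tot / r
    usable = (n_i >= 1).all(axis=0) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    usable &= nc > 0
    return a, b, c, usable


def weir_cockerham_fst(
    gm: GenotypeMatrix, species_map: SpeciesMap, group_a: str, group_b: str
) -> FstResult:
    """Pairwise weighted FST = sum(a) / sum(a+b+c) over usable sites.

    A site contributes when both groups have at least one called diploid
    (>= 2 alleles) and the overall sample allows the variance decomposition;
    negative per-site components are retained in the sums, so the weighted
    ratio may be slightly negative for undifferentiated groups.
    """
    groups_idx = []
    for g in (group_a, group_b):
        members = [s for s in species_map.analysis_members(g) if s in gm.specimens]
        if not members:
            raise PopgenError(f"group {g!r} has no specimens in the matrix")
        groups_idx.append(np.array([gm.specimen_index(s) for s in members]))
    a, b, c, ok = _wc_components(gm, groups_idx)
    return FstResult(
        group_a=group_a,
        group_b=group_b,
        a=a[ok],
        b=b[ok],
        c=c[ok],
        n_sites_used=int(ok.sum()),
        n_skipped=int((~ok).sum()),
    )


def pairwise_fst_table(gm, species_map, groups: list[str]):
    """Lower-triangular weighted FST (and per-site-ratio mean/SD) matrix."""
    import pandas as pd

    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            res = weir_cockerham_fst(gm, species_map, ga, gb)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "weighted_fst": res.weighted,
                    "mean_of_ratios": res.mean_of_ratios,
                    "sd_of_ratios": res.sd_of_ratios,
                    "n_sites_used": res.n_sites_used,
                }
            )
    return pd.DataFrame(rows)
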