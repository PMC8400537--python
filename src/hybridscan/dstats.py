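"""Trio allele-sharing tests: Patterson's D (ABBA-BABA), f4-ratio and Dmin.

Frequency-weighted formulation over group allele frequencies polarised by the
outgroup: after flipping alleles so the outgroup's major allele is ancestral,

    abba = (1 - p1) p2 p3 (1 - pO)      baba = p1 (1 - p2) p3 (1 - pO)

and D = (sum abba - sum baba) / (sum abba + sum baba) over the genome.
Sites where the outgroup is polymorphic are retained with their frequency
weight rather than dropped.  Significance comes from a delete-one block
jackknife whose natural block is the locus — the linkage unit of
target-capture data — and p-values across many trios are adjusted with
Bonferroni and Benjamini-Hochberg corrections.

The f4-ratio admixture fraction follows the two-subsample form: the donor
group P3 is split into random halves P3a/P3b (seeded) and

    f4_ratio = D-numerator(P1, P2, P3a, O) / D-numerator(P1, P3b, P3a, O),

which is ~0 without gene flow and ~alpha when a fraction alpha of P2's
ancestry derives from P3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix, SpeciesMap

__all__ = [
    "TrioDResult",
    "site_pattern_terms",
    "patterson_d",
    "f4_ratio",
    "dmin",
    "adjust_pvalues",
    "all_trios",
]


class DStatError(ValueError):
    pass


def site_pattern_terms(p1, p2, p3, p_out):
    """(abba, baba) weights at one site from polarised alt-allele
    frequencies."""
    p1, p2, p3, p_out = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p_out))
    abba = (1 - p1) * p2 * p3 * (1 - p_out)
    baba = p1 * (1 - p2) * p3 * (1 - p_out)
    return abba, baba


@dataclass
class TrioDResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    original_order: tuple[str, str, str]
    sum_abba: float
    sum_baba: float
    d: float | None
    z: float | None
    p_raw: float | None
    n_sites_used: int
    n_blocks: int
    f4: float | None = None
    f4_clamped: float | None = None
    dmin: float | None = None
    dmin_z: float | None = None
    dmin_p: float | None = None
    p_bonferroni: float | None = None
    p_bh: float | None = None
    swapped: bool = False  # P1/P2 swapped to make D >= 0


def _group_freqs(gm: GenotypeMatrix, species_map: SpeciesMap, group: str):
    members = [s for s in species_map.analysis_members(group) if s in gm.specimens]
    if not members:
        raise DStatError(f"group {group!r} has no specimens in the matrix")
    idx = np.array([gm.specimen_index(s) for s in members])
    alt, n = gm.alt_allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / n, np.nan)
    return freq


def _polarised_freqs(gm, species_map, trio, outgroup):
    """Alt-allele frequencies per group with alleles flipped so the outgroup
    major allele is ancestral; sites with any group fully missing are
    dropped (skip-and-count).  Also returns the mask of polarisation ties
    (outgroup frequency exactly 1/2), where the ancestral state is
    ambiguous."""
    freqs = [_group_freqs(gm, species_map, g) for g in (*trio, outgroup)]
    ok = ~np.any([np.isnan(f) for f in freqs], axis=0)
    p1, p2, p3, po = (f[ok] for f in freqs)
    flip = po > 0.5
    p1, p2, p3, po = (np.where(flip, 1 - p, p) for p in (p1, p2, p3, po))
    loci = gm.sites["locus"].to_numpy()[ok]
    tie = po == 0.5
    return (p1, p2, p3, po), tie, loci, int((~ok).sum())


def _pattern_arrays(gm, species_map, trio, outgroup):
    """Per-site (abba, baba, bbaa) after outgroup polarisation.

    At tie sites (outgroup frequency exactly 1/2, ancestral ambiguous) the
    two polarisations are averaged, which makes every statistic exactly
    invariant to which allele the matrix labels 'alt'.
    """
    (p1, p2, p3, po), tie, loci, n_skip = _polarised_freqs(
        gm, species_map, trio, outgroup
    )

    def terms(a, b, c, o):
        abba = (1 - a) * b * c * (1 - o)
        baba = a * (1 - b) * c * (1 - o)
        bbaa = a * b * (1 - c) * (1 - o)
        return abba, baba, bbaa

    fwd = terms(p1, p2, p3, po)
    rev = terms(1 - p1, 1 - p2, 1 - p3, 1 - po)
    out = tuple(np.where(tie, (f + r) / 2.0, f) for f, r in zip(fwd, rev))
    return out, loci, n_skip


def _block_sums(values: np.ndarray, loci: np.ndarray) -> np.ndarray:
    """Sum values per locus-contiguous block, in order of first appearance."""
    _, first_idx, inv = np.unique(loci, return_index=True, return_inverse=True)
    order = np.argsort(first_idx)
    sums = np.zeros(len(first_idx))
    np.add.at(sums, inv, values)
    return sums[order]


def _jackknife_z(num_blocks: np.ndarray, den_blocks: np.ndarray):
    """Delete-one-block jackknife z for a ratio statistic sum(num)/sum(den)."""
    tot_n, tot_d = num_blocks.sum(), den_blocks.sum()
    if tot_d == 0:
        return None, None, 0
    keep = den_blocks != tot_d  # leaving out block j must keep a denominator
    loo_d = tot_d - den_blocks
    ok = loo_d != 0
    if ok.sum() < 2:
        return None, None, int(ok.sum())
    d_full = tot_n / tot_d
    d_loo = (tot_n - num_blocks[ok]) / loo_d[ok]
    g = len(d_loo)
    var = (g - 1) / g * ((d_loo - d_loo.mean()) ** 2).sum()
    se = np.sqrt(var)
    if se == 0:
        return None, None, g
    return float(d_full / se), float(se), g


def patterson_d(
    gm: GenotypeMatrix,
    species_map: SpeciesMap,
    trio: tuple[str, str, str],
    outgroup: str,
    orient_positive: bool = True,
    block_size: int | None = None,
) -> TrioDResult:
    """Genome-wide D with block-jackknife Z and two-sided normal p.

    The default jackknife block is the locus — the natural linkage unit of
    target-capture data; pass ``block_size`` for Dsuite-style blocks of that
    many consecutive retained sites instead.  By convention the reported trio
    is arranged so that D >= 0 (P1/P2 swap negates D exactly); the original
    order is retained in the result.
    """
    (abba, baba, _), loci, n_skip = _pattern_arrays(gm, species_map, trio, outgroup)
    if block_size is not None:
        if block_size < 1:
            raise DStatError("block_size must be >= 1")
        loci = np.arange(len(abba)) // int(block_size)
    sum_abba, sum_baba = float(abba.sum()), float(baba.sum())
    p1n, p2n, p3n = trio
    swapped = False
    if orient_positive and sum_abba < sum_baba:
        p1n, p2n = p2n, p1n
        abba, baba = baba, abba
        sum_abba, sum_baba = sum_baba, sum_abba
        swapped = True
    denom = sum_abba + sum_baba
    num_blocks = _block_sums(abba - baba, loci)
    den_blocks = _block_sums(abba + baba, loci)
    if denom == 0:
        return TrioDResult(
            p1n, p2n, p3n, outgroup, trio, sum_abba, sum_baba,
            None, None, None, len(loci), 0, swapped=swapped,
        )
    d = (sum_abba - sum_baba) / denom
    z, _, n_blocks = _jackknife_z(num_blocks, den_blocks)
    p = None if z is None else float(2 * sps.norm.sf(abs(z)))
    return TrioDResult(
        p1n, p2n, p3n, outgroup, trio, sum_abba, sum_baba,
        float(d), z, p, len(loci), n_blocks, swapped=swapped,
    )


def f4_ratio(
    gm: GenotypeMatrix,
    species_map: SpeciesMap,
    trio: tuple[str, str, str],
    outgroup: str,
    seed: int = 0,
) -> tuple[float | None, float | None]:
    """Admixture fraction of P3 ancestry in P2 via a seeded half-split of P3.

    Returns (raw, clamped-to-[0,1]); None when P3 cannot be split or the
    denominator vanishes.
    """
    p1g, p2g, p3g = trio
    members = [s for s in species_map.analysis_members(p3g) if s in gm.specimens]
    if len(members) < 2:
        return None, None
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(members))
    half = len(members) // 2
    set_a = [members[i] for i in perm[:half]]
    set_b = [members[i] for i in perm[half:]]

    sub_map = SpeciesMap(
        species={
            **{s: species_map.species_of(s) for s in species_map.species},
        },
        roles=dict(species_map.roles),
    )
    # re-label the two halves as pseudo-groups
    for s in set_a:
        sub_map.species[s] = "__P3a__"
    for s in set_b:
        sub_map.species[s] = "__P3b__"

    def numerator(a, b, c):
        (abba, baba, _), _, _ = _pattern_arrays(gm, sub_map, (a, b, c), outgroup)
        return float(abba.sum() - baba.sum())

    num = numerator(p1g, p2g, "__P3a__")
    den = numerator(p1g, "__P3b__", "__P3a__")
    if den == 0:
        return None, None
    raw = num / den
    return float(raw), float(min(1.0, max(0.0, raw)))


def dmin(
    gm: GenotypeMatrix,
    species_map: SpeciesMap,
    groups: tuple[str, str, str],
    outgroup: str,
) -> tuple[float | None, float | None, float | None]:
    """Minimum |D| over the three arrangements of a trio, with the jackknife
    z and p of the minimising arrangement.

    A significantly positive Dmin means derived-allele sharing among the
    three groups is inconsistent with *any* single species tree relating
    them, even under incomplete lineage sorting.
    """
    a, b, c = groups
    arrangements = [(a, b, c), (a, c, b), (b, c, a)]
    best = None
    for arr in arrangements:
        res = patterson_d(gm, species_map, arr, outgroup, orient_positive=True)
        if res.d is None:
            continue
        if best is None or abs(res.d) < abs(best.d):
            best = res
    if best is None:
        return None, None, None
    return abs(best.d), best.z, best.p_raw


def adjust_pvalues(p_list, method: str):
    """Bonferroni (min(1, m p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(list(p_list), dtype=float)
    if len(p) == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DStatError("p-values must be in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method in ("benjamini_hochberg", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise DStatError(f"unknown correction method {method!r}")


def _bbaa_sum(gm, species_map, trio, outgroup) -> float:
    (_, _, bbaa), _, _ = _pattern_arrays(gm, species_map, trio, outgroup)
    return float(bbaa.sum())


def all_trios(
    gm: GenotypeMatrix,
    species_map: SpeciesMap,
    groups: list[str] | None = None,
    outgroup: str | None = None,
    f4_seed: int = 0,
) -> pd.DataFrame:
    """D / f4 / Dmin for every C(k,3) trio of reference groups, with
    Bonferroni and Benjamini-Hochberg adjusted p-values across trios.

    Each trio is arranged Dsuite-style: the pair maximising the BBAA sum is
    taken as (P1, P2) — the sister pair under the site patterns — and then
    P1/P2 are ordered so D >= 0.
    """
    if outgroup is None:
        og_specs = species_map.with_role("outgroup")
        if not og_specs:
            raise DStatError("D-statistics need >= 1 outgroup specimen")
        outgroup = species_map.species_of(og_specs[0])
    if groups is None:
        groups = [g for g in species_map.reference_species if g != outgroup]
    results = []
    for combo in itertools.combinations(groups, 3):
        a, b, c = combo
        arrangements = [(a, b, c), (a, c, b), (b, c, a)]
        best_arr = max(
            arrangements, key=lambda arr: _bbaa_sum(gm, species_map, arr, outgroup)
        )
        res = patterson_d(gm, species_map, best_arr, outgroup)
        res.f4, res.f4_clamped = f4_ratio(
            gm, species_map, (res.p1, res.p2, res.p3), outgroup, seed=f4_seed
        )
        res.dmin, res.dmin_z, res.dmin_p = dmin(gm, species_map, combo, outgroup)
        results.append(res)
    ps = [r.p_raw if r.p_raw is not None else np.nan for r in results]
    defined = ~np.isnan(ps)
    if defined.any():
        bonf = np.full(len(ps), np.nan)
        bh = np.full(len(ps), np.nan)
        bonf[defined] = adjust_pvalues(np.array(ps)[defined], "bonferroni")
        bh[defined] = adjust_pvalues(np.array(ps)[defined], "benjamini_hochberg")
        for r, pb, ph in zip(results, bonf, bh):
            r.p_bonferroni = None if np.isnan(pb) else float(pb)
            r.p_bh = None if np.isnan(ph) else float(ph)
    return pd.DataFrame(
        [
            {
                "P1": r.p1,
                "P2": r.p2,
                "P3": r.p3,
                "outgroup": r.outgroup,
                "D": r.d,
                "Z": r.z,
                "p": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "p_BH": r.p_bh,
                "f4": r.f4,
                "f4_clamped": r.f4_clamped,
                "Dmin": r.dmin,
                "Dmin_Z": r.dmin_z,
                "Dmin_p": r.dmin_p,
                "n_sites": r.n_sites_used,
                "n_blocks": r.n_blocks,
            }
            for r in results
        ]
    )
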