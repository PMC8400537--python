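"""Per-specimen observed heterozygosity and the hybrid-candidate outlier scan.

H_obs for a specimen is the fraction of its non-missing genotyped SNP sites
that are heterozygous — missing calls enter neither numerator nor
denominator, which keeps H_obs in [0, 1] under arbitrary missingness.  F1
hybrids between diverged species stand out because every site fixed for
different alleles in the parents is heterozygous in the hybrid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix, SpeciesMap

__all__ = ["HetResult", "observed_heterozygosity", "het_table", "het_outlier_scan"]


@dataclass(frozen=True)
class HetResult:
    specimen: str
    n_sites_used: int
    h_obs: float | None  # None when no usable site
    group: str | None = None

    @property
    def defined(self) -> bool:
        return self.h_obs is not None


def observed_heterozygosity(
    gm: GenotypeMatrix, specimen: str, group: str | None = None
) -> HetResult:
    """H_obs = het calls / (het + hom calls) for one specimen."""
    row = gm.calls[gm.specimen_index(specimen), :]
    used = row != MISSING
    n_used = int(used.sum())
    if n_used == 0:
        return HetResult(specimen, 0, None, group)
    h = float((row[used] == HET).mean())
    return HetResult(specimen, n_used, h, group)


def het_table(gm: GenotypeMatrix, species_map: SpeciesMap) -> pd.DataFrame:
    rows = []
    for s in gm.specimens:
        r = observed_heterozygosity(gm, s, species_map.species_of(s))
        rows.append(
            {
                "specimen": s,
                "species": r.group,
                "n_sites": r.n_sites_used,
                "h_obs": np.nan if r.h_obs is None else r.h_obs,
            }
        )
    return pd.DataFrame(rows)


def het_outlier_scan(
    results: pd.DataFrame | list[HetResult],
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Rank specimens by leave-one-out z-score against their own putative
    species.

    For each specimen the comparison group is the *other* members of its
    species; the candidate itself is excluded from the mean and SD so that a
    genuine outlier cannot mask itself (with n group members an included
    outlier is bounded at |z| <= (n-1)/sqrt(n)).  Groups too small for a
    leave-one-out dispersion (fewer than 3 members) are flagged
    ``insufficient group size`` and excluded from z-scoring.
    """
    if isinstance(results, list):
        df = pd.DataFrame(
            {
                "specimen": [r.specimen for r in results],
                "species": [r.group for r in results],
                "n_sites": [r.n_sites_used for r in results],
                "h_obs": [np.nan if r.h_obs is None else r.h_obs for r in results],
            }
        )
    else:
        df = results.copy()
    out_rows = []
    for _, row in df.iterrows():
        grp = df[(df["species"] == row["species"]) & (df["specimen"] != row["specimen"])]
        grp = grp.dropna(subset=["h_obs"])
        rec = dict(row)
        if np.isnan(row["h_obs"]):
            rec.update(group_mean=np.nan, group_sd=np.nan, z=np.nan, flag="undefined")
        elif len(grp) < 2:
            rec.update(
                group_mean=np.nan, group_sd=np.nan, z=np.nan,
                flag="insufficient group size",
            )
        else:
            m = float(grp["h_obs"].mean())
            sd = float(grp["h_obs"].std(ddof=1))
            if row["h_obs"] == m:
                z = 0.0
            elif sd == 0:
                z = math.copysign(math.inf, row["h_obs"] - m)
            else:
                z = (row["h_obs"] - m) / sd
            rec.update(
                group_mean=m,
                group_sd=sd,
                z=float(z),
                flag="hybrid-candidate" if z > z_threshold else "",
            )
        out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    return out.sort_values("z", ascending=False, na_position="last").reset_index(
        drop=True
    )
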