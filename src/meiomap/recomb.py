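"""Chromosome-specific recombination rates (cM/Mb).

For each LG, pairs of markers aligned to the same reference chromosome are
sampled repeatedly and the pairwise genetic distance |dcM| is regressed on
the physical distance |dbp|/1e6 through the origin; the slope of each
replicate is a cM/Mb estimate and the mean/SD over replicates is reported,
separately for the female, male, and sex-averaged maps.
"""
from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["estimate_rates"]

_SEX_COL = {"female": "female_cM", "male": "male_cM", "avg": "avg_cM"}


def _zero_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(x @ x)
    if sxx == 0:
        return np.nan
    return float(x @ y) / sxx


def estimate_rates(
    map_table: pd.DataFrame,
    alignments: pd.DataFrame,
    n_pairs: int = 100,
    n_reps: int = 100,
    mq_min: int = 60,
    min_loci: int = 50,
    rng: np.random.Generator | None = None,
    sexes: tuple[str, ...] = ("female", "male", "avg"),
) -> pd.DataFrame:
    """Resampled through-the-origin regression of cM on Mb per LG.

    ``map_table`` is the ordering module's output (marker, lg, female_cM,
    male_cM, avg_cM); ``alignments`` carries marker, ref_chrom, ref_bp, mq.
    Markers need mapping quality >= ``mq_min`` on reference chromosomes
    holding more than ``min_loci`` such markers.  Each replicate samples
    ``n_pairs`` same-LG same-reference pairs without replacement.
    """
    rng = rng or np.random.default_rng()
    merged = map_table.merge(alignments, on="marker", how="inner")
    merged = merged[merged["mq"] >= mq_min]
    chrom_counts = merged.groupby("ref_chrom")["marker"].count()
    good_chroms = chrom_counts.index[chrom_counts > min_loci]
    merged = merged[merged["ref_chrom"].isin(good_chroms)]
    rows = []
    for lg, sub in merged.groupby("lg", sort=False):
        pairs: list[tuple[int, int]] = []
        for _, grp in sub.groupby("ref_chrom", sort=False):
            idx = grp.index.to_numpy()
            pairs.extend(combinations(idx, 2))
        if not pairs:
            continue
        pairs_arr = np.asarray(pairs)
        take = min(n_pairs, len(pairs))
        if take < n_pairs:
            warnings.warn(
                f"{lg}: only {len(pairs)} eligible pairs (< {n_pairs}); using all",
                stacklevel=2,
            )
        for sex in sexes:
            cm = merged[_SEX_COL[sex]]
            bp = merged["ref_bp"]
            slopes = np.empty(n_reps)
            for rep in range(n_reps):
                sel = pairs_arr[rng.choice(len(pairs_arr), size=take, replace=False)]
                dcm = np.abs(cm.loc[sel[:, 0]].to_numpy() - cm.loc[sel[:, 1]].to_numpy())
                dmb = np.abs(bp.loc[sel[:, 0]].to_numpy() - bp.loc[sel[:, 1]].to_numpy()) / 1e6
                slopes[rep] = _zero_intercept_slope(dmb, dcm)
            rows.append(
                {
                    "lg": lg,
                    "sex": sex,
                    "rate_cM_per_Mb": float(np.nanmean(slopes)),
                    "sd": float(np.nanstd(slopes, ddof=0)),
                    "n_pairs": take,
                    "n_loci": int(sub.shape[0]),
                }
            )
    return pd.DataFrame(rows)
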