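"""Centromere localization from half-tetrad heterozygosity and RFm profiles.

Gynogenetic diploids retain the two sister chromatids of one secondary
oocyte, so offspring heterozygosity at a marker (*y*) estimates the
second-division-segregation frequency: y = 0 at the centromere and rises
towards the 2/3 asymptote with marker-centromere distance.  The centromere
interval is the span of markers with y below a threshold (default 0.1).

The RFm method cross-validates this: the maternal recombination fraction
between each marker and a terminal reference marker plateaus near 0.5 on
the far side of the centromere; the maximal run with RFm >= 0.45 marks the
putative centromeric region, disambiguated between chromosome ends by the
lowest-y markers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING, HalfTetradDataset

__all__ = [
    "CentromereInterval",
    "filter_halftetrad_variants",
    "read_halftetrad_vcf",
    "estimate_y",
    "delineate_centromere_y",
    "rfm_centromere",
    "reconcile_centromeres",
]


@dataclass
class CentromereInterval:
    """Per-LG centromere coordinates (cM, female map) with provenance."""

    lg: str
    start: float
    end: float
    method: str  # "half-tetrad" | "RFm" | "reconciled"
    chrom_class: str = "unknown"  # "metacentric" | "acrocentric/telocentric" | "unknown"
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    def overlaps(self, other: "CentromereInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end


def read_halftetrad_vcf(path: str, mother: str) -> pd.DataFrame:
    """Load a half-tetrad call set from VCF (biallelic SNPs only).

    Returns a long-form table with one row per marker: chrom, pos,
    genotype dosages per sample (MISSING for uncalled or low-GQ handled
    downstream), plus per-sample GQ columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if mother not in samples:
        raise ValueError(f"mother {mother!r} absent from VCF samples")
    rows = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue  # indels and >2-allele records dropped
        gts = np.asarray(var.gt_types, dtype=int)  # 0 hom-ref, 1 het, 2 hom-alt(cyvcf2: 3), 2 unknown
        dosage = np.select(
            [gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING
        )
        gq = np.asarray(var.gt_quals, dtype=float)
        row = {"marker": f"{var.CHROM}:{var.POS}", "chrom": var.CHROM, "pos": var.POS}
        for s, d, q in zip(samples, dosage, gq):
            row[s] = int(d)
            row[f"GQ_{s}"] = float(q)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["samples"] = samples
    df.attrs["mother"] = mother
    return df


def filter_halftetrad_variants(
    calls: pd.DataFrame,
    mother: str,
    gq_min: float = 10.0,
    missing_max: float = 0.3,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Informative-marker filter chain for the gynogenetic call set.

    ``calls`` is the ``read_halftetrad_vcf`` layout (or equivalent TSV):
    one row per biallelic SNP with per-sample dosage columns and optional
    ``GQ_<sample>`` columns.  Genotypes with GQ <= ``gq_min`` are set
    missing; markers are dropped when missingness exceeds ``missing_max``,
    MAF < ``maf_min``, the mother is not heterozygous, or either homozygote
    class is unobserved among offspring.  The mother's column is excluded
    from the returned offspring table.
    """
    if mother not in calls.columns:
        raise ValueError(f"mother column {mother!r} absent")
    samples = [
        c
        for c in calls.columns
        if c not in ("marker", "chrom", "pos") and not c.startswith("GQ_")
    ]
    offspring = [s for s in samples if s != mother]
    geno = calls[samples].to_numpy(dtype=float).copy()
    for j, s in enumerate(samples):
        gq_col = f"GQ_{s}"
        if gq_col in calls.columns:
            geno[calls[gq_col].to_numpy(dtype=float) <= gq_min, j] = MISSING
    geno_df = pd.DataFrame(geno, columns=samples, index=calls.index)
    off = geno_df[offspring].to_numpy()
    obs = off != MISSING
    with np.errstate(invalid="ignore"):
        missing_frac = 1.0 - obs.mean(axis=1)
        alt = np.where(obs, off, 0.0).sum(axis=1)
        tot = 2.0 * obs.sum(axis=1)
        freq = np.divide(alt, tot, out=np.full(len(calls), np.nan), where=tot > 0)
    maf = np.minimum(freq, 1.0 - freq)
    mother_het = geno_df[mother].to_numpy() == 1
    both_homs = np.array(
        [np.any(row[row != MISSING] == 0) and np.any(row[row != MISSING] == 2) for row in off]
    )
    keep = (
        (missing_frac <= missing_max)
        & (maf >= maf_min)
        & mother_het
        & both_homs
    )
    out = calls.loc[keep, ["marker", "chrom", "pos"]].copy()
    for s in offspring:
        out[s] = geno_df.loc[keep, s].astype(int).to_numpy()
    return out.reset_index(drop=True)


def estimate_y(
    data: HalfTetradDataset | pd.DataFrame,
    offspring_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Observed offspring heterozygosity per marker: y = n_het / n_scored.

    Accepts a simulated :class:`HalfTetradDataset` or a filtered call
    table; returns (marker, chrom, pos_cM, y, n).
    """
    if isinstance(data, HalfTetradDataset):
        states = data.states
        scored = states != MISSING
        het = states == 1
        n = scored.sum(axis=0)
        with np.errstate(invalid="ignore"):
            y = np.divide(het.sum(axis=0), n, out=np.full(n.size, np.nan, float), where=n > 0)
        out = data.markers[["marker", "chrom", "pos_cM"]].copy()
        out["y"], out["n"] = y, n
        return out
    cols = offspring_columns or [
        c for c in data.columns if c not in ("marker", "chrom", "pos", "pos_cM")
    ]
    states = data[cols].to_numpy()
    scored = states != MISSING
    n = scored.sum(axis=1)
    with np.errstate(invalid="ignore"):
        y = np.divide((states == 1).sum(axis=1), n, out=np.full(n.size, np.nan, float), where=n > 0)
    out = data[[c for c in ("marker", "chrom", "pos", "pos_cM") if c in data.columns]].copy()
    out["y"], out["n"] = y, n
    return out


def delineate_centromere_y(
    profile: pd.DataFrame,
    lg: str = "LG1",
    y_threshold: float = 0.1,
    pos_col: str = "pos_cM",
) -> CentromereInterval | None:
    """Interval from first to last marker with y below the threshold.

    ``profile`` must be ordered along the LG.  Returns None when no marker
    qualifies (unresolved LG).
    """
    prof = profile.dropna(subset=["y"])
    low = prof.index[prof["y"] < y_threshold]
    if low.empty:
        return None
    pos = prof.loc[low, pos_col]
    return CentromereInterval(lg, float(pos.min()), float(pos.max()), "half-tetrad")


def _rfm_profile(gametes: np.ndarray, ref: int) -> np.ndarray:
    """Recombinant fraction of each marker against one reference marker.

    Unfolded (phase-known maternal haplotypes); values > 0.5 are possible
    only through mis-phasing or noise and are left for the caller to flag.
    """
    refrow = gametes[ref]
    obs = ~np.isnan(gametes) & ~np.isnan(refrow)
    mism = np.where(obs, np.abs(gametes - refrow), 0.0).sum(axis=1)
    n = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.divide(mism, n, out=np.full(n.size, np.nan), where=n > 0)


def _runs_at_cutoff(rfm: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal contiguous index runs with RFm >= cutoff."""
    qual = np.nan_to_num(rfm, nan=-1.0) >= cutoff
    runs = []
    i = 0
    while i < qual.size:
        if qual[i]:
            j = i
            while j + 1 < qual.size and qual[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def rfm_centromere(
    gametes: np.ndarray,
    positions: np.ndarray,
    lg: str = "LG1",
    cutoff: float = 0.45,
    y_profile: pd.DataFrame | None = None,
) -> CentromereInterval | None:
    """Centromeric region from maternal recombination-fraction profiles.

    ``gametes`` is the ordered markers x meioses maternal-origin matrix for
    one LG and ``positions`` the matching cM coordinates.  Profiles are
    computed against both terminal reference markers; the centromeric
    region is the maximal run with RFm >= ``cutoff``.  When both ends
    resolve overlapping runs their intersection is returned (metacentric
    pattern); disjoint candidates are disambiguated by proximity to the
    lowest y value of ``y_profile`` when available, else the longer run
    wins.  Returns None when no run reaches the cutoff.
    """
    m = gametes.shape[0]
    positions = np.asarray(positions, dtype=float)
    if positions.size != m:
        raise ValueError("positions must match gamete matrix rows")

    runs_l = _runs_at_cutoff(_rfm_profile(gametes, 0), cutoff)
    runs_r = _runs_at_cutoff(_rfm_profile(gametes, m - 1), cutoff)
    # metacentric pattern: regions where the two profiles qualify jointly
    intersections = []
    for a in runs_l:
        for b in runs_r:
            lo, hi = max(a[0], b[0]), min(a[1], b[1])
            if lo <= hi:
                intersections.append((lo, hi))
    # acrocentric/telocentric pattern: the run at the end opposite a reference
    run_l = max(runs_l, key=lambda r: (r[1], r[1] - r[0]), default=None)
    run_r = min(runs_r, key=lambda r: (r[0], -(r[1] - r[0])), default=None)
    candidates = intersections + [r for r in (run_l, run_r) if r is not None]
    if not candidates:
        return None
    if y_profile is not None and y_profile["y"].notna().any():
        pos_col = "pos_cM" if "pos_cM" in y_profile else "pos"
        ymin_pos = float(y_profile.loc[y_profile["y"].idxmin(), pos_col])

        def dist(run: tuple[int, int]) -> float:
            lo, hi = positions[run[0]], positions[run[1]]
            if min(lo, hi) <= ymin_pos <= max(lo, hi):
                return 0.0
            return min(abs(ymin_pos - lo), abs(ymin_pos - hi))

        chosen = min(candidates, key=dist)  # ties prefer the intersection
    else:
        chosen = candidates[0]
    return CentromereInterval(lg, float(positions[chosen[0]]), float(positions[chosen[1]]), "RFm")


def reconcile_centromeres(
    y_interval: CentromereInterval | None,
    rfm_interval: CentromereInterval | None,
    female_length: float,
    lg: str = "LG1",
    central_fraction: float = 0.5,
) -> CentromereInterval | None:
    """Combine half-tetrad and RFm intervals and call the chromosome class.

    Overlapping intervals intersect; disjoint ones union with a conflict
    flag.  The class is metacentric when the reconciled midpoint lies in
    the central ``central_fraction`` of the female map, else
    acrocentric/telocentric.  Returns None (class unknown) when neither
    method resolved the LG.
    """
    if y_interval is None and rfm_interval is None:
        return None
    if y_interval is None or rfm_interval is None:
        src = y_interval or rfm_interval
        start, end, conflict = src.start, src.end, False
    elif y_interval.overlaps(rfm_interval):
        start = max(y_interval.start, rfm_interval.start)
        end = min(y_interval.end, rfm_interval.end)
        conflict = False
    else:
        start = min(y_interval.start, rfm_interval.start)
        end = max(y_interval.end, rfm_interval.end)
        conflict = True
    mid = (start + end) / 2.0
    lo = female_length * (0.5 - central_fraction / 2.0)
    hi = female_length * (0.5 + central_fraction / 2.0)
    chrom_class = "metacentric" if lo <= mid <= hi else "acrocentric/telocentric"
    return CentromereInterval(lg, start, end, "reconciled", chrom_class, conflict)
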