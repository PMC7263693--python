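"""Marker quality control for mapping families.

Filters genotyped SNPs on segregation distortion (chi-square against the
Mendelian expectation for the parental cross type), minor allele frequency,
missingness, and informativeness; thins to one SNP per RAD locus (closest
to the restriction cut site); and purges markers whose multipoint LOD
profile over candidate map positions is flat or multimodal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING

__all__ = [
    "FamilyGenotypes",
    "GenotypeTable",
    "filter_markers",
    "thin_to_one_snp_per_locus",
    "lod_position_filter",
    "drop_multi_lg_loci",
]


@dataclass
class FamilyGenotypes:
    """Genotypes of one family: parental codes plus offspring calls.

    All genotypes are allele-1 dosages (0 = A, 1 = H, 2 = B, MISSING = NA),
    indexed by marker; ``offspring`` is markers x individuals.
    """

    mother: pd.Series
    father: pd.Series
    offspring: pd.DataFrame


@dataclass
class GenotypeTable:
    """Marker metadata plus per-family genotypes.

    ``meta`` must carry columns ``marker``, ``rad_locus``, ``offset`` (bp
    from the restriction cut site); every marker belongs to one RAD locus.
    """

    meta: pd.DataFrame
    families: dict[str, FamilyGenotypes] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.meta["offset"] < 0).any():
            raise ValueError("offsets must be >= 0")
        self.meta = self.meta.set_index("marker", drop=False) if self.meta.index.name != "marker" else self.meta

    @property
    def markers(self) -> pd.Index:
        return self.meta.index

    def subset(self, keep: pd.Index) -> "GenotypeTable":
        fams = {
            f: FamilyGenotypes(
                g.mother.loc[keep], g.father.loc[keep], g.offspring.loc[keep]
            )
            for f, g in self.families.items()
        }
        return GenotypeTable(self.meta.loc[keep].copy(), fams)


def _cross_type(mother: int, father: int) -> str:
    """Classify a biallelic cross by parental dosages."""
    if mother == MISSING or father == MISSING:
        return "unknown"
    het = (mother == 1) + (father == 1)
    if het == 2:
        return "intercross"  # H x H -> 1:2:1
    if het == 1:
        return "testcross"  # H x hom -> 1:1
    return "uninformative"  # hom x hom


def _distortion_p(mother: int, father: int, counts: np.ndarray) -> float | None:
    """Chi-square p for segregation distortion; None when untestable.

    ``counts`` are observed offspring counts of dosages (0, 1, 2).
    Offspring classes impossible under the cross are excluded.
    """
    ct = _cross_type(mother, father)
    if ct == "intercross":
        obs = counts.astype(float)
        exp = np.array([0.25, 0.5, 0.25]) * obs.sum()
    elif ct == "testcross":
        hom = mother if mother != 1 else father
        cls = [1, 0 if hom == 0 else 2]  # het and the transmitted homozygote
        obs = counts[cls].astype(float)
        exp = np.array([0.5, 0.5]) * obs.sum()
    else:
        return None
    if obs.sum() == 0:
        return None
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=len(obs) - 1))


def filter_markers(
    table: GenotypeTable,
    p_distortion: float = 0.01,
    maf_min: float = 0.05,
    missing_max: float = 0.3,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply the distortion / MAF / missingness / informativeness filters.

    A marker is removed if any informative family shows segregation
    distortion at p < ``p_distortion``, if its pooled offspring MAF is
    below ``maf_min``, if its pooled missing fraction exceeds
    ``missing_max``, or if it is informative (>= 1 heterozygous parent)
    in no family.  Returns the filtered table and an exhaustive report.
    """
    rows = []
    for marker in table.markers:
        worst_p = None
        n_informative = 0
        unknown_cross = False
        alt = tot = miss = called = 0
        for fam, g in table.families.items():
            off = g.offspring.loc[marker].to_numpy()
            obs = off[off != MISSING]
            miss += int((off == MISSING).sum())
            called += off.size
            alt += int(obs.sum())
            tot += 2 * obs.size
            mo, fa = int(g.mother.loc[marker]), int(g.father.loc[marker])
            ct = _cross_type(mo, fa)
            if ct == "unknown":
                unknown_cross = True
                continue
            if ct == "uninformative":
                continue
            n_informative += 1
            counts = np.bincount(obs, minlength=3)[:3]
            p = _distortion_p(mo, fa, counts)
            if p is not None and (worst_p is None or p < worst_p):
                worst_p = p
        freq = alt / tot if tot else np.nan
        maf = min(freq, 1 - freq) if tot else np.nan
        miss_frac = miss / called if called else 1.0
        reasons = []
        if worst_p is not None and worst_p < p_distortion:
            reasons.append("distortion")
        if not np.isnan(maf) and maf < maf_min:
            reasons.append("maf")
        if miss_frac > missing_max:
            reasons.append("missing")
        if n_informative == 0:
            reasons.append("uninformative")
        rows.append(
            {
                "marker": marker,
                "distortion_p": worst_p,
                "maf": maf,
                "missing_frac": miss_frac,
                "n_informative_families": n_informative,
                "unknown_cross": unknown_cross,
                "keep": not reasons,
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows).set_index("marker", drop=False)
    keep = report.index[report["keep"]]
    return table.subset(keep), report


def thin_to_one_snp_per_locus(table: GenotypeTable) -> GenotypeTable:
    """Keep one SNP per RAD locus: minimal cut-site offset, ties by id."""
    flat = table.meta.reset_index(drop=True)
    ranked = flat.sort_values(["offset", "marker"], kind="mergesort")
    chosen = set(ranked.drop_duplicates("rad_locus", keep="first")["marker"])
    keep = table.meta.index[table.meta["marker"].isin(chosen)]  # original order
    return table.subset(keep)


def _peak_regions(norm: np.ndarray, peak_height: float, min_sep: float) -> int:
    """Number of peak regions: qualifying positions clustered by index gap."""
    idx = np.flatnonzero(norm >= peak_height)
    if idx.size == 0:
        return 0
    gap = min_sep * norm.size
    return 1 + int(np.sum(np.diff(idx) > gap))


def lod_position_filter(
    lod_vectors: dict[str, np.ndarray],
    peak_height: float = 0.95,
    min_peak_separation: float = 0.25,
    sd_mult: float = 1.0,
    use_normalized_sd_rule: bool = False,
) -> pd.DataFrame:
    """Per-marker keep/remove decision from its LOD-by-position vector.

    A marker is removed when its raw vector is degenerate (zero SD), when
    the maximum LOD is less than ``mean + sd_mult * SD`` of its own vector
    (computed on the raw vector by default), or when the min-max normalized
    vector shows >= 2 peak regions of height >= ``peak_height`` separated
    by more than ``min_peak_separation`` of the vector length.
    """
    rows = []
    for marker, vec in lod_vectors.items():
        v = np.asarray(vec, dtype=float)
        if v.size < 4:
            raise ValueError(f"{marker}: need >= 4 candidate positions")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{marker}: non-finite LOD entries")
        sd = float(v.std())
        if sd == 0:
            rows.append({"marker": marker, "keep": False, "reason": "degenerate", "n_peaks": 0})
            continue
        basis = (v - v.min()) / (v.max() - v.min()) if use_normalized_sd_rule else v
        if basis.max() < basis.mean() + sd_mult * basis.std():
            rows.append({"marker": marker, "keep": False, "reason": "low_peak", "n_peaks": 0})
            continue
        norm = (v - v.min()) / (v.max() - v.min())
        n_peaks = _peak_regions(norm, peak_height, min_peak_separation)
        if n_peaks >= 2:
            rows.append({"marker": marker, "keep": False, "reason": "multi_peak", "n_peaks": n_peaks})
        else:
            rows.append({"marker": marker, "keep": True, "reason": "", "n_peaks": n_peaks})
    return pd.DataFrame(rows).set_index("marker", drop=False)


def drop_multi_lg_loci(
    meta: pd.DataFrame, marker_to_lg: dict[str, str]
) -> pd.Index:
    """Markers to keep after removing RAD loci whose SNPs hit multiple LGs."""
    lg = meta["marker"].map(marker_to_lg)
    n_lgs = lg.groupby(meta["rad_locus"]).transform("nunique")
    return meta.index[n_lgs <= 1]
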