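"""Homology assignment and inversion-segment centricity classification.

Linkage groups are called homologous to a reference chromosome when enough
well-mapped loci support the pairing; candidate inversions are maximal
monotone runs of the (cM, bp) scatter whose orientation opposes the
chromosome-wide majority; a segment is pericentric iff it overlaps the
centromere interval (closed intervals).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centromere import CentromereInterval

__all__ = [
    "InversionSegment",
    "assign_homology",
    "detect_inversion_segments",
    "classify_centricity",
]


@dataclass
class InversionSegment:
    """A candidate inversion on an LG (cM, female map)."""

    lg: str
    start: float
    end: float
    orientation: str  # "reversed" | "forward" | "unknown"
    n_markers: int = 0
    centricity: str = "unknown"  # "pericentric" | "paracentric" | "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")


def assign_homology(
    map_table: pd.DataFrame,
    alignments: pd.DataFrame,
    min_loci: int = 50,
    mq_min: int = 60,
) -> pd.DataFrame:
    """Reference-chromosome support counts per LG at high mapping quality.

    A (lg, ref_chrom) pair with >= ``min_loci`` qualifying loci is a
    homolog; smaller counts are reported as suggestive only.
    """
    merged = map_table.merge(alignments, on="marker", how="inner")
    merged = merged[merged["mq"] >= mq_min]
    counts = (
        merged.groupby(["lg", "ref_chrom"])["marker"].count().rename("n_loci").reset_index()
    )
    counts["homolog"] = counts["n_loci"] >= min_loci
    counts["flag"] = np.where(counts["homolog"], "", "suggestive")
    return counts.sort_values(["lg", "n_loci"], ascending=[True, False]).reset_index(drop=True)


def _monotone_runs(
    cm: np.ndarray, bp: np.ndarray, min_run_edges: int = 2
) -> list[tuple[int, int, int, int]]:
    """Maximal same-direction runs as (start, end, sign, n_edges).

    Directions are signs of consecutive bp differences along the cm order;
    runs shorter than ``min_run_edges`` edges (single-marker flickers) are
    absorbed into their longer neighbour.
    """
    dirs = np.sign(np.diff(bp)).astype(int)
    for i in range(1, dirs.size):  # ties in bp inherit the running direction
        if dirs[i] == 0:
            dirs[i] = dirs[i - 1]
    if dirs.size and dirs[0] == 0:
        nz = dirs[dirs != 0]
        dirs[0] = nz[0] if nz.size else 1
    runs: list[list[int]] = []  # [start_edge, end_edge, sign]
    for i, d in enumerate(dirs):
        if runs and runs[-1][2] == d:
            runs[-1][1] = i
        else:
            runs.append([i, i, int(d)])
    # absorb flickers into the longer neighbour
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, r in enumerate(runs):
            if r[1] - r[0] + 1 < min_run_edges:
                nb = runs[k - 1] if k > 0 else runs[k + 1]
                if k > 0 and k + 1 < len(runs):
                    left, right = runs[k - 1], runs[k + 1]
                    nb = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
                nb[0] = min(nb[0], r[0])
                nb[1] = max(nb[1], r[1])
                runs.pop(k)
                changed = True
                break
    # merge now-adjacent runs of equal sign
    merged: list[list[int]] = []
    for r in runs:
        if merged and merged[-1][2] == r[2]:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(r[0], r[1] + 1, r[2], r[1] - r[0] + 1) for r in merged]


def detect_inversion_segments(
    cm: np.ndarray,
    bp: np.ndarray,
    lg: str = "LG1",
    min_segment: int = 10,
    rho_min: float = 0.9,
) -> list[InversionSegment]:
    """Candidate inversions from a linkage-map vs reference scatter.

    The scatter is decomposed into maximal monotone runs; runs opposing
    the marker-weighted majority orientation with >= ``min_segment``
    markers become reversed segments.  A tie in overall orientation marks
    all segments unknown.
    """
    cm = np.asarray(cm, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if cm.size < 2 * min_segment:
        raise ValueError("need >= 2 * min_segment markers")
    order = np.argsort(cm, kind="mergesort")
    cm, bp = cm[order], bp[order]
    runs = _monotone_runs(cm, bp)
    weight = {1: 0, -1: 0}
    for i, j, sign, n_edges in runs:
        weight[sign] += n_edges
    if weight[1] == weight[-1]:
        majority = 0
    else:
        majority = 1 if weight[1] > weight[-1] else -1
    segments = []
    for i, j, sign, _ in runs:
        n = j - i + 1
        if n < min_segment:
            continue
        rho = stats.spearmanr(cm[i : j + 1], bp[i : j + 1]).statistic
        if np.isfinite(rho) and abs(rho) < rho_min:
            continue  # not a coherent monotone block
        if majority == 0:
            orientation = "unknown"
        elif sign == majority:
            continue  # collinear with the chromosome-wide orientation
        else:
            orientation = "reversed"
        segments.append(
            InversionSegment(
                lg=lg,
                start=float(cm[i]),
                end=float(cm[j]),
                orientation=orientation,
                n_markers=n,
            )
        )
    return segments


def classify_centricity(
    segment: InversionSegment, centromere: CentromereInterval | None
) -> InversionSegment:
    """Pericentric iff the segment overlaps the centromere interval.

    Closed intervals: boundary contact counts as overlap.  An unresolved
    centromere leaves the centricity unknown.
    """
    if centromere is None:
        segment.centricity = "unknown"
        return segment
    if centromere.lg != segment.lg:
        raise ValueError(
            f"segment on {segment.lg} but centromere on {centromere.lg}"
        )
    lo, hi = sorted((segment.start, segment.end))
    overlap = lo <= centromere.end and centromere.start <= hi
    segment.centricity = "pericentric" if overlap else "paracentric"
    return segment
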