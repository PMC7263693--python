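"""Within-LG marker ordering and sex-specific map positions.

Ordering is a seriation that minimizes the sum of adjacent recombination
fractions (SARF): greedy nearest-neighbour construction from random starts
refined by 2-opt.  Adjacent recombination fractions per sex are converted
to cM with Haldane's map function d = -(1/2) ln(1 - 2r).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouping import pairwise_lod

__all__ = [
    "MarkerOrder",
    "order_markers",
    "map_positions",
    "summarize_map",
    "haldane_cM",
]


def haldane_cM(r: np.ndarray | float, cap: float = 0.49) -> np.ndarray | float:
    """Map distance in cM from recombination fraction (Haldane, capped)."""
    r = np.minimum(np.asarray(r, dtype=float), cap)
    return -50.0 * np.log1p(-2.0 * r)


@dataclass
class MarkerOrder:
    """A canonical permutation of one LG's markers with its SARF score."""

    markers: list[str]  # in map order
    order: np.ndarray  # indices into the input marker list
    sarf: float
    rfrac: np.ndarray  # full pairwise r-hat matrix in *input* index space


def _greedy_path(d: np.ndarray, start: int) -> np.ndarray:
    m = d.shape[0]
    visited = np.zeros(m, dtype=bool)
    path = [start]
    visited[start] = True
    for _ in range(m - 1):
        row = d[path[-1]].copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        path.append(nxt)
        visited[nxt] = True
    return np.asarray(path)


def _path_cost(d: np.ndarray, path: np.ndarray) -> float:
    return float(d[path[:-1], path[1:]].sum())


def _two_opt(d: np.ndarray, path: np.ndarray) -> np.ndarray:
    """2-opt refinement of an open path (segment reversals)."""
    m = path.size
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                # reversing path[i..j]: edges (i-1,i) and (j,j+1) change
                before = 0.0
                after = 0.0
                if i > 0:
                    before += d[path[i - 1], path[i]]
                    after += d[path[i - 1], path[j]]
                if j < m - 1:
                    before += d[path[j], path[j + 1]]
                    after += d[path[i], path[j + 1]]
                if after < before - 1e-12:
                    path[i : j + 1] = path[i : j + 1][::-1]
                    improved = True
    return path


def order_markers(
    gamete_matrices: list[np.ndarray],
    markers: list[str],
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
) -> MarkerOrder:
    """Order one LG's markers by SARF seriation.

    ``gamete_matrices`` are markers x meioses parental-origin matrices for
    the informative parents of this LG (pooled for the distance matrix).
    The orientation is canonicalized: lower-id terminal marker first.
    """
    m = len(markers)
    if m < 2:
        raise ValueError("need >= 2 markers to order")
    rng = rng or np.random.default_rng()
    pair = pairwise_lod(gamete_matrices, markers)
    d = pair.rfrac.copy()
    d[np.isnan(d)] = 0.5  # unscored pairs are treated as unlinked
    np.fill_diagonal(d, 0.0)
    if m == 2:
        order = np.array([0, 1])
    else:
        best, best_cost = None, np.inf
        starts = rng.integers(0, m, size=n_restarts)
        for s in starts:
            path = _two_opt(d, _greedy_path(d, int(s)))
            cost = _path_cost(d, path)
            if cost < best_cost - 1e-12 or (
                best is None
            ):
                best, best_cost = path.copy(), cost
        order = best
    if markers[order[0]] > markers[order[-1]]:
        order = order[::-1].copy()
    return MarkerOrder(
        markers=[markers[i] for i in order],
        order=order,
        sarf=_path_cost(d, order),
        rfrac=pair.rfrac,
    )


def _adjacent_r(matrices: list[np.ndarray], order: np.ndarray) -> np.ndarray:
    """Pooled folded r-hat between adjacent markers of the ordered LG."""
    k = np.zeros(order.size - 1)
    n = np.zeros(order.size - 1)
    for mat in matrices:
        a = mat[order[:-1]]
        b = mat[order[1:]]
        obs = ~np.isnan(a) & ~np.isnan(b)
        mism = np.nansum(np.where(obs, np.abs(a - b), 0.0), axis=1)
        nn = obs.sum(axis=1)
        k += np.minimum(mism, nn - mism)
        n += nn
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, k / n, 0.0)
    return np.minimum(r, 0.5)


def map_positions(
    order: MarkerOrder,
    female_matrices: list[np.ndarray],
    male_matrices: list[np.ndarray],
    lg: str = "LG1",
) -> pd.DataFrame:
    """Cumulative Haldane positions per sex plus the sex-averaged map.

    Returns a table (marker, lg, female_cM, male_cM, avg_cM) in map order;
    adjacent r exactly 0.5 is flagged by capping at 0.49 before conversion.
    """
    r_f = _adjacent_r(female_matrices, order.order) if female_matrices else np.zeros(order.order.size - 1)
    r_m = _adjacent_r(male_matrices, order.order) if male_matrices else np.zeros(order.order.size - 1)
    pos_f = np.concatenate([[0.0], np.cumsum(haldane_cM(r_f))])
    pos_m = np.concatenate([[0.0], np.cumsum(haldane_cM(r_m))])
    return pd.DataFrame(
        {
            "marker": order.markers,
            "lg": lg,
            "female_cM": pos_f,
            "male_cM": pos_m,
            "avg_cM": (pos_f + pos_m) / 2.0,
        }
    )


def summarize_map(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-LG map summary plus overall totals.

    Expects the concatenated ``map_positions`` output.  The female:male
    ratio is female length / male length (3 decimals; inf flagged where the
    male map has zero length); unique positions are counted on the female
    map.
    """
    if table.empty:
        raise ValueError("empty map table")
    per_lg = []
    for lg, sub in table.groupby("lg", sort=False):
        fl = float(sub["female_cM"].max())
        ml = float(sub["male_cM"].max())
        per_lg.append(
            {
                "lg": lg,
                "n_markers": len(sub),
                "male_length_cM": ml,
                "female_length_cM": fl,
                "female_male_ratio": round(fl / ml, 3) if ml > 0 else np.inf,
                "n_unique_positions": int(np.unique(np.round(sub["female_cM"], 6)).size),
            }
        )
    per_lg = pd.DataFrame(per_lg)
    tot_f = float(per_lg["female_length_cM"].sum())
    tot_m = float(per_lg["male_length_cM"].sum())
    overall = {
        "total_female_cM": tot_f,
        "total_male_cM": tot_m,
        "overall_ratio": round(tot_f / tot_m, 3) if tot_m > 0 else np.inf,
        "n_markers": int(per_lg["n_markers"].sum()),
        "n_lgs": int(per_lg.shape[0]),
    }
    return per_lg, overall
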