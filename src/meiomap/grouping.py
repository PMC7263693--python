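"""Two-point linkage and LOD-threshold linkage-group assignment.

Pairwise LOD scores are computed from phase-known gamete matrices and
summed over informative parents/families; linkage groups are the
single-linkage connected components of the thresholded LOD graph.  The
iterative splitting procedure raises the threshold within oversized groups
until a target chromosome count is reached, and leftover singletons are
attached by a best-vs-second-best LOD rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LodPairMatrix",
    "LinkageGrouping",
    "pairwise_lod",
    "assign_linkage_groups",
    "split_to_target",
    "join_singles",
]


@dataclass
class LodPairMatrix:
    """Symmetric marker x marker two-point LOD with companion r-hat and n."""

    markers: list[str]
    lod: np.ndarray  # NaN where no family scored the pair
    rfrac: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.markers)
        assert self.lod.shape == (m, m)

    def submatrix(self, idx: np.ndarray) -> "LodPairMatrix":
        return LodPairMatrix(
            [self.markers[i] for i in idx],
            self.lod[np.ix_(idx, idx)],
            self.rfrac[np.ix_(idx, idx)],
            self.n[np.ix_(idx, idx)],
        )


def _pair_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n scored, mismatches) for all marker pairs of one gamete matrix."""
    x = np.asarray(matrix, dtype=float)
    obs = ~np.isnan(x)
    a = np.where(obs, x, 0.0)  # indicator of origin 1
    b = np.where(obs, 1.0 - x, 0.0)  # indicator of origin 0
    mism = a @ b.T + b @ a.T
    n = obs.astype(float) @ obs.T.astype(float)
    return n, mism


def _lod_from_counts(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD = n log10 2 + k log10 r + (n-k) log10 (1-r) at r = min(k/n, .5)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.minimum(np.where(n > 0, k / n, np.nan), 0.5)
        t1 = np.where(k > 0, k * np.log10(np.where(r > 0, r, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log10(1.0 - np.where(r < 1, r, 0.0)), 0.0)
        lod = n * np.log10(2.0) + t1 + t2
    return np.where(n > 0, lod, np.nan)


def pairwise_lod(gamete_matrices: list[np.ndarray], markers: list[str] | None = None) -> LodPairMatrix:
    """Summed two-point LOD over informative parents/families.

    Each matrix is markers x meioses with entries 0/1/NaN.  The recombinant
    count for a pair is folded (k = min(mismatch, n - mismatch)), i.e. the
    likelihood is maximized over the unknown inter-marker phase.
    """
    if not gamete_matrices:
        raise ValueError("need at least one gamete matrix")
    m = gamete_matrices[0].shape[0]
    if m < 2:
        raise ValueError("need >= 2 markers")
    if markers is None:
        markers = [f"m{i}" for i in range(m)]
    lod_sum = np.zeros((m, m))
    n_sum = np.zeros((m, m))
    k_sum = np.zeros((m, m))
    any_scored = np.zeros((m, m), dtype=bool)
    for mat in gamete_matrices:
        if mat.shape[0] != m:
            raise ValueError("gamete matrices disagree on marker count")
        n, mism = _pair_counts(mat)
        k = np.minimum(mism, n - mism)
        scored = n > 0
        lod = _lod_from_counts(k, n)
        lod_sum += np.where(scored, lod, 0.0)
        n_sum += np.where(scored, n, 0.0)
        k_sum += np.where(scored, k, 0.0)
        any_scored |= scored
    with np.errstate(invalid="ignore"):
        rfrac = np.minimum(np.where(n_sum > 0, k_sum / n_sum, np.nan), 0.5)
    lod_sum[~any_scored] = np.nan
    np.fill_diagonal(lod_sum, np.nan)
    return LodPairMatrix(list(markers), lod_sum, rfrac, n_sum.astype(int))


@dataclass
class LinkageGrouping:
    """Marker -> LG assignment; unassigned markers are singletons (None)."""

    markers: list[str]
    labels: list[str | None]
    audit: list[dict] = field(default_factory=list)

    @property
    def assignment(self) -> pd.Series:
        return pd.Series(self.labels, index=self.markers, dtype=object)

    @property
    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            if lab is not None:
                out.setdefault(lab, []).append(i)
        return out

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> pd.Series:
        g = self.groups
        return pd.Series({k: len(v) for k, v in g.items()}).sort_values(ascending=False)


def _components(lod: np.ndarray, threshold: float) -> np.ndarray:
    adj = np.nan_to_num(lod, nan=-np.inf) >= threshold
    n, comp = connected_components(csr_matrix(adj), directed=False)
    return comp


def _relabel(markers: list[str], comp: np.ndarray, min_size: int, prefix: str = "LG") -> list[str | None]:
    sizes = np.bincount(comp)
    order = sorted(
        (c for c in range(sizes.size) if sizes[c] >= min_size),
        key=lambda c: (-sizes[c], int(np.flatnonzero(comp == c)[0])),
    )
    label_of = {c: f"{prefix}{i + 1}" for i, c in enumerate(order)}
    return [label_of.get(c) for c in comp]


def assign_linkage_groups(
    lods: LodPairMatrix, lod_threshold: float, min_size: int = 50
) -> LinkageGrouping:
    """Single-linkage components of the LOD >= threshold graph.

    Components smaller than ``min_size`` dissolve into singletons.  Labels
    are assigned by decreasing size (ties by first marker index), which
    makes them stable across reruns.
    """
    if lod_threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not lods.markers:
        return LinkageGrouping([], [])
    comp = _components(lods.lod, lod_threshold)
    labels = _relabel(lods.markers, comp, min_size)
    audit = [{"action": "assign", "threshold": lod_threshold}]
    return LinkageGrouping(list(lods.markers), labels, audit)


def split_to_target(
    grouping: LinkageGrouping,
    lods: LodPairMatrix,
    target_n: int = 42,
    threshold_range: tuple[float, float] = (8.0, 60.0),
    min_size: int = 50,
) -> LinkageGrouping:
    """Iteratively split the largest LGs at the maximum workable threshold.

    For the largest LG, components are recomputed within the group at every
    integer threshold in ``threshold_range``; the split at the *maximum*
    threshold yielding >= 2 components each with more than ``min_size``
    markers is adopted.  Stops at ``target_n`` LGs or when nothing is
    splittable (then returns the best grouping with a warning).
    """
    labels = list(grouping.labels)
    audit = list(grouping.audit)
    thresholds = np.arange(np.ceil(threshold_range[0]), np.floor(threshold_range[1]) + 1)
    unsplittable: set[str] = set()
    while True:
        groups = LinkageGrouping(grouping.markers, labels).groups
        if len(groups) >= target_n:
            break
        candidates = sorted(
            ((lab, idx) for lab, idx in groups.items() if lab not in unsplittable),
            key=lambda t: (-len(t[1]), t[0]),
        )
        split_done = False
        for lab, idx in candidates:
            idx = np.asarray(idx)
            sub = lods.lod[np.ix_(idx, idx)]
            best = None
            for t in thresholds:
                comp = _components(sub, float(t))
                big = np.flatnonzero(np.bincount(comp) > min_size)
                if big.size >= 2:
                    best = (float(t), comp, big)
            if best is None:
                unsplittable.add(lab)
                continue
            t, comp, big = best
            # components > min_size become LGs; the rest become singletons
            for j, c in enumerate(big):
                new_lab = lab if j == 0 else f"{lab}.{j}"
                for i in idx[comp == c]:
                    labels[i] = new_lab
            for i in idx[~np.isin(comp, big)]:
                labels[i] = None
            audit.append({"action": "split", "lg": lab, "threshold": t, "n_new": int(big.size)})
            split_done = True
            break
        if not split_done:
            warnings.warn(
                f"target of {target_n} LGs unreachable; stopping at "
                f"{len(LinkageGrouping(grouping.markers, labels).groups)}",
                stacklevel=2,
            )
            break
    return LinkageGrouping(grouping.markers, labels, audit)


def join_singles(
    grouping: LinkageGrouping,
    lods: LodPairMatrix,
    lod_join: float = 10.0,
    min_lod_diff: float = 5.0,
) -> LinkageGrouping:
    """Attach singletons whose best-LG LOD dominates the second best.

    Joins are applied simultaneously per round and rounds repeat to a
    fixpoint, so the result is independent of scan order.
    """
    labels = list(grouping.labels)
    audit = list(grouping.audit)
    while True:
        groups = LinkageGrouping(grouping.markers, labels).groups
        if not groups:
            break
        singles = [i for i, lab in enumerate(labels) if lab is None]
        joins: list[tuple[int, str, float]] = []
        for i in singles:
            best_lab, best, second = None, -np.inf, -np.inf
            for lab, idx in groups.items():
                vals = lods.lod[i, idx]
                affinity = np.nanmax(vals) if np.any(~np.isnan(vals)) else -np.inf
                if affinity > best:
                    best_lab, best, second = lab, affinity, best
                elif affinity > second:
                    second = affinity
            if second == -np.inf:
                second = 0.0
            if best_lab is not None and best >= lod_join and best - second >= min_lod_diff:
                joins.append((i, best_lab, best))
        if not joins:
            break
        for i, lab, lod in joins:
            labels[i] = lab
            audit.append({"action": "join", "marker": grouping.markers[i], "lg": lab, "lod": float(lod)})
    return LinkageGrouping(list(grouping.markers), labels, audit)
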