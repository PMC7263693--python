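"""Single-QTL genome scans with permutation significance and PVE.

The scan follows the Haley-Knott tradition: genotype probabilities are
computed at markers and 1-cM pseudomarkers from flanking phase-known
calls (independent maternal and paternal chains, Haldane transitions),
and at each position the trait is regressed on the expected additive and
dominance scores.  Normal traits optionally include a kinship random
effect (one null-model variance-component fit, per-position GLS in the
eigenspace of K); binary traits use per-position logistic regression.
Significance comes from trait permutations; the proportion of variance
explained is PVE = 1 - 10^(-2 LOD / n).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .simulate import MISSING, FamilyDataset

__all__ = [
    "GenoProbGrid",
    "ScanResult",
    "QtlPeak",
    "insert_pseudomarkers",
    "calc_genoprob",
    "grid_from_family",
    "calc_kinship",
    "scan_normal",
    "scan_binary",
    "find_peaks_ci",
    "permutation_pvalues",
    "pve",
]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def insert_pseudomarkers(marker_positions: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Union of marker positions and a regular cM grid at ``step``.

    Positions closer than 1e-6 cM are deduplicated; a step larger than the
    LG leaves the marker positions unchanged.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pos = np.sort(np.asarray(marker_positions, dtype=float))
    grid = np.arange(pos[0], pos[-1], step)
    merged = np.sort(np.concatenate([pos, grid]))
    keep = np.concatenate([[True], np.diff(merged) > 1e-6])
    return merged[keep]


@dataclass
class GenoProbGrid:
    """Genotype probabilities at evaluation positions for one or more LGs.

    ``pm`` / ``pp`` are (n_individuals, n_positions) probabilities that the
    maternal / paternal allele at a position is haplotype 1.  The three F2
    genotype-class probabilities follow by independence of the chains.
    """

    positions: np.ndarray
    lgs: np.ndarray
    pm: np.ndarray
    pp: np.ndarray
    individuals: list[str]

    @property
    def n_individuals(self) -> int:
        return self.pm.shape[0]

    def class_probs(self) -> np.ndarray:
        """(n_ind, n_pos, 3) probabilities of genotype classes 0/1/2."""
        p0 = (1 - self.pm) * (1 - self.pp)
        p2 = self.pm * self.pp
        return np.stack([p0, 1 - p0 - p2, p2], axis=-1)

    def lg_names(self) -> list[str]:
        return list(dict.fromkeys(self.lgs))


def _chain_probs(
    obs: np.ndarray, marker_pos: np.ndarray, eval_pos: np.ndarray
) -> np.ndarray:
    """P(origin = 1) along one parental chain for every individual.

    ``obs`` is (n_ind, n_markers) with 0/1/MISSING.  At an informative
    marker the probability is degenerate on the observed origin; elsewhere
    it is conditioned on the flanking informative markers via Haldane
    recombination fractions, falling back to one flank or the uniform
    prior where flanks are missing.
    """
    n_ind = obs.shape[0]
    out = np.full((n_ind, eval_pos.size), 0.5)
    for i in range(n_ind):
        inf = np.flatnonzero(obs[i] != MISSING)
        if inf.size == 0:
            continue
        ipos = marker_pos[inf]
        g = obs[i, inf].astype(float)
        ri = np.searchsorted(ipos, eval_pos, side="right")
        li = ri - 1
        has_l = li >= 0
        has_r = ri < ipos.size
        dl = np.where(has_l, eval_pos - ipos[np.clip(li, 0, None)], np.inf)
        dr = np.where(has_r, ipos[np.clip(ri, None, ipos.size - 1)] - eval_pos, np.inf)
        rl = haldane_r(np.where(np.isfinite(dl), dl, 0.0))
        rr = haldane_r(np.where(np.isfinite(dr), dr, 0.0))
        gl = g[np.clip(li, 0, None)]
        gr = g[np.clip(ri, None, ipos.size - 1)]
        # transition weights toward origin 1 / origin 0 from each flank
        tl1 = np.where(gl == 1, 1 - rl, rl)
        tr1 = np.where(gr == 1, 1 - rr, rr)
        tl0 = 1 - tl1
        tr0 = 1 - tr1
        p = np.full(eval_pos.size, 0.5)
        both = has_l & has_r
        with np.errstate(invalid="ignore"):
            pb = tl1 * tr1 / (tl1 * tr1 + tl0 * tr0)
        p[both] = pb[both]
        only_l = has_l & ~has_r
        p[only_l] = tl1[only_l]
        only_r = has_r & ~has_l
        p[only_r] = tr1[only_r]
        out[i] = p
    return out


def calc_genoprob(
    mat_obs: np.ndarray,
    pat_obs: np.ndarray,
    marker_pos: np.ndarray,
    eval_pos: np.ndarray,
    lg: str = "LG1",
    individuals: list[str] | None = None,
) -> GenoProbGrid:
    """Genotype probabilities for one LG from phased parental-origin calls."""
    marker_pos = np.asarray(marker_pos, dtype=float)
    eval_pos = np.asarray(eval_pos, dtype=float)
    if mat_obs.shape != pat_obs.shape or mat_obs.shape[1] != marker_pos.size:
        raise ValueError("origin matrices must be n_ind x n_markers")
    if individuals is None:
        individuals = [f"ind{i}" for i in range(mat_obs.shape[0])]
    if np.all(mat_obs == MISSING) and np.all(pat_obs == MISSING):
        warnings.warn(f"{lg}: no informative markers; uniform prior", stacklevel=2)
    pm = _chain_probs(mat_obs, marker_pos, eval_pos)
    pp = _chain_probs(pat_obs, marker_pos, eval_pos)
    return GenoProbGrid(
        positions=eval_pos,
        lgs=np.array([lg] * eval_pos.size),
        pm=pm,
        pp=pp,
        individuals=list(individuals),
    )


def grid_from_family(family: FamilyDataset, step: float = 1.0) -> GenoProbGrid:
    """Marker + pseudomarker genotype probabilities for a whole family."""
    grids = []
    for c in family.genome.chromosomes:
        sel = (family.markers["chrom"] == c.name).to_numpy()
        pos = family.markers.loc[sel, "pos_cM"].to_numpy()
        eval_pos = insert_pseudomarkers(pos, step)
        grids.append(
            calc_genoprob(
                family.mat_origin[:, sel],
                family.pat_origin[:, sel],
                pos,
                eval_pos,
                lg=c.name,
                individuals=family.offspring_ids,
            )
        )
    return GenoProbGrid(
        positions=np.concatenate([g.positions for g in grids]),
        lgs=np.concatenate([g.lgs for g in grids]),
        pm=np.hstack([g.pm for g in grids]),
        pp=np.hstack([g.pp for g in grids]),
        individuals=grids[0].individuals,
    )


def _thin_indices(grid: GenoProbGrid, thin_step: float) -> np.ndarray:
    """Indices of a per-LG thinned position grid (nearest to k*step)."""
    keep: list[int] = []
    for lg in grid.lg_names():
        idx = np.flatnonzero(grid.lgs == lg)
        pos = grid.positions[idx]
        targets = np.arange(pos.min(), pos.max() + 1e-9, thin_step)
        sel = {int(idx[np.argmin(np.abs(pos - t))]) for t in targets}
        keep.extend(sorted(sel))
    return np.asarray(sorted(keep))


def calc_kinship(grid: GenoProbGrid, thin_step: float = 3.0) -> np.ndarray:
    """Expected genotype-class identity between individuals.

    K(i, j) averages, over a thinned (default 3-cM) position grid, the
    probability that i and j carry the same genotype class; the matrix is
    normalized so self-kinship equals 1.
    """
    if grid.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    sel = _thin_indices(grid, thin_step)
    probs = grid.class_probs()[:, sel, :]
    s = np.einsum("itc,jtc->ij", probs, probs) / sel.size
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


@dataclass
class ScanResult:
    """LOD curve over the evaluation grid for one trait/model."""

    positions: np.ndarray
    lgs: np.ndarray
    lod: np.ndarray
    model: str  # "normal" | "normal+kinship" | "binary"
    n: int
    additive: np.ndarray | None = None
    dominance: np.ndarray | None = None
    trait: str = "trait"


def _design(grid: GenoProbGrid) -> np.ndarray:
    """Per-position design matrices (n_pos, n_ind, 3): 1, additive, dominance.

    additive = P(class 2) - P(class 0), dominance = P(het).
    """
    probs = grid.class_probs()
    a = probs[..., 2] - probs[..., 0]
    d = probs[..., 1]
    n_ind, n_pos = a.shape
    X = np.empty((n_pos, n_ind, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = a.T
    X[:, :, 2] = d.T
    return X


def _batched_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RSS and coefficients of per-position least squares fits."""
    xtx = np.einsum("tnp,tnq->tpq", X, X)
    xty = np.einsum("tnp,n->tp", X, y)
    n_pos = X.shape[0]
    beta = np.empty((n_pos, X.shape[2]))
    for t in range(n_pos):
        try:
            beta[t] = np.linalg.solve(xtx[t], xty[t])
        except np.linalg.LinAlgError:
            beta[t], *_ = np.linalg.lstsq(xtx[t], xty[t], rcond=None)
    rss = float(y @ y) - np.einsum("tp,tp->t", beta, xty)
    return np.maximum(rss, 1e-300), beta


def _align_trait(grid: GenoProbGrid, trait: pd.Series | np.ndarray):
    if isinstance(trait, pd.Series):
        trait = trait.reindex(grid.individuals)
    y = np.asarray(trait, dtype=float)
    keep = np.isfinite(y)
    return y[keep], keep


def scan_normal(
    grid: GenoProbGrid,
    trait: pd.Series | np.ndarray,
    kinship: np.ndarray | None = None,
    trait_name: str = "trait",
) -> ScanResult:
    """Haley-Knott genome scan for a continuous trait.

    Without kinship: per-position OLS on the expected additive/dominance
    scores, LOD = (n/2) log10(RSS0 / RSS1).  With kinship: variance
    components are estimated once under the null by maximum likelihood in
    the eigenspace of K and reused for per-position GLS.
    """
    y, keep = _align_trait(grid, trait)
    n = y.size
    X = _design(grid)[:, keep, :]
    model = "normal"
    if kinship is not None:
        model = "normal+kinship"
        K = kinship[np.ix_(keep, keep)]
        evals, evecs = np.linalg.eigh(K)
        evals = np.maximum(evals, 0.0)
        yr = evecs.T @ y
        Xr = np.einsum("ij,tjp->tip", evecs.T, X)

        def negll(log_lam: float) -> float:
            lam = 10.0**log_lam
            w = lam * evals + 1.0
            b = np.sum(yr / w) / np.sum(1.0 / w)
            rss = np.sum((yr - b) ** 2 / w)
            return 0.5 * (n * np.log(rss / n) + np.sum(np.log(w)))

        res = minimize_scalar(negll, bounds=(-5.0, 5.0), method="bounded")
        lam = 10.0**res.x
        w = lam * evals + 1.0
        sw = np.sqrt(w)
        y = yr / sw
        X = Xr / sw[None, :, None]
    # null model: weighted intercept only
    x0 = X[0, :, 0]
    b0 = float(x0 @ y) / float(x0 @ x0)
    rss0 = float(np.sum((y - b0 * x0) ** 2))
    rss1, beta = _batched_ols(X, y)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
    lod = np.where(np.isfinite(lod), np.maximum(lod, 0.0), 0.0)
    return ScanResult(
        positions=grid.positions.copy(),
        lgs=grid.lgs.copy(),
        lod=lod,
        model=model,
        n=n,
        additive=beta[:, 1],
        dominance=beta[:, 2],
        trait=trait_name,
    )


def _logistic_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-8, 1 - 1e-8)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50
) -> tuple[float, np.ndarray]:
    """Log-likelihood and coefficients of a logistic fit by IRLS."""
    beta = np.zeros(X.shape[1])
    ll = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        xtwx = X.T @ (X * w[:, None])
        try:
            beta_new = np.linalg.solve(xtwx, X.T @ (w * z))
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(xtwx, X.T @ (w * z), rcond=None)
        ll_new = _logistic_ll(y, 1.0 / (1.0 + np.exp(-np.clip(X @ beta_new, -30, 30))))
        if ll_new < ll - 1e-9:
            break
        beta, ll_prev, ll = beta_new, ll, ll_new
        if abs(ll - ll_prev) < 1e-10:
            break
    return ll, beta


def scan_binary(
    grid: GenoProbGrid,
    trait: pd.Series | np.ndarray,
    trait_name: str = "trait",
) -> ScanResult:
    """Per-position logistic-regression scan for a 0/1 trait."""
    y, keep = _align_trait(grid, trait)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary trait must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both trait classes must be present")
    n = y.size
    X = _design(grid)[:, keep, :]
    pbar = y.mean()
    ll0 = _logistic_ll(y, np.full(n, pbar))
    n_pos = X.shape[0]
    lod = np.empty(n_pos)
    add = np.empty(n_pos)
    dom = np.empty(n_pos)
    for t in range(n_pos):
        ll1, beta = _irls_logistic(X[t], y)
        lod[t] = max((ll1 - ll0) / np.log(10.0), 0.0)
        add[t], dom[t] = beta[1], beta[2]
    return ScanResult(
        positions=grid.positions.copy(),
        lgs=grid.lgs.copy(),
        lod=lod,
        model="binary",
        n=n,
        additive=add,
        dominance=dom,
        trait=trait_name,
    )


@dataclass
class QtlPeak:
    """A LOD peak with credible interval, significance and effect sizes."""

    lg: str
    position: float
    lod: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    p_label: str = ""
    pve: float | None = None
    additive: float | None = None
    dominance: float | None = None
    merge_flag: bool = False  # CI touches an adjacent peak's CI


def _local_maxima(lod: np.ndarray) -> list[int]:
    """Indices of local maxima (first index of any plateau)."""
    idx = []
    m = lod.size
    for i in range(m):
        left = lod[i - 1] if i > 0 else -np.inf
        right = lod[i + 1] if i < m - 1 else -np.inf
        if lod[i] >= right and lod[i] > left:
            idx.append(i)
    return idx


def find_peaks_ci(
    scan: ScanResult,
    threshold: float = 3.0,
    peakdrop: float = 2.0,
    ci_prob: float = 0.95,
) -> list[QtlPeak]:
    """Peaks above ``threshold`` with Bayes-type credible intervals.

    Within each LG, local maxima are merged unless the intervening minimum
    drops at least ``peakdrop`` below the smaller maximum.  The credible
    interval is the smallest position set holding >= ``ci_prob`` of the
    normalized 10^LOD mass on the peak's territory (bounded by the deepest
    valleys separating it from neighbouring peaks).
    """
    peaks: list[QtlPeak] = []
    for lg in dict.fromkeys(scan.lgs):
        sel = np.flatnonzero(scan.lgs == lg)
        lod = scan.lod[sel]
        pos = scan.positions[sel]
        cand = [i for i in _local_maxima(lod) if lod[i] >= threshold]
        # merge peaks not separated by a deep enough valley
        merged = True
        while merged and len(cand) > 1:
            merged = False
            for a, b in zip(cand[:-1], cand[1:]):
                valley = lod[a : b + 1].min()
                if valley > min(lod[a], lod[b]) - peakdrop:
                    cand.remove(a if lod[a] <= lod[b] else b)
                    merged = True
                    break
        lg_peaks: list[QtlPeak] = []
        for k, i in enumerate(cand):
            lo_b = 0 if k == 0 else cand[k - 1] + int(np.argmin(lod[cand[k - 1] : i + 1]))
            hi_b = lod.size - 1 if k == len(cand) - 1 else i + int(np.argmin(lod[i : cand[k + 1] + 1]))
            terr = np.arange(lo_b, hi_b + 1)
            w = 10.0 ** (lod[terr] - lod[terr].max())
            # ties broken toward lower index so the interval stays anchored
            order = terr[np.lexsort((np.arange(terr.size), -lod[terr]))]
            wsort = 10.0 ** (lod[order] - lod[terr].max())
            csum = np.cumsum(wsort) / w.sum()
            take = order[: int(np.searchsorted(csum, ci_prob) + 1)]
            lg_peaks.append(
                QtlPeak(
                    lg=str(lg),
                    position=float(pos[i]),
                    lod=float(lod[i]),
                    ci_low=float(pos[take].min()),
                    ci_high=float(pos[take].max()),
                    additive=float(scan.additive[sel][i]) if scan.additive is not None else None,
                    dominance=float(scan.dominance[sel][i]) if scan.dominance is not None else None,
                    pve=pve(float(lod[i]), scan.n),
                )
            )
        for a, b in zip(lg_peaks[:-1], lg_peaks[1:]):
            if a.ci_high >= b.ci_low:
                a.merge_flag = b.merge_flag = True
        peaks.extend(lg_peaks)
    return peaks


def permutation_pvalues(
    scan_fn,
    trait: pd.Series | np.ndarray,
    peaks: list[QtlPeak],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[list[QtlPeak], float, np.ndarray]:
    """Permutation p-values for observed peaks and the genome-wide threshold.

    ``scan_fn`` maps a permuted trait vector to a ScanResult (same settings
    as the observed scan); trait values are shuffled across individuals,
    keeping genotypes fixed.  p = proportion of permuted genome-wide maxima
    >= the observed peak LOD, floored at 1/(n_perm + 1).
    """
    rng = rng or np.random.default_rng()
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation tail is unstable", stacklevel=2)
    values = trait.to_numpy() if isinstance(trait, pd.Series) else np.asarray(trait)
    index = trait.index if isinstance(trait, pd.Series) else None
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(values)
        y = pd.Series(perm, index=index) if index is not None else perm
        maxima[b] = float(np.max(scan_fn(y).lod))
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    floor = 1.0 / (n_perm + 1)
    for pk in peaks:
        count = int(np.sum(maxima >= pk.lod))
        if count == 0:
            pk.p_value = floor
            pk.p_label = f"< {floor:.4g}"
        else:
            pk.p_value = count / n_perm
            pk.p_label = f"{pk.p_value:.4g}"
    return peaks, threshold, maxima


def pve(lod: float, n: int) -> float:
    """Proportion of phenotypic variance explained by a QTL.

    PVE = 1 - 10^(-2 LOD / n) for a peak of the given LOD score in a
    sample of n phenotyped individuals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lod < 0:
        raise ValueError("lod must be >= 0")
    return 1.0 - 10.0 ** (-2.0 * lod / n)
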