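"""Shared fixtures and independent oracles for the test suite."""
from itertools import product
from math import exp, factorial

import numpy as np
import pytest

import meiomap as mm


def make_chrom(
    L=100.0, male=None, cen=50.0, frac=0.1, name="c1", bp=50_000_000
) -> mm.ChromosomeModel:
    return mm.ChromosomeModel(name, L, L if male is None else male, bp, cen, frac)


def y_enumeration_oracle(d_morgans: float, kmax: int = 9) -> float:
    """Exhaustive half-tetrad heterozygosity oracle.

    Enumerates Poisson crossover counts k <= kmax in the centromere-marker
    interval and all 4^k non-sister strand assignments on the bundle; the
    retained pair is one homolog's sister chromatids.  The truncated tail
    is closed at the classical 2/3 limit.
    """
    mean = 2.0 * d_morgans
    y = 0.0
    mass = 0.0
    for k in range(kmax + 1):
        pk = exp(-mean) * mean**k / factorial(k)
        mass += pk
        if k == 0:
            continue
        het = 0
        for choice in product(range(4), repeat=k):
            # marker-side origins of the four chromatids; each crossover
            # (processed from centromere to marker) joins one strand of each
            # local origin class
            origins = [0, 0, 1, 1]
            for c in choice:
                zeros = [r for r in range(4) if origins[r] == 0]
                ones = [r for r in range(4) if origins[r] == 1]
                a, b = zeros[c // 2], ones[c % 2]
                origins[a], origins[b] = origins[b], origins[a]
            het += origins[0] != origins[1]
        y += pk * het / 4**k
    return y + (1.0 - mass) * (2.0 / 3.0)


def two_point_lod_oracle(k: int, n: int) -> float:
    """Two-point LOD by numeric likelihood maximization over r in (0, 0.5]."""
    from scipy.optimize import minimize_scalar

    def negll(r):
        r = min(max(r, 1e-12), 0.5)
        return -(k * np.log10(r) + (n - k) * np.log10(1 - r))

    res = minimize_scalar(
        negll, bounds=(1e-12, 0.5), method="bounded", options={"xatol": 1e-13}
    )
    ll_max = -res.fun
    ll_null = k * np.log10(0.5) + (n - k) * np.log10(0.5)
    return max(ll_max - ll_null, 0.0)


def brute_force_normal_scan(grid: mm.GenoProbGrid, y: np.ndarray) -> np.ndarray:
    """Per-position OLS LOD by independent lstsq fits (scan_normal oracle)."""
    probs = grid.class_probs()
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    lods = np.empty(grid.positions.size)
    for t in range(grid.positions.size):
        X = np.column_stack(
            [np.ones(n), probs[:, t, 2] - probs[:, t, 0], probs[:, t, 1]]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(np.sum((y - X @ beta) ** 2))
        lods[t] = (n / 2.0) * np.log10(rss0 / rss1)
    return lods


@pytest.fixture(scope="session")
def small_genome() -> mm.GenomeModel:
    chroms = [make_chrom(name="chrA"), make_chrom(name="chrB", cen=0.0)]
    return mm.GenomeModel.regular(chroms, 30)


@pytest.fixture(scope="session")
def small_family(small_genome) -> mm.FamilyDataset:
    mother, father = mm.intercross_founders(small_genome)
    rng = np.random.default_rng(123)
    return mm.simulate_diploid_family(
        small_genome, mother, father, 120, rng, family_id="FAM"
    )
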