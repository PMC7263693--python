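"""Meiosis, family, half-tetrad, and phenotype simulation.

The crossover model is a no-interference (Poisson) process on the
four-chromatid bundle: the number of crossovers is Poisson with mean
``2 * map length in Morgans``, each crossover exchanges the distal segments
of one maternal- and one paternal-homolog chromatid chosen uniformly
(no chromatid interference), and a gamete is one uniformly chosen chromatid.
This yields Haldane's map function for gametes, r = (1 - exp(-2d)) / 2.

Male meiosis mimics salmonid heterochiasmy: crossovers are drawn with
intensity ``male_length`` but positions falling outside the telomeric
windows (``male_telomere_fraction`` of each chromosome end) are discarded,
so male recombination is suppressed except near telomeres and the emergent
male map length is ``2 * fraction * male_length``.

Gynogenetic (half-tetrad) offspring retain the two sister chromatids of one
secondary oocyte (second-polar-body retention); heterozygosity at a marker
then reveals a crossover between that marker and the centromere.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ChromosomeModel, GenomeModel, TraitModel

__all__ = [
    "simulate_meiosis",
    "simulate_gametes",
    "simulate_diploid_family",
    "simulate_half_tetrad_family",
    "simulate_phenotypes",
    "intercross_founders",
    "FamilyDataset",
    "HalfTetradDataset",
]

MISSING = -9  # genotype / origin sentinel in integer-coded arrays

GENO_CODES = {0: "A", 1: "H", 2: "B", MISSING: "NA"}


def _crossover_positions(
    chromosome: ChromosomeModel,
    sex: str,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> np.ndarray:
    """Accepted crossover positions (cM, female map) for one bundle."""
    L = chromosome.female_length
    if sex == "female":
        mean = 2.0 * L / 100.0
    elif sex == "male":
        mean = 2.0 * chromosome.male_length / 100.0
    else:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if L <= 0:
        return np.empty(0)
    k = int(rng.poisson(mean))
    if obligate_chiasma:
        k += 1
    xs = rng.uniform(0.0, L, size=k)
    if sex == "male":
        w = chromosome.male_telomere_fraction * L
        xs = xs[(xs < w) | (xs > L - w)]
    return np.sort(xs)


def _bundle(
    chromosome: ChromosomeModel,
    positions: np.ndarray,
    sex: str,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the four-chromatid bundle at the given sampling positions.

    Returns ``(origins, crossovers)`` where origins is (4, n_positions) with
    values 0/1 (parental haplotype of origin) and rows 0-1 / 2-3 are the
    sister-chromatid pairs of the two homologs.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty marker list")
    xs = _crossover_positions(chromosome, sex, rng, obligate_chiasma)
    origins = np.zeros((4, positions.size), dtype=np.int8)
    origins[2:, :] = 1
    # process crossovers left to right; each joins one strand of each local
    # parental-origin class (homologous duplexes pair by origin, so every
    # exchange is between opposite-origin segments)
    cur = np.array([0, 0, 1, 1], dtype=np.int8)  # origin just left of x
    for x in xs:
        zeros = np.flatnonzero(cur == 0)
        ones = np.flatnonzero(cur == 1)
        i = int(zeros[rng.integers(2)])
        j = int(ones[rng.integers(2)])
        mask = positions > x
        tmp = origins[i, mask].copy()
        origins[i, mask] = origins[j, mask]
        origins[j, mask] = tmp
        cur[i], cur[j] = cur[j], cur[i]
    return origins, xs


def simulate_meiosis(
    chromosome: ChromosomeModel,
    positions: np.ndarray,
    parent_phase: np.ndarray,
    sex: str,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One meiosis: returns (gamete alleles, gamete origins, crossovers).

    ``parent_phase`` is a (2, n_markers) array of allele codes, one row per
    parental haplotype; the gamete is a mosaic of the two rows.
    """
    parent_phase = np.asarray(parent_phase)
    positions = np.asarray(positions, dtype=float)
    if parent_phase.shape != (2, positions.size):
        raise ValueError("parent_phase must cover all markers (shape (2, n))")
    origins, xs = _bundle(chromosome, positions, sex, rng, obligate_chiasma)
    gamete = origins[int(rng.integers(4))]
    alleles = parent_phase[gamete, np.arange(positions.size)]
    return alleles, gamete, xs


def simulate_gametes(
    chromosome: ChromosomeModel,
    positions: np.ndarray,
    sex: str,
    n: int,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> np.ndarray:
    """Parental-origin codes for ``n`` independent gametes, shape (n, M)."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty marker list")
    out = np.empty((n, positions.size), dtype=np.int8)
    for i in range(n):
        origins, _ = _bundle(chromosome, positions, sex, rng, obligate_chiasma)
        out[i] = origins[int(rng.integers(4))]
    return out


def intercross_founders(genome: GenomeModel) -> tuple[dict, dict]:
    """Fully informative founders: both parents heterozygous 0|1 everywhere."""
    mother, father = {}, {}
    for c in genome.chromosomes:
        m = genome.n_markers(c.name)
        phase = np.vstack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])
        mother[c.name] = phase
        father[c.name] = phase.copy()
    return mother, father


@dataclass
class FamilyDataset:
    """Phase-known offspring of one cross, with simulated noise and truth.

    ``mat_origin`` / ``pat_origin`` are (n_offspring, n_markers) int8 arrays
    of parental-origin codes (0/1, MISSING for dropped calls) *after* error
    and missingness; the ``*_truth`` arrays are the clean record.
    """

    family_id: str
    genome: GenomeModel
    markers: pd.DataFrame  # marker, chrom, pos_cM, pos_bp
    mother_phase: dict[str, np.ndarray]
    father_phase: dict[str, np.ndarray]
    mat_origin: np.ndarray
    pat_origin: np.ndarray
    mat_truth: np.ndarray
    pat_truth: np.ndarray
    crossovers: dict = field(default_factory=dict)  # (parent, chrom) -> list of arrays
    error_mask: np.ndarray | None = None  # (2, n_off, M) flips applied (mat, pat)

    @property
    def n_offspring(self) -> int:
        return self.mat_origin.shape[0]

    @property
    def offspring_ids(self) -> list[str]:
        return [f"{self.family_id}_o{i:03d}" for i in range(self.n_offspring)]

    def _phase_concat(self, which: str) -> np.ndarray:
        src = self.mother_phase if which == "mother" else self.father_phase
        return np.hstack([src[c.name] for c in self.genome.chromosomes])

    def genotypes(self, coded: bool = False) -> pd.DataFrame:
        """Offspring genotypes as allele-1 dosage (0/1/2, MISSING), markers x inds.

        With ``coded=True`` values are the A/H/B/NA strings.
        """
        mp = self._phase_concat("mother")
        fp = self._phase_concat("father")
        m = self.markers.shape[0]
        cols = np.arange(m)
        out = np.full((self.n_offspring, m), MISSING, dtype=np.int8)
        ok = (self.mat_origin != MISSING) & (self.pat_origin != MISSING)
        for i in range(self.n_offspring):
            idx = ok[i]
            a_m = mp[self.mat_origin[i, idx], cols[idx]]
            a_f = fp[self.pat_origin[i, idx], cols[idx]]
            out[i, idx] = a_m + a_f
        df = pd.DataFrame(
            out.T, index=self.markers["marker"].to_numpy(), columns=self.offspring_ids
        )
        if coded:
            df = df.replace(GENO_CODES).infer_objects(copy=False)
        return df

    def gamete_matrix(self, parent: str = "mother", chrom: str | None = None) -> np.ndarray:
        """Markers x meioses parental-origin matrix (float, NaN = missing)."""
        src = self.mat_origin if parent == "mother" else self.pat_origin
        arr = src.T.astype(float)
        arr[arr == MISSING] = np.nan
        if chrom is not None:
            sel = (self.markers["chrom"] == chrom).to_numpy()
            arr = arr[sel]
        return arr


def simulate_diploid_family(
    genome: GenomeModel,
    mother_phase: dict[str, np.ndarray],
    father_phase: dict[str, np.ndarray],
    n_offspring: int,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    family_id: str = "F1",
    obligate_chiasma: bool = False,
) -> FamilyDataset:
    """Simulate a full-sib family: one maternal + one paternal meiosis each."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    markers = genome.marker_table()
    total = markers.shape[0]
    mat = np.empty((n_offspring, total), dtype=np.int8)
    pat = np.empty((n_offspring, total), dtype=np.int8)
    crossovers: dict = {}
    col = 0
    for c in genome.chromosomes:
        pos = genome.marker_positions[c.name]
        m = pos.size
        for i in range(n_offspring):
            _, g, xs = simulate_meiosis(
                c, pos, mother_phase[c.name], "female", rng, obligate_chiasma
            )
            mat[i, col : col + m] = g
            crossovers.setdefault(("mother", c.name), []).append(xs)
            _, g, xs = simulate_meiosis(
                c, pos, father_phase[c.name], "male", rng, obligate_chiasma
            )
            pat[i, col : col + m] = g
            crossovers.setdefault(("father", c.name), []).append(xs)
        col += m
    mat_truth, pat_truth = mat.copy(), pat.copy()
    err = None
    if error_rate > 0:
        err = rng.random((2, n_offspring, total)) < error_rate
        mat ^= err[0].astype(np.int8)
        pat ^= err[1].astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((2, n_offspring, total)) < missing_rate
        mat[miss[0]] = MISSING
        pat[miss[1]] = MISSING
    return FamilyDataset(
        family_id=family_id,
        genome=genome,
        markers=markers,
        mother_phase=mother_phase,
        father_phase=father_phase,
        mat_origin=mat,
        pat_origin=pat,
        mat_truth=mat_truth,
        pat_truth=pat_truth,
        crossovers=crossovers,
        error_mask=err,
    )


@dataclass
class HalfTetradDataset:
    """Gynogenetic-diploid offspring: zygosity states per marker.

    ``states`` is (n_offspring, n_markers) int8 with the dosage of the
    mother's haplotype-1 allele: 0 = homozygous hap0, 2 = homozygous hap1,
    1 = heterozygous, MISSING where not scored.
    """

    genome: GenomeModel
    markers: pd.DataFrame
    mother_phase: dict[str, np.ndarray]
    states: np.ndarray

    @property
    def n_offspring(self) -> int:
        return self.states.shape[0]

    def chrom_slice(self, chrom: str) -> np.ndarray:
        sel = (self.markers["chrom"] == chrom).to_numpy()
        return self.states[:, sel]


def simulate_half_tetrad_family(
    genome: GenomeModel,
    mother_phase: dict[str, np.ndarray],
    n_offspring: int,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> HalfTetradDataset:
    """Gynogenesis by second-polar-body retention.

    Each offspring keeps the two *sister* chromatids of one secondary
    oocyte, i.e. the pair sharing a centromere.  A marker is heterozygous
    iff an odd crossover count between marker and centromere put different
    parental alleles on the retained sisters.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    markers = genome.marker_table()
    total = markers.shape[0]
    states = np.empty((n_offspring, total), dtype=np.int8)
    col = 0
    for c in genome.chromosomes:
        pos = genome.marker_positions[c.name]
        m = pos.size
        # evaluate chromatid origins at markers plus the centromere itself
        aug = np.append(pos, c.centromere_pos)
        for i in range(n_offspring):
            origins, _ = _bundle(c, aug, "female", rng, obligate_chiasma)
            homolog = int(rng.integers(2))
            sisters = origins[origins[:, -1] == homolog]  # the retained pair
            states[i, col : col + m] = sisters[0, :-1] + sisters[1, :-1]
        col += m
    return HalfTetradDataset(
        genome=genome, markers=markers, mother_phase=mother_phase, states=states
    )


def _qtl_genotypes(trait: TraitModel, family: FamilyDataset) -> np.ndarray:
    """True genotype class (0/1/2) of each offspring at each QTL."""
    trait.validate_against(family.genome)
    markers = family.markers
    classes = np.empty((family.n_offspring, len(trait.qtl)), dtype=np.int8)
    for k, q in enumerate(trait.qtl):
        on_chrom = markers.index[markers["chrom"] == q.chromosome]
        if on_chrom.empty:
            raise ValueError(f"no markers on {q.chromosome} to anchor QTL")
        pos = markers.loc[on_chrom, "pos_cM"].to_numpy()
        j = on_chrom[np.argmin(np.abs(pos - q.position))]
        classes[:, k] = family.mat_truth[:, j] + family.pat_truth[:, j]
    return classes


def simulate_phenotypes(
    trait: TraitModel,
    family: FamilyDataset,
    rng: np.random.Generator,
) -> pd.Series:
    """Trait values for the offspring of ``family`` under ``trait``.

    Normal traits: sum of QTL effects plus N(0, residual_sd).  Binary
    traits: the same liability thresholded at ``binary_link``.
    """
    classes = _qtl_genotypes(trait, family)
    score = np.zeros(family.n_offspring)
    for k, q in enumerate(trait.qtl):
        effect = np.select(
            [classes[:, k] == 0, classes[:, k] == 1, classes[:, k] == 2],
            [-q.additive, q.dominance, q.additive],
        )
        score = score + effect
    noise = rng.normal(0.0, trait.residual_sd, size=score.size) if trait.residual_sd > 0 else 0.0
    liability = score + noise
    if trait.trait_type == "binary":
        if np.ptp(liability) == 0:
            raise ValueError("degenerate binary trait: all liabilities identical")
        values = (liability > trait.binary_link).astype(float)
    else:
        values = liability
    return pd.Series(values, index=family.offspring_ids, name="trait")
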