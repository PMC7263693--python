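"""Truth models for simulated genomes and traits.

A :class:`GenomeModel` describes a set of chromosomes with sex-specific
genetic lengths, a centromere position, and marker positions on the female
map.  It is the ground-truth record against which every downstream stage
(grouping, ordering, centromere mapping, QTL scanning) can be validated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChromosomeModel", "GenomeModel", "Qtl", "TraitModel"]


@dataclass(frozen=True)
class ChromosomeModel:
    """One simulated chromosome.

    Parameters
    ----------
    name:
        Chromosome / linkage-group label.
    female_length:
        Female genetic map length in centimorgans.  Marker and centromere
        coordinates are expressed on this map.
    male_length:
        Intensity of the male crossover process in centimorgans.  Because
        male crossovers are restricted to telomeric windows (see
        ``male_telomere_fraction``) the *emergent* male map length is
        ``2 * male_telomere_fraction * male_length``.
    physical_length:
        Physical size in base pairs.
    centromere_pos:
        Centromere position in cM on the female map.
    male_telomere_fraction:
        Fraction of each chromosome end (of the female map) in which male
        crossovers are permitted; 0 suppresses male recombination entirely,
        0.5 permits it everywhere.
    """

    name: str
    female_length: float
    male_length: float
    physical_length: int
    centromere_pos: float
    male_telomere_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.female_length < 0:
            raise ValueError(f"{self.name}: female_length must be >= 0")
        if self.male_length < 0:
            raise ValueError(f"{self.name}: male_length must be >= 0")
        if not 0 <= self.centromere_pos <= self.female_length:
            raise ValueError(
                f"{self.name}: centromere_pos must lie in [0, female_length]"
            )
        if not 0 <= self.male_telomere_fraction <= 0.5:
            raise ValueError(
                f"{self.name}: male_telomere_fraction must lie in [0, 0.5]"
            )


@dataclass
class GenomeModel:
    """A set of chromosomes plus marker positions on the female map.

    ``marker_positions`` maps chromosome name -> sorted array of cM positions;
    ``marker_bp`` holds the matching physical coordinates.
    """

    chromosomes: list[ChromosomeModel]
    marker_positions: dict[str, np.ndarray] = field(default_factory=dict)
    marker_bp: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        for name, pos in self.marker_positions.items():
            chrom = by_name[name]
            pos = np.asarray(pos, dtype=float)
            if pos.size and (pos.min() < 0 or pos.max() > chrom.female_length):
                raise ValueError(f"{name}: marker positions outside [0, length]")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"{name}: marker positions must be sorted")
            self.marker_positions[name] = pos
            if name in self.marker_bp:
                bp = np.asarray(self.marker_bp[name], dtype=float)
                if bp.shape != pos.shape:
                    raise ValueError(f"{name}: bp/cM length mismatch")
                # physical order must agree with genetic order where it changes
                inc = np.diff(pos) > 0
                if np.any(np.diff(bp)[inc] <= 0):
                    raise ValueError(f"{name}: physical coords not increasing")

    @property
    def chromosome_by_name(self) -> dict[str, ChromosomeModel]:
        return {c.name: c for c in self.chromosomes}

    def n_markers(self, name: str) -> int:
        return int(self.marker_positions[name].size)

    def marker_table(self) -> pd.DataFrame:
        """Flat marker table: chrom, marker id, cM (female map), bp."""
        rows = []
        for chrom in self.chromosomes:
            pos = self.marker_positions.get(chrom.name, np.empty(0))
            bp = self.marker_bp.get(
                chrom.name, np.full(pos.shape, np.nan, dtype=float)
            )
            for i, (p, b) in enumerate(zip(pos, bp)):
                rows.append(
                    {
                        "marker": f"{chrom.name}_m{i:04d}",
                        "chrom": chrom.name,
                        "pos_cM": float(p),
                        "pos_bp": float(b),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def regular(
        cls,
        chromosomes: list[ChromosomeModel],
        markers_per_chromosome: int,
        cM_per_Mb: float | None = None,
    ) -> "GenomeModel":
        """Genome with evenly spaced markers (endpoints included).

        Physical coordinates are spread uniformly over ``physical_length``
        so the genome is exactly linear at ``female_length / physical`` cM/Mb
        unless ``cM_per_Mb`` overrides the physical spacing.
        """
        if markers_per_chromosome < 2:
            raise ValueError("need at least two markers per chromosome")
        positions, bps = {}, {}
        for c in chromosomes:
            pos = np.linspace(0.0, c.female_length, markers_per_chromosome)
            if cM_per_Mb is not None and cM_per_Mb > 0:
                bp = pos / cM_per_Mb * 1e6
            else:
                bp = np.linspace(0.0, float(c.physical_length), markers_per_chromosome)
            positions[c.name] = pos
            bps[c.name] = bp
        return cls(list(chromosomes), positions, bps)


@dataclass(frozen=True)
class Qtl:
    """A single simulated QTL with F2-style additive/dominance effects."""

    chromosome: str
    position: float  # cM, female map
    additive: float
    dominance: float = 0.0


@dataclass
class TraitModel:
    """Genetic architecture of a simulated trait.

    Genotypic value is the sum over QTL of -a / d / +a for the three
    genotype classes; normal traits add N(0, residual_sd) noise, binary
    traits threshold the same liability at ``binary_link``.
    """

    qtl: list[Qtl]
    residual_sd: float = 1.0
    trait_type: str = "normal"  # "normal" | "binary"
    binary_link: float = 0.0

    def __post_init__(self) -> None:
        if self.trait_type not in ("normal", "binary"):
            raise ValueError("trait_type must be 'normal' or 'binary'")
        if self.trait_type == "normal" and self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def validate_against(self, genome: GenomeModel) -> None:
        by_name = genome.chromosome_by_name
        for q in self.qtl:
            if q.chromosome not in by_name:
                raise ValueError(f"QTL chromosome {q.chromosome} not in genome")
            if not 0 <= q.position <= by_name[q.chromosome].female_length:
                raise ValueError(f"QTL position {q.position} off {q.chromosome}")


def residual_sd_for_pve(additive: float, dominance: float, pve: float) -> float:
    """Residual SD giving a target single-QTL PVE in an intercross.

    With genotype frequencies 1/4 : 1/2 : 1/4 the genetic variance is
    a^2/2 + d^2/4; solve pve = Vg / (Vg + sd^2).
    """
    if not 0 < pve < 1:
        raise ValueError("pve must be in (0, 1)")
    vg = additive**2 / 2.0 + dominance**2 / 4.0
    return float(np.sqrt(vg * (1.0 - pve) / pve))
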