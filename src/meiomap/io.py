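"""File formats and pipeline configuration.

Conventions: genetic positions are cM decimals; physical positions are
0-based half-open in internal tables (1-based only in VCF, per that
standard); the missing-genotype sentinel is "NA" in TSV and "./." in VCF.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PipelineConfig",
    "DEFAULT_THRESHOLDS",
    "write_tsv",
    "read_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_gametes_tsv",
    "read_gametes_tsv",
    "write_provenance",
    "read_provenance",
    "file_sha256",
]

DEFAULT_THRESHOLDS: dict = {
    "distortion_p": 0.01,
    "maf_min": 0.05,
    "missing_max": 0.3,
    "lod_range": [8.0, 60.0],
    "min_lg_size": 50,
    "join_lod": 10.0,
    "join_diff": 5.0,
    "y_threshold": 0.1,
    "rfm_cutoff": 0.45,
    "gq_min": 10.0,
    "pseudomarker_step": 1.0,
    "kinship_step": 3.0,
    "peak_threshold": 3.0,
    "peakdrop": 2.0,
    "ci_prob": 0.95,
    "n_perm": 1000,
    "rate_pairs": 100,
    "rate_reps": 100,
    "mq_min": 60,
    "min_loci": 50,
}

ALL_STAGES = ("simulate", "qc", "group", "order", "centromere", "scan", "recombrate")


@dataclass
class PipelineConfig:
    """Pipeline configuration: stage toggles, thresholds, and the RNG seed."""

    seed: int = 0
    genome: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)
    trait: dict | None = None
    target_n_lgs: int | None = None
    thresholds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        self.thresholds = merged
        self.stages = {s: self.stages.get(s, True) for s in ALL_STAGES}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome": self.genome,
            "families": self.families,
            "trait": self.trait,
            "target_n_lgs": self.target_n_lgs,
            "thresholds": self.thresholds,
            "stages": self.stages,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_genotypes_tsv(coded: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    """Markers x individuals genotype TSV with marker metadata columns."""
    out = meta.reset_index(drop=True).merge(
        coded.rename_axis("marker").reset_index(), on="marker", how="right"
    )
    write_tsv(out, path)


def read_genotypes_tsv(path: str | Path, meta_cols: tuple[str, ...] = ("marker", "chrom", "pos_cM", "pos_bp", "rad_locus", "offset")) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    present = [c for c in meta_cols if c in df.columns]
    meta = df[present].copy()
    calls = df.drop(columns=present).set_index(df["marker"])
    return calls, meta


def write_gametes_tsv(matrix: np.ndarray, markers: list[str], path: str | Path) -> None:
    """Phased gamete TSV: markers x meioses parental-origin codes (0/1/NA)."""
    df = pd.DataFrame(matrix, index=markers)
    df.columns = [f"meiosis{j}" for j in range(matrix.shape[1])]
    df.rename_axis("marker").reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gametes_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    markers = df["marker"].tolist()
    return df.drop(columns=["marker"]).to_numpy(dtype=float), markers


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(
    stage_dir: str | Path, config: PipelineConfig, inputs: dict[str, str] | None = None
) -> None:
    from . import __version__

    payload = {
        "version": __version__,
        "config_hash": config.digest(),
        "input_hashes": inputs or {},
    }
    Path(stage_dir, "provenance.json").write_text(json.dumps(payload, indent=2))


def read_provenance(stage_dir: str | Path) -> dict | None:
    p = Path(stage_dir, "provenance.json")
    if not p.exists():
        return None
    return json.loads(p.read_text())
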