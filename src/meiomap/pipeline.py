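"""End-to-end pipeline on a simulated mapping design.

Runs simulate -> qc -> group -> order -> centromere -> scan -> recombrate
from a YAML-derived :class:`~meiomap.io.PipelineConfig`, writing one TSV
(+ provenance JSON) per stage.  Deterministic for a given seed; a stage
whose provenance already matches the current configuration is reused
rather than rewritten.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import centromere as cen
from . import grouping, ordering, qc, qtl, recomb
from .genome import ChromosomeModel, GenomeModel, Qtl, TraitModel
from .io import PipelineConfig, read_provenance, write_gametes_tsv, write_provenance, write_tsv
from .simulate import (
    FamilyDataset,
    intercross_founders,
    simulate_diploid_family,
    simulate_half_tetrad_family,
    simulate_phenotypes,
)

__all__ = ["run_pipeline", "genome_from_config"]


def genome_from_config(cfg: dict) -> GenomeModel:
    chroms = [ChromosomeModel(**c) for c in cfg["chromosomes"]]
    return GenomeModel.regular(chroms, int(cfg.get("markers_per_chromosome", 50)))


def _stage_dir(outdir: Path, name: str) -> Path:
    d = outdir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _fresh(outdir: Path, name: str, config: PipelineConfig) -> bool:
    prov = read_provenance(outdir / name)
    return prov is not None and prov.get("config_hash") == config.digest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages; returns the in-memory artifacts.

    Fails fast (before any stage output is written) on configuration
    contradictions such as an enabled scan stage without a trait model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    if stages.get("scan") and not config.trait:
        raise ValueError("scan stage enabled but no trait model configured")
    if not config.genome:
        raise ValueError("no genome configured")
    th = config.thresholds
    rng = np.random.default_rng(config.seed)
    genome = genome_from_config(config.genome)
    artifacts: dict = {"genome": genome}

    # --- simulate ----------------------------------------------------------
    mother, father = intercross_founders(genome)
    families: list[FamilyDataset] = []
    for fam_cfg in config.families.get("diploid", []):
        families.append(
            simulate_diploid_family(
                genome,
                mother,
                father,
                int(fam_cfg["n_offspring"]),
                rng,
                error_rate=float(fam_cfg.get("error_rate", 0.0)),
                missing_rate=float(fam_cfg.get("missing_rate", 0.0)),
                family_id=str(fam_cfg.get("id", f"F{len(families) + 1}")),
            )
        )
    if not families:
        raise ValueError("at least one diploid family is required")
    gyno_cfg = config.families.get("gynogenetic")
    halftetrad = None
    if gyno_cfg:
        halftetrad = simulate_half_tetrad_family(
            genome, mother, int(gyno_cfg["n_offspring"]), rng
        )
    trait_values = None
    trait_model = None
    if config.trait:
        trait_model = TraitModel(
            qtl=[Qtl(**q) for q in config.trait.get("qtl", [])],
            residual_sd=float(config.trait.get("residual_sd", 1.0)),
            trait_type=str(config.trait.get("type", "normal")),
            binary_link=float(config.trait.get("binary_link", 0.0)),
        )
        trait_values = simulate_phenotypes(trait_model, families[0], rng)
    artifacts.update(families=families, halftetrad=halftetrad, trait=trait_values)
    if stages.get("simulate"):
        d = _stage_dir(outdir, "simulate")
        if not _fresh(outdir, "simulate", config):
            for fam in families:
                write_tsv(
                    fam.genotypes(coded=True).rename_axis("marker").reset_index(),
                    d / f"genotypes_{fam.family_id}.tsv",
                )
                write_gametes_tsv(
                    fam.gamete_matrix("mother"), list(fam.markers["marker"]),
                    d / f"gametes_{fam.family_id}_mother.tsv",
                )
                write_gametes_tsv(
                    fam.gamete_matrix("father"), list(fam.markers["marker"]),
                    d / f"gametes_{fam.family_id}_father.tsv",
                )
            if halftetrad is not None:
                ht = halftetrad.markers[["marker", "chrom", "pos_cM"]].copy()
                for i in range(halftetrad.n_offspring):
                    ht[f"g{i:03d}"] = halftetrad.states[i]
                write_tsv(ht, d / "halftetrad.tsv")
            if trait_values is not None:
                write_tsv(
                    trait_values.rename_axis("individual").reset_index(),
                    d / "traits.tsv",
                )
            truth = {
                "seed": config.seed,
                "centromeres": {c.name: c.centromere_pos for c in genome.chromosomes},
                "qtl": [vars(q) for q in (trait_model.qtl if trait_model else [])],
            }
            (d / "truth.json").write_text(json.dumps(truth, indent=2))
            write_provenance(d, config)

    # --- qc ----------------------------------------------------------------
    fam0 = families[0]
    meta = fam0.markers[["marker", "chrom", "pos_cM", "pos_bp"]].copy()
    meta["rad_locus"] = meta["marker"]
    meta["offset"] = 0
    gt = qc.GenotypeTable(
        meta,
        {
            f.family_id: qc.FamilyGenotypes(
                mother=pd.Series(1, index=meta["marker"]),
                father=pd.Series(1, index=meta["marker"]),
                offspring=f.genotypes(),
            )
            for f in families
        },
    )
    if stages.get("qc"):
        filtered, report = qc.filter_markers(
            gt,
            p_distortion=th["distortion_p"],
            maf_min=th["maf_min"],
            missing_max=th["missing_max"],
        )
        filtered = qc.thin_to_one_snp_per_locus(filtered)
        d = _stage_dir(outdir, "qc")
        if not _fresh(outdir, "qc", config):
            write_tsv(report.reset_index(drop=True), d / "filter_report.tsv")
            write_provenance(d, config)
    else:
        filtered = gt
    keep = filtered.markers
    keep_idx = fam0.markers.index[fam0.markers["marker"].isin(set(keep))].to_numpy()
    artifacts["qc_markers"] = list(keep)

    # --- group -------------------------------------------------------------
    marker_names = fam0.markers.loc[keep_idx, "marker"].tolist()
    matrices = []
    for fam in families:
        matrices.append(fam.gamete_matrix("mother")[keep_idx])
        matrices.append(fam.gamete_matrix("father")[keep_idx])
    pair = grouping.pairwise_lod(matrices, marker_names)
    lo, hi = th["lod_range"]
    target = config.target_n_lgs or len(genome.chromosomes)
    groups = grouping.assign_linkage_groups(pair, float(lo) + 2.0, int(th["min_lg_size"]))
    groups = grouping.split_to_target(
        groups, pair, target, (float(lo), float(hi)), int(th["min_lg_size"])
    )
    groups = grouping.join_singles(groups, pair, th["join_lod"], th["join_diff"])
    artifacts["grouping"] = groups
    if stages.get("group"):
        d = _stage_dir(outdir, "group")
        if not _fresh(outdir, "group", config):
            write_tsv(
                groups.assignment.rename("lg").rename_axis("marker").reset_index(),
                d / "grouping.tsv",
            )
            (d / "audit.json").write_text(json.dumps(groups.audit, indent=2))
            write_provenance(d, config)

    # --- order -------------------------------------------------------------
    tables = []
    lg_orders: dict[str, ordering.MarkerOrder] = {}
    name_to_idx = {m: i for i, m in enumerate(marker_names)}
    for lg, members in sorted(groups.groups.items(), key=lambda t: -len(t[1])):
        sub_idx = np.asarray(members)
        sub_markers = [marker_names[i] for i in sub_idx]
        f_mats = [m[sub_idx] for m in matrices[0::2]]
        m_mats = [m[sub_idx] for m in matrices[1::2]]
        order = ordering.order_markers(f_mats + m_mats, sub_markers, rng=rng)
        lg_orders[lg] = order
        tables.append(ordering.map_positions(order, f_mats, m_mats, lg=lg))
    map_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    artifacts["map"] = map_table
    if stages.get("order") and not map_table.empty:
        per_lg, overall = ordering.summarize_map(map_table)
        artifacts["map_summary"] = (per_lg, overall)
        d = _stage_dir(outdir, "order")
        if not _fresh(outdir, "order", config):
            write_tsv(map_table, d / "map.tsv")
            write_tsv(per_lg, d / "summary.tsv")
            (d / "overall.json").write_text(json.dumps(overall, indent=2))
            write_provenance(d, config)

    # --- centromere --------------------------------------------------------
    if stages.get("centromere") and halftetrad is not None and not map_table.empty:
        y_all = cen.estimate_y(halftetrad)
        intervals = []
        for lg, order in lg_orders.items():
            sub = map_table[map_table["lg"] == lg]
            prof = y_all[y_all["marker"].isin(set(sub["marker"]))].copy()
            pos_map = dict(zip(sub["marker"], sub["female_cM"]))
            prof["pos_cM"] = prof["marker"].map(pos_map)
            prof = prof.sort_values("pos_cM").reset_index(drop=True)
            y_int = cen.delineate_centromere_y(prof, lg=lg, y_threshold=th["y_threshold"])
            sub_idx = np.asarray([name_to_idx[m] for m in order.markers])
            gam = np.hstack([m[sub_idx] for m in matrices[0::2]])
            rfm_int = cen.rfm_centromere(
                gam,
                sub.set_index("marker").loc[order.markers, "female_cM"].to_numpy(),
                lg=lg,
                cutoff=th["rfm_cutoff"],
                y_profile=prof,
            )
            rec = cen.reconcile_centromeres(
                y_int, rfm_int, float(sub["female_cM"].max()), lg=lg
            )
            intervals.append(
                {
                    "lg": lg,
                    "start": rec.start if rec else np.nan,
                    "end": rec.end if rec else np.nan,
                    "method": rec.method if rec else "unresolved",
                    "class": rec.chrom_class if rec else "unknown",
                    "conflict": rec.conflict if rec else False,
                }
            )
        d = _stage_dir(outdir, "centromere")
        artifacts["centromeres"] = pd.DataFrame(intervals)
        if not _fresh(outdir, "centromere", config):
            write_tsv(y_all, d / "y_profile.tsv")
            write_tsv(artifacts["centromeres"], d / "centromeres.tsv")
            write_provenance(d, config)

    # --- scan --------------------------------------------------------------
    if stages.get("scan") and trait_values is not None:
        grid = qtl.grid_from_family(fam0, step=th["pseudomarker_step"])
        if trait_model.trait_type == "binary":
            scan_fn = lambda y: qtl.scan_binary(grid, y)  # noqa: E731
        else:
            K = qtl.calc_kinship(grid, th["kinship_step"])
            scan_fn = lambda y: qtl.scan_normal(grid, y, kinship=K)  # noqa: E731
        scan = scan_fn(trait_values)
        peaks = qtl.find_peaks_ci(
            scan, th["peak_threshold"], th["peakdrop"], th["ci_prob"]
        )
        peaks, threshold, _ = qtl.permutation_pvalues(
            scan_fn, trait_values, peaks, int(th["n_perm"]), rng
        )
        artifacts["scan"] = scan
        artifacts["peaks"] = peaks
        d = _stage_dir(outdir, "scan")
        if not _fresh(outdir, "scan", config):
            write_tsv(
                pd.DataFrame(
                    {"lg": scan.lgs, "pos_cM": scan.positions, "lod": scan.lod}
                ),
                d / "scan.tsv",
            )
            write_tsv(pd.DataFrame([vars(p) for p in peaks]), d / "peaks.tsv")
            (d / "threshold.json").write_text(
                json.dumps({"alpha": 0.05, "lod_threshold": threshold})
            )
            write_provenance(d, config)

    # --- recombination rate ------------------------------------------------
    if stages.get("recombrate") and not map_table.empty:
        truth_map = fam0.markers.set_index("marker")
        aln = pd.DataFrame(
            {
                "marker": map_table["marker"],
                "ref_chrom": truth_map.loc[map_table["marker"], "chrom"].to_numpy(),
                "ref_bp": truth_map.loc[map_table["marker"], "pos_bp"].to_numpy(),
                "mq": 60,
            }
        )
        rates = recomb.estimate_rates(
            map_table,
            aln,
            n_pairs=int(th["rate_pairs"]),
            n_reps=int(th["rate_reps"]),
            mq_min=int(th["mq_min"]),
            min_loci=int(th["min_loci"]),
            rng=rng,
        )
        artifacts["rates"] = rates
        d = _stage_dir(outdir, "recombrate")
        if not _fresh(outdir, "recombrate", config):
            write_tsv(rates, d / "rates.tsv")
            write_provenance(d, config)

    return artifacts
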