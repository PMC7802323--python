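"""Pipeline orchestration: simulate-or-load, analyze, write a manifest.

Each stage either simulates its inputs (the default) or reads them from
the paths in its config block.  All randomness is derived from the
single run seed, so a fixed (config, seed) pair reproduces every
summary file byte for byte.  The manifest echoes the validated config,
the package version, and every artifact written.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, gp, imio, morpho, omics, simgen, tfm
from .config import GpStageConfig, OmicsStageConfig, RunConfig, TfmStageConfig, TracksStageConfig
from .errors import CellMechError, MissingInputError, StageError

log = logging.getLogger(__name__)


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    order = {"tfm": 0, "gp": 1, "tracks": 2, "omics": 3}
    ss = np.random.SeedSequence([seed, order[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write a run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "artifacts": [],
    }
    runners = {"tfm": _run_tfm, "gp": _run_gp, "tracks": _run_tracks, "omics": _run_omics}
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            info, artifacts = runners[stage](getattr(config, stage), outdir,
                                             _stage_seed(config.seed, stage))
        except CellMechError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = info
        manifest["artifacts"].extend(str(a.relative_to(outdir)) for a in artifacts)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _run_tfm(cfg: TfmStageConfig, outdir: Path, seed: int) -> tuple[dict, list[Path]]:
    geom = tfm.PillarGeometry(
        diameter_um=cfg.geometry.diameter_um,
        height_um=cfg.geometry.height_um,
        youngs_modulus_pa=cfg.geometry.youngs_modulus_pa,
        pitch_um=cfg.geometry.pitch_um,
        stiffness_override_nn_per_um=cfg.geometry.stiffness_override_nn_per_um,
    )
    artifacts: list[Path] = []
    if cfg.stack is not None:
        stack_obj = imio.read_image_stack(cfg.stack, cfg.scene.pixel_size_um)
        stack, pixel_size = stack_obj.data, stack_obj.pixel_size_um
        if cfg.mask is None:
            raise MissingInputError("tfm: analyzing an existing stack requires a mask path")
        mask = imio.read_image_stack(cfg.mask, pixel_size).data.astype(bool)
        truth = None
    else:
        sc = cfg.scene
        h, w = sc.image_shape
        mask = simgen.disk_mask((h, w), (w / 2, h / 2), sc.cell_radius_um / sc.pixel_size_um)
        spec = simgen.PillarSceneSpec(
            lattice_pitch=geom.pitch_um,
            pillar_diameter=geom.diameter_um,
            image_shape=(h, w),
            pixel_size=sc.pixel_size_um,
            n_frames=sc.n_frames,
            psf_sigma=sc.psf_sigma_px,
            photon_level=sc.photon_level,
            background=sc.background,
            read_noise_sd=sc.read_noise_sd,
            drift_per_frame=sc.drift_per_frame_um,
            cell_mask=mask,
            seed=seed,
        )
        spec = simgen.add_random_deflections(spec, sc.n_deflected, sc.deflection_range_um)
        scene = simgen.simulate_pillar_sequence(spec)
        stack, truth, pixel_size = scene.stack, scene.truth, sc.pixel_size_um
        stack_path = outdir / "tfm_stack.tif"
        imio.write_stack(stack_path, stack, pixel_size)
        truth_path = outdir / "tfm_truth.csv"
        truth.to_csv(truth_path, index=False)
        artifacts += [stack_path, truth_path]

    field, summary = tfm.analyze_pillar_stack(
        stack, geom, pixel_size, mask, margin_um=cfg.margin_um, lattice=cfg.lattice
    )
    table_path = outdir / "tfm_deflections.csv"
    field.table.round(6).to_csv(table_path, index=False)
    per_pillar = summary.pop("per_pillar")
    pp_path = outdir / "tfm_per_pillar.csv"
    per_pillar.round(6).to_csv(pp_path, index=False)
    report = field.stiffness
    summary_out = dict(summary)
    summary_out["stiffness_nn_per_um"] = report.used_nn_per_um
    summary_out["stiffness_source"] = report.source
    summary_out["stiffness_formula_nn_per_um"] = report.formula_nn_per_um
    if report.note:
        summary_out["stiffness_note"] = report.note
    if truth is not None:
        merged = per_pillar.merge(
            truth[truth.frame == truth.frame.max()][["pillar_id", "defl_x_um", "defl_y_um"]],
            on="pillar_id",
        )
        planted = np.hypot(merged["defl_x_um"], merged["defl_y_um"])
        nonzero = planted > 0
        if nonzero.any():
            rel = np.abs(merged.loc[nonzero, "d_um"] - planted[nonzero]) / planted[nonzero]
            summary_out["median_recovery_rel_error"] = float(np.median(rel))
    summary_path = outdir / "tfm_summary.json"
    summary_path.write_text(json.dumps(summary_out, indent=2, sort_keys=True))
    artifacts += [table_path, pp_path, summary_path]
    info = {
        "n_pillars": int(len(field.grid.ids)),
        "n_frames": int(field.table["frame"].nunique()),
        "n_reference": int(field.table.loc[field.table.frame == 0, "is_reference"].sum()),
        "mean_force_nN": summary["mean_force_nN"],
    }
    return info, artifacts


def _run_gp(cfg: GpStageConfig, outdir: Path, seed: int) -> tuple[dict, list[Path]]:
    artifacts: list[Path] = []
    if cfg.ch420 is not None and cfg.ch473 is not None:
        i420 = imio.read_image_stack(cfg.ch420, 1.0).data.astype(float)
        i473 = imio.read_image_stack(cfg.ch473, 1.0).data.astype(float)
        np_ch = (
            imio.read_image_stack(cfg.np_channel, 1.0).data.astype(float)
            if cfg.np_channel is not None else None
        )
    else:
        sc = cfg.scene
        h, w = sc.image_shape
        gp_field = simgen.two_domain_gp_field(
            (h, w), sc.ordered_gp, sc.fluid_gp, (w / 2, h / 2), sc.domain_radius_px
        )
        cell = simgen.disk_mask((h, w), (w / 2, h / 2), min(h, w) / 2.2)
        total = np.where(cell, sc.total_intensity, 0.0)
        rigid = gp_field > (sc.ordered_gp + sc.fluid_gp) / 2
        np_field = np.where(rigid & cell, sc.np_level, 10.0)
        scene = simgen.simulate_laurdan_cell(simgen.LaurdanSceneSpec(
            gp_field=gp_field, total_intensity_field=total,
            np_channel_field=np_field, shot_noise=sc.shot_noise, seed=seed,
        ))
        i420, i473, np_ch = scene.i420, scene.i473, scene.np_channel
        stack_path = outdir / "gp_channels.tif"
        imio.write_stack(stack_path, np.stack([i420, i473, np_ch]), 1.0,
                         axes="CYX", channel_names=["ch420", "ch473", "np"])
        artifacts.append(stack_path)

    pair = gp.RatiometricImagePair(i420=i420, i473=i473, np_channel=np_ch)
    gp_map = gp.compute_gp_map(pair, intensity_threshold=cfg.intensity_threshold)
    dist = gp.fit_gaussian(gp.gp_frequency_distribution(gp_map, n_bins=cfg.n_bins))
    dist_path = outdir / "gp_distribution.csv"
    pd.DataFrame({"gp": dist.bin_centers, "frequency": dist.frequencies}).to_csv(
        dist_path, index=False
    )
    summary = {
        "total_mean_gp": gp.total_mean_gp(gp_map),
        "n_pixels": dist.n_pixels,
        "gaussian_fit": {
            "amplitude": dist.gaussian_fit.amplitude,
            "mean": dist.gaussian_fit.mean,
            "sd": dist.gaussian_fit.sd,
            "residual_rms": dist.gaussian_fit.residual_rms,
            "converged": dist.gaussian_fit.converged,
        },
    }
    if np_ch is not None:
        coloc = gp.high_gp_colocalization(gp_map, np_ch, cfg.gp_threshold, cfg.np_threshold)
        summary["high_gp_np_overlap_fraction"] = coloc.fraction if coloc.defined else None
    summary_path = outdir / "gp_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    artifacts += [dist_path, summary_path]
    return {"n_pixels": dist.n_pixels, "total_mean_gp": summary["total_mean_gp"]}, artifacts


def _run_tracks(cfg: TracksStageConfig, outdir: Path, seed: int) -> tuple[dict, list[Path]]:
    artifacts: list[Path] = []
    if cfg.tracks is not None:
        if not Path(cfg.tracks).exists():
            raise MissingInputError(f"track table not found: {cfg.tracks}")
        positions = pd.read_csv(cfg.tracks)
        truth = None
    else:
        spec = simgen.TrackSpec(
            n_cells=cfg.n_cells, sampling_interval_min=cfg.sampling_interval_min,
            duration_h=cfg.duration_h, speed_mean=cfg.speed_mean,
            speed_sd=cfg.speed_sd, turning_sd_rad=cfg.turning_sd_rad, seed=seed,
        )
        positions, truth = simgen.simulate_tracks(spec)
        pos_path = outdir / "tracks_positions.csv"
        positions.round(6).to_csv(pos_path, index=False)
        artifacts.append(pos_path)
    tracks = morpho.tracks_from_table(positions, cfg.sampling_interval_min)
    rows = []
    for tr in tracks:
        m = morpho.track_metrics(tr)
        rows.append((m.cell_id, m.path_distance_um, m.net_displacement_um,
                     m.mean_velocity_um_per_min))
    metrics = pd.DataFrame(
        rows, columns=["cell_id", "path_distance_um", "net_displacement_um",
                       "mean_velocity_um_per_min"]
    )
    if truth is not None:
        metrics = metrics.merge(truth, on="cell_id", how="left")
    metrics_path = outdir / "tracks_metrics.csv"
    metrics.round(6).to_csv(metrics_path, index=False)
    artifacts.append(metrics_path)
    return {
        "n_tracks": int(len(metrics)),
        "mean_velocity_um_per_min": float(metrics["mean_velocity_um_per_min"].mean()),
    }, artifacts


def _run_omics(cfg: OmicsStageConfig, outdir: Path, seed: int) -> tuple[dict, list[Path]]:
    artifacts: list[Path] = []
    if cfg.genes is not None and cfg.metabolites is not None:
        for p in (cfg.genes, cfg.metabolites):
            if not Path(p).exists():
                raise MissingInputError(f"omics table not found: {p}")
        genes = pd.read_csv(cfg.genes)
        mets = pd.read_csv(cfg.metabolites)
    else:
        genes, mets = simgen.simulate_omics_table(
            n_genes=cfg.n_genes, n_metabolites=cfg.n_metabolites,
            planted_gene_fc={i: cfg.planted_gene_fc for i in range(cfg.n_planted_genes)},
            planted_metabolite_change={
                i: cfg.planted_metabolite_change for i in range(cfg.n_planted_metabolites)
            },
            noise_sd=cfg.noise_sd, gene_cutoff=cfg.gene_cutoff,
            metabolite_cutoff=cfg.metabolite_cutoff, seed=seed,
        )
    genes_f = omics.fold_change_filter(genes, gene_cutoff=cfg.gene_cutoff)
    mets_f = omics.metabolite_change_filter(mets, cutoff=cfg.metabolite_cutoff)
    nodes_path = outdir / "omics_nodes.csv"
    nodes = omics.export_network_nodes(genes_f, mets_f, nodes_path)
    genes_path, mets_path = outdir / "omics_genes.csv", outdir / "omics_metabolites.csv"
    genes_f.round(6).to_csv(genes_path, index=False)
    mets_f.round(6).to_csv(mets_path, index=False)
    artifacts += [genes_path, mets_path, nodes_path]
    return {
        "n_genes_flagged": int(genes_f["passes_filter"].sum()),
        "n_metabolites_flagged": int(mets_f["passes_filter"].sum()),
        "n_nodes": int(len(nodes)),
    }, artifacts
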