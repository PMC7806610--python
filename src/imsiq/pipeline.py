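"""End-to-end orchestration: phantom → reconstruct → filter → calibrate →
segment → quantify.

All randomness derives from the single top-level config seed, fanned out
deterministically per stage and replicate, so identical configurations
produce identical outputs.  Each stage writes its products to the output
directory and is skipped on rerun when the products already exist (unless
forced), making a run idempotent.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibrate import (
    CalibrationModel,
    CalibrationStandard,
    apply_calibration,
    attach_lloq,
    bracketed_calibration,
    fit_calibration,
)
from .config import RunConfig
from .core import AcquisitionSpec, ElementalImage
from .errors import ImsiqError
from .filters import (FilterParams, gaussian_filter, make_disk_psf,
                      make_srr_psf, rltv_deconvolve)
from .linescan_io import read_image, write_image, write_linescan_csv
from .phantom import (
    PhantomSpec,
    generate_fiber_map,
    render_concentration_field,
    simulate_linescans,
    generate_standard_block,
)
from .quantify import masked_mean_concentration, replicate_stats
from .reconstruct import assemble_raster, srr_fuse
from .segment import METHOD_NAMES, ThresholdParams, run_method

log = logging.getLogger(__name__)


@dataclass
class PipelineRun:
    """Record of one pipeline execution: config, products and history."""

    config: RunConfig
    outputs: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _round_sig(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits for stable JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_sig(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, sig) for v in obj]
    return obj


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2^31) from one top-level seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


def _phantom_spec(cfg: RunConfig, seed: int) -> PhantomSpec:
    p = cfg.phantom
    return PhantomSpec(
        width_um=p.width_um,
        height_um=p.height_um,
        n_fibers=p.n_fibers,
        membrane_width_um=p.membrane_width_um,
        c_membrane=p.c_membrane,
        c_interior=p.c_interior,
        c_background=p.c_background,
        revertant_fraction=p.revertant_fraction,
        revertant_boost=p.revertant_boost,
        tissue_margin_um=p.tissue_margin_um,
        seed=int(seed),
    )


def _acq(cfg: RunConfig, direction: str, offset_um: float, seed: int) -> AcquisitionSpec:
    a = cfg.acquisition
    return AcquisitionSpec(
        spot_um=a.spot_um,
        scan_speed_um_s=a.scan_speed_um_s,
        acq_hz=a.acq_hz,
        line_pitch_um=a.line_pitch_um,
        direction=direction,
        offset_um=offset_um,
        sensitivity_cps_per_ugkg=a.sensitivity_cps_per_ugkg,
        flicker_fraction=a.flicker_fraction,
        dark_cps=a.dark_cps,
        seed=int(seed),
    )


def _filter_image(img: ElementalImage, cfg: RunConfig, srr: bool) -> ElementalImage:
    """The shared conditioning path: optional Gaussian blur, then RLTV.

    Applied identically to tissue reconstructions and calibration
    standards; both filters preserve the image mean, so the calibration
    transfer is unaffected.  SRR images deconvolve against the fused
    forward-model PSF; plain rasters against the (possibly elliptical)
    laser-spot disk.
    """
    f = cfg.filtering
    out = img
    if f.gaussian_sigma_px > 0:
        out = gaussian_filter(out, f.gaussian_sigma_px)
    spot = cfg.acquisition.spot_um
    if srr:
        psf = make_srr_psf(spot, cfg.acquisition.line_pitch_um, img.pixel_dx_um)
    else:
        psf = make_disk_psf(spot / img.pixel_dx_um, spot / img.pixel_dy_um)
    params = FilterParams(
        gaussian_sigma_px=f.gaussian_sigma_px,
        rl_iterations=f.rl_iterations,
        rl_tv_lambda=f.rl_tv_lambda,
        psf=psf,
    )
    return rltv_deconvolve(out, params)


def simulate_replicate(
    truth: ElementalImage, cfg: RunConfig, seed1: int, seed2: int
) -> tuple:
    """Simulate the two orthogonal passes of one serial section."""
    acq1 = _acq(cfg, "horizontal", 0.0, seed1)
    acq2 = _acq(cfg, "vertical", cfg.acquisition.offset_um, seed2)
    return simulate_linescans(truth, acq1), simulate_linescans(truth, acq2)


def reconstruct_replicate(scans1, scans2, cfg: RunConfig) -> ElementalImage:
    p1 = assemble_raster(scans1)
    p2 = assemble_raster(scans2)
    return srr_fuse(
        p1,
        p2,
        offset_um=cfg.acquisition.offset_um,
        target_pitch_um=cfg.reconstruction.target_pitch_um,
        method=cfg.reconstruction.fusion,
    )


def _measure_standard(level: float, cfg: RunConfig, seed: int) -> ElementalImage:
    """Ablate, assemble and condition one uniform gelatine standard block.

    Standards get the Gaussian conditioning stage only: the deconvolution's
    PSF models the SRR reconstruction operator, which a single-pass raster
    of a uniform block never passes through, and deconvolving a flat field
    carries no signal while amplifying the blank noise that defines the
    LLOQ.  The calibration transfer is unaffected either way because both
    filters preserve the image mean.
    """
    acq = _acq(cfg, "horizontal", 0.0, seed)
    scans = generate_standard_block(level, acq, (cfg.calibration.standard_size_um,) * 2)
    raster = assemble_raster(scans)
    if cfg.filtering.gaussian_sigma_px > 0:
        raster = gaussian_filter(raster, cfg.filtering.gaussian_sigma_px)
    return raster


def calibrate_run(cfg: RunConfig, seeds: np.ndarray) -> CalibrationModel:
    """Fit the (optionally bracketed) calibration and derive the LLOQ.

    The blank is the lowest gelatine level; its calibrated pixels provide
    the blank SD for LLOQ = 5 x SD(blank).
    """
    levels = sorted(cfg.calibration.standard_levels_ugkg)
    n = len(levels)

    def one_curve(seed_block: np.ndarray) -> CalibrationModel:
        images = [
            _measure_standard(lv, cfg, sd) for lv, sd in zip(levels, seed_block)
        ]
        standards = [
            CalibrationStandard(
                concentration_ugkg=lv,
                mean_intensity_cps=float(im.values.mean()),
                sd_intensity_cps=float(im.values.std(ddof=1)),
                n_pixels=im.values.size,
            )
            for lv, im in zip(levels, images)
        ]
        model = fit_calibration(standards)
        # unclamped blank residuals: clamping negatives at 0 would truncate
        # the blank distribution and understate the LLOQ
        blank_conc = (images[0].values - model.intercept) / model.slope
        return attach_lloq(model, blank_conc)

    pre = one_curve(seeds[:n])
    if not cfg.calibration.bracketed:
        return pre
    post = one_curve(seeds[n : 2 * n])
    return bracketed_calibration(pre, post, cfg.calibration.drift_limit_percent)


def run_pipeline(cfg: RunConfig, force: bool = False) -> PipelineRun:
    """Execute every stage in order and write a machine-readable report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=cfg)
    n_rep = cfg.n_replicates
    n_lv = len(cfg.calibration.standard_levels_ugkg)
    seeds = _derive_seeds(cfg.seed, 1 + 2 * n_rep + 2 * n_lv)
    phantom_seed, rep_seeds, std_seeds = seeds[0], seeds[1 : 1 + 2 * n_rep], seeds[1 + 2 * n_rep :]

    def stage(msg: str) -> None:
        log.info(msg)
        run.log.append(msg)

    # -- phantom ----------------------------------------------------------
    spec = _phantom_spec(cfg, phantom_seed)
    truth_path = out / "truth.tiff"
    if truth_path.exists() and not force:
        truth = read_image(truth_path)
        stage("phantom: reused existing truth image")
    else:
        labels = generate_fiber_map(spec, cfg.phantom.resolution_um)
        truth = render_concentration_field(labels, spec, cfg.phantom.resolution_um)
        write_image(truth, truth_path)
        stage(f"phantom: {spec.n_fibers} fibers on {truth.shape} grid")
    run.outputs["truth"] = str(truth_path)

    # -- acquisition + reconstruction + filtering per replicate -----------
    calibrated_paths = []
    intensity_images = []
    for r in range(n_rep):
        fpath = out / f"replicate_{r}_filtered.tiff"
        if fpath.exists() and not force:
            intensity_images.append(read_image(fpath))
            stage(f"replicate {r}: reused filtered image")
        else:
            scans1, scans2 = simulate_replicate(
                truth, cfg, rep_seeds[2 * r], rep_seeds[2 * r + 1]
            )
            write_linescan_csv(scans1, out / f"replicate_{r}_pass1.csv")
            write_linescan_csv(scans2, out / f"replicate_{r}_pass2.csv")
            fused = reconstruct_replicate(scans1, scans2, cfg)
            filtered = _filter_image(fused, cfg, srr=True)
            write_image(filtered, fpath)
            intensity_images.append(filtered)
            stage(f"replicate {r}: reconstructed {fused.shape} and filtered")
        run.outputs[f"replicate_{r}"] = str(fpath)

    # -- calibration -------------------------------------------------------
    model_path = out / "calibration.json"
    if model_path.exists() and not force:
        model = CalibrationModel.from_json(model_path)
        stage("calibration: reused existing model")
    else:
        model = calibrate_run(cfg, std_seeds)
        model.to_json(model_path)
        stage(
            f"calibration: slope={model.slope:.4g}, R2={model.r_squared:.5f}, "
            f"LLOQ={model.lloq_ugkg:.4g} ug/kg"
        )
    run.outputs["calibration"] = str(model_path)

    # -- segmentation + quantification ------------------------------------
    s = cfg.segmentation
    params = ThresholdParams(window_px=s.window_px)
    sections = []
    for r, img in enumerate(intensity_images):
        conc = apply_calibration(img, model)
        seg = run_method(conc, s.method, params, k=s.k_clusters, keep=s.keep_clusters)
        mask_img = ElementalImage(
            values=seg.mask.astype(float),
            pixel_dx_um=conc.pixel_dx_um,
            pixel_dy_um=conc.pixel_dy_um,
            unit="mask",
            channel=conc.channel,
            provenance=[*conc.provenance, f"mask: {seg.method}"],
        )
        write_image(mask_img, out / f"replicate_{r}_mask.tiff")
        calibrated_paths.append(str(out / f"replicate_{r}_mask.tiff"))
        sections.append(
            masked_mean_concentration(conc, seg, model.lloq_ugkg, f"replicate_{r}")
        )
    stage(f"segmentation: {s.method} on {n_rep} replicates")

    if n_rep >= 2:
        rep = replicate_stats(sections, lloq_ugkg=model.lloq_ugkg)
        summary = {
            "mean_ugkg": rep.mean_ugkg,
            "sd_ugkg": rep.sd_ugkg,
            "cv_percent": rep.cv_percent,
            "n_used": rep.n_used,
            "n_below_lloq": rep.n_below_lloq,
            "grubbs_removed": rep.grubbs.removed,
            "cv_within_fda_limit": rep.cv_within_fda_limit,
        }
    else:
        summary = {"mean_ugkg": sections[0].mean_conc_ugkg, "n_used": 1}

    run.report = _round_sig(
        {
            "seed": cfg.seed,
            "method": s.method,
            "lloq_ugkg": model.lloq_ugkg,
            "calibration_r_squared": model.r_squared,
            "sections": [
                {
                    "section_id": q.section_id,
                    "mean_ugkg": q.mean_conc_ugkg,
                    "reported": q.formatted(),
                    "n_mask_pixels": q.n_mask_pixels,
                    "below_lloq": q.below_lloq,
                }
                for q in sections
            ],
            "summary": summary,
        }
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(run.report, indent=1, sort_keys=True))
    run.outputs["report"] = str(report_path)
    stage(f"report written to {report_path}")
    return run


def compare_segmentation(
    images: list,
    model: CalibrationModel,
    cfg: RunConfig,
):
    """Six-method comparison: per-method replicate concentration and CV.

    ``images`` are filtered intensity images (one per replicate section);
    returns a pandas DataFrame with one row per method, mirroring a
    method x (concentration, CV) comparison table.
    """
    import pandas as pd

    s = cfg.segmentation
    params = ThresholdParams(window_px=s.window_px)
    rows = []
    for method in METHOD_NAMES:
        sections = []
        for r, img in enumerate(images):
            conc = apply_calibration(img, model)
            try:
                seg = run_method(conc, method, params, k=s.k_clusters, keep=s.keep_clusters)
            except ImsiqError as e:
                log.warning("method %s failed on replicate %d: %s", method, r, e)
                continue
            sections.append(
                masked_mean_concentration(conc, seg, model.lloq_ugkg, f"replicate_{r}")
            )
        if len(sections) >= 2:
            try:
                rep = replicate_stats(sections, lloq_ugkg=model.lloq_ugkg)
                mean, cv, n_used = rep.mean_ugkg, rep.cv_percent, rep.n_used
            except ImsiqError:
                # most sections below LLOQ: report the raw mean without a CV
                mean = float(np.mean([q.mean_conc_ugkg for q in sections]))
                cv, n_used = np.nan, 0
            rows.append(
                {
                    "method": method,
                    "mean_ugkg": mean,
                    "cv_percent": cv,
                    "n_used": n_used,
                    "positive_fraction": float(
                        np.mean([q.n_mask_pixels for q in sections])
                        / images[0].values.size
                    ),
                }
            )
        elif sections:
            rows.append(
                {
                    "method": method,
                    "mean_ugkg": sections[0].mean_conc_ugkg,
                    "cv_percent": np.nan,
                    "n_used": 1,
                    "positive_fraction": sections[0].n_mask_pixels / images[0].values.size,
                }
            )
    return pd.DataFrame(rows)
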