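"""End-to-end analysis drivers: simulate/load -> preprocess -> calibrate ->
E/S maps -> confidence filter -> report.

The functional pieces (:func:`preprocess_simulated_study`,
:func:`analyze_study`) are reusable from scripts and tests;
:func:`run_pipeline` wires them to files and a YAML-style config for the
command line.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CorrectionFactors, calibrate_dataset, corrected_fret_image
from .forward_model import (
    CameraModel,
    SimulatedStudy,
    instrument_from_factors,
    render_dark_frame,
    simulate_calibration_study,
)
from .fret_maps import (
    compute_es_maps,
    correlation_diagnostics,
    per_cell_stats,
    summarize_per_cell,
)
from .preprocessing import (
    ImageTriplet,
    SegmentationConfig,
    apply_registration,
    correct_triplet,
    label_cells,
    segment_cells,
)
from .stoichiometry_filter import FilterConfig, confidence_weights, weighted_gaussian_filter

__all__ = [
    "PipelineError",
    "PreparedStudy",
    "StudyAnalysis",
    "preprocess_simulated_study",
    "analyze_study",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PreparedStudy:
    """Camera-corrected, masked triplets grouped by sample kind."""

    donor_only: list[ImageTriplet]
    acceptor_only: list[ImageTriplet]
    constructs: dict[str, list[ImageTriplet]]
    stoichiometry: float = 0.5


@dataclass
class StudyAnalysis:
    """Calibration, pooled pixel maps and diagnostics for one study."""

    factors: CorrectionFactors
    per_construct: dict[str, dict] = field(default_factory=dict)
    per_cell: pd.DataFrame | None = None
    pooled_E: np.ndarray | None = None
    pooled_S: np.ndarray | None = None
    pooled_I_AA: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def preprocess_simulated_study(
    study: SimulatedStudy,
    seg_config: SegmentationConfig | None = None,
    n_dark_average: int = 20,
    rng: np.random.Generator | int | None = None,
) -> PreparedStudy:
    """Camera-correct and segment every rendered field of a synthetic study.

    The dark reference is an average of ``n_dark_average`` rendered dark
    frames, exactly as one would acquire it at the microscope.
    """
    rng = np.random.default_rng(rng)
    shape = study.donor_only[0].scene.shape if study.donor_only else \
        next(iter(study.constructs.values()))[0].scene.shape
    dark = render_dark_frame(study.camera, shape, n_average=n_dark_average,
                             rng=rng)

    def _prep(fields):
        out = []
        for f in fields:
            trip = correct_triplet(f.raw.I_DD, f.raw.I_DA, f.raw.I_AA,
                                   dark=dark)
            trip.mask = segment_cells(trip, seg_config)
            out.append(trip)
        return out

    return PreparedStudy(
        donor_only=_prep(study.donor_only),
        acceptor_only=_prep(study.acceptor_only),
        constructs={k: _prep(v) for k, v in study.constructs.items()},
        stoichiometry=study.stoichiometry,
    )


def analyze_study(
    prepared: PreparedStudy,
    factors: CorrectionFactors | None = None,
    s0: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> StudyAnalysis:
    """Calibrate (unless factors are supplied) and map every construct field.

    Produces pooled in-cell pixel vectors of E, S and I_AA, per-cell
    medians per construct, and the rank-correlation diagnostics:
    Spearman(E, I_AA) for concentration independence, Spearman(E, S) for
    calibration quality, and the same with gamma = beta = 1 to expose what
    the full calibration corrects.
    """
    rng = np.random.default_rng(rng)
    s0 = prepared.stoichiometry if s0 is None else s0
    if factors is None:
        all_fret = [t for ts in prepared.constructs.values() for t in ts]
        factors = calibrate_dataset(
            prepared.donor_only, prepared.acceptor_only, all_fret,
            s0=s0, rng=rng,
        )

    raw_factors = CorrectionFactors(
        alpha_BT=factors.alpha_BT, delta_DE=factors.delta_DE,
        gamma_M=1.0, beta_X=1.0, S0_assumed=s0,
    )

    analysis = StudyAnalysis(factors=factors)
    pooled_e, pooled_s, pooled_aa = [], [], []
    pooled_e_raw, pooled_s_raw = [], []
    tables = []
    for name, triplets in prepared.constructs.items():
        cell_tables = []
        offset = 0
        for trip in triplets:
            labels = label_cells(trip.mask)
            maps = compute_es_maps(trip, factors)
            tab = per_cell_stats(maps.E, maps.S, labels, maps.valid)
            tab["cell"] += offset
            offset += int(labels.max())
            cell_tables.append(tab)
            pooled_e.append(maps.E[maps.valid])
            pooled_s.append(maps.S[maps.valid])
            pooled_aa.append(trip.I_AA[maps.valid])
            raw_maps = compute_es_maps(trip, raw_factors)
            pooled_e_raw.append(raw_maps.E[raw_maps.valid])
            pooled_s_raw.append(raw_maps.S[raw_maps.valid])
        table = pd.concat(cell_tables, ignore_index=True)
        table.insert(0, "construct", name)
        tables.append(table)
        analysis.per_construct[name] = summarize_per_cell(table)
    analysis.per_cell = pd.concat(tables, ignore_index=True)
    analysis.pooled_E = np.concatenate(pooled_e)
    analysis.pooled_S = np.concatenate(pooled_s)
    analysis.pooled_I_AA = np.concatenate(pooled_aa)

    e, s, aa = analysis.pooled_E, analysis.pooled_S, analysis.pooled_I_AA
    e_raw = np.concatenate(pooled_e_raw)
    s_raw = np.concatenate(pooled_s_raw)
    analysis.diagnostics = {
        "n_pixels": int(e.size),
        "spearman_E_IAA": correlation_diagnostics(e, aa),
        "spearman_E_S": correlation_diagnostics(e, s),
        "spearman_E_S_uncalibrated": correlation_diagnostics(e_raw, s_raw),
        "r_squared": factors.r_squared,
    }
    return analysis


def _simulate_stage(sim_cfg: dict, rng) -> SimulatedStudy:
    kwargs = dict(sim_cfg)
    factors = kwargs.pop("factors", None)
    photon_scale = kwargs.pop("photon_scale", 1.0)
    if factors is not None:
        kwargs["instrument"] = instrument_from_factors(
            photon_scale=photon_scale, **factors
        )
    camera = kwargs.pop("camera", None)
    if camera is not None:
        kwargs["camera"] = CameraModel(**camera)
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "concentration_range" in kwargs:
        kwargs["concentration_range"] = tuple(kwargs["concentration_range"])
    if "radius_range" in kwargs:
        kwargs["radius_range"] = tuple(kwargs["radius_range"])
    return simulate_calibration_study(rng=rng, **kwargs)


def _load_stage(inputs: dict) -> PreparedStudy:
    from . import io as qio

    order = inputs.get("channel_order", "DD,DA,AA")
    dark = qio.read_map(inputs["dark"]) if inputs.get("dark") else None
    flat = qio.read_map(inputs["flat"]) if inputs.get("flat") else None
    transform = (qio.load_transform(inputs["transform"])
                 if inputs.get("transform") else None)
    seg = SegmentationConfig(**inputs.get("segmentation", {}))

    def _prep(paths):
        out = []
        for p in paths:
            raw = qio.read_triplet(p, channel_order=order)
            trip = correct_triplet(raw.I_DD, raw.I_DA, raw.I_AA,
                                   dark=dark, flat=flat)
            if transform is not None:
                trip.I_DD = apply_registration(trip.I_DD, transform)
            trip.mask = segment_cells(trip, seg)
            out.append(trip)
        return out

    return PreparedStudy(
        donor_only=_prep(inputs.get("donor_only", [])),
        acceptor_only=_prep(inputs.get("acceptor_only", [])),
        constructs={k: _prep(v)
                    for k, v in inputs.get("constructs", {}).items()},
        stoichiometry=float(inputs.get("s0", 0.5)),
    )


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a configuration mapping.

    The config either carries a ``simulate`` block (a synthetic study is
    generated from the given seed) or an ``inputs`` block pointing at TIFF
    triplets.  Writes calibration JSON, E/S/W/E_filt maps, masks, the
    per-cell CSV and a diagnostics JSON to ``output_dir``; returns the
    diagnostics.  Deterministic for a fixed seed.
    """
    from . import io as qio

    output_dir = Path(output_dir or config.get("output_dir", "quantifret_out"))
    output_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    log: list[str] = [f"quantifret {__version__}", f"seed {seed}"]

    try:
        if "simulate" in config:
            study = _simulate_stage(config["simulate"], rng)
            prepared = preprocess_simulated_study(study, rng=rng)
            log.append("stage simulate: synthetic study generated")
        elif "inputs" in config:
            prepared = _load_stage(config["inputs"])
            log.append("stage load: triplets read and corrected")
        else:
            raise PipelineError(
                "[configure] config needs a 'simulate' or 'inputs' block"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[preprocess] {exc}") from exc

    try:
        factors = None
        if config.get("calibration_file"):
            factors = qio.load_calibration(config["calibration_file"])
            log.append(f"stage calibrate: loaded {config['calibration_file']}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            analysis = analyze_study(prepared, factors=factors,
                                     s0=config.get("s0"), rng=rng)
        log.append("stage analyze: E/S maps and diagnostics computed")
    except Exception as exc:
        raise PipelineError(f"[calibrate/analyze] {exc}") from exc

    try:
        fcfg = FilterConfig(**config.get("filter", {}))
        outputs: dict[str, str] = {}
        cal_path = qio.save_calibration(output_dir / "calibration.json",
                                        analysis.factors)
        outputs["calibration"] = str(cal_path)
        for name, triplets in prepared.constructs.items():
            for i, trip in enumerate(triplets):
                maps = compute_es_maps(trip, analysis.factors)
                w = confidence_weights(maps.S, fcfg.S0, fcfg.sigma_S,
                                       valid=maps.valid)
                e_filt, _ = weighted_gaussian_filter(maps.E, w, fcfg)
                stem = f"{name}_{i:02d}"
                qio.write_triplet(output_dir / f"{stem}_triplet.tif", trip)
                qio.write_mask(output_dir / f"{stem}_mask.tif", trip.mask)
                qio.write_map(output_dir / f"{stem}_E.tif", maps.E)
                qio.write_map(output_dir / f"{stem}_S.tif", maps.S)
                qio.write_map(output_dir / f"{stem}_W.tif", w)
                qio.write_map(output_dir / f"{stem}_E_filt.tif", e_filt)
        analysis.per_cell.to_csv(output_dir / "per_cell.csv", index=False)
        outputs["per_cell"] = str(output_dir / "per_cell.csv")
        log.append("stage filter/write: maps and tables written")
    except Exception as exc:
        raise PipelineError(f"[filter/write] {exc}") from exc

    diagnostics = {
        "seed": seed,
        "software_version": __version__,
        "factors": analysis.factors.to_dict(),
        "per_construct": analysis.per_construct,
        **analysis.diagnostics,
    }
    (output_dir / "diagnostics.json").write_text(
        json.dumps(diagnostics, indent=2, sort_keys=True)
    )
    (output_dir / "run.log").write_text("\n".join(log) + "\n")
    return diagnostics
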