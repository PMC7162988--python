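"""Pixelwise FRET-efficiency and stoichiometry maps and their diagnostics.

With the crosstalk-corrected sensitized emission
``I_DA_corr = I_DA - alpha_BT*I_DD - delta_DE*I_AA`` the two master
equations are evaluated in every pixel:

    E = I_DA_corr / (gamma_M * I_DD + I_DA_corr)
    S = (gamma_M * I_DD + I_DA_corr) / (gamma_M * I_DD + I_DA_corr + I_AA / beta_X)

E is the FRET probability; S the donor fraction n_D/(n_D+n_A).  Noise can
push either outside [0, 1]; values are never clipped (that would bias
medians) — instead pixels with a non-positive denominator are flagged
invalid (NaN) and excluded from every statistic.  The stoichiometry-based
confidence filter downstream handles the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CorrectionFactors, corrected_fret_image
from .preprocessing import ImageTriplet

__all__ = [
    "ESMaps",
    "fret_efficiency",
    "stoichiometry",
    "compute_es_maps",
    "es_histogram",
    "correlation_diagnostics",
    "per_cell_stats",
    "summarize_per_cell",
]


@dataclass
class ESMaps:
    """Pixelwise E and S maps with a validity flag and per-cell summaries."""

    E: np.ndarray
    S: np.ndarray
    valid: np.ndarray
    per_cell: pd.DataFrame | None = None


def _base_valid(triplet: ImageTriplet) -> np.ndarray:
    valid = np.isfinite(triplet.I_DD) & np.isfinite(triplet.I_DA) \
        & np.isfinite(triplet.I_AA)
    if triplet.mask is not None:
        valid &= triplet.mask
    return valid


def fret_efficiency(
    triplet: ImageTriplet, factors: CorrectionFactors
) -> tuple[np.ndarray, np.ndarray]:
    """FRET probability map E and its validity flag.

    Pixels where the total donor signal ``gamma_M*I_DD + I_DA_corr`` is
    non-positive carry no usable FRET information and are NaN/invalid.
    """
    c = corrected_fret_image(triplet, factors.alpha_BT, factors.delta_DE)
    q = factors.gamma_M * triplet.I_DD + c
    valid = _base_valid(triplet) & np.isfinite(q) & (q > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(valid, c / np.where(valid, q, 1.0), np.nan)
    return e, valid


def stoichiometry(
    triplet: ImageTriplet, factors: CorrectionFactors
) -> tuple[np.ndarray, np.ndarray]:
    """Stoichiometry map S (donor fraction) and its validity flag."""
    c = corrected_fret_image(triplet, factors.alpha_BT, factors.delta_DE)
    q = factors.gamma_M * triplet.I_DD + c
    den = q + triplet.I_AA / factors.beta_X
    valid = _base_valid(triplet) & np.isfinite(den) & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(valid, q / np.where(valid, den, 1.0), np.nan)
    return s, valid


def compute_es_maps(
    triplet: ImageTriplet,
    factors: CorrectionFactors,
    cell_label: np.ndarray | None = None,
    min_pixels_per_cell: int = 10,
) -> ESMaps:
    """Joint E/S maps; a pixel is valid when both maps are defined."""
    e, ve = fret_efficiency(triplet, factors)
    s, vs = stoichiometry(triplet, factors)
    valid = ve & vs
    e = np.where(valid, e, np.nan)
    s = np.where(valid, s, np.nan)
    per_cell = None
    if cell_label is not None:
        per_cell = per_cell_stats(e, s, cell_label, valid,
                                  min_pixels=min_pixels_per_cell)
    return ESMaps(E=e, S=s, valid=valid, per_cell=per_cell)


def es_histogram(
    e_map: np.ndarray,
    s_map: np.ndarray,
    valid: np.ndarray | None = None,
    bins: int | tuple[int, int] = 100,
    extent: tuple[tuple[float, float], tuple[float, float]] = ((-0.2, 1.2),
                                                              (-0.2, 1.2)),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of (E, S) over valid pixels.

    Returns (counts, e_edges, s_edges); counts[i, j] is the number of valid
    pixels in E bin i and S bin j, so the marginals are recovered by
    summing over an axis.
    """
    e = np.ravel(e_map)
    s = np.ravel(s_map)
    sel = np.isfinite(e) & np.isfinite(s)
    if valid is not None:
        sel &= np.ravel(valid)
    h, e_edges, s_edges = np.histogram2d(e[sel], s[sel], bins=bins,
                                         range=extent)
    return h, e_edges, s_edges


def correlation_diagnostics(
    e_map: np.ndarray,
    reference: np.ndarray,
    valid: np.ndarray | None = None,
    min_pixels: int = 10,
) -> float:
    """Spearman rank correlation between E and a reference map.

    Used with reference = I_AA (concentration independence: I_AA is the
    only channel unaffected by FRET), reference = S (calibration quality)
    or reference = total donor signal.  Returns NaN with a warning for
    constant inputs, where the rank correlation is undefined.
    """
    e = np.ravel(e_map)
    r = np.ravel(reference)
    sel = np.isfinite(e) & np.isfinite(r)
    if valid is not None:
        sel &= np.ravel(valid)
    if sel.sum() < min_pixels:
        raise ValueError(f"need at least {min_pixels} valid pixels")
    e, r = e[sel], r[sel]
    if np.ptp(e) == 0 or np.ptp(r) == 0:
        warnings.warn("constant input: rank correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(e, r).statistic)


def per_cell_stats(
    e_map: np.ndarray,
    s_map: np.ndarray,
    cell_label: np.ndarray,
    valid: np.ndarray | None = None,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Median E and S per labelled cell.

    Cells with fewer than ``min_pixels`` valid pixels are excluded with a
    warning; pixel-poor medians would be dominated by noise.
    """
    e = np.ravel(e_map)
    s = np.ravel(s_map)
    lab = np.ravel(np.asarray(cell_label))
    sel = np.isfinite(e) & (lab > 0)
    if valid is not None:
        sel &= np.ravel(valid)
    rows, skipped = [], 0
    for cid in np.unique(lab[sel]):
        in_cell = sel & (lab == cid)
        n = int(in_cell.sum())
        if n < min_pixels:
            skipped += 1
            continue
        rows.append({
            "cell": int(cid),
            "n_pixels": n,
            "median_E": float(np.median(e[in_cell])),
            "median_S": float(np.nanmedian(s[in_cell])),
        })
    if skipped:
        warnings.warn(
            f"excluded {skipped} cells with fewer than {min_pixels} valid pixels",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["cell", "n_pixels", "median_E",
                                       "median_S"])


def summarize_per_cell(per_cell: pd.DataFrame) -> dict:
    """Dataset summary: mean of per-cell medians with its standard error.

    Cell-to-cell variability, not pixel statistics, dominates the
    uncertainty of the dataset mean, so the SEM is taken over cells.
    """
    n = len(per_cell)
    if n == 0:
        raise ValueError("empty per-cell table")
    out = {"n_cells": n}
    for col, key in (("median_E", "E"), ("median_S", "S")):
        vals = per_cell[col].to_numpy(dtype=float)
        out[f"mean_{key}"] = float(np.mean(vals))
        out[f"sem_{key}"] = (
            float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        )
    return out
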