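"""Calibration of the four correction factors.

Sensitized-emission FRET needs four instrument constants before pixel
intensities can be turned into absolute FRET efficiencies:

* ``alpha_BT`` — donor bleedthrough into the acceptor channel,
* ``delta_DE`` — direct excitation of the acceptor at the donor wavelength,
* ``gamma_M``  — relative detected brightness of acceptor vs donor emission,
* ``beta_X``   — relative excitation rate of acceptor vs donor.

The crosstalks come from donor-only and acceptor-only samples as pixelwise
intensity ratios (pooled median).  ``gamma_M`` and ``beta_X`` come from a
single least-squares plane fit in the 3D intensity space
{I_DD, I_DA_corr, I_AA} of a known-stoichiometry dataset:

    beta*gamma*I_DD + beta*I_DA_corr = S0/(1-S0) * I_AA

which for a 1:1 construct (S0 = 0.5) reduces to the right-hand side I_AA.
A dataset with a single FRET level collapses onto a line in that space and
leaves the plane undetermined; the fit therefore refuses near-collinear
clouds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocessing import ImageTriplet

__all__ = [
    "CorrectionFactors",
    "CrosstalkResult",
    "PlaneFitResult",
    "CollinearityError",
    "crosstalk_factor",
    "corrected_fret_image",
    "fit_plane",
    "bootstrap_calibration",
    "calibrate_dataset",
]


class CollinearityError(ValueError):
    """Raised when the pixel cloud does not constrain the calibration plane."""


@dataclass
class CorrectionFactors:
    """The four calibration constants with optional fit diagnostics.

    All four factors are dimensionless.  ``S0_assumed`` records the
    stoichiometry assumed during the plane fit (0.5 for 1:1 constructs).
    """

    alpha_BT: float
    delta_DE: float
    gamma_M: float
    beta_X: float
    alpha_sd: float | None = None
    delta_sd: float | None = None
    gamma_sd: float | None = None
    beta_sd: float | None = None
    r_squared: float | None = None
    n_pixels: int | None = None
    n_cells: int | None = None
    S0_assumed: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma_M <= 0 or self.beta_X <= 0:
            raise ValueError("gamma_M and beta_X must be strictly positive")
        if self.alpha_BT < 0 or self.delta_DE < 0:
            raise ValueError("crosstalk factors must be non-negative")
        if self.r_squared is not None and not -np.inf < self.r_squared <= 1:
            raise ValueError("r_squared must be <= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionFactors":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class CrosstalkResult:
    """Pooled-median crosstalk ratio with a cell-bootstrap uncertainty."""

    factor: float
    sd: float
    kind: str
    n_pixels: int
    n_cells: int
    histogram: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


@dataclass
class PlaneFitResult:
    """Result of the single-step plane fit for (beta_X, gamma_M)."""

    beta_X: float
    gamma_M: float
    r_squared: float
    n_pixels: int
    singular_value_ratio: float
    S0: float


def _iter_cell_pixel_ratios(
    triplets: Iterable[ImageTriplet], kind: str, noise_floor: float
) -> list[np.ndarray]:
    """Per-cell arrays of pixelwise crosstalk ratios."""
    from skimage import measure

    cells: list[np.ndarray] = []
    for t in triplets:
        if t.mask is None:
            raise ValueError("crosstalk triplets must carry a cell mask")
        num = t.I_DA
        den = t.I_DD if kind == "donor_only" else t.I_AA
        labels = measure.label(t.mask)
        for lab in range(1, labels.max() + 1):
            sel = (labels == lab) & np.isfinite(num) & np.isfinite(den)
            sel &= den > noise_floor
            if sel.any():
                cells.append(num[sel] / den[sel])
    return cells


def crosstalk_factor(
    triplets: Sequence[ImageTriplet],
    kind: str,
    noise_floor: float | None = None,
    read_noise_sd: float = 2.0,
    floor_k: float = 5.0,
    n_boot: int = 1000,
    hist_bins: int = 200,
    rng: np.random.Generator | int | None = None,
) -> CrosstalkResult:
    """Median pixelwise crosstalk ratio from single-fluorophore cells.

    ``kind`` selects the ratio: ``donor_only`` gives I_DA/I_DD (bleedthrough
    alpha_BT), ``acceptor_only`` gives I_DA/I_AA (direct excitation
    delta_DE).  Ratios are pooled over all masked pixels of all cells and
    the median is taken; the uncertainty is the s.d. of the pooled median
    under bootstrap resampling of whole cells.  Pixels whose denominator
    falls below ``noise_floor`` (default ``floor_k * read_noise_sd``) are
    excluded to avoid ratio blow-up in dark pixels.
    """
    if kind not in ("donor_only", "acceptor_only"):
        raise ValueError(f"unknown kind {kind!r}")
    if not triplets:
        raise ValueError("need at least one triplet")
    if noise_floor is None:
        noise_floor = floor_k * read_noise_sd

    # crude heuristic against swapped sample types
    med_aa = np.nanmedian([np.nanmedian(t.I_AA[t.mask]) for t in triplets if t.mask.any()])
    med_dd = np.nanmedian([np.nanmedian(t.I_DD[t.mask]) for t in triplets if t.mask.any()])
    if kind == "donor_only" and med_aa > 0.25 * max(med_dd, 1e-12):
        warnings.warn(
            "donor-only data shows substantial I_AA signal; check sample kind",
            stacklevel=2,
        )
    if kind == "acceptor_only" and med_dd > 0.25 * max(med_aa, 1e-12):
        warnings.warn(
            "acceptor-only data shows substantial I_DD signal; check sample kind",
            stacklevel=2,
        )

    cells = _iter_cell_pixel_ratios(triplets, kind, noise_floor)
    if not cells:
        raise ValueError("no usable pixels above the noise floor")
    if len(cells) < 5:
        warnings.warn(
            f"only {len(cells)} cells for {kind} crosstalk; at least 5 recommended",
            stacklevel=2,
        )

    pooled = np.concatenate(cells)
    factor = float(np.median(pooled))

    rng = np.random.default_rng(rng)
    n = len(cells)
    meds = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        meds[i] = np.median(np.concatenate([cells[j] for j in idx]))
    sd = float(meds.std(ddof=1)) if n_boot > 1 else 0.0

    lo, hi = np.percentile(pooled, [0.5, 99.5])
    if hi - lo < 1e-9 * max(1.0, abs(lo)):
        # degenerate (noise-free) ratio distribution
        lo, hi = lo - 0.5, hi + 0.5
    hist = np.histogram(pooled, bins=hist_bins, range=(lo, hi))
    return CrosstalkResult(
        factor=factor, sd=sd, kind=kind,
        n_pixels=pooled.size, n_cells=n, histogram=hist,
    )


def corrected_fret_image(
    triplet: ImageTriplet, alpha_BT: float, delta_DE: float
) -> np.ndarray:
    """Crosstalk-corrected sensitized-emission image.

    I_DA_corr = I_DA - alpha_BT * I_DD - delta_DE * I_AA.  Negative values
    (noise around zero) are preserved, not clipped.
    """
    if alpha_BT < 0 or delta_DE < 0:
        raise ValueError("crosstalk factors must be non-negative")
    return triplet.I_DA - alpha_BT * triplet.I_DD - delta_DE * triplet.I_AA


def fit_plane(
    i_dd: np.ndarray,
    i_da_corr: np.ndarray,
    i_aa: np.ndarray,
    s0: float = 0.5,
    cond_threshold: float = 1e-3,
) -> PlaneFitResult:
    """Single-step determination of beta_X and gamma_M.

    Solves, by ordinary least squares without intercept,

        [I_DD, I_DA_corr] @ [gamma*beta, beta] = S0/(1-S0) * I_AA

    over all supplied pixels.  Requires the pixel cloud to spread over at
    least two FRET levels; a near-collinear cloud (ratio of singular values
    of the design matrix below ``cond_threshold``) raises
    :class:`CollinearityError`.
    """
    if not 0.0 < s0 < 1.0:
        raise ValueError("S0 must lie strictly between 0 and 1")
    i_dd = np.ravel(np.asarray(i_dd, dtype=float))
    i_da_corr = np.ravel(np.asarray(i_da_corr, dtype=float))
    i_aa = np.ravel(np.asarray(i_aa, dtype=float))
    ok = np.isfinite(i_dd) & np.isfinite(i_da_corr) & np.isfinite(i_aa)
    i_dd, i_da_corr, i_aa = i_dd[ok], i_da_corr[ok], i_aa[ok]
    if i_dd.size < 2:
        raise ValueError("need at least two pixels for the plane fit")

    X = np.column_stack([i_dd, i_da_corr])
    y = (s0 / (1.0 - s0)) * i_aa

    # column-normalise before the conditioning check so the ratio measures
    # geometric spread, not intensity units
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        sv_ratio = 0.0
    else:
        sv = np.linalg.svd(X / norms, compute_uv=False)
        sv_ratio = float(sv[-1] / sv[0])
    if sv_ratio < cond_threshold:
        raise CollinearityError(
            "FRET range insufficient to determine plane: the pixel cloud is "
            f"collinear in {{I_DD, I_DA_corr, I_AA}} (singular-value ratio "
            f"{sv_ratio:.2e} < {cond_threshold:.0e})"
        )

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    gamma_beta, beta = coef
    if beta <= 0:
        raise ValueError(f"plane fit produced non-positive beta_X = {beta:.4g}")
    gamma = gamma_beta / beta
    if gamma <= 0:
        raise ValueError(f"plane fit produced non-positive gamma_M = {gamma:.4g}")

    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PlaneFitResult(
        beta_X=float(beta), gamma_M=float(gamma), r_squared=r2,
        n_pixels=int(i_dd.size), singular_value_ratio=sv_ratio, S0=s0,
    )


def bootstrap_calibration(
    i_dd: np.ndarray,
    i_da_corr: np.ndarray,
    i_aa: np.ndarray,
    s0: float = 0.5,
    sample_sizes: Sequence[int] = (1000, 10_000, 100_000),
    n_reps: int = 200,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Plane-fit dispersion as a function of dataset size.

    For each requested size, draws ``n_reps`` random pixel subsets (without
    replacement), refits the plane, and reports the standard deviation of
    beta_X and gamma_M over the repetitions.  Subsets that trigger the
    collinearity guard are skipped and counted.
    """
    rng = np.random.default_rng(rng)
    i_dd = np.ravel(i_dd)
    i_da_corr = np.ravel(i_da_corr)
    i_aa = np.ravel(i_aa)
    n = i_dd.size
    rows = []
    for size in sample_sizes:
        if size > n:
            raise ValueError(f"sample size {size} exceeds dataset size {n}")
        betas, gammas, failed = [], [], 0
        for _ in range(n_reps):
            idx = rng.choice(n, size=size, replace=False)
            try:
                fit = fit_plane(i_dd[idx], i_da_corr[idx], i_aa[idx], s0=s0)
            except (CollinearityError, ValueError):
                failed += 1
                continue
            betas.append(fit.beta_X)
            gammas.append(fit.gamma_M)
        rows.append({
            "sample_size": size,
            "sd_beta": float(np.std(betas, ddof=1)) if len(betas) > 1 else 0.0,
            "sd_gamma": float(np.std(gammas, ddof=1)) if len(gammas) > 1 else 0.0,
            "n_ok": len(betas),
            "n_failed": failed,
        })
    return pd.DataFrame(rows)


def calibrate_dataset(
    donor_only: Sequence[ImageTriplet],
    acceptor_only: Sequence[ImageTriplet],
    fret_triplets: Sequence[ImageTriplet],
    s0: float = 0.5,
    noise_floor: float | None = None,
    n_boot_crosstalk: int = 200,
    n_boot_plane: int = 100,
    rng: np.random.Generator | int | None = None,
) -> CorrectionFactors:
    """Full four-factor calibration from the three sample types.

    Runs the crosstalk medians, builds crosstalk-corrected FRET images for
    the known-stoichiometry dataset, pools all in-mask pixels and performs
    the plane fit.  Uncertainties on gamma_M/beta_X come from a pixel
    bootstrap at the full dataset size.
    """
    rng = np.random.default_rng(rng)
    alpha = crosstalk_factor(
        donor_only, "donor_only", noise_floor=noise_floor,
        n_boot=n_boot_crosstalk, rng=rng,
    )
    delta = crosstalk_factor(
        acceptor_only, "acceptor_only", noise_floor=noise_floor,
        n_boot=n_boot_crosstalk, rng=rng,
    )

    from skimage import measure

    dd_parts, c_parts, aa_parts = [], [], []
    n_cells = 0
    for t in fret_triplets:
        if t.mask is None:
            raise ValueError("calibration triplets must carry a cell mask")
        c = corrected_fret_image(t, alpha.factor, delta.factor)
        sel = t.mask & np.isfinite(t.I_DD) & np.isfinite(c) & np.isfinite(t.I_AA)
        dd_parts.append(t.I_DD[sel])
        c_parts.append(c[sel])
        aa_parts.append(t.I_AA[sel])
        n_cells += int(measure.label(t.mask).max())
    i_dd = np.concatenate(dd_parts)
    i_c = np.concatenate(c_parts)
    i_aa = np.concatenate(aa_parts)

    fit = fit_plane(i_dd, i_c, i_aa, s0=s0)

    gamma_sd = beta_sd = None
    if n_boot_plane > 1:
        betas, gammas = [], []
        n = i_dd.size
        for _ in range(n_boot_plane):
            idx = rng.integers(0, n, n)
            try:
                f = fit_plane(i_dd[idx], i_c[idx], i_aa[idx], s0=s0)
            except (CollinearityError, ValueError):
                continue
            betas.append(f.beta_X)
            gammas.append(f.gamma_M)
        if len(betas) > 1:
            beta_sd = float(np.std(betas, ddof=1))
            gamma_sd = float(np.std(gammas, ddof=1))

    return CorrectionFactors(
        alpha_BT=alpha.factor, delta_DE=delta.factor,
        gamma_M=fit.gamma_M, beta_X=fit.beta_X,
        alpha_sd=alpha.sd, delta_sd=delta.sd,
        gamma_sd=gamma_sd, beta_sd=beta_sd,
        r_squared=fit.r_squared, n_pixels=fit.n_pixels,
        n_cells=n_cells, S0_assumed=s0,
    )
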