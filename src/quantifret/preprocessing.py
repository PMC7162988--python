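"""Camera correction, channel registration and cell segmentation.

Raw frames are corrected by subtracting the camera dark frame and dividing
by a mean-normalised flat-field image.  The donor-channel image is then
warped onto the acceptor-channel grid with an affine transform estimated
from bead images (local cross-correlation displacements, least-squares
affine fit).  Finally a cell mask restricts all downstream statistics to
in-cell pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageTriplet",
    "ChannelTransform",
    "SegmentationConfig",
    "correct_camera",
    "correct_triplet",
    "estimate_registration",
    "apply_registration",
    "segment_cells",
    "label_cells",
]


@dataclass
class ImageTriplet:
    """The three registered, camera-corrected images for one field of view.

    ``I_DD``: donor excitation / donor emission, ``I_DA``: donor excitation /
    acceptor emission (sensitized), ``I_AA``: acceptor excitation / acceptor
    emission.  Pixels invalidated by warping are NaN.  ``mask`` flags
    in-cell pixels; ``provenance`` records the corrections applied.
    """

    I_DD: np.ndarray
    I_DA: np.ndarray
    I_AA: np.ndarray
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I_DD = np.asarray(self.I_DD, dtype=float)
        self.I_DA = np.asarray(self.I_DA, dtype=float)
        self.I_AA = np.asarray(self.I_AA, dtype=float)
        if not (self.I_DD.shape == self.I_DA.shape == self.I_AA.shape):
            raise ValueError("the three images must share one shape")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.I_DD.shape:
                raise ValueError("mask shape must match the images")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.I_DD.shape

    def masked_pixels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """In-mask, all-finite pixel values as three flat arrays."""
        if self.mask is None:
            raise ValueError("triplet has no mask")
        sel = self.mask & np.isfinite(self.I_DD) & np.isfinite(self.I_DA) \
            & np.isfinite(self.I_AA)
        return self.I_DD[sel], self.I_DA[sel], self.I_AA[sel]


@dataclass
class ChannelTransform:
    """Affine map from reference-grid coordinates to moving-image coordinates.

    ``matrix`` is 2x3 in (row, col) convention: a point ``o`` on the
    reference grid samples the moving image at ``matrix[:, :2] @ o +
    matrix[:, 2]``.  ``residual`` is the RMS misfit (px) of the affine to
    the measured local displacements.
    """

    matrix: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("transform matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("transform linear part is singular")

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "residual": self.residual}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTransform":
        return cls(np.asarray(d["matrix"]), float(d.get("residual", 0.0)))


def correct_camera(
    raw: np.ndarray, dark: np.ndarray | float | None = None,
    flat: np.ndarray | None = None,
) -> np.ndarray:
    """Dark-subtract and flatten a raw camera frame.

    ``flat`` must already be dark-subtracted; it is normalised to unit
    spatial mean before division, so the output keeps the intensity scale
    of the input.  Small negative values (read noise around zero) are
    preserved, not clipped.
    """
    out = np.asarray(raw, dtype=float)
    if dark is not None:
        dark = np.asarray(dark, dtype=float)
        if dark.ndim and dark.shape != out.shape:
            raise ValueError("dark frame shape must match the image")
        out = out - dark
    if flat is not None:
        flat = np.asarray(flat, dtype=float)
        if flat.shape != out.shape:
            raise ValueError("flat-field shape must match the image")
        n_bad = int(np.count_nonzero(flat <= 0))
        if n_bad:
            raise ValueError(
                f"flat-field has {n_bad} non-positive pixels; cannot divide"
            )
        out = out / (flat / flat.mean())
    return out


def correct_triplet(
    raw_dd: np.ndarray, raw_da: np.ndarray, raw_aa: np.ndarray,
    dark: np.ndarray | float | None = None,
    flat: np.ndarray | None = None,
) -> ImageTriplet:
    """Apply :func:`correct_camera` to all three channels of a field."""
    prov = {"dark_subtracted": dark is not None, "flat_fielded": flat is not None}
    return ImageTriplet(
        correct_camera(raw_dd, dark, flat),
        correct_camera(raw_da, dark, flat),
        correct_camera(raw_aa, dark, flat),
        provenance=prov,
    )


def estimate_registration(
    ref_image: np.ndarray,
    moving_image: np.ndarray,
    grid_shape: tuple[int, int] = (4, 4),
    upsample_factor: int = 100,
    min_regions: int = 3,
    n_iter: int = 3,
) -> ChannelTransform:
    """Affine registration from local cross-correlation displacements.

    The image pair (typically bead fields seen in the two channels) is cut
    into ``grid_shape`` blocks; each block yields a sub-pixel displacement
    from the cross-correlation peak.  A least-squares affine is fitted to
    the displacement map.  Blocks without signal are dropped; fewer than
    ``min_regions`` usable blocks is an error.

    Rotation or scale blurs the correlation peak within a block, which
    biases single-pass estimates; up to ``n_iter`` passes re-estimate the
    residual transform on the warped image and compose, stopping early
    once the residual stops improving.
    """
    ref = np.asarray(ref_image, dtype=float)
    mov = np.asarray(moving_image, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving images must share a shape")

    total = _estimate_registration_once(ref, mov, grid_shape,
                                        upsample_factor, min_regions)
    for _ in range(n_iter - 1):
        warped = apply_registration(mov, total)
        warped_filled = np.where(np.isfinite(warped), warped, 0.0)
        try:
            resid_tf = _estimate_registration_once(
                ref, warped_filled, grid_shape, upsample_factor, min_regions
            )
        except ValueError:
            break
        if resid_tf.residual >= total.residual:
            break
        L1, t1 = total.matrix[:, :2], total.matrix[:, 2]
        L2, t2 = resid_tf.matrix[:, :2], resid_tf.matrix[:, 2]
        composed = np.hstack([(L1 @ L2), (L1 @ t2 + t1)[:, None]])
        total = ChannelTransform(matrix=composed, residual=resid_tf.residual)
    return total


def _estimate_registration_once(
    ref: np.ndarray,
    mov: np.ndarray,
    grid_shape: tuple[int, int],
    upsample_factor: int,
    min_regions: int,
) -> ChannelTransform:
    gy, gx = grid_shape
    h, w = ref.shape
    ys = np.linspace(0, h, gy + 1, dtype=int)
    xs = np.linspace(0, w, gx + 1, dtype=int)

    centers, targets = [], []
    for i in range(gy):
        for j in range(gx):
            rb = ref[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            mb = mov[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            if rb.std() < 1e-9 * (abs(rb.mean()) + 1) or mb.std() == 0:
                continue
            shift, error, _ = phase_cross_correlation(
                rb, mb, upsample_factor=upsample_factor, normalization=None
            )
            center = np.array([(ys[i] + ys[i + 1]) / 2.0,
                               (xs[j] + xs[j + 1]) / 2.0])
            # phase_cross_correlation returns the shift that registers the
            # moving block onto the reference block; the feature seen at
            # `center` in the reference sits at `center - shift` in the
            # moving image.
            centers.append(center)
            targets.append(center - shift)
    if len(centers) < min_regions:
        raise ValueError(
            f"insufficient registration features: {len(centers)} usable "
            f"regions, need >= {min_regions}"
        )
    centers = np.asarray(centers)
    targets = np.asarray(targets)

    design = np.column_stack([centers, np.ones(len(centers))])
    coef, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)  # (3, 2)
    matrix = coef.T  # rows: output dims
    pred = design @ coef
    residual = float(np.sqrt(np.mean(np.sum((pred - targets) ** 2, axis=1))))
    return ChannelTransform(matrix=matrix, residual=residual)


def apply_registration(
    image: np.ndarray, transform: ChannelTransform, order: int = 1,
) -> np.ndarray:
    """Resample ``image`` onto the reference grid.

    Uses bilinear interpolation by default (``order=1``); ``order=0`` gives
    nearest-neighbour for exactness checks.  Pixels sampling outside the
    frame become NaN so that masks can exclude them; they are never
    zero-filled, which would bias the plane fit.
    """
    img = np.asarray(image, dtype=float)
    out = ndimage.affine_transform(
        img, transform.matrix[:, :2], offset=transform.matrix[:, 2],
        order=order, mode="constant", cval=np.nan,
    )
    return out


@dataclass
class SegmentationConfig:
    """Parameters of the Otsu-based cell mask.

    ``log_transform`` thresholds log1p(intensity) instead of intensity:
    expression levels span orders of magnitude, and a linear Otsu
    threshold silently drops the dimmest cells.
    """

    smooth_sigma: float = 2.0
    min_area: int = 100
    fill_holes: bool = True
    log_transform: bool = True
    threshold: float | None = None  # absolute threshold overriding Otsu


def segment_cells(
    triplet: ImageTriplet, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Boolean in-cell mask from the summed donor + acceptor image.

    Smooths I_DD + I_AA, thresholds (Otsu unless an absolute threshold is
    configured), removes components below ``min_area`` pixels, optionally
    fills holes, and excludes pixels invalidated by registration (NaN in
    any channel).
    """
    config = config or SegmentationConfig()
    total = triplet.I_DD + triplet.I_AA
    finite = np.isfinite(total) & np.isfinite(triplet.I_DA)
    work = np.where(finite, total, 0.0)
    if config.log_transform and config.threshold is None:
        work = np.log1p(np.clip(work, 0.0, None))
    if config.smooth_sigma > 0:
        work = ndimage.gaussian_filter(work, config.smooth_sigma)
    vals = work[finite]
    if vals.size == 0 or np.ptp(vals) == 0:
        warnings.warn("image is constant; returning empty mask", stacklevel=2)
        return np.zeros(triplet.shape, dtype=bool)
    thr = config.threshold if config.threshold is not None else threshold_otsu(vals)
    mask = (work > thr) & finite
    if config.min_area > 0:
        labels = measure.label(mask)
        counts = np.bincount(labels.ravel())
        keep = counts >= config.min_area
        keep[0] = False
        mask = keep[labels]
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask) & finite
    if not mask.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return mask


def label_cells(mask: np.ndarray) -> np.ndarray:
    """Integer label map of connected cell regions (0 = background)."""
    return measure.label(np.asarray(mask, dtype=bool))
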