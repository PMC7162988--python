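"""File formats: TIFF images, JSON calibrations/transforms, CSV tables.

Triplets travel as 3-page TIFF stacks with the channel order recorded in
the image description — the order is always declared explicitly, never
guessed, because a silent channel swap is the most dangerous failure mode
in three-image FRET.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .calibration import CorrectionFactors
from .preprocessing import ChannelTransform, ImageTriplet

__all__ = [
    "CHANNELS",
    "read_triplet",
    "write_triplet",
    "read_map",
    "write_map",
    "write_mask",
    "read_mask",
    "save_calibration",
    "load_calibration",
    "save_transform",
    "load_transform",
    "file_digest",
]

CHANNELS = ("DD", "DA", "AA")


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_order(channel_order: str) -> list[str]:
    order = [c.strip().upper() for c in channel_order.split(",")]
    if sorted(order) != sorted(CHANNELS):
        raise ValueError(
            f"channel order must be a permutation of {CHANNELS}, "
            f"got {channel_order!r}"
        )
    return order


def read_triplet(
    paths: str | Path | list[str | Path], channel_order: str = "DD,DA,AA"
) -> ImageTriplet:
    """Load a raw triplet from one 3-page TIFF or three single-page TIFFs.

    ``channel_order`` declares which page/file is which channel; there is
    deliberately no auto-detection.
    """
    order = _parse_order(channel_order)
    if isinstance(paths, (str, Path)):
        pages = tifffile.imread(paths)
        if pages.ndim != 3 or pages.shape[0] < 3:
            found = pages.shape[0] if pages.ndim == 3 else 1
            raise ValueError(
                f"expected a TIFF with >= 3 pages, found {found} in {paths}"
            )
        if pages.shape[0] > 3:
            raise ValueError(
                f"expected exactly 3 pages, found {pages.shape[0]} in {paths}"
            )
        images = {order[i]: pages[i].astype(float) for i in range(3)}
        source = [str(paths)]
    else:
        if len(paths) != 3:
            raise ValueError(f"expected 3 files, got {len(paths)}")
        images = {}
        for ch, p in zip(order, paths):
            img = tifffile.imread(p)
            if img.ndim != 2:
                raise ValueError(f"{p} is not a single-page 2D image")
            images[ch] = img.astype(float)
        source = [str(p) for p in paths]
    shapes = {im.shape for im in images.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    return ImageTriplet(
        images["DD"], images["DA"], images["AA"],
        provenance={"source": source, "channel_order": channel_order},
    )


def write_triplet(
    path: str | Path, triplet: ImageTriplet, dtype=np.float32
) -> Path:
    """Write a triplet as a 3-page TIFF in channel order DD, DA, AA."""
    path = Path(path)
    stack = np.stack([triplet.I_DD, triplet.I_DA, triplet.I_AA]).astype(dtype)
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        description=json.dumps({"channel_order": "DD,DA,AA",
                                "software": f"quantifret {__version__}"}),
    )
    return path


def write_map(path: str | Path, arr: np.ndarray) -> Path:
    """Write a float map (E, S, W, ...) as 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean mask as 8-bit TIFF (255 = in cell)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def save_calibration(
    path: str | Path, factors: CorrectionFactors,
    input_digests: dict[str, str] | None = None,
) -> Path:
    """Persist a calibration as JSON with version and input digests."""
    path = Path(path)
    payload = factors.to_dict()
    payload["software_version"] = __version__
    if input_digests:
        payload["input_digests"] = input_digests
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_calibration(path: str | Path) -> CorrectionFactors:
    return CorrectionFactors.from_dict(json.loads(Path(path).read_text()))


def save_transform(path: str | Path, transform: ChannelTransform) -> Path:
    path = Path(path)
    path.write_text(json.dumps(transform.to_dict(), indent=2))
    return path


def load_transform(path: str | Path) -> ChannelTransform:
    return ChannelTransform.from_dict(json.loads(Path(path).read_text()))
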