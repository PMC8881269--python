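"""Render cell records into synthetic 3-channel 16-bit fluorescence fields.

Each cell is drawn as a disc (two discs for a binucleated record) whose
per-channel pixel sum reproduces the record's integrated intensity up to
integer quantization: the scaled total is spread as evenly as possible over
the disc pixels, so the sum is exact before background and noise are added.
Channel order is DAPI, mKO2 (G1 sensor), mAG (G2 sensor); pixel coordinates
are 0-based with origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk

CHANNELS = ("dapi_int", "g1_int", "g2_int")


@dataclass(frozen=True)
class ImageParams:
    shape: tuple[int, int] = (512, 512)
    cell_radius: int = 8
    background: float = 100.0
    noise_sd: float = 0.0
    #: Multiplies integrated intensities before pixel allocation so that
    #: per-pixel values are large relative to integer quantization.
    intensity_scale: float = 50.0
    #: Pixel gap between the two nuclei of a binucleated cell; 0 renders
    #: tangent (touching) lobes that form a single connected component.
    binucleate_gap: int = 2
    #: Extra clearance between different cells, beyond their bounding radii.
    cell_margin: int = 8
    allow_overlap: bool = False


def _allocate(total: int, n_pix: int) -> np.ndarray:
    """Spread an integer total over n_pix pixels, exactly."""
    base, rem = divmod(int(total), n_pix)
    vals = np.full(n_pix, base, dtype=np.int64)
    vals[:rem] += 1
    return vals


def _place_cells(
    n: int, n_nuclei: np.ndarray, params: ImageParams, rng: np.random.Generator
) -> np.ndarray:
    """Seeded rejection sampling of non-overlapping cell centres."""
    h, w = params.shape
    r = params.cell_radius
    half_sep = r + params.binucleate_gap / 2.0  # lobe centre offset from cell centre
    bound = np.where(n_nuclei == 2, half_sep + r, r)  # bounding radius per cell
    margin = params.cell_margin
    centers = np.zeros((n, 2))
    max_tries = 200 * max(n, 1)
    placed = 0
    tries = 0
    while placed < n:
        if tries > max_tries:
            raise ValueError("image too small for requested cells at this radius/margin")
        tries += 1
        b = bound[placed]
        y = rng.uniform(b + 1, h - b - 1)
        x = rng.uniform(bound[placed] + 1, w - b - 1)
        if not params.allow_overlap and placed:
            d = np.hypot(centers[:placed, 0] - y, centers[:placed, 1] - x)
            if np.any(d < bound[:placed] + b + margin):
                continue
        centers[placed] = (y, x)
        placed += 1
    return centers


def render_field(
    records: pd.DataFrame,
    image_params: ImageParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render cell records into a (3, H, W) uint16 image.

    Returns the image and a placement table (cell_id, y, x).  Raises if the
    cells cannot be placed without overlap or if a pixel would exceed the
    16-bit range after scaling.
    """
    params = image_params or ImageParams()
    rng = np.random.default_rng(seed)
    h, w = params.shape
    img = np.zeros((3, h, w), dtype=np.float64)

    n = len(records)
    n_nuclei = records["n_nuclei"].to_numpy() if n else np.zeros(0, dtype=int)
    centers = _place_cells(n, n_nuclei, params, rng)

    r = params.cell_radius
    half_sep = r + params.binucleate_gap / 2.0
    placements = []
    for i, (_, rec) in enumerate(records.iterrows()):
        cy, cx = centers[i]
        if rec["n_nuclei"] == 2:
            lobes = [(cy, cx - half_sep), (cy, cx + half_sep)]
        else:
            lobes = [(cy, cx)]
        lobe_pix = [disk((ly, lx), r, shape=(h, w)) for ly, lx in lobes]
        for ch, col in enumerate(CHANNELS):
            total = int(round(float(rec[col]) * params.intensity_scale))
            # split across lobes, then spread exactly over each lobe's pixels
            per_lobe = [total // len(lobes)] * len(lobes)
            per_lobe[-1] += total - sum(per_lobe)
            for (rr, cc), t in zip(lobe_pix, per_lobe):
                img[ch, rr, cc] += _allocate(t, len(rr))
        placements.append((rec.get("cell_id", i + 1), cy, cx))

    if img.max() + params.background > 65535:
        raise ValueError("intensities exceed the 16-bit range; lower intensity_scale")
    img += params.background
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return img, pd.DataFrame(placements, columns=["cell_id", "y", "x"])


def save_field(path, image: np.ndarray) -> None:
    """Write a (3, H, W) field as a multi-page 16-bit TIFF (DAPI, mKO2, mAG)."""
    tifffile.imwrite(path, image, photometric="minisblack")


def load_field(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError("expected a 3-channel field (DAPI, mKO2, mAG)")
    return img
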