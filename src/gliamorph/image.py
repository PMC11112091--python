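"""Grayscale-to-binary preprocessing for single-cell morphometry.

A fluorescent image of one microglial cell is reduced to a matched pair of
binary masks: the *filled* silhouette and its *outlined* boundary.  All
downstream shape measurements operate on such pairs.

Conventions, used everywhere in the package:

* foreground connectivity is 8 (diagonal pixels touch);
* the outline is the set of filled pixels 4-adjacent to background
  (pixels on the image border count as boundary);
* masks are boolean ``numpy`` arrays indexed ``[row, col]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
from scipy import ndimage
from skimage import filters
from skimage.measure import label

__all__ = [
    "BinaryCellPair",
    "outline_of",
    "preprocess",
    "crop_and_isolate",
    "read_grayscale",
    "write_pair",
]

#: structuring element for the 4-neighbourhood (von Neumann cross)
_CROSS = ndimage.generate_binary_structure(2, 1)
#: structuring element for the 8-neighbourhood (Moore square)
_SQUARE = ndimage.generate_binary_structure(2, 2)

DEFAULT_FRAME = 340  # px, the fixed single-cell crop size


def outline_of(filled: np.ndarray) -> np.ndarray:
    """Boundary of a filled mask: filled pixels 4-adjacent to background.

    Image-border foreground counts as boundary (erosion with zero border).
    Applying ``outline_of`` to an already-computed outline's source filled
    mask is stable: ``outline_of(filled)`` is a pure function of ``filled``.
    """
    filled = np.asarray(filled, dtype=bool)
    interior = ndimage.binary_erosion(filled, structure=_CROSS, border_value=0)
    return filled & ~interior


@dataclass
class BinaryCellPair:
    """Matched filled/outlined binary images of one cell.

    Invariants (checked on construction): both masks share a shape, the
    outline is a subset of the fill and equals ``outline_of(filled)``, and
    the fill is a single 8-connected component.
    """

    filled: np.ndarray
    outlined: np.ndarray
    cell_id: str = "cell"
    frame: int = field(default=DEFAULT_FRAME)

    def __post_init__(self) -> None:
        self.filled = np.asarray(self.filled, dtype=bool)
        self.outlined = np.asarray(self.outlined, dtype=bool)
        if self.filled.shape != self.outlined.shape:
            raise ValueError("filled and outlined images must share a shape")
        if not self.filled.any():
            raise ValueError("empty cell mask")
        if np.any(self.outlined & ~self.filled):
            raise ValueError("outlined image is not a subset of the filled image")
        n = label(self.filled, connectivity=2, return_num=True)[1]
        if n != 1:
            raise ValueError(f"filled image has {n} 8-connected components, expected 1")

    @classmethod
    def from_filled(cls, filled: np.ndarray, cell_id: str = "cell") -> "BinaryCellPair":
        """Build a pair from a filled mask; the outline is derived."""
        filled = np.asarray(filled, dtype=bool)
        return cls(filled=filled, outlined=outline_of(filled), cell_id=cell_id,
                   frame=max(filled.shape) if filled.size else DEFAULT_FRAME)

    @property
    def shape(self) -> tuple[int, int]:
        return self.filled.shape


def preprocess(
    image: np.ndarray,
    blur_sigma: float = 0.5,
    threshold_method: str | float = "otsu",
    unsharp: bool = False,
) -> np.ndarray:
    """Binarize a grayscale cell image: Gaussian smoothing then thresholding.

    Parameters
    ----------
    image
        2-D grayscale array, intensities in [0, 255] (any numeric dtype).
    blur_sigma
        Standard deviation of the Gaussian smoothing kernel, in pixels.
        ``0`` disables smoothing.  The default (0.5 px) stays below the
        finest process width (~2 px) so denoising does not erase thin
        ramifications.
    threshold_method
        ``"otsu"`` for a global automatic threshold, a number or the string
        ``"fixed:<v>"`` for an explicit cut.  Pixels strictly above the
        threshold are foreground, so raising the threshold can only remove
        foreground (monotonicity).
    unsharp
        If true, apply an unsharp mask (edge sharpening) instead of plain
        smoothing before thresholding.  Off by default.

    Returns
    -------
    Boolean foreground mask of the same shape.

    Raises
    ------
    ValueError
        If the image is empty or the result contains no foreground
        (``"no cell detected"``).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")

    if unsharp:
        smoothed = filters.unsharp_mask(img / 255.0, radius=blur_sigma, amount=1.0) * 255.0
    elif blur_sigma > 0:
        smoothed = ndimage.gaussian_filter(img, sigma=blur_sigma)
    else:
        smoothed = img

    if isinstance(threshold_method, str):
        if threshold_method == "otsu":
            thresh = filters.threshold_otsu(smoothed)
        elif threshold_method.startswith("fixed:"):
            thresh = float(threshold_method.split(":", 1)[1])
        else:
            raise ValueError(f"unknown threshold method {threshold_method!r}")
    else:
        thresh = float(threshold_method)

    mask = smoothed > thresh
    if not mask.any():
        raise ValueError("no cell detected")
    return mask


def crop_and_isolate(
    binary: np.ndarray,
    center: tuple[int, int] | None = None,
    frame: int = DEFAULT_FRAME,
    min_size: int = 20,
    cell_id: str = "cell",
) -> BinaryCellPair:
    """Crop a fixed window around ``center`` and keep one cell.

    The window is ``frame``×``frame``, padded with background where it
    leaves the source image.  Within the window, connected components
    smaller than ``min_size`` pixels are treated as speckle and dropped;
    of the rest, the component whose nearest pixel lies closest to the
    window centre is retained (deterministic stand-in for manual noise
    editing).  Ties go to the larger, then the first-labelled, component.

    Raises ``ValueError`` if ``center`` is outside the image or if no
    component survives.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if center is None:
        center = (h // 2, w // 2)
    cy, cx = int(center[0]), int(center[1])
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("center outside image")

    half = frame // 2
    window = np.zeros((frame, frame), dtype=bool)
    r0, c0 = cy - half, cx - half
    src_r0, src_c0 = max(r0, 0), max(c0, 0)
    src_r1, src_c1 = min(r0 + frame, h), min(c0 + frame, w)
    window[src_r0 - r0:src_r1 - r0, src_c0 - c0:src_c1 - c0] = (
        binary[src_r0:src_r1, src_c0:src_c1]
    )

    labels, n = label(window, connectivity=2, return_num=True)
    if n == 0:
        raise ValueError("empty window: no cell found")

    wc = np.array([frame / 2.0, frame / 2.0])
    best = None  # (distance, -size, label)
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        size = len(coords)
        if size < min_size:
            continue
        dist = np.min(np.linalg.norm(coords + 0.5 - wc, axis=1))
        key = (dist, -size, lab)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("empty window: all components below the size floor")

    return BinaryCellPair.from_filled(labels == best[2], cell_id=cell_id)


def read_grayscale(path) -> np.ndarray:
    """Read a PNG/TIFF image as 2-D grayscale (multichannel is averaged)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def write_pair(pair: BinaryCellPair, filled_path, outlined_path) -> None:
    """Write the pair as 8-bit images, 0 background / 255 foreground."""
    iio.imwrite(filled_path, (pair.filled.astype(np.uint8) * 255))
    iio.imwrite(outlined_path, (pair.outlined.astype(np.uint8) * 255))
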