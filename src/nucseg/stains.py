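"""Stain separation: RGB <-> optical density <-> per-stain concentration maps.

The two-stain Beer-Lambert model writes each pixel's optical density as a
non-negative combination of a hematoxylin (DNA) and an eosin (protein)
unit vector; ``decompose`` inverts it by per-pixel least squares with
negative residues clipped to zero.  The default vectors are the widely
used published H&E directions, overridable from a 6-number text file.
"""

from __future__ import annotations

import numpy as np

OD_EPS = 1.0  # intensity offset guarding log(0)

# Published H&E optical-density directions (columns: hematoxylin, eosin),
# normalized to unit length.
_RAW_HE = np.array([[0.650, 0.072],
                    [0.704, 0.990],
                    [0.286, 0.105]])


class StainMatrix:
    """3x2 matrix whose unit-norm columns are the H and E OD directions."""

    def __init__(self, columns: np.ndarray):
        m = np.asarray(columns, dtype=np.float64)
        if m.shape != (3, 2):
            raise ValueError("stain matrix must be 3x2")
        if np.any(m < 0):
            raise ValueError("stain matrix entries must be non-negative")
        norms = np.linalg.norm(m, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain matrix columns must have unit norm")
        if np.linalg.norm(np.cross(m[:, 0], m[:, 1])) < 1e-6:
            raise ValueError("stain vectors are collinear (degenerate)")
        self.matrix = m

    @classmethod
    def normalized(cls, columns: np.ndarray) -> "StainMatrix":
        m = np.asarray(columns, dtype=np.float64)
        return cls(m / np.linalg.norm(m, axis=0, keepdims=True))

    @classmethod
    def default(cls) -> "StainMatrix":
        return cls.normalized(_RAW_HE)

    @classmethod
    def from_file(cls, path) -> "StainMatrix":
        vals = np.loadtxt(path).reshape(3, 2)
        return cls.normalized(vals)

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.10f")

    def swapped(self) -> "StainMatrix":
        return StainMatrix(self.matrix[:, ::-1])


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Per-channel optical density, ``-ln(max(I, 1)/255)``.

    The one-intensity floor keeps a zero intensity finite (giving the
    maximum OD of -ln(1/255) ~ 5.54) while leaving every positive
    intensity an exact inverse of Beer-Lambert rendering, so OD is
    non-negative and the rendering round trip is lossless above the
    floor.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return -np.log(np.maximum(img, OD_EPS) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded into [0, 255]."""
    inten = np.rint(255.0 * np.exp(-np.asarray(od, dtype=np.float64)))
    return np.clip(inten, 0, 255).astype(np.uint8)


def decompose(image: np.ndarray, stains: StainMatrix | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares per-pixel stain concentrations (negatives clipped)."""
    stains = stains or StainMatrix.default()
    od = rgb_to_od(image)
    h, e = decompose_od(od, stains)
    return h, e


def decompose_od(od: np.ndarray, stains: StainMatrix
                 ) -> tuple[np.ndarray, np.ndarray]:
    s = stains.matrix
    pinv = np.linalg.pinv(s)  # (2, 3)
    flat = od.reshape(-1, 3) @ pinv.T
    flat = np.maximum(flat, 0.0)
    hw = od.shape[:2]
    return flat[:, 0].reshape(hw), flat[:, 1].reshape(hw)


def nuclear_channel(image: np.ndarray, stains: StainMatrix | None = None
                    ) -> np.ndarray:
    """Hematoxylin concentration min-max rescaled to [0, 1] per tile.

    A constant-OD tile (e.g. pure white) rescales to all zeros.
    """
    h, _ = decompose(image, stains)
    lo, hi = float(h.min()), float(h.max())
    if hi - lo < 1e-12:
        return np.zeros_like(h)
    return (h - lo) / (hi - lo)
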