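"""Beer-Lambert optical density conversion and two-stain color deconvolution.

Bright-field H&E absorbance is additive in optical density (OD): for incident
intensity ``I0`` and transmitted intensity ``I``, ``OD = -log10(I / I0)`` per
RGB channel, and the OD of a pixel is the concentration-weighted sum of the
unit stain vectors.  Unmixing solves the per-pixel least-squares problem
``od ~= c_h * s_H + c_e * s_E`` via the Moore-Penrose pseudoinverse of the
stain matrix; the residual (third) channel is discarded and negative
concentrations are clamped to zero.

The default stain vectors are the published hematoxylin / eosin absorbance
directions (Ruifrok & Johnston); they are configurable because real scanners
and stain batches deviate from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Published H&E absorbance directions (un-normalized).
DEFAULT_HEMATOXYLIN = (0.650, 0.704, 0.286)
DEFAULT_EOSIN = (0.072, 0.990, 0.105)

#: Epsilon (in intensity levels) guarding log(0) on saturated black pixels.
OD_EPSILON = 1.0


def build_stain_matrix(hematoxylin=DEFAULT_HEMATOXYLIN, eosin=DEFAULT_EOSIN) -> np.ndarray:
    """Return a 2x3 stain matrix with unit-Euclidean-norm rows (H first)."""
    m = np.asarray([hematoxylin, eosin], dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ConfigurationError("stain vector has zero norm")
    return m / norms


@dataclass
class StainPair:
    """Co-registered hematoxylin and eosin concentration channels (OD units).

    Attributes
    ----------
    h_channel, e_channel:
        Non-negative float images, same shape as the source tile.
    stain_matrix:
        The 2x3 unit-norm stain matrix used for unmixing.
    """

    h_channel: np.ndarray
    e_channel: np.ndarray
    stain_matrix: np.ndarray = field(default_factory=build_stain_matrix)

    @property
    def total_od(self) -> np.ndarray:
        """Summed stain concentration; the guide image for fold detection
        and cell propagation."""
        return self.h_channel + self.e_channel


def rgb_to_od(rgb: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert RGB intensities in [0, i0] to optical density.

    ``od = -log10((I + eps) / i0)`` with ``eps = 1`` intensity level, clamped
    to be non-negative (a fully white pixel maps to OD 0 exactly).
    """
    rgb = np.asarray(rgb, dtype=float)
    od = -np.log10((rgb + OD_EPSILON) / i0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od` (returns float intensities in [0, i0])."""
    od = np.asarray(od, dtype=float)
    rgb = i0 * np.power(10.0, -od) - OD_EPSILON
    return np.clip(rgb, 0.0, i0)


def deconvolve(od: np.ndarray, stain_matrix: np.ndarray | None = None) -> StainPair:
    """Unmix an H x W x 3 OD image into hematoxylin and eosin concentrations.

    Per-pixel least squares onto the two stain vectors (pseudoinverse);
    negative concentrations are clamped to 0.

    Raises
    ------
    ConfigurationError
        If the stain matrix rows are linearly dependent.
    """
    if stain_matrix is None:
        stain_matrix = build_stain_matrix()
    stain_matrix = np.asarray(stain_matrix, dtype=float)
    if stain_matrix.shape != (2, 3):
        raise ConfigurationError(f"stain matrix must be 2x3, got {stain_matrix.shape}")
    if np.linalg.matrix_rank(stain_matrix) < 2:
        raise ConfigurationError("stain matrix is rank-deficient")

    od = np.asarray(od, dtype=float)
    pinv = np.linalg.pinv(stain_matrix)  # 3 x 2
    conc = od @ pinv
    conc = np.maximum(conc, 0.0)
    return StainPair(h_channel=conc[..., 0], e_channel=conc[..., 1],
                     stain_matrix=stain_matrix)


def tile_to_stains(pixels: np.ndarray, stain_matrix: np.ndarray | None = None,
                   i0: float = 255.0) -> StainPair:
    """RGB tile -> OD -> unmixed :class:`StainPair` in one call."""
    return deconvolve(rgb_to_od(pixels, i0=i0), stain_matrix)
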