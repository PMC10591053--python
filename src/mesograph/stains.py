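"""H&E stain separation in optical-density space.

RGB transmittance images are converted to optical density (OD) with
``OD = -log10((I + 1) / 256)`` and unmixed into per-stain concentration
images by projecting onto the rows of a stain matrix.  The default matrix
is the standard Ruifrok-Johnston hematoxylin / eosin basis with a residual
third channel completing an orthogonal-ish frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HE_STAIN_MATRIX", "StainChannels", "optical_density",
           "stain_deconvolve", "recompose_od"]


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)

#: rows: hematoxylin, eosin, residual; each unit-norm in OD space.
HE_STAIN_MATRIX = np.vstack([
    _unit([0.65, 0.70, 0.29]),
    _unit([0.07, 0.99, 0.11]),
    _unit(np.cross([0.65, 0.70, 0.29], [0.07, 0.99, 0.11])),
])


@dataclass
class StainChannels:
    """Per-stain OD concentration images plus the total OD image."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    od_sum: np.ndarray


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density per channel."""
    return -np.log10((rgb.astype(np.float64) + 1.0) / 256.0)


def stain_deconvolve(rgb: np.ndarray,
                     stain_matrix: np.ndarray = HE_STAIN_MATRIX
                     ) -> StainChannels:
    """Unmix an RGB patch into hematoxylin / eosin concentration images.

    Projections are obtained with the pseudo-inverse of the stain matrix;
    negative concentrations are clipped at zero.  ``od_sum`` is the total
    optical density (sum of the three RGB OD channels), the stain-agnostic
    darkness of the pixel.
    """
    stain_matrix = np.asarray(stain_matrix, dtype=np.float64)
    if stain_matrix.ndim != 2 or stain_matrix.shape[1] != 3:
        raise ValueError("stain matrix must have shape (k, 3)")
    if np.linalg.matrix_rank(stain_matrix) < stain_matrix.shape[0]:
        raise ValueError("stain matrix is singular")
    od = optical_density(rgb)
    flat = od.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(stain_matrix)
    conc = np.clip(conc, 0.0, None)
    shape = rgb.shape[:-1]
    return StainChannels(
        hematoxylin=conc[:, 0].reshape(shape),
        eosin=conc[:, 1].reshape(shape),
        od_sum=od.sum(axis=-1),
    )


def recompose_od(channels_conc: np.ndarray,
                 stain_matrix: np.ndarray = HE_STAIN_MATRIX) -> np.ndarray:
    """Rebuild the RGB OD image from stain concentrations (round trip)."""
    conc = np.asarray(channels_conc, dtype=np.float64)
    return conc @ np.asarray(stain_matrix, dtype=np.float64)
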