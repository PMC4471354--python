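"""64-channel 10-20 montage labels, a schematic 2-D layout, and posterior source topographies.

The layout is a coarse grid derived from the 10-20 naming convention
(row letters -> anterior/posterior coordinate, digits -> laterality).
It is used only to shape the synthetic forward model and the spatial
correlation of the simulated sensor noise; no anatomical fidelity is
claimed.
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np

# BioSemi 64-electrode cap in standard A1..A32 / B1..B32 order.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

EOG_CHANNELS: tuple[str, str] = ("hEOG", "vEOG")
ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS

N_EEG = len(EEG_CHANNELS)

# Posterior channel groups carrying the largest forward-model weights of the
# two simulated alpha sources (left and right parieto-occipital cortex).
LEFT_POSTERIOR = ("P7", "P5", "PO7", "PO3", "O1")
RIGHT_POSTERIOR = ("P8", "P6", "PO8", "PO4", "O2")

_ROW_Y = {
    "Fp": 4.0, "AF": 3.2, "F": 2.4, "FT": 1.2, "FC": 1.2,
    "C": 0.0, "T": 0.0, "TP": -1.2, "CP": -1.2, "P": -2.4,
    "PO": -3.2, "O": -4.0, "I": -4.6,
}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def channel_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) position of a 10-20 label; x<0 is the left hemisphere."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a 10-20 label: {label!r}")
    row, idx = m.group(1), m.group(2)
    if row not in _ROW_Y:
        raise ValueError(f"unknown 10-20 row in label {label!r}")
    y = _ROW_Y[row]
    if idx == "z":
        return 0.0, y
    d = int(idx)
    x = float(-((d + 1) // 2) if d % 2 == 1 else d // 2)
    return x, y


@lru_cache(maxsize=1)
def layout() -> np.ndarray:
    """(64, 2) array of schematic positions for ``EEG_CHANNELS``."""
    return np.array([channel_position(c) for c in EEG_CHANNELS])


def source_topography(group: tuple[str, ...], sigma: float = 2.5,
                      floor: float = 0.8, spread: float = 0.7) -> np.ndarray:
    """Unit-norm forward-model topography peaking on ``group`` channels.

    Channels in ``group`` receive weight in [``floor``, 1]; every other
    channel gets ``spread`` times a Gaussian falloff (scale ``sigma`` in
    layout units) from the group centroid, bounded by ``spread`` < ``floor``
    so the largest-magnitude coefficients always lie on the designated
    channels. The wide falloff leaves a graded, strictly ordered gradient
    across the whole montage — volume conduction smears real scalp
    topographies similarly — so the planted vector is identifiable by
    rank statistics, not only by its peak.
    """
    if not 0 < spread < floor <= 1:
        raise ValueError("need 0 < spread < floor <= 1")
    pos = layout()
    idx = [EEG_CHANNELS.index(c) for c in group]
    centroid = pos[idx].mean(axis=0)
    d2 = ((pos - centroid) ** 2).sum(axis=1)
    w = spread * np.exp(-d2 / (2.0 * sigma ** 2))
    w[idx] = np.maximum(np.exp(-d2[idx] / (2.0 * sigma ** 2)), floor)
    return w / np.linalg.norm(w)


@lru_cache(maxsize=1)
def noise_mixing(scale: float = 2.0) -> np.ndarray:
    """Cholesky factor of a distance-decaying spatial noise covariance.

    Cov_ij = exp(-d_ij / scale) over the schematic layout, unit diagonal, so
    multiplying unit-variance noise by this factor yields unit-variance,
    spatially correlated sensor noise.
    """
    pos = layout()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = np.exp(-d / scale)
    return np.linalg.cholesky(cov)
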