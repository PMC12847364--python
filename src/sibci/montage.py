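"""10-10 montage geometry for the simulator's source topographies.

The full layout is the standard 64-channel active-electrode cap.  For
reduced-channel simulations a deterministic farthest-point subsample is
taken so that scalp coverage stays roughly uniform (a naive prefix of the
channel list would be strongly left-lateralized).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Standard 64-channel actiCAP ordering (10-10 labels).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
)


@lru_cache(maxsize=None)
def _positions_64() -> np.ndarray:
    """Azimuthal-equidistant 2-D projection (x: left->right, y: back->front).

    Each electrode maps to polar angle from the vertex times the unit
    azimuth vector — the standard topographic-map projection.  Unlike a
    naive (x, y) drop of the z coordinate, this preserves arc distances
    from the vertex, so the lateral ring (T7/T8) stays well separated
    from the central strip (C3/C4).  Units: 1.0 = the equatorial ring
    (90 degrees of arc from Cz).
    """
    import mne

    for name in ("colin27_1005", "standard_1005"):
        try:
            montage = mne.channels.make_standard_montage(name)
            break
        except ValueError:
            continue
    ch_pos = montage.get_positions()["ch_pos"]
    xyz = np.array([ch_pos[ch] for ch in CHANNELS_64])
    center = (xyz.max(axis=0) + xyz.min(axis=0)) / 2
    v = xyz - center
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    polar = np.arccos(np.clip(v[:, 2], -1, 1))  # angle from vertex
    azimuth = np.arctan2(v[:, 1], v[:, 0])
    radius = polar / (np.pi / 2)
    return np.column_stack([radius * np.cos(azimuth), radius * np.sin(azimuth)])


def montage_2d(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Channel names and 2-D positions for an n-channel cap.

    ``n_channels == 64`` returns the full standard layout.  Smaller counts
    are chosen by greedy farthest-point sampling seeded with the central
    motor triplet (C3, Cz, C4), guaranteeing bilateral sensorimotor
    coverage at any size >= 3.
    """
    if not 2 <= n_channels <= 64:
        raise ValueError("n_channels must be in [2, 64]")
    xy = _positions_64()
    if n_channels == 64:
        return list(CHANNELS_64), xy.copy()

    seed_chs = ["C3", "C4", "Cz"][:n_channels]
    selected = [CHANNELS_64.index(ch) for ch in seed_chs]
    while len(selected) < n_channels:
        d = np.min(
            np.linalg.norm(xy[:, None, :] - xy[selected][None, :, :], axis=2), axis=1
        )
        d[selected] = -1
        selected.append(int(np.argmax(d)))
    selected_arr = sorted(selected)
    return [CHANNELS_64[i] for i in selected_arr], xy[selected_arr].copy()


def gaussian_topography(
    centers: list[str], xy: np.ndarray, names: list[str], width: float
) -> np.ndarray:
    """Unit-peak topography: sum of Gaussian kernels around named electrodes.

    Kernel centers may name electrodes absent from a reduced montage; their
    positions are taken from the full 64-channel layout, so the topography
    shape is montage-independent.
    """
    full_xy = _positions_64()
    topo = np.zeros(len(names))
    for center in centers:
        cx = full_xy[CHANNELS_64.index(center)]
        d2 = np.sum((xy - cx) ** 2, axis=1)
        topo += np.exp(-d2 / (2 * width**2))
    peak = np.abs(topo).max()
    if peak == 0:
        raise ValueError("topography is identically zero; widen the kernel")
    return topo / peak
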