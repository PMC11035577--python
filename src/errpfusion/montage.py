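"""EEG montage definitions for the 63-channel 10-5 recording setup.

The recording montage covers frontal through occipital sites, including the
intermediate 10-5 positions (FFC3h, FCC1h/2h/4h, CCP1h-4h).  CPz served as
the online reference and AFz as ground, so neither carries recorded data.
The frontopolar and anterior-frontal row is removed before decoding to limit
residual ocular contamination.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: The 63 recorded channels, in amplifier order.
CHANNELS_63: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "FFC3h", "FCC1h", "FCC2h", "FCC4h",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CCP3h", "CCP1h", "CCP2h", "CCP4h",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
)

#: Frontal row dropped after ocular-artifact attenuation.
FRONTAL_DROP: tuple[str, ...] = ("Fp1", "Fp2", "AF3", "AFz", "AF4")

#: The 58 channels that enter epoching and decoding.
CHANNELS_58: tuple[str, ...] = tuple(c for c in CHANNELS_63 if c not in FRONTAL_DROP)

#: Reduced decoding layouts (name -> channel labels).
LAYOUTS: dict[str, tuple[str, ...]] = {
    "one_channel": ("FCz",),
    "three_channel": ("FCz", "Cz", "Pz"),
    "full": CHANNELS_58,
}


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """3D head-surface positions (meters) for every montage label.

    Positions come from the standard 10-5 template montage shipped with MNE
    and are used for synthetic topographies and spherical-spline
    interpolation of bad channels.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - renamed template
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos = mont.get_positions()["ch_pos"]
    return {name: np.asarray(pos[name], dtype=float) for name in CHANNELS_63}


def position_array(names) -> np.ndarray:
    """Stack positions for ``names`` into an (n, 3) array."""
    pos = channel_positions()
    return np.stack([pos[n] for n in names])


def scalp_topography(center: str, sigma_m: float = 0.05,
                     names=CHANNELS_63) -> np.ndarray:
    """Gaussian spatial gain map peaking at ``center``.

    Parameters
    ----------
    center
        Channel label of the maximum (e.g. ``"FCz"``).
    sigma_m
        Spatial scale in meters; 0.05 m gives a focal frontocentral or
        parietal patch comparable to event-related potential topographies.
    """
    pos = position_array(names)
    c = channel_positions()[center]
    d2 = np.sum((pos - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma_m**2))


def layout_channels(layout: str) -> tuple[str, ...]:
    """Resolve a layout name to its channel tuple."""
    try:
        return LAYOUTS[layout]
    except KeyError:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(LAYOUTS)}")
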