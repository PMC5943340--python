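"""Semi-automated spectral artifact rejection.

Channel-epochs are flagged when their summed power in a low (0.8-4.6 Hz) or
high (20-40 Hz) frequency range exceeds a multiple of a centered moving median
of that channel's band-power series, computed within the same sleep-state
class (NREM vs REM vs other). Because the reference is the subject's own
moving median, flagging is invariant to global rescaling of the recording.

Channels flagged in a large fraction of epochs are condemned as bad channels;
epochs flagged on a large fraction of the remaining good channels are dropped.
An optional user-supplied epoch drop list stands in for interactive visual
inspection of spectrograms. Excluded channels are repaired at the
normalized-map level by inverse-distance-weighted interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import EpochSpectra, NREM_STAGES, REM_STAGES

__all__ = [
    "ArtifactPolicy",
    "flag_epochs",
    "screen_channels",
    "consolidate_epoch_mask",
    "interpolate_channel_maps",
]


@dataclass(frozen=True)
class ArtifactPolicy:
    """Thresholds of the semi-automated rejection procedure.

    k_low / k_high multiply the moving median of low- and high-band power;
    window is the moving-median half-width in epochs; channel_bad_fraction
    and epoch_bad_fraction are the flagged fractions that condemn a channel
    or an epoch.
    """

    low_band: tuple[float, float] = (0.8, 4.6)
    high_band: tuple[float, float] = (20.0, 40.0)
    k_low: float = 4.0
    k_high: float = 3.0
    window: int = 10
    channel_bad_fraction: float = 0.2
    epoch_bad_fraction: float = 0.1

    def __post_init__(self) -> None:
        for lo, hi in (self.low_band, self.high_band):
            if not (0 <= lo < hi):
                raise ValueError("band edges must satisfy 0 <= lo < hi")
        if self.k_low <= 1 or self.k_high <= 1:
            raise ValueError("threshold multipliers must exceed 1")
        for f in (self.channel_bad_fraction, self.epoch_bad_fraction):
            if not (0 < f <= 1):
                raise ValueError("bad fractions must lie in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1 epoch")


def _stage_class(stages: np.ndarray) -> np.ndarray:
    out = np.empty(len(stages), dtype=object)
    for i, s in enumerate(stages):
        if s in NREM_STAGES:
            out[i] = "NREM"
        elif s in REM_STAGES:
            out[i] = "REM"
        else:
            out[i] = "OTHER"
    return out


def _band_power(spectra: EpochSpectra, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    sel = (spectra.bin_centers >= lo - 1e-9) & (spectra.bin_centers <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"no spectral bins inside band {band}")
    return spectra.power[:, :, sel].sum(axis=2)


def _moving_median(series: np.ndarray, half_width: int) -> np.ndarray:
    # series: epochs x channels within one stage class
    df = pd.DataFrame(series)
    return df.rolling(window=2 * half_width + 1, center=True,
                      min_periods=1).median().to_numpy()


def flag_epochs(spectra: EpochSpectra, policy: ArtifactPolicy = ArtifactPolicy()
                ) -> np.ndarray:
    """Boolean epochs x channels mask of channel-epochs exceeding thresholds."""
    low = _band_power(spectra, policy.low_band)
    high = _band_power(spectra, policy.high_band)
    if np.any((low.sum(axis=0) == 0) & (high.sum(axis=0) == 0)):
        raise ValueError("degenerate all-zero channel in spectra")
    classes = _stage_class(spectra.stage)
    flags = np.zeros(low.shape, dtype=bool)
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        if idx.size == 0:
            raise ValueError(f"empty stage class {cls}")
        med_low = _moving_median(low[idx], policy.window)
        med_high = _moving_median(high[idx], policy.window)
        flags[idx] = (low[idx] > policy.k_low * med_low) | \
                     (high[idx] > policy.k_high * med_high)
    return flags


def screen_channels(flags: np.ndarray,
                    policy: ArtifactPolicy = ArtifactPolicy()) -> list[int]:
    """Indices of channels flagged in more than channel_bad_fraction of epochs."""
    frac = flags.mean(axis=0)
    return sorted(np.flatnonzero(frac > policy.channel_bad_fraction).tolist())


def consolidate_epoch_mask(flags: np.ndarray, bad_channels: list[int],
                           policy: ArtifactPolicy = ArtifactPolicy(),
                           user_mask: np.ndarray | list[int] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Combine flags, bad channels and the optional user drop list.

    Returns (keep_epochs, good_channels): an epoch is dropped when the
    flagged fraction among good channels exceeds epoch_bad_fraction, or when
    the user mask drops it (the user mask always wins). good_channels is a
    boolean per-channel validity vector.
    """
    n_epochs, n_channels = flags.shape
    good = np.ones(n_channels, dtype=bool)
    good[list(bad_channels)] = False
    if not good.any():
        raise ValueError("all channels marked bad")
    frac = flags[:, good].mean(axis=1)
    keep = frac <= policy.epoch_bad_fraction
    if user_mask is not None:
        user_mask = np.asarray(user_mask)
        if user_mask.dtype == bool:
            if len(user_mask) != n_epochs:
                raise ValueError("user_mask length mismatch")
            keep &= ~user_mask
        else:
            if user_mask.size and (user_mask.min() < 0
                                   or user_mask.max() >= n_epochs):
                raise ValueError("user_mask epoch index out of range")
            keep[user_mask.astype(int)] = False
    return keep, good


def interpolate_channel_maps(tmap, bad_channels: list[int],
                             positions: np.ndarray, n_neighbors: int = 3):
    """Fill bad channels of a topographic map from their nearest good neighbours.

    Each bad channel's normalized power is replaced, band by band, with the
    inverse-distance-weighted mean of its ``n_neighbors`` nearest good
    channels; each band is then renormalized to sum to 1 over channels.
    """
    from .topography import TopographyMap  # local import to avoid a cycle

    if not isinstance(tmap, TopographyMap):
        raise TypeError("tmap must be a TopographyMap")
    bad = sorted(set(int(b) for b in bad_channels))
    if not bad:
        return tmap
    n_channels = tmap.values.shape[0]
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != n_channels:
        raise ValueError("positions must cover every channel")
    good = np.setdiff1d(np.arange(n_channels), bad)
    if good.size < n_neighbors:
        raise ValueError("need at least %d good channels" % n_neighbors)
    values = tmap.values.copy()
    for ch in bad:
        d = np.linalg.norm(positions[good] - positions[ch], axis=1)
        if not np.all(np.isfinite(d)) or np.all(d == 0):
            raise ValueError(f"bad channel {ch} has no usable neighbours")
        order = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[order], 1e-12)
        values[ch] = (w[:, None] * values[good[order]]).sum(axis=0) / w.sum()
    values = values / values.sum(axis=0, keepdims=True)
    return TopographyMap(values=values, bands=tmap.bands, state=tmap.state,
                         subject_id=tmap.subject_id, time_point=tmap.time_point,
                         n_epochs_used=tmap.n_epochs_used)
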