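"""Normalized topographic maps of sleep EEG power.

Per-epoch spectra are averaged within a sleep state (NREM = stages S2 + SWS,
REM), normalized per 0.2-Hz bin to the total power over all derivations at
that bin — removing absolute power and leaving the topographic distribution —
and aggregated into the eight classical frequency bands (delta 1-4.6 Hz up to
gamma2 34.2-44 Hz) or into 1-Hz bins for map displays. Within a twin pair the
maximal common number of clean epochs is used for both siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import BIN_STEP, EpochSpectra, NREM_STAGES, REM_STAGES

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "TopographyMap",
    "match_pair_epochs",
    "state_average",
    "normalize_bins",
    "aggregate_bands",
    "one_hz_maps",
    "grand_average_map",
    "STATE_STAGES",
]

STATE_STAGES = {"NREM": NREM_STAGES, "REM": REM_STAGES}

#: (label, low bin center, high bin center) in Hz, inclusive of both edges.
DEFAULT_BANDS = (
    ("delta", 1.0, 4.6),
    ("theta", 4.8, 7.8),
    ("alpha", 8.0, 10.8),
    ("sigma", 11.0, 16.0),
    ("beta1", 16.2, 20.0),
    ("beta2", 20.2, 24.0),
    ("gamma1", 24.2, 34.0),
    ("gamma2", 34.2, 44.0),
)


def _bin_index(freq: float) -> int:
    idx = freq / BIN_STEP
    if abs(idx - round(idx)) > 1e-6:
        raise ValueError(f"band edge {freq} is not a multiple of {BIN_STEP} Hz")
    return int(round(idx))


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands on the 0.2-Hz bin grid."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for label, lo, hi in self.bands:
            if lo > hi:
                raise ValueError(f"band {label}: lo > hi")
            _bin_index(lo), _bin_index(hi)
            if lo <= prev_hi:
                raise ValueError(f"band {label} overlaps its predecessor")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bands]

    def bin_slices(self, bin_centers: np.ndarray) -> dict[str, np.ndarray]:
        """Map each band label to the indices of its member bins."""
        centers = np.round(np.asarray(bin_centers) / BIN_STEP).astype(int)
        out: dict[str, np.ndarray] = {}
        for label, lo, hi in self.bands:
            sel = np.flatnonzero((centers >= _bin_index(lo))
                                 & (centers <= _bin_index(hi)))
            expected = _bin_index(hi) - _bin_index(lo) + 1
            if sel.size != expected:
                raise ValueError(
                    f"band {label}: {sel.size} bins available, {expected} required")
            out[label] = sel
        return out


@dataclass
class TopographyMap:
    """Channels x bands normalized power for one subject, state and time point.

    In normalized form every band's values are non-negative and sum to 1 over
    channels; synthetic maps generated in "linear" mode set ``normalized``
    False and may carry negative values.
    """

    values: np.ndarray
    bands: list[str]
    state: str
    subject_id: str = ""
    time_point: int = 1
    n_epochs_used: int = 0
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be channels x bands")
        if self.values.shape[1] != len(self.bands):
            raise ValueError("band labels must match value columns")
        if self.normalized:
            if np.any(self.values < -1e-12):
                raise ValueError("normalized map has negative values")
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("each band must sum to 1 over channels")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def band(self, label: str) -> np.ndarray:
        return self.values[:, self.bands.index(label)]


def match_pair_epochs(clean_counts_a: dict[str, int],
                      clean_counts_b: dict[str, int]) -> dict[str, int]:
    """Maximal common clean-epoch count per state for a twin pair.

    Both twins contribute the same number of epochs (the first n clean ones,
    chronologically) so that within-pair similarity is not biased by unequal
    averaging noise.
    """
    out: dict[str, int] = {}
    for state in clean_counts_a:
        n = min(int(clean_counts_a[state]), int(clean_counts_b[state]))
        if n <= 0:
            raise ValueError(f"no common clean epochs for state {state}")
        out[state] = n
    return out


def state_average(spectra: EpochSpectra, keep_mask: np.ndarray, state: str,
                  n_epochs: int | None = None,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Mean power over the first n clean epochs of a state (channels x bins).

    ``valid`` (epochs x channels, defaults to ``spectra.valid``) additionally
    masks isolated flagged channel-epochs: within the selected epochs each
    channel is averaged over its own valid entries only, so a transient
    artifact on one derivation does not cost the whole epoch. A channel with
    no valid entry falls back to the plain mean (such channels are screened
    as bad and interpolated downstream).
    """
    stages = STATE_STAGES[state]
    eligible = np.flatnonzero(
        np.fromiter((s in stages for s in spectra.stage), dtype=bool,
                    count=spectra.n_epochs) & np.asarray(keep_mask, dtype=bool))
    if n_epochs is None:
        n_epochs = eligible.size
    if eligible.size < n_epochs or n_epochs < 1:
        raise ValueError(
            f"insufficient clean {state} epochs: {eligible.size} < {n_epochs}")
    sel = eligible[:n_epochs]
    if valid is None:
        valid = spectra.valid
    v = np.asarray(valid, dtype=bool)[sel]  # epochs x channels
    counts = v.sum(axis=0).astype(float)    # per channel
    power = spectra.power[sel]
    masked = np.where(v[:, :, None], power, 0.0).sum(axis=0)
    plain = power.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = masked / counts[:, None]
    return np.where(counts[:, None] > 0, out, plain)


def normalize_bins(mean_spectra: np.ndarray) -> np.ndarray:
    """Normalize power at each bin to the total over all derivations.

    q(ch, f) = P(ch, f) / sum_ch' P(ch', f); every bin's channel sum is 1 and
    the result is invariant to any global rescaling of the input.
    """
    mean_spectra = np.asarray(mean_spectra, dtype=float)
    totals = mean_spectra.sum(axis=0, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("bin with non-positive total power cannot be normalized")
    return mean_spectra / totals


def aggregate_bands(fractions: np.ndarray, bin_centers: np.ndarray,
                    scheme: BandScheme = BandScheme(), *, state: str = "NREM",
                    subject_id: str = "", time_point: int = 1,
                    n_epochs_used: int = 0) -> TopographyMap:
    """Average per-bin fractions into band maps (mean over member bins).

    The unweighted mean of sum-to-1 bin vectors again sums to 1 per band, so
    the topographic normalization survives band aggregation.
    """
    slices = scheme.bin_slices(bin_centers)
    values = np.column_stack([fractions[:, idx].mean(axis=1)
                              for idx in slices.values()])
    return TopographyMap(values=values, bands=scheme.labels, state=state,
                         subject_id=subject_id, time_point=time_point,
                         n_epochs_used=n_epochs_used)


def one_hz_maps(fractions: np.ndarray, bin_centers: np.ndarray) -> np.ndarray:
    """Aggregate 0.2-Hz fractions into 1-Hz bins (channels x 44).

    Bin k (k = 1..44, labelled by its upper edge) is the mean of the five
    0.2-Hz bins centered at k-0.8 .. k Hz.
    """
    centers = np.round(np.asarray(bin_centers) / BIN_STEP).astype(int)
    out = []
    for k in range(1, 45):
        sel = np.flatnonzero((centers >= 5 * (k - 1) + 1) & (centers <= 5 * k))
        if sel.size != 5:
            raise ValueError(f"1-Hz bin {k}: expected 5 bins, found {sel.size}")
        out.append(fractions[:, sel].mean(axis=1))
    return np.column_stack(out)


def grand_average_map(maps: list[TopographyMap]) -> TopographyMap:
    """Unweighted mean map across subjects, renormalized per band."""
    if not maps:
        raise ValueError("cannot average an empty collection of maps")
    first = maps[0]
    for m in maps[1:]:
        if m.bands != first.bands or m.state != first.state:
            raise ValueError("maps must share band scheme and state")
        if m.values.shape != first.values.shape:
            raise ValueError("maps must share channel count")
    values = np.mean([m.values for m in maps], axis=0)
    values = values / values.sum(axis=0, keepdims=True)
    return TopographyMap(values=values, bands=list(first.bands),
                         state=first.state, subject_id="grand_average",
                         time_point=first.time_point,
                         n_epochs_used=sum(m.n_epochs_used for m in maps))
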