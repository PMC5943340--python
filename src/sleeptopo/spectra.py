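"""Recording preprocessing and per-epoch power density spectra.

The spectral pipeline mirrors standard sleep-EEG practice: recordings are
(optionally) decimated with an anti-alias filter, re-referenced to the average
of all derivations, and power density spectra are computed per 30-s scoring
epoch as the average of six non-overlapping 5-s Hanning-windowed periodograms,
giving a frequency resolution of 0.2 Hz. Analysis is retained up to 44 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

__all__ = [
    "STAGES",
    "NREM_STAGES",
    "REM_STAGES",
    "Recording",
    "Hypnogram",
    "EpochSpectra",
    "downsample",
    "average_reference",
    "epoch_psd",
]

#: Recognised sleep-stage labels (R&K stages; SWS pools stages 3 and 4).
STAGES = ("Wake", "S1", "S2", "SWS", "REM", "Movement")
#: Stage composition of the two analysis states.
NREM_STAGES = frozenset({"S2", "SWS"})
REM_STAGES = frozenset({"REM"})

#: Default analysis ceiling (Hz); the highest band edge analysed.
FMAX = 44.0
#: Spectral bin spacing (Hz), fixed by the 5-s analysis window.
BIN_STEP = 0.2


@dataclass
class Recording:
    """One subject-night of multichannel EEG.

    samples are channels x time in microvolts; channel_positions is an
    optional (n_channels, 2) layout used for channel interpolation.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None
    subject_id: str = ""
    time_point: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels; epoch k covers seconds [30k, 30(k+1))."""

    stages: np.ndarray
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class EpochSpectra:
    """Per-epoch power density spectra.

    power: epochs x channels x bins (uV^2/Hz); bin_centers in Hz at 0.2-Hz
    spacing starting at 0.2; valid marks channel-epochs that survive artifact
    screening (all True on construction).
    """

    power: np.ndarray
    bin_centers: np.ndarray
    stage: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be epochs x channels x bins")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        steps = np.diff(self.bin_centers)
        if len(steps) and not np.allclose(steps, BIN_STEP, atol=1e-9):
            raise ValueError("bin spacing must be exactly 0.2 Hz")
        if self.valid is None:
            self.valid = np.ones(self.power.shape[:2], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]


def _antialias_fir(sampling_rate: float, target_rate: float) -> np.ndarray:
    """Kaiser-window low-pass: >=60 dB down at the new Nyquist frequency."""
    nyq_new = target_rate / 2.0
    width = 0.2 * nyq_new  # transition band 0.8..1.0 x new Nyquist
    numtaps, beta = sps.kaiserord(ripple=75.0, width=width / (sampling_rate / 2.0))
    numtaps |= 1  # odd length -> integer group delay, exact linear phase
    return sps.firwin(numtaps, 0.9 * nyq_new, window=("kaiser", beta),
                      fs=sampling_rate)


def downsample(recording: Recording, target_rate: float) -> Recording:
    """Anti-alias low-pass filter and decimate to ``target_rate``.

    The decimation factor must be an integer. Filtering is zero-phase
    (forward-backward), so pure tones in the passband keep their amplitude
    and phase and a constant signal is unchanged.
    """
    q = recording.sampling_rate / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"target_rate {target_rate} does not divide sampling rate "
            f"{recording.sampling_rate}")
    q = int(round(q))
    if q == 1:
        return replace(recording, samples=recording.samples.copy())
    b = _antialias_fir(recording.sampling_rate, target_rate)
    padlen = min(3 * len(b), recording.samples.shape[1] - 1)
    filtered = sps.filtfilt(b, [1.0], recording.samples, axis=-1, padlen=padlen)
    return replace(recording, samples=filtered[:, ::q], sampling_rate=target_rate)


def average_reference(recording: Recording,
                      good_channels: np.ndarray | list[int] | None = None
                      ) -> Recording:
    """Re-reference every channel to the mean of the good channels.

    After referencing, the mean over good channels is zero at every sample;
    bad channels are re-expressed against the same good-channel mean so that
    all channels share one reference.
    """
    if good_channels is None:
        good = np.arange(recording.n_channels)
    else:
        good = np.asarray(good_channels, dtype=int)
    if good.size < 2:
        raise ValueError("average reference requires at least 2 good channels")
    ref = recording.samples[good].mean(axis=0, keepdims=True)
    return replace(recording, samples=recording.samples - ref)


def epoch_psd(recording: Recording, hypnogram: Hypnogram, *,
              window_len: float = 5.0, fmax: float = FMAX) -> EpochSpectra:
    """Per-epoch power density: mean of six 5-s Hanning periodograms.

    Each 30-s epoch is split into non-overlapping 5-s segments from epoch
    start; each segment is multiplied by a (periodic) Hann window and its
    one-sided periodogram computed with density scaling
    ``2 |X(f)|^2 / (fs * sum(w^2))``. The six periodograms are averaged. The
    DC bin is discarded; bins are kept up to ``fmax``.
    """
    fs = recording.sampling_rate
    spw = window_len * fs
    if abs(spw - round(spw)) > 1e-9:
        raise ValueError("window length must be an integer number of samples")
    nper = int(round(spw))
    epoch_len = hypnogram.epoch_len
    spe = int(round(epoch_len * fs))
    n_win = spe // nper
    n_epochs = min(len(hypnogram), recording.samples.shape[1] // spe)
    if n_epochs < 1:
        raise ValueError("recording is shorter than one epoch")
    step = 1.0 / window_len
    if abs(step - BIN_STEP) > 1e-12:
        raise ValueError("window length must yield 0.2-Hz resolution")
    window = sps.get_window("hann", nper, fftbins=True)
    scale = 2.0 / (fs * np.sum(window ** 2))
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    sel = (freqs > step / 2) & (freqs <= fmax + step / 2)
    n_ch = recording.n_channels
    x = recording.samples[:, : n_epochs * spe]
    x = x.reshape(n_ch, n_epochs, spe).transpose(1, 0, 2)
    # float32 inputs (e.g. synthetic cohorts) are processed in single
    # precision for speed; float64 inputs keep full precision
    work = np.float32 if x.dtype == np.float32 else np.float64
    win = window.astype(work)
    power = np.empty((n_epochs, n_ch, int(sel.sum())))
    chunk = max(1, int(2e7) // (n_ch * spe))  # bound transient memory
    for lo in range(0, n_epochs, chunk):
        segs = x[lo: lo + chunk, :, : n_win * nper].reshape(
            -1, n_ch, n_win, nper).astype(work, copy=False)
        spec = sfft.rfft(segs * win, axis=-1)  # preserves float32 precision
        pxx = scale * (spec.real ** 2 + spec.imag ** 2)
        power[lo: lo + chunk] = pxx.mean(axis=2)[..., sel]
    return EpochSpectra(power=power, bin_centers=freqs[sel],
                        stage=hypnogram.stages[:n_epochs].copy(),
                        channel_labels=list(recording.channel_labels))
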