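"""Synthetic twin cohorts with known ACE structure.

The generator is the test bed for the whole pipeline: it produces per-band
channel topographies for MZ/DZ twin pairs under an additive-genetic /
common-environment / unique-environment (ACE) decomposition, and can render
those topographies as raw multichannel band-limited noise with a Markov
hypnogram and injected artifact epochs.

Generative model, per band. Let T be a shared population template field with
spatial variance ``template_var`` and let each subject's deviation be

    d = sqrt(a2) A + sqrt(c2) C + sqrt(e2) E,       a2 + c2 + e2 = 1,

where A is shared between MZ co-twins and correlated 0.5 between DZ co-twins
(constructed explicitly as A_2 = 0.5 A_1 + sqrt(0.75) A'), C is shared within
every pair, and E is unique. In "linear" mode the map is T + d (negative
values possible; the closed-form expected Pearson correlation between two
subjects' maps across channels is

    E[r] ~= (template_var + a2 rho_A + c2 rho_C) / (template_var + 1)

with rho_A = 1 (MZ), 0.5 (DZ), 0 (non-related) and rho_C = 1 for co-twins).
In "compositional" mode the map is exp(T) * exp(d), renormalized to sum to 1
over channels — positive and realistic, but with no closed-form oracle.

Across the two assessments a subject's A and C persist while E is partially
re-drawn with correlation ``retest_stability``, echoing the high within-person
stability of sleep-EEG topography over months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import BIN_STEP, Hypnogram, Recording, STAGES
from .topography import DEFAULT_BANDS, TopographyMap
from .util import circular_layout, smooth_field, substream

__all__ = [
    "ACEParams",
    "CohortSpec",
    "SignalSpec",
    "CohortTruth",
    "expected_pair_correlation",
    "expected_self_correlation",
    "generate_twin_maps",
    "generate_hypnogram",
    "generate_signal_cohort",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_BAND_AMPLITUDE",
]


@dataclass(frozen=True)
class ACEParams:
    """Variance decomposition of one band's topographic deviation.

    a2, c2, e2 are the additive-genetic, common-environment and unique
    fractions of a unit deviation variance; template_var is the spatial
    variance of the shared population template relative to that unit;
    smoothness is the spatial correlation length (in channels) of all random
    fields.
    """

    a2: float
    c2: float
    e2: float
    template_var: float = 0.0
    n_channels: int = 58
    smoothness: int = 1

    def __post_init__(self) -> None:
        for name, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ValueError("a2 + c2 + e2 must equal 1")
        if self.template_var < 0:
            raise ValueError("template_var must be >= 0")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")


@dataclass(frozen=True)
class CohortSpec:
    """Size and structure of a synthetic twin cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    n_timepoints: int = 2
    retest_stability: float = 0.85
    bands: tuple[str, ...] = tuple(b[0] for b in DEFAULT_BANDS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be >= 0")
        if self.n_mz_pairs + self.n_dz_pairs < 1:
            raise ValueError("cohort needs at least one pair")
        if self.n_timepoints not in (1, 2):
            raise ValueError("n_timepoints must be 1 or 2")
        if not (0.0 <= self.retest_stability <= 1.0):
            raise ValueError("retest_stability must lie in [0, 1]")


#: First-order Markov transition probabilities between sleep stages; rows are
#: the current stage in STAGES order (Wake, S1, S2, SWS, REM, Movement).
DEFAULT_TRANSITIONS = {
    "Wake": {"Wake": 0.88, "S1": 0.10, "S2": 0.02},
    "S1": {"Wake": 0.05, "S1": 0.65, "S2": 0.28, "REM": 0.02},
    "S2": {"Wake": 0.005, "S1": 0.02, "S2": 0.90, "SWS": 0.055, "REM": 0.02},
    "SWS": {"S2": 0.06, "SWS": 0.93, "REM": 0.01},
    "REM": {"Wake": 0.01, "S1": 0.03, "S2": 0.04, "REM": 0.92},
    "Movement": {"Wake": 0.5, "Movement": 0.5},
}

#: Stage- and band-dependent global amplitude scales (sqrt of power density,
#: uV/sqrt(Hz)) for the eight default bands: SWS is dominated by slow waves,
#: S2 carries spindle-band (sigma) activity, REM is flatter and faster.
DEFAULT_BAND_AMPLITUDE = {
    "Wake": (2.0, 1.5, 2.0, 1.0, 0.8, 0.6, 0.4, 0.3),
    "S1": (3.0, 2.0, 1.5, 1.0, 0.7, 0.5, 0.35, 0.25),
    "S2": (5.0, 2.5, 1.5, 1.6, 0.8, 0.5, 0.3, 0.2),
    "SWS": (7.0, 3.0, 1.5, 1.2, 0.7, 0.45, 0.3, 0.2),
    "REM": (3.0, 2.0, 1.2, 0.8, 0.7, 0.5, 0.35, 0.25),
    "Movement": (8.0, 4.0, 3.0, 2.0, 1.5, 1.2, 1.0, 0.8),
}


@dataclass(frozen=True)
class SignalSpec:
    """How to render topographies as raw multichannel recordings."""

    sampling_rate: float = 250.0
    epoch_len: float = 30.0
    n_epochs: int = 840
    stage_transition: dict = field(
        default_factory=lambda: {s: dict(p) for s, p in
                                 DEFAULT_TRANSITIONS.items()})
    band_amplitude: dict = field(
        default_factory=lambda: {s: tuple(a) for s, a in
                                 DEFAULT_BAND_AMPLITUDE.items()})
    background_amplitude: float = 0.5
    artifact_rate: float = 0.0
    artifact_gain: float = 10.0
    artifact_max_channels: int = 4
    initial_stage: str = "Wake"

    def __post_init__(self) -> None:
        if self.sampling_rate < 2 * 44.0:
            raise ValueError("sampling_rate must exceed twice the 44-Hz "
                             "analysis ceiling")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.artifact_rate > 0 and self.artifact_gain <= 1:
            raise ValueError("artifact_gain must exceed 1")
        for stage, probs in self.stage_transition.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row {stage} does not sum to 1")
            if set(probs) - set(STAGES):
                raise ValueError(f"unknown target stage in row {stage}")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort.

    maps is keyed by (subject_id, time_point) and holds the true channels x
    bands topography; pairs lists (family_id, subject_a, subject_b, zygosity);
    ace maps band label -> generator ACEParams; artifacts lists injected
    (subject_id, epoch, channel) triples.
    """

    maps: dict[tuple[str, int], np.ndarray]
    pairs: list[tuple[str, str, str, str]]
    ace: dict[str, ACEParams]
    mode: str
    artifacts: list[tuple[str, int, int]] = field(default_factory=list)
    templates: np.ndarray | None = None  # channels x bands population template

    def manifest(self) -> pd.DataFrame:
        rows = []
        for fam, s1, s2, zyg in self.pairs:
            for sid in (s1, s2):
                rows.append({"subject_id": sid, "family_id": fam,
                             "zygosity": zyg})
        return pd.DataFrame(rows)

    def subjects(self) -> list[str]:
        return [sid for fam, s1, s2, zyg in self.pairs for sid in (s1, s2)]


_RHO_A = {"MZ": 1.0, "DZ": 0.5, "NR": 0.0}


def expected_pair_correlation(ace: ACEParams, relationship: str) -> float:
    """Closed-form expected map correlation in linear mode.

    E[r] = (template_var + a2 rho_A + c2 rho_C) / (template_var + 1) with
    rho_A = 1 (MZ), 0.5 (DZ), 0 (NR) and rho_C = 1 for co-twins, 0 for NR.
    """
    if relationship not in _RHO_A:
        raise ValueError(f"unknown relationship {relationship!r}")
    rho = ace.a2 * _RHO_A[relationship]
    if relationship in ("MZ", "DZ"):
        rho += ace.c2
    return (ace.template_var + rho) / (ace.template_var + 1.0)


def expected_self_correlation(ace: ACEParams, retest_stability: float) -> float:
    """Expected linear-mode correlation of one subject across assessments."""
    rho = ace.a2 + ace.c2 + ace.e2 * retest_stability
    return (ace.template_var + rho) / (ace.template_var + 1.0)


def _resolve_ace(ace, bands) -> dict[str, ACEParams]:
    if isinstance(ace, ACEParams):
        return {b: ace for b in bands}
    if set(ace) != set(bands):
        raise ValueError("ACE band labels do not match the cohort band list")
    n_ch = {p.n_channels for p in ace.values()}
    if len(n_ch) != 1:
        raise ValueError("all bands must share n_channels")
    return dict(ace)


def generate_twin_maps(ace, spec: CohortSpec, mode: str = "compositional",
                       state: str = "NREM",
                       rng: np.random.Generator | None = None,
                       templates: np.ndarray | None = None
                       ) -> tuple[list[TopographyMap], CohortTruth]:
    """Generate one topographic map per subject, band and time point.

    ``ace`` is a single ACEParams applied to every band in ``spec.bands`` or
    a mapping band -> ACEParams. Linear mode returns template + deviation
    (closed-form checkable, possibly negative); compositional mode returns
    exp(template) * exp(deviation) renormalized per band (positive, sum-1).
    ``templates`` (channels x bands) overrides the drawn population template,
    e.g. to share one template between the NREM and REM cohorts.
    """
    if mode not in ("linear", "compositional"):
        raise ValueError("mode must be 'linear' or 'compositional'")
    ace_by_band = _resolve_ace(ace, spec.bands)
    n_ch = next(iter(ace_by_band.values())).n_channels
    if rng is None:
        rng = substream(spec.seed, "maps", state)
    zygosities = ["MZ"] * spec.n_mz_pairs + ["DZ"] * spec.n_dz_pairs
    pairs = []
    # deviations[(sid, tp)] -> channels x bands
    dev: dict[tuple[str, int], np.ndarray] = {}
    if templates is not None:
        templates = np.asarray(templates, dtype=float).T.copy()
        if templates.shape != (len(spec.bands), n_ch):
            raise ValueError("templates must be channels x bands")
    else:
        templates = np.empty((len(spec.bands), n_ch))
        for j, band in enumerate(spec.bands):
            p = ace_by_band[band]
            templates[j] = np.sqrt(p.template_var) * smooth_field(
                rng, n_ch, p.smoothness)
    for i, zyg in enumerate(zygosities):
        fam = f"fam{i:04d}"
        sid1, sid2 = f"{fam}a", f"{fam}b"
        pairs.append((fam, sid1, sid2, zyg))
        d1 = np.empty((n_ch, len(spec.bands)))
        d2 = np.empty((n_ch, len(spec.bands)))
        e1 = np.empty((n_ch, len(spec.bands)))
        e2c = np.empty((n_ch, len(spec.bands)))
        for j, band in enumerate(spec.bands):
            p = ace_by_band[band]
            a1 = smooth_field(rng, n_ch, p.smoothness)
            if zyg == "MZ":
                a2 = a1
            else:
                a2 = 0.5 * a1 + np.sqrt(0.75) * smooth_field(
                    rng, n_ch, p.smoothness)
            c = smooth_field(rng, n_ch, p.smoothness)
            e_1 = smooth_field(rng, n_ch, p.smoothness)
            e_2 = smooth_field(rng, n_ch, p.smoothness)
            d1[:, j] = np.sqrt(p.a2) * a1 + np.sqrt(p.c2) * c
            d2[:, j] = np.sqrt(p.a2) * a2 + np.sqrt(p.c2) * c
            e1[:, j] = np.sqrt(p.e2) * e_1
            e2c[:, j] = np.sqrt(p.e2) * e_2
        dev[(sid1, 1)] = d1 + e1
        dev[(sid2, 1)] = d2 + e2c
        if spec.n_timepoints == 2:
            rho = spec.retest_stability
            mix = rho * np.array([e1, e2c]) + np.sqrt(1 - rho ** 2) * np.array([
                np.column_stack([
                    np.sqrt(ace_by_band[b].e2) * smooth_field(
                        rng, n_ch, ace_by_band[b].smoothness)
                    for b in spec.bands]) for _ in range(2)])
            dev[(sid1, 2)] = d1 + mix[0]
            dev[(sid2, 2)] = d2 + mix[1]
    truth_maps: dict[tuple[str, int], np.ndarray] = {}
    maps: list[TopographyMap] = []
    tmpl = templates.T  # channels x bands
    for (sid, tp), d in dev.items():
        if mode == "linear":
            values = tmpl + d
            normalized = False
        else:
            values = np.exp(tmpl) * np.exp(d)
            values = values / values.sum(axis=0, keepdims=True)
            normalized = True
        truth_maps[(sid, tp)] = values
        maps.append(TopographyMap(values=values, bands=list(spec.bands),
                                  state=state, subject_id=sid, time_point=tp,
                                  normalized=normalized))
    truth = CohortTruth(maps=truth_maps, pairs=pairs, ace=ace_by_band,
                        mode=mode, templates=tmpl)
    return maps, truth


def generate_hypnogram(spec: SignalSpec,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> Hypnogram:
    """First-order Markov stage sequence over 30-s epochs."""
    if rng is None:
        rng = substream(seed, "hypnogram")
    trans = spec.stage_transition
    stage = spec.initial_stage
    stages = []
    for _ in range(spec.n_epochs):
        stages.append(stage)
        probs = trans.get(stage)
        if probs is None:
            raise ValueError(f"no transition row for stage {stage}")
        labels = sorted(probs)
        stage = labels[rng.choice(len(labels), p=[probs[l] for l in labels])]
    return Hypnogram(stages=np.array(stages, dtype=object),
                     epoch_len=spec.epoch_len)


# Band edges (Hz) of the default scheme, used to paint band-limited power.
_BAND_EDGES = {label: (lo - BIN_STEP / 2, hi + BIN_STEP / 2)
               for label, lo, hi in DEFAULT_BANDS}


def _psd_targets(band_values: np.ndarray, bands: list[str], stage: str,
                 spec: SignalSpec, freqs: np.ndarray) -> np.ndarray:
    """Channels x rfft-bins power density target for one epoch."""
    n_ch = band_values.shape[0]
    psd = np.zeros((n_ch, freqs.size))
    amp = spec.band_amplitude[stage]
    for j, band in enumerate(bands):
        lo, hi = _BAND_EDGES[band]
        sel = (freqs > lo) & (freqs <= hi)
        # channel gain proportional to sqrt(normalized band power); uniform
        # maps give equal gains across channels
        gain = np.sqrt(np.maximum(band_values[:, j], 0.0) * n_ch) * amp[j]
        psd[:, sel] = (gain ** 2)[:, None]
    # common 1/f background
    with np.errstate(divide="ignore"):
        bg = spec.background_amplitude ** 2 / np.maximum(freqs, 0.5)
    psd += bg[None, :]
    psd[:, 0] = 0.0  # no DC
    return psd


def generate_signal_cohort(maps_by_state: dict[str, list[TopographyMap]],
                           truth: CohortTruth, spec: SignalSpec, seed: int = 0,
                           subjects: list[str] | None = None):
    """Render subjects' topographies as raw recordings, one at a time.

    ``maps_by_state`` maps "NREM"/"REM" to the per-subject compositional
    TopographyMap lists (as produced by generate_twin_maps). Yields
    (Recording, Hypnogram) per subject-time; injected artifact channel-epochs
    are appended to ``truth.artifacts``. Signals are synthesized per epoch in
    the frequency domain: independent Gaussian spectra with the target band
    power density per channel plus a common 1/f background, multiplied by
    ``artifact_gain`` on randomly chosen channels of corrupted epochs.
    """
    fs = spec.sampling_rate
    spe = int(round(spec.epoch_len * fs))
    if abs(spec.epoch_len * fs - spe) > 1e-9:
        raise ValueError("epoch length must be an integer number of samples")
    if fs < 100:
        raise ValueError("sampling_rate must be >= 100 Hz for signal rendering")
    map_idx: dict[tuple[str, int, str], TopographyMap] = {}
    for st, maps in maps_by_state.items():
        for m in maps:
            if not m.normalized:
                raise ValueError("signal rendering requires positive "
                                 "(compositional) maps")
            map_idx[(m.subject_id, m.time_point, st)] = m
    freqs = np.fft.rfftfreq(spe, d=1.0 / fs)
    if max(hi for _, hi in _BAND_EDGES.values()) > fs / 2:
        raise ValueError("band edge above Nyquist")
    timepoints = sorted({tp for (_, tp, _) in map_idx})
    all_subjects = truth.subjects() if subjects is None else subjects
    stage_for_state = {"NREM": {"S2", "SWS"}, "REM": {"REM"}}
    for sid in all_subjects:
        for tp in timepoints:
            rng = substream(seed, "signal", sid, str(tp))
            hyp = generate_hypnogram(spec, rng=substream(
                seed, "hypnogram", sid, str(tp)))
            art_rng = substream(seed, "artifacts", sid, str(tp))
            n_art = int(round(spec.artifact_rate * spec.n_epochs))
            art_epochs = (sorted(art_rng.choice(spec.n_epochs, size=n_art,
                                                replace=False).tolist())
                          if n_art else [])
            nrem_map = map_idx[(sid, tp, "NREM")]
            rem_map = map_idx.get((sid, tp, "REM"), nrem_map)
            n_ch = nrem_map.n_channels
            scale_by_stage: dict[str, np.ndarray] = {}
            for stage in set(hyp.stages):
                tmap = rem_map if stage in stage_for_state["REM"] else nrem_map
                psd = _psd_targets(tmap.values, tmap.bands, stage, spec, freqs)
                scale_by_stage[stage] = np.sqrt(psd * fs * spe / 2.0) \
                    .astype(np.float32)
            sig = np.empty((n_ch, spec.n_epochs * spe), dtype=np.float32)
            for k in range(spec.n_epochs):
                z = (rng.standard_normal((n_ch, freqs.size))
                     + 1j * rng.standard_normal((n_ch, freqs.size))) / np.sqrt(2)
                x = np.fft.irfft(z * scale_by_stage[hyp.stages[k]],
                                 n=spe, axis=1)
                sig[:, k * spe:(k + 1) * spe] = x
            for k in art_epochs:
                n_bad = int(art_rng.integers(1, spec.artifact_max_channels + 1))
                chans = sorted(art_rng.choice(n_ch, size=n_bad,
                                              replace=False).tolist())
                sig[chans, k * spe:(k + 1) * spe] *= spec.artifact_gain
                for ch in chans:
                    truth.artifacts.append((f"{sid}@{tp}", k, ch))
            rec = Recording(samples=sig, sampling_rate=fs,
                            channel_labels=[f"E{i + 1}" for i in range(n_ch)],
                            channel_positions=circular_layout(n_ch),
                            subject_id=sid, time_point=tp)
            yield rec, hyp
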