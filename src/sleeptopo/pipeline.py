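"""End-to-end orchestration: recordings -> spectra -> maps -> heritability.

The pipeline runs in five stages that can be invoked separately (each reads
and writes files under the configured output directory) or chained by
``run_pipeline``:

1. spectra    — per subject-night: decimate, per-epoch PSD on the raw signal,
                spectral artifact flagging and bad-channel screening, average
                reference over good channels, second PSD pass, epoch mask.
2. topo       — per twin pair and state: match the common clean-epoch count,
                average, normalize per bin across derivations, aggregate into
                bands, repair bad channels by interpolation.
3. similarity — MZ/DZ/NR/Self topographic correlations, Fisher-z averaged.
4. herit      — Falconer h2 / c2 tables, grand-average maps, NREM-vs-REM
                cross-state correlations, 1-Hz-bin maps.
5. report     — a YAML run manifest with configuration and record counts.

Bad-channel exclusion precedes average referencing: flags and channel
screening are computed on unreferenced spectra, the reference is the mean of
the surviving good channels, and downstream spectra are recomputed on the
re-referenced signal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artifacts import (consolidate_epoch_mask, flag_epochs,
                        interpolate_channel_maps, screen_channels)
from .edf import read_edf, write_edf
from .heritability import cross_state_correlation, heritability_table
from .io import (RunConfig, read_hypnogram, read_manifest, read_map,
                 read_spectra_cache, write_hypnogram, write_manifest,
                 write_map, write_spectra_cache, write_table)
from .similarity import build_pair_groups, group_mean_similarity
from .spectra import (EpochSpectra, Hypnogram, Recording, average_reference,
                      downsample, epoch_psd)
from .synthetic import (ACEParams, CohortSpec, SignalSpec, generate_signal_cohort,
                        generate_twin_maps)
from .topography import (BandScheme, TopographyMap, aggregate_bands,
                         grand_average_map, match_pair_epochs, normalize_bins,
                         one_hz_maps, state_average, STATE_STAGES)
from .util import circular_layout, substream

log = logging.getLogger(__name__)

__all__ = [
    "SubjectClean",
    "preprocess_subject",
    "pair_maps",
    "cohort_maps",
    "analyze_maps",
    "SimulateSpec",
    "simulate_cohort",
    "stage_spectra",
    "stage_topo",
    "stage_similarity",
    "stage_herit",
    "run_pipeline",
]

STATES = ("NREM", "REM")


# ---------------------------------------------------------------------------
# in-memory pipeline (also the engine behind the file stages)

@dataclass
class SubjectClean:
    """Artifact-screened spectra of one subject-night."""

    spectra: EpochSpectra          # after average referencing
    flags: np.ndarray              # raw-pass channel-epoch flags
    bad_channels: list[int]
    keep: np.ndarray               # per-epoch keep mask
    good: np.ndarray               # per-channel validity
    subject_id: str
    time_point: int

    def clean_counts(self) -> dict[str, int]:
        out = {}
        for state, stages in STATE_STAGES.items():
            in_state = np.fromiter((s in stages for s in self.spectra.stage),
                                   dtype=bool, count=self.spectra.n_epochs)
            out[state] = int((in_state & self.keep).sum())
        return out


def preprocess_subject(recording: Recording, hypnogram: Hypnogram,
                       config: RunConfig,
                       user_mask: np.ndarray | None = None) -> SubjectClean:
    """Stage-1 processing of one subject-night.

    PSD and artifact screening run on the unreferenced recording so that a
    single noisy channel cannot leak into the reference; the spectra used by
    all later stages are recomputed after average-referencing over the good
    channels.
    """
    if config.target_rate is not None:
        recording = downsample(recording, config.target_rate)
    raw_spectra = epoch_psd(recording, hypnogram,
                            window_len=config.window_len, fmax=config.fmax)
    flags = flag_epochs(raw_spectra, config.artifact)
    bad = screen_channels(flags, config.artifact)
    keep, good = consolidate_epoch_mask(flags, bad, config.artifact,
                                        user_mask=user_mask)
    referenced = average_reference(recording, np.flatnonzero(good))
    spectra = epoch_psd(referenced, hypnogram,
                        window_len=config.window_len, fmax=config.fmax)
    n_ep = spectra.n_epochs
    spectra.valid = (~flags[:n_ep]) & good[None, :] & keep[:n_ep, None]
    return SubjectClean(spectra=spectra, flags=flags, bad_channels=bad,
                        keep=keep, good=good,
                        subject_id=recording.subject_id,
                        time_point=recording.time_point)


def _subject_map(clean: SubjectClean, state: str, n_epochs: int,
                 scheme: BandScheme, positions: np.ndarray) -> TopographyMap:
    mean_spec = state_average(clean.spectra, clean.keep, state, n_epochs)
    fractions = normalize_bins(mean_spec)
    tmap = aggregate_bands(fractions, clean.spectra.bin_centers, scheme,
                           state=state, subject_id=clean.subject_id,
                           time_point=clean.time_point, n_epochs_used=n_epochs)
    return interpolate_channel_maps(tmap, clean.bad_channels, positions)


def pair_maps(clean_a: SubjectClean, clean_b: SubjectClean,
              scheme: BandScheme, positions: np.ndarray
              ) -> list[TopographyMap]:
    """Maps for one co-twin pair using the maximal common clean-epoch count."""
    n_common = match_pair_epochs(clean_a.clean_counts(),
                                 clean_b.clean_counts())
    out = []
    for state in STATES:
        for clean in (clean_a, clean_b):
            out.append(_subject_map(clean, state, n_common[state], scheme,
                                    positions))
    return out


def cohort_maps(cleans: dict[tuple[str, int], SubjectClean],
                manifest: pd.DataFrame, scheme: BandScheme,
                positions: np.ndarray
                ) -> dict[tuple[str, int, str], TopographyMap]:
    """One map per subject x time point x state, with within-pair matching.

    Epoch matching is applied once per twin pair; the resulting per-subject
    maps are reused for the Self and non-related comparisons.
    """
    fam_members = {fam: sorted(grp["subject_id"])
                   for fam, grp in manifest.groupby("family_id")}
    timepoints = sorted({tp for (_, tp) in cleans})
    maps: dict[tuple[str, int, str], TopographyMap] = {}
    for fam, (sid_a, sid_b) in sorted(fam_members.items()):
        for tp in timepoints:
            if (sid_a, tp) not in cleans or (sid_b, tp) not in cleans:
                log.warning("family %s incomplete at time %d; skipped",
                            fam, tp)
                continue
            for m in pair_maps(cleans[(sid_a, tp)], cleans[(sid_b, tp)],
                               scheme, positions):
                maps[(m.subject_id, m.time_point, m.state)] = m
    return maps


def analyze_maps(maps: dict[tuple[str, int, str], TopographyMap],
                 manifest: pd.DataFrame, config: RunConfig):
    """Similarity + heritability + cross-state tables from subject maps."""
    scheme = config.band_scheme()
    timepoints = sorted({tp for (_, tp, _) in maps})
    pair_lists: dict[str, list] = {}
    for tp in timepoints:
        groups = build_pair_groups(manifest, tp,
                                   exclude_subjects=config.exclude_subjects)
        for g, pairs in groups.items():
            if g == "Self" and (tp != timepoints[0] or len(timepoints) < 2):
                continue
            pair_lists.setdefault(g, []).extend(pairs)
    similarity = group_mean_similarity(pair_lists, maps, scheme.labels,
                                       list(STATES))
    herit = heritability_table(similarity, clip=config.clip_estimates,
                               domain=config.falconer_domain)
    grand = {state: grand_average_map(
        [m for (_, _, st), m in sorted(maps.items()) if st == state])
        for state in STATES}
    cross = cross_state_correlation(grand["NREM"], grand["REM"])
    return similarity, herit, cross, grand


# ---------------------------------------------------------------------------
# synthetic cohort on disk

#: Default per-band ACE fractions (a2, c2) echoing the pattern reported for
#: adolescent sleep-EEG topography: strong shared-environment contributions
#: in delta..sigma, strongest genetic contribution in the beta bands.
DEFAULT_BAND_ACE = {
    "delta": (0.12, 0.70), "theta": (0.15, 0.65), "alpha": (0.15, 0.65),
    "sigma": (0.15, 0.60), "beta1": (0.50, 0.20), "beta2": (0.55, 0.15),
    "gamma1": (0.45, 0.20), "gamma2": (0.20, 0.40),
}


@dataclass
class SimulateSpec:
    """What the synthetic cohort emulates: the study's stated world.

    Defaults mirror the study cohort: 14 MZ and 11 DZ same-sex pairs, 58 EEG
    derivations, two assessments 6 months apart, ~7-h nights in 30-s epochs.
    """

    n_mz_pairs: int = 14
    n_dz_pairs: int = 11
    n_timepoints: int = 2
    n_channels: int = 58
    retest_stability: float = 0.85
    template_var: float = 1.0
    smoothness: int = 5
    band_ace: dict = field(default_factory=lambda: dict(DEFAULT_BAND_ACE))
    mode: str = "compositional"
    signal: SignalSpec = field(default_factory=SignalSpec)
    seed: int = 0

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_mz_pairs=self.n_mz_pairs,
                          n_dz_pairs=self.n_dz_pairs,
                          n_timepoints=self.n_timepoints,
                          retest_stability=self.retest_stability,
                          bands=tuple(self.band_ace), seed=self.seed)

    def ace_params(self) -> dict[str, ACEParams]:
        out = {}
        for band, (a2, c2) in self.band_ace.items():
            out[band] = ACEParams(a2=a2, c2=c2, e2=round(1.0 - a2 - c2, 12),
                                  template_var=self.template_var,
                                  n_channels=self.n_channels,
                                  smoothness=self.smoothness)
        return out


def simulate_cohort(spec: SimulateSpec, out_dir: str | Path) -> Path:
    """Write a synthetic cohort (EDF + hypnograms + manifest + truth) to disk."""
    out = Path(out_dir)
    rec_dir = out / "recordings"
    hyp_dir = out / "hypnograms"
    rec_dir.mkdir(parents=True, exist_ok=True)
    hyp_dir.mkdir(parents=True, exist_ok=True)
    cohort = spec.cohort_spec()
    ace = spec.ace_params()
    maps_by_state = {}
    truth = None
    for state in STATES:
        maps, truth_state = generate_twin_maps(
            ace, cohort, mode=spec.mode, state=state,
            rng=substream(spec.seed, "maps", state))
        maps_by_state[state] = maps
        if truth is None:
            truth = truth_state
    for rec, hyp in generate_signal_cohort(maps_by_state, truth, spec.signal,
                                           seed=spec.seed):
        stem = f"{rec.subject_id}_t{rec.time_point}"
        write_edf(rec, rec_dir / f"{stem}.edf")
        write_hypnogram(hyp, hyp_dir / f"{stem}.tsv")
    manifest = truth.manifest()
    write_manifest(manifest, out / "manifest.tsv")
    truth_rows = [{"subject": s, "epoch": e, "channel": c}
                  for s, e, c in truth.artifacts]
    write_table(pd.DataFrame(truth_rows,
                             columns=["subject", "epoch", "channel"]),
                out / "artifact_truth.tsv")
    for (sid, tp), values in sorted(truth.maps.items()):
        df = pd.DataFrame(values, columns=list(cohort.bands))
        df.insert(0, "channel", np.arange(values.shape[0]))
        write_table(df, out / f"truth_map_{sid}_t{tp}.tsv")
    with open(out / "simulate_manifest.yaml", "w") as f:
        d = dataclasses.asdict(spec)
        d["version"] = __version__
        yaml.safe_dump(d, f, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# file-based stages

def _subject_files(config: RunConfig) -> list[tuple[str, int, Path, Path]]:
    manifest = read_manifest(config.manifest)
    rec_dir = Path(config.recordings_dir)
    hyp_dir = Path(config.hypnograms_dir)
    out = []
    for sid in manifest["subject_id"]:
        for tp in (1, 2):
            edf = rec_dir / f"{sid}_t{tp}.edf"
            hyp = hyp_dir / f"{sid}_t{tp}.tsv"
            if edf.exists():
                out.append((sid, tp, edf, hyp))
    return out


def stage_spectra(config: RunConfig) -> list[tuple[str, int]]:
    """EDF + hypnogram -> artifact-screened spectra caches."""
    cache_dir = Path(config.out_dir) / "spectra"
    cache_dir.mkdir(parents=True, exist_ok=True)
    done = []
    for sid, tp, edf_path, hyp_path in _subject_files(config):
        rec = read_edf(edf_path, channels=config.eeg_channels)
        rec.subject_id, rec.time_point = sid, tp
        hyp = read_hypnogram(hyp_path, epoch_len=config.epoch_len)
        user_mask = None
        if sid in config.user_masks:
            user_mask = np.loadtxt(config.user_masks[sid], dtype=int, ndmin=1)
        try:
            clean = preprocess_subject(rec, hyp, config, user_mask=user_mask)
        except Exception as exc:
            raise RuntimeError(
                f"stage spectra failed for subject {sid} t{tp}: {exc}"
            ) from exc
        write_spectra_cache(clean.spectra, cache_dir / f"{sid}_t{tp}.npz",
                            flags=clean.flags, keep=clean.keep,
                            good=clean.good,
                            bad_channels=np.array(clean.bad_channels,
                                                  dtype=int))
        done.append((sid, tp))
        log.info("spectra: %s t%d — %d epochs, %d bad channels", sid, tp,
                 clean.spectra.n_epochs, len(clean.bad_channels))
    return done


def _load_cleans(config: RunConfig) -> dict[tuple[str, int], SubjectClean]:
    cache_dir = Path(config.out_dir) / "spectra"
    cleans = {}
    for npz in sorted(cache_dir.glob("*.npz")):
        sid, tp = npz.stem.rsplit("_t", 1)
        spectra, extra = read_spectra_cache(npz)
        cleans[(sid, int(tp))] = SubjectClean(
            spectra=spectra, flags=extra["flags"],
            bad_channels=extra["bad_channels"].tolist(),
            keep=extra["keep"], good=extra["good"], subject_id=sid,
            time_point=int(tp))
    if not cleans:
        raise RuntimeError("no spectra caches found; run the spectra stage")
    return cleans


def stage_topo(config: RunConfig) -> dict[tuple[str, int, str], TopographyMap]:
    """Spectra caches -> per-subject normalized topographic maps."""
    manifest = read_manifest(config.manifest)
    cleans = _load_cleans(config)
    n_ch = next(iter(cleans.values())).spectra.n_channels
    positions = circular_layout(n_ch)
    maps = cohort_maps(cleans, manifest, config.band_scheme(), positions)
    map_dir = Path(config.out_dir) / "maps"
    map_dir.mkdir(parents=True, exist_ok=True)
    for (sid, tp, state), m in sorted(maps.items()):
        write_map(m, map_dir / f"{sid}_t{tp}_{state}.tsv")
    return maps


def _load_maps(config: RunConfig) -> dict[tuple[str, int, str], TopographyMap]:
    map_dir = Path(config.out_dir) / "maps"
    maps = {}
    for tsv in sorted(map_dir.glob("*.tsv")):
        m = read_map(tsv)
        maps[(m.subject_id, m.time_point, m.state)] = m
    if not maps:
        raise RuntimeError("no maps found; run the topo stage")
    return maps


def stage_similarity(config: RunConfig):
    """Maps -> per-pair and group-mean similarity tables."""
    manifest = read_manifest(config.manifest)
    maps = _load_maps(config)
    scheme = config.band_scheme()
    timepoints = sorted({tp for (_, tp, _) in maps})
    pair_lists: dict[str, list] = {}
    for tp in timepoints:
        groups = build_pair_groups(manifest, tp,
                                   exclude_subjects=config.exclude_subjects)
        for g, pairs in groups.items():
            if g == "Self" and (tp != timepoints[0] or len(timepoints) < 2):
                continue
            pair_lists.setdefault(g, []).extend(pairs)
    similarity = group_mean_similarity(pair_lists, maps, scheme.labels,
                                       list(STATES))
    out = Path(config.out_dir)
    write_table(similarity.pairs, out / "similarity_pairs.tsv")
    write_table(similarity.summary, out / "similarity_summary.tsv")
    return similarity


def stage_herit(config: RunConfig):
    """Similarity tables -> heritability and cross-state tables + maps."""
    out = Path(config.out_dir)
    from .similarity import SimilarityTable
    pairs = pd.read_csv(out / "similarity_pairs.tsv", sep="\t")
    summary = pd.read_csv(out / "similarity_summary.tsv", sep="\t")
    similarity = SimilarityTable(pairs=pairs, summary=summary)
    herit = heritability_table(similarity, clip=config.clip_estimates,
                               domain=config.falconer_domain)
    write_table(herit, out / "heritability.tsv")
    maps = _load_maps(config)
    grand = {state: grand_average_map(
        [m for (_, _, st), m in sorted(maps.items()) if st == state])
        for state in STATES}
    for state, m in grand.items():
        write_map(m, out / f"grand_average_{state}.tsv")
    cross = cross_state_correlation(grand["NREM"], grand["REM"])
    write_table(cross, out / "cross_state.tsv")
    return herit, cross


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write a run report; deterministic given the config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    processed = stage_spectra(config)
    maps = stage_topo(config)
    similarity = stage_similarity(config)
    herit, cross = stage_herit(config)
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_subject_nights": len(processed),
        "n_maps": len(maps),
        "n_pair_correlations": int(len(similarity.pairs)),
        "n_heritability_cells": int(len(herit)),
    }
    with open(out / "run_report.yaml", "w") as f:
        yaml.safe_dump(report, f, sort_keys=True)
    return report
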