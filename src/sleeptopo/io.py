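"""Text-based file formats and run configuration.

Hypnograms are 2-column delimited text (epoch_index, stage) with an alias
table accepting both R&K (S1-S4) and AASM (N1-N3, W, R) labels. Manifests,
similarity tables, heritability tables and topographic maps are TSV with
header rows; configurations round-trip through YAML. Per-subject spectra are
cached as compressed ``.npz`` arrays with a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .artifacts import ArtifactPolicy
from .spectra import EpochSpectra, Hypnogram, STAGES
from .topography import BandScheme, DEFAULT_BANDS, TopographyMap

__all__ = [
    "STAGE_ALIASES",
    "read_hypnogram",
    "write_hypnogram",
    "read_manifest",
    "write_manifest",
    "write_map",
    "read_map",
    "write_spectra_cache",
    "read_spectra_cache",
    "write_table",
    "RunConfig",
]

#: Accepted stage-label spellings -> canonical labels.
STAGE_ALIASES = {
    "W": "Wake", "WAKE": "Wake", "0": "Wake",
    "N1": "S1", "1": "S1", "S1": "S1",
    "N2": "S2", "2": "S2", "S2": "S2",
    "N3": "SWS", "3": "SWS", "4": "SWS", "S3": "SWS", "S4": "SWS",
    "SWS": "SWS",
    "R": "REM", "REM": "REM", "5": "REM",
    "M": "Movement", "MT": "Movement", "MOVEMENT": "Movement",
}


def normalize_stage(label: str) -> str:
    key = str(label).strip()
    canon = STAGE_ALIASES.get(key) or STAGE_ALIASES.get(key.upper())
    if canon is None and key in STAGES:
        canon = key
    if canon is None:
        raise ValueError(f"unknown sleep-stage label {label!r}")
    return canon


def read_hypnogram(path: str | os.PathLike,
                   n_epochs_expected: int | None = None,
                   epoch_len: float = 30.0) -> Hypnogram:
    """Read a delimited (epoch_index, stage) file; labels are normalized."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", names=["epoch", "stage"])
    stages = np.array([normalize_stage(s) for s in df["stage"]], dtype=object)
    if n_epochs_expected is not None and len(stages) != n_epochs_expected:
        raise ValueError(f"hypnogram {path} has {len(stages)} epochs, "
                         f"expected {n_epochs_expected}")
    return Hypnogram(stages=stages, epoch_len=epoch_len)


def write_hypnogram(hyp: Hypnogram, path: str | os.PathLike) -> None:
    with open(path, "w") as f:
        for i, s in enumerate(hyp.stages):
            f.write(f"{i}\t{s}\n")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    from .similarity import validate_manifest
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest.to_csv(path, sep="\t", index=False)


_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV export with a fixed float format, for byte-stable reruns."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_map(tmap: TopographyMap, path: str | os.PathLike) -> None:
    """Map as TSV (rows = channels, columns = bands) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(tmap.values, columns=tmap.bands)
    df.insert(0, "channel", np.arange(tmap.n_channels))
    write_table(df, path)
    sidecar = {"state": tmap.state, "subject_id": tmap.subject_id,
               "time_point": tmap.time_point,
               "n_epochs_used": tmap.n_epochs_used,
               "normalized": tmap.normalized}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_map(path: str | os.PathLike) -> TopographyMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    bands = [c for c in df.columns if c != "channel"]
    return TopographyMap(values=df[bands].to_numpy(), bands=bands,
                         state=meta["state"], subject_id=meta["subject_id"],
                         time_point=int(meta["time_point"]),
                         n_epochs_used=int(meta["n_epochs_used"]),
                         normalized=bool(meta["normalized"]))


def write_spectra_cache(spectra: EpochSpectra, path: str | os.PathLike,
                        **extra: np.ndarray) -> None:
    """Compressed array cache plus a JSON sidecar with labels and stages."""
    path = Path(path)
    np.savez_compressed(path, power=spectra.power.astype(np.float32),
                        bin_centers=spectra.bin_centers,
                        valid=spectra.valid, **extra)
    sidecar = {"stage": [str(s) for s in spectra.stage],
               "channel_labels": spectra.channel_labels}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_spectra_cache(path: str | os.PathLike
                       ) -> tuple[EpochSpectra, dict[str, np.ndarray]]:
    path = Path(path)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path
                 ) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    spectra = EpochSpectra(power=arrays.pop("power").astype(float),
                           bin_centers=arrays.pop("bin_centers"),
                           valid=arrays.pop("valid"),
                           stage=np.array(meta["stage"], dtype=object),
                           channel_labels=meta.get("channel_labels"))
    return spectra, arrays


@dataclass
class RunConfig:
    """End-to-end pipeline settings; round-trips through YAML unchanged."""

    out_dir: str = "out"
    manifest: str = "manifest.tsv"
    recordings_dir: str = "recordings"
    hypnograms_dir: str = "hypnograms"
    target_rate: float | None = None
    epoch_len: float = 30.0
    window_len: float = 5.0
    fmax: float = 44.0
    bands: tuple = DEFAULT_BANDS
    artifact: ArtifactPolicy = field(default_factory=ArtifactPolicy)
    eeg_channels: list[str] | None = None
    exclude_subjects: list[str] = field(default_factory=list)
    user_masks: dict[str, str] = field(default_factory=dict)
    clip_estimates: bool = False
    falconer_domain: str = "r"
    seed: int = 0

    def band_scheme(self) -> BandScheme:
        return BandScheme(bands=tuple(tuple(b) for b in self.bands))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "artifact" in d and isinstance(d["artifact"], dict):
            art = dict(d["artifact"])
            for k in ("low_band", "high_band"):
                if k in art:
                    art[k] = tuple(art[k])
            d["artifact"] = ArtifactPolicy(**art)
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.band_scheme()  # validate band labels/edges before any computation
        if cfg.falconer_domain not in ("r", "z"):
            raise ValueError("falconer_domain must be 'r' or 'z'")
        return cfg

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
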