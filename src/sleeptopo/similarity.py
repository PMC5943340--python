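"""Twin-pair topographic similarity.

For each frequency band, sleep state and time point, the topographic maps of
two subjects are compared by the Pearson correlation of their normalized
power across derivations. Four comparison groups are formed: MZ co-twins,
DZ co-twins, all non-related (cross-family) pairs, and Self (the same subject
at the two assessments). Correlations are Fisher z-transformed before
averaging and back-transformed for reporting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topography import TopographyMap

__all__ = [
    "GROUPS",
    "fisher_z",
    "fisher_z_inv",
    "topo_correlation",
    "build_pair_groups",
    "group_mean_similarity",
    "SimilarityTable",
    "validate_manifest",
]

log = logging.getLogger(__name__)

GROUPS = ("MZ", "DZ", "NR", "Self")

#: A subject observation: (subject_id, time_point)
Obs = tuple[str, int]


def fisher_z(r):
    """Variance-stabilizing z = arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z transform requires |r| < 1")
    return np.arctanh(r)


def fisher_z_inv(z):
    """Inverse Fisher transform, tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def topo_correlation(map_a: TopographyMap, map_b: TopographyMap,
                     band: str) -> float:
    """Pearson correlation across derivations of one band's normalized power.

    Returns NaN (with a logged warning) when either vector has zero variance,
    e.g. a perfectly uniform map; callers exclude such pairs.
    """
    a = map_a.band(band)
    b = map_b.band(band)
    if a.shape != b.shape:
        raise ValueError("maps must share the channel set and ordering")
    if a.size < 3:
        raise ValueError("need at least 3 channels for a correlation")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        log.warning("zero-variance topography in band %s (%s vs %s); "
                    "correlation undefined", band, map_a.subject_id,
                    map_b.subject_id)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort manifest: two co-twins per family, shared zygosity."""
    required = {"subject_id", "family_id", "zygosity"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for fam, grp in manifest.groupby("family_id"):
        if len(grp) != 2:
            raise ValueError(f"family {fam} has {len(grp)} members, expected 2")
        if grp["zygosity"].nunique() != 1:
            raise ValueError(f"family {fam} mixes zygosity labels")
        if not set(grp["zygosity"]) <= {"MZ", "DZ"}:
            raise ValueError(f"family {fam} has unknown zygosity")
    return manifest


def build_pair_groups(manifest: pd.DataFrame, time_point: int,
                      exclude_subjects: list[str] | None = None
                      ) -> dict[str, list[tuple[Obs, Obs]]]:
    """Construct the four comparison groups at one time point.

    MZ and DZ are co-twin pairs; NR is every unordered pair of subjects from
    different families (both zygosity groups pooled); Self pairs a subject's
    time-1 and time-2 observations. ``exclude_subjects`` removes subjects
    (e.g. unavailable recordings) from all groups.
    """
    validate_manifest(manifest)
    excl = set(exclude_subjects or ())
    m = manifest[~manifest["subject_id"].isin(excl)]
    groups: dict[str, list[tuple[Obs, Obs]]] = {g: [] for g in GROUPS}
    for fam, grp in m.groupby("family_id", sort=True):
        if len(grp) != 2:
            continue  # co-twin excluded -> pair unusable
        s1, s2 = sorted(grp["subject_id"])
        zyg = grp["zygosity"].iloc[0]
        groups[zyg].append(((s1, time_point), (s2, time_point)))
    fam_of = dict(zip(m["subject_id"], m["family_id"]))
    subjects = sorted(m["subject_id"])
    for a, b in itertools.combinations(subjects, 2):
        if fam_of[a] != fam_of[b]:
            groups["NR"].append(((a, time_point), (b, time_point)))
    for s in subjects:
        groups["Self"].append(((s, 1), (s, 2)))
    return groups


@dataclass
class SimilarityTable:
    """Per-pair correlations and Fisher-z group means.

    pairs: long format — group, band, state, time, pair_id, r, z.
    summary: per (group, band, state, time) — mean_z, mean_r, n_pairs.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame

    def cell(self, group: str, band: str, state: str, time: int) -> pd.Series:
        s = self.summary
        row = s[(s["group"] == group) & (s["band"] == band)
                & (s["state"] == state) & (s["time"] == time)]
        if len(row) != 1:
            raise KeyError((group, band, state, time))
        return row.iloc[0]


def group_mean_similarity(pair_lists: dict[str, list[tuple[Obs, Obs]]],
                          maps: dict[tuple[str, int, str], TopographyMap],
                          bands: list[str], states: list[str],
                          time_label: int | None = None) -> SimilarityTable:
    """Correlate every pair per band and state; average in Fisher-z space.

    ``maps`` is keyed by (subject_id, time_point, state). Undefined
    correlations (zero-variance maps) are excluded from their cell with a
    logged warning. The per-pair values are retained for export to external
    ANOVA tooling. ``time_label`` tags the output rows (Self pairs span both
    time points and keep their own label "1-2" unless overridden).
    """
    records = []
    for group, pairs in pair_lists.items():
        for (sid_a, tp_a), (sid_b, tp_b) in pairs:
            for state in states:
                key_a, key_b = (sid_a, tp_a, state), (sid_b, tp_b, state)
                if key_a not in maps:
                    raise KeyError(f"missing map for {key_a}")
                if key_b not in maps:
                    raise KeyError(f"missing map for {key_b}")
                for band in bands:
                    r = topo_correlation(maps[key_a], maps[key_b], band)
                    records.append({
                        "group": group, "band": band, "state": state,
                        "time": (time_label if time_label is not None
                                 else tp_a) if group != "Self" else 0,
                        "pair_id": f"{sid_a}@{tp_a}|{sid_b}@{tp_b}",
                        "r": r,
                    })
    pairs_df = pd.DataFrame.from_records(records)
    n_undef = int(pairs_df["r"].isna().sum()) if len(pairs_df) else 0
    if n_undef:
        log.warning("excluding %d undefined pair correlations", n_undef)
    defined = pairs_df.dropna(subset=["r"]).copy()
    # |r| can hit 1.0 to machine precision for degenerate (identical) maps;
    # clip just inside the open interval so the z-mean stays finite.
    defined["z"] = fisher_z(np.clip(defined["r"].to_numpy(),
                                    -1 + 1e-15, 1 - 1e-15))
    summary = (defined.groupby(["group", "band", "state", "time"], sort=True)
               .agg(mean_z=("z", "mean"), n_pairs=("z", "size"))
               .reset_index())
    summary["mean_r"] = fisher_z_inv(summary["mean_z"].to_numpy())
    return SimilarityTable(pairs=defined, summary=summary)
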