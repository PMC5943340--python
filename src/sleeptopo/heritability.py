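"""Falconer heritability and shared-environment estimates.

The classical twin estimate of narrow-sense heritability compares group-mean
topographic correlations of monozygotic (MZ) and dizygotic (DZ) twin pairs:

    h2 = 2 (r_MZ - r_DZ)
    c2 = r_MZ - h2 = r_DZ - h2 / 2

h2 attributes the excess MZ similarity to the doubled fraction of shared
segregating genes; c2 is the residual similarity due to environment common to
co-twins. Both can leave [0, 1] by construction when sampling noise or model
misfit intervene; estimates are reported raw and flagged, never silently
truncated. A shared population template inflates all group correlations
equally and attenuates h2 toward a2 / (1 + template_var) — see the synthetic
generator for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import SimilarityTable, fisher_z_inv
from .topography import TopographyMap

__all__ = [
    "falconer_h2",
    "shared_env_c2",
    "heritability_table",
    "cross_state_correlation",
]


def falconer_h2(r_mz, r_dz, clip: bool = False):
    """Falconer's formula h2 = 2 (r_MZ - r_DZ); optionally clipped to [0, 1]."""
    h2 = 2.0 * (np.asarray(r_mz, dtype=float) - np.asarray(r_dz, dtype=float))
    if clip:
        h2 = np.clip(h2, 0.0, 1.0)
    return h2 if h2.ndim else float(h2)


def shared_env_c2(r_mz, r_dz, clip: bool = False):
    """Shared environment c2 = r_MZ - h2 (equivalently 2 r_DZ - r_MZ)."""
    r_mz = np.asarray(r_mz, dtype=float)
    r_dz = np.asarray(r_dz, dtype=float)
    c2 = r_mz - 2.0 * (r_mz - r_dz)
    if clip:
        c2 = np.clip(c2, 0.0, 1.0)
    return c2 if c2.ndim else float(c2)


def heritability_table(similarity: SimilarityTable, *, clip: bool = False,
                       domain: str = "r") -> pd.DataFrame:
    """h2 and c2 per band x state x time from a similarity table.

    Group correlations entering the formulas are the back-transformed
    Fisher-z means (``domain="r"``, default) or the raw z-means
    (``domain="z"``). Rows are ordered by band, then state, then time;
    out-of-range estimates (h2 or c2 outside [0, 1]) are flagged.
    """
    if domain not in ("r", "z"):
        raise ValueError("domain must be 'r' or 'z'")
    s = similarity.summary
    mz = s[s["group"] == "MZ"].set_index(["band", "state", "time"])
    dz = s[s["group"] == "DZ"].set_index(["band", "state", "time"])
    if mz.empty or dz.empty:
        raise ValueError("similarity table lacks MZ or DZ cells")
    missing = set(mz.index.symmetric_difference(dz.index))
    if missing:
        raise ValueError(f"MZ/DZ cells do not align: {sorted(missing)}")
    band_order = list(dict.fromkeys(s["band"]))
    rows = []
    for (band, state, time), mz_row in mz.iterrows():
        dz_row = dz.loc[(band, state, time)]
        col = "mean_r" if domain == "r" else "mean_z"
        r_mz, r_dz = float(mz_row[col]), float(dz_row[col])
        h2 = falconer_h2(r_mz, r_dz)
        c2 = shared_env_c2(r_mz, r_dz)
        rows.append({
            "band": band, "state": state, "time": time,
            "r_mz": float(mz_row["mean_r"]), "r_dz": float(dz_row["mean_r"]),
            "n_mz_pairs": int(mz_row["n_pairs"]),
            "n_dz_pairs": int(dz_row["n_pairs"]),
            "h2": np.clip(h2, 0, 1) if clip else h2,
            "c2": np.clip(c2, 0, 1) if clip else c2,
            "out_of_range": bool(not (0 <= h2 <= 1) or not (0 <= c2 <= 1)),
        })
    out = pd.DataFrame(rows)
    out["band"] = pd.Categorical(out["band"], categories=band_order,
                                 ordered=True)
    out = out.sort_values(["band", "state", "time"]).reset_index(drop=True)
    out["band"] = out["band"].astype(str)
    return out


def cross_state_correlation(grand_nrem: TopographyMap,
                            grand_rem: TopographyMap) -> pd.DataFrame:
    """Correlation between NREM and REM grand-average topographies per band.

    Pearson r across derivations plus the two-sided p-value of the ordinary
    correlation t-test, t = r sqrt((n-2) / (1-r^2)) with df = n_channels - 2.
    Spatial autocorrelation between neighbouring derivations is ignored, so
    these p-values are anticonservative for smooth maps.
    """
    if grand_nrem.bands != grand_rem.bands:
        raise ValueError("grand averages must share the band scheme")
    if grand_nrem.n_channels != grand_rem.n_channels:
        raise ValueError("grand averages must share the channel set")
    rows = []
    for band in grand_nrem.bands:
        a, b = grand_nrem.band(band), grand_rem.band(band)
        if a.std() == 0 or b.std() == 0:
            raise ValueError(f"zero-variance band {band}")
        res = stats.pearsonr(a, b)
        rows.append({"band": band, "r": float(res.statistic),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows)
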