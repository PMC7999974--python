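"""Point-biserial discriminability ranking of band/channel-pair features.

Every PLV feature (one channel pair in one frequency band) is scored for
each pairwise stage contrast (REM|N2, REM|N3, N2|N3) with the squared
point-biserial correlation

    r = √(N⁺N⁻)/(N⁺+N⁻) · (mean(X⁺) − mean(X⁻)) / std(X⁺ ∪ X⁻),

std taken over the pooled sample (population form), so r² ∈ [0, 1] and
equals the squared Pearson correlation between the feature and a binary
class indicator.  A full run scores 3 class pairs × 6 bands × 66 channel
pairs = 1188 records.  Derived summaries:

* top-k band percentages — share of each band among the k highest-r²
  records pooled over class pairs;
* discriminative ratio — per class pair, each band's share of the total
  r² mass among the top-t records (t = 36 by default);
* 2-D feature selection — per band, the two features with the largest
  class-pair-averaged r², for scatter inspection.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_RANK, CLASS_PAIRS, class_pair_label
from .connectivity import feature_columns, upper_triangle_pairs

DEFAULT_TOP_T = 36


def biserial_r2(x_pos: np.ndarray, x_neg: np.ndarray) -> float:
    """Squared point-biserial correlation between a feature and class membership."""
    x_pos = np.asarray(x_pos, dtype=float)
    x_neg = np.asarray(x_neg, dtype=float)
    if x_pos.size < 1 or x_neg.size < 1:
        raise ValueError("both classes need at least one sample")
    pooled = np.concatenate([x_pos, x_neg])
    std = pooled.std()  # population std: perfect separation gives exactly 1
    if std == 0:
        raise ValueError("pooled values are all identical; r2 undefined")
    n_pos, n_neg = x_pos.size, x_neg.size
    r = (np.sqrt(n_pos * n_neg) / (n_pos + n_neg)
         * (x_pos.mean() - x_neg.mean()) / std)
    return float(r * r)


def score_all(features: pd.DataFrame,
              class_pairs: Sequence[tuple[str, str]] = CLASS_PAIRS) -> pd.DataFrame:
    """Score every (class pair, band, channel pair) and rank globally.

    ``features`` is the long table from
    :func:`plvsleep.connectivity.plv_feature_table`.  Returns the ranking
    table sorted by r² descending with deterministic tie-breaks
    (canonical band order, then channel-pair index); the ``rank`` column
    is 0-based over the pooled table.
    """
    cols = feature_columns(features)
    records = []
    for band, sub in features.groupby("band", sort=False):
        stages = sub["stage"].to_numpy()
        values = sub[cols].to_numpy()
        for a, b in class_pairs:
            mask_a = stages == a
            mask_b = stages == b
            if mask_a.sum() < 2 or mask_b.sum() < 2:
                raise ValueError(f"class pair ({a}, {b}) lacks samples in band {band}")
            for pair_index, col in enumerate(cols):
                records.append({
                    "class_pair": class_pair_label(a, b),
                    "band": band,
                    "pair_index": pair_index,
                    "pair": col,
                    "channel_i": int(col.split("-")[0]),
                    "channel_j": int(col.split("-")[1]),
                    "r2": biserial_r2(values[mask_a, pair_index],
                                      values[mask_b, pair_index]),
                })
    table = pd.DataFrame.from_records(records)
    table["band_rank"] = table["band"].map(BAND_RANK)
    table = table.sort_values(
        ["r2", "band_rank", "pair_index"], ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="band_rank").reset_index(drop=True)
    table["rank"] = np.arange(len(table))
    return table


def top_k_band_percentage(ranking: pd.DataFrame, k: int) -> dict[str, float]:
    """Percent of the k best records (pooled over class pairs) per band."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds {len(ranking)} records")
    top = ranking.nsmallest(k, "rank")
    counts = top["band"].value_counts()
    bands = sorted(set(ranking["band"]), key=lambda b: BAND_RANK.get(b, 99))
    return {band: 100.0 * counts.get(band, 0) / k for band in bands}


def discriminative_ratio(ranking: pd.DataFrame,
                         t: int = DEFAULT_TOP_T) -> pd.DataFrame:
    """Per class pair, each band's share of the r² mass in the top-t records.

    Returns a class_pair × band frame of ratios; rows sum to 1.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    bands = sorted(set(ranking["band"]), key=lambda b: BAND_RANK.get(b, 99))
    rows = {}
    for cp, sub in ranking.groupby("class_pair", sort=False):
        if len(sub) < t:
            raise ValueError(f"class pair {cp} has fewer than t={t} records")
        top = sub.sort_values(["r2", "rank"], ascending=[False, True],
                              kind="mergesort").head(t)
        total = top["r2"].sum()
        per_band = top.groupby("band")["r2"].sum()
        rows[cp] = {band: float(per_band.get(band, 0.0) / total) for band in bands}
    order = [class_pair_label(a, b) for a, b in CLASS_PAIRS if class_pair_label(a, b) in rows]
    order += [cp for cp in rows if cp not in order]
    return pd.DataFrame.from_dict(rows, orient="index").loc[order, bands]


def mean_r2_per_feature(ranking: pd.DataFrame) -> pd.DataFrame:
    """Average each (band, channel pair)'s r² over the three class pairs."""
    out = (ranking.groupby(["band", "pair_index", "pair"], sort=False)["r2"]
           .mean().reset_index().rename(columns={"r2": "mean_r2"}))
    out["band_rank"] = out["band"].map(BAND_RANK)
    return (out.sort_values(["mean_r2", "band_rank", "pair_index"],
                            ascending=[False, True, True], kind="mergesort")
            .drop(columns="band_rank").reset_index(drop=True))


def select_2d_features(ranking: pd.DataFrame, band: str) -> tuple[str, str]:
    """The two channel-pair features of ``band`` with largest mean r²."""
    mean = mean_r2_per_feature(ranking)
    sub = mean[mean["band"] == band]
    if len(sub) < 2:
        raise ValueError(f"band {band!r} has fewer than two features")
    return tuple(sub["pair"].head(2))


def feature_scatter(features: pd.DataFrame, band: str,
                    pair_names: Sequence[str]) -> pd.DataFrame:
    """Values of the selected features per epoch (scatter-plot data, no rendering)."""
    sub = features[features["band"] == band]
    return sub[["epoch", "stage", *pair_names]].reset_index(drop=True)
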