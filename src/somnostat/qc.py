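"""Anomaly-based per-event outlier rejection.

Every detected event (slow wave or spindle) is scored on its
(frequency, peak-to-peak amplitude, duration) feature triple by an
isolation forest; the ``ceil(contamination * n)`` most anomalous events
are flagged and excluded from downstream counts and summaries.

Rows are canonically ordered (sorted by the feature triple) before
scoring so that flags are invariant to the order events arrive in, and a
fixed seed makes the procedure deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

__all__ = ["QCParams", "flag_outlier_events", "QC_FEATURES"]

QC_FEATURES = ("frequency_hz", "p2p_amplitude_uv", "duration_s")


@dataclass(frozen=True)
class QCParams:
    """Outlier-flagging configuration.

    ``contamination`` is the fraction of events to remove (the flagged
    count is exactly ``ceil(contamination * n)``); the method family calls
    for no particular tree count, 100 is the standard default.
    """

    contamination: float = 0.025
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 0.5:
            raise ValueError("contamination must be in [0, 0.5)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def flag_outlier_events(events: pd.DataFrame, params: QCParams = QCParams()) -> pd.DataFrame:
    """Return a copy of ``events`` with ``qc_flag`` set on the outliers.

    Features are standardized to unit variance before scoring.  Raises on
    empty input or non-finite feature values (naming the row).
    """
    if not len(events):
        raise ValueError("event table is empty")
    feats = events.loc[:, list(QC_FEATURES)].to_numpy(dtype=float)
    finite = np.isfinite(feats).all(axis=1)
    if not finite.all():
        bad = events.index[~finite][0]
        raise ValueError(f"non-finite feature in event row {bad}")

    n = len(events)
    n_flag = math.ceil(params.contamination * n)
    out = events.copy()
    out["qc_flag"] = False
    if n_flag == 0:
        return out

    # canonical order: flags must not depend on arrival order
    order = np.lexsort(feats.T[::-1])
    sorted_feats = feats[order]
    sd = sorted_feats.std(axis=0)
    sd[sd == 0] = 1.0
    standardized = (sorted_feats - sorted_feats.mean(axis=0)) / sd

    forest = IsolationForest(
        n_estimators=params.n_trees,
        contamination="auto",
        random_state=params.seed,
    )
    forest.fit(standardized)
    scores = forest.score_samples(standardized)  # lower = more anomalous
    worst = np.argsort(scores, kind="stable")[:n_flag]
    flag_positions = order[worst]
    out.iloc[flag_positions, out.columns.get_loc("qc_flag")] = True
    return out
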