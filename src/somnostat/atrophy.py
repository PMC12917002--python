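"""Composite atrophy scoring from a per-subject ROI volume table.

Each anatomical region's raw volume (mm³, from a standard volumetric
segmentation) is normalised by total intracranial volume (TIV) and scaled
by 100, putting values on a percent-of-TIV scale (bilateral amygdala
≈ 0.19).  The composite anxiety-sensitive atrophy score is the sum of the
normalised values over five a-priori regions — bilateral amygdala, left
insula, bilateral putamen, posterior cingulate, left parahippocampal
cortex — where *higher* means more preserved volume.  "Bilateral" columns
are left+right sums.

Subjects more than 2.5 sample SDs below the sample mean composite are
excluded in a single pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ANXIETY_ROIS",
    "composite_atrophy_score",
    "network_scores",
    "apply_exclusion",
]

#: A-priori anxiety-sensitive ROI column names (bilateral = left+right sum).
ANXIETY_ROIS = (
    "amygdala_bilateral",
    "insula_left",
    "putamen_bilateral",
    "posterior_cingulate",
    "parahippocampal_left",
)

TIV_COLUMN = "tiv"
NORMALIZATION_SCALE = 100.0


def _check_volumes(volumes: pd.DataFrame, rois: tuple[str, ...]) -> None:
    if TIV_COLUMN not in volumes.columns:
        raise ValueError(f"missing required column {TIV_COLUMN!r}")
    for roi in rois:
        if roi not in volumes.columns:
            raise ValueError(f"missing ROI column {roi!r}")
    for row in volumes.itertuples():
        sid = getattr(row, "subject_id", row.Index)
        for roi in rois:
            v = getattr(row, roi)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"subject {sid}: invalid volume for ROI {roi!r}: {v}")
        tiv = getattr(row, TIV_COLUMN)
        if not np.isfinite(tiv) or tiv <= 0:
            raise ValueError(f"subject {sid}: invalid TIV: {tiv}")


def composite_atrophy_score(
    volumes: pd.DataFrame,
    roi_set: tuple[str, ...] = ANXIETY_ROIS,
) -> pd.DataFrame:
    """Normalise ROI volumes by TIV and sum them into a composite score.

    Adds ``norm_<roi>`` columns (100 × raw / TIV) and an
    ``atrophy_composite`` column (their sum over ``roi_set``).
    """
    _check_volumes(volumes, roi_set)
    out = volumes.copy()
    norm_cols = []
    for roi in roi_set:
        col = f"norm_{roi}"
        out[col] = NORMALIZATION_SCALE * out[roi] / out[TIV_COLUMN]
        norm_cols.append(col)
    out["atrophy_composite"] = out[norm_cols].sum(axis=1)
    return out


def network_scores(
    volumes: pd.DataFrame,
    parcellation: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Network-level composites from any user-supplied parcellation.

    ``parcellation`` maps a network name to the raw-volume columns that
    compose it; scoring is identical to the a-priori composite.
    """
    out = volumes.copy()
    for network, rois in parcellation.items():
        scored = composite_atrophy_score(volumes, roi_set=tuple(rois))
        out[f"network_{network}"] = scored["atrophy_composite"]
    return out


def apply_exclusion(scores, k_sd: float = 2.5) -> np.ndarray:
    """Single-pass low-composite exclusion: keep score ≥ mean − k·SD.

    Mean and sample SD (ddof=1) are computed once over the full submitted
    sample; the inequality is strict, and a zero-variance sample excludes
    nobody.  Returns a boolean *inclusion* array.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 scores to estimate the exclusion cutoff")
    sd = scores.std(ddof=1)
    if sd == 0:
        return np.ones(len(scores), dtype=bool)
    cutoff = scores.mean() - k_sd * sd
    return ~(scores < cutoff)
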