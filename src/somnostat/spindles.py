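"""Sleep-spindle detection: sigma-band RMS threshold plus three validators.

Candidates are maximal runs of the 12–15 Hz RMS envelope above
mean + 2·SD (statistics taken over N2+N3 samples of the same channel),
lasting 0.4–2 s.  Each candidate must then pass three criteria:

1. **correlation** — Pearson correlation ≥ 0.5 between the broadband
   (1–30 Hz) and sigma-filtered traces over the event window;
2. **neighbor** — at least one candidate on an adjacent 10-20 channel
   overlapping it in time;
3. **sigma power** — at least 5% of the 1–30 Hz periodogram power of the
   window inside the 12–15 Hz band (guards against broadband artifacts
   that bleed through the sigma filter).

Criterion 2 is checked against *candidate* (not validated) neighbors, so
validation is order-independent and the neighbor relation symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from somnostat import filters
from somnostat.signal_io import EEGRecording, Hypnogram, empty_events

__all__ = [
    "ADJACENCY_10_20",
    "SpindleParams",
    "detect_candidate_spindles",
    "validate_spindles",
    "detect_spindles",
]

#: Symmetric nearest-neighbor map for the 19-channel 10-20 montage.
ADJACENCY_10_20: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3", "Fz"),
    "Fp2": ("Fp1", "F8", "F4", "Fz"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "Pz", "O2"),
    "O2": ("T6", "P4", "Pz", "O1"),
}


@dataclass(frozen=True)
class SpindleParams:
    """Spindle detection/validation parameters.

    The ``use_*`` switches exist for criterion-ablation experiments; all
    three criteria are on by default.
    """

    sigma_low_hz: float = 12.0
    sigma_high_hz: float = 15.0
    broad_low_hz: float = 1.0
    broad_high_hz: float = 30.0
    target_rate_hz: float = 100.0
    rms_window_s: float = 0.2
    threshold_sd: float = 2.0
    min_duration_s: float = 0.4
    max_duration_s: float = 2.0
    corr_threshold: float = 0.5
    rel_power_threshold: float = 0.05
    adjacency: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ADJACENCY_10_20)
    )
    use_correlation: bool = True
    use_neighbor: bool = True
    use_power: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_duration_s < self.max_duration_s:
            raise ValueError("need 0 < min_duration < max_duration")
        if min(self.threshold_sd, self.corr_threshold, self.rel_power_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        for ch, nbrs in self.adjacency.items():
            for nb in nbrs:
                if ch not in self.adjacency.get(nb, ()):
                    raise ValueError(f"adjacency not symmetric: {ch}->{nb}")


def _sigma_trace(rec: EEGRecording, channel: str, params: SpindleParams) -> np.ndarray:
    y = filters.downsample(rec.get_channel(channel), rec.sfreq, params.target_rate_hz)
    return filters.bandpass(y, params.target_rate_hz, params.sigma_low_hz, params.sigma_high_hz)


def _broad_trace(rec: EEGRecording, channel: str, params: SpindleParams) -> np.ndarray:
    y = filters.downsample(rec.get_channel(channel), rec.sfreq, params.target_rate_hz)
    return filters.bandpass(y, params.target_rate_hz, params.broad_low_hz, params.broad_high_hz)


def detect_candidate_spindles(
    rec: EEGRecording,
    channel: str,
    hypnogram: Hypnogram,
    params: SpindleParams = SpindleParams(),
) -> pd.DataFrame:
    """Threshold the sigma RMS envelope on one channel.

    The envelope threshold is mean + ``threshold_sd``·SD of the envelope
    over N2+N3 samples; candidate runs must lie in NREM and last
    0.4–2 s.  With no NREM epochs a warning is issued and the result is
    empty.
    """
    fs = params.target_rate_hz
    sigma = _sigma_trace(rec, channel, params)
    stages = hypnogram.sample_stages(fs, len(sigma))
    nrem = np.isin(stages, ("N2", "N3"))
    if not nrem.any():
        warnings.warn("no NREM epochs in hypnogram; no spindle candidates")
        return empty_events()
    env = filters.moving_rms(sigma, fs, params.rms_window_s)
    thr = env[nrem].mean() + params.threshold_sd * env[nrem].std()

    above = (env > thr) & nrem
    rows = []
    for start, end in _runs_bool(above):
        duration = (end - start) / fs
        if not params.min_duration_s <= duration <= params.max_duration_s:
            continue
        window = sigma[start:end]
        trough = float(window.min())
        p2p = float(window.max() - window.min())
        # dominant sigma frequency from zero-crossing count of the window
        zc = int(np.sum(np.diff(np.signbit(window)) != 0))
        freq = zc / 2.0 / duration if duration > 0 else np.nan
        rows.append(
            {
                "kind": "spindle",
                "channel": channel,
                "start_s": start / fs,
                "end_s": end / fs,
                "trough_amplitude_uv": trough,
                "p2p_amplitude_uv": p2p,
                "duration_s": duration,
                "frequency_hz": freq,
                "stage": stages[start],
                "qc_flag": False,
            }
        )
    if not rows:
        return empty_events()
    return pd.DataFrame(rows)


def _runs_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _rel_sigma_power(window: np.ndarray, fs: float, params: SpindleParams) -> float:
    freqs, pxx = _signal.periodogram(window, fs=fs)
    broad = (freqs >= params.broad_low_hz) & (freqs <= params.broad_high_hz)
    sigma = (freqs >= params.sigma_low_hz) & (freqs <= params.sigma_high_hz)
    denom = pxx[broad].sum()
    if denom <= 0:
        return 0.0
    return float(pxx[sigma].sum() / denom)


def validate_spindles(
    candidates: pd.DataFrame,
    rec: EEGRecording,
    params: SpindleParams = SpindleParams(),
) -> pd.DataFrame:
    """Evaluate the three validation criteria on every candidate.

    Returns the candidate table augmented with ``corr``, ``rel_power``,
    ``pass_correlation``, ``pass_neighbor``, ``pass_power`` and
    ``validated`` columns; disabled criteria (see :class:`SpindleParams`)
    count as passed.  Raises if a candidate channel is missing from the
    adjacency map.
    """
    if not len(candidates):
        out = candidates.copy()
        for col in ("corr", "rel_power", "pass_correlation", "pass_neighbor",
                    "pass_power", "validated"):
            out[col] = pd.Series(dtype=float if col in ("corr", "rel_power") else bool)
        return out
    fs = params.target_rate_hz
    channels = sorted(candidates["channel"].unique())
    for ch in channels:
        if ch not in params.adjacency:
            raise ValueError(f"adjacency map missing channel {ch!r}")
    sigma = {ch: _sigma_trace(rec, ch, params) for ch in channels}
    broad = {ch: _broad_trace(rec, ch, params) for ch in channels}

    corr_v, pow_v, nb_v = [], [], []
    for row in candidates.itertuples():
        i0, i1 = int(round(row.start_s * fs)), int(round(row.end_s * fs))
        s = sigma[row.channel][i0:i1]
        b = broad[row.channel][i0:i1]
        if len(s) < 3 or s.std() == 0 or b.std() == 0:
            corr_v.append(0.0)
        else:
            corr_v.append(float(np.corrcoef(b, s)[0, 1]))
        pow_v.append(_rel_sigma_power(b, fs, params))
        nbrs = params.adjacency[row.channel]
        overlap = candidates[
            candidates["channel"].isin(nbrs)
            & (candidates["start_s"] < row.end_s)
            & (candidates["end_s"] > row.start_s)
        ]
        nb_v.append(bool(len(overlap)))

    out = candidates.copy()
    out["corr"] = corr_v
    out["rel_power"] = pow_v
    out["pass_correlation"] = (
        np.asarray(corr_v) >= params.corr_threshold
        if params.use_correlation
        else np.ones(len(out), bool)
    )
    out["pass_neighbor"] = (
        np.asarray(nb_v) if params.use_neighbor else np.ones(len(out), bool)
    )
    out["pass_power"] = (
        np.asarray(pow_v) >= params.rel_power_threshold
        if params.use_power
        else np.ones(len(out), bool)
    )
    out["validated"] = out["pass_correlation"] & out["pass_neighbor"] & out["pass_power"]
    return out


def detect_spindles(
    rec: EEGRecording,
    hypnogram: Hypnogram,
    params: SpindleParams = SpindleParams(),
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Candidate detection on all channels followed by validation.

    Returns only validated spindles in the canonical event schema.
    """
    chans = channels if channels is not None else tuple(rec.ch_names)
    parts = [detect_candidate_spindles(rec, ch, hypnogram, params) for ch in chans]
    parts = [p for p in parts if len(p)]
    if not parts:
        return empty_events()
    cands = pd.concat(parts, ignore_index=True)
    checked = validate_spindles(cands, rec, params)
    keep = checked[checked["validated"]].reset_index(drop=True)
    return keep.loc[:, list(cands.columns)]
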