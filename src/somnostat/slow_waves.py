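"""Age-adapted slow-wave detection and the subject-level SWA summary.

Slow waves (slow oscillations, 0.5–2 Hz) are detected on each channel's
trace after downsampling to 100 Hz and 0.5–2 Hz zero-phase band-pass
filtering.  A candidate wave is a maximal negative excursion followed by
the next positive excursion of the filtered trace (negative half-wave
first, delimited by descending zero crossings).  The age-adapted criteria
applied to each candidate are:

* trough depth ≥ 32 μV (trough ≤ −32 μV on the filtered trace),
* peak-to-peak amplitude ≥ 60 μV,
* duration between 0.5 s (the 2 Hz band edge) and 2.5 s,
* trough sample inside an N2 or N3 epoch.

The subject-level SWA summary is the log10 of the summed detection count
over the central channels (C3, C4, Cz); subjects need at least 120
detections in Fz or Cz to be included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10

import numpy as np
import pandas as pd

from somnostat import filters
from somnostat.signal_io import EPOCH_SEC, EEGRecording, Hypnogram, empty_events

__all__ = [
    "SWParams",
    "SWASummary",
    "bandpass_downsample",
    "detect_slow_waves",
    "detect_slow_waves_recording",
    "summarize_sw",
]


@dataclass(frozen=True)
class SWParams:
    """Detection thresholds and channel conventions for slow waves."""

    band_low_hz: float = 0.5
    band_high_hz: float = 2.0
    target_rate_hz: float = 100.0
    min_p2p_uv: float = 60.0
    min_trough_uv: float = 32.0
    max_duration_s: float = 2.5
    min_duration_s: float = 0.5
    min_detections: int = 120
    central_channels: tuple[str, ...] = ("C3", "C4", "Cz")
    anchor_channels: tuple[str, ...] = ("Fz", "Cz")

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low < band_high")
        if not 0 < self.min_duration_s < self.max_duration_s:
            raise ValueError("need 0 < min_duration < max_duration")
        if min(self.min_p2p_uv, self.min_trough_uv, self.target_rate_hz) <= 0:
            raise ValueError("thresholds and target rate must be positive")


@dataclass(frozen=True)
class SWASummary:
    """Per-subject slow-wave activity summary.

    ``central_log_sum`` is log10 of the summed detection count over the
    central channel set and is NaN when that sum is zero; ``included``
    requires ≥ ``min_detections`` on at least one anchor channel (Fz or
    Cz) *and* a nonzero central sum.
    """

    counts: dict[str, int] = field(default_factory=dict)
    central_log_sum: float = float("nan")
    included: bool = False


def bandpass_downsample(rec: EEGRecording, channel: str, params: SWParams = SWParams()) -> np.ndarray:
    """Downsample one channel to the target rate and band-pass 0.5–2 Hz."""
    x = rec.get_channel(channel)
    if rec.sfreq < 2.0 * params.band_high_hz:
        raise ValueError(
            f"sampling rate {rec.sfreq} Hz below Nyquist requirement for "
            f"{params.band_high_hz} Hz band edge"
        )
    # remove DC before filtering so filtfilt edge transients do not depend
    # on an arbitrary offset (detection is offset-invariant)
    x = x - x.mean()
    y = filters.downsample(x, rec.sfreq, params.target_rate_hz)
    return filters.bandpass(y, params.target_rate_hz, params.band_low_hz, params.band_high_hz)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) bounds of maximal True runs."""
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


def _candidate_waves(x: np.ndarray) -> list[tuple[int, int, int, float, float]]:
    """Candidate waves as (start, end, trough_idx, trough, peak).

    A candidate pairs a maximal negative run with the next positive run
    that begins before any further negative run — i.e. the span between
    consecutive descending zero crossings, with the negative half first.
    """
    neg = _runs(x < 0)
    pos = _runs(x > 0)
    out = []
    pi = 0
    for k, (ns, ne) in enumerate(neg):
        while pi < len(pos) and pos[pi][0] < ne:
            pi += 1
        if pi == len(pos):
            break
        ps, pe = pos[pi]
        next_neg_start = neg[k + 1][0] if k + 1 < len(neg) else len(x)
        if ps >= next_neg_start:
            continue  # no positive half before the next wave begins
        trough_idx = ns + int(np.argmin(x[ns:ne]))
        trough = float(x[trough_idx])
        peak = float(np.max(x[ps:pe]))
        out.append((ns, pe, trough_idx, trough, peak))
    return out


def detect_slow_waves(
    filtered: np.ndarray,
    hypnogram: Hypnogram,
    params: SWParams = SWParams(),
    channel: str = "Cz",
) -> pd.DataFrame:
    """Apply the amplitude/duration criteria to a filtered 100 Hz trace.

    Only candidates whose trough sample falls in an N2 or N3 epoch are
    emitted.  Raises if the trace and hypnogram disagree in length by more
    than one epoch.
    """
    fs = params.target_rate_hz
    n = len(filtered)
    mismatch = abs(n / fs - hypnogram.duration_s)
    if mismatch > EPOCH_SEC:
        raise ValueError(
            f"hypnogram covers {hypnogram.duration_s}s but trace spans {n / fs}s"
        )
    stages = hypnogram.sample_stages(fs, n)

    rows = []
    for start, end, trough_idx, trough, peak in _candidate_waves(np.asarray(filtered, float)):
        duration = (end - start) / fs
        stage = stages[trough_idx]
        if stage not in ("N2", "N3"):
            continue
        if trough > -params.min_trough_uv:
            continue
        if (peak - trough) < params.min_p2p_uv:
            continue
        if not params.min_duration_s <= duration <= params.max_duration_s:
            continue
        rows.append(
            {
                "kind": "slow_wave",
                "channel": channel,
                "start_s": start / fs,
                "end_s": end / fs,
                "trough_amplitude_uv": trough,
                "p2p_amplitude_uv": peak - trough,
                "duration_s": duration,
                "frequency_hz": 1.0 / duration,
                "stage": stage,
                "qc_flag": False,
            }
        )
    if not rows:
        return empty_events()
    return pd.DataFrame(rows)


def detect_slow_waves_recording(
    rec: EEGRecording,
    hypnogram: Hypnogram,
    params: SWParams = SWParams(),
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Filter and detect on each requested channel of a raw recording."""
    chans = channels if channels is not None else tuple(rec.ch_names)
    parts = []
    for ch in chans:
        trace = bandpass_downsample(rec, ch, params)
        parts.append(detect_slow_waves(trace, hypnogram, params, channel=ch))
    out = pd.concat(parts, ignore_index=True) if parts else empty_events()
    return out


def summarize_sw(events: pd.DataFrame, params: SWParams = SWParams()) -> SWASummary:
    """Per-subject summary: channel counts, central log-sum, inclusion.

    QC-flagged events are excluded from all counts.  Inclusion requires
    ≥ ``min_detections`` in Fz *or* Cz; a zero central sum leaves the
    summary undefined (NaN) and the subject excluded.
    """
    if len(events):
        live = events.loc[~events["qc_flag"].astype(bool)]
        counts = live.groupby("channel").size().to_dict()
    else:
        counts = {}
    counts = {str(k): int(v) for k, v in counts.items()}
    anchor_ok = any(counts.get(c, 0) >= params.min_detections for c in params.anchor_channels)
    central_sum = sum(counts.get(c, 0) for c in params.central_channels)
    if central_sum > 0:
        return SWASummary(counts=counts, central_log_sum=log10(central_sum), included=anchor_ok)
    return SWASummary(counts=counts, central_log_sum=float("nan"), included=False)
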