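"""Readers and writers for the formats the pipeline touches.

Recordings travel as EDF (European Data Format: one 256-byte ASCII header,
256 bytes per signal, then little-endian int16 data records), hypnograms as
a two-column TSV (``epoch_index<TAB>stage``, 30-s epochs), and event /
cohort tables as plain CSV.  All readers reject malformed input with a
:class:`FormatError` naming the offending field rather than silently
coercing it.

Time coordinates are seconds from recording start, 0-based, with half-open
event intervals ``[start_s, end_s)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "EPOCH_SEC",
    "MONTAGE_10_20",
    "EVENT_COLUMNS",
    "FormatError",
    "EEGRecording",
    "Hypnogram",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_table",
    "write_table",
    "subtract_reference",
]

#: Sleep-stage alphabet (AASM nomenclature, N4 folded into N3 upstream).
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Fixed scoring epoch length in seconds.
EPOCH_SEC = 30.0

#: The standard 19-channel 10-20 scalp montage (mastoid references A1/A2
#: are subtracted at acquisition and not carried as data channels).
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Canonical event-table schema shared by slow waves and spindles.
EVENT_COLUMNS = (
    "kind",
    "channel",
    "start_s",
    "end_s",
    "trough_amplitude_uv",
    "p2p_amplitude_uv",
    "duration_s",
    "frequency_hz",
    "stage",
    "qc_flag",
)


class FormatError(ValueError):
    """Raised when a file does not conform to the expected format."""


@dataclass
class EEGRecording:
    """A multichannel sampled EEG signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Per-channel samples in μV.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique 10-20 channel labels, one per row of ``data``.
    reference : str, optional
        Free-text annotation of the reference scheme (e.g. "A1+A2").
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    reference: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.ch_names = list(self.ch_names)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def get_channel(self, label: str) -> np.ndarray:
        """Return the sample vector for ``label``."""
        try:
            idx = self.ch_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage {self.ch_names}") from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Per-30-s-epoch sleep-stage sequence aligned to a recording."""

    stages: np.ndarray = field(default_factory=lambda: np.array([], dtype="U3"))

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U3")
        bad = set(self.stages.tolist()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage symbols: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_SEC

    def sample_stages(self, sfreq: float, n_samples: int) -> np.ndarray:
        """Stage symbol for each of ``n_samples`` samples at ``sfreq``.

        Samples past the hypnogram end (at most one epoch of slack is
        accepted by callers) are labelled 'W'.
        """
        epoch_idx = (np.arange(n_samples) / (EPOCH_SEC * sfreq)).astype(int)
        out = np.full(n_samples, "W", dtype="U3")
        valid = epoch_idx < self.n_epochs
        out[valid] = self.stages[epoch_idx[valid]]
        return out

    def stage_minutes(self) -> dict[str, float]:
        """Total minutes spent in each stage."""
        return {
            s: float(np.sum(self.stages == s)) * EPOCH_SEC / 60.0 for s in STAGES
        }


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

# symmetric digital range so that 0 μV is an exact fixed point of the
# physical<->digital mapping (with a symmetric physical range)
_EDF_DIG_MIN, _EDF_DIG_MAX = -32767, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF field too long: {text!r} (> {width} bytes)")
    return raw.ljust(width)


def write_edf(
    path: str | Path,
    rec: EEGRecording,
    phys_range: tuple[float, float] = (-500.0, 500.0),
) -> None:
    """Write a recording as a plain EDF file.

    One data record per second; all channels share ``phys_range`` (μV),
    which defaults to ±500 μV — wide enough for slow-wave amplitudes with
    a quantization step of 1000/65536 ≈ 0.015 μV.  Values outside the
    physical range raise rather than clip.
    """
    pmin, pmax = map(float, phys_range)
    if not pmin < pmax:
        raise ValueError("phys_range must be (min, max) with min < max")
    if rec.data.size and (rec.data.min() < pmin or rec.data.max() > pmax):
        raise ValueError(
            f"samples exceed physical range {phys_range}; pass a wider phys_range"
        )
    if abs(rec.sfreq - round(rec.sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    sfreq = int(round(rec.sfreq))
    n_rec, rem = divmod(rec.n_samples, sfreq)
    if rem:
        raise ValueError("recording length must be a whole number of seconds")

    n_sig = rec.n_channels
    header_bytes = 256 * (1 + n_sig)
    now = _dt.datetime(2000, 1, 1)
    head = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    fields = [
        [_pad(name, 16) for name in rec.ch_names],
        [_pad("AgAgCl electrode", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(f"{pmin:g}", 8)] * n_sig,
        [_pad(f"{pmax:g}", 8)] * n_sig,
        [_pad(str(_EDF_DIG_MIN), 8)] * n_sig,
        [_pad(str(_EDF_DIG_MAX), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(sfreq), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    sig_head = b"".join(b"".join(f) for f in fields)

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    dig = np.round((rec.data - pmin) * scale + _EDF_DIG_MIN).astype("<i2")
    # records are channel-blocked per second: (n_rec, n_sig, sfreq)
    blocks = dig.reshape(n_sig, n_rec, sfreq).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        fh.write(blocks.tobytes())


def _read_field(buf: bytes, offset: int, width: int, name: str) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def _int_field(buf: bytes, offset: int, width: int, name: str) -> int:
    text = _read_field(buf, offset, width, name)
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"EDF header field {name!r} is not an integer: {text!r}")


def _float_field(text: str, name: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"EDF header field {name!r} is not numeric: {text!r}")


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording`.

    Only equal-rate μV signals are supported (all this pipeline writes).
    Header problems raise :class:`FormatError` naming the offending field.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("EDF header field 'version': file shorter than 256 bytes")
    version = _read_field(raw, 0, 8, "version")
    if version != "0":
        raise FormatError(f"EDF header field 'version' must be '0', got {version!r}")
    header_bytes = _int_field(raw, 184, 8, "header_bytes")
    n_rec = _int_field(raw, 236, 8, "n_records")
    rec_dur = _float_field(_read_field(raw, 244, 8, "record_duration"), "record_duration")
    n_sig = _int_field(raw, 252, 4, "n_signals")
    if n_sig <= 0:
        raise FormatError(f"EDF header field 'n_signals' must be positive, got {n_sig}")
    if header_bytes != 256 * (1 + n_sig):
        raise FormatError(
            f"EDF header field 'header_bytes' inconsistent: {header_bytes} "
            f"for {n_sig} signals"
        )
    if len(raw) < header_bytes:
        raise FormatError("EDF header field 'header_bytes': file truncated")

    # signal-header layout: label 16, transducer 80, dim 8, pmin 8, pmax 8,
    # dmin 8, dmax 8, prefilter 80, samples 8, reserved 32; each field is
    # stored contiguously for all signals.
    off = {}
    cursor = 0
    for name, width in [
        ("label", 16), ("transducer", 80), ("dimension", 8),
        ("physical_min", 8), ("physical_max", 8),
        ("digital_min", 8), ("digital_max", 8),
        ("prefilter", 80), ("n_samples", 8), ("reserved", 32),
    ]:
        off[name] = (cursor, width)
        cursor += width

    def field_list(name: str) -> list[str]:
        start, width = off[name]
        base = 256 + start * n_sig
        return [
            raw[base + i * width : base + (i + 1) * width]
            .decode("ascii", errors="replace")
            .strip()
            for i in range(n_sig)
        ]

    labels = field_list("label")
    pmins = [_float_field(t, "physical_min") for t in field_list("physical_min")]
    pmaxs = [_float_field(t, "physical_max") for t in field_list("physical_max")]
    dmins = [int(_float_field(t, "digital_min")) for t in field_list("digital_min")]
    dmaxs = [int(_float_field(t, "digital_max")) for t in field_list("digital_max")]
    spr = [int(_float_field(t, "n_samples")) for t in field_list("n_samples")]

    if len(set(spr)) != 1:
        raise FormatError("EDF header field 'n_samples': unequal rates not supported")
    if rec_dur <= 0:
        raise FormatError(
            f"EDF header field 'record_duration' must be positive, got {rec_dur}"
        )
    for i, (pmn, pmx, dmn, dmx) in enumerate(zip(pmins, pmaxs, dmins, dmaxs)):
        if not pmn < pmx:
            raise FormatError(
                f"EDF header field 'physical_min/max' invalid for signal {labels[i]!r}"
            )
        if not dmn < dmx:
            raise FormatError(
                f"EDF header field 'digital_min/max' invalid for signal {labels[i]!r}"
            )

    n_per = spr[0]
    expected = header_bytes + 2 * n_rec * n_sig * n_per
    if len(raw) < expected:
        raise FormatError("EDF header field 'n_records': data section truncated")
    dig = np.frombuffer(raw, dtype="<i2", count=n_rec * n_sig * n_per, offset=header_bytes)
    blocks = dig.reshape(n_rec, n_sig, n_per).transpose(1, 0, 2).reshape(n_sig, -1)
    data = np.empty(blocks.shape, dtype=float)
    for i in range(n_sig):
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        data[i] = (blocks[i].astype(float) - dmins[i]) * scale + pmins[i]
    sfreq = n_per / rec_dur
    return EEGRecording(data=data, sfreq=sfreq, ch_names=labels)


# ---------------------------------------------------------------------------
# Hypnogram TSV
# ---------------------------------------------------------------------------

def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    """Write a hypnogram as two-column TSV: epoch_index<TAB>stage."""
    with open(path, "w") as fh:
        for i, stage in enumerate(hyp.stages):
            fh.write(f"{i}\t{stage}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read the package's two-column hypnogram TSV.

    Raises :class:`FormatError` with a line number for unknown stage
    symbols, and "no epochs" for an empty file.
    """
    stages: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'epoch<TAB>stage', got {line!r}")
            _, stage = parts
            if stage not in STAGES:
                raise FormatError(f"line {lineno}: unknown stage symbol {stage!r}")
            stages.append(stage)
    if not stages:
        raise FormatError("no epochs")
    return Hypnogram(np.array(stages))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV table, checking that ``required`` columns are present."""
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return table


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    events = read_table(path, required=EVENT_COLUMNS)
    if len(events) and (events["start_s"] >= events["end_s"]).any():
        raise FormatError("event table violates start_s < end_s")
    return events


def empty_events() -> pd.DataFrame:
    """An empty event table with the canonical schema."""
    return pd.DataFrame(
        {
            "kind": pd.Series(dtype=str),
            "channel": pd.Series(dtype=str),
            "start_s": pd.Series(dtype=float),
            "end_s": pd.Series(dtype=float),
            "trough_amplitude_uv": pd.Series(dtype=float),
            "p2p_amplitude_uv": pd.Series(dtype=float),
            "duration_s": pd.Series(dtype=float),
            "frequency_hz": pd.Series(dtype=float),
            "stage": pd.Series(dtype=str),
            "qc_flag": pd.Series(dtype=bool),
        }
    )


def subtract_reference(rec: EEGRecording, ref_label: str) -> EEGRecording:
    """Re-reference all channels to a single (e.g. unilateral mastoid) channel.

    Optional transform for recordings carrying a reference channel; the
    reference channel itself is dropped from the output.
    """
    ref = rec.get_channel(ref_label)
    keep = [c for c in rec.ch_names if c != ref_label]
    data = np.stack([rec.get_channel(c) - ref for c in keep])
    return EEGRecording(data=data, sfreq=rec.sfreq, ch_names=keep, reference=ref_label)
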