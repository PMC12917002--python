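"""Spindle candidate detection and the three validation criteria."""

import numpy as np
import pandas as pd
import pytest

from somnostat.signal_io import EEGRecording, Hypnogram, MONTAGE_10_20
from somnostat.simulate import EventPlan, NoiseSpec, synthesize_recording
from somnostat.spindles import (
    ADJACENCY_10_20,
    SpindleParams,
    detect_candidate_spindles,
    detect_spindles,
    validate_spindles,
)

HYP = Hypnogram(np.array(["N2"] * 20))  # 10 min of N2


def planted_burst_recording(channels=("Cz", "C3"), onsets=(60.0, 180.0, 300.0),
                            p2p=60.0, seed=21):
    events = [
        EventPlan("spindle", ch, t, 13.0, p2p, 1.0) for t in onsets for ch in channels
    ]
    rec, truth = synthesize_recording(HYP, events=events, noise=NoiseSpec("pink", 10.0, seed))
    return rec, truth


class TestCandidates:
    def test_zero_signal_no_candidates(self):
        rec = EEGRecording(np.zeros((1, int(400 * HYP.duration_s))), 400.0, ["Cz"])
        out = detect_candidate_spindles(rec, "Cz", HYP)
        assert len(out) == 0

    def test_planted_burst_yields_one_overlapping_candidate(self):
        rec, truth = planted_burst_recording(channels=("Cz",), onsets=(120.0,), p2p=100.0)
        out = detect_candidate_spindles(rec, "Cz", HYP)
        hits = out[(out["start_s"] < 121.0) & (out["end_s"] > 120.0)]
        assert len(hits) == 1
        assert 11.0 <= hits.iloc[0]["frequency_hz"] <= 16.0

    @pytest.mark.parametrize(
        "duration,p2p,expected", [(0.12, 40.0, 0), (1.0, 120.0, 1), (2.5, 120.0, 0)]
    )
    def test_duration_bounds(self, duration, p2p, expected):
        # envelope runs must last 0.4-2 s; the 200-ms RMS window and sigma
        # filter ringing smear a planted burst, so the short burst is
        # planted well below the bound and at moderate amplitude
        ev = [EventPlan("spindle", "Cz", 120.0, 13.0, p2p, duration)]
        rec, _ = synthesize_recording(HYP, events=ev, noise=NoiseSpec("pink", 10.0, 3))
        out = detect_candidate_spindles(rec, "Cz", HYP)
        hits = out[(out["start_s"] < 120.0 + duration) & (out["end_s"] > 120.0)]
        assert len(hits) == expected

    def test_no_nrem_warns_and_returns_empty(self):
        rec, _ = planted_burst_recording(channels=("Cz",), onsets=(60.0,))
        wake = Hypnogram(np.array(["W"] * 20))
        with pytest.warns(UserWarning, match="NREM"):
            out = detect_candidate_spindles(rec, "Cz", wake)
        assert len(out) == 0


def _candidate_row(channel, start, end):
    return {
        "kind": "spindle",
        "channel": channel,
        "start_s": start,
        "end_s": end,
        "trough_amplitude_uv": -10.0,
        "p2p_amplitude_uv": 20.0,
        "duration_s": end - start,
        "frequency_hz": 13.0,
        "stage": "N2",
        "qc_flag": False,
    }


class TestValidation:
    def test_coincident_bursts_pass_all_three(self):
        rec, _ = planted_burst_recording()
        out = detect_spindles(rec, HYP, channels=("Cz", "C3", "C4"))
        for t in (60.0, 180.0, 300.0):
            for ch in ("Cz", "C3"):
                assert len(out[(out["channel"] == ch)
                               & (out["start_s"] < t + 1.0)
                               & (out["end_s"] > t)]) >= 1

    def test_missing_neighbor_rejected_by_neighbor_only(self):
        rec, _ = planted_burst_recording(channels=("Cz",), onsets=(120.0,), p2p=100.0)
        cands = detect_candidate_spindles(rec, "Cz", HYP)
        cands = cands[(cands["start_s"] < 121.0) & (cands["end_s"] > 120.0)]
        checked = validate_spindles(cands, rec)
        row = checked.iloc[0]
        assert row["pass_correlation"] and row["pass_power"]
        assert not row["pass_neighbor"]
        assert not row["validated"]

    def test_low_correlation_rejected_by_correlation_only(self):
        # sigma burst swamped in-window by a 5 Hz component: corr < 0.5 but
        # relative sigma power stays >= 5% and a neighbor burst overlaps
        t = np.arange(int(400 * HYP.duration_s)) / 400.0
        data = np.zeros((2, len(t)))
        window = (t >= 120.0) & (t < 121.0)
        data[0, window] += 20.0 * np.sin(2 * np.pi * 13.0 * t[window])
        data[0, window] += 45.0 * np.sin(2 * np.pi * 5.0 * t[window])
        data[1, window] += 20.0 * np.sin(2 * np.pi * 13.0 * t[window])
        rec = EEGRecording(data, 400.0, ["Cz", "C3"])
        cands = pd.DataFrame(
            [_candidate_row("Cz", 120.0, 121.0), _candidate_row("C3", 120.0, 121.0)]
        )
        checked = validate_spindles(cands, rec)
        row = checked[checked["channel"] == "Cz"].iloc[0]
        assert row["corr"] < 0.5 and not row["pass_correlation"]
        assert row["rel_power"] >= 0.05 and row["pass_power"]
        assert row["pass_neighbor"]

    def test_low_sigma_power_rejected_by_power_only(self):
        # a strong 11.5 Hz artifact leaks through the sigma filter's skirt:
        # broadband/sigma correlation is high but true 12-15 Hz power is <5%.
        # (11.5 Hz sits exactly on a periodogram bin of the 2-s window, so
        # none of its power leaks into the 12-15 Hz band.)
        t = np.arange(int(400 * HYP.duration_s)) / 400.0
        data = np.zeros((2, len(t)))
        window = (t >= 120.0) & (t < 122.0)
        data[0, window] += 60.0 * np.sin(2 * np.pi * 11.5 * t[window])
        data[0, window] += 6.0 * np.sin(2 * np.pi * 13.0 * t[window])
        data[1, window] += 30.0 * np.sin(2 * np.pi * 13.0 * t[window])
        rec = EEGRecording(data, 400.0, ["Cz", "C3"])
        cands = pd.DataFrame(
            [_candidate_row("Cz", 120.0, 122.0), _candidate_row("C3", 120.0, 122.0)]
        )
        checked = validate_spindles(cands, rec)
        row = checked[checked["channel"] == "Cz"].iloc[0]
        assert row["rel_power"] < 0.05 and not row["pass_power"]
        assert row["pass_correlation"], f"corr was {row['corr']}"
        assert row["pass_neighbor"]

    def test_ablation_admits_exactly_the_matching_counterexample(self):
        rec, _ = planted_burst_recording(channels=("Cz",), onsets=(120.0,), p2p=100.0)
        cands = detect_candidate_spindles(rec, "Cz", HYP)
        cands = cands[(cands["start_s"] < 121.0) & (cands["end_s"] > 120.0)]
        rejected = validate_spindles(cands, rec)
        assert not rejected["validated"].iloc[0]
        admitted = validate_spindles(cands, rec, SpindleParams(use_neighbor=False))
        assert admitted["validated"].iloc[0]
        # disabling a different criterion does not admit it
        still = validate_spindles(cands, rec, SpindleParams(use_power=False))
        assert not still["validated"].iloc[0]

    def test_neighbor_symmetry(self):
        rec, _ = planted_burst_recording()
        cands = pd.concat(
            [detect_candidate_spindles(rec, ch, HYP) for ch in ("Cz", "C3")],
            ignore_index=True,
        )
        checked = validate_spindles(cands, rec)
        near = checked[(checked["start_s"] < 61.0) & (checked["end_s"] > 60.0)]
        by_ch = near.set_index("channel")["pass_neighbor"]
        assert bool(by_ch.get("Cz", False)) == bool(by_ch.get("C3", False)) == True

    def test_validated_subset_of_candidates(self):
        rec, _ = planted_burst_recording(seed=5)
        cands = pd.concat(
            [detect_candidate_spindles(rec, ch, HYP) for ch in ("Cz", "C3", "C4")],
            ignore_index=True,
        )
        checked = validate_spindles(cands, rec)
        assert checked["validated"].sum() <= len(cands)
        assert len(checked) == len(cands)

    def test_missing_adjacency_rejected(self):
        rec, _ = planted_burst_recording(channels=("Cz",), onsets=(120.0,))
        cands = pd.DataFrame([_candidate_row("Cz", 120.0, 121.0)])
        params = SpindleParams(adjacency={})
        with pytest.raises(ValueError, match="adjacency"):
            validate_spindles(cands, rec, params)


def test_adjacency_table_is_symmetric_and_covers_montage():
    for ch in MONTAGE_10_20:
        assert ch in ADJACENCY_10_20
        for nb in ADJACENCY_10_20[ch]:
            assert ch in ADJACENCY_10_20[nb]
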