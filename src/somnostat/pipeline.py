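"""End-to-end orchestration: simulate → detect → QC → score → analyze.

A single :class:`RunConfig` drives the whole study.  Two execution modes
coexist:

* **summary mode** (default): the cohort mediator (log central slow-wave
  count) comes straight from the generative cohort model — fast enough
  for repeated seeded replicates;
* **signal mode** (``eeg_subjects > 0``): for the first few subjects a
  short staged EEG is synthesized with a planted slow-wave/spindle load,
  run through detection + QC, and summarised, demonstrating the full
  signal path; its per-subject counts are reported alongside.

Every run writes a manifest recording package version, all parameters and
seeds, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from somnostat.atrophy import apply_exclusion, composite_atrophy_score
from somnostat.qc import QCParams, flag_outlier_events
from somnostat.signal_io import Hypnogram, write_events, write_table
from somnostat.simulate import (
    CohortSimConfig,
    EventPlan,
    NoiseSpec,
    StagePlan,
    generate_cohort,
    generate_hypnogram,
    generate_volume_table,
    synthesize_recording,
)
from somnostat.slow_waves import SWParams, detect_slow_waves_recording, summarize_sw
from somnostat.spindles import SpindleParams, detect_spindles
from somnostat.stats import (
    correlate,
    mediation_bootstrap,
    ols_regression,
    overnight_change,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, with reproducible seeds."""

    seed: int = 0
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    sw_params: SWParams = field(default_factory=SWParams)
    spindle_params: SpindleParams = field(default_factory=SpindleParams)
    qc_params: QCParams = field(default_factory=QCParams)
    covariates: tuple[str, ...] = ("age", "gender", "trait_anxiety")
    n_boot: int = 1000
    eeg_subjects: int = 0
    eeg_minutes: float = 10.0

    def __post_init__(self) -> None:
        if not isinstance(self.cohort, CohortSimConfig):
            self.cohort = CohortSimConfig(**self.cohort)
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)


def _corr_dict(res) -> dict:
    return {
        "r": res.r,
        "ci": [res.ci_low, res.ci_high],
        "p": res.p,
        "n": res.n,
        "method": res.method,
    }


def _reg_dict(table: pd.DataFrame) -> dict:
    return {
        "r2": table.attrs["r2"],
        "n": table.attrs["n"],
        "terms": table.to_dict(orient="records"),
    }


def _eeg_demo(config: RunConfig, subject_rows: pd.DataFrame, outdir: Path) -> list[dict]:
    """Run the signal-level path for a handful of subjects."""
    results = []
    epochs = int(round(config.eeg_minutes * 2))
    for i, row in enumerate(subject_rows.itertuples()):
        seed = (config.seed * 1009 + 17 * i + 1) % (2**31)
        plan = StagePlan(
            epoch_count=epochs,
            stage_minutes={"N2": config.eeg_minutes * 0.7, "N3": config.eeg_minutes * 0.3},
            seed=seed,
        )
        hyp = generate_hypnogram(plan)
        # plant a slow-wave load proportional to the subject's mediator,
        # scaled from a full night to this short demo window
        night_count = 10.0 ** row.swa_log / 3.0  # per central channel
        demo_count = max(5, int(round(night_count * config.eeg_minutes / (8 * 60))))
        rng = np.random.default_rng(seed + 1)
        duration_s = hyp.n_epochs * 30.0
        onsets = np.sort(rng.uniform(1.0, duration_s - 3.0, demo_count))
        onsets = onsets[np.concatenate(([True], np.diff(onsets) > 2.0))]
        events = []
        for ch in ("C3", "C4", "Cz"):
            events.extend(
                EventPlan("slow_wave", ch, float(t), 1.0, 80.0) for t in onsets
            )
        rec, truth = synthesize_recording(
            hyp, events=events, noise=NoiseSpec("pink", 10.0, seed + 2)
        )
        detected = detect_slow_waves_recording(
            rec, hyp, config.sw_params, channels=("C3", "C4", "Cz", "Fz")
        )
        if len(detected):
            detected = flag_outlier_events(detected, config.qc_params)
        summary = summarize_sw(detected, config.sw_params)
        spind = detect_spindles(rec, hyp, config.spindle_params, channels=("C3", "Cz", "C4"))
        write_events(outdir / f"events_{row.subject_id}.csv", detected)
        results.append(
            {
                "subject_id": row.subject_id,
                "planted": int(len(truth)),
                "detected": {k: int(v) for k, v in summary.counts.items()},
                "central_log_sum": summary.central_log_sum,
                "spindles": int(len(spind)),
            }
        )
    return results


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full study and write the results bundle to ``outdir``.

    Stages: cohort simulation → volume-table scoring → 2.5-SD exclusion →
    (optional per-subject EEG detection demo) → correlations, adjusted
    regressions and bootstrap mediation.  Returns the report dict; writes
    ``cohort.csv``, ``volumes.csv``, ``report.json`` and
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.cohort.n_subjects < 1:
        raise ValueError("empty cohort")

    stage = "simulate"
    try:
        cohort, truth = generate_cohort(config.cohort)

        stage = "score-atrophy"
        volumes = generate_volume_table(
            cohort["atrophy"].to_numpy(),
            subject_ids=list(cohort["subject_id"]),
            seed=(config.seed + 101) % (2**31),
        )
        scored = composite_atrophy_score(volumes)
        if not np.allclose(scored["atrophy_composite"], cohort["atrophy"]):
            raise ValueError("volume table does not reproduce composite scores")
        include = apply_exclusion(scored["atrophy_composite"].to_numpy())
        cohort = cohort.assign(atrophy_included=include)
        analysis = cohort[cohort["atrophy_included"]].reset_index(drop=True)
        if len(analysis) < 10:
            raise ValueError("fewer than 10 subjects after exclusion")

        stage = "detect"
        eeg_report = []
        if config.eeg_subjects > 0:
            eeg_report = _eeg_demo(config, analysis.head(config.eeg_subjects), outdir)

        stage = "analyze"
        # the analysis outcome is always recomputed from the pre/post STAI
        # columns rather than trusted from the simulator
        analysis = analysis.assign(
            anx_change=overnight_change(
                analysis["pre_anxiety_1"],
                analysis["pre_anxiety_2"],
                analysis["post_anxiety"],
            )
        )
        report = {
            "n_simulated": int(config.cohort.n_subjects),
            "n_analyzed": int(len(analysis)),
            "n_excluded_atrophy": int((~include).sum()),
            "correlations": {
                "swa_vs_anx_change": _corr_dict(
                    correlate(analysis["swa_log"], analysis["anx_change"])
                ),
                "atrophy_vs_anx_change": _corr_dict(
                    correlate(analysis["atrophy"], analysis["anx_change"])
                ),
                "atrophy_vs_swa": _corr_dict(
                    correlate(analysis["atrophy"], analysis["swa_log"])
                ),
            },
            "adjusted_models": {
                "anx_change~swa_log": _reg_dict(
                    ols_regression(analysis, "anx_change", "swa_log", config.covariates)
                ),
                "anx_change~atrophy": _reg_dict(
                    ols_regression(analysis, "anx_change", "atrophy", config.covariates)
                ),
                "swa_log~atrophy": _reg_dict(
                    ols_regression(analysis, "swa_log", "atrophy", config.covariates)
                ),
            },
        }

        stage = "mediate"
        med = mediation_bootstrap(
            analysis,
            x="atrophy",
            m="swa_log",
            y="anx_change",
            covariates=config.covariates,
            n_boot=config.n_boot,
            seed=(config.seed + 7) % (2**31),
        )
        report["mediation"] = {
            "a": med.a,
            "b": med.b,
            "c_prime": med.c_prime,
            "total": med.total,
            "indirect": med.indirect,
            "ci": [med.ci_low, med.ci_high],
            "p_boot": med.p_boot,
            "significant": med.significant,
            "n_boot": med.n_boot,
            "n": med.n,
        }
        direct_table = ols_regression(
            analysis, "anx_change", "atrophy", ("swa_log", *config.covariates)
        )
        drow = direct_table[direct_table["term"] == "atrophy"].iloc[0]
        report["direct_effect"] = {
            "coef": float(drow["coef"]),
            "ci": [float(drow["ci_low"]), float(drow["ci_high"])],
            "p": float(drow["p"]),
        }
        if eeg_report:
            report["eeg_demo"] = eeg_report
        report["true_parameters"] = truth
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    write_table(outdir / "cohort.csv", cohort)
    write_table(outdir / "volumes.csv", scored)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    from importlib.metadata import version as _pkg_version

    manifest = {
        "package_version": _pkg_version("somnostat"),
        "seed": config.seed,
        "cohort": dataclasses.asdict(config.cohort),
        "sw_params": dataclasses.asdict(config.sw_params),
        "spindle_params": dataclasses.asdict(config.spindle_params),
        "qc_params": dataclasses.asdict(config.qc_params),
        "covariates": list(config.covariates),
        "n_boot": config.n_boot,
        "eeg_subjects": config.eeg_subjects,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report
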