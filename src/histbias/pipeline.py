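"""End-to-end orchestration: cohort -> behaviour -> physiology -> model -> stats.

``run_all`` generates (or ingests) a cohort, computes behavioural summaries,
preprocesses per-session physiology, fits the history-conditioned diffusion
model per participant and drug condition, runs the statistics battery, and
writes a structured report (JSON plus tidy CSV tables).  Every random
consumer receives a named child seed derived from the run seed, so a re-run
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from histbias import behavior, ddm, physio, stats
from histbias.synth import CohortDataset, CohortSpec, TaskDesign, generate_cohort

__all__ = ["RunConfig", "run_all", "validate_dataset"]

log = logging.getLogger("histbias")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int = 0
    n_participants: int = 19
    out_dir: str | None = None
    design: TaskDesign = field(default_factory=TaskDesign)
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    run_physio: bool = True
    run_ddm: bool = True
    ddm_starts: int = 3
    physio_fs: float = 100.0
    n_pupil_bins: int = 8
    n_perm: int = 10000
    n_boot: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = TaskDesign(**raw.pop("design", {}))
        spec = CohortSpec(**raw.pop("cohort_spec", {}))
        for key in ("design", "cohort_spec"):
            raw.pop(key, None)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=design, cohort_spec=spec, **raw)


def _child_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return None if obj.size > 100 else obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _physio_stage(cohort: CohortDataset, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-session pupil/ECG processing.

    Returns (per-trial tpr table, per-participant block-level summary with
    mean pupil size and heart rate per drug condition).
    """
    tpr_rows = []
    block_rows = []
    sessions = cohort.trials[["participant_id", "session_id", "drug"]].drop_duplicates()
    for _, (pid, ses, drug) in sessions.iterrows():
        pupil, ecg = cohort.session_physio(pid, int(ses), fs_pupil=config.physio_fs)
        clean, _ = physio.preprocess(pupil)
        sub = cohort.trials[
            (cohort.trials["participant_id"] == pid) & (cohort.trials["session_id"] == ses)
        ]
        tpr = physio.task_evoked_response(clean, sub["choice_time"].to_numpy(),
                                          sub["onset_time"].to_numpy())
        tpr_rows.append(pd.DataFrame({"index": sub.index, "tpr": tpr}))
        bp = physio.blockwise_pupil(pupil)
        hr = physio.blockwise_heart_rate(ecg)
        block_rows.append(
            {"participant_id": pid, "session_id": int(ses), "drug": drug,
             "pupil_block_mean": float(np.mean(bp)), "heart_rate": float(np.mean(hr))}
        )
    tpr_table = pd.concat(tpr_rows).set_index("index").sort_index()
    return tpr_table, pd.DataFrame(block_rows)


def _ddm_stage(trials: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Fit the diffusion model per participant x drug on pooled sessions."""
    rows = []
    for (pid, drug), sub in trials.groupby(["participant_id", "drug"], sort=True):
        cfg = ddm.FitConfig(n_starts=config.ddm_starts,
                            seed=_child_seed(config.seed, 3, hash(pid) % 10000, int(drug == "atomoxetine")))
        fit = ddm.fit_session(sub, cfg)
        shifts = ddm.history_shifts(fit)
        row = {"participant_id": pid, "drug": drug, "loglik": fit.loglik,
               "converged": fit.converged, "z_shift": shifts.z_shift,
               "vbias_shift": shifts.vbias_shift}
        row.update(fit.params.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_stage(summary, summary_strength, fits, blocks, binned, config) -> dict:
    out = {}
    piv = summary.pivot(index="participant_id", columns="drug", values=["p_repeat", "abs_bias"])
    pl_rep = piv[("p_repeat", "placebo")].to_numpy()
    at_rep = piv[("p_repeat", "atomoxetine")].to_numpy()
    out["abs_bias_paired_t"] = stats.paired_t(
        piv[("abs_bias", "atomoxetine")].to_numpy(), piv[("abs_bias", "placebo")].to_numpy()
    ).to_dict()
    for metric in ("p_repeat", "accuracy", "mean_rt", "abs_bias"):
        try:
            res = stats.rm_anova_2x2(summary_strength, dv=metric)
            out[f"rmanova_{metric}"] = {k: v.to_dict() for k, v in res.items()}
        except ValueError as exc:
            out[f"rmanova_{metric}"] = {"error": str(exc)}

    shift = at_rep - pl_rep
    out["repeat_shift_vs_placebo"] = stats.pearson_with_bootstrap(
        pl_rep, shift, n_boot=config.n_boot, seed=_child_seed(config.seed, 41)
    ).to_dict()
    out["reversion_to_mean_perm"] = stats.perm_reversion_to_mean(
        pl_rep, at_rep, n_perm=config.n_perm, seed=_child_seed(config.seed, 42)
    ).to_dict()

    if fits is not None and not fits.empty:
        fpiv = fits.pivot(index="participant_id", columns="drug",
                          values=["z_shift", "vbias_shift"])
        out["vbias_shift_paired_t"] = stats.paired_t(
            fpiv[("vbias_shift", "atomoxetine")].to_numpy(),
            fpiv[("vbias_shift", "placebo")].to_numpy(),
        ).to_dict()
        out["z_shift_paired_t"] = stats.paired_t(
            fpiv[("z_shift", "atomoxetine")].to_numpy(),
            fpiv[("z_shift", "placebo")].to_numpy(),
        ).to_dict()
        z_mean = fpiv["z_shift"].mean(axis=1).to_numpy()
        vb_mean = fpiv["vbias_shift"].mean(axis=1).to_numpy()
        out["corr_difference_perm"] = stats.perm_corr_difference(
            shift, z_mean, vb_mean, n_perm=config.n_perm,
            seed=_child_seed(config.seed, 43),
        ).to_dict()

    if blocks is not None and not blocks.empty:
        bpiv = blocks.groupby(["participant_id", "drug"])[["pupil_block_mean", "heart_rate"]].mean().reset_index()
        bw = bpiv.pivot(index="participant_id", columns="drug",
                        values=["pupil_block_mean", "heart_rate"])
        for metric in ("pupil_block_mean", "heart_rate"):
            out[f"{metric}_paired_t"] = stats.paired_t(
                bw[(metric, "atomoxetine")].to_numpy(), bw[(metric, "placebo")].to_numpy()
            ).to_dict()
        pupil_shift = (bw[("pupil_block_mean", "atomoxetine")] - bw[("pupil_block_mean", "placebo")]).to_numpy()
        out["pupil_shift_vs_repeat_shift"] = stats.pearson_with_bootstrap(
            pupil_shift, shift, n_boot=config.n_boot, seed=_child_seed(config.seed, 44)
        ).to_dict()

    if binned is not None and not binned.empty:
        try:
            lmm = stats.lmm_bin_analysis(binned, y="repeat")
            out["pupil_bin_lmm_repeat"] = dataclasses.asdict(lmm)
        except (RuntimeError, ValueError) as exc:
            out["pupil_bin_lmm_repeat"] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and return (and optionally write) the report."""
    failures = {}
    report: dict = {"config": {"seed": config.seed, "n_participants": config.n_participants}}

    cohort = generate_cohort(
        n_participants=config.n_participants,
        design=config.design,
        spec_distribution=config.cohort_spec,
        seed=_child_seed(config.seed, 1),
    )
    filtered, exclusion_report = behavior.apply_exclusions(cohort.trials)
    report["exclusions"] = exclusion_report
    summary = behavior.summarize(cohort.trials)
    summary_strength = behavior.summarize(cohort.trials, by_strength=True)
    report["stimulus_repetition_probability"] = float(
        np.mean([
            behavior.stimulus_repetition_probability(sub)
            for _, sub in cohort.trials.groupby("participant_id")
        ])
    )

    tpr_table = blocks = binned = None
    if config.run_physio:
        try:
            tpr_table, blocks = _physio_stage(cohort, config)
            trials_tpr = cohort.trials.join(tpr_table)
            incl, _ = behavior.apply_exclusions(trials_tpr)
            binned = physio.bin_trials_by_tpr(incl, n_bins=config.n_pupil_bins)
        except Exception as exc:  # noqa: BLE001 - partial report on stage failure
            failures["physio"] = repr(exc)
            log.exception("physio stage failed")

    fits = None
    if config.run_ddm:
        try:
            fits = _ddm_stage(filtered, config)
        except Exception as exc:  # noqa: BLE001
            failures["ddm"] = repr(exc)
            log.exception("ddm stage failed")

    try:
        report["stats"] = _stats_stage(summary, summary_strength, fits, blocks, binned, config)
    except Exception as exc:  # noqa: BLE001
        failures["stats"] = repr(exc)
        log.exception("stats stage failed")

    # ground-truth comparison block
    truth = cohort.ground_truth
    gt_vb_shift_pl = [v["ddm_placebo"]["vbias_prev_right"] - v["ddm_placebo"]["vbias_prev_left"]
                      for v in truth.values()]
    report["ground_truth"] = {
        "mean_vbias_shift_placebo": float(np.mean(gt_vb_shift_pl)),
        "drug_bias_shrinkage": config.cohort_spec.drug_bias_shrinkage,
        "pupil_coupling": config.cohort_spec.pupil_coupling,
    }
    report["behavior_group"] = {
        m: behavior.group_summary(summary, m).to_dict(orient="records")
        for m in ("p_repeat", "abs_bias", "accuracy", "mean_rt")
    }
    if failures:
        report["failures"] = failures

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_dir(out / "cohort")
        summary.to_csv(out / "behavior_summary.csv", index=False)
        summary_strength.to_csv(out / "behavior_summary_by_strength.csv", index=False)
        if fits is not None:
            fits.to_csv(out / "ddm_fits.csv", index=False)
        if blocks is not None:
            blocks.to_csv(out / "block_physio.csv", index=False)
        if binned is not None:
            binned.to_csv(out / "pupil_bins.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1)
    return report


def validate_dataset(trials: pd.DataFrame, design: TaskDesign | None = None) -> list:
    """Schema and invariant checks on an ingested trial table.

    Returns a list of violation strings (empty when the table is clean);
    violations are reported, not raised.
    """
    design = design or TaskDesign()
    violations = []
    required = ["participant_id", "session_id", "drug", "block", "trial_in_block",
                "stimulus_side", "strength", "choice", "rt", "prev_choice_available"]
    missing = [c for c in required if c not in trials.columns]
    if missing:
        return [f"missing columns: {missing}"]

    rt = trials["rt"]
    bad_rt = rt.notna() & ((rt <= 0) | (rt > design.max_rt))
    if bad_rt.any():
        violations.append(f"{int(bad_rt.sum())} trials with rt outside (0, {design.max_rt}]")
    mism = rt.notna() != trials["choice"].notna()
    if mism.any():
        violations.append(f"{int(mism.sum())} trials where rt and choice presence disagree")
    if "correct" in trials.columns:
        resp = trials["choice"].notna() & trials["correct"].notna()
        exp = (trials.loc[resp, "choice"] == trials.loc[resp, "stimulus_side"]).astype(float)
        if not np.allclose(exp, trials.loc[resp, "correct"]):
            violations.append("correct flag inconsistent with choice == stimulus_side")
    bad_sides = ~trials["stimulus_side"].isin([-1, 1])
    if bad_sides.any():
        violations.append(f"{int(bad_sides.sum())} trials with stimulus_side not in {{-1,+1}}")
    for (pid, ses, b), sub in trials.groupby(["participant_id", "session_id", "block"]):
        counts = sub["stimulus_side"].value_counts()
        if len(sub) == design.trials_per_block and counts.get(1, 0) != counts.get(-1, 0):
            violations.append(f"block {pid}/{ses}/{b} not 50/50 counterbalanced")
        first = sub.sort_values("trial_in_block").iloc[0]
        if bool(first["prev_choice_available"]):
            violations.append(f"block {pid}/{ses}/{b}: first trial marked as having a previous choice")
    return violations
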