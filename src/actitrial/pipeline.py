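"""End-to-end orchestration: simulate → process → analyze → adherence → report.

``run_all`` executes the full pipeline from a single YAML config into an
output directory, producing ``summaries.csv``, ``results.csv``,
``adherence_summary.csv``, a human-readable ``report.md`` and a
``manifest.json`` with content hashes of every artifact, so a run is
reproducible bit-for-bit from its config and seed.  ``recovery_experiment``
repeats simulate+analyze across derived seeds and reports bias, empirical SE,
CI coverage and rejection rates for the two effect estimators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import summarize_adherence
from .analysis import (
    AnalysisError,
    ancova_adjusted_difference,
    build_analysis_dataset,
    estimate_all,
    fit_delay_control_lmm,
)
from .bouts import DEFAULT_RULES
from .epochs import (
    DEFAULT_MIN_ON_BODY_MINUTES,
    DEFAULT_MIN_VALID_DAYS,
    read_epochs,
)
from .bouts import summarize_assessment
from .synth import TrialConfig, config_from_file, generate_trial

log = logging.getLogger("actitrial")

__all__ = ["setup_logging", "process_epochs", "run_all", "recovery_experiment",
            "write_report"]


def setup_logging(logfile: Path | None = None, level: int = logging.INFO) -> None:
    """Plain-text logging to stderr and, optionally, a logfile."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_epochs(
    epochs_dir: Path,
    rules=DEFAULT_RULES,
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    min_on_body_minutes: int = DEFAULT_MIN_ON_BODY_MINUTES,
) -> pd.DataFrame:
    """Run the bout engine over every ``<participant>_<week>.csv`` epoch file.

    Returns the tidy long summaries table (participant_id, week, outcome,
    value, n_valid_days, valid); invalid assessments keep their rows with NaN
    values and ``valid=False`` so downstream exclusion is explicit.
    """
    rows = []
    files = sorted(Path(epochs_dir).glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no epoch CSVs in {epochs_dir}")
    for path in files:
        stem = path.stem
        pid, _, week_s = stem.rpartition("_")
        week = int(week_s)
        days = read_epochs(path, min_on_body_minutes=min_on_body_minutes)
        summ = summarize_assessment(days, week, rules, min_valid_days=min_valid_days)
        for outcome in ("mvpa_bout_minutes", "purposeful_bout_minutes",
                        "sedentary_bout_minutes", "steps_total"):
            rows.append(
                {
                    "participant_id": pid,
                    "week": week,
                    "outcome": outcome,
                    "value": getattr(summ, outcome),
                    "n_valid_days": summ.n_valid_days,
                    "valid": summ.valid,
                }
            )
    df = pd.DataFrame(rows)
    n_invalid = int((~df["valid"]).sum() // 4)
    log.info("processed %d epoch files -> %d summary rows (%d invalid assessments)",
             len(files), len(df), n_invalid)
    return df


def _fmt(x: float, nd: int = 1) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.{nd}f}"


def write_report(out_dir: Path, roster: pd.DataFrame, dataset: pd.DataFrame,
                 results: pd.DataFrame, adherence_summary: pd.DataFrame) -> Path:
    """Write report.md: group means (SD) per timepoint, adjusted differences,
    mixed-model exposure effects and secular trends, adherence percentages."""
    lines = ["# Synthetic trial report", ""]
    weeks = sorted(dataset["week"].unique())
    lines += ["## Group means (SD) by assessment", ""]
    header = "| Outcome | " + " | ".join(
        f"{arm} wk{w}" for arm in ("IG", "DG") for w in weeks
    ) + " |"
    lines += [header, "|" + "---|" * (1 + 2 * len(weeks))]
    for outcome in sorted(dataset["outcome"].unique()):
        cells = [outcome]
        for arm in ("IG", "DG"):
            for w in weeks:
                v = dataset.query("outcome == @outcome and arm == @arm and week == @w")[
                    "value"
                ].dropna()
                cells.append(f"{_fmt(v.mean())} ({_fmt(v.std(ddof=1))})" if len(v) else "")
        lines.append("| " + " | ".join(cells) + " |")

    lines += ["", "## Adjusted mean differences at the primary endpoint (ANCOVA)", ""]
    anc = results[results["estimator"] == "ancova"]
    lines += ["| Outcome | Difference | 95% CI | p |", "|---|---|---|---|"]
    for r in anc.itertuples(index=False):
        lines.append(
            f"| {r.outcome} | {_fmt(r.estimate)} | "
            f"({_fmt(r.ci_low)} to {_fmt(r.ci_high)}) | {_fmt(r.p, 3)} |"
        )

    lines += ["", "## Mixed-model intervention effects and secular trend", ""]
    lmm = results[results["estimator"] == "lmm_sandwich"]
    lines += ["| Outcome | Term | Estimate | 95% CI |", "|---|---|---|---|"]
    for r in lmm.itertuples(index=False):
        if r.term.startswith(("E_", "T_")):
            lines.append(
                f"| {r.outcome} | {r.term} | {_fmt(r.estimate)} | "
                f"({_fmt(r.ci_low)} to {_fmt(r.ci_high)}) |"
            )

    lines += ["", "## Intervention adherence", ""]
    lines += ["| Group | n | Education n (%) | Calls n (%) | Tracker n (%) | "
              "≥2 criteria n (%) | All 3 n (%) |", "|---|---|---|---|---|---|---|"]
    for r in adherence_summary.itertuples(index=False):
        lines.append(
            f"| {r.group} | {r.n} | {r.edu_met_n} ({_fmt(r.edu_met_pct, 0)}) | "
            f"{r.calls_met_n} ({_fmt(r.calls_met_pct, 0)}) | "
            f"{r.fitbit_met_n} ({_fmt(r.fitbit_met_pct, 0)}) | "
            f"{r.two_of_three_n} ({_fmt(r.two_of_three_pct, 0)}) | "
            f"{r.all_three_n} ({_fmt(r.all_three_pct, 0)}) |"
        )
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def run_all(config_path, out_dir, write_epochs: bool = True) -> dict:
    """Execute simulate → process → analyze → adherence → report.

    Any stage failure aborts with the failing stage named and partial outputs
    removed.  Returns the run manifest (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config_from_file(config_path)
    produced: list[Path] = []
    stage = "simulate"
    try:
        t0 = time.time()
        log.info("stage simulate: n_per_arm=%d seed=%d", config.n_per_arm, config.seed)
        trial = generate_trial(config, out_dir=out_dir, write_epochs=write_epochs)
        produced += [out_dir / n for n in
                     ("roster.csv", "questionnaires.csv", "adherence.csv",
                      "truth.json", "latent_summaries.csv")]
        produced += list(trial.epoch_files)

        stage = "process"
        if write_epochs:
            summaries = process_epochs(out_dir / "epochs")
        else:
            summaries = trial.summaries
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        produced.append(out_dir / "summaries.csv")

        stage = "analyze"
        usable = summaries[summaries["valid"]] if "valid" in summaries else summaries
        dataset = build_analysis_dataset(usable, trial.roster, trial.questionnaires)
        log.info("stage analyze: %d rows, %d outcomes",
                 len(dataset), dataset["outcome"].nunique())
        results = estimate_all(dataset)
        results.to_csv(out_dir / "results.csv", index=False)
        produced.append(out_dir / "results.csv")

        stage = "adherence"
        adh = summarize_adherence(trial.adherence, trial.roster)
        adh.to_csv(out_dir / "adherence_summary.csv", index=False)
        produced.append(out_dir / "adherence_summary.csv")

        stage = "report"
        produced.append(write_report(out_dir, trial.roster, dataset, results, adh))
    except Exception:
        log.error("stage %r failed; removing partial outputs", stage)
        for p in produced:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise

    manifest = {
        "tool": "actitrial",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(produced)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run complete: %d artifacts", len(produced))
    return manifest


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Counter-based per-replicate seed: independent and order-invariant."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def recovery_experiment(
    config: TrialConfig,
    n_replicates: int,
    master_seed: int | None = None,
    true_ancova_effect: float | None = None,
    correction: str = "none",
    estimators: tuple[str, ...] = ("ancova", "lmm"),
) -> dict:
    """Monte-Carlo check of effect recovery at the summary level.

    Repeats simulate+analyze with per-replicate counter-derived seeds and
    summarizes the ANCOVA arm effect and the 12-week exposure term of the
    mixed model: mean estimate, bias, empirical SE, 95% CI coverage, and
    rejection rate at two-sided 5%.
    """
    import dataclasses

    master_seed = config.seed if master_seed is None else master_seed
    if true_ancova_effect is None:
        e12 = config.true_exposure_effects.get(12, 0.0)
        true_ancova_effect = e12
    true_e12 = config.true_exposure_effects.get(12, 0.0)

    anc_est, anc_cover, anc_reject = [], [], []
    lmm_est, lmm_cover, lmm_reject = [], [], []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=replicate_seed(master_seed, rep))
        trial = generate_trial(cfg, out_dir=None, write_epochs=False)
        ds = build_analysis_dataset(trial.summaries, trial.roster)
        if "ancova" in estimators:
            try:
                a = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
                anc_est.append(a.estimate)
                anc_cover.append(a.ci_low <= true_ancova_effect <= a.ci_high)
                anc_reject.append(a.p_value < 0.05)
            except AnalysisError as exc:
                log.warning("replicate %d ANCOVA failed: %s", rep, exc)
        if "lmm" in estimators:
            try:
                terms = {e.term: e for e in fit_delay_control_lmm(
                    ds, "mvpa_bout_minutes", correction=correction,
                    emit_trend_contrasts=False)}
                e = terms["E_12wk"]
                lmm_est.append(e.estimate)
                lmm_cover.append(e.ci_low <= true_e12 <= e.ci_high)
                lmm_reject.append(e.p_value < 0.05)
            except AnalysisError as exc:
                log.warning("replicate %d LMM failed: %s", rep, exc)

    def _summary(est, cover, reject, truth):
        est = np.asarray(est, dtype=float)
        return {
            "n_replicates": int(est.size),
            "truth": float(truth),
            "mean_estimate": float(est.mean()) if est.size else float("nan"),
            "bias": float(est.mean() - truth) if est.size else float("nan"),
            "empirical_se": float(est.std(ddof=1)) if est.size > 1 else float("nan"),
            "mcse": float(est.std(ddof=1) / np.sqrt(est.size)) if est.size > 1 else float("nan"),
            "ci_coverage": float(np.mean(cover)) if cover else float("nan"),
            "rejection_rate": float(np.mean(reject)) if reject else float("nan"),
        }

    return {
        "ancova_arm_effect": _summary(anc_est, anc_cover, anc_reject, true_ancova_effect),
        "lmm_E12": _summary(lmm_est, lmm_cover, lmm_reject, true_e12),
    }
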