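"""Synthetic delay-control trial generator.

Emulates a two-arm randomized trial in which the control (delay) arm receives
the identical 12-week physical-activity intervention 13 weeks after the
immediate arm, so intervention exposure is staggered across arms and calendar
time.  The generator produces every input the analysis pipeline consumes —
participant roster with permuted-block randomization, minute-epoch wearable
streams, questionnaire subscale tables, and adherence logs — from known
ground-truth parameters, so each downstream stage can be tested against truth
without any external data.

The outcome model mirrors the estimand of the longitudinal analysis::

    mu[i, t] = baseline_mean(arm_i) + secular_trend(t)
               + exposure_effect(weeks_since_initiation(arm_i, t)) + b_i

with participant random intercepts ``b_i ~ N(0, participant_sd^2)``.  Observed
assessment means add day-level noise: daily bouted-MVPA values are drawn from a
gamma distribution around ``mu`` (right-skewed, SD can exceed the mean, as is
typical of bouted MVPA in older adults with knee osteoarthritis), and a small
outlier mixture produces participants averaging >300 min/day.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import MINUTES_PER_DAY

__all__ = [
    "TrialConfig",
    "GroundTruth",
    "TrialData",
    "generate_roster",
    "latent_outcome",
    "synthesize_epoch_day",
    "generate_trial",
    "config_from_file",
    "INSTRUMENT_BOUNDS",
]

ARMS = ("IG", "DG")

# questionnaire subscales: (instrument, subscale) -> (lo, hi, baseline mean, sd)
INSTRUMENT_BOUNDS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("KOOS", "symptoms"): (0, 100, 67.0, 12.0),
    ("KOOS", "pain"): (0, 100, 69.0, 14.0),
    ("KOOS", "adl"): (0, 100, 74.0, 15.0),
    ("KOOS", "sport_rec"): (0, 100, 47.0, 24.0),
    ("KOOS", "qol"): (0, 100, 46.0, 16.0),
    ("PIHS", "total"): (0, 96, 77.0, 11.0),
    ("PHQ9", "total"): (0, 27, 5.0, 4.5),
    ("SRHI", "sitting_work"): (1, 7, 4.8, 1.7),
    ("SRHI", "sitting_leisure"): (1, 7, 4.9, 1.3),
    ("SRHI", "walking"): (1, 7, 4.5, 1.9),
    ("TPB", "attitude"): (1, 7, 6.0, 0.6),
    ("TPB", "subjective_norm"): (1, 7, 6.2, 0.7),
    ("TPB", "perceived_control"): (1, 7, 5.9, 0.9),
    ("TPB", "intention"): (1, 7, 6.2, 0.8),
}


def _default_exposure_map() -> dict[tuple[str, int], int]:
    # immediate arm starts at randomization; delay arm starts in week 14
    return {
        ("IG", 0): 0, ("IG", 13): 12, ("IG", 26): 25, ("IG", 39): 38,
        ("DG", 0): 0, ("DG", 13): 0, ("DG", 26): 12, ("DG", 39): 25,
    }


@dataclass
class TrialConfig:
    """All knobs of the synthetic trial; defaults match the study conditions.

    Units are minutes/day for all MVPA-scale quantities.
    """

    n_per_arm: int = 25
    assessment_weeks: tuple[int, ...] = (0, 13, 26, 39)
    exposure_weeks_by_arm_time: dict = field(default_factory=_default_exposure_map)
    true_exposure_effects: dict = field(
        default_factory=lambda: {0: 0.0, 12: 0.0, 25: 0.0, 38: 0.0}
    )
    true_secular_trend: dict = field(
        default_factory=lambda: {0: 0.0, 13: 0.0, 26: 0.0, 39: 0.0}
    )
    participant_sd: float = 35.0
    residual_sd: float = 25.0
    baseline_mean_by_arm: dict = field(default_factory=lambda: {"IG": 50.0, "DG": 50.0})
    skew_outlier_rate: float = 0.04
    outlier_shift: float = 320.0
    wear_days_per_assessment: int = 7
    dropout_rate: float = 0.06
    block_sizes: tuple[int, ...] = (2, 4)
    sedentary_mean: float = 540.0
    sedentary_sd: float = 90.0
    steps_base_mean: float = 4000.0
    steps_base_sd: float = 1800.0
    steps_per_mvpa_minute: float = 50.0
    steps_day_sd: float = 1200.0
    sleep_start_minute: int = 23 * 60
    sleep_end_minute: int = 7 * 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.assessment_weeks = tuple(int(w) for w in self.assessment_weeks)
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if isinstance(self.exposure_weeks_by_arm_time, dict):
            self.exposure_weeks_by_arm_time = {
                (str(k[0]), int(k[1])) if isinstance(k, (tuple, list)) else k: int(v)
                for k, v in self.exposure_weeks_by_arm_time.items()
            }
        self.true_exposure_effects = {int(k): float(v) for k, v in self.true_exposure_effects.items()}
        self.true_secular_trend = {int(k): float(v) for k, v in self.true_secular_trend.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if any(s < 0 for s in (self.participant_sd, self.residual_sd,
                               self.sedentary_sd, self.steps_base_sd, self.steps_day_sd)):
            raise ValueError("standard deviations must be >= 0")
        for p in (self.skew_outlier_rate, self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if list(self.assessment_weeks) != sorted(set(self.assessment_weeks)):
            raise ValueError("assessment_weeks must be strictly increasing")
        if any(b <= 0 or b % 2 for b in self.block_sizes):
            raise ValueError("block sizes must be positive and even for 1:1 allocation")
        emap = self.exposure_weeks_by_arm_time
        for arm in ARMS:
            if emap.get((arm, 0), None) != 0:
                raise ValueError("both arms must have exposure 0 at week 0")
        # delay design: DG exposure at week w equals IG exposure at w - 13
        for (arm, week), exp in emap.items():
            if arm == "DG" and week >= 13:
                ig = emap.get(("IG", week - 13))
                if ig is not None and ig != exp:
                    raise ValueError(
                        f"delay-design violation: DG exposure at week {week} is {exp}, "
                        f"IG exposure at week {week - 13} is {ig}"
                    )

    def exposure(self, arm: str, week: int) -> int:
        try:
            return self.exposure_weeks_by_arm_time[(arm, week)]
        except KeyError:
            raise KeyError(f"no exposure defined for arm={arm!r}, week={week}") from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure_weeks_by_arm_time"] = {
            f"{arm}:{week}": v for (arm, week), v in self.exposure_weeks_by_arm_time.items()
        }
        return d


def config_from_file(path) -> TrialConfig:
    """Load a :class:`TrialConfig` from a YAML or JSON file (1:1 field mapping)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "exposure_weeks_by_arm_time" in raw:
        raw["exposure_weeks_by_arm_time"] = {
            (k.split(":")[0], int(k.split(":")[1])): v
            for k, v in raw["exposure_weeks_by_arm_time"].items()
        }
    known = {f.name for f in dataclasses.fields(TrialConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TrialConfig(**raw)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the generating process."""

    config: TrialConfig
    intercepts: dict  # participant_id -> random intercept (includes outlier shift)
    is_outlier: dict
    latent_means: dict  # (participant_id, week) -> latent mean daily bouted MVPA
    questionnaire_effects: dict
    adherence_propensities: dict

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "intercepts": self.intercepts,
            "is_outlier": {k: bool(v) for k, v in self.is_outlier.items()},
            "latent_means": {f"{p}:{w}": v for (p, w), v in self.latent_means.items()},
            "questionnaire_effects": self.questionnaire_effects,
            "adherence_propensities": self.adherence_propensities,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class TrialData:
    roster: pd.DataFrame
    summaries: pd.DataFrame  # tidy long: participant_id, week, outcome, value, ...
    questionnaires: pd.DataFrame
    adherence: pd.DataFrame
    truth: GroundTruth
    epoch_files: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# roster / randomization


def generate_roster(config: TrialConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Randomize ``2 * n_per_arm`` participants in permuted variable blocks.

    Block sizes are drawn from ``config.block_sizes`` (even, so each completed
    block is balanced 1:1); the draw is constrained so the blocks tile the
    sample exactly, which forces equal arm totals.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total = 2 * config.n_per_arm
    sizes: list[int] = []
    remaining = total
    smallest = min(config.block_sizes)
    while remaining > 0:
        candidates = [s for s in config.block_sizes if s <= remaining and
                      (remaining - s) % smallest == 0]
        if not candidates:
            candidates = [s for s in config.block_sizes if s <= remaining]
        if not candidates:
            raise ValueError(
                f"block sizes {config.block_sizes} cannot tile {total} participants"
            )
        s = int(rng.choice(candidates))
        sizes.append(s)
        remaining -= s

    rows = []
    pid = 0
    for block_id, size in enumerate(sizes, start=1):
        arms = ["IG"] * (size // 2) + ["DG"] * (size // 2)
        rng.shuffle(arms)
        for arm in arms:
            pid += 1
            rows.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "arm": arm,
                    "block_id": block_id,
                    "age": float(np.clip(rng.normal(62, 9), 40, 85).round(1)),
                    "sex": "F" if rng.random() < 0.82 else "M",
                    "bmi": float(np.clip(rng.normal(29.4, 7.7), 17, 55).round(1)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent outcome model


def latent_outcome(arm: str, participant_id: str, week: int,
                   config: TrialConfig, truth: GroundTruth) -> float:
    """Latent mean daily bouted MVPA for one participant at one assessment."""
    if week not in config.assessment_weeks:
        raise KeyError(f"week {week} is not an assessment week")
    exp = config.exposure(arm, week)
    return (
        config.baseline_mean_by_arm[arm]
        + config.true_secular_trend[week]
        + config.true_exposure_effects[exp]
        + truth.intercepts[participant_id]
    )


# ---------------------------------------------------------------------------
# constructive epoch-day synthesis (inverse of the bout engine)


def _partition(total: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` into random parts, each in [lo, hi]; total is 0 or >= lo."""
    parts: list[int] = []
    remaining = int(total)
    while remaining > 0:
        c = int(rng.integers(lo, hi + 1))
        c = min(c, remaining)
        if 0 < remaining - c < lo:
            # avoid leaving an unrepresentable remainder
            c = remaining if remaining <= hi else remaining - lo
        parts.append(c)
        remaining -= c
    return parts


def synthesize_epoch_day(
    target_bouted_mvpa: int,
    target_steps: int,
    target_sedentary_bout_min: int,
    rng: np.random.Generator,
    sleep_start_minute: int = 23 * 60,
    sleep_end_minute: int = 7 * 60,
    with_interruptions: bool = True,
    with_junk: bool = True,
) -> pd.DataFrame:
    """Construct a 1440-minute day whose bout-engine output equals the targets.

    Above-threshold minutes are placed as explicit MVPA bouts (each ≥10 min,
    optionally carrying legal ≤2-min interruptions that still count toward the
    bout's duration); sedentary time is placed as ≥20-min runs at ≤1.5 MET
    during waking hours.  Segments are separated by ≥3 minutes of 2.0-MET
    filler so they can never merge, and sub-minimum "junk" runs (short MVPA
    spells, short sitting spells) are sprinkled in to exercise the engine's
    rejection of sub-bout activity.

    Returns a canonical epoch frame (without participant/date columns filled —
    callers set them).  Raises ``ValueError`` for infeasible targets.
    """
    t_mvpa = int(target_bouted_mvpa)
    t_sed = int(target_sedentary_bout_min)
    t_steps = int(target_steps)
    if min(t_mvpa, t_sed, t_steps) < 0:
        raise ValueError("targets must be non-negative")
    if 0 < t_mvpa < 10:
        raise ValueError("bouted MVPA target must be 0 or >= 10 (minimum bout length)")
    if 0 < t_sed < 20:
        raise ValueError("sedentary target must be 0 or >= 20 (minimum bout length)")

    minute = np.arange(MINUTES_PER_DAY)
    if sleep_start_minute > sleep_end_minute:
        asleep = (minute >= sleep_start_minute) | (minute < sleep_end_minute)
    else:
        asleep = (minute >= sleep_start_minute) & (minute < sleep_end_minute)
    waking_idx = np.flatnonzero(~asleep)
    n_waking = waking_idx.size

    mvpa_parts = _partition(t_mvpa, 10, 60, rng)
    sed_parts = _partition(t_sed, 20, 120, rng)
    segments: list[tuple[str, int]] = [("mvpa", p) for p in mvpa_parts] + [
        ("sed", p) for p in sed_parts
    ]
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]

    gap = 3  # below the 2-min interruption allowance threshold for merging
    used = sum(p for _, p in segments) + gap * (len(segments) + 1)
    if used > n_waking:
        # fall back to one block per class (minimal separator overhead)
        segments = [(k, t) for k, t in (("mvpa", t_mvpa), ("sed", t_sed)) if t > 0]
        used = sum(p for _, p in segments) + gap * (len(segments) + 1)
        if used > n_waking:
            raise ValueError(
                f"targets need {used} waking minutes but only {n_waking} are available"
            )

    met = np.full(MINUTES_PER_DAY, 2.0)  # filler: above sedentary, below MVPA
    met[asleep] = 0.9
    on_body = np.ones(MINUTES_PER_DAY, dtype=bool)

    cursor = 0  # position within waking_idx
    cursor += gap
    mvpa_minute_pool: list[int] = []
    for kind, length in segments:
        sl = waking_idx[cursor: cursor + length]
        if kind == "mvpa":
            level = float(rng.uniform(3.2, 6.0))
            met[sl] = level
            if with_interruptions and length >= 14 and rng.random() < 0.5:
                # one legal interruption run of 1-2 min, not touching the ends
                run = int(rng.integers(1, 3))
                pos = int(rng.integers(1, length - run))
                met[sl[pos: pos + run]] = 2.0
            mvpa_minute_pool.extend(int(m) for m in sl)
        else:
            met[sl] = float(rng.uniform(0.9, 1.4))
        cursor += length + gap

    if with_junk:
        free = n_waking - cursor
        n_junk = int(rng.integers(1, 4)) if free > 40 else 0
        for _ in range(n_junk):
            if free < 25:
                break
            if rng.random() < 0.5:
                jl = int(rng.integers(3, 10))  # sub-10-min MVPA spell: not a bout
                met[waking_idx[cursor: cursor + jl]] = 3.5
            else:
                jl = int(rng.integers(10, 20))  # sub-20-min sitting spell
                met[waking_idx[cursor: cursor + jl]] = 1.0
            cursor += jl + gap
            free = n_waking - cursor

    # distribute steps over on-body waking minutes, heavier on MVPA minutes
    steps = np.zeros(MINUTES_PER_DAY, dtype=int)
    if t_steps > 0:
        weights = np.zeros(MINUTES_PER_DAY)
        weights[waking_idx] = 1.0
        if mvpa_minute_pool:
            weights[mvpa_minute_pool] = 20.0
        weights /= weights.sum()
        cum = np.floor(np.cumsum(weights) * t_steps + 0.5).astype(int)
        steps = np.diff(np.concatenate([[0], cum]))
        steps = np.maximum(steps, 0)
        # rounding residual goes to a waking minute so asleep steps stay 0
        residual = t_steps - int(steps.sum())
        steps[waking_idx[0]] = max(0, steps[waking_idx[0]] + residual)

    return pd.DataFrame(
        {
            "participant_id": "",
            "date": "",
            "minute_of_day": minute,
            "met": met,
            "steps": steps,
            "on_body": np.ones(MINUTES_PER_DAY, dtype=int),
            "asleep": asleep.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# daily outcome realization


def _snap_day_target(value: float, lo: int) -> int:
    """Round a latent daily value to a feasible bout target (0 or >= lo)."""
    v = int(round(max(value, 0.0)))
    if 0 < v < lo:
        return 0 if v < lo / 2 else lo
    return v


def _draw_daily_mvpa(mu: float, config: TrialConfig, rng: np.random.Generator,
                     n_days: int) -> np.ndarray:
    """Day-level values with gamma multiplicative skew around the latent mean.

    The day SD is ``residual_sd * sqrt(n_days)`` so the assessment mean over
    ``n_days`` days has SD ``residual_sd``.  With ``residual_sd == 0`` the days
    equal the latent mean exactly (noiseless construction).
    """
    if mu <= 0:
        return np.zeros(n_days)
    if config.residual_sd == 0:
        return np.full(n_days, mu)
    day_sd = config.residual_sd * np.sqrt(config.wear_days_per_assessment)
    shape = (mu / day_sd) ** 2
    return rng.gamma(shape, mu / shape, size=n_days)


# ---------------------------------------------------------------------------
# full trial generation


def generate_trial(
    config: TrialConfig,
    out_dir: str | Path | None = None,
    write_epochs: bool = True,
) -> TrialData:
    """Generate a complete synthetic trial, optionally materializing files.

    When ``out_dir`` is given, writes ``roster.csv``, ``questionnaires.csv``,
    ``adherence.csv``, ``truth.json`` and (if ``write_epochs``)
    ``epochs/<participant>_<week>.csv``.  The returned ``summaries`` frame
    holds the per-assessment mean daily outcomes implied by the generated
    days — when epochs are materialized, running them through the bout engine
    reproduces these values exactly for MVPA and sedentary time.
    """
    rng = np.random.default_rng(config.seed)
    roster = generate_roster(config, rng)

    intercepts: dict[str, float] = {}
    is_outlier: dict[str, bool] = {}
    for row in roster.itertuples(index=False):
        out = bool(rng.random() < config.skew_outlier_rate)
        b = float(rng.normal(0.0, config.participant_sd)) if config.participant_sd else 0.0
        if out:
            b += config.outlier_shift
        intercepts[row.participant_id] = b
        is_outlier[row.participant_id] = out

    truth = GroundTruth(config, intercepts, is_outlier, {}, {}, {})

    # monotone dropout after baseline
    observed: dict[str, set[int]] = {}
    for row in roster.itertuples(index=False):
        weeks = set()
        dropped = False
        for w in config.assessment_weeks:
            if w != config.assessment_weeks[0] and not dropped:
                dropped = rng.random() < config.dropout_rate
            if w == config.assessment_weeks[0] or not dropped:
                weeks.add(w)
        observed[row.participant_id] = weeks

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_epochs:
            (out_dir / "epochs").mkdir(exist_ok=True)

    epoch_files: list[Path] = []
    summary_rows = []
    n_days = config.wear_days_per_assessment
    for row in roster.itertuples(index=False):
        pid, arm = row.participant_id, row.arm
        step_base = max(0.0, rng.normal(config.steps_base_mean, config.steps_base_sd))
        for week in config.assessment_weeks:
            mu = latent_outcome(arm, pid, week, config, truth)
            truth.latent_means[(pid, week)] = mu
            if week not in observed[pid]:
                continue
            raw_days = _draw_daily_mvpa(mu, config, rng, n_days)
            mvpa_days = np.array([min(_snap_day_target(v, 10), 600) for v in raw_days])
            sed_days = np.array(
                [
                    _snap_day_target(
                        min(rng.normal(config.sedentary_mean, config.sedentary_sd)
                            if config.sedentary_sd else config.sedentary_mean,
                            900 - m),
                        20,
                    )
                    for m in mvpa_days
                ]
            )
            step_days = np.array(
                [
                    max(0, int(round(
                        step_base + config.steps_per_mvpa_minute * m
                        + (rng.normal(0, config.steps_day_sd) if config.steps_day_sd else 0.0)
                    )))
                    for m in mvpa_days
                ]
            )
            if out_dir is not None and write_epochs:
                frames = []
                for d in range(n_days):
                    day = synthesize_epoch_day(
                        int(mvpa_days[d]), int(step_days[d]), int(sed_days[d]), rng,
                        sleep_start_minute=config.sleep_start_minute,
                        sleep_end_minute=config.sleep_end_minute,
                    )
                    day["participant_id"] = pid
                    day["date"] = f"W{week:02d}D{d + 1}"
                    frames.append(day)
                from .epochs import write_epoch_frame

                path = out_dir / "epochs" / f"{pid}_{week}.csv"
                write_epoch_frame(pd.concat(frames, ignore_index=True), path)
                epoch_files.append(path)
            for name, value in (
                ("mvpa_bout_minutes", float(mvpa_days.mean())),
                ("sedentary_bout_minutes", float(sed_days.mean())),
                ("steps_total", float(step_days.mean())),
            ):
                summary_rows.append(
                    {
                        "participant_id": pid,
                        "week": week,
                        "outcome": name,
                        "value": value,
                        "n_valid_days": n_days,
                        "valid": True,
                    }
                )

    summaries = pd.DataFrame(summary_rows)

    # questionnaires: participant random effect + bounded noise, clipped in range
    q_rows = []
    q_re: dict[str, dict[str, float]] = {}
    for row in roster.itertuples(index=False):
        pid = row.participant_id
        q_re[pid] = {}
        for (instr, sub), (lo, hi, mean, sd) in INSTRUMENT_BOUNDS.items():
            q_re[pid][f"{instr}:{sub}"] = float(rng.normal(0.0, 0.5 * sd))
        for week in config.assessment_weeks:
            if week not in observed[pid]:
                continue
            for (instr, sub), (lo, hi, mean, sd) in INSTRUMENT_BOUNDS.items():
                val = mean + q_re[pid][f"{instr}:{sub}"] + rng.normal(0.0, 0.6 * sd)
                q_rows.append(
                    {
                        "participant_id": pid,
                        "week": week,
                        "instrument": instr,
                        "subscale": sub,
                        "score": float(np.clip(round(val, 1), lo, hi)),
                    }
                )
    questionnaires = pd.DataFrame(q_rows)
    truth.questionnaire_effects = {"participant_effects": q_re}

    # adherence log: education attendance, counseling calls, weekly Fitbit wear
    a_rows = []
    a_prop: dict[str, dict[str, float]] = {}
    for row in roster.itertuples(index=False):
        pid = row.participant_id
        wear_p = float(np.clip(rng.beta(8, 1.6), 0.0, 1.0))
        calls_p = 0.93
        a_prop[pid] = {"wear_p": wear_p, "calls_p": calls_p}
        rec = {
            "participant_id": pid,
            "attended_education": int(rng.random() < 0.995),
            "calls_completed": int(rng.binomial(4, calls_p)),
        }
        for wk in range(1, 13):
            rec[f"wk{wk}"] = int(rng.binomial(7, wear_p))
        a_rows.append(rec)
    adherence = pd.DataFrame(a_rows)
    truth.adherence_propensities = a_prop

    if out_dir is not None:
        roster.to_csv(out_dir / "roster.csv", index=False)
        questionnaires.to_csv(out_dir / "questionnaires.csv", index=False)
        adherence.to_csv(out_dir / "adherence.csv", index=False)
        truth.to_json(out_dir / "truth.json")
        summaries.to_csv(out_dir / "latent_summaries.csv", index=False)

    return TrialData(roster, summaries, questionnaires, adherence, truth, epoch_files)
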