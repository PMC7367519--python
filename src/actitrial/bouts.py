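"""Bout detection on minute-epoch MET sequences and daily/assessment summaries.

Activity bouts are the unit in which physical-activity guidelines count
moderate-to-vigorous physical activity (MVPA): a bout is a sustained episode of
at least ``min_bout_minutes`` in which every minute meets a MET threshold,
optionally tolerating brief sub-threshold interruptions.  Three standard rules
are provided:

* ``mvpa``        — ≥3.0 MET, bouts ≥10 min, interruption runs ≤2 min allowed;
* ``purposeful``  — ≥4.0 MET, bouts ≥10 min, interruption runs ≤2 min allowed;
* ``sedentary``   — ≤1.5 MET, bouts ≥20 min, no interruption allowance,
  counted during waking hours only.

Minutes are half-open integer indices ``[start, end)`` within one calendar day
(0–1439).  Off-body minutes terminate any candidate bout; asleep minutes
additionally terminate candidates for waking-only rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoutRule",
    "Bout",
    "DailySummary",
    "AssessmentSummary",
    "MVPA_RULE",
    "PURPOSEFUL_RULE",
    "SEDENTARY_RULE",
    "DEFAULT_RULES",
    "detect_bouts",
    "bouted_minutes",
    "summarize_day",
    "summarize_assessment",
]

MINUTES_PER_DAY = 1440

#: weekly guideline threshold: ≥150 min of bouted MVPA per week
GUIDELINE_WEEKLY_MINUTES = 150.0


@dataclass(frozen=True)
class BoutRule:
    """Parameters defining one bout class.

    Parameters
    ----------
    name
        Label for the rule (``mvpa`` / ``purposeful`` / ``sedentary``).
    met_comparator
        ``"at_least"`` (activity rules) or ``"at_most"`` (sedentary).
    met_threshold
        MET cut-point a minute must meet to qualify.
    min_bout_minutes
        Minimum bout duration in minutes.
    max_interruption_run
        Interruption allowance.  Under the default ``interruption_mode="run"``
        this bounds the length of any single run of consecutive sub-threshold
        minutes inside a bout; under ``"total"`` it bounds the total number of
        interruption minutes per bout.
    waking_only
        If true, asleep minutes terminate candidate bouts (sedentary behaviour
        is only defined during waking hours).
    credit
        ``"full"`` credits a bout's whole duration (qualifying + tolerated
        interruptions) toward daily totals; ``"qualifying_only"`` credits only
        threshold-meeting minutes.
    interruption_mode
        ``"run"`` (per-run cap, the dominant accelerometry convention) or
        ``"total"`` (per-bout budget).
    """

    name: str
    met_comparator: str
    met_threshold: float
    min_bout_minutes: int
    max_interruption_run: int
    waking_only: bool = False
    credit: str = "full"
    interruption_mode: str = "run"

    def __post_init__(self) -> None:
        if self.met_comparator not in ("at_least", "at_most"):
            raise ValueError(f"unknown met_comparator {self.met_comparator!r}")
        if self.met_threshold <= 0:
            raise ValueError("met_threshold must be > 0")
        if self.min_bout_minutes < 1:
            raise ValueError("min_bout_minutes must be >= 1")
        if self.max_interruption_run < 0:
            raise ValueError("max_interruption_run must be >= 0")
        if self.credit not in ("full", "qualifying_only"):
            raise ValueError(f"unknown credit mode {self.credit!r}")
        if self.interruption_mode not in ("run", "total"):
            raise ValueError(f"unknown interruption_mode {self.interruption_mode!r}")

    def qualifies(self, met: np.ndarray) -> np.ndarray:
        """Boolean mask of minutes meeting the MET cut-point."""
        met = np.asarray(met, dtype=float)
        if self.met_comparator == "at_least":
            return met >= self.met_threshold
        return met <= self.met_threshold


MVPA_RULE = BoutRule("mvpa", "at_least", 3.0, 10, 2)
PURPOSEFUL_RULE = BoutRule("purposeful", "at_least", 4.0, 10, 2)
SEDENTARY_RULE = BoutRule("sedentary", "at_most", 1.5, 20, 0, waking_only=True)
DEFAULT_RULES: tuple[BoutRule, ...] = (MVPA_RULE, PURPOSEFUL_RULE, SEDENTARY_RULE)


@dataclass(frozen=True)
class Bout:
    """One detected bout; ``[start_minute, end_minute)`` half-open."""

    rule: str
    start_minute: int
    end_minute: int
    qualifying_minutes: int

    @property
    def duration_minutes(self) -> int:
        return self.end_minute - self.start_minute

    @property
    def interruption_minutes(self) -> int:
        return self.duration_minutes - self.qualifying_minutes


@dataclass(frozen=True)
class DailySummary:
    participant_id: str
    date: str
    mvpa_bout_minutes: float
    purposeful_bout_minutes: float
    sedentary_bout_minutes: float
    steps_total: int
    valid: bool


@dataclass(frozen=True)
class AssessmentSummary:
    """Per-participant, per-assessment means over valid wear days."""

    participant_id: str
    week: int
    mvpa_bout_minutes: float
    purposeful_bout_minutes: float
    sedentary_bout_minutes: float
    steps_total: float
    n_valid_days: int
    valid: bool
    meets_guideline: bool


def _as_mask(x, n: int, name: str) -> np.ndarray:
    if x is None:
        return np.zeros(n, dtype=bool)
    arr = np.asarray(x, dtype=bool)
    if arr.shape != (n,):
        raise ValueError(
            f"{name} mask length {arr.shape} does not match sequence length {n}"
        )
    return arr


def detect_bouts(
    met: Sequence[float],
    rule: BoutRule,
    on_body: Sequence[bool] | None = None,
    asleep: Sequence[bool] | None = None,
) -> list[Bout]:
    """Detect bouts in one day's MET sequence by greedy maximal extension.

    The scan starts at the first unconsumed qualifying minute, extends right
    while the interruption tolerance holds, trims trailing sub-threshold
    minutes, emits the window when its duration reaches the rule minimum, and
    resumes after the trimmed end.  The segmentation is the unique set of
    maximal windows whose first and last minutes qualify, containing no
    blocked minute, with every internal interruption within tolerance.

    Parameters
    ----------
    met
        Per-minute MET values for a single calendar day.
    rule
        The :class:`BoutRule` to apply.
    on_body, asleep
        Optional boolean masks aligned with ``met``.  Off-body minutes never
        qualify and terminate candidates immediately; asleep minutes do the
        same for waking-only rules.
    """
    met = np.asarray(met, dtype=float)
    n = met.shape[0]
    if met.ndim != 1:
        raise ValueError("met must be one-dimensional")
    on = _as_mask(on_body, n, "on_body") if on_body is not None else np.ones(n, bool)
    slp = _as_mask(asleep, n, "asleep")

    blocked = ~on
    if rule.waking_only:
        blocked = blocked | slp
    qual = rule.qualifies(met) & ~blocked

    bouts: list[Bout] = []
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        last_q = i
        run = 0
        total_gap = 0
        while j < n:
            if qual[j]:
                last_q = j
                run = 0
                j += 1
            elif blocked[j]:
                break
            else:
                run += 1
                total_gap += 1
                if rule.interruption_mode == "run":
                    if run > rule.max_interruption_run:
                        break
                else:  # total budget per bout
                    if total_gap > rule.max_interruption_run:
                        break
                j += 1
        end = last_q + 1
        duration = end - i
        if duration >= rule.min_bout_minutes:
            q = int(qual[i:end].sum())
            bouts.append(Bout(rule.name, i, end, q))
        i = end
    return bouts


def bouted_minutes(
    met: Sequence[float],
    rule: BoutRule,
    on_body: Sequence[bool] | None = None,
    asleep: Sequence[bool] | None = None,
) -> int:
    """Total credited minutes in bouts for one day under ``rule``."""
    bouts = detect_bouts(met, rule, on_body=on_body, asleep=asleep)
    if rule.credit == "qualifying_only":
        return sum(b.qualifying_minutes for b in bouts)
    return sum(b.duration_minutes for b in bouts)


def summarize_day(day, rules: Iterable[BoutRule] = DEFAULT_RULES) -> DailySummary:
    """Compute the daily activity outcomes for one :class:`~actitrial.epochs.WearDay`.

    Steps are summed over on-body waking minutes only; step counts logged while
    the device is off the body or the wearer is asleep are excluded.
    """
    totals = {r.name: 0.0 for r in rules}
    for rule in rules:
        totals[rule.name] = float(
            bouted_minutes(day.met, rule, on_body=day.on_body, asleep=day.asleep)
        )
    steps = int(day.steps[day.on_body & ~day.asleep].sum())
    return DailySummary(
        participant_id=day.participant_id,
        date=day.date,
        mvpa_bout_minutes=totals.get("mvpa", 0.0),
        purposeful_bout_minutes=totals.get("purposeful", 0.0),
        sedentary_bout_minutes=totals.get("sedentary", 0.0),
        steps_total=steps,
        valid=day.valid,
    )


def summarize_assessment(
    days,
    week: int,
    rules: Iterable[BoutRule] = DEFAULT_RULES,
    min_valid_days: int = 4,
) -> AssessmentSummary:
    """Mean daily outcomes over valid wear days of one assessment.

    The assessment is valid when at least ``min_valid_days`` days are valid
    (inclusive bound); otherwise the summary is flagged invalid and its means
    are NaN.  ``meets_guideline`` is true when mean daily bouted MVPA times 7
    reaches the 150 min/week guideline.
    """
    days = list(days)
    summaries = [summarize_day(d, rules) for d in days]
    valid = [s for s in summaries if s.valid]
    n_valid = len(valid)
    pid = days[0].participant_id if days else ""
    if n_valid < min_valid_days:
        nan = float("nan")
        return AssessmentSummary(pid, week, nan, nan, nan, nan, n_valid, False, False)
    mvpa = float(np.mean([s.mvpa_bout_minutes for s in valid]))
    purp = float(np.mean([s.purposeful_bout_minutes for s in valid]))
    sed = float(np.mean([s.sedentary_bout_minutes for s in valid]))
    steps = float(np.mean([s.steps_total for s in valid]))
    meets = mvpa * 7.0 >= GUIDELINE_WEEKLY_MINUTES
    return AssessmentSummary(pid, week, mvpa, purp, sed, steps, n_valid, True, meets)


def rules_from_yaml(path) -> list[BoutRule]:
    """Load bout rules from a YAML file (a list of BoutRule field mappings)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [BoutRule(**entry) for entry in raw]


def rules_to_yaml(rules: Iterable[BoutRule], path) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([dataclasses.asdict(r) for r in rules], fh, sort_keys=False)
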