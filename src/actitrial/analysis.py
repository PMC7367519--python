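"""Intervention-effect estimation for the delay-control trial.

Two estimators are provided.

* **ANCOVA** at the primary endpoint (week 13): a regression of the endpoint
  value on the randomization-arm indicator plus the baseline value (and
  optionally randomization-block factors).  The arm coefficient is the
  baseline-adjusted mean difference.

* **Delay-control linear mixed model** over all four assessments: fixed
  effects are an intercept, the arm indicator (baseline difference between
  randomized groups), indicator variables for the follow-up assessment
  occasions (weeks 13/26/39 — the secular trend), and indicator variables for
  weeks since intervention initiation (12/25/38 — the intervention effects);
  participants enter as random intercepts.  Because the delay arm starts the
  program 13 weeks late, occasion and exposure are not collinear and the model
  separates secular change from intervention exposure.  The model is fitted by
  REML; standard errors are reported both model-based and via the
  cluster-by-participant empirical (sandwich) estimator

      cov_r = A^{-1} ( sum_i X_i' V_i^{-1} r_i r_i' V_i^{-1} X_i ) A^{-1},
      A     = sum_i X_i' V_i^{-1} X_i,   V_i = sigma^2 I + tau^2 J,

  which is consistent under misspecification of the residual covariance.

Missing follow-ups are handled likelihood-based (all available rows) in the
mixed model and complete-case at the endpoint for ANCOVA; nobody is excluded
by adherence (intention-to-treat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisError",
    "EffectEstimate",
    "EXPOSURE_BY_ARM_WEEK",
    "build_analysis_dataset",
    "ancova_adjusted_difference",
    "fit_delay_control_lmm",
    "estimate_all",
    "power_two_sample",
]

#: fixed mapping (arm, assessment week) -> weeks since intervention initiation
EXPOSURE_BY_ARM_WEEK: dict[tuple[str, int], int] = {
    ("IG", 0): 0, ("IG", 13): 12, ("IG", 26): 25, ("IG", 39): 38,
    ("DG", 0): 0, ("DG", 13): 0, ("DG", 26): 12, ("DG", 39): 25,
}

FOLLOWUP_WEEKS = (13, 26, 39)
EXPOSURE_LEVELS = (12, 25, 38)

LMM_TERMS = (
    "intercept", "group_IG",
    "T_week13", "T_week26", "T_week39",
    "E_12wk", "E_25wk", "E_38wk",
)


class AnalysisError(ValueError):
    """Raised for unusable analysis inputs (rank deficiency, degeneracy...)."""


@dataclass(frozen=True)
class EffectEstimate:
    """One estimated coefficient with its uncertainty."""

    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    estimator: str  # ancova | lmm_sandwich | lmm_model_based
    se_model: float = float("nan")
    n_obs: int = 0
    n_participants: int = 0


def build_analysis_dataset(
    summaries: pd.DataFrame,
    roster: pd.DataFrame,
    questionnaires: pd.DataFrame | None = None,
    exposure_map: dict | None = None,
) -> pd.DataFrame:
    """Join outcome summaries (and questionnaire scores) to the roster.

    Returns the long analysis table with one row per available
    (participant, week, outcome): columns ``participant_id, arm, block_id,
    week, exposure, outcome, value``.  Every randomized participant is kept
    regardless of adherence; missing follow-ups simply have no rows.
    """
    exposure_map = EXPOSURE_BY_ARM_WEEK if exposure_map is None else exposure_map
    frames = [summaries.loc[:, ["participant_id", "week", "outcome", "value"]]]
    if questionnaires is not None and len(questionnaires):
        q = questionnaires.copy()
        q["outcome"] = q["instrument"].astype(str) + "_" + q["subscale"].astype(str)
        q = q.rename(columns={"score": "value"})
        frames.append(q.loc[:, ["participant_id", "week", "outcome", "value"]])
    long = pd.concat(frames, ignore_index=True)

    known = set(roster["participant_id"])
    missing = sorted(set(long["participant_id"]) - known)
    if missing:
        raise AnalysisError(f"participants with outcomes but no roster entry: {missing}")
    dup = long.duplicated(subset=["participant_id", "week", "outcome"])
    if dup.any():
        bad = long.loc[dup, ["participant_id", "week", "outcome"]].iloc[0].tolist()
        raise AnalysisError(f"duplicated (participant, week, outcome) row: {bad}")

    ds = long.merge(
        roster.loc[:, ["participant_id", "arm", "block_id"]],
        on="participant_id", how="left", validate="many_to_one",
    )
    try:
        ds["exposure"] = [
            exposure_map[(arm, int(week))] for arm, week in zip(ds["arm"], ds["week"])
        ]
    except KeyError as exc:
        raise AnalysisError(f"no exposure level defined for (arm, week)={exc}") from exc
    return ds


def _t_interval(est: float, se: float, df: float) -> tuple[float, float, float]:
    tcrit = st.t.ppf(0.975, df)
    p = 2.0 * st.t.sf(abs(est / se), df) if se > 0 else (0.0 if est else 1.0)
    return est - tcrit * se, est + tcrit * se, p


def _z_interval(est: float, se: float) -> tuple[float, float, float]:
    if se > 0:
        p = 2.0 * st.norm.sf(abs(est / se))
    else:
        p = 0.0 if est else 1.0
    return est - 1.96 * se, est + 1.96 * se, p


def ancova_adjusted_difference(
    dataset: pd.DataFrame,
    outcome: str,
    endpoint_week: int = 13,
    baseline_week: int = 0,
    adjust_block: bool = False,
) -> EffectEstimate:
    """Baseline-adjusted mean difference (IG − DG) at the endpoint.

    Fits ``endpoint ~ 1 + arm + baseline (+ block factors)`` on participants
    with both a baseline and an endpoint value (complete-case at the
    endpoint), and returns the arm coefficient with a t-based CI on the
    residual degrees of freedom.
    """
    rows = dataset[dataset["outcome"] == outcome]
    wide = rows.pivot_table(index="participant_id", columns="week", values="value",
                            aggfunc="first")
    if baseline_week not in wide.columns or endpoint_week not in wide.columns:
        raise AnalysisError(
            f"outcome {outcome!r} lacks baseline or endpoint rows"
        )
    info = rows.drop_duplicates("participant_id").set_index("participant_id")
    wide = wide.loc[:, [baseline_week, endpoint_week]].dropna()
    arms = info.loc[wide.index, "arm"]
    n_by_arm = arms.value_counts()
    if n_by_arm.get("IG", 0) < 3 or n_by_arm.get("DG", 0) < 3:
        raise AnalysisError(
            f"need >=3 complete cases per arm for {outcome!r}, got {dict(n_by_arm)}"
        )
    baseline = wide[baseline_week].to_numpy(dtype=float)
    if np.var(baseline) == 0:
        raise AnalysisError(
            f"degenerate covariate: baseline of {outcome!r} has zero variance"
        )
    y = wide[endpoint_week].to_numpy(dtype=float)
    arm_ind = (arms == "IG").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), arm_ind, baseline])
    names = ["intercept", "arm_IG", "baseline"]
    if adjust_block:
        blocks = info.loc[wide.index, "block_id"]
        dummies = pd.get_dummies(blocks, prefix="block", drop_first=True)
        X = np.column_stack([X, dummies.to_numpy(dtype=float)])
        names += list(dummies.columns)
    fit = sm.OLS(y, X).fit()
    est = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi, p = _t_interval(est, se, fit.df_resid)
    return EffectEstimate(
        term=f"arm_IG@week{endpoint_week}", estimate=est, se=se,
        ci_low=lo, ci_high=hi, p_value=p, estimator="ancova", se_model=se,
        n_obs=len(y), n_participants=len(y),
    )


def _lmm_design(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    y = rows["value"].to_numpy(dtype=float)
    n = len(rows)
    cols = [np.ones(n), (rows["arm"] == "IG").to_numpy(dtype=float)]
    for w in FOLLOWUP_WEEKS:
        cols.append((rows["week"] == w).to_numpy(dtype=float))
    for e in EXPOSURE_LEVELS:
        cols.append((rows["exposure"] == e).to_numpy(dtype=float))
    X = np.column_stack(cols)
    groups = rows["participant_id"].to_numpy()
    return y, X, groups, list(LMM_TERMS)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name aliased columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] <= tol]
        raise AnalysisError(
            f"design matrix rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased or 'undetermined'}"
        )


def _sandwich_cov(X: np.ndarray, resid: np.ndarray, groups: np.ndarray,
                  sigma2: float, tau2: float, correction: str = "none") -> np.ndarray:
    """Cluster-by-participant empirical covariance of the GLS fixed effects."""
    p = X.shape[1]
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    n_groups = 0
    for g in pd.unique(groups):
        idx = groups == g
        Xi = X[idx]
        ri = resid[idx]
        ni = Xi.shape[0]
        Vi = sigma2 * np.eye(ni) + tau2 * np.ones((ni, ni))
        Vinv = np.linalg.inv(Vi)
        XtV = Xi.T @ Vinv
        A += XtV @ Xi
        u = XtV @ ri
        B += np.outer(u, u)
        n_groups += 1
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    if correction == "cr1" and n_groups > 1:
        cov = cov * n_groups / (n_groups - 1)
    elif correction not in ("none", "cr1"):
        raise ValueError(f"unknown sandwich correction {correction!r}")
    return cov


def fit_delay_control_lmm(
    dataset: pd.DataFrame,
    outcome: str,
    correction: str = "none",
    random_intercept: bool = True,
    emit_trend_contrasts: bool = True,
) -> list[EffectEstimate]:
    """Fit the delay-control random-intercept model for one outcome.

    Returns one :class:`EffectEstimate` per fixed effect (sandwich SEs, with
    the model-based SE carried in ``se_model``), plus the secular-trend
    contrasts ``T_week26 − T_week13`` and ``T_week39 − T_week13`` with
    delta-method SEs.  With ``random_intercept=False`` the random-intercept
    variance is fixed at zero, which reduces the fit to ordinary least squares
    on the same fixed-effects design.
    """
    rows = dataset[dataset["outcome"] == outcome].dropna(subset=["value"])
    if not len(rows):
        raise AnalysisError(f"no rows for outcome {outcome!r}")
    y, X, groups, names = _lmm_design(rows)
    _check_rank(X, names)
    n_participants = len(pd.unique(groups))

    ols = sm.OLS(y, X).fit()
    perfect = float(np.sum(ols.resid**2)) <= 1e-10 * max(1.0, float(np.sum(y**2)))
    fit = None
    if random_intercept and not perfect:
        model = sm.MixedLM(y, X, groups=groups)
        last_exc: Exception | None = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except Exception as exc:
                last_exc = exc
                continue
            if getattr(cand, "converged", True):
                fit = cand
                break
        # REML solutions on the tau^2 = 0 boundary can defeat every optimizer
        # ("singular matrix"); the boundary fit itself is plain OLS, so fall
        # through to that branch rather than failing the outcome.
        if fit is None:
            if last_exc is None:
                raise AnalysisError(
                    f"mixed-model did not converge for {outcome!r}; "
                    "see the statsmodels optimizer history for the iteration trace"
                )
            if "singular" not in str(last_exc).lower():
                raise AnalysisError(
                    f"mixed-model fit failed for {outcome!r}: {last_exc}"
                ) from last_exc
    if fit is not None:
        params = np.asarray(fit.fe_params, dtype=float)
        cov_model = np.asarray(fit.cov_params())[: len(names), : len(names)]
        sigma2 = float(fit.scale)
        # cov_re is already on the response scale in statsmodels
        tau2 = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    else:
        # tau^2 = 0 (or a perfectly interpolated response): GLS == OLS
        params = np.asarray(ols.params, dtype=float)
        cov_model = np.asarray(ols.cov_params())
        sigma2 = float(ols.scale) if not perfect else 0.0
        tau2 = 0.0

    resid = y - X @ params
    if sigma2 > 0:
        cov_r = _sandwich_cov(X, resid, groups, sigma2, tau2, correction)
    else:
        cov_r = np.zeros((len(names), len(names)))

    out: list[EffectEstimate] = []
    for i, name in enumerate(names):
        est = float(params[i])
        se_r = float(np.sqrt(max(cov_r[i, i], 0.0)))
        se_m = float(np.sqrt(max(cov_model[i, i], 0.0)))
        lo, hi, p = _z_interval(est, se_r)
        out.append(
            EffectEstimate(name, est, se_r, lo, hi, p, "lmm_sandwich", se_m,
                           n_obs=len(y), n_participants=n_participants)
        )
    if emit_trend_contrasts:
        for wk, label in ((26, "T_week26_vs_week13"), (39, "T_week39_vs_week13")):
            L = np.zeros(len(names))
            L[names.index(f"T_week{wk}")] = 1.0
            L[names.index("T_week13")] = -1.0
            est = float(L @ params)
            se_r = float(np.sqrt(max(L @ cov_r @ L, 0.0)))
            se_m = float(np.sqrt(max(L @ cov_model @ L, 0.0)))
            lo, hi, p = _z_interval(est, se_r)
            out.append(
                EffectEstimate(label, est, se_r, lo, hi, p, "lmm_sandwich", se_m,
                               n_obs=len(y), n_participants=n_participants)
            )
    return out


def estimate_all(
    dataset: pd.DataFrame,
    endpoint_week: int = 13,
    adjust_block: bool = False,
    correction: str = "none",
) -> pd.DataFrame:
    """Run ANCOVA (at the endpoint) and the LMM for every outcome present.

    One outcome's failure is logged and flagged (estimator ``error``) without
    aborting the others.
    """
    records = []
    for outcome in sorted(dataset["outcome"].unique()):
        try:
            est = ancova_adjusted_difference(
                dataset, outcome, endpoint_week=endpoint_week, adjust_block=adjust_block
            )
            records.append((outcome, est))
        except AnalysisError as exc:
            log.warning("ANCOVA failed for %s: %s", outcome, exc)
            records.append((outcome, EffectEstimate(
                f"arm_IG@week{endpoint_week}", np.nan, np.nan, np.nan, np.nan,
                np.nan, f"error: {exc}")))
        try:
            for est in fit_delay_control_lmm(dataset, outcome, correction=correction,
                                             emit_trend_contrasts=False):
                records.append((outcome, est))
        except AnalysisError as exc:
            log.warning("LMM failed for %s: %s", outcome, exc)
            records.append((outcome, EffectEstimate(
                "lmm", np.nan, np.nan, np.nan, np.nan, np.nan, f"error: {exc}")))
    return pd.DataFrame(
        {
            "outcome": [o for o, _ in records],
            "term": [e.term for _, e in records],
            "estimate": [e.estimate for _, e in records],
            "se_model": [e.se_model for _, e in records],
            "se_sandwich": [e.se for _, e in records],
            "ci_low": [e.ci_low for _, e in records],
            "ci_high": [e.ci_high for _, e in records],
            "p": [e.p_value for _, e in records],
            "estimator": [e.estimator for _, e in records],
            "n_obs": [e.n_obs for _, e in records],
            "n_participants": [e.n_participants for _, e in records],
        }
    )


def power_two_sample(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    n_total: int,
    alpha: float = 0.05,
    one_sided: bool = False,
) -> float:
    """Power of the two-sample pooled-variance t-test under the alternative.

    Uses the noncentral-t distribution with ``n_total - 2`` degrees of freedom
    and equal allocation (odd totals put the extra participant in group a).
    The one-sided test is in the direction of the stated alternative
    (``mean_a > mean_b`` when positive).
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be > 0")
    if n_total < 4:
        raise ValueError("n_total must be >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_a = (n_total + 1) // 2
    n_b = n_total - n_a
    df = n_total - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    ncp = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    if one_sided:
        tcrit = st.t.ppf(1 - alpha, df)
        return float(st.nct.sf(tcrit, df, ncp))
    tcrit = st.t.ppf(1 - alpha / 2, df)
    return float(st.nct.sf(tcrit, df, ncp) + st.nct.cdf(-tcrit, df, ncp))
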