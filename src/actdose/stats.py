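"""Trial evaluation statistics.

Contingency measures (odds ratios with Woolf confidence intervals, chi
square, Fisher exact), mean comparisons, linear/logistic regression with
Wald intervals, the univariate-screen-then-multivariate modelling
procedure with variance-inflation-factor exclusion, System Usability
Scale scoring, and an arm-level trial summary.

Regression fits are delegated to statsmodels (OLS and Logit with Wald
intervals); the contingency formulas are computed directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .engine import ValidationError

Z975 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Logistic fit abandoned: the classes are perfectly separable."""


class CollinearityError(ValueError):
    """Design matrix is exactly collinear; offending columns named."""


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts (exposed = the condition of interest)."""

    events_exposed: int
    n_exposed: int
    events_ref: int
    n_ref: int

    def __post_init__(self) -> None:
        for e, n in ((self.events_exposed, self.n_exposed),
                     (self.events_ref, self.n_ref)):
            if n <= 0:
                raise ValidationError("group sizes must be > 0")
            if not 0 <= e <= n:
                raise ValidationError("events must lie in [0, n]")

    @property
    def cells(self):
        """(a, b, c, d) = (exposed events, exposed non-events, ref events,
        ref non-events)."""
        return (
            self.events_exposed,
            self.n_exposed - self.events_exposed,
            self.events_ref,
            self.n_ref - self.events_ref,
        )

    def as_table(self) -> np.ndarray:
        a, b, c, d = self.cells
        return np.array([[a, b], [c, d]], dtype=float)


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane 0.5 added to every cell because of a zero


def odds_ratio(t: TwoByTwo, conf_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio with the Woolf (log) confidence interval.

    The variance of ``ln OR`` is the sum of reciprocal cell counts.  Any
    zero cell triggers the Haldane-Anscombe 0.5 correction on every cell,
    flagged in the result.
    """
    a, b, c, d = (float(x) for x in t.cells)
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return OddsRatioResult(or_, lo, hi, corrected)


def chi_square(table) -> tuple:
    """Pearson chi-square on an r x c count table: (statistic, df, p)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValidationError("table must be a 2-D array of counts >= 0")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("all table margins must be > 0")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables (at the observed margins) no more probable than the observed."""
    _, p = sps.fisher_exact(t.as_table(), alternative="two-sided")
    return float(p)


def t_test(x: Sequence[float], y: Sequence[float], pooled: bool = True) -> tuple:
    """Two-sample t test: (t, df, p).  Student (pooled variance) by
    default; ``pooled=False`` gives the Welch form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Per-predictor estimates from a linear or logistic fit.

    ``table`` is indexed by predictor (including ``const``) with columns
    ``beta``, ``ci_low``, ``ci_high``, ``p``; logistic tables add
    ``odds_ratio``/``or_ci_low``/``or_ci_high`` (the exponentiated row).
    """

    kind: str  # "linear" | "logistic"
    table: pd.DataFrame
    nobs: int

    def __post_init__(self) -> None:
        bad = ~(
            (self.table["ci_low"] <= self.table["beta"] + 1e-12)
            & (self.table["beta"] <= self.table["ci_high"] + 1e-12)
        )
        if bad.any():
            raise ValidationError("confidence interval must bracket beta")

    @property
    def predictors(self) -> list:
        return [p for p in self.table.index if p != "const"]


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(predictors).astype(float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValidationError("need more observations than predictors")
    return sm.add_constant(X, has_constant="add")


def _check_collinearity(X: pd.DataFrame) -> None:
    """Raise, naming the offending columns, on exact linear dependence."""
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    offenders = []
    cols = list(X.columns)
    for j in range(1, len(cols)):  # skip const
        prior = arr[:, :j]
        col = arr[:, j]
        resid = col - prior @ np.linalg.lstsq(prior, col, rcond=None)[0]
        denom = max(np.linalg.norm(col), 1.0)
        if np.linalg.norm(resid) / denom < 1e-10:
            offenders.append(cols[j])
    raise CollinearityError(
        f"exactly collinear predictor columns: {offenders or cols}"
    )


def _result_table(params, conf, pvals) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": params,
            "ci_low": conf[0],
            "ci_high": conf[1],
            "p": pvals,
        }
    )


def linear_fit(y: Sequence[float], predictors: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with Wald 95% intervals."""
    X = _design(predictors)
    _check_collinearity(X)
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    conf = fit.conf_int()
    table = _result_table(fit.params, {0: conf[0], 1: conf[1]}, fit.pvalues)
    return RegressionResult("linear", table, int(fit.nobs))


def logistic_fit(y01: Sequence[int], predictors: pd.DataFrame) -> RegressionResult:
    """Maximum-likelihood logistic regression; betas are log odds ratios.

    Raises :class:`SeparationError` (no estimate) under perfect
    separation, and requires both outcome classes to be present.
    """
    y = np.asarray(y01, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("logistic outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("logistic fit requires both outcome classes")
    X = _design(predictors)
    _check_collinearity(X)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
        raise SeparationError("perfect separation: estimates diverged")
    conf = fit.conf_int()
    table = _result_table(fit.params, {0: conf[0], 1: conf[1]}, fit.pvalues)
    table["odds_ratio"] = np.exp(table["beta"])
    table["or_ci_low"] = np.exp(table["ci_low"])
    table["or_ci_high"] = np.exp(table["ci_high"])
    return RegressionResult("logistic", table, int(fit.nobs))


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column regressed on the others
    (with intercept): ``VIF_j = 1 / (1 - R^2_j)``."""
    X = pd.DataFrame(predictors).astype(float)
    if (X.std(ddof=0) == 0).any():
        const_cols = list(X.columns[X.std(ddof=0) == 0])
        raise ValidationError(f"VIF undefined for constant columns: {const_cols}")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            out[col] = 1.0
            continue
        fit = sm.OLS(X[col], sm.add_constant(others, has_constant="add")).fit()
        r2 = min(fit.rsquared, 1.0)
        out[col] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class ModelSelection:
    """Outcome of the univariate screen -> multivariate fit procedure."""

    univariate: pd.DataFrame  # per-candidate beta / ci / p from solo fits
    promoted: list  # candidates passing the univariate screen
    excluded: dict  # candidate -> reason ("preference:<kept>" | "vif=<x>")
    selected: list  # predictors entering the joint model
    model: RegressionResult  # the joint (or intercept-only) fit


def univariate_then_multivariate(
    y: Sequence[float],
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    vif_cutoff: float = 10.0,
    kind: str = "linear",
    prefer: Sequence[tuple] = (("weight", "bmi"),),
) -> ModelSelection:
    """Univariate screen, collinearity pruning, then one adjusted model.

    Each candidate is first fit alone; those with p <= ``alpha`` are
    promoted.  Declared preferences then drop a redundant twin when both
    members are promoted (by default weight is kept over BMI, which is
    derived from it).  Remaining promoted predictors with VIF >=
    ``vif_cutoff`` are excluded, worst first.  The survivors enter the
    joint model.
    """
    candidates = pd.DataFrame(candidates).astype(float)
    if candidates.shape[1] == 0:
        raise ValidationError("candidate set must be nonempty")
    fitter = linear_fit if kind == "linear" else logistic_fit

    uni_rows = {}
    promoted = []
    for col in candidates.columns:
        res = fitter(y, candidates[[col]])
        uni_rows[col] = res.table.loc[col]
        if res.table.loc[col, "p"] <= alpha:
            promoted.append(col)
    univariate = pd.DataFrame(uni_rows).T

    excluded: dict = {}
    selected = list(promoted)
    for keep, drop in prefer:
        if keep in selected and drop in selected:
            selected.remove(drop)
            excluded[drop] = f"preference:{keep}"

    while len(selected) >= 2:
        vifs = vif(candidates[selected])
        worst = vifs.idxmax()
        if vifs[worst] >= vif_cutoff:
            selected.remove(worst)
            excluded[worst] = f"vif={vifs[worst]:.3g}"
        else:
            break

    if selected:
        model = fitter(y, candidates[selected])
    else:
        intercept_only = pd.DataFrame(index=range(len(y)))
        X = sm.add_constant(intercept_only, has_constant="add")
        if kind == "linear":
            fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
        else:
            fit = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0)
        conf = fit.conf_int()
        table = _result_table(fit.params, {0: conf[0], 1: conf[1]}, fit.pvalues)
        model = RegressionResult(kind, table, int(fit.nobs))

    return ModelSelection(univariate, promoted, excluded, selected, model)


# ---------------------------------------------------------------------------
# System Usability Scale
# ---------------------------------------------------------------------------

SUS_AVERAGE = 68.0
SUS_EXCELLENT = 80.3


def sus_score(responses: Sequence[int]) -> float:
    """Standard SUS scoring of a 10-item questionnaire.

    Odd items (positively phrased) contribute ``score - 1``, even items
    (negatively phrased) ``5 - score``; the sum is scaled by 2.5 onto
    0-100.  Scores above 68 are considered average, above 80.3 excellent.
    """
    items = list(responses)
    if len(items) != 10:
        raise ValidationError("SUS requires exactly 10 item scores")
    for s in items:
        if int(s) != s or not 1 <= s <= 5:
            raise ValidationError("SUS items must be integers in 1..5")
    total = sum(
        (s - 1) if i % 2 == 0 else (5 - s) for i, s in enumerate(items)
    )
    return 2.5 * total


# ---------------------------------------------------------------------------
# Trial summary
# ---------------------------------------------------------------------------


@dataclass
class ArmSummary:
    n: int
    mean_time_to_goal: float
    sd_time_to_goal: float
    n_below_in_la: int
    pct_below_in_la: float
    n_above_400: int
    pct_above_400: float
    mean_total_bolus: float


@dataclass
class TrialSummary:
    """Arm-level outcome summary with between-arm comparisons.

    The odds ratios treat the algorithm arm as exposed and the control arm
    as reference, so values below 1 favour the algorithm.
    """

    arms: dict  # arm name -> ArmSummary
    or_below_in_la: Optional[OddsRatioResult] = None
    or_above_400: Optional[OddsRatioResult] = None
    p_below_fisher: Optional[float] = None
    p_above_fisher: Optional[float] = None
    time_to_goal_beta: Optional[tuple] = None  # (beta, lo, hi, p)
    time_to_goal_p_t: Optional[float] = None

    def to_text(self) -> str:
        lines = []
        for name in ("control", "algorithm"):
            if name not in self.arms:
                continue
            a = self.arms[name]
            lines.append(
                f"{name:>9}: n={a.n}  time-to-goal {a.mean_time_to_goal:.1f}"
                f" +/- {a.sd_time_to_goal:.1f} min  "
                f"below-goal-in-LA {a.n_below_in_la}/{a.n} "
                f"({a.pct_below_in_la:.0f}%)  "
                f"ACT>400 {a.n_above_400}/{a.n} ({a.pct_above_400:.0f}%)  "
                f"mean bolus {a.mean_total_bolus:.0f} u"
            )
        if self.or_below_in_la is not None:
            o = self.or_below_in_la
            lines.append(
                f"below-goal-in-LA OR {o.odds_ratio:.2f} "
                f"(95% CI {o.ci_low:.2f}-{o.ci_high:.2f}), "
                f"Fisher p={self.p_below_fisher:.3g}"
            )
        if self.or_above_400 is not None:
            o = self.or_above_400
            lines.append(
                f"ACT>400 OR {o.odds_ratio:.2f} "
                f"(95% CI {o.ci_low:.2f}-{o.ci_high:.2f}), "
                f"Fisher p={self.p_above_fisher:.3g}"
            )
        if self.time_to_goal_beta is not None:
            b, lo, hi, p = self.time_to_goal_beta
            lines.append(
                f"time-to-goal regression beta (algorithm vs control) "
                f"{b:.1f} min (95% CI {lo:.1f} to {hi:.1f}), p={p:.3g}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, a in self.arms.items():
            rows.append({"arm": name, **a.__dict__})
        return pd.DataFrame(rows)


def _arm_summary(sub: pd.DataFrame) -> ArmSummary:
    n = len(sub)
    below = int(sub["any_below_in_la"].sum())
    above = int(sub["any_above_400"].sum())
    return ArmSummary(
        n=n,
        mean_time_to_goal=float(sub["time_to_goal_min"].mean()),
        sd_time_to_goal=float(sub["time_to_goal_min"].std(ddof=1))
        if n > 1
        else 0.0,
        n_below_in_la=below,
        pct_below_in_la=100.0 * below / n,
        n_above_400=above,
        pct_above_400=100.0 * above / n,
        mean_total_bolus=float(sub["total_bolus_units"].mean()),
    )


def summarize_trial(table: pd.DataFrame) -> TrialSummary:
    """Fig-3-style summary of a per-case trial table.

    With both arms present, reports the two odds ratios (Woolf CIs),
    Fisher p values, the pooled t test and the group-indicator linear
    regression for time to goal.  With a single arm, only the descriptive
    block is produced.
    """
    if len(table) == 0:
        raise ValidationError("empty trial table")
    arms = {name: _arm_summary(sub) for name, sub in table.groupby("arm")}
    summary = TrialSummary(arms=arms)
    if "control" not in arms or "algorithm" not in arms:
        return summary

    algo, ctrl = arms["algorithm"], arms["control"]
    t_below = TwoByTwo(algo.n_below_in_la, algo.n, ctrl.n_below_in_la, ctrl.n)
    t_above = TwoByTwo(algo.n_above_400, algo.n, ctrl.n_above_400, ctrl.n)
    summary.or_below_in_la = odds_ratio(t_below)
    summary.or_above_400 = odds_ratio(t_above)
    summary.p_below_fisher = fisher_exact(t_below)
    summary.p_above_fisher = fisher_exact(t_above)

    y = table["time_to_goal_min"].to_numpy(dtype=float)
    g = (table["arm"] == "algorithm").astype(float).rename("algorithm")
    res = linear_fit(y, pd.DataFrame({"algorithm": g}))
    row = res.table.loc["algorithm"]
    summary.time_to_goal_beta = (
        float(row["beta"]), float(row["ci_low"]),
        float(row["ci_high"]), float(row["p"]),
    )
    x = table.loc[table["arm"] == "algorithm", "time_to_goal_min"]
    yv = table.loc[table["arm"] == "control", "time_to_goal_min"]
    if len(x) >= 2 and len(yv) >= 2:
        summary.time_to_goal_p_t = t_test(x, yv, pooled=True)[2]
    return summary


# ---------------------------------------------------------------------------
# Synthetic regression data with known ground truth
# ---------------------------------------------------------------------------

TRUE_EFFECTS = {"weight": 95.0, "baseline_act": -80.0, "warfarin": -2800.0}


def synthetic_bolus_dataset(n: int, rng) -> tuple:
    """Synthetic per-case heparin-requirement data with known effects.

    The response emulates the total bolus (units) needed to reach goal:
    it genuinely depends on weight, baseline ACT and warfarin use (the
    coefficients in :data:`TRUE_EFFECTS`), while age is pure noise and BMI
    is derived from weight (height is an independent nuisance), making it
    a collinear decoy that the weight-over-BMI preference must absorb.
    Returns ``(y, candidates)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    weight = rng.normal(97.0, 20.0, n).clip(45.0, 180.0)
    height = rng.normal(1.72, 0.10, n).clip(1.45, 2.05)
    bmi = weight / height**2
    baseline_act = rng.normal(133.0, 14.0, n).clip(90.0, 220.0)
    warfarin = (rng.random(n) < 0.12).astype(float)
    age = rng.normal(63.0, 10.0, n).clip(30.0, 90.0)

    y = (
        2000.0
        + TRUE_EFFECTS["weight"] * weight
        + TRUE_EFFECTS["baseline_act"] * baseline_act
        + TRUE_EFFECTS["warfarin"] * warfarin
        + rng.normal(0.0, 1800.0, n)
    )
    candidates = pd.DataFrame(
        {
            "weight": weight,
            "baseline_act": baseline_act,
            "warfarin": warfarin,
            "bmi": bmi,
            "age": age,
        }
    )
    return y, candidates
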