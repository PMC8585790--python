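"""Cox proportional-hazards fitting and absolute-risk prediction.

The model is fitted by Newton–Raphson on the Breslow-ties partial likelihood;
the baseline cumulative hazard H0(t) is the Breslow estimator evaluated with
covariates centered at the training means, so the linear predictor at
prediction time is lp = βᵀ(x − x̄) and the absolute risk over a horizon t is

    risk(t) = 1 − exp(−H0(t) · exp(lp)).

The fitted summary (β, x̄, H0 step function) is a self-contained transfer
artifact: it can be exported to JSON, shipped to a deployment population, and
re-imported with bit-identical predictions — the time-to-event model never
needs the training data at prediction time.

Assumptions: follow-up time is the time scale (age enters as a covariate);
ties are handled by the Breslow approximation; no delayed entry, competing
risks, or time-varying covariates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FittingError, FormatError, ValidationError

__all__ = [
    "COVARIATE_ORDER",
    "TRADITIONAL_COVARIATES",
    "CALCULATOR_FIELDS",
    "CovariateVector",
    "SurvivalCohort",
    "CoxSummary",
    "RiskEstimate",
    "fit_cox",
    "breslow_baseline",
    "absolute_risk",
    "project_risk_at_age",
    "risk_calculator",
    "export_summary",
    "import_summary",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

logger = logging.getLogger(__name__)

#: Canonical covariate ordering shared by fits, summaries, and predictions.
COVARIATE_ORDER = (
    "age",
    "sex",
    "bmi",
    "total_chol",
    "hdl",
    "sbp",
    "bp_med",
    "lipid_med",
    "family_history",
    "smoking",
    "prs_z",
)

#: The traditional-risk-factor subset (no genetic score).
TRADITIONAL_COVARIATES = tuple(c for c in COVARIATE_ORDER if c != "prs_z")

#: Lifestyle fields the counterfactual risk calculator may change.
CALCULATOR_FIELDS = frozenset({"bmi", "sbp", "smoking"})

#: Training-age support; projections outside it are clamped.
AGE_SUPPORT = (24.0, 75.0)

_BINARY_FIELDS = ("sex", "bp_med", "lipid_med", "family_history", "smoking")
_POSITIVE_FIELDS = ("age", "bmi", "total_chol", "hdl", "sbp")


@dataclass(frozen=True)
class CovariateVector:
    """One individual's risk-factor profile.

    Units: age in years, BMI in kg/m², cholesterol in mmol/L, systolic blood
    pressure in mmHg; medication, family-history and smoking status are 0/1;
    ``prs_z`` is the standardized polygenic score (SD units).
    """

    age: float
    sex: int
    bmi: float
    total_chol: float
    hdl: float
    sbp: float
    bp_med: int
    lipid_med: int
    family_history: int
    smoking: int
    prs_z: float = 0.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in _BINARY_FIELDS:
            if getattr(self, name) not in (0, 1):
                raise ValidationError(
                    f"{name} must be 0 or 1, got {getattr(self, name)}"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in COVARIATE_ORDER}


@dataclass
class SurvivalCohort:
    """Covariates plus right-censored follow-up for a training cohort.

    ``data`` holds one row per sample with the :data:`COVARIATE_ORDER`
    columns, ``time`` (years of follow-up, > 0) and ``event`` (0/1).
    """

    data: pd.DataFrame
    sample_id_col: str = "sample_id"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"cohort table is missing column {col!r}")
        t = self.data["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValidationError("follow-up times must be finite and positive")
        e = self.data["event"].to_numpy()
        if not np.isin(e, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass(frozen=True)
class RiskEstimate:
    """Absolute probability of disease onset within a horizon."""

    probability: float
    horizon_years: float
    basis: str  # "with_prs" | "traditional_only"

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"probability must lie in [0,1], got {self.probability}"
            )
        if not self.horizon_years > 0:
            raise ValidationError("horizon must be positive")


@dataclass
class CoxSummary:
    """Fitted coefficients, covariate means and baseline cumulative hazard.

    ``baseline_times``/``baseline_cumhaz`` define a right-continuous step
    function with H0(0) = 0; ``horizon_cumhaz_10y`` caches H0(10).
    """

    covariates: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    covariate_means: dict[str, float]
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    horizon_cumhaz_10y: float
    loglik: float = float("nan")
    n: int = 0
    n_events: int = 0
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_cumhaz = np.asarray(self.baseline_cumhaz, dtype=float)
        if self.baseline_times.shape != self.baseline_cumhaz.shape:
            raise ValidationError("baseline time/H0 grids differ in length")
        if np.any(np.diff(self.baseline_times) <= 0):
            raise ValidationError("baseline time grid must be strictly increasing")
        if self.baseline_cumhaz.size and (
            self.baseline_cumhaz[0] < 0 or np.any(np.diff(self.baseline_cumhaz) < 0)
        ):
            raise ValidationError("baseline cumulative hazard must be non-decreasing")
        for name in self.covariates:
            if name not in self.beta:
                raise FormatError(f"model summary is missing coefficient for {name!r}")
            if name not in self.covariate_means:
                raise FormatError(f"model summary is missing mean for {name!r}")

    @property
    def basis(self) -> str:
        return "with_prs" if "prs_z" in self.covariates else "traditional_only"

    def cumhaz(self, t: float) -> float:
        """H0(t): right-continuous step lookup, constant beyond the last event."""
        if t < 0:
            raise ValidationError("cumulative hazard requested at negative time")
        if self.baseline_times.size == 0:
            return 0.0
        if t > self.baseline_times[-1]:
            logger.warning(
                "horizon %.3g beyond last event time %.3g; extrapolating H0 as constant",
                t,
                self.baseline_times[-1],
            )
        idx = int(np.searchsorted(self.baseline_times, t, side="right")) - 1
        return 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])

    def linear_predictor(self, x: Mapping[str, float] | CovariateVector) -> float:
        """lp = βᵀ(x − x̄) over this summary's covariates."""
        xd = x.as_dict() if isinstance(x, CovariateVector) else dict(x)
        lp = 0.0
        for name in self.covariates:
            if name not in xd:
                raise ValidationError(f"covariate {name!r} missing from input vector")
            lp += self.beta[name] * (float(xd[name]) - self.covariate_means[name])
        return lp

    def confint(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one log hazard ratio."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        b, s = self.beta[name], self.se[name]
        return (b - z * s, b + z * s)


def _design(cohort: SurvivalCohort, covariates: Sequence[str]) -> np.ndarray:
    for name in covariates:
        if name not in cohort.data.columns:
            raise ValidationError(f"cohort table is missing covariate {name!r}")
    X = cohort.data[list(covariates)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    for j, name in enumerate(covariates):
        if sd[j] == 0:
            raise ValidationError(f"covariate {name!r} is constant across samples")
    return X


def _breslow_loglik_grad_hess(
    Xc: np.ndarray, t: np.ndarray, e: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow-ties partial log-likelihood with gradient and information.

    Arrays must be sorted by ascending time; Xc is mean-centered.
    """
    n, p = Xc.shape
    lp = Xc @ beta
    lp -= lp.max()  # guard exp overflow; cancels in all ratios and in ll up to const
    w = np.exp(lp)
    wx = w[:, None] * Xc
    wxx = wx[:, :, None] * Xc[:, None, :]
    # reverse cumulative sums: entry i = sum over j >= i (risk set of t_i)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    # first index of each tie group, so S*(first) covers all t_j >= t_i
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev = np.flatnonzero(e == 1)
    if ev.size == 0:
        raise ValidationError("cohort contains no events")
    f = first[ev]
    s0 = S0[f]
    xbar = S1[f] / s0[:, None]
    ll = float(lp[ev].sum() - np.log(s0).sum())
    grad = Xc[ev].sum(axis=0) - xbar.sum(axis=0)
    info = (S2[f] / s0[:, None, None]).sum(axis=0) - np.einsum(
        "ij,ik->jk", xbar, xbar
    )
    return ll, grad, info


def _breslow_baseline_arrays(
    Xc: np.ndarray, t: np.ndarray, e: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow H0 jumps d_k / Σ_{R_k} exp(lp) on the unique event-time grid.

    Inputs must be sorted by ascending time; Xc mean-centered.
    """
    w = np.exp(Xc @ beta)
    S0 = np.cumsum(w[::-1])[::-1]
    event_times, d = np.unique(t[e == 1], return_counts=True)
    # first index of each tie group: S0 there covers the whole risk set
    pos = np.searchsorted(t, event_times, side="left")
    return event_times, np.cumsum(d / S0[pos])


def breslow_baseline(
    cohort: SurvivalCohort,
    covariates: Sequence[str] = (),
    beta: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline cumulative hazard at fixed coefficients (zeros by default).

    With no covariates (or all-zero beta) this reduces exactly to the
    Nelson–Aalen estimator Σ_{t_k ≤ t} d_k / n_at_risk(t_k).
    """
    names = tuple(covariates)
    X = (
        cohort.data[list(names)].to_numpy(dtype=float)
        if names
        else np.zeros((cohort.n, 0))
    )
    t = cohort.data["time"].to_numpy(dtype=float)
    e = cohort.data["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    Xc = X - X.mean(axis=0) if names else X
    b = np.array([0.0 if beta is None else float(beta.get(n, 0.0)) for n in names])
    return _breslow_baseline_arrays(Xc, t, e, b)


def fit_cox(
    cohort: SurvivalCohort,
    covariates: str | Sequence[str] = "full",
    max_iter: int = 50,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxSummary:
    """Fit the proportional-hazards model and Breslow baseline hazard.

    ``covariates`` is "full" (all eleven risk factors including the PRS),
    "traditional" (everything except ``prs_z``), or an explicit name list.
    Newton–Raphson with step-halving; converged when the score's max absolute
    component falls below ``grad_tol`` or the relative log-likelihood change
    below ``ll_tol``.
    """
    if isinstance(covariates, str):
        if covariates == "full":
            names: tuple[str, ...] = COVARIATE_ORDER
        elif covariates == "traditional":
            names = TRADITIONAL_COVARIATES
        else:
            raise ValidationError(
                f"covariates must be 'full', 'traditional' or a list, got {covariates!r}"
            )
    else:
        names = tuple(covariates)
    if cohort.n_events < 1:
        raise ValidationError("cannot fit a survival model with zero events")

    X = _design(cohort, names)
    t = cohort.data["time"].to_numpy(dtype=float)
    e = cohort.data["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    means = X.mean(axis=0)
    Xc = X - means

    p = len(names)
    beta = np.zeros(p)
    ll, grad, info = _breslow_loglik_grad_hess(Xc, t, e, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < grad_tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FittingError(f"singular information matrix: {exc}") from exc
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            ll_new, grad_new, info_new = _breslow_loglik_grad_hess(
                Xc, t, e, beta + factor * step
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        converged_ll = abs(ll_new - ll) < ll_tol * max(1.0, abs(ll))
        ll, grad, info = ll_new, grad_new, info_new
        if converged_ll:
            break
    else:
        raise FittingError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(last max|score| = {np.max(np.abs(grad)):.3g})"
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))

    event_times, H0 = _breslow_baseline_arrays(Xc, t, e, beta)

    summary = CoxSummary(
        covariates=names,
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        covariate_means=dict(zip(names, means.tolist())),
        baseline_times=event_times,
        baseline_cumhaz=H0,
        horizon_cumhaz_10y=0.0,
        loglik=ll,
        n=cohort.n,
        n_events=cohort.n_events,
        n_iter=n_iter,
    )
    summary.horizon_cumhaz_10y = summary.cumhaz(10.0)
    return summary


def absolute_risk(
    model: CoxSummary,
    x: Mapping[str, float] | CovariateVector,
    horizon: float = 10.0,
) -> RiskEstimate:
    """risk = 1 − exp(−H0(horizon) · exp(βᵀ(x − x̄)))."""
    lp = model.linear_predictor(x)
    prob = 1.0 - np.exp(-model.cumhaz(horizon) * np.exp(lp))
    return RiskEstimate(
        probability=float(prob), horizon_years=float(horizon), basis=model.basis
    )


def _with_field(
    x: Mapping[str, float] | CovariateVector, **changes: float
) -> Mapping[str, float] | CovariateVector:
    if isinstance(x, CovariateVector):
        return replace(x, **changes)
    out = dict(x)
    out.update(changes)
    return out


def project_risk_at_age(
    model: CoxSummary,
    x: Mapping[str, float] | CovariateVector,
    target_age: float = 60.0,
    horizon: float = 10.0,
) -> RiskEstimate:
    """Risk with the age covariate moved to ``target_age``, all else fixed.

    The training population covers ages 24–75, so evaluation ages are clamped
    to that range; individuals already over 75 are evaluated at 75 ("your
    risk at the age of 75"), whatever the target.
    """
    age = float(x.age if isinstance(x, CovariateVector) else x["age"])
    if age > AGE_SUPPORT[1]:
        eval_age = AGE_SUPPORT[1]
        logger.warning(
            "current age %.1f beyond training support; risk given at age %.0f",
            age,
            eval_age,
        )
    else:
        eval_age = float(np.clip(target_age, *AGE_SUPPORT))
        if eval_age != target_age:
            logger.warning(
                "target age %.1f outside training support %s; clamped to %.0f",
                target_age,
                AGE_SUPPORT,
                eval_age,
            )
    return absolute_risk(model, _with_field(x, age=eval_age), horizon=horizon)


def risk_calculator(
    model: CoxSummary,
    x: Mapping[str, float] | CovariateVector,
    changes: Mapping[str, float],
    horizon: float = 10.0,
) -> tuple[RiskEstimate, RiskEstimate]:
    """Counterfactual lifestyle calculator: (risk before, risk after).

    Only BMI, systolic blood pressure and smoking status may be changed;
    age, the genetic score and the remaining covariates are off-limits.
    """
    bad = set(changes) - CALCULATOR_FIELDS
    if bad:
        raise ValidationError(
            f"calculator may only change {sorted(CALCULATOR_FIELDS)}; "
            f"got {sorted(bad)}"
        )
    before = absolute_risk(model, x, horizon=horizon)
    after = absolute_risk(model, _with_field(x, **changes), horizon=horizon)
    return before, after


# ---------------------------------------------------------------------------
# Summary serialization (the training → deployment transfer artifact)


def export_summary(model: CoxSummary, path: str | Path) -> None:
    obj = {
        "covariates": list(model.covariates),
        "beta": model.beta,
        "se": model.se,
        "covariate_means": model.covariate_means,
        "baseline_times": model.baseline_times.tolist(),
        "baseline_cumhaz": model.baseline_cumhaz.tolist(),
        "horizon_cumhaz_10y": model.horizon_cumhaz_10y,
        "loglik": model.loglik,
        "n": model.n,
        "n_events": model.n_events,
        "n_iter": model.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def import_summary(path: str | Path) -> CoxSummary:
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse model summary {path}: {exc}") from exc
    try:
        names = tuple(obj["covariates"])
        summary = CoxSummary(
            covariates=names,
            beta={k: float(v) for k, v in obj["beta"].items()},
            se={k: float(v) for k, v in obj.get("se", {}).items()},
            covariate_means={
                k: float(v) for k, v in obj["covariate_means"].items()
            },
            baseline_times=np.asarray(obj["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(obj["baseline_cumhaz"], dtype=float),
            horizon_cumhaz_10y=float(obj["horizon_cumhaz_10y"]),
            loglik=float(obj.get("loglik", float("nan"))),
            n=int(obj.get("n", 0)),
            n_events=int(obj.get("n_events", 0)),
            n_iter=int(obj.get("n_iter", 0)),
        )
    except KeyError as exc:
        raise FormatError(f"model summary {path} is missing field {exc}") from exc
    return summary


# ---------------------------------------------------------------------------
# Cohort tables


def write_cohort_tsv(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> SurvivalCohort:
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse cohort table {path}: {exc}") from exc
    return SurvivalCohort(data=df)
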