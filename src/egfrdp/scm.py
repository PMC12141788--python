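"""Stepwise covariate modeling (SCM) by likelihood-ratio ΔOFV.

Workflow mirrors standard pharmacometric practice: univariate screening
of each candidate on the base model, forward addition at p < 0.05
(ΔOFV drop ≥ 3.84 for 1 df), backward elimination at p < 0.01 (removal
must cost > 6.63), and AIC for non-nested structural comparisons.  Every
step refits all parameters (no coefficient freezing), warm-started from
the parent fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LongitudinalDataset
from .estimate import FitResult, fit_model
from .model import CovariateTerm, ModelSpec

__all__ = [
    "ScmStep",
    "ScmResult",
    "lrt_threshold",
    "univariate_screen",
    "forward_addition",
    "backward_elimination",
    "compare_aic",
    "steps_to_frame",
]


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Critical ΔOFV: upper-alpha chi-square quantile with *df* degrees."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass
class ScmStep:
    """One screening or stepwise decision."""

    covariate: str
    direction: str          # "add" | "remove"
    delta_ofv: float        # candidate OFV − reference OFV (negative = better fit)
    df: int
    p_value: float
    decision: str           # "kept" | "rejected"
    theta: float = float("nan")
    converged: bool = True


@dataclass
class ScmResult:
    steps: list[ScmStep] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None


def steps_to_frame(steps: list[ScmStep]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "covariate": [s.covariate for s in steps],
            "direction": [s.direction for s in steps],
            "delta_ofv": [s.delta_ofv for s in steps],
            "df": [s.df for s in steps],
            "p_value": [s.p_value for s in steps],
            "theta": [s.theta for s in steps],
            "decision": [s.decision for s in steps],
            "converged": [s.converged for s in steps],
        }
    )


def _p_from_delta(delta_ofv: float, df: int) -> float:
    """LRT p-value; an OFV increase carries no evidence (p = 1)."""
    if not np.isfinite(delta_ofv) or delta_ofv >= 0:
        return 1.0
    return float(stats.chi2.sf(-delta_ofv, df))


def _fit_with_added(data, parent: FitResult, term: CovariateTerm, **fit_kw):
    """Refit with one more covariate, warm-started from the parent.

    The (s0, theta) profile is a narrow diagonal valley: raising theta must
    be offset by lowering the typical baseline.  Trial starts therefore
    pair each candidate theta with a mean-compensated s0, and the
    best-scoring start (by OFV) seeds the optimizer.
    """
    from .estimate import OfvEvaluator

    spec = parent.spec.with_covariate(term)
    x = np.concatenate(
        [s.covariates[term.name] - term.reference for s in data.subjects()]
    )
    xbar = float(np.mean(x))
    scale = max(float(np.std(x)), 1e-6)
    evaluator = OfvEvaluator(data, spec)
    best_inits, best_val = None, np.inf
    for delta in (0.0, 0.15, -0.15):
        th = delta / scale if term.kind == "continuous" else delta
        comp = 1.0 + th * xbar
        if comp <= 0.05:
            continue
        theta = dict(parent.estimates.theta)
        theta[term.name] = th
        cand = parent.estimates.replace(theta=theta, s0=parent.estimates.s0 / comp)
        try:
            val = evaluator.ofv(cand)
        except (ValueError, KeyError):
            continue
        if val < best_val:
            best_inits, best_val = cand, val
    if best_inits is None:
        theta = dict(parent.estimates.theta)
        theta[term.name] = 0.0
        best_inits = parent.estimates.replace(theta=theta)
    return fit_model(data, spec, best_inits, **fit_kw), spec


def _fit_with_removed(data, parent: FitResult, name: str, **fit_kw):
    spec = parent.spec.without_covariate(name)
    theta = {k: v for k, v in parent.estimates.theta.items() if k != name}
    inits = parent.estimates.replace(theta=theta)
    return fit_model(data, spec, inits, **fit_kw), spec


def univariate_screen(
    data: LongitudinalDataset,
    base_fit: FitResult,
    candidates: list[CovariateTerm],
    alpha: float = 0.05,
    **fit_kw,
) -> list[ScmStep]:
    """Fit base-plus-one-covariate for each candidate independently.

    Returns steps sorted by ΔOFV ascending (largest improvement first); a
    non-converging candidate fit is recorded as rejected, not fatal.
    """
    if not base_fit.converged:
        raise ValueError("base fit has not converged")
    for term in candidates:
        if term.name in base_fit.spec.covariate_names:
            raise ValueError(f"candidate {term.name!r} already in the base model")
    steps: list[ScmStep] = []
    for term in candidates:
        try:
            fit, _ = _fit_with_added(data, base_fit, term, **fit_kw)
            delta = fit.ofv - base_fit.ofv
            ok = fit.converged
            theta = fit.estimates.theta.get(term.name, float("nan"))
        except Exception:
            delta, ok, theta = float("inf"), False, float("nan")
        p = _p_from_delta(delta, 1) if ok else 1.0
        keep = ok and p < alpha
        steps.append(
            ScmStep(
                covariate=term.name,
                direction="add",
                delta_ofv=delta,
                df=1,
                p_value=p,
                decision="kept" if keep else "rejected",
                theta=theta,
                converged=ok,
            )
        )
    steps.sort(key=lambda s: s.delta_ofv)
    return steps


def forward_addition(
    data: LongitudinalDataset,
    base_fit: FitResult,
    candidates: list[CovariateTerm],
    alpha: float = 0.05,
    **fit_kw,
) -> ScmResult:
    """Iteratively add the candidate with the largest significant ΔOFV drop.

    Exact ties are broken by candidate list order (deterministic).
    """
    threshold = lrt_threshold(alpha, 1)
    result = ScmResult()
    current = base_fit
    remaining = list(candidates)
    while remaining:
        trials = []
        for term in remaining:
            try:
                fit, _ = _fit_with_added(data, current, term, **fit_kw)
                delta = fit.ofv - current.ofv
                ok = fit.converged
            except Exception:
                fit, delta, ok = None, float("inf"), False
            trials.append((term, fit, delta, ok))
        best = min(trials, key=lambda tr: tr[2])
        term, fit, delta, ok = best
        accepted = ok and (-delta) > threshold
        result.steps.append(
            ScmStep(
                covariate=term.name,
                direction="add",
                delta_ofv=delta,
                df=1,
                p_value=_p_from_delta(delta, 1) if ok else 1.0,
                decision="kept" if accepted else "rejected",
                theta=fit.estimates.theta.get(term.name, float("nan")) if fit else float("nan"),
                converged=ok,
            )
        )
        if not accepted:
            break
        current = fit
        remaining = [t for t in remaining if t.name != term.name]
    result.final_fit = current
    result.final_spec = current.spec
    return result


def backward_elimination(
    data: LongitudinalDataset,
    full_fit: FitResult,
    alpha: float = 0.01,
    **fit_kw,
) -> ScmResult:
    """Iteratively remove the cheapest covariate while its loss ≤ threshold.

    A covariate is retained only if its removal *increases* the OFV by
    more than the chi-square critical value (6.63 at p < 0.01, 1 df).
    """
    if not full_fit.spec.covariates:
        raise ValueError("full model has no covariates to eliminate")
    if not full_fit.converged:
        raise ValueError("full fit has not converged")
    threshold = lrt_threshold(alpha, 1)
    result = ScmResult()
    current = full_fit
    while current.spec.covariates:
        trials = []
        for term in current.spec.covariates:
            try:
                fit, _ = _fit_with_removed(data, current, term.name, **fit_kw)
                delta = fit.ofv - current.ofv  # ≥ 0 in exact arithmetic
                ok = fit.converged
            except Exception:
                fit, delta, ok = None, float("inf"), False
            trials.append((term, fit, delta, ok))
        term, fit, delta, ok = min(trials, key=lambda tr: tr[2])
        removable = ok and delta <= threshold
        result.steps.append(
            ScmStep(
                covariate=term.name,
                direction="remove",
                delta_ofv=delta,
                df=1,
                p_value=float(stats.chi2.sf(max(delta, 0.0), 1)),
                decision="kept" if not removable else "rejected",
                theta=current.estimates.theta.get(term.name, float("nan")),
                converged=ok,
            )
        )
        if not removable:
            break
        current = fit
    result.final_fit = current
    result.final_spec = current.spec
    return result


def compare_aic(fit_a: FitResult, fit_b: FitResult) -> FitResult:
    """Prefer the lower-AIC fit (non-nested comparison); ties → first."""
    if (fit_a.n_subjects, fit_a.n_obs) != (fit_b.n_subjects, fit_b.n_obs):
        raise ValueError("AIC comparison requires fits on the same dataset")
    return fit_a if fit_a.aic <= fit_b.aic else fit_b
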