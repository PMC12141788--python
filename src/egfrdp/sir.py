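"""Sampling importance resampling (SIR) parameter uncertainty.

Draws parameter vectors from a multivariate-normal proposal centered at
the point estimates (on the estimation transform scale), weights each
draw by ``exp(-0.5 * OFV) / proposal density``, and resamples without
replacement with probability proportional to weight.  Run as a schedule
of (samples, resamples) stages — default (1000, 500) then (2000, 1000) —
where each stage's proposal is rebuilt from the previous stage's
resamples.  SIR needs no covariance step from the estimation, which is
why it is the supported uncertainty path here.

RSE% is reported as ``100 * SD(resampled natural-scale values) /
|point estimate|``; variances are summarized on the SD (omega) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .estimate import FitResult, OfvEvaluator

__all__ = ["SirResult", "sir", "sir_from_objective", "rse_table", "DEFAULT_SCHEDULE"]

DEFAULT_SCHEDULE: tuple[tuple[int, int], ...] = ((1000, 500), (2000, 1000))


@dataclass
class SirStage:
    samples: np.ndarray       # (m, k) proposal draws, transform scale
    ofv: np.ndarray           # (m,)
    weights: np.ndarray       # normalized importance weights
    resample_idx: np.ndarray  # indices into samples
    ess: float
    n_zero_weight: int


@dataclass
class SirResult:
    stages: list[SirStage]
    param_names: list[str]
    point: dict[str, float]           # natural-scale point estimates
    resamples: pd.DataFrame           # final-stage resamples, natural scale
    summary: pd.DataFrame             # median / CI / RSE% per parameter

    @property
    def final(self) -> SirStage:
        return self.stages[-1]


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
    k = mean.size
    dev = x - mean
    sol = np.linalg.solve(chol, dev.T).T
    logdet = np.sum(np.log(np.diag(chol)))
    return -0.5 * np.sum(sol**2, axis=1) - logdet - 0.5 * k * np.log(2 * np.pi)


def sir_from_objective(
    objective,
    center: np.ndarray,
    cov: np.ndarray,
    m_samples: int,
    m_resamples: int,
    rng: np.random.Generator,
) -> SirStage:
    """One SIR stage against an arbitrary OFV (−2 log L) callable."""
    if m_resamples >= m_samples:
        raise ValueError("m_resamples must be smaller than m_samples")
    center = np.asarray(center, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    chol = np.linalg.cholesky(cov + 1e-300 * np.eye(len(center)))
    draws = center + rng.standard_normal((m_samples, center.size)) @ chol.T
    ofv = np.array([objective(x) for x in draws], dtype=float)
    finite = np.isfinite(ofv)
    n_zero = int(np.sum(~finite))
    logq = _mvn_logpdf(draws, center, chol)
    logw = np.where(finite, -0.5 * np.where(finite, ofv, 0.0) - logq, -np.inf)
    logw -= np.max(logw[finite]) if np.any(finite) else 0.0
    w = np.exp(logw)
    total = w.sum()
    if total <= 0:
        raise ValueError("all importance weights are zero")
    w /= total
    ess = float(1.0 / np.sum(w**2))
    if ess < 0.05 * m_samples:
        warnings.warn(
            f"effective sample size {ess:.1f} < 5% of {m_samples}; "
            "consider inflating the proposal",
            RuntimeWarning,
        )
    n_pos = int(np.sum(w > 0))
    if n_pos < m_resamples:
        raise ValueError("fewer positive-weight samples than resamples requested")
    idx = rng.choice(m_samples, size=m_resamples, replace=False, p=w)
    return SirStage(
        samples=draws,
        ofv=ofv,
        weights=w,
        resample_idx=idx,
        ess=ess,
        n_zero_weight=n_zero,
    )


def _diag_proposal(center: np.ndarray, rsd: float) -> np.ndarray:
    sd = rsd * np.maximum(np.abs(center), 0.1)
    return np.diag(sd**2)


def sir(
    fit: FitResult,
    data: LongitudinalDataset,
    schedule=DEFAULT_SCHEDULE,
    proposal_rsd: float = 0.3,
    seed: int = 0,
) -> SirResult:
    """Multi-stage SIR uncertainty for a fitted model.

    With no covariance matrix from the fit, the first-stage proposal is
    an independent-normal over-dispersed guess (relative SD
    ``proposal_rsd`` per parameter on the transform scale); later stages
    use the moments of the previous stage's resamples.
    """
    if not fit.converged:
        raise ValueError("fit has not converged")
    evaluator = OfvEvaluator(data, fit.spec)
    transform = fit.transform

    def objective(u: np.ndarray) -> float:
        try:
            return evaluator.ofv(transform.from_vector(u))
        except (ValueError, KeyError):
            return np.inf

    center = transform.to_vector(fit.estimates)
    if fit.covariance is not None:
        cov = np.asarray(fit.covariance, dtype=float)
    else:
        cov = _diag_proposal(center, proposal_rsd)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stages: list[SirStage] = []
    for m_samples, m_resamples in schedule:
        stage = sir_from_objective(objective, center, cov, m_samples, m_resamples, rng)
        stages.append(stage)
        kept = stage.samples[stage.resample_idx]
        center = kept.mean(axis=0)
        cov = np.cov(kept.T) + 1e-10 * np.eye(len(center))
    final_kept = stages[-1].samples[stages[-1].resample_idx]
    natural_rows = [transform.natural(u) for u in final_kept]
    resamples = pd.DataFrame(natural_rows)
    point = fit.natural_estimates()
    summary = _summarize(resamples, point)
    return SirResult(
        stages=stages,
        param_names=list(resamples.columns),
        point=point,
        resamples=resamples,
        summary=summary,
    )


def _summarize(resamples: pd.DataFrame, point: dict[str, float]) -> pd.DataFrame:
    rows = []
    for name in resamples.columns:
        vals = resamples[name].to_numpy()
        est = point.get(name, np.nan)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rse = 100.0 * sd / abs(est) if est != 0 and np.isfinite(est) else np.nan
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "median": float(np.median(vals)),
                "ci_2.5": float(np.percentile(vals, 2.5)),
                "ci_97.5": float(np.percentile(vals, 97.5)),
                "sd": sd,
                "rse_pct": rse,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def rse_table(result: SirResult, fit: FitResult) -> pd.Series:
    """RSE% per parameter: 100 × SD(resamples) / |point estimate|.

    A zero point estimate leaves RSE undefined (NaN).
    """
    point = fit.natural_estimates()
    out = {}
    for name in result.resamples.columns:
        est = point.get(name, np.nan)
        sd = float(np.std(result.resamples[name].to_numpy(), ddof=1))
        out[name] = 100.0 * sd / abs(est) if est != 0 and np.isfinite(est) else np.nan
    return pd.Series(out, name="rse_pct")
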