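"""Visual predictive checks and goodness-of-fit diagnostics.

A VPC simulates many replicate datasets on the observed design (same
subjects, times and covariates), computes observed and replicate
percentiles per time bin, and compares the observed percentile in each
bin against the 95% interval of that percentile across replicates.  The
external-validation VPC is the same computation on a new cohort with the
parameters frozen from the internal fit — nothing is ever refit here.

Percentiles use linear interpolation of order statistics (numpy's
default dialect), fixed so results are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .dataset import LongitudinalDataset
from .estimate import FitResult, _Design, _active_dims
from .model import LINEAR, ModelSpec, ParameterSet

__all__ = [
    "VPCResult",
    "simulate_replicates",
    "vpc",
    "default_bins",
    "gof_tables",
    "plot_vpc",
]


def _design_arrays(data: LongitudinalDataset, spec: ModelSpec):
    subs = data.subjects()
    times = np.concatenate([s.times for s in subs])
    dv = np.concatenate([s.dv for s in subs])
    sizes = [len(s.times) for s in subs]
    return subs, times, dv, sizes


def simulate_replicates(
    data: LongitudinalDataset,
    spec: ModelSpec,
    params: ParameterSet,
    n_rep: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Simulate replicate DV arrays on the observed design.

    Returns an ``(n_rep, n_obs)`` array, rows aligned with the dataset's
    observation rows (sorted by ID, TIME).  Each replicate draws fresh
    etas per subject and residuals per observation; deterministic given
    the seed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    # zero-noise simulation is legitimate here, so no likelihood validation
    subs, _, _, sizes = _design_arrays(data, spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_obs = int(np.sum(sizes))
    out = np.empty((n_rep, n_obs))
    eta_s0 = rng.normal(0.0, np.sqrt(params.omega2_s0), size=(n_rep, len(subs)))
    eta_al = rng.normal(0.0, np.sqrt(params.omega2_alpha), size=(n_rep, len(subs)))
    pos = 0
    for i, s in enumerate(subs):
        k = sizes[i]
        t = s.times
        if spec.structural == LINEAR:
            m = np.ones(k)
            for term in spec.covariates:
                m = m + params.theta[term.name] * (s.covariates[term.name] - term.reference)
            if np.any(m <= 0):
                raise ValueError("covariate multiplier non-positive in dataset")
            s0i = params.s0 * np.exp(eta_s0[:, i])[:, None]
            ai = params.alpha * np.exp(eta_al[:, i])[:, None]
            f = s0i * (1.0 + ai * t[None, :]) * m[None, :]
        else:
            s0i = params.s0 * np.exp(eta_s0[:, i])[:, None]
            f = s0i + params.smax * t[None, :] / (params.s50 + t[None, :])
        dv = f
        if spec.residual in ("proportional", "combined") and params.sigma_prop > 0:
            dv = dv * (1.0 + rng.normal(0.0, params.sigma_prop, size=f.shape))
        if spec.residual in ("additive", "combined") and params.sigma_add > 0:
            dv = dv + rng.normal(0.0, params.sigma_add, size=f.shape)
        out[:, pos : pos + k] = dv
        pos += k
    return out


def default_bins(times: np.ndarray, interval: float = 0.5) -> np.ndarray:
    """Bin edges centered on the scheduled visit grid (half-interval width)."""
    lo = np.floor(np.min(times) / interval) * interval
    hi = np.ceil(np.max(times) / interval) * interval
    return np.arange(lo - interval / 2.0, hi + interval, interval)


@dataclass
class VPCResult:
    """Binned percentile comparison of observed vs simulated data."""

    table: pd.DataFrame   # bin_left, bin_right, level, n, observed, band_lo, band_hi, inside
    levels: tuple[float, ...]
    n_replicates: int
    bins: np.ndarray

    @property
    def fraction_inside(self) -> float:
        return float(self.table["inside"].mean())


def vpc(
    data: LongitudinalDataset,
    spec: ModelSpec,
    params: ParameterSet,
    n_rep: int = 1000,
    levels: tuple[float, ...] = (5.0, 50.0, 95.0),
    bins: np.ndarray | None = None,
    seed: int = 0,
) -> VPCResult:
    """Visual predictive check on the observed design.

    The band for each (bin, level) cell is the 2.5–97.5 percentile range
    of the replicate percentiles; ``inside`` flags observed percentiles
    within their band.  Empty bins are dropped with a warning-free skip.
    """
    levels = tuple(sorted(float(l) for l in levels))
    _, times, dv, _ = _design_arrays(data, spec)
    if bins is None:
        bins = default_bins(times)
    bins = np.asarray(bins, dtype=float)
    reps = simulate_replicates(data, spec, params, n_rep=n_rep, seed=seed)
    rows = []
    for b in range(len(bins) - 1):
        left, right = bins[b], bins[b + 1]
        sel = (times >= left) & (times < right)
        if b == len(bins) - 2:
            sel = (times >= left) & (times <= right)
        if not np.any(sel):
            continue
        obs_p = np.percentile(dv[sel], levels)
        rep_p = np.percentile(reps[:, sel], levels, axis=1)  # (n_levels, n_rep)
        lo = np.percentile(rep_p, 2.5, axis=1)
        hi = np.percentile(rep_p, 97.5, axis=1)
        for li, lev in enumerate(levels):
            rows.append(
                {
                    "bin_left": left,
                    "bin_right": right,
                    "level": lev,
                    "n": int(sel.sum()),
                    "observed": obs_p[li],
                    "band_lo": lo[li],
                    "band_hi": hi[li],
                    "inside": bool(lo[li] <= obs_p[li] <= hi[li]),
                }
            )
    return VPCResult(
        table=pd.DataFrame(rows), levels=levels, n_replicates=n_rep, bins=bins
    )


def gof_tables(fit: FitResult, data: LongitudinalDataset) -> pd.DataFrame:
    """Per-observation goodness-of-fit records.

    PRED: population prediction (etas 0); IPRED: prediction at the EBEs;
    IWRES = (DV − IPRED)/sqrt(V(IPRED)); CWRES: FOCE-linearized marginal
    residuals decorrelated by the Cholesky factor of each subject's
    linearized covariance (≈ iid N(0,1) under the model).
    """
    if not fit.converged:
        raise ValueError("fit has not converged")
    spec, params = fit.spec, fit.estimates
    design = _Design(data, spec)
    dims = _active_dims(spec, params)
    m = design.multiplier(params.theta)
    S = design.S
    eta_full = np.zeros((S, 2))
    for i, sid in enumerate(design.ids):
        eb = fit.ebes.get(sid)
        if eb is not None:
            eta_full[i] = (eb.eta_s0, eb.eta_alpha)
    pred0, _ = design.predict(params, np.zeros((S, 2)), m, [])
    ipred, G = design.predict(params, eta_full, m, dims)
    V = design.resvar(params, ipred)
    if np.any(V[design.mask] <= 0):
        raise ValueError("zero residual variance")
    iwres = np.where(design.mask, (design.Y - ipred) / np.sqrt(V), np.nan)

    omega = np.array([params.omega2_s0, params.omega2_alpha])[dims] if dims else None
    rows = []
    for i, sid in enumerate(design.ids):
        k = design.nobs[i]
        y = design.Y[i, :k]
        t = design.T[i, :k]
        if dims:
            Gi = G[i, :k, :]
            r = y - ipred[i, :k] + Gi @ eta_full[i, dims]
            C = Gi @ np.diag(omega) @ Gi.T + np.diag(V[i, :k])
            L = sla.cholesky(C, lower=True)
            cwres = sla.solve_triangular(L, r, lower=True)
        else:
            cwres = (y - pred0[i, :k]) / np.sqrt(V[i, :k])
        for j in range(k):
            rows.append(
                {
                    "ID": sid,
                    "TIME": t[j],
                    "DV": y[j],
                    "PRED": pred0[i, j],
                    "IPRED": ipred[i, j],
                    "IWRES": iwres[i, j],
                    "CWRES": cwres[j],
                }
            )
    return pd.DataFrame(rows)


def plot_vpc(result: VPCResult, path=None, title: str = "Visual predictive check"):
    """Convenience plot: observed percentile lines over simulated bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    centers = (result.table["bin_left"] + result.table["bin_right"]) / 2.0
    for lev in result.levels:
        sub = result.table[result.table["level"] == lev]
        c = (sub["bin_left"] + sub["bin_right"]) / 2.0
        ax.fill_between(c, sub["band_lo"], sub["band_hi"], alpha=0.3, color="gray")
        ax.plot(c, sub["observed"], marker="o", label=f"observed p{lev:g}")
    ax.set_xlabel("years since T2DM diagnosis")
    ax.set_ylabel("eGFR (mL/min/1.73 m$^2$)")
    ax.set_title(title)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
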