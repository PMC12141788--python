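"""Approximate marginal likelihood (FOCE-I) estimation for the eGFR models.

The objective function value (OFV) is −2× the approximate log marginal
likelihood, with the additive constant ``N log(2π)`` EXCLUDED (the common
NONMEM convention); only OFV differences between models on the same data
are meaningful across implementations.  Pass ``include_constant=True`` to
add the constant back (used to show ΔOFV does not depend on it).

Per subject *i*, FOCE with interaction linearizes the model around the
subject's conditional mode (MAP) etas ``eta_hat``:

    f(eta) ≈ f(eta_hat) + G (eta − eta_hat),      G = df/deta |_{eta_hat}

with the residual variance evaluated at the *individual* prediction
(the "interaction" part).  The approximate marginal distribution of the
data is Gaussian with covariance ``C = G Ω Gᵀ + diag(V)`` and residual
``r = y − f(eta_hat) + G eta_hat``, giving

    OFV_i = log|C| + rᵀ C⁻¹ r.

``quadrature_ofv`` evaluates the exact marginal likelihood by adaptive
Gauss–Hermite quadrature over the random effects and serves as the
independent oracle for the FOCE approximation on small instances.

All subjects are evaluated simultaneously on padded rectangular arrays;
the inner MAP step is a damped Newton iteration with a Gauss–Newton
Hessian (closed-form 1×1/2×2 solves), warm-started across outer
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import LongitudinalDataset
from .model import (
    ADDITIVE,
    COMBINED,
    EMAX,
    LINEAR,
    PROPORTIONAL,
    ModelSpec,
    ParameterSet,
    SubjectEffects,
)

__all__ = [
    "FitResult",
    "OfvEvaluator",
    "ParamTransform",
    "marginal_ofv",
    "quadrature_ofv",
    "map_etas",
    "fit_model",
    "default_inits",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_INNER_TOL = 1e-8
_PENALTY = 1e12


def _active_dims(spec: ModelSpec, params: ParameterSet) -> list[int]:
    """Random-effect dimensions with non-zero variance (0 = baseline, 1 = rate)."""
    dims = []
    if params.omega2_s0 > 0:
        dims.append(0)
    if spec.structural == LINEAR and params.omega2_alpha > 0:
        dims.append(1)
    return dims


class _Design:
    """Padded (n_subjects × max_obs) design arrays for one dataset + spec."""

    def __init__(self, data: LongitudinalDataset, spec: ModelSpec):
        subs = data.subjects()
        if not subs:
            raise ValueError("empty dataset")
        for s in subs:
            if len(s.times) == 0:
                raise ValueError(f"subject {s.id} has no observations")
        self.spec = spec
        self.ids = [s.id for s in subs]
        S = len(subs)
        J = max(len(s.times) for s in subs)
        self.S, self.J = S, J
        self.T = np.zeros((S, J))
        self.Y = np.zeros((S, J))
        self.mask = np.zeros((S, J), dtype=bool)
        self.nobs = np.array([len(s.times) for s in subs])
        for i, s in enumerate(subs):
            k = len(s.times)
            self.T[i, :k] = s.times
            self.Y[i, :k] = s.dv
            self.mask[i, :k] = True
        self.cov: dict[str, np.ndarray] = {}
        for term in spec.covariates:
            arr = np.zeros((S, J))
            for i, s in enumerate(subs):
                if term.name not in s.covariates:
                    raise KeyError(f"no value for covariate {term.name!r}")
                arr[i, : len(s.times)] = s.covariates[term.name]
            self.cov[term.name] = arr
        self.n_total = int(self.mask.sum())

    def multiplier(self, theta) -> np.ndarray:
        m = np.ones((self.S, self.J))
        for term in self.spec.covariates:
            if term.name not in theta:
                raise KeyError(f"no coefficient for covariate {term.name!r}")
            m = m + theta[term.name] * (self.cov[term.name] - term.reference)
        if np.any(m[self.mask] <= 0.0):
            raise ValueError("covariate multiplier non-positive in dataset")
        m[~self.mask] = 1.0
        return m

    # -- model evaluation ---------------------------------------------
    def predict(self, params: ParameterSet, eta_full: np.ndarray, m: np.ndarray, dims):
        """Predictions F (S,J) and derivatives dF/deta for active dims (S,J,d)."""
        if self.spec.structural == LINEAR:
            s0i = params.s0 * np.exp(eta_full[:, 0])[:, None]
            ai = params.alpha * np.exp(eta_full[:, 1])[:, None]
            F = s0i * (1.0 + ai * self.T) * m
            grads = {0: F, 1: s0i * ai * self.T * m}
        else:
            s0i = params.s0 * np.exp(eta_full[:, 0])[:, None]
            F = s0i + params.smax * self.T / (params.s50 + self.T)
            grads = {0: np.broadcast_to(s0i, F.shape), 1: np.zeros_like(F)}
        if dims:
            G = np.stack([grads[k] for k in dims], axis=2)
            G = np.where(self.mask[:, :, None], G, 0.0)
        else:
            G = np.zeros((self.S, self.J, 0))
        return F, G

    def resvar(self, params: ParameterSet, F: np.ndarray) -> np.ndarray:
        spec = self.spec
        if spec.residual == ADDITIVE:
            V = np.full_like(F, params.sigma_add**2)
        elif spec.residual == PROPORTIONAL:
            V = (F * params.sigma_prop) ** 2
        else:
            V = params.sigma_add**2 + (F * params.sigma_prop) ** 2
        V = np.where(self.mask, V, 1.0)
        if np.any(V[self.mask] <= 0.0):
            raise ValueError("degenerate residual variance")
        return V

    def dresvar(self, params: ParameterSet, F: np.ndarray) -> np.ndarray:
        """dV/dF (zero for the additive model)."""
        if self.spec.residual == ADDITIVE:
            return np.zeros_like(F)
        return 2.0 * F * params.sigma_prop**2


def _inner_objective(design: _Design, params, m, dims, omega_act, eta_act):
    """−2 log joint density of (data, eta), without 2π/log-omega constants."""
    eta_full = np.zeros((design.S, 2))
    if dims:
        eta_full[:, dims] = eta_act
    F, G = design.predict(params, eta_full, m, dims)
    V = design.resvar(params, F)
    r = np.where(design.mask, design.Y - F, 0.0)
    q = np.sum(r * r / V + np.where(design.mask, np.log(V), 0.0), axis=1)
    if dims:
        q = q + np.sum(eta_act**2 / omega_act, axis=1)
    return q, F, G, V, r


def _solve_posdef_small(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve H x = g per subject for d in {1, 2} with a ridge fallback."""
    d = H.shape[-1]
    if d == 1:
        return g / np.maximum(H[:, :, 0], 1e-12)
    a, b, c = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
    det = a * c - b * b
    bad = det <= 1e-12 * np.maximum(a * c, 1e-300)
    if np.any(bad):
        ridge = 1e-8 * (a + c) + 1e-12
        a = np.where(bad, a + ridge, a)
        c = np.where(bad, c + ridge, c)
        det = a * c - b * b
    x = np.empty_like(g)
    x[:, 0] = (c * g[:, 0] - b * g[:, 1]) / det
    x[:, 1] = (a * g[:, 1] - b * g[:, 0]) / det
    return x


def _map_etas_vec(design: _Design, params: ParameterSet, m, dims, eta0_act,
                  max_iter: int = 100):
    """Vectorized damped Gauss–Newton search for the conditional modes.

    Deterministic multi-start rule: evaluate the warm start and the zero
    start, begin from whichever has the lower objective per subject.
    """
    S = design.S
    d = len(dims)
    if d == 0:
        q, *_ = _inner_objective(design, params, m, dims, None, None)
        return np.zeros((S, 0)), q, np.zeros(S, dtype=bool)
    omega_act = np.array([params.omega2_s0, params.omega2_alpha])[dims]

    q_warm, *_ = _inner_objective(design, params, m, dims, omega_act, eta0_act)
    zeros = np.zeros_like(eta0_act)
    q_zero, *_ = _inner_objective(design, params, m, dims, omega_act, zeros)
    eta = np.where((q_warm <= q_zero)[:, None], eta0_act, zeros)
    q = np.minimum(q_warm, q_zero)

    stalled = np.zeros(S, dtype=bool)
    not_conv = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        _, F, G, V, r = _inner_objective(design, params, m, dims, omega_act, eta)
        Vf = design.dresvar(params, F)
        w = np.where(design.mask, -2.0 * r / V + (Vf / V) * (1.0 - r * r / V), 0.0)
        grad = np.einsum("sj,sjk->sk", w, G) + 2.0 * eta / omega_act
        gnorm = np.max(np.abs(grad), axis=1)
        not_conv = gnorm > _INNER_TOL * (1.0 + np.abs(q))
        active = not_conv & ~stalled
        if not np.any(active):
            break
        Gw = G / V[:, :, None]
        H = 2.0 * np.einsum("sjk,sjl->skl", Gw, G)
        H[:, np.arange(d), np.arange(d)] += 2.0 / omega_act
        step = _solve_posdef_small(H, grad)
        # backtracking line search per active subject (Armijo); a subject
        # whose search exhausts is stalled: keep its best iterate, flag it
        slope = np.sum(grad * step, axis=1)
        s = np.where(active, 1.0, 0.0)
        improved = np.zeros(S, dtype=bool)
        for _ls in range(25):
            cand = eta - s[:, None] * step
            q_cand, *_ = _inner_objective(design, params, m, dims, omega_act, cand)
            ok = q_cand <= q - 1e-4 * s * slope
            newly = active & ~improved & ok
            eta = np.where(newly[:, None], cand, eta)
            q = np.where(newly, q_cand, q)
            improved |= newly
            remaining = active & ~improved
            if not np.any(remaining):
                break
            s = np.where(remaining, s * 0.5, s)
        stalled |= active & ~improved
    return eta, q, not_conv


def _foce_ofv_from_design(design: _Design, params: ParameterSet, eta0_act=None):
    """FOCE-I OFV plus the conditional modes used (for warm starting)."""
    params.validate_for(design.spec)
    dims = _active_dims(design.spec, params)
    d = len(dims)
    m = design.multiplier(params.theta)
    if eta0_act is None or eta0_act.shape != (design.S, d):
        eta0_act = np.zeros((design.S, d))
    eta, q, not_conv = _map_etas_vec(design, params, m, dims, eta0_act)
    if d == 0:
        return float(np.sum(q)), eta, not_conv
    omega_act = np.array([params.omega2_s0, params.omega2_alpha])[dims]
    _, F, G, V, _ = _inner_objective(design, params, m, dims, omega_act, eta)
    r = np.where(design.mask, design.Y - F, 0.0) + np.einsum("sjk,sk->sj", G, eta)
    r = np.where(design.mask, r, 0.0)
    Gv = G / V[:, :, None]
    A = np.einsum("sjk,sjl->skl", Gv, G)            # Gᵀ D⁻¹ G
    A[:, np.arange(d), np.arange(d)] += 1.0 / omega_act
    u = np.einsum("sjk,sj->sk", Gv, r)              # Gᵀ D⁻¹ r
    if d == 1:
        logdetA = np.log(A[:, 0, 0])
        quad_corr = u[:, 0] ** 2 / A[:, 0, 0]
    else:
        detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
        logdetA = np.log(detA)
        x = _solve_posdef_small(A, u)
        quad_corr = np.sum(u * x, axis=1)
    logdetC = (
        np.sum(np.where(design.mask, np.log(V), 0.0), axis=1)
        + np.sum(np.log(omega_act))
        + logdetA
    )
    quad = np.sum(r * r / V, axis=1) - quad_corr
    return float(np.sum(logdetC + quad)), eta, not_conv


class OfvEvaluator:
    """Reusable FOCE-I objective for one (dataset, spec) pair.

    Keeps the padded design and a warm-start cache of conditional modes
    across calls, which is what makes repeated evaluation (outer
    optimization, SIR sampling) fast.
    """

    def __init__(self, data: LongitudinalDataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.design = _Design(data, spec)
        self._eta_cache: np.ndarray | None = None
        self.last_not_converged = 0

    def ofv(self, params: ParameterSet, include_constant: bool = False) -> float:
        ofv, eta, not_conv = _foce_ofv_from_design(self.design, params, self._eta_cache)
        self._eta_cache = eta
        self.last_not_converged = int(np.sum(not_conv))
        if include_constant:
            ofv += self.design.n_total * _LOG2PI
        return ofv

    def ebes(self, params: ParameterSet) -> dict:
        """Empirical Bayes estimates (conditional modes) per subject id."""
        dims = _active_dims(self.spec, params)
        m = self.design.multiplier(params.theta)
        eta0 = self._eta_cache
        if eta0 is None or eta0.shape != (self.design.S, len(dims)):
            eta0 = np.zeros((self.design.S, len(dims)))
        eta, _, _ = _map_etas_vec(self.design, params, m, dims, eta0)
        full = np.zeros((self.design.S, 2))
        if dims:
            full[:, dims] = eta
        return {
            sid: SubjectEffects(float(full[i, 0]), float(full[i, 1]))
            for i, sid in enumerate(self.design.ids)
        }


def marginal_ofv(
    data: LongitudinalDataset,
    spec: ModelSpec,
    params: ParameterSet,
    include_constant: bool = False,
) -> float:
    """FOCE-I objective function value for the whole dataset."""
    return OfvEvaluator(data, spec).ofv(params, include_constant=include_constant)


def map_etas(data: LongitudinalDataset, spec: ModelSpec, params: ParameterSet) -> dict:
    """Conditional-mode (MAP) etas per subject id."""
    return OfvEvaluator(data, spec).ebes(params)


def quadrature_ofv(
    data: LongitudinalDataset,
    spec: ModelSpec,
    params: ParameterSet,
    nodes: int = 15,
    include_constant: bool = False,
    max_subjects: int = 20,
) -> float:
    """Exact −2 log marginal likelihood by adaptive Gauss–Hermite quadrature.

    Test oracle for :func:`marginal_ofv`; same additive-constant
    convention.  Cost grows as ``nodes**d`` per subject, so the number of
    subjects is guarded.
    """
    if data.n_subjects > max_subjects:
        raise ValueError(
            f"quadrature oracle limited to {max_subjects} subjects; "
            "evaluate on a subset"
        )
    if nodes < 5:
        raise ValueError("need at least 5 quadrature nodes")
    params.validate_for(spec)
    design = _Design(data, spec)
    dims = _active_dims(spec, params)
    d = len(dims)
    m = design.multiplier(params.theta)
    if d == 0:
        q, *_ = _inner_objective(design, params, m, dims, None, None)
        ofv = float(np.sum(q))
        return ofv + design.n_total * _LOG2PI if include_constant else ofv

    omega_act = np.array([params.omega2_s0, params.omega2_alpha])[dims]
    eta_hat, _, _ = _map_etas_vec(design, params, m, dims, np.zeros((design.S, d)))

    def qfun(eta_act):
        q, *_ = _inner_objective(design, params, m, dims, omega_act, eta_act)
        return q

    # numeric Hessian of 0.5*q at the mode (central differences)
    h = 1e-4
    H = np.empty((design.S, d, d))
    q0 = qfun(eta_hat)
    for a in range(d):
        ea = np.zeros((1, d))
        ea[0, a] = h
        H[:, a, a] = (qfun(eta_hat + ea) - 2 * q0 + qfun(eta_hat - ea)) / h**2
        for b in range(a + 1, d):
            eb = np.zeros((1, d))
            eb[0, b] = h
            mixed = (
                qfun(eta_hat + ea + eb)
                - qfun(eta_hat + ea - eb)
                - qfun(eta_hat - ea + eb)
                + qfun(eta_hat - ea - eb)
            ) / (4 * h**2)
            H[:, a, b] = H[:, b, a] = mixed
    Hn = 0.5 * H  # Hessian of −log joint
    # per-subject Cholesky of Hn⁻¹ (d ≤ 2, explicit)
    if d == 1:
        L = 1.0 / np.sqrt(np.maximum(Hn[:, 0, 0], 1e-12))[:, None, None]
        logdetL = np.log(L[:, 0, 0])
    else:
        Sigma = np.linalg.inv(Hn)
        L = np.linalg.cholesky(Sigma)
        logdetL = np.log(L[:, 0, 0] * L[:, 1, 1])

    x, w = np.polynomial.hermite.hermgauss(nodes)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=1)          # (n_nodes, d)
    logw = np.sum(
        np.stack(np.meshgrid(*([np.log(w)] * d), indexing="ij"), axis=-1).reshape(-1, d),
        axis=1,
    )
    const_prior = 0.5 * np.sum(np.log(omega_act) + _LOG2PI)
    terms = np.empty((design.S, Z.shape[0]))
    for j in range(Z.shape[0]):
        z = Z[j]
        eta = eta_hat + np.sqrt(2.0) * np.einsum("sab,b->sa", L, z)
        ll = -0.5 * qfun(eta) - 0.5 * design.nobs * _LOG2PI - const_prior
        terms[:, j] = ll + np.sum(z * z) + logw[j]
    tmax = terms.max(axis=1)
    logL = (
        tmax
        + np.log(np.sum(np.exp(terms - tmax[:, None]), axis=1))
        + 0.5 * d * np.log(2.0)
        + logdetL
    )
    ofv = float(np.sum(-2.0 * logL - design.nobs * _LOG2PI))
    return ofv + design.n_total * _LOG2PI if include_constant else ofv


# ---------------------------------------------------------------------
# parameter transform and fitting
# ---------------------------------------------------------------------

_LOG_LOWER = np.log(1e-8)


@dataclass
class _Entry:
    key: str       # ParameterSet field, or covariate name for thetas
    kind: str      # "scaled" | "log"
    scale: float = 1.0
    lower: float | None = None
    upper: float | None = None
    is_theta: bool = False


class ParamTransform:
    """Maps between a ParameterSet and the unconstrained outer vector.

    SDs and variances are optimized on the log scale; structural
    parameters on a scaled identity (scale = initial magnitude) so the
    outer vector is O(1) in every coordinate.  A variance initialized at
    exactly zero is treated as structurally absent and not estimated.
    """

    def __init__(self, spec: ModelSpec, inits: ParameterSet):
        self.spec = spec
        self.template = inits
        e: list[_Entry] = []
        e.append(_Entry("s0", "scaled", scale=abs(inits.s0), lower=1e-3))
        if spec.structural == LINEAR:
            e.append(_Entry("alpha", "scaled", scale=max(abs(inits.alpha), 1e-3)))
            for term in spec.covariates:
                e.append(_Entry(term.name, "scaled", scale=0.05, is_theta=True))
        else:
            e.append(_Entry("smax", "scaled", scale=max(abs(inits.smax), 1.0)))
            e.append(_Entry("s50", "log"))
        if inits.omega2_s0 > 0:
            e.append(_Entry("omega2_s0", "log", lower=_LOG_LOWER, upper=np.log(1e4)))
        if spec.structural == LINEAR and inits.omega2_alpha > 0:
            e.append(_Entry("omega2_alpha", "log", lower=_LOG_LOWER, upper=np.log(1e4)))
        if spec.residual in (ADDITIVE, COMBINED):
            e.append(_Entry("sigma_add", "log"))
        if spec.residual in (PROPORTIONAL, COMBINED):
            e.append(_Entry("sigma_prop", "log"))
        self.entries = e

    @property
    def names(self) -> list[str]:
        return [
            ("theta_" + en.key) if en.is_theta else en.key for en in self.entries
        ]

    def to_vector(self, params: ParameterSet) -> np.ndarray:
        u = np.empty(len(self.entries))
        for i, en in enumerate(self.entries):
            val = params.theta.get(en.key, 0.0) if en.is_theta else getattr(params, en.key)
            u[i] = np.log(val) if en.kind == "log" else val / en.scale
        return u

    def from_vector(self, u) -> ParameterSet:
        changes: dict = {}
        theta = dict(self.template.theta)
        for en, ui in zip(self.entries, u):
            val = float(np.exp(ui)) if en.kind == "log" else float(ui) * en.scale
            if en.is_theta:
                theta[en.key] = val
            else:
                changes[en.key] = val
        changes["theta"] = theta
        return self.template.replace(**changes)

    def natural(self, u) -> dict[str, float]:
        """Reporting-scale values: variances as SDs (omega), sigmas as SDs."""
        params = self.from_vector(u)
        out: dict[str, float] = {}
        for en in self.entries:
            if en.is_theta:
                out["theta_" + en.key] = params.theta[en.key]
            elif en.key == "omega2_s0":
                out["omega_s0"] = float(np.sqrt(params.omega2_s0))
            elif en.key == "omega2_alpha":
                out["omega_alpha"] = float(np.sqrt(params.omega2_alpha))
            else:
                out[en.key] = float(getattr(params, en.key))
        return out

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [(en.lower, en.upper) for en in self.entries]


@dataclass
class FitResult:
    """Output of :func:`fit_model`; input to selection, VPC and SIR."""

    spec: ModelSpec
    estimates: ParameterSet
    ofv: float
    ebes: dict
    converged: bool
    n_subjects: int
    n_obs: int
    n_params: int
    param_names: list[str]
    transform: ParamTransform
    message: str = ""
    inits: ParameterSet | None = None
    covariance: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_params

    def natural_estimates(self) -> dict[str, float]:
        return self.transform.natural(self.transform.to_vector(self.estimates))

    def summary(self) -> str:
        lines = [
            f"structural={self.spec.structural} residual={self.spec.residual}",
            f"OFV={self.ofv:.4f}  AIC={self.aic:.4f}  converged={self.converged}",
            f"subjects={self.n_subjects}  observations={self.n_obs}",
        ]
        for k, v in self.natural_estimates().items():
            lines.append(f"  {k:>14s} = {v:.6g}")
        return "\n".join(lines)


def default_inits(data: LongitudinalDataset, spec: ModelSpec) -> ParameterSet:
    """Scale-free data-driven initial estimates.

    Baseline from the mean of each subject's earliest observation; rate
    from the pooled OLS slope expressed as a fraction of baseline;
    residual SD from the pooled OLS residuals; baseline BSV from the
    moment estimate Var(log first observation); rate BSV at 0.1.
    """
    subs = data.subjects()
    first = np.array([s.dv[0] for s in subs])
    s0 = float(np.mean(first))
    omega2_s0_init = 0.1
    if len(first) >= 5 and np.all(first > 0):
        omega2_s0_init = float(np.clip(np.var(np.log(first)), 0.01, 1.0))
    theta0 = {term.name: 0.0 for term in spec.covariates}
    if spec.covariates and len(first) >= 5 and np.all(first > 0):
        # regression of log baseline on centered covariates: a fractional
        # covariate effect is (to first order) a log-scale coefficient,
        # which puts the optimizer near the (s0, theta) valley floor
        Xc = np.column_stack(
            [np.ones(len(subs))]
            + [
                np.array([s.covariates[t.name][0] - t.reference for s in subs])
                for t in spec.covariates
            ]
        )
        coef, *_ = np.linalg.lstsq(Xc, np.log(first), rcond=None)
        s0 = float(np.exp(coef[0]))
        theta0 = {
            t.name: float(np.clip(coef[1 + i], -0.5, 0.5))
            for i, t in enumerate(spec.covariates)
        }
        design = _Design(data, spec)
        for _ in range(10):  # shrink until the multiplier is valid everywhere
            try:
                design.multiplier(theta0)
                break
            except ValueError:
                theta0 = {k: v / 2.0 for k, v in theta0.items()}
    t = np.concatenate([s.times for s in subs])
    y = np.concatenate([s.dv for s in subs])
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_sd = float(np.std(y - X @ beta))
    alpha = float(beta[1] / s0)
    kw: dict = {}
    if spec.structural == EMAX:
        tmax = float(np.max(t)) if np.max(t) > 0 else 1.0
        kw.update(smax=float(beta[1]) * tmax, s50=tmax / 2.0, alpha=0.0)
    else:
        kw.update(alpha=alpha)
    if spec.residual in (ADDITIVE, COMBINED):
        kw["sigma_add"] = max(resid_sd, 1e-3)
    if spec.residual in (PROPORTIONAL, COMBINED):
        kw["sigma_prop"] = max(resid_sd / s0, 1e-4)
    return ParameterSet(
        s0=s0,
        theta=theta0,
        omega2_s0=omega2_s0_init,
        omega2_alpha=0.1 if spec.structural == LINEAR else 0.0,
        **kw,
    )


def fit_model(
    data: LongitudinalDataset,
    spec: ModelSpec,
    inits: ParameterSet | None = None,
    *,
    maxiter: int = 500,
    gtol: float = 1e-6,
    n_starts: int = 1,
    seed: int = 0,
    polish: int = 3,
) -> FitResult:
    """Minimize the FOCE-I OFV over fixed effects and variance parameters."""
    if inits is None:
        inits = default_inits(data, spec)
    inits.validate_for(spec)
    transform = ParamTransform(spec, inits)
    evaluator = OfvEvaluator(data, spec)

    def objective(u: np.ndarray) -> float:
        try:
            params = transform.from_vector(u)
            val = evaluator.ofv(params)
        except (ValueError, KeyError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(val):
            return _PENALTY
        return val

    x0 = transform.to_vector(inits)
    starts = [x0]
    # the rate-BSV direction is prone to local optima: add a deterministic
    # second start at a large rate variance whenever it is estimated
    if "omega2_alpha" in transform.names and inits.omega2_alpha < 0.5:
        alt = inits.replace(omega2_alpha=1.0)
        starts.append(transform.to_vector(alt))
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [x0 + rng.normal(0.0, 0.1, size=x0.shape) for _ in range(n_starts - 1)]

    opts = {"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol, "eps": 1e-6}
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x_start in starts:
            res = optimize.minimize(
                objective, x_start, method="L-BFGS-B",
                bounds=transform.bounds(), options=opts,
            )
            if best is None or res.fun < best.fun:
                best = res
        # restart-polish the winner: resetting the Hessian approximation
        # escapes premature termination on this ridge-shaped surface
        for _ in range(polish):
            res2 = optimize.minimize(
                objective, best.x, method="L-BFGS-B",
                bounds=transform.bounds(), options=opts,
            )
            improved = best.fun - res2.fun
            if res2.fun <= best.fun:
                best = res2
            if improved < 0.01:
                break

    estimates = transform.from_vector(best.x)
    ofv = evaluator.ofv(estimates)
    ebes = evaluator.ebes(estimates)
    boundary = estimates.omega2_s0 <= 1.5e-8 or (
        spec.structural == LINEAR
        and inits.omega2_alpha > 0
        and estimates.omega2_alpha <= 1.5e-8
    )
    message = str(best.message)
    if boundary:
        message += " [variance at lower boundary]"
    return FitResult(
        spec=spec,
        estimates=estimates,
        ofv=float(ofv),
        ebes=ebes,
        converged=bool(best.success) and ofv < _PENALTY / 2,
        n_subjects=data.n_subjects,
        n_obs=data.n_obs,
        n_params=len(best.x),
        param_names=transform.names,
        transform=transform,
        message=message,
        inits=inits,
    )
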