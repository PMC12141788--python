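"""Structural disease-progression models for longitudinal eGFR.

Disease status :math:`S(t)` is the estimated glomerular filtration rate
(mL/min/1.73 m^2) as a function of time since T2DM diagnosis (years).
Two structural forms are supported:

* ``linear`` — :math:`S(t) = S_0 (1 + \\alpha t) \\cdot M(x)`, where
  :math:`\\alpha` is a fractional rate of change per year (negative for
  decline) and :math:`M(x) = 1 + \\sum_k \\theta_k (x_k - x_k^{ref})` is a
  multiplicative covariate factor over centered covariates.
* ``emax`` — :math:`S(t) = S_0 + S_{max}\\, t / (S_{50} + t)`, the
  hyperbolic recovery/decline-in-time form (``Smax`` is the maximum change,
  ``S50`` the time at half-maximal change).

Between-subject variability is exponential (log-normal) on baseline and
rate: :math:`S_{0,i} = S_0 e^{\\eta_{S0,i}}`,
:math:`\\alpha_i = \\alpha e^{\\eta_{\\alpha,i}}` — sign-preserving, with
the typical value equal to the subject-level median.  Residual error is
additive, proportional, or combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "LINEAR",
    "EMAX",
    "ADDITIVE",
    "PROPORTIONAL",
    "COMBINED",
    "CovariateTerm",
    "ModelSpec",
    "ParameterSet",
    "SubjectEffects",
    "covariate_multiplier",
    "structural_predict",
    "residual_variance",
]

LINEAR = "linear"
EMAX = "emax"
ADDITIVE = "additive"
PROPORTIONAL = "proportional"
COMBINED = "combined"

_STRUCTURALS = (LINEAR, EMAX)
_RESIDUALS = (ADDITIVE, PROPORTIONAL, COMBINED)


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate entering the multiplicative covariate factor.

    ``reference`` is subtracted before multiplication by the coefficient;
    binary flags use 0 (so carriers get the full effect), continuous
    covariates use a clinical centering value (7.4 mmol/L for FBS).
    """

    name: str
    kind: str = "binary"  # "binary" | "continuous"
    reference: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: structural form + residual form + covariate set."""

    structural: str = LINEAR
    residual: str = ADDITIVE
    covariates: tuple[CovariateTerm, ...] = ()

    def __post_init__(self) -> None:
        if self.structural not in _STRUCTURALS:
            raise ValueError(f"unknown structural form {self.structural!r}")
        if self.residual not in _RESIDUALS:
            raise ValueError(f"unknown residual form {self.residual!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [t.name for t in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        if self.structural == EMAX and self.covariates:
            raise ValueError("covariate terms apply to the linear form only")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.covariates)

    def with_covariate(self, term: CovariateTerm) -> "ModelSpec":
        if term.name in self.covariate_names:
            raise ValueError(f"covariate {term.name!r} already in the model")
        return replace(self, covariates=self.covariates + (term,))

    def without_covariate(self, name: str) -> "ModelSpec":
        if name not in self.covariate_names:
            raise ValueError(f"covariate {name!r} not in the model")
        return replace(
            self, covariates=tuple(t for t in self.covariates if t.name != name)
        )


@dataclass(frozen=True)
class ParameterSet:
    """One point in parameter space.

    Fixed effects (``s0``, ``alpha``, ``theta``, and for the Emax form
    ``smax``/``s50``), between-subject variances on the log scale
    (``omega2_s0``, ``omega2_alpha``), and residual error SDs
    (``sigma_add`` in eGFR units, ``sigma_prop`` as a fraction).
    BSV is conventionally reported as ``100*sqrt(omega2)`` percent.
    """

    s0: float
    alpha: float = 0.0
    theta: Mapping[str, float] = field(default_factory=dict)
    smax: float = 0.0
    s50: float = 1.0
    omega2_s0: float = 0.0
    omega2_alpha: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", dict(self.theta))
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")
        for name in ("omega2_s0", "omega2_alpha", "sigma_add", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def validate_for(self, spec: ModelSpec) -> None:
        """Check this parameter set can evaluate a likelihood under *spec*."""
        for term in spec.covariates:
            if term.name not in self.theta:
                raise ValueError(f"missing coefficient for covariate {term.name!r}")
        if spec.structural == EMAX and not self.s50 > 0:
            raise ValueError("s50 must be positive for the Emax form")
        if spec.residual == ADDITIVE and self.sigma_add <= 0:
            raise ValueError("additive residual requires sigma_add > 0")
        if spec.residual == PROPORTIONAL and self.sigma_prop <= 0:
            raise ValueError("proportional residual requires sigma_prop > 0")
        if spec.residual == COMBINED and self.sigma_add <= 0 and self.sigma_prop <= 0:
            raise ValueError("combined residual requires a positive sigma")

    def bsv_percent(self, which: str = "s0") -> float:
        """BSV reported on the conventional 100*sqrt(omega^2) % scale."""
        omega2 = self.omega2_s0 if which == "s0" else self.omega2_alpha
        return 100.0 * float(np.sqrt(omega2))

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


@dataclass(frozen=True)
class SubjectEffects:
    """Subject-level random effects on the log scale (eta)."""

    eta_s0: float = 0.0
    eta_alpha: float = 0.0


ZERO_EFFECTS = SubjectEffects(0.0, 0.0)


def covariate_multiplier(
    terms,
    theta: Mapping[str, float],
    covariates: Mapping[str, object],
):
    """Multiplicative covariate factor ``1 + sum_k theta_k * (x_k - ref_k)``.

    Accepts scalar or array covariate values (broadcast together).  An
    empty term list returns exactly 1.  A non-positive result is rejected:
    the prediction would flip sign, which is physiologically meaningless.
    """
    m = np.asarray(1.0)
    for term in terms:
        if term.name not in theta:
            raise KeyError(f"no coefficient for covariate {term.name!r}")
        if term.name not in covariates:
            raise KeyError(f"no value for covariate {term.name!r}")
        x = np.asarray(covariates[term.name], dtype=float)
        m = m + theta[term.name] * (x - term.reference)
    if np.any(np.asarray(m) <= 0.0):
        raise ValueError(
            "covariate multiplier is non-positive (prediction would change "
            "sign); check coefficients and covariate ranges"
        )
    return m


def structural_predict(
    spec: ModelSpec,
    params: ParameterSet,
    effects: SubjectEffects,
    covariates: Mapping[str, object],
    t,
):
    """Individual structural prediction at time(s) *t* (years).

    The population prediction is the same call with both etas zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    s0_i = params.s0 * np.exp(effects.eta_s0)
    if spec.structural == LINEAR:
        alpha_i = params.alpha * np.exp(effects.eta_alpha)
        m = covariate_multiplier(spec.covariates, params.theta, covariates)
        return s0_i * (1.0 + alpha_i * t) * m
    # Emax-in-time form; BSV on baseline only.
    return s0_i + params.smax * t / (params.s50 + t)


def residual_variance(spec: ModelSpec, params: ParameterSet, prediction):
    """Residual (observation-level) variance at the given prediction(s)."""
    pred = np.asarray(prediction, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("prediction must be finite")
    if spec.residual == ADDITIVE:
        if params.sigma_add <= 0:
            raise ValueError("degenerate likelihood: sigma_add is zero")
        return np.broadcast_to(
            np.asarray(params.sigma_add**2), pred.shape
        ).copy() if pred.shape else params.sigma_add**2
    if spec.residual == PROPORTIONAL:
        if params.sigma_prop <= 0:
            raise ValueError("degenerate likelihood: sigma_prop is zero")
        return (pred * params.sigma_prop) ** 2
    if params.sigma_add <= 0 and params.sigma_prop <= 0:
        raise ValueError("degenerate likelihood: both sigmas are zero")
    return params.sigma_add**2 + (pred * params.sigma_prop) ** 2
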