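"""Virtual T2DM cohort generator.

Emulates the study design of a Malaysian type-2-diabetes eGFR cohort:
251 subjects contributing ~3241 observations at 6-month visits over at
most 6.6 years of follow-up since diagnosis, with an external validation
cohort of 109 subjects.  Binary covariates are subject-constant Bernoulli
draws at configured prevalences; fasting blood sugar (FBS, mmol/L) is a
subject-level mean (diabetic-nephropathy patients run higher) plus
independent visit-to-visit noise, carried in the dataset as a time-varying
column.  eGFR trajectories come from a truth model (structural form +
parameters) with exponential between-subject variability and residual
noise.

All randomness flows from a single mandatory seed, split into named
substreams (visit counts, covariates, etas, residuals) so that changing
one component of the design does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .model import (
    ADDITIVE,
    COMBINED,
    LINEAR,
    PROPORTIONAL,
    CovariateTerm,
    ModelSpec,
    ParameterSet,
    SubjectEffects,
    structural_predict,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_external_cohort",
    "base_model_spec",
    "final_model_spec",
    "default_base_parameters",
    "default_final_parameters",
    "FBS_REFERENCE",
]

#: Clinical centering value for fasting blood sugar (mmol/L).
FBS_REFERENCE = 7.4

#: Drug / comorbidity / demographic prevalences. Gender, smoking and the
#: nephropathy fraction follow the study's demographics table; drug
#: exposures are plausible T2DM-clinic defaults and are configurable.
DEFAULT_PREVALENCES: dict[str, float] = {
    "metformin": 0.8,
    "statin": 0.6,
    "arbs": 0.3,
    "cvd": 0.2,
    "male": 0.617,
    "smoker": 0.171,
}


def base_model_spec() -> ModelSpec:
    """Base structural model: linear progression, additive residual."""
    return ModelSpec(structural=LINEAR, residual=ADDITIVE)


def final_covariate_terms() -> tuple[CovariateTerm, ...]:
    return (
        CovariateTerm("metformin", "binary"),
        CovariateTerm("fbs", "continuous", reference=FBS_REFERENCE),
        CovariateTerm("arbs", "binary"),
        CovariateTerm("statin", "binary"),
        CovariateTerm("cvd", "binary"),
    )


def final_model_spec(residual: str = ADDITIVE) -> ModelSpec:
    """Final covariate model: linear progression scaled by five covariates."""
    return ModelSpec(structural=LINEAR, residual=residual, covariates=final_covariate_terms())


def default_base_parameters() -> ParameterSet:
    """Reference base-model estimates for the T2DM eGFR cohort.

    Typical baseline 84.5 mL/min/1.73 m^2, fractional decline
    −0.0021/year, BSV 19.3% (baseline) and 180.8% (rate), additive
    residual SD 6.46.
    """
    return ParameterSet(
        s0=84.5,
        alpha=-0.0021,
        omega2_s0=0.193**2,
        omega2_alpha=1.808**2,
        sigma_add=6.46,
    )


def default_final_parameters() -> ParameterSet:
    """Reference final-model estimates (five-covariate model)."""
    return ParameterSet(
        s0=84.6,
        alpha=-0.0041,
        theta={
            "metformin": 0.029,
            "fbs": -0.0038,
            "arbs": 0.0361,
            "statin": 0.0314,
            "cvd": -0.0925,
        },
        omega2_s0=0.187**2,
        omega2_alpha=1.578**2,
        sigma_add=6.29,
    )


@dataclass
class CohortConfig:
    """Design and truth configuration for cohort generation.

    ``target_obs`` is achieved in expectation by drawing per-subject visit
    counts from ``2 + Binomial(n_slots - 2, p)`` with ``p`` chosen so the
    mean count equals ``target_obs / n_subjects``; each subject's visits
    are the first ``k`` points of the 6-month grid starting at diagnosis
    (follow-up truncation, no explicit dropout model).
    """

    n_subjects: int = 251
    visit_interval: float = 0.5
    max_followup: float = 6.6
    target_obs: int = 3241
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    dn_prevalence: float = 96 / 251
    #: FBS subject-mean distribution (mmol/L): (non-DN, DN) means and SDs.
    fbs_group_means: tuple[float, float] = (7.8, 9.1)
    fbs_group_sds: tuple[float, float] = (2.2, 3.1)
    #: independent visit-to-visit FBS noise SD (mmol/L)
    fbs_visit_sd: float = 1.5
    fbs_floor: float = 0.5
    truth_params: ParameterSet = field(default_factory=default_base_parameters)
    truth_spec: ModelSpec = field(default_factory=base_model_spec)
    seed: int | None = None
    n_subjects_external: int = 109

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        if not 0.0 <= self.dn_prevalence <= 1.0:
            raise ValueError("dn_prevalence outside [0, 1]")
        if self.target_obs < self.n_subjects:
            raise ValueError("target_obs must be at least n_subjects")

    def replace(self, **changes) -> "CohortConfig":
        return replace(self, **changes)


def _visit_count_params(config: CohortConfig, n_subjects: int) -> tuple[int, float]:
    n_slots = int(np.floor(config.max_followup / config.visit_interval)) + 1
    mean = config.target_obs / config.n_subjects
    if not 2.0 <= mean <= n_slots:
        raise ValueError(
            f"target mean visit count {mean:.2f} outside [2, {n_slots}] "
            "achievable with this visit grid"
        )
    p = (mean - 2.0) / (n_slots - 2.0)
    return n_slots, p


def _generate(config: CohortConfig, n_subjects: int, stream_offset: int, id_start: int) -> LongitudinalDataset:
    if config.seed is None:
        raise ValueError("CohortConfig.seed is mandatory for generation")
    # noise-free simulation is legitimate, so only the covariate
    # coefficients are checked against the truth spec here
    for term in config.truth_spec.covariates:
        if term.name not in config.truth_params.theta:
            raise ValueError(f"missing coefficient for covariate {term.name!r}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(8)
    visit_rng, cov_rng, eta_rng, res_rng = (
        np.random.default_rng(children[stream_offset + k]) for k in range(4)
    )
    n_slots, p_visit = _visit_count_params(config, n_subjects)

    n_visits = 2 + visit_rng.binomial(n_slots - 2, p_visit, size=n_subjects)

    flags = {
        name: cov_rng.binomial(1, p, size=n_subjects)
        for name, p in config.covariate_prevalences.items()
    }
    dn = cov_rng.binomial(1, config.dn_prevalence, size=n_subjects)
    mu = np.where(dn == 1, config.fbs_group_means[1], config.fbs_group_means[0])
    sd = np.where(dn == 1, config.fbs_group_sds[1], config.fbs_group_sds[0])
    fbs_mean = np.maximum(cov_rng.normal(mu, sd), config.fbs_floor)

    params = config.truth_params
    eta_s0 = eta_rng.normal(0.0, np.sqrt(params.omega2_s0), size=n_subjects)
    eta_alpha = eta_rng.normal(0.0, np.sqrt(params.omega2_alpha), size=n_subjects)

    frames = []
    for i in range(n_subjects):
        k = n_visits[i]
        t = np.arange(k) * config.visit_interval
        fbs = np.maximum(
            fbs_mean[i] + res_rng.normal(0.0, config.fbs_visit_sd, size=k),
            config.fbs_floor,
        )
        cov_values = {name: np.full(k, float(flags[name][i])) for name in flags}
        cov_values["fbs"] = fbs
        cov_values["dn"] = np.full(k, float(dn[i]))
        pred = structural_predict(
            config.truth_spec,
            params,
            SubjectEffects(eta_s0[i], eta_alpha[i]),
            cov_values,
            t,
        )
        dv = np.asarray(pred, dtype=float).copy()
        if config.truth_spec.residual in (PROPORTIONAL, COMBINED) and params.sigma_prop > 0:
            dv = dv * (1.0 + res_rng.normal(0.0, params.sigma_prop, size=k))
        if config.truth_spec.residual in (ADDITIVE, COMBINED) and params.sigma_add > 0:
            dv = dv + res_rng.normal(0.0, params.sigma_add, size=k)
        row = {"ID": np.full(k, id_start + i, dtype=int), "TIME": t, "DV": dv}
        row.update(cov_values)
        frames.append(pd.DataFrame(row))
    return LongitudinalDataset(pd.concat(frames, ignore_index=True))


def generate_cohort(config: CohortConfig) -> LongitudinalDataset:
    """Generate the internal (model-building) cohort."""
    return _generate(config, config.n_subjects, stream_offset=0, id_start=1)


def generate_external_cohort(config: CohortConfig) -> LongitudinalDataset:
    """Generate the external validation cohort.

    Uses an independent substream of the same master seed and a disjoint
    subject-id range, so it never shares subjects or draws with the paired
    internal cohort.
    """
    return _generate(
        config, config.n_subjects_external, stream_offset=4, id_start=100001
    )
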