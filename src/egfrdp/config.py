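"""Run configuration: YAML in, validated dataclass out.

Every stage of the pipeline draws its options (thresholds, replicate
counts, SIR schedule, cohort design, master seed) from one RunConfig so
a run is fully reproducible from its config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .cohort import CohortConfig, default_base_parameters, default_final_parameters
from .model import ADDITIVE, LINEAR, CovariateTerm, ModelSpec, ParameterSet

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    output_dir: str = "egfrdp_run"
    seed: int = 12345
    dataset_path: str | None = None          # if given, skip simulation
    external_path: str | None = None
    # model section
    structural: str = LINEAR
    residual: str = ADDITIVE
    covariates: list[dict] = field(default_factory=list)  # {name, kind, reference}
    # estimation
    maxiter: int = 500
    n_starts: int = 1
    # scm thresholds
    forward_alpha: float = 0.05
    backward_alpha: float = 0.01
    candidates: list[dict] = field(default_factory=list)
    # vpc
    vpc_n_rep: int = 1000
    vpc_levels: tuple[float, ...] = (5.0, 50.0, 95.0)
    # sir
    sir_schedule: tuple[tuple[int, int], ...] = ((1000, 500), (2000, 1000))
    sir_proposal_rsd: float = 0.3
    # cohort generation
    cohort: dict = field(default_factory=dict)
    truth: str = "base"  # "base" | "final"

    def __post_init__(self) -> None:
        for a in (self.forward_alpha, self.backward_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("SCM thresholds must lie in (0, 1)")

    def model_spec(self) -> ModelSpec:
        terms = tuple(
            CovariateTerm(
                c["name"], c.get("kind", "binary"), float(c.get("reference", 0.0))
            )
            for c in self.covariates
        )
        return ModelSpec(self.structural, self.residual, terms)

    def candidate_terms(self) -> list[CovariateTerm]:
        return [
            CovariateTerm(
                c["name"], c.get("kind", "binary"), float(c.get("reference", 0.0))
            )
            for c in self.candidates
        ]

    def cohort_config(self) -> CohortConfig:
        truth_params: ParameterSet = (
            default_final_parameters() if self.truth == "final" else default_base_parameters()
        )
        from .cohort import base_model_spec, final_model_spec

        truth_spec = final_model_spec() if self.truth == "final" else base_model_spec()
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        return CohortConfig(truth_params=truth_params, truth_spec=truth_spec, **kw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "vpc_levels" in raw:
        raw["vpc_levels"] = tuple(raw["vpc_levels"])
    if "sir_schedule" in raw:
        raw["sir_schedule"] = tuple(tuple(pair) for pair in raw["sir_schedule"])
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    if isinstance(data.get("sir_schedule"), list):
        data["sir_schedule"] = [list(p) for p in config.sir_schedule]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
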