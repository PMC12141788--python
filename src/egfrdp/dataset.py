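"""Long-format longitudinal dataset container.

NONMEM-style column dialect: mandatory ``ID``, ``TIME`` (years since T2DM
diagnosis), ``DV`` (observed eGFR, mL/min/1.73 m^2); optional ``MDV`` flag
(1 = design-only row, no likelihood contribution); any further columns are
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MANDATORY = ("ID", "TIME", "DV")


@dataclass
class Subject:
    """Per-subject observation arrays (rows with MDV=1 excluded)."""

    id: int
    times: np.ndarray
    dv: np.ndarray
    covariates: dict[str, np.ndarray]


class LongitudinalDataset:
    """Validated wrapper around a long-format observation DataFrame.

    Rows are sorted by (ID, TIME); times must be non-negative and unique
    within subject.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in MANDATORY:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r}")
        if "MDV" not in df.columns:
            df["MDV"] = 0
        for col in df.columns:
            if col == "ID":
                continue
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["TIME"].isna().any():
            raise ValueError("non-numeric TIME value")
        if np.any(df["TIME"].to_numpy() < 0):
            raise ValueError("TIME must be non-negative")
        bad_dv = df["DV"].isna() & (df["MDV"] != 1)
        if bad_dv.any():
            raise ValueError("non-numeric DV in a row not flagged MDV=1")
        df = df.sort_values(["ID", "TIME"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(subset=["ID", "TIME"]).any():
            raise ValueError("duplicate (ID, TIME) rows")
        self.df = df
        self._subjects: list[Subject] | None = None

    # -- shape ---------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        """Observation rows (MDV=0) contributing to the likelihood."""
        return int((self.df["MDV"] != 1).sum())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("ID", "TIME", "DV", "MDV")]

    def subjects(self) -> list[Subject]:
        if self._subjects is None:
            covs = self.covariate_columns
            out = []
            obs = self.df[self.df["MDV"] != 1]
            for sid, g in obs.groupby("ID", sort=True):
                out.append(
                    Subject(
                        id=sid,
                        times=g["TIME"].to_numpy(float),
                        dv=g["DV"].to_numpy(float),
                        covariates={c: g[c].to_numpy(float) for c in covs},
                    )
                )
            self._subjects = out
        return self._subjects

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "LongitudinalDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        # full precision so a round-trip does not perturb the likelihood
        self.df.to_csv(path, index=False, float_format="%.17g")

    def validation_report(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_rows": len(self.df),
            "covariates": self.covariate_columns,
            "time_range": [float(self.df["TIME"].min()), float(self.df["TIME"].max())],
        }
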