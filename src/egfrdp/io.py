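"""Dataset file I/O (NONMEM-style long-format CSV)."""

from __future__ import annotations

from .dataset import LongitudinalDataset

__all__ = ["read_dataset", "write_dataset"]


def read_dataset(path) -> LongitudinalDataset:
    """Read and validate a long-format CSV (ID, TIME, DV[, MDV], covariates)."""
    return LongitudinalDataset.from_csv(path)


def write_dataset(data: LongitudinalDataset, path) -> None:
    """Write at full numeric precision so round-trips preserve the OFV."""
    data.to_csv(path)
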