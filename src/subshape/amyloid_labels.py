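"""Global amyloid (PiB) retention ratio from regional uptake tables.

The amyloid status that defines the two classes is derived from PET
regional quantification: each cortical volume of interest (VOI) has a
standardized uptake value ratio SUVR = mean uptake / cerebellar-cortex
mean uptake, and the global retention ratio is the VOI-volume-weighted
average SUVR over the 28 bilateral cortical VOIs. A global ratio strictly
greater than 1.5 is amyloid-positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EXPECTED_N_VOIS = 28
DEFAULT_THRESHOLD = 1.5
REFERENCE_NAME = "cerebellar_cortex"


@dataclass
class RegionalUptakeTable:
    """Per-VOI mean uptake and volume plus the cerebellar reference uptake."""

    voi_names: list
    mean_suv: np.ndarray
    volume_ml: np.ndarray
    reference_suv: float

    def __post_init__(self) -> None:
        self.mean_suv = np.asarray(self.mean_suv, float).ravel()
        self.volume_ml = np.asarray(self.volume_ml, float).ravel()
        if not (len(self.voi_names) == len(self.mean_suv) == len(self.volume_ml)):
            raise ValueError("table columns must have equal length")
        if np.any(self.volume_ml <= 0):
            raise ValueError("VOI volumes must be > 0")
        if not np.isfinite(self.reference_suv) or self.reference_suv <= 0:
            raise ValueError("reference uptake must be finite and > 0")
        if len(self.voi_names) != EXPECTED_N_VOIS:
            warnings.warn(
                f"{len(self.voi_names)} VOIs (protocol expects "
                f"{EXPECTED_N_VOIS})",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   reference_name: str = REFERENCE_NAME) -> "RegionalUptakeTable":
        """Build from a (voi_name, mean_suv, volume_ml) frame containing a
        reference row named ``reference_name``."""
        ref = df[df["voi_name"] == reference_name]
        if len(ref) != 1:
            raise ValueError(f"expected exactly one {reference_name!r} row")
        cort = df[df["voi_name"] != reference_name]
        return cls(
            voi_names=list(cort["voi_name"]),
            mean_suv=cort["mean_suv"].to_numpy(),
            volume_ml=cort["volume_ml"].to_numpy(),
            reference_suv=float(ref["mean_suv"].iloc[0]),
        )


def global_pib_ratio(table: RegionalUptakeTable) -> float:
    """Volume-weighted average SUVR over the cortical VOIs.

    SUVR_i = mean_suv_i / reference;  global = Σ v_i·SUVR_i / Σ v_i.
    """
    suvr = table.mean_suv / table.reference_suv
    return float(np.sum(table.volume_ml * suvr) / np.sum(table.volume_ml))


def assign_pib_label(ratio: float, threshold: float = DEFAULT_THRESHOLD) -> int:
    """1 (amyloid-positive) iff ratio > threshold, strictly; the boundary
    value is negative."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"retention ratio must be finite and > 0, got {ratio}")
    return int(ratio > threshold)


def label_subjects(tables, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-subject global ratios and labels from a list of uptake frames."""
    rows = []
    for i, df in enumerate(tables):
        tab = RegionalUptakeTable.from_frame(df)
        ratio = global_pib_ratio(tab)
        rows.append(
            {
                "subject_id": f"sub{i:03d}",
                "global_pib_ratio": ratio,
                "pib_positive": assign_pib_label(ratio, threshold),
            }
        )
    return pd.DataFrame(rows)
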