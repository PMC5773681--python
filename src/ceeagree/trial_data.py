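"""Data model, I/O and validation for paired two-source trial data.

The canonical layout is one row per patient ("wide"): each patient carries
an arm label and a (cost, outcome) pair from each of the two data sources.
Pairing across sources is structural — the two observations sit on the same
row — so downstream statistics never need to join on a key. Only complete
cases are accepted; rows with missing values are rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
INTERVENTION = "intervention"

REQUIRED_COLUMNS = ("patient_id", "arm", "cost_1", "outcome_1", "cost_2", "outcome_2")


class ValidationError(ValueError):
    """Raised when input data violate the paired-trial contract."""


class FormatError(ValidationError):
    """Raised when a file lacks the expected columns."""


class InsufficientDataError(ValidationError):
    """Raised when an arm has too few records for a variance estimate."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm assignment plus (cost, outcome) from both sources.

    Costs are in money units (£ in the motivating trial) and must be finite
    and non-negative. Outcomes are event indicators in {0, 1}; a continuous
    effect measure is accepted by the same code path but the binary case is
    the one exercised throughout.
    """

    patient_id: str
    arm: str
    cost_1: float
    outcome_1: float
    cost_2: float
    outcome_2: float


@dataclass(frozen=True)
class ArmSummary:
    """Sample moments of one arm, for one source.

    Means, standard deviations (n−1 denominator) and the within-arm sample
    covariance between cost and effect — the building blocks of the
    incremental-net-benefit standard error.
    """

    arm: str
    n: int
    mean_cost: float
    sd_cost: float
    mean_effect: float
    sd_effect: float
    cov_cost_effect: float


@dataclass
class PairedTrialData:
    """Validated paired two-source, two-arm patient-level dataset.

    Parameters
    ----------
    frame
        One row per patient with columns ``patient_id, arm, cost_1,
        outcome_1, cost_2, outcome_2``; arm labels normalized to
        ``control`` / ``intervention``.
    adverse_outcome
        True when the clinical event is harmful (e.g. sepsis). The effect
        differential is then reversed so that "effect" counts events
        averted; see :func:`ceeagree.inb_core.oriented_effect`.
    """

    frame: pd.DataFrame
    adverse_outcome: bool = True
    n_control: int = field(init=False)
    n_intervention: int = field(init=False)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)
        self.n_control = int((self.frame["arm"] == CONTROL).sum())
        self.n_intervention = int((self.frame["arm"] == INTERVENTION).sum())

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], adverse_outcome: bool = True
    ) -> "PairedTrialData":
        frame = pd.DataFrame([r.__dict__ for r in records])
        return cls(frame=frame, adverse_outcome=adverse_outcome)

    def records(self) -> list[PatientRecord]:
        return [
            PatientRecord(
                patient_id=str(r.patient_id),
                arm=str(r.arm),
                cost_1=float(r.cost_1),
                outcome_1=float(r.outcome_1),
                cost_2=float(r.cost_2),
                outcome_2=float(r.outcome_2),
            )
            for r in self.frame.itertuples(index=False)
        ]

    def arm_frame(self, arm: str) -> pd.DataFrame:
        if arm not in (CONTROL, INTERVENTION):
            raise ValidationError(f"unknown arm label: {arm!r}")
        return self.frame[self.frame["arm"] == arm]

    def arm_arrays(self, source: int, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """(cost, raw outcome) arrays for one source and arm."""
        _check_source(source)
        sub = self.arm_frame(arm)
        return (
            sub[f"cost_{source}"].to_numpy(dtype=float),
            sub[f"outcome_{source}"].to_numpy(dtype=float),
        )

    def __len__(self) -> int:
        return len(self.frame)


def _check_source(source: int) -> None:
    if source not in (1, 2):
        raise ValidationError(f"source must be 1 or 2, got {source!r}")


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["arm"] = frame["arm"].astype(str)

    if frame.empty:
        raise ValidationError("dataset is empty")

    for col in ("cost_1", "outcome_1", "cost_2", "outcome_2"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(
                f"non-numeric or missing value in column {col!r} at row {row}"
            )
        frame[col] = vals.astype(float)

    for col in ("cost_1", "cost_2"):
        neg = frame[col] < 0
        if neg.any():
            row = int(np.nonzero(neg.to_numpy())[0][0])
            raise ValidationError(f"negative cost in column {col!r} at row {row}")

    for col in ("outcome_1", "outcome_2"):
        nonbin = ~frame[col].isin([0.0, 1.0])
        if nonbin.any():
            row = int(np.nonzero(nonbin.to_numpy())[0][0])
            raise ValidationError(
                f"non-binary outcome in column {col!r} at row {row} "
                f"(value {frame[col].iloc[row]!r})"
            )

    dup = frame["patient_id"].duplicated()
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0])
        raise ValidationError(
            f"duplicated patient_id {frame['patient_id'].iloc[row]!r} at row {row}"
        )

    labels = set(frame["arm"].unique())
    if not labels <= {CONTROL, INTERVENTION}:
        unknown = sorted(labels - {CONTROL, INTERVENTION})
        raise ValidationError(
            f"unrecognized arm label(s) {unknown}; normalize to "
            f"{CONTROL!r}/{INTERVENTION!r} or pass label mappings"
        )
    if labels != {CONTROL, INTERVENTION}:
        raise ValidationError("both arms required: dataset contains a single arm")

    return frame.reset_index(drop=True)


def read_paired_csv(
    path: str | Path,
    adverse_outcome: bool = True,
    control_label: str = CONTROL,
    intervention_label: str = INTERVENTION,
) -> PairedTrialData:
    """Read a wide-format paired trial CSV and validate it.

    The header must contain ``patient_id, arm, cost_1, outcome_1, cost_2,
    outcome_2``. Arm labels equal to *control_label* / *intervention_label*
    are normalized to the canonical ``control`` / ``intervention``. Row
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    mapping = {control_label: CONTROL, intervention_label: INTERVENTION}
    frame["arm"] = frame["arm"].map(lambda a: mapping.get(a, a))
    return PairedTrialData(frame=frame, adverse_outcome=adverse_outcome)


def write_paired_csv(data: PairedTrialData, path: str | Path) -> None:
    """Write the validated dataset back out in the canonical wide format."""
    data.frame.to_csv(path, index=False)


def to_long(data: PairedTrialData) -> pd.DataFrame:
    """Long-format view: one row per (patient, source).

    Secondary convenience for plotting/auditing; analyses use the wide
    frame, where cross-source pairing is structural.
    """
    rows = []
    for source in (1, 2):
        sub = data.frame[["patient_id", "arm", f"cost_{source}", f"outcome_{source}"]]
        sub = sub.rename(columns={f"cost_{source}": "cost", f"outcome_{source}": "outcome"})
        sub.insert(2, "source", source)
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def summarize_arm(data: PairedTrialData, source: int, arm: str) -> ArmSummary:
    """Sample moments of cost and (raw) outcome for one source and arm.

    Uses n−1 denominators throughout, matching the unbiased sample
    variances the standard-error formulas presume. The outcome here is the
    recorded event indicator; orientation for adverse events happens later,
    at net-benefit construction.
    """
    cost, outcome = data.arm_arrays(source, arm)
    n = cost.size
    if n < 2:
        raise InsufficientDataError(
            f"arm {arm!r} has {n} record(s); need at least 2"
        )
    cov = float(np.cov(cost, outcome, ddof=1)[0, 1])
    return ArmSummary(
        arm=arm,
        n=int(n),
        mean_cost=float(cost.mean()),
        sd_cost=float(cost.std(ddof=1)),
        mean_effect=float(outcome.mean()),
        sd_effect=float(outcome.std(ddof=1)),
        cov_cost_effect=cov,
    )
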