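"""Expected analytical sensitivity: FF-distribution-weighted aggregation.

The expected analytical sensitivity of a trisomy at a BMI is the dot
product of the FF-specific sensitivity curve with the conditional FF
distribution for that BMI and trisomy, over an FF window whose probability
is renormalized to 1:

    E[AS] = sum_ff AS(trisomy, reads, ff) * p(ff | BMI, trisomy)

A failure-threshold policy models laboratories that report no result below
a published FF cutoff: sensitivity is set to zero for ff strictly below the
threshold (a missed trisomy among failed samples counts as undetected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .ffmodel import ConditionalFFModel, conditional_ff_pdf
from .wgs import SensitivityCurve

__all__ = [
    "ThresholdPolicy",
    "STANDARD_POLICIES",
    "ComparatorTable",
    "ExpectedSensitivityTable",
    "expected_as",
    "bmi_sweep",
    "cohort_size_requirement",
    "compare_to_non_dna",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """FF failure policy: report no result (sensitivity 0) below threshold."""

    name: str
    ff_failure_threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_failure_threshold <= 0.40:
            raise ValueError("threshold outside [0, 0.40]")


# The studied policy variants: no failure threshold, and the two published
# cutoffs of other NIPS implementations (2.8% and 4.0% FF).
STANDARD_POLICIES: tuple[ThresholdPolicy, ...] = (
    ThresholdPolicy("no_cutoff", 0.0),
    ThresholdPolicy("fail_below_2.8%", 0.028),
    ThresholdPolicy("fail_below_4.0%", 0.040),
)


@dataclass(frozen=True)
class ComparatorTable:
    """Reference sensitivities of non-DNA (serum/ultrasound) screening."""

    sensitivity: dict[str, float] = field(
        default_factory=lambda: {"T21": 0.929, "T18": 0.932, "T13": 0.804}
    )


@dataclass
class ExpectedSensitivityTable:
    """BMI x trisomy x policy expected analytical sensitivity."""

    frame: pd.DataFrame
    ff_window: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def expected_as(
    curve: SensitivityCurve,
    pdf: tuple[np.ndarray, np.ndarray],
    policy: ThresholdPolicy,
) -> float:
    """Aggregate one curve against one conditional FF pdf under a policy.

    The curve and the pdf must be tabulated on identical grids; a mismatch
    is an error, never silently resampled.
    """
    grid, p = pdf
    if len(grid) != len(curve.ff) or not np.allclose(grid, curve.ff, atol=1e-12):
        raise ValueError("sensitivity curve and FF pdf are on different grids")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("FF pdf does not sum to 1")
    as_vals = np.where(grid < policy.ff_failure_threshold, 0.0, curve.sensitivity)
    return float(as_vals @ p)


def bmi_sweep(
    model: ConditionalFFModel,
    curves: dict[str, SensitivityCurve],
    policies: tuple[ThresholdPolicy, ...] = STANDARD_POLICIES,
    bmi_values: np.ndarray | None = None,
    ff_window: tuple[float, float] = (0.0, 0.40),
    comparator: ComparatorTable | None = None,
) -> ExpectedSensitivityTable:
    """Expected AS over a BMI grid for every trisomy and policy.

    Policy ordering (no-cutoff >= 2.8% >= 4%) is checked as an invariant
    of the output, not enforced by mutation.
    """
    if bmi_values is None:
        bmi_values = np.arange(18, 51)
    rows = []
    for bmi in bmi_values:
        for trisomy, curve in curves.items():
            pdf = conditional_ff_pdf(model, float(bmi), trisomy, *ff_window)
            for policy in policies:
                rows.append(
                    {
                        "bmi": float(bmi),
                        "trisomy": trisomy,
                        "policy": policy.name,
                        "ff_failure_threshold": policy.ff_failure_threshold,
                        "expected_as": expected_as(curve, pdf, policy),
                    }
                )
    frame = pd.DataFrame(rows)
    _check_policy_ordering(frame)
    table = ExpectedSensitivityTable(frame=frame, ff_window=ff_window)
    if comparator is not None:
        table = compare_to_non_dna(table, comparator)
    return table


def _check_policy_ordering(frame: pd.DataFrame) -> None:
    for (_, _), grp in frame.groupby(["bmi", "trisomy"]):
        ordered = grp.sort_values("ff_failure_threshold")["expected_as"].to_numpy()
        if not np.all(np.diff(ordered) <= 1e-12):
            raise AssertionError("policy ordering violated: higher threshold raised expected AS")


def cohort_size_requirement(stratum_freqs, n_positives_needed: int) -> int:
    """Patients needed for ``n_positives_needed`` cases in a joint stratum.

    Exact arithmetic: ``ceil(n / prod(freqs))``, with the float frequencies
    snapped to their shortest decimal representation so that, e.g.,
    frequencies 0.1 * 0.02 * 0.01 with 100 needed positives give exactly
    5,000,000.
    """
    if n_positives_needed <= 0:
        raise ValueError("n_positives_needed must be positive")
    prod = Fraction(1)
    for f in stratum_freqs:
        if f == 0:
            raise ValueError("zero stratum frequency: requirement is infinite")
        if not 0 < f <= 1:
            raise ValueError(f"stratum frequency {f} outside (0, 1]")
        prod *= Fraction(f).limit_denominator(10**9)
    return ceil(Fraction(n_positives_needed) / prod)


def compare_to_non_dna(
    table: ExpectedSensitivityTable, comparator: ComparatorTable | None = None
) -> ExpectedSensitivityTable:
    """Flag each row against the non-DNA comparator for its trisomy.

    Superiority is strict: a tie is flagged "not above".
    """
    comparator = comparator or ComparatorTable()
    frame = table.frame.copy()
    ref = frame["trisomy"].map(comparator.sensitivity)
    if ref.isna().any():
        missing = sorted(frame.loc[ref.isna(), "trisomy"].unique())
        raise ValueError(f"comparator has no sensitivity for {missing}")
    frame["non_dna_sensitivity"] = ref
    frame["flag"] = np.where(frame["expected_as"] > ref, "above", "not above")
    return ExpectedSensitivityTable(
        frame=frame, ff_window=table.ff_window, provenance=dict(table.provenance)
    )
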