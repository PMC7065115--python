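"""Descriptive cohort reports: ethnicity-stratified BMI summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import PatientRecord, cohort_to_frame
from .ffmodel import BMI_CLASSES, classify_bmi

__all__ = ["ethnicity_bmi_summary"]


def ethnicity_bmi_summary(records: list[PatientRecord], min_n: int = 100) -> pd.DataFrame:
    """Per-ethnicity BMI-class frequencies and percent with BMI > 30.

    Ethnicities with fewer than ``min_n`` records are pooled into "other".
    Class frequencies are normalized per ethnicity (each row sums to 1).
    """
    if not records:
        raise ValueError("no records to summarize")
    df = cohort_to_frame(records)
    counts = df["ethnicity"].value_counts()
    small = counts[counts < min_n].index
    df["ethnicity"] = df["ethnicity"].where(~df["ethnicity"].isin(small), "other")
    df["bmi_class"] = df["bmi"].map(classify_bmi)

    labels = [label for label, _, _ in BMI_CLASSES]
    rows = []
    for eth, grp in df.groupby("ethnicity", sort=True):
        freqs = grp["bmi_class"].value_counts(normalize=True)
        row = {"ethnicity": eth, "n": len(grp)}
        for label in labels:
            row[f"frac_{label}"] = float(freqs.get(label, 0.0))
        row["pct_bmi_gt_30"] = float(100.0 * (grp["bmi"] > 30).mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    frac_cols = [f"frac_{label}" for label in labels]
    assert np.allclose(out[frac_cols].sum(axis=1), 1.0, atol=1e-9)
    return out
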