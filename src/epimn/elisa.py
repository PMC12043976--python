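"""Colorimetric (ELISA-style) m6A percentage quantification.

The assay reads optical densities for a sample well, a negative control, and
a positive control of known m6A content. The m6A percentage normalizes the
background-subtracted sample slope by the positive-control slope:

    m6A% = 100 * [(sample_od - negative_od) / input_rna_ng]
               / [(positive_od - negative_od) / positive_rna_ng]

The value may exceed 100; sub-background wells are clamped to 0 with a
warning (real plates produce them), and a positive control at or below the
negative control invalidates the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["ElisaMeasurement", "m6a_percent", "normalize_to_reference",
           "read_plate_csv"]


@dataclass(frozen=True)
class ElisaMeasurement:
    sample_od: float
    negative_od: float
    positive_od: float
    input_rna_ng: float
    positive_rna_ng: float

    def __post_init__(self) -> None:
        if self.input_rna_ng <= 0 or self.positive_rna_ng <= 0:
            raise ValueError("RNA amounts must be > 0")
        if self.positive_od <= self.negative_od:
            raise ValueError(
                "assay invalid: positive control OD must exceed negative control OD"
            )


def m6a_percent(m: ElisaMeasurement) -> float:
    """m6A percentage of a well; negative estimates clamp to 0 (warned)."""
    sample_slope = (m.sample_od - m.negative_od) / m.input_rna_ng
    positive_slope = (m.positive_od - m.negative_od) / m.positive_rna_ng
    percent = 100.0 * sample_slope / positive_slope
    if percent < 0:
        warnings.warn("sub-background well; m6A%% clamped to 0", stacklevel=2)
        return 0.0
    return percent


def normalize_to_reference(percent: float, reference_percent: float) -> float:
    """Fold level relative to a reference condition (e.g. day-0 or vehicle)."""
    if reference_percent <= 0:
        raise ValueError("reference percentage must be > 0")
    return percent / reference_percent


def read_plate_csv(path_or_buf) -> pd.DataFrame:
    """Read one row per well and average replicates per sample.

    Columns: sample, sample_od, negative_od, positive_od, input_rna_ng,
    positive_rna_ng. Returns per-sample means plus the computed m6A%.
    """
    df = pd.read_csv(path_or_buf)
    required = {"sample", "sample_od", "negative_od", "positive_od",
                "input_rna_ng", "positive_rna_ng"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    grouped = df.groupby("sample", sort=False).mean(numeric_only=True).reset_index()
    grouped["m6a_percent"] = [
        m6a_percent(
            ElisaMeasurement(
                sample_od=row.sample_od,
                negative_od=row.negative_od,
                positive_od=row.positive_od,
                input_rna_ng=row.input_rna_ng,
                positive_rna_ng=row.positive_rna_ng,
            )
        )
        for row in grouped.itertuples(index=False)
    ]
    return grouped
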