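"""Relative qPCR quantification by the 2^-ΔΔCt method.

Target-gene Ct values are normalised to a reference gene measured in the
same sample (ΔCt = Ct_target − Ct_reference; the reference is 18S rRNA
by convention in this workflow), then to a calibrator sample
(ΔΔCt = ΔCt_sample − ΔCt_calibrator).  The relative expression ratio is
2^−ΔΔCt: 1 means no change versus the calibrator, each unit of −ΔΔCt is
one doubling, so log2(ratio) = −ΔΔCt exactly.

Technical replicates are summarised by mean Ct before ΔΔCt by default
(median available).  Amplification-efficiency correction and standard
curves are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd


@dataclass(frozen=True)
class QpcrMeasurement:
    """One sample's target and reference Ct values (cycles)."""

    sample_id: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_ratio(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression of ``sample`` versus ``calibrator``: 2^−ΔΔCt."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


def ddct_table(
    measurements: pd.DataFrame,
    calibrator_condition: str,
    reference_gene: str = "18S",
    agg: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Relative expression for a long-format Ct table.

    ``measurements`` needs columns sample, condition, gene, ct; replicate
    rows are aggregated per (sample, condition, gene) before ΔΔCt.  Each
    target gene is normalised to ``reference_gene`` within its sample and
    then to the mean ΔCt of the calibrator condition.  Returns a frame
    with columns sample, condition, gene, ratio_vs_calibrator.
    """
    required = {"sample", "condition", "gene", "ct"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if not measurements["ct"].map(math.isfinite).all():
        raise ValueError("non-finite Ct value in table")

    ct = (
        measurements.groupby(["sample", "condition", "gene"], as_index=False)["ct"]
        .agg(agg)
        .pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    )
    if reference_gene not in ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    delta = ct.drop(columns=reference_gene).sub(ct[reference_gene], axis=0)

    calib = delta.loc[
        delta.index.get_level_values("condition") == calibrator_condition
    ]
    if calib.empty:
        raise ValueError(f"no measurements for calibrator condition {calibrator_condition!r}")
    ddct = delta - calib.mean(axis=0)

    out = (2.0 ** (-ddct)).reset_index().melt(
        id_vars=["sample", "condition"],
        var_name="gene",
        value_name="ratio_vs_calibrator",
    )
    return out.dropna(subset=["ratio_vs_calibrator"]).reset_index(drop=True)
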