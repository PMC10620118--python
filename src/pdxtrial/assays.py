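"""Molecular-readout formulas: efficiency-corrected qPCR ratios and
densitometry fold changes.

Both are small, exactly testable computations. The qPCR ratio follows the
Pfaffl method: the expression ratio of a target gene between a control and
a treated sample, corrected for the amplification efficiency of each assay
and normalized to one or more housekeeping (reference) genes combined by
geometric mean of their expression — which, on the Ct scale, is the
arithmetic mean of the reference Ct values.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence


@dataclass(frozen=True)
class QpcrSample:
    """Ct values and efficiencies for one cDNA sample.

    ``efficiency`` 2.0 means perfect doubling per cycle. Triplicate Ct
    readings should be averaged (arithmetic mean) before constructing the
    sample. ``reference_cts`` holds one Ct per housekeeping gene.
    """

    target_ct: float
    reference_cts: Sequence[float]
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self) -> None:
        for eff in (self.efficiency_target, self.efficiency_reference):
            if not 1.0 < eff <= 2.2:
                raise ValueError(f"amplification efficiency {eff} outside (1, 2.2]")
        if self.target_ct <= 0 or not self.reference_cts or \
                any(ct <= 0 for ct in self.reference_cts):
            raise ValueError("Ct values must be positive and non-empty")

    @property
    def reference_ct(self) -> float:
        """Combined reference Ct: the Ct whose expression equals the
        geometric mean of the housekeeping expressions."""
        return fmean(self.reference_cts)


@dataclass(frozen=True)
class DensitometryRecord:
    """Band and loading-control intensities for one lane (arbitrary units)."""

    band_intensity: float
    loading_controls: Sequence[float]  # beta-actin and/or GAPDH
    group: str = "treated"

    def __post_init__(self) -> None:
        if self.band_intensity <= 0 or not self.loading_controls or \
                any(v <= 0 for v in self.loading_controls):
            raise ValueError("intensities must be positive and non-empty")

    @property
    def loading(self) -> float:
        """Geometric mean of the loading-control intensities."""
        prod = 1.0
        for v in self.loading_controls:
            prod *= v
        return prod ** (1.0 / len(self.loading_controls))


def pfaffl_ratio(control: QpcrSample, sample: QpcrSample) -> float:
    """Efficiency-corrected expression ratio of sample relative to control.

        ratio = E_t^(Ct_control,t − Ct_sample,t) / E_r^(Ct_control,r − Ct_sample,r)

    With both efficiencies equal to 2 this reduces to the familiar
    2^−ΔΔCt. Efficiencies must agree between the two samples (same assay).
    """
    if control.efficiency_target != sample.efficiency_target or \
            control.efficiency_reference != sample.efficiency_reference:
        raise ValueError("control and sample must share assay efficiencies")
    num = control.efficiency_target ** (control.target_ct - sample.target_ct)
    den = control.efficiency_reference ** (control.reference_ct - sample.reference_ct)
    return num / den


def fold_change(treated: DensitometryRecord, control: DensitometryRecord) -> float:
    """Loading-normalized densitometry fold change, treated over control."""
    return (treated.band_intensity / treated.loading) / \
        (control.band_intensity / control.loading)
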