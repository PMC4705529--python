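"""Relative quantification of qPCR data by the comparative-Ct (ddCt) method.

Fold change is computed assuming perfect amplification efficiency
(one doubling per cycle), so a ddCt of -1 corresponds to a two-fold
increase of the target in the treated sample relative to control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class FoldChange:
    """Linear and log2 fold change of target expression, treated vs control."""

    fold: float
    log2_fold: float


def delta_delta_ct(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control."""
    for name, ct in (
        ("ct_target_treated", ct_target_treated),
        ("ct_reference_treated", ct_reference_treated),
        ("ct_target_control", ct_target_control),
        ("ct_reference_control", ct_reference_control),
    ):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct!r}")
        if ct <= 0:
            raise ValueError(f"{name} must be > 0 cycles, got {ct!r}")
    return (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )


def fold_change(ddct: float) -> FoldChange:
    """Fold change from a ddCt value: fold = 2**(-ddCt), log2 fold = -ddCt."""
    if not math.isfinite(ddct):
        raise ValueError(f"ddCt must be finite, got {ddct!r}")
    return FoldChange(fold=2.0 ** (-ddct), log2_fold=-ddct)


def fold_change_from_cts(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> FoldChange:
    """Convenience wrapper: raw Ct values in, fold change out."""
    return fold_change(
        delta_delta_ct(
            ct_target_treated,
            ct_reference_treated,
            ct_target_control,
            ct_reference_control,
        )
    )
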