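"""Relative quantification for stem-loop RT-PCR: ΔCt, ΔΔCt and 2^−ΔΔCt.

Threshold cycles (Ct) are reference-corrected within each sample group
(ΔCt = Ct_target − Ct_reference, the reference being 18S rRNA in the assays
this models), then contrasted between case and control (ΔΔCt) and
exponentiated.  Replicate ΔCt values are averaged per group before the
contrast; the SEM of the fold change is propagated from the per-replicate
ΔCt spread by the delta method.

Amplification efficiency defaults to a perfect doubling per cycle
(``efficiency=2.0``); the raw positive ratio is kept everywhere and the
negative-reciprocal signed convention is applied only when rendering
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "RelativeExpression",
    "delta_ct",
    "group_delta_ct",
    "ddct_fold_change",
    "relative_expression",
    "signed_from_ratio",
]

CT_COLUMNS = ("feature_id", "sample_group", "replicate", "ct")


def signed_from_ratio(ratio: float) -> float:
    """Report a positive ratio with the negative-reciprocal convention.

    Ratios at or above 1 are returned unchanged; ratios below 1 become the
    negative reciprocal (0.5 → −2.0), so |signed| is always ≥ 1.
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


@dataclass
class CtTable:
    """Long-format qPCR plate: one row per (feature, group, replicate)."""

    data: pd.DataFrame
    reference_id: str

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s): {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("all Ct values must be finite and > 0")
        groups = set(self.data["sample_group"])
        ref_groups = set(self.data.loc[self.data.feature_id == self.reference_id, "sample_group"])
        if groups - ref_groups:
            raise ValueError(
                f"reference {self.reference_id!r} missing in group(s): {sorted(groups - ref_groups)}"
            )

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.data["sample_group"]))

    @property
    def targets(self) -> list[str]:
        return sorted(set(self.data["feature_id"]) - {self.reference_id})

    def cts(self, feature_id: str, group: str) -> np.ndarray:
        mask = (self.data.feature_id == feature_id) & (self.data.sample_group == group)
        out = self.data.loc[mask, "ct"].to_numpy(dtype=float)
        if out.size == 0:
            raise KeyError(f"no Ct values for {feature_id!r} in group {group!r}")
        return out


@dataclass
class RelativeExpression:
    """2^−ΔΔCt result for one target and one case-vs-control contrast."""

    feature_id: str
    contrast: str
    ddct: float
    fold_change: float  # always positive
    signed_fc: float  # negative-reciprocal rendering of fold_change
    sem: float  # SEM of fold_change, delta-method propagated


def delta_ct(ct_target, ct_reference):
    """ΔCt = Ct_target − Ct_reference (element-wise over arrays)."""
    return np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)


def group_delta_ct(table: CtTable, feature_id: str, group: str) -> np.ndarray:
    """Per-replicate ΔCt of a target in one group.

    Each target replicate is corrected by the group's mean reference Ct
    (reference replicates are not paired to target replicates on the plate).
    """
    ref_mean = float(np.mean(table.cts(table.reference_id, group)))
    return delta_ct(table.cts(feature_id, group), ref_mean)


def ddct_fold_change(
    delta_ct_case,
    delta_ct_control,
    feature_id: str = "",
    contrast: str = "",
    efficiency: float = 2.0,
) -> RelativeExpression:
    """Fold change efficiency^−ΔΔCt from replicate ΔCt values of the two groups.

    ΔΔCt is the difference of group-mean ΔCt values; the SEM of the fold
    change is ``fc · ln(efficiency) · sem(ΔΔCt)`` with the ΔΔCt variance
    summed from both groups' standard errors.
    """
    dca = np.atleast_1d(np.asarray(delta_ct_case, dtype=float))
    dcc = np.atleast_1d(np.asarray(delta_ct_control, dtype=float))
    ddct = float(dca.mean() - dcc.mean())
    fc = float(efficiency ** (-ddct))

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    sem_ddct = float(np.hypot(_sem(dca), _sem(dcc)))
    sem_fc = fc * np.log(efficiency) * sem_ddct
    return RelativeExpression(
        feature_id=feature_id,
        contrast=contrast,
        ddct=ddct,
        fold_change=fc,
        signed_fc=signed_from_ratio(fc),
        sem=sem_fc,
    )


def relative_expression(
    table: CtTable,
    case_group: str,
    control_group: str,
    targets=None,
    efficiency: float = 2.0,
) -> list[RelativeExpression]:
    """2^−ΔΔCt for every target on a plate, case vs control."""
    if targets is None:
        targets = table.targets
    out = []
    for t in targets:
        out.append(
            ddct_fold_change(
                group_delta_ct(table, t, case_group),
                group_delta_ct(table, t, control_group),
                feature_id=t,
                contrast=f"{case_group}_vs_{control_group}",
                efficiency=efficiency,
            )
        )
    return out
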