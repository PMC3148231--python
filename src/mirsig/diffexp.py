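"""Per-stratum case-vs-control contrasts and the three differential filters.

Each detected feature in a stratum gets a :class:`FoldChangeRecord` holding

* the **signed fold change** of case over control group means, reported with
  the negative-reciprocal convention (a ratio of 0.5 becomes −2.0 so that
  |signed_fc| ≥ 1 always);
* a two-tailed **Welch t-test** p-value computed on log2 intensities
  (variance stabilization; fold changes stay on the linear scale);
* the **replication fraction** — the share of case subjects whose individual
  ratio against the control-group mean agrees in direction with the
  group-level change;

and three boolean flags against the filter thresholds: significance
(p < 0.05), magnitude (|signed_fc| ≥ 1.5) and replication (≥ 50% of
subjects).  Benjamini–Hochberg q-values are attached for information only;
the default filtering uses raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ConfigurationError, ExpressionMatrix, SampleSheet

__all__ = [
    "FilterConfig",
    "FoldChangeRecord",
    "signed_fold_change",
    "ratio_from_signed",
    "two_tailed_t",
    "replication_fraction",
    "contrast",
    "anova_lsd",
    "records_to_frame",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the significance / magnitude / replication filters."""

    p_max: float = 0.05
    min_abs_fc: float = 1.5
    min_replication: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ConfigurationError("p_max must be in (0, 1)")
        if self.min_abs_fc < 1:
            raise ConfigurationError("min_abs_fc must be >= 1")
        if not 0 <= self.min_replication <= 1:
            raise ConfigurationError("min_replication must be in [0, 1]")


@dataclass
class FoldChangeRecord:
    feature_id: str
    species: str
    source: str
    case_label: str
    ratio: float  # case mean / control mean, > 0
    signed_fc: float  # ratio if >= 1 else -1/ratio
    p_value: float
    q_value: float  # BH-adjusted, informational
    replication_fraction: float
    n_case: int
    n_control: int
    significant: bool = False
    magnitude: bool = False
    replicated: bool = False
    degenerate_variance: bool = False

    @property
    def direction(self) -> str:
        if self.ratio > 1:
            return "up"
        if self.ratio < 1:
            return "down"
        return "none"

    @property
    def passes_all(self) -> bool:
        return self.significant and self.magnitude and self.replicated


def signed_fold_change(case_mean: float, control_mean: float) -> float:
    """Ratio reported as r when r ≥ 1 and as −1/r when r < 1.

    Antisymmetric for r ≠ 1: swapping the groups negates the result.
    """
    if not (case_mean > 0 and control_mean > 0):
        raise ValueError(
            f"group means must be > 0 (got case={case_mean}, control={control_mean}); "
            "non-detected features should have been removed by the detection filter"
        )
    r = case_mean / control_mean
    return r if r >= 1.0 else -1.0 / r


def ratio_from_signed(signed_fc: float) -> float:
    """Inverse of :func:`signed_fold_change` back to a positive ratio."""
    if abs(signed_fc) < 1:
        raise ValueError(f"|signed_fc| must be >= 1, got {signed_fc}")
    return signed_fc if signed_fc > 0 else -1.0 / signed_fc


def two_tailed_t(case_values, control_values) -> tuple[float, bool]:
    """Two-tailed Welch (unequal variance) t-test.

    Returns ``(p_value, degenerate)``; when the pooled variance is zero or a
    group has fewer than two values the p-value is reported as 1.0 with the
    degenerate flag set (and a warning).
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2 or (np.var(a) == 0 and np.var(b) == 0):
        warnings.warn("degenerate variance or fewer than two values per group; p set to 1.0")
        return 1.0, True
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, False


def replication_fraction(per_subject_ratios, group_direction: str) -> float:
    """Fraction of case subjects replicating the group-level direction.

    A subject replicates iff its ratio against the control-group mean is
    strictly on the group's side of 1 (>1 for "up", <1 for "down"); a ratio of
    exactly 1 never replicates.
    """
    ratios = np.asarray(list(per_subject_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("no per-subject ratios given")
    if np.any(ratios <= 0):
        raise ValueError("per-subject ratios must be > 0")
    if group_direction == "up":
        return float(np.mean(ratios > 1.0))
    if group_direction == "down":
        return float(np.mean(ratios < 1.0))
    if group_direction == "none":
        return 0.0
    raise ValueError(f"group_direction must be up/down/none, got {group_direction!r}")


def _subject_means(matrix: ExpressionMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Features × subjects matrix of per-subject mean intensities.

    Subjects are the unit of replication: multiple samples (replicates) of a
    subject are averaged before any statistic.
    """
    cols = {}
    for subject, grp in samples.groupby("subject_id", sort=False):
        sub = matrix.data[list(grp["sample_id"])]
        cols[subject] = sub.mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def contrast(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    species: str,
    source: str,
    case_label: str,
    config: FilterConfig | None = None,
    features: Sequence[str] | None = None,
) -> list[FoldChangeRecord]:
    """Case-vs-control records for every (detected) feature of one stratum.

    ``features`` restricts the records to a detected set (normalizer excluded
    either way); the matrix should already be normalized.  Features whose
    group means are non-positive or undetected in a group are skipped.
    """
    config = config or FilterConfig()
    case_samples = sheet.samples(species, source, "case", case_label)
    control_samples = sheet.samples(species, source, "control")
    if len(case_samples) == 0 or len(control_samples) == 0:
        raise ConfigurationError(
            f"stratum ({species}, {source}) lacks case {case_label!r} or control samples"
        )
    if features is None:
        features = [f for f in matrix.feature_ids if f != matrix.normalizer_id]
    else:
        features = [f for f in features if f != matrix.normalizer_id]

    case_mat = _subject_means(matrix, case_samples).loc[features].to_numpy(dtype=float)
    ctrl_mat = _subject_means(matrix, control_samples).loc[features].to_numpy(dtype=float)

    case_finite = np.isfinite(case_mat)
    ctrl_finite = np.isfinite(ctrl_mat)
    n_case = case_finite.sum(axis=1)
    n_ctrl = ctrl_finite.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        case_mean = np.nanmean(case_mat, axis=1)
        ctrl_mean = np.nanmean(ctrl_mat, axis=1)
        log_case = np.where(case_mat > 0, np.log2(np.where(case_mat > 0, case_mat, 1.0)), np.nan)
        log_ctrl = np.where(ctrl_mat > 0, np.log2(np.where(ctrl_mat > 0, ctrl_mat, 1.0)), np.nan)
        pvals = stats.ttest_ind(
            log_case, log_ctrl, axis=1, equal_var=False, nan_policy="omit"
        ).pvalue
        pvals = np.asarray(pvals, dtype=float)
        case_var = np.nanvar(log_case, axis=1)
        ctrl_var = np.nanvar(log_ctrl, axis=1)
        ratios = case_mat / ctrl_mean[:, None]
        frac_up = np.where(case_finite, ratios > 1.0, False).sum(axis=1) / np.maximum(n_case, 1)
        frac_down = np.where(case_finite, ratios < 1.0, False).sum(axis=1) / np.maximum(n_case, 1)

    degenerate = ~np.isfinite(pvals) | ((case_var == 0) & (ctrl_var == 0))
    pvals = np.where(degenerate, 1.0, pvals)

    records: list[FoldChangeRecord] = []
    for i, f in enumerate(features):
        if n_case[i] == 0 or n_ctrl[i] == 0:
            continue
        if not (case_mean[i] > 0 and ctrl_mean[i] > 0):
            continue
        ratio = float(case_mean[i] / ctrl_mean[i])
        fc = signed_fold_change(float(case_mean[i]), float(ctrl_mean[i]))
        if ratio > 1:
            repl = float(frac_up[i])
        elif ratio < 1:
            repl = float(frac_down[i])
        else:
            repl = 0.0
        p = float(pvals[i])
        records.append(
            FoldChangeRecord(
                feature_id=f,
                species=species,
                source=source,
                case_label=case_label,
                ratio=ratio,
                signed_fc=fc,
                p_value=p,
                q_value=np.nan,
                replication_fraction=repl,
                n_case=int(n_case[i]),
                n_control=int(n_ctrl[i]),
                significant=p < config.p_max,
                magnitude=abs(fc) >= config.min_abs_fc,
                replicated=repl >= config.min_replication,
                degenerate_variance=bool(degenerate[i]),
            )
        )
    if records:
        qs = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return records


def anova_lsd(groups: dict[str, Sequence[float]]) -> tuple[float, dict[tuple[str, str], float]]:
    """One-way ANOVA with Fisher's LSD pairwise p-values for ≥3 groups.

    Offered as an alternative to pairwise Welch tests when three or more
    groups (e.g. control / IFG / T2D) are compared simultaneously.  Returns
    the overall F-test p-value and the pairwise LSD p-values computed from
    the pooled within-group mean square.
    """
    if len(groups) < 3:
        raise ValueError("anova_lsd needs at least three groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    f_p = float(stats.f_oneway(*arrays.values()).pvalue)
    n_total = sum(a.size for a in arrays.values())
    df_within = n_total - len(arrays)
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()) / df_within
    pairwise = {}
    names = list(arrays)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            a, b = arrays[gi], arrays[gj]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se
            pairwise[(gi, gj)] = float(2 * stats.t.sf(abs(t), df_within))
    return f_p, pairwise


def records_to_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (for TSV export)."""
    rows = [
        {
            "feature_id": r.feature_id,
            "species": r.species,
            "source": r.source,
            "case_label": r.case_label,
            "ratio": r.ratio,
            "signed_fc": r.signed_fc,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "replication_fraction": r.replication_fraction,
            "n_case": r.n_case,
            "n_control": r.n_control,
            "significant": r.significant,
            "magnitude": r.magnitude,
            "replicated": r.replicated,
            "passes_all": r.passes_all,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
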