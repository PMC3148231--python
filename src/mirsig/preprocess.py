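"""Background subtraction, detection filtering, U6 normalization, mRNA prefilter.

The processing order matches standard miRNA array practice: background is
subtracted (clamped at zero), features are called *detected* in a stratum when
their background-subtracted mean intensity exceeds the detection threshold
(default 300), and only then are intensities normalized against the U6 snRNA
reference probe.  Detection is deliberately computed before normalization.

For mRNA (Illumina BeadChip style) data a vendor-convention prefilter keeps
genes with p < 0.05, |Diff score| > 20 and average signal > 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, ExpressionMatrix, SampleSheet

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "detection_filter",
    "normalize_u6",
    "mrna_prefilter",
    "diff_score_from_p",
]


@dataclass
class PreprocessConfig:
    detection_threshold: float = 300.0
    normalizer_id: str = "U6"
    mrna_p_max: float = 0.05
    mrna_diffscore_min: float = 20.0
    mrna_avg_signal_min: float = 100.0

    def __post_init__(self) -> None:
        if not self.detection_threshold > 0:
            raise ConfigurationError("detection_threshold must be > 0")
        for name in ("mrna_p_max", "mrna_diffscore_min", "mrna_avg_signal_min"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


def subtract_background(
    matrix: ExpressionMatrix, background: float | Sequence[float] | Mapping[str, float]
) -> ExpressionMatrix:
    """Subtract a per-sample background offset, clamping at zero.

    ``background`` is a scalar, a sequence aligned with the matrix's sample
    order, or a mapping sample_id → offset.  Not-detected (NaN) cells are left
    unchanged.
    """
    samples = matrix.sample_ids
    if isinstance(background, Mapping):
        missing = [s for s in samples if s not in background]
        if missing:
            raise ConfigurationError(f"no background offset for sample(s): {missing}")
        offsets = np.array([background[s] for s in samples], dtype=float)
    elif np.isscalar(background):
        offsets = np.full(len(samples), float(background))
    else:
        offsets = np.asarray(list(background), dtype=float)
        if offsets.size != len(samples):
            raise ConfigurationError(
                f"{offsets.size} background offsets for {len(samples)} samples"
            )
    if np.any(offsets < 0):
        raise ConfigurationError("background offsets must be >= 0")
    out = matrix.data.to_numpy(dtype=float) - offsets[None, :]
    out = np.maximum(out, 0.0)  # NaN propagates: not-detected stays not-detected
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        matrix.normalizer_id,
    )


def detection_filter(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    threshold: float = 300.0,
) -> dict[tuple[str, str], set[str]]:
    """Detected feature ids per (species, source) stratum.

    A feature is detected in a stratum iff its mean background-subtracted
    intensity across the stratum's samples (both groups, not-detected cells
    excluded) is strictly greater than ``threshold``.  The normalizer probe is
    not reported as a detected feature.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for species, source in sheet.strata():
        sample_ids = list(sheet.samples(species, source)["sample_id"])
        if not sample_ids:
            raise ConfigurationError(f"stratum ({species}, {source}) has no samples")
        missing = [s for s in sample_ids if s not in matrix.data.columns]
        if missing:
            raise ConfigurationError(
                f"stratum ({species}, {source}) samples absent from matrix: {missing}"
            )
        sub = matrix.data[sample_ids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            means = np.nanmean(sub.to_numpy(dtype=float), axis=1)
        detected = set(sub.index[np.nan_to_num(means, nan=-np.inf) > threshold])
        detected.discard(matrix.normalizer_id)
        out[(species, source)] = detected
    return out


def normalize_u6(matrix: ExpressionMatrix, normalizer_id: str | None = None) -> ExpressionMatrix:
    """Scale each sample so the normalizer probe equals its geometric mean.

    Anchoring to the across-sample geometric mean (rather than to any single
    sample) makes the result invariant to sample order; within-sample ratios
    between features are unchanged.  Idempotent.  Raises if the normalizer is
    missing, zero or not-detected in any sample, naming the sample.
    """
    norm_id = normalizer_id or matrix.normalizer_id
    if norm_id is None:
        raise ConfigurationError("no normalizer id given and none set on the matrix")
    if norm_id not in matrix.data.index:
        raise ConfigurationError(f"normalizer {norm_id!r} not found in matrix")
    norm = matrix.data.loc[norm_id].to_numpy(dtype=float)
    bad = ~np.isfinite(norm) | (norm <= 0)
    if bad.any():
        sample = matrix.sample_ids[int(np.argmax(bad))]
        raise ConfigurationError(
            f"normalizer {norm_id!r} missing or non-positive in sample {sample!r}"
        )
    geo_mean = np.exp(np.mean(np.log(norm)))
    scale = geo_mean / norm
    out = matrix.data.to_numpy(dtype=float) * scale[None, :]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        norm_id,
    )


def diff_score_from_p(p_value, direction_sign=1.0):
    """Illumina-style differential score, ``10·sgn(case−control)·(−log10 p)``.

    |score| = 20 corresponds to p = 0.01.  Provided for users who have p-values
    but no vendor-computed score.
    """
    p = np.asarray(p_value, dtype=float)
    return np.sign(np.asarray(direction_sign, dtype=float)) * (-10.0 * np.log10(p))


def mrna_prefilter(
    stats: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> set[str]:
    """Gene ids passing p < p_max AND |diff_score| > diffscore_min AND avg_signal > min.

    ``stats`` needs columns ``gene_id``, ``p_value``, ``diff_score``,
    ``avg_signal`` (all finite).  All three cuts are strict, per the vendor
    convention.  An empty result is allowed.
    """
    config = config or PreprocessConfig()
    required = ["gene_id", "p_value", "diff_score", "avg_signal"]
    missing = [c for c in required if c not in stats.columns]
    if missing:
        raise ConfigurationError(f"mRNA stats missing column(s): {missing}")
    vals = stats[["p_value", "diff_score", "avg_signal"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConfigurationError("mRNA stats must be finite")
    keep = (
        (vals[:, 0] < config.mrna_p_max)
        & (np.abs(vals[:, 1]) > config.mrna_diffscore_min)
        & (vals[:, 2] > config.mrna_avg_signal_min)
    )
    return set(stats.loc[keep, "gene_id"])
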