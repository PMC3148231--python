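"""Synthetic expression studies with a planted miRNA signature.

The generator emulates the structure the downstream analysis assumes: a rat
study with five sources (pancreas, liver, adipose, skeletal muscle, blood),
each with diet-control and diet-plus-STZ diabetic groups of six animals; a
human whole-blood cohort with control, impaired-fasting-glucose (IFG) and
T2D groups; a constant U6 normalizer probe; log-normal intensity noise with
per-array multiplicative scale jitter; and eight planted signature miRNAs
(miR-144, miR-150, miR-192, miR-29a, miR-320a up; miR-146a, miR-30d, miR-182
down in T2D) whose fold changes default to the magnitudes the study design
targets.  A truth table accompanies every generated dataset so recovery can
be scored exactly.

Intensity model (log2 scale)::

    log2 I(f, s) = baseline(f, source) + effect(f, stratum) + jitter(s) + N(0, noise_sd)

The U6 row carries only the per-sample jitter, so U6 normalization has a real
array effect to remove.  Dropout is simulated by drawing a low baseline below
the detection threshold for the affected (feature, source), which exercises
the detection filter rather than deleting cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, ExpressionMatrix, PredictionSet, SampleSheet
from .qpcr import CtTable

__all__ = [
    "PlantedEffect",
    "GeneratorConfig",
    "generate_microarray_study",
    "generate_qpcr_plate",
    "generate_prediction_tables",
    "default_rat_config",
    "default_human_config",
    "default_human_mrna_config",
    "SIGNATURE_UP",
    "SIGNATURE_DOWN",
    "TRUE_TARGET_PAIRS",
    "PREDICTION_DATABASES",
]

SIGNATURE_UP = ("miR-144", "miR-150", "miR-192", "miR-29a", "miR-320a")
SIGNATURE_DOWN = ("miR-146a", "miR-30d", "miR-182")

#: the insulin-signaling target panel paired with each signature miRNA
TRUE_TARGET_PAIRS = (
    ("miR-144", "IRS1"),
    ("miR-146a", "PTPN1"),
    ("miR-150", "GLUT4"),
    ("miR-150", "CBL"),
    ("miR-182", "FOXO1"),
    ("miR-192", "INSR"),
    ("miR-30d", "INS"),
    ("miR-29a", "AKT2"),
    ("miR-320a", "AKT2"),
)

PREDICTION_DATABASES = ("RegRNA", "MirBase", "TargetScan", "Mirgen", "microRNA.org")

RAT_SOURCES = ("pancreas", "liver", "adipose", "skeletal_muscle", "blood")


@dataclass(frozen=True)
class PlantedEffect:
    """A true differential-expression effect injected into one stratum."""

    feature_id: str
    species: str
    source: str
    case_label: str
    direction: str  # "up" or "down"
    log2_effect: float  # > 0; applied with the sign implied by direction

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be up/down, got {self.direction!r}")
        if not self.log2_effect > 0:
            raise ConfigurationError("log2_effect must be > 0 (direction carries the sign)")

    @property
    def signed_log2(self) -> float:
        return self.log2_effect if self.direction == "up" else -self.log2_effect

    @property
    def fold_change(self) -> float:
        """Signed fold change (negative-reciprocal convention)."""
        fc = 2.0 ** self.log2_effect
        return fc if self.direction == "up" else -fc


@dataclass
class GeneratorConfig:
    """Study design and noise model for one synthetic microarray study."""

    species: str = "rat"
    sources: tuple[str, ...] = RAT_SOURCES
    case_labels: tuple[str, ...] = ("HFD",)
    n_background_features: int = 200
    n_control: int = 6
    n_case: int = 6
    replicates_per_subject: int = 1
    baseline_log2_mean: float = 11.0
    baseline_log2_sd: float = 0.8
    noise_sd: float = 0.25
    u6_intensity: float = 5000.0
    scale_jitter_sd: float = 0.2
    dropout_rate: float = 0.05
    normalizer_id: str | None = "U6"
    feature_prefix: str = "miR-sim"
    planted: tuple[PlantedEffect, ...] = ()
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_log2_sd", "noise_sd", "scale_jitter_sd", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.n_control < 1 or self.n_case < 1:
            raise ConfigurationError("need at least one subject per group")
        planted_ids = {e.feature_id for e in self.planted}
        if self.normalizer_id is not None and self.normalizer_id in planted_ids:
            raise ConfigurationError(
                f"planted feature collides with normalizer {self.normalizer_id!r}"
            )


def _planted_for(config: GeneratorConfig) -> list[PlantedEffect]:
    return [
        e
        for e in config.planted
        if e.species == config.species
        and e.source in config.sources
        and e.case_label in config.case_labels
    ]


def generate_microarray_study(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    """Generate one intensity matrix, its sample sheet, and the ground truth.

    The truth table has one row per (feature, source, case_label) with the true
    direction ("up"/"down"/"none"), the true signed fold change, and a
    ``signature`` flag that is True exactly for the planted features.
    Bit-reproducible for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    planted = _planted_for(config)
    planted_ids: list[str] = []
    for e in planted:
        if e.feature_id not in planted_ids:
            planted_ids.append(e.feature_id)

    n_bg = config.n_background_features
    background_ids = [
        f"{config.feature_prefix}-{i:03d}"
        for i in range(1, n_bg + 1)
    ]
    clash = set(background_ids) & set(planted_ids)
    if clash:
        raise ConfigurationError(f"background ids collide with planted ids: {sorted(clash)}")
    feature_ids = planted_ids + background_ids
    n_feat = len(feature_ids)
    n_src = len(config.sources)
    feat_index = {f: i for i, f in enumerate(feature_ids)}

    # per-feature baseline, shared across sources; dropout re-draws a low
    # baseline below the detection threshold for background features only
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_feat)
    drop = rng.random((n_feat, n_src)) < config.dropout_rate
    drop[: len(planted_ids), :] = False
    low = rng.uniform(4.0, 7.0, (n_feat, n_src))
    baseline_fs = np.where(drop, low, baseline[:, None])

    # subjects shared across sources (each rat contributes every tissue)
    control_subjects = [f"{config.species}-ctl-{i:02d}" for i in range(1, config.n_control + 1)]
    case_subjects = {
        label: [f"{config.species}-{label}-{i:02d}" for i in range(1, config.n_case + 1)]
        for label in config.case_labels
    }

    rows = []
    for source in config.sources:
        for subj in control_subjects:
            for rep in range(1, config.replicates_per_subject + 1):
                rows.append((f"{subj}.{source}.r{rep}", subj, config.species, source, "control", ""))
        for label in config.case_labels:
            for subj in case_subjects[label]:
                for rep in range(1, config.replicates_per_subject + 1):
                    rows.append((f"{subj}.{source}.r{rep}", subj, config.species, source, "case", label))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "species", "source", "group", "case_label"])
    )
    sample_source = sheet.data["source"].to_numpy()
    sample_label = sheet.data["case_label"].to_numpy()
    n_samp = len(sheet)

    src_index = {s: i for i, s in enumerate(config.sources)}
    col_src = np.array([src_index[s] for s in sample_source])
    log2 = baseline_fs[:, col_src].astype(float)

    for e in planted:
        cols = (sample_source == e.source) & (sample_label == e.case_label)
        log2[feat_index[e.feature_id], cols] += e.signed_log2

    jitter = rng.normal(0.0, config.scale_jitter_sd, n_samp)
    log2 += jitter[None, :]
    log2 += rng.normal(0.0, config.noise_sd, (n_feat, n_samp))

    data = pd.DataFrame(2.0 ** log2, index=feature_ids, columns=sheet.sample_ids)
    if config.normalizer_id is not None:
        data.loc[config.normalizer_id] = config.u6_intensity * 2.0 ** jitter
    matrix = ExpressionMatrix(data, normalizer_id=config.normalizer_id)

    truth_rows = []
    effect_lookup = {(e.feature_id, e.source, e.case_label): e for e in planted}
    for label in config.case_labels:
        for source in config.sources:
            for f in feature_ids:
                e = effect_lookup.get((f, source, label))
                if e is not None:
                    truth_rows.append((f, config.species, source, label, e.direction, e.fold_change, True))
                else:
                    truth_rows.append((f, config.species, source, label, "none", 1.0, f in planted_ids))
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "species", "source", "case_label", "direction", "fold_change", "signature"],
    )
    return matrix, sheet, truth


def generate_qpcr_plate(
    config: GeneratorConfig,
    targets: Sequence[str],
    reference_id: str = "18S",
    source: str = "blood",
    n_replicates: int = 3,
) -> CtTable:
    """Simulate a qPCR plate with triplicate Ct values per (feature, group).

    A planted log2 effect *e* in a case group lowers the target's Ct by *e*
    cycles relative to control, so the expected ΔΔCt is −e and the recovered
    2^−ΔΔCt equals 2^e.  Groups are ``control`` plus the config's case labels.
    """
    targets = list(targets)
    if not targets:
        raise ConfigurationError("empty target list")
    if reference_id in targets:
        raise ConfigurationError(f"reference {reference_id!r} must not be a target")
    rng = np.random.default_rng([config.seed, 7])
    groups = ["control"] + list(config.case_labels)
    effect = {
        (e.feature_id, e.case_label): e.signed_log2
        for e in config.planted
        if e.species == config.species and e.source == source
    }
    ref_ct = 15.0
    rows = []
    for target in targets:
        base_dct = rng.uniform(5.0, 12.0)  # control ΔCt vs reference
        for group in groups:
            shift = 0.0 if group == "control" else effect.get((target, group), 0.0)
            mean_ct = ref_ct + base_dct - shift
            for rep in range(1, n_replicates + 1):
                ct = mean_ct + rng.normal(0.0, config.ct_noise_sd)
                rows.append((target, group, rep, ct))
    for group in groups:
        for rep in range(1, n_replicates + 1):
            ct = ref_ct + rng.normal(0.0, config.ct_noise_sd)
            rows.append((reference_id, group, rep, ct))
    df = pd.DataFrame(rows, columns=["feature_id", "sample_group", "replicate", "ct"])
    return CtTable(df, reference_id=reference_id)


def generate_prediction_tables(
    config: GeneratorConfig,
    true_pairs: Sequence[tuple[str, str]],
    k: int = 5,
    votes_per_true_pair: int = 4,
    n_decoys: int = 50,
    database_names: Sequence[str] | None = None,
) -> tuple[PredictionSet, pd.DataFrame]:
    """Build k prediction databases with controlled vote counts.

    Each true pair is listed in exactly ``votes_per_true_pair`` databases;
    decoy pairs are listed in at most ``min(2, k-1)`` databases, so the
    3-of-k consensus rule retains the true pairs and drops every decoy.
    Returns the PredictionSet and a truth table (pair, votes, is_true).
    """
    if votes_per_true_pair > k:
        raise ConfigurationError("votes_per_true_pair must be <= k")
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    if database_names is None:
        database_names = list(PREDICTION_DATABASES[:k]) if k <= len(PREDICTION_DATABASES) else [
            f"db{i+1}" for i in range(k)
        ]
    if len(database_names) != k:
        raise ConfigurationError("need exactly k database names")
    rng = np.random.default_rng([config.seed, 13])
    databases: dict[str, set[tuple[str, str]]] = {name: set() for name in database_names}
    truth_rows = []
    seen = set()
    for pair in true_pairs:
        pair = (str(pair[0]), str(pair[1]))
        if pair in seen:
            continue
        seen.add(pair)
        for i in rng.choice(k, size=votes_per_true_pair, replace=False):
            databases[database_names[i]].add(pair)
        truth_rows.append((*pair, votes_per_true_pair, True))
    max_decoy_votes = min(2, k - 1)
    i = 0
    made = 0
    while made < n_decoys:
        i += 1
        pair = (f"miR-decoy-{i:03d}", f"GENE{i:03d}")
        if pair in seen:
            continue
        seen.add(pair)
        v = int(rng.integers(1, max_decoy_votes + 1)) if max_decoy_votes >= 1 else 0
        for j in rng.choice(k, size=v, replace=False):
            databases[database_names[j]].add(pair)
        truth_rows.append((*pair, v, False))
        made += 1
    predictions = PredictionSet({n: frozenset(p) for n, p in databases.items()})
    truth = pd.DataFrame(truth_rows, columns=["mirna_id", "gene_id", "votes", "is_true"])
    return predictions, truth


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def _effects(species: str, case_label: str, source_fcs: dict[str, dict[str, float]]) -> list[PlantedEffect]:
    out = []
    for mirna, per_source in source_fcs.items():
        for source, fc in per_source.items():
            direction = "up" if fc > 0 else "down"
            out.append(
                PlantedEffect(mirna, species, source, case_label, direction, float(np.log2(abs(fc))))
            )
    return out


def _uniform(fc: float, exceptions: dict[str, float] | None = None) -> dict[str, float]:
    d = {s: fc for s in RAT_SOURCES}
    d.update(exceptions or {})
    return d


#: per-source rat fold changes (HFD/STZ vs control); magnitudes printed for a
#: source are used as given, the rest default to moderate 2–3-fold effects
RAT_SIGNATURE_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "miR-144": _uniform(3.0, {"pancreas": 7.94, "adipose": 4.34, "liver": 4.26}),
    "miR-150": _uniform(2.0, {"adipose": 3.21, "liver": 2.07}),
    "miR-192": _uniform(2.5),
    "miR-29a": _uniform(2.5),
    "miR-320a": _uniform(2.0),
    "miR-146a": _uniform(-2.5, {"adipose": -4.62}),
    "miR-30d": _uniform(-2.0, {"pancreas": -2.81}),
    "miR-182": _uniform(-2.5, {"skeletal_muscle": -4.23}),
}

#: human whole-blood fold changes; T2D mirrors the rat directions, IFG flips
#: miR-30d/miR-182 up and shrinks miR-144 to ~1.4-fold
HUMAN_BLOOD_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "T2D": {
        "miR-144": 3.070,
        "miR-150": 2.0,
        "miR-192": 2.5,
        "miR-29a": 2.0,
        "miR-320a": 2.0,
        "miR-146a": -2.0,
        "miR-30d": -2.0,
        "miR-182": -2.0,
    },
    "IFG": {
        "miR-144": 1.385,
        "miR-150": 1.6,
        "miR-192": 1.15,
        "miR-29a": 1.6,
        "miR-320a": 1.6,
        "miR-146a": -1.8,
        "miR-30d": 1.8,
        "miR-182": 1.5,
    },
}

#: human whole-blood mRNA fold changes for the insulin-signaling panel,
#: inverse to their miRNA regulators in T2D (except the miR-30d/INS pair,
#: which moves with its miRNA)
HUMAN_MRNA_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "T2D": {
        "IRS1": -2.0,
        "PTPN1": 2.5,
        "GLUT4": -2.6,
        "CBL": -2.0,
        "FOXO1": 1.8,
        "INSR": -1.8,
        "INS": -3.0,
        "AKT2": -2.2,
    },
    "IFG": {
        "IRS1": -1.6,
        "PTPN1": 1.1,
        "GLUT4": -1.2,
        "CBL": 2.0,
        "FOXO1": -1.5,
        "INSR": -1.1,
        "INS": 2.0,
        "AKT2": -1.1,
    },
}


def default_rat_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Five-source rat study, n=6 per group, eight planted signature miRNAs."""
    planted = tuple(
        e
        for mirna, per_source in RAT_SIGNATURE_FOLD_CHANGES.items()
        for e in _effects("rat", "HFD", {mirna: per_source})
    )
    return replace(GeneratorConfig(planted=planted, seed=seed), **overrides)


def default_human_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Human whole-blood cohort (control / IFG / T2D) with per-subject replicates."""
    planted = []
    for label, fcs in HUMAN_BLOOD_FOLD_CHANGES.items():
        planted.extend(_effects("human", label, {m: {"blood": fc} for m, fc in fcs.items()}))
    cfg = GeneratorConfig(
        species="human",
        sources=("blood",),
        case_labels=("IFG", "T2D"),
        replicates_per_subject=2,
        planted=tuple(planted),
        seed=seed,
    )
    return replace(cfg, **overrides)


def default_human_mrna_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Human whole-blood mRNA study for the insulin-signaling gene panel.

    mRNA arrays are not U6-normalized, so the normalizer row and array scale
    jitter are disabled by default.
    """
    planted = []
    for label, fcs in HUMAN_MRNA_FOLD_CHANGES.items():
        planted.extend(_effects("human", label, {g: {"blood": fc} for g, fc in fcs.items()}))
    cfg = GeneratorConfig(
        species="human",
        sources=("blood",),
        case_labels=("IFG", "T2D"),
        replicates_per_subject=2,
        normalizer_id=None,
        scale_jitter_sd=0.0,
        feature_prefix="GENE-sim",
        planted=tuple(planted),
        seed=seed,
    )
    return replace(cfg, **overrides)
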