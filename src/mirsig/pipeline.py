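"""End-to-end orchestration: simulate/load → preprocess → contrasts → signature
→ targets → qPCR → report bundle.

``run_synthetic_pipeline`` runs the whole analysis on generated data with the
default study conditions (five-source rat study and a human whole-blood
cohort, eight planted signature miRNAs) and returns every intermediate
product.  ``run_pipeline`` additionally accepts a YAML/dict config that can
point at user-supplied TSV inputs instead of the generator, and writes the
report bundle (fold-change tables, signature list, Venn counts, pair
evaluations, Newick dendrogram, PCA scores, figures, machine-readable run
log) to an output directory.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import FilterConfig, FoldChangeRecord, contrast, records_to_frame
from .io_formats import (
    ConfigurationError,
    ExpressionMatrix,
    PredictionSet,
    SampleSheet,
    read_expression_matrix,
    read_prediction_tables,
    read_sample_sheet,
    write_expression_matrix,
    write_sample_sheet,
)
from .preprocess import PreprocessConfig, detection_filter, normalize_u6
from .qpcr import CtTable, RelativeExpression, relative_expression
from .report import (
    Dendrogram,
    PCAResult,
    fold_change_profile_matrix,
    hierarchical_cluster,
    pca,
    pearson_r,
    plot_heatmap,
    plot_pca_scores,
)
from .signature import SignatureEntry, VennCounts, cross_source_signature, cross_species_signature, venn_counts
from .synthetic_data import (
    SIGNATURE_DOWN,
    SIGNATURE_UP,
    TRUE_TARGET_PAIRS,
    GeneratorConfig,
    default_human_config,
    default_human_mrna_config,
    default_rat_config,
    generate_microarray_study,
    generate_prediction_tables,
    generate_qpcr_plate,
)
from .targets import PairEvaluation, TargetVote, consensus_targets, evaluate_pairs

__all__ = ["PipelineResult", "run_synthetic_pipeline", "run_pipeline"]

_MOD = 2**31


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    seed: int
    rat_records: dict[str, list[FoldChangeRecord]]  # source -> records
    human_records: dict[str, list[FoldChangeRecord]]  # case label -> records
    mrna_records: dict[str, list[FoldChangeRecord]]
    detected: dict[tuple[str, str], set[str]]
    venn: VennCounts
    rat_signature: list[SignatureEntry]
    signature: list[SignatureEntry]  # cross-species, with concordance flags
    votes: list[TargetVote]
    pair_evaluations: list[PairEvaluation]
    qpcr_results: dict[str, list[RelativeExpression]]  # contrast -> per-target
    profiles: pd.DataFrame
    dendrogram: Dendrogram
    subject_pca: PCAResult | None
    subject_groups: pd.Series | None
    correlations: dict[str, float]  # case label -> Pearson r vs control
    rat_truth: pd.DataFrame | None = None
    human_truth: pd.DataFrame | None = None

    @property
    def concordant_signature(self) -> list[SignatureEntry]:
        return [e for e in self.signature if e.concordant]


def _subject_log_ratio_profiles(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    species: str,
    source: str,
    features: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-case-subject log2 ratio profiles against the control-group mean."""
    control = sheet.samples(species, source, "control")
    ctrl_mean = matrix.data.loc[features, list(control["sample_id"])].mean(axis=1, skipna=True)
    rows, labels = {}, {}
    cases = sheet.samples(species, source, "case")
    for (subject, label), grp in cases.groupby(["subject_id", "case_label"], sort=False):
        subj_mean = matrix.data.loc[features, list(grp["sample_id"])].mean(axis=1, skipna=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[subject] = np.log2(subj_mean / ctrl_mean)
        labels[subject] = label
    profiles = pd.DataFrame(rows).T
    profiles.columns = features
    return profiles, pd.Series(labels)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_synthetic_pipeline(
    seed: int = 0,
    filter_config: FilterConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    rat_overrides: Mapping[str, Any] | None = None,
    human_overrides: Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on generated data with the default study design.

    Deterministic in ``seed``; the rat, human miRNA, human mRNA, prediction
    and qPCR datasets use decoupled sub-seeds derived from it.
    """
    rat_cfg = default_rat_config(seed=seed % _MOD, **dict(rat_overrides or {}))
    human_cfg = default_human_config(seed=(seed + 1_000_003) % _MOD, **dict(human_overrides or {}))
    mrna_cfg = default_human_mrna_config(seed=(seed + 2_000_003) % _MOD)

    rat = generate_microarray_study(rat_cfg)
    human = generate_microarray_study(human_cfg)
    mrna = generate_microarray_study(mrna_cfg)
    predictions, _ = generate_prediction_tables(rat_cfg, TRUE_TARGET_PAIRS)
    plate = generate_qpcr_plate(human_cfg, list(SIGNATURE_UP + SIGNATURE_DOWN))

    result = analyze(
        rat_matrix=rat[0],
        rat_sheet=rat[1],
        human_matrix=human[0],
        human_sheet=human[1],
        mrna_matrix=mrna[0],
        mrna_sheet=mrna[1],
        predictions=predictions,
        qpcr_plate=plate,
        filter_config=filter_config,
        preprocess_config=preprocess_config,
        seed=seed,
    )
    result.rat_truth = rat[2]
    result.human_truth = human[2]
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def analyze(
    rat_matrix: ExpressionMatrix,
    rat_sheet: SampleSheet,
    human_matrix: ExpressionMatrix,
    human_sheet: SampleSheet,
    mrna_matrix: ExpressionMatrix | None = None,
    mrna_sheet: SampleSheet | None = None,
    predictions: PredictionSet | None = None,
    qpcr_plate: CtTable | None = None,
    filter_config: FilterConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run preprocessing, contrasts, signature selection, targets and reports."""
    fcfg = filter_config or FilterConfig()
    pcfg = preprocess_config or PreprocessConfig()

    with _stage("preprocess"):
        detected = detection_filter(rat_matrix, rat_sheet, pcfg.detection_threshold)
        detected.update(detection_filter(human_matrix, human_sheet, pcfg.detection_threshold))
        rat_norm = normalize_u6(rat_matrix) if rat_matrix.normalizer_id else rat_matrix
        human_norm = normalize_u6(human_matrix) if human_matrix.normalizer_id else human_matrix

    with _stage("diffexp"):
        rat_sources = [src for sp, src in rat_sheet.strata() if sp == "rat"]
        rat_records = {
            src: contrast(
                rat_norm, rat_sheet, "rat", src, rat_sheet.case_labels("rat", src)[0],
                fcfg, features=sorted(detected[("rat", src)]),
            )
            for src in rat_sources
        }
        human_source = [src for sp, src in human_sheet.strata() if sp == "human"][0]
        human_records = {
            label: contrast(
                human_norm, human_sheet, "human", human_source, label,
                fcfg, features=sorted(detected[("human", human_source)]),
            )
            for label in human_sheet.case_labels("human", human_source)
        }
        mrna_records: dict[str, list[FoldChangeRecord]] = {}
        if mrna_matrix is not None and mrna_sheet is not None:
            m_norm = normalize_u6(mrna_matrix) if mrna_matrix.normalizer_id else mrna_matrix
            m_species, m_source = mrna_sheet.strata()[0]
            for label in mrna_sheet.case_labels(m_species, m_source):
                mrna_records[label] = contrast(m_norm, mrna_sheet, m_species, m_source, label, fcfg)

    with _stage("signature"):
        significant_sets = {
            src: {r.feature_id for r in recs if r.significant}
            for src, recs in rat_records.items()
        }
        venn = venn_counts(significant_sets)
        rat_signature = cross_source_signature(rat_records, required_sources=rat_sources)
        signature = cross_species_signature(rat_signature, human_records, p_max=fcfg.p_max)

    with _stage("targets"):
        votes: list[TargetVote] = []
        pairs: list[PairEvaluation] = []
        if predictions is not None:
            votes = consensus_targets(predictions)
            if mrna_records:
                pairs = evaluate_pairs(signature, mrna_records, votes, fcfg)

    with _stage("qpcr"):
        qpcr_results: dict[str, list[RelativeExpression]] = {}
        if qpcr_plate is not None:
            for group in qpcr_plate.groups:
                if group == "control":
                    continue
                qpcr_results[group] = relative_expression(qpcr_plate, group, "control")

    with _stage("report"):
        records_by_profile: dict[str, list[FoldChangeRecord]] = {
            f"rat_{src}": recs for src, recs in rat_records.items()
        }
        for label, recs in human_records.items():
            records_by_profile[f"human_{label}"] = recs
        profiles = fold_change_profile_matrix(records_by_profile)
        dendrogram = hierarchical_cluster(profiles)

        subject_pca = None
        subject_groups = None
        human_detected = sorted(detected[("human", human_source)])
        if human_detected:
            subj_profiles, subject_groups = _subject_log_ratio_profiles(
                human_norm, human_sheet, "human", human_source, human_detected
            )
            if len(subj_profiles) >= 3:
                subject_pca = pca(subj_profiles, n_components=min(5, len(subj_profiles) - 1))

        # Pearson correlation of case vs control mean log2 intensities over
        # the features surviving the second-stage (significance+replication)
        # filter, mirroring the patient-cohort correlation analysis
        correlations: dict[str, float] = {}
        ctrl_samples = list(human_sheet.samples("human", human_source, "control")["sample_id"])
        for label, recs in human_records.items():
            keep = [r.feature_id for r in recs if r.significant and r.replicated]
            if len(keep) < 3:
                continue
            case_samples = list(
                human_sheet.samples("human", human_source, "case", label)["sample_id"]
            )
            x = np.log2(human_norm.data.loc[keep, ctrl_samples].mean(axis=1))
            y = np.log2(human_norm.data.loc[keep, case_samples].mean(axis=1))
            correlations[label] = pearson_r(x.to_numpy(), y.to_numpy())

    return PipelineResult(
        seed=seed,
        rat_records=rat_records,
        human_records=human_records,
        mrna_records=mrna_records,
        detected=detected,
        venn=venn,
        rat_signature=rat_signature,
        signature=signature,
        votes=votes,
        pair_evaluations=pairs,
        qpcr_results=qpcr_results,
        profiles=profiles,
        dendrogram=dendrogram,
        subject_pca=subject_pca,
        subject_groups=subject_groups,
        correlations=correlations,
    )


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path, seed: int = 0) -> PipelineResult:
    """Run from a YAML/dict config and write the report bundle.

    The config either contains ``synthetic:`` (generator overrides applied to
    the default study design) or ``inputs:`` with paths to rat/human matrices
    and sample sheets (plus optional mRNA matrices, prediction tables and a
    qPCR Ct table).  Thresholds live under ``filters:`` and ``preprocess:``.
    """
    if not isinstance(config, Mapping):
        import yaml

        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text()) or {}

    fcfg = FilterConfig(**config.get("filters", {}))
    pcfg = PreprocessConfig(**config.get("preprocess", {}))
    seed = int(config.get("seed", seed))

    if "inputs" in config:
        inp = config["inputs"]

        def _need(key: str) -> Path:
            if key not in inp:
                raise ConfigurationError(f"config inputs missing {key!r}")
            p = Path(inp[key])
            if not p.exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
            return p

        rat_matrix = read_expression_matrix(_need("rat_matrix"), normalizer_id=pcfg.normalizer_id)
        rat_sheet = read_sample_sheet(_need("rat_sheet"))
        human_matrix = read_expression_matrix(_need("human_matrix"), normalizer_id=pcfg.normalizer_id)
        human_sheet = read_sample_sheet(_need("human_sheet"))
        mrna_matrix = mrna_sheet = None
        if "mrna_matrix" in inp:
            mrna_matrix = read_expression_matrix(_need("mrna_matrix"))
            mrna_sheet = read_sample_sheet(_need("mrna_sheet"))
        predictions = None
        if "predictions" in inp:
            predictions = read_prediction_tables(
                {name: Path(p) for name, p in inp["predictions"].items()}
            )
        result = analyze(
            rat_matrix, rat_sheet, human_matrix, human_sheet,
            mrna_matrix, mrna_sheet, predictions,
            filter_config=fcfg, preprocess_config=pcfg, seed=seed,
        )
    else:
        synth = config.get("synthetic", {})
        result = run_synthetic_pipeline(
            seed=seed,
            filter_config=fcfg,
            preprocess_config=pcfg,
            rat_overrides=synth.get("rat", {}),
            human_overrides=synth.get("human", {}),
        )
    write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write all tables, the Newick tree, figures and the run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_records = [r for recs in result.rat_records.values() for r in recs]
    records_to_frame(all_records).to_csv(out / "rat_fold_changes.tsv", sep="\t", index=False)
    human_all = [r for recs in result.human_records.values() for r in recs]
    records_to_frame(human_all).to_csv(out / "human_fold_changes.tsv", sep="\t", index=False)
    if result.mrna_records:
        mrna_all = [r for recs in result.mrna_records.values() for r in recs]
        records_to_frame(mrna_all).to_csv(out / "mrna_fold_changes.tsv", sep="\t", index=False)

    sig_rows = [
        {
            "mirna_id": e.mirna_id,
            "direction": e.direction,
            "concordant": e.concordant,
            **{f"rat_{s}_fc": fc for s, fc in e.rat_fc.items()},
            **{f"human_{l}_fc": fc for l, fc in e.human_fc.items()},
        }
        for e in result.signature
    ]
    pd.DataFrame(sig_rows).to_csv(out / "signature.tsv", sep="\t", index=False)

    venn_rows = [
        {"sets": "|".join(sorted(pattern)), "count": count}
        for pattern, count in sorted(result.venn.regions.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(venn_rows).to_csv(out / "venn_counts.tsv", sep="\t", index=False)

    if result.pair_evaluations:
        pd.DataFrame([vars(p) for p in result.pair_evaluations]).to_csv(
            out / "pair_evaluations.tsv", sep="\t", index=False
        )
    if result.votes:
        pd.DataFrame(
            [
                {"mirna_id": v.mirna_id, "gene_id": v.gene_id, "votes": v.votes,
                 "accepted": v.accepted, "databases": "|".join(sorted(v.databases))}
                for v in result.votes
            ]
        ).to_csv(out / "target_votes.tsv", sep="\t", index=False)
    if result.qpcr_results:
        rows = [
            {"contrast": contrast_name, "feature_id": r.feature_id, "ddct": r.ddct,
             "fold_change": r.fold_change, "signed_fc": r.signed_fc, "sem": r.sem}
            for contrast_name, rels in result.qpcr_results.items()
            for r in rels
        ]
        pd.DataFrame(rows).to_csv(out / "qpcr_fold_changes.tsv", sep="\t", index=False)

    (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    if result.subject_pca is not None:
        result.subject_pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="subject")
    pd.DataFrame(
        [{"case_label": k, "pearson_r": v} for k, v in result.correlations.items()]
    ).to_csv(out / "pearson_correlations.tsv", sep="\t", index=False)

    plot_heatmap(result.profiles, out / "heatmap.png")
    if result.subject_pca is not None and result.subject_groups is not None:
        plot_pca_scores(
            result.subject_pca, out / "pca.png",
            color_by=result.subject_groups.reindex(result.subject_pca.scores.index),
        )

    log = {
        "package": "mirsig",
        "version": __version__,
        "seed": result.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "signature": [e.mirna_id for e in result.concordant_signature],
        "n_detected": {f"{sp}:{src}": len(v) for (sp, src), v in result.detected.items()},
        "venn_all_sources": result.venn.in_all(),
        "correlations": result.correlations,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
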