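"""Generator correctness: determinism, closed-form effects, noise calibration."""

import numpy as np
import pytest

from mirsig.diffexp import contrast
from mirsig.io_formats import ConfigurationError
from mirsig.preprocess import normalize_u6
from mirsig.qpcr import relative_expression
from mirsig.synthetic_data import (
    GeneratorConfig,
    PlantedEffect,
    default_human_config,
    default_rat_config,
    generate_microarray_study,
    generate_prediction_tables,
    generate_qpcr_plate,
)


def _pancreas_cfg(seed=0, **kw):
    planted = (PlantedEffect("miR-144", "rat", "pancreas", "HFD", "up", 3.0),)
    base = dict(
        sources=("pancreas",),
        planted=planted,
        n_background_features=20,
        seed=seed,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestMicroarrayStudy:
    def test_noiseless_planted_effect_is_exact_after_normalization(self):
        cfg = _pancreas_cfg(noise_sd=0.0, dropout_rate=0.0)
        matrix, sheet, _ = generate_microarray_study(cfg)
        norm = normalize_u6(matrix)
        ctl = sheet.samples("rat", "pancreas", "control")["sample_id"]
        case = sheet.samples("rat", "pancreas", "case", "HFD")["sample_id"]
        fc = norm.data.loc["miR-144", list(case)].mean() / norm.data.loc["miR-144", list(ctl)].mean()
        assert fc == pytest.approx(8.0, rel=1e-12)

    def test_same_seed_is_bit_identical(self):
        m1, s1, t1 = generate_microarray_study(default_rat_config(seed=7))
        m2, s2, t2 = generate_microarray_study(default_rat_config(seed=7))
        assert m1.data.equals(m2.data)
        assert s1.data.equals(s2.data)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        m1, _, _ = generate_microarray_study(default_rat_config(seed=1))
        m2, _, _ = generate_microarray_study(default_rat_config(seed=2))
        assert not m1.data.equals(m2.data)

    def test_truth_flags_exactly_the_planted_features(self):
        cfg = default_rat_config(seed=0)
        _, _, truth = generate_microarray_study(cfg)
        planted_ids = {e.feature_id for e in cfg.planted}
        assert set(truth.loc[truth.signature, "feature_id"]) == planted_ids

    def test_planted_collision_with_normalizer_rejected(self):
        with pytest.raises(ConfigurationError, match="U6"):
            GeneratorConfig(planted=(PlantedEffect("U6", "rat", "pancreas", "HFD", "up", 1.0),))

    def test_background_log_fc_spread_matches_sampling_variance(self):
        """Empirical sd of background log2 fold changes over seeds matches
        noise_sd * sqrt(1/n_case + 1/n_control) within 15%."""
        noise_sd, n = 0.25, 6
        log_fcs = []
        for seed in range(20):
            cfg = _pancreas_cfg(
                seed=seed, noise_sd=noise_sd, dropout_rate=0.0,
                n_background_features=50, scale_jitter_sd=0.0,
            )
            matrix, sheet, _ = generate_microarray_study(cfg)
            ctl = list(sheet.samples("rat", "pancreas", "control")["sample_id"])
            case = list(sheet.samples("rat", "pancreas", "case", "HFD")["sample_id"])
            bg = [f for f in matrix.feature_ids if f.startswith("miR-sim")]
            log_vals = np.log2(matrix.data.loc[bg])
            log_fcs.extend(log_vals[case].mean(axis=1) - log_vals[ctl].mean(axis=1))
        expected = noise_sd * np.sqrt(2 / n)
        assert np.std(log_fcs) == pytest.approx(expected, rel=0.15)

    def test_planted_fold_change_recovered_within_three_sems(self):
        cfg = default_rat_config(seed=11)
        matrix, sheet, truth = generate_microarray_study(cfg)
        norm = normalize_u6(matrix)
        records = {
            r.feature_id: r for r in contrast(norm, sheet, "rat", "pancreas", "HFD")
        }
        n = cfg.n_case
        for e in cfg.planted:
            if e.source != "pancreas":
                continue
            r = records[e.feature_id]
            # sem of the log2 ratio estimate
            sem = cfg.noise_sd * np.sqrt(2 / n)
            assert abs(np.log2(r.ratio) - e.signed_log2) < 3 * sem


class TestQpcrPlate:
    def test_noiseless_one_cycle_effect_gives_fold_two(self):
        cfg = _pancreas_cfg(
            ct_noise_sd=0.0,
            planted=(PlantedEffect("miR-144", "rat", "blood", "HFD", "up", 1.0),),
            case_labels=("HFD",),
        )
        plate = generate_qpcr_plate(cfg, ["miR-144"], source="blood")
        (rel,) = relative_expression(plate, "HFD", "control")
        assert rel.fold_change == pytest.approx(2.0, rel=1e-12)

    def test_noiseless_no_effect_gives_fold_one(self):
        cfg = _pancreas_cfg(ct_noise_sd=0.0, planted=())
        plate = generate_qpcr_plate(cfg, ["miR-999"])
        (rel,) = relative_expression(plate, "HFD", "control")
        assert rel.fold_change == pytest.approx(1.0, rel=1e-12)

    def test_monte_carlo_recovery_is_unbiased(self):
        e = 1.618
        planted = (PlantedEffect("miR-144", "rat", "blood", "HFD", "up", e),)
        fcs = []
        for seed in range(100):
            cfg = _pancreas_cfg(seed=seed, ct_noise_sd=0.1, planted=planted)
            plate = generate_qpcr_plate(cfg, ["miR-144"], source="blood")
            (rel,) = relative_expression(plate, "HFD", "control")
            fcs.append(rel.fold_change)
        fcs = np.asarray(fcs)
        sem = fcs.std(ddof=1) / np.sqrt(len(fcs))
        assert abs(fcs.mean() - 2.0**e) < 3 * sem

    def test_empty_target_list_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_qpcr_plate(_pancreas_cfg(), [])


class TestPredictionTables:
    def test_vote_counts_equal_requested_counts(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 6))
            votes = int(rng.integers(1, k + 1))
            n_true = int(rng.integers(1, 6))
            true_pairs = [(f"miR-{i}", f"G{i}") for i in range(n_true)]
            cfg = GeneratorConfig(seed=seed)
            ps, truth = generate_prediction_tables(
                cfg, true_pairs, k=k, votes_per_true_pair=votes, n_decoys=10
            )
            observed = {pair: len(dbs) for pair, dbs in ps.votes().items()}
            for _, row in truth.iterrows():
                assert observed.get((row.mirna_id, row.gene_id), 0) == row.votes
                if row.is_true:
                    assert row.votes == votes
                else:
                    assert row.votes <= min(2, k - 1)

    def test_votes_exceeding_k_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_prediction_tables(GeneratorConfig(), [("a", "b")], k=3, votes_per_true_pair=4)


class TestHumanCohort:
    def test_human_study_has_replicates_and_three_groups(self):
        cfg = default_human_config(seed=0)
        matrix, sheet, _ = generate_microarray_study(cfg)
        assert sheet.case_labels("human", "blood") == ["IFG", "T2D"]
        # two replicate samples per subject
        per_subject = sheet.data.groupby("subject_id").size()
        assert (per_subject == 2).all()
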