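"""Venn regions, multi-source concordance, and cross-species signature selection."""

from itertools import chain, combinations

import numpy as np
import pytest

from mirsig.diffexp import FilterConfig, FoldChangeRecord
from mirsig.io_formats import ConfigurationError
from mirsig.signature import (
    SignatureEntry,
    cross_source_signature,
    cross_species_signature,
    venn_counts,
)

SOURCES = ("pancreas", "liver", "adipose", "skeletal_muscle", "blood")


def record(feature, source="blood", fc=2.0, p=0.01, repl=1.0, species="rat", label="HFD"):
    return FoldChangeRecord(
        feature_id=feature, species=species, source=source, case_label=label,
        ratio=fc if fc > 0 else -1 / fc, signed_fc=fc, p_value=p, q_value=p,
        replication_fraction=repl, n_case=6, n_control=6,
        significant=p < 0.05, magnitude=abs(fc) >= 1.5, replicated=repl >= 0.5,
    )


class TestVennCounts:
    def test_two_overlapping_sets(self):
        vc = venn_counts({"A": {"a", "b"}, "B": {"b", "c"}})
        assert vc.count("A") == 1 and vc.count("B") == 1 and vc.count("A", "B") == 1
        assert vc.union_size == 3

    def test_five_identical_sets_of_84(self):
        s = {f"miR-{i}" for i in range(84)}
        vc = venn_counts({name: set(s) for name in SOURCES})
        assert vc.in_all() == 84
        assert sum(vc.regions.values()) == 84

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            venn_counts([("A", {"x"}), ("A", {"y"})])

    def test_matches_exhaustive_membership_enumeration(self):
        rng = np.random.default_rng(0)
        universe = [f"m{i}" for i in range(30)]
        for _ in range(100):
            sets = {
                name: {u for u in universe if rng.random() < 0.4} for name in SOURCES
            }
            vc = venn_counts(sets)
            # oracle: count elements per exact membership pattern
            for pattern in chain.from_iterable(
                combinations(SOURCES, r) for r in range(1, 6)
            ):
                inside = set(pattern)
                expected = sum(
                    1
                    for u in set().union(*sets.values())
                    if {n for n in SOURCES if u in sets[n]} == inside
                )
                assert vc.count(*pattern) == expected
            assert sum(vc.regions.values()) == vc.union_size


class TestCrossSourceSignature:
    def _records(self, spec):
        """spec: feature -> per-source signed fc (passing records)."""
        return {
            src: [record(f, source=src, fc=fcs[src]) for f, fcs in spec.items()]
            for src in SOURCES
        }

    def test_consistent_direction_retained(self):
        spec = {"miR-144": {s: 3.0 for s in SOURCES}}
        entries = cross_source_signature(self._records(spec), SOURCES)
        assert [e.mirna_id for e in entries] == ["miR-144"]
        assert entries[0].direction == "up"

    def test_sign_flip_in_one_source_excluded(self):
        fcs = {s: 2.0 for s in SOURCES}
        fcs["pancreas"] = -2.0
        entries = cross_source_signature(self._records({"miR-x": fcs}), SOURCES)
        assert entries == []

    def test_failing_one_source_filter_excluded(self):
        records = self._records({"miR-x": {s: 2.0 for s in SOURCES}})
        records["liver"] = [record("miR-x", source="liver", fc=2.0, p=0.5)]
        assert cross_source_signature(records, SOURCES) == []

    def test_missing_source_listed_in_error(self):
        records = self._records({"miR-x": {s: 2.0 for s in SOURCES}})
        del records["adipose"]
        with pytest.raises(ConfigurationError, match="adipose"):
            cross_source_signature(records, SOURCES)

    def test_matches_bruteforce_predicate_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            features = [f"miR-{i}" for i in range(15)]
            records = {
                src: [
                    record(
                        f, source=src,
                        fc=float(rng.choice([-3.0, -1.2, 1.2, 3.0])),
                        p=float(rng.choice([0.01, 0.5])),
                        repl=float(rng.choice([0.2, 1.0])),
                    )
                    for f in features
                ]
                for src in SOURCES
            }
            got = {e.mirna_id for e in cross_source_signature(records, SOURCES)}
            expected = set()
            for f in features:
                recs = [next(r for r in records[s] if r.feature_id == f) for s in SOURCES]
                if all(r.passes_all for r in recs) and len({r.signed_fc > 0 for r in recs}) == 1:
                    expected.add(f)
            assert got == expected

    def test_raising_min_fc_never_grows_signature(self):
        rng = np.random.default_rng(11)
        records = {
            src: [
                record(f"miR-{i}", source=src, fc=float(rng.uniform(1.0, 4.0) * rng.choice([-1, 1])))
                for i in range(20)
            ]
            for src in SOURCES
        }
        sizes = [
            len(cross_source_signature(records, SOURCES, FilterConfig(min_abs_fc=fc)))
            for fc in (1.0, 1.5, 2.0, 3.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCrossSpeciesSignature:
    def _rat_entry(self, mirna, direction="up"):
        fc = 3.0 if direction == "up" else -3.0
        return SignatureEntry(mirna_id=mirna, rat_fc={s: fc for s in SOURCES}, direction=direction)

    def test_concordant_t2d_match(self):
        human = {"T2D": [record("miR-144", fc=3.0, species="human", label="T2D")],
                 "IFG": [record("miR-144", fc=1.4, species="human", label="IFG")]}
        (entry,) = cross_species_signature([self._rat_entry("miR-144")], human)
        assert entry.concordant
        assert entry.human_fc["IFG"] == 1.4

    def test_rat_up_human_down_not_concordant(self):
        human = {"T2D": [record("miR-144", fc=-2.0, species="human", label="T2D")]}
        (entry,) = cross_species_signature([self._rat_entry("miR-144")], human)
        assert not entry.concordant

    def test_ifg_discordance_does_not_block(self):
        """IFG moving the other way (miR-30d-like) must not veto concordance."""
        human = {
            "T2D": [record("miR-30d", fc=-2.0, species="human", label="T2D")],
            "IFG": [record("miR-30d", fc=1.8, species="human", label="IFG")],
        }
        (entry,) = cross_species_signature([self._rat_entry("miR-30d", "down")], human)
        assert entry.concordant

    def test_insignificant_human_record_not_concordant(self):
        human = {"T2D": [record("miR-144", fc=3.0, p=0.2, species="human", label="T2D")]}
        (entry,) = cross_species_signature([self._rat_entry("miR-144")], human)
        assert not entry.concordant

    def test_alias_resolves_mir320_to_mir320a(self):
        human = {"T2D": [record("miR-320", fc=2.0, species="human", label="T2D")]}
        (entry,) = cross_species_signature([self._rat_entry("miR-320a")], human)
        assert entry.mirna_id == "miR-320a"
        assert entry.concordant

    def test_empty_rat_list_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert cross_species_signature([], {"T2D": []}) == []
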