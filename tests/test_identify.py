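"""Best-hit identification against planted truth and set-arithmetic oracles."""

import numpy as np
import pytest

from barcodekit.identify import (
    Assignment,
    IdentificationReport,
    blast1_identify,
    combine_markers,
    evaluate_identification,
    nearest_distance_identify,
)
from barcodekit.k2p import DistanceMatrix, distance_matrix
from barcodekit.simulate import SimConfig, simulate_dataset, substream
from barcodekit.taxa import BarcodeDataset
from conftest import make_record


@pytest.fixture(scope="module")
def unique_haplotype_db():
    cfg = SimConfig(
        n_genera=8, species_per_genus=3, individuals_per_species=2,
        seq_length=200, inter_branch=0.05, intra_branch=0.01, seed=21,
    )
    records, _ = simulate_dataset(cfg)
    assert len({r.sequence for r in records}) == len(records), "haplotypes not unique"
    return BarcodeDataset(marker="SIM", records=records)


@pytest.fixture(scope="module")
def planted_db():
    cfg = SimConfig(
        n_genera=10, species_per_genus=3, individuals_per_species=1,
        seq_length=200, inter_branch=0.04, intra_branch=0.0,
        n_cross_species_identicals=2, seed=22,
    )
    records, truth = simulate_dataset(cfg)
    return BarcodeDataset(marker="SIM", records=records), truth


class TestSingleQuery:
    def test_self_match_unique(self):
        db = BarcodeDataset(
            marker="M",
            records=[
                make_record("a", "G s1", "ACGT" * 50),
                make_record("b", "G s2", "TTTT" * 50),
            ],
        )
        a = blast1_identify(db.records[0], db)
        assert a.best_refs == {"a"} and a.species_correct and a.genus_correct

    def test_cross_species_identical_sequence_is_ambiguous(self):
        seq = "ACGT" * 50
        db = BarcodeDataset(
            marker="M",
            records=[
                make_record("a", "G s1", seq),
                make_record("b", "G s2", seq),
            ],
        )
        a = blast1_identify(db.records[0], db)
        assert a.assigned_species == "ambiguous"
        assert not a.species_correct
        assert a.genus_correct  # both best refs share the genus

    def test_leave_one_out_removes_self(self):
        db = BarcodeDataset(
            marker="M",
            records=[
                make_record("a", "G1 s1", "ACGTACGT" * 20),
                make_record("b", "G2 s2", "TTTTACGG" * 20),
                make_record("c", "G1 s1", "ACGTACGA" * 20),
            ],
        )
        a = blast1_identify(db.records[0], db, mode="leave-one-out")
        assert "a" not in a.best_refs
        assert a.best_refs == {"c"} and a.species_correct

    def test_nearest_distance_tie_is_failure(self):
        ids = ["q", "r1", "r2"]
        values = np.array([[0.0, 0.1, 0.1], [0.1, 0.0, 0.3], [0.1, 0.3, 0.0]])
        m = DistanceMatrix(ids=ids, values=values)
        db = BarcodeDataset(
            marker="M",
            records=[
                make_record("q", "G s1", "A" * 100),
                make_record("r1", "G s2", "C" * 100),
                make_record("r2", "G s3", "G" * 100),
            ],
        )
        a = nearest_distance_identify(db.records[0], db, m, mode="leave-one-out")
        assert a.assigned_species == "ambiguous" and not a.species_correct

    def test_all_undefined_distances_flagged_ambiguous(self):
        ids = ["q", "r"]
        values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        m = DistanceMatrix(ids=ids, values=values)
        db = BarcodeDataset(
            marker="M",
            records=[
                make_record("q", "G s1", "A" * 100),
                make_record("r", "G s1", "C" * 100),
            ],
        )
        a = nearest_distance_identify(db.records[0], db, m, mode="leave-one-out")
        assert a.assigned_species == "ambiguous"
        assert not a.species_correct and not a.genus_correct

    def test_species_correct_implies_genus_correct_invariant(self):
        with pytest.raises(ValueError):
            Assignment("q", "blast1", frozenset({"r"}), "G s1", True, False)


class TestEvaluation:
    def test_unique_haplotypes_give_perfect_rates(self, unique_haplotype_db):
        m = distance_matrix(unique_haplotype_db, mode="pre-aligned")
        for method, kwargs in (("blast1", {}), ("distance", {"matrix": m})):
            rep = evaluate_identification(unique_haplotype_db, method=method, **kwargs)
            assert rep.species_rate == 100.0 and rep.genus_rate == 100.0

    def test_methods_agree_per_query_without_ties(self, unique_haplotype_db):
        m = distance_matrix(unique_haplotype_db, mode="pre-aligned")
        rb = evaluate_identification(unique_haplotype_db, method="blast1")
        rd = evaluate_identification(unique_haplotype_db, method="distance", matrix=m)
        for ab, ad in zip(rb.assignments, rd.assignments):
            assert ab.query_id == ad.query_id
            assert ab.assigned_species == ad.assigned_species

    def test_planted_failures_exact_rate(self, planted_db):
        db, truth = planted_db
        planted = {rid for rid, e in truth.entries.items() if e.partner}
        assert len(planted) == 4  # 2 pairs
        m = distance_matrix(db, mode="pre-aligned")
        for method, kwargs in (("blast1", {}), ("distance", {"matrix": m})):
            rep = evaluate_identification(db, method=method, **kwargs)
            n = rep.n_queries
            assert rep.species_rate == pytest.approx(100.0 * (n - 4) / n)
            for a in rep.assignments:
                assert a.species_correct == (a.query_id not in planted)
                assert not a.species_correct or a.genus_correct

    def test_leave_one_out_all_singletons_species_rate_zero(self):
        cfg = SimConfig(
            n_genera=6, species_per_genus=3, individuals_per_species=1,
            inter_branch=0.03, intra_branch=0.0, seed=23,
        )
        records, _ = simulate_dataset(cfg)
        db = BarcodeDataset(marker="SIM", records=records)
        rep = evaluate_identification(db, method="blast1", mode="leave-one-out")
        assert rep.species_rate == 0.0
        assert rep.genus_rate > 50.0  # congeners remain as references

    def test_per_genus_rates_consistent(self, planted_db):
        db, _ = planted_db
        rep = evaluate_identification(db, method="blast1")
        total = sum(n * sr / 100.0 for n, sr, _ in rep.per_genus_rates.values())
        assert total == pytest.approx(rep.n_queries * rep.species_rate / 100.0)


def _report(marker, correct_sp, all_samples):
    assignments = tuple(
        Assignment(
            query_id=s,
            method="blast1",
            best_refs=frozenset({s}),
            assigned_species="G s1" if s in correct_sp else "ambiguous",
            species_correct=s in correct_sp,
            genus_correct=s in correct_sp,
        )
        for s in all_samples
    )
    n = len(all_samples)
    return IdentificationReport(
        marker=marker,
        method="blast1",
        mode="self-inclusive",
        n_queries=n,
        species_rate=100.0 * len(correct_sp) / n,
        genus_rate=100.0 * len(correct_sp) / n,
        assignments=assignments,
    )


class TestCombination:
    SAMPLES = [f"s{i}" for i in range(10)]

    def _map(self, markers):
        return {s: {m: s for m in markers} for s in self.SAMPLES}

    def test_union_rule(self):
        a = _report("A", {"s0", "s1"}, self.SAMPLES[:3])
        b = _report("B", {"s1", "s2"}, self.SAMPLES[:3])
        comb = combine_markers([a, b], self._map(["A", "B"]))
        assert comb.n_common_samples == 3
        assert comb.species_rate == 100.0

    def test_identical_correct_sets_no_gain(self):
        a = _report("A", {"s0", "s1"}, self.SAMPLES[:4])
        b = _report("B", {"s0", "s1"}, self.SAMPLES[:4])
        comb = combine_markers([a, b], self._map(["A", "B"]))
        assert comb.species_rate == a.species_rate

    def test_random_planted_failures_match_set_arithmetic(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, len(self.SAMPLES) + 1))
            samples = self.SAMPLES[:n]
            ca = {s for s in samples if rng.random() < 0.6}
            cb = {s for s in samples if rng.random() < 0.6}
            if not ca:
                ca = {samples[0]}
            if not cb:
                cb = {samples[0]}
            a = _report("A", ca, samples)
            b = _report("B", cb, samples)
            comb = combine_markers(
                [a, b], {s: {"A": s, "B": s} for s in samples}
            )
            expected = 100.0 * len(ca | cb) / n
            assert comb.species_rate == pytest.approx(expected)
            assert comb.species_rate >= max(a.species_rate, b.species_rate) - 1e-9

    def test_intersection_of_coverage(self):
        a = _report("A", {"s0"}, ["s0", "s1"])
        b = _report("B", {"s2"}, ["s1", "s2"])
        comb = combine_markers(
            [a, b], {s: {"A": s, "B": s} for s in ["s0", "s1", "s2"]}
        )
        assert comb.n_common_samples == 1  # only s1 covered by both
        assert comb.species_rate == 0.0

    def test_empty_common_set_error(self):
        a = _report("A", {"s0"}, ["s0"])
        b = _report("B", {"s1"}, ["s1"])
        with pytest.raises(ValueError, match="no sample"):
            combine_markers([a, b], {s: {"A": s, "B": s} for s in ["s0", "s1"]})

    def test_end_to_end_two_marker_combination(self):
        base = dict(
            n_genera=8, species_per_genus=2, individuals_per_species=1,
            seq_length=150, inter_branch=0.04, intra_branch=0.0, seed=31,
        )
        reports = []
        datasets = {}
        for marker, k in (("A", 2), ("B", 2)):
            records, _ = simulate_dataset(
                SimConfig(marker=marker, n_cross_species_identicals=k, **base)
            )
            ds = BarcodeDataset(marker=marker, records=records)
            datasets[marker] = ds
            m = distance_matrix(ds, mode="pre-aligned")
            reports.append(evaluate_identification(ds, method="distance", matrix=m))
        sample_map = {}
        for marker, ds in datasets.items():
            for rid in ds.record_ids:
                sample_map.setdefault(rid.split("-", 1)[1], {})[marker] = rid
        comb = combine_markers(reports, sample_map)
        assert comb.n_common_samples == reports[0].n_queries
        assert comb.species_rate >= max(r.species_rate for r in reports)
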