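"""Concordance, opposing homozygotes, Mendelian consistency, scans."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from axiomcurate import (
    AA,
    AB,
    BB,
    NOCALL,
    CurationLedger,
    concordance,
    count_mendel_errors,
    filterp,
    mendel_consistent,
    opposing_homozygote_rate,
    scan_duos,
    scan_trios,
)
from axiomcurate.pedigree import MendelianErrorTable
from axiomcurate.synthetic import clean_config, simulate


class TestConcordance:
    def test_identical_vectors(self):
        a = np.array([AA, AB, BB, AA])
        assert concordance(a, a) == (1.0, 4)

    def test_fully_discordant(self):
        a = np.array([AA, AA, AA])
        b = np.array([BB, BB, BB])
        assert concordance(a, b) == (0.0, 3)

    def test_hand_counted_toy_pair(self):
        """20 SNPs, 2 NoCalls in one vector, 3 mismatches among the 18
        mutually called -> 15/18."""
        a = np.array([AA] * 20)
        b = np.array([AA] * 20)
        b[[0, 1]] = NOCALL
        b[[5, 6, 7]] = BB
        frac, n = concordance(a, b)
        assert n == 18
        assert frac == pytest.approx(15 / 18)

    def test_no_overlap_indeterminate(self):
        a = np.array([AA, NOCALL])
        b = np.array([NOCALL, AA])
        frac, n = concordance(a, b)
        assert n == 0 and np.isnan(frac)


class TestOpposingHomozygotes:
    def test_identical_homozygotes_rate_zero(self):
        a = np.array([AA] * 10)
        assert opposing_homozygote_rate(a, a) == (0.0, 10)

    def test_enumerated_example(self):
        a = np.array([AA, AA, BB, AB])
        b = np.array([BB, AA, BB, AA])
        rate, n = opposing_homozygote_rate(a, b)
        assert n == 3  # the AB position is uninformative
        assert rate == pytest.approx(1 / 3)


def _alleles(code):
    return {AA: "AA", AB: "AB", BB: "BB"}[code]


def _brute_force_consistent(p1, p2, c):
    """Independent oracle: enumerate every transmissible allele pair."""
    if NOCALL in (p1, p2, c):
        return True
    for a1 in _alleles(p1):
        for a2 in _alleles(p2):
            if "".join(sorted(a1 + a2)) == _alleles(c):
                return True
    return False


class TestMendelConsistency:
    def test_matches_exhaustive_enumeration_on_all_64_triples(self):
        codes = (NOCALL, BB, AB, AA)
        for p1, p2, c in itertools.product(codes, repeat=3):
            assert mendel_consistent(p1, p2, c) == _brute_force_consistent(
                p1, p2, c
            ), (p1, p2, c)

    def test_forced_transmission_error(self):
        assert not mendel_consistent(AA, AA, AB)

    def test_opposite_homozygote_parents_force_het(self):
        assert mendel_consistent(AA, BB, AB)
        assert not mendel_consistent(AA, BB, AA)

    def test_symmetric_in_parents(self):
        codes = (NOCALL, BB, AB, AA)
        for p1, p2, c in itertools.product(codes, repeat=3):
            assert mendel_consistent(p1, p2, c) == mendel_consistent(p2, p1, c)

    def test_vectorized_counts_match_scalar_loop(self, rng):
        p1 = rng.choice([NOCALL, BB, AB, AA], 300).astype(np.int8)
        p2 = rng.choice([NOCALL, BB, AB, AA], 300).astype(np.int8)
        c = rng.choice([NOCALL, BB, AB, AA], 300).astype(np.int8)
        errors, tested = count_mendel_errors(p1, p2, c)
        for k in range(300):
            t = NOCALL not in (p1[k], p2[k], c[k])
            assert tested[k] == t
            assert errors[k] == (t and not mendel_consistent(p1[k], p2[k], c[k]))


class TestScans:
    @pytest.fixture(scope="class")
    def scanned(self, relationship_sim):
        dataset, truth = relationship_sim
        ledger = CurationLedger()
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
        rels = scan_duos(dataset, ledger)
        trios, table = scan_trios(dataset, ledger)
        return dataset, truth, ledger, rels, trios, table

    def test_planted_duplicate_found_and_one_member_excluded(self, scanned):
        dataset, truth, ledger, rels, _, _ = scanned
        dups = [r for r in rels if r.kind == "duplicate"]
        assert {tuple(sorted(r.members)) for r in dups} == {
            tuple(sorted(p)) for p in truth.duplicates
        }
        excluded = [s for s, st in ledger.sample_status.items() if st.excluded]
        assert len(excluded) == 1
        assert excluded[0] in truth.duplicates[0]
        assert ledger.sample_status[excluded[0]].exclusion_reason == "duplicate"

    def test_po_pairs_recovered_without_false_positives(self, scanned):
        _, truth, _, rels, _, _ = scanned
        got = {
            frozenset(r.members) for r in rels if r.kind == "parent_offspring"
        }
        want = {frozenset(p) for p in truth.parent_offspring}
        assert got == want

    def test_trios_recovered_exactly(self, scanned):
        _, truth, _, _, trios, _ = scanned
        got = {(frozenset(r.members[:2]), r.members[2]) for r in trios}
        want = {(frozenset(t[:2]), t[2]) for t in truth.trios}
        assert got == want

    def test_trio_error_rates_reflect_planted_corruption(self, scanned):
        _, truth, _, _, trios, table = scanned
        # 0.2% call corruption puts every true trio far below the 2%
        # confirmation bound but rarely at exactly zero
        for _, (n_err, n_tested, rate) in table.trio_stats.items():
            assert rate == n_err / n_tested
            assert rate <= 0.02

    def test_duplicate_statistic_symmetric(self, relationship_sim):
        dataset, truth = relationship_sim
        a, b = truth.duplicates[0]
        ia, ib = dataset.sample_index(a), dataset.sample_index(b)
        f1, n1 = concordance(dataset.calls[:, ia], dataset.calls[:, ib])
        f2, n2 = concordance(dataset.calls[:, ib], dataset.calls[:, ia])
        assert (f1, n1) == (f2, n2)
        assert f1 >= 0.98

    def test_parent_swap_leaves_trio_decision_unchanged(self, relationship_sim):
        dataset, truth = relationship_sim
        p1, p2, child = truth.trios[0]
        cols = {s: dataset.sample_index(s) for s in (p1, p2, child)}
        e1, t1 = count_mendel_errors(
            dataset.calls[:, cols[p1]], dataset.calls[:, cols[p2]],
            dataset.calls[:, cols[child]],
        )
        e2, t2 = count_mendel_errors(
            dataset.calls[:, cols[p2]], dataset.calls[:, cols[p1]],
            dataset.calls[:, cols[child]],
        )
        assert np.array_equal(e1, e2) and np.array_equal(t1, t2)

    def test_error_free_family_has_zero_error_counts(self):
        # 2500 SNPs keep every PO pair above the 500 jointly-homozygous
        # informative-site minimum
        dataset, truth = simulate(clean_config(n_snps=2500, seed=9))
        ledger = CurationLedger()
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
        scan_duos(dataset, ledger)
        trios, table = scan_trios(dataset, ledger)
        assert len(trios) == len(truth.trios) == 16
        assert all(n_err == 0 for n_err, _, _ in table.trio_stats.values())
        assert all(v[0] == 0 for v in table.snp_errors.values())

    def test_unrelated_samples_yield_no_po_calls(self):
        # independent draws at frequency 0.5: opposing-homozygote rate
        # concentrates near 0.5, far above the 0.01 threshold
        rng = np.random.default_rng(13)
        calls = rng.binomial(2, 0.5, size=(5000, 12)).astype(np.int8)
        from axiomcurate import AxiomDataset

        dataset = AxiomDataset(
            sample_ids=[f"u{i}" for i in range(12)],
            probeset_ids=[f"p{i}" for i in range(5000)],
            calls=calls,
        )
        ledger = CurationLedger()
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
        rels = scan_duos(dataset, ledger)
        assert rels == []

    def test_pair_below_minimum_is_skipped_with_warning(self):
        from axiomcurate import AxiomDataset

        calls = np.full((100, 2), AA, dtype=np.int8)
        dataset = AxiomDataset(
            sample_ids=["a", "b"],
            probeset_ids=[f"p{i}" for i in range(100)],
            calls=calls,
        )
        ledger = CurationLedger()
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
        with pytest.warns(UserWarning, match="indeterminate"):
            rels = scan_duos(dataset, ledger)
        assert rels == []


class TestFilterp:
    def test_high_error_snp_labeled(self):
        ledger = CurationLedger()
        ledger.register_dataset(["snp0", "snp1"], ["s0"])
        table = MendelianErrorTable(
            snp_errors={"snp0": (3, 10), "snp1": (0, 10)}
        )
        n = filterp(table, ledger, max_errors=2)
        assert n == 1
        assert ledger.snps_in_class("MendelianErrorFilter") == ["snp0"]

    def test_matches_direct_threshold_scan_on_random_tables(self, rng):
        pids = [f"snp{i}" for i in range(200)]
        for rep in range(100):
            ledger = CurationLedger()
            ledger.register_dataset(pids, ["s0"])
            errors = {
                p: (int(rng.integers(0, 6)), 10) for p in pids
            }
            max_errors = int(rng.integers(1, 5))
            filterp(MendelianErrorTable(snp_errors=errors), ledger, max_errors)
            expected = sorted(
                p for p, (n, _) in errors.items() if n >= max_errors
            )
            assert sorted(ledger.snps_in_class("MendelianErrorFilter")) == expected

    def test_lowering_threshold_never_unlabels(self, rng):
        pids = [f"snp{i}" for i in range(50)]
        ledger = CurationLedger()
        ledger.register_dataset(pids, ["s0"])
        errors = {p: (int(rng.integers(0, 5)), 8) for p in pids}
        filterp(MendelianErrorTable(snp_errors=errors), ledger, max_errors=4)
        first = set(ledger.snps_in_class("MendelianErrorFilter"))
        filterp(MendelianErrorTable(snp_errors=errors), ledger, max_errors=2)
        second = set(ledger.snps_in_class("MendelianErrorFilter"))
        assert first <= second

    def test_empty_table_warns(self):
        ledger = CurationLedger()
        ledger.register_dataset(["snp0"], ["s0"])
        with pytest.warns(UserWarning, match="empty"):
            assert filterp(MendelianErrorTable(), ledger) == 0
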