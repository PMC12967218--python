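"""Ledger label semantics, pass-set computation, persistence."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axiomcurate.ledger import (
    AUTOMATIC_EXCLUDING,
    CurationLedger,
    LedgerError,
    Relationship,
    SNPClassLabel,
    SubclusterRecord,
)


def make_ledger(n_snps=10, n_samples=4):
    led = CurationLedger()
    led.register_dataset(
        [f"snp{i}" for i in range(n_snps)], [f"s{j}" for j in range(n_samples)]
    )
    return led


class TestLabelSemantics:
    def test_excluding_label_removes_pass(self):
        led = make_ledger()
        led.apply_labels("snp0", [SNPClassLabel("MonoHighResolution")])
        snps, _ = led.pass_set()
        assert "snp0" not in snps and len(snps) == 9

    def test_apply_twice_is_idempotent(self):
        led = make_ledger()
        lab = [SNPClassLabel("MetricsThreshold", "FLD=2")]
        led.apply_labels("snp1", lab)
        before = led.state_dict()
        led.apply_labels("snp1", lab)
        assert led.state_dict() == before

    def test_manual_include_overrides_automatic(self):
        led = make_ledger()
        led.apply_labels("snp2", [SNPClassLabel("MetricsThreshold")])
        led.apply_labels("snp2", [SNPClassLabel("ManualInclude")])
        assert led.snp_is_pass("snp2")

    def test_manual_exclude_overrides_everything(self):
        led = make_ledger()
        led.apply_labels("snp3", [SNPClassLabel("ManualInclude")])
        led.apply_labels("snp3", [SNPClassLabel("ManualExclude")])
        assert not led.snp_is_pass("snp3")

    def test_unknown_probeset_raises(self):
        led = make_ledger()
        with pytest.raises(KeyError):
            led.apply_labels("nope", [SNPClassLabel("MultipleCluster")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            SNPClassLabel("NotAClass")

    def test_empty_ledger_all_pass(self):
        led = make_ledger(n_snps=25)
        snps, samples = led.pass_set()
        assert len(snps) == 25 and len(samples) == 4


class TestPassSetOracle:
    def test_matches_brute_force_on_random_assignments(self):
        """pass_set equals an independent recomputation of the label-set
        semantics over 1000 random label assignments."""
        rnd = random.Random(42)
        all_labels = list(AUTOMATIC_EXCLUDING) + ["ManualInclude", "ManualExclude"]
        led = make_ledger(n_snps=1000)
        assigned: dict[str, set[str]] = {}
        for pid in led.probeset_ids:
            labels = {
                l for l in all_labels if rnd.random() < 0.15
            }
            assigned[pid] = labels
            led.apply_labels(pid, [SNPClassLabel(l) for l in labels])

        def oracle(labels: set[str]) -> bool:
            if "ManualExclude" in labels:
                return False
            if "ManualInclude" in labels:
                return True
            return not any(l in AUTOMATIC_EXCLUDING for l in labels)

        expected = {pid for pid, labs in assigned.items() if oracle(labs)}
        got, _ = led.pass_set()
        assert got == expected

    def test_pass_set_monotone_under_automatic_labels(self):
        led = make_ledger(n_snps=50)
        rnd = random.Random(7)
        previous, _ = led.pass_set()
        for _ in range(20):
            pid = f"snp{rnd.randrange(50)}"
            led.apply_labels(pid, [SNPClassLabel(rnd.choice(list(AUTOMATIC_EXCLUDING)))])
            current, _ = led.pass_set()
            assert current <= previous
            previous = current


label_strategy = st.builds(
    SNPClassLabel,
    value=st.sampled_from(list(AUTOMATIC_EXCLUDING) + ["ManualInclude", "ManualExclude"]),
    detail=st.text(alphabet="abcXYZ0129 =.<", max_size=12),
)


class TestPersistence:
    def test_round_trip_small(self, tmp_path):
        led = make_ledger()
        led.apply_labels("snp0", [SNPClassLabel("MultipleCluster", "AB split")])
        led.set_ploidy("s0", "triploid", 4)
        led.exclude_sample("s1", "duplicate")
        led.add_relationship(Relationship("duplicate", ("s0", "s1"), 900, 0.995))
        led.add_relationship(Relationship("trio", ("s0", "s2", "s3"), 800, 0.003))
        led.subclusters["snp0"] = [
            SubclusterRecord("AB", 30, 2, 0.6, (14, 16), (-0.3, 0.3))
        ]
        led.mendel_errors = {"snp0": (3, 10)}
        led.log_run("filterc", {"min_separation": 0.3})
        led.save(tmp_path / "ledger.json")
        again = CurationLedger.load(tmp_path / "ledger.json")
        assert again.same_state(led)
        assert again.run_log == led.run_log

    def test_truncated_file_raises_cleanly(self, tmp_path):
        led = make_ledger()
        path = led.save(tmp_path / "ledger.json")
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(LedgerError):
            CurationLedger.load(path)

    def test_register_different_dataset_rejected(self):
        led = make_ledger()
        with pytest.raises(LedgerError):
            led.register_dataset(["other"], ["s0"])

    @settings(max_examples=25, deadline=None)
    @given(data=st.dictionaries(
        st.sampled_from([f"snp{i}" for i in range(10)]),
        st.sets(label_strategy, max_size=4),
    ))
    def test_round_trip_arbitrary_labels(self, tmp_path_factory, data):
        led = make_ledger()
        for pid, labels in data.items():
            led.apply_labels(pid, labels)
        path = tmp_path_factory.mktemp("led") / "ledger.json"
        led.save(path)
        assert CurationLedger.load(path).same_state(led)


def test_sequential_commands_accumulate_label_families(defect_sim):
    """filterm then filterc on the same ledger keeps both label families."""
    from axiomcurate import filterc, filterm

    dataset, _ = defect_sim
    led = CurationLedger()
    led.register_dataset(dataset.probeset_ids, dataset.sample_ids)
    filterm(dataset, led)
    mono = set(led.snps_in_class("MonoHighResolution"))
    sub = dataset.probeset_ids[:400]
    # restrict filterc to a subset for speed by running on a sliced dataset
    from axiomcurate import AxiomDataset

    small = AxiomDataset(
        sample_ids=dataset.sample_ids,
        probeset_ids=sub,
        calls=dataset.calls[:400],
        contrast=dataset.contrast[:400],
        size=dataset.size[:400],
        metrics=dataset.metrics.iloc[:400],
    )
    led2 = CurationLedger()
    led2.register_dataset(small.probeset_ids, small.sample_ids)
    filterm(small, led2)
    filterc(small, led2)
    multi = set(led2.snps_in_class("MultipleCluster"))
    monos = set(led2.snps_in_class("MonoHighResolution"))
    assert multi and monos  # both families present in one ledger
    assert mono  # and filterm alone found the injected monomorphic SNPs
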