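"""Cluster summaries and SNP classes (i)-(iv)."""

from __future__ import annotations

import numpy as np
import pytest

from axiomcurate import (
    AA,
    AB,
    BB,
    NOCALL,
    CurationLedger,
    MetricThresholds,
    VarianceZContext,
    apply_metric_thresholds,
    classify_hom_hom,
    classify_mono_high_resolution,
    classify_unexpected_distribution,
    filterm,
    summarize_clusters,
)
from axiomcurate.filter_metrics import ClusterSummary
from axiomcurate.types import SNPMetrics, SNPRecord


def make_snp(calls, contrasts, metrics=None, pid="snp"):
    calls = np.asarray(calls, dtype=np.int8)
    return SNPRecord(
        probeset_id=pid,
        calls=calls,
        contrast=np.asarray(contrasts, dtype=float),
        size=np.full(len(calls), 1.5),
        metrics=metrics or SNPMetrics(),
    )


def summaries_for(calls, contrasts):
    return summarize_clusters(make_snp(calls, contrasts))


class TestSummarizeClusters:
    def test_midpoint_arithmetic(self):
        s = summaries_for([AA, AA, AB, BB], [1.0, 1.2, 0.0, -1.1])
        by_geno = {x.genotype: x for x in s}
        assert by_geno[AA].n == 2
        assert by_geno[AA].contrast_midpoint == pytest.approx(1.1)
        assert by_geno[AB].n == 1
        assert np.isnan(by_geno[AB].contrast_variance)  # undefined at n=1

    def test_all_nocall_gives_empty_list(self):
        assert summaries_for([NOCALL, NOCALL], [0.1, 0.2]) == []

    def test_matches_group_by_oracle_on_random_snps(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            calls = rng.choice([AA, AB, BB, NOCALL], n).astype(np.int8)
            contrasts = rng.normal(0, 1, n)
            got = {
                s.genotype: s for s in summaries_for(calls, contrasts)
            }
            for g in (AA, AB, BB):
                sel = contrasts[calls == g]
                if len(sel) == 0:
                    assert g not in got
                    continue
                assert got[g].n == len(sel)
                assert got[g].contrast_midpoint == pytest.approx(sel.mean())
                if len(sel) >= 2:
                    assert got[g].contrast_variance == pytest.approx(
                        sel.var(ddof=1)
                    )

    def test_invariant_under_sample_reordering(self, rng):
        calls = rng.choice([AA, AB, BB, NOCALL], 30).astype(np.int8)
        contrasts = rng.normal(0, 1, 30)
        perm = rng.permutation(30)
        a = summaries_for(calls, contrasts)
        b = summaries_for(calls[perm], contrasts[perm])
        for x, y in zip(a, b):
            assert x.genotype == y.genotype and x.n == y.n
            assert x.contrast_midpoint == pytest.approx(y.contrast_midpoint)


class TestClassRules:
    def test_mono_only_one_cluster(self):
        assert classify_mono_high_resolution(
            summaries_for([AA, AA, AA], [1.0, 1.1, 0.9])
        ) is not None

    def test_mono_not_fired_with_two_clusters(self):
        assert classify_mono_high_resolution(
            summaries_for([AA, AB], [1.0, 0.0])
        ) is None

    def test_mono_not_fired_on_zero_clusters(self):
        assert classify_mono_high_resolution([]) is None

    def test_hom_hom_exactly_aa_and_bb(self):
        assert classify_hom_hom(
            summaries_for([AA, BB, AA], [1.0, -1.0, 1.1])
        ) is not None
        assert classify_hom_hom(summaries_for([AA, AB], [1.0, 0.0])) is None
        assert classify_hom_hom(
            summaries_for([AA, AB, BB], [1.0, 0.0, -1.0])
        ) is None

    def test_mono_and_hom_hom_mutually_exclusive(self, rng):
        for _ in range(100):
            calls = rng.choice([AA, AB, BB, NOCALL], 20).astype(np.int8)
            s = summaries_for(calls, rng.normal(0, 1, 20))
            fired = [
                classify_mono_high_resolution(s) is not None,
                classify_hom_hom(s) is not None,
            ]
            assert sum(fired) <= 1

    @pytest.mark.parametrize(
        "midpoints,expected",
        [
            ({AA: 1.6, BB: -1.0}, True),  # one displaced cluster suffices
            ({AA: 1.0, BB: -1.0}, False),
            ({AA: 1.0, BB: -1.5}, True),  # inclusive bound: "at least"
        ],
    )
    def test_unexpected_distribution_bound(self, midpoints, expected):
        summaries = [
            ClusterSummary(g, 10, mid, 0.01) for g, mid in midpoints.items()
        ]
        fired = classify_unexpected_distribution(summaries) is not None
        assert fired == expected

    def test_het_midpoint_never_triggers_class_iii(self):
        summaries = [ClusterSummary(AB, 10, 1.9, 0.01)]
        assert classify_unexpected_distribution(summaries) is None


class TestMetricThresholds:
    def _ctx(self, mean=0.01, sd=0.002):
        return VarianceZContext(mean=mean, sd=sd)

    def test_low_fld_flagged(self):
        snp = make_snp([AA, AB, BB], [1, 0, -1], SNPMetrics(fld=2.0))
        labels = apply_metric_thresholds(
            snp, summaries_for(snp.calls, snp.contrast), MetricThresholds(), self._ctx()
        )
        assert any("FLD" in l.detail for l in labels)

    def test_all_metrics_missing_no_labels(self):
        snp = make_snp([AA, AB, BB], [1, 0, -1], SNPMetrics())
        assert apply_metric_thresholds(
            snp, summaries_for(snp.calls, snp.contrast), MetricThresholds(), self._ctx()
        ) == []

    def test_variance_at_dataset_mean_never_z_flagged(self):
        snp = make_snp(
            [AA, AB, BB], [1, 0, -1],
            SNPMetrics(cluster_variance={AA: 0.01, AB: 0.01, BB: 0.01}),
        )
        labels = apply_metric_thresholds(
            snp,
            summaries_for(snp.calls, snp.contrast),
            MetricThresholds(),
            self._ctx(mean=0.01, sd=0.002),
        )
        assert labels == []

    def test_hom_fld_applies_only_without_het_cluster(self):
        m = SNPMetrics(hom_fld=2.0)
        with_het = make_snp([AA, AB, BB], [1, 0, -1], m)
        no_het = make_snp([AA, BB], [1, -1], m)
        assert apply_metric_thresholds(
            with_het, summaries_for(with_het.calls, with_het.contrast),
            MetricThresholds(), self._ctx(),
        ) == []
        assert apply_metric_thresholds(
            no_het, summaries_for(no_het.calls, no_het.contrast),
            MetricThresholds(), self._ctx(),
        ) != []

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            MetricThresholds(min_fld=float("nan")).validate()


class TestFilterm:
    def test_injected_classes_recovered_exactly(self, defect_sim, registered_ledger):
        dataset, truth = defect_sim
        filterm(dataset, registered_ledger)
        for cls in ("MonoHighResolution", "HomHomCluster"):
            detected = set(registered_ledger.snps_in_class(cls))
            expected = {p for p, c in truth.snp_class.items() if c == cls}
            assert detected == expected

    def test_idempotent(self, defect_sim, registered_ledger):
        dataset, _ = defect_sim
        filterm(dataset, registered_ledger)
        before = registered_ledger.state_dict()
        filterm(dataset, registered_ledger)
        assert registered_ledger.state_dict() == before

    def test_disabled_thresholds_leave_only_composition_classes(
        self, defect_sim
    ):
        dataset, truth = defect_sim
        led = CurationLedger()
        led.register_dataset(dataset.probeset_ids, dataset.sample_ids)
        off = MetricThresholds(
            min_fld=None, min_hom_fld=None, min_het_so=None,
            min_hom_ro=None, max_cluster_variance=None,
            max_abs_variance_zscore=None,
        )
        counts = filterm(dataset, led, thresholds=off)
        assert "MetricsThreshold" not in counts
        assert counts.get("MonoHighResolution", 0) > 0
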