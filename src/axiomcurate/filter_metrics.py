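"""Genotype-count and metric-threshold SNP filters (the ``filterm`` step).

Four problematic-SNP classes are assigned from the composition of
genotype calls, the positions of the homozygote clusters on the
contrast axis, and the vendor clustering metrics:

(i)   *MonoHighResolution* — only one genotype cluster is present;
(ii)  *HomHomCluster* — exactly the two homozygote clusters, no
      heterozygotes (a null-allele-like pattern);
(iii) *UnexpectedDistribution* — a homozygote cluster's contrast
      midpoint lies at least ``midpoint_limit`` (default 1.5) from 0;
(iv)  *MetricsThreshold* — a quality metric (FLD, HomFLD, HetSO, HomRO,
      cluster variance, or its dataset-wide z-score) fails its
      threshold.

Default thresholds follow the published Axiom Best Practices values;
every threshold is optional — unset disables that test.  Minima fail on
strict ``<``, maxima on strict ``>``; the class-(iii) bound is
inclusive ("at least").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ledger import CurationLedger, SNPClassLabel
from .types import AA, AB, BB, AxiomDataset, SNPRecord, CODE_TO_LETTER


@dataclass(frozen=True)
class ClusterSummary:
    """One called genotype cluster of one SNP among included samples."""

    genotype: int  # AA | AB | BB
    n: int
    contrast_midpoint: float  # mean contrast; NaN if no finite signal
    contrast_variance: float  # sample variance; NaN if n < 2

    @property
    def genotype_letter(self) -> str:
        return CODE_TO_LETTER[self.genotype]


@dataclass(frozen=True)
class MetricThresholds:
    """Metric acceptance thresholds; ``None`` disables a test.

    ``min_hom_ro`` is keyed by the number of genotype clusters present
    (1, 2 or 3).  The HomFLD test applies only when no heterozygote
    cluster exists.  The variance z-score test compares each cluster
    variance against the dataset-wide mean/sd of cluster variances.
    """

    min_fld: float | None = 3.6
    min_hom_fld: float | None = 6.5
    min_het_so: float | None = -0.1
    min_hom_ro: Mapping[int, float] | None = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: -0.9}
    )
    max_cluster_variance: float | None = None
    max_abs_variance_zscore: float | None = 2.0

    def validate(self) -> None:
        scalars = [
            self.min_fld,
            self.min_hom_fld,
            self.min_het_so,
            self.max_cluster_variance,
            self.max_abs_variance_zscore,
        ]
        if self.min_hom_ro is not None:
            scalars += list(self.min_hom_ro.values())
        for v in scalars:
            if v is not None and not math.isfinite(v):
                raise ValueError(f"non-finite threshold {v!r} in configuration")


@dataclass(frozen=True)
class VarianceZContext:
    """Dataset-wide mean and sd of per-cluster contrast variances,
    computed once per run from the metrics table."""

    mean: float
    sd: float

    @classmethod
    def from_dataset(cls, dataset: AxiomDataset) -> "VarianceZContext":
        v = dataset.metrics[["var_aa", "var_ab", "var_bb"]].to_numpy().ravel()
        v = v[np.isfinite(v)]
        if v.size < 2:
            return cls(mean=float("nan"), sd=float("nan"))
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)))


def summarize_clusters(
    snp: SNPRecord, included: np.ndarray | Sequence[bool] | None = None
) -> list[ClusterSummary]:
    """Per-genotype call counts and contrast midpoint/variance.

    ``included`` is a boolean mask over the dataset's samples; NoCall
    samples are always ignored.  Returns one summary per genotype class
    with at least one call, in AA, AB, BB order.
    """
    calls = snp.calls
    mask = np.ones(len(calls), dtype=bool) if included is None else np.asarray(included, bool)
    out: list[ClusterSummary] = []
    for g in (AA, AB, BB):
        sel = mask & (calls == g)
        n = int(sel.sum())
        if n == 0:
            continue
        c = snp.contrast[sel]
        c = c[np.isfinite(c)]
        midpoint = float(c.mean()) if c.size else float("nan")
        variance = float(c.var(ddof=1)) if c.size >= 2 else float("nan")
        out.append(ClusterSummary(g, n, midpoint, variance))
    return out


def classify_mono_high_resolution(
    summaries: Sequence[ClusterSummary],
) -> SNPClassLabel | None:
    """Class (i): exactly one genotype cluster among called samples.

    Zero clusters (all NoCall) is not this class — it is handled as a
    call-rate concern by :func:`filterm`.
    """
    if len(summaries) == 1:
        return SNPClassLabel(
            "MonoHighResolution", f"only {summaries[0].genotype_letter} called"
        )
    return None


def classify_hom_hom(
    summaries: Sequence[ClusterSummary],
) -> SNPClassLabel | None:
    """Class (ii): exactly the AA and BB clusters, no AB."""
    present = {s.genotype for s in summaries}
    if present == {AA, BB}:
        return SNPClassLabel("HomHomCluster", "AA and BB only, no AB")
    return None


def classify_unexpected_distribution(
    summaries: Sequence[ClusterSummary], midpoint_limit: float = 1.5
) -> SNPClassLabel | None:
    """Class (iii): a homozygote cluster midpoint at least
    ``midpoint_limit`` from contrast 0 (inclusive bound; flags on any
    one displaced cluster)."""
    if not midpoint_limit > 0:
        raise ValueError("midpoint_limit must be positive")
    for s in summaries:
        if s.genotype in (AA, BB) and math.isfinite(s.contrast_midpoint):
            if abs(s.contrast_midpoint) >= midpoint_limit:
                return SNPClassLabel(
                    "UnexpectedDistribution",
                    f"{s.genotype_letter} midpoint {s.contrast_midpoint:.3f}",
                )
    return None


def apply_metric_thresholds(
    snp: SNPRecord,
    summaries: Sequence[ClusterSummary],
    thresholds: MetricThresholds,
    variance_z_context: VarianceZContext,
) -> list[SNPClassLabel]:
    """Class (iv): one MetricsThreshold label per failed metric test.

    Missing metrics skip their test; the HomFLD test applies only when
    no AB cluster exists among the summaries.
    """
    thresholds.validate()
    labels: list[SNPClassLabel] = []
    m = snp.metrics

    def fail(name: str, value: float, bound: float) -> None:
        labels.append(
            SNPClassLabel("MetricsThreshold", f"{name}={value:.4g} vs {bound:.4g}")
        )

    if thresholds.min_fld is not None and math.isfinite(m.fld):
        if m.fld < thresholds.min_fld:
            fail("FLD", m.fld, thresholds.min_fld)
    has_het = any(s.genotype == AB for s in summaries)
    if (
        thresholds.min_hom_fld is not None
        and not has_het
        and math.isfinite(m.hom_fld)
        and m.hom_fld < thresholds.min_hom_fld
    ):
        fail("HomFLD", m.hom_fld, thresholds.min_hom_fld)
    if thresholds.min_het_so is not None and math.isfinite(m.het_so):
        if m.het_so < thresholds.min_het_so:
            fail("HetSO", m.het_so, thresholds.min_het_so)
    if thresholds.min_hom_ro is not None and math.isfinite(m.hom_ro):
        bound = thresholds.min_hom_ro.get(len(summaries))
        if bound is not None and m.hom_ro < bound:
            fail("HomRO", m.hom_ro, bound)

    for g, letter in ((AA, "AA"), (AB, "AB"), (BB, "BB")):
        v = m.variance(g)
        if not math.isfinite(v):
            continue
        if thresholds.max_cluster_variance is not None and v > thresholds.max_cluster_variance:
            fail(f"Var.{letter}", v, thresholds.max_cluster_variance)
        if thresholds.max_abs_variance_zscore is not None and math.isfinite(
            variance_z_context.sd
        ) and variance_z_context.sd > 0:
            z = abs(v - variance_z_context.mean) / variance_z_context.sd
            if z > thresholds.max_abs_variance_zscore:
                fail(f"Var.{letter} z-score", z, thresholds.max_abs_variance_zscore)
    return labels


def filterm(
    dataset: AxiomDataset,
    ledger: CurationLedger,
    thresholds: MetricThresholds | None = None,
    midpoint_limit: float = 1.5,
) -> dict[str, int]:
    """Run filters (i)-(iv) over every SNP and merge labels into the ledger.

    Samples excluded in the ledger (and samples flagged non-diploid)
    are ignored in all counts.  A SNP with zero called samples receives
    ``MetricsThreshold(no-calls)``.  Returns per-class label counts;
    re-running with identical inputs leaves the ledger unchanged.
    """
    thresholds = thresholds or MetricThresholds()
    thresholds.validate()
    if not ledger.registered:
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
    elif ledger.sample_ids != dataset.sample_ids:
        raise ValueError("dataset samples do not match the ledger")

    analysis = ledger.analysis_samples()
    included = np.array([s in analysis for s in dataset.sample_ids])
    zctx = VarianceZContext.from_dataset(dataset)
    counts: dict[str, int] = {}
    for snp in dataset.iter_snps():
        summaries = summarize_clusters(snp, included)
        labels: list[SNPClassLabel] = []
        if not summaries:
            labels.append(SNPClassLabel("MetricsThreshold", "no-calls"))
        else:
            for lab in (
                classify_mono_high_resolution(summaries),
                classify_hom_hom(summaries),
                classify_unexpected_distribution(summaries, midpoint_limit),
            ):
                if lab is not None:
                    labels.append(lab)
            labels.extend(
                apply_metric_thresholds(snp, summaries, thresholds, zctx)
            )
        if labels:
            ledger.apply_labels(snp.probeset_id, labels)
            for lab in labels:
                counts[lab.value] = counts.get(lab.value, 0) + 1
    return counts
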