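"""Sub-cluster detection within genotype clusters (the ``filterc`` step).

A well-behaved biallelic SNP shows three clusters on the contrast axis.
Genotype-calling artifacts (null alleles, probe cross-hybridisation,
copy-number variation) can split one called cluster into two, producing
four or more visible clusters; such *MultipleCluster* SNPs are
error-prone and must be flagged.

Each called genotype cluster is analyzed independently in one dimension
(the contrast axis).  The detector compares a one-component Gaussian
description of the cluster against a two-component Gaussian mixture
fitted by EM with a deterministic median-split initialisation, using
the Bayesian information criterion: the split wins only if its
penalized fit score improves on the single component.  A winning split
must then pass acceptance gates — each subcluster at least
``min_points`` samples and ``min_fraction`` of the cluster, and a
center separation of at least ``min_separation`` contrast units —
otherwise the cluster is reported as one component.  The gates keep the
detector robust at array scale without per-SNP tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ledger import CurationLedger, SNPClassLabel, SubclusterRecord
from .types import AA, AB, BB, AxiomDataset, CODE_TO_LETTER

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SubclusterConfig:
    """Acceptance gates and EM settings for the split test."""

    min_points: int = 5
    min_fraction: float = 0.05
    min_separation: float = 0.3
    max_iter: int = 60
    tol: float = 1e-6
    var_floor: float = 1e-6


def _gaussian_loglik(x: np.ndarray, mean: float, var: float) -> float:
    return float(
        -0.5 * np.sum(_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)
    )


def _fit_two_component(
    x: np.ndarray, config: SubclusterConfig
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """EM fit of a two-component 1-D Gaussian mixture.

    Initialisation splits the sorted points at the median, which makes
    the fit deterministic (no seed required).  Returns the maximized
    log-likelihood, component means, variances, and responsibilities of
    component 2.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    half = n // 2
    lo, hi = x[order[:half]], x[order[half:]]
    m0, m1 = lo.mean(), hi.mean()
    v0 = max(lo.var(), config.var_floor)
    v1 = max(hi.var(), config.var_floor)
    w1 = 1.0 - half / n

    loglik = -np.inf
    resp = np.full(n, w1)
    for _ in range(config.max_iter):
        # E step: two components, so logaddexp does the normalization
        lp0 = (
            np.log1p(-w1)
            - 0.5 * (_LOG_2PI + np.log(v0))
            - 0.5 * (x - m0) ** 2 / v0
        )
        lp1 = (
            np.log(w1)
            - 0.5 * (_LOG_2PI + np.log(v1))
            - 0.5 * (x - m1) ** 2 / v1
        )
        log_total = np.logaddexp(lp0, lp1)
        new_loglik = float(log_total.sum())
        resp = np.exp(lp1 - log_total)

        # M step
        r1 = float(np.clip(resp.sum(), 1e-12, n - 1e-12))
        r0 = n - r1
        m0 = float(np.dot(1 - resp, x)) / r0
        m1 = float(np.dot(resp, x)) / r1
        v0 = max(float(np.dot(1 - resp, (x - m0) ** 2)) / r0, config.var_floor)
        v1 = max(float(np.dot(resp, (x - m1) ** 2)) / r1, config.var_floor)
        w1 = r1 / n

        if abs(new_loglik - loglik) < config.tol * max(1.0, abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    return loglik, np.array([m0, m1]), np.array([v0, v1]), resp


def detect_subclusters(
    points: Sequence[float] | np.ndarray,
    config: SubclusterConfig = SubclusterConfig(),
    genotype: str = "",
) -> SubclusterRecord:
    """Decide whether one genotype cluster hides two sub-clusters.

    The decision is invariant under translation of all contrast values
    by a constant.  Fewer than ``2 * min_points`` points trivially give
    one subcluster (no model fit attempted).
    """
    x = np.asarray(points, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)

    def single() -> SubclusterRecord:
        return SubclusterRecord(
            genotype=genotype,
            n_points=n,
            n_subclusters=1,
            separation=0.0,
            subcluster_sizes=(n,),
            centers=(float(x.mean()),) if n else (),
        )

    if n < 2 * config.min_points:
        return single()

    var1 = max(float(x.var()), config.var_floor)
    loglik1 = _gaussian_loglik(x, float(x.mean()), var1)
    bic1 = -2.0 * loglik1 + 2.0 * np.log(n)

    loglik2, means, _, resp = _fit_two_component(x, config)
    bic2 = -2.0 * loglik2 + 5.0 * np.log(n)
    if not bic2 < bic1:
        return single()

    assign = resp > 0.5
    sizes = (int((~assign).sum()), int(assign.sum()))
    separation = float(abs(means[1] - means[0]))
    min_size = max(config.min_points, int(np.ceil(config.min_fraction * n)))
    if min(sizes) < min_size or separation < config.min_separation:
        return single()
    order = np.argsort(means)
    return SubclusterRecord(
        genotype=genotype,
        n_points=n,
        n_subclusters=2,
        separation=separation,
        subcluster_sizes=tuple(sizes[i] for i in order),
        centers=tuple(float(means[i]) for i in order),
    )


def filterc(
    dataset: AxiomDataset,
    ledger: CurationLedger,
    config: SubclusterConfig = SubclusterConfig(),
) -> dict[str, int]:
    """Test every SNP's called clusters for sub-structure.

    A SNP gains the *MultipleCluster* label iff any of its genotype
    clusters splits in two; the fitted sub-cluster descriptions of
    labeled SNPs are retained in the ledger for review plotting.
    Samples excluded upstream (duplicates, manual) or flagged
    non-diploid are omitted before fitting.
    """
    if not ledger.registered:
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
    elif ledger.sample_ids != dataset.sample_ids:
        raise ValueError("dataset samples do not match the ledger")

    analysis = ledger.analysis_samples()
    included = np.array([s in analysis for s in dataset.sample_ids])
    n_labeled = 0
    for i, pid in enumerate(dataset.probeset_ids):
        calls = dataset.calls[i]
        contrast = dataset.contrast[i]
        records = []
        any_split = False
        for g in (AA, AB, BB):
            sel = included & (calls == g)
            if not sel.any():
                continue
            rec = detect_subclusters(
                contrast[sel], config=config, genotype=CODE_TO_LETTER[g]
            )
            records.append(rec)
            any_split = any_split or rec.n_subclusters == 2
        if any_split:
            ledger.apply_labels(
                pid,
                [
                    SNPClassLabel(
                        "MultipleCluster",
                        ";".join(
                            f"{r.genotype} split {r.separation:.3f}"
                            for r in records
                            if r.n_subclusters == 2
                        ),
                    )
                ],
            )
            ledger.subclusters[pid] = records
            n_labeled += 1
    return {"MultipleCluster": n_labeled}
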