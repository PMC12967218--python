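"""Sample ploidy inference from Contrast-signal distributions.

Across all SNPs, one sample's Contrast values form a mixture whose
modes correspond to its genotype states.  A diploid sample shows three
modes (BB near -1, AB near 0, AA near +1); a triploid sample shows four
(BBB, ABB, AAB, AAA near -1, -1/3, +1/3, +1).  Counting the modes of
the per-sample histogram therefore reads off the ploidy: 3 peaks ->
diploid, 4 -> triploid, anything else -> other (flagged for review,
never auto-excluded).

Peak counting uses multi-scale (continuous wavelet transform) peak
detection over a range of smoothing widths, followed by a prominence
filter relative to the maximum density, which suppresses shoulder peaks
on heavy-tailed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks_cwt

from .types import AxiomDataset
from .ledger import CurationLedger


class InsufficientDataError(ValueError):
    """Too few usable SNPs to estimate a contrast distribution."""


@dataclass(frozen=True)
class PloidyConfig:
    """Histogram and peak-detection settings.

    ``n_bins`` bins span ``value_range`` (which must cover [-2, 2]);
    ``min_snps`` usable signals are required per sample; at most
    ``max_snps`` randomly chosen SNPs are used (distribution shape
    converges long before full-array size); widths between
    ``width_frac_lo/hi`` of the bin count feed the multi-scale
    detector; peaks below ``min_prominence`` of the maximum density are
    discarded.
    """

    n_bins: int = 88
    value_range: tuple[float, float] = (-2.2, 2.2)
    min_snps: int = 500
    max_snps: int = 50_000
    subsample_seed: int = 0
    width_frac_lo: float = 0.01
    width_frac_hi: float = 0.10
    min_prominence: float = 0.05
    min_peak_distance: float = 0.2


@dataclass(frozen=True)
class ContrastDistribution:
    """Normalized per-sample histogram of Contrast values."""

    sample_id: str
    bin_centers: np.ndarray
    densities: np.ndarray
    n_snps_used: int


@dataclass(frozen=True)
class PloidyCall:
    sample_id: str
    peak_positions: tuple[float, ...]
    n_peaks: int
    label: str


def contrast_distribution(
    dataset: AxiomDataset,
    sample_id: str,
    snp_subset: Sequence[str] | None = None,
    config: PloidyConfig = PloidyConfig(),
) -> ContrastDistribution:
    """Histogram one sample's Contrast values over (a subset of) SNPs.

    Values outside the histogram range are clipped into the edge bins;
    densities are normalized frequencies summing to 1.

    Raises :class:`InsufficientDataError` when fewer than
    ``config.min_snps`` SNPs carry a finite contrast for the sample.
    """
    j = dataset.sample_index(sample_id)
    if snp_subset is None:
        values = dataset.contrast[:, j]
    else:
        rows = [dataset.snp_index(p) for p in snp_subset]
        values = dataset.contrast[rows, j]
    values = values[np.isfinite(values)]
    if len(values) < config.min_snps:
        raise InsufficientDataError(
            f"{sample_id}: only {len(values)} SNPs with usable contrast "
            f"(minimum {config.min_snps})"
        )
    if len(values) > config.max_snps:
        rng = np.random.default_rng(config.subsample_seed)
        values = rng.choice(values, size=config.max_snps, replace=False)

    lo, hi = config.value_range
    edges = np.linspace(lo, hi, config.n_bins + 1)
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=edges)
    densities = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ContrastDistribution(
        sample_id=sample_id,
        bin_centers=centers,
        densities=densities,
        n_snps_used=len(values),
    )


def detect_peaks(
    dist: ContrastDistribution, config: PloidyConfig = PloidyConfig()
) -> tuple[float, ...]:
    """Mode positions of a contrast distribution, sorted ascending.

    Multi-scale detection (ridge persistence across smoothing widths
    spanning ``width_frac_lo``-``width_frac_hi`` of the bin count),
    then a prominence filter: a peak's density must reach
    ``min_prominence`` of the maximum density.  Zero peaks is a legal
    return.  The result is invariant under rescaling the densities by
    any positive constant.
    """
    d = np.asarray(dist.densities, dtype=float)
    if d.max() <= 0 or d.max() == d.min():  # empty or flat: no modes
        return ()
    n_bins = len(d)
    w_lo = max(1, int(round(config.width_frac_lo * n_bins)))
    w_hi = max(w_lo + 1, int(round(config.width_frac_hi * n_bins)))
    widths = np.arange(w_lo, w_hi + 1)
    idx = find_peaks_cwt(d / d.max(), widths)
    idx = [i for i in np.atleast_1d(idx) if d[i] >= config.min_prominence * d.max()]
    # merge ridge duplicates: peaks closer than min_peak_distance are one
    # mode (genotype modes sit at least ~2/3 contrast unit apart); keep
    # the denser representative of each group
    idx = sorted(idx, key=lambda i: float(dist.bin_centers[i]))
    merged: list[int] = []
    for i in idx:
        if merged and (
            dist.bin_centers[i] - dist.bin_centers[merged[-1]]
            < config.min_peak_distance
        ):
            if d[i] > d[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return tuple(sorted(float(dist.bin_centers[i]) for i in merged))


def classify_ploidy(sample_id: str, peaks: Sequence[float]) -> PloidyCall:
    """3 peaks -> diploid, 4 -> triploid, anything else -> other."""
    n = len(peaks)
    label = {3: "diploid", 4: "triploid"}.get(n, "other")
    return PloidyCall(
        sample_id=sample_id,
        peak_positions=tuple(sorted(peaks)),
        n_peaks=n,
        label=label,
    )


def ploidy_check(
    dataset: AxiomDataset,
    ledger: CurationLedger | None = None,
    config: PloidyConfig = PloidyConfig(),
) -> Mapping[str, PloidyCall]:
    """Classify every sample's ploidy; record the calls in the ledger.

    Samples labeled ``other`` are flagged for review, not excluded.
    """
    calls: dict[str, PloidyCall] = {}
    for sid in dataset.sample_ids:
        dist = contrast_distribution(dataset, sid, config=config)
        call = classify_ploidy(sid, detect_peaks(dist, config=config))
        calls[sid] = call
        if ledger is not None:
            ledger.set_ploidy(sid, call.label, call.n_peaks)
    return calls
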