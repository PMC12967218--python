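"""Core data containers for Axiom-style genotype datasets.

Genotype calls are stored as small integers following the numeric
convention used by Axiom Analysis Suite exports::

    -1 = NoCall    0 = BB    1 = AB    2 = AA

Contrast is the transformed allele-signal ratio (homozygotes near +-1,
heterozygotes near 0, AA on the positive side); Size is the log-scale
mean probe intensity.  Missing signals and missing per-SNP metrics are
NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

# genotype call codes (match the numeric AxAS export convention)
NOCALL: int = -1
BB: int = 0
AB: int = 1
AA: int = 2

CALL_CODES: tuple[int, ...] = (NOCALL, BB, AB, AA)
CODE_TO_LETTER: dict[int, str] = {AA: "AA", AB: "AB", BB: "BB", NOCALL: "NoCall"}
LETTER_TO_CODE: dict[str, int] = {v: k for k, v in CODE_TO_LETTER.items()}

#: metric column order used throughout I/O and the metrics frame
METRIC_COLUMNS: tuple[str, ...] = (
    "fld",
    "hom_fld",
    "het_so",
    "hom_ro",
    "var_aa",
    "var_ab",
    "var_bb",
)

_VAR_COLUMN = {AA: "var_aa", AB: "var_ab", BB: "var_bb"}


def call_to_letter(code: int) -> str:
    try:
        return CODE_TO_LETTER[int(code)]
    except KeyError:
        raise ValueError(f"unknown genotype code {code!r}") from None


def letter_to_call(letter: str) -> int:
    try:
        return LETTER_TO_CODE[letter]
    except KeyError:
        raise ValueError(f"unknown genotype call {letter!r}") from None


@dataclass(frozen=True)
class SNPMetrics:
    """Per-SNP Axiom clustering quality metrics.

    Any metric may be undefined for a SNP; undefined values are NaN.
    ``cluster_variance`` maps a genotype code (AA/AB/BB) to the contrast
    variance of that called cluster, omitting undefined entries.
    """

    fld: float = float("nan")
    hom_fld: float = float("nan")
    het_so: float = float("nan")
    hom_ro: float = float("nan")
    cluster_variance: Mapping[int, float] = field(default_factory=dict)

    def variance(self, genotype: int) -> float:
        return float(self.cluster_variance.get(genotype, float("nan")))


@dataclass(frozen=True)
class SNPRecord:
    """One probeset: per-sample calls and signals plus its metrics.

    ``calls``, ``contrast`` and ``size`` are aligned with the owning
    dataset's ``sample_ids``.
    """

    probeset_id: str
    calls: np.ndarray  # int8, codes above
    contrast: np.ndarray  # float64, NaN = missing
    size: np.ndarray  # float64, NaN = missing
    metrics: SNPMetrics

    def __post_init__(self) -> None:
        n = len(self.calls)
        if len(self.contrast) != n or len(self.size) != n:
            raise ValueError(
                f"{self.probeset_id}: calls/contrast/size lengths differ"
            )


@dataclass(frozen=True)
class PedigreeEntry:
    """A declared parentage: individual with up to two known parents.

    Unknown parents are ``None``.
    """

    individual: str
    parent1: str | None = None
    parent2: str | None = None

    def __post_init__(self) -> None:
        for p in (self.parent1, self.parent2):
            if p is not None and p == self.individual:
                raise ValueError(f"{self.individual}: individual listed as its own parent")

    @property
    def known_parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.parent1, self.parent2) if p is not None)


class AxiomDataset:
    """Marker x sample matrix of genotype calls, signals and metrics.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers (file column order).
    probeset_ids : ordered unique probeset identifiers.
    calls : int8 array, shape (n_snps, n_samples).
    contrast, size : float arrays, same shape; NaN where the export
        carries no signal.
    metrics : DataFrame indexed by probeset_id with METRIC_COLUMNS
        (missing metrics NaN).  May be None when the export has none.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        probeset_ids: Sequence[str],
        calls: np.ndarray,
        contrast: np.ndarray | None = None,
        size: np.ndarray | None = None,
        metrics: pd.DataFrame | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.probeset_ids = list(probeset_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("probeset_ids are not unique")

        n_snps, n_samples = len(self.probeset_ids), len(self.sample_ids)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (n_snps, n_samples):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_snps}, {n_samples})"
            )
        bad = ~np.isin(self.calls, CALL_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[i, j]} at "
                f"{self.probeset_ids[i]}/{self.sample_ids[j]}"
            )

        shape = (n_snps, n_samples)
        self.contrast = (
            np.full(shape, np.nan) if contrast is None else np.asarray(contrast, float)
        )
        self.size = (
            np.full(shape, np.nan) if size is None else np.asarray(size, float)
        )
        for name, arr in (("contrast", self.contrast), ("size", self.size)):
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")

        if metrics is None:
            metrics = pd.DataFrame(
                np.nan, index=self.probeset_ids, columns=list(METRIC_COLUMNS)
            )
        else:
            metrics = metrics.reindex(
                index=self.probeset_ids, columns=list(METRIC_COLUMNS)
            )
        neg = metrics[["var_aa", "var_ab", "var_bb"]].lt(0).any(axis=None)
        if neg:
            raise ValueError("cluster variances must be nonnegative where present")
        self.metrics = metrics

        self._snp_index = {pid: i for i, pid in enumerate(self.probeset_ids)}
        self._sample_index = {sid: j for j, sid in enumerate(self.sample_ids)}

    # ------------------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snp_index(self, probeset_id: str) -> int:
        return self._snp_index[probeset_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def snp(self, probeset_id: str) -> SNPRecord:
        i = self._snp_index[probeset_id]
        row = self.metrics.iloc[i]
        cv = {
            g: float(row[_VAR_COLUMN[g]])
            for g in (AA, AB, BB)
            if np.isfinite(row[_VAR_COLUMN[g]])
        }
        return SNPRecord(
            probeset_id=probeset_id,
            calls=self.calls[i],
            contrast=self.contrast[i],
            size=self.size[i],
            metrics=SNPMetrics(
                fld=float(row["fld"]),
                hom_fld=float(row["hom_fld"]),
                het_so=float(row["het_so"]),
                hom_ro=float(row["hom_ro"]),
                cluster_variance=cv,
            ),
        )

    def iter_snps(self) -> Iterator[SNPRecord]:
        for pid in self.probeset_ids:
            yield self.snp(pid)

    def call_rate(self, sample_id: str) -> float:
        """Fraction of SNPs called (not NoCall) for one sample."""
        j = self._sample_index[sample_id]
        col = self.calls[:, j]
        return float(np.mean(col != NOCALL)) if len(col) else 0.0

    def equals(self, other: "AxiomDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.probeset_ids == other.probeset_ids
            and np.array_equal(self.calls, other.calls)
            and np.allclose(self.contrast, other.contrast, equal_nan=True)
            and np.allclose(self.size, other.size, equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AxiomDataset(n_snps={self.n_snps}, n_samples={self.n_samples})"
        )
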