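"""Readers and writers for Axiom genotype-export tables and exports.

The expected input is the tab-separated genotype table exported by the
vendor calling software (Axiom Analysis Suite / Power Tools): one row
per probeset, one call column per sample, optional per-sample Contrast
and Size signal columns, optional per-SNP quality-metric columns.
Column naming varies between export flavours, so the reader takes an
:class:`AxiomDialect` describing how to recognise each column family.

All text I/O is UTF-8, tab-separated, Unix newlines; lines beginning
with ``#`` are comments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AA,
    AB,
    BB,
    NOCALL,
    METRIC_COLUMNS,
    AxiomDataset,
    PedigreeEntry,
    call_to_letter,
)


class AxiomFormatError(ValueError):
    """Malformed header or table structure."""


class AxiomConsistencyError(ValueError):
    """Call/signal sample sets disagree, or data contradicts itself."""


class AxiomParseError(ValueError):
    """A cell value could not be interpreted."""


#: numeric AxAS convention
NUMERIC_CODE_MAP: dict[str, int] = {"-1": NOCALL, "0": BB, "1": AB, "2": AA}
#: letter convention
LETTER_CODE_MAP: dict[str, int] = {
    "AA": AA,
    "AB": AB,
    "BA": AB,
    "BB": BB,
    "NoCall": NOCALL,
    "NN": NOCALL,
    "---": NOCALL,
}

_DEFAULT_METRIC_MAP: dict[str, str] = {
    "FLD": "fld",
    "HomFLD": "hom_fld",
    "HetSO": "het_so",
    "HomRO": "hom_ro",
    "Var.AA": "var_aa",
    "Var.AB": "var_ab",
    "Var.BB": "var_bb",
}


@dataclass
class AxiomDialect:
    """Column-naming conventions of one export flavour.

    ``genotype_codes`` maps file cell values to call codes; ``None``
    selects auto-detection (numeric -1/0/1/2 versus letter AA/AB/BB/
    NoCall, decided from the distinct values present).
    """

    probeset_column: str = "probeset_id"
    contrast_prefix: str = "Contrast."
    size_prefix: str = "Size."
    metric_columns: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_METRIC_MAP)
    )
    genotype_codes: Mapping[str, int] | None = None


def _detect_code_map(values: Iterable[str]) -> Mapping[str, int]:
    """Pick the coding family by overlap with the distinct cell values;
    cells outside the chosen family are reported later with their row
    and column."""
    distinct = {v for v in values if v == v and v != ""}  # drop NaN
    n_letter = len(distinct & set(LETTER_CODE_MAP))
    n_numeric = len(distinct & set(NUMERIC_CODE_MAP))
    if n_letter == 0 and n_numeric == 0:
        raise AxiomParseError(
            f"cannot auto-detect genotype coding; call values look like "
            f"{sorted(distinct)[:4]!r}"
        )
    return LETTER_CODE_MAP if n_letter >= n_numeric else NUMERIC_CODE_MAP


def read_axiom_export(
    path: str | Path, dialect: AxiomDialect | None = None
) -> AxiomDataset:
    """Read an Axiom genotype-export table into an :class:`AxiomDataset`.

    The header must contain the probeset-id column and at least one call
    column; signal columns (recognised by the dialect prefixes) are
    optional but, when present for either channel, must cover exactly
    the call-column sample set.  Metric columns are optional and missing
    metrics stay missing (NaN), never 0.

    Raises
    ------
    AxiomFormatError
        missing probeset column or no call columns.
    AxiomConsistencyError
        signal columns cover a different sample set than the calls.
    AxiomParseError
        a genotype cell holds an unknown code (reported with row and
        column) or a signal cell is not numeric.
    """
    dialect = dialect or AxiomDialect()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if dialect.probeset_column not in df.columns:
        raise AxiomFormatError(
            f"missing required column {dialect.probeset_column!r}"
        )

    metric_file_cols = [c for c in df.columns if c in dialect.metric_columns]
    contrast_cols, size_cols, call_cols = [], [], []
    for c in df.columns:
        if c == dialect.probeset_column or c in dialect.metric_columns:
            continue
        if c.startswith(dialect.contrast_prefix):
            contrast_cols.append(c)
        elif c.startswith(dialect.size_prefix):
            size_cols.append(c)
        else:
            call_cols.append(c)
    if not call_cols:
        raise AxiomFormatError("no sample call columns found in header")

    sample_ids = call_cols
    for prefix, cols, channel in (
        (dialect.contrast_prefix, contrast_cols, "Contrast"),
        (dialect.size_prefix, size_cols, "Size"),
    ):
        if cols:
            found = [c[len(prefix):] for c in cols]
            if sorted(found) != sorted(sample_ids):
                missing = set(sample_ids) ^ set(found)
                raise AxiomConsistencyError(
                    f"{channel} columns do not match call samples "
                    f"(mismatch: {sorted(missing)})"
                )

    probeset_ids = df[dialect.probeset_column].tolist()

    call_values = df[call_cols]
    code_map = dialect.genotype_codes
    if code_map is None:
        code_map = _detect_code_map(call_values.to_numpy().ravel())
    calls = np.empty((len(df), len(sample_ids)), dtype=np.int8)
    for j, col in enumerate(call_cols):
        for i, v in enumerate(call_values[col]):
            if v != v or v == "":  # NaN cell: treat as NoCall
                calls[i, j] = NOCALL
                continue
            try:
                calls[i, j] = code_map[v]
            except KeyError:
                raise AxiomParseError(
                    f"unknown genotype code {v!r} at row {i + 2}, column {col!r}"
                ) from None

    def _signals(cols: list[str], prefix: str) -> np.ndarray | None:
        if not cols:
            return None
        ordered = [prefix + s for s in sample_ids]
        try:
            return df[ordered].astype(float).to_numpy()
        except ValueError as exc:
            raise AxiomParseError(f"non-numeric signal value: {exc}") from None

    contrast = _signals(contrast_cols, dialect.contrast_prefix)
    size = _signals(size_cols, dialect.size_prefix)

    metrics = None
    if metric_file_cols:
        metrics = pd.DataFrame(index=probeset_ids, columns=list(METRIC_COLUMNS), dtype=float)
        for c in metric_file_cols:
            try:
                metrics[dialect.metric_columns[c]] = df[c].astype(float).to_numpy()
            except ValueError as exc:
                raise AxiomParseError(f"non-numeric metric in {c!r}: {exc}") from None

    return AxiomDataset(
        sample_ids=sample_ids,
        probeset_ids=probeset_ids,
        calls=calls,
        contrast=contrast,
        size=size,
        metrics=metrics,
    )


def read_pedigree(path: str | Path) -> list[PedigreeEntry]:
    """Read a 3-column pedigree file: individual, parent1, parent2.

    ``-`` or ``0`` marks an unknown parent; ``#`` lines are comments.
    """
    entries: list[PedigreeEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise AxiomFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            ind, p1, p2 = parts

            def _parent(p: str) -> str | None:
                return None if p in ("-", "0", "") else p

            entries.append(PedigreeEntry(ind, _parent(p1), _parent(p2)))
    return entries


def read_reference(
    genotype_path: str | Path, pedigree_path: str | Path | None = None
) -> tuple[AxiomDataset, list[PedigreeEntry]]:
    """Read a reference genotype table plus an optional pedigree file.

    Pedigree individuals absent from the genotype table are kept with a
    warning; self-parentage raises.
    """
    reference = read_axiom_export(genotype_path)
    entries: list[PedigreeEntry] = []
    if pedigree_path is not None:
        entries = read_pedigree(pedigree_path)
        known = set(reference.sample_ids)
        for e in entries:
            if e.individual not in known:
                warnings.warn(
                    f"pedigree individual {e.individual!r} absent from "
                    f"reference genotypes; entry kept",
                    stacklevel=2,
                )
    return reference, entries


# ----------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.10g"


def _select(
    dataset: AxiomDataset,
    pass_snps: Iterable[str],
    pass_samples: Iterable[str],
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    pass_snps = set(pass_snps)
    pass_samples = set(pass_samples)
    unknown_snps = pass_snps - set(dataset.probeset_ids)
    unknown_samples = pass_samples - set(dataset.sample_ids)
    if unknown_snps or unknown_samples:
        raise AxiomConsistencyError(
            f"pass sets are not subsets of the dataset "
            f"(snps: {sorted(unknown_snps)[:3]}, samples: {sorted(unknown_samples)[:3]})"
        )
    snp_ids = [p for p in dataset.probeset_ids if p in pass_snps]
    sample_ids = [s for s in dataset.sample_ids if s in pass_samples]
    if not snp_ids or not sample_ids:
        raise ValueError("refusing to write an empty export (empty pass set)")
    rows = np.array([dataset.snp_index(p) for p in snp_ids])
    cols = np.array([dataset.sample_index(s) for s in sample_ids])
    return snp_ids, sample_ids, rows, cols


def write_tabular(
    dataset: AxiomDataset,
    pass_snps: Iterable[str],
    pass_samples: Iterable[str],
    out_path: str | Path,
) -> Path:
    """Write the Pass submatrix as a generic TSV of letter-coded calls.

    One SNP per row, one sample per column, header row of sample ids.
    The output is readable back by :func:`read_axiom_export`.
    """
    snp_ids, sample_ids, rows, cols = _select(dataset, pass_snps, pass_samples)
    out_path = Path(out_path)
    sub = dataset.calls[np.ix_(rows, cols)]
    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probeset_id\t" + "\t".join(sample_ids) + "\n")
        for pid, row in zip(snp_ids, sub):
            fh.write(pid + "\t" + "\t".join(call_to_letter(c) for c in row) + "\n")
    return out_path


_TPED_ALLELES = {AA: "A A", AB: "A B", BB: "B B", NOCALL: "0 0"}


def write_tped_tfam(
    dataset: AxiomDataset,
    pass_snps: Iterable[str],
    pass_samples: Iterable[str],
    trios: Sequence | None,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the Pass set as a transposed PLINK fileset (.tped/.tfam).

    TPED: one row per passing SNP — chromosome 0, probeset id, genetic
    distance 0, position 0, then two allele columns per passing sample
    (abstract probe alleles A/B; NoCall is ``0 0``).  TFAM: one row per
    passing sample — family id (the sample id), sample id, father and
    mother from confirmed trios (0 if unknown), sex 0, phenotype -9.
    Sample order is identical in both files.

    ``trios`` is an iterable of confirmed trio relationships whose
    ``members`` are ordered (parent1, parent2, offspring).
    """
    snp_ids, sample_ids, rows, cols = _select(dataset, pass_snps, pass_samples)
    out_prefix = Path(out_prefix)
    tped = out_prefix.with_suffix(".tped")
    tfam = out_prefix.with_suffix(".tfam")

    parents: dict[str, tuple[str, str]] = {}
    for rel in trios or []:
        members = getattr(rel, "members", rel)
        if getattr(rel, "kind", "trio") != "trio":
            continue
        p1, p2, child = members
        parents.setdefault(child, (p1, p2))

    sub = dataset.calls[np.ix_(rows, cols)]
    with open(tped, "w", encoding="utf-8", newline="\n") as fh:
        for pid, row in zip(snp_ids, sub):
            alleles = " ".join(_TPED_ALLELES[c] for c in row)
            fh.write(f"0 {pid} 0 0 {alleles}\n")
    with open(tfam, "w", encoding="utf-8", newline="\n") as fh:
        for sid in sample_ids:
            father, mother = parents.get(sid, ("0", "0"))
            fh.write(f"{sid} {sid} {father} {mother} 0 -9\n")
    return tped, tfam


def write_axiom_export(
    dataset: AxiomDataset,
    out_path: str | Path,
    dialect: AxiomDialect | None = None,
) -> Path:
    """Write a full Axiom-style export (calls, signals, metrics).

    Inverse of :func:`read_axiom_export` for the default dialect; used
    by the synthetic generator to emit test fixtures.
    """
    dialect = dialect or AxiomDialect()
    out_path = Path(out_path)
    inv_metric = {v: k for k, v in dialect.metric_columns.items()}
    have_metrics = bool(np.isfinite(dataset.metrics.to_numpy()).any())
    have_signals = bool(np.isfinite(dataset.contrast).any())

    header = [dialect.probeset_column] + list(dataset.sample_ids)
    if have_signals:
        header += [dialect.contrast_prefix + s for s in dataset.sample_ids]
        header += [dialect.size_prefix + s for s in dataset.sample_ids]
    if have_metrics:
        header += [inv_metric[m] for m in METRIC_COLUMNS]

    def _fmt(x: float) -> str:
        return "" if not np.isfinite(x) else _FLOAT_FMT % x

    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for i, pid in enumerate(dataset.probeset_ids):
            fields = [pid]
            fields += [call_to_letter(c) for c in dataset.calls[i]]
            if have_signals:
                fields += [_fmt(x) for x in dataset.contrast[i]]
                fields += [_fmt(x) for x in dataset.size[i]]
            if have_metrics:
                fields += [_fmt(dataset.metrics.iloc[i][m]) for m in METRIC_COLUMNS]
            fh.write("\t".join(fields) + "\n")
    return out_path
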