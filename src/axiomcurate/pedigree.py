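"""Duplicate, parent-offspring and trio scanning; Mendelian-error filtering.

Relationship evidence at a biallelic locus:

* **Duplicates** — near-total genotype concordance between two samples.
* **Parent-offspring (PO)** — a true parent and child can never be
  *opposing homozygotes* (AA vs BB), so a near-zero opposing-homozygote
  rate among jointly homozygous SNPs indicates a PO link.  Genotypes
  alone cannot orient the pair; direction is taken from a reference
  pedigree when one is supplied.
* **Trios (PPO)** — a candidate parent-parent-offspring triple is
  confirmed when its rate of Mendelian-inconsistent genotypes is below
  a threshold.  Candidates are formed from PO pairs sharing an
  offspring candidate, and from reference pedigree entries.

Per-SNP Mendelian-error counts accumulated over confirmed trios drive
the *MendelianErrorFilter* class: SNPs whose genotypes are repeatedly
impossible under biparental transmission are flagged for exclusion.
All scans use only SNPs and samples that passed the previous curation
steps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ledger import CurationLedger, Relationship, SNPClassLabel
from .types import AA, AB, BB, NOCALL, AxiomDataset, PedigreeEntry


@dataclass(frozen=True)
class PedigreeConfig:
    """Scan thresholds.

    A pair needs ``min_snps`` mutually called (for duplicates) or
    jointly homozygous (for PO) SNPs to be scored at all; pairs below
    the minimum are indeterminate and skipped with a warning.
    """

    dup_threshold: float = 0.98  # concordance at/above -> duplicate
    po_threshold: float = 0.01  # opposing-homozygote rate at/below -> PO
    trio_threshold: float = 0.02  # Mendelian-error rate at/below -> trio
    min_snps: int = 500
    max_errors: int = 2  # filterp: label SNPs with >= this many errors


# ----------------------------------------------------------------------
# pairwise statistics

def concordance(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, int]:
    """Fraction of identical calls among mutually called SNPs.

    Returns (NaN, 0) when no SNP is called in both samples.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    both = (a != NOCALL) & (b != NOCALL)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.mean(a[both] == b[both])), n


def opposing_homozygote_rate(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, int]:
    """Rate of opposing homozygotes among jointly homozygous SNPs.

    Informative positions are those where both samples are called
    homozygous; opposing means one AA and the other BB.  Returns
    (NaN, 0) with no informative position.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    hom_a = (a == AA) | (a == BB)
    hom_b = (b == AA) | (b == BB)
    informative = hom_a & hom_b
    n = int(informative.sum())
    if n == 0:
        return float("nan"), 0
    opposing = informative & (a != b)
    return float(opposing.sum() / n), n


# ----------------------------------------------------------------------
# Mendelian consistency

_ALLELES: dict[int, tuple[str, ...]] = {
    AA: ("A",),
    AB: ("A", "B"),
    BB: ("B",),
}


_CHILD_ALLELES: dict[int, tuple[str, str]] = {
    AA: ("A", "A"),
    AB: ("A", "B"),
    BB: ("B", "B"),
}


def mendel_consistent(parent1: int, parent2: int, child: int) -> bool:
    """Can the child receive one allele from each parent?

    Any NoCall makes the triple vacuously consistent (the position is
    skipped in error counting).  Symmetric in the parents.
    """
    if NOCALL in (parent1, parent2, child):
        return True
    want = _CHILD_ALLELES[child]
    for a1 in _ALLELES[parent1]:
        for a2 in _ALLELES[parent2]:
            if tuple(sorted((a1, a2))) == want:
                return True
    return False


def _build_mendel_table() -> np.ndarray:
    table = np.zeros((4, 4, 4), dtype=bool)
    codes = (NOCALL, BB, AB, AA)
    for p1 in codes:
        for p2 in codes:
            for c in codes:
                table[p1 + 1, p2 + 1, c + 1] = mendel_consistent(p1, p2, c)
    return table


#: lookup: MENDEL_TABLE[p1+1, p2+1, c+1] -> consistent?
MENDEL_TABLE: np.ndarray = _build_mendel_table()


def count_mendel_errors(
    parent1: np.ndarray, parent2: np.ndarray, child: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP error/tested masks for one trio."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    c = np.asarray(child)
    tested = (p1 != NOCALL) & (p2 != NOCALL) & (c != NOCALL)
    consistent = MENDEL_TABLE[p1 + 1, p2 + 1, c + 1]
    return tested & ~consistent, tested


@dataclass
class MendelianErrorTable:
    """Per-SNP and per-trio Mendelian-error accounting over confirmed trios."""

    snp_errors: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: trio members -> (n_errors, n_snps_tested, error_rate)
    trio_stats: dict[tuple[str, str, str], tuple[int, int, float]] = field(
        default_factory=dict
    )

    def mean_error_rate(self) -> float:
        if not self.trio_stats:
            return float("nan")
        return float(np.mean([s[2] for s in self.trio_stats.values()]))

    def mean_error_count(self) -> float:
        if not self.trio_stats:
            return float("nan")
        return float(np.mean([s[0] for s in self.trio_stats.values()]))


# ----------------------------------------------------------------------
# scans

def _pass_matrix(
    dataset: AxiomDataset,
    ledger: CurationLedger,
    reference: AxiomDataset | None,
) -> tuple[np.ndarray, list[str], list[str], set[str]]:
    """Call matrix over Pass SNPs x (Pass samples + reference samples)."""
    if not ledger.registered:
        ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
    pass_snps, pass_samples = ledger.pass_set()
    snp_ids = [p for p in dataset.probeset_ids if p in pass_snps]
    rows = [dataset.snp_index(p) for p in snp_ids]
    samples = [s for s in dataset.sample_ids if s in pass_samples]
    cols = [dataset.sample_index(s) for s in samples]
    matrix = dataset.calls[np.ix_(rows, cols)]
    ref_samples: set[str] = set()
    if reference is not None:
        ref_ids = [s for s in reference.sample_ids if s not in set(samples)]
        ref_rows = []
        keep = []
        ref_index = {p: i for i, p in enumerate(reference.probeset_ids)}
        for k, pid in enumerate(snp_ids):
            if pid in ref_index:
                keep.append(k)
                ref_rows.append(ref_index[pid])
        ref_matrix = np.full((len(snp_ids), len(ref_ids)), NOCALL, dtype=np.int8)
        ref_cols = [reference.sample_index(s) for s in ref_ids]
        if keep:
            ref_matrix[np.array(keep)] = reference.calls[
                np.ix_(np.array(ref_rows), np.array(ref_cols))
            ]
        matrix = np.hstack([matrix, ref_matrix])
        samples = samples + ref_ids
        ref_samples = set(ref_ids)
    return matrix, snp_ids, samples, ref_samples


def scan_duos(
    dataset: AxiomDataset,
    ledger: CurationLedger,
    reference: AxiomDataset | None = None,
    config: PedigreeConfig = PedigreeConfig(),
) -> list[Relationship]:
    """Score all sample pairs for duplicate and parent-offspring links.

    Duplicates (concordance >= ``dup_threshold``) are recorded and, for
    within-dataset pairs, the member with the lower call rate is
    excluded in the ledger (ties broken toward keeping the
    lexicographically smaller id).  PO pairs (opposing-homozygote rate
    <= ``po_threshold``) are declared among non-duplicates.  Reference
    samples join the comparison pool but are never excluded.
    """
    matrix, _, samples, ref_samples = _pass_matrix(dataset, ledger, reference)
    n = len(samples)
    relationships: list[Relationship] = []
    duplicate_pairs: set[frozenset[str]] = set()

    for i, j in itertools.combinations(range(n), 2):
        a, b = samples[i], samples[j]
        conc, n_comp = concordance(matrix[:, i], matrix[:, j])
        if n_comp < config.min_snps:
            warnings.warn(
                f"pair ({a}, {b}): only {n_comp} mutually called SNPs; "
                "indeterminate, skipped",
                stacklevel=2,
            )
            continue
        if conc >= config.dup_threshold:
            rel = Relationship(
                kind="duplicate",
                members=tuple(sorted((a, b))),
                n_snps_compared=n_comp,
                statistic=conc,
            )
            relationships.append(rel)
            ledger.add_relationship(rel)
            duplicate_pairs.add(frozenset((a, b)))
            continue
        rate, n_inf = opposing_homozygote_rate(matrix[:, i], matrix[:, j])
        if n_inf < config.min_snps:
            warnings.warn(
                f"pair ({a}, {b}): only {n_inf} jointly homozygous SNPs; "
                "PO test indeterminate, skipped",
                stacklevel=2,
            )
            continue
        if rate <= config.po_threshold:
            rel = Relationship(
                kind="parent_offspring",
                members=tuple(sorted((a, b))),
                n_snps_compared=n_inf,
                statistic=rate,
            )
            relationships.append(rel)
            ledger.add_relationship(rel)

    # resolve within-dataset duplicates: keep the higher call rate
    for pair in duplicate_pairs:
        members = sorted(pair)
        in_ds = [m for m in members if m not in ref_samples]
        if len(in_ds) < 2:
            continue
        rates = {m: dataset.call_rate(m) for m in in_ds}
        # keep the higher call rate; ties keep the lexicographically smaller id
        keep = sorted(in_ds, key=lambda m: (-rates[m], m))[0]
        for m in in_ds:
            if m != keep:
                ledger.exclude_sample(m, "duplicate")
    return relationships


def scan_trios(
    dataset: AxiomDataset,
    ledger: CurationLedger,
    duo_relationships: Sequence[Relationship] | None = None,
    reference: AxiomDataset | None = None,
    reference_pedigree: Sequence[PedigreeEntry] | None = None,
    config: PedigreeConfig = PedigreeConfig(),
) -> tuple[list[Relationship], MendelianErrorTable]:
    """Confirm parent-parent-offspring trios and count Mendelian errors.

    Candidate trios pair up the PO partners of each offspring
    candidate; reference pedigree entries with two known parents are
    added directly.  A candidate is confirmed when its Mendelian-error
    rate is at most ``trio_threshold``.  The per-SNP error table
    accumulates over confirmed trios only and is stored in the ledger
    for ``filterp``.  Trio scoring is invariant to parent order.
    """
    if duo_relationships is None:
        duo_relationships = [
            r for r in ledger.relationships if r.kind == "parent_offspring"
        ]
    matrix, snp_ids, samples, _ = _pass_matrix(dataset, ledger, reference)
    col = {s: k for k, s in enumerate(samples)}

    partners: dict[str, set[str]] = {}
    for rel in duo_relationships:
        if rel.kind != "parent_offspring":
            continue
        a, b = rel.members
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    candidates: list[tuple[str, str, str]] = []
    seen: set[tuple[frozenset[str], str]] = set()

    def add_candidate(p1: str, p2: str, child: str) -> None:
        if len({p1, p2, child}) != 3:
            return
        if not all(m in col for m in (p1, p2, child)):
            return
        key = (frozenset((p1, p2)), child)
        if key not in seen:
            seen.add(key)
            candidates.append((*sorted((p1, p2)), child))

    for e in reference_pedigree or []:
        if e.parent1 and e.parent2:
            add_candidate(e.parent1, e.parent2, e.individual)
    for child, ps in partners.items():
        for p1, p2 in itertools.combinations(sorted(ps), 2):
            add_candidate(p1, p2, child)

    confirmed: list[Relationship] = []
    table = MendelianErrorTable()
    error_accum = np.zeros(len(snp_ids), dtype=int)
    tested_accum = np.zeros(len(snp_ids), dtype=int)
    for p1, p2, child in candidates:
        errors, tested = count_mendel_errors(
            matrix[:, col[p1]], matrix[:, col[p2]], matrix[:, col[child]]
        )
        n_tested = int(tested.sum())
        if n_tested < config.min_snps:
            continue
        n_err = int(errors.sum())
        rate = n_err / n_tested
        if rate <= config.trio_threshold:
            rel = Relationship(
                kind="trio",
                members=(p1, p2, child),
                n_snps_compared=n_tested,
                statistic=rate,
            )
            confirmed.append(rel)
            ledger.add_relationship(rel)
            table.trio_stats[(p1, p2, child)] = (n_err, n_tested, rate)
            error_accum += errors
            tested_accum += tested

    for k, pid in enumerate(snp_ids):
        table.snp_errors[pid] = (int(error_accum[k]), int(tested_accum[k]))
    ledger.mendel_errors = dict(table.snp_errors)
    return confirmed, table


def filterp(
    error_table: MendelianErrorTable | Mapping[str, tuple[int, int]],
    ledger: CurationLedger,
    max_errors: int = 2,
) -> int:
    """Label SNPs with ``n_errors >= max_errors`` as MendelianErrorFilter.

    Lowering ``max_errors`` never unlabels a SNP (labels are sticky).
    Returns the number of SNPs labeled in this call; an empty table is
    a no-op with a warning.
    """
    if max_errors < 1:
        raise ValueError("max_errors must be >= 1")
    errors = (
        error_table.snp_errors
        if isinstance(error_table, MendelianErrorTable)
        else dict(error_table)
    )
    if not errors:
        warnings.warn("empty Mendelian error table; nothing to filter", stacklevel=2)
        return 0
    n_labeled = 0
    for pid, (n_err, _) in errors.items():
        if n_err >= max_errors:
            ledger.apply_labels(
                pid,
                [SNPClassLabel("MendelianErrorFilter", f"errors={n_err}")],
            )
            n_labeled += 1
    return n_labeled
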