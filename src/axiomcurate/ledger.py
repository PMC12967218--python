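"""Persistent curation ledger.

Every classification, relationship, and manual decision made across
independent pipeline invocations is collected in a single file-backed
store, so that each subcommand can run on its own and the final export
reflects the union of all curation steps.  The backend is one
human-readable JSON document; the contract is single-writer,
last-save-wins.

Label semantics
---------------
A SNP starts in the implicit *Pass* state.  Automatic filters attach
excluding labels (MonoHighResolution, HomHomCluster,
UnexpectedDistribution, MetricsThreshold, MultipleCluster,
MendelianErrorFilter); these are sticky — re-runs only add, never
remove.  Manual review can override: ManualInclude re-admits a SNP
despite automatic labels, ManualExclude removes it regardless of
everything else.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: recognised SNP class labels
SNP_CLASSES: tuple[str, ...] = (
    "MonoHighResolution",
    "HomHomCluster",
    "UnexpectedDistribution",
    "MetricsThreshold",
    "MultipleCluster",
    "MendelianErrorFilter",
    "ManualExclude",
    "ManualInclude",
)
#: labels that remove a SNP from the Pass set (Manual* handled separately)
AUTOMATIC_EXCLUDING: frozenset[str] = frozenset(SNP_CLASSES[:6])

PLOIDY_LABELS: tuple[str, ...] = ("diploid", "triploid", "other", "unknown")


class LedgerError(RuntimeError):
    pass


@dataclass(frozen=True)
class SNPClassLabel:
    """One classification of one SNP; ``detail`` names the evidence
    (e.g. which metric fired and its value)."""

    value: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.value not in SNP_CLASSES:
            raise ValueError(f"unknown SNP class label {self.value!r}")


@dataclass
class SampleStatus:
    sample_id: str
    ploidy_label: str = "unknown"
    n_peaks: int | None = None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class Relationship:
    """A detected duplicate pair, parent-offspring pair, or trio.

    ``members`` is 2 sample ids, or 3 ordered (parent1, parent2,
    offspring) for a trio.  ``statistic`` is the supporting score:
    concordance fraction (duplicate), opposing-homozygote rate
    (parent_offspring), or Mendelian-error rate (trio).
    """

    kind: str  # duplicate | parent_offspring | trio
    members: tuple[str, ...]
    n_snps_compared: int
    statistic: float

    def __post_init__(self) -> None:
        if self.kind not in ("duplicate", "parent_offspring", "trio"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        if len(self.members) not in (2, 3):
            raise ValueError("relationship needs 2 or 3 members")
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("statistic must lie in [0, 1]")


@dataclass(frozen=True)
class SubclusterRecord:
    """Retained sub-cluster fit for one genotype cluster of one SNP.

    ``separation`` is the contrast distance between subcluster centers
    (0 when a single component describes the cluster).
    """

    genotype: str  # "AA" | "AB" | "BB"
    n_points: int
    n_subclusters: int
    separation: float
    subcluster_sizes: tuple[int, ...]
    centers: tuple[float, ...] = ()


@dataclass(frozen=True)
class ReviewDecision:
    target: str  # probeset or sample id
    action: str  # confirm | manual_include | manual_exclude
    timestamp: str
    note: str = ""


class CurationLedger:
    """In-memory ledger; persisted with :meth:`save` / :meth:`load`."""

    SCHEMA = 1

    def __init__(self) -> None:
        self.probeset_ids: list[str] = []
        self.sample_ids: list[str] = []
        self.snp_labels: dict[str, set[SNPClassLabel]] = {}
        self.sample_status: dict[str, SampleStatus] = {}
        self.relationships: list[Relationship] = []
        self.subclusters: dict[str, list[SubclusterRecord]] = {}
        #: probeset -> (n_errors, n_trios_tested), filled by the trio scan
        self.mendel_errors: dict[str, tuple[int, int]] = {}
        self.decisions: list[ReviewDecision] = []
        self.run_log: list[dict] = []

    # ------------------------------------------------------------------
    def register_dataset(
        self, probeset_ids: Sequence[str], sample_ids: Sequence[str]
    ) -> None:
        """Register (or re-register, idempotently) the dataset universe."""
        if self.probeset_ids and (
            list(probeset_ids) != self.probeset_ids
            or list(sample_ids) != self.sample_ids
        ):
            raise LedgerError(
                "ledger was created for a different dataset "
                "(probeset/sample sets differ); reset the ledger to reuse it"
            )
        self.probeset_ids = list(probeset_ids)
        self.sample_ids = list(sample_ids)
        for pid in self.probeset_ids:
            self.snp_labels.setdefault(pid, set())
        for sid in self.sample_ids:
            self.sample_status.setdefault(sid, SampleStatus(sid))

    @property
    def registered(self) -> bool:
        return bool(self.probeset_ids)

    # ------------------------------------------------------------------
    def apply_labels(
        self, probeset_id: str, labels: Iterable[SNPClassLabel]
    ) -> None:
        """Merge labels into a SNP's label set (set union; idempotent)."""
        if probeset_id not in self.snp_labels:
            raise KeyError(f"unknown probeset {probeset_id!r}")
        self.snp_labels[probeset_id].update(labels)

    def snp_is_pass(self, probeset_id: str) -> bool:
        labels = {l.value for l in self.snp_labels[probeset_id]}
        if "ManualExclude" in labels:
            return False
        if "ManualInclude" in labels:
            return True
        return not (labels & AUTOMATIC_EXCLUDING)

    def pass_set(self) -> tuple[set[str], set[str]]:
        """SNPs with no effective excluding label, and non-excluded samples."""
        snps = {pid for pid in self.probeset_ids if self.snp_is_pass(pid)}
        samples = {
            sid for sid in self.sample_ids if not self.sample_status[sid].excluded
        }
        return snps, samples

    def analysis_samples(self) -> set[str]:
        """Samples usable for cluster-shape analysis: not excluded and
        not flagged non-diploid (polyploid samples create exactly the
        spurious intermediate clusters the SNP filters target)."""
        return {
            sid
            for sid, st in self.sample_status.items()
            if not st.excluded and st.ploidy_label in ("diploid", "unknown")
        }

    def snps_in_class(self, class_name: str) -> list[str]:
        if class_name not in SNP_CLASSES:
            raise ValueError(f"unknown SNP class {class_name!r}")
        return [
            pid
            for pid in self.probeset_ids
            if class_name in {l.value for l in self.snp_labels[pid]}
        ]

    # ------------------------------------------------------------------
    def exclude_sample(self, sample_id: str, reason: str) -> None:
        status = self._status(sample_id)
        if not status.excluded:
            status.excluded = True
            status.exclusion_reason = reason

    def set_ploidy(self, sample_id: str, label: str, n_peaks: int) -> None:
        status = self._status(sample_id)
        status.ploidy_label = label
        status.n_peaks = n_peaks

    def _status(self, sample_id: str) -> SampleStatus:
        try:
            return self.sample_status[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def add_relationship(self, rel: Relationship) -> None:
        if rel not in self.relationships:
            self.relationships.append(rel)

    def trios(self) -> list[Relationship]:
        return [r for r in self.relationships if r.kind == "trio"]

    def log_run(self, command: str, params: Mapping) -> None:
        self.run_log.append(
            {
                "command": command,
                "params": dict(params),
                "timestamp": datetime.now(timezone.utc).isoformat(),
            }
        )

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        """Curation state (without the run log) for equality checks."""
        return {
            "probeset_ids": self.probeset_ids,
            "sample_ids": self.sample_ids,
            "snp_labels": {
                pid: sorted((l.value, l.detail) for l in labels)
                for pid, labels in self.snp_labels.items()
            },
            "sample_status": {
                sid: asdict(st) for sid, st in self.sample_status.items()
            },
            "relationships": [asdict(r) for r in self.relationships],
            "subclusters": {
                pid: [asdict(r) for r in recs]
                for pid, recs in self.subclusters.items()
            },
            "mendel_errors": {
                pid: list(v) for pid, v in self.mendel_errors.items()
            },
            "decisions": [asdict(d) for d in self.decisions],
        }

    def same_state(self, other: "CurationLedger") -> bool:
        return self.state_dict() == other.state_dict()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {"schema": self.SCHEMA, **self.state_dict(), "run_log": self.run_log}
        tmp = path.with_suffix(path.suffix + ".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        tmp.replace(path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CurationLedger":
        try:
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise LedgerError(f"cannot load ledger {path}: {exc}") from exc
        if doc.get("schema") != cls.SCHEMA:
            raise LedgerError(
                f"ledger schema {doc.get('schema')!r} != expected {cls.SCHEMA}"
            )
        ledger = cls()
        try:
            ledger.probeset_ids = list(doc["probeset_ids"])
            ledger.sample_ids = list(doc["sample_ids"])
            ledger.snp_labels = {
                pid: {SNPClassLabel(v, d) for v, d in labels}
                for pid, labels in doc["snp_labels"].items()
            }
            ledger.sample_status = {
                sid: SampleStatus(**st) for sid, st in doc["sample_status"].items()
            }
            ledger.relationships = [
                Relationship(
                    kind=r["kind"],
                    members=tuple(r["members"]),
                    n_snps_compared=r["n_snps_compared"],
                    statistic=r["statistic"],
                )
                for r in doc["relationships"]
            ]
            ledger.subclusters = {
                pid: [
                    SubclusterRecord(
                        genotype=r["genotype"],
                        n_points=r["n_points"],
                        n_subclusters=r["n_subclusters"],
                        separation=r["separation"],
                        subcluster_sizes=tuple(r["subcluster_sizes"]),
                        centers=tuple(r.get("centers", ())),
                    )
                    for r in recs
                ]
                for pid, recs in doc["subclusters"].items()
            }
            ledger.mendel_errors = {
                pid: (int(v[0]), int(v[1]))
                for pid, v in doc["mendel_errors"].items()
            }
            ledger.decisions = [ReviewDecision(**d) for d in doc["decisions"]]
            ledger.run_log = list(doc["run_log"])
        except (KeyError, TypeError, ValueError) as exc:
            raise LedgerError(f"malformed ledger {path}: {exc}") from exc
        return ledger


def load_or_create(path: str | Path) -> CurationLedger:
    path = Path(path)
    if path.exists():
        return CurationLedger.load(path)
    return CurationLedger()
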