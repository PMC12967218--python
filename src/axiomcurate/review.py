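"""Manual review of SNP classes and samples.

Automatic filters propose classifications; review lets a curator look
at the cluster plot of every SNP in a class and either confirm the
classification, manually include the SNP back into the Pass set, or
manually exclude it outright.  Decisions are append-only and recorded
in the ledger; the latest effective state wins at export.  Review
never mutates calls, signals, or metrics — only labels and statuses.

The primary interface is a scriptable batch mode (a 2-column decisions
TSV plus a plot directory); the CLI additionally offers a terminal
prompt loop.
"""

from __future__ import annotations

import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ledger import CurationLedger, ReviewDecision, SNPClassLabel
from .types import AA, AB, BB, NOCALL, AxiomDataset

ACTIONS = ("confirm", "manual_include", "manual_exclude")

_GENO_STYLE = {
    AA: ("tab:red", "AA"),
    AB: ("tab:green", "AB"),
    BB: ("tab:blue", "BB"),
}


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def render_cluster_plot(
    dataset: AxiomDataset,
    probeset_id: str,
    ledger: CurationLedger | None,
    out_path: str | Path,
) -> Path:
    """Scatter Contrast (x) vs Size (y) colored by called genotype.

    NoCall samples are drawn in a distinct grey cross style; detected
    subcluster centers are overlaid when present in the ledger; the
    SNP's class labels appear in the title.  With zero plottable points
    a placeholder image carrying a warning text is produced.
    """
    i = dataset.snp_index(probeset_id)
    calls = dataset.calls[i]
    x = dataset.contrast[i]
    y = dataset.size[i]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 4))
    plottable = np.isfinite(x) & np.isfinite(y)
    if not plottable.any():
        ax.text(
            0.5, 0.5, f"{probeset_id}: no plottable signal",
            ha="center", va="center", transform=ax.transAxes, color="tab:red",
        )
        ax.set_axis_off()
    else:
        for g, (color, name) in _GENO_STYLE.items():
            sel = plottable & (calls == g)
            if sel.any():
                ax.scatter(x[sel], y[sel], s=12, c=color, label=name)
        nc = plottable & (calls == NOCALL)
        if nc.any():
            ax.scatter(
                x[nc], y[nc], s=18, c="grey", marker="x", label="NoCall"
            )
        if ledger is not None:
            for rec in ledger.subclusters.get(probeset_id, []):
                if rec.n_subclusters == 2:
                    for c in rec.centers:
                        ax.axvline(c, color="k", ls="--", lw=0.8)
        ax.set_xlabel("Contrast")
        ax.set_ylabel("Size")
        ax.legend(fontsize=7)
    labels = ""
    if ledger is not None and probeset_id in ledger.snp_labels:
        labels = ", ".join(
            sorted({l.value for l in ledger.snp_labels[probeset_id]})
        )
    ax.set_title(f"{probeset_id}" + (f" [{labels}]" if labels else ""), fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path


def read_decisions_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of (id, action) decisions."""
    out: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            target, action = parts
            if action not in ACTIONS:
                raise ValueError(
                    f"{path}:{lineno}: unknown action {action!r}; "
                    f"expected one of {ACTIONS}"
                )
            out.append((target, action))
    return out


def apply_snp_decision(
    ledger: CurationLedger, probeset_id: str, action: str, note: str = ""
) -> None:
    """Apply one review decision to one SNP and record it."""
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if action == "manual_include":
        ledger.apply_labels(probeset_id, [SNPClassLabel("ManualInclude", note)])
    elif action == "manual_exclude":
        ledger.apply_labels(probeset_id, [SNPClassLabel("ManualExclude", note)])
    ledger.decisions.append(
        ReviewDecision(target=probeset_id, action=action, timestamp=_now(), note=note)
    )


def review_class(
    ledger: CurationLedger,
    class_name: str,
    decisions: Iterable[tuple[str, str]] | str | Path,
    dataset: AxiomDataset | None = None,
    plots_dir: str | Path | None = None,
) -> list[str]:
    """Batch-review the SNPs of one class.

    ``decisions`` is a sequence of (probeset_id, action) pairs or a
    path to a decisions TSV.  Decisions for SNPs not in the class are
    skipped with a warning.  When ``dataset`` and ``plots_dir`` are
    given, a cluster plot is rendered for every reviewed SNP.  Returns
    the probeset ids actually reviewed.
    """
    if isinstance(decisions, (str, Path)):
        decisions = read_decisions_file(decisions)
    in_class = set(ledger.snps_in_class(class_name))
    reviewed: list[str] = []
    for pid, action in decisions:
        if pid not in in_class:
            warnings.warn(
                f"{pid} is not in class {class_name}; decision skipped",
                stacklevel=2,
            )
            continue
        apply_snp_decision(ledger, pid, action, note=f"review {class_name}")
        reviewed.append(pid)
        if dataset is not None and plots_dir is not None:
            render_cluster_plot(
                dataset, pid, ledger, Path(plots_dir) / f"{pid}.png"
            )
    return reviewed


def review_sample(
    ledger: CurationLedger, sample_id: str, action: str, note: str = ""
) -> None:
    """Manually exclude a sample, or lift a manual exclusion.

    ``manual_include`` clears manual exclusions only: a sample excluded
    automatically (e.g. as a duplicate) stays excluded — undoing that
    requires a ledger reset.
    """
    if action not in ("manual_include", "manual_exclude", "confirm"):
        raise ValueError(f"unknown action {action!r}")
    status = ledger.sample_status.get(sample_id)
    if status is None:
        raise KeyError(f"unknown sample {sample_id!r}")
    if action == "manual_exclude":
        ledger.exclude_sample(sample_id, "manual")
    elif action == "manual_include" and status.excluded and status.exclusion_reason == "manual":
        status.excluded = False
        status.exclusion_reason = ""
    ledger.decisions.append(
        ReviewDecision(target=sample_id, action=action, timestamp=_now(), note=note)
    )
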