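"""Synthetic Axiom-style datasets with known ground truth.

The generator emulates the structure of a called SNP-array export:
per-sample genotype calls, Contrast/Size signal clouds with the
canonical three-cluster geometry (homozygotes near +-1, heterozygotes
near 0), per-SNP quality metrics, a pedigree (founders drawn under
Hardy-Weinberg, offspring by Mendelian transmission), optional
triploid samples with a four-mode contrast geometry, planted duplicate
samples, and injected problematic-SNP classes:

* ``mono`` — a single genotype cluster (the SNP is fixed for one allele,
  so transmission stays consistent);
* ``hom_hom`` — heterozygous samples mis-called to a homozygote class,
  with their signals redrawn at the new homozygote center (a null-allele
  -like pattern: only AA and BB calls remain);
* ``unexpected`` — homozygote clusters displaced beyond the expected
  contrast range;
* ``multi_cluster`` — the heterozygote cluster split into two
  sub-clusters at a configurable separation;
* ``bad_metrics`` — quality metrics set below the default thresholds.

Planted genotyping errors and no-calls are applied last, to clean SNPs
only, so that each injected class keeps its defining call pattern
exactly.  Everything is driven by one seed and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .io import write_axiom_export
from .types import AA, AB, BB, NOCALL, METRIC_COLUMNS, AxiomDataset

SNP_CLASS_NAMES = {
    "clean": "Pass",
    "mono": "MonoHighResolution",
    "hom_hom": "HomHomCluster",
    "unexpected": "UnexpectedDistribution",
    "multi_cluster": "MultipleCluster",
    "bad_metrics": "MetricsThreshold",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults give the standard test fixture: 5000 SNPs, 40 founders plus
    two full-sib families of 8 offspring each (56 samples), 2% of SNPs
    injected per problematic class, a heterozygote split of 0.6 contrast
    units (sd 0.08) for the multi-cluster class, 0.2% genotyping error
    and 0.5% no-calls on clean SNPs.
    """

    n_snps: int = 5000
    n_founders: int = 40
    offspring_per_family: tuple[int, ...] = (8, 8)
    n_duplicates: int = 0
    seed: int = 17

    # allele-frequency distribution (uniform)
    freq_low: float = 0.2
    freq_high: float = 0.8

    # cluster geometry
    hom_center: float = 1.0
    cluster_sd: float = 0.10
    size_mean: float = 1.5
    size_sd: float = 0.15

    # injected problematic-SNP fractions
    frac_mono: float = 0.02
    frac_hom_hom: float = 0.02
    frac_unexpected: float = 0.02
    frac_multi_cluster: float = 0.02
    frac_bad_metrics: float = 0.02
    multi_cluster_separation: float = 0.6
    multi_cluster_sd: float = 0.08
    unexpected_shift_low: float = 1.6
    unexpected_shift_high: float = 1.9

    # ploidy mix: fraction of non-parent founders that are triploid
    frac_triploid: float = 0.0

    genotyping_error_rate: float = 0.002
    no_call_rate: float = 0.005

    def validate(self) -> None:
        fracs = (
            self.frac_mono,
            self.frac_hom_hom,
            self.frac_unexpected,
            self.frac_multi_cluster,
            self.frac_bad_metrics,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class-injection fractions must lie in [0,1] and sum to <= 1")
        for name in ("frac_triploid", "genotyping_error_rate", "no_call_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.freq_low <= self.freq_high <= 1:
            raise ValueError("need 0 <= freq_low <= freq_high <= 1")
        n_parents = 2 * len(self.offspring_per_family)
        if self.n_founders < n_parents:
            raise ValueError(
                f"{len(self.offspring_per_family)} families need "
                f"{n_parents} parent founders, have {self.n_founders}"
            )
        if self.n_duplicates > self.n_founders - n_parents:
            raise ValueError("not enough non-parent founders to duplicate")

    @property
    def n_samples(self) -> int:
        return (
            self.n_founders + sum(self.offspring_per_family) + self.n_duplicates
        )


@dataclass
class TruthLabels:
    """Ground truth paired with a simulated dataset."""

    snp_class: dict[str, str]  # probeset -> class name ("Pass" or a label)
    sample_ploidy: dict[str, str]  # sample -> diploid | triploid
    duplicates: list[tuple[str, str]]  # (original, copy)
    parent_offspring: list[tuple[str, str]]  # (parent, offspring)
    trios: list[tuple[str, str, str]]  # (parent1, parent2, offspring)
    error_positions: list[tuple[str, str]]  # (probeset, sample) planted errors


def _transmit(rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    """One allele per SNP from a diploid parent (A with prob dosage/2)."""
    return (rng.random(dosage.shape) < dosage / 2.0).astype(np.int8)


def simulate(config: SimulationConfig) -> tuple[AxiomDataset, TruthLabels]:
    """Draw one dataset and its ground truth under ``config``.

    Founders are independent Hardy-Weinberg draws from per-SNP allele
    frequencies; offspring receive one allele from each assigned parent;
    duplicates copy a non-parent founder's genotypes and redraw signal
    noise.  Identical seeds give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps

    # ---- sample plan -------------------------------------------------
    founders = [f"F{i:03d}" for i in range(config.n_founders)]
    n_families = len(config.offspring_per_family)
    parent_pairs = [(founders[2 * k], founders[2 * k + 1]) for k in range(n_families)]
    offspring: list[str] = []
    offspring_parents: dict[str, tuple[str, str]] = {}
    for k, n_off in enumerate(config.offspring_per_family):
        for j in range(n_off):
            sid = f"FAM{k + 1}_O{j + 1:02d}"
            offspring.append(sid)
            offspring_parents[sid] = parent_pairs[k]
    # duplicates copy the last non-parent founders
    dup_sources = founders[config.n_founders - config.n_duplicates:]
    duplicates = [f"{src}_dup" for src in dup_sources]
    sample_ids = founders + offspring + duplicates
    n_samples = len(sample_ids)
    sidx = {s: i for i, s in enumerate(sample_ids)}

    # triploids among founders that are neither parents nor duplicated
    parents_flat = {p for pair in parent_pairs for p in pair}
    eligible = [
        f for f in founders if f not in parents_flat and f not in dup_sources
    ]
    n_tri = int(round(config.frac_triploid * len(eligible)))
    tri_samples = set(
        rng.choice(eligible, size=n_tri, replace=False) if n_tri else []
    )
    ploidy = {s: ("triploid" if s in tri_samples else "diploid") for s in sample_ids}

    # ---- SNP class assignment ---------------------------------------
    probeset_ids = [f"AX-{i:06d}" for i in range(n_snps)]
    snp_class = np.full(n_snps, "clean", dtype=object)
    order = rng.permutation(n_snps)
    cursor = 0
    for name, frac in (
        ("mono", config.frac_mono),
        ("hom_hom", config.frac_hom_hom),
        ("unexpected", config.frac_unexpected),
        ("multi_cluster", config.frac_multi_cluster),
        ("bad_metrics", config.frac_bad_metrics),
    ):
        k = int(round(frac * n_snps))
        snp_class[order[cursor:cursor + k]] = name
        cursor += k

    freqs = rng.uniform(config.freq_low, config.freq_high, n_snps)
    mono_mask = snp_class == "mono"
    freqs[mono_mask] = rng.integers(0, 2, mono_mask.sum()).astype(float)  # fixed A or B
    multi_mask = snp_class == "multi_cluster"
    freqs[multi_mask] = rng.uniform(0.35, 0.65, multi_mask.sum())

    # ---- genotypes (allele-A dosage) --------------------------------
    # diploid dosage 0..2; triploid samples carry dosage 0..3
    dosage = np.zeros((n_snps, n_samples), dtype=np.int8)
    for s in founders:
        n_alleles = 3 if s in tri_samples else 2
        dosage[:, sidx[s]] = rng.binomial(n_alleles, freqs)
    for s in offspring:
        p1, p2 = offspring_parents[s]
        dosage[:, sidx[s]] = _transmit(rng, dosage[:, sidx[p1]]) + _transmit(
            rng, dosage[:, sidx[p2]]
        )
    for src, dup in zip(dup_sources, duplicates):
        dosage[:, sidx[dup]] = dosage[:, sidx[src]]

    # ---- calls -------------------------------------------------------
    is_tri = np.array([s in tri_samples for s in sample_ids])
    calls = np.empty((n_snps, n_samples), dtype=np.int8)
    calls[:, ~is_tri] = dosage[:, ~is_tri]  # 0/1/2 == BB/AB/AA
    if is_tri.any():
        tri_d = dosage[:, is_tri]
        tri_c = np.full(tri_d.shape, AB, dtype=np.int8)
        tri_c[tri_d == 0] = BB
        tri_c[tri_d == 3] = AA
        calls[:, is_tri] = tri_c

    # hom-hom injection: mis-call heterozygotes to a random homozygote
    hh_rows = np.flatnonzero(snp_class == "hom_hom")
    signal_calls = calls.copy()  # genotype class driving the signal draw
    for i in hh_rows:
        het = np.flatnonzero((calls[i] == AB) & ~is_tri)
        new = np.where(rng.random(het.size) < 0.5, AA, BB).astype(np.int8)
        calls[i, het] = new
        signal_calls[i, het] = new

    # ---- signals -----------------------------------------------------
    # diploid geometry: centers scale * (call - 1); scale is hom_center,
    # or the displaced magnitude for "unexpected" SNPs
    scale = np.full(n_snps, config.hom_center)
    unexp_rows = snp_class == "unexpected"
    scale[unexp_rows] = rng.uniform(
        config.unexpected_shift_low, config.unexpected_shift_high, unexp_rows.sum()
    )
    centers = scale[:, None] * (signal_calls.astype(float) - 1.0)
    if is_tri.any():
        centers[:, is_tri] = config.hom_center * (
            2.0 * dosage[:, is_tri].astype(float) - 3.0
        ) / 3.0
    sd = np.full((n_snps, n_samples), config.cluster_sd)
    for i in np.flatnonzero(multi_mask):
        het = np.flatnonzero((signal_calls[i] == AB) & ~is_tri)
        side = np.where(rng.random(het.size) < 0.5, -1.0, 1.0)
        centers[i, het] = side * config.multi_cluster_separation / 2.0
        sd[i, het] = config.multi_cluster_sd
    contrast = centers + rng.normal(0.0, 1.0, centers.shape) * sd
    size = rng.normal(config.size_mean, config.size_sd, centers.shape)

    # ---- metrics -----------------------------------------------------
    # clean metrics come from bounded uniform ranges clear of the default
    # thresholds; bad-metrics SNPs sit half a unit below the FLD/HetSO
    # thresholds so strict-inequality semantics are testable
    metrics = pd.DataFrame(index=probeset_ids, columns=list(METRIC_COLUMNS), dtype=float)
    metrics["fld"] = rng.uniform(6.0, 14.0, n_snps)
    metrics["hom_fld"] = rng.uniform(8.0, 16.0, n_snps)
    metrics["het_so"] = rng.uniform(0.0, 0.3, n_snps)
    metrics["hom_ro"] = rng.uniform(0.7, 1.3, n_snps)
    for col in ("var_aa", "var_ab", "var_bb"):
        metrics[col] = rng.uniform(0.007, 0.013, n_snps)
    bad_rows = snp_class == "bad_metrics"
    metrics.loc[bad_rows, "fld"] = 3.6 - 0.5
    metrics.loc[bad_rows, "het_so"] = -0.1 - 0.5

    # ---- planted errors and no-calls (clean SNPs only) ---------------
    clean_rows = snp_class == "clean"
    error_positions: list[tuple[str, str]] = []
    if config.genotyping_error_rate > 0:
        err = (rng.random(calls.shape) < config.genotyping_error_rate) & clean_rows[
            :, None
        ] & (calls != NOCALL)
        for i, j in np.argwhere(err):
            old = calls[i, j]
            others = [c for c in (BB, AB, AA) if c != old]
            calls[i, j] = others[int(rng.integers(0, 2))]
            error_positions.append((probeset_ids[i], sample_ids[j]))
    if config.no_call_rate > 0:
        nc = (rng.random(calls.shape) < config.no_call_rate) & clean_rows[:, None]
        calls[nc] = NOCALL

    dataset = AxiomDataset(
        sample_ids=sample_ids,
        probeset_ids=probeset_ids,
        calls=calls,
        contrast=contrast,
        size=size,
        metrics=metrics,
    )

    po_pairs = [
        (p, o) for o, (p1, p2) in offspring_parents.items() for p in (p1, p2)
    ]
    truth = TruthLabels(
        snp_class={
            pid: SNP_CLASS_NAMES[c] for pid, c in zip(probeset_ids, snp_class)
        },
        sample_ploidy=ploidy,
        duplicates=list(zip(dup_sources, duplicates)),
        parent_offspring=po_pairs,
        trios=[
            (p1, p2, o) for o, (p1, p2) in offspring_parents.items()
        ],
        error_positions=error_positions,
    )
    return dataset, truth


def write_fixture(
    dataset: AxiomDataset, truth: TruthLabels, out_dir: str | Path
) -> dict[str, Path]:
    """Write a fixture directory: the Axiom-style export plus truth files.

    ``genotypes.tsv`` is readable by :func:`axiomcurate.io.read_axiom_export`;
    truth files are plain TSV for test assertions and the tutorial.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"genotypes": write_axiom_export(dataset, out_dir / "genotypes.tsv")}

    p = out_dir / "truth_snps.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probeset_id\ttrue_class\n")
        for pid in dataset.probeset_ids:
            fh.write(f"{pid}\t{truth.snp_class[pid]}\n")
    paths["truth_snps"] = p

    p = out_dir / "truth_samples.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\ttrue_ploidy\n")
        for sid in dataset.sample_ids:
            fh.write(f"{sid}\t{truth.sample_ploidy[sid]}\n")
    paths["truth_samples"] = p

    p = out_dir / "truth_relationships.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("kind\tmember1\tmember2\tmember3\n")
        for a, b in truth.duplicates:
            fh.write(f"duplicate\t{a}\t{b}\t-\n")
        for a, b in truth.parent_offspring:
            fh.write(f"parent_offspring\t{a}\t{b}\t-\n")
        for a, b, c in truth.trios:
            fh.write(f"trio\t{a}\t{b}\t{c}\n")
    paths["truth_relationships"] = p

    p = out_dir / "truth_errors.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probeset_id\tsample_id\n")
        for pid, sid in truth.error_positions:
            fh.write(f"{pid}\t{sid}\n")
    paths["truth_errors"] = p
    return paths


def clean_config(**overrides) -> SimulationConfig:
    """A defect-free, error-free variant of the default conditions."""
    base = SimulationConfig(
        frac_mono=0.0,
        frac_hom_hom=0.0,
        frac_unexpected=0.0,
        frac_multi_cluster=0.0,
        frac_bad_metrics=0.0,
        genotyping_error_rate=0.0,
        no_call_rate=0.0,
    )
    return replace(base, **overrides)
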