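# axiomcurate

Curation engine for genotyping datasets from Thermo Fisher Axiom® SNP
arrays. Vendor calling software (Axiom Analysis Suite / Axiom Power
Tools) exports genotype calls together with transformed signal
intensities ("Contrast", "Size") and per-SNP clustering metrics (FLD,
HomFLD, HetSO, HomRO, cluster variances). Those exports still contain
systematic calling artifacts — monomorphic probes, null-allele
patterns, displaced or split clusters — that propagate into Mendelian
segregation errors downstream. `axiomcurate` is a semi-automatic
pipeline that finds and removes them, aimed at plant-breeding datasets
(apple, grapevine and similar crops with occasional polyploid
individuals), usable from Python or the shell.

## What it does

* **Ploidy check** — a sample's Contrast values across all SNPs form a
  mixture with one mode per genotype state: three modes (BB, AB, AA
  near −1, 0, +1) for a diploid, four (near −1, −⅓, +⅓, +1) for a
  triploid. Modes are counted by multi-scale (CWT) peak detection on
  the per-sample histogram; 3 peaks → diploid, 4 → triploid, anything
  else is flagged for review.
* **SNP filtering** (`filterm`, `filterc`) — each SNP accumulates class
  labels: *MonoHighResolution* (one genotype cluster),
  *HomHomCluster* (AA and BB without AB), *UnexpectedDistribution*
  (a homozygote cluster midpoint ≥ 1.5 from Contrast 0),
  *MetricsThreshold* (FLD < 3.6, HomFLD < 6.5, HetSO < −0.1, HomRO
  below its per-cluster-count bound, or a cluster-variance z-score
  beyond ±2), and *MultipleCluster* — a genotype cluster that splits
  into two sub-clusters under a penalized (BIC) one- vs two-component
  Gaussian comparison on the Contrast axis, gated by minimum subcluster
  size (5 samples, 5%) and separation (0.3 Contrast units).
* **Pedigree scanning** (`duos`, `trios`, `filterp`) — duplicates by
  genotype concordance (≥ 0.98), parent–offspring pairs by the
  opposing-homozygote test (rate ≤ 0.01 among jointly homozygous SNPs),
  parent-parent-offspring trios confirmed at a Mendelian-error rate
  ≤ 0.02; SNPs with errors in ≥ 2 confirmed trios get
  *MendelianErrorFilter*.
* **Review and export** (`review`, `review-sample`, `export`) — cluster
  plots per flagged SNP, batch or interactive confirm/include/exclude
  decisions, and export of the surviving Pass set to transposed PLINK
  (.tped/.tfam, with trio parents in the TFAM) or a generic TSV.
* **Persistent ledger** — every label, relationship, ploidy call and
  manual decision is stored in one human-readable JSON ledger, so each
  command can run in its own invocation and re-runs are idempotent.
* **Synthetic data** — a fully seeded generator producing Axiom-style
  datasets with known truth (cluster geometry, injected defect classes,
  pedigrees, duplicates, error rates); it is the package's universal
  test fixture.

## Worked example

```python
from axiomcurate import (CurationLedger, SimulationConfig, simulate,
                         filterm, filterc)

dataset, truth = simulate(SimulationConfig(seed=11))   # 5000 SNPs, 56 samples
ledger = CurationLedger()
ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
print(filterm(dataset, ledger))
print(filterc(dataset, ledger))
pass_snps, _ = ledger.pass_set()
print(len(pass_snps))
```

prints

```
{'MetricsThreshold': 200, 'MonoHighResolution': 100, 'UnexpectedDistribution': 100, 'HomHomCluster': 100}
{'MultipleCluster': 103}
4497
```

The generator injected 100 SNPs per defect class (2% each of 5000);
`filterm` recovers all 400 of its classes exactly (the 200
MetricsThreshold entries are two failed metrics on each of the 100
bad-metrics SNPs), `filterc` finds all 100 split-cluster SNPs plus 3
false positives caused by planted genotyping errors, and the Pass set
shrinks to 4497 SNPs. The `examples/` scripts walk through each
capability the same way — simulation, ploidy, filtering, pedigree
scanning, review and export — and the same pipeline is available from
the shell:

```sh
axiomcurate init-config my.yaml             # all defaults, documented
axiomcurate -c my.yaml import
axiomcurate -c my.yaml ploidy
axiomcurate -c my.yaml filterm
axiomcurate -c my.yaml filterc
axiomcurate -c my.yaml duos
axiomcurate -c my.yaml trios
axiomcurate -c my.yaml filterp
axiomcurate -c my.yaml export
```

## Scope

The engine starts from already-called exports: it does not process CEL
files, re-call genotypes, or phase (haplotype phasing around an
external phasing binary is deliberately out of scope). Aneuploidy
detection and null-allele re-calling are not attempted.
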