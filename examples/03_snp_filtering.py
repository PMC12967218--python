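"""Run the SNP filters (filterm + filterc) and compare against truth.

filterm assigns classes from call composition, homozygote-cluster
midpoints and quality metrics; filterc tests each genotype cluster for
hidden sub-structure (a split heterozygote cluster here, at 0.6
contrast-unit separation).
"""

from axiomcurate import CurationLedger, SimulationConfig, filterc, filterm, simulate

dataset, truth = simulate(SimulationConfig(seed=11))
ledger = CurationLedger()
ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)

print("filterm counts:", filterm(dataset, ledger))
print("filterc counts:", filterc(dataset, ledger))

for cls in ("MonoHighResolution", "HomHomCluster", "UnexpectedDistribution",
            "MetricsThreshold", "MultipleCluster"):
    detected = set(ledger.snps_in_class(cls))
    planted = {p for p, c in truth.snp_class.items() if c == cls}
    tp = len(detected & planted)
    print(f"{cls}: {tp}/{len(planted)} planted found, "
          f"{len(detected - planted)} false positives")

pass_snps, _ = ledger.pass_set()
print(f"Pass set: {len(pass_snps)}/{dataset.n_snps} SNPs")
# Each planted defect class should be recovered essentially in full;
# the Pass set shrinks by roughly the 10% of SNPs that were injected.
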