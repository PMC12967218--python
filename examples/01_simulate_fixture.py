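"""Generate a synthetic Axiom-style dataset with known ground truth.

The generator draws founders under Hardy-Weinberg, breeds two full-sib
families by Mendelian transmission, plants one duplicate sample, and
injects 2% of SNPs per problematic class.  The written fixture is a
plain TSV readable by the package's own reader.
"""

from collections import Counter

from axiomcurate import SimulationConfig, simulate, write_fixture

config = SimulationConfig(n_duplicates=1, seed=11)
dataset, truth = simulate(config)
paths = write_fixture(dataset, truth, "example_fixture")

print(f"dataset: {dataset.n_snps} SNPs x {dataset.n_samples} samples")
print("true SNP classes:", dict(Counter(truth.snp_class.values())))
print("planted duplicate pairs:", truth.duplicates)
print("planted trios:", len(truth.trios))
print("files:", ", ".join(str(p) for p in paths.values()))
# The class counts are the injection fractions times n_snps; every later
# example measures its step against exactly this truth.
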