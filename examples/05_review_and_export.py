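"""Review a flagged class, then export the Pass set as TPED/TFAM.

Review decisions override the automatic labels: manual_include
re-admits a SNP, manual_exclude removes it outright; everything is
recorded in the ledger.  The export writes transposed PLINK text files
whose TFAM parent columns come from the confirmed trios.
"""

import warnings

from axiomcurate import (
    CurationLedger, SimulationConfig, filterc, filterm, render_cluster_plot,
    review_class, scan_duos, scan_trios, simulate, write_tped_tfam,
)

dataset, truth = simulate(SimulationConfig(n_duplicates=1, seed=11))
ledger = CurationLedger()
ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
filterm(dataset, ledger)
filterc(dataset, ledger)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    scan_duos(dataset, ledger)
    scan_trios(dataset, ledger)

flagged = ledger.snps_in_class("MultipleCluster")
print(f"{len(flagged)} SNPs flagged MultipleCluster; plotting the first")
render_cluster_plot(dataset, flagged[0], ledger, "example_fixture/cluster.png")

# a curator re-admits the first flagged SNP and confirms the second
review_class(ledger, "MultipleCluster",
             [(flagged[0], "manual_include"), (flagged[1], "confirm")])

pass_snps, pass_samples = ledger.pass_set()
tped, tfam = write_tped_tfam(
    dataset, pass_snps, pass_samples, ledger.trios(), "example_fixture/curated"
)
print(f"exported {len(pass_snps)} SNPs x {len(pass_samples)} samples")
print(f"wrote {tped} and {tfam}")
with open(tfam) as fh:
    for line in list(fh)[40:43]:
        print("tfam:", line.rstrip())
# Offspring rows carry their confirmed parents' ids in columns 3-4;
# the re-admitted SNP is back in the TPED despite its automatic label.
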