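"""Detect duplicates, parent-offspring pairs and trios; filter
high-Mendelian-error SNPs.

Duplicates are near-perfect concordance; a parent and child are never
opposing homozygotes; a trio is confirmed when its Mendelian-error
rate stays below 2%.
"""

import warnings

from axiomcurate import (
    CurationLedger, clean_config, filterp, scan_duos, scan_trios, simulate,
)

dataset, truth = simulate(
    clean_config(n_duplicates=1, genotyping_error_rate=0.002,
                 no_call_rate=0.005, seed=7)
)
ledger = CurationLedger()
ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # sibling pairs are indeterminate, fine
    relationships = scan_duos(dataset, ledger)
    trios, table = scan_trios(dataset, ledger)

dups = [r for r in relationships if r.kind == "duplicate"]
po = [r for r in relationships if r.kind == "parent_offspring"]
print(f"duplicates: {[r.members for r in dups]} (planted: {truth.duplicates})")
print(f"parent-offspring pairs: {len(po)} (planted: {len(truth.parent_offspring)})")
print(f"confirmed trios: {len(trios)} (planted: {len(truth.trios)})")
print(f"mean Mendelian errors per trio: {table.mean_error_count():.1f} "
      f"({100 * table.mean_error_rate():.2f}%)")

n_labeled = filterp(table, ledger, max_errors=2)
print(f"SNPs labeled MendelianErrorFilter: {n_labeled}")
excluded = [s for s, st in ledger.sample_status.items() if st.excluded]
print(f"samples excluded: {excluded}")
# The 0.2% planted call-error rate shows up as a small per-trio error
# percentage; SNPs hit by errors in 2+ trios are filtered out.
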