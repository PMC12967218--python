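"""Infer sample ploidy from Contrast-distribution peak counts.

A diploid sample's Contrast values pile up in three modes (BB, AB, AA
near -1, 0, +1); a triploid sample shows four (near -1, -1/3, +1/3,
+1).  Counting histogram modes therefore reads off the ploidy.
"""

from axiomcurate import clean_config, contrast_distribution, detect_peaks, ploidy_check, simulate

# 30% of non-parent founders triploid, mode noise at the hard end (sd 0.15)
dataset, truth = simulate(clean_config(frac_triploid=0.3, cluster_sd=0.15, seed=3))
calls = ploidy_check(dataset)

correct = sum(calls[s].label == truth.sample_ploidy[s] for s in dataset.sample_ids)
print(f"correct ploidy labels: {correct}/{dataset.n_samples}")

sample = next(s for s, p in truth.sample_ploidy.items() if p == "triploid")
dist = contrast_distribution(dataset, sample)
peaks = detect_peaks(dist)
print(f"{sample} (true triploid): {len(peaks)} peaks at "
      + ", ".join(f"{p:+.2f}" for p in peaks))
# Four peaks near -1, -1/3, +1/3 and +1 are the two homozygote and two
# heterozygote dosage states of a triploid genome.
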