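"""Generate a study-scale synthetic paired dataset and apply the rare-OTU filter.

The generator plants eight co-occurrence modules, nitrate-sensitive species
with known fold changes, and module-trait couplings; the filter removes OTUs
that never reach 10 counts or fall below 5 counts in half the samples.
"""

import micronet as mn

ds = mn.generate(seed=1)
print(f"dataset: {ds.otus.counts.shape[0]} OTUs x {ds.otus.counts.shape[1]} samples "
      f"({len(ds.otus.subjects)} subjects x 2 conditions)")

filtered, report = mn.filter_rare_otus(ds.otus)
print(f"filter: rule 1 removed {report.n_removed_rule1} OTUs (<10 counts everywhere), "
      f"rule 2 removed {report.n_removed_rule2} (<5 counts in >=50% of samples), "
      f"{len(report.surviving_otu_ids)} OTUs survive")

truth = ds.truth
print(f"planted truth: {truth.module_of.max()} modules, "
      f"{(truth.module_of == 0).sum()} background OTUs, "
      f"{(truth.condition_log_fc != 0).sum()} nitrate-sensitive OTUs")
# The surviving table is what every downstream stage consumes.
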