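"""Alpha diversity, NMDS ordination and stratified PERMANOVA on paired data.

A shift of the community between conditions shows up as a significant
PERMANOVA p-value (permutations restricted within subjects, because the
design is paired) even when alpha diversity is unchanged.
"""

import numpy as np

import micronet as mn

ds = mn.generate(seed=1)
filtered, _ = mn.filter_rare_otus(ds.otus)
rel = mn.to_relative_abundance(filtered)
meta = rel.sample_meta

counts_t = filtered.counts.T
shannon = np.array([mn.shannon(row) for row in counts_t.to_numpy()])
for cond in ("PL", "BR"):
    sel = (meta["condition"] == cond).to_numpy()
    print(f"Shannon H' ({cond}): {shannon[sel].mean():.2f} +- {shannon[sel].std():.2f}")

d = mn.bray_curtis_matrix(rel.fractions.T.to_numpy())
ordination = mn.nmds(d, k=2, seed=1)
print(f"NMDS: stress = {ordination.stress:.3f} after {ordination.n_iterations} iterations")

res = mn.permanova(
    d, meta["condition"].to_numpy(), n_perm=999, seed=1,
    strata=meta["subject_id"].to_numpy(),
)
print(f"PERMANOVA (condition | subject strata): pseudo-F = {res.pseudo_F:.2f}, "
      f"R2 = {res.R2:.3f}, p = {res.p_value:.3f}")
# p <= 0.05 -> overall community composition differs between diets.
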