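"""Module-driver identification with Kruskal-Wallis + LDA effect size.

Within each module, finds the OTUs that separate the two dietary conditions
with |log10 LDA effect| >= 2 (on the parts-per-million scale).
"""

import micronet as mn

ds = mn.generate(seed=1)
filtered, _ = mn.filter_rare_otus(ds.otus)
rel = mn.to_relative_abundance(filtered)
meta = rel.sample_meta
labels = ds.truth.module_of.reindex(rel.fractions.index)

result = mn.lefse_modules(
    rel.fractions.T, meta["condition"].to_numpy(), labels,
    alpha=0.05, threshold=2.0, seed=1,
)
drivers = mn.module_drivers(result)
for m, df in drivers.items():
    if len(df) == 0:
        print(f"MM{m}: no OTU exceeded the LDA threshold")
        continue
    names = ", ".join(
        f"{filtered.taxonomy[r.feature].split(';')[-1]} ({r.enriched_class} "
        f"{r.lda_effect:+.1f})" for r in df.head(4).itertuples()
    )
    print(f"MM{m}: {len(df)} driver(s): {names}")
# Positive score = enriched under nitrate (BR); the score is log10 of the
# effect in ppm, so 2 corresponds to a 100 ppm (0.01%) class difference.
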