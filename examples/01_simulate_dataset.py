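"""Generate a synthetic compound screening dataset and explore it.

Draws 40 compounds from the generative qAOP model with realistic missingness
(sparse literature BDNF labels, in silico gaps, assay inactives), writes the
CSV fixture, and prints the exploratory summary a modeller would inspect
before fitting: missingness per column and class balance of the outcomes.
"""

from qaop import DEFAULT_MISSINGNESS, GeneratorConfig, explore_dataset, simulate_study, write_fixture

cfg = GeneratorConfig(n_compounds=40, seed=11, missingness=DEFAULT_MISSINGNESS)
ds, true = simulate_study(cfg)
write_fixture(ds, "scratch_dataset.csv", true)

eda = explore_dataset(ds)
print(f"simulated {len(ds)} compounds -> scratch_dataset.csv")
print("\nmissing fraction per column (0 = fully observed):")
for col, frac in eda.missing_fraction.items():
    if frac > 0:
        print(f"  {col:18s} {frac:.2f}")
print("\nfraction positive among observed labels:")
for col, bal in eda.class_balance.items():
    print(f"  {col:12s} {bal:.2f}")
# The DNT label is never missing: every compound carries an in vivo
# classification. BDNF labels are the sparsest, as in real evidence bases.
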