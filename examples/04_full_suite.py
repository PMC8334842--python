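"""Heterogeneity and the depression-dependent slope from the model suite.

Runs the intercept-only meta-analyses (heterogeneity: how much variation in
the effect sizes is real rather than sampling noise, and how much of that is
phylogenetic) plus the depression-interaction model.
"""

from phylometa.bpmm import MCMCSettings
from phylometa.effect_sizes import build_species_table
from phylometa.phylo import phylo_correlation
from phylometa.simulate import GeneratorParams, generate
from phylometa.suite import run_suite

raw, tree, _ = generate(GeneratorParams(seed=3))
table = build_species_table(raw)
cov = phylo_correlation(tree)

settings = MCMCSettings(iterations=12_000, burn_in=2_000, thin=10,
                        n_chains=1, seed=2)
result = run_suite(table, cov, settings, models=["1.1", "1.4", "3"])

for name, label in (("1.1", "ZrPairs"), ("1.4", "ZrAverage")):
    het = result.models[name].heterogeneity
    print(f"Model {name} ({label}, n = {result.models[name].n_used}):")
    print(f"  I2_total = {100 * het.i2_total.pm:.0f}% "
          f"(CI {100 * het.i2_total.ci_lower:.0f} to "
          f"{100 * het.i2_total.ci_upper:.0f}%), "
          f"H2 = {100 * het.h2.pm:.0f}%, "
          f"sigma_m2 = {het.sigma_m2:.4f}")

m3 = result.models["3"]
print(f"\nModel 3 (depression x ZrAverage, n = {m3.n_used}):")
for lev in ("yes", "no"):
    s = m3.summaries[f"slope[depression={lev}]"]
    d = m3.summaries[f"slope[depression={lev}]_minus_1"]
    print(f"  depression={lev}: slope PM = {s.pm:.2f} "
          f"(CI {s.ci_lower:.2f} to {s.ci_upper:.2f}); "
          f"vs 1: pMCMC = {d.pmcmc:.3f}")
print()
print("I2_total near 100% would mean sampling error explains almost nothing;")
print("a depression-class slope credibly below 1 with the no-depression slope")
print("near 1 reproduces the avoid-only-when-it-hurts pattern the generator")
print("encodes.")
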