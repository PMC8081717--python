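"""Significance reporting: z-tests, Bonferroni, heatmap and letters.

Every predicted pairwise difference is z-tested against its SEPD; the
compact letter display encodes the adjusted significance pattern
exactly (genotypes sharing no letter differ significantly).
"""

from pathlib import Path

import zonemet as zm

cfg = zm.SimulationConfig(seed=5, n_genotypes=12, block_size=4,
                          sigma2_genotype=2500.0)
dataset, cov, _ = zm.simulate_met(cfg)
new_cov, _ = zm.simulate_new_locations(cfg)
allcov = zm.merged_covariates(cov, new_cov)

fit = zm.fit_reml(zm.build_stage2_design(
    zm.make_model("RG1"), zm.assemble_stage2(zm.run_stage1(dataset)), allcov))
loc = allcov.new_locations[0]
pred = zm.predict_new_location(fit, allcov, loc)
pairs = zm.pairwise_differences(fit, allcov, loc)

pmatrix = zm.pairwise_pvalues(pairs, alpha=0.05)
print(f"{pmatrix.n_pairs} pairs; smallest adjusted p = "
      f"{pmatrix.p_adj.values[pmatrix.p_adj.values < 1].min():.4f}")

letters = zm.letter_display(pmatrix, pred.table.set_index("genotype")["eta"])
print("\nmean-sorted letter display (shared letter = not significantly "
      "different):")
print(letters.table.round(1).to_string(index=False))

out = Path("scratch/report")
paths = zm.export_report(pred, pairs, pmatrix, letters, out)
print("\nwrote:", ", ".join(str(p) for p in paths.values()))
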