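"""Predict genotype performance in new locations with SEPV/SEPD.

Fits the RC2 model -- random genotype main effect plus random
intercept/linear/quadratic genotype x zone response to scaled clay --
and predicts every genotype at each untested location.
"""

import zonemet as zm

cfg = zm.SimulationConfig(seed=3, n_genotypes=10, block_size=5)
dataset, cov, _ = zm.simulate_met(cfg)
new_cov, _ = zm.simulate_new_locations(cfg)
allcov = zm.merged_covariates(cov, new_cov)

clay = zm.CovariateSpec("clay", "shift_scale", 40.0, 10.0)
fit = zm.fit_reml(zm.build_stage2_design(
    zm.make_model("RC2", clay), zm.assemble_stage2(zm.run_stage1(dataset)),
    allcov))

for loc in allcov.new_locations:
    pred = zm.predict_new_location(fit, allcov, loc, alpha=0.05)
    print(f"\n{loc} ({pred.zone} zone, clay {allcov.value(loc, 'clay'):.1f} %):")
    print(pred.table.round(1).head(5).to_string(index=False))
# eta is the predicted yield (g/m^2), sepv its standard error of
# prediction including the unobservable location and genotype x location
# variability, and [lower, upper] the 95% prediction interval.

loc = allcov.new_locations[0]
pairs = zm.pairwise_differences(fit, allcov, loc, alpha=0.05)
print(f"\npairwise differences at {loc} (SEPD excludes the shared "
      "location effect, so comparisons are sharper):")
print(pairs.table.round(1).head(5).to_string(index=False))
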