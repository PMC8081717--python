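"""Screen candidate soil covariates before choosing a stage-II model.

Clay, pH and humus each contribute scaled linear + quadratic fixed
terms to the fixed-genotype baseline; Wald F tests (quadratic first,
polynomial hierarchy) decide what to keep.  Here the generator gives
yield a genuine quadratic clay response, so clay should survive and the
null covariates should drop.
"""

import zonemet as zm

cfg = zm.SimulationConfig(seed=8, zones={"North": 10, "Middle": 10, "South": 10},
                          n_new={}, n_genotypes=8, block_size=4,
                          beta=20.0, gamma=-40.0)
dataset, covariates, _ = zm.simulate_met(cfg)
stage2 = zm.assemble_stage2(zm.run_stage1(dataset))

candidates = [zm.CovariateSpec("clay", "shift_scale", 40.0, 10.0),
              zm.CovariateSpec("ph", "standardise", None, None),
              zm.CovariateSpec("humus", "standardise", None, None)]
result = zm.select_covariates(stage2, covariates, candidates, alpha=0.05)

print(result.tests[["covariate", "degree", "stage", "statistic", "ddf",
                    "p_value", "kept"]].round(4).to_string(index=False))
print("\nkept:", {k: v for k, v in result.kept.items() if v} or "none")
# 'quadratic' means both the linear and quadratic terms stay (hierarchy);
# the retained covariate then feeds the FGC/FGCQ/RGC/RGCQ/RC models.
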