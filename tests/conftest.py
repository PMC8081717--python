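"""Shared fixtures: small simulated METs and their stage-II data.

Everything is generated in-process from seeded configs; module-scoped
fixtures keep the REML fits to a handful per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import zonemet as zm


@pytest.fixture(scope="session")
def small_config() -> zm.SimulationConfig:
    """3 zones x 5 locations, 8 genotypes, 2 new locations."""
    return zm.SimulationConfig(
        seed=42, zones={"North": 5, "Middle": 5, "South": 5},
        n_new={"North": 1, "South": 1}, n_genotypes=8, block_size=4)


@pytest.fixture(scope="session")
def small_met(small_config):
    dataset, cov, truth = zm.simulate_met(small_config)
    new_cov, new_truth = zm.simulate_new_locations(small_config)
    return {"dataset": dataset, "covariates": zm.merged_covariates(cov, new_cov),
            "truth": truth, "new_truth": new_truth, "config": small_config}


@pytest.fixture(scope="session")
def small_stage2(small_met):
    fits = zm.run_stage1(small_met["dataset"])
    return zm.assemble_stage2(fits)


@pytest.fixture(scope="session")
def rg1_fit(small_stage2, small_met):
    model = zm.build_stage2_design(zm.make_model("RG1"), small_stage2,
                                   small_met["covariates"])
    return zm.fit_reml(model)


@pytest.fixture(scope="session")
def clay_spec() -> zm.CovariateSpec:
    return zm.CovariateSpec("clay", "shift_scale", 40.0, 10.0)


def make_stage2_direct(seed: int, zones: dict, n_genotypes: int,
                       sigma2_loc=5000.0, sigma2_g=600.0, sigma2_gz=65.0,
                       sigma2_gl=800.0, r_diag=400.0, mean=800.0,
                       covariate_effect=None):
    """Build Stage2Data straight at the adjusted-means level (known
    diagonal R), bypassing stage I -- cheap input for screening and
    engine-level tests.

    ``covariate_effect``: optional callable (x, rng) -> added mean shift
    per location, with x the location's raw clay value.
    """
    rng = np.random.default_rng(seed)
    zval = lambda v, z: float(v[z]) if isinstance(v, dict) else float(v)
    genotypes = [f"G{i:02d}" for i in range(1, n_genotypes + 1)]
    rows, loc_zone, clay = [], {}, {}
    cov_rows = []
    for z, nloc in sorted(zones.items()):
        for j in range(1, nloc + 1):
            loc = f"{z[:1]}{j:02d}"
            loc_zone[loc] = z
            clay[loc] = rng.uniform(10, 70)
            cov_rows.append({"location": loc, "zone": z, "clay": clay[loc],
                             "ph": rng.normal(6.5, 0.5),
                             "humus": rng.lognormal(0.9, 0.35),
                             "is_new": False})
    g_eff = dict(zip(genotypes, rng.normal(0, np.sqrt(sigma2_g), len(genotypes))))
    gz_eff = {(g, z): rng.normal(0, np.sqrt(sigma2_gz))
              for g in genotypes for z in sorted(zones)}
    for loc, z in loc_zone.items():
        l_eff = rng.normal(0, np.sqrt(zval(sigma2_loc, z)))
        shift = covariate_effect(clay[loc], rng) if covariate_effect else 0.0
        for g in genotypes:
            gl = rng.normal(0, np.sqrt(zval(sigma2_gl, z)))
            e = rng.normal(0, np.sqrt(r_diag))
            rows.append({"location": loc, "zone": z, "genotype": g,
                         "mean": mean + shift + l_eff + g_eff[g]
                         + gz_eff[(g, z)] + gl + e})
    df = pd.DataFrame(rows).sort_values(["location", "genotype"]).reset_index(drop=True)
    R = np.eye(len(df)) * r_diag
    stage2 = zm.Stage2Data(df, R, loc_zone)
    covariates = zm.CovariateTable(pd.DataFrame(cov_rows))
    return stage2, covariates
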