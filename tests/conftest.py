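"""Shared fixtures: a small reference genome and a simulated paired-read study."""

import numpy as np
import pytest

from microdiv.genome import make_reference
from microdiv.population import apply_block_structure, implant_sweep, make_population
from microdiv.reads import default_sample_plan, simulate_study


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(2, 15_000, 12, seed=7)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A 2-block, 8-sample synthetic study with one implanted sweep.

    Session-scoped: read simulation and SAM parsing dominate test runtime.
    """
    outdir = tmp_path_factory.mktemp("study")
    ref = make_reference(1, 40_000, 60, seed=1)
    pool = make_population(ref, 800, rho_sim=5.0, n_haplotypes=200, seed=2)
    pool = apply_block_structure(pool, 2, 0.05, seed=3)
    order = [g.gene_id for g in ref.genes_sorted()]
    pool = implant_sweep(pool, order[30:36], "B1", 0.95, seed=4)
    plan = default_sample_plan(["B1", "B2"])
    paths = simulate_study(pool, plan, outdir, seed=5, coverage_per_sample=12)
    return {"ref": ref, "pool": pool, "plan": plan, "dir": outdir, "paths": paths}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
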