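import numpy as np
import pandas as pd
import pytest

from mdtr import (
    ExpressionDataset,
    SampleTable,
    SynthConfig,
    build_spaces,
    compute_mdtr,
    fit_dual_boundaries,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 30 samples/group, effect size 3,
    Oxidative stress perturbed."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for unit-level pipeline tests."""
    cfg = SynthConfig(
        seed=3,
        n_genes=400,
        pathway_sizes=[12, 10, 8, 10, 8, 6],
        mechanism_layout={"A": [0, 1], "B": [2, 3], "C": [4, 5]},
        perturbed_mechanism="A",
        n_dmso=20,
        n_nontoxic=20,
        n_toxic=20,
    )
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def fitted_pipeline(default_cohort):
    """Boundary, spaces and profiles for the default cohort (computed once)."""
    expr, meta, pathways, mech_map, truth = default_cohort
    boundary = fit_dual_boundaries(expr, meta)
    spaces = build_spaces(expr, pathways, boundary.pt_sample_ids)
    profiles = compute_mdtr(
        expr, meta, spaces, mech_map, pt_ids=set(boundary.pt_sample_ids)
    )
    return boundary, spaces, profiles


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(4)]
    return ExpressionDataset(genes, samples, rng.normal(size=(6, 4)))


@pytest.fixture()
def tiny_meta():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s0", "s1", "s2", "s3"],
                "drug": ["DMSO", "DMSO", "aspirin", "doxorubicin"],
                "dose_um": [0.0, 0.0, 1.0, 10.0],
                "time_h": [24.0, 24.0, 24.0, 24.0],
                "cell_line": ["HEPG2"] * 4,
                "group": ["DMSO", "DMSO", "NONTOXIC", "TOXIC"],
            }
        )
    )
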