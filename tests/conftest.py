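import numpy as np
import pandas as pd
import pytest

from saltwise import (
    SimConfig,
    build_interaction_contrasts,
    build_salinity_contrasts,
    estimate_dispersions,
    filter_genes,
    fit_glm,
    normalization_factors,
    simulate_experiment,
    stagewise_test,
)
from saltwise.glm import offsets_from_library_sizes
from saltwise.stagewise import StagewiseResult


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-gene default-design simulation shared across tests."""
    cfg = SimConfig(n_genes=300, seed=11)
    counts, design, truth = simulate_experiment(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def small_fit(small_experiment):
    _, counts, design, truth = small_experiment
    filtered = filter_genes(counts, design)
    lib = normalization_factors(filtered)
    offsets = offsets_from_library_sizes(lib)
    disp = estimate_dispersions(filtered, design, offsets)
    return fit_glm(filtered, design, offsets, disp)


@pytest.fixture(scope="session")
def small_results(small_experiment, small_fit):
    _, _, design, _ = small_experiment
    sal = build_salinity_contrasts(design.strains, design.salinities)
    inter = build_interaction_contrasts(design.strains, design.salinities)
    with pytest.warns(UserWarning):
        sal_res = stagewise_test(small_fit, sal)
    with pytest.warns(UserWarning):
        int_res = stagewise_test(small_fit, inter)
    return sal_res, int_res


def make_stagewise(calls: pd.DataFrame, logfc: pd.DataFrame, family="salinity-set",
                   alpha=0.05) -> StagewiseResult:
    """Build a StagewiseResult from explicit call/logFC matrices (for set-logic
    tests that need exact control over the calls)."""
    genes = calls.index
    screen_p = pd.Series(0.001, index=genes)
    padj_screen = pd.Series(
        np.where(calls.any(axis=1), 0.01, 1.0), index=genes
    )
    raw_p = pd.DataFrame(
        np.where(calls.to_numpy(), 1e-4, 0.9), index=genes, columns=calls.columns
    )
    padj = pd.DataFrame(
        np.where(calls.to_numpy(), 0.01, 1.0), index=genes, columns=calls.columns
    )
    return StagewiseResult(
        family=family,
        alpha=alpha,
        screen_p=screen_p,
        padj_screen=padj_screen,
        logfc=logfc,
        raw_p=raw_p,
        padj=padj,
        calls=calls.astype(bool),
    )
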