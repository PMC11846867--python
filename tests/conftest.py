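import numpy as np
import pandas as pd
import pytest

from scired.io_model import CountMatrix, CovariateTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """20 cells x 5 genes Poisson counts, no zero rows/columns."""
    values = rng.poisson(4.0, size=(20, 5)) + 1
    return CountMatrix(
        values,
        [f"c{i}" for i in range(20)],
        [f"g{j}" for j in range(5)],
    )


@pytest.fixture
def small_cov(small_counts, rng):
    df = pd.DataFrame(
        {
            "group": rng.choice(["A", "B"], size=20),
            "library_size": small_counts.library_size(),
        },
        index=pd.Index(small_counts.cell_ids, name="cell_id"),
    )
    return CovariateTable(df, {"group": "annotation", "library_size": "technical"})


@pytest.fixture(scope="session")
def planted_run():
    """One full planted-structure pipeline run, shared across tests."""
    from scired.factorize import factorize
    from scired.fca import build_fca
    from scired.io_model import encode_design, preprocess
    from scired.residualize import fit_poisson_glm, residuals
    from scired.simulate import PlantedCountSpec, simulate_counts

    spec = PlantedCountSpec(
        n_cells=1200, n_genes=400, block_size=40,
        effect=2.5, effect_sd=1.0, seed=7,
    )
    counts, cov, truth = simulate_counts(spec)
    counts, cov = preprocess(counts, n_hvg=400, cov=cov)
    design, names = encode_design(cov, ["library_size"])
    fit = fit_poisson_glm(counts, design, design_cols=names)
    res = residuals(counts, fit, "pearson")
    model = factorize(res, k=8)
    model.gene_ids = counts.gene_ids
    model.cell_ids = counts.cell_ids
    fca = build_fca(model, cov, seed=7)
    return dict(
        spec=spec, counts=counts, cov=cov, truth=truth, design=design,
        design_cols=names, fit=fit, residuals=res, model=model, fca=fca,
    )
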