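import numpy as np
import pandas as pd
import pytest

from ghufinder import (
    GeneMatrix,
    PipelineConfig,
    PlantedGHU,
    SyntheticSpec,
    build_ahplus,
    generate_bundle,
    run_core,
)


@pytest.fixture(scope="session")
def desk_bundle():
    """Small structured bundle: 3 planted GHUs of 25 genes in 400."""
    spec = SyntheticSpec(
        n_genes=400,
        n_tfs=24,
        ghus=(PlantedGHU(1, 1, 1, 25), PlantedGHU(2, 2, 2, 25), PlantedGHU(3, 3, 3, 25)),
        seed=7,
    )
    return generate_bundle(spec)


@pytest.fixture(scope="session")
def desk_ahplus(desk_bundle):
    return build_ahplus(desk_bundle.ah, desk_bundle.hs)


@pytest.fixture(scope="session")
def desk_result(desk_bundle, desk_ahplus):
    cfg = PipelineConfig(k_tf=4, k_hm=4, k_expr=3, kappa=10.0, n_restarts=30, seed=7)
    return run_core(desk_bundle.tr, desk_ahplus, desk_bundle.expr, desk_bundle.annotation, cfg)


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["GA", "GB", "GC"],
        columns=["f1", "f2"],
    )
    return GeneMatrix(data, "EXPR")


def make_matrix(values, genes=None, features=None, tag="EXPR"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    features = features or [f"f{j + 1}" for j in range(values.shape[1])]
    return GeneMatrix(pd.DataFrame(values, index=genes, columns=features), tag)
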