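import numpy as np
import pandas as pd
import pytest

from kinoforge.containers import BetaMatrix, ExpressionMatrix, IntensityMatrix
from kinoforge.kinome import KinasePeptideMap


def two_group_labels(n1: int, n2: int) -> pd.Series:
    treated = [f"T{i+1}" for i in range(n1)]
    control = [f"C{i+1}" for i in range(n2)]
    return pd.Series(["treated"] * n1 + ["control"] * n2, index=treated + control)


@pytest.fixture
def groups6():
    return two_group_labels(6, 6)


@pytest.fixture
def small_intensity(groups6):
    """10 peptides x 12 samples, no real effects, deterministic."""
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.normal(10, 1, (10, 12)),
        index=[f"P{i+1:02d}" for i in range(10)],
        columns=groups6.index,
    )
    return IntensityMatrix(values, groups6, scale="log2")


@pytest.fixture
def small_map():
    return KinasePeptideMap(
        [("KA", f"P{i:02d}") for i in (1, 2, 3, 4)]
        + [("KB", f"P{i:02d}") for i in (3, 4, 5, 6)]
        + [("KC", f"P{i:02d}") for i in (7, 8)]
    )


@pytest.fixture
def small_beta(groups6):
    rng = np.random.default_rng(5)
    beta = 1 / (1 + np.exp(-rng.normal(0, 1.5, (20, 12))))
    values = pd.DataFrame(
        beta, index=[f"cg{i+1:04d}" for i in range(20)], columns=groups6.index
    )
    return BetaMatrix(values, groups6)


@pytest.fixture
def small_expression(groups6):
    rng = np.random.default_rng(7)
    probes = [f"ILMN_{i+1:03d}" for i in range(12)]
    values = pd.DataFrame(rng.normal(8, 1, (12, 12)), index=probes,
                          columns=groups6.index)
    detection = pd.DataFrame(np.full((12, 12), 0.001), index=probes,
                             columns=groups6.index)
    gene_map = pd.DataFrame({"probe_id": probes,
                             "gene": [f"G{i // 2 + 1}" for i in range(12)]})
    return ExpressionMatrix(values, groups6, scale="log2",
                            detection_p=detection, probe_gene_map=gene_map)
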