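import numpy as np
import pandas as pd
import pytest

from tfbsreg import FeatureMatrix, PWM, ExpressionMatrix


@pytest.fixture
def toy_pwm() -> PWM:
    """Width-6 PWM with three fully informative and three mixed positions."""
    freq = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.5, 0.5, 0.0, 0.0],
            [0.7, 0.1, 0.1, 0.1],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return PWM("TOY", freq, tf_names=("ToyTF",))


@pytest.fixture
def small_features() -> FeatureMatrix:
    """20 genes, 3 TFBS count columns, noiseless response 2*m1 + 1."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.integers(0, 4, size=(20, 3)),
        index=pd.Index([f"G{i:02d}" for i in range(20)], name="gene_id"),
        columns=["m1", "m2", "m3"],
    )
    response = pd.Series(
        2.0 * values["m1"] + 1.0, index=values.index, name="resp"
    )
    return FeatureMatrix(values, response)


def make_expression(
    control: np.ndarray, treated: np.ndarray, genes=None
) -> ExpressionMatrix:
    """Two-condition matrix from per-gene replicate arrays."""
    control = np.atleast_2d(control)
    treated = np.atleast_2d(treated)
    genes = genes or [f"g{i}" for i in range(control.shape[0])]
    cols = [f"control_{i+1}" for i in range(control.shape[1])] + [
        f"treated_{i+1}" for i in range(treated.shape[1])
    ]
    values = pd.DataFrame(
        np.hstack([control, treated]), index=pd.Index(genes, name="gene_id"),
        columns=cols,
    )
    design = {c: tuple([c.rsplit("_", 1)[0], int(c.rsplit("_", 1)[1])]) for c in cols}
    return ExpressionMatrix(values, design)
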