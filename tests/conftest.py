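import numpy as np
import pytest

from nutridecomp import (
    GeneratorConfig,
    Schema,
    Variable,
    build_design,
    default_config,
    generate_survey,
)
from nutridecomp.core_data import DesignMatrix
from nutridecomp.weighted_logit import fit as logit_fit


@pytest.fixture
def binary_schema():
    return Schema((Variable("x", ("0", "1")),))


@pytest.fixture
def three_var_schema():
    return Schema((
        Variable("edu", ("None", "Primary", "Secondary")),
        Variable("wealth", ("Poor", "Middle", "Rich")),
        Variable("residence", ("Urban", "Rural")),
    ))


def make_three_var_config(schema, seed=0, n=2000):
    """A well-conditioned two-survey scenario over a 3-variable schema."""
    comp = {
        "B": {"edu": (0.6, 0.3, 0.1), "wealth": (0.5, 0.3, 0.2),
              "residence": (0.3, 0.7)},
        "A": {"edu": (0.4, 0.4, 0.2), "wealth": (0.4, 0.3, 0.3),
              "residence": (0.4, 0.6)},
    }
    beta = {
        "B": (-0.3, -0.4, -0.9, -0.2, -0.6, 0.5),
        "A": (-0.6, -0.3, -0.8, -0.3, -0.9, 0.4),
    }
    return GeneratorConfig(schema=schema, surveys=("B", "A"), n_per_survey=n,
                           composition=comp, beta=beta, seed=seed)


@pytest.fixture
def three_var_config(three_var_schema):
    return make_three_var_config(three_var_schema)


@pytest.fixture
def fitted_pair(three_var_config):
    """(design_A, design_B, fit_A, fit_B) from the 3-variable scenario."""
    ds_B = generate_survey(three_var_config, 0)
    ds_A = generate_survey(three_var_config, 1)
    d_B, d_A = build_design(ds_B), build_design(ds_A)
    return d_A, d_B, logit_fit(d_A), logit_fit(d_B)


def simple_design(x, y, w=None, schema=None):
    """Intercept + one binary dummy design from plain arrays."""
    x = np.asarray(x, dtype=float)
    values = np.column_stack([np.ones(len(x)), x])
    return DesignMatrix(
        values=values,
        weights=np.ones(len(x)) if w is None else np.asarray(w, dtype=float),
        outcome=np.asarray(y, dtype=float),
        groups={"x": [1]},
        columns=["intercept", "x=1"],
        schema=schema,
    )


@pytest.fixture
def default_scenario():
    return default_config()
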