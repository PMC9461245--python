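import numpy as np
import pandas as pd
import pytest

import iop_lifecycle as il


@pytest.fixture(scope="session")
def saturated_2x2():
    """Balanced binary cell realising P(y=1|x=1)=0.75, P(y=1|x=0)=0.25 exactly.

    The saturated logit MLE is available in closed form:
    beta = log(0.75/0.25) - log(0.25/0.75) = log 9, alpha = log(1/3).
    """
    x = np.repeat([0, 1], 8)
    y = np.concatenate([np.repeat([0, 1], [6, 2]), np.repeat([0, 1], [2, 6])])
    return pd.DataFrame({"x": x, "y": y})


@pytest.fixture(scope="session")
def small_panel():
    cfg = il.default_config(n_per_cell=300, countries=("AT", "DE"), seed=42)
    return il.generate_panel(cfg)


@pytest.fixture(scope="session")
def coded_cell():
    """One coded country×cohort cell with outcomes built at age 55."""
    cfg = il.default_config(
        n_per_cell=1500, countries=("AT",), cohort_bounds=((1940, 1945),),
        seed=7,
    )
    coded, _ = il.code_panel(il.generate_panel(cfg))
    coded = coded.copy()
    coded[["outcome_any", "outcome_ge_median"]] = il.build_outcomes(coded, 55)
    return coded
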