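import numpy as np
import pandas as pd
import pytest

from panelign import synthetic_data as sd
from panelign.io_model import ExpressionMatrix


def make_expression(values: np.ndarray, genes, samples,
                    unit="log_normalized", group=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with minimal annotations."""
    df = pd.DataFrame(values, index=list(genes), columns=list(samples))
    ann = pd.DataFrame({
        "group": group if group is not None else ["g"] * len(samples),
        "model": "m", "age_months": 6, "sex": "M",
        "lane": [f"L{i + 1}" for i in range(len(samples))]},
        index=list(samples))
    ann.index.name = "sample"
    return ExpressionMatrix(df, unit, ann)


@pytest.fixture(scope="session")
def small_sim():
    """A 10-module synthetic dataset shared across read-only tests."""
    cfg = sd.SimulationConfig(seed=11, n_modules=10)
    modules, clusters = sd.simulate_modules(cfg)
    expr, human_truth = sd.simulate_human_cohort(modules, cfg)
    orth, mouse_ref = sd.simulate_orthology(modules, cfg)
    counts, mouse_truth = sd.simulate_mouse_models(modules, orth,
                                                   human_truth, cfg)
    return dict(config=cfg, modules=modules, clusters=clusters, expr=expr,
                human_truth=human_truth, orthology=orth, mouse_ref=mouse_ref,
                counts=counts, mouse_truth=mouse_truth)
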