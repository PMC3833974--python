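import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from allerules.dtable import AFFECTED, UNAFFECTED, Attribute, DecisionTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def build_table(columns: dict, decision: list, domains: dict | None = None,
                kinds: dict | None = None, ids: list | None = None) -> DecisionTable:
    """Construct a DecisionTable from plain lists (codes as strings)."""
    n = len(decision)
    ids = ids or [f"o{i}" for i in range(n)]
    data = pd.DataFrame({k: pd.Series(v, index=ids, dtype=object) for k, v in columns.items()})
    attrs = []
    for name, col in columns.items():
        dom = (domains or {}).get(name)
        if dom is None:
            dom = tuple(sorted({str(v) for v in col if v is not None and v == v}))
        attrs.append(
            Attribute(name=name, kind=(kinds or {}).get(name, "environment"), domain=dom)
        )
    return DecisionTable(data, attrs, pd.Series(decision, index=ids))


@pytest.fixture
def toy3():
    """Three objects, two binary attributes: the canonical reduct example."""
    return build_table(
        {"a": ["0", "1", "0"], "b": ["0", "0", "1"]},
        [UNAFFECTED, AFFECTED, AFFECTED],
        ids=["o1", "o2", "o3"],
    )


def random_table(n: int, d: int, seed: int, n_categories: int = 3,
                 missing_rate: float = 0.0) -> DecisionTable:
    rng = np.random.default_rng(seed)
    codes = [str(c) for c in range(n_categories)]
    cols = {}
    for j in range(d):
        col = rng.choice(codes, size=n).astype(object)
        if missing_rate > 0:
            col[rng.random(n) < missing_rate] = np.nan
        cols[f"f{j:02d}"] = col
    decision = [AFFECTED if rng.random() < 0.5 else UNAFFECTED for _ in range(n)]
    return build_table(cols, decision, domains={f"f{j:02d}": tuple(codes) for j in range(d)})
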