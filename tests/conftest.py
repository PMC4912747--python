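import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def peak_table():
    """Build a minimal sized-peak table from (size, area) pairs."""

    def build(pairs, sample="S1"):
        return pd.DataFrame(
            {
                "sample": sample,
                "size_bp": [s for s, _ in pairs],
                "height": [a / 10 for _, a in pairs],
                "area": [a for _, a in pairs],
            }
        )

    return build


@pytest.fixture
def random_rooted_newick():
    """Random bifurcating rooted tree with positive branch lengths."""

    def build(names, rng: np.random.Generator) -> str:
        nodes = [f"{n}:{rng.uniform(0.1, 2.0):.6f}" for n in names]
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
        return f"({nodes[0]},{nodes[1]});"

    return build
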