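import numpy as np
import pandas as pd
import pytest

from connsel.connectome import build_edge_index_map, synthetic_atlas
from connsel.synthetic import SyntheticSpec, generate_cohort_pair


@pytest.fixture(scope="session")
def toy_atlas() -> pd.DataFrame:
    """Four regions: two DMN, one SMN, one unassigned."""
    return pd.DataFrame(
        {
            "index": [1, 2, 3, 4],
            "name": ["A", "B", "C", "D"],
            "anatomical_class": ["cortical", "cortical", "cortical", "subcortical"],
            "network": ["DMN", "DMN", "SMN", "UNASSIGNED"],
        }
    )


@pytest.fixture(scope="session")
def small_emap():
    """Edge map for a 20-region atlas (7 networks of 2-3 regions + 1 unassigned)."""
    sizes = {"VN": 3, "SMN": 3, "dATN": 3, "vATN": 3, "LN": 2, "FPN": 3, "DMN": 2}
    sizes["UNASSIGNED"] = 1
    return build_edge_index_map(synthetic_atlas(sizes))


@pytest.fixture(scope="session")
def small_cohort_pair():
    """Reduced-scale two-cohort dataset with planted ground truth (P=30, n=60)."""
    sizes = {net: 4 for net in ("VN", "SMN", "dATN", "vATN", "LN", "FPN", "DMN")}
    sizes["DMN"] = 5
    sizes["UNASSIGNED"] = 1
    spec = SyntheticSpec(
        network_sizes=sizes,
        n_case=30,
        n_control=30,
        shared_edges=5,
        child_only_edges=3,
        adult_only_edges=3,
        seed=202,
    )
    return generate_cohort_pair(spec)


def planted_feature(rng: np.random.Generator, n: int = 80, e: int = 10,
                    effect: float = 3.0, noise: float = 0.3,
                    informative: int = 1) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """n×e matrix of noise with `informative` leading columns tracking y."""
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, e))
    cols = list(range(informative))
    for j in cols:
        X[:, j] = effect * y + noise * rng.standard_normal(n)
    return X, y, cols
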