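from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from misrank import (
    ClassSpec,
    SyntheticStudySpec,
    WeightedPPINetwork,
    generate_study,
    score_study,
)

settings.register_profile(
    "misrank",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("misrank")


@pytest.fixture
def toy_network() -> WeightedPPINetwork:
    """Six proteins; g is the hub whose MIS against subsets is easy to read off."""
    return WeightedPPINetwork.from_edges(
        [
            ("g", "a", 400),
            ("g", "b", 700),
            ("g", "c", 999),
            ("a", "b", 300),
            ("b", "c", 150),
            ("d", "a", 500),
        ]
    )


# Conditions of the synthetic null-calibration study.  The network is sized so
# the tie regime (query inclusion probability pi = 20/200, mean degree ~20)
# keeps the strict-greater exceedance bias small; see docs/methods.md.
NULL_STUDY = dict(
    n_proteins=200,
    edge_probability=0.1,
    query_size=20,
    n_classes=20,
    class_size=30,
    n_permutations=200,
    n_seeds=10,
)


@pytest.fixture(scope="session")
def null_study_aucs() -> np.ndarray:
    """(n_seeds x n_classes) AUC matrix from all-null synthetic studies."""
    cfg = NULL_STUDY
    aucs = np.empty((cfg["n_seeds"], cfg["n_classes"]))
    for i in range(cfg["n_seeds"]):
        spec = SyntheticStudySpec(
            n_proteins=cfg["n_proteins"],
            edge_probability=cfg["edge_probability"],
            query_size=cfg["query_size"],
            classes=tuple(
                ClassSpec(f"c{k:02d}", cfg["class_size"], 0.0)
                for k in range(cfg["n_classes"])
            ),
            seed=1000 + i,
            disjoint=False,
        )
        study = generate_study(spec)
        results = score_study(
            study.network, study.query_set, study.catalog,
            cfg["n_permutations"], seed=2000 + i,
        )
        by_name = {r.class_name: r.auc for r in results}
        aucs[i] = [by_name[f"c{k:02d}"] for k in range(cfg["n_classes"])]
    return aucs
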