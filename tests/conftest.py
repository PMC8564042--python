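"""Shared fixtures: the synthetic case study and its derived products.

The case-study bundle is expensive enough (~3 s) to build once per session;
all derivation, scoring and acceptance tests share it.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from lsec_sigkit import (
    CountMatrix,
    DerivationConfig,
    derive_case_signatures,
    normalize_log1p_cp10k,
    simulate_case_study,
)
from lsec_sigkit.io_formats import concat_annotations, concat_cells


@pytest.fixture(scope="session")
def case_bundle():
    return simulate_case_study(seed=1)


@pytest.fixture(scope="session")
def case_combined(case_bundle):
    """(counts, annotation, normalized) for healthy + cirrhotic cells pooled."""
    cm = concat_cells(case_bundle.healthy_counts, case_bundle.cirrhotic_counts)
    ann = concat_annotations(case_bundle.healthy_annotation, case_bundle.cirrhotic_annotation)
    nm = normalize_log1p_cp10k(cm)
    return cm, ann, nm


@pytest.fixture(scope="session")
def derived_sets(case_bundle, case_combined):
    cm, ann, nm = case_combined
    return derive_case_signatures(cm, nm, ann, case_bundle.bulk, DerivationConfig())


@pytest.fixture
def small_counts():
    """A tiny deterministic 4-gene x 4-cell matrix for filter/normalize tests."""
    counts = np.array(
        [
            [5, 0, 2, 0],
            [1, 1, 0, 0],
            [0, 3, 4, 0],
            [2, 2, 2, 0],
        ]
    )
    return CountMatrix(
        ["G1", "G2", "G3", "G4"], ["c1", "c2", "c3", "c4"], sp.csr_matrix(counts)
    )
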