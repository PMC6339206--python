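"""Shared fixtures: the bundled case study and its published reference values."""

import numpy as np
import pytest

import danpmv

# Published total-influence matrices (right panels of the case study's
# influence tables), rounded to 3 decimals as printed.
PUBLISHED_T = {
    "dimensions": np.array([
        [0.873, 1.334, 1.086, 0.926],
        [1.146, 1.108, 1.196, 0.967],
        [0.924, 1.174, 0.787, 0.829],
        [1.038, 1.222, 0.990, 0.702],
    ]),
    "D1": np.array([
        [0.463, 0.583, 0.703, 0.612, 0.600, 0.661, 0.665],
        [0.507, 0.346, 0.569, 0.485, 0.482, 0.531, 0.528],
        [0.509, 0.456, 0.465, 0.528, 0.517, 0.586, 0.574],
        [0.465, 0.425, 0.559, 0.373, 0.457, 0.555, 0.551],
        [0.514, 0.477, 0.604, 0.512, 0.394, 0.565, 0.561],
        [0.406, 0.366, 0.495, 0.432, 0.426, 0.362, 0.453],
        [0.365, 0.339, 0.443, 0.368, 0.376, 0.422, 0.321],
    ]),
    "D2": np.array([
        [1.733, 1.836, 1.402, 1.591, 1.911, 1.795],
        [1.827, 1.590, 1.335, 1.492, 1.822, 1.724],
        [1.461, 1.410, 0.974, 1.192, 1.449, 1.397],
        [1.647, 1.580, 1.181, 1.236, 1.649, 1.539],
        [1.963, 1.894, 1.424, 1.630, 1.766, 1.839],
        [1.897, 1.813, 1.384, 1.575, 1.874, 1.612],
    ]),
    "D3": np.array([
        [1.021, 0.733, 1.229, 1.190],
        [0.794, 0.361, 0.718, 0.715],
        [1.310, 0.719, 0.994, 1.246],
        [1.318, 0.735, 1.251, 0.979],
    ]),
    "D4": np.array([
        [0.642, 0.747, 0.702, 0.591, 0.765, 0.715, 0.650, 0.606, 0.574],
        [0.819, 0.683, 0.701, 0.661, 0.822, 0.777, 0.699, 0.688, 0.651],
        [0.818, 0.795, 0.627, 0.669, 0.826, 0.782, 0.682, 0.679, 0.654],
        [0.648, 0.634, 0.599, 0.452, 0.671, 0.617, 0.556, 0.546, 0.509],
        [0.611, 0.625, 0.575, 0.513, 0.537, 0.593, 0.519, 0.521, 0.498],
        [0.713, 0.710, 0.628, 0.563, 0.693, 0.556, 0.577, 0.557, 0.535],
        [0.698, 0.664, 0.599, 0.543, 0.665, 0.625, 0.488, 0.576, 0.539],
        [0.733, 0.717, 0.653, 0.594, 0.725, 0.662, 0.621, 0.511, 0.586],
        [0.600, 0.591, 0.548, 0.490, 0.607, 0.548, 0.508, 0.490, 0.403],
    ]),
}

# Published weight table: dimension -> (local dim weight, {criterion: (local, global)}).
PUBLISHED_WEIGHTS = {
    "D1": (0.245, {
        "C11": (0.136, 0.033), "C12": (0.125, 0.031), "C13": (0.160, 0.039),
        "C14": (0.138, 0.034), "C15": (0.136, 0.033), "C16": (0.153, 0.037),
        "C17": (0.151, 0.037),
    }),
    "D2": (0.295, {
        "C21": (0.183, 0.054), "C22": (0.176, 0.052), "C23": (0.134, 0.040),
        "C24": (0.152, 0.045), "C25": (0.182, 0.054), "C26": (0.173, 0.051),
    }),
    "D3": (0.249, {
        "C31": (0.289, 0.072), "C32": (0.167, 0.041), "C33": (0.274, 0.068),
        "C34": (0.270, 0.067),
    }),
    "D4": (0.211, {
        "C41": (0.124, 0.026), "C42": (0.122, 0.026), "C43": (0.111, 0.024),
        "C44": (0.100, 0.021), "C45": (0.124, 0.026), "C46": (0.116, 0.024),
        "C47": (0.104, 0.022), "C48": (0.102, 0.022), "C49": (0.097, 0.021),
    }),
}

# Published dimension-level performance/gap rollup and overall pair.
PUBLISHED_ROLLUP = {
    "D1": (4.843, 2.157),
    "D2": (5.908, 1.092),
    "D3": (5.741, 1.259),
    "D4": (6.880, 0.120),
}
PUBLISHED_OVERALL = (5.811, 1.189)

# Published cause/receiver classification per block.
PUBLISHED_ROLES = {
    "dimensions": {"D1": "cause", "D4": "cause", "D2": "receiver", "D3": "receiver"},
    "D4": {
        "C42": "cause", "C43": "cause", "C44": "cause", "C47": "cause", "C48": "cause",
        "C41": "receiver", "C45": "receiver", "C46": "receiver", "C49": "receiver",
    },
}


@pytest.fixture(scope="session")
def case():
    """The bundled rural quality-of-life case: (hierarchy, panels, survey)."""
    return danpmv.load_case_fixture("xingshisi")


@pytest.fixture(scope="session")
def case_run(case):
    """Full hierarchical pipeline result on the case fixture."""
    h, panels, _ = case
    return danpmv.run_hierarchical(panels, h)


@pytest.fixture()
def toy_hierarchy():
    """Minimal 2-dimension / 4-criterion hierarchy on small scales."""
    return danpmv.DecisionHierarchy(
        dimensions=[("DA", "Alpha"), ("DB", "Beta")],
        criteria=[
            ("a1", "a one", "DA"), ("a2", "a two", "DA"),
            ("b1", "b one", "DB"), ("b2", "b two", "DB"),
        ],
        influence_scale=(0, 4),
        performance_scale=(0.0, 7.0),
        f_aspired=7.0,
        f_worst=0.0,
    )
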