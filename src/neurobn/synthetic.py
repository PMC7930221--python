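"""Ground-truth generators: random Gaussian BNs, sampled tables, toy SWC trees.

This module is the test bed for every downstream stage.  It generates
linear-Gaussian networks with a *known* DAG, samples feature tables from
them by ancestral sampling, and provides hand-built SWC fixtures whose
morphometric features are known in closed form.

The generator is a stand-in for (not a replication of) any particular
empirical data set: coefficients are uniform with a dead zone around zero so
that no true arc is vacuous, residual variances are uniform, and intercepts
are zero (structure learning and partial correlations are
location-invariant).  Seeds are explicit everywhere; there is no global RNG
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import substream_seed
from .gbn import GaussianBN
from .graphs import DAGStructure
from .morphometry import NeuronReconstruction, SwcNode


def default_names(n: int) -> tuple[str, ...]:
    return tuple(f"X{i + 1}" for i in range(n))


def random_dag(n: int, edge_prob: float, seed: int) -> DAGStructure:
    """Random DAG: order the nodes by a random permutation, then include each
    forward arc independently with probability ``edge_prob``."""
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = default_names(n)
    order = [names[i] for i in rng.permutation(n)]
    arcs = set()
    for i, j in combinations(range(n), 2):
        if rng.random() < edge_prob:
            arcs.add((order[i], order[j]))
    return DAGStructure(names, frozenset(arcs))


def random_parameters(
    structure: DAGStructure,
    coef_range: tuple[float, float] = (-1.0, 1.0),
    var_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    min_abs: float = 0.1,
) -> GaussianBN:
    """Fill a structure with parameters: zero intercepts, uniform coefficients
    excluding the dead zone (-min_abs, min_abs), uniform residual variances."""
    lo, hi = var_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("var_range must be a positive interval")
    clo, chi = coef_range
    if chi < clo:
        raise ValueError("coef_range must be an interval")
    if max(abs(clo), abs(chi)) < min_abs:
        raise ValueError("coef_range lies entirely inside the dead zone")
    rng = np.random.default_rng(seed)
    intercepts, coefs, variances = {}, {}, {}
    for v in structure.variables:
        intercepts[v] = 0.0
        cs = {}
        for p in sorted(structure.parents(v)):
            while True:
                c = float(rng.uniform(clo, chi))
                if abs(c) >= min_abs:
                    break
            cs[p] = c
        coefs[v] = cs
        variances[v] = float(rng.uniform(lo, hi))
    return GaussianBN(structure, intercepts, coefs, variances)


def sample(bn: GaussianBN, N: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling: each node in topological order is Gaussian given
    its parents.  Deterministic given the seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in bn.structure.topological_order():
        mean = np.full(N, bn.intercepts[v])
        for p, b in bn.coefficients[v].items():
            mean = mean + b * cols[p]
        cols[v] = mean + math.sqrt(bn.variances[v]) * rng.standard_normal(N)
    return pd.DataFrame({v: cols[v] for v in bn.variables})


@dataclass(frozen=True)
class GroundTruthScenario:
    """A known network plus a sampling design (N, seed) for recovery experiments."""

    true_bn: GaussianBN
    sample_size: int
    seed: int

    def __post_init__(self):
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return self.true_bn.variables

    def data(self) -> pd.DataFrame:
        return sample(self.true_bn, self.sample_size, self.seed)

    def all_pairs(self) -> frozenset[frozenset[str]]:
        return frozenset(
            frozenset(p) for p in combinations(self.variable_names, 2)
        )

    def nonspurious_pairs(self) -> frozenset[frozenset[str]]:
        """Unordered pairs present in the true skeleton."""
        return self.true_bn.structure.skeleton()

    def spurious_pairs(self) -> frozenset[frozenset[str]]:
        return self.all_pairs() - self.nonspurious_pairs()


def make_confidence_scenario(n: int, N: int, seed: int) -> GroundTruthScenario:
    """Strong-signal scenario for arc-confidence experiments.

    Defaults (fixed, documented in the methods note): arc probability 0.25,
    coefficient magnitudes uniform in [0.5, 1.5] with random sign, residual
    variances uniform in [0.5, 1.5].
    """
    if n < 3:
        raise ValueError("need n >= 3")
    structure = random_dag(n, 0.25, substream_seed(seed, "dag"))
    bn = random_parameters(
        structure,
        coef_range=(-1.5, 1.5),
        var_range=(0.5, 1.5),
        seed=substream_seed(seed, "params"),
        min_abs=0.5,
    )
    return GroundTruthScenario(bn, N, substream_seed(seed, "data"))


# --------------------------------------------------------------------------
# Toy SWC fixtures.  All geometry hand-specified; the analytic feature
# values live in TOY_SWC_FEATURES next to each fixture.
# --------------------------------------------------------------------------

_S = math.sqrt(2.0) / 2.0

_TOY_NODES: dict[str, list[tuple]] = {
    # soma at the origin; unbranched basal chain along +Y
    "straight_branch": [
        (1, 1, 0, 0, 0, 1.0, -1),
        (2, 3, 0, 1, 0, 0.2, 1),
        (3, 3, 0, 2, 0, 0.2, 2),
        (4, 3, 0, 3, 0, 0.2, 3),
    ],
    # unit stem, then daughters ending along +X and +Y from the fork
    "right_angle_bifurcation": [
        (1, 1, 0, 0, 0, 1.0, -1),
        (2, 3, 0, 1, 0, 0.2, 1),
        (3, 3, 0, 2, 0, 0.2, 2),
        (4, 3, 1, 2, 0, 0.2, 3),
        (5, 3, 0, 3, 0, 0.2, 3),
    ],
    # stem of length 2, two unit daughters at +-45 degrees from the stem axis
    "symmetric_Y": [
        (1, 1, 0, 0, 0, 1.0, -1),
        (2, 3, 0, 1, 0, 0.2, 1),
        (3, 3, 0, 2, 0, 0.2, 2),
        (4, 3, 0, 3, 0, 0.2, 3),
        (5, 3, _S, 3 + _S, 0, 0.2, 4),
        (6, 3, -_S, 3 + _S, 0, 0.2, 4),
    ],
}
# basal symmetric_Y plus an apical (type 4) stem with a symmetric fork, thicker branches
_TOY_NODES["two_arbor_cell"] = _TOY_NODES["symmetric_Y"] + [
    (7, 4, 0, -1, 0, 0.3, 1),
    (8, 4, 0, -2, 0, 0.3, 7),
    (9, 4, 1, -3, 0, 0.3, 8),
    (10, 4, -1, -3, 0, 0.3, 8),
]

_SY_BASAL = {
    "distance": 2.0,
    "length": 4.0 / 3.0,
    "tortuosity": 1.0,
    "angle": math.pi / 2.0,
    "diameter": 0.4,
    "height": 2.0 + _S,
    "width": 2.0 * _S,
    "depth": 0.0,
    "total_length": 4.0,
}

#: Analytic ground truth for each fixture (NaN = feature undefined there).
TOY_SWC_FEATURES: dict[str, dict[str, float]] = {
    "straight_branch": {
        "distance": math.nan, "length": 2.0, "tortuosity": 1.0,
        "angle": math.nan, "diameter": 0.4,
        "height": 2.0, "width": 0.0, "depth": 0.0, "total_length": 2.0,
    },
    "right_angle_bifurcation": {
        "distance": 1.0, "length": 1.0, "tortuosity": 1.0,
        "angle": math.pi / 2.0, "diameter": 0.4,
        "height": 2.0, "width": 1.0, "depth": 0.0, "total_length": 3.0,
    },
    "symmetric_Y": dict(_SY_BASAL),
    "two_arbor_cell": {
        **_SY_BASAL,
        "a.distance": 1.0,
        "a.length": (1.0 + 2.0 * math.sqrt(2.0)) / 3.0,
        "a.tortuosity": 1.0,
        "a.angle": math.pi / 2.0,
        "a.diameter": 0.6,
        "a.height": 2.0,
        "a.width": 2.0,
        "a.depth": 0.0,
        "a.total_length": 1.0 + 2.0 * math.sqrt(2.0),
    },
}


def toy_swc(case_name: str) -> NeuronReconstruction:
    """One of the documented geometric fixtures (see TOY_SWC_FEATURES)."""
    if case_name not in _TOY_NODES:
        raise ValueError(
            f"unknown fixture {case_name!r}; available: {sorted(_TOY_NODES)}"
        )
    return NeuronReconstruction([SwcNode(*row) for row in _TOY_NODES[case_name]])
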