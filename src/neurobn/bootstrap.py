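"""Bootstrap arc confidence and blacklist construction.

With few observations relative to variables, many structures score almost
equally well; single learned networks are unstable.  Confidence in a
directed arc X -> Y is estimated as the fraction of B networks, each
learned on a full-size resample (with replacement) of the data, that
contain the arc.  A variable pair is deemed spurious — and blacklisted for
the definitive learning run — when p(X -> Y) + p(Y -> X) <= t (inclusive).

Standardization is computed once on the original sample and applied before
resampling: location and scale do not affect which structure is learned, and
it keeps replicates comparable.  A degenerate resample that leaves a column
constant (possible at N ~ 20) is logged and redrawn from the replicate's
next substream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import substream_seed, standardize
from .graphs import DAGStructure
from .learn import SearchConfig, tabu_search
from .synthetic import GroundTruthScenario

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArcConfidence:
    variables: tuple[str, ...]
    frequencies: dict[tuple[str, str], float]  # (parent, child) -> p in [0, 1]
    n_replicates: int
    seed: int | None = None

    def p(self, parent: str, child: str) -> float:
        return self.frequencies.get((parent, child), 0.0)

    def combined(self, a: str, b: str) -> float:
        """p(a -> b) + p(a <- b): confidence that the pair is connected at all."""
        return self.p(a, b) + self.p(b, a)

    def to_dataframe(self, threshold: float | None = None) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.variables, 2):
            comb = self.combined(a, b)
            row = {
                "from": a,
                "to": b,
                "confidence_forward": self.p(a, b),
                "confidence_backward": self.p(b, a),
                "combined_confidence": comb,
            }
            if threshold is not None:
                row["blacklisted"] = comb <= threshold
            rows.append(row)
        return pd.DataFrame(rows)


def bootstrap_networks(
    data: pd.DataFrame,
    B: int,
    seed: int,
    search: SearchConfig | None = None,
    pre_standardized: bool = False,
) -> list[DAGStructure]:
    """Learn one network per bootstrap resample (no blacklist).

    Replicate seeds derive deterministically from the master seed, so the
    result is reproducible and independent of evaluation order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    search = search or SearchConfig()
    z = data if pre_standardized else standardize(data)
    x = z.to_numpy(float)
    n_rows = x.shape[0]
    structures = []
    for b in range(B):
        for attempt in range(100):
            rng = np.random.default_rng(substream_seed(seed, "bootstrap", b, attempt))
            idx = rng.integers(0, n_rows, n_rows)
            resample = x[idx]
            if np.all(resample.max(axis=0) > resample.min(axis=0)):
                break
            logger.warning("replicate %d: constant column in resample, redrawing", b)
        else:
            raise RuntimeError(f"replicate {b}: could not draw a non-degenerate resample")
        structures.append(
            tabu_search(pd.DataFrame(resample, columns=z.columns), search)
        )
    return structures


def arc_confidence(structures: list[DAGStructure], seed: int | None = None) -> ArcConfidence:
    """Empirical frequency of each directed arc across replicate networks."""
    if not structures:
        raise ValueError("need at least one structure")
    variables = structures[0].variables
    for s in structures[1:]:
        if set(s.variables) != set(variables):
            raise ValueError("structures have inconsistent variable sets")
    counts: dict[tuple[str, str], int] = {}
    for s in structures:
        for arc in s.arcs:
            counts[arc] = counts.get(arc, 0) + 1
    B = len(structures)
    return ArcConfidence(
        variables, {a: c / B for a, c in counts.items()}, B, seed
    )


def build_blacklist(conf: ArcConfidence, t: float) -> frozenset[frozenset[str]]:
    """Unordered pairs with combined confidence <= t (inclusive rule)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold t must be in [0, 1]")
    return frozenset(
        frozenset((a, b))
        for a, b in combinations(conf.variables, 2)
        if conf.combined(a, b) <= t
    )


def _summary(values: list[float]) -> dict[str, float | int | None]:
    if not values:
        return {"n": 0, "min": None, "q1": None, "median": None, "q3": None, "max": None}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": len(values),
        "min": float(min(values)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(max(values)),
    }


def confidence_separation_experiment(
    scenario: GroundTruthScenario,
    B: int,
    seed: int | None = None,
    search: SearchConfig | None = None,
) -> dict:
    """Combined-confidence summaries for true-skeleton vs spurious pairs.

    On strong-signal data the nonspurious distribution should stochastically
    dominate the spurious one; at small N the classes can overlap, which is
    precisely why a conservative blacklist threshold is needed.
    """
    seed = scenario.seed if seed is None else seed
    structures = bootstrap_networks(scenario.data(), B, seed, search)
    conf = arc_confidence(structures, seed)
    non = [conf.combined(*sorted(p)) for p in sorted(map(sorted, scenario.nonspurious_pairs()))]
    spu = [conf.combined(*sorted(p)) for p in sorted(map(sorted, scenario.spurious_pairs()))]
    return {
        "nonspurious": _summary(non),
        "spurious": _summary(spu),
        "confidence": conf,
    }
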