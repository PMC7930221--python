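"""Cross-group comparison of fitted Gaussian Bayesian networks.

The headline statistic is the Hellinger distance between two multivariate
normals.  To isolate differences in *dependence structure* from differences
in the variables' magnitudes, the parameters of one group's network are
re-fitted on the other group's data before comparing, so the two compared
distributions always share the same mean and the distance becomes a function
of the covariance matrices only:

    H(B1, B2) = sqrt(1 - det(S1)^(1/4) det(S2)^(1/4) / det((S1+S2)/2)^(1/2))

Two distances are reported, one per data set (refit A's structure on B's
data and compare with B's network, and vice versa).  The report also counts
CPDAG arcs common to both groups (adjacency plus matching orientation
class) and per-variable Markov-blanket agreement.

Also here: thresholded marginal-correlation networks, per-variable Welch
t-tables, and subgroup correlations split at a covariate cutpoint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gbn import GaussianBN, JointGaussian, bn_to_joint, fit_parameters
from .graphs import CPDAG, DAGStructure, dag_to_cpdag, markov_blanket


def refit_parameters(structure: DAGStructure, other_data: pd.DataFrame) -> GaussianBN:
    """Keep the structure, re-estimate all local parameters on another data set."""
    return fit_parameters(structure, other_data)


def hellinger_distance(
    joint1: JointGaussian, joint2: JointGaussian, mean_tol: float = 1e-8
) -> float:
    """Closed-form Gaussian Hellinger distance for equal-mean distributions.

    Computed via Cholesky log-determinants for stability.  The equal-mean
    precondition (guaranteed upstream by mean-refitting on a shared data
    set) is asserted to ``mean_tol``.
    """
    if joint1.cov.shape != joint2.cov.shape:
        raise ValueError("dimension mismatch")
    if np.max(np.abs(joint1.mean - joint2.mean)) > mean_tol:
        raise ValueError(
            "means differ beyond tolerance; refit parameters on a common data set first"
        )

    def logdet(m: np.ndarray) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(np.linalg.cholesky(m)))))

    ld1 = logdet(joint1.cov)
    ld2 = logdet(joint2.cov)
    ldm = logdet((joint1.cov + joint2.cov) / 2.0)
    h2 = 1.0 - math.exp(0.25 * ld1 + 0.25 * ld2 - 0.5 * ldm)
    return math.sqrt(min(max(h2, 0.0), 1.0))


def common_cpdag_arcs(cp1: CPDAG, cp2: CPDAG) -> frozenset:
    """Edges shared by two CPDAGs with matching orientation class.

    An edge counts as common when the adjacency exists in both and is either
    directed with the same head in both, or undirected in both.
    """
    common = set()
    for arc in cp1.directed & cp2.directed:
        common.add(arc)
    for edge in cp1.undirected & cp2.undirected:
        common.add(tuple(sorted(edge)))
    return frozenset(common)


@dataclass(frozen=True)
class ComparisonReport:
    hellinger_on_a: float
    hellinger_on_b: float
    common_arcs: frozenset
    markov_blanket_agreement: dict[str, bool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "hellinger_on_a": self.hellinger_on_a,
                "hellinger_on_b": self.hellinger_on_b,
                "common_arcs": sorted(map(list, self.common_arcs)),
                "markov_blanket_agreement": dict(
                    sorted(self.markov_blanket_agreement.items())
                ),
            },
            indent=1,
        )


def compare_networks(
    bn_a: GaussianBN,
    bn_b: GaussianBN,
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
) -> ComparisonReport:
    """Two Hellinger distances (one per data set) plus structural overlap."""
    if set(bn_a.variables) != set(bn_b.variables):
        raise ValueError("networks must share a variable set")
    cols = list(bn_a.variables)
    # distance evaluated on B's data: refit A's structure there
    d_on_b = hellinger_distance(
        bn_to_joint(refit_parameters(bn_a.structure, data_b[cols])),
        bn_to_joint(refit_parameters(bn_b.structure, data_b[cols])),
    )
    d_on_a = hellinger_distance(
        bn_to_joint(refit_parameters(bn_b.structure, data_a[cols])),
        bn_to_joint(refit_parameters(bn_a.structure, data_a[cols])),
    )
    cp_a = dag_to_cpdag(bn_a.structure)
    cp_b = dag_to_cpdag(bn_b.structure)
    mb = {
        v: markov_blanket(bn_a.structure, v) == markov_blanket(bn_b.structure, v)
        for v in bn_a.variables
    }
    return ComparisonReport(d_on_a, d_on_b, common_cpdag_arcs(cp_a, cp_b), mb)


@dataclass(frozen=True)
class CorrelationNetwork:
    variables: tuple[str, ...]
    correlations: pd.DataFrame  # symmetric marginal Pearson correlations
    threshold: float
    edges: frozenset[frozenset[str]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.variables)
        for e in self.edges:
            a, b = sorted(e)
            g.add_edge(a, b, weight=float(abs(self.correlations.loc[a, b])))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def correlation_network(data: pd.DataFrame, tau: float) -> CorrelationNetwork:
    """Undirected graph with an edge wherever |Pearson rho| strictly exceeds tau."""
    if len(data) < 3:
        raise ValueError("need at least 3 observations")
    sd = data.std(ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"correlation undefined for constant column(s): {bad}")
    corr = data.corr()
    edges = frozenset(
        frozenset((a, b))
        for i, a in enumerate(data.columns)
        for b in data.columns[i + 1 :]
        if abs(corr.loc[a, b]) > tau
    )
    return CorrelationNetwork(tuple(data.columns), corr, tau, edges)


def welch_t_table(data_a: pd.DataFrame, data_b: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group means +- SD and two-sided Welch t-test p-values."""
    cols = [c for c in data_a.columns if c in data_b.columns]
    rows = []
    for c in cols:
        a = data_a[c].dropna()
        b = data_b[c].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"variable {c!r}: need >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": c,
                "mean_a": a.mean(), "sd_a": a.std(ddof=1),
                "mean_b": b.mean(), "sd_b": b.std(ddof=1),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def subgroup_correlations(
    data: pd.DataFrame,
    split_var: str,
    cutpoint: float,
    target_var: str,
    min_size: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of every variable with ``target_var``, overall and
    within the subgroups split_var < cutpoint ('below') and >= cutpoint
    ('above').  A subgroup smaller than ``min_size`` yields NaN, not an error.
    """
    for v in (split_var, target_var):
        if v not in data.columns:
            raise ValueError(f"unknown variable {v!r}")
    below = data[data[split_var] < cutpoint]
    above = data[data[split_var] >= cutpoint]

    def corr_with_target(df: pd.DataFrame) -> pd.Series:
        if len(df) < min_size:
            return pd.Series(np.nan, index=data.columns)
        return df.corrwith(df[target_var])

    return pd.DataFrame(
        {
            "all": data.corrwith(data[target_var]),
            "below": corr_with_target(below),
            "above": corr_with_target(above),
        }
    )
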