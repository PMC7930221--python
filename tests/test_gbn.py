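"""Parameter fitting, BIC, the implied joint, precision and partial correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from neurobn import (
    SingularFitError,
    bic_score,
    bn_to_joint,
    fit_parameters,
    partial_correlations,
    precision_matrix,
    random_dag,
    random_parameters,
    sample,
)
from neurobn.graphs import DAGStructure, enumerate_dags


class TestFitParameters:
    def test_empty_structure_gives_mean_and_biased_variance(self, independent_data):
        s = DAGStructure(tuple(independent_data.columns), frozenset())
        bn = fit_parameters(s, independent_data)
        for c in independent_data.columns:
            assert bn.intercepts[c] == pytest.approx(independent_data[c].mean())
            assert bn.variances[c] == pytest.approx(independent_data[c].var(ddof=0))

    def test_recovers_chain_coefficient(self, chain_xy):
        data = sample(chain_xy, 100_000, seed=3)
        refit = fit_parameters(chain_xy.structure, data)
        assert refit.coefficients["Y"]["X"] == pytest.approx(2.0, abs=0.05)

    def test_deterministic_on_same_sample(self, chain_data, chain_xy):
        a = fit_parameters(chain_xy.structure, chain_data)
        b = fit_parameters(chain_xy.structure, chain_data)
        assert a.coefficients == b.coefficients and a.variances == b.variances

    def test_duplicate_column_parent_raises_singular(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        data = pd.DataFrame({"A": x, "B": x.copy(), "C": rng.standard_normal(50)})
        s = DAGStructure(("A", "B", "C"), frozenset({("A", "C"), ("B", "C")}))
        with pytest.raises(SingularFitError, match="C"):
            fit_parameters(s, data)


class TestBIC:
    def test_univariate_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        data = pd.DataFrame({"X": x})
        s2 = x.var()  # MLE, denominator N
        loglik = -0.5 * 100 * (math.log(2 * math.pi * s2) + 1)
        expected = loglik - 0.5 * 2 * math.log(100)
        assert bic_score(DAGStructure(("X",), frozenset()), data) == pytest.approx(expected)

    def test_score_equivalence_bivariate(self, chain_data):
        fwd = DAGStructure(("X", "Y"), frozenset({("X", "Y")}))
        bwd = DAGStructure(("X", "Y"), frozenset({("Y", "X")}))
        assert bic_score(fwd, chain_data) == pytest.approx(bic_score(bwd, chain_data), abs=1e-8)

    def test_useless_parent_lowers_score(self, independent_data):
        empty = DAGStructure(tuple(independent_data.columns), frozenset())
        with_arc = DAGStructure(tuple(independent_data.columns), frozenset({("A", "B")}))
        assert bic_score(with_arc, independent_data) < bic_score(empty, independent_data)

    def test_score_equivalence_across_enumerated_classes(self):
        """Markov-equivalent DAGs get identical BIC on arbitrary data (n = 3)."""
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.standard_normal((60, 3)) @ rng.standard_normal((3, 3)),
                            columns=("A", "B", "C"))
        from neurobn import dag_to_cpdag

        scores = {}
        for g in enumerate_dags(("A", "B", "C")):
            cp = dag_to_cpdag(g)
            key = (cp.directed, cp.undirected)
            scores.setdefault(key, []).append(bic_score(g, data))
        for vals in scores.values():
            assert np.ptp(vals) < 1e-8


class TestJointAndPrecision:
    def test_empty_graph_is_standard_normal(self):
        s = DAGStructure(("A", "B"), frozenset())
        bn = fit_parameters(s, pd.DataFrame(np.random.default_rng(0).standard_normal((500, 2)),
                                            columns=("A", "B")))
        # analytic case: zero intercepts / unit variances
        from neurobn import GaussianBN

        bn = GaussianBN(s, {"A": 0.0, "B": 0.0}, {"A": {}, "B": {}}, {"A": 1.0, "B": 1.0})
        j = bn_to_joint(bn)
        assert np.allclose(j.mean, 0) and np.allclose(j.cov, np.eye(2))

    def test_chain_covariance_and_precision(self, chain_xy):
        j = bn_to_joint(chain_xy)
        assert np.allclose(j.cov, [[1, 2], [2, 5]])
        om = np.asarray(precision_matrix(chain_xy))
        assert np.allclose(om, [[5, -2], [-2, 1]])

    def test_joint_matches_monte_carlo(self, chain_xyz):
        n = 200_000
        data = sample(chain_xyz, n, seed=11)
        j = bn_to_joint(chain_xyz)
        se = 3 * np.sqrt((np.outer(np.diag(j.cov), np.diag(j.cov)) + j.cov**2) / n)
        assert np.all(np.abs(data.cov(ddof=0).to_numpy() - j.cov) < se + 1e-9)

    def test_precision_is_inverse_of_joint(self):
        for seed in range(10):
            bn = random_parameters(random_dag(6, 0.4, seed), seed=seed)
            om = np.asarray(precision_matrix(bn))
            sig = bn_to_joint(bn).cov
            assert np.max(np.abs(om @ sig - np.eye(6))) < 1e-8

    def test_nonadjacent_nonspouse_pairs_have_zero_precision(self):
        """Omega_XY = 0 exactly when X, Y are non-adjacent in the moral graph."""
        for g in enumerate_dags(("A", "B", "C", "D"))[::7]:
            bn = random_parameters(g, seed=1)
            om = np.asarray(precision_matrix(bn))
            idx = {v: i for i, v in enumerate(g.variables)}
            for i, a in enumerate(g.variables):
                for b in g.variables[i + 1 :]:
                    adjacent = frozenset((a, b)) in g.skeleton()
                    share_child = bool(g.children(a) & g.children(b))
                    if not adjacent and not share_child:
                        assert abs(om[idx[a], idx[b]]) < 1e-12


class TestPartialCorrelations:
    def test_identity_precision_gives_zero(self):
        rho = partial_correlations(np.eye(3))
        assert np.allclose(rho, np.eye(3))

    def test_chain_conditional_independence(self, chain_xyz):
        rho = partial_correlations(np.asarray(precision_matrix(chain_xyz)))
        assert rho[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_residual_regression_on_raw_data(self):
        """Complete-DAG fit reproduces the empirical covariance, so its partial
        correlations must equal residual-regression correlations on the data."""
        rng = np.random.default_rng(9)
        raw = rng.standard_normal((80, 5)) @ rng.standard_normal((5, 5))
        cols = tuple("ABCDE")
        data = pd.DataFrame(raw, columns=cols)
        complete = DAGStructure(
            cols, frozenset((cols[i], cols[j]) for i in range(5) for j in range(i + 1, 5))
        )
        rho = partial_correlations(np.asarray(precision_matrix(fit_parameters(complete, data))))
        x = raw - raw.mean(axis=0)
        for i in range(5):
            for j in range(i + 1, 5):
                rest = [k for k in range(5) if k not in (i, j)]
                z = x[:, rest]
                ri = x[:, i] - z @ np.linalg.lstsq(z, x[:, i], rcond=None)[0]
                rj = x[:, j] - z @ np.linalg.lstsq(z, x[:, j], rcond=None)[0]
                expected = np.corrcoef(ri, rj)[0, 1]
                assert rho[i, j] == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_column_rescaling(self, chain_data):
        s = DAGStructure(("X", "Y"), frozenset({("X", "Y")}))
        rho1 = partial_correlations(np.asarray(precision_matrix(fit_parameters(s, chain_data))))
        scaled = chain_data.assign(Y=chain_data["Y"] * 10)
        rho2 = partial_correlations(np.asarray(precision_matrix(fit_parameters(s, scaled))))
        assert np.allclose(rho1, rho2, atol=1e-10)

    def test_rejects_nonpositive_diagonal(self):
        with pytest.raises(ValueError):
            partial_correlations(np.array([[1.0, 0.0], [0.0, -1.0]]))


def test_parameter_json_round_trip(chain_xyz):
    from neurobn import GaussianBN

    restored = GaussianBN.from_json(chain_xyz.to_json())
    assert restored.structure == chain_xyz.structure
    assert restored.coefficients == chain_xyz.coefficients
    assert restored.variances == chain_xyz.variances
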