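"""Gaussian Bayesian networks: parameters, scoring, and the implied joint.

A linear-Gaussian network attaches to every node i a local conditional
N(x_i; beta_i0 + beta_i' pa(x_i), sigma_i^2).  Jointly the variables are
multivariate normal with

    mu = (I - W)^-1 beta_0,    Sigma = (I - W)^-1 S (I - W)^-T,

where row i of W holds node i's parent coefficients and S = diag(sigma_i^2).
The precision matrix follows directly from the parameters,
Omega = (I - W)' S^-1 (I - W), without inverting Sigma — well-defined even
when the empirical covariance is singular (N <= n).  Partial correlations are
rho_XY|Z = -Omega_XY / sqrt(Omega_XX Omega_YY).

Parameter fitting is node-wise least squares with the maximum-likelihood
variance (denominator N, not N - p - 1): this keeps the BIC an exact
penalized log-likelihood.  BIC here is node-decomposable,
sum_i [logL_i - (k_i / 2) log N] with k_i = |Pa(i)| + 2 (intercept,
coefficients, variance); higher is better; natural logs throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import DAGStructure


class SingularFitError(ValueError):
    """Rank-deficient parent design matrix for some node."""


@dataclass(frozen=True)
class GaussianBN:
    structure: DAGStructure
    intercepts: dict[str, float]
    coefficients: dict[str, dict[str, float]]  # node -> {parent: beta}
    variances: dict[str, float]

    def __post_init__(self):
        for v in self.structure.variables:
            pa = self.structure.parents(v)
            if set(self.coefficients.get(v, {})) != pa:
                raise ValueError(f"coefficients of {v!r} do not match its parents")
            if not self.variances[v] > 0:
                raise ValueError(f"non-positive residual variance for {v!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        return self.structure.variables

    def to_json(self) -> str:
        payload = {
            v: {
                "intercept": self.intercepts[v],
                "coefficients": dict(sorted(self.coefficients[v].items())),
                "variance": self.variances[v],
            }
            for v in self.variables
        }
        return json.dumps({"variables": list(self.variables), "nodes": payload}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GaussianBN":
        obj = json.loads(text)
        variables = tuple(obj["variables"])
        nodes = obj["nodes"]
        arcs = {
            (p, v) for v in variables for p in nodes[v]["coefficients"]
        }
        structure = DAGStructure(variables, frozenset(arcs))
        return cls(
            structure,
            {v: float(nodes[v]["intercept"]) for v in variables},
            {v: {p: float(b) for p, b in nodes[v]["coefficients"].items()} for v in variables},
            {v: float(nodes[v]["variance"]) for v in variables},
        )


@dataclass(frozen=True)
class JointGaussian:
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, float)
        cov = np.asarray(self.cov, float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("mean/covariance dimension mismatch")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if np.linalg.eigvalsh(cov).min() <= 1e-12 * max(1.0, np.abs(cov).max()):
            raise ValueError("covariance not positive definite")


class PrecisionMatrix:
    """Symmetric positive-definite inverse covariance with named axes."""

    def __init__(self, omega: np.ndarray, variables: tuple[str, ...] | None = None):
        omega = np.asarray(omega, float)
        if not np.allclose(omega, omega.T, atol=1e-9 * max(1.0, np.abs(omega).max())):
            raise ValueError("precision matrix not symmetric")
        self.omega = (omega + omega.T) / 2.0
        self.variables = tuple(variables) if variables is not None else None

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.omega, dtype=dtype)


class CovarianceScorer:
    """Node-family OLS fits and BIC local scores from a cached MLE covariance.

    All local quantities (coefficients, residual variance, Gaussian
    log-likelihood) are functions of the data's mean vector and covariance
    matrix, so each is computed once; family scores are memoized, which is
    what makes local search over thousands of candidate families cheap.
    """

    def __init__(self, data: pd.DataFrame):
        self.columns = tuple(data.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        x = data.to_numpy(float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        self.n_obs = x.shape[0]
        self.means = x.mean(axis=0)
        xc = x - self.means
        self.cov = xc.T @ xc / self.n_obs  # MLE denominator N
        self._score_cache: dict[tuple[int, frozenset[int]], float] = {}

    def local_fit(self, child: str, parents: tuple[str, ...]):
        """OLS of child on parents: (beta per parent, intercept, sigma^2 MLE)."""
        i = self.index[child]
        pidx = [self.index[p] for p in parents]
        if not pidx:
            s2 = float(self.cov[i, i])
            if s2 <= 0:
                raise SingularFitError(f"zero variance for node {child!r}")
            return {}, float(self.means[i]), s2
        spp = self.cov[np.ix_(pidx, pidx)]
        spi = self.cov[pidx, i]
        try:
            c = np.linalg.cholesky(spp)
        except np.linalg.LinAlgError:
            raise SingularFitError(
                f"rank-deficient parent design matrix for node {child!r}"
            ) from None
        beta = np.linalg.solve(c.T, np.linalg.solve(c, spi))
        s2 = float(self.cov[i, i] - spi @ beta)
        if s2 <= 0:
            raise SingularFitError(f"degenerate residual variance for node {child!r}")
        intercept = float(self.means[i] - beta @ self.means[pidx])
        return dict(zip(parents, map(float, beta))), intercept, s2

    def local_score(self, child_idx: int, parent_idxs: frozenset[int]) -> float:
        """BIC contribution of one family; -inf for a singular family."""
        key = (child_idx, parent_idxs)
        hit = self._score_cache.get(key)
        if hit is not None:
            return hit
        n = self.n_obs
        i = child_idx
        pidx = sorted(parent_idxs)
        if pidx:
            spp = self.cov[np.ix_(pidx, pidx)]
            spi = self.cov[pidx, i]
            try:
                c = np.linalg.cholesky(spp)
            except np.linalg.LinAlgError:
                self._score_cache[key] = -math.inf
                return -math.inf
            beta = np.linalg.solve(c.T, np.linalg.solve(c, spi))
            s2 = float(self.cov[i, i] - spi @ beta)
        else:
            s2 = float(self.cov[i, i])
        if s2 <= 1e-300:
            score = -math.inf
        else:
            loglik = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
            k = len(pidx) + 2
            score = loglik - 0.5 * k * math.log(n)
        self._score_cache[key] = score
        return score

    def structure_score(self, structure: DAGStructure) -> float:
        return sum(
            self.local_score(
                self.index[v], frozenset(self.index[p] for p in structure.parents(v))
            )
            for v in structure.variables
        )


def fit_parameters(structure: DAGStructure, data: pd.DataFrame) -> GaussianBN:
    """Fit node-wise linear-Gaussian parameters by least squares (MLE variance)."""
    missing = set(structure.variables) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")
    scorer = CovarianceScorer(data[list(structure.variables)])
    intercepts, coefs, variances = {}, {}, {}
    for v in structure.variables:
        pa = tuple(sorted(structure.parents(v)))
        if scorer.n_obs <= len(pa) + 1:
            raise SingularFitError(
                f"too few observations ({scorer.n_obs}) for node {v!r} with {len(pa)} parents"
            )
        coefs[v], intercepts[v], variances[v] = scorer.local_fit(v, pa)
    return GaussianBN(structure, intercepts, coefs, variances)


def bic_score(structure: DAGStructure, data: pd.DataFrame) -> float:
    """Node-decomposable Gaussian BIC (nats); higher is better."""
    scorer = CovarianceScorer(data[list(structure.variables)])
    return scorer.structure_score(structure)


def _coefficient_matrix(bn: GaussianBN) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    names = bn.variables
    idx = {v: i for i, v in enumerate(names)}
    n = len(names)
    w = np.zeros((n, n))
    for v, cs in bn.coefficients.items():
        for p, b in cs.items():
            w[idx[v], idx[p]] = b
    s = np.array([bn.variances[v] for v in names])
    b0 = np.array([bn.intercepts[v] for v in names])
    return w, s, b0


def bn_to_joint(bn: GaussianBN) -> JointGaussian:
    """The multivariate normal implied by the network's factorization."""
    w, s, b0 = _coefficient_matrix(bn)
    n = len(s)
    a = np.eye(n) - w  # always invertible: permutable to unit triangular
    mu = np.linalg.solve(a, b0)
    ainv = np.linalg.inv(a)
    sigma = ainv @ np.diag(s) @ ainv.T
    return JointGaussian(mu, (sigma + sigma.T) / 2.0)


def precision_matrix(bn: GaussianBN) -> PrecisionMatrix:
    """Omega = (I - W)' S^-1 (I - W), straight from the parameters.

    No covariance inversion: the estimate exists even when N <= n makes the
    empirical covariance singular.
    """
    w, s, _ = _coefficient_matrix(bn)
    a = np.eye(len(s)) - w
    omega = a.T @ np.diag(1.0 / s) @ a
    return PrecisionMatrix(omega, bn.variables)


def partial_correlations(omega: PrecisionMatrix | np.ndarray) -> np.ndarray:
    """rho_XY|Z = -Omega_XY / sqrt(Omega_XX Omega_YY); unit diagonal."""
    om = np.asarray(omega, float)
    d = np.diag(om)
    if np.any(d <= 0):
        raise ValueError("invalid precision matrix: non-positive diagonal")
    denom = np.sqrt(np.outer(d, d))
    rho = -om / denom
    np.fill_diagonal(rho, 1.0)
    return rho
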