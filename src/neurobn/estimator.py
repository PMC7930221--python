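"""Scikit-learn style estimator wrapping the full learning stack.

``GaussianBNEstimator.fit`` standardizes the data, optionally runs the
bootstrap arc-confidence filter to build a blacklist, learns the definitive
structure by tabu search, and fits the linear-Gaussian parameters.  Fitted
attributes follow sklearn conventions (trailing underscore), and the
estimator composes with sklearn model selection via get_params/set_params.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._utils import standardize as _zscore
from .bootstrap import arc_confidence, bootstrap_networks, build_blacklist
from .gbn import bn_to_joint, fit_parameters, partial_correlations, precision_matrix
from .graphs import dag_to_cpdag
from .learn import SearchConfig, tabu_search
from .synthetic import default_names, sample as _sample


class GaussianBNEstimator(BaseEstimator):
    """Gaussian Bayesian network learner (tabu/BIC with optional bootstrap blacklist).

    Parameters
    ----------
    tabu_list_size, max_nonimproving : int
        Tabu search controls (defaults 30/30).
    bootstrap_replicates : int
        If > 0, run this many bootstrap replicates first and blacklist every
        variable pair whose combined arc confidence is <= ``confidence_threshold``.
    confidence_threshold : float
        Inclusive blacklist threshold t.
    blacklist : iterable of 2-sets of column names, optional
        Extra pairs to bar a priori.
    standardize : bool
        Z-standardize columns before learning (default True).
    random_state : int
        Master seed for the bootstrap substreams.

    Attributes
    ----------
    structure_ : DAGStructure
    model_ : GaussianBN
    cpdag_ : CPDAG
    joint_ : JointGaussian
    precision_ : ndarray
    partial_correlations_ : ndarray
    confidence_ : ArcConfidence (only when bootstrap_replicates > 0)
    blacklist_ : frozenset of frozenset pairs
    """

    def __init__(
        self,
        tabu_list_size: int = 30,
        max_nonimproving: int = 30,
        bootstrap_replicates: int = 0,
        confidence_threshold: float = 0.7,
        blacklist=None,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.tabu_list_size = tabu_list_size
        self.max_nonimproving = max_nonimproving
        self.bootstrap_replicates = bootstrap_replicates
        self.confidence_threshold = confidence_threshold
        self.blacklist = blacklist
        self.standardize = standardize
        self.random_state = random_state

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(X, columns=list(default_names(X.shape[1])))

    def fit(self, X, y=None):
        df = self._as_frame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.mean_ = df.mean().to_numpy()
        self.scale_ = df.std(ddof=1).to_numpy() if self.standardize else np.ones(df.shape[1])
        z = _zscore(df) if self.standardize else df

        blacklist = frozenset(
            frozenset(p) for p in (self.blacklist or [])
        )
        base = SearchConfig(
            self.tabu_list_size, self.max_nonimproving, frozenset(), self.random_state
        )
        if self.bootstrap_replicates > 0:
            structures = bootstrap_networks(
                z, self.bootstrap_replicates, self.random_state, base,
                pre_standardized=True,
            )
            self.confidence_ = arc_confidence(structures, self.random_state)
            blacklist = blacklist | build_blacklist(
                self.confidence_, self.confidence_threshold
            )
        self.blacklist_ = blacklist

        config = SearchConfig(
            self.tabu_list_size, self.max_nonimproving, blacklist, self.random_state
        )
        self.structure_ = tabu_search(z, config)
        self.model_ = fit_parameters(self.structure_, z)
        self.cpdag_ = dag_to_cpdag(self.structure_)
        self.joint_ = bn_to_joint(self.model_)
        self.precision_ = np.asarray(precision_matrix(self.model_))
        self.partial_correlations_ = partial_correlations(self.precision_)
        return self

    def score(self, X, y=None) -> float:
        """Mean joint-Gaussian log-likelihood of X under the fitted network."""
        check_is_fitted(self, "model_")
        df = self._as_frame(X)[list(self.feature_names_in_)]
        z = (df.to_numpy() - self.mean_) / self.scale_
        n = self.n_features_in_
        cov = self.joint_.cov
        chol = np.linalg.cholesky(cov)
        dev = np.linalg.solve(chol, (z - self.joint_.mean).T)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + np.sum(dev**2, axis=0))
        return float(np.mean(ll))

    def sample(self, n_samples: int, random_state: int = 0) -> pd.DataFrame:
        """Draw from the fitted network, mapped back to the original scale."""
        check_is_fitted(self, "model_")
        z = _sample(self.model_, n_samples, random_state)
        return z * self.scale_ + self.mean_
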