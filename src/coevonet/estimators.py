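"""Estimator-style front end to the gain/loss co-evolution pipeline.

Three scikit-learn-compatible classes cover the pipeline stages; samples are
*genes* and features are *genomes* (a 0/1 presence matrix in tree leaf
order):

* :class:`GainLossEstimator` — ``fit(X)`` maximizes the likelihood of the
  two-state gain/loss chain (rates, gamma shapes, branch scale).
* :class:`EventMapper` — ``transform(X)`` turns each gene row into its
  ``4n - 4`` vector of posterior expected gains and losses per branch.
* :class:`CoevolutionDetector` — ``fit(X)`` runs the whole detection: model
  fit (unless a model is supplied), mapping, parametric-bootstrap null,
  binned empirical P-values and BH FDR; fitted attributes expose the results
  table and the significant-pair network.

The module-level functions in :mod:`coevonet.markov`, :mod:`coevonet.mapping`
and :mod:`coevonet.coevolution` remain available for script use; these
classes are thin stateful wrappers that make the stages composable with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import coevolution as _coevo
from . import mapping as _mapping
from . import markov as _markov
from . import network as _network
from .errors import ValidationError
from .markov import GainLossModel
from .phylo import PhyleticPattern, Phylogeny

__all__ = ["GainLossEstimator", "EventMapper", "CoevolutionDetector"]


def _as_matrix(X, tree: Phylogeny):
    if isinstance(X, PhyleticPattern):
        return X.matrix, list(X.gene_ids)
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != tree.n_leaves:
        raise ValidationError("X must be a genes x genomes matrix in tree leaf order")
    if not np.isin(X, (0, 1)).all():
        raise ValidationError("X entries must be 0 or 1")
    return X.astype(np.int8), [f"g{i}" for i in range(X.shape[0])]


class GainLossEstimator(BaseEstimator):
    """Maximum-likelihood fit of the stationary gain/loss Markov model.

    Parameters
    ----------
    tree : Phylogeny
        Rooted bifurcating species tree; columns of ``X`` must follow its
        preorder leaf order.
    n_categories : int, default 4
        Number of equiprobable gamma rate categories (1 disables rate
        variability).
    tol : float, default 1e-4
        Convergence tolerance on the total log-likelihood of the
        coordinate-wise search.
    max_cycles : int, default 50
        Maximum coordinate cycles.

    Attributes
    ----------
    model_ : GainLossModel
        Fitted parameters (gain, loss, alpha_gain, alpha_loss, rho).
    log_likelihood_ : float
        Total log-likelihood at the optimum.
    """

    def __init__(self, tree: Phylogeny, n_categories: int = 4, tol: float = 1e-4, max_cycles: int = 50):
        self.tree = tree
        self.n_categories = n_categories
        self.tol = tol
        self.max_cycles = max_cycles

    def fit(self, X, y=None):
        M, _ = _as_matrix(X, self.tree)
        self.model_, lik = _markov.fit_model(
            M, self.tree, n_categories=self.n_categories, tol=self.tol, max_cycles=self.max_cycles
        )
        self.log_likelihood_ = lik.total
        self.n_features_in_ = M.shape[1]
        return self

    def score(self, X, y=None):
        """Total log-likelihood of ``X`` under the fitted model."""
        check_is_fitted(self, "model_")
        M, _ = _as_matrix(X, self.tree)
        return _markov.log_likelihood(M, self.tree, self.model_).total


class EventMapper(TransformerMixin, BaseEstimator):
    """Stochastic-mapping transformer: leaf patterns -> branch event vectors.

    ``transform(X)`` returns a ``(G, 4n - 4)`` array of posterior expected
    gains then losses per branch.  If ``model`` is None, ``fit`` estimates it
    with :class:`GainLossEstimator`; otherwise ``fit`` is a no-op.
    """

    def __init__(self, tree: Phylogeny, model: GainLossModel | None = None, n_categories: int = 4):
        self.tree = tree
        self.model = model
        self.n_categories = n_categories

    def fit(self, X, y=None):
        if self.model is not None:
            self.model_ = self.model
        else:
            est = GainLossEstimator(self.tree, n_categories=self.n_categories).fit(X)
            self.model_ = est.model_
        self.n_features_in_ = self.tree.n_leaves
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        M, ids = _as_matrix(X, self.tree)
        table = _mapping.expected_events(M, self.tree, self.model_, gene_ids=ids)
        self.event_table_ = table
        return table.events

    def exchangeability(self, X) -> np.ndarray:
        """Per-gene exchangeability of ``X`` under the fitted model."""
        check_is_fitted(self, "model_")
        M, ids = _as_matrix(X, self.tree)
        return _mapping.expected_events(M, self.tree, self.model_, gene_ids=ids).exchangeability


class CoevolutionDetector(BaseEstimator):
    """End-to-end detector of significantly co-evolving gene pairs.

    Parameters
    ----------
    tree : Phylogeny
    model : GainLossModel or None
        Null model for mapping and bootstrap; fitted from the data when None.
    n_categories : int, default 4
        Rate categories used when fitting the model.
    exchangeability_threshold : float, default 5.0
        Genes must exceed this many expected events (gain/loss average) to be
        tested.
    fdr : float, default 0.01
        Benjamini-Hochberg FDR level.
    bin_edges : sequence of float
        Exchangeability bin edges of the null table (first edge = threshold,
        last = inf).
    null_per_bin : int, default 10000
        Bootstrap correlations per bin.
    max_null_pairs : int or None
        Simulation budget for the null table.
    two_sided : bool, default False
        Test |r| instead of r (the default screens for positive
        co-evolution only).
    seed : int, default 0
        Seed of the bootstrap simulation.

    Attributes
    ----------
    model_ : GainLossModel
    events_ : EventTable
    null_ : NullTable
    results_ : pandas.DataFrame
        One row per tested pair: r, minimal exchangeability, bin, P-value,
        q-value, significance flag.
    edges_ : EdgeList
        Significant pairs.
    network_ : networkx.Graph
        Graph over all genes with the significant edges.
    """

    def __init__(
        self,
        tree: Phylogeny,
        model: GainLossModel | None = None,
        n_categories: int = 4,
        exchangeability_threshold: float = _coevo.DEFAULT_EXCHANGEABILITY_THRESHOLD,
        fdr: float = 0.01,
        bin_edges=_coevo.DEFAULT_BIN_EDGES,
        null_per_bin: int = 10_000,
        max_null_pairs: int | None = None,
        two_sided: bool = False,
        seed: int = 0,
    ):
        self.tree = tree
        self.model = model
        self.n_categories = n_categories
        self.exchangeability_threshold = exchangeability_threshold
        self.fdr = fdr
        self.bin_edges = bin_edges
        self.null_per_bin = null_per_bin
        self.max_null_pairs = max_null_pairs
        self.two_sided = two_sided
        self.seed = seed

    def fit(self, X, y=None):
        if not 0.0 < self.fdr < 1.0:
            raise ValidationError("fdr must lie in (0, 1)")
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges[0] != self.exchangeability_threshold:
            raise ValidationError("first bin edge must equal the exchangeability threshold")
        M, ids = _as_matrix(X, self.tree)
        if self.model is not None:
            self.model_ = self.model
        else:
            self.model_ = GainLossEstimator(self.tree, n_categories=self.n_categories).fit(M).model_
        self.events_ = _mapping.expected_events(M, self.tree, self.model_, gene_ids=ids)
        self.null_ = _coevo.build_null(
            self.tree,
            self.model_,
            bin_edges=edges,
            per_bin=self.null_per_bin,
            seed=self.seed,
            max_pairs=self.max_null_pairs,
        )
        self.results_ = _coevo.coevolution_test(
            self.events_,
            self.null_,
            threshold=self.exchangeability_threshold,
            fdr=self.fdr,
            two_sided=self.two_sided,
        )
        self.edges_ = _coevo.significant_edges(self.results_)
        self.network_ = _network.build_network(self.edges_, nodes=ids)
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the results table of tested pairs."""
        return self.fit(X).results_
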