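"""Two-state gain/loss continuous-time Markov model.

State 0 is absence and state 1 presence of a gene family.  The generator is

    Q = [[-g, g], [l, -l]]

with gain rate ``g`` (0 -> 1) and loss rate ``l`` (1 -> 0), both in events per
unit of *rescaled* branch length.  The chain is stationary with frequencies
``pi1 = g / (g + l)`` and ``pi0 = l / (g + l)``, and the transition matrix has
the closed form

    P01(t) = pi1 (1 - e^{-(g+l) t}),     P00(t) = pi0 + pi1 e^{-(g+l) t},
    P10(t) = pi0 (1 - e^{-(g+l) t}),     P11(t) = pi1 + pi0 e^{-(g+l) t}.

Rate variability across gene families is modeled by K equiprobable rate
categories whose (gain, loss) multipliers are mean-1 gamma quantiles, and a
single branch-scale factor ``rho`` converts the input tree's branch lengths
(substitutions/site) into gain/loss time units.  Because only the products
``rate * rho * t`` are identifiable, the fit constrains ``g + l = 2`` and lets
``rho`` absorb the overall scale.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .phylo import PhyleticPattern, Phylogeny

logger = logging.getLogger("coevonet")

__all__ = [
    "GainLossModel",
    "LikelihoodResult",
    "transition_matrix",
    "log_likelihood",
    "fit_model",
]

_RATE_SUM = 2.0  # identifiability constraint g + l = const during fitting


def transition_matrix(gain: float, loss: float, t: float) -> np.ndarray:
    """2x2 row-stochastic transition matrix of the gain/loss chain at time t."""
    if gain <= 0 or loss <= 0:
        raise ValidationError("rates must be positive")
    if t < 0:
        raise ValidationError("elapsed time must be nonnegative")
    return _transition_matrices(gain, loss, np.asarray([float(t)]))[0]


def _transition_matrices(gain: float, loss: float, t: np.ndarray) -> np.ndarray:
    """Stack of 2x2 transition matrices for an array of branch lengths."""
    r = gain + loss
    pi1 = gain / r
    pi0 = loss / r
    e = np.exp(-r * t)
    out = np.empty(t.shape + (2, 2))
    out[..., 0, 0] = pi0 + pi1 * e
    out[..., 0, 1] = pi1 * (1.0 - e)
    out[..., 1, 0] = pi0 * (1.0 - e)
    out[..., 1, 1] = pi1 + pi0 * e
    return out


def _gamma_multipliers(alpha: float, k: int) -> np.ndarray:
    """K equiprobable mean-1 rate multipliers: category medians of gamma(alpha, 1/alpha)."""
    if k == 1:
        return np.ones(1)
    q = (np.arange(k) + 0.5) / k
    return stats.gamma.ppf(q, a=alpha, scale=1.0 / alpha)


@dataclass(frozen=True)
class GainLossModel:
    """Fitted (or assumed) parameters of the gain/loss process.

    Parameters
    ----------
    gain, loss : float
        Base rates of the 0->1 and 1->0 transitions (per unit rescaled
        branch length).  After fitting these satisfy ``gain + loss = 2``.
    alpha_gain, alpha_loss : float
        Shape parameters of the mean-1 gamma distributions from which the
        per-category gain and loss multipliers are discretized.  Ignored
        when ``n_categories == 1``.
    rho : float
        Branch-scale factor: effective branch length = ``rho * t``.
    n_categories : int
        Number of equiprobable rate categories.  Gain and loss multipliers
        are paired (same quantile on both axes).
    """

    gain: float
    loss: float
    alpha_gain: float = 1.0
    alpha_loss: float = 1.0
    rho: float = 1.0
    n_categories: int = 1

    def __post_init__(self):
        if self.gain <= 0 or self.loss <= 0:
            raise ValidationError("rates must be positive")
        if self.rho <= 0:
            raise ValidationError("rho must be positive")
        if self.n_categories < 1:
            raise ValidationError("need at least one rate category")

    # -- category machinery ------------------------------------------------

    def category_rates(self) -> np.ndarray:
        """(K, 2) array of per-category (gain, loss) rates."""
        k = self.n_categories
        mg = _gamma_multipliers(self.alpha_gain, k)
        ml = _gamma_multipliers(self.alpha_loss, k)
        return np.column_stack([self.gain * mg, self.loss * ml])

    def stationary(self, category: int | None = None) -> np.ndarray:
        """Stationary distribution (pi0, pi1) of the chain (per category)."""
        if category is None:
            g, l = self.gain, self.loss
        else:
            g, l = self.category_rates()[category]
        return np.array([l / (g + l), g / (g + l)])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "g": self.gain,
                "l": self.loss,
                "alpha_gain": self.alpha_gain,
                "alpha_loss": self.alpha_loss,
                "rho": self.rho,
                "K": self.n_categories,
                "constraint": f"g+l={_RATE_SUM}",
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GainLossModel":
        d = json.loads(text)
        return cls(
            gain=d["g"],
            loss=d["l"],
            alpha_gain=d.get("alpha_gain", 1.0),
            alpha_loss=d.get("alpha_loss", 1.0),
            rho=d.get("rho", 1.0),
            n_categories=d.get("K", 1),
        )


@dataclass
class LikelihoodResult:
    """Per-gene log-likelihoods and rate-category posteriors."""

    per_gene: np.ndarray          # (G,) log-likelihood of each gene
    category_posterior: np.ndarray  # (G, K), rows sum to 1

    @property
    def total(self) -> float:
        return float(self.per_gene.sum())


def _leaf_matrix(pattern, tree: Phylogeny) -> np.ndarray:
    """Genes x leaves int8 matrix in the tree's preorder leaf order."""
    if isinstance(pattern, PhyleticPattern):
        if list(pattern.genome_ids) != list(tree.leaf_names):
            raise ValidationError("pattern genomes are not aligned to the tree")
        return pattern.matrix
    x = np.atleast_2d(np.asarray(pattern, dtype=np.int8))
    if x.shape[1] != tree.n_leaves:
        raise ValidationError("row length does not match the number of leaves")
    return x


def _pruning_up(X: np.ndarray, tree: Phylogeny, P: np.ndarray):
    """Felsenstein pruning (up/inside pass), vectorized over genes.

    Parameters
    ----------
    X : (G, n_leaves) int matrix in tree leaf order.
    P : (n_nodes, 2, 2) transition matrix for the branch into each node
        (entry 0 unused).

    Returns
    -------
    F : (n_nodes, G, 2) scaled partial likelihoods P(leaves below v | v = s).
    M : (n_nodes, G, 2) scaled branch messages M_v(a) = sum_s P_v[a, s] F_v(s).
    log_scale : (G,) accumulated log of the per-gene scaling factors.
    """
    n_nodes, G = tree.n_nodes, X.shape[0]
    leaves = tree.leaves
    leaf_col = {v: i for i, v in enumerate(leaves)}
    F = np.zeros((n_nodes, G, 2))
    M = np.zeros((n_nodes, G, 2))
    log_scale = np.zeros(G)
    for v in tree.postorder():
        if not tree.children[v]:
            F[v][np.arange(G), X[:, leaf_col[v]]] = 1.0
        else:
            c1, c2 = tree.children[v]
            F[v] = M[c1] * M[c2]
            # rescale to dodge underflow on deep trees
            mx = F[v].max(axis=1)
            mx[mx == 0.0] = 1.0
            F[v] /= mx[:, None]
            log_scale += np.log(mx)
        if v != 0:
            M[v] = F[v] @ P[v].T
    return F, M, log_scale


def _category_loglik(X: np.ndarray, tree: Phylogeny, model: GainLossModel) -> np.ndarray:
    """(G, K) log-likelihood of each gene under each rate category."""
    rates = model.category_rates()
    eff = model.rho * tree.lengths
    out = np.empty((X.shape[0], model.n_categories))
    for k, (g, l) in enumerate(rates):
        P = _transition_matrices(g, l, eff)
        F, _, log_scale = _pruning_up(X, tree, P)
        pi = np.array([l / (g + l), g / (g + l)])
        lik = F[0] @ pi
        with np.errstate(divide="ignore"):
            out[:, k] = np.log(lik) + log_scale
    return out


def log_likelihood(pattern, tree: Phylogeny, model: GainLossModel) -> LikelihoodResult:
    """Mixture log-likelihood of a phyletic pattern under the model.

    Per gene, ``L = (1/K) sum_k L_k`` where ``L_k`` is the pruning-algorithm
    likelihood with branch lengths ``rho * t`` and category-k rates, rooted at
    the category-k stationary distribution.
    """
    X = _leaf_matrix(pattern, tree)
    ll_k = _category_loglik(X, tree, model)  # (G, K)
    k = model.n_categories
    mx = ll_k.max(axis=1, keepdims=True)
    w = np.exp(ll_k - mx)
    per_gene = mx[:, 0] + np.log(w.sum(axis=1)) - math.log(k)
    posterior = w / w.sum(axis=1, keepdims=True)
    return LikelihoodResult(per_gene=per_gene, category_posterior=posterior)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_BOUNDS = {
    "p": (0.01, 0.99),        # p = g / (g + l)
    "alpha": (0.05, 100.0),
    "rho": (1e-3, 1e3),
}
_START = {"p": 0.5, "alpha_gain": 1.0, "alpha_loss": 1.0, "rho": 1.0}


def _model_from_params(p, ag, al, rho, k) -> GainLossModel:
    return GainLossModel(
        gain=_RATE_SUM * p,
        loss=_RATE_SUM * (1.0 - p),
        alpha_gain=ag,
        alpha_loss=al,
        rho=rho,
        n_categories=k,
    )


def fit_model(
    pattern,
    tree: Phylogeny,
    n_categories: int = 4,
    tol: float = 1e-4,
    max_cycles: int = 50,
    start: dict | None = None,
) -> tuple[GainLossModel, LikelihoodResult]:
    """Fit (g, l, alpha_g, alpha_l, rho) by maximum likelihood.

    Coordinate-wise bounded scalar optimization (Brent) over
    ``p = g/(g+l)``, the two gamma shapes (log scale) and ``rho`` (log
    scale), cycled until the total log-likelihood improves by less than
    ``tol``.  Deterministic given the configuration.  ``g + l = 2`` is held
    fixed for identifiability; ``rho`` carries the overall event scale.
    """
    X = _leaf_matrix(pattern, tree)
    params = dict(_START)
    if start:
        params.update(start)
    k = n_categories

    def total(p, ag, al, rho):
        model = _model_from_params(p, ag, al, rho, k)
        ll_k = _category_loglik(X, tree, model)
        mx = ll_k.max(axis=1, keepdims=True)
        return float((mx[:, 0] + np.log(np.exp(ll_k - mx).sum(axis=1))).sum()) - X.shape[0] * math.log(k)

    def current():
        return total(params["p"], params["alpha_gain"], params["alpha_loss"], params["rho"])

    best = current()
    converged = False
    coords = ["p", "rho"] + (["alpha_gain", "alpha_loss"] if k > 1 else [])
    for _ in range(max_cycles):
        before = best
        for name in coords:
            if name == "p":
                lo, hi = _BOUNDS["p"]
                obj = lambda v: -total(v, params["alpha_gain"], params["alpha_loss"], params["rho"])
                res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded")
                cand = float(res.x)
            else:
                key = "alpha" if name.startswith("alpha") else "rho"
                lo, hi = _BOUNDS[key]

                def obj(logv, _name=name):
                    trial = dict(params)
                    trial[_name] = math.exp(logv)
                    return -total(trial["p"], trial["alpha_gain"], trial["alpha_loss"], trial["rho"])

                res = optimize.minimize_scalar(
                    obj, bounds=(math.log(lo), math.log(hi)), method="bounded"
                )
                cand = math.exp(float(res.x))
            trial = dict(params)
            trial[name] = cand
            val = total(trial["p"], trial["alpha_gain"], trial["alpha_loss"], trial["rho"])
            if val > best:
                best = val
                params = trial
        if best - before < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_model: coordinate search hit max_cycles without converging")
    model = _model_from_params(
        params["p"], params["alpha_gain"], params["alpha_loss"], params["rho"], k
    )
    return model, log_likelihood(X, tree, model)
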