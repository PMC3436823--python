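"""Stochastic mapping: posterior expected gain/loss events per branch.

For every gene and every branch we compute the posterior expectation of the
number of 0->1 (gain) and 1->0 (loss) transitions, conditional on the leaf
states and the fitted model.  With only two states the conditional expected
counts admit exact closed forms: writing ``r = g + l`` and
``P_ij(s) = pi_j + e^{-r s} (delta_ij - pi_j)``, the joint density of "a gain
occurs at time s on a branch of length t with endpoints (a, c)" integrates to

    J01[a, c] = g * Int_0^t P_a0(s) P_1c(t - s) ds,

a sum of elementary terms in ``t``, ``e^{-r t}`` and ``(1 - e^{-r t}) / r``,
and the conditional expectation given the endpoints is ``J01 / P_ac(t)``
(symmetrically for losses).  Endpoint posteriors come from inside/outside
pruning passes; no trajectory sampling is involved, so the vectors are exact
expectations rather than Monte-Carlo estimates.

Expectations are averaged over rate categories weighted by each gene's
posterior category probabilities.

The per-gene output is laid out as a vector of length ``4n - 4``: positions
``0 .. 2n-3`` hold expected gains per branch (by branch index) and positions
``2n-2 .. 4n-5`` expected losses.  The *exchangeability* of a gene is the
average of its total expected gains and total expected losses — a scalar
measure of how much evolutionary signal the gene carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markov import GainLossModel, _leaf_matrix, _pruning_up, _transition_matrices
from .phylo import Phylogeny

__all__ = ["EventTable", "expected_events", "exchangeability"]


def _event_integrals(g: float, l: float, t: np.ndarray):
    """Closed-form J01[a, c] and J10[a, c] per branch.

    Returns two (B, 2, 2) arrays: the expected number of gains (losses)
    jointly with the endpoint pair (a, c), i.e. E[N * 1{X(t)=c} | X(0)=a].
    """
    r = g + l
    pi1 = g / r
    pi0 = l / r
    e = np.exp(-r * t)                # e^{-rt}
    I = -np.expm1(-r * t) / r         # (1 - e^{-rt}) / r, stable for small rt
    d = np.eye(2)

    def J(rate, mid_from, mid_to):
        # rate * Int P_{a, mid_from}(s) P_{mid_to, c}(t-s) ds
        out = np.empty(t.shape + (2, 2))
        pis = np.array([pi0, pi1])
        for a in range(2):
            for c in range(2):
                u0, v0 = pis[mid_from], d[a, mid_from] - pis[mid_from]
                u1, v1 = pis[c], d[mid_to, c] - pis[c]
                out[..., a, c] = rate * (
                    u0 * u1 * t + (u0 * v1 + v0 * u1) * I + v0 * v1 * t * e
                )
        return out

    return J(g, 0, 1), J(l, 1, 0)


@dataclass
class EventTable:
    """Mapped event vectors for a set of genes.

    ``events`` has shape (G, 4n-4): expected gains per branch followed by
    expected losses per branch.  ``exchangeability`` is the per-gene average
    of total gains and total losses.  ``degenerate`` flags genes absent from
    every leaf, whose vectors are forced to zero (no events inferable).
    """

    gene_ids: list
    n_branches: int
    events: np.ndarray
    exchangeability: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self):
        if self.events.shape[1] != 2 * self.n_branches:
            raise ValidationError("event vectors must have length 4n - 4")

    @property
    def gains(self) -> np.ndarray:
        return self.events[:, : self.n_branches]

    @property
    def losses(self) -> np.ndarray:
        return self.events[:, self.n_branches :]

    def to_events_frame(self) -> pd.DataFrame:
        """Long-format table: gene, branch, expected_gains, expected_losses."""
        G, B = len(self.gene_ids), self.n_branches
        return pd.DataFrame(
            {
                "gene": np.repeat(self.gene_ids, B),
                "branch": np.tile(np.arange(B), G),
                "expected_gains": self.gains.ravel(),
                "expected_losses": self.losses.ravel(),
            }
        )

    def to_summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "total_gains": self.gains.sum(axis=1),
                "total_losses": self.losses.sum(axis=1),
                "exchangeability": self.exchangeability,
                "degenerate": self.degenerate.astype(int),
            }
        )


def exchangeability(vector: np.ndarray) -> float:
    """Average of total expected gains and total expected losses."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size % 2:
        raise ValidationError("expected a flat vector of even length 4n - 4")
    if (v < -1e-12).any():
        raise ValidationError("event expectations must be nonnegative")
    half = v.size // 2
    return float(v[:half].sum() + v[half:].sum()) / 2.0


def expected_events(
    pattern,
    tree: Phylogeny,
    model: GainLossModel,
    gene_ids: list | None = None,
) -> EventTable:
    """Posterior expected gains and losses per branch for every gene.

    Accepts a :class:`~coevonet.phylo.PhyleticPattern` or a raw (G, n_leaves)
    0/1 array in tree leaf order.  Category averaging uses the per-gene
    posterior over rate categories, not the uniform prior.
    """
    X = _leaf_matrix(pattern, tree)
    if gene_ids is None:
        gene_ids = (
            list(pattern.gene_ids)
            if hasattr(pattern, "gene_ids")
            else [f"g{i}" for i in range(X.shape[0])]
        )
    G = X.shape[0]
    B = tree.n_branches
    eff = model.rho * tree.lengths  # effective length of branch into node v
    rates = model.category_rates()
    K = model.n_categories

    gains_k = np.zeros((K, G, B))
    losses_k = np.zeros((K, G, B))
    ll_k = np.empty((G, K))

    for k, (g, l) in enumerate(rates):
        P = _transition_matrices(g, l, eff)  # (n_nodes, 2, 2)
        J01, J10 = _event_integrals(g, l, eff)
        # conditional expected counts given endpoints; 0 where P_ac ~ 0
        with np.errstate(divide="ignore", invalid="ignore"):
            n01 = np.where(P > 1e-300, J01 / P, 0.0)
            n10 = np.where(P > 1e-300, J10 / P, 0.0)

        F, M, log_scale = _pruning_up(X, tree, P)
        pi = np.array([l / (g + l), g / (g + l)])
        lik = F[0] @ pi  # (G,)
        with np.errstate(divide="ignore"):
            ll_k[:, k] = np.log(lik) + log_scale

        # outside pass: H[v] (G, 2) proportional to P(data outside v, v = a)
        H = np.zeros((tree.n_nodes, G, 2))
        H[0] = pi[None, :]
        for v in range(1, tree.n_nodes):
            u = int(tree.parent[v])
            sibs = [w for w in tree.children[u] if w != v]
            Hu = H[u]
            for w in sibs:
                Hu = Hu * M[w]
            H[v] = Hu @ P[v]
            mx = H[v].max(axis=1)
            mx[mx == 0.0] = 1.0
            H[v] /= mx[:, None]
            # joint posterior over branch endpoints (parent a, child c):
            # proportional to H_parent-side(a) * P[a, c] * F_v(c)
            joint = Hu[:, :, None] * P[v][None, :, :] * F[v][:, None, :]
            tot = joint.sum(axis=(1, 2))
            tot[tot == 0.0] = 1.0
            joint /= tot[:, None, None]
            b = v - 1  # branch index
            gains_k[k, :, b] = (joint * n01[v][None, :, :]).sum(axis=(1, 2))
            losses_k[k, :, b] = (joint * n10[v][None, :, :]).sum(axis=(1, 2))

    # posterior category weights per gene
    mx = ll_k.max(axis=1, keepdims=True)
    w = np.exp(ll_k - mx)
    w /= w.sum(axis=1, keepdims=True)  # (G, K)

    gains = np.einsum("gk,kgb->gb", w, gains_k)
    losses = np.einsum("gk,kgb->gb", w, losses_k)

    degenerate = X.sum(axis=1) == 0
    gains[degenerate] = 0.0
    losses[degenerate] = 0.0

    events = np.hstack([gains, losses])
    exch = (gains.sum(axis=1) + losses.sum(axis=1)) / 2.0
    return EventTable(
        gene_ids=list(gene_ids),
        n_branches=B,
        events=events,
        exchangeability=exch,
        degenerate=degenerate,
    )
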