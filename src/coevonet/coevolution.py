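"""Detection of co-evolving gene pairs from mapped event vectors.

The statistic for a pair of genes is the Pearson correlation between their
``4n - 4`` event vectors (expected gains and losses per branch).  Because the
null distribution of that correlation depends strongly on how many events the
genes experienced, pairs are compared against a parametric-bootstrap null that
is *binned by minimal exchangeability*: independent gene pairs are simulated
under the fitted model, mapped exactly like the data, and their correlations
deposited into the bin of their pairwise-minimum exchangeability.  An observed
pair is assigned an empirical one-sided P-value within its own bin (add-one
rule, so P is never 0) and significance is decided by Benjamini-Hochberg FDR
across all tested pairs.

Only genes whose exchangeability strictly exceeds a threshold (default 5
events) are tested: genes with few gains and losses can reach extreme
correlations by chance and carry little co-evolutionary signal.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoevonetError, ValidationError
from .mapping import EventTable, expected_events
from .markov import GainLossModel
from .phylo import EdgeList, Phylogeny
from .simulate import simulate_genes

logger = logging.getLogger("coevonet")

__all__ = [
    "pearson",
    "CandidatePairs",
    "candidate_pairs",
    "NullTable",
    "build_null",
    "empirical_pvalue",
    "bh_critical_value",
    "bh_fdr",
    "BHResult",
    "coevolution_test",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_EXCHANGEABILITY_THRESHOLD",
]

DEFAULT_EXCHANGEABILITY_THRESHOLD = 5.0
DEFAULT_BIN_EDGES = (5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 50.0, np.inf)


def pearson(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson correlation of two event vectors; NaN if either is constant."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValidationError("vectors must be one-dimensional and equal length")
    d1 = v1 - v1.mean()
    d2 = v2 - v2.mean()
    n1 = np.sqrt((d1 * d1).sum())
    n2 = np.sqrt((d2 * d2).sum())
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    return float(np.clip((d1 * d2).sum() / (n1 * n2), -1.0, 1.0))


class CandidatePairs:
    """Lazy set of unordered gene pairs passing the exchangeability filter.

    ``len()`` is ``C(m, 2)`` for the ``m`` passing genes, computed without
    materializing the pairs; iteration yields canonical (sorted-id) pairs.
    """

    def __init__(self, genes: list):
        self.genes = sorted(genes)

    def __len__(self) -> int:
        m = len(self.genes)
        return m * (m - 1) // 2

    def __iter__(self):
        return itertools.combinations(self.genes, 2)


def candidate_pairs(exchangeability: dict, threshold: float = DEFAULT_EXCHANGEABILITY_THRESHOLD) -> CandidatePairs:
    """All unordered pairs of genes with exchangeability strictly above threshold."""
    passing = [g for g, e in exchangeability.items() if e > threshold]
    return CandidatePairs(passing)


# ---------------------------------------------------------------------------
# Null table
# ---------------------------------------------------------------------------


@dataclass
class NullTable:
    """Binned parametric-bootstrap null of pair correlations.

    ``bin_edges`` partition ``[threshold, inf)``; a pair's bin is chosen by
    its minimal exchangeability, with ties at an edge going to the lower bin.
    ``samples[i]`` is the sorted array of null correlations deposited in bin
    ``i``.  Bins that could not be filled to the requested size within the
    simulation budget are flagged in ``shortfall``.
    """

    bin_edges: np.ndarray
    samples: list
    seed: int | None = None
    model_json: str | None = None
    shortfall: list = field(default_factory=list)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) < 2 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if not np.isinf(self.bin_edges[-1]):
            raise ValidationError("last bin edge must be +inf")
        if len(self.samples) != self.n_bins:
            raise ValidationError("one sample array required per bin")
        self.samples = [np.sort(np.asarray(s, dtype=float)) for s in self.samples]
        for s in self.samples:
            if s.size and (s[0] < -1.0 - 1e-12 or s[-1] > 1.0 + 1e-12):
                raise ValidationError("null correlations must lie in [-1, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def threshold(self) -> float:
        return float(self.bin_edges[0])

    def bin_of(self, min_exch: float) -> int:
        """Bin index of a pair with this minimal exchangeability."""
        if min_exch <= self.bin_edges[0]:
            raise ValidationError(
                f"exchangeability {min_exch} does not exceed the threshold "
                f"{self.bin_edges[0]}"
            )
        return int(np.searchsorted(self.bin_edges, min_exch, side="left")) - 1

    def counts(self) -> list:
        return [int(s.size) for s in self.samples]

    # -- serialization: JSON metadata plus a TSV of samples ----------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": [float(e) for e in self.bin_edges],
                "counts": self.counts(),
                "seed": self.seed,
                "model": json.loads(self.model_json) if self.model_json else None,
                "shortfall": self.shortfall,
            },
            indent=2,
        )

    def save(self, json_path, tsv_path) -> None:
        with open(json_path, "w") as fh:
            fh.write(self.to_json())
        with open(tsv_path, "w") as fh:
            fh.write("bin\tr\n")
            for i, s in enumerate(self.samples):
                for r in s:
                    fh.write(f"{i}\t{float(r)!r}\n")

    @classmethod
    def load(cls, json_path, tsv_path) -> "NullTable":
        with open(json_path) as fh:
            meta = json.load(fh)
        df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
        edges = np.asarray(meta["bin_edges"], dtype=float)
        samples = [
            df.loc[df["bin"] == i, "r"].to_numpy(dtype=float)
            for i in range(len(edges) - 1)
        ]
        return cls(
            bin_edges=edges,
            samples=samples,
            seed=meta.get("seed"),
            model_json=json.dumps(meta["model"]) if meta.get("model") else None,
            shortfall=meta.get("shortfall", []),
        )


def build_null(
    tree: Phylogeny,
    model: GainLossModel,
    bin_edges=DEFAULT_BIN_EDGES,
    per_bin: int = 10_000,
    seed: int = 0,
    max_pairs: int | None = None,
    batch: int = 2_000,
) -> NullTable:
    """Simulate independent gene pairs and bin their mapped correlations.

    Pairs are simulated under ``model``, mapped through stochastic mapping
    exactly like observed data, and the Pearson correlation of each pair's
    event vectors is deposited in the bin of the pair's minimal
    exchangeability.  Simulation continues until every bin holds at least
    ``per_bin`` samples or ``max_pairs`` pairs have been drawn; bins still
    short at that point (unreachable under the model) are flagged.
    """
    edges = np.asarray(bin_edges, dtype=float)
    null = NullTable(bin_edges=edges, samples=[np.empty(0)] * (len(edges) - 1))
    buckets = [[] for _ in range(null.n_bins)]
    rng = np.random.default_rng(seed)
    if max_pairs is None:
        max_pairs = 50 * per_bin * null.n_bins
    drawn = 0
    while drawn < max_pairs and any(len(b) < per_bin for b in buckets):
        m = min(batch, max_pairs - drawn)
        sim = simulate_genes(tree, model, 2 * m, rng)
        table = expected_events(sim.leaf_states, tree, model)
        drawn += m
        ev = table.events
        ex = table.exchangeability
        for i in range(m):
            e = min(ex[2 * i], ex[2 * i + 1])
            if e <= edges[0]:
                continue
            b = int(np.searchsorted(edges, e, side="left")) - 1
            if len(buckets[b]) >= per_bin:
                continue
            r = pearson(ev[2 * i], ev[2 * i + 1])
            if np.isnan(r):
                continue
            buckets[b].append(r)
    shortfall = [
        {"bin": i, "have": len(b), "want": per_bin}
        for i, b in enumerate(buckets)
        if len(b) < per_bin
    ]
    for s in shortfall:
        logger.warning(
            "null bin %d under-filled: %d of %d samples", s["bin"], s["have"], s["want"]
        )
    return NullTable(
        bin_edges=edges,
        samples=[np.asarray(b) for b in buckets],
        seed=seed,
        model_json=model.to_json(),
        shortfall=shortfall,
    )


def empirical_pvalue(r: float, null_sample: np.ndarray) -> float:
    """One-sided add-one empirical P-value: (#{null >= r} + 1) / (N + 1)."""
    s = np.asarray(null_sample, dtype=float)
    if s.size == 0:
        raise CoevonetError("empty null bin — build or extend the null table first")
    s = np.sort(s)
    n_ge = s.size - int(np.searchsorted(s, r, side="left"))
    return (n_ge + 1) / (s.size + 1)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_critical_value(n_rejected: int, n_tests: int, q: float) -> float:
    """Step-up critical value k*q/m at which the BH procedure stops."""
    if n_tests <= 0:
        return 0.0
    return n_rejected * q / n_tests


@dataclass
class BHResult:
    critical_value: float
    reject: np.ndarray
    qvalues: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def bh_fdr(pvalues, q: float) -> BHResult:
    """Benjamini-Hochberg step-up procedure at FDR level ``q``.

    Rejects the ``k`` smallest P-values where ``k`` is the largest rank with
    ``p_(k) <= k q / m``; the returned critical value is ``k q / m``.
    q-values are the usual monotone (cumulative-minimum) adjusted P-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return BHResult(0.0, np.zeros(0, dtype=bool), np.zeros(0))
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("P-values must lie in (0, 1]")
    if not 0.0 < q < 1.0:
        raise ValidationError("FDR level must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(ranked <= thresh)[0]
    k = int(passing[-1]) + 1 if passing.size else 0
    crit = bh_critical_value(k, m, q)
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    qv = ranked * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    qvalues = np.empty(m)
    qvalues[order] = qv
    return BHResult(critical_value=crit, reject=reject, qvalues=qvalues)


# ---------------------------------------------------------------------------
# Full test
# ---------------------------------------------------------------------------


def coevolution_test(
    events: EventTable,
    null: NullTable,
    threshold: float | None = None,
    fdr: float = 0.01,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Test every candidate pair of genes for correlated gain/loss histories.

    Returns a DataFrame with one row per tested pair: gene ids (canonical
    order), Pearson r, minimal exchangeability, null bin, empirical P-value,
    BH q-value and the significance flag at the requested FDR level.
    """
    if threshold is None:
        threshold = null.threshold
    if threshold < null.threshold:
        raise ValidationError("threshold below the null table's first bin edge")
    exch = dict(zip(events.gene_ids, events.exchangeability))
    pairs = candidate_pairs(exch, threshold)
    idx = {g: i for i, g in enumerate(events.gene_ids)}
    passing = pairs.genes
    if not passing:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "r", "min_exch", "bin", "pvalue", "qvalue", "significant"]
        )
    sub = events.events[[idx[g] for g in passing]]
    # full correlation matrix over passing genes
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(sub)
    ex = np.array([exch[g] for g in passing])
    ii, jj = np.triu_indices(len(passing), k=1)
    rows = {
        "gene_a": [passing[i] for i in ii],
        "gene_b": [passing[j] for j in jj],
        "r": np.clip(R[ii, jj], -1.0, 1.0),
        "min_exch": np.minimum(ex[ii], ex[jj]),
    }
    df = pd.DataFrame(rows)
    nan_r = df["r"].isna()
    if nan_r.any():
        logger.warning("%d pair(s) with constant event vectors dropped", int(nan_r.sum()))
        df = df[~nan_r].reset_index(drop=True)
    df["bin"] = [null.bin_of(e) for e in df["min_exch"]]
    stat = df["r"].abs() if two_sided else df["r"]
    null_stat = [np.sort(np.abs(s)) if two_sided else s for s in null.samples]
    df["pvalue"] = [
        empirical_pvalue(r, null_stat[b]) for r, b in zip(stat, df["bin"])
    ]
    bh = bh_fdr(df["pvalue"].to_numpy(), fdr)
    df["qvalue"] = bh.qvalues
    df["significant"] = bh.reject
    return df


def significant_edges(results: pd.DataFrame) -> EdgeList:
    """Edge list of the significant pairs of a results table."""
    sig = results[results["significant"]]
    return EdgeList.from_pairs(zip(sig["gene_a"], sig["gene_b"]))
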