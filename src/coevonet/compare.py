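"""Overlap of the co-evolutionary network with external cellular networks.

For an external network X over the same gene universe (protein-protein
interactions, genomic proximity, co-expression, gene fusion, metabolic
pathways, ...), overlap with the co-evolution network C is summarized by

* frequency          = |X| / U,  U = C(m, 2) possible pairs over m genes,
* conditional freq.  = |X & C| / |C|  (fraction of co-evolving edges in X),
* enrichment ratio   = conditional frequency / frequency,

estimating Pr(edge in X | edge in C) / Pr(edge in X); a two-sided Fisher
exact test on the 2x2 pair classification gives the significance of departure
from enrichment 1.  Restricting C to *functionally informative* edges (both
endpoints sharing a functional-category annotation) repeats the analysis on
the edges most likely to reflect shared function.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .phylo import EdgeList

__all__ = ["OverlapStats", "overlap", "informative_filter", "fisher_exact", "compare_table"]


@dataclass
class OverlapStats:
    universe: int
    n_external: int
    n_coevo: int
    n_both: int
    frequency: float
    conditional_frequency: float
    enrichment: float
    pvalue: float


def fisher_exact(table) -> float:
    """Two-sided Fisher exact P-value (probability-mass rule) for a 2x2 table."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("table entries must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def overlap(coevo: EdgeList, external: EdgeList, universe) -> OverlapStats:
    """Overlap statistics of a co-evolution edge set against an external one.

    ``universe`` is the full gene set; both edge lists are restricted to it.
    With no co-evolving edges the conditional frequency (and hence the
    enrichment) is undefined and reported as NaN.
    """
    genes = sorted(set(universe))
    m = len(genes)
    U = m * (m - 1) // 2
    if U == 0:
        raise ValidationError("universe must contain at least two genes")
    C = coevo.restrict(genes)
    X = external.restrict(genes)
    both = len(C.edges & X.edges)
    freq = len(X) / U
    if len(C) == 0:
        cond = float("nan")
        enr = float("nan")
    else:
        cond = both / len(C)
        enr = cond / freq if freq > 0 else float("nan")
    tbl = [
        [both, len(C) - both],
        [len(X) - both, U - len(C) - len(X) + both],
    ]
    return OverlapStats(
        universe=U,
        n_external=len(X),
        n_coevo=len(C),
        n_both=both,
        frequency=freq,
        conditional_frequency=cond,
        enrichment=enr,
        pvalue=fisher_exact(tbl),
    )


def informative_filter(coevo: EdgeList, annotation: dict) -> tuple[EdgeList, int]:
    """Keep edges whose endpoints share the same functional category.

    Edges with one or both endpoints unlabeled are excluded; their count is
    returned alongside the filtered edge list.
    """
    if not annotation:
        raise ValidationError("annotation map is empty")
    kept, excluded = set(), 0
    for a, b in coevo:
        ca, cb = annotation.get(a), annotation.get(b)
        if ca is None or cb is None:
            excluded += 1
            continue
        if ca == cb:
            kept.add((a, b))
    return EdgeList(edges=kept), excluded


def compare_table(
    coevo: EdgeList,
    externals: dict,
    universe,
    annotation: dict | None = None,
) -> pd.DataFrame:
    """Overlap of the co-evolution network with each named external network.

    One row per external network; when an annotation map is supplied the
    analysis is repeated with the co-evolution edges restricted to
    functionally informative ones (``informative`` column).
    """
    variants = [("all", coevo)]
    if annotation is not None:
        informative, _ = informative_filter(coevo, annotation)
        variants.append(("informative", informative))
    rows = []
    for label, cset in variants:
        for name, ext in externals.items():
            s = overlap(cset, ext, universe)
            rows.append(
                {
                    "network": name,
                    "informative": label == "informative",
                    "frequency": s.frequency,
                    "conditional_frequency": s.conditional_frequency,
                    "enrichment": s.enrichment,
                    "pvalue": s.pvalue,
                    "n_external": s.n_external,
                    "n_coevo": s.n_coevo,
                    "n_both": s.n_both,
                }
            )
    return pd.DataFrame(rows)
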