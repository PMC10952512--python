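"""GO-style over-representation analysis with directional z-scores.

Classic Fisher-test enrichment: annotations are first propagated up the term
DAG (true-path rule: a gene annotated to a term is annotated to all its
ancestors), then each term is tested with the one-sided hypergeometric tail
against the analysis universe and BH-adjusted.  The per-term z-score
(up - down)/sqrt(up + down) summarizes whether the term's study genes move
up or down in expression.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import AnnotationMap
from .de import bh_adjust
from .overlap import hypergeom_tail

__all__ = ["propagate_annotations", "fisher_enrichment", "term_zscore"]


def propagate_annotations(ann: AnnotationMap) -> AnnotationMap:
    """Close each gene's annotations over the term DAG (true-path rule).

    Idempotent: propagating a propagated map is a no-op.
    """
    dag = ann.dag()
    ancestors: dict[str, frozenset[str]] = {}

    def anc(term: str) -> frozenset[str]:
        if term not in ancestors:
            ancestors[term] = (
                frozenset(nx.descendants(dag, term)) if term in dag else frozenset()
            )
        return ancestors[term]

    propagated = {
        gene: frozenset().union(*[anc(t) | {t} for t in terms]) if terms else frozenset()
        for gene, terms in ann.gene_terms.items()
    }
    return AnnotationMap(propagated, list(ann.edges))


def fisher_enrichment(
    study,
    universe,
    ann: AnnotationMap,
    min_term_size: int = 5,
    alpha: float = 0.05,
    log2fc: pd.Series | None = None,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each term in the study set.

    ``ann`` should already be propagated.  Terms with fewer than
    ``min_term_size`` annotated universe genes are skipped.  When ``log2fc``
    is given (indexed by gene), each term also gets a directional z-score over
    its study genes.

    Returns a DataFrame sorted by p with columns term_id,
    n_annotated_universe, n_annotated_study, p, p_adj, significant, z.
    """
    study, universe = set(study), set(universe)
    if not study:
        raise ValueError("empty study set")
    if not study <= universe:
        raise ValueError("study set is not a subset of the universe")

    term_universe: dict[str, set[str]] = {}
    term_study: dict[str, set[str]] = {}
    for gene in universe:
        for term in ann.gene_terms.get(gene, ()):
            term_universe.setdefault(term, set()).add(gene)
            if gene in study:
                term_study.setdefault(term, set()).add(gene)

    rows = []
    N, n_study = len(universe), len(study)
    for term in sorted(term_universe):
        members = term_universe[term]
        if len(members) < min_term_size:
            continue
        k = len(term_study.get(term, ()))
        p = hypergeom_tail(N, len(members), n_study, k)
        z = (
            term_zscore(log2fc.reindex(sorted(term_study.get(term, ()))))
            if log2fc is not None
            else np.nan
        )
        rows.append((term, len(members), k, p, z))
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "n_annotated_universe", "n_annotated_study",
                "p", "p_adj", "significant", "z",
            ]
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "n_annotated_universe", "n_annotated_study", "p", "z"]
    )
    df["p_adj"] = bh_adjust(df["p"].values)
    df["significant"] = df["p_adj"] < alpha
    df = df[
        ["term_id", "n_annotated_universe", "n_annotated_study",
         "p", "p_adj", "significant", "z"]
    ]
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def term_zscore(log2fc) -> float:
    """Directional z-score (up - down)/sqrt(up + down) of a term's study genes.

    Genes with log2fc exactly 0 count in neither direction; with no eligible
    gene the score is NaN.
    """
    fc = np.asarray(pd.Series(log2fc).dropna(), dtype=float)
    up = int((fc > 0).sum())
    down = int((fc < 0).sum())
    if up + down == 0:
        return float("nan")
    return (up - down) / np.sqrt(up + down)
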