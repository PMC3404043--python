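"""Fisher-exact (hypergeometric) over-representation analysis.

Given a DE gene list of size ``n`` drawn from a universe of ``N`` genes of
which ``K`` carry a term's annotation, the enrichment p-value is the
one-sided upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

i.e. the probability of seeing at least the observed ``k`` annotated DE
genes by chance. This equals the one-sided Fisher exact test on the 2x2
table (DE x annotated). The universe should be the detectability-filtered
gene set, so the test conditions on which genes could have been called at
all. Optional GO-slim collapsing unions detailed terms' gene sets into
their broad slim parents before testing.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stratde.io_formats import ConfigError, SlimMapping, Term, TermAnnotation

ENRICH_RESULT_COLUMNS = ["acc", "name", "namespace", "k", "n", "K", "N", "p"]


def collapse_to_slim(annotation: TermAnnotation) -> TermAnnotation:
    """Union each slim parent's member sets over the terms mapping to it."""
    if annotation.slim is None:
        raise ConfigError(
            "annotation has no slim mapping; supply one (term -> slim term table) or skip collapsing"
        )
    slim = annotation.slim
    grouped: dict[str, set] = {}
    for acc, term in annotation.terms.items():
        target = slim.mapping[acc]
        grouped.setdefault(target, set()).update(term.genes)
    terms = {
        target: Term(target, slim.names[target], slim.namespaces[target], frozenset(genes))
        for target, genes in grouped.items()
    }
    identity = SlimMapping(
        {t: t for t in terms},
        {t: slim.names[t] for t in terms},
        {t: slim.namespaces[t] for t in terms},
    )
    return TermAnnotation(terms, identity)


def fisher_enrichment(
    de_genes,
    universe,
    annotation: TermAnnotation,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term enrichment of ``de_genes`` within ``universe``.

    Term gene sets are intersected with the universe before counting; terms
    with no universe genes are omitted. Results are sorted by ascending p,
    ties broken by acc. ``alternative='two-sided'`` switches to the
    two-sided Fisher exact test.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = sorted(de_genes - universe)
    if stray:
        raise ValueError(f"de_genes not contained in universe: {stray[:10]}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    N = len(universe)
    n = len(de_genes)
    rows = []
    for acc, term in annotation.terms.items():
        members = term.genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_genes)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {"acc": acc, "name": term.name, "namespace": term.namespace,
             "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=ENRICH_RESULT_COLUMNS)
    if not out.empty:
        out = out.sort_values(["p", "acc"], kind="mergesort").reset_index(drop=True)
    return out


def adjust_pvalues(results: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Append a ``q`` column: raw p copied through, or Benjamini-Hochberg."""
    if method not in ("none", "bh"):
        raise ValueError(f"method must be 'none' or 'bh', got {method!r}")
    out = results.copy()
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    if method == "none":
        out["q"] = out["p"]
    else:
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
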