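"""Flat-annotation term enrichment by the one-sided hypergeometric test.

Used to categorize interactor sets (e.g. early-only vs shared vs late-only
coprecipitated proteins) against a background population with a flat
gene -> term map. No ontology-graph propagation is performed here; if
ancestor terms should count, propagate the annotation upstream.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def enrich_terms(
    study: set[str],
    population: set[str],
    annotation: dict[str, set[str]],
    correction: str = "none",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``study`` within ``population``.

    For each term with ``K`` annotated loci in the population and ``k`` in
    the study set (``n`` = study size within the population, ``N`` =
    population size), the raw p-value is ``P(X >= k)`` for ``X ~
    Hypergeom(N, K, n)``. ``correction='bh'`` adds Benjamini-Hochberg
    adjusted p-values; by default ``p_adj`` equals ``p_raw``.

    Returns a DataFrame with columns ``term, k, K, n, N, p_raw, p_adj``
    sorted by ascending ``p_raw``, ties broken by term id.
    """
    if not study:
        raise ValueError("study set is empty")
    extra = study - population
    if extra:
        raise ValueError(f"study loci outside the population: {sorted(extra)[:5]}")
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}; expected 'none' or 'bh'")
    annotated_pop = set().union(*annotation.values()) & population if annotation else set()
    if not annotated_pop:
        raise ValueError("no annotated locus intersects the population")

    N = len(population)
    n = len(study & population)
    rows = []
    for term in sorted(annotation):
        term_loci = annotation[term]
        K = len(term_loci & population)
        if K == 0:
            continue
        k = len(term_loci & study)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p_raw, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    if correction == "bh":
        table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table["p_adj"] = table["p_raw"]
    return table.sort_values(["p_raw", "term"], kind="mergesort").reset_index(drop=True)
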