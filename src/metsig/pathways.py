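"""Metabolite-to-gene mapping and hypergeometric overrepresentation analysis.

A differential metabolite list is converted to the union of its mapped gene
symbols (with provenance), and gene sets are scored for over-intersection
with that gene list by the upper-tail hypergeometric probability
P(X >= k) with population N (universe), K successes (set size), n draws
(query size) and k the observed overlap.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection, MetaboliteGeneMap
from .differential import bh_adjust
from .exceptions import MetsigError

logger = logging.getLogger(__name__)


def map_metabolites_to_genes(metabolite_ids, mapping: MetaboliteGeneMap):
    """Union of mapped gene symbols for a metabolite list.

    Returns ``(genes, provenance)`` where ``provenance`` is a DataFrame with
    one (metabolite_id, gene_symbol) row per contribution.  Unmapped
    metabolites contribute nothing and are reported in a warning.
    """
    genes: set[str] = set()
    records: list[tuple[str, str]] = []
    unmapped: list[str] = []
    for metabolite in metabolite_ids:
        mapped = mapping.genes_for(metabolite)
        if not mapped:
            unmapped.append(metabolite)
            continue
        genes |= mapped
        records.extend((metabolite, g) for g in sorted(mapped))
    if unmapped:
        logger.warning("%d metabolite(s) had no gene mapping: %s", len(unmapped), unmapped)
    provenance = pd.DataFrame(records, columns=["metabolite_id", "gene_symbol"])
    return frozenset(genes), provenance


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail (inclusive) hypergeometric probability P(X >= k)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    query,
    collection: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation analysis of each gene set against a query list.

    The universe defaults to the union of all collection members plus the
    query.  Query genes outside the universe are dropped with a warning and
    sets are intersected with the universe.  Raw p is the inclusive upper
    hypergeometric tail; q is BH-adjusted across the collection; the
    ``significant`` flag uses raw p < alpha.  Results are sorted by
    (p, set_name).
    """
    query = frozenset(g.upper() for g in query)
    if not query:
        raise MetsigError("empty query gene list")
    if universe is None:
        universe = collection.derived_universe() | query
    universe = frozenset(g.upper() for g in universe)
    if not universe:
        raise MetsigError("empty gene universe")

    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(outside),
            sorted(outside)[:10],
        )
        query = query & universe
        if not query:
            raise MetsigError("no query genes remain inside the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = hypergeometric_tail(k, N, K, n)
        rows.append((name, N, K, n, k, p, ",".join(overlap)))
    result = pd.DataFrame(
        rows, columns=["set_name", "N", "K", "n", "k", "p", "overlapping_genes"]
    ).set_index("set_name")
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["p"] < alpha
        result = result.sort_values(["p", "set_name"], kind="stable")
    else:
        result["q"] = []
        result["significant"] = []
    return result[["N", "K", "n", "k", "p", "q", "significant", "overlapping_genes"]]
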