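"""Over-representation analysis of a gene list against GMT collections.

For each gene set, the overlap with the query list is scored by the upper
tail of the hypergeometric distribution (one-sided over-representation) over
a universe of all genes in the corpus database, with Benjamini–Hochberg
adjustment across the tested sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_corpus import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_id",
    "description",
    "k",
    "K_set",
    "n",
    "N",
    "p",
    "p_adj",
    "overlap_symbols",
]


def empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(columns=ENRICHMENT_COLUMNS)


def enrich(
    query: list[str], sets: GeneSetCollection, universe: set[str] | list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped (logged); set members are
    likewise restricted to the universe. Sets with no overlap are omitted.
    p = P[X >= k] with X ~ Hypergeom(N, K_set, n); BH across tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    q = set(query)
    outside = q - universe
    if outside:
        logger.info("%d query gene(s) outside the universe dropped", len(outside))
    q &= universe
    n, N = len(q), len(universe)

    rows = []
    for set_id, (desc, members) in sets.sets.items():
        m = set(members) & universe
        overlap = sorted(q & m)
        k = len(overlap)
        if k == 0 or not m:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, len(m), n))
        rows.append((set_id, desc, k, len(m), n, N, min(p, 1.0), ";".join(overlap)))
    if not rows:
        return empty_enrichment()
    out = pd.DataFrame(
        rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "p_adj"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p_adj", "p", "set_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out[ENRICHMENT_COLUMNS]
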