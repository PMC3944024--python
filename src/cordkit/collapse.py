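"""Condense probe-level results to one entry per gene locus.

Microarray platforms carry multiple probesets per transcript. Per comparison,
significant probes (adjusted p below alpha) are grouped by their mapped gene
symbol; a gene whose significant probes disagree in fold-change direction is
removed outright (the discordance rule), otherwise its log2 fold changes are
averaged, and the averaged gene is kept only if it clears the fold-change
threshold. Native mouse/rat symbols are then harmonized to human symbols so
fold changes are comparable across species, re-applying the same rule when
two native symbols collide on one human symbol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_corpus import OrthologMap, ProbeGeneMap

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["symbol", "log2fc", "n_probes", "p_adj_min"]


@dataclass
class CollapseDiagnostics:
    """Counts retained for the corpus-level discordance rate."""

    n_analyzed: int = 0  # symbols with >=1 significant probe
    n_discordant: int = 0  # symbols removed for opposite-direction probes
    n_unmapped_probes: int = 0  # significant probes without a gene symbol

    def __add__(self, other: "CollapseDiagnostics") -> "CollapseDiagnostics":
        return CollapseDiagnostics(
            self.n_analyzed + other.n_analyzed,
            self.n_discordant + other.n_discordant,
            self.n_unmapped_probes + other.n_unmapped_probes,
        )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": pd.Series(dtype=str),
            "log2fc": pd.Series(dtype=float),
            "n_probes": pd.Series(dtype=int),
            "p_adj_min": pd.Series(dtype=float),
        }
    )


def _collapse_frame(
    df: pd.DataFrame, fc_threshold: float
) -> tuple[pd.DataFrame, int, int]:
    """Group (symbol, log2fc, n_probes, p_adj_min) rows by symbol, applying
    the discordance rule to signs and weighted-averaging fold changes.
    Returns (table, n_analyzed, n_discordant)."""
    if df.empty:
        return _empty_table(), 0, 0

    def agg(group: pd.DataFrame):
        signs = np.sign(group["log2fc"].to_numpy())
        nonzero = signs[signs != 0]  # zero fold change is neither direction
        if nonzero.size and not (np.all(nonzero > 0) or np.all(nonzero < 0)):
            return None  # discordant: drop the symbol
        w = group["n_probes"].to_numpy(dtype=float)
        return pd.Series(
            {
                "log2fc": float(np.average(group["log2fc"], weights=w)),
                "n_probes": int(w.sum()),
                "p_adj_min": float(group["p_adj_min"].min()),
            }
        )

    rows, n_discordant = {}, 0
    for symbol, group in df.groupby("symbol", sort=True):
        res = agg(group)
        if res is None:
            n_discordant += 1
        else:
            rows[symbol] = res
    n_analyzed = df["symbol"].nunique()
    if not rows:
        return _empty_table(), n_analyzed, n_discordant
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "symbol"
    table = table.reset_index()
    table = table[np.abs(table["log2fc"]) >= math.log2(fc_threshold)]
    table = table.reset_index(drop=True)
    table["n_probes"] = table["n_probes"].astype(int)
    return table, n_analyzed, n_discordant


def collapse_probes(
    de: pd.DataFrame,
    probe_map: ProbeGeneMap,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
) -> tuple[pd.DataFrame, CollapseDiagnostics]:
    """Collapse one comparison's probe table to gene level.

    Steps: keep probes with p_adj < alpha; map to gene symbols (unmapped
    probes are excluded, counted); drop symbols whose significant probes have
    opposite fold-change signs; average log2fc over the remaining probes;
    keep genes with |averaged log2fc| >= log2(fc_threshold).

    Significance for the discordance check is by adjusted p only — a probe
    below the fold-change threshold still vetoes its gene if it points the
    other way; the fold-change cut applies to the gene-level average.
    """
    diag = CollapseDiagnostics()
    if de.empty:
        return _empty_table(), diag
    sig = de[de["p_adj"] < alpha].copy()
    if sig.empty:
        return _empty_table(), diag
    sig["symbol"] = [probe_map.symbol(p) for p in sig["probe_id"]]
    unmapped = sig["symbol"].isna()
    diag.n_unmapped_probes = int(unmapped.sum())
    if diag.n_unmapped_probes:
        logger.info("%d significant probe(s) had no gene symbol", diag.n_unmapped_probes)
    sig = sig[~unmapped]
    frame = pd.DataFrame(
        {
            "symbol": sig["symbol"].to_numpy(),
            "log2fc": sig["log2fc"].to_numpy(),
            "n_probes": 1,
            "p_adj_min": sig["p_adj"].to_numpy(),
        }
    )
    table, diag.n_analyzed, diag.n_discordant = _collapse_frame(frame, fc_threshold)
    return table, diag


def harmonize_orthologs(
    table: pd.DataFrame, species: str, orth: OrthologMap
) -> tuple[pd.DataFrame, CollapseDiagnostics]:
    """Re-key a collapsed gene table by human ortholog symbols.

    Native symbols with no ortholog entry are dropped (counted as unmapped);
    two native symbols landing on one human symbol go back through the
    discordance/averaging rule. Human tables pass through unchanged.
    """
    diag = CollapseDiagnostics()
    if table.empty:
        return table.copy(), diag
    human = [orth.to_human(species, s) for s in table["symbol"]]
    keep = pd.notna(pd.Series(human, index=table.index))
    diag.n_unmapped_probes = 0
    n_unmapped = int((~keep).sum())
    if n_unmapped:
        logger.info(
            "%d symbol(s) without a human ortholog dropped (%s)", n_unmapped, species
        )
    mapped = table[keep.to_numpy()].copy()
    mapped["symbol"] = [h for h in human if h is not None]
    # fold-change threshold was already applied upstream; do not re-apply here
    out, diag.n_analyzed, diag.n_discordant = _collapse_frame(mapped, 1.0)
    return out, diag


def discordance_rate(diags: list[CollapseDiagnostics]) -> float:
    """Fraction of analyzed gene-comparison events removed as discordant."""
    total = sum(d.n_analyzed for d in diags)
    removed = sum(d.n_discordant for d in diags)
    return removed / total if total else 0.0
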