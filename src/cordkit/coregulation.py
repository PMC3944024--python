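"""Assemble oriented fold-change profiles for a query and rank genes by
correlation with the target.

For a query gene (or several queried "in the same manner"), every comparison
in which the target is differentially expressed is collected. Each retained
comparison's fold changes are sign-flipped so the first target is
upregulated; the per-gene Pearson correlation of oriented log2 fold changes
with the target, over pairwise-complete comparisons, then ranks candidate
co-regulated genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_corpus import CordDatabase

logger = logging.getLogger(__name__)

CORRELATION_COLUMNS = ["gene", "r", "n_shared"]


@dataclass
class FoldChangeMatrix:
    """Genes × retained comparisons of oriented log2 fold changes.

    ``values`` has NaN where a gene was not differentially expressed in a
    comparison; ``orientation`` records the per-comparison sign flip that made
    the (first) target's fold change positive.
    """

    target: str
    method: str
    values: pd.DataFrame  # index = gene symbols, columns = comparison ids
    orientation: pd.Series  # comparison id -> +1 / -1
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_comparisons(self) -> int:
        return self.values.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.values.shape[1] == 0


def collect_target_experiments(
    db: CordDatabase,
    targets: list[str],
    method: str,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
    species: tuple[str, ...] = ("human", "mouse"),
    min_samples: int = 3,
    exclude_factors: frozenset[str] = frozenset(),
) -> FoldChangeMatrix:
    """Gather comparisons where every query gene is differentially expressed
    in the same manner.

    A comparison is retained when it passes the species / group-size /
    contrast-factor filters, every target has an entry with p_adj_min < alpha
    and |log2fc| >= log2(fc_threshold), and — after flipping the comparison's
    sign so the first target is upregulated — all targets are upregulated.
    Returns an empty matrix (not an error) when nothing qualifies.
    """
    if not targets:
        raise ValueError("need at least one target symbol")
    if method not in db.genes:
        raise ValueError(f"database has no {method!r} partition")
    genes = db.genes[method]
    comps = db.comparisons
    comps = comps[comps["method"] == method]
    comps = comps[comps["experiment_id"].map(db.species).isin(species)]
    comps = comps[(comps["n_a"] >= min_samples) & (comps["n_b"] >= min_samples)]
    if exclude_factors:
        comps = comps[~comps["contrast_factor"].str.lower().isin(exclude_factors)]
    eligible = set(comps["comparison_id"])

    genes = genes[genes["comparison_id"].isin(eligible)]
    lfc_min = math.log2(fc_threshold)
    tgt = genes[genes["symbol"].isin(targets)]
    tgt = tgt[(tgt["p_adj_min"] < alpha) & (tgt["log2fc"].abs() >= lfc_min)]
    counts = tgt.groupby("comparison_id")["symbol"].nunique()
    candidate_ids = set(counts[counts == len(set(targets))].index)

    # orient on the first query gene, then require a common direction
    first = targets[0]
    retained: dict[str, float] = {}
    tgt_by_comp = {cid: g for cid, g in tgt.groupby("comparison_id") if cid in candidate_ids}
    for cid, g in tgt_by_comp.items():
        sign = 1.0 if float(g.loc[g["symbol"] == first, "log2fc"].iloc[0]) > 0 else -1.0
        if (sign * g["log2fc"] > 0).all():
            retained[cid] = sign
    if not retained:
        logger.warning("no comparisons retained for target(s) %s", targets)
        empty = pd.DataFrame(index=pd.Index([], name="symbol"))
        return FoldChangeMatrix(first, method, empty, pd.Series(dtype=float))

    order = [cid for cid in comps["comparison_id"] if cid in retained]
    sub = genes[genes["comparison_id"].isin(retained)]
    wide = sub.pivot_table(
        index="symbol", columns="comparison_id", values="log2fc", aggfunc="first"
    )
    wide = wide.reindex(columns=order)
    orientation = pd.Series({cid: retained[cid] for cid in order}, name="orientation")
    wide = wide * orientation
    meta = comps[comps["comparison_id"].isin(retained)].reset_index(drop=True)
    return FoldChangeMatrix(first, method, wide, orientation, meta)


def correlate_genes(m: FoldChangeMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation of every non-target gene with the target.

    Uses pairwise-complete comparisons; genes observed with the target in
    fewer than ``min_shared`` comparisons, or with zero variance across the
    shared comparisons, are excluded. Result is sorted by r descending, ties
    broken by symbol.
    """
    if m.is_empty:
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    if m.target not in m.values.index:
        raise ValueError(f"target {m.target!r} missing from matrix")
    t = m.values.loc[m.target].to_numpy(dtype=float)
    genes = m.values.index.to_numpy()
    x = m.values.to_numpy(dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(t)[None, :]
    n_shared = mask.sum(axis=1)

    records = []
    n_zero_var = 0
    for i, gene in enumerate(genes):
        if gene == m.target:
            continue
        if n_shared[i] < min_shared:
            continue
        sel = mask[i]
        xi, ti = x[i, sel], t[sel]
        sx, st = xi.std(), ti.std()
        if sx == 0 or st == 0:
            n_zero_var += 1
            continue
        r = float(np.corrcoef(xi, ti)[0, 1])
        records.append((gene, r, int(n_shared[i])))
    if n_zero_var:
        logger.info("%d gene(s) excluded for zero variance", n_zero_var)
    out = pd.DataFrame(records, columns=CORRELATION_COLUMNS)
    return out.sort_values(
        ["r", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
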