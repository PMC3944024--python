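"""Enumerate group-by-group comparisons from an experimental design.

Two grouping strategies are supported. The *individual factor method* groups
samples by the levels of one factor at a time, irrespective of every other
factor, and compares all level pairs; a design whose factors have 2, 3 and 2
occupied levels therefore yields C(2,2)+C(3,2)+C(2,2) = 5 comparisons. The
*grouped factor method* first partitions samples by their full combination of
factor levels and then compares occupied cells that differ in exactly one
factor, all other factors held equal (the comparison's *context*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .io_corpus import ExperimentDesign

INDIVIDUAL = "individual"
GROUPED = "grouped"
METHODS = (INDIVIDUAL, GROUPED)


@dataclass(frozen=True)
class ComparisonSpec:
    """One group-vs-group contrast.

    Orientation is deterministic: ``level_a`` is the lexicographically smaller
    level label and fold changes downstream are mean(b) − mean(a). Direction
    is re-oriented per query, so the convention carries no meaning.
    """

    experiment_id: str
    method: str
    contrast_factor: str
    context: tuple[tuple[str, str], ...]  # fixed (factor, level) pairs, sorted
    level_a: str
    level_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.samples_a or not self.samples_b:
            raise ValueError("both groups must be non-empty")
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError("groups overlap")
        if self.level_a == self.level_b:
            raise ValueError("group level labels must differ")

    @property
    def comparison_id(self) -> str:
        ctx = ",".join(f"{f}={v}" for f, v in self.context)
        return (
            f"{self.experiment_id}|{self.method}|{self.contrast_factor}"
            f"|{ctx}|{self.level_a}~{self.level_b}"
        )

    @property
    def context_str(self) -> str:
        return ";".join(f"{f}={v}" for f, v in self.context)

    def sort_key(self):
        return (self.contrast_factor, self.context, self.level_a, self.level_b)


def _sorted(comps: list[ComparisonSpec]) -> list[ComparisonSpec]:
    return sorted(comps, key=ComparisonSpec.sort_key)


def individual_factor_comparisons(design: ExperimentDesign) -> list[ComparisonSpec]:
    """All unordered level pairs of each factor, pooling over other factors.

    Samples lacking a level entry for a factor (empty label) are excluded
    from that factor's groups. Single-level factors contribute nothing.
    """
    comps: list[ComparisonSpec] = []
    for factor in design.factor_names:
        by_level: dict[str, list[str]] = {}
        for s in design.sample_ids:
            level = design.sample_factors[s].get(factor, "")
            if level != "":
                by_level.setdefault(level, []).append(s)
        for la, lb in combinations(sorted(by_level), 2):
            comps.append(
                ComparisonSpec(
                    experiment_id=design.experiment_id,
                    method=INDIVIDUAL,
                    contrast_factor=factor,
                    context=(),
                    level_a=la,
                    level_b=lb,
                    samples_a=tuple(by_level[la]),
                    samples_b=tuple(by_level[lb]),
                )
            )
    return _sorted(comps)


def grouped_factor_comparisons(design: ExperimentDesign) -> list[ComparisonSpec]:
    """Compare occupied full-factorial cells differing in exactly one factor.

    Samples are partitioned by their complete level tuple; a comparison is
    emitted for every pair of occupied cells whose tuples differ in a single
    factor, the shared levels forming the comparison's context. With one
    factor this coincides with the individual factor method.
    """
    cells: dict[tuple[str, ...], list[str]] = {}
    for s in design.sample_ids:
        key = design.levels(s)
        if "" in key:  # sample unannotated for some factor: no complete cell
            continue
        cells.setdefault(key, []).append(s)

    comps: list[ComparisonSpec] = []
    names = design.factor_names
    for ka, kb in combinations(sorted(cells), 2):
        diff = [i for i in range(len(names)) if ka[i] != kb[i]]
        if len(diff) != 1:
            continue
        i = diff[0]
        la, lb = sorted((ka[i], kb[i]))
        sa, sb = (cells[ka], cells[kb]) if (la == ka[i]) else (cells[kb], cells[ka])
        context = tuple(
            sorted((names[j], ka[j]) for j in range(len(names)) if j != i)
        )
        comps.append(
            ComparisonSpec(
                experiment_id=design.experiment_id,
                method=GROUPED,
                contrast_factor=names[i],
                context=context,
                level_a=la,
                level_b=lb,
                samples_a=tuple(sa),
                samples_b=tuple(sb),
            )
        )
    return _sorted(comps)


def filter_comparisons(
    comps: list[ComparisonSpec], min_samples: int
) -> list[ComparisonSpec]:
    """Keep comparisons whose groups both have at least ``min_samples``."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    return [
        c
        for c in comps
        if len(c.samples_a) >= min_samples and len(c.samples_b) >= min_samples
    ]
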