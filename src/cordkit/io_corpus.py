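"""Corpus and report I/O.

A corpus is a directory of experiments, each holding an already log2-normalized
expression matrix, a sample annotation table and a probe→gene map, plus
corpus-level ortholog and gene-set (GMT) files::

    corpus/
        orthologs.tsv            species <TAB> symbol <TAB> human_symbol
        <experiment_id>/
            experiment.yaml      experiment_id, species, platform_id
            matrix.tsv           probe_id <TAB> sample1 <TAB> ...
            samples.tsv          sample_id <TAB> factor:<name> ...
            probes.tsv           probe_id <TAB> gene_symbol

Normalization itself is out of scope: matrices are consumed as provided.
Missing values are permitted (empty cells / NA) and propagate as missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse", "rat")

#: report tab titles, in order; tabs 5-6 are emitted empty when no matching
#: gene-set collection is supplied
REPORT_TABS = (
    "experiments",
    "similar_genes",
    "dissimilar_genes",
    "pathway_enrichment",
    "secondary_enrichment",
    "tissue_enrichment",
)


class CorpusError(ValueError):
    """Malformed or inconsistent corpus artifact."""


@dataclass
class ExpressionMatrix:
    """Probes × samples matrix of log2 intensities; NaN marks missing."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise CorpusError(f"duplicate probe ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise CorpusError(f"duplicate sample ids: {dupes[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ExperimentDesign:
    """Factor→level assignment of every sample, with a species tag."""

    experiment_id: str
    species: str
    sample_factors: dict[str, dict[str, str]]  # sample -> factor -> level
    factor_names: list[str]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise CorpusError(
                f"{self.experiment_id}: species {self.species!r} not in {SPECIES}"
            )
        if not self.factor_names:
            raise CorpusError(f"{self.experiment_id}: design needs >=1 factor")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_factors)

    def levels(self, sample_id: str) -> tuple[str, ...]:
        """Full level tuple of one sample, in factor_names order."""
        fac = self.sample_factors[sample_id]
        return tuple(fac.get(name, "") for name in self.factor_names)


@dataclass
class ProbeGeneMap:
    platform_id: str
    entries: dict[str, str]  # probe -> native gene symbol

    def symbol(self, probe_id: str) -> str | None:
        return self.entries.get(probe_id)


@dataclass
class OrthologMap:
    """(species, native symbol) → human symbol; human maps to itself."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_human(self, species: str, symbol: str) -> str | None:
        if species == "human":
            return symbol
        return self.entries.get((species, symbol))


@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]]  # set_id -> (description, members)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise CorpusError(f"gene set {set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_experiment(
    dir_path: str | Path,
) -> tuple[ExpressionMatrix, ExperimentDesign, ProbeGeneMap]:
    """Read one experiment directory and cross-reference its artifacts.

    Samples present in only one of matrix/annotation are dropped (warning with
    the count); a duplicate sample or probe id, a missing file, or zero common
    samples is a hard error.
    """
    dir_path = Path(dir_path)
    for name in ("matrix.tsv", "samples.tsv", "probes.tsv", "experiment.yaml"):
        if not (dir_path / name).is_file():
            raise CorpusError(f"{dir_path}: missing required file {name}")

    meta = yaml.safe_load((dir_path / "experiment.yaml").read_text())
    experiment_id = str(meta["experiment_id"])
    species = str(meta["species"])
    platform_id = str(meta.get("platform_id", "unknown"))

    raw = pd.read_csv(dir_path / "matrix.tsv", sep="\t", index_col=0, dtype={0: str})
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    matrix = ExpressionMatrix(raw.astype(float))

    ann = pd.read_csv(dir_path / "samples.tsv", sep="\t", dtype=str)
    if ann.columns[0] != "sample_id":
        raise CorpusError(f"{dir_path}: samples.tsv must start with 'sample_id'")
    if ann["sample_id"].duplicated().any():
        raise CorpusError(f"{dir_path}: duplicate sample id in samples.tsv")
    factor_cols = [c for c in ann.columns if c.startswith("factor:")]
    if not factor_cols:
        raise CorpusError(f"{dir_path}: samples.tsv declares no factor: columns")
    factor_names = [c.split(":", 1)[1] for c in factor_cols]

    ann_samples = list(ann["sample_id"])
    common = [s for s in matrix.sample_ids if s in set(ann_samples)]
    if not common:
        raise CorpusError(f"{dir_path}: no samples shared by matrix and annotation")
    n_dropped = (len(matrix.sample_ids) - len(common)) + (
        len(ann_samples) - len(common)
    )
    if n_dropped:
        logger.warning(
            "%s: dropped %d sample(s) present in only matrix or annotation",
            experiment_id,
            n_dropped,
        )
    matrix = ExpressionMatrix(matrix.data[common])

    ann = ann.set_index("sample_id")
    sample_factors = {
        s: {
            name: "" if pd.isna(ann.at[s, col]) else str(ann.at[s, col])
            for name, col in zip(factor_names, factor_cols)
        }
        for s in common
    }
    design = ExperimentDesign(experiment_id, species, sample_factors, factor_names)

    probes = pd.read_csv(dir_path / "probes.tsv", sep="\t", dtype=str)
    pmap = ProbeGeneMap(
        platform_id, dict(zip(probes["probe_id"], probes["gene_symbol"]))
    )
    return matrix, design, pmap


def write_experiment(
    dir_path: str | Path,
    matrix: ExpressionMatrix,
    design: ExperimentDesign,
    pmap: ProbeGeneMap,
) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    (dir_path / "experiment.yaml").write_text(
        yaml.safe_dump(
            {
                "experiment_id": design.experiment_id,
                "species": design.species,
                "platform_id": pmap.platform_id,
            },
            sort_keys=True,
        )
    )
    out = matrix.data.copy()
    out.index.name = "probe_id"
    out.to_csv(dir_path / "matrix.tsv", sep="\t", float_format="%.6g")
    rows = {
        s: {f"factor:{n}": design.sample_factors[s].get(n, "") for n in design.factor_names}
        for s in design.sample_ids
    }
    ann = pd.DataFrame.from_dict(rows, orient="index")
    ann.index.name = "sample_id"
    ann.to_csv(dir_path / "samples.tsv", sep="\t")
    pd.DataFrame(
        {"probe_id": list(pmap.entries), "gene_symbol": list(pmap.entries.values())}
    ).to_csv(dir_path / "probes.tsv", sep="\t", index=False)


def read_orthologs(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = {
        (sp, sym): hum
        for sp, sym, hum in zip(df["species"], df["symbol"], df["human_symbol"])
    }
    return OrthologMap(entries)


def write_orthologs(path: str | Path, orth: OrthologMap) -> None:
    rows = sorted((sp, sym, hum) for (sp, sym), hum in orth.entries.items())
    pd.DataFrame(rows, columns=["species", "symbol", "human_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set id, description, members; tab-separated)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CorpusError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            set_id, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise CorpusError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# report writer


def write_report(result, path: str | Path, format: str = "workbook") -> None:
    """Write the six-tab query report.

    ``result`` is a :class:`~cordkit.cli_report.CordResult`. Tabs, in order:
    experiments; similar genes; dissimilar genes; and three enrichment tabs
    (primary/pathway, secondary, tissue), empty when no matching collection
    was supplied. ``format`` is ``workbook`` (single .xlsx) or ``tsv_dir``
    (directory of six TSV files with identical cell content).
    """
    tabs = result.tabs()
    assert len(tabs) == len(REPORT_TABS)
    path = Path(path)
    if format == "workbook":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, df in zip(REPORT_TABS, tabs):
                df.to_excel(writer, sheet_name=name[:31], index=False)
    elif format == "tsv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for i, (name, df) in enumerate(zip(REPORT_TABS, tabs), start=1):
            df.to_csv(
                path / f"{i}_{name}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
                lineterminator="\n",
            )
    else:
        raise ValueError(f"unknown report format {format!r}")


# ---------------------------------------------------------------------------
# built database (gene-level DE tables per comparison, per grouping method)

DB_VERSION = 1

GENE_TABLE_COLUMNS = ["comparison_id", "symbol", "log2fc", "n_probes", "p_adj_min"]
COMPARISON_COLUMNS = [
    "comparison_id",
    "experiment_id",
    "method",
    "contrast_factor",
    "context",
    "level_a",
    "level_b",
    "n_a",
    "n_b",
]


@dataclass
class CordDatabase:
    """On-disk product of ``cord build``: one gene-level DE table per method.

    ``genes[method]`` is long-format (comparison_id, symbol, log2fc, n_probes,
    p_adj_min); ``comparisons`` carries per-comparison metadata including the
    experiment's species and group sizes, so query-time filters need no access
    to the original corpus.
    """

    comparisons: pd.DataFrame
    genes: dict[str, pd.DataFrame]  # method -> long-format gene table
    species: dict[str, str]  # experiment_id -> species
    universe: list[str]  # all human symbols ever significant
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.comparisons.to_csv(
            path / "comparisons.tsv", sep="\t", index=False, lineterminator="\n"
        )
        for method, df in self.genes.items():
            df.to_csv(
                path / f"genes_{method}.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
                lineterminator="\n",
            )
        (path / "universe.txt").write_text("\n".join(self.universe) + "\n")
        (path / "meta.yaml").write_text(
            yaml.safe_dump(
                {"db_version": DB_VERSION, "species": self.species, **self.meta},
                sort_keys=True,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "CordDatabase":
        path = Path(path)
        meta = yaml.safe_load((path / "meta.yaml").read_text())
        if meta.get("db_version") != DB_VERSION:
            raise CorpusError(f"{path}: unsupported db_version {meta.get('db_version')}")
        species = {str(k): str(v) for k, v in meta.pop("species").items()}
        meta.pop("db_version")
        comparisons = pd.read_csv(
            path / "comparisons.tsv",
            sep="\t",
            dtype={"comparison_id": str, "context": str},
            keep_default_na=False,
        )
        genes = {}
        for f in sorted(path.glob("genes_*.tsv")):
            method = f.stem.split("_", 1)[1]
            genes[method] = pd.read_csv(f, sep="\t", dtype={"comparison_id": str})
        universe = (path / "universe.txt").read_text().split()
        return cls(comparisons, genes, species, universe, meta)
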