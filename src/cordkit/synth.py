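"""Synthetic corpus generator with planted ground truth.

Emulates the corpus the pipeline consumes: factor-annotated experiments with
log2 expression matrices, multiple probes per gene, a mouse/human species mix
with an ortholog table, and a planted co-regulation module. In perturbed
experiments the target gene receives a log2 effect δ (random sign, magnitude
uniform on a configured range) between the levels of the first factor, and
every module gene responds with slope·δ plus coupling noise — the correlation
structure the ranking stage is meant to recover. Background genes are
differentially expressed independently at a configured rate, with random
signs, so they populate DE lists without correlating with the target.
Discordant probe pairs (one probe reporting the opposite direction) are
planted at a configured rate to exercise the collapse rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_corpus import (
    ExperimentDesign,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    ProbeGeneMap,
    write_experiment,
    write_gmt,
    write_orthologs,
)


@dataclass
class SynthConfig:
    """Study conditions for a synthetic corpus. Defaults describe a desk-scale
    corpus: 50 two-factor (2×2, 3 samples/cell) experiments, 40 of which
    perturb the target, a 30-gene module coupled at slope 0.8 with coupling
    noise sd 0.2, and 2 probes per gene."""

    seed: int
    n_experiments: int = 50
    perturbed_fraction: float = 0.8
    factor_levels: dict[str, list[str]] = field(
        default_factory=lambda: {"genotype": ["ko", "wt"], "time": ["t0", "t1"]}
    )
    samples_per_cell: int = 3
    n_genes: int = 2000
    module_size: int = 30
    slope: float = 0.8
    coupling_noise_sd: float = 0.2
    effect_low: float = 1.5
    effect_high: float = 4.0
    background_de_rate: float = 0.10
    sample_noise_sd: float = 0.25
    probes_per_gene: int = 2
    probe_noise_sd: float = 0.1
    discordant_rate: float = 0.0274
    mouse_fraction: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    target_symbol: str = "TARGET"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_experiments", "samples_per_cell", "n_genes", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.module_size < 0 or self.module_size >= self.n_genes:
            raise ValueError("module_size must be in [0, n_genes)")
        for name in (
            "perturbed_fraction",
            "background_de_rate",
            "discordant_rate",
            "mouse_fraction",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.factor_levels:
            raise ValueError("need at least one factor")

    @property
    def module_genes(self) -> list[str]:
        return [f"MOD{i:03d}" for i in range(1, self.module_size + 1)]

    @property
    def background_genes(self) -> list[str]:
        n_bg = self.n_genes - self.module_size - 1
        return [f"BG{i:04d}" for i in range(1, n_bg + 1)]

    @property
    def gene_symbols(self) -> list[str]:
        return [self.target_symbol, *self.module_genes, *self.background_genes]


def _native(symbol: str, species: str) -> str:
    return symbol.capitalize() if species == "mouse" else symbol


def generate_corpus(cfg: SynthConfig, out_dir: str | Path) -> dict:
    """Write a synthetic corpus (experiments + orthologs + gene sets + truth).

    Returns a truth dict with the module genes and per-experiment target
    effects; the same content is written to ``module.txt``, ``truth.tsv``,
    ``truth_effects.tsv`` and ``config.yaml`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = cfg.gene_symbols
    module = cfg.module_genes
    n_perturbed = round(cfg.n_experiments * cfg.perturbed_fraction)

    factor_names = list(cfg.factor_levels)
    perturb_factor = factor_names[0]
    perturb_level = cfg.factor_levels[perturb_factor][0]

    # full factorial sample layout, shared by every experiment
    cells: list[tuple[str, ...]] = [()]
    for f in factor_names:
        cells = [(*c, lv) for c in cells for lv in cfg.factor_levels[f]]

    truth_rows, effect_rows = [], []
    orth_entries: dict[tuple[str, str], str] = {}
    for sym in genes:
        orth_entries[("mouse", _native(sym, "mouse"))] = sym
    for i in range(cfg.n_experiments):
        exp_id = f"SYN{i + 1:04d}"
        species = "mouse" if rng.random() < cfg.mouse_fraction else "human"
        perturbed = i < n_perturbed
        delta = 0.0
        if perturbed:
            delta = float(
                rng.choice([-1.0, 1.0])
                * rng.uniform(cfg.effect_low, cfg.effect_high)
            )

        effects = np.zeros(len(genes))
        effects[0] = delta
        if perturbed and module:
            effects[1 : 1 + len(module)] = cfg.slope * delta + rng.normal(
                0.0, cfg.coupling_noise_sd, len(module)
            )
        n_bg = len(genes) - 1 - len(module)
        bg_de = rng.random(n_bg) < cfg.background_de_rate
        bg_eff = (
            rng.choice([-1.0, 1.0], n_bg)
            * rng.uniform(cfg.effect_low, cfg.effect_high, n_bg)
            * bg_de
        )
        effects[1 + len(module) :] = bg_eff

        # sample layout
        sample_ids, sample_factors, on = [], {}, []
        for cell in cells:
            for r in range(cfg.samples_per_cell):
                sid = f"{exp_id}_{'_'.join(cell)}_{r + 1}"
                sample_ids.append(sid)
                sample_factors[sid] = dict(zip(factor_names, cell))
                on.append(cell[0] == perturb_level)
        on = np.asarray(on, dtype=float)

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes))
        gene_noise = rng.normal(0.0, cfg.sample_noise_sd, (len(genes), len(on)))
        gene_vals = baseline[:, None] + np.outer(effects, on) + gene_noise

        multi = cfg.probes_per_gene >= 2
        flip = (rng.random(len(genes)) < cfg.discordant_rate) if multi else None
        probe_ids, rows_list, probe_syms = [], [], []
        for k in range(cfg.probes_per_gene):
            sign = np.ones(len(genes))
            if multi and k == 1 and flip is not None:
                sign[flip] = -1.0
            vals = (
                baseline[:, None]
                + np.outer(sign * effects, on)
                + gene_noise
                + rng.normal(0.0, cfg.probe_noise_sd, gene_vals.shape)
            )
            rows_list.append(vals)
            probe_ids.extend(f"{sym}_p{k + 1}" for sym in genes)
            probe_syms.extend(_native(sym, species) for sym in genes)
        data = pd.DataFrame(
            np.vstack(rows_list), index=probe_ids, columns=sample_ids
        )
        data = data.sort_index()
        order = np.argsort(probe_ids, kind="stable")
        probe_syms = [probe_syms[j] for j in order]
        probe_ids = sorted(probe_ids)

        matrix = ExpressionMatrix(data)
        design = ExperimentDesign(exp_id, species, sample_factors, factor_names)
        pmap = ProbeGeneMap("synthetic", dict(zip(probe_ids, probe_syms)))
        write_experiment(out_dir / exp_id, matrix, design, pmap)

        truth_rows.append((exp_id, species, int(perturbed), delta))
        if perturbed:
            effect_rows.append((exp_id, cfg.target_symbol, delta))
            effect_rows.extend(
                (exp_id, sym, float(effects[1 + j])) for j, sym in enumerate(module)
            )

    write_orthologs(out_dir / "orthologs.tsv", OrthologMap(orth_entries))

    # gene sets: the planted module plus random background sets
    sets: dict[str, tuple[str, list[str]]] = {}
    if module:
        sets["PLANTED_MODULE"] = ("planted co-regulation module", list(module))
    bg = cfg.background_genes
    for j in range(10):
        size = min(50, max(1, len(bg)))
        members = sorted(rng.choice(bg, size=size, replace=False)) if bg else []
        if members:
            sets[f"RANDOM_SET_{j + 1:02d}"] = ("random background set", members)
    if sets:
        write_gmt(out_dir / "gene_sets.gmt", GeneSetCollection(sets))

    pd.DataFrame(
        truth_rows, columns=["experiment_id", "species", "perturbed", "delta"]
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        effect_rows, columns=["experiment_id", "symbol", "effect"]
    ).to_csv(out_dir / "truth_effects.tsv", sep="\t", index=False, float_format="%.6g")
    (out_dir / "module.txt").write_text("\n".join(module) + "\n")
    (out_dir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))

    return {
        "module": module,
        "target": cfg.target_symbol,
        "experiments": truth_rows,
    }


def two_phase_rank_lists(
    breakpoint: int = 300,
    plateau_pct: float = 50.0,
    length: int = 1000,
    step: int = 10,
) -> tuple[list[str], list[str]]:
    """Two ranked lists with a known informative-overlap breakpoint.

    The percent overlap of the returned lists rises quadratically (zero slope
    at the breakpoint) to ``plateau_pct`` at ``breakpoint`` and is exactly
    flat beyond it — the idealized two-phase shape against which the
    informative-list-size estimator is validated. Overlap counts are realized
    per ``step``-sized rank block by error-diffusion rounding, so the curve
    deviates from the ideal by less than one symbol at any size.
    """
    if not (0 < breakpoint <= length):
        raise ValueError("breakpoint must be in (0, length]")
    grid = np.arange(step, length + 1, step)
    u = np.minimum(grid / breakpoint, 1.0)
    pct = plateau_pct * (2 * u - u**2)
    target_counts = pct * grid / 100.0

    a: list[str] = []
    b: list[str] = []
    realized = 0.0
    counter = 0

    def fresh(tag: str) -> str:
        nonlocal counter
        counter += 1
        return f"{tag}{counter:06d}"

    for c in target_counts:
        k = max(0, min(int(round(c - realized)), step))
        realized += k
        shared = [fresh("S") for _ in range(k)]
        a.extend(shared + [fresh("A") for _ in range(step - k)])
        b.extend(shared + [fresh("B") for _ in range(step - k)])
    return a, b


def truth_eval(result, module: list[str], universe: list[str] | None = None) -> dict[str, float]:
    """Recovery metrics of a query result against the planted module.

    ``result`` is a :class:`~cordkit.cli_report.CordResult`. Reports recall of
    the module in the similar-genes tab, precision among the top |module|
    entries, and the count of module genes contaminating the dissimilar tab.
    When the database ``universe`` is supplied, module symbols missing from it
    indicate a truth/result mismatch and raise.
    """
    if not module:
        raise ValueError("empty module truth")
    mod = set(module)
    if universe is not None and not mod <= set(universe):
        missing = sorted(mod - set(universe))
        raise ValueError(f"module symbols absent from result universe: {missing[:5]}")
    similar = list(result.similar["gene"])
    found = [g for g in similar if g in mod]
    top = similar[: len(mod)]
    metrics = {
        "recall": len(set(found)) / len(mod),
        "precision_at_module_size": (
            sum(g in mod for g in top) / len(top) if top else 0.0
        ),
        "dissimilar_contamination": float(
            sum(g in mod for g in result.dissimilar["gene"])
        ),
    }
    return metrics
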