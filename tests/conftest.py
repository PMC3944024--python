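import numpy as np
import pandas as pd
import pytest

from cordkit import SynthConfig, build_database, generate_corpus
from cordkit.io_corpus import ExperimentDesign, ExpressionMatrix, ProbeGeneMap


def make_design(levels_per_factor: dict[str, int], experiment_id="E1", species="human"):
    """Fully occupied factorial design, one sample per cell."""
    factor_names = list(levels_per_factor)
    cells = [()]
    for f in factor_names:
        cells = [(*c, f"{f}{i}") for c in cells for i in range(levels_per_factor[f])]
    sample_factors = {
        f"s{j}": dict(zip(factor_names, cell)) for j, cell in enumerate(cells)
    }
    return ExperimentDesign(experiment_id, species, sample_factors, factor_names)


def make_matrix(n_probes, samples, rng=None, loc=8.0, scale=1.0):
    rng = rng or np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(loc, scale, (n_probes, len(samples))),
        index=[f"p{i}" for i in range(n_probes)],
        columns=list(samples),
    )
    return ExpressionMatrix(data)


def identity_probe_map(probe_ids):
    return ProbeGeneMap("test", {p: p.upper() for p in probe_ids})


@pytest.fixture(scope="session")
def synth_corpus(tmp_path_factory):
    """Small shared synthetic corpus: 12 experiments, 300 genes, 10-gene module."""
    path = tmp_path_factory.mktemp("corpus")
    cfg = SynthConfig(seed=11, n_experiments=12, n_genes=300, module_size=10)
    truth = generate_corpus(cfg, path)
    return path, cfg, truth


@pytest.fixture(scope="session")
def built_db(synth_corpus, tmp_path_factory):
    corpus, _, _ = synth_corpus
    out = tmp_path_factory.mktemp("db") / "db"
    return build_database(corpus, out)
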