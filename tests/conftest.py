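import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from regnet import CircularGenome, ExpressionSeries

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_circular_genome(rng):
    from helpers import random_genome

    return CircularGenome(id="rand", sequence=random_genome(5000, rng))


def make_series(gene_counts: dict[str, dict[tuple[str, int], list[int]]]) -> ExpressionSeries:
    """Build an ExpressionSeries from {gene: {(arm, time): [replicate counts]}}."""
    cells = sorted({cell for g in gene_counts.values() for cell in g})
    sample_rows, columns = [], []
    for arm, t in cells:
        n_rep = len(next(iter(gene_counts.values()))[(arm, t)])
        for r in range(1, n_rep + 1):
            name = f"{arm}_t{t}_r{r}"
            columns.append(name)
            sample_rows.append({"sample": name, "arm": arm, "time_min": t, "replicate": r})
    samples = pd.DataFrame(sample_rows).set_index("sample")
    data = {}
    for gene, cellmap in gene_counts.items():
        row = []
        for arm, t in cells:
            row.extend(cellmap[(arm, t)])
        data[gene] = row
    counts = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    counts.index.name = "locus_tag"
    return ExpressionSeries(counts=counts, samples=samples)


@pytest.fixture
def series_builder():
    return make_series
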