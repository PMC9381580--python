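import numpy as np
import pytest

from pcrsig.core_data import (
    CohortBundle,
    ExpressionMatrix,
    SampleAnnotation,
    derive_labels,
)
from pcrsig.simdata import SimulationConfig, generate_cohort


def make_bundle(values, trg, probe_prefix="P", gene_prefix="G"):
    """Assemble a CohortBundle from a raw matrix and TRG percentages."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    expr = ExpressionMatrix(
        values,
        [f"{probe_prefix}{i}" for i in range(n_genes)],
        [f"{gene_prefix}{i}" for i in range(n_genes)],
        [f"S{j}" for j in range(n_samples)],
    )
    ann = [
        SampleAnnotation(sample_id=s, trg_percent=float(t))
        for s, t in zip(expr.sample_ids, trg)
    ]
    return CohortBundle(expression=expr, annotation=ann, labels=derive_labels(ann))


@pytest.fixture(scope="session")
def planted_cohort():
    """32+32 extreme cohort, 500 genes, 10 informative at effect 2."""
    return generate_cohort(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with no planted effect."""
    return generate_cohort(SimulationConfig(effect_size=0.0, seed=2024))
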