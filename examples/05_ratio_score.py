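"""The normalization-free ratio score: published instance and training.

score(sample) = sum(numerator gene expression) / sum(denominator gene
expression), computed on positive linear-scale intensities as-is. A global
scaling factor cancels, so the score needs no normalization — usable on a
single new patient profile.
"""

import numpy as np

from pcrsig import compute_ratio_score, published_score, train_score_classifier
from pcrsig.core_data import ExpressionMatrix
from pcrsig.ratio_score import PUBLISHED_TRANSCRIPT_PROBES
from pcrsig.simdata import SimulationConfig, generate_cohort

score = published_score()
print(f"published score: {len(score.numerator_genes)} numerator / "
      f"{len(score.denominator_genes)} denominator genes, "
      f"{len(set(score.numerator_genes) & set(score.denominator_genes))} shared")

# uniform input: the value is forced by the set sizes alone
symbols = list(PUBLISHED_TRANSCRIPT_PROBES)
uniform = ExpressionMatrix(
    np.ones((21, 1)), [PUBLISHED_TRANSCRIPT_PROBES[s] for s in symbols],
    symbols, ["S0"],
)
print(f"score on all-ones input: {compute_ratio_score(uniform, score)[0]:.4f} "
      f"(= 14/12)")

# scale invariance: multiply every intensity by 1000, score unchanged
rng = np.random.default_rng(0)
m = uniform.with_values(rng.uniform(50, 5000, size=(21, 1)))
a = compute_ratio_score(m, score)[0]
b = compute_ratio_score(m.with_values(m.values * 1000), score)[0]
print(f"score before/after x1000 rescale: {a:.6f} / {b:.6f}")

# training a score on synthetic extreme responders
cohort = generate_cohort(SimulationConfig(n_genes=21, n_informative=6, seed=8))
universe = cohort.expression.gene_symbols
trained = train_score_classifier(cohort, universe, n_restarts=100, seed=8)
up_genes = set(universe[:6])
print(f"trained score numerator: {sorted(trained.numerator_genes)}")
print(f"planted up-genes in numerator: "
      f"{len(up_genes & set(trained.numerator_genes))}/6")
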