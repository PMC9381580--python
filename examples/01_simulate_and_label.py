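"""Generate a synthetic rectal-cancer expression cohort and derive response labels.

The generator emulates a pretreatment biopsy study: log2 microarray
intensities with per-gene baselines, Gaussian noise, and a block of
informative genes shifted upward in pathological complete responders
(TRG = 100%). Labels follow the extreme-response rule: positive = pCR
(TRG = 100), negative = poor response (TRG < 45), intermediate otherwise.
"""

import numpy as np

from pcrsig import SimulationConfig, generate_cohort

config = SimulationConfig(
    n_genes=500,        # transcripts on the array
    n_informative=10,   # genes carrying the response signal
    n_positive=32,      # pCR cases (TRG = 100%)
    n_negative=32,      # poor responders (TRG < 45%)
    n_intermediate=97,  # remaining full-range cases (TRG 45-99.9%)
    effect_size=2.0,    # log2 shift of informative genes in responders
    noise_sd=1.0,
    seed=1,
)
cohort = generate_cohort(config)

labels, counts = np.unique(cohort.label_array(), return_counts=True)
print(f"expression matrix: {cohort.expression.n_probes} transcripts "
      f"x {cohort.expression.n_samples} samples")
print("label counts:", {l: int(c) for l, c in zip(labels, counts)})

trg = np.array([a.trg_percent for a in cohort.annotation])
print(f"TRG range: {trg.min():.1f}% - {trg.max():.1f}%")
# The 64 extreme responders (32 pCR + 32 poor) form the discovery set used
# for feature selection; the 161-sample full-range cohort is what a frozen
# classifier is later evaluated on.
extremes = cohort.restrict_to_extremes()
print(f"discovery subset: {extremes.expression.n_samples} extreme responders")
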