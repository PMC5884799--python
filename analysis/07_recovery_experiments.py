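#!/usr/bin/env python
"""Quantitative validation of the vote-counting pipeline on planted truth.

Three experiments: exact recovery of the planted panel in the zero-noise,
full-penetrance limit; convergence of the detected consensus frequency to
the planted penetrance (500 replicates at effect 2, unit noise, penetrance
0.3 over 13 comparisons); and the false-consensus rate of null compendia at
the 20% tier against the binomial tail bound implied by alpha = 0.05.
"""

import json
from pathlib import Path

from consensusde.experiments import (
    frequency_recovery,
    null_false_consensus,
    zero_noise_recovery,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

zero = zero_noise_recovery(seed=SEED)
print(f"zero-noise exact recovery at every tier: {zero.exact}")

freq = frequency_recovery(n_replicates=500, seed=SEED)
print(
    f"mean detected frequency {freq.mean_frequency:.4f} vs penetrance "
    f"{freq.penetrance} (95% CI [{freq.ci_low:.4f}, {freq.ci_high:.4f}]): "
    f"{'within' if freq.within_ci else 'OUTSIDE'} CI"
)

null = null_false_consensus(n_replicates=100, seed=SEED)
print(
    f"null false-consensus rate {null.false_rate:.2e} "
    f"(binomial bound {null.bound:.4f}): "
    f"{'below' if null.below_bound else 'ABOVE'} bound"
)

(ROOT / "recovery_experiments.json").write_text(
    json.dumps(
        {
            "zero_noise_exact": zero.exact,
            "mean_frequency": freq.mean_frequency,
            "penetrance": freq.penetrance,
            "ci": [freq.ci_low, freq.ci_high],
            "null_false_rate": null.false_rate,
            "null_bound": null.bound,
        },
        indent=2,
    )
    + "\n"
)
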