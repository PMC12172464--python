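"""Choose the number of components with fit, CORCONDIA, and a jackknife.

On rank-2 data: the 2-component model explains the most variance per added
component and keeps CORCONDIA near 100, while a 4-component model shows
degenerate (highly congruent) components and unstable loadings when
subjects are left out one at a time.
"""

import pandas as pd

from microtensor import (
    FitConfig,
    SimSpec,
    assess_model_quality,
    assess_model_stability,
    simulate_trilinear,
)

cube, _ = simulate_trilinear(SimSpec(I=15, J=10, K=8, F=2,
                                     noise_sd=0.05, seed=4))

report = assess_model_quality(cube, F_range=range(1, 5), n_starts=5,
                              cfg=FitConfig(seed=5))
cols = ["mean_variance_explained", "share_corcondia_ge_50",
        "max_offdiag_congruence", "share_converged"]
with pd.option_context("display.width", 120, "display.max_columns", None):
    print(report.summary[cols].round(3))

for F in (2, 4):
    stab = assess_model_stability(cube, F, n_iterations=8,
                                  cfg=FitConfig(seed=6))
    print(f"F={F}: median jackknife loading SD = "
          f"{stab.median_loading_sd():.4g}")
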