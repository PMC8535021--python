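"""Dynamical correlation on longitudinal curves, with bootstrap inference.

Pearson correlation on pooled breath-level values is biased by the strong
autocorrelation of repeated measures. Dynamical correlation instead
standardises each subject's trajectory and averages subject-level inner
products, measuring whether two parameters co-move over the course of
ventilation. Here: subjects whose Y curve is a noisy copy of X (strong
positive co-movement) versus independent noise (none).
"""

import numpy as np
import pandas as pd

from venticomp import bootstrap_dyncorr

rng = np.random.default_rng(0)


def make_panel(x_curves, y_curves):
    rows = []
    for param, curves in (("x", x_curves), ("y", y_curves)):
        for sid, vals in curves.items():
            rows += [(sid, t + 1, param, float(v), "M", "S")
                     for t, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["subject_id", "breath_index",
                                       "parameter", "value", "group",
                                       "duration_class"])


x = {f"s{i}": rng.normal(size=12) for i in range(10)}
coupled = {k: v + rng.normal(0, 0.3, 12) for k, v in x.items()}
independent = {k: rng.normal(size=12) for k in x}

for label, y in (("coupled", coupled), ("independent", independent)):
    res = bootstrap_dyncorr(make_panel(x, y), "x", "y",
                            n_boot=1000, seed=1)
    print(f"{label:12s} rho = {res.rho:+.2f} "
          f"(95% CI {res.ci_low:+.2f} to {res.ci_high:+.2f}), "
          f"p = {res.p_value:.3f}")

print("\nThe coupled curves give rho near +1 with a CI excluding zero; the")
print("independent ones give rho near 0 with a CI straddling zero.")
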