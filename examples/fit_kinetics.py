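"""Recover growth kinetics from one synthetic flask.

Generates a densely sampled control culture (VCD + glucose every 4 h, 2% CV
noise), then fits mu_max and K_glc by bound-constrained least squares while
co-estimating the flask's initial state, and prints fitted vs generating
values.
"""

import numpy as np

from chosoft.core import Channel, CultureTable
from chosoft.estimation import fit
from chosoft.kinetics import DEFAULT_PARAMS
from chosoft.pipeline import mmk_initial_state
from chosoft.synthetic import (MissingnessSpec, NoiseSpec,
                               build_feed_schedule, default_design,
                               generate_dataset)

truth = DEFAULT_PARAMS
control = default_design()[0]

def dense(cond):
    g = list(np.arange(0.0, cond.duration_h + 1e-9, 4.0))
    return {Channel.VCD: g, Channel.GLC: g}

observed, _ = generate_dataset(design=[control],
                               noise=NoiseSpec(default_cv=0.02),
                               missing=MissingnessSpec(fraction={}),
                               seed=3, schedule_fn=dense)
flask = CultureTable(observed.df[observed.df["replicate"] == 1],
                     validate=False)

result = fit(truth.replace(mu_max=0.08, K_glc=3.0),
             bounds={"mu_max": (0.01, 0.2), "K_glc": (0.5, 40.0),
                     "init.Xv": (0.1e6, 0.6e6), "init.Glc": (20.0, 45.0)},
             data=flask, schedule=build_feed_schedule(control),
             init=mmk_initial_state(flask, "Control"),
             mode="free", n_starts=2, seed=3, tolerance=1e-10,
             residual_scale="observation")

print(f"converged: {result.converged}  SSE: {result.sse:.4g}  "
      f"function evals: {result.n_function_evals}")
for name in ("mu_max", "K_glc"):
    t, f = getattr(truth, name), getattr(result.params, name)
    print(f"{name:8s} true {t:8.4g}  fitted {f:8.4g}  "
          f"({100 * abs(f - t) / t:.1f}% off)")

print("\nBoth growth parameters come back within a few percent: the Monod "
      "constant is identifiable because glucose passes through its "
      "half-saturation region during the culture.")
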