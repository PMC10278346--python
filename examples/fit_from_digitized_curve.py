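"""From a published KM figure to a selected survival model.

Simulates a 200-subject trial arm, digitizes its KM curve the way a figure
digitizer would (25 step coordinates plus a yearly numbers-at-risk table),
reconstructs pseudo individual-patient data with the Guyot-style algorithm,
fits all seven candidate parametric families, and selects by AIC/BIC.
"""

import warnings

import numpy as np

import tkicea as tk

warnings.simplefilter("ignore", RuntimeWarning)

true_rate = 0.2  # per-year event hazard of the simulated arm
ipd = tk.simulate_ipd("exponential", (true_rate,), n=200, censor_rate=0.05, seed=0)
curve = tk.make_digitized_fixture(
    ipd, n_points=25, risk_times=np.arange(0.0, ipd.time.max(), 1.0)
)
rec = tk.reconstruct_ipd(curve)
print(f"reconstructed {rec.n} subjects: {rec.n_events} events, "
      f"{rec.n_censored} censored (true events: {ipd.event.sum()})")

selection = tk.fit_all_families(rec)
print(selection.criterion_table()[["family", "aic", "bic", "chosen"]]
      .to_string(index=False))
lam = selection.chosen_model.params[0]
print(f"\nselected {selection.chosen}, rate {lam:.4f}/year "
      f"(generating rate {true_rate}).\nAIC ranks the memoryless model first "
      "on memoryless data; the recovered hazard is\nattenuated by the coarse "
      "25-point digitization (merged steps shift pooled events\nlater), an "
      "information loss that shrinks as more of the curve is digitized.")
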