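"""Fit the multi-species functional response to simulated diet data.

Simulates 300 stranded-predator diet observations from a type III response
with known attack rates, fits both candidate shapes by MCMC, compares them
by DIC and prints the posterior attack-rate summary.  The true rates
(sandeel fixed at 1; others 0.5, 0.25, 0.1) should sit inside the 95%
credible intervals, and the type III model should win the DIC comparison.
"""

import warnings

from msfr.msfr_model import compare_models, compute_dic, fit_mcmc
from msfr.synthetic_data import simulate_diet_observations

TRUE_A = {"sandeel": 1.0, "whiting": 0.5, "cod": 0.25, "herring": 0.1}

obs = simulate_diet_observations(TRUE_A, shape_m=1.5, n=300, tau=80.0, seed=11)

entries = []
samples = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for m in (1.0, 1.5):
        s = fit_mcmc(obs, shape_m=m, chains=2, iterations=1500, burn_in=300, seed=4)
        samples[m] = s
        entries.append(compute_dic(s, obs, label=f"type {'II' if m == 1 else 'III'} (m={m})"))

print("DIC comparison (lower is better; data generated from type III):")
print(compare_models(entries).round(1).to_string(index=False))

print("\nPosterior attack rates under the preferred model (true: 0.5, 0.25, 0.1):")
print(samples[1.5].summary().round(3).to_string(index=False))
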