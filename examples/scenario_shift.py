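"""Predict consumption consequences of a shift in prey availability.

Loads the shipped worked example — predicted harbour-porpoise diet
compositions for a high-sandeel year (2011) and a low-sandeel year (2020),
with literature energy densities — and converts the compositional shift
into daily-ration consequences for an average adult male porpoise.
"""

from importlib import resources

import pandas as pd

from msfr.scenario import consumption_deltas, mass_to_energy_shares, relative_change, scenario_table

with resources.files("msfr.data").joinpath("scenario_diet_shares.csv").open() as f:
    df = pd.read_csv(f)
m2011 = dict(zip(df["species"], df["mass_pct_2011"]))
m2020 = dict(zip(df["species"], df["mass_pct_2020"]))
energy = dict(zip(df["species"], df["energy_kj_per_g"]))

print(scenario_table(m2011, m2020, energy, "2011", "2020").round(1).to_string(index=False))

print("\nRelative change in biomass share (%):")
for sp, ch in relative_change(m2011, m2020).items():
    print(f"  {sp:8s} {ch:+6.0f}")

d = consumption_deltas(m2011, m2020, energy, daily_mass_kg=1.7, daily_energy_mj=6.7)
print(f"\nAt a fixed 6.7 MJ/day energy requirement, the lower-energy 2020 diet")
print(f"demands {d.grams_per_day_at_fixed_energy:+.0f} g/day more biomass;")
print(f"at a fixed 1.7 kg/day intake it delivers {d.kj_per_day_at_fixed_mass:+.0f} kJ/day")
print(f"({d.pct_change:+.1f}% change in required biomass).")
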