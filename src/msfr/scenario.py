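"""Diet and consumption prediction under changed prey availability.

Given a fitted MSFR posterior and a scenario that rescales each prey's
availability by a spawning-stock-biomass (SSB) ratio, this module predicts
the new diet composition, converts biomass shares (%M) into energy shares
(%E) using per-species energy densities, and translates the compositional
shift into daily-ration consequences for a predator that either forages to a
fixed energy requirement (default 6.7 MJ/day) or to a fixed biomass intake
(default 1.7 kg/day) — the published daily ration of an average adult male
harbour porpoise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msfr_model import MSFRParams, PosteriorSample, msfr_proportions


@dataclass
class ScenarioSpec:
    """Availability rescaling between a reference and a target year."""

    reference_year: int
    target_year: int
    ssb_scalers: dict[str, float]  # target SSB / reference SSB per species
    daily_mass_kg: float = 1.7
    daily_energy_mj: float = 6.7

    def __post_init__(self):
        if any(v <= 0 for v in self.ssb_scalers.values()):
            raise ValueError("SSB scalers must be positive")


def scale_availability(availability: dict[str, float], spec: ScenarioSpec) -> dict[str, float]:
    """Apply the per-species SSB ratios; every species needs a scaler."""
    missing = set(availability) - set(spec.ssb_scalers)
    if missing:
        raise ValueError(f"no SSB scaler for species: {sorted(missing)}")
    return {s: availability[s] * spec.ssb_scalers[s] for s in availability}


def predict_scenario_diet(
    sample: PosteriorSample,
    availability: dict[str, float],
    spec: ScenarioSpec | None = None,
    return_draws: bool = False,
):
    """Posterior-mean diet (%M) at (optionally rescaled) availabilities.

    Evaluates the functional response at every posterior draw and averages
    the resulting proportions, so the nonlinearity of the response is
    respected; with ``return_draws`` the full posterior-predictive matrix of
    percentages is returned alongside the means.
    """
    B = dict(availability) if spec is None else scale_availability(availability, spec)
    species = sample.species
    Bv = np.array([B[s] for s in species], dtype=float)
    flat = sample.flat_a  # (d, n_free)
    a_full = np.ones((flat.shape[0], len(species)))
    for j, s in enumerate(sample.free_species):
        a_full[:, species.index(s)] = flat[:, j]
    num = a_full * Bv[None, :] ** sample.shape_m
    tot = num.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("scenario availabilities are all zero")
    p = 100.0 * num / tot
    means = dict(zip(species, p.mean(axis=0)))
    if return_draws:
        return means, pd.DataFrame(p, columns=species)
    return means


def predict_diet_at_mean(params: MSFRParams, availability: dict[str, float]) -> dict[str, float]:
    """Plug-in diet (%M) at the posterior-mean attack rates."""
    return {s: 100.0 * p for s, p in msfr_proportions(params, availability).items()}


def mass_to_energy_shares(mass_pct: dict[str, float], energy_kj_per_g: dict[str, float]) -> dict[str, float]:
    """Convert biomass shares %M into energy shares %E.

    %E_i = %M_i * E_i / sum_j %M_j * E_j * 100, with E in kJ/g.  Inputs are
    tolerated to sum to 100 +/- 0.5 so published, rounded columns can be fed
    straight in.
    """
    total = sum(mass_pct.values())
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"%M shares must sum to 100 (+/-0.5), got {total:.3f}")
    missing = set(mass_pct) - set(energy_kj_per_g)
    if missing:
        raise ValueError(f"no energy density for species: {sorted(missing)}")
    weighted = {s: mass_pct[s] * energy_kj_per_g[s] for s in mass_pct}
    denom = sum(weighted.values())
    return {s: 100.0 * w / denom for s, w in weighted.items()}


def mean_energy_density(mass_pct: dict[str, float], energy_kj_per_g: dict[str, float]) -> float:
    """Diet-average energy density in kJ/g: sum %M_i E_i / 100."""
    return sum(mass_pct[s] * energy_kj_per_g[s] for s in mass_pct) / 100.0


@dataclass
class ConsumptionDelta:
    """Daily-ration consequences of a diet shift."""

    grams_per_day_at_fixed_energy: float
    kj_per_day_at_fixed_mass: float
    pct_change: float


def consumption_deltas(
    ref_mass_pct: dict[str, float],
    target_mass_pct: dict[str, float],
    energy_kj_per_g: dict[str, float],
    daily_mass_kg: float = 1.7,
    daily_energy_mj: float = 6.7,
) -> ConsumptionDelta:
    """Change in daily intake implied by a shift in diet energy density.

    If the predator forages to a fixed energy requirement, a lower diet
    energy density forces extra grams per day:
    ``daily_energy*1e3/e_target - daily_energy*1e3/e_ref``.  If it forages to
    a fixed biomass, the energy intake changes by
    ``daily_mass*1e3*(e_target - e_ref)`` kJ/day.  ``pct_change`` is the
    relative change in required biomass (equivalently, in delivered energy
    magnitude) versus the reference.
    """
    e_ref = mean_energy_density(ref_mass_pct, energy_kj_per_g)
    e_tgt = mean_energy_density(target_mass_pct, energy_kj_per_g)
    grams_ref = daily_energy_mj * 1e3 / e_ref
    grams_tgt = daily_energy_mj * 1e3 / e_tgt
    d_grams = grams_tgt - grams_ref
    d_kj = daily_mass_kg * 1e3 * (e_tgt - e_ref)
    pct = 100.0 * d_grams / grams_ref
    return ConsumptionDelta(d_grams, d_kj, pct)


def relative_change(ref_mass_pct: dict[str, float], target_mass_pct: dict[str, float]) -> dict[str, float]:
    """Per-species percent change 100*(target-ref)/ref; NaN where ref is 0."""
    out = {}
    for s in ref_mass_pct:
        r = ref_mass_pct[s]
        t = target_mass_pct.get(s, np.nan)
        out[s] = np.nan if r == 0 else 100.0 * (t - r) / r
    return out


def scenario_table(
    ref_mass_pct: dict[str, float],
    target_mass_pct: dict[str, float],
    energy_kj_per_g: dict[str, float],
    ref_label: str = "reference",
    target_label: str = "target",
) -> pd.DataFrame:
    """Side-by-side %M and %E per scenario, plus the energy-density column."""
    e_ref = mass_to_energy_shares(ref_mass_pct, energy_kj_per_g)
    e_tgt = mass_to_energy_shares(target_mass_pct, energy_kj_per_g)
    rows = [
        {
            "species": s,
            f"%M {ref_label}": ref_mass_pct[s],
            f"%M {target_label}": target_mass_pct[s],
            f"%E {ref_label}": e_ref[s],
            f"%E {target_label}": e_tgt[s],
            "energy_kj_per_g": energy_kj_per_g[s],
        }
        for s in ref_mass_pct
    ]
    return pd.DataFrame(rows)
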