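"""Diet composition from stomach otolith records, with bootstrap uncertainty.

Stomach contents of stranded animals are reduced to otolith records (species,
measured length, wear grade, count).  Digestion shrinks otoliths, so measured
lengths are multiplied by grade-specific correction factors before an
otolith-length to fish-mass allometry converts each record to prey mass.
Only reasonably fresh carcasses (decomposition codes 1-3) enter the analysis.
Species contributing at least 5% of the pooled reconstructed prey mass are
kept as "main prey"; the rest (plus gobies, whose availability cannot be
estimated from trawl surveys) are merged into an "other" category.

Sampling error is quantified by a nonparametric bootstrap that resamples
individuals (not otoliths) with replacement within season strata: strandings
from November-April are assigned to quarter 1, May-October to quarter 3,
matching the survey quarters used for prey availability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OTHER = "other"

# months -> survey quarter used for availability matching
Q1_MONTHS = {11, 12, 1, 2, 3, 4}
Q3_MONTHS = {5, 6, 7, 8, 9, 10}


def season_quarter(dates: pd.Series) -> pd.Series:
    """Survey quarter per stranding date: Nov-Apr -> Q1, May-Oct -> Q3."""
    months = pd.to_datetime(dates).dt.month
    return months.map(lambda m: "Q1" if m in Q1_MONTHS else "Q3")


@dataclass
class DietComposition:
    """Mean prey-mass proportions with bootstrap SDs."""

    proportions: dict[str, float]
    sd: dict[str, float]
    n_individuals: int
    stratification: str = "season"

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.proportions),
                "mean": list(self.proportions.values()),
                "sd": [self.sd[s] for s in self.proportions],
            }
        )


def filter_carcasses(strandings: pd.DataFrame, max_code: int = 4) -> pd.DataFrame:
    """Keep carcasses with decomposition code below ``max_code`` (default < 4).

    Warns when nothing survives the filter; the dropped count is attached to
    the returned frame's ``attrs``.
    """
    keep = strandings["decomposition_code"] < max_code
    dropped = int((~keep).sum())
    out = strandings.loc[keep].copy()
    out.attrs["n_dropped_decomposed"] = dropped
    if len(out) == 0:
        warnings.warn("no carcasses left after the decomposition-code filter")
    return out


def reconstruct_prey_mass(
    otoliths: pd.DataFrame,
    grade_corrections: dict[int, float] | pd.DataFrame,
    allometry: dict[str, tuple[float, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Prey mass (g) per otolith record.

    corrected length = measured length * grade factor;
    mass = a * corrected_length**b * count, with (a, b) per species.

    Raises ``KeyError`` naming the offending record for unknown species or
    wear grades.
    """
    if isinstance(grade_corrections, pd.DataFrame):
        grade_corrections = dict(
            zip(grade_corrections["grade"].astype(int), grade_corrections["factor"])
        )
    if isinstance(allometry, pd.DataFrame):
        allometry = {
            r["species"]: (float(r["a"]), float(r["b"])) for _, r in allometry.iterrows()
        }
    out = otoliths.copy()
    bad_sp = set(out["species"]) - set(allometry)
    if bad_sp:
        rec = out[out["species"].isin(bad_sp)].iloc[0]
        raise KeyError(
            f"no allometry for species {rec['species']!r} (stranding {rec['stranding_id']})"
        )
    grades = out["wear_grade"].astype(int)
    bad_g = set(grades) - set(grade_corrections)
    if bad_g:
        rec = out[grades.isin(bad_g)].iloc[0]
        raise KeyError(
            f"unknown wear grade {int(rec['wear_grade'])} "
            f"(stranding {rec['stranding_id']}, {rec['species']})"
        )
    a = out["species"].map({s: v[0] for s, v in allometry.items()}).to_numpy(dtype=float)
    b = out["species"].map({s: v[1] for s, v in allometry.items()}).to_numpy(dtype=float)
    factor = grades.map(grade_corrections).to_numpy(dtype=float)
    corrected = out["otolith_length"].to_numpy(dtype=float) * factor
    out["prey_mass_g"] = a * corrected**b * out["count"].to_numpy(dtype=float)
    return out


def pooled_composition(masses: pd.DataFrame) -> dict[str, float]:
    """Pooled prey-mass proportions over all records."""
    by_sp = masses.groupby("species")["prey_mass_g"].sum()
    total = by_sp.sum()
    if total <= 0:
        raise ValueError("total reconstructed prey mass is zero")
    return (by_sp / total).to_dict()


def select_main_prey(
    pooled: dict[str, float],
    threshold: float = 0.05,
    force_other: tuple[str, ...] = (),
) -> list[str]:
    """Species with pooled mass share >= ``threshold`` (boundary inclusive).

    Species named in ``force_other`` (e.g. gobies, which cannot be assigned
    an availability index) are merged into the "other" category regardless
    of their share.
    """
    return [
        sp
        for sp, share in pooled.items()
        if share >= threshold and sp not in force_other and sp != OTHER
    ]


def merge_other(masses: pd.DataFrame, main_prey: list[str]) -> pd.DataFrame:
    """Relabel all non-main species as "other"; total mass is preserved."""
    out = masses.copy()
    out["species"] = out["species"].where(out["species"].isin(main_prey), OTHER)
    return out


def bootstrap_diet(
    strandings: pd.DataFrame,
    masses: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    stratify_by: str = "season_quarter",
) -> DietComposition:
    """Stratified nonparametric bootstrap of the pooled diet composition.

    Individuals (strandings) are the sampling unit, resampled with
    replacement within each stratum (season by default).  Per replicate the
    pooled mass proportions are recomputed; the summary reports their mean
    and SD per species.  A single replicate returns SD 0 with a warning.

    Raises ``ValueError`` naming any stratum with zero individuals.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if stratify_by not in strandings.columns:
        raise ValueError(f"stratification column {stratify_by!r} missing from strandings")
    species = sorted(masses["species"].unique())
    sp_idx = {s: j for j, s in enumerate(species)}

    # per-individual mass vectors
    per_ind = (
        masses.groupby(["stranding_id", "species"])["prey_mass_g"].sum().unstack(fill_value=0.0)
    )
    per_ind = per_ind.reindex(columns=species, fill_value=0.0)

    strata: dict[str, np.ndarray] = {}
    for name, grp in strandings.groupby(stratify_by):
        ids = grp["id"].to_numpy()
        if len(ids) == 0:
            raise ValueError(f"stratum {name!r} has zero individuals")
        strata[name] = ids
    if not strata:
        raise ValueError("no strata found")
    for name, ids in strata.items():
        if len(ids) == 0:
            raise ValueError(f"stratum {name!r} has zero individuals")

    # individuals with no otoliths contribute zero mass
    M = np.zeros((len(strandings), len(species)))
    id_to_row = {i: k for k, i in enumerate(strandings["id"].to_numpy())}
    for sid, row in per_ind.iterrows():
        if sid in id_to_row:
            M[id_to_row[sid]] = row.to_numpy()

    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, len(species)))
    for b in range(n_boot):
        tot = np.zeros(len(species))
        for ids in strata.values():
            rows = np.array([id_to_row[i] for i in ids])
            pick = rng.choice(rows, size=len(rows), replace=True)
            tot += M[pick].sum(axis=0)
        if tot.sum() <= 0:
            reps[b] = np.nan
        else:
            reps[b] = tot / tot.sum()
    good = ~np.isnan(reps).any(axis=1)
    reps = reps[good]
    if len(reps) == 0:
        raise ValueError("every bootstrap replicate had zero total mass")
    mean = reps.mean(axis=0)
    if n_boot == 1:
        warnings.warn("single bootstrap replicate: SD is 0 by convention")
        sd = np.zeros(len(species))
    else:
        sd = reps.std(axis=0, ddof=1)
    mean = mean / mean.sum()
    return DietComposition(
        proportions=dict(zip(species, mean)),
        sd=dict(zip(species, sd)),
        n_individuals=len(strandings),
        stratification=stratify_by,
    )


def estimate_diet(
    strandings: pd.DataFrame,
    otoliths: pd.DataFrame,
    grade_corrections: dict[int, float] | pd.DataFrame,
    allometry: dict[str, tuple[float, float]] | pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
    force_other: tuple[str, ...] = ("goby",),
) -> tuple[DietComposition, list[str]]:
    """Full diet stage: filter carcasses, reconstruct, select main prey, bootstrap."""
    kept = filter_carcasses(strandings)
    if "season_quarter" not in kept.columns:
        kept = kept.assign(season_quarter=season_quarter(kept["date"]))
    oto = otoliths[otoliths["stranding_id"].isin(kept["id"])]
    masses = reconstruct_prey_mass(oto, grade_corrections, allometry)
    main = select_main_prey(pooled_composition(masses), threshold, force_other)
    merged = merge_other(masses, main)
    comp = bootstrap_diet(kept, merged, n_boot=n_boot, seed=seed)
    return comp, main
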