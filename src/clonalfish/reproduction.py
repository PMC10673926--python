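"""Reproductive profiles and analytics.

Builds per-female reproductive profiles from brood records (age at
parturition, brood size) and a long table of measured offspring lengths:
onset of reproduction, per-brood mean offspring length, cumulative offspring
output, and the trade-off-adjusted mixed models whose variance components
quantify reproductive individuality.

Bookkeeping follows the field convention for partially measured data: broods
whose offspring were counted but not measured stay in every brood-size
analysis; offspring-size analyses use only measured broods.  Females with no
broods at all are excluded (with a logged count) from profile building.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .errors import ValidationError
from .growth import GrowthFit, predicted_size_at

logger = logging.getLogger(__name__)

#: canonical column names of the brood CSV dialect
BROOD_COLUMNS = [
    "brood_id", "individual_id", "mother_id",
    "age_at_parturition_days", "brood_size",
]
#: canonical column names of the long offspring CSV dialect
OFFSPRING_COLUMNS = ["brood_id", "offspring_length_cm"]


@dataclass(frozen=True)
class Brood:
    brood_id: str
    individual_id: str
    mother_id: str
    age_at_parturition: float
    brood_size: int
    offspring_lengths: tuple[float, ...] = ()
    female_size_at_parturition: float = float("nan")

    def __post_init__(self):
        if self.brood_size < 1:
            raise ValidationError(f"{self.brood_id}: brood_size must be >= 1")
        if len(self.offspring_lengths) > self.brood_size:
            raise ValidationError(
                f"{self.brood_id}: more measured lengths than brood_size"
            )
        if any(L <= 0 for L in self.offspring_lengths):
            raise ValidationError(f"{self.brood_id}: lengths must be > 0")

    @property
    def mean_offspring_length(self) -> float:
        if not self.offspring_lengths:
            return float("nan")
        return float(np.mean(self.offspring_lengths))


@dataclass
class ReproductiveProfile:
    individual_id: str
    mother_id: str
    broods: list[Brood] = field(default_factory=list)

    @property
    def onset(self) -> float:
        """Age (days) at first parturition."""
        return self.broods[0].age_at_parturition

    @property
    def total_offspring(self) -> int:
        return sum(b.brood_size for b in self.broods)


def build_profiles(
    broods: pd.DataFrame,
    offspring: pd.DataFrame,
    growth_fits: dict[str, GrowthFit] | None = None,
) -> tuple[dict[str, ReproductiveProfile], pd.DataFrame]:
    """Assemble profiles and the tidy per-brood analysis table.

    ``female_size_at_parturition`` is filled from growth-curve predictions at
    each brood's parturition age when fits are supplied.  Individuals present
    in the brood table but with zero rows never arise; individuals absent
    from it are simply not profiled (their count is the caller's concern).
    Non-increasing parturition ages within a female raise a data error.

    Returns (profiles by individual, brood_rows) where brood_rows has one row
    per brood with onset, mean offspring length and size covariates -- the
    input to the repeatability and trade-off models.
    """
    missing = [c for c in BROOD_COLUMNS if c not in broods.columns]
    if missing:
        raise ValidationError(f"brood table missing columns: {missing}")
    if broods["brood_id"].duplicated().any():
        raise ValidationError("duplicate brood_id in brood table")
    lengths_by_brood = (
        offspring.groupby("brood_id")["offspring_length_cm"].apply(tuple)
        if len(offspring) else pd.Series(dtype=object)
    )

    profiles: dict[str, ReproductiveProfile] = {}
    rows = []
    for ind, sub in broods.groupby("individual_id", sort=True):
        sub = sub.sort_values("age_at_parturition_days")
        ages = sub["age_at_parturition_days"].to_numpy()
        if np.any(ages <= 0):
            raise ValidationError(f"{ind}: parturition before birth")
        if np.any(np.diff(ages) <= 0):
            raise ValidationError(f"{ind}: non-increasing parturition ages")
        fit = growth_fits.get(str(ind)) if growth_fits else None
        profile = ReproductiveProfile(str(ind), str(sub["mother_id"].iloc[0]))
        for _, r in sub.iterrows():
            size = (
                float(predicted_size_at(fit, r["age_at_parturition_days"]))
                if fit is not None else float("nan")
            )
            brood = Brood(
                brood_id=str(r["brood_id"]),
                individual_id=str(ind),
                mother_id=str(r["mother_id"]),
                age_at_parturition=float(r["age_at_parturition_days"]),
                brood_size=int(r["brood_size"]),
                offspring_lengths=tuple(
                    lengths_by_brood.get(r["brood_id"], ())
                ),
                female_size_at_parturition=size,
            )
            profile.broods.append(brood)
        profiles[str(ind)] = profile
        onset = profile.onset
        for b in profile.broods:
            rows.append(
                {
                    "brood_id": b.brood_id,
                    "individual_id": b.individual_id,
                    "mother_id": b.mother_id,
                    "age_at_parturition_days": b.age_at_parturition,
                    "brood_size": b.brood_size,
                    "mean_offspring_length": b.mean_offspring_length,
                    "n_measured": len(b.offspring_lengths),
                    "onset": onset,
                    "female_size_at_parturition": b.female_size_at_parturition,
                }
            )
    return profiles, pd.DataFrame(rows)


def cumulative_offspring(profile: ReproductiveProfile, t: float) -> int:
    """Right-continuous cumulative offspring count at age ``t`` days."""
    return sum(
        b.brood_size for b in profile.broods if b.age_at_parturition <= t
    )


def cumulative_curve(
    profiles: dict[str, ReproductiveProfile], horizon_days: int
) -> pd.DataFrame:
    """Step-curve table (individual_id, age_days, cumulative_offspring)."""
    rows = []
    for ind, prof in profiles.items():
        ages = [0.0] + [b.age_at_parturition for b in prof.broods] + [
            float(horizon_days)
        ]
        for a in ages:
            rows.append(
                {
                    "individual_id": ind,
                    "age_days": a,
                    "cumulative_offspring": cumulative_offspring(prof, a),
                }
            )
    return pd.DataFrame(rows)


def profile_summary(profiles: dict[str, ReproductiveProfile]) -> pd.DataFrame:
    """Per-female descriptive table."""
    rows = []
    for ind, p in profiles.items():
        measured = [b.mean_offspring_length for b in p.broods
                    if b.offspring_lengths]
        rows.append(
            {
                "individual_id": ind,
                "mother_id": p.mother_id,
                "onset": p.onset,
                "n_broods": len(p.broods),
                "mean_brood_size": float(
                    np.mean([b.brood_size for b in p.broods])
                ),
                "mean_offspring_length": float(np.mean(measured))
                if measured else float("nan"),
                "total_offspring": p.total_offspring,
            }
        )
    return pd.DataFrame(rows)


def tradeoff_models(
    brood_rows: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
) -> dict:
    """Trade-off-adjusted mixed models and the four reproductive
    repeatabilities.

    Two per-brood mixed models with an individual random intercept:

    (a) mean offspring length ~ brood size + onset + female size at
        parturition + mother ID  (measured broods only)
    (b) brood size ~ mean offspring length + onset + female size at
        parturition + mother ID

    Raw repeatabilities come from intercept-only models (brood size over all
    broods; offspring size over measured broods); adjusted repeatabilities
    from the models above.  All CIs are percentile intervals over ``n_sim``
    parametric simulations.
    """
    if brood_rows["individual_id"].nunique() < 2:
        raise ValidationError("trade-off models need >= 2 individuals")
    covs = ("onset", "female_size_at_parturition", "mother_id")
    spec_off = lmm.ModelSpec(
        "mean_offspring_length", ("brood_size",) + covs, "individual_id"
    )
    spec_brood = lmm.ModelSpec(
        "brood_size", ("mean_offspring_length",) + covs, "individual_id"
    )
    raw_off = lmm.fit_lmm(
        brood_rows, lmm.ModelSpec("mean_offspring_length", (), "individual_id")
    )
    raw_brood = lmm.fit_lmm(
        brood_rows, lmm.ModelSpec("brood_size", (), "individual_id")
    )
    adj_off = lmm.fit_lmm(brood_rows, spec_off)
    adj_brood = lmm.fit_lmm(brood_rows, spec_brood)
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    return {
        "offspring_size_model": adj_off,
        "brood_size_model": adj_brood,
        "offspring_size_table": lmm.summary_table(adj_off),
        "brood_size_table": lmm.summary_table(adj_brood),
        "repeatability": {
            ("offspring_size", "raw"): lmm.simulate_ci(raw_off, n_sim, seeds[0]),
            ("offspring_size", "adjusted"): lmm.simulate_ci(
                adj_off, n_sim, seeds[1]
            ),
            ("brood_size", "raw"): lmm.simulate_ci(raw_brood, n_sim, seeds[2]),
            ("brood_size", "adjusted"): lmm.simulate_ci(
                adj_brood, n_sim, seeds[3]
            ),
        },
    }
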