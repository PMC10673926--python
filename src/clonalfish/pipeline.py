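"""End-to-end analysis pipeline.

Chains the stages of the individuality analysis: daily behavior metrics ->
behavioral repeatabilities -> individual growth curves -> reproductive
profiles and trade-off-adjusted repeatabilities -> the behavior/growth/
reproduction linkage models, producing a results bundle with full
provenance (seed, config hash, software version).

Every model selection step is stepwise-backward removal of non-significant
predictors at ``alpha`` with mother ID always protected, and female size at
parturition additionally protected in the direct behavior->reproduction
models.  Behavioral predictors in linkage models are per-individual means
over the observation days.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import lmm, reproduction
from .errors import AlignmentError, ValidationError
from .synthetic import SimConfig, simulate_dataset
from .trajectory import ZoneSpec, summarize_trajectories, validate_behavior_table

logger = logging.getLogger(__name__)

PROTECTED_ALWAYS = frozenset({"mother_id"})


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and options for a full pipeline run."""

    sizes_path: str
    broods_path: str
    offspring_path: str
    behavior_path: str | None = None
    trajectories_path: str | None = None
    zone: tuple[float, float, float, float] | None = None  # x, y, w, h
    step_s: float = 0.2
    alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 0
    out_dir: str = "results"
    log_activity: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_sim < 2:
            raise ValidationError("n_sim must be >= 2")
        if self.behavior_path is None and self.trajectories_path is None:
            raise ValidationError(
                "one of behavior_path or trajectories_path is required"
            )


@dataclass
class ResultsBundle:
    repeatability: pd.DataFrame
    models: dict[str, pd.DataFrame]
    growth_fits: pd.DataFrame
    profiles: pd.DataFrame
    activity_feeding: dict
    k_linf: dict
    provenance: dict
    final_specs: dict = field(default_factory=dict)


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _rep_row(est: lmm.RepeatabilityEstimate, trait: str) -> dict:
    return {
        "trait": trait,
        "kind": est.kind,
        "R": est.R,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "significant": est.significant,
        "n_sim": est.n_sim,
        "seed": est.seed,
        "n_obs": est.n_obs,
        "n_groups": est.n_groups,
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_behavior_stage(
    behavior: pd.DataFrame,
    growth_fits: dict[str, growth_mod.GrowthFit],
    n_sim: int = 1000,
    seed: int | None = None,
    log_activity: bool = True,
) -> dict:
    """Behavioral repeatabilities (raw + adjusted) and the activity~feeding
    model.

    Adjusted models control for size (growth-curve-predicted size at each
    day), age class (weeks 1-4 as a categorical factor) and their
    interaction.  Activity is log-transformed for repeatability when
    ``log_activity`` is set.
    """
    behavior = validate_behavior_table(behavior).copy()
    behavior["age_class"] = "w" + np.ceil(
        behavior["day"] / 7.0
    ).astype(int).astype(str)
    size = np.full(len(behavior), np.nan)
    for i, (ind, day) in enumerate(
        zip(behavior["individual_id"], behavior["day"])
    ):
        fit = growth_fits.get(str(ind))
        if fit is not None and fit.converged:
            size[i] = growth_mod.predicted_size_at(fit, float(day))
    behavior["size_cm"] = size

    seeds = _spawn_seeds(seed, 5)
    adj_terms = ("size_cm", "age_class", "size_cm:age_class")
    specs = {
        ("activity", "raw"): lmm.ModelSpec(
            "activity_cm_per_s", (), "individual_id", log_response=log_activity
        ),
        ("activity", "adjusted"): lmm.ModelSpec(
            "activity_cm_per_s", adj_terms, "individual_id",
            log_response=log_activity,
        ),
        ("feeding", "raw"): lmm.ModelSpec(
            "feeding_min", (), "individual_id"
        ),
        ("feeding", "adjusted"): lmm.ModelSpec(
            "feeding_min", adj_terms, "individual_id"
        ),
    }
    rows = []
    for k, ((trait, kind), spec) in enumerate(specs.items()):
        fit = lmm.fit_lmm(behavior, spec)
        est = lmm.simulate_ci(fit, n_sim=n_sim, seed=seeds[k])
        rows.append(_rep_row(est, trait))

    af_spec = lmm.ModelSpec(
        "activity_cm_per_s", ("feeding_min",), "individual_id"
    )
    af_fit = lmm.fit_lmm(behavior, af_spec)
    marg, cond = lmm.r2_nakagawa(af_fit)
    return {
        "repeatability_rows": rows,
        "activity_feeding": {
            "fit": af_fit,
            "table": lmm.summary_table(af_fit),
            "r2_marginal": marg,
            "r2_conditional": cond,
        },
        "behavior": behavior,
    }


def run_growth_stage(sizes: pd.DataFrame, mother_ids: pd.Series) -> dict:
    """Individual von Bertalanffy fits plus the K--L_inf regression."""
    fits, fits_df = growth_mod.fit_vb_table(sizes)
    k_fit, k_table, k_r2 = growth_mod.k_linf_model(fits_df, mother_ids)
    return {
        "fits": fits,
        "fits_df": fits_df,
        "k_linf": {"fit": k_fit, "table": k_table, "r2": k_r2},
    }


def run_reproduction_stage(
    broods: pd.DataFrame,
    offspring: pd.DataFrame,
    growth_fits: dict[str, growth_mod.GrowthFit],
    n_sim: int = 1000,
    seed: int | None = None,
) -> dict:
    """Profiles, cumulative curves, trade-off models, reproductive
    repeatabilities."""
    profiles, brood_rows = reproduction.build_profiles(
        broods, offspring, growth_fits
    )
    trade = reproduction.tradeoff_models(brood_rows, n_sim=n_sim, seed=seed)
    rep_rows = [
        _rep_row(est, trait)
        for (trait, _), est in trade["repeatability"].items()
    ]
    return {
        "profiles": profiles,
        "brood_rows": brood_rows,
        "tradeoff": trade,
        "repeatability_rows": rep_rows,
        "profile_summary": reproduction.profile_summary(profiles),
    }


def _align_individuals(*index_sets: tuple[str, set[str]]) -> set[str]:
    """Intersect individual sets across stages; log dropped ids."""
    common = None
    for name, ids in index_sets:
        common = set(ids) if common is None else common & set(ids)
    for name, ids in index_sets:
        dropped = sorted(set(ids) - common)
        if dropped:
            logger.info("linkage: dropping %s (only in %s)", dropped, name)
    if len(common) < 5:
        offenders = {
            name: sorted(set(ids) ^ common) for name, ids in index_sets
        }
        raise AlignmentError(
            f"fewer than 5 individuals shared across stages; offenders: {offenders}"
        )
    return common


def run_linkage_stage(
    behavior: pd.DataFrame,
    fits_df: pd.DataFrame,
    brood_rows: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Behavior -> growth -> reproduction model chain.

    Three groups of stepwise-selected models:
    direct (behavioral means as predictors of brood size, offspring size and
    onset), growth (L_inf and K on behavioral means), and growth ->
    reproduction (brood size, offspring size, onset on K and L_inf).
    """
    means = behavior.groupby("individual_id").agg(
        mean_activity=("activity_cm_per_s", "mean"),
        mean_feeding=("feeding_min", "mean"),
    ).reset_index()
    conv = fits_df[fits_df["converged"]]
    mothers = brood_rows.drop_duplicates("individual_id").set_index(
        "individual_id"
    )["mother_id"]
    common = _align_individuals(
        ("behavior", set(means["individual_id"].astype(str))),
        ("growth", set(conv["individual_id"].astype(str))),
        ("reproduction", set(brood_rows["individual_id"].astype(str))),
    )
    means = means[means["individual_id"].astype(str).isin(common)]
    conv = conv[conv["individual_id"].astype(str).isin(common)]
    brood_rows = brood_rows[
        brood_rows["individual_id"].astype(str).isin(common)
    ]

    ind = means.merge(
        conv[["individual_id", "L_inf", "K"]], on="individual_id"
    )
    ind["mother_id"] = ind["individual_id"].map(mothers).astype(str)
    onset = brood_rows.drop_duplicates("individual_id")[
        ["individual_id", "onset"]
    ]
    ind = ind.merge(onset, on="individual_id")
    brows = brood_rows.merge(
        means, on="individual_id"
    ).merge(conv[["individual_id", "L_inf", "K"]], on="individual_id")

    behav = ("mean_activity", "mean_feeding")
    size_prot = PROTECTED_ALWAYS | {"female_size_at_parturition"}
    model_defs = {
        "direct_offspring_size": (
            brows,
            lmm.ModelSpec(
                "mean_offspring_length",
                behav + ("female_size_at_parturition", "mother_id"),
                "individual_id",
            ),
            size_prot,
        ),
        "direct_brood_size": (
            brows,
            lmm.ModelSpec(
                "brood_size",
                behav + ("female_size_at_parturition", "mother_id"),
                "individual_id",
            ),
            size_prot,
        ),
        "direct_onset": (
            ind,
            lmm.ModelSpec("onset", behav + ("mother_id",), None),
            PROTECTED_ALWAYS,
        ),
        "growth_linf": (
            ind,
            lmm.ModelSpec("L_inf", behav + ("mother_id",), None),
            PROTECTED_ALWAYS,
        ),
        "growth_k": (
            ind,
            lmm.ModelSpec("K", behav + ("L_inf", "mother_id"), None),
            PROTECTED_ALWAYS | {"L_inf"},
        ),
        "growth_offspring_size": (
            brows,
            lmm.ModelSpec(
                "mean_offspring_length",
                ("K", "L_inf", "age_at_parturition_days", "mother_id"),
                "individual_id",
            ),
            PROTECTED_ALWAYS,
        ),
        "growth_brood_size": (
            brows,
            lmm.ModelSpec(
                "brood_size",
                ("K", "L_inf", "age_at_parturition_days", "mother_id"),
                "individual_id",
            ),
            PROTECTED_ALWAYS,
        ),
        "growth_onset": (
            ind,
            lmm.ModelSpec("onset", ("K", "L_inf", "mother_id"), None),
            PROTECTED_ALWAYS,
        ),
    }
    out = {}
    for name, (data, spec, protected) in model_defs.items():
        final_spec, fit, removed = lmm.stepwise_backward(
            data, spec, alpha=alpha, protected=protected
        )
        out[name] = {
            "spec": final_spec,
            "fit": fit,
            "table": lmm.summary_table(fit),
            "removed": removed,
        }
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_tables(
    behavior: pd.DataFrame,
    sizes: pd.DataFrame,
    broods: pd.DataFrame,
    offspring: pd.DataFrame,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    log_activity: bool = True,
    provenance_extra: dict | None = None,
) -> ResultsBundle:
    """Run the full in-memory analysis on tidy tables."""
    t_start = time.perf_counter()
    stage_seeds = _spawn_seeds(seed, 2)
    timings = {}

    t0 = time.perf_counter()
    mothers = broods.drop_duplicates("individual_id").set_index(
        "individual_id"
    )["mother_id"]
    g = run_growth_stage(sizes, mothers)
    timings["growth_s"] = time.perf_counter() - t0
    logger.info("growth stage: %d fits", len(g["fits_df"]))

    t0 = time.perf_counter()
    b = run_behavior_stage(
        behavior, g["fits"], n_sim=n_sim, seed=stage_seeds[0],
        log_activity=log_activity,
    )
    timings["behavior_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    r = run_reproduction_stage(
        broods, offspring, g["fits"], n_sim=n_sim, seed=stage_seeds[1]
    )
    timings["reproduction_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    linkage = run_linkage_stage(
        b["behavior"], g["fits_df"], r["brood_rows"], alpha=alpha
    )
    timings["linkage_s"] = time.perf_counter() - t0
    timings["total_s"] = time.perf_counter() - t_start

    rep = pd.DataFrame(b["repeatability_rows"] + r["repeatability_rows"])
    models = {name: res["table"] for name, res in linkage.items()}
    models["activity_feeding"] = b["activity_feeding"]["table"]
    models["tradeoff_offspring_size"] = r["tradeoff"]["offspring_size_table"]
    models["tradeoff_brood_size"] = r["tradeoff"]["brood_size_table"]
    models["k_linf"] = g["k_linf"]["table"]

    from . import __version__

    provenance = {
        "seed": seed,
        "n_sim": n_sim,
        "alpha": alpha,
        "log_activity": log_activity,
        "version": __version__,
        "n_individuals": int(behavior["individual_id"].nunique()),
        "n_behavior_rows": int(len(behavior)),
        "n_broods": int(len(broods)),
        "n_offspring": int(len(offspring)),
        "timings": {k: round(v, 3) for k, v in timings.items()},
    }
    if provenance_extra:
        provenance.update(provenance_extra)
    return ResultsBundle(
        repeatability=rep,
        models=models,
        growth_fits=g["fits_df"],
        profiles=r["profile_summary"],
        activity_feeding={
            "r2_marginal": b["activity_feeding"]["r2_marginal"],
            "r2_conditional": b["activity_feeding"]["r2_conditional"],
        },
        k_linf={"r2": g["k_linf"]["r2"]},
        provenance=provenance,
        final_specs={
            name: res["spec"].formula for name, res in linkage.items()
        },
    )


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: AnalysisConfig) -> ResultsBundle:
    """Read input tables per ``config``, run every stage, write the bundle."""
    sizes = pd.read_csv(config.sizes_path)
    broods = pd.read_csv(config.broods_path)
    offspring = pd.read_csv(config.offspring_path)
    if config.behavior_path is not None:
        behavior = pd.read_csv(config.behavior_path)
    else:
        traj = pd.read_csv(config.trajectories_path)
        if config.zone is not None:
            x, y, w, h = config.zone
            zone = ZoneSpec(x, y, w, h)
        else:
            zone = ZoneSpec(
                x_min=(traj["x_cm"].max() - 5.0) / 2.0, y_min=0.0
            )
        behavior = summarize_trajectories(traj, zone, step_s=config.step_s)

    bundle = analyze_tables(
        behavior, sizes, broods, offspring,
        alpha=config.alpha, n_sim=config.n_sim, seed=config.seed,
        log_activity=config.log_activity,
        provenance_extra={"config_hash": _config_hash(config)},
    )
    write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    bundle.repeatability.to_csv(out / "repeatability.csv", index=False)
    bundle.growth_fits.to_csv(out / "growth_fits.csv", index=False)
    bundle.profiles.to_csv(out / "profiles.csv", index=False)
    for name, table in bundle.models.items():
        table.to_csv(out / "models" / f"{name}.csv", index=False)
    summary = {
        "provenance": bundle.provenance,
        "repeatability": bundle.repeatability.to_dict(orient="records"),
        "final_model_formulas": bundle.final_specs,
        "activity_feeding": bundle.activity_feeding,
        "k_linf": bundle.k_linf,
    }
    (out / "bundle.json").write_text(json.dumps(summary, indent=2, default=float))


def run_synthetic(
    sim_config: SimConfig | None = None,
    seed: int = 0,
    n_sim: int = 1000,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> tuple[ResultsBundle, dict[str, pd.DataFrame]]:
    """Simulate a cohort at ``sim_config`` and analyze it end to end."""
    cfg = sim_config or SimConfig(seed=seed)
    data = simulate_dataset(cfg, seed=seed)
    bundle = analyze_tables(
        data["behavior"], data["sizes"], data["broods"], data["offspring"],
        alpha=alpha, n_sim=n_sim, seed=seed,
        provenance_extra={"generator": "synthetic", "sim_seed": seed},
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle, data
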