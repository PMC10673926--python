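"""Synthetic clonal-cohort generator.

Emulates the structure of a life-history experiment on naturally clonal fish
reared individually in standardized tanks: 34 individuals observed daily over
their first 28 days (an 8-h activity phase followed by a 2-h feeding phase at
0.2 s sampling), weekly standard-length measurements to day 280, and a
sequence of broods (~30-day gestation) with counted and measured offspring.

The generative model mirrors the assumptions of the downstream analysis:

- latent individual effects for (log-)activity and feeding are drawn from a
  zero-mean bivariate normal with configurable variances and correlation
  (negative by default: active fish spend less time at the stationary food
  patch); independent latent effects drive brood size and offspring size;
- daily behavior = latent effect + age trend + within-individual noise, so
  repeatability of each trait is V_ID / (V_ID + V_res) by construction;
- asymptotic size L_inf increases with an individual's mean feeding time,
  and reproduction (onset, female size at parturition, offspring size)
  depends on growth -- giving the feeding -> growth -> offspring-size chain
  with no direct behavior -> reproduction effect;
- brood sizes are Poisson with a log-link on the individual effect and
  female size; offspring lengths trade off against brood size.

Trajectories are generated by a persistent-heading random walk with
reflecting walls whose per-day speed is exp(latent log-activity), and whose
feeding-phase heading is attracted to the feeding zone with strength
increasing in the latent feeding effect.  They are structurally, not
quantitatively, faithful to real tracks (no tank dimensions or movement
statistics are available to calibrate against).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .growth import VBParams, vb_length
from .trajectory import ZoneSpec


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    # cohort geometry
    n_individuals: int = 34
    n_days_behavior: int = 28
    horizon_days: int = 280
    n_mothers: int = 3

    # recording setup
    step_s: float = 0.2
    activity_phase_h: float = 8.0
    feeding_phase_h: float = 2.0
    arena_w_cm: float = 20.0
    arena_h_cm: float = 20.0
    zone_w_cm: float = 5.0
    zone_h_cm: float = 13.0

    # daily behavior (log-activity in log cm/s; feeding in minutes)
    mean_log_activity: float = math.log(2.5)
    V_ID_act: float = 0.15
    V_res_act: float = 0.25
    act_age_slope: float = 0.03        # per day, on log-activity
    mean_feeding_min: float = 30.0
    V_ID_feed: float = 25.0
    V_res_feed: float = 110.0
    feed_age_slope: float = -0.3       # min per day
    rho_act_feed: float = -0.5

    # trajectory mechanics
    base_speed_scale: float = 1.0
    heading_sd: float = 0.6            # rad per step
    feed_attraction_base: float = 0.3
    feed_attraction_scale: float = 5.0  # min of feeding effect per e-fold

    # growth (von Bertalanffy)
    vb_Linf_base: float = 4.9          # cm at zero mean feeding offset
    beta_feed_Linf: float = 0.02       # cm per minute of mean feeding
    linf_sd: float = 0.15
    vb_K_mean: float = 0.02            # per day
    vb_K_sd: float = 0.003
    t0_mean: float = -4.0
    t0_sd: float = 1.0
    size_noise_cm: float = 0.05

    # reproduction
    gestation_days: float = 30.0
    gestation_jitter_days: float = 3.0
    onset_base_days: float = 160.0
    onset_beta_linf: float = 55.0      # days per cm of L_inf
    onset_sd_days: float = 12.0
    onset_min_days: float = 60.0
    brood_size_log_mean: float = math.log(16.6)
    V_ID_broodsize: float = 0.013      # log scale
    beta_size_brood: float = 0.10      # log-brood-size per cm of female size
    offspring_base_cm: float = 0.95
    V_ID_offsize: float = 0.004
    tradeoff_slope: float = -0.013     # cm of offspring length per offspring
    beta_size_off: float = 0.6         # cm offspring length per cm female size
    offsize_brood_sd: float = 0.10     # brood-level residual SD
    offspring_within_sd: float = 0.06  # within-brood SD of lengths

    # dropout / measurement emulation (off by default)
    n_dropout_activity: int = 0
    n_dropout_feeding: int = 0
    p_brood_unmeasured: float = 0.0

    seed: int = 0

    def __post_init__(self):
        for name in (
            "V_ID_act", "V_res_act", "V_ID_feed", "V_res_feed",
            "V_ID_broodsize", "V_ID_offsize", "linf_sd", "vb_K_sd", "t0_sd",
            "size_noise_cm", "onset_sd_days", "offsize_brood_sd",
            "offspring_within_sd", "gestation_jitter_days",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if abs(self.rho_act_feed) > 1:
            raise ValidationError("rho_act_feed must satisfy |rho| <= 1")
        if self.step_s <= 0:
            raise ValidationError("step_s must be > 0")
        if self.zone_w_cm > self.arena_w_cm or self.zone_h_cm > self.arena_h_cm:
            raise ValidationError("zone must fit inside the arena")
        for name in (
            "n_individuals", "n_days_behavior", "horizon_days", "n_mothers",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.horizon_days < 7:
            raise ValidationError("horizon_days must be >= 7")
        if self.gestation_days <= 0:
            raise ValidationError("gestation_days must be > 0")
        if not 0 <= self.p_brood_unmeasured <= 1:
            raise ValidationError("p_brood_unmeasured must be in [0, 1]")
        if self.vb_K_mean <= 0:
            raise ValidationError("vb_K_mean must be > 0")

    @property
    def zone(self) -> ZoneSpec:
        """Feeding zone centred horizontally, flush with the lower wall."""
        return ZoneSpec(
            x_min=(self.arena_w_cm - self.zone_w_cm) / 2.0,
            y_min=0.0,
            width_cm=self.zone_w_cm,
            height_cm=self.zone_h_cm,
        )

    @property
    def expected_linf(self) -> float:
        return self.vb_Linf_base + self.beta_feed_Linf * self.mean_feeding_min

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class LatentIndividual:
    """Latent individual effects (zero-mean deviations) plus descent."""

    id: str
    u_act: float
    u_feed: float
    u_offsize: float
    u_broodsize: float
    mother_id: str


def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[LatentIndividual]:
    """Draw the latent cohort; reproducible under a fixed config seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    rho = config.rho_act_feed
    u_act = math.sqrt(config.V_ID_act) * z1
    u_feed = math.sqrt(config.V_ID_feed) * (
        rho * z1 + math.sqrt(1.0 - rho**2) * z2
    )
    u_off = math.sqrt(config.V_ID_offsize) * rng.standard_normal(n)
    u_brood = math.sqrt(config.V_ID_broodsize) * rng.standard_normal(n)
    width = len(str(n))
    return [
        LatentIndividual(
            id=f"F{i + 1:0{width}d}",
            u_act=float(u_act[i]),
            u_feed=float(u_feed[i]),
            u_offsize=float(u_off[i]),
            u_broodsize=float(u_brood[i]),
            mother_id=f"M{(i % config.n_mothers) + 1}",
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Daily behavior (calibrated path used by the statistical stages)
# ---------------------------------------------------------------------------

def simulate_behavior_table(
    cohort: list[LatentIndividual],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """DailyBehavior table drawn directly from the latent model.

    log-activity_ij = mean + age trend + u_act_i + e_ij with
    e ~ N(0, V_res_act); feeding_ij analogous on the minutes scale, truncated
    to the feeding-phase duration.  Optional dropout removes whole
    individual-day metric values (emulating corrupt recordings).
    """
    days = np.arange(1, config.n_days_behavior + 1)
    mid = days.mean()
    feed_max = config.feeding_phase_h * 60.0
    rows = []
    for ind in cohort:
        log_act = (
            config.mean_log_activity
            + config.act_age_slope * (days - mid)
            + ind.u_act
            + math.sqrt(config.V_res_act) * rng.standard_normal(len(days))
        )
        feed = (
            config.mean_feeding_min
            + config.feed_age_slope * (days - mid)
            + ind.u_feed
            + math.sqrt(config.V_res_feed) * rng.standard_normal(len(days))
        )
        feed = np.clip(feed, 0.0, feed_max)
        for j, day in enumerate(days):
            rows.append(
                {
                    "individual_id": ind.id,
                    "day": int(day),
                    "activity_cm_per_s": float(np.exp(log_act[j])),
                    "feeding_min": float(feed[j]),
                    "activity_duration_min": config.activity_phase_h * 60.0,
                    "feeding_duration_min": feed_max,
                }
            )
    behavior = pd.DataFrame(rows)
    for col, n_drop in (
        ("activity_cm_per_s", config.n_dropout_activity),
        ("feeding_min", config.n_dropout_feeding),
    ):
        if n_drop > 0:
            idx = rng.choice(len(behavior), size=n_drop, replace=False)
            behavior.loc[behavior.index[idx], col] = np.nan
    return behavior


# ---------------------------------------------------------------------------
# Trajectories (structural path; feeds the trajectory_metrics module)
# ---------------------------------------------------------------------------

def _fold(z: np.ndarray, width: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [0, width] (triangular fold)."""
    z = np.mod(z, 2.0 * width)
    return np.where(z > width, 2.0 * width - z, z)


def simulate_trajectory(
    ind: LatentIndividual,
    day: int,
    config: SimConfig,
    rng: np.random.Generator,
    day_log_act_resid: float | None = None,
    day_feed_resid: float | None = None,
) -> pd.DataFrame:
    """Simulate one individual-day track (activity phase then feeding phase).

    The walk moves at constant speed ``base_speed_scale * exp(log-activity)``
    with a persistent heading; during the feeding phase the heading is blended
    toward the feeding-zone centre with a weight that increases in the latent
    feeding effect.  Walls reflect.
    """
    if not 1 <= day <= config.n_days_behavior:
        raise ValidationError(
            f"day must be in [1, {config.n_days_behavior}], got {day}"
        )
    mid = (config.n_days_behavior + 1) / 2.0
    e_act = (
        math.sqrt(config.V_res_act) * rng.standard_normal()
        if day_log_act_resid is None else day_log_act_resid
    )
    e_feed = (
        math.sqrt(config.V_res_feed) * rng.standard_normal()
        if day_feed_resid is None else day_feed_resid
    )
    log_act = (
        config.mean_log_activity
        + config.act_age_slope * (day - mid)
        + ind.u_act
        + e_act
    )
    speed = config.base_speed_scale * math.exp(log_act)  # cm/s
    step_len = speed * config.step_s
    W, H = config.arena_w_cm, config.arena_h_cm
    zone = config.zone
    n_act = int(round(config.activity_phase_h * 3600.0 / config.step_s))
    n_feed = int(round(config.feeding_phase_h * 3600.0 / config.step_s))

    # activity phase: vectorised heading walk, folded into the arena
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    theta = theta0 + np.cumsum(rng.normal(0.0, config.heading_sd, n_act))
    x0, y0 = rng.uniform(0.2 * W, 0.8 * W), rng.uniform(0.2 * H, 0.8 * H)
    xs = _fold(x0 + np.cumsum(step_len * np.cos(theta)), W)
    ys = _fold(y0 + np.cumsum(step_len * np.sin(theta)), H)
    t_act = config.step_s * np.arange(1, n_act + 1)

    # feeding phase: sequential walk with attraction toward the zone centre
    att = config.feed_attraction_base * math.exp(
        min((ind.u_feed + e_feed) / config.feed_attraction_scale, 50.0)
    )
    w = att / (1.0 + att)
    cx = zone.x_min + zone.width_cm / 2.0
    cy = zone.y_min + zone.height_cm / 2.0
    xf = np.empty(n_feed)
    yf = np.empty(n_feed)
    x, y = (xs[-1], ys[-1]) if n_act else (x0, y0)
    th = float(theta[-1]) if n_act else theta0
    noise = rng.normal(0.0, config.heading_sd, n_feed)
    for i in range(n_feed):
        th = th + noise[i]
        dx, dy = math.cos(th), math.sin(th)
        gx, gy = cx - x, cy - y
        gn = math.hypot(gx, gy)
        if gn > 1e-12:
            dx = (1.0 - w) * dx + w * gx / gn
            dy = (1.0 - w) * dy + w * gy / gn
            dn = math.hypot(dx, dy)
            if dn > 1e-12:
                dx, dy = dx / dn, dy / dn
        x += step_len * dx
        y += step_len * dy
        th = math.atan2(dy, dx)  # heading follows the blended direction
        if x < 0.0 or x > W:
            x = min(max(-x if x < 0 else 2 * W - x, 0.0), W)
            th = math.pi - th
        if y < 0.0 or y > H:
            y = min(max(-y if y < 0 else 2 * H - y, 0.0), H)
            th = -th
        xf[i], yf[i] = x, y
    t_feed = t_act[-1] + config.step_s * np.arange(1, n_feed + 1) if n_act else (
        config.step_s * np.arange(1, n_feed + 1)
    )
    return pd.DataFrame(
        {
            "individual_id": ind.id,
            "day": day,
            "phase": ["activity"] * n_act + ["feeding"] * n_feed,
            "t_s": np.concatenate([t_act, t_feed]),
            "x_cm": np.concatenate([xs, xf]),
            "y_cm": np.concatenate([ys, yf]),
        }
    )


def simulate_trajectory_table(
    cohort: list[LatentIndividual],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tracks for every individual-day (use a scaled-down config)."""
    parts = [
        simulate_trajectory(ind, day, config, rng)
        for ind in cohort
        for day in range(1, config.n_days_behavior + 1)
    ]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Growth and reproduction
# ---------------------------------------------------------------------------

def simulate_growth(
    ind: LatentIndividual,
    mean_feeding: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, VBParams]:
    """Weekly size records from an individual von Bertalanffy curve.

    L_inf increases with the individual's mean feeding time
    (``beta_feed_Linf`` cm per minute) plus individual noise; measurement
    noise is added on top of the exact curve.  Returns the records and the
    true parameters.
    """
    linf = (
        config.vb_Linf_base
        + config.beta_feed_Linf * mean_feeding
        + config.linf_sd * rng.standard_normal()
    )
    if linf <= 0:
        raise ValidationError(
            f"{ind.id}: simulated L_inf <= 0; check vb_Linf_base/beta_feed_Linf"
        )
    k = max(config.vb_K_mean + config.vb_K_sd * rng.standard_normal(), 1e-4)
    t0 = config.t0_mean + config.t0_sd * rng.standard_normal()
    params = VBParams(float(linf), float(k), float(t0))
    ages = np.arange(7, config.horizon_days + 1, 7, dtype=float)
    lengths = vb_length(ages, params) + config.size_noise_cm * rng.standard_normal(
        len(ages)
    )
    lengths = np.maximum(lengths, 0.05)
    return (
        pd.DataFrame(
            {
                "individual_id": ind.id,
                "age_days": ages,
                "length_cm": lengths,
            }
        ),
        params,
    )


def simulate_reproduction(
    ind: LatentIndividual,
    params: VBParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Brood sequence and offspring lengths for one female.

    Onset increases with L_inf (larger fish start reproducing later);
    successive broods follow at ~gestation_days intervals until the horizon.
    Brood size is Poisson with a log-link on the individual effect and female
    size at parturition; offspring lengths are normal around a mean tied to
    the individual effect, the brood-size trade-off, and female size.
    Returns (broods, offspring) tables; both empty if onset > horizon.
    """
    linf_ref = config.expected_linf
    size_ref = 0.97 * linf_ref  # typical female size over the parturition ages
    brood_ref = math.exp(config.brood_size_log_mean)
    onset = (
        config.onset_base_days
        + config.onset_beta_linf * (params.L_inf - linf_ref)
        + config.onset_sd_days * rng.standard_normal()
    )
    onset = max(onset, config.onset_min_days)
    brood_rows, off_rows = [], []
    age = onset
    k = 0
    while age <= config.horizon_days:
        k += 1
        size_at_part = max(vb_length(age, params), 0.0)
        lam = math.exp(
            config.brood_size_log_mean
            + ind.u_broodsize
            + config.beta_size_brood * (size_at_part - size_ref)
        )
        brood_size = max(int(rng.poisson(lam)), 1)
        measured = rng.uniform() >= config.p_brood_unmeasured
        brood_id = f"{ind.id}_b{k}"
        brood_rows.append(
            {
                "brood_id": brood_id,
                "individual_id": ind.id,
                "mother_id": ind.mother_id,
                "age_at_parturition_days": float(age),
                "brood_size": brood_size,
            }
        )
        if measured:
            mu = (
                config.offspring_base_cm
                + ind.u_offsize
                + config.tradeoff_slope * (brood_size - brood_ref)
                + config.beta_size_off * (size_at_part - size_ref)
                + config.offsize_brood_sd * rng.standard_normal()
            )
            lengths = np.maximum(
                mu + config.offspring_within_sd * rng.standard_normal(brood_size),
                0.05,
            )
            for L in lengths:
                off_rows.append(
                    {
                        "brood_id": brood_id,
                        "individual_id": ind.id,
                        "age_at_parturition_days": float(age),
                        "offspring_length_cm": float(L),
                    }
                )
        age += config.gestation_days + rng.uniform(
            -config.gestation_jitter_days, config.gestation_jitter_days
        )
    brood_cols = [
        "brood_id", "individual_id", "mother_id",
        "age_at_parturition_days", "brood_size",
    ]
    off_cols = [
        "brood_id", "individual_id", "age_at_parturition_days",
        "offspring_length_cm",
    ]
    return (
        pd.DataFrame(brood_rows, columns=brood_cols),
        pd.DataFrame(off_rows, columns=off_cols),
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate a full cohort dataset (no trajectories; the behavior table is
    drawn directly from the latent model).

    Returns behavior, sizes, broods, offspring and a truth table holding the
    latent effects and true growth parameters per individual.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = simulate_cohort(config, rng)
    behavior = simulate_behavior_table(cohort, config, rng)
    mean_feed = behavior.groupby("individual_id")["feeding_min"].mean()
    sizes_parts, brood_parts, off_parts, truth_rows = [], [], [], []
    for ind in cohort:
        records, params = simulate_growth(
            ind, float(mean_feed[ind.id]), config, rng
        )
        sizes_parts.append(records)
        broods, offspring = simulate_reproduction(ind, params, config, rng)
        brood_parts.append(broods)
        off_parts.append(offspring)
        truth_rows.append(
            {
                "individual_id": ind.id,
                "mother_id": ind.mother_id,
                "u_act": ind.u_act,
                "u_feed": ind.u_feed,
                "u_offsize": ind.u_offsize,
                "u_broodsize": ind.u_broodsize,
                "L_inf_true": params.L_inf,
                "K_true": params.K,
                "t0_true": params.t0,
            }
        )
    def _concat(parts: list[pd.DataFrame]) -> pd.DataFrame:
        nonempty = [p for p in parts if len(p)]
        return (
            pd.concat(nonempty, ignore_index=True) if nonempty else parts[0]
        )

    return {
        "behavior": behavior,
        "sizes": _concat(sizes_parts),
        "broods": _concat(brood_parts),
        "offspring": _concat(off_parts),
        "truth": pd.DataFrame(truth_rows),
    }


def write_dataset(data: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in data.items():
        df.to_csv(out / f"{name}.csv", index=False)
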