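"""Synthetic multi-group right-censored survival cohorts.

Cohorts are drawn from a Weibull proportional-hazards model. Subject ``i``
in group ``g`` has hazard multiplier ``exp(x_i' beta + group_log_hr[g])`` on
a per-group Weibull baseline; latent event times come from the
inverse-transform

    T_i = scale_g * (-log U / exp(eta_i)) ** (1 / shape_g),

censoring is the minimum of an exponential time and an administrative
horizon, and the observed data are ``(min(T, C), 1[T <= C])``.

The sensitive-attribute effect enters the hazard ONLY through
``group_log_hr`` — the group label itself is never a covariate column,
mirroring cohorts where the protected attribute shifts outcomes but is
excluded from predictors. Covariate *distributions* may still differ by
group (``group_feature_shift``): such proxy columns are what lets any
group-blind model, fair or not, react to group structure at all, emulating
the socioeconomic and clinical proxies present in registry data.

Latent times and censoring use two independent random streams spawned from
the seed, so changing the censoring configuration leaves latent event times
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import SurvivalCohort

DEFAULT_GROUP_NAMES = ("White", "Black", "Hispanic", "Asian", "Other")

# Registry race/ethnicity mix: 78.5% / 13.2% / 4.5% / 1.9% / 2.0%.
# The printed percentages sum to 100.1%; stored renormalized.
_RAW_NCDB_PROPS = np.array([0.785, 0.132, 0.045, 0.019, 0.020])
NCDB_GROUP_PROBS = _RAW_NCDB_PROPS / _RAW_NCDB_PROPS.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Weibull proportional-hazards cohort generator.

    ``group_probs`` are the group membership probabilities (length K, sum 1);
    ``baseline_shape``/``baseline_scale`` the per-group Weibull parameters
    (scalars are broadcast); ``beta`` the log-hazard covariate coefficients;
    ``group_log_hr`` per-group log hazard ratios with group 1 the reference;
    ``group_feature_shift`` an optional (K, p) matrix of group-dependent
    covariate mean shifts (proxy structure); ``censor_rate`` the exponential
    censoring rate and ``admin_time`` the administrative horizon.
    """

    n: int
    group_probs: np.ndarray
    baseline_shape: np.ndarray
    baseline_scale: np.ndarray
    beta: np.ndarray
    group_log_hr: np.ndarray
    censor_rate: float = 0.0
    admin_time: float = np.inf
    group_feature_shift: np.ndarray | None = None
    group_frailty_sd: np.ndarray | None = None
    group_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.group_probs, dtype=float)
        K = probs.size
        if K == 0 or np.any(probs < 0) or probs.sum() == 0:
            raise ValueError("group_probs must be a nonempty nonnegative vector")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("group_probs must sum to 1 (renormalize first)")
        shape = np.broadcast_to(np.asarray(self.baseline_shape, float), (K,)).copy()
        scale = np.broadcast_to(np.asarray(self.baseline_scale, float), (K,)).copy()
        if np.any(shape <= 0) or np.any(scale <= 0):
            raise ValueError("Weibull shapes and scales must be positive")
        beta = np.asarray(self.beta, dtype=float)
        loghr = np.asarray(self.group_log_hr, dtype=float)
        if loghr.shape != (K,):
            raise ValueError("group_log_hr must have one entry per group")
        if self.n < K:
            raise ValueError("n must be at least the number of groups")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")
        shift = self.group_feature_shift
        if shift is not None:
            shift = np.asarray(shift, dtype=float)
            if shift.shape != (K, beta.size):
                raise ValueError("group_feature_shift must be (K, p)")
        frailty = self.group_frailty_sd
        if frailty is not None:
            frailty = np.asarray(frailty, dtype=float)
            if frailty.shape != (K,) or np.any(frailty < 0):
                raise ValueError("group_frailty_sd must be a nonnegative K-vector")
        names = tuple(self.group_names) or tuple(f"group{k}" for k in range(1, K + 1))
        if len(names) != K:
            raise ValueError("group_names length must equal K")
        object.__setattr__(self, "group_probs", probs)
        object.__setattr__(self, "baseline_shape", shape)
        object.__setattr__(self, "baseline_scale", scale)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "group_log_hr", loghr)
        object.__setattr__(self, "group_feature_shift", shift)
        object.__setattr__(self, "group_frailty_sd", frailty)
        object.__setattr__(self, "group_names", names)

    @property
    def n_groups(self) -> int:
        return self.group_probs.size

    @property
    def p(self) -> int:
        return self.beta.size

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "group_probs": self.group_probs.tolist(),
            "baseline_shape": self.baseline_shape.tolist(),
            "baseline_scale": self.baseline_scale.tolist(),
            "beta": self.beta.tolist(),
            "group_log_hr": self.group_log_hr.tolist(),
            "censor_rate": self.censor_rate,
            "admin_time": self.admin_time if np.isfinite(self.admin_time) else None,
            "group_feature_shift": (
                None if self.group_feature_shift is None
                else self.group_feature_shift.tolist()
            ),
            "group_frailty_sd": (
                None if self.group_frailty_sd is None
                else self.group_frailty_sd.tolist()
            ),
            "group_names": list(self.group_names),
            "seed": self.seed,
        }


def linear_predictor(cfg: SimulationConfig, X: np.ndarray, group: np.ndarray) -> np.ndarray:
    """True log-hazard eta = X beta + group_log_hr[group] (group in 1..K)."""
    return X @ cfg.beta + cfg.group_log_hr[np.asarray(group) - 1]


def true_survival(
    cfg: SimulationConfig, X: np.ndarray, group: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Generative survival probabilities S_i(t), an (n, len(times)) matrix.

    Used as the oracle prediction in calibration tests: under the Weibull PH
    model S(t | x, g) = exp(-(t/scale_g)^shape_g * exp(eta)).
    """
    g = np.asarray(group) - 1
    eta = linear_predictor(cfg, X, group)
    t = np.asarray(times, dtype=float)[None, :]
    cum = (t / cfg.baseline_scale[g][:, None]) ** cfg.baseline_shape[g][:, None]
    return np.exp(-cum * np.exp(eta)[:, None])


def simulate_cohort(cfg: SimulationConfig) -> tuple[SurvivalCohort, np.ndarray]:
    """Draw a cohort; returns ``(cohort, latent_event_times)``.

    The latent (uncensored) event times are returned for oracle checks.
    """
    ss = np.random.SeedSequence(cfg.seed)
    latent_ss, censor_ss = ss.spawn(2)
    rng = np.random.default_rng(latent_ss)

    group = rng.choice(cfg.n_groups, size=cfg.n, p=cfg.group_probs) + 1
    X = rng.standard_normal((cfg.n, cfg.p))
    if cfg.group_feature_shift is not None:
        X = X + cfg.group_feature_shift[group - 1]
    eta = linear_predictor(cfg, X, group)
    g0 = group - 1
    if cfg.group_frailty_sd is not None:
        # withheld per-subject heterogeneity: shifts the hazard but never
        # appears in the covariate matrix (unexplainable by any model)
        z = rng.standard_normal(cfg.n)
        eta = eta + cfg.group_frailty_sd[g0] * z
    u = rng.uniform(size=cfg.n)
    latent = cfg.baseline_scale[g0] * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.baseline_shape[g0])

    crng = np.random.default_rng(censor_ss)
    if cfg.censor_rate > 0:
        cens = crng.exponential(1.0 / cfg.censor_rate, size=cfg.n)
    else:
        cens = np.full(cfg.n, np.inf)
    cens = np.minimum(cens, cfg.admin_time)

    time = np.minimum(latent, cens)
    event = (latent <= cens).astype(int)
    # guard against zero times from pathological configs (floating underflow)
    time = np.maximum(time, np.finfo(float).tiny)
    cohort = SurvivalCohort(
        time=time,
        event=event,
        group=group,
        covariates=X,
        feature_names=tuple(f"x{j}" for j in range(1, cfg.p + 1)),
        group_names=cfg.group_names,
    )
    return cohort, latent


def default_ncdb_like(seed: int = 0, n: int = 20_000) -> SimulationConfig:
    """Registry-like default configuration: 5 highly imbalanced groups.

    Group proportions follow the renormalized registry mix (majority 78.5%,
    smallest 1.9%). Group 2 carries a positive log hazard ratio (+0.5, lower
    survival); groups 3-5 mild negative ones (-0.2). Ten standard-normal
    covariates; five carry direct effects, and the last two are pure proxy
    columns (zero coefficient) whose means shift with group, so that a
    group-blind model can partially infer group membership — the structure
    fairness-aware objectives need to act on. Group 2 additionally carries
    withheld heterogeneity (frailty sd 0.6, comparable to the observed
    covariate signal): part of its hazard is driven by a covariate no model
    sees, so a model trained on the average loss under-serves this group.
    """
    p = 10
    beta = np.array([0.5, -0.5, 0.3, -0.3, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0])
    group_log_hr = np.array([0.0, 0.5, -0.2, -0.2, -0.2])
    shift = np.zeros((5, p))
    shift[:, 8] = [0.0, 0.8, -0.3, -0.3, -0.3]   # x9: strong group-2 proxy
    shift[:, 9] = [0.0, 0.5, 0.0, 0.0, 0.0]      # x10: weaker group-2 proxy
    return SimulationConfig(
        n=n,
        group_probs=NCDB_GROUP_PROBS,
        baseline_shape=1.1,
        baseline_scale=10.0,
        beta=beta,
        group_log_hr=group_log_hr,
        censor_rate=0.04,
        admin_time=15.0,
        group_feature_shift=shift,
        group_frailty_sd=np.array([0.0, 0.6, 0.0, 0.0, 0.0]),
        group_names=DEFAULT_GROUP_NAMES,
        seed=seed,
    )
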