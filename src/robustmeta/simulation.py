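"""Small-study-effects data generator and scenario runner.

Each simulated meta-analysis draws K studies reporting a mean difference

    β̂_j = β + b_j + σ_j ε_j,      σ_j = √(4 / n_j),

with n_j ~ Uniform(n1, n2) and ε_j a standard normal truncated to
(l_j, u_j). Two bias mechanisms are supported:

* type (a) — study-quality bias: a fraction δ of studies receives a fixed
  offset b_j that declines linearly with study size, from b_max at n = n1
  to zero at n ≥ N;
* type (b) — publication bias: studies below the size threshold N are
  published only if their one-sided p-value (against H0: effect ≤ 0)
  beats a size-dependent ceiling p_j, implemented as a lower truncation
  limit l_j = z_{1−p_j} − β/σ_j on ε_j. The severity profile p(n) can be
  linear, square-root, quadratic or a step in study size.

Seven standard scenarios mirror this design space: 1 = no bias, β = 0;
2 = type (a); 3–6 = type (b) with the four p(n) profiles; 7 = no bias
with β = 0.02 (power). The scenario runner applies any subset of the five
pooled estimators to each replicate and summarises bias, empirical and
model-based SE, coverage and rejection rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import comparators, estimators
from .data import StudySet

__all__ = [
    "SimulationConfig",
    "TruncationLimits",
    "ZembaProfile",
    "ScenarioSummary",
    "SCENARIOS",
    "draw_study_sizes",
    "type_a_bias",
    "type_b_limits",
    "selection_p",
    "simulate_meta",
    "zemba_profile",
    "run_scenario",
]

ESTIMATOR_NAMES = (
    "weighted_mean",
    "regression_extrapolation",
    "trim_and_fill",
    "weighted_median",
    "mbe",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the study-level data-generating mechanism.

    K            studies per meta-analysis
    beta         true average effect (mean-difference scale)
    n1, n2       study-size range, n_j ~ Uniform(n1, n2)
    bias_type    "none", "type_a" or "type_b"
    delta        proportion of biased studies (type (a))
    b_max        bias magnitude at n = n1 (type (a))
    N            size threshold beyond which bias vanishes
    selection_fn "linear" | "sqrt" | "quadratic" | "step" (type (b))
    p_min        strictest one-sided p-value ceiling, applied at n = n1
    fixed_count  type (a): flag exactly round(δK) studies instead of
                 independent Bernoulli(δ) draws
    """

    K: int = 10
    beta: float = 0.0
    n1: int = 100
    n2: int = 5000
    bias_type: str = "none"
    delta: float = 1.0
    b_max: float = 0.5
    N: int = 4500
    selection_fn: str = "linear"
    p_min: float = 0.05
    fixed_count: bool = False

    def __post_init__(self) -> None:
        if self.n1 >= self.n2:
            raise ValueError("need n1 < n2")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if self.N <= self.n1:
            raise ValueError("N must exceed n1")
        if not 0 < self.p_min <= 1:
            raise ValueError("p_min must be in (0, 1]")
        if self.bias_type not in ("none", "type_a", "type_b"):
            raise ValueError(f"unknown bias_type {self.bias_type!r}")
        if self.selection_fn not in ("linear", "sqrt", "quadratic", "step"):
            raise ValueError(f"unknown selection_fn {self.selection_fn!r}")


@dataclass(frozen=True)
class TruncationLimits:
    """Per-study truncation limits (l_j, u_j) for the error term."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower >= self.upper):
            raise ValueError("need l_j < u_j")


@dataclass(frozen=True)
class ZembaProfile:
    """Weight accounting for the zero-modal-bias assumption.

    ``satisfied`` is True when the zero-bias group carries strictly more
    standardized weight than any group of identically biased studies.
    """

    omega_0: float
    omega_max: float
    satisfied: bool


def draw_study_sizes(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw K study sizes uniformly on [n1, n2] and their SEs √(4/n)."""
    n = np.rint(rng.uniform(cfg.n1, cfg.n2, size=cfg.K)).astype(int)
    sigma = np.sqrt(4.0 / n)
    return n, sigma


def type_a_bias(
    n: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Fixed study-quality bias, linear in size, zero at n ≥ N.

    Each study is flagged biased with probability δ (or exactly
    round(δK) studies when ``fixed_count``); flagged studies get
    b = b_max · max(0, (N − n)/(N − n1)).
    """
    if cfg.fixed_count:
        m = int(round(cfg.delta * cfg.K))
        flags = np.zeros(cfg.K, dtype=bool)
        flags[rng.choice(cfg.K, size=m, replace=False)] = True
    else:
        flags = rng.uniform(size=cfg.K) < cfg.delta
    ramp = np.clip((cfg.N - n) / (cfg.N - cfg.n1), 0.0, None)
    return np.where(flags, cfg.b_max * ramp, 0.0)


def selection_p(n: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Maximum one-sided p-value permitting publication, as a function of n.

    Maps [n1, N] onto [p_min, 1] (clamped at 1 for n ≥ N): linear,
    square-root or quadratic in the scaled size t = (n − n1)/(N − n1), or
    a step (p_min below N, 1 at and above).
    """
    n = np.asarray(n, dtype=float)
    t = np.clip((n - cfg.n1) / (cfg.N - cfg.n1), 0.0, 1.0)
    if cfg.selection_fn == "linear":
        g = t
    elif cfg.selection_fn == "sqrt":
        g = np.sqrt(t)
    elif cfg.selection_fn == "quadratic":
        g = t**2
    else:  # step
        g = np.where(n >= cfg.N, 1.0, 0.0)
    p = cfg.p_min + (1.0 - cfg.p_min) * g
    return np.where(n >= cfg.N, 1.0, p)


def type_b_limits(
    n: np.ndarray, cfg: SimulationConfig, sigma: np.ndarray
) -> TruncationLimits:
    """Lower truncation limits implementing one-sided selective publication.

    l_j = z_{1−p_j} − β/σ_j, so a published estimate attains one-sided
    p ≤ p_j against H0: effect ≤ 0; l_j = −∞ once p_j = 1 (no selection).
    """
    p = selection_p(n, cfg)
    lower = np.where(
        p >= 1.0, -np.inf, stats.norm.ppf(1.0 - p) - cfg.beta / sigma
    )
    return TruncationLimits(lower=lower, upper=np.full(n.shape, np.inf))


def _truncated_normal(
    lower: np.ndarray, upper: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw from N(0,1) truncated to (lower, upper).

    Valid for arbitrarily extreme limits — no rejection loops.
    """
    a = special.ndtr(lower)
    b = special.ndtr(upper)
    u = rng.uniform(size=np.shape(lower))
    return special.ndtri(a + u * (b - a))


def simulate_meta(cfg: SimulationConfig, rng: np.random.Generator):
    """Generate one meta-analysis; returns (StudySet, truth dict).

    ``truth`` retains the hidden bias vector and truncation limits for
    diagnostics (e.g. the ZEMBA profile).
    """
    n, sigma = draw_study_sizes(cfg, rng)
    if cfg.bias_type == "type_a":
        b = type_a_bias(n, cfg, rng)
        limits = TruncationLimits(
            lower=np.full(cfg.K, -np.inf), upper=np.full(cfg.K, np.inf)
        )
    elif cfg.bias_type == "type_b":
        b = np.zeros(cfg.K)
        limits = type_b_limits(n, cfg, sigma)
    else:
        b = np.zeros(cfg.K)
        limits = TruncationLimits(
            lower=np.full(cfg.K, -np.inf), upper=np.full(cfg.K, np.inf)
        )
    eps = _truncated_normal(limits.lower, limits.upper, rng)
    est = cfg.beta + b + sigma * eps
    data = StudySet(estimates=est, std_errors=sigma, sizes=n)
    truth = {"bias": b, "lower": limits.lower, "upper": limits.upper}
    return data, truth


def zemba_profile(bias: np.ndarray, weights: np.ndarray) -> ZembaProfile:
    """Summed weights of the zero-bias group vs identically-biased groups."""
    bias = np.asarray(bias, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    omega_0 = float(w[bias == 0.0].sum())
    nonzero = np.unique(bias[bias != 0.0])
    omega_max = max((float(w[bias == v].sum()) for v in nonzero), default=0.0)
    return ZembaProfile(
        omega_0=omega_0, omega_max=omega_max, satisfied=omega_0 > omega_max
    )


# ---------------------------------------------------------------------------
# Scenario runner

#: Table of standard scenarios: configuration deltas applied on top of the
#: base SimulationConfig.
SCENARIOS: dict[int, dict] = {
    1: {"bias_type": "none", "beta": 0.0},
    2: {"bias_type": "type_a", "beta": 0.0, "delta": 1.0, "b_max": 0.5, "N": 5000},
    3: {"bias_type": "type_b", "beta": 0.0, "selection_fn": "linear"},
    4: {"bias_type": "type_b", "beta": 0.0, "selection_fn": "sqrt"},
    5: {"bias_type": "type_b", "beta": 0.0, "selection_fn": "quadratic"},
    6: {"bias_type": "type_b", "beta": 0.0, "selection_fn": "step"},
    7: {"bias_type": "none", "beta": 0.02},
}


@dataclass
class ScenarioSummary:
    """Per-estimator performance over the replicates of one scenario.

    ``table`` has one row per estimator with columns mean_estimate, bias,
    empirical_se (SD of the point estimates), mean_model_se, coverage
    (fraction of CIs containing β), rejection_rate (fraction excluding 0)
    and n_ok (replicates where the estimator succeeded). ``mean_i2`` and
    ``mean_gamma`` average the replicate diagnostics.
    """

    scenario: int
    config: SimulationConfig
    reps: int
    seed: int
    table: pd.DataFrame
    mean_i2: float
    mean_gamma: float
    failures: dict = field(default_factory=dict)
    replicates: pd.DataFrame | None = None


def scenario_config(scenario: int, **overrides) -> SimulationConfig:
    """Build the SimulationConfig for a standard scenario id (1–7)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be 1..7, got {scenario}")
    params = dict(SCENARIOS[scenario])
    params.update(overrides)
    return SimulationConfig(**params)


def _apply_estimator(name, data, boot_seed, n_boot, alpha):
    if name == "weighted_mean":
        return estimators.weighted_mean(data, alpha=alpha)
    if name == "weighted_median":
        spec = estimators.BootstrapSpec(n_boot=n_boot, seed=boot_seed)
        return estimators.weighted_median(data, spec, alpha=alpha)
    if name == "mbe":
        spec = estimators.BootstrapSpec(n_boot=n_boot, seed=boot_seed)
        return estimators.mode_based_estimate(data, spec, alpha=alpha)
    if name == "regression_extrapolation":
        return comparators.regression_extrapolation(data, alpha=alpha)
    if name == "trim_and_fill":
        return comparators.trim_and_fill(data, alpha=alpha).pooled
    raise ValueError(f"unknown estimator {name!r}")


def run_scenario(
    scenario: int,
    overrides: dict | None = None,
    estimator_names: Sequence[str] = ESTIMATOR_NAMES,
    reps: int = 10_000,
    seed: int = 0,
    n_boot: int = 1000,
    alpha: float = 0.05,
    keep_replicates: bool = False,
) -> ScenarioSummary:
    """Run one scenario: generate ``reps`` meta-analyses, apply estimators.

    Per-replicate RNG substreams are spawned from a single SeedSequence,
    so results are bit-reproducible for a given seed and independent of
    the estimator list. Estimator failures on a replicate are recorded
    and that replicate excluded from the failing estimator's summary.
    """
    cfg = scenario_config(scenario, **(overrides or {}))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    records: dict[str, list] = {name: [] for name in estimator_names}
    failures = {name: 0 for name in estimator_names}
    i2_vals, gamma_vals = [], []
    rep_rows = [] if keep_replicates else None

    for r in range(reps):
        child = children[r]
        rng = np.random.default_rng(child)
        data, _ = simulate_meta(cfg, rng)
        # bootstrap seed derived from the replicate's substream
        boot_seed = int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
        if data.k >= 3 and np.ptp(data.std_errors) > 0:
            diag = comparators.heterogeneity(data)
            i2_vals.append(diag.i_squared)
            if diag.gamma is not None:
                gamma_vals.append(diag.gamma)
        for name in estimator_names:
            try:
                res = _apply_estimator(name, data, boot_seed, n_boot, alpha)
            except Exception:
                failures[name] += 1
                continue
            covered = res.ci_low <= cfg.beta <= res.ci_high
            rejected = not (res.ci_low <= 0.0 <= res.ci_high)
            records[name].append(
                (res.estimate, res.std_error, covered, rejected)
            )
            if rep_rows is not None:
                rep_rows.append(
                    {
                        "replicate": r,
                        "estimator": name,
                        "estimate": res.estimate,
                        "se": res.std_error,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "covered": covered,
                        "rejected": rejected,
                    }
                )

    rows = []
    for name in estimator_names:
        arr = np.asarray(records[name], dtype=float)
        if arr.size == 0:
            rows.append(
                {
                    "estimator": name,
                    "mean_estimate": np.nan,
                    "bias": np.nan,
                    "empirical_se": np.nan,
                    "mean_model_se": np.nan,
                    "coverage": np.nan,
                    "rejection_rate": np.nan,
                    "n_ok": 0,
                }
            )
            continue
        rows.append(
            {
                "estimator": name,
                "mean_estimate": arr[:, 0].mean(),
                "bias": arr[:, 0].mean() - cfg.beta,
                "empirical_se": arr[:, 0].std(ddof=1) if arr.shape[0] > 1 else 0.0,
                "mean_model_se": arr[:, 1].mean(),
                "coverage": arr[:, 2].mean(),
                "rejection_rate": arr[:, 3].mean(),
                "n_ok": arr.shape[0],
            }
        )
    table = pd.DataFrame(rows).set_index("estimator")
    return ScenarioSummary(
        scenario=scenario,
        config=cfg,
        reps=reps,
        seed=seed,
        table=table,
        mean_i2=float(np.mean(i2_vals)) if i2_vals else np.nan,
        mean_gamma=float(np.mean(gamma_vals)) if gamma_vals else np.nan,
        failures=failures,
        replicates=pd.DataFrame(rep_rows) if rep_rows is not None else None,
    )
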