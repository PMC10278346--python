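"""Deterministic (one-way) and probabilistic sensitivity analysis.

Each model parameter carries a base value and a range — the published 95%
CI where one exists, otherwise ±20% of the base value. For the probabilistic
analysis the range is converted to a standard deviation via sd = (high −
low)/3.92 (symmetric normal-approximate CI) and a distribution is
moment-matched to (mean, sd): gamma for costs, beta for probabilities and
utilities, log-normal for doses, uniform on [low, high] for the discount
rate. Survival-model parameters are not sampled — the published distribution
table assigns no uncertainty to them — which is a known limitation.

Doses have no direct channel into the cycle model (the per-cycle TKI prices
are model inputs), so a sampled or perturbed dose scales the arm's TKI cost
per cycle proportionally (cost × dose/base-dose).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import ArmResult, accumulate_arm, compare
from .markov import ModelSpec, run_cohort

DISTRIBUTIONS = ("gamma", "beta", "lognormal", "uniform", "point")


@dataclass(frozen=True)
class ParamSpec:
    """One scalar model parameter with its base value, range and PSA family."""

    name: str
    base: float
    low: float
    high: float
    distribution: str
    from_ci: bool = True  # False = ±20% default range

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not 0.0 <= self.base <= 1.0:
            raise ValueError(f"{self.name}: beta requires a base in [0, 1]")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 3.92


def pm20(name: str, base: float, distribution: str) -> ParamSpec:
    """A parameter with the default ±20% range (no published CI)."""
    return ParamSpec(name, base, 0.8 * base, 1.2 * base, distribution, from_ci=False)


class _PointSampler:
    def __init__(self, value):
        self.value = value

    def __call__(self, rng, size=None):
        return self.value if size is None else np.full(size, self.value)


def parameterize_distribution(p: ParamSpec):
    """Moment-matched sampler ``f(rng, size)`` for one parameter.

    Degenerate ranges (sd = 0) give a point mass. A beta whose (mean, sd)
    imply non-positive shape parameters falls back to uniform on
    [low, high] with a warning.
    """
    mean, sd = p.base, p.sd
    if sd == 0.0 or p.distribution == "point":
        return _PointSampler(mean)
    if p.distribution == "gamma":
        shape = mean**2 / sd**2
        rate = mean / sd**2
        return lambda rng, size=None: rng.gamma(shape, 1.0 / rate, size)
    if p.distribution == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"{p.name}: beta mean must lie in (0, 1)")
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        alpha, beta = mean * nu, (1.0 - mean) * nu
        if alpha <= 0 or beta <= 0:
            warnings.warn(
                f"{p.name}: implied beta shapes non-positive "
                f"(alpha={alpha:.3g}, beta={beta:.3g}); falling back to "
                "uniform on the stated range",
                UserWarning,
                stacklevel=2,
            )
            return lambda rng, size=None: rng.uniform(p.low, p.high, size)
        return lambda rng, size=None: rng.beta(alpha, beta, size)
    if p.distribution == "lognormal":
        sigma2 = math.log1p(sd**2 / mean**2)
        mu = math.log(mean) - sigma2 / 2.0
        sigma = math.sqrt(sigma2)
        return lambda rng, size=None: rng.lognormal(mu, sigma, size)
    if p.distribution == "uniform":
        return lambda rng, size=None: rng.uniform(p.low, p.high, size)
    raise AssertionError(p.distribution)


def table_parameters(spec: ModelSpec) -> list[ParamSpec]:
    """The twelve tabulated parameters of the published one-way analysis.

    Arm-specific entries are named ``<quantity>_<arm name>``; ranges are the
    published 95% CIs (doses and the discount rate carry asymmetric /
    uniform ranges as tabulated).
    """
    a0, a1 = spec.arms
    return [
        ParamSpec(f"tki_cost_{a0.name}", a0.tki_cost_per_cycle, 116.0, 174.0, "gamma"),
        ParamSpec(f"tki_cost_{a1.name}", a1.tki_cost_per_cycle, 301.0, 451.0, "gamma"),
        ParamSpec(f"dose_{a0.name}", 300.0, 260.0, 340.0, "lognormal"),
        ParamSpec(f"dose_{a1.name}", 80.0, 40.0, 80.0, "lognormal"),
        ParamSpec(f"sae_cost_{a0.name}", a0.sae_cost_per_cycle, 713.0, 1785.0, "gamma"),
        ParamSpec(f"sae_cost_{a1.name}", a1.sae_cost_per_cycle, 893.0, 2232.0, "gamma"),
        ParamSpec("chemo_cost", spec.chemo_cost_total, 20_400.0, 34_000.0, "gamma"),
        ParamSpec("pd_cost", spec.pd_cost_onetime, 46_637.0, 155_458.0, "gamma"),
        ParamSpec("utility_pd", spec.utility_pd, 0.19, 0.30, "beta"),
        ParamSpec("utility_pfs", spec.utility_pfs, 0.43, 0.48, "beta"),
        ParamSpec("sae_probability", spec.sae_probability, 0.10, 0.30, "beta"),
        ParamSpec("discount_rate", spec.discount_rate, 0.0, 0.08, "uniform"),
    ]


def apply_overrides(spec: ModelSpec, values: dict[str, float],
                    params: list[ParamSpec] | None = None) -> ModelSpec:
    """Rebuild a spec with the named parameters overridden.

    Dose entries scale the matching arm's per-cycle TKI cost by
    value / base-dose (applied after any absolute TKI-cost override).
    """
    params = params if params is not None else table_parameters(spec)
    base = {p.name: p for p in params}
    unknown = set(values) - set(base)
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")

    shared: dict[str, float] = {}
    arm_costs = {a.name: {"tki": a.tki_cost_per_cycle, "sae": a.sae_cost_per_cycle}
                 for a in spec.arms}
    dose_scale = {a.name: 1.0 for a in spec.arms}
    for name, value in values.items():
        if name.startswith("tki_cost_"):
            arm_costs[name.removeprefix("tki_cost_")]["tki"] = value
        elif name.startswith("sae_cost_"):
            arm_costs[name.removeprefix("sae_cost_")]["sae"] = value
        elif name.startswith("dose_"):
            dose_scale[name.removeprefix("dose_")] = value / base[name].base
        elif name == "chemo_cost":
            shared["chemo_cost_total"] = value
        elif name == "pd_cost":
            shared["pd_cost_onetime"] = value
        else:  # utility_pfs, utility_pd, sae_probability, discount_rate
            shared[name] = value
    arms = tuple(
        replace(
            a,
            tki_cost_per_cycle=arm_costs[a.name]["tki"] * dose_scale[a.name],
            sae_cost_per_cycle=arm_costs[a.name]["sae"],
        )
        for a in spec.arms
    )
    return spec.replace(arms=arms, **shared)


def evaluate_spec(spec: ModelSpec) -> tuple[dict[str, ArmResult], "pd.DataFrame | None"]:
    """Run both arms and return per-arm results keyed by arm name."""
    results = {}
    for name in spec.arm_names:
        trace = run_cohort(spec, name)
        results[name] = accumulate_arm(trace, spec, name)
    return results, None


def one_way_dsa(spec: ModelSpec, params: list[ParamSpec] | None = None) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis over every parameter.

    Each parameter is set to its low and high limit in turn (others at
    base), both arms are rerun, and the comparison of the second arm versus
    the first is reported: ICER (NaN under dominance), dominance flag, WHO
    class, and the incremental NMB at the scenario WTP. ``nmb_spread`` is
    the tornado bar width on the incremental-NMB scale, which stays
    well-defined when dominance makes the ICER itself flip or vanish.
    """
    params = params if params is not None else table_parameters(spec)
    rows = []
    for p in params:
        row: dict = {"param": p.name, "base": p.base, "low": p.low, "high": p.high}
        nmbs = {}
        for side, value in (("low", p.low), ("high", p.high)):
            mod = apply_overrides(spec, {p.name: value}, params)
            results, _ = evaluate_spec(mod)
            a, b = (results[n] for n in mod.arm_names)
            cmp_ = compare(a, b, wtp=mod.wtp, gdp_per_capita=mod.gdp_per_capita)
            row[f"icer_{side}"] = cmp_.icer
            row[f"flag_{side}"] = cmp_.flag or "icer"
            row[f"who_class_{side}"] = cmp_.who_class
            nmbs[side] = cmp_.nmb_b - cmp_.nmb_a
            row[f"inc_nmb_{side}"] = nmbs[side]
        row["nmb_spread"] = abs(nmbs["high"] - nmbs["low"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PSAResult:
    """Per-iteration discounted (cost, QALY) pairs per arm."""

    arm_names: tuple[str, str]
    cost: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    seed: int
    n_redraws: int = 0

    @property
    def n_iter(self) -> int:
        return self.cost[self.arm_names[0]].size

    @property
    def inc_cost(self) -> np.ndarray:
        a, b = self.arm_names
        return self.cost[b] - self.cost[a]

    @property
    def inc_qaly(self) -> np.ndarray:
        a, b = self.arm_names
        return self.qaly[b] - self.qaly[a]

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations where arm b's NMB strictly exceeds arm a's.

        NMB_b > NMB_a ⟺ inc_cost < wtp·inc_qaly, which is also the
        below-the-WTP-line test on the cost-effectiveness plane.
        """
        return float(np.mean(self.inc_cost < wtp * self.inc_qaly))

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "iteration": np.arange(self.n_iter),
                    "arm": name,
                    "cost": self.cost[name],
                    "qaly": self.qaly[name],
                }
            )
            for name in self.arm_names
        ]
        return pd.concat(frames, ignore_index=True)


def run_psa(
    spec: ModelSpec,
    params: list[ParamSpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter distributions.

    Every parameter is drawn independently from its moment-matched sampler;
    shared parameters (utilities, chemotherapy cost, PD cost, SAE
    probability, discount rate) use one draw for both arms, arm-specific
    parameters their own. Out-of-support draws (utility above 1) are
    redrawn and counted. The state-occupancy traces depend only on the
    survival models — which carry no sampled uncertainty — so they are
    computed once per arm and re-costed per iteration.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    params = params if params is not None else table_parameters(spec)
    rng = np.random.default_rng(seed)
    samplers = {p.name: parameterize_distribution(p) for p in params}
    bounded = {p.name: (0.0, 1.0) for p in params
               if p.name.startswith("utility") or p.name == "sae_probability"}

    traces = {name: run_cohort(spec, name) for name in spec.arm_names}
    cost = {name: np.empty(n_iter) for name in spec.arm_names}
    qaly = {name: np.empty(n_iter) for name in spec.arm_names}
    n_redraws = 0
    for it in range(n_iter):
        draw: dict[str, float] = {}
        for name, sampler in samplers.items():
            value = float(sampler(rng))
            lo_hi = bounded.get(name)
            while lo_hi and not lo_hi[0] <= value <= lo_hi[1]:
                value = float(sampler(rng))
                n_redraws += 1
            draw[name] = value
        mod = apply_overrides(spec, draw, params)
        for name in spec.arm_names:
            res = accumulate_arm(traces[name], mod, name)
            cost[name][it] = res.total_cost
            qaly[name][it] = res.total_qaly
    return PSAResult(
        arm_names=spec.arm_names, cost=cost, qaly=qaly, seed=seed, n_redraws=n_redraws
    )


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve on a WTP grid."""
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    prob = [psa.prob_cost_effective(w) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def ce_plane(psa: PSAResult, wtp: float | None = None) -> pd.DataFrame:
    """Cost-effectiveness plane scatter (one row per iteration).

    ``below_wtp_line`` marks iterations with inc_cost < wtp·inc_qaly, i.e.
    exactly the iterations the CEAC counts at that WTP.
    """
    df = pd.DataFrame({"inc_qaly": psa.inc_qaly, "inc_cost": psa.inc_cost})
    if wtp is not None:
        df["below_wtp_line"] = df["inc_cost"] < wtp * df["inc_qaly"]
    return df


def quadrant_counts(psa: PSAResult) -> dict[str, int]:
    """CE-plane quadrant occupancy (NE, SE, SW, NW)."""
    dq, dc = psa.inc_qaly, psa.inc_cost
    return {
        "NE": int(np.sum((dq >= 0) & (dc >= 0))),
        "SE": int(np.sum((dq >= 0) & (dc < 0))),
        "SW": int(np.sum((dq < 0) & (dc < 0))),
        "NW": int(np.sum((dq < 0) & (dc >= 0))),
    }
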