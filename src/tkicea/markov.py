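"""Three-state (PFS / PD / Death) cohort model driven by survival curves.

The cohort is partitioned by the two fitted curves — partitioned-survival
closure: at any time t,

    PFS(t)  = S_EFS(t)
    Dead(t) = 1 − S_OS(t)
    PD(t)   = S_OS(t) − S_EFS(t)

The Markov transition rows are then solved each cycle so the trace lands
exactly on these memberships. The split of PFS exits between PD and Death is
not identified by the two curves alone, hence ``allocation_mode``:

* ``os-hazard`` — PFS→Death uses the overall-survival hazard over the cycle
  (capped by the total PFS exit) and the remainder enters PD;
* ``all-to-pd`` — every PFS exit passes through PD first (PFS→Death = 0).

Memberships (and therefore QALYs) are identical in the two modes; only the
flow of new PD entrants — which carries the one-time progression cost —
differs. PD→Death is solved in both modes to close the identity, clamped to
[0, 1] with a warning when digitization noise makes the closure infeasible.

Person-time uses a half-cycle (trapezoidal) correction and each cycle's
accruals are discounted at its midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .survival import SurvivalModel

AllocationMode = Literal["os-hazard", "all-to-pd"]
ALLOCATION_MODES: tuple[str, ...] = ("os-hazard", "all-to-pd")


@dataclass(frozen=True)
class ArmSpec:
    """Treatment-arm inputs: the two fitted curves and arm-specific costs."""

    name: str
    efs_model: SurvivalModel
    os_model: SurvivalModel
    tki_cost_per_cycle: float  # USD per 3-month cycle
    sae_cost_per_cycle: float  # USD per cycle of managing a severe adverse event


@dataclass(frozen=True)
class ModelSpec:
    """Complete economic scenario: two arms plus shared model parameters.

    Costs are USD, utilities per year in [0, 1], discount rate per year.
    ``treatment_cycles`` bounds the window over which chemotherapy and TKI
    costs accrue; ``chemo_cost_total`` is amortized uniformly over it.
    """

    arms: tuple[ArmSpec, ArmSpec]
    chemo_cost_total: float
    pd_cost_onetime: float
    sae_probability: float
    utility_pfs: float
    utility_pd: float
    discount_rate: float
    wtp: float
    gdp_per_capita: float
    cycle_years: float = 0.25
    n_cycles: int = 40
    treatment_cycles: int = 12
    allocation_mode: str = "os-hazard"

    def __post_init__(self):
        if not (0.0 <= self.utility_pd <= 1.0 and 0.0 <= self.utility_pfs <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be nonnegative")
        if self.cycle_years <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_years must be > 0 and n_cycles >= 1")
        if self.treatment_cycles > self.n_cycles:
            raise ValueError("treatment_cycles cannot exceed n_cycles")
        if self.allocation_mode not in ALLOCATION_MODES:
            raise ValueError(f"allocation_mode must be one of {ALLOCATION_MODES}")
        if min(self.chemo_cost_total, self.pd_cost_onetime) < 0:
            raise ValueError("costs must be nonnegative")
        if not 0.0 <= self.sae_probability <= 1.0:
            raise ValueError("sae_probability must lie in [0, 1]")

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_years

    @property
    def arm_names(self) -> tuple[str, str]:
        return tuple(a.name for a in self.arms)

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}; arms are {self.arm_names}")

    def replace(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "chemo_cost_total": self.chemo_cost_total,
            "pd_cost_onetime": self.pd_cost_onetime,
            "sae_probability": self.sae_probability,
            "utility_pfs": self.utility_pfs,
            "utility_pd": self.utility_pd,
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
            "gdp_per_capita": self.gdp_per_capita,
            "cycle_years": self.cycle_years,
            "n_cycles": self.n_cycles,
            "treatment_cycles": self.treatment_cycles,
            "allocation_mode": self.allocation_mode,
            "arms": [
                {
                    "name": a.name,
                    "efs_model": {"family": a.efs_model.family,
                                  "params": list(a.efs_model.params)},
                    "os_model": {"family": a.os_model.family,
                                 "params": list(a.os_model.params)},
                    "tki_cost_per_cycle": a.tki_cost_per_cycle,
                    "sae_cost_per_cycle": a.sae_cost_per_cycle,
                }
                for a in self.arms
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        arms = tuple(
            ArmSpec(
                name=a["name"],
                efs_model=SurvivalModel(a["efs_model"]["family"],
                                        tuple(a["efs_model"]["params"])),
                os_model=SurvivalModel(a["os_model"]["family"],
                                       tuple(a["os_model"]["params"])),
                tki_cost_per_cycle=float(a["tki_cost_per_cycle"]),
                sae_cost_per_cycle=float(a["sae_cost_per_cycle"]),
            )
            for a in d["arms"]
        )
        kwargs = {k: v for k, v in d.items() if k != "arms"}
        return cls(arms=arms, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def state_memberships(efs_model: SurvivalModel, os_model: SurvivalModel, t: float):
    """(pfs, pd, dead) fractions at time t under partitioned-survival closure.

    Requires S_EFS(t) ≤ S_OS(t); small violations (crossing extrapolations)
    are clamped to PD = 0 with a warning.
    """
    s_efs = efs_model.survival(t)
    s_os = os_model.survival(t)
    if s_efs > s_os + 1e-12:
        warnings.warn(
            f"S_EFS({t:.4g}) = {s_efs:.6g} exceeds S_OS = {s_os:.6g}; "
            "clamping PD membership to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        s_efs = s_os
    return s_efs, s_os - s_efs, 1.0 - s_os


def build_transition_row(
    efs_model: SurvivalModel,
    os_model: SurvivalModel,
    k: int,
    cycle_years: float,
    mode: str = "os-hazard",
    state: tuple[float, float, float] | None = None,
) -> dict[str, float]:
    """Per-cycle transition probabilities for cycle k (time k·dt → (k+1)·dt).

    Death is absorbing; each origin state's probabilities sum to 1. PD→Death
    is solved so that applying the row to the cycle-k memberships reproduces
    the cycle-(k+1) partitioned-survival memberships exactly. ``state`` is
    the (pfs, pd, dead) occupancy the row will be applied to; it defaults to
    the analytic cycle-k memberships, but a cohort run passes its actual
    trace state so that any earlier clamping (possible in ``all-to-pd``
    mode, where an empty early PD pool cannot supply the required deaths)
    is corrected in later cycles rather than compounded.
    """
    if mode not in ALLOCATION_MODES:
        raise ValueError(f"unknown allocation mode {mode!r}")
    dt = cycle_years
    t = k * dt
    if state is None:
        pfs_k, pd_k, dead_k = state_memberships(efs_model, os_model, t)
    else:
        pfs_k, pd_k, dead_k = state
    _, _, dead_n = state_memberships(efs_model, os_model, t + dt)

    p_exit_pfs = efs_model.transition_probability(t, dt)
    if mode == "os-hazard":
        p_pfs_dead = min(os_model.transition_probability(t, dt), p_exit_pfs)
        p_pfs_pd = p_exit_pfs - p_pfs_dead
    else:  # all-to-pd
        p_pfs_dead = 0.0
        p_pfs_pd = p_exit_pfs

    required_pd_deaths = (dead_n - dead_k) - pfs_k * p_pfs_dead
    if pd_k > 1e-15:
        p_pd_dead = required_pd_deaths / pd_k
        if not -1e-9 <= p_pd_dead <= 1.0 + 1e-9:
            warnings.warn(
                f"cycle {k}: closure requires pd→dead = {p_pd_dead:.4g}; "
                "clamping to [0, 1]",
                RuntimeWarning,
                stacklevel=2,
            )
        p_pd_dead = min(max(p_pd_dead, 0.0), 1.0)
    else:
        p_pd_dead = 0.0
        if required_pd_deaths > 1e-12:
            # empty PD state cannot supply deaths; route them from PFS
            extra = required_pd_deaths / pfs_k if pfs_k > 0 else 0.0
            warnings.warn(
                f"cycle {k}: PD state empty but closure requires deaths; "
                "assigning them to pfs→dead",
                RuntimeWarning,
                stacklevel=2,
            )
            p_pfs_dead = min(p_pfs_dead + extra, p_exit_pfs)
            p_pfs_pd = p_exit_pfs - p_pfs_dead

    return {
        "pfs_pfs": 1.0 - p_exit_pfs,
        "pfs_pd": p_pfs_pd,
        "pfs_dead": p_pfs_dead,
        "pd_pd": 1.0 - p_pd_dead,
        "pd_dead": p_pd_dead,
    }


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one arm's simulated cohort.

    ``pfs``/``pd``/``dead`` are cycle-boundary membership fractions
    (length n_cycles + 1); ``pd_entrants`` is the fraction newly entering PD
    during each cycle; ``pfs_person_time``/``pd_person_time`` are trapezoidal
    (half-cycle-corrected) person-years per cycle; ``discount`` is the
    mid-cycle discount factor actually used for accrual.
    """

    arm: str
    cycle_years: float
    discount_rate: float
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    pd_entrants: np.ndarray
    allocation_mode: str = "os-hazard"
    clamp_warnings: int = 0

    @property
    def n_cycles(self) -> int:
        return self.pd_entrants.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_years

    @property
    def mid_times(self) -> np.ndarray:
        return (np.arange(self.n_cycles) + 0.5) * self.cycle_years

    @property
    def discount(self) -> np.ndarray:
        return (1.0 + self.discount_rate) ** (-self.mid_times)

    @property
    def pfs_person_time(self) -> np.ndarray:
        return 0.5 * (self.pfs[:-1] + self.pfs[1:]) * self.cycle_years

    @property
    def pd_person_time(self) -> np.ndarray:
        return 0.5 * (self.pd[:-1] + self.pd[1:]) * self.cycle_years

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        return pd.DataFrame(
            {
                "cycle": np.arange(n + 1),
                "t_years": self.times,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "pd_entrants": np.append(self.pd_entrants, np.nan),
                "discount_factor": np.append(self.discount, np.nan),
            }
        )


def run_cohort(spec: ModelSpec, arm: str) -> CohortTrace:
    """Run the cohort through ``spec.n_cycles`` cycles starting 100% in PFS."""
    a = spec.arm(arm)
    n = spec.n_cycles
    dt = spec.cycle_years
    pfs = np.zeros(n + 1)
    pd_ = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    entrants = np.zeros(n)
    pfs[0] = 1.0
    n_clamp = 0
    for k in range(n):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            row = build_transition_row(
                a.efs_model,
                a.os_model,
                k,
                dt,
                mode=spec.allocation_mode,
                state=(pfs[k], pd_[k], dead[k]),
            )
        n_clamp += len(caught)
        for w in caught:
            warnings.warn(w.message, w.category, stacklevel=2)
        entrants[k] = pfs[k] * row["pfs_pd"]
        pfs[k + 1] = pfs[k] * row["pfs_pfs"]
        pd_[k + 1] = pd_[k] * row["pd_pd"] + entrants[k]
        dead[k + 1] = dead[k] + pfs[k] * row["pfs_dead"] + pd_[k] * row["pd_dead"]
    return CohortTrace(
        arm=arm,
        cycle_years=dt,
        discount_rate=spec.discount_rate,
        pfs=pfs,
        pd=pd_,
        dead=dead,
        pd_entrants=entrants,
        allocation_mode=spec.allocation_mode,
        clamp_warnings=n_clamp,
    )
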