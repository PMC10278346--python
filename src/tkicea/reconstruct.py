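"""Pseudo individual-patient data from digitized Kaplan–Meier curves.

Published KM figures carry two pieces of information: the step-function
coordinates (time, survival) that can be digitized off the plot, and the
numbers-at-risk printed beneath it. The Guyot-style reconstruction inverts
the KM estimator interval by interval: within each span between consecutive
at-risk times it solves for integer event and censoring counts such that

* the running KM product matches the digitized survival value at every
  digitized time (to the 1/n quantization that integer counts force), and
* the implied number at risk at the next at-risk time matches the published
  count.

Censoring times inside an interval are placed at the midpoint between
adjacent digitized time points; subjects still at risk after the last
digitized time are administratively censored there. The procedure is fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class MonotonicityError(ValueError):
    """Digitized survival values increase over time."""


class RiskTableError(ValueError):
    """Numbers at risk increase over time or exceed the cohort size."""


class EmptyInputError(ValueError):
    """No usable digitized points / subjects."""


@dataclass
class DigitizedCurve:
    """Digitized KM coordinates plus the figure's at-risk table.

    ``points`` has columns (time_years, survival); ``risk_table`` has
    (time_years, n_at_risk). A (0, 1) anchor point is inserted if the
    digitization does not include one. ``total_n`` defaults to the first
    at-risk count.
    """

    points: pd.DataFrame
    risk_table: pd.DataFrame
    total_n: int = 0

    def __post_init__(self):
        pts = self.points[["time_years", "survival"]].astype(float).copy()
        pts = pts.sort_values("time_years", ignore_index=True)
        if len(pts) == 0:
            raise EmptyInputError("digitized curve has no points")
        if not (pts["time_years"].iloc[0] == 0.0 and pts["survival"].iloc[0] == 1.0):
            pts = pd.concat(
                [pd.DataFrame({"time_years": [0.0], "survival": [1.0]}), pts],
                ignore_index=True,
            )
        s = pts["survival"].to_numpy()
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise MonotonicityError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            raise MonotonicityError("digitized survival must be non-increasing in time")
        self.points = pts

        rt = self.risk_table[["time_years", "n_at_risk"]].copy()
        rt = rt.sort_values("time_years", ignore_index=True)
        if len(rt) == 0:
            raise EmptyInputError("risk table is empty")
        n = rt["n_at_risk"].to_numpy()
        if np.any(np.diff(n) > 0):
            raise RiskTableError("numbers at risk must be non-increasing")
        if self.total_n == 0:
            self.total_n = int(n[0])
        if n[0] > self.total_n:
            raise RiskTableError("first at-risk count exceeds total_n")
        self.risk_table = rt

    def write(self, points_path, risk_path) -> None:
        self.points.to_csv(points_path, index=False)
        self.risk_table.to_csv(risk_path, index=False)

    @classmethod
    def read(cls, points_path, risk_path, total_n: int = 0) -> "DigitizedCurve":
        return cls(
            points=pd.read_csv(points_path, comment="#"),
            risk_table=pd.read_csv(risk_path, comment="#"),
            total_n=total_n,
        )


@dataclass
class ReconstructedIPD:
    """Per-subject (time, event) records recovered from a digitized curve."""

    time: np.ndarray
    event: np.ndarray
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        order = np.argsort(self.time, kind="stable")
        self.time = self.time[order]
        self.event = self.event[order]

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(np.sum(self.event))

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_years": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReconstructedIPD":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_years"].to_numpy(), df["event"].to_numpy())


def _run_interval(
    n_start: int,
    km_start: float,
    times: np.ndarray,
    survs: np.ndarray,
    next_time: float,
    n_censor: int,
):
    """Step through one inter-risk-time interval with a fixed censor count.

    Censorings are spread as evenly as possible over the gaps following each
    digitized point, at the midpoint of each gap. Returns (events per point,
    censor times, n at risk at interval end, KM product at interval end).
    """
    k = times.size
    cens_per_gap = np.full(k, n_censor // k, dtype=int)
    cens_per_gap[: n_censor % k] += 1
    events = np.zeros(k, dtype=int)
    cens_times: list[float] = []
    n_risk = n_start
    km = km_start
    carry = 0.0  # fractional-event residual, so rounding cannot drift
    for i in range(k):
        if n_risk > 0 and km > 0:
            d_real = n_risk * (1.0 - survs[i] / km)
            d = int(round(d_real + carry))
            d = max(0, min(d, n_risk))
            carry += d_real - d
        else:
            d = 0
        if d > 0:
            km *= 1.0 - d / n_risk
        events[i] = d
        n_risk -= d
        c = min(cens_per_gap[i], n_risk)
        if c > 0:
            upper = times[i + 1] if i + 1 < k else next_time
            mid = 0.5 * (times[i] + upper) if upper > times[i] else times[i]
            cens_times.extend([mid] * c)
            n_risk -= c
    return events, cens_times, n_risk, km


def reconstruct_ipd(curve: DigitizedCurve) -> ReconstructedIPD:
    """Recover (time, event) records whose KM estimator matches ``curve``.

    Within each interval (r_j, r_{j+1}] between consecutive risk-table
    times, the integer censor count is solved by fixed-point iteration so
    that the implied number at risk just after r_{j+1} equals the published
    count (printed at-risk tables count subjects whose observed time
    exceeds the landmark); event counts follow from the digitized survival drops.
    Infeasible intervals (digitization noise) fall back to zero censorings,
    with the interval index recorded as a warning — survival drops carry
    more information than rounded at-risk counts, so events win.
    """
    if curve.total_n < 1:
        raise EmptyInputError("total_n must be at least 1")
    pts_t = curve.points["time_years"].to_numpy()
    pts_s = curve.points["survival"].to_numpy()
    risk_t = curve.risk_table["time_years"].to_numpy()
    risk_n = curve.risk_table["n_at_risk"].to_numpy().astype(int)

    all_times: list[float] = []
    all_events: list[int] = []
    notes: list[str] = []

    n_risk = int(risk_n[0])
    km = 1.0
    n_intervals = risk_t.size
    for j in range(n_intervals):
        lo = risk_t[j]
        hi = risk_t[j + 1] if j + 1 < n_intervals else np.inf
        # right-closed intervals: a drop digitized exactly at the next
        # at-risk time is deducted before matching that published count,
        # which counts subjects still at risk after events at that instant
        if j == 0:
            mask = (pts_t >= lo) & (pts_t <= hi)
        elif j == n_intervals - 1:
            mask = pts_t > lo
        else:
            mask = (pts_t > lo) & (pts_t <= hi)
        times_j = pts_t[mask]
        survs_j = pts_s[mask]
        if times_j.size == 0:
            continue
        end_time = hi if np.isfinite(hi) else times_j[-1]

        if j + 1 < n_intervals:
            target = int(risk_n[j + 1])
            # fixed-point iteration on the interval censor count
            n_cen = 0
            best = None
            for _ in range(60):
                ev, ct, n_end, km_end = _run_interval(
                    n_risk, km, times_j, survs_j, end_time, n_cen
                )
                diff = n_end - target
                if best is None or abs(diff) < abs(best[0]):
                    best = (diff, n_cen, ev, ct, n_end, km_end)
                if diff == 0:
                    break
                n_new = n_cen + diff
                if n_new < 0 or n_new == n_cen:
                    break
                n_cen = n_new
            diff, n_cen, ev, ct, n_end, km_end = best
            if diff != 0 and n_cen == 0:
                notes.append(
                    f"interval {j} ([{lo}, {hi})): no nonnegative integer censor "
                    f"count matches the published at-risk count {target} "
                    f"(closest implied count {n_end}); censorings set to zero"
                )
            elif diff != 0:
                notes.append(
                    f"interval {j} ([{lo}, {hi})): at-risk count off by {diff} "
                    "after best integer censor allocation"
                )
        else:
            # last interval: events from drops only, survivors censored at end
            ev, ct, n_end, km_end = _run_interval(
                n_risk, km, times_j, survs_j, end_time, 0
            )

        for t_i, d_i in zip(times_j, ev):
            all_times.extend([t_i] * d_i)
            all_events.extend([1] * d_i)
        all_times.extend(ct)
        all_events.extend([0] * len(ct))
        n_risk, km = n_end, km_end

    # administrative censoring of everyone still at risk at the last time seen
    if n_risk > 0:
        last_t = float(pts_t[-1])
        all_times.extend([last_t] * n_risk)
        all_events.extend([0] * n_risk)

    ipd = ReconstructedIPD(np.array(all_times), np.array(all_events), warnings_=notes)
    for note in notes:
        warnings.warn(note, RuntimeWarning, stacklevel=2)
    if ipd.n != curve.total_n:
        warnings.warn(
            f"reconstructed {ipd.n} subjects but the curve declares "
            f"total_n={curve.total_n}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ipd


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan–Meier survival estimate, via lifelines, as (time, survival)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time_years": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def km_at(time, event, query_times) -> np.ndarray:
    """KM estimate evaluated at arbitrary times (right-continuous step)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    return kmf.predict(q).to_numpy(dtype=float)
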