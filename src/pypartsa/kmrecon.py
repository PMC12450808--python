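"""Pseudo individual-patient data (IPD) from published Kaplan-Meier curves.

When trial IPD is unavailable, survival extrapolation has to start from
what publications actually print: the digitized KM step coordinates and
the number-at-risk table beneath the figure.  :func:`reconstruct_ipd`
implements the interval-wise reconstruction algorithm of Guyot and
colleagues: within each risk-table interval it estimates the number of
censored subjects (placed at evenly spaced times), converts the KM drops
into integer event counts, and iterates the censoring guess until the
implied number at risk at the interval end matches the published count.

:func:`km_estimate` is the product-limit estimator (via lifelines) used
both downstream and as the round-trip validation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "km_estimate",
    "reconstruct_ipd",
]


@dataclass
class DigitizedCurve:
    """Ordered (time, survival) points extracted from a published KM plot.

    The curve is interpreted as a right-continuous step function; a
    leading (0, 1) point is prepended when absent.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("curve times must be >= 0")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        elif s[0] != 1.0:
            raise ValueError("survival at time 0 must equal 1")
        self.times = t
        self.survival = s

    def evaluate(self, at) -> np.ndarray:
        """Step-function value S(t) (right-continuous) at the given times."""
        at = np.atleast_1d(np.asarray(at, dtype=float))
        idx = np.searchsorted(self.times, at, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.survival[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


@dataclass
class RiskTable:
    """Number-at-risk table: (time, n at risk), first entry at time 0."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk)
        if t.ndim != 1 or t.shape != n.shape or t.size == 0:
            raise ValueError("risk table must be non-empty 1-d (time, count) columns")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("risk table must start at time 0 (total sample size)")
        if np.any(n < 0) or np.any(n != np.floor(n)):
            raise ValueError("n_at_risk must be non-negative integers")
        if np.any(np.diff(n) > 0):
            raise ValueError("n_at_risk must be non-increasing")
        self.times = t
        self.n_at_risk = n.astype(int)

    @property
    def total_n(self) -> int:
        return int(self.n_at_risk[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "n_at_risk": self.n_at_risk})


@dataclass
class PseudoIPD:
    """Per-patient (time, event) records; event 1 = event, 0 = censored."""

    times: np.ndarray
    events: np.ndarray
    #: risk-table interval indices whose published at-risk count could not
    #: be matched exactly (best-so-far assignment used)
    unmatched_intervals: tuple[int, ...] = field(default=())

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise ValueError("IPD times must be finite and >= 0")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("events must be 0 or 1")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.events = e[order].astype(int)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit survival estimate of an IPD set as a step curve.

    The returned curve holds the (0, 1) origin plus one point per distinct
    event time carrying the post-drop survival value.
    """
    if ipd.n == 0:
        raise ValueError("cannot estimate a KM curve from empty IPD")
    kmf = KaplanMeierFitter().fit(ipd.times, ipd.events)
    sf = kmf.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    drops = np.concatenate([[True], np.diff(s) < 0])
    drops[0] = t[0] == 0  # keep an explicit origin only if lifelines put one there
    t, s = t[drops], s[drops]
    if t.size == 0 or t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return DigitizedCurve(t, s)


def _interval_pass(coord_t, coord_s, k_lo, k_hi, n_start, km_start, cen_times, d_out):
    """Sweep one risk-table interval.

    Processes the merged sequence of KM drop coordinates (indices
    k_lo..k_hi) and censoring times; events at a coordinate are the
    accumulated fractional KM drops rounded to integers, with the running
    KM estimate updated from the integers actually emitted so rounding
    errors self-correct.  Returns (n_end, km_end).
    """
    items = [(coord_t[k], 0, k) for k in range(k_lo, k_hi + 1)]
    items += [(ct, 1, -1) for ct in cen_times]
    items.sort()  # ties: events (kind 0) before censorings at the same time
    n = n_start
    km = km_start
    acc = 0.0
    for _, kind, k in items:
        if kind == 1:
            n -= 1
            continue
        if coord_t[k] == 0.0:
            continue  # origin carries no drop
        if n <= 0 or km <= 0:
            d_out[k] = 0
            continue
        acc += n * (1.0 - coord_s[k] / km)
        d = int(np.floor(acc + 0.5))
        d = max(0, min(d, n))
        acc -= d
        d_out[k] = d
        if d > 0:
            km *= 1.0 - d / n
            n -= d
    return n, km


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
    max_iter: int = 30,
) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve and risk table.

    Parameters
    ----------
    curve
        Digitized step coordinates of the published KM curve.
    risk
        Published number-at-risk table; its first entry fixes the output
        sample size.
    total_events
        If the publication reports the total number of events, the final
        interval's censoring is adjusted so the reconstructed total
        matches.
    max_iter
        Iteration cap per interval when matching the published at-risk
        counts; on failure the best assignment is kept and the interval is
        flagged in ``unmatched_intervals``.
    """
    ct, cs = curve.times, curve.survival
    rt, rn = risk.times, risk.n_at_risk
    n_coord = len(ct)
    n_int = len(rt)
    end_time = max(ct[-1], rt[-1])

    # coordinate index range of each interval; boundary-time coordinates
    # open the later interval (they are counted at risk at the boundary)
    lower = np.searchsorted(ct, rt, side="left")
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = np.searchsorted(ct, rt[1:], side="left") - 1
    upper[-1] = n_coord - 1

    d = np.zeros(n_coord, dtype=int)
    censor_times: list[float] = []
    unmatched: list[int] = []
    n_cur = int(rn[0])
    km_cur = 1.0

    for i in range(n_int):
        t_lo = rt[i]
        t_hi = rt[i + 1] if i < n_int - 1 else end_time
        k_lo, k_hi = int(lower[i]), int(upper[i])
        width = t_hi - t_lo

        if i < n_int - 1:
            target = int(rn[i + 1])
            s_lo = curve.evaluate(t_lo)[0]
            s_hi = curve.evaluate(t_hi)[0]
            guess = int(round(n_cur * (s_hi / s_lo if s_lo > 0 else 0.0))) - target
        elif total_events is not None:
            target = None
            guess = 0
        else:
            target = None
            guess = 0

        n_cen = max(0, guess)
        best = None  # (|mismatch|, n_cen, n_end, km_end, d_slice, cen_times)
        tried: set[int] = set()
        for _ in range(max_iter):
            if n_cen in tried:
                break
            tried.add(n_cen)
            d_trial = np.zeros(n_coord, dtype=int)
            if n_cen > 0 and width > 0:
                cen = [t_lo + j * width / (n_cen + 1) for j in range(1, n_cen + 1)]
            else:
                cen = []
                n_cen = 0
            n_end, km_end = _interval_pass(ct, cs, k_lo, k_hi, n_cur, km_cur, cen, d_trial)
            if target is None and total_events is not None and i == n_int - 1:
                # match the reported total event count instead of a risk count
                ev_so_far = int(d.sum())
                mism = (ev_so_far + int(d_trial[k_lo : k_hi + 1].sum())) - int(total_events)
            elif target is None:
                mism = 0
            else:
                mism = n_end - target
            if best is None or abs(mism) < best[0]:
                best = (abs(mism), n_cen, n_end, km_end, d_trial, cen)
            if mism == 0:
                break
            n_cen = max(0, n_cen + mism)
        assert best is not None
        mis, _, n_end, km_end, d_trial, cen = best
        cen = list(cen)
        if mis != 0:
            # the censoring count and the event rounding can disagree by a
            # couple of subjects (adding a censor flips an event); reconcile
            # by freezing the event counts and adjusting censorings so the
            # published decrement is conserved exactly
            residual = 0
            if target is not None:
                delta = n_end - target
                if delta > 0:  # too many still at risk implied: censor them
                    cen += [t_lo + j * width / (delta + 1) for j in range(1, delta + 1)]
                    n_end = target
                else:  # too few: un-censor, then un-event (subjects stay at risk)
                    need = -delta
                    drop = min(need, len(cen))
                    if drop:
                        cen = cen[:-drop]
                    need -= drop
                    k = k_hi
                    while need > 0 and k >= k_lo:
                        take = min(need, int(d_trial[k]))
                        d_trial[k] -= take
                        need -= take
                        k -= 1
                    residual = -need
                    n_end = target - need
            else:  # last interval with a reported total event count
                delta = int(d.sum()) + int(d_trial[k_lo : k_hi + 1].sum()) - int(total_events)
                if delta > 0:  # too many events: re-label the latest as censored
                    k = k_hi
                    while delta > 0 and k >= k_lo:
                        take = min(delta, int(d_trial[k]))
                        d_trial[k] -= take
                        cen += [ct[k]] * take
                        delta -= take
                        k -= 1
                    residual = delta
                # delta < 0 (too few events) is repaired after the interval
                # loop by promoting end-of-study survivors to events
            if residual != 0:
                unmatched.append(i)
                warnings.warn(
                    f"risk-table interval {i} ([{t_lo}, {t_hi})) could not be matched "
                    f"exactly (residual {residual}); using best assignment",
                    stacklevel=2,
                )
        d[k_lo : k_hi + 1] = d_trial[k_lo : k_hi + 1]
        censor_times.extend(cen)
        n_cur, km_cur = n_end, km_end

    promote = 0
    if total_events is not None and int(d.sum()) < int(total_events):
        # reported total exceeds the drops on the curve: the missing events
        # occur after the last coordinate, among the end-of-study survivors
        promote = min(int(total_events) - int(d.sum()), n_cur)
        if int(d.sum()) + promote < int(total_events):
            unmatched.append(n_int - 1)
            warnings.warn(
                f"total_events={total_events} cannot be reached "
                f"({int(d.sum()) + promote} attainable)",
                stacklevel=2,
            )
    times = np.repeat(ct, d).tolist() + censor_times
    events = [1] * int(d.sum()) + [0] * len(censor_times)
    if promote:
        times += [end_time] * promote
        events += [1] * promote
        n_cur -= promote
    if n_cur > 0:  # follow-up continues past the last drop: censor at study end
        times += [end_time] * n_cur
        events += [0] * n_cur
    return PseudoIPD(np.asarray(times), np.asarray(events), tuple(sorted(set(unmatched))))
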