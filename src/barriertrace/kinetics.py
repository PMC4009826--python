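"""One-phase decay (FLIP) and exponential recovery (FRAP) fitting.

FLIP traces are fit with ``y(t) = plateau + (100 - plateau) exp(-rate t)``,
which pins the first bleaching point to 100 % by construction; the time of
50 % fluorescence loss (t50) is then read from the fitted curve,

    t50 = ln((100 - plateau) / (50 - plateau)) / rate,

and is undefined when the plateau sits at or above 50 %.  Traces that do
not cross 50 % within the acquisition window still get a model t50,
flagged ``extrapolated``, because the Barrier Index needs a bud t50 even
when the barrier keeps bud loss shallow.

FRAP traces (percent of the pre-bleach level) are fit with one or two
recovering exponentials.  t_half is the time to recover half of the span
between the post-bleach floor and the fitted plateau; the mobile fraction
is that span over the pre-bleach deficit, and the fast fraction is the
amplitude share of the faster component of a two-component fit.

All fits use a fixed log-spaced multi-start on the rate(s) followed by
bounded least-squares refinement, with deterministic tie-breaking (lowest
residual, then lowest rate), so repeated runs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .quant import NormalizedBundle

__all__ = [
    "DecayFit",
    "RecoveryFit",
    "fit_one_phase_decay",
    "t50_of",
    "fit_recovery",
    "halftime_dataset",
    "interpolated_half_loss_time",
]

_RATE_GRID = np.logspace(-4, 0, 13)  # 1/s, multi-start initializations
_RATE_BOUNDS = (1e-6, 1e2)


@dataclass
class DecayFit:
    """One-phase decay fit of a FLIP loss trace (percent units)."""

    amplitude: float  # 100 - plateau
    rate: float  # 1/s
    plateau: float  # percent
    residual_rms: float
    flags: tuple[str, ...] = ()

    @property
    def t50(self) -> Optional[float]:
        """Fitted time of 50 % fluorescence loss; None if unreachable."""
        if self.plateau >= 50.0:
            return None
        return math.log((100.0 - self.plateau) / (50.0 - self.plateau)) / self.rate

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.plateau + (100.0 - self.plateau) * np.exp(-self.rate * np.asarray(t))


@dataclass
class RecoveryFit:
    """Exponential recovery fit of a FRAP trace (percent of pre-bleach)."""

    post_bleach_level: float
    plateau: float
    rate: float  # 1/s; the fast rate for two-component fits
    pre_bleach_level: float
    t_half: Optional[float]
    mobile_fraction: float
    fast_fraction: Optional[float] = None
    slow_rate: Optional[float] = None
    residual_rms: float = 0.0
    flags: tuple[str, ...] = ()

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.fast_fraction is None or self.slow_rate is None:
            span = self.plateau - self.post_bleach_level
            return self.post_bleach_level + span * (1.0 - np.exp(-self.rate * t))
        span = self.plateau - self.post_bleach_level
        a_fast = self.fast_fraction * span
        a_slow = span - a_fast
        return (
            self.post_bleach_level
            + a_fast * (1.0 - np.exp(-self.rate * t))
            + a_slow * (1.0 - np.exp(-self.slow_rate * t))
        )


def _as_trace(trace: np.ndarray | NormalizedBundle, roi: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, NormalizedBundle):
        return trace.times, trace.roi(roi)
    raise TypeError("pass a NormalizedBundle or call with explicit (times, values)")


def fit_one_phase_decay(
    times: np.ndarray | NormalizedBundle,
    values: Optional[np.ndarray] = None,
    roi: str = "mother",
) -> DecayFit:
    """Least-squares one-phase decay with the first point constrained to 100 %.

    Accepts either a :class:`NormalizedBundle` (with ``roi``) or explicit
    ``(times, values)`` arrays in percent units.  For each start rate the
    optimal plateau is the closed-form linear solution; the best start is
    refined with bounded least squares on (log rate, plateau).
    """
    if values is None:
        times, values = _as_trace(times, roi)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 frames for a decay fit")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trace")
    if np.ptp(y) < 1e-9:
        raise ValueError("constant trace: decay rate is unidentifiable")
    t = t - t[0]

    def _plateau_for(rate: float) -> float:
        e = np.exp(-rate * t)
        basis = 1.0 - e
        denom = float(basis @ basis)
        if denom <= 0:
            return 0.0
        p = float(basis @ (y - 100.0 * e)) / denom
        return min(max(p, 0.0), 100.0)

    def _residual(params: np.ndarray) -> np.ndarray:
        rate = math.exp(params[0])
        plateau = params[1]
        return plateau + (100.0 - plateau) * np.exp(-rate * t) - y

    candidates = []
    for r0 in _RATE_GRID:
        p0 = _plateau_for(r0)
        sol = least_squares(
            _residual,
            x0=[math.log(r0), p0],
            bounds=([math.log(_RATE_BOUNDS[0]), 0.0], [math.log(_RATE_BOUNDS[1]), 100.0]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        rate = math.exp(sol.x[0])
        candidates.append((float(np.sum(sol.fun**2)), rate, float(sol.x[1])))
    candidates.sort(key=lambda c: (c[0], c[1]))
    ssr, rate, plateau = candidates[0]
    rms = math.sqrt(ssr / t.size)

    flags = []
    if y.min() > 50.0:
        flags.append("extrapolated")
    if plateau >= 50.0:
        flags.append("t50_undefined")
    return DecayFit(
        amplitude=100.0 - plateau,
        rate=rate,
        plateau=plateau,
        residual_rms=rms,
        flags=tuple(flags),
    )


def t50_of(fit: DecayFit) -> float:
    """Time of 50 % loss read from a fitted decay curve."""
    t50 = fit.t50
    if t50 is None:
        raise ValueError(f"t50 undefined: fitted plateau {fit.plateau:.1f} % >= 50 %")
    return t50


def interpolated_half_loss_time(times: np.ndarray, values: np.ndarray) -> float:
    """Model-free cross-check: linear interpolation of the raw 50 % crossing."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    below = np.nonzero(y <= 50.0)[0]
    if below.size == 0:
        raise ValueError("trace never reaches 50 %")
    k = below[0]
    if k == 0:
        return float(t[0])
    frac = (y[k - 1] - 50.0) / (y[k - 1] - y[k])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def _fit_recovery_one(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Best (ssr, y0, plateau, rate) for a single-exponential recovery."""

    def _residual(params: np.ndarray) -> np.ndarray:
        y0, span, lograte = params
        return y0 + span * (1.0 - np.exp(-math.exp(lograte) * t)) - y

    y0_init = float(y[0])
    span_init = max(float(np.median(y[-5:])) - y0_init, 0.0)
    best = None
    for r0 in _RATE_GRID:
        sol = least_squares(
            _residual,
            x0=[y0_init, span_init, math.log(r0)],
            bounds=(
                [-np.inf, 0.0, math.log(_RATE_BOUNDS[0])],
                [np.inf, np.inf, math.log(_RATE_BOUNDS[1])],
            ),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        cand = (float(np.sum(sol.fun**2)), float(sol.x[0]), float(sol.x[1]), math.exp(sol.x[2]))
        if best is None or (cand[0], cand[3]) < (best[0], best[3]):
            best = cand
    ssr, y0, span, rate = best
    return ssr, y0, y0 + span, rate


def _fit_recovery_two(
    t: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Best (ssr, y0, a_fast, r_fast, a_slow, r_slow) for two components."""

    def _residual(params: np.ndarray) -> np.ndarray:
        y0, a1, a2, lr1, lr2 = params
        return (
            y0
            + a1 * (1.0 - np.exp(-math.exp(lr1) * t))
            + a2 * (1.0 - np.exp(-math.exp(lr2) * t))
            - y
        )

    y0_init = float(y[0])
    span_init = max(float(np.median(y[-5:])) - y0_init, 1e-6)
    coarse = np.logspace(-3, 0, 7)
    best = None
    for i, r_fast in enumerate(coarse):
        for r_slow in coarse[: i + 1]:
            sol = least_squares(
                _residual,
                x0=[y0_init, 0.5 * span_init, 0.5 * span_init, math.log(r_fast), math.log(max(r_slow, 1e-4))],
                bounds=(
                    [-np.inf, 0.0, 0.0, math.log(_RATE_BOUNDS[0]), math.log(_RATE_BOUNDS[0])],
                    [np.inf, np.inf, np.inf, math.log(_RATE_BOUNDS[1]), math.log(_RATE_BOUNDS[1])],
                ),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            y0, a1, a2, lr1, lr2 = sol.x
            r1, r2 = math.exp(lr1), math.exp(lr2)
            # order components fast-first
            if r1 < r2:
                a1, a2, r1, r2 = a2, a1, r2, r1
            cand = (float(np.sum(sol.fun**2)), float(y0), float(a1), r1, float(a2), r2)
            if best is None or (cand[0], cand[3]) < (best[0], best[3]):
                best = cand
    return best


def fit_recovery(
    times: np.ndarray,
    values: np.ndarray,
    pre_bleach_level: float = 100.0,
    components: int = 1,
) -> RecoveryFit:
    """Fit a FRAP recovery trace whose first frame is the post-bleach minimum.

    ``values`` are in percent of ``pre_bleach_level``.  The mobile fraction
    is (plateau - floor) / (pre-bleach - floor); t_half is where the fitted
    curve crosses half of the recovered span.  Two-component fits with a
    rate ratio below 3 are flagged ``unidentifiable_components``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 15:
        raise ValueError("need at least 15 frames for a recovery fit")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trace")
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    if pre_bleach_level <= 0:
        raise ValueError("pre_bleach_level must be > 0")
    t = t - t[0]

    flags: list[str] = []
    if np.ptp(y) < 1e-9 * max(1.0, abs(float(y[0]))):
        # flat trace: nothing recovers
        return RecoveryFit(
            post_bleach_level=float(y[0]),
            plateau=float(y[0]),
            rate=float("nan"),
            pre_bleach_level=pre_bleach_level,
            t_half=None,
            mobile_fraction=0.0,
            flags=("no_recovery",),
        )

    if components == 1:
        ssr, y0, plateau, rate = _fit_recovery_one(t, y)
        if plateau < y0:
            raise ValueError("fitted plateau below the post-bleach level")
        span = plateau - y0
        deficit = pre_bleach_level - y0
        mobile = float(np.clip(span / deficit, 0.0, 1.0)) if deficit > 0 else 0.0
        t_half = math.log(2.0) / rate if span > 0 else None
        if t_half is None:
            flags.append("no_recovery")
        return RecoveryFit(
            post_bleach_level=y0,
            plateau=plateau,
            rate=rate,
            pre_bleach_level=pre_bleach_level,
            t_half=t_half,
            mobile_fraction=mobile,
            residual_rms=math.sqrt(ssr / t.size),
            flags=tuple(flags),
        )

    ssr, y0, a_fast, r_fast, a_slow, r_slow = _fit_recovery_two(t, y)
    total = a_fast + a_slow
    plateau = y0 + total
    if plateau < y0:
        raise ValueError("fitted plateau below the post-bleach level")
    if r_slow > 0 and r_fast / r_slow < 3.0:
        flags.append("unidentifiable_components")
    deficit = pre_bleach_level - y0
    mobile = float(np.clip(total / deficit, 0.0, 1.0)) if deficit > 0 else 0.0
    fast_fraction = float(a_fast / total) if total > 0 else None

    t_half: Optional[float] = None
    if total > 0:
        target = y0 + total / 2.0

        def _gap(tt: float) -> float:
            return (
                y0
                + a_fast * (1.0 - math.exp(-r_fast * tt))
                + a_slow * (1.0 - math.exp(-r_slow * tt))
                - target
            )

        upper = 10.0 * max(t[-1], 1.0 / max(r_slow, 1e-6))
        while _gap(upper) < 0 and upper < 1e9:
            upper *= 10.0
        t_half = float(brentq(_gap, 0.0, upper, xtol=1e-12))
    else:
        flags.append("no_recovery")

    return RecoveryFit(
        post_bleach_level=y0,
        plateau=plateau,
        rate=r_fast,
        pre_bleach_level=pre_bleach_level,
        t_half=t_half,
        mobile_fraction=mobile,
        fast_fraction=fast_fraction,
        slow_rate=r_slow,
        residual_rms=math.sqrt(ssr / t.size),
        flags=tuple(flags),
    )


def halftime_dataset(
    traces: Sequence[tuple[str, np.ndarray, np.ndarray]],
    pre_bleach_level: float = 100.0,
    components: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Fit many FRAP cells and tabulate per-cell t_half.

    ``traces`` holds (cell_id, times, values) with the first frame of each
    trace the post-bleach minimum in percent of ``pre_bleach_level``.
    Failed fits are kept as flagged NaN rows, never dropped silently.
    Returns the per-cell table and a mean +/- SD summary.
    """
    if not traces:
        raise ValueError("need at least one trace")
    rows = []
    for cell_id, t, y in traces:
        try:
            fit = fit_recovery(t, y, pre_bleach_level=pre_bleach_level, components=components)
            rows.append(
                {
                    "cell_id": cell_id,
                    "t_half_s": fit.t_half if fit.t_half is not None else np.nan,
                    "mobile_fraction": fit.mobile_fraction,
                    "fast_fraction": fit.fast_fraction,
                    "rate_per_s": fit.rate,
                    "flags": ";".join(fit.flags),
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "cell_id": cell_id,
                    "t_half_s": np.nan,
                    "mobile_fraction": np.nan,
                    "fast_fraction": np.nan,
                    "rate_per_s": np.nan,
                    "flags": f"fit_failed:{exc}",
                }
            )
    table = pd.DataFrame(rows)
    ok = table["t_half_s"].dropna()
    summary = {
        "n": int(len(table)),
        "n_fit": int(ok.size),
        "t_half_mean_s": float(ok.mean()) if ok.size else float("nan"),
        "t_half_sd_s": float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
    }
    return table, summary
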