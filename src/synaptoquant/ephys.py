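"""Evoked-current metrics: amplitude, 10-90% rise time, mono-exponential
decay tau, charge, and paired-pulse ratio.

Traces are (time_s, current_nA) tables. Inward currents are negative;
amplitudes are reported signed (peak minus baseline) and ratios on
magnitudes. A configurable blanking window after each stimulus (default
1 ms) excludes the stimulation artifact from the peak search. The second
pulse of a pair is baseline-corrected by extrapolating the mono-exponential
decay fit of the first response to the second peak's time (alternative:
subtract the pre-pulse-2 current).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class NoResponseError(ValueError):
    """No evoked deflection beyond the noise floor after the stimulus."""


@dataclass
class EvokedMetrics:
    amplitude_nA: float  # signed, peak minus baseline
    rise_time_10_90_ms: float
    decay_tau_ms: float
    charge_pC: float  # integral of (I - baseline) over the integration window
    baseline_nA: float
    peak_time_s: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _trace_arrays(trace: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, float]:
    t = np.asarray(trace["time_s"], dtype=np.float64)
    i = np.asarray(trace["current_nA"], dtype=np.float64)
    dt = float(np.median(np.diff(t)))
    return t, i, dt


def _fit_decay(
    t_ms: np.ndarray, y: np.ndarray, tau_guess: float
) -> Tuple[float, float]:
    """LSQ fit of A * exp(-t/tau); returns (tau_ms, A). t_ms starts at 0."""
    if len(t_ms) < 4:
        raise ValueError("decay fit window too short")
    a0 = y[0]
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            t_ms,
            y,
            p0=(a0, tau_guess),
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"decay fit did not converge (n={len(t_ms)}, span={t_ms[-1]:.2f} ms)"
        ) from err
    return float(popt[1]), float(popt[0])


def evoked_metrics(
    trace: pd.DataFrame,
    stim_time: float,
    baseline_window: Tuple[float, float],
    integration_window: Optional[Tuple[float, float]] = None,
    blank_ms: float = 0.5,
    decay_fit_to_frac: float = 0.1,
    decay_fit_skip_rise: bool = True,
) -> EvokedMetrics:
    """Extract standard evoked-response parameters around one stimulus.

    Baseline is the mean over ``baseline_window`` (s, must precede the
    stimulus). The peak is the largest |I - baseline| deflection after
    ``stim_time + blank_ms``. Rise time is the 10%->90% crossing interval
    (linear interpolation); decay tau is a least-squares mono-exponential
    fit ending at ``decay_fit_to_frac`` of peak recovery (or at the end of
    the integration window, whichever comes first) and starting at the peak
    or, with ``decay_fit_skip_rise`` (default), two rise times past the
    peak — near the peak the not-yet-vanished rising component biases a
    mono-exponential fit of a difference-of-exponentials response; charge
    is the trapezoidal integral of (I - baseline) over
    ``integration_window`` (default: stimulus to end of trace), in pC.
    """
    t, i, dt = _trace_arrays(trace)
    b0, b1 = baseline_window
    if b1 > stim_time:
        raise ValueError("baseline_window must precede stim_time")
    bsel = (t >= b0) & (t < b1)
    if not bsel.any():
        raise ValueError("empty baseline window")
    baseline = float(i[bsel].mean())
    noise_sd = float(i[bsel].std())

    search = t >= stim_time + blank_ms / 1000.0
    if integration_window is not None:
        search &= t <= integration_window[1]
    dev = i - baseline
    if not search.any():
        raise ValueError("no samples after stimulus")
    k = int(np.argmax(np.abs(dev[search])))
    idx = np.nonzero(search)[0][k]
    peak = dev[idx]
    # response gate: a ~1 ms smoothed deflection must exceed 3x baseline SD
    # (the raw per-sample maximum of pure noise crosses 3 SD routinely)
    from scipy.ndimage import uniform_filter1d

    smooth_n = max(1, int(round(0.001 / dt)))
    dev_sm = uniform_filter1d(dev, smooth_n)
    floor = 3 * noise_sd if noise_sd > 0 else 1e-9
    if np.max(np.abs(dev_sm[search])) <= floor:
        raise NoResponseError(
            f"smoothed deflection below noise floor {floor:.3g} nA"
        )
    sign = np.sign(peak)
    mag = sign * dev  # positive-going response magnitude

    # rise time: last 10% crossing before peak -> first 90% crossing
    pre = np.nonzero((t >= stim_time) & (t <= t[idx]))[0]
    rise = np.nan
    m = mag[pre]
    t10 = _cross_time(t[pre], m, 0.1 * abs(peak), forward=False)
    t90 = _cross_time(t[pre], m, 0.9 * abs(peak), forward=False)
    if t10 is not None and t90 is not None:
        rise = (t90 - t10) * 1000.0

    # decay fit: (near) peak -> decay_fit_to_frac of peak, capped at the
    # integration window so a following stimulus never enters the fit
    last = (
        int(np.searchsorted(t, integration_window[1], side="right")) - 1
        if integration_window is not None
        else len(t) - 1
    )
    start = idx
    if decay_fit_skip_rise and np.isfinite(rise):
        start = int(np.searchsorted(t, t[idx] + 2 * rise / 1000.0))
        start = min(start, max(idx, last - 4))
    after = np.arange(start, last + 1)
    below = after[mag[after] <= decay_fit_to_frac * abs(peak)]
    end = below[0] if len(below) else last
    win = np.arange(start, end + 1)
    tau, _ = _fit_decay((t[win] - t[win[0]]) * 1000.0, mag[win], tau_guess=5.0)

    if integration_window is None:
        integration_window = (stim_time, float(t[-1]))
    isel = (t >= integration_window[0]) & (t <= integration_window[1])
    charge_nC = float(np.trapezoid(dev[isel], t[isel]))  # nA * s = nC
    return EvokedMetrics(
        amplitude_nA=float(peak),
        rise_time_10_90_ms=float(rise),
        decay_tau_ms=tau,
        charge_pC=charge_nC * 1000.0,
        baseline_nA=baseline,
        peak_time_s=float(t[idx]),
    )


def _cross_time(t, y, level, forward=True) -> Optional[float]:
    """Interpolated time where y crosses level (scanning backwards from the
    end when forward=False, i.e. the crossing nearest the peak)."""
    above = y >= level
    if not above.any() or above.all():
        return float(t[0]) if above.all() else None
    # first index where it becomes above
    j = int(np.argmax(above))
    if j == 0:
        return float(t[0])
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t[j])
    frac = (level - y0) / (y1 - y0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def pp_ratio(
    trace: pd.DataFrame,
    stim1: float,
    stim2: float,
    baseline_window: Optional[Tuple[float, float]] = None,
    blank_ms: float = 0.5,
    correction: str = "extrapolate",
) -> pd.Series:
    """Paired-pulse ratio A2/A1 on response magnitudes.

    A1 is the first response's amplitude. For A2 the first response's
    fitted mono-exponential decay is extrapolated to the second peak's time
    and subtracted (``correction="extrapolate"``, default), or the current
    just before the second stimulus is used as the local baseline
    (``correction="pre_pulse"``).
    """
    if stim2 <= stim1:
        raise ValueError("stim2 must be after stim1")
    if correction not in ("extrapolate", "pre_pulse"):
        raise ValueError(f"unknown correction {correction!r}")
    t, i, dt = _trace_arrays(trace)
    if baseline_window is None:
        baseline_window = (max(0.0, stim1 - 0.02), stim1)
    first = evoked_metrics(
        trace, stim1, baseline_window, integration_window=(stim1, stim2),
        blank_ms=blank_ms,
    )
    a1 = first.amplitude_nA
    sign = np.sign(a1)

    sel2 = (t >= stim2 + blank_ms / 1000.0) & (
        t <= stim2 + 10 * first.decay_tau_ms / 1000.0
    )
    if not sel2.any():
        raise ValueError("no samples after second stimulus")
    dev = i - first.baseline_nA
    k = int(np.argmax(sign * dev[sel2]))
    idx2 = np.nonzero(sel2)[0][k]
    t2 = t[idx2]

    if correction == "extrapolate":
        residue = a1 * np.exp(-(t2 - first.peak_time_s) * 1000.0 / first.decay_tau_ms)
    else:
        pre2 = (t >= stim2 - 0.002) & (t < stim2)
        residue = float(dev[pre2].mean()) if pre2.any() else 0.0
    a2 = dev[idx2] - residue
    if sign * a2 <= 0:
        raise NoResponseError("no second response after correction")
    return pd.Series(
        {
            "a1_nA": a1,
            "a2_nA": float(a2),
            "pp_ratio": float(abs(a2) / abs(a1)),
            "decay_tau_ms": first.decay_tau_ms,
        }
    )
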