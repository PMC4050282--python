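"""Kinetic model of axonal Na⁺ dynamics reported by the indicator SBFI.

The single-compartment reaction system couples spike-evoked Na⁺ entry, the
binding–unbinding reaction with the low-affinity indicator SBFI
(K_D ≈ 25 mM), first-order Na⁺ extrusion (P_Na) and first-order longitudinal
diffusion escape (D_Na):

    d[Na]/dt     = j_Na(t) − k_on[Na][SBFI] + k_off[NaSBFI]
                   − (P_Na + D_Na)([Na] − Na_rest)
    d[NaSBFI]/dt =            k_on[Na][SBFI] − k_off[NaSBFI]
    [SBFI] + [NaSBFI] = SBFI_total            (mass conservation)

with k_off = k_on·K_D.  The influx is a train of Gaussian pulses (width σ of
the order of the spike half-width, ~0.5 ms), each carrying a total entry of
ΔNa per spike.  Removal acts on the entered Na⁺ ([Na]−Na_rest) so the system
is at equilibrium before the stimulus.  Integration uses an explicit
finite-difference (forward Euler) scheme.

Fluorescence is a two-species brightness model, F ∝ [SBFI] + r·[NaSBFI] with
bound:free brightness ratio r < 1, so ΔF/F is negative-going on Na⁺ binding.

The staged fitting procedure mirrors the estimation pipeline: ``fit_kon``
estimates the association rate from the rising phase of the response to a
single brief entry pulse (extrusion neglected on that 20–30 ms timescale);
``fit_dna_pna`` jointly fits ΔNa and P_Na across the 5 AP @ 20 Hz and
100 AP @ 50 Hz protocols, where ΔNa controls the response amplitude and
P_Na its decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize

__all__ = [
    "NaKineticParams",
    "NaStateTrace",
    "SbfiFluorescence",
    "gaussian_influx",
    "simulate_na_system",
    "sbfi_fluorescence",
    "fit_kon",
    "fit_dna_pna",
    "protocol_spike_times",
    "FitResult",
]

FIT_SEED = 20140523  # multi-start ordering


@dataclass
class NaKineticParams:
    """Parameters of the Na⁺–SBFI reaction system.

    Units: ``k_on`` M⁻¹·ms⁻¹, ``k_d`` mM, ``p_na`` ms⁻¹, ``d_na`` s⁻¹,
    concentrations mM, ``sigma`` ms.  ``na_rest`` (10 mM) and the bound:free
    brightness ratio are assumptions exposed in configuration.
    """

    k_on: float = 2.0
    k_d: float = 25.0
    p_na: float = 0.0022
    d_na: float = 0.8
    sbfi_total: float = 1.0
    na_rest: float = 10.0
    dna_per_spike: float = 0.4
    sigma: float = 0.5
    spike_times: tuple[float, ...] = (50.0,)

    def __post_init__(self) -> None:
        for name in ("k_on", "k_d", "p_na", "d_na", "sbfi_total", "na_rest",
                     "dna_per_spike"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def k_on_mM(self) -> float:
        return self.k_on * 1e-3  # mM⁻¹·ms⁻¹

    @property
    def k_off(self) -> float:
        return self.k_on_mM * self.k_d  # ms⁻¹

    @property
    def removal_rate(self) -> float:
        return self.p_na + self.d_na * 1e-3  # ms⁻¹

    def equilibrium(self) -> tuple[float, float]:
        """Equilibrium (free SBFI, bound NaSBFI) in mM."""
        bound = self.sbfi_total * self.na_rest / (self.na_rest + self.k_d)
        return self.sbfi_total - bound, bound


@dataclass
class NaStateTrace:
    t: np.ndarray  # ms
    na: np.ndarray  # mM, free intracellular Na+
    sbfi: np.ndarray  # mM, free indicator
    nasbfi: np.ndarray  # mM, bound indicator
    j_na: np.ndarray  # mM/ms
    removed: np.ndarray  # mM, cumulative removal by P_Na + D_Na
    params: NaKineticParams


@dataclass
class SbfiFluorescence:
    t: np.ndarray
    dff: np.ndarray  # relative fluorescence change, negative-going
    brightness_ratio: float


def gaussian_influx(t, t0: float, sigma: float, dna_tot: float) -> np.ndarray:
    """Gaussian influx-rate pulse (mM/ms) whose time integral is ``dna_tot``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = np.asarray(t, dtype=float)
    return (
        dna_tot / (sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-((t - t0) ** 2) / (2.0 * sigma**2))
    )


def influx_waveform(params: NaKineticParams, t: np.ndarray) -> np.ndarray:
    j = np.zeros_like(t)
    for t0 in params.spike_times:
        j += gaussian_influx(t, t0, params.sigma, params.dna_per_spike)
    return j


@njit(cache=True)
def _euler(j, dt, kon, koff, stot, na_rest, removal, na0, bound0):  # pragma: no cover
    n = j.shape[0]
    na = np.empty(n)
    bound = np.empty(n)
    removed = np.empty(n)
    na[0] = na0
    bound[0] = bound0
    removed[0] = 0.0
    for k in range(n - 1):
        free = stot - bound[k]
        rxn = kon * na[k] * free - koff * bound[k]
        rem = removal * (na[k] - na_rest)
        na[k + 1] = na[k] + dt * (j[k] - rxn - rem)
        bound[k + 1] = bound[k] + dt * rxn
        removed[k + 1] = removed[k] + dt * rem
    return na, bound, removed


def simulate_na_system(
    params: NaKineticParams, duration: float, dt: float = 0.01
) -> NaStateTrace:
    """Integrate the reaction system with the explicit finite-difference scheme.

    Stability requires ``dt <= sigma/10`` (to resolve the influx pulse) and
    ``dt <= 0.1/(k_on·SBFI_total + k_off)`` (binding kinetics); violations
    raise with a suggested step.
    """
    dt_max = min(params.sigma / 10.0,
                 0.1 / (params.k_on_mM * params.sbfi_total + params.k_off + 1e-30))
    if dt > dt_max:
        raise ValueError(f"dt={dt} unstable for these parameters; use dt <= {dt_max:.4g}")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    j = influx_waveform(params, t)
    free0, bound0 = params.equilibrium()
    na, bound, removed = _euler(
        j, dt, params.k_on_mM, params.k_off, params.sbfi_total,
        params.na_rest, params.removal_rate, params.na_rest, bound0,
    )
    return NaStateTrace(
        t=t, na=na, sbfi=params.sbfi_total - bound, nasbfi=bound,
        j_na=j, removed=removed, params=params,
    )


def sbfi_fluorescence(
    trace: NaStateTrace, brightness_ratio: float = 0.5
) -> SbfiFluorescence:
    """Map the bound-indicator time course to relative fluorescence ΔF/F."""
    if not 0.0 <= brightness_ratio < 1.0:
        raise ValueError("brightness ratio must be in [0, 1)")
    r = brightness_ratio
    f = trace.sbfi + r * trace.nasbfi
    f_pre = trace.sbfi[0] + r * trace.nasbfi[0]
    return SbfiFluorescence(
        t=trace.t, dff=(f - f_pre) / f_pre, brightness_ratio=r
    )


def protocol_spike_times(protocol: str, onset: float = 50.0) -> tuple[float, ...]:
    """Spike times for the named stimulation protocol."""
    if protocol in ("step", "single"):
        return (onset,)
    if protocol in ("5AP20Hz", "5ap20hz"):
        return tuple(onset + 50.0 * k for k in range(5))
    if protocol in ("100AP50Hz", "100ap50hz"):
        return tuple(onset + 20.0 * k for k in range(100))
    raise ValueError(f"unknown protocol {protocol!r}")


def protocol_duration(protocol: str, onset: float = 50.0) -> float:
    times = protocol_spike_times(protocol, onset)
    return times[-1] + (1500.0 if len(times) > 1 else 150.0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    values: dict
    cost: float
    flags: list[str] = field(default_factory=list)


def _forward_dff(
    params: NaKineticParams, t_samples: np.ndarray, dt: float,
    brightness_ratio: float,
) -> np.ndarray:
    duration = float(t_samples[-1])
    dt_max = min(params.sigma / 10.0,
                 0.1 / (params.k_on_mM * params.sbfi_total + params.k_off + 1e-30))
    dt = min(dt, 0.9 * dt_max)
    trace = simulate_na_system(params, duration, dt=dt)
    fl = sbfi_fluorescence(trace, brightness_ratio)
    return np.interp(t_samples, fl.t, fl.dff)


def fit_kon(
    t: np.ndarray,
    dff: np.ndarray,
    k_d: float = 25.0,
    sbfi_total: float = 1.0,
    na_rest: float = 10.0,
    pulse_time: float | None = None,
    sigma: float = 0.5,
    brightness_ratio: float = 0.5,
    dt: float = 0.02,
    fit_window: float = 25.0,
) -> FitResult:
    """Estimate the SBFI association rate from a single-pulse rising phase.

    The trace is the fluorescence response to a brief Na⁺ entry pulse (the
    voltage-step protocol).  Extrusion is neglected in the fit window — on
    the 20–30 ms binding timescale its effect on [Na⁺] is negligible — so
    the free parameters are (k_on, ΔNa).  Returns the estimate in M⁻¹·ms⁻¹.
    """
    t = np.asarray(t, dtype=float)
    dff = np.asarray(dff, dtype=float)
    if pulse_time is None:
        g = np.gradient(dff)
        k = int(np.argmin(g))
        if 0 < k < g.size - 1:
            den = g[k - 1] - 2.0 * g[k] + g[k + 1]
            off = 0.5 * (g[k - 1] - g[k + 1]) / den if den != 0 else 0.0
            off = float(np.clip(off, -0.5, 0.5))
        else:
            off = 0.0
        pulse_time = float(t[k] + off * (t[1] - t[0]))
    # rising (binding) phase only, on the 20-30 ms binding timescale where
    # slow removal (neglected by the P=D=0 fit model) has no visible effect
    k_end = int(np.argmin(dff))
    m = (
        (t >= max(0.0, pulse_time - 5.0 * sigma))
        & (np.arange(t.size) <= k_end)
        & (t <= pulse_time + fit_window)
    )
    tw, yw = t[m], dff[m]
    if tw.size < 10:
        raise ValueError("trace too short for a rising-phase fit")
    amp0 = max(abs(float(np.min(yw))), 1e-4)

    def residual(p):
        kon, dna = p
        par = NaKineticParams(
            k_on=kon, k_d=k_d, p_na=0.0, d_na=0.0, sbfi_total=sbfi_total,
            na_rest=na_rest, dna_per_spike=dna, sigma=sigma,
            spike_times=(pulse_time,),
        )
        return _forward_dff(par, tw, dt, brightness_ratio) - yw

    best = None
    for kon0 in (0.5, 2.0, 8.0):
        sol = optimize.least_squares(
            residual, x0=[kon0, amp0 * 20.0],
            bounds=([1e-3, 1e-4], [100.0, 50.0]), xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    flags = []
    # non-monotone rising phase beyond noise -> quality warning
    ymin_k = int(np.argmin(yw))
    rising = yw[: ymin_k + 1]
    if rising.size > 3:
        backtrack = float(np.max(rising[1:] - np.minimum.accumulate(rising)[:-1]))
        if backtrack > 0.1 * abs(float(np.min(yw))):
            flags.append("non-monotone rising phase")
    return FitResult(
        values={"k_on": float(best.x[0]), "dna_per_spike": float(best.x[1])},
        cost=float(best.cost), flags=flags,
    )


def fit_dna_pna(
    t5: np.ndarray,
    dff5: np.ndarray,
    t100: np.ndarray,
    dff100: np.ndarray,
    k_on: float = 2.0,
    k_d: float = 25.0,
    d_na: float = 0.8,
    sbfi_total: float = 1.0,
    na_rest: float = 10.0,
    sigma: float = 0.5,
    onset: float = 50.0,
    brightness_ratio: float = 0.5,
    dt: float = 0.05,
    n_starts: int = 5,
) -> FitResult:
    """Joint two-protocol fit of the per-spike Na⁺ entry and extrusion rate.

    The 5 AP @ 20 Hz and 100 AP @ 50 Hz traces jointly constrain
    (ΔNa, P_Na): ΔNa scales the (inverse) fluorescence increment and P_Na
    predominantly sets its decay.  Bounded trust-region least squares with
    multi-starts over log-spaced initial values.
    """
    t5 = np.asarray(t5, dtype=float)
    t100 = np.asarray(t100, dtype=float)
    dff5 = np.asarray(dff5, dtype=float)
    dff100 = np.asarray(dff100, dtype=float)
    times5 = protocol_spike_times("5AP20Hz", onset)
    times100 = protocol_spike_times("100AP50Hz", onset)

    def residual(p):
        dna, pna = p
        res = []
        for times, ts, ys in ((times5, t5, dff5), (times100, t100, dff100)):
            par = NaKineticParams(
                k_on=k_on, k_d=k_d, p_na=pna, d_na=d_na, sbfi_total=sbfi_total,
                na_rest=na_rest, dna_per_spike=dna, sigma=sigma,
                spike_times=times,
            )
            res.append(_forward_dff(par, ts, dt, brightness_ratio) - ys)
        return np.concatenate(res)

    lb = np.array([0.0, 0.0])
    ub = np.array([5.0, 0.05])
    rng = np.random.default_rng(FIT_SEED)
    starts = [(0.4, 0.0022)]
    dna_grid = np.geomspace(0.05, 2.0, n_starts)
    pna_grid = np.geomspace(2e-4, 2e-2, n_starts)
    order = rng.permutation(n_starts)
    starts += [(float(dna_grid[i]), float(pna_grid[i])) for i in order]
    best = None
    for x0 in starts[: n_starts + 1]:
        sol = optimize.least_squares(
            residual, x0=np.array(x0), bounds=(lb, ub), xtol=1e-12, ftol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
    dna, pna = float(best.x[0]), float(best.x[1])
    flags = []
    if dna < 1e-3:
        flags.append("dna ~ 0: p_na unidentifiable")
    for name, val, lo, hi in (("dna", dna, lb[0], ub[0]), ("p_na", pna, lb[1], ub[1])):
        if val <= lo + 1e-12 or val >= hi - 1e-12:
            if name != "dna" or "unidentifiable" not in " ".join(flags):
                flags.append(f"{name} at bound")
    return FitResult(
        values={"dna_per_spike": dna, "p_na": pna}, cost=float(best.cost), flags=flags
    )


def conservation_error(trace: NaStateTrace) -> tuple[float, float]:
    """(indicator, sodium) mass-conservation errors in mM.

    Indicator: max deviation of free+bound from total.  Sodium: max deviation
    of entered − removed − free excess − bound excess from zero, using the
    trapezoidal integral of the influx waveform.
    """
    p = trace.params
    ind = float(np.max(np.abs(trace.sbfi + trace.nasbfi - p.sbfi_total)))
    entered = np.concatenate(
        ([0.0], np.cumsum((trace.j_na[1:] + trace.j_na[:-1]) / 2.0
                          * np.diff(trace.t)))
    )
    free_ex = trace.na - p.na_rest
    bound_ex = trace.nasbfi - trace.nasbfi[0]
    na_err = float(np.max(np.abs(entered - trace.removed - free_ex - bound_ex)))
    return ind, na_err
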