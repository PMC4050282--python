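"""Spike-evoked Ca²⁺ entry along the axon and Fluo-4 quantifications.

Ca²⁺ entry is measured as the integral of the Ca²⁺ current over each spike
window, per recording site.  Because intracellular Ca²⁺ buffering and
extrusion are deliberately outside the model, all increments scale linearly
with channel density and all ratios are density-independent.

Fluorescence quantifications follow the experimental definitions:
``ΔF/F_B = (F − F_pre)/(F_pre − F₀)`` with F₀ the background and F_pre the
pre-stimulus fluorescence; the early/late ratio compares mean increments
0–40 ms and 40–200 ms after stimulus onset; ΔF₃/ΔF₁ compares the step
increments evoked by the third and first time-locked spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import StateTrace

__all__ = [
    "CA_ANALYSIS_SITES_UM",
    "CaIncrementProfile",
    "FluoTrace",
    "per_spike_ca_increment",
    "fluo4_dff",
    "early_late_ratio",
    "dff_spike_ratio",
    "fluo_forward",
]


# canonical axonal recording distances (µm) for the Ca²⁺ ratio profile;
# sites within ~40 µm of the soma are shaped by the somatic stimulus itself
CA_ANALYSIS_SITES_UM = (20.0, 100.0, 180.0, 260.0)


def sites_near(trace: StateTrace, distances) -> np.ndarray:
    """Main-axon compartment indices nearest the requested distances (µm)."""
    return np.asarray([trace.site_index(d) for d in distances], dtype=int)


@dataclass
class FluoTrace:
    """A fluorescence time series with background and pre-stimulus markers."""

    t: np.ndarray  # ms
    f: np.ndarray  # a.u.
    f0: float  # background fluorescence
    f_pre: float  # pre-stimulus fluorescence

    def __post_init__(self) -> None:
        if self.f_pre <= self.f0:
            raise ValueError("F_pre must exceed the background F0")


@dataclass
class CaIncrementProfile:
    """Per (site, spike) integrated Ca²⁺ influx, in nC·cm⁻²."""

    table: pd.DataFrame  # distance_um, spike_index, increment_nc_cm2

    def ratio_profile(self, num: int = 3, den: int = 1) -> pd.DataFrame:
        """Per-site increment ratio (e.g. ΔCa₃/ΔCa₁), where ΔCa_den > 0."""
        piv = self.table.pivot(index="distance_um", columns="spike_index",
                               values="increment_nc_cm2")
        if num not in piv.columns or den not in piv.columns:
            raise ValueError(f"spike indices {num} and {den} not both present")
        out = piv[[den, num]].dropna()
        out = out[out[den] > 0]
        return pd.DataFrame(
            {"distance_um": out.index.to_numpy(),
             "ratio": (out[num] / out[den]).to_numpy()}
        )


def per_spike_ca_increment(
    trace: StateTrace,
    spike_windows: list[tuple[float, float]],
    sites: np.ndarray | None = None,
) -> CaIncrementProfile:
    """Integrate the Ca²⁺ current over each spike window at each axonal site.

    ``spike_windows`` are (start, stop) times in ms, typically built from
    detected somatic spikes; overlapping windows are rejected.  Inward Ca²⁺
    current yields positive increments.
    """
    if "ca" not in trace.currents:
        raise ValueError("trace carries no Ca²⁺ current; record it in SolverConfig")
    for k in range(len(spike_windows) - 1):
        if spike_windows[k][1] > spike_windows[k + 1][0]:
            raise ValueError(f"spike windows {k + 1} and {k + 2} overlap")
    ica = trace.currents["ca"]  # mA/cm², negative inward
    if sites is None:
        sites = trace.axon_indices()
    rows = []
    for i in sites:
        for k, (t0, t1) in enumerate(spike_windows):
            m = (trace.t >= t0) & (trace.t <= t1)
            if m.sum() < 2:
                raise ValueError(f"spike window {k + 1} outside the trace")
            q = -np.trapezoid(ica[m, i], trace.t[m])  # mA/cm²·ms = µC/cm²
            rows.append((float(trace.dist_um[i]), k + 1, q * 1e3))  # -> nC/cm²
    return CaIncrementProfile(
        pd.DataFrame(rows, columns=["distance_um", "spike_index", "increment_nc_cm2"])
    )


def fluo4_dff(trace: FluoTrace) -> np.ndarray:
    """ΔF/F_B = (F − F_pre)/(F_pre − F₀)."""
    return (trace.f - trace.f_pre) / (trace.f_pre - trace.f0)


def early_late_ratio(trace: FluoTrace, onset: float) -> float:
    """(F_late − F_B)/(F_early − F_B) with windows 0–40 and 40–200 ms post onset."""
    t = np.asarray(trace.t, dtype=float)
    if t[-1] < onset + 200.0:
        raise ValueError("trace must cover 200 ms after stimulus onset")
    early = (t >= onset) & (t < onset + 40.0)
    late = (t >= onset + 40.0) & (t <= onset + 200.0)
    f_early = float(np.mean(trace.f[early]))
    f_late = float(np.mean(trace.f[late]))
    if np.isclose(f_early, trace.f_pre):
        raise ValueError("early increment is zero; ratio undefined")
    return (f_late - trace.f_pre) / (f_early - trace.f_pre)


def dff_spike_ratio(
    trace: FluoTrace, spike_times: np.ndarray, window: float = 5.0
) -> float:
    """ΔF₃/ΔF₁ from time-locked spikes.

    Each per-spike increment is the difference of the mean fluorescence over
    ``window`` ms immediately after vs immediately before the spike time.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise ValueError("need at least 3 time-locked spikes")
    t = np.asarray(trace.t, dtype=float)
    incs = []
    for ts in spike_times[:3]:
        pre = (t >= ts - window) & (t < ts)
        post = (t > ts) & (t <= ts + window)
        if pre.sum() < 1 or post.sum() < 1:
            raise ValueError("spike window outside the trace")
        incs.append(float(np.mean(trace.f[post]) - np.mean(trace.f[pre])))
    if incs[0] == 0:
        raise ValueError("first-spike increment is zero; ratio undefined")
    return incs[2] / incs[0]


def fluo_forward(
    t: np.ndarray,
    ica: np.ndarray,
    tau: float = 150.0,
    gain: float = 1000.0,
    f_pre: float = 30.0,
    f0: float = 10.0,
) -> FluoTrace:
    """Linear-indicator forward model for synthetic Fluo-4 fluorescence.

    ΔF follows the cumulative Ca²⁺ influx convolved with a single-exponential
    indicator decay (default τ = 150 ms); there is no saturation, matching
    the treatment of Fluo-4 as a linear reporter of Ca²⁺ entry.
    ``ica`` is the Ca²⁺ current (mA/cm², negative inward).
    """
    t = np.asarray(t, dtype=float)
    ica = np.asarray(ica, dtype=float)
    dt = float(t[1] - t[0])
    influx = np.clip(-ica, 0.0, None)  # inward charge rate
    df = np.zeros_like(t)
    decay = np.exp(-dt / tau)
    for k in range(1, t.size):
        df[k] = df[k - 1] * decay + gain * influx[k] * dt
    return FluoTrace(t=t, f=f_pre + df, f0=f0, f_pre=f_pre)
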