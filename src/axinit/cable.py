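"""Branched-cable integrator with Hodgkin–Huxley channel dynamics.

The spatially discretized cable equation is advanced with a Crank–Nicolson
scheme on the voltage (tree-structured linear solve, Hines elimination) and
staggered exponential (Rush–Larsen) updates of the gating variables.  The
state is initialized by a settling run to steady state before each protocol.

Internal unit system: voltage mV, time ms, conductance density mS·cm⁻²,
current density µA·cm⁻² (exported as mA·cm⁻²), capacitance µF·cm⁻², axial
coupling µS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .morphology import CableModel, CompartmentGrid

__all__ = [
    "StimulusProtocol",
    "SolverConfig",
    "StateTrace",
    "SolverError",
    "run",
    "make_synaptic_train",
    "forced_spike_protocol",
    "voltage_step_clamp",
]

_GBIG = 1e9  # clamp penalty conductance, mS/cm²


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


@dataclass
class StimulusProtocol:
    """A stimulation protocol applied at one site.

    ``kind`` is one of ``current_step``, ``pulse_train``, ``synaptic_train``,
    ``voltage_step_clamp``.  Amplitudes are pA for current injections and mV
    for the clamp.
    """

    kind: str
    section: str = "soma"
    position: float = 0.5
    amplitude: float = 0.0  # pA (current) or mV (clamp step level)
    onset: float = 20.0  # ms
    duration: float = 200.0  # ms
    n_pulses: int = 1
    interval: float = 50.0  # ms between pulse onsets
    pulse_width: float = 0.5  # ms
    baseline: float = 0.0  # pA held between pulses (pulse_train)
    baseline_onset: float = 0.0  # ms, onset of the holding current
    rise: float = 0.5  # ms (synaptic events)
    decay: float = 5.0  # ms
    event_times: tuple[float, ...] = ()
    event_peak: float = 0.0  # pA per synaptic event
    hold_potential: float = -75.0  # mV (clamp)

    def __post_init__(self) -> None:
        if self.kind not in (
            "current_step", "pulse_train", "synaptic_train", "voltage_step_clamp"
        ):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0 or self.pulse_width <= 0:
            raise ValueError("times must be nonnegative and widths positive")
        if self.kind == "synaptic_train":
            if self.rise <= 0 or self.decay <= 0:
                raise ValueError("synaptic rise/decay must be positive")
            if any(t < 0 for t in self.event_times) or list(self.event_times) != sorted(
                self.event_times
            ):
                raise ValueError("event times must be nonnegative and ordered")

    @property
    def is_clamp(self) -> bool:
        return self.kind == "voltage_step_clamp"

    def current_pA(self, t: np.ndarray) -> np.ndarray:
        """Injected current (pA) sampled at times ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        i = np.zeros_like(t)
        if self.kind == "current_step":
            i[(t >= self.onset) & (t < self.onset + self.duration)] = self.amplitude
        elif self.kind == "pulse_train":
            i[(t >= self.baseline_onset) & (t < self.onset + self.duration)] = self.baseline
            for k in range(self.n_pulses):
                t0 = self.onset + k * self.interval
                m = (t >= t0) & (t < t0 + self.pulse_width)
                i[m] += self.amplitude
        elif self.kind == "synaptic_train":
            i[(t >= self.baseline_onset) & (t < self.onset + self.duration)] = self.baseline
            # double-exponential normalized to unit peak
            tpk = (
                self.rise * self.decay / (self.decay - self.rise)
                * math.log(self.decay / self.rise)
                if self.decay != self.rise
                else self.rise
            )
            norm = math.exp(-tpk / self.decay) - math.exp(-tpk / self.rise)
            for t0 in self.event_times:
                dt = t - t0
                m = dt >= 0
                i[m] += (
                    self.event_peak
                    * (np.exp(-dt[m] / self.decay) - np.exp(-dt[m] / self.rise))
                    / norm
                )
        else:
            raise ValueError("clamp protocol carries no current waveform")
        return i

    def command_mV(self, t: np.ndarray) -> np.ndarray:
        """Clamp command voltage (mV) at times ``t``."""
        if not self.is_clamp:
            raise ValueError("not a clamp protocol")
        t = np.asarray(t, dtype=float)
        v = np.full_like(t, self.hold_potential)
        v[(t >= self.onset) & (t < self.onset + self.duration)] = self.amplitude
        return v


def make_synaptic_train(
    intensity: float,
    n_events: int = 10,
    rate: float = 100.0,
    rise: float = 0.5,
    decay: float = 5.0,
    unit_peak: float = 40.0,
    onset: float = 20.0,
) -> StimulusProtocol:
    """Somatic synaptic-like current train of configurable intensity.

    ``intensity`` scales the per-event peak (``unit_peak`` pA at intensity 1).
    Over intensities of roughly 1–30 the somatic depolarization rise time
    from rest to the first-spike threshold spans ~5–200 ms in the default
    model.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if rise <= 0 or decay <= 0 or rate <= 0:
        raise ValueError("kinetic constants must be positive")
    times = tuple(onset + 1000.0 * k / rate for k in range(n_events))
    return StimulusProtocol(
        kind="synaptic_train",
        section="soma",
        rise=rise,
        decay=decay,
        event_times=times,
        event_peak=intensity * unit_peak,
        onset=onset,
        duration=times[-1] - onset + 10.0 * decay if n_events > 0 else decay,
    )


def forced_spike_protocol(
    n_spikes: int = 5,
    rate: float = 20.0,
    hold_at_rest: bool = True,
    pulse_amplitude: float = 2500.0,
    pulse_rise: float = 0.3,
    pulse_decay: float = 0.8,
    depolarizing_current: float = 90.0,
    onset: float = 40.0,
    square: bool = False,
    pulse_width: float = 0.5,
) -> StimulusProtocol:
    """Brief suprathreshold pulses with or without a holding depolarization.

    ``hold_at_rest=True`` is the "Spikes only" protocol (inter-pulse baseline
    current zero); ``False`` superimposes a constant subthreshold
    depolarizing current ("Depo+Spikes").  Pulses default to smooth-edged
    (double-exponential, ~0.9 ms half-width) waveforms, emulating a filtered
    stimulus; ``square=True`` gives ideal rectangular pulses of
    ``pulse_width`` ms (their instantaneous edges superimpose a capacitive
    dV/dt transient on the somatic trace).
    """
    if n_spikes < 1 or rate <= 0:
        raise ValueError("n_spikes and rate must be positive")
    baseline = 0.0 if hold_at_rest else depolarizing_current
    baseline_onset = max(0.0, onset - 15.0)
    if square:
        return StimulusProtocol(
            kind="pulse_train",
            section="soma",
            amplitude=pulse_amplitude,
            pulse_width=pulse_width,
            onset=onset,
            n_pulses=n_spikes,
            interval=1000.0 / rate,
            baseline=baseline,
            baseline_onset=baseline_onset,
            duration=n_spikes * 1000.0 / rate,
        )
    times = tuple(onset + 1000.0 * k / rate for k in range(n_spikes))
    return StimulusProtocol(
        kind="synaptic_train",
        section="soma",
        rise=pulse_rise,
        decay=pulse_decay,
        event_times=times,
        event_peak=pulse_amplitude,
        baseline=baseline,
        baseline_onset=baseline_onset,
        onset=onset,
        duration=n_spikes * 1000.0 / rate,
    )


def voltage_step_clamp(
    hold: float = -75.0, step_to: float = 10.0, onset: float = 20.0,
    duration: float = 50.0, section: str = "soma",
) -> StimulusProtocol:
    """Ideal somatic voltage clamp stepping from ``hold`` to ``step_to`` mV."""
    return StimulusProtocol(
        kind="voltage_step_clamp", section=section, amplitude=step_to,
        hold_potential=hold, onset=onset, duration=duration,
    )


# ---------------------------------------------------------------------------
# Solver configuration and output container
# ---------------------------------------------------------------------------


@dataclass
class SolverConfig:
    dt: float = 0.01  # ms
    duration: float = 300.0  # ms
    record_dt: float = 0.02  # ms
    init_duration: float = 500.0  # ms settling run
    init_dt: float = 0.025  # ms
    theta: float = 0.5  # Crank-Nicolson weight
    record_currents: tuple[str, ...] = ()  # channel names, e.g. ("ca",)
    record_gates: tuple[str, ...] = ()  # "channel.gate", e.g. ("na_a.h",)

    def __post_init__(self) -> None:
        if not 0.001 <= self.dt <= 0.05:
            raise ValueError("dt must be in [0.001, 0.05] ms")
        if self.record_dt < self.dt:
            raise ValueError("record_dt must be >= dt")


@dataclass
class StateTrace:
    """Multi-site recording from one simulation run."""

    t: np.ndarray  # ms, from protocol start
    v: np.ndarray  # (nt, ncomp) mV
    dist_um: np.ndarray
    kind_code: np.ndarray
    section_id: list[str]
    currents: dict[str, np.ndarray] = field(default_factory=dict)  # mA/cm²
    gates: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def soma_index(self) -> int:
        return int(np.nonzero(self.kind_code == 0)[0][len(np.nonzero(self.kind_code == 0)[0]) // 2])

    def axon_indices(self) -> np.ndarray:
        idx = np.nonzero(self.kind_code == 1)[0]
        return idx[np.argsort(self.dist_um[idx])]

    def site_index(self, distance: float, kind: str = "axon_main") -> int:
        from .morphology import SECTION_KINDS

        code = SECTION_KINDS.index(kind)
        idx = np.nonzero(self.kind_code == code)[0]
        if idx.size == 0:
            raise ValueError(f"no sites of kind {kind}")
        return int(idx[np.argmin(np.abs(self.dist_um[idx] - distance))])

    def voltage_at(self, distance: float, kind: str = "axon_main") -> np.ndarray:
        return self.v[:, self.site_index(distance, kind)]


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate(
    v, x, parent, lcoef, ucoef, axd, cm_over, gbar, erev,
    gate_chan, gate_exp, gvhalf, gslope, gfloor, gtkind, gtbase, gtamp,
    gtvpeak, gtwidth, dt, theta, nsteps, stim_comp, stim_uacm2, clamp_comp,
    clamp_v, rec_every, rec_chan, rec_gate, v_out, i_out, g_out,
):  # pragma: no cover - exercised via run()
    ncomp = v.shape[0]
    nchan = gbar.shape[1]
    ngate = gate_chan.shape[0]
    d = np.empty(ncomp)
    b = np.empty(ncomp)
    gtot = np.empty(ncomp)
    gesum = np.empty(ncomp)
    for n in range(nsteps):
        # staggered gating update (Rush-Larsen at current V)
        for i in range(ncomp):
            vi = v[i]
            for g in range(ngate):
                xinf = gfloor[g] + (1.0 - gfloor[g]) / (
                    1.0 + math.exp(-(vi - gvhalf[g]) / gslope[g])
                )
                if gtkind[g] == 0:
                    dv = vi - gtvpeak[g]
                    tau = gtbase[g] + gtamp[g] * math.exp(
                        -(dv * dv) / (2.0 * gtwidth[g] * gtwidth[g])
                    )
                else:
                    tau = gtbase[g] + gtamp[g] / (
                        1.0 + math.exp((vi - gtvpeak[g]) / gtwidth[g])
                    )
                x[i, g] = xinf + (x[i, g] - xinf) * math.exp(-dt / tau)
        # channel conductances with frozen gates
        for i in range(ncomp):
            gt = 0.0
            ge = 0.0
            for c in range(nchan):
                gb = gbar[i, c]
                if gb > 0.0:
                    p = 1.0
                    for g in range(ngate):
                        if gate_chan[g] == c:
                            xv = x[i, g]
                            for _ in range(gate_exp[g]):
                                p *= xv
                    gc = gb * p
                    gt += gc
                    ge += gc * erev[i, c]
            gtot[i] = gt
            gesum[i] = ge
        # assemble diag and rhs
        for i in range(ncomp):
            d[i] = cm_over + theta * (gtot[i] + axd[i])
            b[i] = (cm_over - (1.0 - theta) * (gtot[i] + axd[i])) * v[i] + gesum[i]
        for i in range(1, ncomp):
            p = parent[i]
            b[i] += (1.0 - theta) * lcoef[i] * v[p]
            b[p] += (1.0 - theta) * ucoef[i] * v[i]
        if stim_comp >= 0:
            b[stim_comp] += stim_uacm2[n]
        if clamp_comp >= 0:
            d[clamp_comp] += _GBIG
            b[clamp_comp] += _GBIG * clamp_v[n]
        # Hines elimination (children into parents), then forward substitution
        for i in range(ncomp - 1, 0, -1):
            p = parent[i]
            f = (-theta * ucoef[i]) / d[i]
            d[p] -= f * (-theta * lcoef[i])
            b[p] -= f * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, ncomp):
            v[i] = (b[i] + theta * lcoef[i] * v[parent[i]]) / d[i]
        for i in range(ncomp):
            if not (-120.0 <= v[i] <= 80.0):
                return n, i
        if rec_every > 0 and (n + 1) % rec_every == 0:
            r = (n + 1) // rec_every
            for i in range(ncomp):
                v_out[r, i] = v[i]
            for k in range(rec_chan.shape[0]):
                c = rec_chan[k]
                for i in range(ncomp):
                    p = 1.0
                    for g in range(ngate):
                        if gate_chan[g] == c:
                            xv = x[i, g]
                            for _ in range(gate_exp[g]):
                                p *= xv
                    i_out[r, k, i] = gbar[i, c] * p * (v[i] - erev[i, c]) / 1000.0
            for k in range(rec_gate.shape[0]):
                for i in range(ncomp):
                    g_out[r, k, i] = x[i, rec_gate[k]]
    return -1, -1


def _kernel_args(grid: CompartmentGrid, dt: float, theta: float):
    ncomp = grid.n_comp
    lcoef = np.zeros(ncomp)
    ucoef = np.zeros(ncomp)
    axd = np.zeros(ncomp)
    for i in range(1, ncomp):
        p = grid.parent[i]
        lcoef[i] = grid.gpair_uS[i] / (1e3 * grid.area_cm2[i])
        ucoef[i] = grid.gpair_uS[i] / (1e3 * grid.area_cm2[p])
        axd[i] += lcoef[i]
        axd[p] += ucoef[i]
    return lcoef, ucoef, axd


def _comp_of(grid: CompartmentGrid, section: str, position: float) -> int:
    idx = [i for i, s in enumerate(grid.section_id) if s == section]
    if not idx:
        raise ValueError(f"unknown section {section!r}")
    k = min(int(position * len(idx)), len(idx) - 1)
    return idx[k]


def _settle(model: CableModel, config: SolverConfig):
    """Steady-state initialization; cached on the model."""
    key = (config.init_duration, config.init_dt, config.theta)
    if model._init_state is not None and model._init_state[0] == key:
        return model._init_state[1].copy(), model._init_state[2].copy()
    grid = model.discretize()
    v = np.full(grid.n_comp, model.resting_potential, dtype=float)
    x = grid.steady_gates(v)
    lcoef, ucoef, axd = _kernel_args(grid, config.init_dt, config.theta)
    nsteps = int(round(config.init_duration / config.init_dt))
    empty_i = np.zeros(0, dtype=np.int64)
    status = _integrate(
        v, x, grid.parent, lcoef, ucoef, axd,
        grid.cm_uF / config.init_dt, grid.gbar_mS, grid.erev,
        grid.gate_channel, grid.gate_exp, grid.gate_vhalf, grid.gate_slope,
        grid.gate_floor, grid.gate_tau_kind, grid.gate_tau_base,
        grid.gate_tau_amp, grid.gate_tau_vpeak, grid.gate_tau_width,
        config.init_dt, config.theta, nsteps, -1, np.zeros(0), -1, np.zeros(0),
        0, empty_i, empty_i,
        np.zeros((1, grid.n_comp)), np.zeros((1, 0, grid.n_comp)),
        np.zeros((1, 0, grid.n_comp)),
    )
    if status[0] >= 0:
        raise SolverError(
            f"steady-state initialization diverged at step {status[0]}, "
            f"compartment {status[1]}"
        )
    drift = np.max(np.abs(v - model.resting_potential))
    if drift > 2.0:
        raise SolverError(
            f"steady-state initialization settled {drift:.2f} mV away from "
            "the configured resting potential"
        )
    model._init_state = (key, v.copy(), x.copy())
    return v, x


def run(
    model: CableModel, protocol: StimulusProtocol, config: SolverConfig | None = None
) -> StateTrace:
    """Integrate the model under a protocol and return the recorded trace.

    Deterministic given identical inputs.  Raises :class:`SolverError` on
    divergence (voltage outside [-120, +80] mV), naming the offending time
    and site.
    """
    if config is None:
        config = SolverConfig()
    grid = model.discretize()
    v, x = _settle(model, config)
    lcoef, ucoef, axd = _kernel_args(grid, config.dt, config.theta)
    rec_every = max(1, int(round(config.record_dt / config.dt)))
    nsteps = int(round(config.duration / config.dt))
    nsteps = (nsteps // rec_every) * rec_every
    nrec = nsteps // rec_every + 1

    stim_comp = -1
    clamp_comp = -1
    stim_arr = np.zeros(0)
    clamp_arr = np.zeros(0)
    comp = _comp_of(grid, protocol.section, protocol.position)
    tmid = (np.arange(nsteps) + 0.5) * config.dt
    if protocol.is_clamp:
        clamp_comp = comp
        clamp_arr = protocol.command_mV((np.arange(nsteps) + 1.0) * config.dt)
    else:
        stim_comp = comp
        # pA -> µA/cm² at the injected compartment
        stim_arr = protocol.current_pA(tmid) * 1e-6 / grid.area_cm2[comp]

    rec_chan = np.asarray(
        [grid.channel_index(c) for c in config.record_currents], dtype=np.int64
    )
    gate_names: list[str] = []
    for ci, cname in enumerate(grid.channel_names):
        count = 0
        for g in np.nonzero(grid.gate_channel == ci)[0]:
            gate_names.append(f"{cname}.{_gate_label(grid, ci, count)}")
            count += 1
    rec_gate = np.asarray(
        [gate_names.index(n) for n in config.record_gates], dtype=np.int64
    )

    v_out = np.zeros((nrec, grid.n_comp))
    i_out = np.zeros((nrec, rec_chan.size, grid.n_comp))
    g_out = np.zeros((nrec, rec_gate.size, grid.n_comp))
    v_out[0] = v
    status = _integrate(
        v, x, grid.parent, lcoef, ucoef, axd,
        grid.cm_uF / config.dt, grid.gbar_mS, grid.erev,
        grid.gate_channel, grid.gate_exp, grid.gate_vhalf, grid.gate_slope,
        grid.gate_floor, grid.gate_tau_kind, grid.gate_tau_base,
        grid.gate_tau_amp, grid.gate_tau_vpeak, grid.gate_tau_width,
        config.dt, config.theta, nsteps, stim_comp, stim_arr, clamp_comp,
        clamp_arr, rec_every, rec_chan, rec_gate, v_out, i_out, g_out,
    )
    if status[0] >= 0:
        raise SolverError(
            f"solver diverged at t={status[0] * config.dt:.3f} ms, "
            f"compartment {status[1]} "
            f"(section {grid.section_id[status[1]]}, "
            f"{grid.dist_um[status[1]]:.1f} µm)"
        )
    # fill initial current/gate rows from initial state for completeness
    if rec_chan.size or rec_gate.size:
        i_out[0] = i_out[1]
        g_out[0] = g_out[1]
    t = np.arange(nrec) * rec_every * config.dt
    currents = {
        config.record_currents[k]: i_out[:, k, :] for k in range(rec_chan.size)
    }
    gates = {config.record_gates[k]: g_out[:, k, :] for k in range(rec_gate.size)}
    return StateTrace(
        t=t,
        v=v_out,
        dist_um=grid.dist_um.copy(),
        kind_code=grid.kind_code.copy(),
        section_id=list(grid.section_id),
        currents=currents,
        gates=gates,
        meta={
            "protocol": protocol.kind,
            "dt": config.dt,
            "record_dt": rec_every * config.dt,
            "resting_potential": model.resting_potential,
        },
    )


def _gate_label(grid: CompartmentGrid, chan_idx: int, ordinal: int) -> str:
    # gate names are not stored in the grid; label by conventional order
    names = {"na_s": ["m", "h", "s"], "na_a": ["m", "h", "s"], "kdr": ["n", "z"],
             "kv1": ["d"], "ca": ["mc", "hc"], "leak": []}
    cname = grid.channel_names[chan_idx]
    lst = names.get(cname)
    if lst is None or ordinal >= len(lst):
        return f"g{ordinal}"
    return lst[ordinal]


def na_availability(trace: StateTrace) -> np.ndarray | None:
    """Product of recorded axonal-Na inactivation gates (h and, if present, s)."""
    h = trace.gates.get("na_a.h")
    if h is None:
        return None
    s = trace.gates.get("na_a.s")
    return h * s if s is not None else h.copy()
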