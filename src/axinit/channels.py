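"""Hodgkin–Huxley-style channel models with configurable gating kinetics.

All channels follow the generic formalism ``g = gbar * prod_k x_k^p_k`` with
first-order gating variables relaxing to a sigmoidal steady state

    x_inf(V) = floor + (1 - floor) / (1 + exp(-(V - vhalf)/slope))

(``slope`` > 0: activation, increasing with depolarization; ``slope`` < 0:
inactivation, decreasing).  Time constants are either bell-shaped

    tau(V) = tau_base + tau_amp * exp(-(V - tau_vpeak)^2 / (2 tau_width^2))

or sigmoidal (used for slow inactivation, where recovery at rest is much
slower than onset during depolarization)

    tau(V) = tau_base + tau_amp / (1 + exp((V - tau_vpeak)/tau_width)).

The somatic and axonal Na+ variants differ in their inactivation: the axonal
variant inactivates at voltages ~10 mV more hyperpolarized and carries an
optional slow, depolarization-dependent inactivation gate with a recovery
time constant of hundreds of milliseconds at rest.  That slow component is
the mechanistic ingredient by which sustained somatic depolarization reduces
proximal-axonal Na+ channel availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "gate_inf",
    "gate_tau",
    "default_channel_set",
    "VALID_VARIANTS",
]

VALID_VARIANTS = ("Na_somatic", "Na_axonal", "K_dr", "Ca_generic", "leak")

TAU_BELL = 0
TAU_SIGMOID = 1


@dataclass(frozen=True)
class GateSpec:
    """One first-order gating variable."""

    name: str
    exponent: int
    vhalf: float  # mV
    slope: float  # mV, sign selects activation (+) vs inactivation (-)
    tau_base: float  # ms
    tau_amp: float = 0.0  # ms
    tau_vpeak: float = -50.0  # mV
    tau_width: float = 20.0  # mV
    floor: float = 0.0  # lower bound of the steady-state curve
    tau_kind: str = "bell"  # "bell" | "sigmoid"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError(f"gate {self.name}: slope must be nonzero")
        if self.exponent < 1:
            raise ValueError(f"gate {self.name}: exponent must be >= 1")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError(f"gate {self.name}: floor must be in [0, 1)")
        if self.tau_kind not in ("bell", "sigmoid"):
            raise ValueError(f"gate {self.name}: unknown tau_kind {self.tau_kind!r}")
        v = np.linspace(-100.0, 60.0, 321)
        if np.any(gate_tau(self, v) <= 0):
            raise ValueError(
                f"gate {self.name}: time constant must be positive on [-100, 60] mV"
            )


def gate_inf(gate: GateSpec, v) -> np.ndarray:
    """Steady-state value of a gate at voltage ``v`` (mV)."""
    v = np.asarray(v, dtype=float)
    return gate.floor + (1.0 - gate.floor) / (1.0 + np.exp(-(v - gate.vhalf) / gate.slope))


def gate_tau(gate: GateSpec, v) -> np.ndarray:
    """Voltage-dependent time constant of a gate (ms)."""
    v = np.asarray(v, dtype=float)
    if gate.tau_kind == "bell":
        return gate.tau_base + gate.tau_amp * np.exp(
            -((v - gate.tau_vpeak) ** 2) / (2.0 * gate.tau_width**2)
        )
    return gate.tau_base + gate.tau_amp / (1.0 + np.exp((v - gate.tau_vpeak) / gate.tau_width))


@dataclass(frozen=True)
class ChannelSpec:
    """A membrane conductance with its reversal potential and gating scheme."""

    name: str
    variant: str
    reversal_potential: float  # mV
    gates: tuple[GateSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.variant not in VALID_VARIANTS:
            raise ValueError(f"unknown channel variant {self.variant!r}")

    def open_fraction(self, v) -> np.ndarray:
        """Steady-state open probability at voltage ``v``."""
        v = np.asarray(v, dtype=float)
        p = np.ones_like(v)
        for g in self.gates:
            p = p * gate_inf(g, v) ** g.exponent
        return p

    def availability(self, v) -> np.ndarray:
        """Steady-state product of inactivation gates (slope < 0) at ``v``."""
        v = np.asarray(v, dtype=float)
        p = np.ones_like(v)
        for g in self.gates:
            if g.slope < 0:
                p = p * gate_inf(g, v) ** g.exponent
        return p

    def with_gate(self, gate: GateSpec) -> "ChannelSpec":
        return replace(self, gates=self.gates + (gate,))


# ---------------------------------------------------------------------------
# Default channel set
# ---------------------------------------------------------------------------

E_NA = 58.0
E_K = -95.0
E_LEAK = -80.0
E_CA = 120.0


def _na_m(vhalf: float) -> GateSpec:
    return GateSpec(
        "m", 3, vhalf=vhalf, slope=6.0,
        tau_base=0.04, tau_amp=0.30, tau_vpeak=vhalf, tau_width=15.0,
    )


def _na_h(vhalf: float) -> GateSpec:
    return GateSpec(
        "h", 1, vhalf=vhalf, slope=-6.0,
        tau_base=0.25, tau_amp=5.0, tau_vpeak=vhalf, tau_width=15.0,
    )


def na_slow_gate(
    vhalf: float = -60.0,
    slope: float = -3.5,
    floor: float = 0.02,
    tau_slow: float = 460.0,
    tau_dip: float = 425.0,
    tau_dip_v: float = None,
    tau_dip_width: float = 6.0,
) -> GateSpec:
    """Slow, depolarization-dependent inactivation gate for axonal Na+.

    The steady state is near 1 at rest and falls steeply over the
    subthreshold depolarized range.  The time constant is slow (~0.5 s) both
    at rest and at spike voltages but dips to ~40 ms in the subthreshold
    band around -55 mV: sustained depolarization drives inactivation within
    tens of milliseconds, whereas brief spikes barely move the gate and
    recovery at rest takes hundreds of milliseconds — the voltage
    selectivity that separates depolarization-dependent inactivation from
    ordinary post-spike inactivation.
    """
    if tau_dip_v is None:
        tau_dip_v = vhalf + 5.0
    return GateSpec(
        "s", 1, vhalf=vhalf, slope=slope, floor=floor,
        tau_base=tau_slow, tau_amp=-tau_dip, tau_vpeak=tau_dip_v,
        tau_width=tau_dip_width, tau_kind="bell",
    )


def k_slow_gate(
    vhalf: float = -66.0,
    slope: float = -4.0,
    floor: float = 0.0,
) -> GateSpec:
    """Optional slow inactivation gate for the delayed rectifier.

    Disabled by default; enabling it emulates strong depolarization-dependent
    K+ channel inactivation (spike broadening), the direction-of-effect
    control for the Ca2+ readout.
    """
    return GateSpec(
        "z", 1, vhalf=vhalf, slope=slope, floor=floor,
        tau_base=460.0, tau_amp=-445.0, tau_vpeak=vhalf + 6.0, tau_width=10.0,
        tau_kind="bell",
    )


def default_channel_set(
    slow_inactivation: bool = True,
    k_inactivation: bool = False,
    na_axonal_h_shift: float = -13.0,
) -> dict[str, ChannelSpec]:
    """Build the default channel specs.

    Parameters
    ----------
    slow_inactivation:
        Attach the slow inactivation gate to the axonal Na+ variant.
    k_inactivation:
        Attach a slow inactivation gate to the delayed rectifier (control
        configuration; off by default).
    na_axonal_h_shift:
        Shift (mV) of the axonal Na+ fast-inactivation half-voltage relative
        to the somatic variant; negative = hyperpolarized.
    """
    na_s = ChannelSpec(
        "na_s", "Na_somatic", E_NA, gates=(_na_m(-36.0), _na_h(-52.0))
    )
    na_a = ChannelSpec(
        "na_a", "Na_axonal", E_NA,
        gates=(_na_m(-41.0), _na_h(-52.0 + na_axonal_h_shift)),
    )
    if slow_inactivation:
        # both variants carry the slow component; the axonal variant
        # inactivates at ~10 mV more hyperpolarized potentials
        na_a = na_a.with_gate(na_slow_gate(vhalf=-60.0))
        na_s = na_s.with_gate(na_slow_gate(vhalf=-60.0 - na_axonal_h_shift))
    kdr = ChannelSpec(
        "kdr", "K_dr", E_K,
        gates=(
            GateSpec(
                "n", 4, vhalf=-33.0, slope=10.0,
                tau_base=0.6, tau_amp=2.6, tau_vpeak=-55.0, tau_width=25.0,
            ),
        ),
    )
    if k_inactivation:
        kdr = kdr.with_gate(k_slow_gate())
    kv1 = ChannelSpec(
        "kv1", "K_dr", E_K,
        gates=(
            GateSpec(
                "d", 1, vhalf=-50.0, slope=6.0,
                tau_base=1.5, tau_amp=8.0, tau_vpeak=-60.0, tau_width=20.0,
            ),
        ),
    )
    ca = ChannelSpec(
        "ca", "Ca_generic", E_CA,
        gates=(
            GateSpec(
                "mc", 2, vhalf=-5.0, slope=6.0,
                tau_base=0.4, tau_amp=1.0, tau_vpeak=-10.0, tau_width=20.0,
            ),
            # inactivates only during prolonged strong depolarization;
            # effectively non-inactivating at subthreshold voltages
            GateSpec(
                "hc", 1, vhalf=-30.0, slope=-8.0,
                tau_base=80.0, tau_amp=0.0,
            ),
        ),
    )
    leak = ChannelSpec("leak", "leak", E_LEAK, gates=())
    return {"na_s": na_s, "na_a": na_a, "kdr": kdr, "kv1": kv1, "ca": ca,
            "leak": leak}
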