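"""Simplified dentate granule-cell morphology and channel-density maps.

The morphology is a tree of cylindrical sections: a compact soma, one
equivalent dendritic cylinder, a long unmyelinated main axon (a mossy
fibre), and optional thin axon collaterals.  It preserves the property the
initiation-zone mechanism depends on — electrotonic coupling between the
soma and the proximal axon — without attempting to reproduce a full 3D
reconstruction.

Distance convention: arc length along the axon from the soma–axon junction,
in µm; the soma sits at 0 and dendritic positions are negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelSpec, GateSpec, default_channel_set, gate_inf, gate_tau

__all__ = [
    "Section",
    "DensityProfile",
    "CableModel",
    "CompartmentGrid",
    "GranuleCellParams",
    "build_granule_cell",
    "density_at",
    "read_swc",
    "write_swc",
]

SECTION_KINDS = ("soma", "axon_main", "axon_collateral", "dendrite")
_KIND_CODE = {k: i for i, k in enumerate(SECTION_KINDS)}


@dataclass(frozen=True)
class Section:
    """One cylindrical piece of the cell."""

    id: str
    parent: str | None
    length: float  # µm
    diameter: float  # µm
    axial_resistivity: float  # Ω·cm
    n_compartments: int
    kind: str
    parent_position: float = 1.0  # 0..1 fraction of parent arc length

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"section {self.id}: length must be > 0")
        if self.diameter <= 0:
            raise ValueError(f"section {self.id}: diameter must be > 0")
        if self.axial_resistivity <= 0:
            raise ValueError(f"section {self.id}: axial resistivity must be > 0")
        if self.n_compartments < 1:
            raise ValueError(f"section {self.id}: n_compartments must be >= 1")
        if self.kind not in SECTION_KINDS:
            raise ValueError(f"section {self.id}: unknown kind {self.kind!r}")
        if not 0.0 <= self.parent_position <= 1.0:
            raise ValueError(f"section {self.id}: parent_position must be in [0, 1]")


@dataclass(frozen=True)
class DensityProfile:
    """Conductance density as a function of axial distance from the soma."""

    channel: str
    profile_kind: str  # "uniform" | "gaussian_hotspot" | "piecewise_linear"
    baseline: float = 0.0  # S·cm⁻²
    peak: float = 0.0  # S·cm⁻² above baseline (gaussian_hotspot)
    peak_position: float = 0.0  # µm
    width: float = 1.0  # µm
    xs: tuple[float, ...] = ()  # piecewise_linear nodes
    ys: tuple[float, ...] = ()
    applies_to: tuple[str, ...] = SECTION_KINDS

    def __post_init__(self) -> None:
        if self.profile_kind not in ("uniform", "gaussian_hotspot", "piecewise_linear"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        if self.baseline < 0 or self.peak < 0:
            raise ValueError("densities must be nonnegative")
        if self.profile_kind == "gaussian_hotspot" and self.width <= 0:
            raise ValueError("gaussian width must be positive")
        if self.profile_kind == "piecewise_linear":
            if len(self.xs) != len(self.ys) or len(self.xs) < 2:
                raise ValueError("piecewise_linear needs matching xs/ys with >= 2 nodes")
            if any(y < 0 for y in self.ys):
                raise ValueError("densities must be nonnegative")


def density_at(profile: DensityProfile, distance) -> np.ndarray:
    """Evaluate a density profile (S·cm⁻²) at axial distance(s) in µm."""
    x = np.asarray(distance, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be >= 0")
    if profile.profile_kind == "uniform":
        return np.broadcast_to(np.float64(profile.baseline), x.shape).copy()
    if profile.profile_kind == "gaussian_hotspot":
        return profile.baseline + profile.peak * np.exp(
            -((x - profile.peak_position) ** 2) / (2.0 * profile.width**2)
        )
    return np.interp(x, profile.xs, profile.ys)


@dataclass
class CompartmentGrid:
    """Flattened, solver-ready discretization of a :class:`CableModel`."""

    parent: np.ndarray  # int, -1 for root; parent[i] < i
    area_cm2: np.ndarray
    gpair_uS: np.ndarray  # coupling conductance to parent, µS
    dist_um: np.ndarray  # signed arc distance (soma 0, dendrite < 0)
    kind_code: np.ndarray
    section_id: list[str]
    comp_length_um: np.ndarray
    diameter_um: np.ndarray
    gbar_mS: np.ndarray  # (ncomp, nchan) mS·cm⁻²
    erev: np.ndarray  # (ncomp, nchan) mV
    channel_names: list[str]
    channel_variants: list[str]
    gate_channel: np.ndarray
    gate_exp: np.ndarray
    gate_vhalf: np.ndarray
    gate_slope: np.ndarray
    gate_floor: np.ndarray
    gate_tau_kind: np.ndarray
    gate_tau_base: np.ndarray
    gate_tau_amp: np.ndarray
    gate_tau_vpeak: np.ndarray
    gate_tau_width: np.ndarray
    cm_uF: float = 1.0

    @property
    def n_comp(self) -> int:
        return self.parent.size

    @property
    def n_gates(self) -> int:
        return self.gate_channel.size

    def axon_main_mask(self) -> np.ndarray:
        return self.kind_code == _KIND_CODE["axon_main"]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def steady_gates(self, v: np.ndarray) -> np.ndarray:
        """Steady-state gate matrix (ncomp, ngates) at per-compartment voltage."""
        x = np.empty((self.n_comp, self.n_gates))
        for g in range(self.n_gates):
            x[:, g] = self.gate_floor[g] + (1.0 - self.gate_floor[g]) / (
                1.0 + np.exp(-(v - self.gate_vhalf[g]) / self.gate_slope[g])
            )
        return x


@dataclass
class CableModel:
    """A branched cable with attached channel conductances."""

    sections: list[Section]
    channels: list[tuple[ChannelSpec, DensityProfile]]
    membrane_capacitance: float = 1.0  # µF·cm⁻²
    resting_potential: float = -79.0  # mV
    temperature_label: float = 25.0  # °C, metadata only
    calibrate_rest: bool = True
    _grid: CompartmentGrid | None = field(default=None, repr=False, compare=False)
    _init_state: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate section ids")
        by_id = {s.id: s for s in self.sections}
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1 or roots[0].kind != "soma":
            raise ValueError("connectivity must be a tree rooted at a single soma")
        seen: set[str] = set()
        for s in self.sections:
            if s.parent is not None and s.parent not in by_id:
                raise ValueError(f"section {s.id}: unknown parent {s.parent}")
            node, hops = s, 0
            while node.parent is not None:
                node = by_id[node.parent]
                hops += 1
                if hops > len(self.sections):
                    raise ValueError("connectivity contains a cycle (not a tree)")
            seen.add(s.id)
        leaks = [c for c, _ in self.channels if c.variant == "leak"]
        if len(leaks) != 1:
            raise ValueError("model must have exactly one leak conductance")

    # -- discretization ----------------------------------------------------
    def discretize(self) -> CompartmentGrid:
        if self._grid is not None:
            return self._grid
        by_id = {s.id: s for s in self.sections}
        # topological order: parents before children
        ordered: list[Section] = []
        placed: set[str] = set()
        pending = list(self.sections)
        while pending:
            progressed = False
            for s in list(pending):
                if s.parent is None or s.parent in placed:
                    ordered.append(s)
                    placed.add(s.id)
                    pending.remove(s)
                    progressed = True
            if not progressed:  # pragma: no cover - validate() catches this
                raise ValueError("sections do not form a tree")

        comp_sec: list[str] = []
        parent: list[int] = []
        area: list[float] = []
        gpair: list[float] = []
        dist: list[float] = []
        kind: list[int] = []
        clen: list[float] = []
        cdiam: list[float] = []
        # per-section bookkeeping: first comp index, comp centers (arc in section)
        sec_first: dict[str, int] = {}
        sec_centers: dict[str, np.ndarray] = {}
        sec_base_dist: dict[str, float] = {}

        def half_r(sec: Section, length_um: float) -> float:
            """Axial resistance (MΩ→Ω) of half a compartment of given length."""
            r_cm = sec.diameter * 1e-4 / 2.0
            l_cm = length_um * 1e-4 / 2.0
            return sec.axial_resistivity * l_cm / (math.pi * r_cm**2)

        for s in ordered:
            n = s.n_compartments
            dl = s.length / n
            centers = (np.arange(n) + 0.5) * dl
            sec_first[s.id] = len(comp_sec)
            sec_centers[s.id] = centers
            if s.parent is None:
                base = 0.0
                pcomp = -1
            else:
                psec = by_id[s.parent]
                # distance of the attachment point along the parent
                p_centers = sec_centers[s.parent]
                attach_arc = s.parent_position * psec.length
                j = int(np.argmin(np.abs(p_centers - attach_arc)))
                pcomp = sec_first[s.parent] + j
                pbase = sec_base_dist[s.parent]
                if psec.kind == "soma":
                    base = 0.0  # soma-axon junction defines distance 0
                elif s.kind == "dendrite":
                    base = 0.0
                else:
                    base = pbase + attach_arc if psec.kind != "soma" else 0.0
            sec_base_dist[s.id] = base
            sign = -1.0 if s.kind == "dendrite" else 1.0
            lateral = math.pi * s.diameter * dl * 1e-8  # µm² -> cm²
            for k in range(n):
                comp_sec.append(s.id)
                kind.append(_KIND_CODE[s.kind])
                area.append(lateral)
                clen.append(dl)
                cdiam.append(s.diameter)
                if s.kind == "soma":
                    dist.append(0.0)
                else:
                    dist.append(sign * (base + centers[k]))
                if k == 0:
                    parent.append(pcomp)
                    if pcomp < 0:
                        gpair.append(0.0)
                    else:
                        psec = by_id[s.parent]
                        p_dl = psec.length / psec.n_compartments
                        r_ohm = half_r(s, dl) + half_r(psec, p_dl)
                        gpair.append(1e6 / r_ohm)
                else:
                    parent.append(len(comp_sec) - 2)
                    gpair.append(1e6 / (2.0 * half_r(s, dl)))

        parent_arr = np.asarray(parent, dtype=np.int64)
        if np.any(parent_arr >= np.arange(parent_arr.size)):
            raise RuntimeError("internal error: compartments not in tree order")

        # channel density assembly
        chan_names = [c.name for c, _ in self.channels]
        chan_vars = [c.variant for c, _ in self.channels]
        ncomp = parent_arr.size
        nchan = len(self.channels)
        gbar = np.zeros((ncomp, nchan))
        erev = np.zeros((ncomp, nchan))
        dist_arr = np.asarray(dist)
        kind_arr = np.asarray(kind, dtype=np.int64)
        for ci, (spec, prof) in enumerate(self.channels):
            erev[:, ci] = spec.reversal_potential
            mask = np.isin(kind_arr, [_KIND_CODE[k] for k in prof.applies_to])
            x = np.abs(dist_arr[mask])
            gbar[mask, ci] = density_at(prof, x) * 1e3  # S/cm² -> mS/cm²

        gates: list[tuple[int, GateSpec]] = []
        for ci, (spec, _) in enumerate(self.channels):
            for g in spec.gates:
                gates.append((ci, g))
        ng = len(gates)
        grid = CompartmentGrid(
            parent=parent_arr,
            area_cm2=np.asarray(area),
            gpair_uS=np.asarray(gpair),
            dist_um=dist_arr,
            kind_code=kind_arr,
            section_id=comp_sec,
            comp_length_um=np.asarray(clen),
            diameter_um=np.asarray(cdiam),
            gbar_mS=gbar,
            erev=erev,
            channel_names=chan_names,
            channel_variants=chan_vars,
            gate_channel=np.asarray([c for c, _ in gates], dtype=np.int64),
            gate_exp=np.asarray([g.exponent for _, g in gates], dtype=np.int64),
            gate_vhalf=np.asarray([g.vhalf for _, g in gates]),
            gate_slope=np.asarray([g.slope for _, g in gates]),
            gate_floor=np.asarray([g.floor for _, g in gates]),
            gate_tau_kind=np.asarray(
                [0 if g.tau_kind == "bell" else 1 for _, g in gates], dtype=np.int64
            ),
            gate_tau_base=np.asarray([g.tau_base for _, g in gates]),
            gate_tau_amp=np.asarray([g.tau_amp for _, g in gates]),
            gate_tau_vpeak=np.asarray([g.tau_vpeak for _, g in gates]),
            gate_tau_width=np.asarray([g.tau_width for _, g in gates]),
            cm_uF=self.membrane_capacitance,
        )
        if self.calibrate_rest:
            self._pin_rest(grid)
        self._grid = grid
        return grid

    def _pin_rest(self, grid: CompartmentGrid) -> None:
        """Shift the leak reversal so the configured rest is an exact fixed point.

        With stand-in channel kinetics the ionic window currents at rest do
        not exactly cancel at the configured resting potential; the leak
        reversal is adjusted per compartment (typically by < 1 mV) so that
        the total membrane current vanishes at rest in every compartment.
        """
        v = np.full(grid.n_comp, self.resting_potential)
        x = grid.steady_gates(v)
        li = grid.channel_index("leak")
        ionic = np.zeros(grid.n_comp)  # µA/cm², channels other than leak
        for ci in range(len(grid.channel_names)):
            if ci == li:
                continue
            p = np.ones(grid.n_comp)
            for g in np.nonzero(grid.gate_channel == ci)[0]:
                p *= x[:, g] ** grid.gate_exp[g]
            ionic += grid.gbar_mS[:, ci] * p * (v - grid.erev[:, ci])
        gl = grid.gbar_mS[:, li]
        if np.any(gl <= 0):
            raise ValueError("leak conductance must be positive everywhere to pin rest")
        grid.erev[:, li] = self.resting_potential + ionic / gl


# ---------------------------------------------------------------------------
# Default granule-cell fixture
# ---------------------------------------------------------------------------


@dataclass
class GranuleCellParams:
    """Parameters of the simplified granule-cell model.

    Printed defaults follow the study conditions: axonal axial resistivity
    80 Ω·cm, 0.25-µm collaterals at 300 Ω·cm with Na+/K+ maxima 0.012 and
    0.003 S·cm⁻², E_Na/E_K/E_leak = 58/−95/−80 mV, a uniform low-density
    generic Ca²⁺ channel (1e-7 S·cm⁻², as printed "100 nS cm⁻²"), resting
    potential −79 mV.  Channel kinetics and the axonal Na+ hotspot geometry
    are configurable stand-ins (see docs/methods.md).
    """

    soma_length: float = 10.0
    soma_diameter: float = 10.0
    dendrite_length: float = 400.0
    dendrite_diameter: float = 6.0
    axon_length: float = 1000.0
    axon_diameter: float = 0.5
    axon_ra: float = 80.0
    soma_ra: float = 150.0
    collateral_positions: tuple[float, ...] = (100.0, 200.0)
    collateral_length: float = 150.0
    collateral_diameter: float = 0.25
    collateral_ra: float = 300.0
    # spatial discretization (compartment length, µm)
    dx_proximal: float = 2.5  # 0-100 µm
    dx_mid: float = 5.0  # 100-200 µm
    dx_distal: float = 20.0
    # channel densities (S·cm⁻²)
    leak_density: float = 2.5e-5
    na_soma_density: float = 0.060
    na_dend_density: float = 0.004
    na_axon_baseline: float = 0.20
    na_axon_peak: float = 0.40  # above baseline
    na_hotspot_center: float = 13.0
    na_hotspot_width: float = 10.0
    k_soma_density: float = 0.020
    k_dend_density: float = 0.003
    k_axon_density: float = 0.045
    kv1_axon_density: float = 0.0008  # low-threshold (D-type) axonal K+
    na_collateral_density: float = 0.012
    k_collateral_density: float = 0.003
    ca_density: float = 1e-7
    # kinetics toggles
    slow_inactivation: bool = True
    k_inactivation: bool = False
    passive: bool = False
    resting_potential: float = -79.0
    temperature_label: float = 25.0

    def __post_init__(self) -> None:
        positive = (
            "soma_length", "soma_diameter", "dendrite_length",
            "dendrite_diameter", "axon_length", "axon_diameter", "axon_ra",
            "soma_ra", "collateral_length", "collateral_diameter",
            "collateral_ra", "dx_proximal", "dx_mid", "dx_distal",
            "leak_density", "na_hotspot_width",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nonnegative = (
            "na_soma_density", "na_dend_density", "na_axon_baseline",
            "na_axon_peak", "k_soma_density", "k_dend_density",
            "k_axon_density", "kv1_axon_density", "na_collateral_density",
            "k_collateral_density", "ca_density", "na_hotspot_center",
        )
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def build_granule_cell(params: GranuleCellParams | dict | None = None) -> CableModel:
    """Assemble the default soma–dendrite–axon(–collaterals) model.

    With ``passive=True`` all voltage-gated densities are zeroed and the
    resting potential equals the leak reversal (−80 mV).
    """
    if params is None:
        params = GranuleCellParams()
    elif isinstance(params, dict):
        params = GranuleCellParams(**params)
    p = params
    if p.axon_length < 500.0:
        raise ValueError("axon length must be >= 500 µm")
    if p.dx_proximal > 5.0 or p.dx_mid > 5.0:
        raise ValueError("compartment length must be <= 5 µm in the proximal 200 µm")

    def nseg(length: float, dx: float) -> int:
        return max(1, int(round(length / dx)))

    sections = [
        Section("soma", None, p.soma_length, p.soma_diameter, p.soma_ra, 3, "soma"),
        Section(
            "dend", "soma", p.dendrite_length, p.dendrite_diameter, p.soma_ra,
            nseg(p.dendrite_length, 20.0), "dendrite", parent_position=0.0,
        ),
        Section(
            "axon_prox", "soma", 100.0, p.axon_diameter, p.axon_ra,
            nseg(100.0, p.dx_proximal), "axon_main", parent_position=1.0,
        ),
        Section(
            "axon_mid", "axon_prox", 100.0, p.axon_diameter, p.axon_ra,
            nseg(100.0, p.dx_mid), "axon_main",
        ),
        Section(
            "axon_dist", "axon_mid", p.axon_length - 200.0, p.axon_diameter, p.axon_ra,
            nseg(p.axon_length - 200.0, p.dx_distal), "axon_main",
        ),
    ]
    for i, pos in enumerate(p.collateral_positions):
        if pos <= 100.0:
            par, frac = "axon_prox", pos / 100.0
        elif pos <= 200.0:
            par, frac = "axon_mid", (pos - 100.0) / 100.0
        else:
            par, frac = "axon_dist", (pos - 200.0) / (p.axon_length - 200.0)
        sections.append(
            Section(
                f"coll{i}", par, p.collateral_length, p.collateral_diameter,
                p.collateral_ra, nseg(p.collateral_length, 15.0),
                "axon_collateral", parent_position=frac,
            )
        )

    specs = default_channel_set(
        slow_inactivation=p.slow_inactivation, k_inactivation=p.k_inactivation
    )
    z = 0.0 if p.passive else 1.0
    channels = [
        (
            specs["na_s"],
            DensityProfile(
                "na_s", "piecewise_linear",
                xs=(0.0, p.dendrite_length),
                ys=(z * p.na_soma_density, z * p.na_dend_density),
                applies_to=("soma", "dendrite"),
            ),
        ),
        (
            specs["na_a"],
            DensityProfile(
                "na_a", "gaussian_hotspot",
                baseline=z * p.na_axon_baseline, peak=z * p.na_axon_peak,
                peak_position=p.na_hotspot_center, width=p.na_hotspot_width,
                applies_to=("axon_main",),
            ),
        ),
        (
            specs["na_a"],
            DensityProfile(
                "na_coll", "uniform", baseline=z * p.na_collateral_density,
                applies_to=("axon_collateral",),
            ),
        ),
        (
            specs["kdr"],
            DensityProfile(
                "kdr", "piecewise_linear",
                xs=(0.0, p.dendrite_length),
                ys=(z * p.k_soma_density, z * p.k_dend_density),
                applies_to=("soma", "dendrite"),
            ),
        ),
        (
            specs["kdr"],
            DensityProfile(
                "kdr_axon", "uniform", baseline=z * p.k_axon_density,
                applies_to=("axon_main",),
            ),
        ),
        (
            specs["kdr"],
            DensityProfile(
                "kdr_coll", "uniform", baseline=z * p.k_collateral_density,
                applies_to=("axon_collateral",),
            ),
        ),
        (
            specs["kv1"],
            DensityProfile(
                "kv1", "uniform", baseline=z * p.kv1_axon_density,
                applies_to=("axon_main", "axon_collateral"),
            ),
        ),
        (
            specs["ca"],
            DensityProfile("ca", "uniform", baseline=z * p.ca_density),
        ),
        (
            specs["leak"],
            DensityProfile("leak", "uniform", baseline=p.leak_density),
        ),
    ]
    rest = -80.0 if p.passive else p.resting_potential
    return CableModel(
        sections=sections,
        channels=channels,
        resting_potential=rest,
        temperature_label=p.temperature_label,
        calibrate_rest=not p.passive,
    )


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column; 1=soma, 2=axon, 3=dendrite)
# ---------------------------------------------------------------------------

_SWC_TYPE = {"soma": 1, "axon_main": 2, "axon_collateral": 2, "dendrite": 3}
_SWC_KIND = {1: "soma", 2: "axon_main", 3: "dendrite"}


def write_swc(model: CableModel, path, collateral_map: dict[str, bool] | None = None) -> None:
    """Write the section tree as a 7-column SWC file (one sample per section end).

    Sections are laid out along a single spatial axis per branch; SWC is used
    here as a topology + calibre exchange format, not a 3D reconstruction.
    """
    by_id = {s.id: s for s in model.sections}
    index = {s.id: i + 1 for i, s in enumerate(model.sections)}
    lines = ["# id type x y z radius parent"]
    xpos: dict[str, float] = {}
    for s in model.sections:
        if s.parent is None:
            base = 0.0
        else:
            base = xpos.get(s.parent, 0.0)
        sign = -1.0 if s.kind == "dendrite" else 1.0
        xpos[s.id] = base + sign * s.length
        pid = -1 if s.parent is None else index[s.parent]
        lines.append(
            f"{index[s.id]} {_SWC_TYPE[s.kind]} {xpos[s.id]:.3f} 0.0 0.0 "
            f"{s.diameter / 2.0:.4f} {pid}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(
    path,
    axial_resistivity: float = 80.0,
    n_compartments: int = 11,
    collateral_ids: set[int] | None = None,
) -> list[Section]:
    """Read a 7-column SWC file into a list of :class:`Section`.

    Each SWC sample (other than the root) becomes one section whose length is
    the distance to its parent sample.  ``collateral_ids`` is the sidecar
    mapping marking axonal samples that belong to collaterals.
    """
    collateral_ids = collateral_ids or set()
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append(
                (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), int(parts[6]))
            )
    by_idx = {r[0]: r for r in rows}
    sections: list[Section] = []
    for idx, typ, x, y, z, radius, pidx in rows:
        if typ not in _SWC_KIND:
            raise ValueError(f"SWC sample {idx}: unsupported type code {typ}")
        kind = _SWC_KIND[typ]
        if typ == 2 and idx in collateral_ids:
            kind = "axon_collateral"
        if pidx == -1:
            if kind != "soma":
                raise ValueError("SWC root must be a soma sample")
            sections.append(
                Section(f"swc{idx}", None, max(2.0 * radius, 1e-3), 2.0 * radius,
                        axial_resistivity, 1, "soma")
            )
            continue
        px, py, pz = by_idx[pidx][2:5]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            raise ValueError(f"SWC sample {idx}: zero-length segment")
        sections.append(
            Section(
                f"swc{idx}", f"swc{pidx}", length, 2.0 * radius,
                axial_resistivity, n_compartments, kind,
            )
        )
    return sections
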