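"""Unit conventions and conversions.

Global conventions used throughout the package:

* time — ms
* voltage — mV
* distance along the axon — µm, arc length from the soma–axon junction
  (soma = 0, dendrite negative)
* membrane conductance density — S·cm⁻² in configuration, mS·cm⁻² internally
* membrane current density — mA·cm⁻²
* concentration — mM
"""

from __future__ import annotations

import numpy as np

__all__ = ["flux_to_concentration_rate", "surface_to_volume_rate"]


def flux_to_concentration_rate(flux_pmol_cm2_s: float, diameter_um: float) -> float:
    """Convert a membrane flux into a bulk concentration rate for a cylinder.

    For a cylindrical process of diameter ``d`` the surface-to-volume ratio is
    ``4/d``, so a flux ``J`` (pmol·cm⁻²·s⁻¹) across the membrane changes the
    intracellular concentration at ``J * 4/d`` (per unit time).

    Parameters
    ----------
    flux_pmol_cm2_s:
        Membrane flux in pmol·cm⁻²·s⁻¹.
    diameter_um:
        Cylinder diameter in µm.

    Returns
    -------
    float
        Concentration rate in mM·s⁻¹.

    Examples
    --------
    A 20 pmol·cm⁻²·s⁻¹ Na⁺ efflux across the membrane of a 0.5-µm-wide axon
    removes intracellular Na⁺ at 1.6 mM·s⁻¹:

    >>> round(flux_to_concentration_rate(20.0, 0.5), 6)
    1.6
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_cm = diameter_um * 1e-4
    # pmol/cm^2/s * (4/d) cm^-1 = pmol/cm^3/s = 1e-12 mol/cm^3/s = 1e-9 mol/L/s
    mol_per_l_per_s = flux_pmol_cm2_s * (4.0 / d_cm) * 1e-12 * 1e3
    return mol_per_l_per_s * 1e3  # -> mM/s


def surface_to_volume_rate(diameter_um: float) -> float:
    """Surface-to-volume ratio of a cylinder, in cm⁻¹."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 / (diameter_um * 1e-4)


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")
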