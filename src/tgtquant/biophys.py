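"""Closed-form biophysical models for tension-gauge-tether (TGT) experiments.

Three small models underpin the interpretation of TGT rupture data:

* the de Gennes shear-rupture formula, which maps the length of a DNA
  duplex loaded in shear geometry to its approximate tension tolerance
  ``T_tol``;
* a two-state Boltzmann model of integrin conformational activation, in
  which tensile force ``F`` across the integrin tilts the free-energy
  difference between the bent-closed (BC) and extended-open (EO) states
  by ``F * delta_x``;
* a competitive-occupancy model for the fraction of an integrin subtype
  left unbound by a panel of inhibitory Fab fragments.

All forces are in pN, lengths in nm (duplex length in base pairs),
energies in kcal/mol at the API surface and pN*nm internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

__all__ = [
    "BOLTZMANN_J_PER_K",
    "AVOGADRO_PER_MOL",
    "TGTGeometry",
    "TwoStateIntegrinModel",
    "FabPanel",
    "kcalmol_to_pN_nm",
    "thermal_energy",
    "degennes_tension_tolerance",
    "eo_occupancy",
    "force_for_occupancy",
    "fab_unbound_fraction",
    "load_fab_panel_csv",
]

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214e23

#: 1 J expressed in pN*nm (1 J = 1e12 pN * 1e9 nm).
_J_TO_PN_NM = 1e21


def kcalmol_to_pN_nm(energy_kcal_mol: float) -> float:
    """Convert a molar energy in kcal/mol to a per-molecule energy in pN*nm.

    1 kcal/mol = 4184 J / N_A per molecule = 6.9477 pN*nm.
    """
    return energy_kcal_mol * 4184.0 / AVOGADRO_PER_MOL * _J_TO_PN_NM


def thermal_energy(temperature_K: float) -> float:
    """Thermal energy k_B*T in pN*nm; 4.280 pN*nm at 310 K."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return BOLTZMANN_J_PER_K * temperature_K * _J_TO_PN_NM


# ---------------------------------------------------------------------------
# DNA duplex tension tolerance (shear geometry)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TGTGeometry:
    """Geometry of a TGT DNA duplex loaded in shear.

    Parameters
    ----------
    n_basepairs:
        Number of duplexed base pairs ``l``.
    f_c:
        Breaking force per base pair in pN (3.9 pN for B-DNA).
    kappa_inv:
        Adjustment length ``kappa^-1`` in base pairs (6.8 bp), the
        characteristic length over which shear stress is distributed.
    nominal_label:
        Free-text tag for the construct's nominal tolerance class
        (e.g. ``"12pN"``, ``"54pN"``). Nominal tolerances depend on the
        biotin attachment geometry, which this formula does not
        parameterize, so the label is configuration, not an output.
    """

    n_basepairs: int
    f_c: float = 3.9
    kappa_inv: float = 6.8
    nominal_label: str = ""

    def __post_init__(self) -> None:
        if self.n_basepairs < 0:
            raise ValueError(f"n_basepairs must be >= 0, got {self.n_basepairs}")
        if self.f_c <= 0:
            raise ValueError(f"f_c must be > 0, got {self.f_c}")
        if self.kappa_inv <= 0:
            raise ValueError(f"kappa_inv must be > 0, got {self.kappa_inv}")


def degennes_tension_tolerance(geometry: TGTGeometry) -> float:
    """Tension tolerance of a sheared DNA duplex, de Gennes model.

    ``T_tol = 2 * f_c * kappa_inv * tanh(kappa * l / 2)`` in pN.

    Monotonically non-decreasing in the duplex length ``l`` and bounded
    above by the long-duplex asymptote ``2 * f_c * kappa_inv`` (53.0 pN
    at the default parameters). The 18-bp duplex used in shear-mode TGTs
    evaluates to 46.0 pN.
    """
    l = geometry.n_basepairs
    return 2.0 * geometry.f_c * geometry.kappa_inv * math.tanh(l / (2.0 * geometry.kappa_inv))


# ---------------------------------------------------------------------------
# Two-state BC <-> EO integrin activation under force
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStateIntegrinModel:
    """Two-state (bent-closed / extended-open) integrin activation model.

    Force applied between the ligand-binding site and the beta-subunit
    tail does work ``F * delta_x`` on the BC->EO conformational change,
    so the EO occupancy follows a Boltzmann form tilted by force.

    Parameters
    ----------
    delta_G:
        BC->EO free-energy difference at zero force, kcal/mol
        (measured values ~2.5-4 kcal/mol for beta1 integrins).
    delta_x:
        Increase in ligand-site-to-beta-tail distance on BC->EO
        conversion, nm (~14.5 nm).
    temperature:
        Absolute temperature in K; defaults to 310 K (cell experiments
        at 37 C).
    """

    delta_G: float
    delta_x: float = 14.5
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.delta_G <= 0:
            raise ValueError(f"delta_G must be > 0, got {self.delta_G}")
        if self.delta_x <= 0:
            raise ValueError(f"delta_x must be > 0, got {self.delta_x}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


def eo_occupancy(model: TwoStateIntegrinModel, force_pN: float) -> float:
    """Equilibrium fraction of integrins in the extended-open state at force F.

    ``p = 1 / (1 + exp((dG - F*dx) / kT))`` with dG in pN*nm.
    Strictly increasing in F; p -> 1 as F -> infinity; p = 1/2 exactly
    when ``F = dG / dx``.
    """
    if force_pN < 0:
        raise ValueError(f"force must be >= 0, got {force_pN}")
    dg = kcalmol_to_pN_nm(model.delta_G)
    kt = thermal_energy(model.temperature)
    return 1.0 / (1.0 + math.exp((dg - force_pN * model.delta_x) / kt))


def force_for_occupancy(model: TwoStateIntegrinModel, p: float) -> float:
    """Force in pN at which the EO occupancy equals ``p`` (exact inverse).

    ``F = (dG + kT * ln(p / (1 - p))) / dx``. At the measured
    dG = 2.5-4 kcal/mol and dx = 14.5 nm this gives 1.2-1.9 pN for 50%
    occupancy and 2.6-3.3 pN for 99% occupancy at 310 K.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"occupancy must lie in (0, 1), got {p}")
    dg = kcalmol_to_pN_nm(model.delta_G)
    kt = thermal_energy(model.temperature)
    return (dg + kt * math.log(p / (1.0 - p))) / model.delta_x


# ---------------------------------------------------------------------------
# Fab competition occupancy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FabPanel:
    """Panel of inhibitory Fabs applied at known concentrations.

    ``entries`` is a list of ``(fab_name, concentration_M, kd_map)``
    where ``kd_map`` maps integrin subtype names to dissociation
    constants K_d in molar units. A subtype missing from an entry's
    ``kd_map`` means that Fab does not bind that subtype and the entry
    is excluded from the calculation for it.
    """

    entries: Tuple[Tuple[str, float, Dict[str, float]], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(
            (name, float(conc), dict(kds)) for name, conc, kds in self.entries
        ))
        for name, conc, kds in self.entries:
            if conc < 0:
                raise ValueError(f"Fab {name!r}: concentration must be >= 0, got {conc}")
            for subtype, kd in kds.items():
                if kd <= 0:
                    raise ValueError(f"Fab {name!r}, subtype {subtype!r}: K_d must be > 0, got {kd}")

    def binding_entries(self, subtype: str) -> List[Tuple[str, float, float]]:
        """(name, concentration, K_d) for every Fab that binds ``subtype``."""
        return [(name, conc, kds[subtype]) for name, conc, kds in self.entries if subtype in kds]


def fab_unbound_fraction(subtype: str, panel: FabPanel, mode: str = "competitive") -> float:
    """Fraction of an integrin subtype left unbound by a Fab panel.

    mode="competitive" (default) treats the Fabs as competing for one
    site: ``P = 1 / (1 + sum_i C_i / K_d,i)``, bounded in [0, 1] for any
    panel. mode="as_printed" evaluates the per-Fab sum
    ``P = sum_i 1 / (1 + C_i / K_d,i)``, which is how multi-Fab panels
    are sometimes tabulated but exceeds 1 for more than one Fab at low
    concentration. The two forms agree exactly for single-Fab panels.
    Fabs whose K_d map lacks ``subtype`` are treated as non-binding.
    """
    binding = panel.binding_entries(subtype)
    if not binding:
        return 1.0
    ratios = [conc / kd for _, conc, kd in binding]
    if mode == "competitive":
        return 1.0 / (1.0 + sum(ratios))
    if mode == "as_printed":
        return sum(1.0 / (1.0 + r) for r in ratios)
    raise ValueError(f"unknown mode {mode!r}; expected 'competitive' or 'as_printed'")


def load_fab_panel_csv(path: str | Path) -> FabPanel:
    """Read a Fab panel from CSV.

    Expected columns: ``fab_name``, ``concentration_nM``, and one
    ``K_d_nM_<subtype>`` column per integrin subtype. An empty K_d cell
    means the Fab does not bind that subtype. Concentrations and K_d are
    converted from nM to molar.
    """
    df = pd.read_csv(path)
    required = {"fab_name", "concentration_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Fab panel CSV missing columns: {sorted(missing)}")
    kd_cols = [c for c in df.columns if c.startswith("K_d_nM_")]
    entries = []
    for _, row in df.iterrows():
        kds = {
            c[len("K_d_nM_"):]: float(row[c]) * 1e-9
            for c in kd_cols
            if pd.notna(row[c])
        }
        entries.append((str(row["fab_name"]), float(row["concentration_nM"]) * 1e-9, kds))
    return FabPanel(entries=tuple(entries))
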