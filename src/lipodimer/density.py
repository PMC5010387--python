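"""Membrane protein density unit conversions.

Membrane density is quoted on several scales in the reconstitution
literature and all of them appear in this analysis:

* ``rho_mass`` — reconstitution mass density, µg protein per mg lipid;
* ``chi_recon`` — reconstituted subunit/lipid mole fraction;
* ``chi_obs`` — observed mole fraction after freeze/thaw + extrusion
  (a constant recovery factor of the reconstituted value);
* ``chi_star`` — reactive mole fraction: only similarly oriented
  subunits can dimerize, so half of the observed protein participates;
* ``rho_area`` — subunits per nm² of bilayer, ``2*chi/SA_lipid`` with
  ``SA_lipid`` the area per lipid in one leaflet (the factor 2 counts
  both leaflets' lipids against the bilayer area).

``box_nm`` is the side of the square bilayer patch containing one
subunit at a given area density — a geometric mental picture of how far
apart subunits sit at that dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConversionConstants",
    "DensityRecord",
    "build_density_record",
    "record_from_chi_recon",
    "mole_to_area_density",
    "area_to_mole_density",
    "box_length",
    "MW_CLC_WT",
    "MW_CLC_W",
    "MW_CLC_WW",
    "MW_CLC_WT_NS",
    "MW_CLC_W_NS",
    "MW_CLC_WW_NS",
    "EPS_CLC_WT",
    "EPS_CLC_W",
    "EPS_CLC_WW",
    "MW_POPE",
    "MW_POPG_NA",
    "MW_LIPID_POPE_POPG_NA",
]

# Construct-specific subunit masses (g/mol) and 280-nm extinction
# coefficients (M^-1 cm^-1) for the single-cysteine ClC-ec1 isoforms and
# their non-specific-labeling controls.
MW_CLC_WT = 51_997.0
MW_CLC_W = 52_070.0
MW_CLC_WW = 52_146.0
MW_CLC_WT_NS = 52_031.0
MW_CLC_W_NS = 52_104.0
MW_CLC_WW_NS = 52_177.0
EPS_CLC_WT = 46_020.0
EPS_CLC_W = 51_700.0
EPS_CLC_WW = 57_410.0

# 2:1 POPE:POPG molar-mean lipid masses (g/mol). The sodium-salt mean is
# kept as a reference; the conversion default is the round-number pair
# (50 kDa protein, 750 g/mol lipid) that reproduces the published
# conversion table at printed precision (see docs/methods.md).
MW_POPE = 717.996
MW_POPG_NA = 770.99
MW_LIPID_POPE_POPG_NA = (2.0 * MW_POPE + MW_POPG_NA) / 3.0

_CHI_SCALES = ("reactive", "observed", "reconstitution")


@dataclass(frozen=True)
class ConversionConstants:
    """Physical constants tying the density scales together.

    Parameters
    ----------
    mw_protein : float
        Subunit molar mass, g/mol.
    mw_lipid : float
        Mean lipid molar mass, g/mol.
    sa_lipid : float
        Surface area per lipid in one leaflet, nm².
    recovery_factor : float
        Observed / reconstituted mole fraction, from protein and lipid
        quantification after freeze/thaw and extrusion.
    orientation_factor : float
        Reactive fraction of the observed protein; 0.5 when insertion
        orientation is random and only like-oriented subunits react.
    """

    mw_protein: float = 50_000.0
    mw_lipid: float = 750.0
    sa_lipid: float = 0.6
    recovery_factor: float = 0.50
    orientation_factor: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mw_protein", "mw_lipid", "sa_lipid"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("recovery_factor", "orientation_factor"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class DensityRecord:
    """One membrane-density point on every unit scale."""

    rho_mass: float  # µg protein / mg lipid
    chi_recon: float  # subunit / lipid
    chi_obs: float  # subunit / lipid
    chi_star: float  # subunit / lipid (reactive)
    rho_area: float  # subunit / nm² bilayer
    lipids_per_subunit: float  # (chi_star)^-1
    area_per_subunit: float  # nm² bilayer / subunit
    box_nm: float  # nm


def build_density_record(
    rho_mass: float,
    constants: ConversionConstants = ConversionConstants(),
    chi_scale_for_area: str = "reactive",
) -> DensityRecord:
    """Convert a reconstitution mass density to all other scales.

    ``chi_recon = (rho_mass µg -> mol protein) / (1 mg -> mol lipid)``,
    i.e. ``rho_mass * 1e-3 * mw_lipid / mw_protein``. The area density is
    computed from the reactive mole fraction by default, matching the
    published lookup table; pass ``chi_scale_for_area`` to apply the
    mole->area conversion on another chi scale.
    """
    if rho_mass < 0:
        raise ValueError("rho_mass must be non-negative")
    if chi_scale_for_area not in _CHI_SCALES:
        raise ValueError(f"chi_scale_for_area must be one of {_CHI_SCALES}")
    c = constants
    chi_recon = rho_mass * 1e-3 * c.mw_lipid / c.mw_protein
    return record_from_chi_recon(chi_recon, c, chi_scale_for_area)


def record_from_chi_recon(
    chi_recon: float,
    constants: ConversionConstants = ConversionConstants(),
    chi_scale_for_area: str = "reactive",
) -> DensityRecord:
    """Build a :class:`DensityRecord` starting from the reconstituted
    mole fraction (useful when quoting printed table values exactly)."""
    if chi_recon < 0:
        raise ValueError("chi_recon must be non-negative")
    c = constants
    chi_obs = c.recovery_factor * chi_recon
    chi_star = c.orientation_factor * chi_obs
    area_chi = {
        "reactive": chi_star,
        "observed": chi_obs,
        "reconstitution": chi_recon,
    }[chi_scale_for_area]
    rho_area = mole_to_area_density(area_chi, c.sa_lipid)
    if chi_star > 0:
        lipids_per_subunit = 1.0 / chi_star
        area_per_subunit = 1.0 / rho_area
        box_nm = box_length(rho_area)
    else:
        lipids_per_subunit = math.inf
        area_per_subunit = math.inf
        box_nm = math.inf
    rho_mass = chi_recon * 1e3 * c.mw_protein / c.mw_lipid
    return DensityRecord(
        rho_mass=rho_mass,
        chi_recon=chi_recon,
        chi_obs=chi_obs,
        chi_star=chi_star,
        rho_area=rho_area,
        lipids_per_subunit=lipids_per_subunit,
        area_per_subunit=area_per_subunit,
        box_nm=box_nm,
    )


def mole_to_area_density(chi: float, sa_lipid: float = 0.6) -> float:
    """Subunit/lipid mole fraction -> subunits per nm² of bilayer.

    ``rho_area = 2 * chi / SA_lipid``: a bilayer patch of area A holds
    ``2 A / SA_lipid`` lipids (two leaflets), hence ``chi`` times that
    many subunits.
    """
    if sa_lipid <= 0:
        raise ValueError("sa_lipid must be strictly positive")
    if chi < 0:
        raise ValueError("chi must be non-negative")
    return 2.0 * chi / sa_lipid


def area_to_mole_density(rho_area: float, sa_lipid: float = 0.6) -> float:
    """Inverse of :func:`mole_to_area_density`."""
    if sa_lipid <= 0:
        raise ValueError("sa_lipid must be strictly positive")
    if rho_area < 0:
        raise ValueError("rho_area must be non-negative")
    return rho_area * sa_lipid / 2.0


def box_length(rho_area: float) -> float:
    """Side (nm) of the square bilayer patch holding one subunit."""
    if rho_area <= 0:
        raise ValueError("rho_area must be strictly positive")
    return math.sqrt(1.0 / rho_area)
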