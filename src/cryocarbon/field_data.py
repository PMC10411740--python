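"""Field measurements, unit conversions, and borehole scenario assembly.

Cryopeg brines are volumes of hypersaline liquid water enclosed in subzero
permafrost; the Utqiagvik (Alaska) system modelled here has been isolated
for roughly 40,000 years.  The organic-carbon budget of a brine is framed
by its frozen surroundings: the particulate (POC) and dissolved (DOC)
organic carbon measured today in the continuously frozen sediment or ice
around a borehole is taken as the brine's starting inventory.

This module converts raw laboratory measurements on thawed frozen material
into in-situ volumetric carbon concentrations, and assembles the three
borehole scenarios (CB1, CB4 intra-sediment; CBIW intra-ice) together with
the model constants shared across them.  Presets ship as YAML data so new
boreholes can be defined without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from ._units import DAYS_PER_YEAR, g_to_fg, ug_to_fg

__all__ = [
    "RawSedimentMeasurement",
    "ScenarioDefinition",
    "ModelConstants",
    "poc_insitu_concentration",
    "doc_insitu_concentration",
    "cell_carbon_from_biovolume",
    "build_scenario",
    "load_presets",
    "load_raw_measurement",
    "scenario_names",
]

_DATA_FILE = "scenarios.yaml"


@dataclass(frozen=True)
class RawSedimentMeasurement:
    """One frozen-sediment (or massive-ice) sample as measured in the lab.

    Parameters
    ----------
    poc_mass_fraction
        Organic carbon per unit dry sediment mass (ug C / ug sediment).
    porewater_doc
        DOC concentration of the thawed porewater (ug C mL^-1).
    volumetric_ice_content
        Fraction of the bulk frozen volume occupied by ice (0-1).
    dry_sediment_density
        Dry sediment mass per unit sediment volume (g mL^-1).
    expansion_factor
        Fractional volume increase of porewater on freezing (e.g. 0.0905
        for permafrost porewater, 0.08042 for massive ice); thaw-based
        concentrations are corrected back to the frozen volume with it.
    """

    poc_mass_fraction: float
    porewater_doc: float
    volumetric_ice_content: float
    dry_sediment_density: float
    expansion_factor: float

    def __post_init__(self) -> None:
        for name in (
            "poc_mass_fraction",
            "porewater_doc",
            "volumetric_ice_content",
            "dry_sediment_density",
            "expansion_factor",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.volumetric_ice_content > 1:
            raise ValueError("volumetric_ice_content must be <= 1")
        if self.poc_mass_fraction > 1:
            raise ValueError("poc_mass_fraction is a mass fraction, must be <= 1")
        if self.expansion_factor >= 1:
            raise ValueError("expansion_factor must be < 1")


@dataclass(frozen=True)
class ScenarioDefinition:
    """Variable set defining one borehole scenario.

    Carbon pools are fg C per cm^3 (surroundings, ``P_0``/``D_0``) or per
    mL of brine (``P_f``/``D_f``/pulses); the two volume units are treated
    as identical.  ``addition_time`` is years since brine enclosure.
    """

    name: str
    N_f: float
    P_0: float
    D_0: float
    P_f: float
    D_f: float
    D_in: float = 0.0
    P_in: float = 0.0
    addition_time: Optional[float] = None
    alpha_D: float = 15.7
    mu_max: float = 0.06
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("N_f", "P_0", "D_0", "P_f", "D_f", "D_in", "P_in",
                     "alpha_D", "mu_max"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.N_f <= 0:
            raise ValueError("N_f must be positive")
        if self.addition_time is None and (self.D_in or self.P_in):
            raise ValueError("pulsed additions require addition_time")

    @property
    def S_0(self) -> float:
        """Total organic carbon of the surroundings (fg C cm^-3)."""
        return self.P_0 + self.D_0

    @property
    def S_f(self) -> float:
        """Total organic carbon of the present-day brine (fg C mL^-1)."""
        return self.P_f + self.D_f

    @property
    def S_in(self) -> float:
        """Total pulsed organic-carbon addition (fg C mL^-1)."""
        return self.P_in + self.D_in


@dataclass(frozen=True)
class ModelConstants:
    """Constants shared across borehole scenarios."""

    N_max: float = 1.0e9
    K_D: float = 8.82e5
    N_0: float = 1.0e5
    gamma_measured: float = 1.22e-2
    t_f: float = 40_000.0
    alpha_I: float = 0.0
    I_xr: float = 0.0
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        if not self.N_0 < self.N_max:
            raise ValueError("N_0 must be below the carrying capacity N_max")
        for name in ("N_max", "K_D", "N_0", "gamma_measured", "alpha_I", "I_xr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def t_f_days(self) -> float:
        return self.t_f * self.days_per_year


def poc_insitu_concentration(meas: RawSedimentMeasurement) -> float:
    """In-situ POC concentration of frozen bulk sediment, fg C cm^-3.

    The dry-mass carbon fraction is scaled by the sediment volume fraction
    (1 - ice content) and the dry sediment density.
    """
    sediment_fraction = 1.0 - meas.volumetric_ice_content
    grams_c_per_cm3 = (
        meas.poc_mass_fraction * sediment_fraction * meas.dry_sediment_density
    )
    return g_to_fg(grams_c_per_cm3)


def doc_insitu_concentration(meas: RawSedimentMeasurement) -> float:
    """In-situ porewater DOC of frozen bulk sediment, fg C cm^-3.

    The thawed-porewater concentration is mapped back to frozen bulk volume
    through the volumetric ice content and, because thawing expands the
    measured volume, the (1 - expansion_factor) correction.  The additive
    convention ``concentration / (1 + e)`` is available via
    ``convention="divide"``; the default multiplicative form is the one
    consistent with the shipped scenario presets.
    """
    return _doc_insitu(meas, convention="multiply")


def _doc_insitu(meas: RawSedimentMeasurement, convention: str = "multiply") -> float:
    per_ml_thawed = ug_to_fg(meas.porewater_doc)
    if convention == "multiply":
        correction = 1.0 - meas.expansion_factor
    elif convention == "divide":
        correction = 1.0 / (1.0 + meas.expansion_factor)
    else:
        raise ValueError(f"unknown expansion convention: {convention!r}")
    return per_ml_thawed * meas.volumetric_ice_content * correction


def cell_carbon_from_biovolume(volume_um3: float, conversion_fg_per_um3: float) -> float:
    """Carbon content per cell from mean biovolume and a conversion factor.

    E.g. a 0.365 um^3 *Psychrobacter* sp. cell at 148 fg C um^-3 carries
    ~54 fg C.
    """
    if volume_um3 <= 0 or conversion_fg_per_um3 <= 0:
        raise ValueError("biovolume and conversion factor must be positive")
    return volume_um3 * conversion_fg_per_um3


def _package_presets_path() -> Path:
    return Path(str(resources.files("cryocarbon").joinpath("data", _DATA_FILE)))


def load_presets(path: Optional[Path] = None) -> dict:
    """Load and validate the scenario preset file (YAML)."""
    p = Path(path) if path is not None else _package_presets_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    for key in ("constants", "scenarios", "raw_measurements"):
        if key not in raw:
            raise ValueError(f"preset file missing section {key!r}")
    return raw


def load_raw_measurement(name: str, path: Optional[Path] = None) -> RawSedimentMeasurement:
    """Load a named raw sediment measurement from the preset file."""
    raw = load_presets(path)
    try:
        entry = raw["raw_measurements"][name]
    except KeyError:
        known = sorted(raw["raw_measurements"])
        raise KeyError(f"unknown measurement {name!r}; known: {known}") from None
    return RawSedimentMeasurement(**{k: float(v) for k, v in entry.items()})


def scenario_names(path: Optional[Path] = None) -> list[str]:
    return sorted(load_presets(path)["scenarios"])


def build_scenario(
    name: str,
    p0: str = "table",
    path: Optional[Path] = None,
) -> tuple[ScenarioDefinition, ModelConstants]:
    """Assemble a named borehole scenario and the shared constants.

    Parameters
    ----------
    name
        One of the preset boreholes (``CB1``, ``CB4``, ``CBIW``).
    p0
        For CB4 only: ``"table"`` uses the published surrounding-POC value
        (1.75e13 fg C cm^-3); ``"derived"`` recomputes it from the raw CB4
        sediment measurement (~1.69e13), the value consistent with the
        published enzyme-activity bounds and implied timespan.  The two
        disagree by ~3%; both are exposed rather than silently reconciled.
    """
    raw = load_presets(path)
    try:
        entry = dict(raw["scenarios"][name])
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(raw['scenarios'])}"
        ) from None

    addition_time = entry.pop("addition_time", None)
    fields = {k: float(v) for k, v in entry.items()}
    scenario = ScenarioDefinition(
        name=name,
        addition_time=None if addition_time is None else float(addition_time),
        **fields,
    )
    if p0 == "derived":
        if name in raw["raw_measurements"]:
            meas = load_raw_measurement(name, path)
            derived = poc_insitu_concentration(meas)
            scenario = replace(scenario, P_0=derived,
                               notes="P_0 derived from raw sediment measurement")
    elif p0 != "table":
        raise ValueError("p0 must be 'table' or 'derived'")

    constants = ModelConstants(**{k: float(v) for k, v in raw["constants"].items()})
    return scenario, constants
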