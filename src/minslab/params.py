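"""Model parameters, protein totals, and slab geometry.

Units follow the bulk-surface convention used throughout the package:
bulk concentrations in molecules/μm³, membrane densities in molecules/μm²,
lengths in μm, times in s.  The conversion 1 μM = 602 molecules/μm³ is
applied only at the I/O boundary (CLI / parameter files annotated in μM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml

#: molecules per μm³ in a 1 μM solution (6.022e23 / litre * 1e-15 litre/μm³)
MOLECULES_PER_UM3_PER_UM = 602.0

DEFAULT_PARAMS_RESOURCE = "skeleton_fallback.yaml"


class ParameterError(ValueError):
    """Raised for invalid or inconsistent parameter values/files."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and diffusivities of the skeleton MinDE model.

    Attributes
    ----------
    k_D : float
        Spontaneous MinD-ATP membrane attachment rate, μm s⁻¹.
    k_dD : float
        Cooperative MinD recruitment rate by membrane-bound MinD, μm³ s⁻¹.
    k_dE : float
        MinE recruitment rate onto membrane-bound MinD, μm³ s⁻¹.
    k_de : float
        MinDE complex hydrolysis/detachment rate, s⁻¹.  Detachment releases
        one MinD-ADP and one MinE into the bulk.
    lambda_exch : float
        Cytosolic nucleotide exchange rate (MinD-ADP → MinD-ATP), s⁻¹.
    D_b : float
        Bulk (cytosolic) diffusivity, μm² s⁻¹, shared by all bulk species
        unless per-species values are given.
    D_m : float
        Membrane diffusivity of m_d and m_de, μm² s⁻¹.
    D_b_E : float | None
        Optional distinct bulk diffusivity for MinE.
    D_b_D : float | None
        Optional distinct bulk diffusivity for the two MinD bulk species.
    """

    k_D: float
    k_dD: float
    k_dE: float
    k_de: float
    lambda_exch: float
    D_b: float
    D_m: float
    D_b_E: float | None = None
    D_b_D: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_D", "k_dD", "k_dE", "k_de", "lambda_exch", "D_m"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if not (self.D_b > 0):
            raise ParameterError(f"D_b must be > 0, got {self.D_b}")
        for name in ("D_b_E", "D_b_D"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ParameterError(f"{name} must be > 0 when given, got {v}")

    @property
    def D_bulk_D(self) -> float:
        """Bulk diffusivity used for c_DD and c_DT."""
        return self.D_b if self.D_b_D is None else self.D_b_D

    @property
    def D_bulk_E(self) -> float:
        """Bulk diffusivity used for c_E."""
        return self.D_b if self.D_b_E is None else self.D_b_E

    @property
    def penetration_depth(self) -> float:
        """Vertical decay length ℓ = sqrt(D_b/λ) of cytosolic MinD-ADP gradients, μm."""
        if self.lambda_exch == 0:
            return math.inf
        return math.sqrt(self.D_bulk_D / self.lambda_exch)


@dataclass(frozen=True)
class Totals:
    """Mean total protein concentrations, volume-averaged over bulk + membranes.

    n_D, n_E in molecules/μm³; the E:D ratio is derived.
    """

    n_D: float
    n_E: float

    def __post_init__(self) -> None:
        if not (self.n_D > 0):
            raise ParameterError(f"n_D must be > 0, got {self.n_D}")
        if not (self.n_E >= 0):
            raise ParameterError(f"n_E must be >= 0, got {self.n_E}")

    @property
    def ed_ratio(self) -> float:
        return self.n_E / self.n_D

    @classmethod
    def from_ed_ratio(cls, n_D: float, ed: float) -> "Totals":
        return cls(n_D=n_D, n_E=ed * n_D)


@dataclass(frozen=True)
class Geometry:
    """Two-membrane slab: z ∈ [0, H] with membranes at z = 0 and z = H
    (or bottom only), x ∈ [0, L_x] with reflective lateral walls.

    dz, dx are the cell-centred finite-volume grid spacings.  L_x/dx may be
    None for laterally uniform (1D-in-z) problems.
    """

    H: float
    dz: float
    L_x: float | None = None
    dx: float | None = None
    membranes: Literal["both_faces", "bottom_only"] = "both_faces"

    def __post_init__(self) -> None:
        if not (self.H > 0):
            raise ParameterError(f"H must be > 0, got {self.H}")
        if not (0 < self.dz <= self.H / 8 + 1e-12):
            raise ParameterError(
                f"dz must satisfy 0 < dz <= H/8 (= {self.H / 8:g}), got {self.dz}"
            )
        if self.membranes not in ("both_faces", "bottom_only"):
            raise ParameterError(f"unknown membranes option {self.membranes!r}")
        if (self.L_x is None) != (self.dx is None):
            raise ParameterError("L_x and dx must be given together")
        if self.L_x is not None:
            if not (self.L_x > 0 and self.dx > 0 and self.dx <= self.L_x):
                raise ParameterError(f"invalid lateral extent L_x={self.L_x}, dx={self.dx}")

    @property
    def nz(self) -> int:
        return max(8, round(self.H / self.dz))

    @property
    def nx(self) -> int:
        if self.L_x is None:
            return 1
        return max(1, round(self.L_x / self.dx))

    @property
    def z_centers(self):
        import numpy as np

        dz = self.H / self.nz
        return (np.arange(self.nz) + 0.5) * dz

    @property
    def x_centers(self):
        import numpy as np

        if self.L_x is None:
            return np.zeros(1)
        dx = self.L_x / self.nx
        return (np.arange(self.nx) + 0.5) * dx

    @property
    def n_membranes(self) -> int:
        return 2 if self.membranes == "both_faces" else 1


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

_RATE_KEYS = {
    "k_D": "um/s",
    "k_dD": "um^3/s",
    "k_dE": "um^3/s",
    "k_de": "1/s",
    "lambda_exch": "1/s",
    "D_b": "um^2/s",
    "D_m": "um^2/s",
}
_OPTIONAL_RATE_KEYS = {"D_b_E": "um^2/s", "D_b_D": "um^2/s"}
_TOTAL_KEYS = {"n_D", "n_E"}
_ALLOWED_TOP = {"kinetics", "totals", "meta"}
_CONC_UNITS = {"per_um3": 1.0, "uM": MOLECULES_PER_UM3_PER_UM}


def _parse_quantity(key: str, entry, expected_unit: str) -> float:
    """Entries are {value: x, unit: 'u'} mappings; unit must match exactly
    (concentrations may instead be given in μM and are converted)."""
    if not isinstance(entry, dict) or set(entry) - {"value", "unit"}:
        raise ParameterError(f"{key}: expected a {{value, unit}} mapping, got {entry!r}")
    if "value" not in entry or "unit" not in entry:
        raise ParameterError(f"{key}: both 'value' and 'unit' are required")
    value = entry["value"]
    unit = entry["unit"]
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ParameterError(f"{key}: value must be numeric, got {value!r}")
    if expected_unit == "conc":
        if unit not in _CONC_UNITS:
            raise ParameterError(
                f"{key}: unit must be one of {sorted(_CONC_UNITS)}, got {unit!r}"
            )
        return float(value) * _CONC_UNITS[unit]
    if unit != expected_unit:
        raise ParameterError(f"{key}: unit must be {expected_unit!r}, got {unit!r}")
    return float(value)


def load_parameter_file(path: str | Path) -> tuple[KineticParameters, Totals]:
    """Load a YAML parameter file with strict schema validation.

    Layout::

        kinetics:
          k_D: {value: 0.0375, unit: um/s}
          ...
        totals:
          n_D: {value: 676.0, unit: per_um3}   # or unit: uM
          n_E: {value: 507.0, unit: per_um3}

    Unknown keys anywhere are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_parameter_mapping(raw, source=str(path))


def parse_parameter_mapping(raw, source: str = "<mapping>") -> tuple[KineticParameters, Totals]:
    if not isinstance(raw, dict):
        raise ParameterError(f"{source}: top level must be a mapping")
    unknown = set(raw) - _ALLOWED_TOP
    if unknown:
        raise ParameterError(f"{source}: unknown top-level keys {sorted(unknown)}")
    for section in ("kinetics", "totals"):
        if section not in raw:
            raise ParameterError(f"{source}: missing section {section!r}")
    kin_raw = raw["kinetics"]
    if not isinstance(kin_raw, dict):
        raise ParameterError(f"{source}: kinetics must be a mapping")
    unknown = set(kin_raw) - set(_RATE_KEYS) - set(_OPTIONAL_RATE_KEYS)
    if unknown:
        raise ParameterError(f"{source}: unknown kinetics keys {sorted(unknown)}")
    missing = set(_RATE_KEYS) - set(kin_raw)
    if missing:
        raise ParameterError(f"{source}: missing kinetics keys {sorted(missing)}")
    kin = {k: _parse_quantity(k, kin_raw[k], u) for k, u in _RATE_KEYS.items()}
    for k, u in _OPTIONAL_RATE_KEYS.items():
        if k in kin_raw:
            kin[k] = _parse_quantity(k, kin_raw[k], u)
    tot_raw = raw["totals"]
    if not isinstance(tot_raw, dict):
        raise ParameterError(f"{source}: totals must be a mapping")
    unknown = set(tot_raw) - _TOTAL_KEYS
    if unknown:
        raise ParameterError(f"{source}: unknown totals keys {sorted(unknown)}")
    missing = _TOTAL_KEYS - set(tot_raw)
    if missing:
        raise ParameterError(f"{source}: missing totals keys {sorted(missing)}")
    tot = {k: _parse_quantity(k, tot_raw[k], "conc") for k in _TOTAL_KEYS}
    return KineticParameters(**kin), Totals(**tot)


def save_parameter_file(
    path: str | Path, params: KineticParameters, totals: Totals, meta: dict | None = None
) -> None:
    """Write a parameter file that :func:`load_parameter_file` round-trips exactly."""
    doc: dict = {"kinetics": {}, "totals": {}}
    for k, unit in _RATE_KEYS.items():
        doc["kinetics"][k] = {"value": getattr(params, k), "unit": unit}
    for k, unit in _OPTIONAL_RATE_KEYS.items():
        v = getattr(params, k)
        if v is not None:
            doc["kinetics"][k] = {"value": v, "unit": unit}
    doc["totals"]["n_D"] = {"value": totals.n_D, "unit": "per_um3"}
    doc["totals"]["n_E"] = {"value": totals.n_E, "unit": "per_um3"}
    if meta:
        doc["meta"] = meta
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_parameters() -> tuple[KineticParameters, Totals]:
    """The package's calibrated fallback parameter set (see data/skeleton_fallback.yaml)."""
    ref = resources.files("minslab").joinpath("data", DEFAULT_PARAMS_RESOURCE)
    with resources.as_file(ref) as path:
        return load_parameter_file(path)
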