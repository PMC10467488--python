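"""Phantom formulation solvers.

Turns target optical properties (mu_a, mu_s' at the excitation wavelength)
into material quantities for a gelatin/intralipid tissue phantom:

* hemoglobin concentration from a target mu_a via the molar extinction of
  partially saturated hemoglobin,
* multi-absorber mixtures at fixed color-matching ratios,
* intralipid concentration from a linear mu_s'-versus-concentration slope,
  corrected for the scattering reduction caused by mixing into gelatin,
* proportional rescaling of a prototype recipe after a measured mu_a,
* dispense volumes for thin-film phantoms of prescribed thickness.

Targets may be given directly in cm^-1 or via the models in
:mod:`phantomforge.optical_models`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import presets

__all__ = [
    "GELATIN_CORRECTION_8PCT",
    "HB_MOLECULAR_WEIGHT",
    "HB_EXTINCTION_405NM",
    "INTRALIPID_SLOPE_405NM",
    "HemoglobinSpec",
    "MixtureSpec",
    "Recipe",
    "FilmSpec",
    "mixed_extinction",
    "hemoglobin_concentration",
    "solve_mixture",
    "adjust_base_quantity",
    "intralipid_concentration",
    "film_volume",
    "design_recipe",
]

#: Hemoglobin molecular weight, g/mol.
HB_MOLECULAR_WEIGHT = 64_500.0
#: Effective extinction of 70%-saturated hemoglobin at 405 nm, cm^-1 M^-1.
HB_EXTINCTION_405NM = 310_610.8
#: mu_s' versus intralipid concentration slope at 405 nm, mm^-1 per % (v/v).
INTRALIPID_SLOPE_405NM = 1.9035
#: Factor by which 8% gelatin reduces intralipid-derived mu_s' (80/220).
GELATIN_CORRECTION_8PCT = 80.0 / 220.0


@dataclass(frozen=True)
class HemoglobinSpec:
    """Hemoglobin absorber description.

    Either supply ``eps_mixed`` (the effective extinction of partially
    saturated hemoglobin, cm^-1 M^-1) directly, or supply ``eps_oxy`` and
    ``eps_deoxy`` and let the saturation-weighted mixture be computed.
    """

    molecular_weight: float = HB_MOLECULAR_WEIGHT
    saturation: float = 0.70
    eps_oxy: float | None = None
    eps_deoxy: float | None = None
    eps_mixed: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")
        if self.eps_mixed is None and (self.eps_oxy is None or self.eps_deoxy is None):
            raise ValueError("supply eps_mixed, or both eps_oxy and eps_deoxy")

    @property
    def extinction(self) -> float:
        """Effective extinction, cm^-1 M^-1."""
        if self.eps_mixed is not None:
            return self.eps_mixed
        return mixed_extinction(self.eps_oxy, self.eps_deoxy, self.saturation)


@dataclass(frozen=True)
class MixtureSpec:
    """A multi-absorber mixture at fixed relative ratios.

    ``absorbers`` is a sequence of (name, ratio r_i, per-unit mu_a_i at the
    target wavelength).  Concentrations are C_i = r_i * q where q is the
    base quantity chosen so the summed absorption hits ``target_mu_a``.
    """

    absorbers: Sequence[tuple[str, float, float]]
    target_mu_a: float

    def __post_init__(self) -> None:
        if self.target_mu_a < 0:
            raise ValueError("target mu_a must be >= 0")
        if not self.absorbers:
            raise ValueError("mixture needs at least one absorber")
        for name, r, mu in self.absorbers:
            if r < 0:
                raise ValueError(f"ratio for {name!r} must be >= 0")
            if mu < 0:
                raise ValueError(f"per-unit mu_a for {name!r} must be >= 0")
        if not any(r > 0 for _, r, _ in self.absorbers):
            raise ValueError("at least one ratio must be > 0")


@dataclass
class FilmSpec:
    """Thin-film phantom: thickness in um and the dispense volume in mL."""

    thickness_um: float
    dispense_volume_ml: float = field(init=False)

    def __post_init__(self) -> None:
        self.dispense_volume_ml = film_volume(self.thickness_um)


@dataclass
class Recipe:
    """Complete phantom formulation (concentrations per final volume).

    ``absorbers`` maps name -> (concentration, unit); ``notes`` records the
    provenance of every solved quantity.
    """

    gelatin_pct: float
    intralipid_pct: float
    absorbers: dict[str, tuple[float, str]]
    excitation_wavelength: float
    target_mu_a: float
    target_mu_s_prime: float
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gelatin_pct < 4.0 and self.gelatin_pct != 0.0:
            raise ValueError(
                "gelatin below 4% w/v is mechanically too weak for a solid phantom"
            )
        if self.intralipid_pct < 0:
            raise ValueError("intralipid concentration must be >= 0")
        for name, (c, _) in self.absorbers.items():
            if c < 0:
                raise ValueError(f"negative concentration for absorber {name!r}")

    @property
    def water_balance_pct(self) -> float:
        """Percent of final volume made up with water (gelatin, IL and mass-%
        absorbers deducted)."""
        absorber_pct = sum(
            c for c, unit in self.absorbers.values() if unit.strip() == "%"
        ) + sum(
            c / 10.0 for c, unit in self.absorbers.values() if unit.strip() == "g/L"
        )
        return 100.0 - self.gelatin_pct - self.intralipid_pct - absorber_pct

    def to_json(self, *, indent: int = 2) -> str:
        payload = {
            "gelatin_pct_w_v": self.gelatin_pct,
            "intralipid_pct_v_v": self.intralipid_pct,
            "absorbers": {
                name: {"concentration": c, "unit": unit}
                for name, (c, unit) in sorted(self.absorbers.items())
            },
            "water_balance_pct": self.water_balance_pct,
            "excitation_wavelength_nm": self.excitation_wavelength,
            "targets": {
                "mu_a_cm1": self.target_mu_a,
                "mu_s_prime_cm1": self.target_mu_s_prime,
            },
            "notes": dict(sorted(self.notes.items())),
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    def formulation_sheet(self, volume_ml: float = 100.0) -> str:
        """Human-readable per-``volume_ml`` formulation table."""
        lines = [
            f"Phantom formulation (per {volume_ml:g} mL)",
            f"  gelatin:     {self.gelatin_pct * volume_ml / 100:.3g} g"
            f"  ({self.gelatin_pct:g}% w/v)",
            f"  intralipid:  {self.intralipid_pct * volume_ml / 100:.3g} mL"
            f"  ({self.intralipid_pct:.3g}% v/v)",
        ]
        for name, (c, unit) in sorted(self.absorbers.items()):
            if unit.strip() == "g/L":
                qty = f"{c * volume_ml / 1000:.4g} g"
            elif unit.strip() == "%":
                qty = f"{c * volume_ml / 100:.4g} mL"
            else:
                qty = f"{c:.4g} {unit}"
            lines.append(f"  {name + ':':<12} {qty}  ({c:.4g} {unit})")
        lines.append(f"  water to volume ({self.water_balance_pct:.3g}% balance)")
        return "\n".join(lines)


def mixed_extinction(eps_oxy: float, eps_deoxy: float, saturation: float) -> float:
    """Saturation-weighted hemoglobin extinction S*eps_HbO2 + (1-S)*eps_Hb."""
    if eps_oxy <= 0 or eps_deoxy <= 0:
        raise ValueError("extinction coefficients must be > 0")
    if not 0.0 <= saturation <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    return saturation * eps_oxy + (1.0 - saturation) * eps_deoxy


def hemoglobin_concentration(target_mu_a: float, spec: HemoglobinSpec) -> float:
    """Hemoglobin concentration in g/L giving the target mu_a (cm^-1).

    C = MW * mu_a / (ln(10) * eps), with eps the effective extinction of the
    saturation-weighted oxy/deoxy mixture.  Mass percent is C/10.
    """
    if target_mu_a < 0:
        raise ValueError("target mu_a must be >= 0")
    eps = spec.extinction
    if eps <= 0:
        raise ValueError("extinction must be > 0")
    return spec.molecular_weight * target_mu_a / (np.log(10.0) * eps)


def solve_mixture(spec: MixtureSpec) -> list[tuple[str, float]]:
    """Concentrations C_i = target * r_i / sum_j(r_j * mu_a_j) for each absorber.

    The solution conserves sum_i C_i * mu_a_i = target exactly; absorbers
    with zero ratio get zero concentration.
    """
    denom = sum(r * mu for _, r, mu in spec.absorbers)
    if denom <= 0:
        raise ValueError("sum of ratio * per-unit mu_a must be > 0")
    return [(name, spec.target_mu_a * r / denom) for name, r, _ in spec.absorbers]


def adjust_base_quantity(
    q_old: float, mu_a_measured: float, mu_a_target: float
) -> float:
    """Rescale the mixture base quantity after a measured prototype mu_a.

    Assuming linear absorbers, q_new = q_old * target / measured brings the
    summed absorption onto target; all C_i = r_i*q rescale proportionally.
    """
    if mu_a_measured <= 0:
        raise ValueError("measured mu_a must be > 0")
    return q_old * (mu_a_target / mu_a_measured)


def intralipid_concentration(
    target_mu_s_prime: float,
    slope: float = INTRALIPID_SLOPE_405NM,
    gelatin_correction: float = GELATIN_CORRECTION_8PCT,
) -> tuple[float, float]:
    """Intralipid % (v/v) for a target mu_s' given in cm^-1.

    Returns ``(pre_correction, final)``: the concentration implied by the
    linear slope alone (``slope`` in mm^-1 per %, so the cm^-1 target is
    divided by 10 first), and the concentration after compensating for the
    gelatin-induced scattering reduction (dividing by ``gelatin_correction``
    < 1 increases the required concentration).
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if gelatin_correction <= 0:
        raise ValueError("gelatin correction factor must be > 0")
    if target_mu_s_prime < 0:
        raise ValueError("target mu_s' must be >= 0")
    pre = (target_mu_s_prime / 10.0) / slope
    return pre, pre / gelatin_correction


def film_volume(thickness_um: float) -> float:
    """Dispense volume (mL) for a thin film of the given thickness (um).

    3 mL at the 200 um minimum, plus 1.5 mL per additional 100 um, capped
    at 7 mL.  Thicknesses below 200 um are not moldable and raise.
    """
    if thickness_um < 200.0:
        raise ValueError("film thickness below the 200 um minimum")
    return min(3.0 + 1.5 * (thickness_um - 200.0) / 100.0, 7.0)


def _resolve_mu_target(entry, wavelength: float, *, what: str) -> float:
    """A target entry is a number (cm^-1), a preset-model name, or a model."""
    if isinstance(entry, (int, float)):
        return float(entry)
    if isinstance(entry, str):
        entry = presets.get_model(entry)
    if callable(entry):
        return float(entry(wavelength))
    raise ValueError(f"cannot interpret {what} target {entry!r}")


def design_recipe(config: dict) -> Recipe:
    """Solve a complete phantom recipe from a declarative config.

    Config keys
    -----------
    excitation_wavelength_nm : float (default 405)
    mu_a_target : number in cm^-1, bundled model preset name, or model object
    mu_s_prime_target : same conventions
    gelatin_pct : float (default 8)
    intralipid_slope : mm^-1 per %, default the bundled 405 nm slope
    gelatin_correction : default 80/220 (valid for 8% gelatin)
    absorber : one of
        {"kind": "hemoglobin", "eps_mixed": ... | "eps_oxy"/"eps_deoxy",
         "saturation": 0.70}
        {"kind": "mixture",
         "components": [{"name", "ratio", "mu_a_per_unit", "unit"}, ...]}

    The result is a pure function of the config: identical configs give
    byte-identical serializations.
    """
    cfg = dict(config)
    wavelength = float(cfg.get("excitation_wavelength_nm", 405.0))
    if "mu_a_target" not in cfg or "mu_s_prime_target" not in cfg:
        raise ValueError("config must name both mu_a_target and mu_s_prime_target")
    mu_a = _resolve_mu_target(cfg["mu_a_target"], wavelength, what="mu_a")
    mu_s = _resolve_mu_target(cfg["mu_s_prime_target"], wavelength, what="mu_s_prime")
    gelatin = float(cfg.get("gelatin_pct", 8.0))
    slope = float(cfg.get("intralipid_slope", INTRALIPID_SLOPE_405NM))
    correction = float(cfg.get("gelatin_correction", GELATIN_CORRECTION_8PCT))
    if gelatin != 8.0 and "gelatin_correction" not in cfg:
        raise ValueError(
            "the default 80/220 scattering correction holds at 8% gelatin only; "
            "supply gelatin_correction explicitly for other gelatin fractions"
        )

    notes: dict[str, str] = {
        "mu_a_target": f"{mu_a:.6g} cm^-1 at {wavelength:g} nm "
        f"(from {cfg['mu_a_target']!r})",
        "mu_s_prime_target": f"{mu_s:.6g} cm^-1 at {wavelength:g} nm "
        f"(from {cfg['mu_s_prime_target']!r})",
    }

    pre, final_il = intralipid_concentration(mu_s, slope=slope, gelatin_correction=correction)
    notes["intralipid"] = (
        f"linear slope {slope:g} mm^-1/%: {pre:.6g}% pre-correction, "
        f"divided by gelatin factor {correction:.6g} -> {final_il:.6g}%"
    )

    absorber_cfg = cfg.get("absorber")
    absorbers: dict[str, tuple[float, str]] = {}
    if mu_a == 0 or absorber_cfg is None:
        if mu_a > 0:
            raise ValueError("nonzero mu_a target requires an absorber config")
        notes["absorbers"] = "zero absorption target: no absorbers"
    elif absorber_cfg.get("kind") == "hemoglobin":
        spec = HemoglobinSpec(
            molecular_weight=float(absorber_cfg.get("molecular_weight", HB_MOLECULAR_WEIGHT)),
            saturation=float(absorber_cfg.get("saturation", 0.70)),
            eps_oxy=absorber_cfg.get("eps_oxy"),
            eps_deoxy=absorber_cfg.get("eps_deoxy"),
            eps_mixed=absorber_cfg.get(
                "eps_mixed", None if "eps_oxy" in absorber_cfg else HB_EXTINCTION_405NM
            ),
        )
        c = hemoglobin_concentration(mu_a, spec)
        absorbers["hemoglobin"] = (c, "g/L")
        notes["absorbers"] = (
            f"hemoglobin {c:.6g} g/L from eps={spec.extinction:.6g} cm^-1/M, "
            f"MW={spec.molecular_weight:g} g/mol"
        )
    elif absorber_cfg.get("kind") == "mixture":
        comps = absorber_cfg["components"]
        mix = MixtureSpec(
            absorbers=[(c["name"], float(c["ratio"]), float(c["mu_a_per_unit"])) for c in comps],
            target_mu_a=mu_a,
        )
        units = {c["name"]: c.get("unit", "g/L") for c in comps}
        for name, conc in solve_mixture(mix):
            absorbers[name] = (conc, units[name])
        notes["absorbers"] = (
            "mixture at fixed ratios; concentrations conserve "
            "sum C_i * mu_a_i = mu_a target"
        )
    else:
        raise ValueError("absorber config must have kind 'hemoglobin' or 'mixture'")

    return Recipe(
        gelatin_pct=gelatin,
        intralipid_pct=final_il,
        absorbers=absorbers,
        excitation_wavelength=wavelength,
        target_mu_a=mu_a,
        target_mu_s_prime=mu_s,
        notes=notes,
    )
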