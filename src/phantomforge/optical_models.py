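"""Wavelength-dependent tissue optical-property models.

Absorption and reduced-scattering coefficient models used to set phantom
design targets: an exponential absorption law for collagen-dominated
connective tissue, Mie-type power laws (with analytic error propagation)
and a combined Rayleigh–Mie law for scattering, and the empirical quadratic
polynomial describing intralipid scattering versus wavelength.

All evaluation functions accept scalar or array wavelengths in nm and
return coefficients in cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidityRangeWarning",
    "ExponentialAbsorptionModel",
    "ScatteringPowerLaw",
    "RayleighMieModel",
    "IntralipidPolynomial",
    "eval_exponential_absorption",
    "fit_exponential_absorption",
    "eval_power_law",
    "power_law_error",
    "eval_rayleigh_mie",
    "scattering_bound_interval",
    "eval_intralipid_polynomial",
]


class ValidityRangeWarning(UserWarning):
    """Raised (as warning) when a model is evaluated outside its declared range."""


def _check_range(
    wavelength_nm, valid_range: tuple[float, float] | None, name: str, strict: bool
) -> None:
    if valid_range is None:
        return
    lo, hi = valid_range
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w < lo) or np.any(w > hi):
        msg = (
            f"{name} evaluated outside its declared validity range "
            f"[{lo:g}, {hi:g}] nm (requested {np.min(w):g}-{np.max(w):g} nm)"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, ValidityRangeWarning, stacklevel=3)


@dataclass(frozen=True)
class ExponentialAbsorptionModel:
    """mu_a(lambda) = amplitude * exp(-decay * lambda).

    Parameters
    ----------
    amplitude : float
        Prefactor A in cm^-1.  Must be positive.
    decay : float
        Decay rate k in nm^-1.  Must be positive so that absorption
        strictly decreases with wavelength.
    valid_range : (float, float)
        Wavelength interval (nm) over which the fit is declared valid.
    """

    amplitude: float
    decay: float
    valid_range: tuple[float, float] = (300.0, 600.0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")

    def __call__(self, wavelength_nm, *, strict: bool = False):
        return eval_exponential_absorption(self, wavelength_nm, strict=strict)

    def to_dict(self) -> dict:
        return {
            "kind": "exponential_absorption",
            "amplitude": self.amplitude,
            "decay": self.decay,
            "valid_range": list(self.valid_range),
            "label": self.label,
        }


@dataclass(frozen=True)
class ScatteringPowerLaw:
    """mu_s'(lambda) = a * (lambda / lambda_ref)^(-b), with parameter errors.

    ``delta_a`` and ``delta_b`` are one-standard-deviation uncertainties on
    the fitted amplitude and power, used for first-order error propagation.
    """

    a: float
    b: float
    delta_a: float = 0.0
    delta_b: float = 0.0
    lambda_ref: float = 600.0
    valid_range: tuple[float, float] = (400.0, 1300.0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("amplitude a must be > 0")
        if self.lambda_ref <= 0:
            raise ValueError("lambda_ref must be > 0")
        if self.delta_a < 0 or self.delta_b < 0:
            raise ValueError("parameter uncertainties must be >= 0")

    def __call__(self, wavelength_nm, *, strict: bool = False):
        return eval_power_law(self, wavelength_nm, strict=strict)

    def error(self, wavelength_nm):
        return power_law_error(self, wavelength_nm)

    def to_dict(self) -> dict:
        return {
            "kind": "power_law",
            "a": self.a,
            "b": self.b,
            "delta_a": self.delta_a,
            "delta_b": self.delta_b,
            "lambda_ref": self.lambda_ref,
            "valid_range": list(self.valid_range),
            "label": self.label,
        }


@dataclass(frozen=True)
class RayleighMieModel:
    """Combined Rayleigh + Mie reduced-scattering model.

    mu_s'(lambda) = a' * [ f_ray*(lambda/500)^-4 + (1-f_ray)*(lambda/500)^-b_mie ]

    ``f_ray`` is the fractional Rayleigh contribution at the 500 nm
    reference wavelength.
    """

    a_prime: float
    f_ray: float
    b_mie: float
    lambda_ref: float = 500.0
    valid_range: tuple[float, float] = (400.0, 1300.0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.a_prime <= 0:
            raise ValueError("a_prime must be > 0")
        if not 0.0 <= self.f_ray <= 1.0:
            raise ValueError("f_ray must lie in [0, 1]")

    def __call__(self, wavelength_nm, *, strict: bool = False):
        return eval_rayleigh_mie(self, wavelength_nm, strict=strict)

    def to_dict(self) -> dict:
        return {
            "kind": "rayleigh_mie",
            "a_prime": self.a_prime,
            "f_ray": self.f_ray,
            "b_mie": self.b_mie,
            "lambda_ref": self.lambda_ref,
            "valid_range": list(self.valid_range),
            "label": self.label,
        }


@dataclass(frozen=True)
class IntralipidPolynomial:
    """Empirical quadratic mu_s'(lambda) = y0 + a_lin*lambda + b_quad*lambda^2
    for an intralipid stock emulsion (coefficients tabulated per stock %)."""

    y0: float
    a_lin: float
    b_quad: float
    stock_pct: float = 10.0
    valid_range: tuple[float, float] | None = None
    label: str = ""

    def __call__(self, wavelength_nm, *, strict: bool = False):
        return eval_intralipid_polynomial(self, wavelength_nm, strict=strict)

    def to_dict(self) -> dict:
        return {
            "kind": "intralipid_polynomial",
            "y0": self.y0,
            "a_lin": self.a_lin,
            "b_quad": self.b_quad,
            "stock_pct": self.stock_pct,
            "valid_range": None if self.valid_range is None else list(self.valid_range),
            "label": self.label,
        }


def eval_exponential_absorption(
    model: ExponentialAbsorptionModel, wavelength_nm, *, strict: bool = False
):
    """Absorption coefficient A*exp(-k*lambda) in cm^-1."""
    _check_range(wavelength_nm, model.valid_range, "exponential absorption model", strict)
    w = np.asarray(wavelength_nm, dtype=float)
    out = model.amplitude * np.exp(-model.decay * w)
    return float(out) if np.isscalar(wavelength_nm) else out


def fit_exponential_absorption(
    points: Sequence[tuple[float, float]],
) -> tuple[ExponentialAbsorptionModel, float]:
    """Fit A*exp(-k*lambda) to (wavelength, mu_a) points by log-linear least squares.

    The fit is linear in ln(mu_a): ln mu_a = ln A - k*lambda.  Returns the
    fitted model and the coefficient of determination R^2 in log space.

    Raises
    ------
    ValueError
        If fewer than 3 points are supplied or any mu_a is non-positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (wavelength, mu_a) points")
    lam, mu = pts[:, 0], pts[:, 1]
    if np.any(mu <= 0):
        raise ValueError("all mu_a values must be > 0 for a log-linear fit")
    y = np.log(mu)
    slope, intercept = np.polyfit(lam, y, 1)
    resid = y - (slope * lam + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    lo, hi = float(lam.min()), float(lam.max())
    model = ExponentialAbsorptionModel(
        amplitude=float(np.exp(intercept)), decay=float(-slope), valid_range=(lo, hi)
    )
    return model, r2


def eval_power_law(model: ScatteringPowerLaw, wavelength_nm, *, strict: bool = False):
    """Reduced scattering coefficient a*(lambda/lambda_ref)^(-b) in cm^-1."""
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be > 0")
    _check_range(wavelength_nm, model.valid_range, "scattering power law", strict)
    out = model.a * (w / model.lambda_ref) ** (-model.b)
    return float(out) if np.isscalar(wavelength_nm) else out


def power_law_error(model: ScatteringPowerLaw, wavelength_nm):
    """First-order propagated uncertainty of the power-law mu_s'.

    delta mu_s' = (lambda/lambda_ref)^(-b) *
                  sqrt(delta_a^2 + [a * ln(lambda/lambda_ref) * delta_b]^2)

    which is the root-sum-square of the partial-derivative terms
    (|d mu/d a| = (lambda/lref)^-b, |d mu/d b| = a (lambda/lref)^-b |ln(lambda/lref)|),
    assuming zero covariance between a and b.
    """
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be > 0")
    ratio = w / model.lambda_ref
    out = ratio ** (-model.b) * np.sqrt(
        model.delta_a**2 + (model.a * np.log(ratio) * model.delta_b) ** 2
    )
    return float(out) if np.isscalar(wavelength_nm) else out


def eval_rayleigh_mie(model: RayleighMieModel, wavelength_nm, *, strict: bool = False):
    """Reduced scattering from the combined Rayleigh (lambda^-4) + Mie terms."""
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be > 0")
    _check_range(wavelength_nm, model.valid_range, "Rayleigh-Mie model", strict)
    ratio = w / model.lambda_ref
    out = model.a_prime * (
        model.f_ray * ratio**-4.0 + (1.0 - model.f_ray) * ratio ** (-model.b_mie)
    )
    return float(out) if np.isscalar(wavelength_nm) else out


def scattering_bound_interval(
    mu_eq4: float, mu_eq5: float, min_eq5_weight: float = 0.5
) -> tuple[float, float]:
    """Bracket mu_s' between two model predictions under a minimum-weight assumption.

    When particles are predominantly Mie-sized, at least ``min_eq5_weight``
    of the scattering is attributed to the combined Rayleigh-Mie prediction
    ``mu_eq5`` and the remainder to the plain power law ``mu_eq4``; the
    admissible interval is then

        [w*mu_eq5 + (1-w)*mu_eq4,  mu_eq5]   with w = min_eq5_weight.

    Bounds are swapped if mu_eq4 > mu_eq5.
    """
    if not 0.0 <= min_eq5_weight <= 1.0:
        raise ValueError("min_eq5_weight must lie in [0, 1]")
    lo_model, hi_model = (mu_eq4, mu_eq5) if mu_eq4 <= mu_eq5 else (mu_eq5, mu_eq4)
    lower = min_eq5_weight * hi_model + (1.0 - min_eq5_weight) * lo_model
    return lower, hi_model


def eval_intralipid_polynomial(
    model: IntralipidPolynomial, wavelength_nm, *, strict: bool = False
):
    """Quadratic intralipid mu_s'(lambda); raises if the result is non-positive."""
    _check_range(wavelength_nm, model.valid_range, "intralipid polynomial", strict)
    w = np.asarray(wavelength_nm, dtype=float)
    out = model.y0 + model.a_lin * w + model.b_quad * w**2
    if np.any(np.asarray(out) <= 0):
        raise ValueError("intralipid polynomial evaluated to a non-positive mu_s'")
    return float(out) if np.isscalar(wavelength_nm) else out


_MODEL_KINDS = {
    "exponential_absorption": ExponentialAbsorptionModel,
    "power_law": ScatteringPowerLaw,
    "rayleigh_mie": RayleighMieModel,
    "intralipid_polynomial": IntralipidPolynomial,
}


def model_from_dict(d: dict):
    """Reconstruct any optical model from its ``to_dict`` representation."""
    d = dict(d)
    kind = d.pop("kind")
    cls = _MODEL_KINDS.get(kind)
    if cls is None:
        raise ValueError(f"unknown optical model kind {kind!r}")
    if d.get("valid_range") is not None:
        d["valid_range"] = tuple(d["valid_range"])
    return cls(**d)
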