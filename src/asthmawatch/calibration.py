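"""Piecewise dust-density calibration with temperature/humidity compensation.

An optical dust sensor's raw voltage reading drifts with ambient temperature
and humidity.  The calibration maps raw voltage ``x`` to dust density
``rho_c`` through five cases selected by the signs of the humidity and
temperature changes (dH = H - H_ref, dT = T - T_ref) relative to the
conditions under which the sensor was bench-calibrated:

    dH = 0, dT = 0:   rho_c = 5.4e-4 * x - 0.15
    dH > 0, dT > 0:   rho_c = aH*H + bH - (aT1*T + bT1)
    dH > 0, dT < 0:   rho_c = aH*H + bH - (aT2*T + bT2)
    dH < 0, dT > 0:   rho_c = 5.4e-4 * x - 0.15 - (aT1 + bT1)
    dH < 0, dT < 0:   rho_c = 5.4e-4 * x - 0.15 - (aT2 + bT2)

with aH = 2.8e-3, bH = 0.1647, aT1 = 0.0005, bT1 = 0.0133, aT2 = 0.0002,
bT2 = 0.0329.  The rising-humidity cases discard the voltage term and the
falling-humidity cases subtract (a + b) without a temperature multiplier;
both are implemented exactly as published (see docs/methods.md for the two
audit switches that expose the physically "repaired" readings).

Zero deltas are routed for continuity with the no-change case: dH = 0 joins
the dH < 0 family (which keeps the affine voltage term), and dT = 0 joins the
T1 sub-branch; dH = dT = 0 is the plain affine case.

The linear fit can go negative at low voltage; densities are clamped to zero
after calibration, with a flag marking clamped samples.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "CalibrationCoefficients",
    "DEFAULT_COEFFICIENTS",
    "dust_density",
    "clamp_nonnegative",
    "load_coefficients",
]


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Published calibration constants plus the bench reference conditions.

    ``ref_temperature`` (degC) and ``ref_humidity`` (%RH) define the baseline
    against which dT and dH are computed; the bench conditions were not
    published, so the defaults (25 degC, 40 %RH) are this package's choice
    and are overridable in config.  ``humid_branch_adds_affine`` is an audit
    switch (default off): when on, the rising-humidity branches also add the
    affine voltage term they discard as published.
    """

    slope: float = 5.4e-4
    intercept: float = -0.15
    alpha_h: float = 2.8e-3
    beta_h: float = 0.1647
    alpha_t1: float = 0.0005
    beta_t1: float = 0.0133
    alpha_t2: float = 0.0002
    beta_t2: float = 0.0329
    ref_temperature: float = 25.0
    ref_humidity: float = 40.0
    humid_branch_adds_affine: bool = False

    def __post_init__(self) -> None:
        for name in (
            "slope",
            "intercept",
            "alpha_h",
            "beta_h",
            "alpha_t1",
            "beta_t1",
            "alpha_t2",
            "beta_t2",
            "ref_temperature",
            "ref_humidity",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")


DEFAULT_COEFFICIENTS = CalibrationCoefficients()


def dust_density(
    x: float,
    temperature: float,
    humidity: float,
    coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Calibrated dust density from raw voltage ``x`` at ambient T (degC)
    and H (%RH).

    The branch is selected by the signs of dT = T - ref_temperature and
    dH = H - ref_humidity.  Raw voltage is treated as the sensor's native
    (opaque) unit; no unit conversion is applied.  The result may be
    negative — apply :func:`clamp_nonnegative` for a physical density.
    """
    for name, v in (("x", x), ("temperature", temperature), ("humidity", humidity)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    dT = temperature - coeffs.ref_temperature
    dH = humidity - coeffs.ref_humidity
    affine = coeffs.slope * x + coeffs.intercept

    if dH == 0 and dT == 0:
        return affine
    if dH > 0:
        # Rising humidity: published formula carries no voltage term.
        if dT >= 0:
            rho = coeffs.alpha_h * humidity + coeffs.beta_h - (
                coeffs.alpha_t1 * temperature + coeffs.beta_t1
            )
        else:
            rho = coeffs.alpha_h * humidity + coeffs.beta_h - (
                coeffs.alpha_t2 * temperature + coeffs.beta_t2
            )
        if coeffs.humid_branch_adds_affine:
            rho += affine
        return rho
    # dH < 0, or dH == 0 with dT != 0 (kept in this family so the voltage
    # term survives a pure temperature change).
    if dT >= 0:
        return affine - (coeffs.alpha_t1 + coeffs.beta_t1)
    return affine - (coeffs.alpha_t2 + coeffs.beta_t2)


def clamp_nonnegative(rho: float) -> tuple[float, bool]:
    """Clamp a calibrated density to zero; returns ``(value, clamped)``.

    ``clamped`` is True only for strictly negative inputs (an exact zero is a
    legitimate reading, not a clamp).
    """
    if not math.isfinite(rho):
        raise ValueError(f"density must be finite, got {rho!r}")
    if rho < 0:
        return 0.0, True
    return rho, False


_FLOAT_KEYS = {
    "slope",
    "intercept",
    "alpha_h",
    "beta_h",
    "alpha_t1",
    "beta_t1",
    "alpha_t2",
    "beta_t2",
    "ref_temperature",
    "ref_humidity",
}


def load_coefficients(path: str | Path) -> CalibrationCoefficients:
    """Load coefficients from a TOML file's ``[dust_calibration]`` section.

    Omitted keys fall back to the published defaults.
    """
    with Path(path).open("rb") as fh:
        config = tomllib.load(fh)
    section = config.get("dust_calibration", {})
    unknown = set(section) - _FLOAT_KEYS - {"humid_branch_adds_affine"}
    if unknown:
        raise ValueError(f"unknown dust_calibration keys: {sorted(unknown)}")
    kwargs: dict = {k: float(v) for k, v in section.items() if k in _FLOAT_KEYS}
    if "humid_branch_adds_affine" in section:
        kwargs["humid_branch_adds_affine"] = bool(section["humid_branch_adds_affine"])
    return replace(DEFAULT_COEFFICIENTS, **kwargs)
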