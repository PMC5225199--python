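"""Acquisition-side quality-control calculators for multi-photon imaging.

Nyquist sampling distances for a multi-photon excitation (MPE) microscope:

    Δx = Δy = λ_ex / (4 k n sin α)        (lateral)
    Δz      = λ_ex / (2 k n (1 − cos α))  (axial)

where n is the lens-medium refractive index (1.338 for water), k the photon
count (2 for two-photon excitation), λ_ex the excitation wavelength, and α
the half-aperture angle of the objective with sin α = NA / n.

The ideal diffraction-limited lateral resolution of MPE imaging is the
single-photon Rayleigh limit improved by √2:

    r = 0.61 λ_ex / (NA √2)

All wavelengths and returned distances are in nm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class OpticsParams:
    """Objective and excitation parameters for sampling calculations."""

    lambda_ex: float                 # excitation wavelength, nm
    numerical_aperture: float
    refractive_index: float = 1.338  # water immersion
    photon_count: int = 2            # two-photon excitation

    def __post_init__(self) -> None:
        if self.lambda_ex <= 0:
            raise ValueError("excitation wavelength must be positive")
        if not (0 < self.numerical_aperture < self.refractive_index):
            raise ValueError(
                "numerical aperture must lie in (0, n); the half-aperture "
                "angle is undefined otherwise"
            )
        if self.photon_count < 1:
            raise ValueError("photon count must be >= 1")

    @property
    def sin_alpha(self) -> float:
        return self.numerical_aperture / self.refractive_index

    @property
    def cos_alpha(self) -> float:
        return math.sqrt(1.0 - self.sin_alpha**2)


def nyquist_sampling(params: OpticsParams) -> tuple[float, float]:
    """(Δxy, Δz) Nyquist sampling distances in nm."""
    k, n = params.photon_count, params.refractive_index
    dxy = params.lambda_ex / (4.0 * k * n * params.sin_alpha)
    dz = params.lambda_ex / (2.0 * k * n * (1.0 - params.cos_alpha))
    return dxy, dz


def mpe_resolution_limit(lambda_ex: float, numerical_aperture: float) -> float:
    """Ideal diffraction-limited MPE lateral resolution 0.61 λ/(NA √2), nm."""
    if lambda_ex <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.61 * lambda_ex / (numerical_aperture * math.sqrt(2.0))


def check_sampling(pixel_xy: float, step_z: float, params: OpticsParams) -> dict:
    """Pass/fail per axis: a spacing passes when it does not exceed the
    corresponding Nyquist distance.  Inputs in nm."""
    if pixel_xy <= 0 or step_z <= 0:
        raise ValueError("pixel size and focal step must be positive")
    dxy, dz = nyquist_sampling(params)
    return {
        "nyquist_xy": dxy,
        "nyquist_z": dz,
        "lateral_pass": pixel_xy <= dxy,
        "axial_pass": step_z <= dz,
    }


def format_qc_table(params: OpticsParams, pixel_xy: float | None = None,
                    step_z: float | None = None) -> str:
    """Human-readable QC summary (nm, with µm at 2 decimals)."""
    dxy, dz = nyquist_sampling(params)
    r = mpe_resolution_limit(params.lambda_ex, params.numerical_aperture)
    lines = [
        f"excitation wavelength    : {params.lambda_ex:.0f} nm",
        f"numerical aperture       : {params.numerical_aperture:.2f}",
        f"refractive index         : {params.refractive_index:.3f}",
        f"photon count             : {params.photon_count}",
        f"Nyquist lateral (XY)     : {dxy:.1f} nm ({dxy/1000:.2f} µm)",
        f"Nyquist axial (Z)        : {dz:.1f} nm ({dz/1000:.2f} µm)",
        f"MPE resolution limit     : {r:.1f} nm ({r/1000:.2f} µm)",
    ]
    if pixel_xy is not None and step_z is not None:
        chk = check_sampling(pixel_xy, step_z, params)
        lines.append(
            f"lateral sampling {pixel_xy:.0f} nm : "
            + ("PASS" if chk["lateral_pass"] else "FAIL")
        )
        lines.append(
            f"axial sampling {step_z:.0f} nm   : "
            + ("PASS" if chk["axial_pass"] else "FAIL")
        )
    return "\n".join(lines)
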