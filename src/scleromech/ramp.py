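"""Tensile ramp testing: engineering stress/strain and exponential fits.

A preloaded strip is stretched at constant strain rate (protocol: 0.1%/s up
to 3.5%).  Engineering stress is force over the undeformed cross-section
(mean B-mode thickness x width); engineering strain is grip displacement
over the post-preload gauge length.  The stress-strain curve is fit to the
exponential constitutive model

    σ = A (exp(B ε) - 1)

by Levenberg-Marquardt least squares.  A·B is the initial tangent modulus
(dσ/dε at ε = 0) and B the rate at which the tangent modulus grows with
stress.  Initialisation takes B0 from the slope of log(dσ/dε) vs ε via
finite differences and A0 from the initial tangent; on non-convergence the
fit restarts from jittered starting points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StripGeometry",
    "RampFit",
    "stress_strain_from_raw",
    "simulate_ramp",
    "fit_exponential",
]


@dataclass(frozen=True)
class StripGeometry:
    """Strip cross-section and gauge length (all mm).

    Thickness is the mean of nine B-mode readings (three per cross-sectional
    scan at three scans); width the mean of three readings; gauge length is
    the grip distance after preloading.
    """

    raw_thickness_readings: tuple[float, ...]
    raw_width_readings: tuple[float, ...]
    gauge_length: float

    def __post_init__(self) -> None:
        if not self.raw_thickness_readings or not self.raw_width_readings:
            raise ValueError("need at least one thickness and one width reading")
        if min(self.raw_thickness_readings) <= 0 or min(self.raw_width_readings) <= 0:
            raise ValueError("all readings must be positive")
        if self.gauge_length <= 0:
            raise ValueError("gauge length must be positive")

    @property
    def thickness(self) -> float:
        return float(np.mean(self.raw_thickness_readings))

    @property
    def width(self) -> float:
        return float(np.mean(self.raw_width_readings))

    @classmethod
    def from_means(cls, thickness: float, width: float, gauge_length: float,
                   n_thickness: int = 9, n_width: int = 3) -> "StripGeometry":
        return cls((thickness,) * n_thickness, (width,) * n_width, gauge_length)


@dataclass(frozen=True)
class RampFit:
    A: float          # MPa
    B: float          # dimensionless
    rmse: float       # MPa
    r_squared: float

    @property
    def AB(self) -> float:
        """Initial tangent modulus dσ/dε at ε = 0, MPa."""
        return self.A * self.B


def stress_strain_from_raw(
    force_n: np.ndarray, displacement_mm: np.ndarray, geometry: StripGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Engineering (strain, stress MPa) from raw force/displacement series.

    σ = F / (thickness·width) with the undeformed cross-section; ε =
    displacement / gauge length, displacement measured from the post-preload
    grip distance.
    """
    force_n = np.asarray(force_n, dtype=float)
    displacement_mm = np.asarray(displacement_mm, dtype=float)
    area_mm2 = geometry.thickness * geometry.width
    if area_mm2 <= 0:
        raise ValueError("strip cross-section must be positive")
    strain = displacement_mm / geometry.gauge_length
    stress = force_n / area_mm2  # N/mm^2 == MPa
    return strain, stress


def simulate_ramp(
    A: float,
    B: float,
    strain_rate: float = 0.001,
    strain_max: float = 0.035,
    sample_rate: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a constant-rate ramp: ε(t) = rate·t, σ = A(e^{Bε} − 1) + noise.

    Defaults follow the protocol (0.1%/s to 3.5% strain).  Returns
    (strain, stress) arrays.
    """
    if min(A, B, strain_rate, strain_max, sample_rate) <= 0:
        raise ValueError("A, B, rates and strain_max must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(strain_max / strain_rate * sample_rate)) + 1
    strain = strain_rate * np.arange(n) / sample_rate
    stress = A * np.expm1(B * strain)
    if noise_sd > 0:
        stress = stress + rng.normal(0.0, noise_sd, size=n)
    return strain, stress


def _initial_guess(strain: np.ndarray, stress: np.ndarray) -> tuple[float, float]:
    """B0 from the log-tangent-modulus slope; A0 from the initial tangent."""
    ds = np.gradient(stress, strain)
    pos = ds > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(strain[pos], np.log(ds[pos]), 1)
        B0 = float(np.clip(slope, 1.0, 500.0))
        AB0 = float(np.exp(intercept))
    else:
        B0, AB0 = 50.0, max(float(ds[np.isfinite(ds)].mean()), 1e-3)
    return max(AB0 / B0, 1e-6), B0


def fit_exponential(
    strain: np.ndarray, stress: np.ndarray, n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
) -> RampFit:
    """Fit σ = A(e^{Bε} − 1) by Levenberg-Marquardt; report A, B, RMSE, R²."""
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.size < 10:
        raise ValueError("need at least 10 samples for a stable fit")
    if np.any(np.diff(strain) <= 0):
        raise ValueError("strain must be strictly increasing")

    def model(eps: np.ndarray, A: float, B: float) -> np.ndarray:
        return A * np.expm1(B * eps)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a0, b0 = _initial_guess(strain, stress)
    guesses = [(a0, b0)]
    guesses += [(a0 * float(rng.lognormal(0, 0.5)), b0 * float(rng.lognormal(0, 0.5)))
                for _ in range(n_restarts)]
    last_err: Exception | None = None
    for g in guesses:
        try:
            popt, _ = curve_fit(model, strain, stress, p0=g, method="lm", maxfev=20000)
            A, B = float(popt[0]), float(popt[1])
            if A <= 0 or B <= 0:
                raise RuntimeError(f"non-physical fit A={A:.4g}, B={B:.4g}")
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        resid = stress - model(strain, A, B)
        sst = float(np.sum((stress - stress.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        return RampFit(A=A, B=B, rmse=float(np.sqrt(np.mean(resid**2))),
                       r_squared=max(min(r2, 1.0), 0.0))
    raise RuntimeError(
        f"exponential fit failed after {len(guesses)} starts; last error: {last_err}"
    )
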