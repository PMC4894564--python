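"""Dynamic mechanical analysis of scleral strips.

Small-amplitude sinusoidal strain is applied to a preloaded strip and the
sinusoidal stress response is recorded.  Under linear viscoelasticity the
stress lags the strain by a phase angle δ; the complex modulus
E* = σ_amp / ε_amp measures overall dynamic stiffness and tan δ = E''/E'
the mechanical damping, with storage modulus E' = E* cos δ and loss modulus
E'' = E* sin δ.

Amplitude and phase of each channel are estimated by harmonic least squares
at the known drive frequency — fitting a + b sin(2πft) + c cos(2πft) (with
an optional linear-drift column that absorbs slow preload relaxation) —
which is exact for non-integer numbers of cycles and robust on short
windows.  Analysis uses the last 8 of the 12 recorded cycles.

The static preloads (0.04 N "normal-IOP" and 0.1 N "high-IOP") are chosen
to match the Laplace-law hoop stress of a thin spherical shell,
σ = P·r/(2t), at ~15 and ~35 mmHg with generic canine globe geometry
(r = 12 mm, t = 500 µm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StressStrainSeries",
    "DMAResult",
    "DMA_FREQUENCIES_HZ",
    "DMA_PRELOADS_N",
    "REFERENCE_CONDITION",
    "LINEARITY_BOUND",
    "simulate_dma",
    "fit_harmonic",
    "viscoelastic_params",
    "run_dma_sweep",
    "laplace_preload_stress",
]

#: Drive frequencies of the sweep protocol, Hz.
DMA_FREQUENCIES_HZ: tuple[float, ...] = (0.1, 0.5, 1.0, 3.0, 5.0, 10.0)
#: Static preloads of the sweep protocol, N.
DMA_PRELOADS_N: tuple[float, float] = (0.04, 0.1)
#: (frequency Hz, preload N) used for all cohort-level statistics.
REFERENCE_CONDITION: tuple[float, float] = (1.0, 0.04)
#: Strain amplitude above which the tissue response is no longer linear.
LINEARITY_BOUND = 0.0025

MMHG_TO_PA = 133.322


@dataclass
class StressStrainSeries:
    """Sampled stress/strain cycles at one frequency x preload cell."""

    time: np.ndarray          # s, uniform grid
    strain: np.ndarray        # dimensionless
    stress: np.ndarray        # MPa
    drive_frequency: float    # Hz
    preload: float            # N
    n_cycles: int
    sample_rate: float        # Hz
    nonlinear_warning: bool = False
    strip_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if not (self.time.shape == self.strain.shape == self.stress.shape):
            raise ValueError("time, strain and stress must share a shape")
        if self.sample_rate < 20 * self.drive_frequency:
            raise ValueError("sample rate must be at least 20x the drive frequency")
        if len(self.time) < self.n_cycles / self.drive_frequency * 1.0:
            pass  # duration check below is the meaningful one
        if self.time[-1] - self.time[0] < (self.n_cycles - 1) / self.drive_frequency:
            raise ValueError("series shorter than the requested number of cycles")


@dataclass(frozen=True)
class DMAResult:
    """Linear-viscoelastic parameters extracted from one series."""

    E_star: float     # MPa
    delta: float      # rad, stress-strain phase lag in [0, pi/2)
    tan_delta: float
    E_storage: float  # MPa
    E_loss: float     # MPa
    frequency: float  # Hz
    preload: float    # N


def simulate_dma(
    E_star: float,
    delta: float,
    frequency: float = 1.0,
    strain_amplitude: float = 0.0015,
    preload_stress: float = 0.024,
    preload_n: float = 0.04,
    n_cycles: int = 12,
    sample_rate: float | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    strip_id: str = "",
) -> StressStrainSeries:
    """Simulate one DMA cell: sinusoidal strain and its lagged stress response.

    strain(t) = ε0 sin(2πft);  stress(t) = σ_pre + E*·ε0 sin(2πft + δ) + noise.

    ``preload_stress`` is the static stress offset (MPa) produced by the
    ``preload_n`` grip force; the series records the force so sweep tables
    can be keyed by the protocol's (frequency, preload N) cells.  Defaults
    follow the protocol: 0.15% strain amplitude, 12 cycles.  A strain
    amplitude above the 0.25% linearity bound flags (not rejects) the
    series.
    """
    if E_star <= 0:
        raise ValueError("E_star must be positive")
    if not 0 <= delta < math.pi / 2:
        raise ValueError("delta must lie in [0, pi/2)")
    if frequency <= 0 or strain_amplitude <= 0 or n_cycles < 1:
        raise ValueError("frequency, strain amplitude and n_cycles must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sample_rate is None:
        sample_rate = max(100.0 * frequency, 20.0 * frequency)
    n = int(round(n_cycles / frequency * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    w = 2 * math.pi * frequency
    strain = strain_amplitude * np.sin(w * t)
    stress = preload_stress + E_star * strain_amplitude * np.sin(w * t + delta)
    if noise_sd > 0:
        stress = stress + rng.normal(0.0, noise_sd, size=n)
    return StressStrainSeries(
        time=t, strain=strain, stress=stress, drive_frequency=frequency,
        preload=preload_n, n_cycles=n_cycles, sample_rate=sample_rate,
        nonlinear_warning=strain_amplitude > LINEARITY_BOUND, strip_id=strip_id,
    )


def _analysis_window(series: StressStrainSeries, last_cycles: int) -> np.ndarray:
    """Boolean mask selecting the last ``last_cycles`` full cycles."""
    t_end = series.time[-1]
    t_start = t_end - last_cycles / series.drive_frequency
    mask = series.time >= t_start - 0.5 / series.sample_rate
    if mask.sum() < 2 * series.sample_rate / series.drive_frequency * 0.9:
        raise ValueError("analysis window shorter than 2 cycles")
    return mask


def fit_harmonic(
    series: StressStrainSeries,
    channel: str,
    last_cycles: int = 8,
    drift: bool = False,
) -> tuple[float, float, float]:
    """Least-squares amplitude/phase/offset of one channel at the drive frequency.

    Fits ``a + b sin(2πft) + c cos(2πft)`` (plus an optional linear time
    column when ``drift``); amplitude = sqrt(b² + c²), phase = atan2(c, b)
    so the fitted signal is amplitude·sin(2πft + phase) + offset.

    Returns (amplitude, phase, offset).
    """
    if channel not in ("stress", "strain"):
        raise ValueError("channel must be 'stress' or 'strain'")
    y = getattr(series, channel)
    mask = _analysis_window(series, last_cycles)
    t = series.time[mask]
    y = y[mask]
    w = 2 * math.pi * series.drive_frequency
    cols = [np.ones_like(t), np.sin(w * t), np.cos(w * t)]
    if drift:
        cols.append(t - t.mean())
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = beta[:3]
    return float(math.hypot(b, c)), float(math.atan2(c, b)), float(a)


def viscoelastic_params(
    series: StressStrainSeries, last_cycles: int = 8, drift: bool = False
) -> DMAResult:
    """Extract E*, δ, tan δ and storage/loss moduli from one series."""
    s_amp, s_ph, _ = fit_harmonic(series, "stress", last_cycles, drift)
    e_amp, e_ph, _ = fit_harmonic(series, "strain", last_cycles, drift)
    if e_amp < 1e-12:
        raise ValueError("degenerate input: strain amplitude is zero")
    delta = (s_ph - e_ph) % (2 * math.pi)
    if delta > math.pi:  # map lags just below 2π to small negatives, then clamp
        delta -= 2 * math.pi
    delta = min(max(delta, 0.0), math.pi / 2 - 1e-12)
    e_star = s_amp / e_amp
    return DMAResult(
        E_star=e_star, delta=delta, tan_delta=math.tan(delta),
        E_storage=e_star * math.cos(delta), E_loss=e_star * math.sin(delta),
        frequency=series.drive_frequency, preload=series.preload,
    )


def run_dma_sweep(
    bundle: dict[tuple[float, float], StressStrainSeries],
    last_cycles: int = 8,
    drift: bool = False,
) -> pd.DataFrame:
    """Analyse a full 6-frequency x 2-preload sweep for one strip.

    Returns a 12-row table with one :class:`DMAResult` per cell and a
    ``reference`` flag on the 1 Hz / 0.04 N row (the condition used in all
    cohort statistics).  Missing cells are reported with NaN parameters,
    never imputed.
    """
    rows = []
    for preload in DMA_PRELOADS_N:
        for freq in DMA_FREQUENCIES_HZ:
            key = (freq, preload)
            rec: dict[str, float | bool] = {
                "frequency_hz": freq, "preload_n": preload,
                "reference": key == REFERENCE_CONDITION,
            }
            series = bundle.get(key)
            if series is None:
                rec.update(E_star=np.nan, tan_delta=np.nan, delta=np.nan,
                           E_storage=np.nan, E_loss=np.nan, missing=True)
            else:
                r = viscoelastic_params(series, last_cycles, drift)
                rec.update(E_star=r.E_star, tan_delta=r.tan_delta, delta=r.delta,
                           E_storage=r.E_storage, E_loss=r.E_loss, missing=False)
            rows.append(rec)
    return pd.DataFrame(rows)


def laplace_preload_stress(pressure_mmhg: float, radius_mm: float = 12.0,
                           thickness_mm: float = 0.5) -> float:
    """Hoop stress (MPa) of a pressurised thin spherical shell, σ = P·r/(2t).

    Defaults use the generic canine globe geometry (r = 12 mm, t = 500 µm)
    that sets the 0.04 N / 0.1 N preloads for ~15 / ~35 mmHg.
    """
    if pressure_mmhg <= 0 or radius_mm <= 0 or thickness_mm <= 0:
        raise ValueError("pressure, radius and thickness must be positive")
    sigma_pa = pressure_mmhg * MMHG_TO_PA * (radius_mm * 1e-3) / (2 * thickness_mm * 1e-3)
    return sigma_pa * 1e-6


# -- delimited-text I/O -------------------------------------------------------

def write_series(series: StressStrainSeries, path: str | Path) -> None:
    header = (
        f"frequency_hz={series.drive_frequency}\npreload_n={series.preload}\n"
        f"n_cycles={series.n_cycles}\nsample_rate_hz={series.sample_rate}\n"
        f"strip_id={series.strip_id}\ncolumns=time_s,strain,stress_MPa"
    )
    np.savetxt(path, np.column_stack([series.time, series.strain, series.stress]),
               header=header)


def read_series(path: str | Path) -> StressStrainSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").strip().partition("=")
            meta[key] = val
    data = np.loadtxt(path)
    return StressStrainSeries(
        time=data[:, 0], strain=data[:, 1], stress=data[:, 2],
        drive_frequency=float(meta["frequency_hz"]), preload=float(meta["preload_n"]),
        n_cycles=int(meta["n_cycles"]), sample_rate=float(meta["sample_rate_hz"]),
        strip_id=meta.get("strip_id", ""),
    )
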