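"""Synthetic instrument data with the statistical structure the analysis assumes.

Three generators stand in for the three instruments:

* :func:`simulate_voltammogram` — a one-electron quasi-reversible
  Butler-Volmer couple under semi-infinite planar diffusion, solved by an
  explicit finite-difference scheme.  This is the minimal textbook model that
  reproduces the growth of the anodic/cathodic peak separation with scan rate
  that the peak-separation kinetics method relies on.
* :func:`simulate_metabolic_dataset` — control-normalised metabolic activity
  on a (particle diameter x PEG linker mass x time x replicate) grid, drawn
  from the survival model ``M = exp(-beta exp(-alpha_loc L) t)`` with
  multiplicative Gaussian noise.
* :func:`simulate_spectrum` — a baseline plus signed Gaussian bands with
  additive noise, for exercising difference-spectrum and band-localization
  code.

All randomness flows from the explicit integer ``seed`` carried by each
parameter object; there is no global random state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import CONSTANTS, ROOM_TEMPERATURE_K, f_over_rt
from .errors import DiscretizationError, InputError
from .kinetics import ScanRateStudy, Voltammogram
from .spectra import Spectrum
from .tunneling import linker_length_from_mw

__all__ = [
    "GridSpec",
    "CVSimParams",
    "MetabolicSimParams",
    "Band",
    "SpectrumSimParams",
    "MetabolicDataset",
    "simulate_voltammogram",
    "simulate_scan_rate_study",
    "simulate_metabolic_dataset",
    "simulate_spectrum",
]


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Space/time discretization of the explicit diffusion solver.

    ``n_time`` is the total number of time steps over both sweep branches;
    the space step is derived from the stability ratio
    ``lambda = D dt / dx^2`` (must stay below 0.5 for the explicit scheme)
    and the simulated slab extends ``bulk_factor`` diffusion lengths.
    """

    n_time: int = 24000
    stability: float = 0.45
    bulk_factor: float = 6.0

    def refined(self, factor: int = 2) -> "GridSpec":
        """Grid with both steps halved (dt scales with factor^2 at fixed lambda)."""
        return GridSpec(
            n_time=self.n_time * factor * factor,
            stability=self.stability,
            bulk_factor=self.bulk_factor,
        )


@dataclass(frozen=True)
class CVSimParams:
    """True parameters of the simulated redox couple and sweep program."""

    k0_true: float = 3.75e-3        # cm s^-1
    alpha_ct_true: float = 0.5
    n_electrons: int = 1
    D_coeff: float = 1e-6           # cm^2 s^-1
    E_formal_true: float = 0.5      # V
    E_start: float = 1.2            # V
    E_reverse: float = -0.2         # V
    scan_rate: float = 0.1          # V s^-1
    temperature_K: float = ROOM_TEMPERATURE_K
    grid: GridSpec = field(default_factory=GridSpec)
    noise_sd_current: float = 0.0   # A
    seed: int = 0
    area_cm2: float = 1.0
    conc_mol_cm3: float = 1e-6      # 1 mM bulk concentration

    def __post_init__(self):
        if self.k0_true <= 0:
            raise InputError("k0_true must be positive")
        if not 0 < self.alpha_ct_true < 1:
            raise InputError("alpha_ct_true must lie in (0, 1)")
        if self.scan_rate <= 0:
            raise InputError("scan_rate must be positive")
        if self.E_start == self.E_reverse:
            raise InputError("degenerate sweep: E_start equals E_reverse")
        if self.D_coeff <= 0 or self.temperature_K <= 0:
            raise InputError("D_coeff and temperature_K must be positive")
        if self.n_electrons < 1:
            raise InputError("n_electrons must be a positive integer")


@dataclass(frozen=True)
class MetabolicSimParams:
    """True parameters of the synthetic metabolic-activity grid.

    Defaults mirror the resonance experiment design: particle diameters of
    20/50/100 nm, PEG linkers of 1/2/3.5/5 kDa, activity read after 12 h of
    stimulation, nine replicate wells, 5% multiplicative noise.
    """

    beta_true: float = 0.1              # h^-1
    alpha_loc_true: float = 0.1         # nm^-1
    linker_masses: tuple[float, ...] = (1.0, 2.0, 3.5, 5.0)   # kDa
    diameters: tuple[float, ...] = (20.0, 50.0, 100.0)        # nm
    times: tuple[float, ...] = (12.0,)                        # h
    replicates: int = 9
    noise_sd_activity: float = 0.05
    cell_line: str = "GIN31"
    seed: int = 0

    def __post_init__(self):
        if self.beta_true < 0 or self.alpha_loc_true < 0:
            raise InputError("beta_true and alpha_loc_true must be >= 0")
        if any(t < 0 for t in self.times):
            raise InputError("times must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.noise_sd_activity < 0:
            raise InputError("noise_sd_activity must be >= 0")


@dataclass(frozen=True)
class Band:
    """One Gaussian band of a synthetic spectrum."""

    center: float      # nm
    width: float       # nm (Gaussian sigma)
    amplitude: float   # a.u.
    sign: int = 1      # +1 peak, -1 dip

    def __post_init__(self):
        if self.width <= 0:
            raise InputError("band width must be positive")
        if self.sign not in (1, -1):
            raise InputError("band sign must be +1 or -1")


@dataclass(frozen=True)
class SpectrumSimParams:
    """Baseline + signed Gaussian bands + additive noise on a regular grid.

    Default band centres sit at the positions relevant to the scattering
    analysis: the substrate peak (465 nm), the Q-band dip region (536 nm),
    the molecular band (568 nm), the bare-particle LSPR (612 nm) and the
    functionalized-particle LSPR (711 nm).
    """

    bands: tuple[Band, ...] = (
        Band(465.0, 15.0, 0.4),
        Band(568.0, 25.0, 0.6),
        Band(711.0, 30.0, 1.0),
    )
    baseline: float = 0.1
    wavelength_range: tuple[float, float] = (400.0, 800.0)
    step: float = 1.0
    noise_sd: float = 0.0
    kind: str = "scattering"
    label: str = ""
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.wavelength_range
        if hi <= lo:
            raise InputError("wavelength_range must satisfy min < max")
        if self.step <= 0:
            raise InputError("step must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


@dataclass
class MetabolicDataset:
    """Synthetic metabolic-activity table plus the generating truth."""

    table: pd.DataFrame
    params: MetabolicSimParams
    length_convention: str = "contour"

    def true_rate(self, linker_length_nm: float) -> float:
        """Noise-free charging rate beta * exp(-alpha_loc * L) for a barrier width."""
        p = self.params
        return p.beta_true * math.exp(-p.alpha_loc_true * linker_length_nm)


# ---------------------------------------------------------------------------
# cyclic voltammetry
# ---------------------------------------------------------------------------

def _potential_program(params: CVSimParams) -> tuple[np.ndarray, float]:
    """Triangular potential program and the time step."""
    span = abs(params.E_start - params.E_reverse)
    t_half = span / params.scan_rate
    n_half = params.grid.n_time // 2
    dt = t_half / n_half
    fwd = np.linspace(params.E_start, params.E_reverse, n_half + 1)
    rev = np.linspace(params.E_reverse, params.E_start, n_half + 1)[1:]
    return np.concatenate([fwd, rev]), dt


def simulate_voltammogram(params: CVSimParams) -> Voltammogram:
    """Simulate one quasi-reversible cyclic voltammogram.

    One-electron Butler-Volmer kinetics at a planar electrode with equal
    diffusion coefficients for both redox forms and semi-infinite diffusion,
    integrated with an explicit finite-difference scheme.  The bulk solution
    contains only the oxidized form, so a sweep starting positive of the
    formal potential produces the cathodic peak first and the anodic peak on
    the return branch (anodic current positive).

    Raises
    ------
    DiscretizationError
        If the grid's stability ratio ``D dt/dx^2`` is not below 0.5.
    """
    grid = params.grid
    if not 0 < grid.stability < 0.5:
        raise DiscretizationError(
            f"stability ratio D*dt/dx^2 = {grid.stability} violates the explicit-scheme "
            "bound (must satisfy 0 < ratio < 0.5)"
        )
    potential, dt = _potential_program(params)
    D = params.D_coeff
    dx = math.sqrt(D * dt / grid.stability)
    t_total = dt * (len(potential) - 1)
    x_max = grid.bulk_factor * math.sqrt(D * t_total)
    n_x = max(int(math.ceil(x_max / dx)), 10)
    lam = D * dt / dx**2  # == grid.stability by construction

    f = f_over_rt(params.temperature_K)
    a = D / dx
    c_bulk = params.conc_mol_cm3

    c_ox = np.full(n_x + 1, c_bulk)
    c_red = np.zeros(n_x + 1)
    current = np.empty_like(potential)

    for k, E in enumerate(potential):
        eta = E - params.E_formal_true
        kf = params.k0_true * math.exp(-params.alpha_ct_true * f * eta)       # reduction
        kb = params.k0_true * math.exp((1 - params.alpha_ct_true) * f * eta)  # oxidation
        # surface concentrations from flux balance:
        #   a (cO1 - cO0) = kf cO0 - kb cR0 ;  a (cR1 - cR0) = -(kf cO0 - kb cR0)
        det = (a + kf) * (a + kb) - kf * kb
        c_o0 = ((a + kb) * a * c_ox[1] + kb * a * c_red[1]) / det
        c_r0 = (kf * a * c_ox[1] + (a + kf) * a * c_red[1]) / det
        c_ox[0], c_red[0] = c_o0, c_r0
        flux = kf * c_o0 - kb * c_r0  # mol cm^-2 s^-1, reduction positive
        current[k] = -params.n_electrons * CONSTANTS.F * params.area_cm2 * flux

        c_ox[1:-1] += lam * (c_ox[2:] - 2 * c_ox[1:-1] + c_ox[:-2])
        c_red[1:-1] += lam * (c_red[2:] - 2 * c_red[1:-1] + c_red[:-2])
        c_ox[-1], c_red[-1] = c_bulk, 0.0

    if params.noise_sd_current > 0:
        rng = np.random.default_rng(params.seed)
        current = current + rng.normal(0.0, params.noise_sd_current, size=current.shape)

    return Voltammogram(
        potential=potential,
        current=current,
        scan_rate=params.scan_rate,
        label=f"sim k0={params.k0_true:g} v={params.scan_rate:g}",
        temperature_K=params.temperature_K,
    )


def simulate_scan_rate_study(params: CVSimParams, rates) -> ScanRateStudy:
    """One voltammogram per scan rate with shared true parameters.

    Rates must be non-empty, positive and distinct; the study records them in
    ascending order.  A single-rate study is valid but flagged as
    insufficient for the peak-shift regression
    (:attr:`ScanRateStudy.sufficient_for_regression`).
    """
    rates = list(rates)
    if not rates:
        raise InputError("rates must be non-empty")
    if any(r <= 0 for r in rates):
        raise InputError("all scan rates must be positive")
    if len(set(rates)) != len(rates):
        raise InputError("scan rates must be distinct")
    vgrams = [
        simulate_voltammogram(replace(params, scan_rate=float(r), seed=params.seed + i))
        for i, r in enumerate(sorted(rates))
    ]
    return ScanRateStudy(voltammograms=vgrams, shared_label=f"sim k0={params.k0_true:g}")


# ---------------------------------------------------------------------------
# metabolic activity
# ---------------------------------------------------------------------------

def simulate_metabolic_dataset(
    params: MetabolicSimParams, length_convention: str = "contour"
) -> MetabolicDataset:
    """Draw a control-normalised activity table from the survival model.

    One row per (diameter x linker mass x time x replicate).  The noiseless
    activity is ``M = exp(-beta exp(-alpha_loc L) t)`` with L derived from
    the linker mass; multiplicative Gaussian noise of s.d.
    ``noise_sd_activity`` is applied and the result clipped to (0, 1.5] —
    values slightly above 1 emulate wells outperforming the untreated
    control, which real normalised assays do produce.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for diam in params.diameters:
        for mass in params.linker_masses:
            L = linker_length_from_mw(mass, convention=length_convention)
            rate = params.beta_true * math.exp(-params.alpha_loc_true * L)
            for t in params.times:
                clean = math.exp(-rate * t)
                for rep in range(1, params.replicates + 1):
                    m = clean
                    if params.noise_sd_activity > 0:
                        m = clean * (1.0 + rng.normal(0.0, params.noise_sd_activity))
                    m = float(np.clip(m, 1e-9, 1.5))
                    rows.append(
                        {
                            "cell_line": params.cell_line,
                            "diameter_nm": diam,
                            "linker_kda": mass,
                            "linker_length_nm": L,
                            "time_h": t,
                            "activity_fraction": m,
                            "replicate": rep,
                        }
                    )
    return MetabolicDataset(
        table=pd.DataFrame(rows), params=params, length_convention=length_convention
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def simulate_spectrum(params: SpectrumSimParams) -> Spectrum:
    """Baseline + signed Gaussian bands + seeded additive noise.

    A band centred outside the wavelength range is still rendered (its tail
    may enter the grid) but a warning is recorded.
    """
    lo, hi = params.wavelength_range
    wl = np.arange(lo, hi + params.step / 2, params.step)
    intensity = np.full_like(wl, params.baseline, dtype=float)
    for band in params.bands:
        if not lo <= band.center <= hi:
            warnings.warn(
                f"band centre {band.center} nm lies outside the range {params.wavelength_range}; "
                "rendered truncated",
                stacklevel=2,
            )
        intensity += band.sign * band.amplitude * np.exp(
            -0.5 * ((wl - band.center) / band.width) ** 2
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=wl.shape)
    return Spectrum(wavelength=wl, intensity=intensity, kind=params.kind, label=params.label)
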