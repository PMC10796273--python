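"""Cyclic-voltammetry peak analysis and heterogeneous electron-transfer kinetics.

The analysis chain is the classical peak-separation route to the standard
heterogeneous rate constant k0 of a surface redox couple:

1. locate the anodic/cathodic peak pair of each voltammogram and form the
   peak separation ``delta_Ep`` and midpoint (formal) potential;
2. regress the peak potential (relative to the formal potential) on
   log10(scan rate) to estimate the Butler-Volmer transfer coefficient
   ``alpha_ct`` from the slope ``-2.3 R T / (alpha n F)``;
3. convert each peak separation into Nicholson's dimensionless kinetic
   parameter psi with the closed-form working curve
   ``psi = 2.18 (alpha/pi)^0.5 exp[-(alpha^2 F / R T) n delta_Ep]``;
4. invert ``psi = k0 [pi D n v F / (R T)]^(-1/2)`` for k0 at each scan rate.

The closed-form psi(delta_Ep) expression is an irreversible-region
approximation: it diverges from the exact working curve as the couple
approaches reversibility, which is why peak pairs with ``delta_Ep < 61/n mV``
are refused for k0 extraction (see :func:`analyze_study`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, ROOM_TEMPERATURE_K, f_over_rt
from .errors import AnalysisError, ConfigurationError, InputError, NoPeakError

__all__ = [
    "Voltammogram",
    "ScanRateStudy",
    "PeakPair",
    "TransferCoefficientFit",
    "KineticsResult",
    "detect_redox_peaks",
    "transfer_coefficient_from_points",
    "estimate_transfer_coefficient",
    "compute_psi",
    "compute_k0",
    "analyze_study",
]

#: Peak separation (V) below which the psi working form is refused (per electron).
NEAR_REVERSIBLE_DELTA_EP = 0.061

#: Peak separations above this (V) are almost certainly mV passed as V.
UNIT_SANITY_DELTA_EP = 1.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Voltammogram:
    """A single potential sweep with exactly one reversal.

    Parameters
    ----------
    potential : array-like
        Applied potential program (V), piecewise monotone with one reversal.
    current : array-like
        Measured current (A), same length; anodic current positive.
    scan_rate : float
        Sweep rate (V s^-1), > 0.
    label : str
        Free-text identifier.
    temperature_K : float
        Measurement temperature, default 298.15 K.
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    label: str = ""
    temperature_K: float = ROOM_TEMPERATURE_K

    def __post_init__(self):
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.ndim != 1 or self.potential.shape != self.current.shape:
            raise InputError("potential and current must be 1-D arrays of equal length")
        if self.potential.size < 50:
            raise InputError("voltammogram needs at least 50 samples")
        if self.scan_rate <= 0:
            raise InputError("scan_rate must be positive")
        if self.n_reversals != 1:
            raise InputError(
                f"potential program must have exactly one reversal, found {self.n_reversals}"
            )

    @property
    def n_reversals(self) -> int:
        d = np.sign(np.diff(self.potential))
        d = d[d != 0]
        return int(np.sum(d[1:] != d[:-1]))

    @property
    def reversal_index(self) -> int:
        """Index of the turning point of the potential program."""
        d = np.sign(np.diff(self.potential))
        d_nz = d[d != 0]
        first = d_nz[0]
        # first index where the sweep direction flips
        flip = np.nonzero((d != 0) & (d != first))[0]
        return int(flip[0])


@dataclass
class ScanRateStudy:
    """A set of voltammograms of one couple at distinct scan rates."""

    voltammograms: list[Voltammogram]
    shared_label: str = ""

    def __post_init__(self):
        rates = [v.scan_rate for v in self.voltammograms]
        if len(set(rates)) != len(rates):
            raise InputError("scan rates must be distinct")
        self.voltammograms = sorted(self.voltammograms, key=lambda v: v.scan_rate)

    @property
    def scan_rates(self) -> list[float]:
        return [v.scan_rate for v in self.voltammograms]

    @property
    def sufficient_for_regression(self) -> bool:
        """At least three distinct rates are needed for the peak-shift slope."""
        return len(self.voltammograms) >= 3


@dataclass(frozen=True)
class PeakPair:
    """Anodic/cathodic peak positions of one voltammogram."""

    E_pa: float
    E_pc: float
    i_pa: float
    i_pc: float

    def __post_init__(self):
        if self.delta_Ep <= 0:
            raise InputError("anodic peak must lie positive of the cathodic peak")

    @property
    def delta_Ep(self) -> float:
        return self.E_pa - self.E_pc

    @property
    def E_formal(self) -> float:
        return 0.5 * (self.E_pa + self.E_pc)


@dataclass(frozen=True)
class TransferCoefficientFit:
    """Transfer coefficient from the peak-potential-vs-log(scan rate) slope."""

    alpha_ct: float
    slope: float          # V per decade of scan rate
    intercept: float      # V
    r_squared: float
    branch: str           # "anodic" | "cathodic"
    n_points: int
    warnings: tuple[str, ...] = ()


@dataclass
class KineticsResult:
    """Full output of a scan-rate kinetics analysis."""

    psi_per_rate: list[tuple[float, float, float]]   # (scan_rate, delta_Ep, psi)
    k0_per_rate: list[tuple[float, float]]           # (scan_rate, k0 cm/s)
    k0_mean: float
    k0_sd: float
    alpha_ct_used: float
    D_used: float
    n_used: int
    temperature_K: float
    warnings: list[str] = field(default_factory=list)
    alpha_fit_cathodic: TransferCoefficientFit | None = None
    alpha_fit_anodic: TransferCoefficientFit | None = None


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _refine_parabolic(x: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """Sub-sample extremum position via a parabola through three points."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(x[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = x[idx + 1] - x[idx] if idx + 1 < len(x) else x[idx] - x[idx - 1]
    x_peak = float(x[idx] + delta * step)
    y_peak = float(y1 - 0.25 * (y0 - y2) * delta)
    return x_peak, y_peak


def _branch_peak(
    potential: np.ndarray,
    current: np.ndarray,
    *,
    maximum: bool,
    smoothing_window: int,
    baseline_fraction: float,
    branch_name: str,
) -> tuple[float, float, list[str]]:
    """Baseline-correct, smooth and locate the extremum of one sweep branch."""
    notes: list[str] = []
    n = len(current)
    n_base = max(3, int(round(baseline_fraction * n)))
    # linear baseline from the leading (pre-peak) part of the branch
    coeffs = np.polyfit(potential[:n_base], current[:n_base], 1)
    corrected = current - np.polyval(coeffs, potential)
    resid_sd = float(np.std(current[:n_base] - np.polyval(coeffs, potential[:n_base])))

    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.pad(corrected, pad, mode="edge")
        smooth = np.convolve(padded, kernel, mode="valid")
    else:
        smooth = corrected

    signal = smooth if maximum else -smooth
    peak_height = float(np.max(signal))
    if not peak_height > 3.0 * resid_sd + 1e-18:
        raise NoPeakError(branch_name)

    # ties: equal-height extrema resolved toward the sweep midpoint
    tie = np.nonzero(signal == peak_height)[0]
    if len(tie) > 1:
        mid = 0.5 * (potential[0] + potential[-1])
        idx = int(tie[np.argmin(np.abs(potential[tie] - mid))])
        notes.append(f"{branch_name}: multiple equal-height extrema, tie broken toward sweep midpoint")
    else:
        idx = int(tie[0])

    e_peak, height = _refine_parabolic(potential, signal, idx)
    i_peak = height if maximum else -height
    return e_peak, i_peak, notes


def detect_redox_peaks(
    vgram: Voltammogram,
    smoothing_window: int = 5,
    baseline_fraction: float = 0.1,
) -> PeakPair:
    """Locate the anodic and cathodic peak of a two-branch voltammogram.

    The sweep is split at its reversal point; on each branch a straight
    baseline is fitted to the leading ``baseline_fraction`` of the branch and
    subtracted, the residual is box-smoothed, and the branch extremum is
    refined by parabolic interpolation.  The anodic peak is taken from the
    positive-going branch, the cathodic peak from the negative-going one.

    Raises
    ------
    NoPeakError
        If a branch has no extremum exceeding 3x the baseline residual s.d.
    """
    if smoothing_window % 2 == 0:
        raise InputError("smoothing_window must be odd")
    if smoothing_window >= vgram.potential.size / 5:
        raise InputError("smoothing_window must be smaller than a fifth of the sweep")

    rev = vgram.reversal_index
    branches = [
        (vgram.potential[: rev + 1], vgram.current[: rev + 1]),
        (vgram.potential[rev:], vgram.current[rev:]),
    ]
    anodic = cathodic = None
    notes: list[str] = []
    for pot, cur in branches:
        positive_going = pot[-1] > pot[0]
        name = "anodic" if positive_going else "cathodic"
        e, i, ns = _branch_peak(
            pot,
            cur,
            maximum=positive_going,
            smoothing_window=smoothing_window,
            baseline_fraction=baseline_fraction,
            branch_name=name,
        )
        notes.extend(ns)
        if positive_going:
            anodic = (e, i)
        else:
            cathodic = (e, i)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    assert anodic is not None and cathodic is not None
    return PeakPair(E_pa=anodic[0], E_pc=cathodic[0], i_pa=anodic[1], i_pc=cathodic[1])


# ---------------------------------------------------------------------------
# transfer coefficient (peak-shift slope)
# ---------------------------------------------------------------------------

def transfer_coefficient_from_points(
    log10_rates: np.ndarray,
    ep_minus_ef: np.ndarray,
    n_electrons: int = 1,
    temperature_K: float = ROOM_TEMPERATURE_K,
    branch: str = "cathodic",
) -> TransferCoefficientFit:
    """Transfer coefficient from (Ep - E_formal) regressed on log10(scan rate).

    The slope of the peak potential against the decadic log of scan rate is
    ``-2.3 R T / (alpha n F)``, so ``alpha = -2.3 R T / (slope n F)``.
    """
    x = np.asarray(log10_rates, dtype=float)
    y = np.asarray(ep_minus_ef, dtype=float)
    if x.size < 3:
        raise InputError("at least 3 scan rates are required for the slope fit")
    if np.ptp(x) == 0:
        raise InputError("scan rates are all equal: regression is singular")

    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    notes: list[str] = []
    expected_sign = -1.0 if branch == "cathodic" else 1.0
    if slope == 0:
        raise InputError("zero peak-shift slope: transfer coefficient undefined")
    if math.copysign(1.0, slope) != expected_sign:
        notes.append(f"slope sign unexpected for the {branch} branch; alpha taken as absolute value")

    alpha = abs(
        CONSTANTS.decade_factor * CONSTANTS.R * temperature_K
        / (slope * n_electrons * CONSTANTS.F)
    )
    if alpha > 1.5:
        notes.append(f"alpha = {alpha:.3g} clipped to 1.5 (slope too shallow for a meaningful fit)")
        alpha = 1.5
    elif alpha > 1.0:
        notes.append(f"alpha = {alpha:.3g} > 1 is physically suspect")

    return TransferCoefficientFit(
        alpha_ct=float(alpha),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        branch=branch,
        n_points=int(x.size),
        warnings=tuple(notes),
    )


def estimate_transfer_coefficient(
    study: ScanRateStudy,
    n_electrons: int = 1,
    branch: str = "cathodic",
    smoothing_window: int = 5,
    baseline_fraction: float = 0.1,
) -> TransferCoefficientFit:
    """Fit the transfer coefficient from the peak shift across a scan-rate study."""
    if branch not in ("anodic", "cathodic"):
        raise InputError("branch must be 'anodic' or 'cathodic'")
    xs, ys = [], []
    for vg in study.voltammograms:
        try:
            pair = detect_redox_peaks(vg, smoothing_window, baseline_fraction)
        except NoPeakError:
            continue
        ep = pair.E_pc if branch == "cathodic" else pair.E_pa
        xs.append(math.log10(vg.scan_rate))
        ys.append(ep - pair.E_formal)
    if len(xs) < 3:
        raise InputError(
            f"need >= 3 scan rates with detected peaks on the {branch} branch, got {len(xs)}"
        )
    temperature = study.voltammograms[0].temperature_K
    return transfer_coefficient_from_points(
        np.array(xs), np.array(ys), n_electrons, temperature, branch
    )


# ---------------------------------------------------------------------------
# psi and k0
# ---------------------------------------------------------------------------

def compute_psi(
    alpha_ct: float,
    n_electrons: int,
    delta_Ep: float,
    temperature_K: float = ROOM_TEMPERATURE_K,
) -> float:
    """Nicholson kinetic parameter psi from the peak separation (Lavagnini form).

    ``psi = 2.18 (alpha/pi)^0.5 exp[-(alpha^2 F / (R T)) n delta_Ep]`` with
    ``delta_Ep`` in volts.  Strictly decreasing in ``delta_Ep``.
    """
    if alpha_ct <= 0:
        raise InputError("alpha_ct must be positive")
    if delta_Ep < 0:
        raise InputError("delta_Ep must be >= 0: fix the peak assignment upstream")
    if delta_Ep > UNIT_SANITY_DELTA_EP:
        raise InputError(
            f"delta_Ep = {delta_Ep} V exceeds {UNIT_SANITY_DELTA_EP} V: "
            "probable unit error (was it given in mV?)"
        )
    return (
        2.18
        * math.sqrt(alpha_ct / math.pi)
        * math.exp(-(alpha_ct**2) * f_over_rt(temperature_K) * n_electrons * delta_Ep)
    )


def compute_k0(
    psi: float,
    D_coeff: float | None,
    n_electrons: int,
    scan_rate: float,
    temperature_K: float = ROOM_TEMPERATURE_K,
) -> float:
    """Standard rate constant k0 (cm s^-1) from psi at one scan rate.

    Inverts ``psi = k0 [pi D n v F/(R T)]^(-1/2)``.  The diffusion
    coefficient has no default: it must be supplied by the caller.
    """
    if D_coeff is None:
        raise ConfigurationError(
            "diffusion coefficient D_coeff is required (no default); "
            "~1e-6 cm^2/s is a typical literature magnitude for cytochrome c"
        )
    if psi <= 0 or D_coeff <= 0 or scan_rate <= 0 or n_electrons <= 0:
        raise InputError("psi, D_coeff, n_electrons and scan_rate must all be positive")
    return psi * math.sqrt(
        math.pi * D_coeff * n_electrons * scan_rate * f_over_rt(temperature_K)
    )


def analyze_study(
    study: ScanRateStudy,
    D_coeff: float | None,
    n_electrons: int = 1,
    alpha_ct: float | None = None,
    smoothing_window: int = 5,
    baseline_fraction: float = 0.1,
) -> KineticsResult:
    """Run the full peak-separation kinetics chain on a scan-rate study.

    Peaks are detected on every voltammogram; the transfer coefficient is
    fitted once on the cathodic branch (the anodic fit is also computed and
    reported).  When the Butler-Volmer symmetry factor is known independently
    it can be passed as ``alpha_ct`` and is then used for the psi working
    form instead of the fitted value.  psi and k0 are computed per scan rate
    and summarised as mean +/- s.d.; peak pairs with ``delta_Ep < 61/n mV``
    are excluded from k0 with a near-reversibility warning, since the
    closed-form psi(delta_Ep) expression is invalid there.
    """
    if D_coeff is None:
        raise ConfigurationError(
            "diffusion coefficient D_coeff is required (no default); "
            "~1e-6 cm^2/s is a typical literature magnitude for cytochrome c"
        )
    notes: list[str] = []
    pairs: list[tuple[Voltammogram, PeakPair]] = []
    for vg in study.voltammograms:
        try:
            pairs.append((vg, detect_redox_peaks(vg, smoothing_window, baseline_fraction)))
        except NoPeakError as err:
            notes.append(f"v = {vg.scan_rate} V/s: {err}")
    if len(pairs) < 3:
        raise AnalysisError(f"fewer than 3 usable peak pairs ({len(pairs)} found)")

    temperature = pairs[0][0].temperature_K
    xs = np.array([math.log10(vg.scan_rate) for vg, _ in pairs])
    fit_c = transfer_coefficient_from_points(
        xs, np.array([p.E_pc - p.E_formal for _, p in pairs]), n_electrons, temperature, "cathodic"
    )
    fit_a = transfer_coefficient_from_points(
        xs, np.array([p.E_pa - p.E_formal for _, p in pairs]), n_electrons, temperature, "anodic"
    )
    notes.extend(fit_c.warnings)

    alpha_used = alpha_ct if alpha_ct is not None else fit_c.alpha_ct
    if not 0 < alpha_used:
        raise InputError("alpha_ct must be positive")

    psi_rows: list[tuple[float, float, float]] = []
    k0_rows: list[tuple[float, float]] = []
    guard = NEAR_REVERSIBLE_DELTA_EP / n_electrons
    for vg, pair in pairs:
        if pair.delta_Ep < guard:
            notes.append(
                f"v = {vg.scan_rate} V/s: delta_Ep = {pair.delta_Ep * 1e3:.1f} mV "
                f"< {guard * 1e3:.0f} mV, near-reversible, psi working form invalid; excluded"
            )
            continue
        psi = compute_psi(alpha_used, n_electrons, pair.delta_Ep, temperature)
        k0 = compute_k0(psi, D_coeff, n_electrons, vg.scan_rate, temperature)
        psi_rows.append((vg.scan_rate, pair.delta_Ep, psi))
        k0_rows.append((vg.scan_rate, k0))

    if not k0_rows:
        raise AnalysisError(
            "every voltammogram is near-reversible (delta_Ep < 61/n mV): "
            "the psi working form cannot be applied"
        )

    k0_values = np.array([k for _, k in k0_rows])
    return KineticsResult(
        psi_per_rate=psi_rows,
        k0_per_rate=k0_rows,
        k0_mean=float(np.mean(k0_values)),
        k0_sd=float(np.std(k0_values, ddof=1)) if k0_values.size > 1 else 0.0,
        alpha_ct_used=float(alpha_used),
        D_used=float(D_coeff),
        n_used=int(n_electrons),
        temperature_K=float(temperature),
        warnings=notes,
        alpha_fit_cathodic=fit_c,
        alpha_fit_anodic=fit_a,
    )
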