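"""Forward model: first-derivative EPR spectra of a nitroxide spin probe
undergoing fast but orientationally restricted motion in a membrane.

The probe's motion within one membrane nanodomain is summarized by an
order parameter S (wobble-in-cone), a rotational correlation time tau_c,
polarity correction factors pA/pg applied to the hyperfine and g tensors,
and a residual Lorentzian broadening W. A laterally heterogeneous membrane
produces a superposition of such components, weighted by the fraction d of
probe molecules in each domain type.

Model outline per component:

1. Fast restricted motion partially averages the rigid-limit tensors to
   effective axial ones, ``A_par/A_perp`` and ``g_par/g_perp``
   (:func:`partial_average`).
2. Membrane-normal directors are isotropically distributed (powder
   average over theta, Gauss-Legendre in cos theta).
3. Each of the three 14N hyperfine lines is a Lorentzian centred at the
   resonance field for that orientation; its half-width is
   ``W + kappa * tau_c * Var[B_res]`` where the variance of the
   instantaneous resonance field is taken over the accessible cone
   (motional broadening vanishes for S = 1 and grows linearly with
   tau_c).
4. The summed absorption is baseline-corrected to vanish at the sweep
   edges, normalized to unit integral, and differentiated analytically
   (first-harmonic detection records the derivative).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from . import _kernels
from .constants import (
    DEFAULT_A_TENSOR,
    DEFAULT_CENTER_FIELD_MT,
    DEFAULT_G_TENSOR,
    DEFAULT_KAPPA,
    DEFAULT_MICROWAVE_FREQUENCY_GHZ,
    DEFAULT_MODULATION_AMPLITUDE_MT,
    DEFAULT_N_POINTS,
    DEFAULT_N_THETA,
    DEFAULT_SWEEP_WIDTH_MT,
    DEFAULT_TEMPERATURE_C,
    FIELD_PER_GHZ,
)

__all__ = [
    "ValidationError",
    "MagneticTensors",
    "DomainParams",
    "SpectrometerSettings",
    "Spectrum",
    "EffectiveTensors",
    "partial_average",
    "cone_angle_from_order",
    "resonance_field",
    "line_width",
    "simulate_component",
    "simulate_spectrum",
]


class ValidationError(ValueError):
    """Raised when model inputs violate their physical constraints."""


@dataclass(frozen=True)
class MagneticTensors:
    """Rigid-limit principal values of the nitroxide A (mT) and g tensors.

    Nitroxide geometry requires A_zz (along the N 2p-pi orbital) to be the
    largest hyperfine value by a wide margin.
    """

    A_xx: float = DEFAULT_A_TENSOR[0]
    A_yy: float = DEFAULT_A_TENSOR[1]
    A_zz: float = DEFAULT_A_TENSOR[2]
    g_xx: float = DEFAULT_G_TENSOR[0]
    g_yy: float = DEFAULT_G_TENSOR[1]
    g_zz: float = DEFAULT_G_TENSOR[2]

    def __post_init__(self) -> None:
        if not (self.A_zz > self.A_xx > 0 and self.A_zz > self.A_yy > 0):
            raise ValidationError(
                "nitroxide hyperfine tensor requires A_zz > A_xx > 0 and "
                f"A_zz > A_yy > 0, got ({self.A_xx}, {self.A_yy}, {self.A_zz})"
            )
        for g in (self.g_xx, self.g_yy, self.g_zz):
            if not (2.000 <= g <= 2.012):
                raise ValidationError(f"g value {g} outside [2.000, 2.012]")

    @property
    def a_iso(self) -> float:
        """Isotropic hyperfine coupling (A_xx + A_yy + A_zz)/3 [mT]."""
        return (self.A_xx + self.A_yy + self.A_zz) / 3.0

    @property
    def delta_A(self) -> float:
        """Axial hyperfine anisotropy A_zz - (A_xx + A_yy)/2 [mT]."""
        return self.A_zz - 0.5 * (self.A_xx + self.A_yy)

    @property
    def g_iso(self) -> float:
        return (self.g_xx + self.g_yy + self.g_zz) / 3.0

    @property
    def delta_g(self) -> float:
        return self.g_zz - 0.5 * (self.g_xx + self.g_yy)


@dataclass
class DomainParams:
    """Spectral parameters of one membrane nanodomain component.

    S       : order parameter, 1 = perfectly ordered, 0 = isotropic
    tau_c   : rotational correlation time [ns]
    pA, pg  : polarity correction factors multiplying A and g
    W       : residual Lorentzian half-width [mT]
    d       : fraction of probe molecules in this domain type
    """

    S: float
    tau_c: float
    pA: float = 1.0
    pg: float = 1.0
    W: float = 0.1
    d: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.S <= 1.0:
            raise ValidationError(f"order parameter S={self.S} outside [0, 1]")
        if self.tau_c <= 0:
            raise ValidationError(f"tau_c={self.tau_c} must be > 0")
        if self.W < 0:
            raise ValidationError(f"W={self.W} must be >= 0")
        if not 0.0 <= self.d <= 1.0:
            raise ValidationError(f"proportion d={self.d} outside [0, 1]")
        if self.pA <= 0 or self.pg <= 0:
            raise ValidationError("polarity factors must be positive")


@dataclass(frozen=True)
class SpectrometerSettings:
    """Acquisition settings; temperature and modulation are metadata by
    default (the analytic derivative is rendered; see ``pseudo_modulation``)."""

    microwave_frequency: float = DEFAULT_MICROWAVE_FREQUENCY_GHZ  # GHz
    center_field: float = DEFAULT_CENTER_FIELD_MT  # mT
    sweep_width: float = DEFAULT_SWEEP_WIDTH_MT  # mT
    n_points: int = DEFAULT_N_POINTS
    modulation_amplitude: float = DEFAULT_MODULATION_AMPLITUDE_MT  # mT
    temperature: float = DEFAULT_TEMPERATURE_C  # Celsius

    def __post_init__(self) -> None:
        if self.n_points < 128:
            raise ValidationError(f"n_points={self.n_points} < 128")
        if self.sweep_width <= 0:
            raise ValidationError("sweep_width must be > 0")
        if self.microwave_frequency <= 0:
            raise ValidationError("microwave_frequency must be > 0")

    def field_grid(self) -> np.ndarray:
        """Uniform ascending field grid [mT]."""
        half = 0.5 * self.sweep_width
        return np.linspace(self.center_field - half, self.center_field + half,
                           self.n_points)


@dataclass
class Spectrum:
    """A first-derivative EPR spectrum on a uniform ascending field grid."""

    field: np.ndarray  # mT
    intensity: np.ndarray  # arbitrary units
    settings: SpectrometerSettings = dc_field(default_factory=SpectrometerSettings)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.shape != self.intensity.shape or self.field.ndim != 1:
            raise ValidationError("field and intensity must be equal-length 1-D")
        if self.field.size < 2 or not np.all(np.diff(self.field) > 0):
            raise ValidationError("field grid must be strictly increasing")

    def copy_with(self, **kw) -> "Spectrum":
        out = replace(self)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


class EffectiveTensors(NamedTuple):
    """Motionally averaged axial tensors (A in mT, g dimensionless)."""

    A_par: float
    A_perp: float
    g_par: float
    g_perp: float


def partial_average(tensors: MagneticTensors, S: float,
                    pA: float = 1.0, pg: float = 1.0) -> EffectiveTensors:
    """Partially average the rigid tensors under fast restricted motion.

    A_par = pA (a_iso + 2/3 S dA), A_perp = pA (a_iso - 1/3 S dA) with
    dA = A_zz - (A_xx + A_yy)/2, and analogously for g with pg. The trace
    is conserved: (A_par + 2 A_perp)/3 = pA a_iso for every S.
    """
    if not 0.0 <= S <= 1.0:
        raise ValidationError(f"order parameter S={S} outside [0, 1]")
    if pA <= 0 or pg <= 0:
        raise ValidationError("polarity factors must be positive")
    a_par = pA * (tensors.a_iso + (2.0 / 3.0) * S * tensors.delta_A)
    a_perp = pA * (tensors.a_iso - (1.0 / 3.0) * S * tensors.delta_A)
    g_par = pg * (tensors.g_iso + (2.0 / 3.0) * S * tensors.delta_g)
    g_perp = pg * (tensors.g_iso - (1.0 / 3.0) * S * tensors.delta_g)
    return EffectiveTensors(a_par, a_perp, g_par, g_perp)


def cone_angle_from_order(S: float, degrees: bool = True) -> float:
    """Cone half-angle theta0 of the wobble-in-cone model.

    Solves S = cos(theta0) (1 + cos(theta0)) / 2; monotone decreasing in S
    (S=1 -> 0 deg, S=0 -> 90 deg).
    """
    if not 0.0 <= S <= 1.0:
        raise ValidationError(f"order parameter S={S} outside [0, 1]")
    c = 0.5 * (np.sqrt(1.0 + 8.0 * S) - 1.0)
    theta0 = float(np.arccos(np.clip(c, 0.0, 1.0)))
    return float(np.degrees(theta0)) if degrees else theta0


def resonance_field(eff: EffectiveTensors, theta: float, m_I: int,
                    frequency: float = DEFAULT_MICROWAVE_FREQUENCY_GHZ) -> float:
    """Resonance field [mT] of hyperfine line m_I at director angle theta [rad].

    B = h nu / (g_eff mu_B) - m_I A_eff with the usual axial angular
    dependences g_eff^2 = g_par^2 cos^2 + g_perp^2 sin^2 (same for A).
    """
    if m_I not in (-1, 0, 1):
        raise ValidationError(f"m_I must be -1, 0 or +1, got {m_I}")
    c2 = np.cos(theta) ** 2
    s2 = 1.0 - c2
    g_eff = np.sqrt(eff.g_par**2 * c2 + eff.g_perp**2 * s2)
    a_eff = np.sqrt(eff.A_par**2 * c2 + eff.A_perp**2 * s2)
    return float(FIELD_PER_GHZ * frequency / g_eff - m_I * a_eff)


# cone quadrature used by the linewidth variance (fixed; part of the model
# definition, not an accuracy knob exposed to fitting)
_CONE_X, _CONE_W = leggauss(12)
_CONE_CA = np.cos(np.pi * (np.arange(16) + 0.5) / 16.0)


def _rigid_tensors(tensors: MagneticTensors, pA: float, pg: float):
    a_par0 = pA * tensors.A_zz
    a_perp0 = pA * 0.5 * (tensors.A_xx + tensors.A_yy)
    g_par0 = pg * tensors.g_zz
    g_perp0 = pg * 0.5 * (tensors.g_xx + tensors.g_yy)
    return a_par0, a_perp0, g_par0, g_perp0


def line_width(domain: DomainParams, tensors: MagneticTensors, theta: float,
               m_I: int, kappa: float = DEFAULT_KAPPA,
               frequency: float = DEFAULT_MICROWAVE_FREQUENCY_GHZ) -> float:
    """Lorentzian half-width [mT]: W plus the motional-narrowing term.

    The motional term is kappa * tau_c * Var[B_res] where the variance of
    the instantaneous (rigid-tensor) resonance field is taken over the
    wobble cone implied by S. It vanishes at S = 1 and is linear in tau_c.
    """
    if m_I not in (-1, 0, 1):
        raise ValidationError(f"m_I must be -1, 0 or +1, got {m_I}")
    cos_t0 = np.cos(cone_angle_from_order(domain.S, degrees=False))
    a_par0, a_perp0, g_par0, g_perp0 = _rigid_tensors(tensors, domain.pA, domain.pg)
    if cos_t0 >= 1.0 - 1e-12:
        return float(domain.W)
    u = float(np.cos(theta))
    su = float(np.sqrt(max(1.0 - u * u, 0.0)))
    var = _kernels.cone_variance(u, su, m_I, a_par0, a_perp0, g_par0, g_perp0,
                                 cos_t0, frequency, _CONE_X, _CONE_W, _CONE_CA)
    return float(domain.W + kappa * domain.tau_c * var)


@lru_cache(maxsize=8)
def _powder_nodes(n_theta: int):
    # integrate f(theta) sin(theta) dtheta over [0, pi/2] == integral over
    # u = cos(theta) in [0, 1]
    x, w = leggauss(n_theta)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    return u, wu


def _kernel_args(domain: DomainParams, tensors: MagneticTensors,
                 settings: SpectrometerSettings, n_theta: int, kappa: float):
    eff = partial_average(tensors, domain.S, domain.pA, domain.pg)
    rigid = _rigid_tensors(tensors, domain.pA, domain.pg)
    cos_t0 = float(np.cos(cone_angle_from_order(domain.S, degrees=False)))
    u, wu = _powder_nodes(n_theta)
    return (u, wu, eff.A_par, eff.A_perp, eff.g_par, eff.g_perp, *rigid,
            cos_t0, domain.tau_c, domain.W, kappa,
            settings.microwave_frequency, _CONE_X, _CONE_W, _CONE_CA,
            np.empty((n_theta, 3)), np.empty((n_theta, 3)))


def _normalization(field: np.ndarray, area: float, a_left: float,
                   a_right: float):
    """Unit-area normalization of the edge-baseline-corrected absorption."""
    span = field[-1] - field[0]
    slope = (a_right - a_left) / span
    area_c = area - 0.5 * (a_left + a_right) * span
    if area_c <= 0:
        raise ValidationError("degenerate spectrum: non-positive absorption area")
    return slope, area_c


def _pseudo_modulate(field: np.ndarray, absorption: np.ndarray,
                     amplitude: float, n_phi: int = 32) -> np.ndarray:
    """First-harmonic field-modulation signal from the absorption spectrum.

    Phase-sensitive detection of A(B + (a/2) cos phi); reduces to the
    analytic derivative (times a/2) as a -> 0.
    """
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    out = np.zeros_like(absorption)
    for p in phi:
        shifted = np.interp(field + 0.5 * amplitude * np.cos(p), field,
                            absorption, left=0.0, right=0.0)
        out += shifted * np.cos(p)
    return out * (2.0 / n_phi)


def simulate_component(domain: DomainParams, tensors: MagneticTensors | None = None,
                       settings: SpectrometerSettings | None = None,
                       n_theta: int = DEFAULT_N_THETA,
                       kappa: float = DEFAULT_KAPPA,
                       derivative: bool = True,
                       pseudo_modulation: bool = False) -> Spectrum:
    """Powder-averaged spectrum of a single domain component.

    Returns the first-derivative lineshape by default, or the underlying
    unit-area absorption with ``derivative=False``. ``pseudo_modulation``
    replaces the analytic derivative with a numerically field-modulated
    signal at the configured modulation amplitude.
    """
    tensors = tensors or MagneticTensors()
    settings = settings or SpectrometerSettings()
    field = settings.field_grid()
    args = _kernel_args(domain, tensors, settings, n_theta, kappa)
    out = np.empty_like(field)
    if derivative and not pseudo_modulation:
        area, a_l, a_r = _kernels.component_derivative(field, *args, out)
        slope, area_c = _normalization(field, area, a_l, a_r)
        intensity = (out - slope) / area_c
    else:
        _kernels.component_absorption(field, *args, out)
        area = float(np.trapezoid(out, field))
        slope, area_c = _normalization(field, area, out[0], out[-1])
        baseline = out[0] + slope * (field - field[0])
        absorption = (out - baseline) / area_c
        if derivative:
            intensity = _pseudo_modulate(field, absorption,
                                         settings.modulation_amplitude)
        else:
            intensity = absorption
    return Spectrum(field=field, intensity=intensity, settings=settings,
                    provenance={"kind": "simulated_component",
                                "S": domain.S, "tau_c": domain.tau_c})


def simulate_spectrum(domains: Sequence[DomainParams],
                      tensors: MagneticTensors | None = None,
                      settings: SpectrometerSettings | None = None,
                      n_theta: int = DEFAULT_N_THETA,
                      kappa: float = DEFAULT_KAPPA,
                      derivative: bool = True,
                      pseudo_modulation: bool = False) -> Spectrum:
    """Superposition spectrum: pointwise sum of d-weighted components.

    The proportions must satisfy sum(d) == 1 (within 1e-9).
    """
    if not domains:
        raise ValidationError("at least one domain component is required")
    total_d = sum(dom.d for dom in domains)
    if abs(total_d - 1.0) > 1e-9:
        raise ValidationError(f"domain proportions must sum to 1, got {total_d}")
    tensors = tensors or MagneticTensors()
    settings = settings or SpectrometerSettings()
    field = settings.field_grid()
    intensity = np.zeros_like(field)
    for dom in domains:
        comp = simulate_component(dom, tensors, settings, n_theta=n_theta,
                                  kappa=kappa, derivative=derivative,
                                  pseudo_modulation=pseudo_modulation)
        intensity += dom.d * comp.intensity
    return Spectrum(field=field, intensity=intensity, settings=settings,
                    provenance={"kind": "simulated_spectrum",
                                "n_domains": len(domains)})
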