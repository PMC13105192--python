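"""Generalized-Lorentzian spectral profiles and their Hida-Matern time kernels.

Each cortical generator carries up to two independent stationary Gaussian
processes: a broadband aperiodic ("xi") component centered at 0 Hz and a
rhythmic alpha component centered at a peak frequency inside the alpha band.
Both have power spectral densities of generalized-Lorentzian form

    psi(omega | A, B, E, F) = A / (1 + B (omega - F)^2)^E

with amplitude ``A`` (linear power-density units), bandwidth ``B`` (s^2),
spectral exponent ``E`` (> 1/2) and center frequency ``F`` (Hz).  The
time-domain counterpart is the cosine-modulated Matern covariance

    cos(2 pi F tau) * M(tau),
    M(tau) = (2 sqrt(pi) A) / (sqrt(B) Gamma(E))
             * (pi |tau| / sqrt(B))^(E - 1/2)
             * K_{E-1/2}(2 pi |tau| / sqrt(B)),

an exact Fourier pair of psi under the convention
``S(omega) = int M(tau) exp(-2 pi i omega tau) d tau`` with omega in Hz.
A real-valued rhythmic process requires an even spectrum, hence the alpha
PSD is symmetrized over +/-F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "LorentzParams",
    "ComponentField",
    "FrequencyGrid",
    "default_grid",
    "psd_lorentz",
    "psd_xi",
    "psd_alpha",
    "matern_autocov",
    "hm_autocov",
]

#: hard ceiling on the spectral exponent; larger values give numerically
#: degenerate, ultra-smooth kernels without changing the spectra visibly
E_MAX = 10.0


@dataclass(frozen=True)
class LorentzParams:
    """Parameters of one generalized-Lorentzian spectral profile.

    A : amplitude (linear power density, >= 0)
    B : bandwidth parameter (s^2, >= 0; 0 gives a flat spectrum)
    E : spectral exponent (> 1/2 whenever A > 0)
    F : center frequency (Hz, >= 0)
    """

    A: float
    B: float
    E: float
    F: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.A, self.B, self.E, self.F)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Lorentzian parameters {vals}")
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")
        if self.B < 0:
            raise ValueError(f"bandwidth B must be >= 0, got {self.B}")
        if self.F < 0:
            raise ValueError(f"center frequency F must be >= 0, got {self.F}")
        if self.A > 0 and not (0.5 < self.E <= E_MAX):
            raise ValueError(
                f"spectral exponent E must lie in (0.5, {E_MAX}], got {self.E}"
            )


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing evaluation frequencies in Hz."""

    omega: np.ndarray
    nonuniform: bool = False

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", omega)
        if omega.ndim != 1 or omega.size < 2:
            raise ValueError("frequency grid must be a 1-d array with >= 2 points")
        if not np.all(np.isfinite(omega)) or np.any(omega <= 0):
            raise ValueError("frequencies must be finite and > 0")
        d = np.diff(omega)
        if np.any(d <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not self.nonuniform and not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("non-uniform grid must be flagged nonuniform=True")

    @property
    def n_omega(self) -> int:
        return self.omega.size

    @property
    def resolution(self) -> float:
        return float(np.diff(self.omega).mean())


def default_grid() -> FrequencyGrid:
    """Default 47-bin grid, 1.17-19.11 Hz in 0.39 Hz steps (quantitative-EEG
    cross-spectrum convention for 19-channel recordings)."""
    return FrequencyGrid(0.39 * np.arange(3, 50))


@dataclass
class ComponentField:
    """Per-generator spectral parameters over ``n_v`` cortical vertices.

    The xi component is centered at 0 Hz (no F array); the alpha component
    carries its own peak frequency ``F_alpha``.  A generator's component is
    active iff its group of parameters is not identically zero; group-lasso
    estimation drives whole groups to exact zeros, so inactive components
    contribute exactly no power.
    """

    A_xi: np.ndarray
    B_xi: np.ndarray
    E_xi: np.ndarray
    A_alpha: np.ndarray
    B_alpha: np.ndarray
    E_alpha: np.ndarray
    F_alpha: np.ndarray
    alpha_band: tuple[float, float] = (7.0, 13.0)

    def __post_init__(self) -> None:
        arrays = [
            np.atleast_1d(np.asarray(a, dtype=float))
            for a in (
                self.A_xi, self.B_xi, self.E_xi,
                self.A_alpha, self.B_alpha, self.E_alpha, self.F_alpha,
            )
        ]
        n = arrays[0].size
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("all component-field arrays must share one length")
        (self.A_xi, self.B_xi, self.E_xi,
         self.A_alpha, self.B_alpha, self.E_alpha, self.F_alpha) = arrays
        self.validate()

    @property
    def n_v(self) -> int:
        return self.A_xi.size

    @property
    def active_xi(self) -> np.ndarray:
        """Boolean mask of generators with an active aperiodic component."""
        return self.A_xi > 0

    @property
    def active_alpha(self) -> np.ndarray:
        return self.A_alpha > 0

    def validate(self) -> None:
        for name, A, B, E in (
            ("xi", self.A_xi, self.B_xi, self.E_xi),
            ("alpha", self.A_alpha, self.B_alpha, self.E_alpha),
        ):
            if np.any(A < 0) or np.any(B < 0):
                raise ValueError(f"negative A or B in {name} component")
            act = A > 0
            if np.any(act & ~((E > 0.5) & (E <= E_MAX))):
                raise ValueError(
                    f"active {name} generators need E in (0.5, {E_MAX}]"
                )
        lo, hi = self.alpha_band
        act = self.active_alpha
        if np.any(act & ((self.F_alpha < lo) | (self.F_alpha > hi))):
            raise ValueError(
                f"active alpha peak frequencies must lie in [{lo}, {hi}] Hz"
            )

    @classmethod
    def zeros(cls, n_v: int, **kw) -> "ComponentField":
        z = np.zeros(n_v)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), **kw)


# ---------------------------------------------------------------------------
# spectral profiles
# ---------------------------------------------------------------------------

def psd_lorentz(omega, p: LorentzParams):
    """Generalized Lorentzian psi(omega | A, B, E, F).

    Peaks at ``omega = F`` with value ``A``; ``B = 0`` degenerates to the
    flat spectrum ``A``.  Vectorized over ``omega``.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega must be finite")
    if p.A == 0:
        return np.zeros_like(omega)
    return p.A / (1.0 + p.B * (omega - p.F) ** 2) ** p.E


def psd_xi(omega, field: ComponentField, i: int):
    """Aperiodic PSD of generator ``i``: psi with F = 0 (zero if inactive)."""
    _check_index(i, field.n_v)
    if field.A_xi[i] == 0:
        return np.zeros_like(np.asarray(omega, dtype=float))
    p = LorentzParams(field.A_xi[i], field.B_xi[i], field.E_xi[i], 0.0)
    return psd_lorentz(omega, p)


def psd_alpha(omega, field: ComponentField, i: int):
    """Rhythmic PSD of generator ``i``: symmetrized Lorentzian peak.

    ``0.5 psi(omega | A,B,E,F) + 0.5 psi(omega | A,B,E,-F)`` — an even
    function of omega, as required for a real-valued process.
    """
    _check_index(i, field.n_v)
    omega = np.asarray(omega, dtype=float)
    A, B, E, F = (field.A_alpha[i], field.B_alpha[i],
                  field.E_alpha[i], field.F_alpha[i])
    if A == 0:
        return np.zeros_like(omega)
    return 0.5 * A * (
        (1.0 + B * (omega - F) ** 2) ** -E + (1.0 + B * (omega + F) ** 2) ** -E
    )


def xi_psd_matrix(grid_omega, field: ComponentField) -> np.ndarray:
    """(n_omega, n_v) aperiodic PSD table; inactive generators give zeros."""
    omega = np.asarray(grid_omega, dtype=float)[:, None]
    out = np.zeros((omega.size, field.n_v))
    act = field.active_xi
    if np.any(act):
        out[:, act] = field.A_xi[act] / (
            1.0 + field.B_xi[act] * omega**2
        ) ** field.E_xi[act]
    return out


def alpha_psd_matrix(grid_omega, field: ComponentField) -> np.ndarray:
    """(n_omega, n_v) symmetrized alpha PSD table."""
    omega = np.asarray(grid_omega, dtype=float)[:, None]
    out = np.zeros((omega.size, field.n_v))
    act = field.active_alpha
    if np.any(act):
        A, B, E, F = (field.A_alpha[act], field.B_alpha[act],
                      field.E_alpha[act], field.F_alpha[act])
        out[:, act] = 0.5 * A * (
            (1.0 + B * (omega - F) ** 2) ** -E + (1.0 + B * (omega + F) ** 2) ** -E
        )
    return out


# ---------------------------------------------------------------------------
# time-domain kernels
# ---------------------------------------------------------------------------

def matern_autocov(tau, A: float, B: float, E: float):
    """Matern autocovariance envelope M(tau).

    Exact inverse Fourier transform of ``psi(omega | A, B, E, 0)``.  The
    tau = 0 value is the small-argument Bessel limit
    ``sqrt(pi) A Gamma(E - 1/2) / (sqrt(B) Gamma(E))`` (never K_nu at 0),
    which also equals the total power ``int psi d omega``.
    """
    if B <= 0:
        raise ValueError("time-domain Matern kernel requires B > 0")
    if A < 0 or not (0.5 < E <= E_MAX):
        raise ValueError("require A >= 0 and E in (0.5, E_MAX]")
    tau = np.asarray(tau, dtype=float)
    at = np.abs(tau)
    nu = E - 0.5
    sqB = np.sqrt(B)
    m0 = np.sqrt(np.pi) * A * special.gamma(nu) / (sqB * special.gamma(E))
    out = np.full(at.shape, m0, dtype=float)
    # below x_small the kernel equals M(0) to ~1e-12 relative (correction
    # O(x^2) for nu >= 1, O(x^(2 nu)) for nu < 1) and the Bessel product
    # over/underflows; above it the scaled Bessel kve is safe, with exp(-x)
    # underflow covering the far tail (true value ~ 0)
    x_small = min(1e-6, 10.0 ** (-6.0 / nu)) if nu < 1 else 1e-6
    x_all = 2.0 * np.pi * at / sqB
    pos = x_all > x_small
    if np.any(pos):
        x = x_all[pos]
        val = (
            2.0 * np.sqrt(np.pi) * A / (sqB * special.gamma(E))
            * (x / 2.0) ** nu
            * special.kve(nu, x) * np.exp(-x)
        )
        out[pos] = np.where(np.isfinite(val), val, 0.0)
    return out if out.shape else float(out)


def hm_autocov(tau, p: LorentzParams):
    """Hida-Matern autocovariance: ``cos(2 pi F tau) * M(tau)``.

    Its spectrum is the symmetrized Lorentzian
    ``0.5 psi(omega - F) + 0.5 psi(omega + F)``; for F = 0 it reduces to the
    plain Matern kernel.
    """
    tau = np.asarray(tau, dtype=float)
    return np.cos(2.0 * np.pi * p.F * tau) * matern_autocov(tau, p.A, p.B, p.E)


def _check_index(i: int, n: int) -> None:
    if not 0 <= i < n:
        raise IndexError(f"generator index {i} out of range [0, {n})")
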