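"""Delayed-connectome MVAR operators and model cross-spectra.

The cortical network is a continuous-time MVAR process whose interaction
kernel is a Hadamard decomposition ``A_tau = C (.) delta(tau - D)``: each
directed link carries a real coupling strength ``C_ik`` and a pure
conduction delay ``D_ik`` (seconds).  In the frequency domain the delay is
the exact phase factor

    A_omega = C (.) exp(-2 pi i omega D),

and the Green function ``G_omega = (I - A_omega)^{-1}`` redistributes the
locally generated spectral power across the network.  With per-vertex
component PSDs ``s_k(omega)`` (xi or alpha), the component transfer function
is ``H_omega = G_omega diag(sqrt(s))`` and the component source
cross-spectrum is ``S_omega = H_omega H_omega^dagger``.  Sensor spectra
follow from the lead field: ``Sigma_omega = K S_omega K^dagger +
sigma_n^2 I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .spectral import ComponentField, FrequencyGrid, alpha_psd_matrix, xi_psd_matrix

__all__ = [
    "StructuralPrior",
    "StructuralWeights",
    "LeadField",
    "SpectrumSet",
    "build_ar_operator",
    "check_stability",
    "green_function",
    "transfer_function",
    "source_cross_spectrum",
    "source_psd_diag",
    "sensor_cross_spectrum",
    "model_sensor_spectra",
]

STABILITY_MARGIN = 0.02
DELAY_BAND = (1e-3, 100e-3)  # physiological cortico-cortical delays, seconds


@dataclass
class StructuralPrior:
    """Population-level connectome strength and conduction-delay priors.

    ``Cbar`` is nonnegative with zero diagonal; ``Dbar`` holds delays in
    seconds and must be positive wherever ``Cbar`` is nonzero.
    """

    Cbar: np.ndarray
    Dbar: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.Cbar, dtype=float)
        D = np.asarray(self.Dbar, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape != D.shape:
            raise ValueError("Cbar and Dbar must be square matrices of one size")
        if not (np.all(np.isfinite(C)) and np.all(np.isfinite(D))):
            raise ValueError("structural matrices must be finite")
        if np.any(C < 0) or np.any(D < 0):
            raise ValueError("strengths and delays must be nonnegative")
        if np.any(np.diag(C) != 0) or np.any(np.diag(D) != 0):
            raise ValueError("structural matrices must have zero diagonals")
        if np.any((C > 0) & (D <= 0)):
            raise ValueError("every connected link needs a positive delay")
        self.Cbar, self.Dbar = C, D

    @property
    def n_v(self) -> int:
        return self.Cbar.shape[0]

    def normalized(self) -> "StructuralPrior":
        """Rescale Cbar to unit spectral radius so the coupling weight w_C is
        a global gain; zero connectomes pass through unchanged."""
        rho = spectral_radius(self.Cbar)
        if rho == 0:
            return self
        return StructuralPrior(self.Cbar / rho, self.Dbar)


@dataclass(frozen=True)
class StructuralWeights:
    """Global scales for the structural priors: C = w_C Cbar, D = w_D Dbar."""

    w_C: float
    w_D: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_C) and np.isfinite(self.w_D)):
            raise ValueError("weights must be finite")
        if self.w_C < 0 or self.w_D <= 0:
            raise ValueError("require w_C >= 0 and w_D > 0")

    def apply(self, prior: StructuralPrior) -> tuple[np.ndarray, np.ndarray]:
        return self.w_C * prior.Cbar, self.w_D * prior.Dbar


@dataclass
class LeadField:
    """Sensor gain matrix K (n_c x n_v) plus sensor noise variance."""

    K: np.ndarray
    sigma_noise2: float = 0.0

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2:
            raise ValueError("lead field must be a 2-d matrix")
        if not np.all(np.isfinite(K)):
            raise ValueError("lead field must be finite")
        if np.any(np.all(K == 0, axis=1)):
            raise ValueError("lead field has an all-zero sensor row")
        if self.sigma_noise2 < 0:
            raise ValueError("sensor noise variance must be >= 0")
        self.K = K

    @property
    def n_c(self) -> int:
        return self.K.shape[0]

    @property
    def n_v(self) -> int:
        return self.K.shape[1]

    def column_normalized(self) -> "LeadField":
        """Unit-norm columns; the amplitude gauge used by the inversion
        (source amplitudes absorb the per-column scale)."""
        norms = np.linalg.norm(self.K, axis=0)
        norms[norms == 0] = 1.0
        return LeadField(self.K / norms, self.sigma_noise2)


@dataclass
class SpectrumSet:
    """Stack of complex Hermitian cross-spectra over a frequency grid.

    ``spectra`` has shape (n_omega, n, n); ``level`` tags source vs sensor;
    ``m`` is the effective trial count of the averaged periodogram.
    """

    grid: FrequencyGrid
    spectra: np.ndarray
    level: str = "sensor"
    m: int = 1

    def __post_init__(self) -> None:
        S = np.asarray(self.spectra, dtype=complex)
        if S.ndim != 3 or S.shape[1] != S.shape[2]:
            raise ValueError("spectra must have shape (n_omega, n, n)")
        if S.shape[0] != self.grid.n_omega:
            raise ValueError("spectra stack does not match the frequency grid")
        herm = np.max(np.abs(S - S.conj().transpose(0, 2, 1)))
        scale = max(np.max(np.abs(S)), 1.0)
        if herm > 1e-6 * scale:
            raise ValueError(f"spectra not Hermitian (max asymmetry {herm:.3g})")
        self.spectra = 0.5 * (S + S.conj().transpose(0, 2, 1))
        if self.m < 1:
            raise ValueError("effective trial count m must be >= 1")

    @property
    def n(self) -> int:
        return self.spectra.shape[1]

    def check_psd(self, tol_factor: float = 1e-8) -> bool:
        for S in self.spectra:
            w = np.linalg.eigvalsh(S)
            if w.min() < -tol_factor * max(np.trace(S).real, 1e-300):
                return False
        return True


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def build_ar_operator(C: np.ndarray, D: np.ndarray, omega: float) -> np.ndarray:
    """Frequency-resolved AR coefficient matrix ``C (.) exp(-2 pi i omega D)``."""
    C = np.asarray(C, dtype=float)
    D = np.asarray(D, dtype=float)
    if C.shape != D.shape or C.ndim != 2:
        raise ValueError("C and D must be matrices of one shape")
    if np.any(np.diag(C) != 0):
        raise ValueError("AR operator requires a zero diagonal in C")
    return C * np.exp(-2j * np.pi * omega * D)


def spectral_radius(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M)))) if M.size else 0.0


def check_stability(
    C: np.ndarray,
    D: np.ndarray,
    grid: FrequencyGrid,
    margin: float = STABILITY_MARGIN,
) -> tuple[bool, float]:
    """Weak-stationarity proxy: the delayed AR operator must have spectral
    radius < 1 - margin at every grid frequency (and at omega = 0)."""
    omegas = np.concatenate([[0.0], np.asarray(grid.omega, dtype=float)])
    rho = max(spectral_radius(build_ar_operator(C, D, w)) for w in omegas)
    return rho < 1.0 - margin, rho


def green_function(A_omega: np.ndarray, cond_limit: float = 1e12) -> np.ndarray:
    """Network propagator ``(I - A_omega)^{-1}``; identity for A = 0."""
    n = A_omega.shape[0]
    M = np.eye(n) - A_omega
    if np.linalg.cond(M) > cond_limit:
        raise np.linalg.LinAlgError(
            "I - A_omega is numerically singular (network at instability)"
        )
    return np.linalg.inv(M)


def transfer_function(G_omega: np.ndarray, component_psd: np.ndarray) -> np.ndarray:
    """Component transfer function ``H = G diag(sqrt(psd))``.

    Columns of inactive generators (zero PSD) are exactly zero, so an
    inactive source cannot propagate power anywhere.
    """
    psd = np.asarray(component_psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("component PSD must be nonnegative")
    return G_omega * np.sqrt(psd)[None, :]


def source_cross_spectrum(H: np.ndarray) -> np.ndarray:
    """Component source cross-spectrum ``S = H H^dagger`` (Hermitian PSD)."""
    S = H @ H.conj().T
    return 0.5 * (S + S.conj().T)


def source_psd_diag(
    G_omega: np.ndarray, xi_vec: np.ndarray, alpha_vec: np.ndarray
) -> np.ndarray:
    """Per-generator spectral power ``sum_k |G_ik|^2 (xi_k + alpha_k)``.

    Equals the diagonal of the sum of the two component cross-spectra; for
    G = I it reduces to the purely local xi + alpha model.
    """
    s = np.asarray(xi_vec, dtype=float) + np.asarray(alpha_vec, dtype=float)
    return (np.abs(G_omega) ** 2) @ s


def sensor_cross_spectrum(
    K: np.ndarray, S_source: np.ndarray, sigma_noise2: float = 0.0
) -> np.ndarray:
    """Observed spectrum ``K S K^dagger + sigma_n^2 I``."""
    K = np.asarray(K, dtype=float)
    if K.shape[1] != S_source.shape[0]:
        raise ValueError("lead-field columns must match source dimension")
    Sig = K @ S_source @ K.T + sigma_noise2 * np.eye(K.shape[0])
    return 0.5 * (Sig + Sig.conj().T)


# ---------------------------------------------------------------------------
# whole-grid forward model
# ---------------------------------------------------------------------------

def greens_over_grid(
    prior: StructuralPrior, weights: StructuralWeights, grid: FrequencyGrid
) -> np.ndarray:
    """(n_omega, n_v, n_v) stack of Green functions for scaled structure."""
    C, D = weights.apply(prior)
    return np.stack(
        [green_function(build_ar_operator(C, D, w)) for w in grid.omega]
    )


def model_sensor_spectra(
    prior: StructuralPrior,
    weights: StructuralWeights,
    lead: LeadField,
    field: ComponentField,
    grid: FrequencyGrid,
    greens: np.ndarray | None = None,
) -> SpectrumSet:
    """Analytic sensor cross-spectra of the full generative model.

    Uses the identity ``Sigma = Kt diag(s) Kt^dagger + sigma^2 I`` with
    ``Kt = K G`` and ``s = xi + alpha`` — the two components are independent,
    so their cross-spectra add.
    """
    if greens is None:
        greens = greens_over_grid(prior, weights, grid)
    s = xi_psd_matrix(grid.omega, field) + alpha_psd_matrix(grid.omega, field)
    out = np.empty((grid.n_omega, lead.n_c, lead.n_c), dtype=complex)
    eye = np.eye(lead.n_c)
    for k in range(grid.n_omega):
        Kt = lead.K @ greens[k]
        Sig = (Kt * s[k][None, :]) @ Kt.conj().T + lead.sigma_noise2 * eye
        out[k] = 0.5 * (Sig + Sig.conj().T)
    return SpectrumSet(grid, out, level="sensor")
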