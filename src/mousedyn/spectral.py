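"""Two-sided discrete Fourier spectra of complex cursor traces.

The spectrum of a uniform complex trace ``z_0..z_{N-1}`` is defined by
the synthesis relation

    z(t_j) = sum_{n=-N/2}^{N/2-1} Z_n exp(i 2 pi f_n t_j),   f_n = n/(N dt),

i.e. the forward transform carries the 1/N factor and coefficients are
stored in ascending-frequency order (negative frequencies first).  This
differs from the common unnormalized library convention by a factor of
1/N and an ``fftshift``; the projection diagnostic downstream is scale
invariant, but a fixed convention keeps persisted spectra stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Spectrum", "PowerSpectrum", "dft", "synthesize", "psd", "loglog_slope"]


@dataclass
class Spectrum:
    """Two-sided DFT coefficients for one participant.

    ``Z[m]`` is the coefficient at frequency index ``n = m - N/2``
    (so negative frequencies come first) and ``f[m] = n/(N*dt)`` is the
    matching frequency in Hz (``dt`` being in milliseconds).
    """

    participant_id: str
    Z: np.ndarray
    f: np.ndarray
    N: int
    dt: float

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=complex)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.Z) != self.N or len(self.f) != self.N:
            raise ValueError("coefficient/frequency length must equal N")

    def __len__(self) -> int:
        return self.N

    @property
    def norm(self) -> float:
        """Euclidean norm of the coefficient vector (ordering-invariant)."""
        return float(np.linalg.norm(self.Z))


@dataclass
class PowerSpectrum:
    """Power per frequency bin: ``p = |Z|**2`` (or ``|u|**2`` for a basis column)."""

    f: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.f.shape != self.p.shape:
            raise ValueError("f and p must have equal length")
        if np.any(self.p < 0):
            raise ValueError("negative power")


def _frequencies(N: int, dt_ms: float) -> np.ndarray:
    # index n = -N/2 .. N/2-1; dt in ms -> f in Hz
    n = np.arange(-N // 2, N // 2)
    return n / (N * dt_ms * 1e-3)


def dft(trace) -> Spectrum:
    """Discrete Fourier spectrum of a uniform complex trace.

    Coefficients are normalized so the synthesis relation (see module
    docstring) reconstructs the input exactly; relative to
    ``numpy.fft.fft`` this divides by N and rotates negative
    frequencies to the front.
    """
    z = np.asarray(trace.z, dtype=complex)
    if len(z) % 2:
        raise ValueError("trace length must be even")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in trace")
    N = len(z)
    Z = np.fft.fftshift(np.fft.fft(z)) / N
    return Spectrum(participant_id=trace.participant_id, Z=Z,
                    f=_frequencies(N, trace.dt), N=N, dt=trace.dt)


def synthesize(spec: Spectrum) -> np.ndarray:
    """Invert a spectrum back to the time series via the synthesis relation."""
    return np.fft.ifft(np.fft.ifftshift(spec.Z)) * spec.N


def psd(obj) -> PowerSpectrum:
    """Power spectrum ``p_n = |Z_n|**2`` of a Spectrum or of a raw
    coefficient vector paired with frequencies ``(f, column)``."""
    if isinstance(obj, Spectrum):
        return PowerSpectrum(f=obj.f, p=np.abs(obj.Z) ** 2)
    f, column = obj
    return PowerSpectrum(f=np.asarray(f, float),
                         p=np.abs(np.asarray(column, complex)) ** 2)


def loglog_slope(ps: PowerSpectrum, fmin: float = 0.0,
                 fmax: float = np.inf) -> dict:
    """OLS slope of log-power on log-frequency over positive frequencies.

    Bins with ``f <= fmin``, ``f > fmax``, non-positive frequency, or
    zero power are excluded; the number of zero-power exclusions is
    reported.  Returns slope, intercept, ``r2`` and bin counts.
    """
    mask = (ps.f > max(fmin, 0.0)) & (ps.f <= fmax)
    zero_power = int(np.sum(mask & (ps.p <= 0)))
    mask &= ps.p > 0
    n_used = int(mask.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 usable bins in range, got {n_used}")
    lf = np.log(ps.f[mask])
    lp = np.log(ps.p[mask])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (slope * lf + intercept)
    ss_tot = np.sum((lp - lp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept),
            "r2": float(r2), "n_bins": n_used, "n_zero_excluded": zero_power}
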