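"""Detrended fluctuation analysis for complex-valued series.

Classical DFA centers a series, integrates it, detrends the integrated
profile inside non-overlapping windows of size ``s`` with a low-order
polynomial, and relates the RMS residual ``F_s`` to ``s``; a power law
``F_s ~ s**α`` signals scale-free temporal correlation.  Here the
series is complex (a 2-D trajectory embedded in the complex plane), so
the detrending polynomial has complex coefficients — equivalent to
independent fits of real and imaginary parts on a shared design — and
residual magnitudes ``|r|²`` replace squared residuals.

Interpretation of the exponent: for α ≤ 1 the series behaves as
fractional Gaussian noise with Hurst parameter H = α; for α > 1 it is
non-stationary, modeled as fractional Brownian motion with H = α − 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFAProfile",
    "DFAFit",
    "DegenerateSeriesError",
    "dfa_profile",
    "dfa_scales",
    "fluctuation",
    "dfa_alpha",
    "hurst_interpret",
]


class DegenerateSeriesError(ValueError):
    """Series has no fluctuation to analyze (e.g. constant input)."""


@dataclass
class DFAProfile:
    """Centered series ``ξ_n = z_n − mean(z)`` and its cumulative sum ``C``."""

    xi: np.ndarray
    C: np.ndarray
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.C)


@dataclass
class DFAFit:
    """Fitted scaling exponent with its Hurst reading.

    ``alpha`` is the OLS slope of ``log F_s`` on ``log s``; ``H`` and the
    correlation/stationarity classes follow from it.  ``scales`` holds the
    window sizes actually used (zero-fluctuation scales are dropped and
    counted in ``n_dropped``).
    """

    scales: np.ndarray
    F: np.ndarray
    alpha: float
    H: float
    correlation: str
    stationarity: str
    d: int = 1
    intercept: float = 0.0
    r2: float = field(default=np.nan)
    n_dropped: int = 0


def dfa_profile(z) -> DFAProfile:
    """Center a complex series and integrate it into the DFA profile."""
    z = np.asarray(z, dtype=complex)
    if len(z) < 8:
        raise ValueError(f"need at least 8 samples, got {len(z)}")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in series")
    xi = z - z.mean()
    scale = np.abs(z).max()
    degenerate = bool(np.abs(xi).max() <= 1e-12 * max(scale, 1.0))
    return DFAProfile(xi=xi, C=np.cumsum(xi), degenerate=degenerate)


def dfa_scales(N: int, min_scale: int = 4, max_scale: int | None = None,
               n_scales: int = 20) -> np.ndarray:
    """Geometrically spaced integer window sizes in ``[min_scale, max_scale]``.

    The default cap ``N // 4`` keeps at least four windows per scale.
    Duplicates arising from rounding are collapsed.
    """
    if max_scale is None:
        max_scale = N // 4
    if min_scale < 4:
        raise ValueError("minimum window size is 4")
    if max_scale > N:
        raise ValueError("max scale exceeds series length")
    if max_scale < min_scale:
        raise ValueError("max scale below min scale")
    grid = np.geomspace(min_scale, max_scale, n_scales)
    return np.unique(np.round(grid).astype(int))


def fluctuation(profile: DFAProfile, s: int, d: int = 1,
                mode: str = "forward") -> float:
    """RMS detrended fluctuation of the profile at window size ``s``.

    The profile is cut into ``⌊N/s⌋`` consecutive non-overlapping
    windows from the start (``mode="forward"``); a degree-``d``
    polynomial in the time index is least-squares fit to each window and
    ``F_s = sqrt(mean |residual|²)`` over all covered points.  Remainder
    points beyond the last full window are excluded.  ``mode="both"``
    additionally tiles windows backwards from the end and pools both
    passes, so no point is left uncovered.
    """
    C, N = profile.C, len(profile.C)
    if profile.degenerate:
        raise DegenerateSeriesError("constant series: fluctuation undefined")
    if not 4 <= s <= N:
        raise ValueError(f"window size {s} outside [4, {N}]")
    if mode not in ("forward", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    m = N // s
    t = np.arange(s, dtype=float)
    X = np.vander(t, d + 1)          # shared design across windows
    pinv = np.linalg.pinv(X)
    segments = [C[: m * s].reshape(m, s)]
    if mode == "both":
        segments.append(C[N - m * s:].reshape(m, s))
    sq_sum, n_pts = 0.0, 0
    for seg in segments:
        resid = seg.T - X @ (pinv @ seg.T)
        sq_sum += float(np.sum(np.abs(resid) ** 2))
        n_pts += seg.size
    return float(np.sqrt(sq_sum / n_pts))


def dfa_alpha(z, scales: np.ndarray | None = None, d: int = 1,
              mode: str = "forward") -> DFAFit:
    """Full DFA: profile, per-scale fluctuations, and the log-log slope α.

    Scales with exactly zero fluctuation (perfectly detrendable windows)
    are dropped from the fit with a warning; at least 4 usable scales
    are required.
    """
    z = np.asarray(z, dtype=complex)
    profile = dfa_profile(z)
    if profile.degenerate:
        raise DegenerateSeriesError("constant series: DFA undefined")
    if scales is None:
        scales = dfa_scales(len(z))
    scales = np.asarray(scales, dtype=int)
    F = np.array([fluctuation(profile, int(s), d=d, mode=mode) for s in scales])
    usable = F > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-fluctuation scales from DFA fit")
    if usable.sum() < 4:
        raise ValueError(f"only {int(usable.sum())} usable scales; need >= 4")
    ls, lF = np.log(scales[usable]), np.log(F[usable])
    alpha, intercept = np.polyfit(ls, lF, 1)
    resid = lF - (alpha * ls + intercept)
    ss_tot = np.sum((lF - lF.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    H, correlation, stationarity = hurst_interpret(float(alpha))
    return DFAFit(scales=scales[usable], F=F[usable], alpha=float(alpha),
                  H=H, correlation=correlation, stationarity=stationarity,
                  d=d, intercept=float(intercept), r2=float(r2),
                  n_dropped=n_dropped)


def hurst_interpret(alpha: float, tol: float = 1e-6) -> tuple[float, str, str]:
    """Hurst parameter and correlation class implied by a DFA exponent.

    For α ≤ 1 the series is read as stationary fractional noise with
    H = α; for α > 1 as non-stationary fractional Brownian motion with
    H = α − 1.  In both regimes H < 0.5 means anti-correlated increments,
    H = 0.5 (within ``tol``) uncorrelated, H > 0.5 positively correlated.
    Values outside [0, 2) are outside the fractional model; H is still
    reported, with a warning.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if alpha < 0 or alpha >= 2:
        warnings.warn(f"alpha={alpha:.3g} outside the fractional model [0, 2)")
    if alpha > 1:
        H, stationarity = alpha - 1.0, "non-stationary"
    else:
        H, stationarity = alpha, "stationary"
    if abs(H - 0.5) <= tol:
        correlation = "uncorrelated"
    elif H < 0.5:
        correlation = "anti-correlated"
    else:
        correlation = "positively-correlated"
    return H, correlation, stationarity
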