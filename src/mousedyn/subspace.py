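"""Cohort spectra matrix, SVD, and the η subspace-projection diagnostic.

Stacking one cohort's spectra as the columns of an ``N x P`` complex
matrix ``A`` and taking its thin SVD ``A = U Σ V*`` yields an ordered
orthonormal basis for the cohort's dominant spectral structure.  The
reference subspace keeps the first ``k`` left singular vectors, with
``k`` the smallest truncation whose squared singular values reach a
cumulative-variance threshold (default 50%).  A new spectrum ``Z`` is
scored by

    η = ||Ũ Ũ* Z|| / ||Z||  in [0, 1],

the fraction of ``Z`` lying in the subspace: 1 when ``Z`` is contained
in it, 0 when orthogonal to it.  No mean-centering is applied to ``A``
before the decomposition (it is decomposed as-is); centering is exposed
as an off-by-default option.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum

__all__ = [
    "SpectraMatrix",
    "SVDResult",
    "ReferenceSubspace",
    "EtaScore",
    "build_matrix",
    "svd",
    "cumulative_variance",
    "choose_k",
    "fit_reference_subspace",
    "eta",
    "save_subspace",
    "load_subspace",
]


@dataclass
class SpectraMatrix:
    """``N x P`` complex matrix whose column p is participant p's spectrum."""

    A: np.ndarray
    participant_ids: list[str]
    N: int
    dt: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=complex)
        if self.A.shape != (self.N, len(self.participant_ids)):
            raise ValueError("matrix shape inconsistent with metadata")

    @property
    def P(self) -> int:
        return self.A.shape[1]

    def column(self, participant_id: str) -> np.ndarray:
        return self.A[:, self.participant_ids.index(participant_id)]


@dataclass
class SVDResult:
    """Thin SVD ``A = U diag(s) V*`` with descending singular values."""

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray


@dataclass
class ReferenceSubspace:
    """Orthonormal basis ``U_tilde`` (N x k) for a cohort's dominant spectral span."""

    U_tilde: np.ndarray
    k: int
    variance_fraction: float
    threshold: float
    N: int
    dt: float
    provenance: str

    def __post_init__(self) -> None:
        self.U_tilde = np.asarray(self.U_tilde, dtype=complex)
        if self.U_tilde.shape != (self.N, self.k):
            raise ValueError("basis shape inconsistent with metadata")


@dataclass
class EtaScore:
    participant_id: str
    eta: float


def build_matrix(spectra: list[Spectrum]) -> SpectraMatrix:
    """Stack cohort spectra column-wise, preserving input order."""
    if not spectra:
        raise ValueError("empty cohort")
    N, dt = spectra[0].N, spectra[0].dt
    for s in spectra[1:]:
        if s.N != N:
            raise ValueError(f"mismatched spectrum lengths: {s.N} vs {N}")
        if s.dt != dt:
            raise ValueError("mismatched sampling intervals")
    P = len(spectra)
    if P >= N:
        # downstream truncation logic assumes more frequencies than participants
        raise ValueError(f"cohort size P={P} must be smaller than N={N}")
    A = np.column_stack([s.Z for s in spectra])
    if np.any(~np.isfinite(A)):
        raise ValueError("non-finite spectra")
    if np.any(np.all(A == 0, axis=0)):
        raise ValueError("all-zero spectrum column")
    return SpectraMatrix(A=A, participant_ids=[s.participant_id for s in spectra],
                         N=N, dt=dt)


def svd(mat: SpectraMatrix, center: bool = False) -> SVDResult:
    """Thin SVD of the spectra matrix (decomposed as-is unless ``center``)."""
    A = mat.A - mat.A.mean(axis=1, keepdims=True) if center else mat.A
    try:
        U, s, Vh = np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise RuntimeError(
            f"SVD failed to converge (shape {A.shape}, "
            f"max|A|={np.abs(A).max():.3g})"
        ) from exc
    return SVDResult(U=U, s=s, V=Vh.conj().T)


def cumulative_variance(res: SVDResult) -> np.ndarray:
    """Cumulative fraction of variance: ``sum_{p<=k} σ_p² / sum_p σ_p²``."""
    s2 = res.s ** 2
    total = s2.sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return np.cumsum(s2) / total


def choose_k(fractions: np.ndarray, threshold: float = 0.5) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return int(np.searchsorted(fractions, threshold) + 1)


def _phase_normalize(U: np.ndarray) -> np.ndarray:
    # rotate each column so its largest-magnitude entry is real-positive;
    # the subspace is unchanged, persisted files become reproducible
    out = U.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        pivot = out[i, j]
        if pivot != 0:
            out[:, j] *= np.abs(pivot) / pivot
    return out


def _provenance(ids: list[str], threshold: float, N: int, dt: float,
                center: bool) -> str:
    payload = json.dumps({"ids": ids, "threshold": threshold, "N": N,
                          "dt": dt, "center": center}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_reference_subspace(cohort: list[Spectrum], threshold: float = 0.5,
                           k: int | None = None,
                           center: bool = False) -> ReferenceSubspace:
    """Fit the reference ("accuracy") subspace from a cohort of spectra.

    ``k`` defaults to the smallest truncation reaching ``threshold``
    cumulative variance; pass ``k`` explicitly to override.
    """
    mat = build_matrix(cohort)
    res = svd(mat, center=center)
    fractions = cumulative_variance(res)
    if k is None:
        k = choose_k(fractions, threshold)
    if not 1 <= k <= mat.P:
        raise ValueError(f"k={k} outside 1..{mat.P}")
    return ReferenceSubspace(
        U_tilde=_phase_normalize(res.U[:, :k]),
        k=k,
        variance_fraction=float(fractions[k - 1]),
        threshold=threshold,
        N=mat.N,
        dt=mat.dt,
        provenance=_provenance(mat.participant_ids, threshold, mat.N, mat.dt,
                               center),
    )


def eta(sub: ReferenceSubspace, Z: Spectrum | np.ndarray,
        participant_id: str | None = None) -> EtaScore:
    """Fraction of a spectrum lying in the reference subspace.

    ``η = ||Ũ Ũ* Z|| / ||Z||``; since the basis is orthonormal this
    equals ``||Ũ* Z|| / ||Z||``.  Clipped into [0, 1] against roundoff.
    """
    if isinstance(Z, Spectrum):
        vec, pid = Z.Z, Z.participant_id
    else:
        vec, pid = np.asarray(Z, dtype=complex), participant_id or ""
    if len(vec) != sub.N:
        raise ValueError(f"spectrum length {len(vec)} != subspace rows {sub.N}")
    denom = np.linalg.norm(vec)
    if denom == 0:
        raise ValueError("η undefined for a zero spectrum")
    val = np.linalg.norm(sub.U_tilde.conj().T @ vec) / denom
    return EtaScore(participant_id=pid, eta=float(np.clip(val, 0.0, 1.0)))


def save_subspace(sub: ReferenceSubspace, path) -> None:
    """Persist a subspace to a single ``.npz`` container."""
    meta = json.dumps({"k": sub.k, "variance_fraction": sub.variance_fraction,
                       "threshold": sub.threshold, "N": sub.N, "dt": sub.dt,
                       "provenance": sub.provenance})
    np.savez(path, U_tilde=sub.U_tilde, meta=np.array(meta))


def load_subspace(path) -> ReferenceSubspace:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return ReferenceSubspace(U_tilde=data["U_tilde"], **meta)
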