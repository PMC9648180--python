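"""Comparison metrics: multireference character and unnormalized errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavefunction import WavefunctionSD

__all__ = ["ErrorReport", "multireference_character", "error_norm",
           "wavefunction_error"]


@dataclass(frozen=True)
class ErrorReport:
    """Root-sum-of-squares deviation of one quantity from a reference."""

    kind: str
    delta: float
    phase: int = 1


def multireference_character(coeffs) -> float:
    """sum_i c_i^2 (1 - c_i^2) over a normalized coefficient vector.

    Zero for a single-configuration state; tends to one as the weight
    spreads over many configurations.  Invariant under permutation and
    global phase.
    """
    c = np.asarray(coeffs, dtype=float).ravel()
    nrm = np.linalg.norm(c)
    if nrm == 0.0:
        raise ValueError("zero-norm coefficient vector")
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"coefficients not normalized (norm {nrm})")
    w = c * c
    return float(np.sum(w * (1.0 - w)))


def error_norm(A, A_ref, phase_align: bool = False,
               kind: str = "generic") -> ErrorReport:
    """Unnormalized error: sqrt of the summed squared elementwise deviation.

    With ``phase_align`` the global sign of ``A`` minimizing the error is
    applied first (wavefunctions are defined up to a global phase).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(A_ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    d_plus = float(np.sqrt(np.sum((A - B) ** 2)))
    if not phase_align:
        return ErrorReport(kind=kind, delta=d_plus, phase=1)
    d_minus = float(np.sqrt(np.sum((A + B) ** 2)))
    if d_minus < d_plus:
        return ErrorReport(kind=kind, delta=d_minus, phase=-1)
    return ErrorReport(kind=kind, delta=d_plus, phase=1)


def wavefunction_error(wfn: WavefunctionSD, wfn_ref: WavefunctionSD,
                       phase_align: bool = True) -> ErrorReport:
    """Coefficient error after embedding both in the union determinant set."""
    keys = sorted(set(wfn.to_dict()) | set(wfn_ref.to_dict()))
    da, db = wfn.to_dict(), wfn_ref.to_dict()
    a = np.array([da.get(k, 0.0) for k in keys])
    b = np.array([db.get(k, 0.0) for k in keys])
    rep = error_norm(a, b, phase_align=phase_align, kind="wavefunction")
    return rep
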