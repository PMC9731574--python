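"""Circular statistics and multiple-comparison helpers shared across modules."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, TWO_PI) - np.pi


def circ_mean(phases: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular mean direction of a set of angles."""
    return np.angle(np.exp(1j * np.asarray(phases)).mean(axis=axis))


def circ_r(phases: np.ndarray, axis=None) -> np.ndarray | float:
    """Mean resultant length R-bar in [0, 1]."""
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=axis))


def rayleigh_test(phases: np.ndarray, axis: int = -1):
    """Rayleigh test of circular uniformity.

    Uses the small-sample exponential approximation of the p-value
    (Zar, Biostatistical Analysis):

        z = n * Rbar**2
        p = exp(-z) * [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288 n^2)]

    Vectorized over every axis except ``axis`` (the sample axis).

    Returns
    -------
    z : ndarray
        Rayleigh statistic n * Rbar**2.
    p : ndarray
        Approximate p-value, clipped to (0, 1].
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[axis]
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 phases")
    rbar = circ_r(phases, axis=axis)
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return z, p


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg FDR correction.

    Returns (reject, p_adjusted) with the same shape as ``pvals``.
    """
    pvals = np.asarray(pvals, dtype=float)
    flat = pvals.ravel()
    reject, p_adj, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    return reject.reshape(pvals.shape), p_adj.reshape(pvals.shape)


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency (PPC0).

    Mean cosine of all pairwise phase differences,

        PPC = 2 / (n (n - 1)) * sum_{j<k} cos(theta_j - theta_k)

    computed via the algebraic identity with the resultant vector,
    PPC = (|sum e^{i theta}|^2 - n) / (n (n - 1)), which is exact.
    The estimator is unbiased with respect to the number of spikes:
    E[PPC] = 0 for uniform phases at any n >= 2.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC needs at least 2 phases")
    resultant = np.exp(1j * phases).sum()
    return float((np.abs(resultant) ** 2 - n) / (n * (n - 1)))


def ppc_along_axis(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vectorized PPC along one axis (e.g. spikes x freqs -> PPC per freq)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[axis]
    if n < 2:
        raise ValueError("PPC needs at least 2 phases")
    resultant = np.exp(1j * phases).sum(axis=axis)
    return (np.abs(resultant) ** 2 - n) / (n * (n - 1))
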