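"""Cross-validation of a fixed reference synergy set against new envelopes.

A subject's envelope matrix is reconstructed by non-negative reconstruction
(NNR): the reference W is held fixed and only H is fitted with the
multiplicative rule H <- H * (W^T M) / (W^T W H). The reconstruction VAF is
compared against the 95th percentile of VAFs obtained with null synergy
vectors built by independently permuting the entries within each W column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .signal_prep import EnvelopeMatrix
from .synergy import vaf as _vaf

__all__ = ["CrossValResult", "nnr_fit", "shuffle_synergy_vectors", "cross_validate"]

_EPS = 1e-12


@dataclass
class CrossValResult:
    vaf_recon: float
    null_vafs: np.ndarray
    vaf_threshold: float
    representative: bool
    n_shuffles: int
    seed: int | None


def _as_matrix(M) -> np.ndarray:
    values = M.values if isinstance(M, EnvelopeMatrix) else M
    return np.atleast_2d(np.asarray(values, dtype=float))


def nnr_fit(
    M,
    W_fixed: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-5,
    seed: int | SeedSequence | None = None,
    return_trace: bool = False,
):
    """Fit H >= 0 to M with W held fixed, by multiplicative updates.

    Returns H, or ``(H, errors)`` when ``return_trace`` is set, where
    ``errors`` holds the squared Frobenius reconstruction error after every
    iteration (non-increasing by construction of the update).
    """
    M = _as_matrix(M)
    W = np.asarray(W_fixed, dtype=float)
    if np.any(M < 0):
        raise ValueError("M must be entrywise nonnegative")
    if np.any(W < 0):
        raise ValueError("W_fixed must be entrywise nonnegative")
    col_norms = np.linalg.norm(W, axis=0)
    if np.any(col_norms == 0):
        j = int(np.nonzero(col_norms == 0)[0][0])
        raise ValueError(f"W_fixed column {j} is all-zero")
    if W.shape[0] != M.shape[0]:
        raise ValueError("row count of W_fixed must match M")

    rng = default_rng(seed)
    k, n = W.shape[1], M.shape[1]
    scale = np.sqrt(max(float(M.mean()), _EPS) / k)
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale + _EPS

    WtM = W.T @ M
    WtW = W.T @ W
    total = float(np.sum(M * M))
    prev_err = np.inf
    errors = []
    for _ in range(max_iter):
        H *= WtM / np.maximum(WtW @ H, _EPS)
        # ||M - WH||^2 via the precomputed Gram pieces
        err = total - 2.0 * float(np.sum(WtM * H)) + float(np.sum((WtW @ H) * H))
        err = max(err, 0.0)
        errors.append(err)
        if total > 0 and (prev_err - err) / total < tol:
            break
        prev_err = err
    if return_trace:
        return H, np.asarray(errors)
    return H


def shuffle_synergy_vectors(W: np.ndarray, rng: Generator | int | None = None) -> np.ndarray:
    """Independently permute the entries within each column of W."""
    W = np.asarray(W, dtype=float)
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    out = np.empty_like(W)
    for j in range(W.shape[1]):
        out[:, j] = rng.permutation(W[:, j])
    return out


def cross_validate(
    M,
    W_ref: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | None = None,
    percentile: float = 95.0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> CrossValResult:
    """Is ``W_ref`` a better-than-chance description of M's envelopes?

    The null distribution comes from NNR reconstructions with column-wise
    shuffled copies of ``W_ref``; the threshold is the ``percentile``-th
    empirical percentile (linear interpolation between order statistics).
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be at least 20 for a stable percentile")
    M = _as_matrix(M)
    ss = SeedSequence(seed)
    fit_seed, *null_seeds = ss.spawn(n_shuffles + 1)

    H = nnr_fit(M, W_ref, max_iter=max_iter, tol=tol, seed=fit_seed)
    vaf_recon = _vaf(M, np.asarray(W_ref, dtype=float), H)

    null_vafs = np.empty(n_shuffles)
    for i, child in enumerate(null_seeds):
        rng = default_rng(child)
        W_null = shuffle_synergy_vectors(W_ref, rng)
        H_null = nnr_fit(M, W_null, max_iter=max_iter, tol=tol, seed=rng)
        null_vafs[i] = _vaf(M, W_null, H_null)

    threshold = float(np.percentile(null_vafs, percentile))
    return CrossValResult(
        vaf_recon=float(vaf_recon),
        null_vafs=null_vafs,
        vaf_threshold=threshold,
        representative=bool(vaf_recon > threshold),
        n_shuffles=n_shuffles,
        seed=seed,
    )
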