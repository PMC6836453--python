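"""Muscle synergy extraction by non-negative matrix factorization.

Factorizes a nonnegative envelope matrix M (muscles x samples) as W @ H under
the synchronous synergy model (time-invariant spatial weights), selects the
model order by a global variance-accounted-for (VAF) threshold, and provides
normalization, optimal column matching, and group averaging of synergy sets.

The factorization uses multiplicative (Lee-Seung type) updates minimizing the
squared Frobenius error, best-of-restarts with sparse initializations, and
nested warm-starting across orders so the VAF-vs-order curve is monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import linear_sum_assignment

from .signal_prep import EnvelopeMatrix

__all__ = [
    "SynergyDecomposition",
    "GroupSynergySet",
    "vaf",
    "per_muscle_vaf",
    "nnmf_extract",
    "vaf_curve",
    "select_order",
    "group_order",
    "normalize_synergies",
    "cosine_similarity",
    "order_synergies",
    "average_synergies",
]

_EPS = 1e-12


@dataclass
class SynergyDecomposition:
    """NNMF result: W (muscles x n_syn), H (n_syn x samples), global VAF."""

    W: np.ndarray
    H: np.ndarray
    vaf: float
    n_syn: int
    converged: bool = True
    restarts_used: int = 1

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class GroupSynergySet:
    """Ordered per-subject synergy sets and their renormalized average."""

    members: list[np.ndarray]
    W_mean: np.ndarray
    reference_id: int
    similarity_matrix: np.ndarray  # n_syn x n_members x n_members


def _as_matrix(M) -> np.ndarray:
    values = M.values if isinstance(M, EnvelopeMatrix) else M
    return np.atleast_2d(np.asarray(values, dtype=float))


def vaf(M, W: np.ndarray, H: np.ndarray) -> float:
    """Global uncentered VAF: 1 - ||M - W@H||_F^2 / ||M||_F^2."""
    M = _as_matrix(M)
    total = float(np.sum(M * M))
    if total == 0.0:
        raise ValueError("VAF undefined for an all-zero matrix")
    resid = M - W @ H
    return 1.0 - float(np.sum(resid * resid)) / total


def per_muscle_vaf(M, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Row-wise VAF; NaN for all-zero rows (reported, never used for selection)."""
    M = _as_matrix(M)
    total = np.sum(M * M, axis=1)
    resid = M - W @ H
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - np.sum(resid * resid, axis=1) / total
    out[total == 0] = np.nan
    return out


def _sparse_uniform(
    rng: Generator, shape: tuple[int, int], sparse_frac: float, axis: int, scale: float
) -> np.ndarray:
    """Uniform nonnegative init with a fraction of entries per column (axis=0)
    or row (axis=1) suppressed to a small positive floor.

    The floor (rather than an exact zero) keeps multiplicative updates able to
    regrow a suppressed entry; exact zeros are absorbing states of the update.
    """
    X = rng.uniform(0.0, 1.0, size=shape) * scale
    n_along = shape[axis]
    n_zero = min(int(math.floor(sparse_frac * n_along)), n_along - 1)
    if n_zero > 0:
        n_vec = shape[1 - axis]
        for j in range(n_vec):
            pick = rng.choice(n_along, size=n_zero, replace=False)
            if axis == 0:
                X[pick, j] = 1e-6 * scale
            else:
                X[j, pick] = 1e-6 * scale
    return X


def _multiplicative_fit(
    M: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
    check_every: int = 5,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    total = float(np.sum(M * M))
    prev = -np.inf
    converged = False
    v = 0.0
    for it in range(1, max_iter + 1):
        H *= (W.T @ M) / np.maximum((W.T @ W) @ H, _EPS)
        W *= (M @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        if it % check_every == 0 or it == max_iter:
            resid = M - W @ H
            v = 1.0 - float(np.sum(resid * resid)) / total
            if v - prev < tol:
                converged = True
                break
            prev = v
    return W, H, v, converged


def nnmf_extract(
    M,
    n_syn: int,
    restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-5,
    sparse_frac: float = 0.5,
    seed: int | SeedSequence | None = None,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> SynergyDecomposition:
    """Best-of-restarts multiplicative-update NNMF of a nonnegative matrix.

    Each restart draws sparse nonnegative uniform initializations for W and H
    (a fraction ``sparse_frac`` of entries per W column / H row suppressed);
    iteration stops when the VAF improvement drops below ``tol``. The restart
    with the highest final VAF wins. An optional ``warm_start`` (W0, H0) is
    evaluated as one additional candidate (used for nested order selection).
    """
    M = _as_matrix(M)
    if np.any(M < 0):
        raise ValueError("M must be entrywise nonnegative")
    if n_syn < 1:
        raise ValueError("n_syn must be at least 1")
    if n_syn > M.shape[0]:
        raise ValueError(f"n_syn={n_syn} exceeds the {M.shape[0]} muscle rows")
    if not np.any(M):
        raise ValueError("cannot factorize an all-zero matrix")

    m, n = M.shape
    scale = math.sqrt(float(M.mean()) / n_syn) or 1.0
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    children = ss.spawn(restarts)

    best: SynergyDecomposition | None = None
    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    for child in children:
        rng = default_rng(child)
        candidates.append(
            (
                _sparse_uniform(rng, (m, n_syn), sparse_frac, 0, scale),
                _sparse_uniform(rng, (n_syn, n), sparse_frac, 1, scale),
            )
        )
    if warm_start is not None:
        W0, H0 = warm_start
        candidates.append((np.asarray(W0, dtype=float).copy(), np.asarray(H0, dtype=float).copy()))

    for W0, H0 in candidates:
        W, H, v, conv = _multiplicative_fit(M, W0, H0, max_iter, tol)
        if best is None or v > best.vaf:
            best = SynergyDecomposition(W, H, v, n_syn, conv, len(candidates))
    assert best is not None
    return best


def vaf_curve(
    M,
    n_max: int = 12,
    threshold: float | None = None,
    restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-5,
    sparse_frac: float = 0.5,
    seed: int | None = None,
) -> dict[int, SynergyDecomposition]:
    """Decompositions for n = 1 .. n_max with nested warm starts.

    Order n is seeded with the order n-1 solution plus one near-zero random
    component, which makes the VAF curve monotone non-decreasing. If
    ``threshold`` is given, stops at the first order whose VAF exceeds it.
    """
    M = _as_matrix(M)
    ss = SeedSequence(seed)
    order_seeds = ss.spawn(n_max)
    curve: dict[int, SynergyDecomposition] = {}
    prev: SynergyDecomposition | None = None
    for n in range(1, n_max + 1):
        warm = None
        if prev is not None:
            rng = default_rng(order_seeds[n - 1].spawn(1)[0])
            tiny = 1e-3 * math.sqrt(float(M.mean()) / n)
            warm = (
                np.hstack([prev.W, rng.uniform(0, 1, (M.shape[0], 1)) * tiny]),
                np.vstack([prev.H, rng.uniform(0, 1, (1, M.shape[1])) * tiny]),
            )
        dec = nnmf_extract(
            M,
            n,
            restarts=restarts,
            max_iter=max_iter,
            tol=tol,
            sparse_frac=sparse_frac,
            seed=order_seeds[n - 1],
            warm_start=warm,
        )
        if prev is not None and 0 < prev.vaf - dec.vaf < 1e-6:
            # the warm start bounds any decrease by the tiny added component;
            # clamp so the public curve is exactly monotone
            dec = replace(dec, vaf=prev.vaf)
        curve[n] = dec
        prev = dec
        if threshold is not None and dec.vaf > threshold:
            break
    return curve


def select_order(
    M,
    threshold: float = 0.90,
    n_max: int = 12,
    **extraction_kwargs,
) -> int:
    """Smallest order whose global VAF exceeds ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    curve = vaf_curve(M, n_max=n_max, threshold=threshold, **extraction_kwargs)
    for n in sorted(curve):
        if curve[n].vaf > threshold:
            return n
    raise ValueError(
        f"VAF threshold {threshold} not reached at any order up to {n_max} "
        f"(best {max(d.vaf for d in curve.values()):.4f})"
    )


def group_order(per_subject_orders) -> int:
    """Ceiling of the mean per-subject order (exact integer means unchanged)."""
    orders = list(per_subject_orders)
    if not orders:
        raise ValueError("need at least one per-subject order")
    return math.ceil(sum(orders) / len(orders))


def normalize_synergies(dec: SynergyDecomposition) -> SynergyDecomposition:
    """Unit-norm W columns, H rows rescaled so W @ H is unchanged."""
    norms = np.linalg.norm(dec.W, axis=0)
    if np.any(norms == 0):
        j = int(np.nonzero(norms == 0)[0][0])
        raise ValueError(f"synergy column {j} is all-zero; cannot normalize")
    return replace(dec, W=dec.W / norms, H=dec.H * norms[:, None])


def cosine_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Normalized dot product; in [0, 1] for nonnegative vectors."""
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    n1 = np.linalg.norm(w1)
    n2 = np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(w1 @ w2 / (n1 * n2))


def order_synergies(
    W_subject: np.ndarray, W_reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one column matching of a subject's W to a reference.

    Returns ``(perm, sims)`` where ``W_subject[:, perm]`` aligns column k with
    reference column k (apply ``H[perm, :]`` to the activations) and ``sims``
    holds the per-pair cosine similarities. The assignment maximizes total
    cosine similarity (Hungarian algorithm, lowest-index tie preference).
    """
    W_subject = np.asarray(W_subject, dtype=float)
    W_reference = np.asarray(W_reference, dtype=float)
    if W_subject.shape != W_reference.shape:
        raise ValueError("subject and reference must share shape (muscles x n_syn)")
    k = W_subject.shape[1]
    S = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            S[i, j] = cosine_similarity(W_reference[:, i], W_subject[:, j])
    rows, cols = linear_sum_assignment(-S)
    perm = cols[np.argsort(rows)]
    return perm, S[np.arange(k), perm]


def average_synergies(
    ordered_sets: list[np.ndarray], reference_id: int = 0
) -> GroupSynergySet:
    """Entrywise mean of ordered synergy sets, columns renormalized to unit norm."""
    if not ordered_sets:
        raise ValueError("need at least one synergy set to average")
    stack = np.stack([np.asarray(W, dtype=float) for W in ordered_sets])
    if len({W.shape for W in map(np.asarray, ordered_sets)}) != 1:
        raise ValueError("all sets must share the same shape")
    W_mean = stack.mean(axis=0)
    norms = np.linalg.norm(W_mean, axis=0)
    if np.any(norms == 0):
        raise ValueError("average produced a zero synergy column")
    W_mean = W_mean / norms
    n_members, _, n_syn = stack.shape
    sim = np.ones((n_syn, n_members, n_members))
    for a in range(n_members):
        for b in range(a + 1, n_members):
            for j in range(n_syn):
                s = cosine_similarity(stack[a, :, j], stack[b, :, j])
                sim[j, a, b] = sim[j, b, a] = s
    return GroupSynergySet(
        members=[stack[i] for i in range(n_members)],
        W_mean=W_mean,
        reference_id=reference_id,
        similarity_matrix=sim,
    )
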