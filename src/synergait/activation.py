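"""Phase-resolved activation statistics.

From 200-sample phase-normalized activation profiles this module computes a
per-phase activity index (the sum of the samples falling in each sub-phase
block) and the center of activity (CoA) — the direction of the circular
resultant of the profile mapped onto the gait cycle (360 degrees = 1 cycle).
Group comparisons use a Kruskal-Wallis test per (synergy, phase) cell with
Bonferroni-corrected post-hoc pairwise tests, and synergy-count equivalence
is tested with the exact (Freeman-Halton) extension of Fisher's test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .signal_prep import N_PROFILE_SAMPLES, PHASE_NAMES, PHASE_SAMPLE_EDGES

__all__ = [
    "phase_activity",
    "center_of_activity",
    "build_phase_activity_table",
    "GroupTestResult",
    "kruskal_wallis_by_cell",
    "synergy_count_test",
]

ACTIVITY_COLUMNS = tuple(f"activity_{p}" for p in PHASE_NAMES)


def phase_activity(profile: np.ndarray) -> np.ndarray:
    """Per-phase activity: sums over the sample blocks [0,20), [20,100),
    [100,120), [120,200). Accepts one 200-sample row or a rows x 200 matrix."""
    p = np.asarray(profile, dtype=float)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != N_PROFILE_SAMPLES:
        raise ValueError(f"profile must have {N_PROFILE_SAMPLES} samples, got {p.shape[1]}")
    e = PHASE_SAMPLE_EDGES
    sums = np.stack([p[:, e[j] : e[j + 1]].sum(axis=1) for j in range(4)], axis=1)
    return sums[0] if squeeze else sums


def center_of_activity(profile: np.ndarray) -> float:
    """CoA in degrees in [0, 360): direction of the circular resultant of the
    profile treated as a mass distribution on the gait cycle.

    Raises on an identically-zero profile or a vanishing resultant (e.g. a
    perfectly uniform profile), where the CoA is undefined.
    """
    p = np.asarray(profile, dtype=float).ravel()
    if p.size != N_PROFILE_SAMPLES:
        raise ValueError(f"profile must have {N_PROFILE_SAMPLES} samples")
    if not np.any(p):
        raise ValueError("CoA undefined for an all-zero profile")
    theta = 2.0 * np.pi * np.arange(N_PROFILE_SAMPLES) / N_PROFILE_SAMPLES
    c = float(np.sum(p * np.cos(theta)))
    s = float(np.sum(p * np.sin(theta)))
    if math.hypot(c, s) <= 1e-12 * float(np.sum(np.abs(p))):
        raise ValueError("CoA undefined: circular resultant is (numerically) zero")
    return float(np.degrees(math.atan2(s, c)) % 360.0)


def build_phase_activity_table(records) -> pd.DataFrame:
    """Assemble the per (subject, group, synergy) activity table.

    ``records`` yields ``(subject, group, profile_matrix)`` where the profile
    matrix is n_synergies x 200 (a subject's mean activation profiles). CoA is
    NaN for identically-zero profiles.
    """
    rows = []
    for subject, group, profiles in records:
        profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
        acts = phase_activity(profiles)
        for i in range(profiles.shape[0]):
            try:
                coa = center_of_activity(profiles[i])
            except ValueError:
                coa = np.nan
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "synergy": i + 1,
                    **dict(zip(ACTIVITY_COLUMNS, acts[i])),
                    "coa_deg": coa,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    """Kruskal-Wallis results per (synergy, phase) with post-hoc pairs."""

    cells: pd.DataFrame
    posthoc: pd.DataFrame
    alpha: float = 0.05


def _dunn_pairwise(values_by_group: dict[str, np.ndarray]) -> list[tuple[str, str, float]]:
    """Dunn's z-based pairwise comparisons on pooled ranks (tie-corrected)."""
    labels = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    offsets = np.cumsum([0] + [len(values_by_group[g]) for g in labels])
    mean_ranks = {
        g: float(np.mean(ranks[offsets[i] : offsets[i + 1]]))
        for i, g in enumerate(labels)
    }
    out = []
    for a, b in combinations(labels, 2):
        na, nb = len(values_by_group[a]), len(values_by_group[b])
        se2 = (n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        if se2 <= 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(se2)
            p = float(2.0 * stats.norm.sf(abs(z)))
        out.append((a, b, p))
    return out


def kruskal_wallis_by_cell(
    table: pd.DataFrame,
    alpha: float = 0.05,
    posthoc: str = "mannwhitney",
) -> GroupTestResult:
    """Kruskal-Wallis test per (synergy, phase) cell with group as the factor.

    Post-hoc pairwise comparisons ("mannwhitney" rank-sum or "dunn") are
    Bonferroni-corrected by the number of group pairs.
    """
    if posthoc not in ("mannwhitney", "dunn"):
        raise ValueError(f"unknown posthoc method {posthoc!r}")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_pairs = len(groups) * (len(groups) - 1) // 2

    cell_rows, post_rows = [], []
    for synergy in sorted(table["synergy"].unique()):
        sub = table[table["synergy"] == synergy]
        for phase, col in zip(PHASE_NAMES, ACTIVITY_COLUMNS):
            by_group = {}
            for g in groups:
                vals = sub.loc[sub["group"] == g, col].to_numpy(dtype=float)
                if len(vals) < 2:
                    raise ValueError(
                        f"group {g} has fewer than 2 observations for synergy "
                        f"{synergy}, phase {phase}"
                    )
                by_group[g] = vals
            pooled = np.concatenate(list(by_group.values()))
            if np.all(pooled == pooled[0]):
                h_stat, p_val = 0.0, 1.0
            else:
                h_stat, p_val = stats.kruskal(*by_group.values())
            cell_rows.append(
                {
                    "synergy": synergy,
                    "phase": phase,
                    "H": float(h_stat),
                    "df": len(groups) - 1,
                    "p": float(p_val),
                    "significant": bool(p_val < alpha),
                }
            )
            if posthoc == "dunn":
                pairs = _dunn_pairwise(by_group)
            else:
                pairs = []
                for a, b in combinations(groups, 2):
                    va, vb = by_group[a], by_group[b]
                    if np.all(np.concatenate([va, vb]) == va[0]):
                        p_raw = 1.0
                    else:
                        p_raw = float(
                            stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
                        )
                    pairs.append((a, b, p_raw))
            for a, b, p_raw in pairs:
                p_adj = min(1.0, p_raw * n_pairs)
                post_rows.append(
                    {
                        "synergy": synergy,
                        "phase": phase,
                        "group_a": a,
                        "group_b": b,
                        "p_raw": p_raw,
                        "p_adj": p_adj,
                        "significant": bool(p_adj < alpha),
                    }
                )
    return GroupTestResult(pd.DataFrame(cell_rows), pd.DataFrame(post_rows), alpha)


def _log_table_prob(table: np.ndarray, const: float) -> float:
    return const - float(np.sum(gammaln(table + 1.0)))


def synergy_count_test(counts) -> float:
    """Exact (Freeman-Halton) test of independence for an r x c count table.

    Enumerates every table with the observed margins; the p-value is the sum
    of hypergeometric probabilities of tables no more probable than the
    observed one. For 2 x 2 tables this reduces to Fisher's exact test.
    """
    T = np.asarray(counts)
    if T.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(T == np.floor(T)):
        raise ValueError("counts must be integers")
    T = T.astype(int)
    # drop empty margins: they carry no information and bloat the enumeration
    T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    if T.size == 0 or min(T.shape) < 2:
        return 1.0
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    n = int(T.sum())
    const = float(
        np.sum(gammaln(row_sums + 1.0))
        + np.sum(gammaln(col_sums + 1.0))
        - gammaln(n + 1.0)
    )
    log_p_obs = _log_table_prob(T, const)
    r, c = T.shape

    total = 0.0
    cell = np.zeros((r, c), dtype=int)

    def fill(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray) -> None:
        nonlocal total
        if i == r - 1:
            # last row is fully determined by the column remainders
            cell[i, :] = col_left
            lp = _log_table_prob(cell, const)
            if lp <= log_p_obs + 1e-9:
                total += math.exp(lp)
            return
        if j == c - 1:
            v = row_left[i]
            if v > col_left[j]:
                return
            cell[i, j] = v
            col_left[j] -= v
            row_left2 = row_left.copy()
            row_left2[i] = 0
            fill(i + 1, 0, row_left2, col_left)
            col_left[j] += v
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            cell[i, j] = v
            row_left[i] -= v
            col_left[j] -= v
            fill(i, j + 1, row_left, col_left)
            row_left[i] += v
            col_left[j] += v

    fill(0, 0, row_sums.copy(), col_sums.copy())
    return float(min(total, 1.0))
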