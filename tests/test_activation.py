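import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import synergait as sg
from synergait.activation import (
    build_phase_activity_table,
    center_of_activity,
    kruskal_wallis_by_cell,
    phase_activity,
    synergy_count_test,
)

from conftest import truth_mean_profiles


class TestPhaseActivity:
    def test_all_ones(self):
        assert phase_activity(np.ones(200)) == pytest.approx([20, 80, 20, 80])

    def test_ds2_only_support(self):
        p = np.zeros(200)
        p[100:120] = 1.0
        acts = phase_activity(p)
        assert acts == pytest.approx([0, 0, 20, 0])

    def test_matches_index_loop_oracle(self, rng):
        p = rng.uniform(0, 3, 200)
        edges = [(0, 20), (20, 100), (100, 120), (120, 200)]
        oracle = [sum(p[i] for i in range(a, b)) for a, b in edges]
        assert phase_activity(p) == pytest.approx(oracle)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            phase_activity(np.ones(201))

    def test_activities_sum_to_total(self, rng):
        p = rng.uniform(0, 1, size=(3, 200))
        assert np.allclose(phase_activity(p).sum(axis=1), p.sum(axis=1), atol=1e-9)


class TestCenterOfActivity:
    def test_unit_impulse_at_quarter_cycle(self):
        p = np.zeros(200)
        p[50] = 1.0
        assert center_of_activity(p) == pytest.approx(90.0)

    def test_symmetric_impulses(self):
        p = np.zeros(200)
        p[40] = p[60] = 1.0
        assert center_of_activity(p) == pytest.approx(90.0)

    def test_weighted_impulses_match_complex_oracle(self):
        p = np.zeros(200)
        p[30], p[90] = 2.0, 1.0
        z = 2.0 * np.exp(1j * np.deg2rad(54.0)) + 1.0 * np.exp(1j * np.deg2rad(162.0))
        expected = np.degrees(np.angle(z)) % 360
        assert center_of_activity(p) == pytest.approx(expected, abs=1e-9)

    def test_random_profile_matches_complex_oracle(self, rng):
        p = rng.uniform(0, 1, 200)
        theta = 2 * np.pi * np.arange(200) / 200
        expected = np.degrees(np.angle(np.sum(p * np.exp(1j * theta)))) % 360
        assert center_of_activity(p) == pytest.approx(expected, abs=1e-9)

    def test_zero_profile_errors(self):
        with pytest.raises(ValueError):
            center_of_activity(np.zeros(200))

    def test_uniform_profile_errors(self):
        with pytest.raises(ValueError):
            center_of_activity(np.ones(200))

    @given(st.integers(min_value=0, max_value=199), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_cyclic_shift_equivariance(self, shift, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 200) ** 2
        base = center_of_activity(p)
        shifted = center_of_activity(np.roll(p, shift))
        expected = (base + 360.0 * shift / 200.0) % 360.0
        diff = (shifted - expected + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6


class TestBuildTable:
    def test_table_structure(self, rng):
        profiles = rng.uniform(0, 1, size=(4, 200))
        df = build_phase_activity_table([("S00", "TF", profiles)])
        assert len(df) == 4
        assert set(df["synergy"]) == {1, 2, 3, 4}
        assert df["coa_deg"].between(0, 360).all()

    def test_zero_profile_gets_nan_coa(self):
        profiles = np.zeros((2, 200))
        profiles[0, 10] = 1.0
        df = build_phase_activity_table([("S00", "TF", profiles)])
        assert np.isnan(df.loc[df["synergy"] == 2, "coa_deg"]).all()


def _table_from(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject": f"{g}{i}", "group": g, "synergy": 1,
                    "activity_DS1": v, "activity_Stance": v,
                    "activity_DS2": v, "activity_Swing": v,
                }
            )
    return pd.DataFrame(rows)


class TestKruskalWallis:
    def test_hand_rank_oracle(self):
        # (1,2,3),(4,5,6),(7,8,9): H = 12/(9*10)*(6^2+15^2+24^2)/3 - 33 = 7.2
        table = _table_from(
            {"A": np.array([1.0, 2, 3]), "B": np.array([4.0, 5, 6]), "C": np.array([7.0, 8, 9])}
        )
        res = kruskal_wallis_by_cell(table)
        assert np.allclose(res.cells["H"], 7.2)
        assert np.allclose(res.cells["p"], stats.chi2.sf(7.2, 2))

    def test_all_ties(self):
        table = _table_from({"A": np.full(4, 2.0), "B": np.full(4, 2.0)})
        res = kruskal_wallis_by_cell(table)
        assert np.allclose(res.cells["H"], 0.0)
        assert np.allclose(res.cells["p"], 1.0)

    def test_small_group_errors(self):
        table = _table_from({"A": np.array([1.0]), "B": np.array([1.0, 2.0])})
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_wallis_by_cell(table)

    def test_bonferroni_adjustment(self, rng):
        table = _table_from(
            {g: rng.uniform(0, 1, 6) for g in ("A", "B", "C")}
        )
        res = kruskal_wallis_by_cell(table)
        assert np.allclose(
            res.posthoc["p_adj"], np.minimum(1.0, res.posthoc["p_raw"] * 3)
        )

    def test_dunn_posthoc_runs(self, rng):
        table = _table_from({g: rng.uniform(0, 1, 6) for g in ("A", "B", "C")})
        res = kruskal_wallis_by_cell(table, posthoc="dunn")
        assert res.posthoc["p_raw"].between(0, 1).all()

    def test_type_one_error_sanity(self):
        # smaller version of the acceptance calibration
        rng = np.random.default_rng(5)
        hits = 0
        n_cells = 300
        for _ in range(n_cells):
            groups = [rng.normal(size=12) for _ in range(3)]
            _, p = stats.kruskal(*groups)
            hits += p < 0.05
        assert 0.01 <= hits / n_cells <= 0.10


class TestSynergyCountTest:
    def test_two_by_two_matches_fisher_exact(self):
        table = np.array([[3, 1], [1, 3]])
        expected = stats.fisher_exact(table)[1]
        assert synergy_count_test(table) == pytest.approx(expected, abs=1e-10)
        assert synergy_count_test(table) == pytest.approx(0.485714, abs=1e-5)

    def test_identical_rows_give_one(self):
        assert synergy_count_test([[5, 3, 2], [5, 3, 2]]) == pytest.approx(1.0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            synergy_count_test([[1, -1], [2, 3]])

    def test_non_integer_counts_error(self):
        with pytest.raises(ValueError):
            synergy_count_test([[1.5, 1], [2, 3]])

    def test_study_like_counts_plausible(self):
        # groups x {3,4,5}-synergy counts in the shape of the study populations
        counts = [[7, 5, 0], [7, 4, 1], [6, 5, 3]]
        p = synergy_count_test(counts)
        assert 0.0 < p <= 1.0

    def test_matches_permutation_oracle_quick(self, rng):
        counts = np.array([[4, 2, 1], [2, 3, 2], [1, 2, 4]])
        p_exact = synergy_count_test(counts)
        p_perm = _permutation_p(counts, 20000, rng)
        assert p_exact == pytest.approx(p_perm, abs=0.02)


def _permutation_p(counts: np.ndarray, n_draws: int, rng) -> float:
    """Margin-preserving permutation estimate of the exact p-value."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=int)
    r, c = counts.shape
    row_of = np.repeat(np.arange(r), counts.sum(axis=1))
    col_of = np.repeat(np.arange(c), counts.sum(axis=0))
    const = (
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(counts.sum(axis=0) + 1).sum()
        - gammaln(counts.sum() + 1)
    )

    def log_prob(tab):
        return const - gammaln(tab + 1.0).sum()

    lp_obs = log_prob(counts)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(col_of)
        tab = np.zeros((r, c))
        np.add.at(tab, (row_of, perm), 1)
        if log_prob(tab) <= lp_obs + 1e-9:
            hits += 1
    return hits / n_draws


class TestPowerOnTfLikeCohorts:
    def test_synergy2_ds2_rejected_in_most_replicates(self, template):
        """Injected calf-module DS2 effect is detected (ground-truth H path)."""
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            records = []
            for group, n_sub, effect, seed in (
                ("TF", 14, "tf_like", 100 + rep),
                ("C_SS", 12, "none", 200 + rep),
                ("C_SL", 12, "none", 300 + rep),
            ):
                cfg = sg.CohortConfig(
                    n_subjects=n_sub, group_effect=effect, seed=seed,
                    sampling_rate_hz=200.0, strides_per_subject=4,
                )
                for s in sg.generate_cohort(cfg, template).subjects:
                    records.append((f"{group}_{s.subject_id}", group,
                                    truth_mean_profiles(s)))
            table = build_phase_activity_table(records)
            res = kruskal_wallis_by_cell(table)
            cell = res.posthoc.query(
                "synergy == 2 and phase == 'DS2' and group_a == 'C_SS' and group_b == 'TF'"
            )
            hits += bool(cell["significant"].iloc[0])
        assert hits >= 4
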