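"""AUC computation, aggregation and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdmbench.evaluation import (
    SweepGrid,
    compute_auc,
    rank_methods,
    summarize_by_scenario,
)
from sdmbench.rng import spawn_rng


def brute_force_auc(scores, labels):
    """Oracle: explicit enumeration of all presence-absence pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_chance(self):
        assert compute_auc([0.4] * 10, [1, 0] * 5) == 0.5

    def test_three_point_example(self):
        # one concordant and one discordant pair out of two
        assert compute_auc([0.9, 0.8, 0.4], [1, 0, 1]) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = spawn_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            scores = rng.choice(np.round(rng.random(8), 2), size=n)
            if y.min() == y.max():
                continue
            assert compute_auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = spawn_rng(2)
        y = (rng.random(200) < 0.4).astype(int)
        s = rng.random(200)
        assert compute_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        # scores on a 0.01 lattice so 1 - s introduces no rounding ties
        st.lists(st.integers(0, 100).map(lambda v: v / 100.0), min_size=4, max_size=60),
        st.data(),
    )
    def test_antisymmetry_property(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        s = np.array(scores)
        auc = compute_auc(s, labels)
        assert compute_auc(1.0 - s, labels) == pytest.approx(1.0 - auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])


def _toy_results():
    rows = []
    rng = spawn_rng(3)
    scenarios = [
        "even & high coverage",
        "clumped & high coverage",
        "even & restricted",
        "clumped & restricted",
    ]
    for mode in ("biological", "random"):
        for i, scen in enumerate(scenarios):
            for k in range(5):
                sid = f"sp{mode[:1]}{i}{k}"
                for j, m in enumerate(("A", "B", "C", "D")):
                    rows.append(
                        dict(
                            species_id=sid,
                            method=m,
                            bias_mode=mode,
                            scenario=scen,
                            auc=0.6 + 0.05 * j + 0.01 * rng.random(),
                        )
                    )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_full_factorial_row_count(self):
        s = summarize_by_scenario(_toy_results())
        assert len(s) == 4 * 4 * 2
        assert (s["ci_low"] <= s["mean_auc"]).all()
        assert (s["mean_auc"] <= s["ci_high"]).all()

    def test_group_mean(self):
        df = pd.DataFrame(
            dict(
                species_id=["a", "b"],
                method=["A", "A"],
                bias_mode=["biological"] * 2,
                scenario=["even & high coverage"] * 2,
                auc=[0.8, 0.9],
            )
        )
        s = summarize_by_scenario(df)
        assert s["mean_auc"].iloc[0] == pytest.approx(0.85)

    def test_single_species_collapses_ci_with_warning(self):
        df = pd.DataFrame(
            dict(
                species_id=["a"],
                method=["A"],
                bias_mode=["biological"],
                scenario=["even & restricted"],
                auc=[0.7],
            )
        )
        with pytest.warns(UserWarning):
            s = summarize_by_scenario(df)
        assert s["ci_low"].iloc[0] == s["ci_high"].iloc[0] == 0.7

    def test_aggregation_conserves_species(self):
        res = _toy_results()
        s = summarize_by_scenario(res)
        per_method = s.groupby("method")["n_species"].sum()
        n_expected = res["species_id"].nunique() * 2  # two bias modes... species unique per mode
        assert (per_method == res.groupby("method")["species_id"].count().iloc[0]).all()


class TestRanking:
    def test_strict_winner_counts_all_cells(self):
        s = summarize_by_scenario(_toy_results())
        ranked, top2 = rank_methods(s)
        # method D has the highest auc in every cell by construction
        assert top2["D"] == 8
        assert top2["C"] == 8
        assert top2["A"] == 0

    def test_ties_share_top_rank(self):
        df = pd.DataFrame(
            dict(
                method=["A", "B", "C"],
                scenario=["even & restricted"] * 3,
                bias_mode=["random"] * 3,
                mean_auc=[0.9, 0.9, 0.8],
                ci_low=[0.9, 0.9, 0.8],
                ci_high=[0.9, 0.9, 0.8],
                n_species=[5] * 3,
            )
        )
        ranked, top2 = rank_methods(df)
        assert top2 == {"A": 1, "B": 1, "C": 0}
        # both tied at second would also count: construct that case
        df2 = df.assign(mean_auc=[0.95, 0.9, 0.9])
        _, top2b = rank_methods(df2)
        assert top2b == {"A": 1, "B": 1, "C": 1}


def test_sweep_grid_validation():
    with pytest.raises(ValueError):
        SweepGrid(axis="nonsense", levels=(1, 2))
    with pytest.raises(ValueError):
        SweepGrid(axis="mesh_cutoff", levels=(1,))
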