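"""K-S shift machinery, checked against brute-force ECDF and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trapshift.errors import ValidationError
from trapshift.target_shift import (
    AnalysisConfig,
    abundance_window,
    ks_two_sample,
    random_set_null,
    shift_test,
)


def brute_force_d(x, y):
    """sup |ECDF_x - ECDF_y| evaluated naively at every pooled point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def _de_table(base_means, lfcs=None):
    genes = [f"g{i}" for i in range(len(base_means))]
    lfcs = lfcs if lfcs is not None else np.zeros(len(base_means))
    return pd.DataFrame(
        {"baseMean": base_means, "log2FoldChange": lfcs}, index=pd.Index(genes, name="gene_id")
    )


class TestAbundanceWindow:
    def test_closed_interval_keeps_boundary(self):
        table = _de_table([10, 10**2.5, 500, 3000, 10**4.5])
        genes = abundance_window(table, 2.5, 4.25)
        assert list(genes) == ["g1", "g2", "g3"]

    def test_wide_window_keeps_all(self):
        table = _de_table([1, 10, 100])
        assert len(abundance_window(table, -10, 10)) == 3

    def test_empty_window_warns_not_raises(self, caplog):
        table = _de_table([1.0, 2.0])
        with caplog.at_level("WARNING"):
            genes = abundance_window(table, 5, 6)
        assert len(genes) == 0
        assert any("no genes" in r.message for r in caplog.records)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_interleaved_hand_example(self):
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == pytest.approx(0.5)

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0 and p < 0.2

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=25),
        st.lists(st.integers(-5, 5), min_size=1, max_size=25),
    )
    def test_d_matches_brute_force(self, x, y):
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(brute_force_d(x, y), abs=1e-12)

    def test_agrees_with_ties_and_floats(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.choice([0.0, 0.5, 1.0, 2.5], size=rng.integers(1, 40))
            y = rng.normal(size=rng.integers(1, 40))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_force_d(x, y), abs=1e-12)


class TestShiftTest:
    def test_target_equals_window_gives_null(self):
        rng = np.random.default_rng(0)
        table = _de_table(np.full(50, 1000.0), rng.normal(size=50))
        res = shift_test(table, table.index, window=(2.0, 4.0))
        assert res.ks_statistic == 0.0 and res.ks_p == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        n_bg, n_t = 4000, 400
        lfc = np.concatenate([rng.normal(0, 0.5, n_bg), rng.normal(-0.4, 0.5, n_t)])
        table = _de_table(np.full(n_bg + n_t, 1000.0), lfc)
        targets = table.index[n_bg:]
        res = shift_test(table, targets, window=(2.0, 4.0))
        assert res.ks_p < 1e-4
        assert res.median_target_lfc < res.median_background_lfc

    def test_updown_fisher_counts(self):
        lfc = np.array([1.0] * 2 + [-1.0] * 8 + [1.0] * 50 + [-1.0] * 50)
        table = _de_table(np.full(110, 1000.0), lfc)
        res = shift_test(table, table.index[:10], window=(2.0, 4.0))
        assert (res.n_target_up, res.n_target_down) == (2, 8)
        assert (res.n_other_up, res.n_other_down) == (50, 50)
        assert 0 < res.updown_fisher_p <= 1

    def test_few_targets_flagged(self):
        rng = np.random.default_rng(2)
        table = _de_table(np.full(100, 1000.0), rng.normal(size=100))
        res = shift_test(table, table.index[:3], window=(2.0, 4.0))
        assert res.few_targets

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        table = _de_table(np.full(200, 1000.0), rng.normal(size=200))
        targets = list(table.index[:40])
        res1 = shift_test(table, targets, window=(2.0, 4.0))
        shuffled = table.sample(frac=1.0, random_state=1)
        res2 = shift_test(shuffled, targets, window=(2.0, 4.0))
        assert res1.ks_statistic == pytest.approx(res2.ks_statistic)
        assert res1.ks_p == pytest.approx(res2.ks_p)


class TestRandomSetNull:
    def test_deterministic_and_sized(self):
        rng = np.random.default_rng(4)
        table = _de_table(np.full(300, 1000.0), rng.normal(size=300))
        a = random_set_null(table, (2.0, 4.0), set_size=50, k=5, seed=9)
        b = random_set_null(table, (2.0, 4.0), set_size=50, k=5, seed=9)
        assert len(a) == 5 and a == b

    def test_oversized_set_rejected(self):
        table = _de_table(np.full(10, 1000.0), np.zeros(10))
        with pytest.raises(ValidationError):
            random_set_null(table, (2.0, 4.0), set_size=11, k=1)


class TestAnalysisConfig:
    def test_default_windows(self):
        cfg = AnalysisConfig()
        assert cfg.windows["Input"] == (2.5, 4.25)
        assert cfg.windows["IP"] == (2.75, 4.75)
        assert cfg.n_random_sets == 5 and cfg.fdr == 0.1 and cfg.clan_alpha == 0.01

    def test_inverted_window_rejected(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(windows={"IP": (4.0, 2.0)})
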