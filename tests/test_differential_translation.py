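"""NB GLM differential-expression stage: oracles, recovery and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trapshift.differential_translation import (
    DEConfig,
    bh_adjust,
    design_matrix,
    estimate_dispersions,
    fit_nb_glm,
    run_de,
)
from trapshift.errors import DesignError, ValidationError
from trapshift.io_formats import CountMatrix, SampleSheet


def bh_oracle(p):
    """Textbook step-up: padj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        out[i] = running
    return out


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_nan_propagates_and_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_textbook_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(200)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)


def _sheet(n_pairs, fraction="IP"):
    rows = []
    for pair in range(1, n_pairs + 1):
        for geno in ("WT", "KO"):
            rows.append(
                {
                    "sample_id": f"P{pair}_{geno}",
                    "fraction": fraction,
                    "genotype": geno,
                    "pair_id": pair,
                    "animal_id": f"P{pair}_{geno}",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


class TestDesignMatrix:
    def test_paired_shapes_and_genotype_last(self):
        x, names = design_matrix(_sheet(6), "paired")
        assert x.shape == (12, 7)
        assert names[-1] == "genotype_KO"

    def test_single_pair_rejected(self):
        with pytest.raises(DesignError):
            design_matrix(_sheet(1), "paired")

    def test_unpaired(self):
        x, names = design_matrix(_sheet(3), "unpaired")
        assert x.shape == (6, 2)


class TestFitNbGlm:
    def test_two_group_poisson_ratio_oracle(self):
        # alpha -> 0 and large counts: genotype coefficient is the log ratio
        rng = np.random.default_rng(1)
        sheet = _sheet(6)
        x, _ = design_matrix(sheet, "unpaired")
        is_ko = sheet.table["genotype"].to_numpy() == "KO"
        y = np.where(is_ko, rng.poisson(200, 12), rng.poisson(100, 12))[None, :]
        beta, se, conv = fit_nb_glm(y, x, np.ones(12), np.array([1e-12]))
        assert conv[0]
        # closed form for the saturated 2-group Poisson fit
        expected = np.log(y[0, is_ko].mean() / y[0, ~is_ko].mean())
        assert beta[0, 1] == pytest.approx(expected, rel=1e-6)
        assert abs(beta[0, 1] - np.log(2)) < 0.05 * np.log(2) * 3

    def test_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        sheet = _sheet(6)
        x, _ = design_matrix(sheet, "paired")
        alpha = 0.05
        mu = 150 * np.exp(x @ rng.normal(0, 0.2, x.shape[1]))
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))[None, :]
        beta, se, conv = fit_nb_glm(y, x, np.ones(12), np.array([alpha]))
        ref = sm.GLM(y[0], x, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.allclose(beta[0], ref.params, atol=1e-4)
        assert np.allclose(se[0], ref.bse, rtol=1e-3)

    def test_identical_groups_near_zero_coefficient(self):
        rng = np.random.default_rng(3)
        sheet = _sheet(6)
        x, _ = design_matrix(sheet, "unpaired")
        y = rng.poisson(100, size=(500, 12)).astype(float)
        beta, se, conv = fit_nb_glm(y, x, np.ones(12), np.full(500, 1e-12))
        wald = beta[:, 1] / se[:, 1]
        assert np.mean(np.abs(wald) < 3) >= 0.99

    def test_offsets_absorb_size_factors(self):
        # doubling one sample's counts while giving it size factor 2 leaves
        # the group contrast approximately unchanged (exactly so only in the
        # large-count limit, since the doubled sample carries more weight)
        rng = np.random.default_rng(4)
        sheet = _sheet(4)
        x, _ = design_matrix(sheet, "unpaired")
        y = rng.poisson(100, size=(50, 8)).astype(float)
        b1, *_ = fit_nb_glm(y, x, np.ones(8), np.full(50, 1e-12))
        s = np.full(8, 1.0)
        s[0] = 2.0
        y2 = y.copy()
        y2[:, 0] *= 2
        b2, *_ = fit_nb_glm(y2, x, s, np.full(50, 1e-12))
        assert np.allclose(b1[:, 1], b2[:, 1], atol=0.05)
        assert np.mean(np.abs(b1[:, 1] - b2[:, 1])) < 0.02


class TestEstimateDispersions:
    def test_poisson_counts_shrink_to_small_alpha(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(100, 2000, 3000)
        y = rng.poisson(mu[:, None], size=(3000, 24)).astype(float)
        groups = np.array(["WT", "KO"] * 12)
        fit = estimate_dispersions(y, np.ones(24), groups)
        assert np.median(fit.alpha_final) <= 0.01

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(200, 2000, 2000)
        alpha = 0.1
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu[:, None]), size=(2000, 24))
        groups = np.array(["WT", "KO"] * 12)
        fit = estimate_dispersions(y.astype(float), np.ones(24), groups)
        assert 0.05 <= np.median(fit.alpha_final) <= 0.2

    def test_constant_counts_floored(self):
        y = np.full((5, 24), 100.0)
        groups = np.array(["WT", "KO"] * 12)
        fit = estimate_dispersions(y, np.ones(24), groups)
        assert np.all(fit.alpha_gene <= 1e-8 * 1.01)

    def test_final_alpha_within_band(self, small_sim):
        from trapshift.quantification import size_factors

        sheet = small_sim.samples.subset(fraction="IP")
        cm = small_sim.counts.subset_samples(sheet.sample_ids)
        sf = size_factors(cm).to_numpy()
        raw = cm.counts.to_numpy(float)
        keep = raw.sum(axis=1) > 0
        fit = estimate_dispersions(raw[keep], sf, sheet.table["genotype"].to_numpy())
        lo = np.minimum(fit.alpha_gene, fit.alpha_trend) / 10
        hi = np.maximum(fit.alpha_gene, fit.alpha_trend) * 10
        assert np.all(fit.alpha_final >= lo - 1e-12)
        assert np.all(fit.alpha_final <= hi + 1e-12)


class TestRunDe:
    def test_recovery_on_planted_simulation(self, small_sim):
        de = run_de(small_sim.counts, small_sim.samples, fraction="IP")
        sig = set(de.significant)
        planted = small_sim.truth.up_genes | small_sim.truth.down_genes
        sens = len(sig & planted) / len(planted)
        assert sens >= 0.8
        # direction agrees with the planted sign
        lfc = de.table["log2FoldChange"]
        assert (lfc.loc[sorted(small_sim.truth.up_genes)] > 0).mean() > 0.9
        assert (lfc.loc[sorted(small_sim.truth.down_genes)] < 0).mean() > 0.9

    def test_ip_only_effects_silent_in_input(self):
        # IP-only planted effects must leave the Input fraction null: the
        # planted genes' Input p-values match the other null genes', and
        # their fold changes are pure estimation noise. Aggregated over
        # three replicates since each carries only 40 planted genes.
        from trapshift.synthetic_data import SimConfig, generate
        from trapshift.target_shift import ks_two_sample

        ks_ps = []
        lfc_ratios = []
        for seed in (1, 2, 3):
            sim = generate(
                SimConfig(
                    n_genes=2000, n_pairs=6, seed=seed, n_up=30, n_down=10,
                    target_size=200, n_clans=20,
                )
            )
            de = run_de(sim.counts, sim.samples, fraction="Input")
            planted = sorted(sim.truth.up_genes | sim.truth.down_genes)
            null_table = de.table.drop(index=list(sim.truth.target_genes) + planted)
            comparable = null_table[null_table["baseMean"] >= 100]
            med_planted = np.nanmedian(np.abs(de.table.loc[planted, "log2FoldChange"]))
            med_null = np.nanmedian(np.abs(comparable["log2FoldChange"]))
            lfc_ratios.append(med_planted / med_null)
            _, p = ks_two_sample(
                de.table.loc[planted, "pvalue"].dropna(), null_table["pvalue"].dropna()
            )
            ks_ps.append(p)
        assert np.median(ks_ps) > 0.05
        assert min(ks_ps) > 1e-4
        assert np.median(lfc_ratios) < 1.5

    def test_all_zero_gene_not_tested(self, small_sim):
        counts = small_sim.counts.counts.copy()
        counts.iloc[0] = 0
        de = run_de(CountMatrix(counts), small_sim.samples, fraction="IP")
        row = de.table.iloc[0]
        assert not row["tested"] and np.isnan(row["pvalue"])

    def test_padj_at_least_p_and_wald_consistency(self, small_sim):
        de = run_de(small_sim.counts, small_sim.samples, fraction="IP")
        t = de.table[de.table["tested"]]
        assert (t["padj"] >= t["pvalue"] - 1e-12).all()
        assert t["padj"].between(0, 1).all()
        assert np.allclose(t["stat"] * t["lfcSE"], t["log2FoldChange"], rtol=1e-8)

    def test_sample_order_permutation_invariance(self, small_sim):
        de1 = run_de(small_sim.counts, small_sim.samples, fraction="IP")
        perm = small_sim.samples.table.sample(frac=1.0, random_state=7)
        sheet = SampleSheet(perm.reset_index(drop=True))
        de2 = run_de(small_sim.counts, sheet, fraction="IP")
        pd.testing.assert_frame_equal(de1.table, de2.table, rtol=1e-8, atol=1e-10)

    def test_fraction_restriction_required_columns(self, small_sim):
        de = run_de(small_sim.counts, small_sim.samples, fraction="IP")
        assert {"baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj", "tested"} <= set(
            de.table.columns
        )
        assert len(de.size_factors) == 12
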