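import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xbias import (
    GeneCatalog,
    QpcrTable,
    SimConfig,
    TimeCourse,
    fold_change_vs_earliest,
    generate_catalog,
    generate_timecourse,
    normalize_arrays,
    qpcr_relative,
    quantile_normalize,
    upregulated_set,
    x_vs_autosome_profile,
)
from xbias.errors import UsageError, ValidationError
from xbias.timecourse import estimate_variance_prior, squeeze_variances


def make_timecourse(values, days, n_rep):
    """values: genes × conditions expected means; replicates identical."""
    cols, meta = {}, {}
    for j, day in enumerate(days):
        for r in range(1, n_rep + 1):
            name = f"d{day}f_r{r}"
            cols[name] = values[:, j]
            meta[name] = {"day": day, "stage": "feeding", "replicate": r}
    frame = pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id"))
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample"
    return TimeCourse(frame, samples)


class TestQuantileNormalize:
    def test_scalar_multiple_columns_become_identical(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(3, 1, 50)
        frame = pd.DataFrame({"s1": a, "s2": 3.7 * a})
        out = quantile_normalize(np.log2(frame))
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_identical_distributions_unchanged(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        frame = pd.DataFrame({"s1": a, "s2": a[::-1]})
        out = quantile_normalize(frame)
        np.testing.assert_allclose(np.sort(out["s1"]), a)
        np.testing.assert_allclose(out["s2"], a[::-1])

    def test_column_means_equalized(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.lognormal(2, 1, (100, 4)), columns=list("abcd"))
        out = quantile_normalize(frame)
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0])

    def test_normalize_arrays_rejects_nonpositive(self):
        tc = make_timecourse(np.full((3, 2), 2.0), [4, 5], 2)
        tc.frame.iloc[0, 0] = 0.0
        with pytest.raises(ValidationError):
            normalize_arrays(tc)


class TestModeratedT:
    def test_constant_gene_has_zero_t_and_p_one(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, (50, 2))
        values[0] = [5.0, 5.0]  # identical at both conditions
        tc = make_timecourse(2.0 ** values, [4, 7], 3)
        # replicate noise for the other genes so variances exist; skip
        # normalization so g0's replicates stay exactly identical
        noisy = tc.frame.to_numpy().copy()
        noisy[1:] *= rng.lognormal(0, 0.1, noisy[1:].shape)
        log_tc = TimeCourse(
            np.log2(pd.DataFrame(noisy, index=tc.frame.index, columns=tc.frame.columns)),
            tc.samples,
        )
        fc = fold_change_vs_earliest(log_tc)
        assert fc.log2fc.iloc[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert fc.t.iloc[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert fc.p.iloc[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_ordinary_t_limit_matches_scipy(self):
        rng = np.random.default_rng(3)
        n_genes = 40
        g1 = rng.normal(8, 1, (n_genes, 3))
        g2 = rng.normal(8.5, 1, (n_genes, 3))
        values = np.concatenate([g1, g2], axis=1)
        cols, meta = {}, {}
        for j in range(6):
            day = 4 if j < 3 else 7
            name = f"d{day}f_r{j % 3 + 1}"
            cols[name] = 2.0 ** values[:, j]
            meta[name] = {"day": day, "stage": "feeding", "replicate": j % 3 + 1}
        frame = pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"))
        samples = pd.DataFrame.from_dict(meta, orient="index")
        tc = TimeCourse(frame, samples)
        log_tc = TimeCourse(np.log2(frame), samples)
        fc = fold_change_vs_earliest(log_tc, moderated=False)
        t_ref, p_ref = stats.ttest_ind(values[:, 3:], values[:, :3], axis=1)
        np.testing.assert_allclose(fc.t.iloc[:, 0], t_ref, rtol=1e-9)
        np.testing.assert_allclose(fc.p.iloc[:, 0], p_ref, rtol=1e-9)

    def test_infinite_prior_degenerates_to_pooled_z(self):
        s2 = np.array([0.5, 1.0, 2.0])
        squeezed = squeeze_variances(s2, df=4, d0=np.inf, s02=1.3)
        np.testing.assert_allclose(squeezed, 1.3)

    def test_variance_prior_recovered_from_scaled_f_sample(self):
        # draw gene variances from the assumed hierarchy and re-estimate
        rng = np.random.default_rng(4)
        d0_true, s02_true, df = 8.0, 0.7, 4
        sigma2 = d0_true * s02_true / rng.chisquare(d0_true, 20000)
        s2 = sigma2 * rng.chisquare(df, 20000) / df
        d0_hat, s02_hat = estimate_variance_prior(s2, df)
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s02_hat == pytest.approx(s02_true, rel=0.05)

    def test_fold_changes_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(5)
        values = rng.normal(8, 1, (30, 2))
        noise = rng.lognormal(0, 0.1, (30, 6))
        tc = make_timecourse(2.0 ** values, [4, 7], 3)
        frame = tc.frame * noise
        fwd = fold_change_vs_earliest(_norm(TimeCourse(frame, tc.samples)))
        swapped_meta = tc.samples.copy()
        swapped_meta["day"] = swapped_meta["day"].map({4: 7, 7: 4})
        rev = fold_change_vs_earliest(_norm(TimeCourse(frame, swapped_meta)))
        np.testing.assert_allclose(
            fwd.log2fc.iloc[:, 0], -rev.log2fc.iloc[:, 0], atol=1e-9
        )


def _norm(tc: TimeCourse) -> TimeCourse:
    return normalize_arrays(tc)


class TestUpregulatedSet:
    def test_all_q_one_empty(self):
        rng = np.random.default_rng(6)
        base = rng.normal(8, 1, (20, 1))
        values = np.repeat(base, 2, axis=1)  # identical conditions
        noise = rng.lognormal(0, 0.2, (20, 6))
        tc = make_timecourse(2.0 ** values, [4, 7], 3)
        fc = fold_change_vs_earliest(_norm(TimeCourse(tc.frame * noise, tc.samples)))
        up = upregulated_set(fc, q_threshold=0.1)
        assert len(up) <= 2  # essentially nothing under the null

    def test_downregulated_significant_gene_excluded(self):
        rng = np.random.default_rng(7)
        values = rng.normal(8, 0.5, (30, 2))
        values[0, 1] = values[0, 0] - 4  # strong DOWN-regulation
        noise = rng.lognormal(0, 0.05, (30, 6))
        tc = make_timecourse(2.0 ** values, [4, 7], 3)
        fc = fold_change_vs_earliest(_norm(TimeCourse(tc.frame * noise, tc.samples)))
        up = upregulated_set(fc, q_threshold=0.1)
        assert "g0" not in up
        assert fc.q.loc["g0"].min() < 0.1  # it *is* significant, just negative

    def test_planted_activation_recovered_with_high_sensitivity(self):
        cfg = SimConfig(
            n_genes=2000,
            activation_fraction=0.2,
            trajectory_slope_range=(0.5, 1.0),
            noise_cv=0.1,
            seed=10,
        )
        catalog, truth = generate_catalog(cfg)
        tc = generate_timecourse(catalog, truth, cfg)
        fc = fold_change_vs_earliest(normalize_arrays(tc))
        up = upregulated_set(fc)
        activated = set(truth.index[truth.activated])
        sensitivity = len(up & activated) / len(activated)
        fdr = len(up - activated) / max(len(up), 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.1


class TestXvsAutosomeProfile:
    def test_group_swap_negates_median_difference(self, small_sim):
        catalog, truth = generate_catalog(small_sim)
        tc = normalize_arrays(generate_timecourse(catalog, truth, small_sim))
        prof = x_vs_autosome_profile(tc, catalog)
        swapped = GeneCatalog(
            catalog.frame.assign(
                arm=np.where(catalog.frame["arm"] == "X", "2L", "X")
            )
        )
        prof_swapped = x_vs_autosome_profile(tc, swapped)
        np.testing.assert_allclose(
            prof["median_diff"], -prof_swapped["median_diff"], atol=1e-12
        )

    def test_planted_global_x_downregulation_detected(self):
        rng = np.random.default_rng(11)
        n = 2000
        arms = np.array(["X"] * 1000 + ["2L"] * 1000)
        catalog = GeneCatalog(
            pd.DataFrame({"arm": arms}, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
        )
        base = rng.normal(8, 1, (n, 1))
        values = np.repeat(base, 2, axis=1)
        values[arms == "X", 1] -= 1.0  # 2x X down at the later timepoint
        tc = make_timecourse(2.0 ** values, [4, 7], 3)
        noise = rng.lognormal(0, 0.1, tc.frame.shape)
        prof = x_vs_autosome_profile(
            normalize_arrays(TimeCourse(tc.frame * noise, tc.samples)), catalog
        )
        later = prof[prof["day"] == 7].iloc[0]
        assert later["p"] < 0.01
        assert later["median_diff"] < -0.5

    def test_empty_group_rejected(self, small_sim):
        catalog, truth = generate_catalog(small_sim)
        tc = normalize_arrays(generate_timecourse(catalog, truth, small_sim))
        all_auto = GeneCatalog(catalog.frame.assign(arm="2L"))
        with pytest.raises(UsageError):
            x_vs_autosome_profile(tc, all_auto)


class TestQpcr:
    def make_table(self):
        rows = []
        for sample, ct in [("pupae", 25.0), ("d5", 22.0), ("d7", 20.0)]:
            rows.append(
                {"gene_id": "Sdic", "sample_id": sample, "ct_target": ct, "ct_reference": 15.0}
            )
        return QpcrTable(pd.DataFrame(rows))

    def test_reference_sample_is_exactly_one(self):
        rel = qpcr_relative(self.make_table(), "pupae")
        ref_row = rel[rel["sample_id"] == "pupae"].iloc[0]
        assert ref_row["relative_expression"] == pytest.approx(1.0)

    def test_three_cycle_advance_is_eightfold(self):
        rel = qpcr_relative(self.make_table(), "pupae")
        d5 = rel[rel["sample_id"] == "d5"].iloc[0]
        assert d5["ddct"] == pytest.approx(-3.0)
        assert d5["relative_expression"] == pytest.approx(8.0)

    def test_loading_control_shift_invariance(self):
        table = self.make_table()
        shifted = QpcrTable(
            table.frame.assign(
                ct_target=table.frame["ct_target"] + 1,
                ct_reference=table.frame["ct_reference"] + 1,
            )
        )
        a = qpcr_relative(table, "pupae")["relative_expression"]
        b = qpcr_relative(shifted, "pupae")["relative_expression"]
        np.testing.assert_allclose(a, b)

    def test_missing_reference_sample_rejected(self):
        table = self.make_table()
        with pytest.raises(ValidationError):
            qpcr_relative(table, "larvae")
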