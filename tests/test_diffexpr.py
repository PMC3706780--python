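"""Contrast statistics, the Bayes-regularized ANOVA, gene-list selection,
interaction quadrants, and the vulnerability/protection classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hippocomp as hc
from hippocomp import diffexpr as de
from conftest import make_matrix, make_phenotypes


def _matrix_from_log2(log2_values, **kwargs):
    """Build a matrix whose log2(x+1) equals the given values exactly."""
    return make_matrix(np.exp2(np.asarray(log2_values, dtype=float)) - 1.0, **kwargs)


class TestContrast:
    def test_unpaired_t_matches_textbook_pooled_formula(self):
        a, b = np.array([10.0, 12.0, 14.0]), np.array([20.0, 22.0, 24.0])
        log2v = np.vstack([np.concatenate([a, b])])
        m = _matrix_from_log2(log2v)
        ph = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(6)],
            "subject_id": [f"u{j}" for j in range(6)],
            "region": ["CA1"] * 6,
            "diagnosis": ["AD"] * 3 + ["control"] * 3,
            "braak": 5, "plaque": 2, "age": 80.0, "sex": "M", "pmi": 10.0, "batch": "b",
        })
        ph = hc.validate_phenotypes(ph)
        res = de.contrast(m, ph, by="diagnosis", groups=("AD", "control"))
        # independent closed form: pooled variance t with 4 df
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert res.table["t"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_paired_identical_groups_null_result(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(5, 10, size=(20, 1))
        log2v = np.tile(profile, (1, 8))  # CA1 == CA3 for every subject
        m = _matrix_from_log2(log2v)
        ph = make_phenotypes(n_subjects=4, n_control=4)
        m.values.columns = ph.index
        res = de.contrast(m, ph, by="region", groups=("CA1", "CA3"), paired=True)
        assert (res.table["t"] == 0).all()
        assert (res.table["p"] == 1).all()
        assert (res.table["fc_signed"] == 1).all()

    def test_fc_ratio_convention(self):
        assert de.signed_fc([200.0], [100.0])[0] == pytest.approx(2.0)
        assert de.signed_fc([100.0], [200.0])[0] == pytest.approx(-2.0)

    def test_fc_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(10, 1000, 50), rng.uniform(10, 1000, 50)
        np.testing.assert_allclose(de.signed_fc(a, b), -de.signed_fc(b, a))
        np.testing.assert_allclose(de.signed_fc(3.7 * a, 3.7 * b), de.signed_fc(a, b))

    def test_z_score_is_signed_normal_quantile(self, standard_contrasts):
        t = standard_contrasts["disease_ca1"].table
        finite = t[np.isfinite(t["z"]) & (t["t"] != 0)]
        expected = np.sign(finite["t"]) * stats.norm.isf(finite["p"] / 2)
        np.testing.assert_allclose(finite["z"], expected, rtol=1e-10)

    def test_permuted_labels_give_uniform_p(self):
        """Null calibration: permuting group labels yields uniform p-values."""
        rng = np.random.default_rng(7)
        m = _matrix_from_log2(rng.normal(8, 1, size=(1000, 20)))
        ph = make_phenotypes(n_subjects=10, n_control=5)
        labels = rng.permutation(["AD"] * 10 + ["control"] * 10)
        ph = ph.copy()
        ph["diagnosis"] = labels
        ph = ph.drop(columns=[]).iloc[:20]
        m.values.columns = ph.index
        res = de.contrast(m, ph, by="diagnosis", groups=("AD", "control"))
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_braak_contrast_pools_regions(self, preprocessed_study):
        mm, ph, truth, _ = preprocessed_study
        res = de.contrast(mm, ph, by="braak", groups=(2, 1),
                          subset={"diagnosis": "control"})
        n_used = (ph["diagnosis"] == "control").sum()
        # both regions of every control subject enter the comparison
        assert res.table.shape[0] == mm.n_probes
        assert res.groups == (2, 1)
        # microglia module genes rise from Braak 1 to 2 in controls
        microglia = truth.genes.index[truth.genes["module"] == "microglia"]
        microglia = [g for g in microglia if g in res.table.index]
        assert res.table.loc[microglia, "t"].median() > 0

    def test_too_few_samples_error(self):
        m = _matrix_from_log2(np.ones((3, 4)) * 8)
        ph = make_phenotypes(n_subjects=2, n_control=1)
        m.values.columns = ph.index
        with pytest.raises(ValueError, match=">=2 samples"):
            de.contrast(m, ph, by="diagnosis", groups=("AD", "control"),
                        subset={"region": "CA1"})


class TestSelectGenes:
    def _result(self, p, fc, mean=2000.0):
        table = pd.DataFrame({
            "gene": [f"G{i}" for i in range(len(p))], "t": 1.0, "p": p, "q": p,
            "fc_signed": fc, "fc_median_signed": fc,
            "mean_a": mean, "mean_b": mean, "median_a": mean, "median_b": mean,
            "z": 1.0,
        }, index=[f"probe{i}" for i in range(len(p))])
        return de.ContrastResult(table, "test", False, ("a", "b"))

    def test_inclusion_and_fc_boundary(self):
        res = self._result(p=[0.04, 0.04, 0.04], fc=[1.25, 1.15, -1.3])
        assert de.select_genes(res, direction="up") == ["G0"]
        assert de.select_genes(res, direction="down") == ["G2"]
        assert "G1" not in de.select_genes(res)  # fc 1.15 <= 1.2 cut

    def test_tiny_p_cut_empty(self):
        res = self._result(p=[0.04], fc=[2.0])
        th = de.GeneListThresholds(p_cut=1e-9)
        assert de.select_genes(res, th) == []

    def test_expression_and_significance_filters(self):
        res = self._result(p=[0.04, 0.001, 0.04], fc=[1.5, 1.5, 1.5], mean=500.0)
        assert de.select_genes(res, highly_expressed=True) == []
        assert de.select_genes(res, very_significant=True) == ["G1"]


class TestBayesAnova:
    def _four_group_setup(self, n_genes=20, seed=0):
        rng = np.random.default_rng(seed)
        ph = make_phenotypes(n_subjects=12, n_control=6)
        m = _matrix_from_log2(rng.normal(8, 1, size=(n_genes, 24)))
        m.values.columns = ph.index
        return m, ph

    def test_conf_zero_equals_classical_anova(self):
        m, ph = self._four_group_setup()
        res = de.bayes_anova(m, ph, conf=0.0, win_size=5)
        groups = ph["diagnosis"].str[:1].str.upper() + ph["region"].str[-1]
        x = m.log2()
        for i, probe in enumerate(m.values.index):
            cells = [x.loc[probe, groups.index[groups == g]] for g in sorted(groups.unique())]
            f_classical, p_classical = stats.f_oneway(*cells)
            assert res["F"].iloc[i] == pytest.approx(f_classical, rel=1e-10)
            assert res["p"].iloc[i] == pytest.approx(p_classical, rel=1e-8)

    def test_matches_double_loop_oracle(self):
        """Gene-by-gene brute-force implementation of the windowed shrinkage."""
        m, ph = self._four_group_setup(seed=3)
        conf, win = 12.0, 5
        res = de.bayes_anova(m, ph, conf=conf, win_size=win)
        groups = (ph["diagnosis"].str[:1].str.upper() + ph["region"].str[-1]).loc[m.sample_ids]
        x = m.log2().to_numpy()
        levels = sorted(groups.unique())
        ng = m.n_probes
        stats_by_level = {}
        for lev in levels:
            idx = np.flatnonzero((groups == lev).to_numpy())
            stats_by_level[lev] = (x[:, idx].mean(1), x[:, idx].var(1, ddof=1), len(idx))
        for g in range(ng):
            ss_between = ss_within = 0.0
            n_tot = sum(n for _, _, n in stats_by_level.values())
            grand = sum(n * mu[g] for mu, _, n in stats_by_level.values()) / n_tot
            df_den = -len(levels)
            for lev in levels:
                mu, var, n = stats_by_level[lev]
                order = np.argsort(mu, kind="mergesort")
                pos = int(np.where(order == g)[0][0])
                start = min(max(0, pos - win // 2), ng - win)
                background = var[order[start:start + win]].mean()
                ss_between += n * (mu[g] - grand) ** 2
                ss_within += conf * background + (n - 1) * var[g]
                df_den += conf + n
            f_expected = (ss_between / (len(levels) - 1)) / (ss_within / df_den)
            assert res["F"].iloc[g] == pytest.approx(f_expected, rel=1e-10)

    def test_large_conf_approaches_background_variance(self):
        m, ph = self._four_group_setup(seed=4)
        res_huge = de.bayes_anova(m, ph, conf=1e9, win_size=m.n_probes)
        res_mod = de.bayes_anova(m, ph, conf=12, win_size=m.n_probes)
        # with conf -> inf and a full-width window, all genes share one
        # within-group variance, so F becomes proportional to SS_between
        groups = ph["diagnosis"].str[:1].str.upper() + ph["region"].str[-1]
        x = m.log2()
        ssb = []
        for probe in m.values.index:
            cells = [x.loc[probe, groups.index[groups == g]] for g in sorted(groups.unique())]
            grand = np.concatenate(cells).mean()
            ssb.append(sum(len(c) * (c.mean() - grand) ** 2 for c in cells))
        r = np.corrcoef(res_huge["F"], ssb)[0, 1]
        assert r > 0.999999

    def test_parameter_validation(self):
        m, ph = self._four_group_setup()
        with pytest.raises(ValueError, match="win_size"):
            de.bayes_anova(m, ph, win_size=m.n_probes + 1)
        with pytest.raises(ValueError, match="conf"):
            de.bayes_anova(m, ph, conf=-1)

    def test_null_calibration_conf_zero(self):
        rng = np.random.default_rng(11)
        ph = make_phenotypes(n_subjects=16, n_control=8)
        m = _matrix_from_log2(rng.normal(8, 1, size=(2000, 32)))
        m.values.columns = ph.index
        res = de.bayes_anova(m, ph, conf=0.0, win_size=11)
        rate = (res["p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.015)


def _mock_contrast(fc, fc_median=None, p=0.001, genes=None):
    fc = np.asarray(fc, dtype=float)
    fc_median = fc if fc_median is None else np.asarray(fc_median, dtype=float)
    idx = [f"probe{i}" for i in range(len(fc))]
    table = pd.DataFrame({
        "gene": genes or [f"G{i}" for i in range(len(fc))],
        "t": np.sign(fc), "p": np.full(len(fc), p), "q": p,
        "fc_signed": fc, "fc_median_signed": fc_median,
        "mean_a": 100.0, "mean_b": 100.0, "median_a": 100.0, "median_b": 100.0,
        "z": np.sign(fc),
    }, index=idx)
    return de.ContrastResult(table, "mock", False, ("a", "b"))


class TestClassifyVulnerability:
    def test_printed_vulnerability_pattern(self):
        region = _mock_contrast([1.5])
        ca1 = _mock_contrast([1.3])
        ca3 = _mock_contrast([1.05])
        bayes_p = pd.Series([0.01], index=region.table.index)
        out = de.classify_vulnerability(region, ca1, ca3, bayes_p)
        assert out["class"].iloc[0] == "vulnerability"

    def test_printed_protection_pattern(self):
        region = _mock_contrast([-1.5])  # CA3-enriched
        ca1 = _mock_contrast([1.1])
        ca3 = _mock_contrast([1.3])
        bayes_p = pd.Series([0.02], index=region.table.index)
        out = de.classify_vulnerability(region, ca1, ca3, bayes_p)
        assert out["class"].iloc[0] == "protection"

    def test_bayes_gate_and_median_requirement(self):
        region = _mock_contrast([1.5], fc_median=[1.5])
        ca1 = _mock_contrast([1.3], fc_median=[1.3])
        ca3 = _mock_contrast([1.05], fc_median=[1.05])
        high_bayes = pd.Series([0.2], index=region.table.index)
        out = de.classify_vulnerability(region, ca1, ca3, high_bayes)
        assert out["class"].iloc[0] == "none"
        # median-based FC failing the cut blocks the call
        ca1_bad_median = _mock_contrast([1.3], fc_median=[1.1])
        ok_bayes = pd.Series([0.01], index=region.table.index)
        out = de.classify_vulnerability(region, ca1_bad_median, ca3, ok_bayes)
        assert out["class"].iloc[0] == "none"

    def test_protection_decreasing_branch_rules(self):
        region = _mock_contrast([-1.5, -1.5, -1.5])
        ca1 = _mock_contrast([-1.6, -1.05, -1.3])
        ca3 = _mock_contrast([-1.3, -1.02, -2.0])
        bayes_p = pd.Series(0.01, index=region.table.index)
        out = de.classify_vulnerability(region, ca1, ca3, bayes_p)
        # gene0: material CA1 decrease, CA3 decreases less -> protection
        assert out["class"].iloc[0] == "protection"
        # gene1: both decreases at the noise floor -> not protection
        assert out["class"].iloc[1] == "none"
        # gene2: CA3 decreases far more than 1.4x CA1 -> not protection
        assert out["class"].iloc[2] == "none"
        strict = de.classify_vulnerability(region, ca1, ca3, bayes_p,
                                           protection_rule="strict")
        # under the strict reading gene0 needs 1.4*1.3 < 1.6, which fails
        assert strict["class"].iloc[0] == "none"

    def test_never_both_labels(self, preprocessed_study, standard_contrasts):
        mm, ph, _, _ = preprocessed_study
        bayes = de.bayes_anova(mm, ph)
        out = de.classify_vulnerability(
            standard_contrasts["region_control"], standard_contrasts["disease_ca1"],
            standard_contrasts["disease_ca3"], bayes["p"])
        vul = out["class"] == "vulnerability"
        pro = out["class"] == "protection"
        assert not (vul & pro).any()
        # the exclusive region clause makes the flag combination impossible too
        assert not (out["vulnerability_fc_mean"] & out["protection_fc_mean"]).any()

    def test_ground_truth_recovery_zero_noise(self):
        cfg = hc.SimulationConfig(seed=13, noise_sd=0.0, n_genes=1000)
        m, ph, truth = hc.generate_dataset(cfg)
        mm, _ = hc.preprocess_pipeline(m)
        ph = ph.loc[mm.sample_ids]
        region = de.contrast(mm, ph, by="region", groups=("CA1", "CA3"),
                             subset={"diagnosis": "control"}, paired=True)
        ca1 = de.contrast(mm, ph, by="diagnosis", groups=("AD", "control"),
                          subset={"region": "CA1"})
        ca3 = de.contrast(mm, ph, by="diagnosis", groups=("AD", "control"),
                          subset={"region": "CA3"})
        bayes = de.bayes_anova(mm, ph)
        out = de.classify_vulnerability(region, ca1, ca3, bayes["p"])
        got_v = set(out.index[out["class"] == "vulnerability"])
        got_p = set(out.index[out["class"] == "protection"])
        assert got_v == set(truth.genes_with_role("vulnerability")) & set(mm.values.index)
        assert got_p == set(truth.genes_with_role("protection")) & set(mm.values.index)

    def test_missing_median_errors(self):
        region = _mock_contrast([1.5])
        broken = _mock_contrast([1.3])
        broken.table = broken.table.drop(columns=["fc_median_signed"])
        bayes_p = pd.Series([0.01], index=region.table.index)
        with pytest.raises(ValueError, match="median"):
            de.classify_vulnerability(region, broken, region, bayes_p)


class TestInteractionQuadrants:
    def test_identical_t_vectors_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        fc = rng.choice([-2.0, 2.0], size=200)
        res = _mock_contrast(fc, p=0.2)
        res.table["t"] = rng.normal(size=200)
        out = de.interaction_quadrants(res, res)
        assert out["t_correlation"] == pytest.approx(1.0)

    def test_constructed_table_matches_hypergeometric_sum(self):
        """Fisher's two-sided p on a 2x2 table equals the exact sum of
        hypergeometric point masses no larger than the observed one."""
        a, b, c = 40, 60, 60  # margins 100/100 of universe 1000
        d = 1000 - a - b - c
        _, p_fisher = stats.fisher_exact([[a, b], [c, d]], "two-sided")
        # independent enumeration over all tables with the same margins
        row1, col1, total = a + b, a + c, a + b + c + d
        support = range(max(0, row1 + col1 - total), min(row1, col1) + 1)
        pmf = {k: stats.hypergeom.pmf(k, total, col1, row1) for k in support}
        p_enum = sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-7))
        assert p_fisher == pytest.approx(p_enum, rel=1e-8)
        # and the quadrant routine reproduces the same fisher p
        rng = np.random.default_rng(8)
        # build p/t vectors realizing exactly that table in one quadrant
        n = 1000
        region_sig = np.zeros(n, bool); region_sig[:row1] = True
        disease_sig = np.zeros(n, bool); disease_sig[:a] = True
        disease_sig[row1:row1 + c] = True
        table = pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)],
            "t": 1.0, "p": np.where(region_sig, 0.01, 0.5), "q": 0.5,
            "fc_signed": 1.5, "fc_median_signed": 1.5,
            "mean_a": 10.0, "mean_b": 10.0, "median_a": 10.0, "median_b": 10.0,
            "z": 1.0}, index=[f"pr{i}" for i in range(n)])
        region = de.ContrastResult(table.copy(), "r", False, ("a", "b"))
        dtable = table.copy()
        dtable["p"] = np.where(disease_sig, 0.01, 0.5)
        disease = de.ContrastResult(dtable, "d", False, ("a", "b"))
        out = de.interaction_quadrants(region, disease)
        assert out["quadrants"]["region_up_disease_up"]["count"] == a
        assert out["quadrants"]["region_up_disease_up"]["fisher_p"] == pytest.approx(p_fisher)

    def test_independent_vectors_near_zero_correlation(self):
        rng = np.random.default_rng(9)
        n = 4000
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        mk = lambda t: de.ContrastResult(pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)], "t": t,
            "p": 2 * stats.norm.sf(np.abs(t)), "q": 0.5,
            "fc_signed": np.sign(t) * 1.5, "fc_median_signed": np.sign(t) * 1.5,
            "mean_a": 10.0, "mean_b": 10.0, "median_a": 10.0, "median_b": 10.0,
            "z": t}, index=[f"p{i}" for i in range(n)]), "x", False, ("a", "b"))
        out = de.interaction_quadrants(mk(t1), mk(t2))
        assert abs(out["t_correlation"]) < 0.05
        for q in out["quadrants"].values():
            assert q["fisher_p"] > 0.001

    def test_empty_universe_errors(self):
        empty = _mock_contrast([])
        with pytest.raises(ValueError, match="empty"):
            de.interaction_quadrants(empty, empty)
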