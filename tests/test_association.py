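"""Association scan: gene filtering, logistic Wald inference, BH, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import radharmon as rh


def _mutmat(columns: dict[str, np.ndarray]) -> rh.MutationMatrix:
    n = len(next(iter(columns.values())))
    return rh.MutationMatrix(values=pd.DataFrame(
        columns, index=[f"s{i}" for i in range(n)]))


class TestFilterGenes:
    @pytest.mark.parametrize("n_mut, kept", [
        (9, False),     # 9/208 = 0.0433 < 0.05
        (11, True),     # 11/208 = 0.0529
        (204, False),   # minor frequency 4/208 = 0.019
    ])
    def test_minor_frequency_floor(self, n_mut, kept):
        col = np.zeros(208, dtype=int)
        col[:n_mut] = 1
        mm = _mutmat({"g": col, "anchor": np.tile([0, 1], 104)})
        out = rh.filter_genes(mm, min_freq=0.05)
        assert ("g" in out.gene_names) == kept

    def test_all_removed_errors(self):
        col = np.zeros(208, dtype=int)
        col[0] = 1
        with pytest.raises(ValueError):
            rh.filter_genes(_mutmat({"g": col}))


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        """Binary predictor: the ML slope is the log odds-ratio and its SE
        is sqrt(sum of reciprocal cell counts)."""
        y = np.r_[np.ones(10), np.zeros(20), np.ones(20), np.zeros(10)]
        x = np.r_[np.zeros(30), np.ones(30)]
        fit = rh.logistic_fit(y, x)
        assert fit.converged
        assert fit.estimate == pytest.approx(np.log(4), abs=1e-6)
        assert fit.se == pytest.approx(np.sqrt(0.3), abs=1e-6)
        assert fit.z == pytest.approx(2.531, abs=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.tuples(*[st.integers(5, 40)] * 4))
    def test_closed_form_on_random_tables(self, counts):
        a, b, c, d = counts  # x=0: a cases/b controls; x=1: c cases/d controls
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.zeros(a + b), np.ones(c + d)]
        fit = rh.logistic_fit(y, x)
        lor = np.log(c * b / (a * d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.estimate == pytest.approx(lor, abs=1e-6)
        assert fit.se == pytest.approx(se, abs=1e-6)

    def test_null_type_one_error_calibrated(self):
        """x independent of y at n=500: empirical rejection at alpha=0.05
        stays in [0.035, 0.065] over 1000 replicates."""
        rng = np.random.default_rng(99)
        rej = 0
        for _ in range(1000):
            y = (rng.random(500) < 0.3).astype(float)
            x = rng.normal(size=500)
            rej += rh.logistic_fit(y, x).p < 0.05
        assert 0.035 <= rej / 1000 <= 0.065

    def test_perfect_separation_flagged(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.r_[np.arange(10.0), np.arange(100.0, 110.0)]
        fit = rh.logistic_fit(y, x)
        assert not fit.converged
        assert np.isnan(fit.p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rh.logistic_fit(np.ones(10), np.arange(10.0))      # constant y
        with pytest.raises(ValueError):
            rh.logistic_fit(np.r_[np.zeros(5), np.ones(5)],
                            np.r_[np.arange(9.0), np.nan])     # non-finite x

    def test_scale_invariance_of_inference(self):
        """A feature rescaled by 1e6 changes the slope, not z or p."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(float)
        f1 = rh.logistic_fit(y, x)
        f2 = rh.logistic_fit(y, x * 1e6)
        assert f2.estimate == pytest.approx(f1.estimate / 1e6, rel=1e-6)
        assert f2.z == pytest.approx(f1.z, rel=1e-6)


class TestWaldP:
    @pytest.mark.parametrize("z, expected, rel", [
        (3.771, 1.63e-4, 5e-3),   # two-sided normal tail at printed precision
        (3.948, 7.89e-5, 2e-3),
        (0.0, 1.0, 1e-12),
    ])
    def test_tail_values(self, z, expected, rel):
        assert rh.wald_p(z) == pytest.approx(expected, rel=rel)

    def test_symmetry(self):
        assert rh.wald_p(-2.5) == rh.wald_p(2.5)


def bh_bruteforce(p):
    """Literal step-up: q_(j) = p_(j) m / j, then running min from the right."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for j in range(m - 2, -1, -1):
        q[j] = min(q[j], q[j + 1])
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBhAdjust:
    def test_rank_one_times_family_size(self):
        """The smallest of m=50 p-values gets multiplied by 50 when the rest
        are large: 2.42e-4 -> 0.0121."""
        p = np.r_[2.42e-4, np.linspace(0.5, 0.99, 49)]
        adj = rh.bh_adjust(p)
        assert adj[0] == pytest.approx(0.0121, abs=1e-6)

    def test_tied_staircase_collapses(self):
        np.testing.assert_allclose(rh.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04] * 4)

    def test_single_p_unchanged(self):
        assert rh.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equals_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 101))
            np.testing.assert_allclose(rh.bh_adjust(p), bh_bruteforce(p),
                                       atol=1e-12)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.0001, 1, 200)
        adj = rh.bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            rh.bh_adjust([])
        with pytest.raises(ValueError):
            rh.bh_adjust([0.5, 0.0])


class TestScan:
    @pytest.fixture(scope="class")
    def small_scan(self):
        cfg = rh.SimulationConfig(n_features=20, n_genes=10,
                                  causal_pairs=[(3, 2, 1.5)], seed=21)
        fm, mm, truth = rh.generate_cohort(cfg)
        corrected = rh.combat(fm, mode="global").corrected
        return corrected, rh.filter_genes(mm), truth

    def test_record_count_is_product(self, small_scan):
        fm, mm, _ = small_scan
        tab = rh.scan(fm, mm, method="combat_global")
        assert len(tab.records) == fm.n_features * mm.n_genes

    def test_strong_causal_pair_detected(self, small_scan):
        """A 1.5-SD-per-mutation coupling at n=208 is the top hit of its
        feature family and survives BH."""
        fm, mm, _ = small_scan
        tab = rh.scan(fm, mm, method="combat_global")
        fam = tab.records[tab.records.feature == "feature_004"]
        best = fam.loc[fam.p_adj.idxmin()]
        assert best.gene == "gene_003"
        assert best.p_adj < 0.05

    def test_adjusted_monotone_in_raw_within_family(self, small_scan):
        fm, mm, _ = small_scan
        tab = rh.scan(fm, mm, method="m")
        for _, grp in tab.records.groupby("feature"):
            grp = grp.sort_values("p")
            assert np.all(np.diff(grp.p_adj.to_numpy()) >= -1e-15)

    def test_misaligned_subjects_error(self, small_scan):
        fm, mm, _ = small_scan
        shuffled = rh.MutationMatrix(values=mm.values.iloc[::-1])
        with pytest.raises(ValueError):
            rh.scan(fm, shuffled, method="m")


class TestMethodConcordance:
    @staticmethod
    def _table(p, method="m"):
        rec = pd.DataFrame({
            "feature": [f"f{i % 10}" for i in range(p.size)],
            "gene": [f"g{i // 10}" for i in range(p.size)],
            "estimate": 0.0, "se": 1.0, "z": 0.0, "p": p,
            "converged": True, "p_adj": p, "significant": False})
        return rh.AssociationTable(method=method, records=rec, m_genes=10)

    def test_self_concordance_is_one(self):
        t = self._table(np.linspace(0.01, 0.99, 100))
        assert rh.method_concordance(t, t) == pytest.approx(1.0)

    def test_perfect_negative_relation_squares_to_one(self):
        p = np.linspace(0.01, 0.99, 100)
        assert rh.method_concordance(self._table(p), self._table(1 - p)) \
            == pytest.approx(1.0)

    def test_matches_correlation_formula(self):
        rng = np.random.default_rng(11)
        pa = rng.uniform(0.001, 1, 4300)
        pb = np.clip(pa + rng.uniform(-0.1, 0.1, 4300), 1e-9, 1)
        r2 = rh.method_concordance(self._table(pa), self._table(pb))
        expect = (np.corrcoef(pa, pb)[0, 1]) ** 2
        assert r2 == pytest.approx(expect, abs=1e-12)

    def test_too_few_records_error(self):
        with pytest.raises(ValueError):
            rh.method_concordance(self._table(np.array([0.5])),
                                  self._table(np.array([0.5])))
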