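"""Oracle and property tests for the four signal-detection algorithms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from faerspv import (ContingencyTable, GammaMixturePrior, SignalCriteria,
                     build_tables, compute_chisq, compute_ebgm, compute_ic,
                     compute_prr, compute_ror, evaluate_signal, fit_mgps_prior,
                     rank_signals, tables_for_drug)
from faerspv.disproportionality import (MGPS_INIT, _mixture_loglik, _theta,
                                        posterior_quantile)

Z = 1.959963984540054


def random_tables(n, seed=0, low=1, high=400):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=(n, 4))


class TestContingency:
    def test_cells_and_derived(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert t.N == 10100
        assert t.E == pytest.approx(100 * 110 / 10100)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_build_tables_hand_count(self):
        # 4 reports, 6 reaction records, one target pair
        events = pd.DataFrame({
            "primary_id": ["1", "1", "2", "3", "3", "4"],
            "drug": ["ANAKINRA", "ANAKINRA", "OTHER", "OTHER", "OTHER", "OTHER"],
            "term": ["Pyrexia", "Rash", "Pyrexia", "Rash", "Nausea", "Nausea"],
        })
        tabs = build_tables(events).set_index(["drug", "term"])
        row = tabs.loc[("ANAKINRA", "Pyrexia")]
        assert (row["a"], row["b"], row["c"], row["d"]) == (1, 1, 1, 3)
        assert row["N"] == 6
        # per-drug record totals: sum of a over a drug's rows = a+b
        anak = tabs.loc["ANAKINRA"]
        assert anak["a"].sum() == 2 and (anak["a"] + anak["b"]).iloc[0] == 2

    def test_tables_for_drug_includes_zero_cells(self):
        events = pd.DataFrame({
            "primary_id": ["1", "2"], "drug": ["A", "B"],
            "term": ["Pyrexia", "Nausea"]})
        tab = tables_for_drug(events, "A").set_index("term")
        assert tab.loc["Nausea", "a"] == 0  # tabulated even when absent from A

    def test_record_count_invariant_on_random_events(self):
        rng = np.random.default_rng(3)
        events = pd.DataFrame({
            "primary_id": rng.integers(0, 50, 500).astype(str),
            "drug": rng.choice(["A", "B", "C"], 500),
            "term": rng.choice([f"T{i}" for i in range(12)], 500)})
        tabs = build_tables(events)
        for drug, sub in tabs.groupby("drug"):
            assert (sub["a"] + sub["c"]).sum() == len(events)


class TestFrequentistOracles:
    def test_ror_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(11.0 * math.exp(-Z * se), rel=1e-12)
        assert hi == pytest.approx(11.0 * math.exp(Z * se), rel=1e-12)

    def test_prr_example_and_symmetry(self):
        prr, _, _ = compute_prr(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)
        assert compute_ror(ContingencyTable(10, 10, 10, 10))[0] == pytest.approx(1.0)

    def test_independent_table_is_null(self):
        t = ContingencyTable(10, 90, 20, 180)  # equal reporting proportions
        assert compute_ror(t)[0] == pytest.approx(1.0)
        assert compute_prr(t)[0] == pytest.approx(1.0)
        assert compute_chisq(t, yates=False) == pytest.approx(0.0)
        ic, _ = compute_ic(t, mode="closed-form")
        assert ic == pytest.approx(0.0)  # a equals E exactly here

    def test_zero_cell_undefined(self):
        assert math.isnan(compute_ror(ContingencyTable(0, 5, 5, 5))[0])
        assert math.isnan(compute_prr(ContingencyTable(3, 2, 0, 5))[0])
        assert math.isnan(compute_chisq(ContingencyTable(0, 0, 5, 5)))

    def test_yates_correction_shrinks(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert compute_chisq(t, yates=True) < compute_chisq(t, yates=False)

    def test_thousand_random_tables_match_brute_force(self):
        """ROR/PRR/chi-square agree with independent arithmetic to 1e-10."""
        for a, b, c, d in random_tables(1000, seed=11):
            t = ContingencyTable(a, b, c, d)
            ror, lo, hi = compute_ror(t)
            assert abs(ror - (a * d) / (b * c)) < 1e-10 * ror
            prr, _, _ = compute_prr(t)
            assert abs(prr - (a / (a + b)) / (c / (c + d))) < 1e-10 * prr
            # chi-square against scipy's implementation, both corrections
            obs = [[a, b], [c, d]]
            for yates in (False, True):
                ours = compute_chisq(t, yates=yates)
                ref = stats.chi2_contingency(obs, correction=yates)[0]
                assert abs(ours - ref) < 1e-10 * max(ref, 1.0)

    def test_ror_prr_identity(self):
        """ROR/PRR = (1+a/b)/(1+c/d) to 1e-12; hence ROR >= PRR iff ROR >= 1."""
        for a, b, c, d in random_tables(300, seed=7):
            t = ContingencyTable(a, b, c, d)
            ror = compute_ror(t)[0]
            prr = compute_prr(t)[0]
            assert ror / prr == pytest.approx((1 + a / b) / (1 + c / d), abs=1e-12)
            if ror >= 1:
                assert ror >= prr - 1e-12


SINGLE = GammaMixturePrior(2.0, 3.0, 2.0, 3.0, 1.0)  # effectively one component


class TestEbgm:
    def test_degenerate_prior_matches_digamma_closed_form(self):
        # posterior Gamma(7, 3): EBGM = exp(psi(7))/3
        ebgm, ebgm05, q = compute_ebgm(5, 1.0, GammaMixturePrior(2, 2, 2, 2, 1.0))
        assert ebgm == pytest.approx(math.exp(special.digamma(7)) / 3, abs=1e-8)
        assert ebgm05 == pytest.approx(stats.gamma.ppf(0.05, 7, scale=1 / 3), abs=1e-8)

    def test_single_component_closed_form_general(self):
        for a, E in [(0, 0.5), (3, 1.0), (25, 10.0), (400, 380.0)]:
            ebgm, ebgm05, _ = compute_ebgm(a, E, SINGLE)
            s, r = 2.0 + a, 3.0 + E
            assert ebgm == pytest.approx(math.exp(special.digamma(s)) / r, abs=1e-8)
            assert ebgm05 == pytest.approx(stats.gamma.ppf(0.05, s, scale=1 / r),
                                           abs=1e-8)

    def test_large_null_count_shrinks_to_one(self):
        ebgm, _, _ = compute_ebgm(1000, 1000.0, MGPS_INIT)
        assert abs(ebgm - 1.0) < 0.02

    def test_strictly_increasing_in_a(self):
        vals = [compute_ebgm(a, 5.0, MGPS_INIT)[0] for a in range(0, 30)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_shrinkage_below_observed_ratio(self):
        for a, E in [(10, 2.0), (50, 10.0), (8, 1.0)]:
            assert MGPS_INIT.mean <= a / E
            ebgm, _, _ = compute_ebgm(a, E, MGPS_INIT)
            assert ebgm <= a / E

    def test_quantile_cdf_consistency(self):
        """The posterior-mixture CDF evaluated at EBGM05 equals 0.05."""
        prior = GammaMixturePrior(0.5, 0.3, 3.0, 2.0, 0.4)
        for a, E in [(0, 0.2), (4, 1.5), (60, 12.0)]:
            x = posterior_quantile(a, E, prior, 0.05)
            q = float(np.clip(special.expit(
                stats.nbinom.logpmf(a, 0.5, 0.3 / (0.3 + E))
                - stats.nbinom.logpmf(a, 3.0, 2.0 / (2.0 + E))
                + special.logit(0.4)), 0, 1))
            cdf = (q * stats.gamma.cdf(x, 0.5 + a, scale=1 / (0.3 + E))
                   + (1 - q) * stats.gamma.cdf(x, 3.0 + a, scale=1 / (2.0 + E)))
            assert abs(cdf - 0.05) < 1e-6


class TestIc:
    def test_closed_form_zero_at_expected(self):
        t = ContingencyTable(10, 90, 20, 180)
        assert compute_ic(t, mode="closed-form")[0] == pytest.approx(0.0)

    def test_mgps_linked_equals_log2_ebgm(self):
        t = ContingencyTable(30, 300, 100, 5000)
        ic, ic025 = compute_ic(t, prior=MGPS_INIT, mode="mgps-linked")
        ebgm, ebgm05, _ = compute_ebgm(t.a, t.E, MGPS_INIT)
        assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)
        # 2.5% posterior quantile sits at or below the 5% quantile
        assert 2 ** ic025 <= ebgm05 + 1e-12


class TestMgpsFit:
    def test_null_corpus_prior_mean_near_one(self):
        rng = np.random.default_rng(5)
        E = rng.lognormal(1.0, 1.0, size=3000)
        a = rng.poisson(E)  # lambda = 1 exactly
        prior = fit_mgps_prior(a, E, seed=1)
        assert abs(prior.mean - 1.0) < 0.1

    def test_loglik_improves_over_initialization(self):
        rng = np.random.default_rng(6)
        E = rng.lognormal(0.5, 1.0, size=500)
        lam = rng.gamma(2.0, 1 / 2.0, size=500)
        a = rng.poisson(lam * E)
        prior = fit_mgps_prior(a, E, seed=1)
        assert prior.loglik >= _mixture_loglik(_theta(MGPS_INIT), a.astype(float), E)

    def test_nonpositive_expected_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([1, 2], [1.0, 0.0])


class TestSignalCalling:
    def stats_row(self, **kw):
        base = dict(n=10, ror_lo95=1.5, prr=3.0, chisq=10.0, ic025=0.5, ebgm05=2.5)
        base.update(kw)
        return base

    def test_count_gate_blocks_strong_pair(self):
        v = evaluate_signal(self.stats_row(n=2))
        assert not v["signal"] and not any(v[k] for k in ("ror", "prr", "bcpnn", "mgps"))

    def test_all_four_flagged(self):
        v = evaluate_signal(self.stats_row())
        assert v["signal"] and all(v[k] for k in ("ror", "prr", "bcpnn", "mgps"))

    def test_conjunction_fails_on_single_algorithm(self):
        v = evaluate_signal(self.stats_row(ror_lo95=0.99))
        assert not v["ror"] and not v["signal"]

    def test_any_rule(self):
        v = evaluate_signal(self.stats_row(ror_lo95=0.99),
                            SignalCriteria(rule="any"))
        assert v["signal"]

    def test_nan_statistics_never_pass(self):
        v = evaluate_signal(self.stats_row(ic025=math.nan, ebgm05=math.nan))
        assert not v["bcpnn"] and not v["mgps"]


class TestRankSignals:
    def frame(self):
        return pd.DataFrame({
            "term": ["X", "Y", "Z"], "n": [10, 10, 5],
            "ebgm": [2.0, 4.0, 9.0], "ic": [1.0, 2.0, 3.17]})

    def test_count_ties_broken_by_ebgm(self):
        out = rank_signals(self.frame(), by="n", top=2)
        assert list(out["term"]) == ["Y", "X"]

    def test_top_larger_than_table(self):
        assert len(rank_signals(self.frame(), top=50)) == 3

    def test_invariant_to_row_order(self):
        f = self.frame()
        shuffled = f.sample(frac=1.0, random_state=4)
        pd.testing.assert_frame_equal(rank_signals(f, top=3),
                                      rank_signals(shuffled, top=3))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            rank_signals(self.frame(), by="ror")
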