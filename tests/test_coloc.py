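"""Colocalisation: ABF closed form, posterior algebra, symmetry, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import regulocal as rl
from regulocal.coloc import HYPOTHESES, ColocPriors, coloc_posteriors, log_abf


def enumeration_oracle(l1, l2, priors):
    """Direct summation over all single-variant causal configurations.

    H1: one of n configs (variant i causal for trait 1); H2 likewise;
    H3: n*(n-1) ordered pairs i != j; H4: n shared configs.  Works on raw
    Bayes factors, so only usable for small log values / small n.
    """
    bf1 = np.exp(np.asarray(l1, dtype=float))
    bf2 = np.exp(np.asarray(l2, dtype=float))
    n = bf1.size
    w0 = 1.0
    w1 = priors.p1 * bf1.sum()
    w2 = priors.p2 * bf2.sum()
    w3 = priors.p1 * priors.p2 * sum(
        bf1[i] * bf2[j] for i in range(n) for j in range(n) if i != j
    )
    w4 = priors.p12 * (bf1 * bf2).sum()
    ws = np.array([w0, w1, w2, w3, w4])
    return ws / ws.sum()


def stats_from_log_abf(l, w=0.0225):
    """Invert the ABF closed form to (beta, se) pairs producing given log BFs."""
    rows = []
    for i, val in enumerate(l):
        se = 0.1
        V = se * se
        r = w / (V + w)
        z2 = (2 * val - math.log1p(-r)) / r
        beta = se * math.sqrt(max(z2, 0.0))
        rows.append({"variant": f"rs{i}", "beta": beta, "se": se})
    return pd.DataFrame(rows)


class TestLogAbf:
    def test_null_effect_is_evidence_against(self):
        val = log_abf(0.0, 0.1, 0.0225)
        r = 0.0225 / (0.01 + 0.0225)
        assert val == pytest.approx(0.5 * math.log(1 - r))
        assert val < 0

    def test_vacuous_prior_limit(self):
        assert log_abf(0.5, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_value(self):
        # V=0.01, r=0.0225/0.0325, z=5 -> 0.5*(log(1-r)+r*25)
        r = 0.0225 / 0.0325
        expected = 0.5 * (math.log(1 - r) + r * 25.0)
        assert log_abf(0.5, 0.1, 0.0225) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.0645, abs=5e-4)

    def test_degenerate_se_rejected(self):
        with pytest.raises(ValueError):
            log_abf(0.5, 0.0, 0.0225)


class TestSummaryStatConversions:
    def test_p_of_one_gives_zero_z(self):
        assert rl.zscore_from_p(1.0) == pytest.approx(0.0)

    def test_quantile_value(self):
        assert rl.zscore_from_p(0.05, 1.0) == pytest.approx(1.959964, abs=1e-6)
        assert rl.zscore_from_p(0.05, -1.0) == pytest.approx(-1.959964, abs=1e-6)

    def test_var_from_freq_arithmetic(self):
        assert rl.var_from_freq(0.5, 1000) == pytest.approx(0.002)

    def test_p_zero_instructs_caller(self):
        with pytest.raises(ValueError, match="beta/se"):
            rl.zscore_from_p(0.0)


class TestPosteriors:
    def test_single_shared_variant_h3_impossible(self):
        s1 = pd.DataFrame({"variant": ["rs1"], "beta": [0.6], "se": [0.05]})
        s2 = pd.DataFrame({"variant": ["rs1"], "beta": [0.5], "se": [0.05]})
        res = coloc_posteriors(s1, s2)
        assert res.pp["H3"] == 0.0
        assert res.pp["H4"] == max(res.pp.values())

    def test_all_null_favours_h0(self):
        s1 = pd.DataFrame({"variant": [f"rs{i}" for i in range(5)], "beta": 0.0, "se": 0.1})
        res = coloc_posteriors(s1, s1.copy())
        assert res.best == "H0"

    def test_matches_enumeration_oracle_hand_values(self):
        priors = ColocPriors()
        l1 = [3.0, -1.0, 0.5]
        l2 = [2.5, 0.0, -0.5]
        s1, s2 = stats_from_log_abf(l1), stats_from_log_abf(l2)
        res = coloc_posteriors(s1, s2, priors)
        expected = enumeration_oracle(res.log_abf_1, res.log_abf_2, priors)
        for h, e in zip(HYPOTHESES, expected):
            assert res.pp[h] == pytest.approx(e, abs=1e-10)

    def test_matches_enumeration_oracle_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 7))
            priors = ColocPriors(
                p1=float(10 ** -rng.uniform(2, 5)),
                p2=float(10 ** -rng.uniform(2, 5)),
                p12=1e-6,
            )
            s1 = pd.DataFrame({
                "variant": [f"rs{i}" for i in range(n)],
                "beta": rng.normal(0, 0.3, n),
                "se": rng.uniform(0.05, 0.3, n),
            })
            s2 = s1.copy()
            s2["beta"] = rng.normal(0, 0.3, n)
            res = coloc_posteriors(s1, s2, priors)
            expected = enumeration_oracle(res.log_abf_1, res.log_abf_2, priors)
            assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in res.pp.values())
            for h, e in zip(HYPOTHESES, expected):
                assert res.pp[h] == pytest.approx(e, abs=1e-10)

    def test_trait_swap_symmetry(self, rng):
        n = 5
        s1 = pd.DataFrame({"variant": [f"rs{i}" for i in range(n)],
                           "beta": rng.normal(0, 0.4, n), "se": rng.uniform(0.05, 0.2, n)})
        s2 = pd.DataFrame({"variant": [f"rs{i}" for i in range(n)],
                           "beta": rng.normal(0, 0.4, n), "se": rng.uniform(0.05, 0.2, n)})
        priors = ColocPriors(p1=2e-4, p2=5e-5, p12=1e-5, w1=0.04, w2=0.01)
        swapped = ColocPriors(p1=5e-5, p2=2e-4, p12=1e-5, w1=0.01, w2=0.04)
        a = coloc_posteriors(s1, s2, priors)
        b = coloc_posteriors(s2, s1, swapped)
        assert a.pp["H1"] == pytest.approx(b.pp["H2"], abs=1e-12)
        assert a.pp["H2"] == pytest.approx(b.pp["H1"], abs=1e-12)
        for h in ("H0", "H3", "H4"):
            assert a.pp[h] == pytest.approx(b.pp[h], abs=1e-12)

    def test_p_maf_n_parameterisation_close_to_beta_se(self):
        # z/V reconstruction should give nearly the same posteriors
        n_samples, maf = 2000, 0.3
        V = rl.var_from_freq(maf, n_samples)
        betas = [0.3, 0.02, -0.1]
        from scipy import stats as ss
        rows = []
        for i, b in enumerate(betas):
            z = b / math.sqrt(V)
            rows.append({"variant": f"rs{i}", "p": 2 * ss.norm.sf(abs(z)),
                         "maf": maf, "n": n_samples, "beta": np.nan, "se": np.nan})
        s_pmn = pd.DataFrame(rows)
        s_bse = pd.DataFrame({"variant": [f"rs{i}" for i in range(3)],
                              "beta": betas, "se": math.sqrt(V)})
        a = coloc_posteriors(s_bse, s_bse.copy())
        b = coloc_posteriors(s_pmn, s_pmn.copy())
        for h in HYPOTHESES:
            assert a.pp[h] == pytest.approx(b.pp[h], abs=1e-6)

    def test_no_shared_variants_raises(self):
        s1 = pd.DataFrame({"variant": ["rs1"], "beta": [0.1], "se": [0.1]})
        s2 = pd.DataFrame({"variant": ["rs2"], "beta": [0.1], "se": [0.1]})
        with pytest.raises(ValueError, match="shared"):
            coloc_posteriors(s1, s2)


class TestClassify:
    def test_strong_label_above_threshold(self):
        res = rl.ColocResult(pp={"H0": 0.01, "H1": 0.02, "H2": 0.02, "H3": 0.026, "H4": 0.924},
                             n_variants=10, priors=ColocPriors())
        assert rl.classify(res)["H4"] == "strong"

    def test_boundary_is_strict(self):
        res = rl.ColocResult(pp={"H0": 0.05, "H1": 0.05, "H2": 0.05, "H3": 0.10, "H4": 0.75},
                             n_variants=10, priors=ColocPriors())
        assert rl.classify(res)["H4"] == "inconclusive"

    def test_uniform_inconclusive(self):
        res = rl.ColocResult(pp={h: 0.2 for h in HYPOTHESES}, n_variants=3, priors=ColocPriors())
        assert set(rl.classify(res).values()) == {"inconclusive"}
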