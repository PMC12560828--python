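"""Vial random-intercept GLMM: quadrature, partition, decision rules."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special

from vialtox.design import ScreenDesign, TruthParams
from vialtox.synthetic import simulate_morphology
from vialtox.vialfx import (VialEffectModel, VialEffectResults,
                            fit_binomial_glmm, partition_variance,
                            scale_concentration, vial_decision,
                            vial_effect_table)

_PI23 = math.pi**2 / 3.0


def simulate_glmm(rng, beta0=-2.0, beta1=1.2, sigma=0.5, n_vials=24,
                  per_vial=8):
    """Direct GLMM generator (independent of the morphology generator)."""
    doses = np.tile([0, 3.125, 6.25, 12.5, 25, 50.0], n_vials // 6 + 1)[:n_vials]
    rows = []
    for v in range(n_vials):
        u = rng.normal(0, sigma)
        x = scale_concentration(doses[v])
        p = special.expit(beta0 + beta1 * x + u)
        y = rng.random(per_vial) < p
        for yi in y:
            rows.append((doses[v], f"V{v}", int(yi)))
    return pd.DataFrame(rows, columns=["conc_um", "vial", "response"])


class TestScaleConcentration:
    def test_values(self):
        assert scale_concentration(0.0) == 0.0
        assert scale_concentration(math.e - 1) == pytest.approx(1.0)
        assert scale_concentration(50.0) == pytest.approx(math.log(51),
                                                          abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scale_concentration(-1.0)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(31)
    df = simulate_glmm(rng)
    return VialEffectModel(df.response, df.conc_um, df.vial)


class TestQuadrature:
    def test_adaptive_nodes_converged(self, model):
        ll15 = model.loglik(-2.0, 1.2, 0.5, nodes=15)
        ll61 = model.loglik(-2.0, 1.2, 0.5, nodes=61)
        assert abs(ll15 - ll61) < 1e-6

    def test_few_nodes_already_converged(self, model):
        ll7 = model.loglik(-2.0, 1.2, 0.5, nodes=7)
        ll61 = model.loglik(-2.0, 1.2, 0.5, nodes=61)
        assert abs(ll7 - ll61) < 1e-5

    def test_laplace_close_to_high_order(self, model):
        # one-node adaptive quadrature = Laplace; its O(1/n_vial) error at
        # 8 embryos per vial is ~1e-3 per vial across 24 vials
        ll1 = model.loglik(-2.0, 1.2, 0.5, nodes=1)
        ll61 = model.loglik(-2.0, 1.2, 0.5, nodes=61)
        assert abs(ll1 - ll61) < 0.05

    def test_sigma_zero_equals_plain_logistic(self, model):
        eta = -2.0 + 1.2 * model.x
        plain = float(np.sum(model.y * eta - np.logaddexp(0, eta)))
        assert model.loglik(-2.0, 1.2, 0.0) == pytest.approx(plain)

    def test_single_vial_rejected(self):
        with pytest.raises(ValueError):
            VialEffectModel([0, 1, 1], [0, 5, 50], ["V1", "V1", "V1"])


class TestRecovery:
    def test_sigma_zero_generator_estimates_near_zero(self):
        ests = []
        for s in range(12):
            df = simulate_glmm(np.random.default_rng(s), sigma=0.0)
            r = VialEffectModel(df.response, df.conc_um, df.vial).fit()
            ests.append(r.sigma2_vial)
        assert np.median(ests) < 0.01

    def test_slope_and_sigma_recovered_in_median(self):
        # at 24 vials x 8 embryos the ML variance component has a known
        # downward small-sample bias (estimates match lme4::glmer to 1e-6),
        # so the slope is held to 20% while sigma gets a wider band
        b1s, sigs = [], []
        for s in range(21):
            df = simulate_glmm(np.random.default_rng(100 + s),
                               beta1=1.2, sigma=0.5)
            r = VialEffectModel(df.response, df.conc_um, df.vial).fit()
            b1s.append(r.beta1)
            sigs.append(math.sqrt(r.sigma2_vial))
        assert np.median(b1s) == pytest.approx(1.2, rel=0.20)
        assert 0.25 <= np.median(sigs) <= 0.75


class TestPartition:
    def _result(self, beta1, s2v, x):
        fit = VialEffectResults(beta0=0.0, beta1=beta1, sigma2_vial=s2v,
                                loglik=0.0, converged=True, n_obs=len(x),
                                n_vials=4)
        return partition_variance(fit, x)

    def test_components_sum_to_one(self):
        r = self._result(1.5, 0.7, np.linspace(0, 4, 40))
        assert r.r2_fixed + r.r2_random + r.remaining == pytest.approx(
            1.0, abs=1e-10)
        assert min(r.r2_fixed, r.r2_random, r.remaining) >= 0

    def test_no_vial_variance_gives_zero_random_r2(self):
        r = self._result(1.5, 0.0, np.linspace(0, 4, 40))
        assert r.r2_random == 0.0

    def test_flat_concentration_gives_zero_fixed_r2(self):
        r = self._result(1.5, 0.5, np.ones(40))
        assert r.r2_fixed == 0.0

    def test_equal_thirds_under_symmetry(self):
        # choose x so var(beta1 * x) = pi^2/3 = sigma2_vial
        x = np.array([0.0, 2 * math.sqrt(_PI23)] * 20)
        r = self._result(1.0, _PI23, x)
        assert r.r2_fixed == pytest.approx(1 / 3, abs=1e-12)
        assert r.r2_random == pytest.approx(1 / 3, abs=1e-12)
        assert r.remaining == pytest.approx(1 / 3, abs=1e-12)


class TestDecision:
    def _decide(self, r2f, r2r):
        fit = VialEffectResults(0.0, 1.0, 0.0, 0.0, True, 10, 4,
                                r2_fixed=r2f, r2_random=r2r,
                                remaining=1 - r2f - r2r)
        return vial_decision(fit)

    def test_fixed_dominates_random(self):
        r = self._decide(0.4, 0.1)
        assert r.ratio_fixed_random == pytest.approx(4.0) and r.decision

    def test_second_branch_small_random_vs_remaining(self):
        r = self._decide(0.05, 0.10)
        assert r.ratio_fixed_random == pytest.approx(0.5)
        assert r.ratio_random_remaining == pytest.approx(0.10 / 0.85)
        assert r.decision

    def test_both_branches_fail_flags_vial_effect(self):
        r = self._decide(0.05, 0.50)
        assert not r.decision

    def test_zero_random_r2_is_treat_individually(self):
        r = self._decide(0.0, 0.0)
        assert math.isinf(r.ratio_fixed_random) and r.decision


class TestInvariances:
    def test_decision_invariant_to_vial_relabeling_and_order(self):
        rng = np.random.default_rng(77)
        df = simulate_glmm(rng, sigma=0.4)
        r1 = VialEffectModel(df.response, df.conc_um, df.vial).fit()
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm].reset_index(drop=True)
        df2["vial"] = df2["vial"].map(lambda v: f"relabeled_{v}")
        r2 = VialEffectModel(df2.response, df2.conc_um, df2.vial).fit()
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-5)
        assert r1.decision == r2.decision

    def test_table_over_morphology_frame(self):
        design = ScreenDesign()
        truth = TruthParams(sigma_vial=0.0)
        df = pd.concat([
            simulate_morphology(design, truth, s, chemical=f"chem{s}")
            for s in (1, 2)], ignore_index=True)
        tab = vial_effect_table(df)
        assert len(tab) == 2 and tab.treat_individually.all()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLme4:
    def test_loglik_and_coefficients_match_glmer(self, tmp_path):
        """Independent oracle: lme4::glmer with adaptive quadrature."""
        rng = np.random.default_rng(55)
        df = simulate_glmm(rng, sigma=0.6, n_vials=24, per_vial=8)
        csv = tmp_path / "glmm.csv"
        df.assign(x=scale_concentration(df.conc_um)).to_csv(csv, index=False)
        script = textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            m <- glmer(response ~ x + (1 | vial), data = d,
                       family = binomial, nAGQ = 25)
            cat(sprintf("%.10f %.10f %.10f %.10f\\n",
                        as.numeric(logLik(m)), fixef(m)[1], fixef(m)[2],
                        as.numeric(VarCorr(m)$vial[1])))
        """)
        rfile = tmp_path / "fit.R"
        rfile.write_text(script)
        out = subprocess.run(["Rscript", str(rfile), str(csv)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ll_r, b0_r, b1_r, s2_r = map(float, out.stdout.split())
        res = VialEffectModel(df.response, df.conc_um, df.vial).fit()
        assert res.loglik == pytest.approx(ll_r, abs=1e-3)
        assert res.beta0 == pytest.approx(b0_r, abs=2e-2)
        assert res.beta1 == pytest.approx(b1_r, abs=2e-2)
        assert res.sigma2_vial == pytest.approx(s2_r, abs=5e-2)
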