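"""Positivity model: closed forms, quadrature and lme4 oracles, flag rule."""

import datetime as dt
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, roots_hermite

from claimscreen import PositivityModel, flag_low_positivity
from claimscreen.positivity import PositivityResults
from claimscreen.simulate import simulate_dataset
from tests.conftest import small_sim_config


def toy_frame(rows):
    df = pd.DataFrame(rows, columns=["centre_id", "week", "n_tests", "n_positive"])
    df["category"] = "practice"
    return df


def make_model(df):
    return PositivityModel(df["n_positive"], df["n_tests"], df["centre_id"], df["week"],
                           df["category"])


class TestClosedForms:
    def test_reduces_to_offset_poisson_mle_when_sigmas_are_zero(self):
        """With both variance components pinned at 0 the intercept is the
        log of the pooled positivity rate (offset-Poisson MLE closed form)."""
        df = toy_frame([("A", 1, 100, 3), ("A", 2, 200, 2), ("B", 1, 50, 1), ("B", 2, 150, 4)])
        r = make_model(df).fit(fix_sigma_u=0.0, fix_sigma_v=0.0)
        expected = np.log(df["n_positive"].sum() / df["n_tests"].sum())
        assert r.params["intercept"] == pytest.approx(expected, abs=1e-5)
        assert abs(r.ranef_centre["mode"]).max() < 1e-5

    def test_zero_modes_flag_nothing(self):
        df = toy_frame([("A", 1, 100, 3), ("A", 2, 200, 2), ("B", 1, 50, 1), ("B", 2, 150, 4)])
        r = make_model(df).fit(fix_sigma_u=0.0, fix_sigma_v=0.0)
        flags = flag_low_positivity(r, alpha=0.05)
        assert flags["flagged"].sum() == 0


def adaptive_gh_sigma_hat(df, nodes=50):
    """Independent oracle: exact marginal ML for the centre-intercept-only
    model by adaptive Gauss-Hermite quadrature (mode-centred, curvature-
    scaled), maximised over (beta0, log sigma_u) by Nelder-Mead."""
    x, w = roots_hermite(nodes)
    y = df["n_positive"].to_numpy(float)
    off = np.log(df["n_tests"].to_numpy(float))
    codes = pd.Categorical(df["centre_id"]).codes

    def centre_loglik(ysel, offsel, b0, s):
        def neg(u):
            eta = offsel + b0 + u
            return -((ysel * eta - np.exp(eta)).sum() - 0.5 * u * u / s**2)

        uhat = minimize_scalar(neg, bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-12}).x
        sd = 1.0 / np.sqrt(np.exp(offsel + b0 + uhat).sum() + 1.0 / s**2)
        uu = uhat + np.sqrt(2) * sd * x
        eta = offsel[:, None] + b0 + uu[None, :]
        lp = (ysel[:, None] * eta - np.exp(eta) - gammaln(ysel + 1)[:, None]).sum(0)
        lp = lp - 0.5 * uu**2 / s**2 - 0.5 * np.log(2 * np.pi * s**2)
        m = lp.max()
        return np.log(np.sqrt(2) * sd) + m + np.log(np.sum(w * np.exp(lp - m + x**2)))

    def negll(theta):
        b0, lsu = theta
        s = np.exp(lsu)
        return -sum(
            centre_loglik(y[codes == j], off[codes == j], b0, s)
            for j in range(codes.max() + 1)
        )

    res = minimize(negll, [-3.6, np.log(0.3)], method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000})
    return float(np.exp(res.x[1]))


def test_laplace_matches_quadrature_oracle_to_three_decimals():
    """5 centres x 4 weeks, week variance pinned at zero: the Laplace
    sigma_u agrees with exact 50-node quadrature ML to 3 decimals."""
    rng = np.random.default_rng(42)
    u = 0.4 * rng.standard_normal(5)
    rows = []
    for j in range(5):
        for k in range(4):
            n = int(rng.integers(800, 1200))
            rows.append((f"C{j}", k + 1, n, rng.poisson(n * np.exp(-3.6 + u[j]))))
    df = toy_frame(rows)
    r = make_model(df).fit(fix_sigma_v=0.0)
    oracle = adaptive_gh_sigma_hat(df)
    assert r.sigma_u == pytest.approx(oracle, abs=5e-4)


def test_matches_lme4_glmer_on_simulated_data(tmp_path):
    """Independent cross-check against R lme4's Laplace glmer fit:
    variance components and EB modes agree."""
    cfg = small_sim_config(seed=5, n_centres={"pharmacy": 8, "practice": 16, "private": 16},
                           centre_sd=0.4)
    claims, _ = simulate_dataset(cfg)
    r = PositivityModel.from_claims(claims, cfg.window).fit()

    df = claims[claims["n_tests"] >= 1].copy()
    df["week"] = cfg.window.week_index(df["date"])
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(n_positive ~ category + (1|centre_id) + (1|week),
                   offset=log(d$n_tests), family=poisson, data=d)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$sdcor[vc$grp=="centre_id"], vc$sdcor[vc$grp=="week"], "\\n")
        re <- ranef(m)$centre_id
        write.csv(data.frame(centre_id=rownames(re), mode=re[,1]),
                  "{tmp_path / 'ranef.csv'}", row.names=FALSE)
    """))
    assert shutil.which("Rscript"), "Rscript is required for the lme4 oracle"
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
    sd_centre, sd_week = map(float, out.stdout.split())
    assert r.sigma_u == pytest.approx(sd_centre, abs=0.02)
    assert r.sigma_v == pytest.approx(sd_week, abs=0.02)
    ref = pd.read_csv(tmp_path / "ranef.csv").set_index("centre_id")["mode"]
    diff = (r.ranef_centre["mode"] - ref).abs()
    assert diff.max() < 0.05


class TestInvariances:
    def test_offset_correctness_under_doubling(self):
        """Doubling every day's tests and positives leaves the positivity
        structure, hence the flag set, unchanged."""
        cfg = small_sim_config(seed=9, centre_sd=0.4)
        claims, _ = simulate_dataset(cfg)
        r1 = PositivityModel.from_claims(claims, cfg.window).fit()
        doubled = claims.assign(n_tests=claims["n_tests"] * 2,
                                n_positive=claims["n_positive"] * 2)
        r2 = PositivityModel.from_claims(doubled, cfg.window).fit()
        # the modelled rate is unchanged, so every fixed effect (including
        # the intercept) is recovered up to Laplace/shrinkage noise
        for name in r1.params.index:
            assert r1.params[name] == pytest.approx(r2.params[name], abs=0.03)
        # the rate structure is unchanged; only borderline-z centres may flip
        # (doubled counts double the information behind each z statistic)
        z1, z2 = r1.centre_z, r2.centre_z
        flips = (z1 < -1.645) != (z2 < -1.645)
        assert (flips & ((z1 + 1.645).abs() > 0.5)).sum() == 0
        assert z1.corr(z2, method="spearman") > 0.98

    def test_lowering_positives_lowers_the_score(self):
        cfg = small_sim_config(seed=10, n_centres={"pharmacy": 5, "practice": 10, "private": 10})
        claims, _ = simulate_dataset(cfg)
        target = claims.groupby("centre_id")["n_positive"].sum().idxmax()
        r1 = PositivityModel.from_claims(claims, cfg.window).fit()
        lowered = claims.copy()
        sel = lowered["centre_id"] == target
        lowered.loc[sel, "n_positive"] = (lowered.loc[sel, "n_positive"] // 3)
        r2 = PositivityModel.from_claims(lowered, cfg.window).fit()
        z1 = (r1.ranef_centre["mode"] / r1.ranef_centre["se"])[target]
        z2 = (r2.ranef_centre["mode"] / r2.ranef_centre["se"])[target]
        assert z2 < z1

    def test_homogeneous_centres_drive_sigma_to_zero(self):
        """All centres share the same positivity: sigma_u collapses and no
        centre is significantly low."""
        cfg = small_sim_config(seed=12, centre_sd=0.0, week_sd=0.2)
        claims, _ = simulate_dataset(cfg)
        r = PositivityModel.from_claims(claims, cfg.window).fit()
        assert r.sigma_u < 0.05
        assert flag_low_positivity(r)["flagged"].sum() == 0


class TestFlagRule:
    def _fake_results(self, modes, ses):
        idx = pd.Index([f"C{i}" for i in range(len(modes))], name="centre_id")
        return PositivityResults(
            model=None, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            sigma_u=0.3, sigma_v=0.3,
            ranef_centre=pd.DataFrame({"category": "private", "mode": modes, "se": ses}, index=idx),
            ranef_week=pd.Series(dtype=float), llf=0.0, converged=True, n_rows=10,
        )

    def test_threshold_arithmetic(self):
        r = self._fake_results([-3.0 * 0.1, -1.0 * 0.1, 0.0], [0.1, 0.1, 0.1])
        flags = flag_low_positivity(r, alpha=0.05)
        # z = -3.0 < -1.645 flagged; z = -1.0 and z = 0 are not
        assert list(flags["flagged"]) == [True, False, False]
        assert flags.loc["C0", "score"] == pytest.approx(-3.0)

    def test_unfitted_centres_are_ineligible(self):
        r = self._fake_results([-0.5, 0.2], [0.1, 0.1])
        flags = flag_low_positivity(r, centres=pd.Index(["C0", "C1", "C9"]))
        assert not flags.loc["C9", "eligible"]
        assert flags.loc["C0", "flagged"]

    def test_zero_se_marks_centre_ineligible(self):
        r = self._fake_results([-0.5, -0.5], [0.1, 0.0])
        flags = flag_low_positivity(r)
        assert not flags.loc["C1", "eligible"]

    def test_invalid_alpha_rejected(self):
        r = self._fake_results([0.0], [0.1])
        with pytest.raises(ValueError):
            flag_low_positivity(r, alpha=1.5)
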