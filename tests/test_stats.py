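import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ccfdq import (
    bonferroni_adjust,
    cluster_ratio_ci,
    fit_eye_level_logistic,
    fit_fd_mixed_model,
    fit_lcv_glmm,
    youden_cutoff,
)
from ccfdq.stats import fit_lcv_models, simulate_fd_percent_table


# ---------------------------------------------------------------------------
# Bonferroni and the cluster ratio estimator


def test_bonferroni_scales_and_caps():
    assert bonferroni_adjust(0.01, 4)[0] == pytest.approx(0.04)
    assert bonferroni_adjust(0.5, 4)[0] == 1.0
    assert bonferroni_adjust(0.000725, 4)[0] == pytest.approx(0.0029)
    with pytest.raises(ValueError):
        bonferroni_adjust(1.2, 4)


def test_cluster_ratio_ci_hand_computed_example():
    p, lo, hi = cluster_ratio_ci([2, 1, 0, 1], [2, 2, 2, 2])
    assert p == pytest.approx(0.5)
    # var = 4 / (3 * 64) * 2 = 0.0416667 -> Wald half-width 0.400
    assert lo == pytest.approx(0.100, abs=5e-4)
    assert hi == pytest.approx(0.900, abs=5e-4)


def test_cluster_ratio_ci_degenerate_and_errors():
    p, lo, hi = cluster_ratio_ci([1, 1, 1], [2, 2, 2])
    assert lo == pytest.approx(p) and hi == pytest.approx(p)
    with pytest.raises(ValueError):
        cluster_ratio_ci([1], [2])
    with pytest.raises(ValueError):
        cluster_ratio_ci([0, 0], [0, 0])


def test_cluster_ratio_ci_bernoulli_clusters_match_formula(rng):
    x = (rng.random(40) < 0.3).astype(int)
    n = np.ones(40, dtype=int)
    p, lo, hi = cluster_ratio_ci(x, n)
    m = 40
    var = m / ((m - 1) * n.sum() ** 2) * np.sum((x - p * n) ** 2)
    assert hi - lo == pytest.approx(2 * 1.959963984540054 * np.sqrt(var), rel=1e-9)


def test_cluster_ratio_ci_approaches_binomial_wald(rng):
    """With independent Bernoulli sectors the ratio CI matches the Wald CI."""
    widths = []
    for _ in range(20):
        x = rng.binomial(4, 0.3, size=200)
        n = np.full(200, 4)
        p, lo, hi = cluster_ratio_ci(x, n)
        wald = 2 * 1.959963984540054 * np.sqrt(p * (1 - p) / 800)
        widths.append((hi - lo) / wald)
    assert abs(np.mean(widths) - 1.0) < 0.1


# ---------------------------------------------------------------------------
# Youden cutoff


def test_youden_exhaustive_toy_example():
    res = youden_cutoff([100, 110, 130, 140], [1, 1, 0, 0], list("abcd"))
    assert res.threshold_um == pytest.approx(120.0)
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.youden_j == pytest.approx(1.0)


def test_youden_matches_bruteforce_scan(rng):
    for _ in range(10):
        n = int(rng.integers(10, 50))
        ct = rng.normal(150, 40, n).round(1)
        y = rng.random(n) < 1 / (1 + np.exp(0.05 * (ct - 140)))
        if y.all() or not y.any() or len(np.unique(ct)) < 2:
            continue
        clusters = np.arange(n)  # one eye per sector: Bernoulli clusters
        res = youden_cutoff(ct, y, clusters)
        distinct = np.unique(ct)
        best_j, best_t = -2.0, None
        for thr in (distinct[:-1] + distinct[1:]) / 2:
            called = ct <= thr
            j = (called & y).sum() / y.sum() + (~called & ~y).sum() / (~y).sum() - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, thr
        assert res.threshold_um == pytest.approx(best_t)
        assert res.youden_j == pytest.approx(best_j)


def test_youden_tie_breaks_to_smallest_threshold():
    # thresholds 15 and 35 both give J = 0.5; the smaller must win
    res = youden_cutoff([10, 20, 30, 40], [1, 0, 1, 0], list("abcd"))
    assert res.threshold_um == pytest.approx(15.0)


def test_youden_permutation_null_is_small(rng):
    ct = rng.normal(150, 60, 472)
    y = np.zeros(472, dtype=bool)
    y[:120] = True
    clusters = np.repeat(np.arange(118), 4)
    js = []
    for _ in range(50):
        perm = rng.permutation(y)
        js.append(youden_cutoff(ct, perm, clusters).youden_j)
    assert np.median(js) < 0.15


def test_youden_input_validation():
    with pytest.raises(ValueError):
        youden_cutoff([1, 2, 3], [1, 1, 1], list("abc"))
    with pytest.raises(ValueError):
        youden_cutoff([5, 5, 5], [1, 0, 1], list("abc"))


# ---------------------------------------------------------------------------
# FD% mixed model


def test_fd_mixed_model_contract(rng):
    df = simulate_fd_percent_table(rng)
    res = fit_fd_mixed_model(df)
    assert len(res.contrasts) == 4
    # adjusted p >= raw p and adjusted CIs contain raw CIs
    assert (res.contrasts.p_adj >= res.contrasts.p_raw - 1e-15).all()
    assert (res.contrasts.ci_low_adj <= res.contrasts.ci_low + 1e-12).all()
    assert (res.contrasts.ci_high_adj >= res.contrasts.ci_high - 1e-12).all()
    assert res.n_obs == int((~df.drusen).sum())
    assert res.random_intercept_var > 0


def test_fd_mixed_model_is_deterministic(rng):
    df = simulate_fd_percent_table(rng)
    a = fit_fd_mixed_model(df)
    b = fit_fd_mixed_model(df)
    pd.testing.assert_frame_equal(a.contrasts, b.contrasts)


def test_fd_mixed_model_recovers_known_contrasts(rng):
    ests_lcv, ests_orient = [], []
    for _ in range(15):
        df = simulate_fd_percent_table(rng, lcv_effect_iamd=-1.3, orientation_effect=-1.16)
        res = fit_fd_mixed_model(df)
        ests_lcv.append(res.contrasts.loc["lcv_within_iamd", "estimate"])
        ests_orient.append(res.fixed_effects.loc["nasal", "estimate"])
    assert np.mean(ests_lcv) == pytest.approx(-1.3, abs=0.35)
    assert np.mean(ests_orient) == pytest.approx(-1.16, abs=0.25)


def test_fd_mixed_model_input_validation(rng):
    df = simulate_fd_percent_table(rng, n_iamd=3, n_control=1)
    with pytest.raises(ValueError):
        fit_fd_mixed_model(df)  # one control eye only
    df2 = simulate_fd_percent_table(rng)
    df2["lcv"] = False
    with pytest.raises(ValueError):
        fit_fd_mixed_model(df2)


# ---------------------------------------------------------------------------
# random-intercept logistic


def _lcv_frame(rng, n_eyes=80, sigma_u=0.0, beta_ct=np.log(0.94), nasal_shift=0.0):
    rows = []
    for i in range(n_eyes):
        u = rng.normal(0, sigma_u)
        for j in range(4):
            nasal = j in (1, 2)
            ct = max(30, rng.normal(150, 60))
            p = 1 / (1 + np.exp(-(7.3 + beta_ct * ct + nasal_shift * nasal + u)))
            rows.append(
                dict(
                    eye_id=f"e{i}",
                    group="iamd" if i % 2 else "control",
                    ct_um=ct,
                    orientation="nasal" if nasal else "temporal",
                    lcv=bool(rng.random() < p),
                )
            )
    return pd.DataFrame(rows)


def test_glmm_reduces_to_plain_logistic_without_clustering(rng):
    import statsmodels.api as sm

    df = _lcv_frame(rng, sigma_u=0.0)
    res = fit_lcv_glmm(df, predictors=("ct",))
    X = sm.add_constant(df.ct_um.to_numpy())
    plain = sm.Logit(df.lcv.astype(float).to_numpy(), X).fit(disp=0)
    assert res.terms["ct"].log_or == pytest.approx(plain.params[1], abs=5e-3)
    assert res.random_intercept_sd < 0.5


def test_glmm_matches_lme4_reference(tmp_path, rng):
    """Cross-check the quadrature fit against glmer (nAGQ=25) on one dataset."""
    df = _lcv_frame(rng, n_eyes=60, sigma_u=1.5, nasal_shift=1.0)
    res = fit_lcv_glmm(df, predictors=("ct", "orientation"))
    csv = tmp_path / "d.csv"
    df.assign(y=df.lcv.astype(int), nasal=(df.orientation == "nasal").astype(int)).to_csv(
        csv, index=False
    )
    script = tmp_path / "m.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ ct_um + nasal + (1|eye_id), data=d, family=binomial, nAGQ=25)
            cat(sprintf("%.8f %.8f %.8f\\n", fixef(m)["ct_um"], fixef(m)["nasal"],
                        sqrt(unlist(VarCorr(m)))))
            """
        )
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    ).stdout.split()
    beta_ct, beta_nasal, sigma = map(float, out[:3])
    assert res.terms["ct"].log_or == pytest.approx(beta_ct, abs=1e-4)
    assert res.terms["orientation"].log_or == pytest.approx(beta_nasal, abs=1e-3)
    assert res.random_intercept_sd == pytest.approx(sigma, abs=1e-3)


def test_glmm_is_deterministic(rng):
    df = _lcv_frame(rng, sigma_u=1.0)
    a = fit_lcv_glmm(df, predictors=("ct",))
    b = fit_lcv_glmm(df, predictors=("ct",))
    assert a.terms["ct"].log_or == b.terms["ct"].log_or
    assert a.random_intercept_sd == b.random_intercept_sd


def test_glmm_flags_separation_without_crashing():
    df = pd.DataFrame(
        dict(
            eye_id=[f"e{i}" for i in range(20)],
            ct_um=np.r_[np.full(10, 80.0), np.full(10, 220.0)],
            orientation=["nasal"] * 20,
            group=["iamd"] * 20,
            lcv=[True] * 10 + [False] * 10,
        )
    )
    res = fit_lcv_glmm(df, predictors=("ct",))
    assert res.separation


def test_glmm_single_class_outcome_raises(rng):
    df = _lcv_frame(rng)
    df["lcv"] = True
    with pytest.raises(ValueError):
        fit_lcv_glmm(df, predictors=("ct",))


def test_univariate_multivariable_selection(rng):
    df = _lcv_frame(rng, n_eyes=100, sigma_u=0.5, nasal_shift=1.8)
    models = fit_lcv_models(df)
    assert "univariate:ct" in models and "univariate:orientation" in models
    # ct and orientation are both strong, so the multivariable model carries
    # their interaction as well
    assert "multivariable" in models
    assert "ct:orientation" in models["multivariable"].terms


# ---------------------------------------------------------------------------
# eye-level logistic


def test_eye_level_logistic_recovery(rng):
    beta = np.log(0.982)
    ors = []
    for _ in range(10):
        cct = rng.normal(200, 80, 300)
        p = 1 / (1 + np.exp(-(3.5 + beta * cct)))
        df = pd.DataFrame(dict(eye_id=range(300), lcv_any=rng.random(300) < p, cct_um=cct))
        ors.append(fit_eye_level_logistic(df, "cct").terms["cct"].odds_ratio)
    assert 0.976 <= np.mean(ors) <= 0.989


def test_eye_level_logistic_single_class_raises(rng):
    df = pd.DataFrame(dict(eye_id=range(20), lcv_any=[True] * 20, cct_um=rng.normal(200, 80, 20)))
    with pytest.raises(ValueError):
        fit_eye_level_logistic(df, "cct")


def test_eye_level_logistic_null_predictor_calibration(rng):
    hits = 0
    for _ in range(30):
        df = pd.DataFrame(
            dict(
                eye_id=range(120),
                lcv_any=rng.random(120) < 0.5,
                cct_um=rng.normal(200, 80, 120),
            )
        )
        t = fit_eye_level_logistic(df, "cct").terms["cct"]
        hits += abs(t.log_or) < 3 * t.se
    assert hits >= 27  # ~93% of null fits stay within 3 SE


# ---------------------------------------------------------------------------
# property tests


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(1, 4)).filter(lambda t: t[0] <= t[1]),
        min_size=2,
        max_size=30,
    ),
    st.floats(0.5, 0.999),
)
def test_cluster_ratio_ci_always_brackets_the_estimate(clusters, level):
    x = [c[0] for c in clusters]
    n = [c[1] for c in clusters]
    p, lo, hi = cluster_ratio_ci(x, n, level)
    assert 0.0 <= lo <= p <= hi <= 1.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10), st.integers(1, 8))
def test_bonferroni_is_monotone_and_capped(ps, m):
    adj = bonferroni_adjust(ps, m)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
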