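import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apakit.config import SurvivalConfig
from apakit.quantify import compute_psi
from apakit.simulate import (ClinicalConfig, ReadDesign, beta_for_group_hr,
                             make_cohort_truth, simulate_clinical,
                             simulate_pair_counts)
from apakit.survival import (PrognosticModel, cox_log_partial_likelihood,
                             fit_pi_model, loocv_prognostic_index,
                             select_features_lasso, stratify_and_logrank)

from _oracles import logrank_chi2


def cohort(n_samples=60, n_genes=12, betas=None, seed=0, depth=300):
    truth = make_cohort_truth(n_genes, 0.0, 0.0, seed=seed,
                              survival_betas=betas or {})
    prox, dist, meta, _ = simulate_pair_counts(
        truth, ReadDesign(n_pairs=n_samples, depth=depth), seed=seed + 1)
    psi = compute_psi(prox, dist)
    tumor = [c for c in psi.columns if c.endswith("T")]
    psi = psi[tumor]
    clin = simulate_clinical(truth, psi, ClinicalConfig(), seed=seed + 2)
    return psi, clin, truth


# ---------------------------------------------------------------------------
# PI arithmetic

def test_pi_equation_arithmetic():
    beta = pd.Series({"g1": 0.5, "g2": -1.0})
    model = PrognosticModel(genes=["g1", "g2"], beta=beta,
                            covariate_coef=pd.Series(dtype=float),
                            pi=pd.Series(dtype=float))
    psi = pd.DataFrame({"k": [0.4, 0.2]}, index=["g1", "g2"])
    assert model.predict_pi(psi)["k"] == pytest.approx(0.0)


def test_zero_betas_give_zero_pi():
    beta = pd.Series({"g1": 0.0, "g2": 0.0})
    model = PrognosticModel(genes=["g1", "g2"], beta=beta,
                            covariate_coef=pd.Series(dtype=float),
                            pi=pd.Series(dtype=float))
    psi = pd.DataFrame({"a": [0.3, 0.9], "b": [0.1, 0.5]},
                       index=["g1", "g2"])
    assert (model.predict_pi(psi) == 0).all()


def test_fitted_pi_is_exactly_sum_beta_chi():
    psi, clin, _ = cohort(n_samples=50, seed=3)
    model = fit_pi_model(psi, clin, selected=list(psi.index[:3]))
    chi = psi.loc[model.genes, model.pi.index].T
    manual = (chi * model.beta).sum(axis=1)
    assert np.max(np.abs(model.pi - manual)) < 1e-12


def test_pi_monotone_in_positive_beta_gene():
    beta = pd.Series({"g1": 1.5})
    model = PrognosticModel(genes=["g1"], beta=beta,
                            covariate_coef=pd.Series(dtype=float),
                            pi=pd.Series(dtype=float))
    low = pd.DataFrame({"k": [0.2]}, index=["g1"])
    high = pd.DataFrame({"k": [0.8]}, index=["g1"])
    assert model.predict_pi(high)["k"] > model.predict_pi(low)["k"]


# ---------------------------------------------------------------------------
# lasso selection

def test_infinite_penalty_selects_nothing():
    psi, clin, _ = cohort(n_samples=60, seed=5)
    assert select_features_lasso(psi, clin, alpha=1e6) == []


def test_lasso_recovers_planted_genes():
    beta = beta_for_group_hr(4.0, 0.1)
    hits = 0
    for s in range(3):
        psi, clin, truth = cohort(n_samples=80, n_genes=25,
                                  betas={"G0001": beta, "G0002": beta},
                                  seed=20 + s)
        sel = select_features_lasso(psi, clin, seed=s)
        hits += {"G0001", "G0002"} <= set(sel)
    assert hits >= 2


def test_null_selection_is_sparse():
    sizes = []
    for s in range(3):
        psi, clin, _ = cohort(n_samples=60, n_genes=20, seed=40 + s)
        sizes.append(len(select_features_lasso(psi, clin, seed=s)))
    assert np.median(sizes) <= 4


def test_zero_events_is_an_error():
    psi, clin, _ = cohort(n_samples=50, seed=7)
    clin["event"] = 0
    with pytest.raises(ValueError, match="events"):
        select_features_lasso(psi, clin)


def test_too_few_samples_is_an_error():
    psi, clin, _ = cohort(n_samples=20, seed=8)
    with pytest.raises(ValueError, match="minimum"):
        select_features_lasso(psi, clin)


# ---------------------------------------------------------------------------
# Cox machinery

def test_cox_recovers_known_coefficient():
    rng = np.random.default_rng(11)
    n = 500
    x = rng.normal(size=n)
    beta_true = 0.7
    t = rng.exponential(1.0 / (0.1 * np.exp(beta_true * x)))
    clin = pd.DataFrame({"time": np.minimum(t, 50),
                         "event": (t <= 50).astype(int)},
                        index=[f"s{i}" for i in range(n)])
    psi = pd.DataFrame([x], index=["g1"], columns=clin.index)
    model = fit_pi_model(psi, clin, covariates=(), selected=["g1"])
    assert abs(model.beta["g1"] - beta_true) < 0.15


def test_breslow_partial_likelihood_simple_case():
    # two subjects, no ties: ll = b*x1 - log(e^{bx1}+e^{bx2}) + 0
    X = np.array([[1.0], [0.0]])
    time = np.array([1.0, 2.0])
    event = np.array([1, 1])
    b = np.array([0.5])
    expected = (0.5 - np.logaddexp(0.5, 0.0)) + 0.0
    got = cox_log_partial_likelihood(X, time, event, b)
    assert got == pytest.approx(expected)


def test_singular_design_names_columns():
    psi, clin, _ = cohort(n_samples=50, seed=13)
    psi.loc["G0002"] = psi.loc["G0001"]     # perfectly collinear
    with pytest.raises(ValueError, match="singular"):
        fit_pi_model(psi, clin, covariates=(),
                     selected=["G0001", "G0002"])


# ---------------------------------------------------------------------------
# LOOCV

def test_loocv_returns_one_pi_per_sample():
    psi, clin, _ = cohort(n_samples=15, seed=17)
    pi = loocv_prognostic_index(psi, clin, list(psi.index[:2]),
                                covariates=())
    assert len(pi) == len(clin)            # one held-out PI per sample
    assert set(pi.index) == set(clin.index)


def test_loocv_minimum_size():
    psi, clin, _ = cohort(n_samples=15, seed=18)
    with pytest.raises(ValueError, match="10"):
        loocv_prognostic_index(psi[psi.columns[:5]], clin.iloc[:5],
                               list(psi.index[:1]))


def test_loocv_stable_on_duplicated_noiseless_data():
    # deterministic linear-hazard toy duplicated so each fold barely changes;
    # held-out PI must approximate the full fit relative to the PI spread
    x = np.tile(np.linspace(-1, 1, 12), 8)
    t = np.exp(-0.8 * x) * np.tile(np.linspace(1, 2, 12), 8)
    clin = pd.DataFrame({"time": t, "event": 1},
                        index=[f"s{i}" for i in range(96)])
    psi = pd.DataFrame([x], index=["g1"], columns=clin.index)
    full = fit_pi_model(psi, clin, covariates=(), selected=["g1"])
    held = loocv_prognostic_index(psi, clin, ["g1"], covariates=())
    spread = full.pi.max() - full.pi.min()
    assert np.max(np.abs(held - full.pi)) < 0.02 * spread


# ---------------------------------------------------------------------------
# stratification + log-rank

def test_identical_groups_give_null_logrank():
    rng = np.random.default_rng(21)
    n = 80
    clin = pd.DataFrame({"time": rng.exponential(10, n), "event": 1},
                        index=[f"s{i}" for i in range(n)])
    pi = pd.Series(rng.normal(size=n), index=clin.index)  # unrelated PI
    rep = stratify_and_logrank(pi, clin, covariates=())
    assert rep.p > 0.01


def test_source_orientation_labels_high_pi_low_risk():
    rng = np.random.default_rng(22)
    clin = pd.DataFrame({"time": rng.exponential(10, 20), "event": 1},
                        index=[f"s{i}" for i in range(20)])
    pi = pd.Series(np.arange(20.0), index=clin.index)
    rep = stratify_and_logrank(pi, clin, covariates=())
    assert (rep.groups[pi > pi.median()] == "low-risk").all()
    rep2 = stratify_and_logrank(pi, clin, covariates=(),
                                orientation="conventional")
    assert (rep2.groups[pi > pi.median()] == "high-risk").all()


def test_all_identical_pi_is_an_error():
    clin = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]},
                        index=list("abc"))
    with pytest.raises(ValueError, match="identical"):
        stratify_and_logrank(pd.Series([1.0, 1.0, 1.0], index=clin.index),
                             clin, covariates=())


def test_single_event_does_not_crash():
    clin = pd.DataFrame({"time": [5.0] * 10, "event": [1] + [0] * 9},
                        index=[f"s{i}" for i in range(10)])
    pi = pd.Series(np.arange(10.0), index=clin.index)
    rep = stratify_and_logrank(pi, clin, covariates=())
    assert rep.p > 0.2


def test_logrank_matches_hand_computation_on_six_subjects():
    times_a, events_a = [1.0, 4.0, 6.0], [1, 1, 0]
    times_b, events_b = [2.0, 5.0, 7.0], [1, 0, 1]
    clin = pd.DataFrame({"time": times_a + times_b,
                         "event": events_a + events_b},
                        index=[f"s{i}" for i in range(6)])
    pi = pd.Series([0, 0, 0, 1, 1, 1.0], index=clin.index)
    rep = stratify_and_logrank(pi, clin, covariates=())
    expected = logrank_chi2(times_b, events_b, times_a, events_a)
    assert rep.chi2 == pytest.approx(expected, rel=1e-6)


def test_null_logrank_p_uniform_over_seeds():
    pvals = []
    for s in range(200):
        rng = np.random.default_rng(1000 + s)
        n = 40
        t = rng.exponential(10, n)
        clin = pd.DataFrame({"time": np.minimum(t, 30),
                             "event": (t <= 30).astype(int)},
                            index=[f"s{i}" for i in range(n)])
        pi = pd.Series(rng.normal(size=n), index=clin.index)
        rep = stratify_and_logrank(pi, clin, covariates=())
        pvals.append(rep.p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
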