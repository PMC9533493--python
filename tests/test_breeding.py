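import numpy as np
import pandas as pd
import pytest

from microbreed import breeding
from microbreed.breeding import (
    VarianceComponents,
    aggregate_rank,
    assemble_covariance,
    bend_to_pd,
    ebv_accuracy,
    predict_goal_ebvs,
    response_to_selection,
    selection_intensity,
    selection_report,
)
from microbreed.gblup import McmcConfig


# -- covariance assembly ------------------------------------------------------


def _pair_row(a, b, cov_g, vga, vgb, cov_e=0.0, vea=1.0, veb=1.0):
    return {
        "trait_a": a, "trait_b": b, "cov_g": cov_g,
        "var_g_a": vga, "var_g_b": vgb,
        "cov_e": cov_e, "var_e_a": vea, "var_e_b": veb,
    }


def test_assemble_two_traits():
    vc = assemble_covariance(pd.DataFrame([_pair_row("A", "B", 0.3, 0.8, 0.6)]))
    assert vc.trait_ids == ["A", "B"]
    assert np.allclose(vc.sigma_g, [[0.8, 0.3], [0.3, 0.6]])
    assert np.allclose(vc.sigma_e, [[1.0, 0.0], [0.0, 1.0]])


def test_assemble_three_traits_diagonal_is_mean_of_pair_estimates():
    rows = [
        _pair_row("A", "B", 0.1, 1.0, 0.5),
        _pair_row("A", "C", 0.2, 1.2, 0.7),
        _pair_row("B", "C", 0.3, 0.7, 0.9),
    ]
    vc = assemble_covariance(pd.DataFrame(rows))
    # trait A's variance was estimated as 1.0 (with B) and 1.2 (with C)
    assert vc.genomic_variance("A") == pytest.approx(1.1)
    assert vc.genomic_variance("B") == pytest.approx(0.6)
    assert vc.genomic_variance("C") == pytest.approx(0.8)
    assert vc.sigma_g[0, 1] == pytest.approx(0.1)
    assert vc.sigma_g[1, 2] == pytest.approx(0.3)


def test_assemble_missing_and_duplicate_pairs_rejected():
    rows = [
        _pair_row("A", "B", 0.1, 1.0, 0.5),
        _pair_row("A", "C", 0.2, 1.2, 0.7),
    ]
    with pytest.raises(ValueError, match="missing"):
        assemble_covariance(pd.DataFrame(rows))
    with pytest.raises(ValueError, match="more than once"):
        assemble_covariance(
            pd.DataFrame([_pair_row("A", "B", 0.1, 1.0, 0.5)] * 2)
        )


def test_variance_components_subset_and_validation():
    vc = assemble_covariance(
        pd.DataFrame(
            [
                _pair_row("A", "B", 0.1, 1.0, 0.5),
                _pair_row("A", "C", 0.2, 1.0, 0.7),
                _pair_row("B", "C", 0.3, 0.5, 0.7),
            ]
        )
    )
    sub = vc.subset(["C", "A"])
    assert sub.trait_ids == ["C", "A"]
    assert sub.sigma_g[0, 1] == pytest.approx(0.2)
    with pytest.raises(ValueError, match="symmetric"):
        VarianceComponents(["A", "B"], np.array([[1.0, 0.5], [0.2, 1.0]]), np.eye(2))


# -- bending ------------------------------------------------------------------


def test_bend_hand_example_2x2():
    m = np.array([[1.0, 1.2], [1.2, 1.0]])  # eigenvalues -0.2 and 2.2
    bent, report = bend_to_pd(m, tolerance=0.001)
    assert report["changed"]
    assert report["min_eig_before"] == pytest.approx(-0.2)
    assert np.linalg.eigvalsh(bent).min() == pytest.approx(0.001, abs=1e-12)
    # eigenvectors are (1,1)/sqrt2 and (1,-1)/sqrt2: closed-form reconstruction
    expected = np.array([[1.1005, 1.0995], [1.0995, 1.1005]])
    assert np.allclose(bent, expected, atol=1e-12)


def test_bend_idempotent_and_pd_unchanged():
    m = np.array([[1.0, 1.2], [1.2, 1.0]])
    bent, _ = bend_to_pd(m)
    again, report2 = bend_to_pd(bent)
    assert not report2["changed"]
    assert np.allclose(again, bent)
    pd_matrix = np.array([[2.0, 0.3], [0.3, 1.0]])
    out, report = bend_to_pd(pd_matrix)
    assert not report["changed"] and np.allclose(out, pd_matrix)


def test_bend_rejects_asymmetric():
    with pytest.raises(ValueError):
        bend_to_pd(np.array([[1.0, 0.5], [0.1, 1.0]]))


def test_vc_bend_records_log():
    vc = VarianceComponents(
        ["A", "B"], np.array([[1.0, 1.2], [1.2, 1.0]]), np.eye(2)
    )
    bent = vc.bend()
    assert bent.bending_log["sigma_g"]["changed"]
    assert not bent.bending_log["sigma_e"]["changed"]
    assert np.linalg.eigvalsh(bent.sigma_g).min() >= 0.001 - 1e-12


# -- accuracy -----------------------------------------------------------------


def test_accuracy_endpoints_and_half():
    assert ebv_accuracy(np.array([0.0]), np.array([1.0]), 1.0)[0] == 1.0
    assert ebv_accuracy(np.array([1.0]), np.array([1.0]), 1.0)[0] == 0.0
    assert ebv_accuracy(np.array([np.sqrt(0.5)]), np.array([1.0]), 1.0)[
        0
    ] == pytest.approx(np.sqrt(0.5))


def test_accuracy_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        acc = ebv_accuracy(np.array([1.2]), np.array([1.0]), 1.0)
    assert acc[0] == 0.0


def test_accuracy_strictly_decreasing_in_sd():
    sds = np.linspace(0.0, 1.0, 11)
    acc = ebv_accuracy(sds, np.ones(11), 1.0)
    assert np.all(np.diff(acc) < 0)


def test_accuracy_validation():
    with pytest.raises(ValueError):
        ebv_accuracy(np.array([0.1]), np.array([1.0]), 0.0)
    with pytest.raises(ValueError):
        ebv_accuracy(np.array([0.1]), np.array([-1.0]), 1.0)


# -- intensity ----------------------------------------------------------------


def test_intensity_printed_values():
    assert selection_intensity(0.30) == pytest.approx(1.159, abs=5e-4)
    assert selection_intensity(0.20) == pytest.approx(1.400, abs=5e-4)
    assert selection_intensity(0.10) == pytest.approx(1.755, abs=5e-4)
    assert selection_intensity(0.05) == pytest.approx(2.063, abs=5e-4)


def test_intensity_endpoints_and_half():
    assert selection_intensity(1.0) == 0.0
    assert selection_intensity(0.5) == pytest.approx(0.7979, abs=5e-4)
    for bad in (0.0, -0.1, 1.01):
        with pytest.raises(ValueError):
            selection_intensity(bad)


# -- aggregate ranking --------------------------------------------------------


def test_rank_single_goal_matches_ebv_order():
    ebvs = pd.DataFrame({"N3": [0.1, 0.9, 0.5]}, index=["x", "y", "z"])
    assert aggregate_rank(ebvs) == ["y", "z", "x"]


def test_rank_sum_example():
    ebvs = pd.DataFrame({"N3": [1.0, 0.6], "CLA": [0.0, 0.6]}, index=["a1", "a2"])
    assert aggregate_rank(ebvs) == ["a2", "a1"]  # 1.2 > 1.0


def test_rank_permutation_invariant_with_id_tiebreak():
    rng = np.random.default_rng(0)
    ebvs = pd.DataFrame(
        {"N3": rng.standard_normal(10), "CLA": rng.standard_normal(10)},
        index=[f"a{i}" for i in range(10)],
    )
    ebvs.loc["a3"] = ebvs.loc["a7"]  # exact tie broken by id
    perm = ebvs.sample(frac=1.0, random_state=1)
    assert aggregate_rank(ebvs) == aggregate_rank(perm)
    r = aggregate_rank(ebvs)
    assert r.index("a3") < r.index("a7")


# -- response to selection ----------------------------------------------------


def test_response_zero_under_equal_ebvs():
    draws = np.ones((50, 20)) * 3.7
    ids = [f"a{i}" for i in range(20)]
    out = response_to_selection(draws, ids, ids, 0.10, phenotypic_sd=1.0)
    assert out["response_mean"] == pytest.approx(0.0, abs=1e-12)
    assert out["n_selected"] == 2
    assert out["intensity"] == pytest.approx(1.755, abs=5e-4)


def test_response_iid_normal_matches_intensity():
    rng = np.random.default_rng(7)
    n = 20_000
    ebv = rng.standard_normal(n)
    ids = [f"a{i}" for i in range(n)]
    ranking = [ids[i] for i in np.argsort(-ebv)]
    out = response_to_selection(
        ebv[None, :], ranking, ids, 0.10, phenotypic_sd=1.0
    )
    assert out["response_mean"] == pytest.approx(selection_intensity(0.10), rel=0.02)


def test_response_monotone_in_intensity():
    rng = np.random.default_rng(9)
    ebv = rng.standard_normal(200)
    ids = [f"a{i}" for i in range(200)]
    ranking = [ids[i] for i in np.argsort(-ebv)]
    resp = [
        response_to_selection(ebv[None, :], ranking, ids, p, 1.0)["response_mean"]
        for p in (0.40, 0.30, 0.20, 0.10, 0.05)
    ]
    assert all(b >= a for a, b in zip(resp, resp[1:]))


def test_response_percent_of_mean_and_errors():
    draws = np.array([[1.0, 2.0, 3.0, 4.0]])
    ids = list("abcd")
    out = response_to_selection(
        draws, ["d", "c", "b", "a"], ids, 0.25, phenotypic_sd=2.0, trait_mean=5.0
    )
    # selected {d}: (4 - 2.5)/2 = 0.75 sd; percent: 0.75*2/5*100 = 30%
    assert out["response_mean"] == pytest.approx(0.75)
    assert out["response_pct_mean"] == pytest.approx(30.0)
    with pytest.raises(ValueError):
        response_to_selection(draws, ids, ids, 0.25, phenotypic_sd=0.0)
    with pytest.raises(ValueError):
        response_to_selection(draws, ids, ids, 0.01, phenotypic_sd=1.0)


# -- microbiome-driven prediction --------------------------------------------


def test_zero_genomic_covariance_gives_null_goal_ebvs(pop_small):
    # with no genomic (or residual) covariance between the observed feature
    # and the goal, the goal's EBV posterior mean stays near zero, while a
    # strong covariance produces clearly larger EBVs from the same data
    feature = pop_small.traits[["N3"]].rename(columns={"N3": "feat"})
    cfg = McmcConfig(n_iter=2000, burn_in=400, thin=2, seed=3)

    def run(cov):
        vc = VarianceComponents(
            ["feat", "goal"],
            np.array([[0.6, cov], [cov, 0.6]]),
            np.array([[0.4, 0.0], [0.0, 0.4]]),
        )
        return predict_goal_ebvs(
            feature, pop_small.grm, vc, pop_small.traits["fixed_level"],
            ["goal"], config=cfg,
        )

    null = run(0.0)
    strong = run(0.55)
    null_spread = float(null.ebv_mean["goal"].std())
    strong_spread = float(strong.ebv_mean["goal"].std())
    assert strong_spread > 3.0 * null_spread
    assert abs(null.ebv_mean["goal"].mean()) < 0.1


def test_predict_requires_pd_vc(pop_small):
    feature = pop_small.traits[["N3"]].rename(columns={"N3": "feat"})
    vc = VarianceComponents(
        ["feat", "goal"],
        np.array([[1.0, 1.2], [1.2, 1.0]]),  # indefinite: must bend first
        np.eye(2),
    )
    with pytest.raises(ValueError, match="positive definite"):
        predict_goal_ebvs(
            feature, pop_small.grm, vc, pop_small.traits["fixed_level"], ["goal"]
        )


def test_selection_report_structure():
    rng = np.random.default_rng(11)
    n = 30
    ids = [f"a{i}" for i in range(n)]
    ebv = pd.DataFrame(
        {"N3": rng.standard_normal(n), "CLA": rng.standard_normal(n)}, index=ids
    )
    res = breeding.EbvResult(
        ebv_mean=ebv,
        ebv_sd=ebv.abs() * 0.1,
        accuracy=ebv.abs() * 0.0 + 0.8,
        ebv_draws={t: rng.standard_normal((40, n)) + ebv[t].to_numpy() for t in ebv},
        grm_diag=pd.Series(np.ones(n), index=ids),
        genomic_variance={"N3": 1.0, "CLA": 1.0},
    )
    rep = selection_report(res, {"N3": 1.0, "CLA": 1.0}, proportions=(0.2, 0.1))
    assert set(rep.table["trait"]) == {"N3", "CLA"}
    assert len(rep.table) == 4
    assert rep.ranking == aggregate_rank(ebv)
    assert len(rep.selected[0.1]) == 3
    assert "Response to selection" in str(rep)
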