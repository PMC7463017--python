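"""Exact-inference unit and property tests for the two-layer network."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from erpathway.exceptions import ConfigurationError, UninformativeModelError
from erpathway.pathway_model import (
    PathwayModel,
    TargetGeneSpec,
    brute_force_posterior,
    build_model,
    compute_score_range,
    extreme_evidence,
    gene_likelihood_ratio,
    infer_log2_odds,
    normalize_score,
)
from conftest import random_gene


def posterior_from_log2_odds(log2_odds: float) -> float:
    return expit(log2_odds * math.log(2.0))


# -- strategies -------------------------------------------------------------

probs = st.floats(min_value=0.05, max_value=0.95)
evidence_vals = st.floats(min_value=0.0, max_value=1.0)


@st.composite
def gene_specs(draw, gene_id="G"):
    return TargetGeneSpec(
        gene_id,
        draw(probs),
        draw(probs),
        draw(probs),
        draw(probs),
    )


@st.composite
def models_with_evidence(draw, max_genes=5):
    n = draw(st.integers(min_value=1, max_value=max_genes))
    genes = [draw(gene_specs(gene_id=f"G{i}")) for i in range(n)]
    prior = draw(st.floats(min_value=0.1, max_value=0.9))
    try:
        model = build_model(genes, prior_active=prior)
    except UninformativeModelError:
        # vanishingly unlikely with continuous CPT draws, but legal
        model = None
    evidence = {
        g.gene_id: draw(evidence_vals)
        for g in genes
        if draw(st.booleans())
    }
    return model, evidence


# -- per-gene likelihood ratio ---------------------------------------------


@pytest.mark.parametrize(
    "gene",
    [
        TargetGeneSpec("G", 0.7, 0.7, 0.9, 0.1),  # identical regulation rows
        TargetGeneSpec("G", 0.95, 0.05, 0.4, 0.4),  # intensity blind to regulation
    ],
)
@pytest.mark.parametrize("e", [0.0, 0.25, 0.5, 1.0])
def test_uninformative_gene_has_unit_likelihood_ratio(gene, e):
    assert gene_likelihood_ratio(gene, e) == pytest.approx(1.0, abs=1e-12)
    assert not gene.is_informative


def test_gene_likelihood_ratio_matches_joint_enumeration(std_gene):
    """The factored per-gene LR equals the odds update of the enumerated joint."""
    model = PathwayModel(
        genes=(std_gene,), prior_active=0.5, log2_odds_min=-1.0, log2_odds_max=1.0
    )
    for e in (0.0, 0.3, 1.0):
        post = brute_force_posterior(model, {"G1": e})
        odds = post / (1.0 - post)  # prior odds are 1:1
        assert gene_likelihood_ratio(std_gene, e) == pytest.approx(odds, rel=1e-12)


@pytest.mark.parametrize("bad", [-0.01, 1.01, 5.0])
def test_evidence_outside_unit_interval_rejected(std_gene, bad):
    with pytest.raises(ValueError):
        gene_likelihood_ratio(std_gene, bad)


# -- factored inference -----------------------------------------------------


def test_neutral_prior_and_no_evidence_gives_zero_log2_odds(symmetric_model):
    res = infer_log2_odds(symmetric_model, {})
    assert res.log2_odds == 0.0
    assert res.n_genes_used == 0
    assert res.score == pytest.approx(50.0)


@pytest.mark.filterwarnings("ignore:log2 odds")
def test_uninformative_genes_leave_prior_odds(std_gene):
    uninf = TargetGeneSpec("U1", 0.6, 0.6, 0.8, 0.2)
    model = PathwayModel(
        genes=(uninf,), prior_active=0.7, log2_odds_min=-1.0, log2_odds_max=1.0
    )
    res = infer_log2_odds(model, {"U1": 0.3})
    assert res.log2_odds == pytest.approx(math.log2(0.7 / 0.3), abs=1e-12)


def test_three_gene_inference_matches_joint_enumeration():
    genes = [
        TargetGeneSpec("A", 0.95, 0.05, 0.9, 0.1),
        TargetGeneSpec("B", 0.85, 0.2, 0.7, 0.35),
        TargetGeneSpec("C", 0.6, 0.3, 0.25, 0.8),  # repressed intensity link
    ]
    model = build_model(genes, prior_active=0.5)
    evidence = {"A": 1.0, "B": 0.5, "C": 0.0}
    res = infer_log2_odds(model, evidence)
    post = brute_force_posterior(model, evidence)
    assert posterior_from_log2_odds(res.log2_odds) == pytest.approx(post, abs=1e-10)
    assert res.n_genes_used == 3


def test_missing_genes_are_marginalised(symmetric_model):
    full = infer_log2_odds(symmetric_model, {"G1": 0.9, "G2": 0.4})
    assert full.n_genes_used == 2
    partial = infer_log2_odds(symmetric_model, {"G1": 0.9})
    delta = abs(full.log2_odds - partial.log2_odds)
    g2 = symmetric_model.genes[1]
    lo, hi = g2.log2_lr_bounds()
    assert delta <= (hi - lo) + 1e-12


def test_empty_model_is_a_configuration_error():
    model = PathwayModel(
        genes=(), prior_active=0.5, log2_odds_min=-1.0, log2_odds_max=1.0
    )
    with pytest.raises(ConfigurationError):
        infer_log2_odds(model, {})


def test_unknown_evidence_key_rejected(symmetric_model):
    with pytest.raises(ConfigurationError):
        infer_log2_odds(symmetric_model, {"NOPE": 0.5})


# -- brute-force oracle ------------------------------------------------------


def test_brute_force_without_evidence_returns_prior(symmetric_model):
    assert brute_force_posterior(symmetric_model, {}) == pytest.approx(0.5)


def test_brute_force_single_gene_hand_bayes(std_gene):
    # P(high|active) = .95*.9 + .05*.1 = .86; P(high|inactive) = .14;
    # with a 1:1 prior the posterior is .86 / (.86 + .14) = .86
    model = build_model([std_gene], prior_active=0.5)
    assert brute_force_posterior(model, {"G1": 1.0}) == pytest.approx(0.86, abs=1e-12)


def test_brute_force_refuses_large_models(rng):
    genes = [random_gene(rng, f"G{i}") for i in range(13)]
    model = build_model(genes)
    with pytest.raises(ValueError, match="refuses"):
        brute_force_posterior(model, {})


def test_brute_force_chunked_enumeration_consistent(rng):
    """The > 8 gene enumeration path agrees with factored inference."""
    genes = [random_gene(rng, f"G{i}") for i in range(10)]
    model = build_model(genes)
    evidence = {g.gene_id: float(rng.uniform()) for g in genes[::2]}
    post = brute_force_posterior(model, evidence)
    res = infer_log2_odds(model, evidence)
    assert posterior_from_log2_odds(res.log2_odds) == pytest.approx(post, abs=1e-10)


@given(models_with_evidence())
def test_factored_inference_equals_joint_enumeration(model_and_evidence):
    model, evidence = model_and_evidence
    if model is None:
        return
    res = infer_log2_odds(model, evidence)
    post = brute_force_posterior(model, evidence)
    assert abs(posterior_from_log2_odds(res.log2_odds) - post) < 1e-10


@given(gene_specs(), st.floats(0, 1), st.floats(0, 1))
def test_score_monotone_in_aligned_evidence(gene, e1, e2):
    assoc = (gene.p_high_given_up - gene.p_high_given_down) * (
        gene.p_up_given_active - gene.p_up_given_inactive
    )
    lr1 = gene_likelihood_ratio(gene, e1)
    lr2 = gene_likelihood_ratio(gene, e2)
    if e1 <= e2:
        if assoc > 0:
            assert lr1 <= lr2 + 1e-12
        elif assoc < 0:
            assert lr1 >= lr2 - 1e-12


@given(models_with_evidence())
def test_scores_always_within_bounds(model_and_evidence):
    model, evidence = model_and_evidence
    if model is None:
        return
    res = infer_log2_odds(model, evidence)
    assert 0.0 <= res.score <= 100.0


# -- score range and normalisation ------------------------------------------


def test_symmetric_gene_range_is_symmetric(std_gene):
    lo, hi = compute_score_range([std_gene], prior_active=0.5)
    assert hi == pytest.approx(-lo, abs=1e-12)


def test_uninformative_gene_does_not_change_range(std_gene):
    lo, hi = compute_score_range([std_gene], 0.5)
    uninf = TargetGeneSpec("U", 0.5, 0.5, 0.9, 0.1)
    lo2, hi2 = compute_score_range([std_gene, uninf], 0.5)
    assert (lo2, hi2) == (pytest.approx(lo), pytest.approx(hi))


def test_all_uninformative_model_rejected():
    uninf = TargetGeneSpec("U", 0.5, 0.5, 0.9, 0.1)
    with pytest.raises(UninformativeModelError):
        compute_score_range([uninf], 0.5)
    with pytest.raises(UninformativeModelError):
        build_model([uninf])


def test_range_matches_grid_search(rng):
    genes = [random_gene(rng, f"G{i}") for i in range(3)]
    model = build_model(genes, prior_active=0.4)
    grid = np.linspace(0.0, 1.0, 11)
    totals = []
    for e0 in grid:
        for e1 in grid:
            for e2 in grid:
                ev = {"G0": e0, "G1": e1, "G2": e2}
                totals.append(infer_log2_odds(model, ev).log2_odds)
    assert min(totals) == pytest.approx(model.log2_odds_min, abs=1e-9)
    assert max(totals) == pytest.approx(model.log2_odds_max, abs=1e-9)


def test_extreme_evidence_attains_exact_score_bounds(rng):
    genes = [random_gene(rng, f"G{i}") for i in range(5)]
    model = build_model(genes, prior_active=0.37)
    assert infer_log2_odds(model, extreme_evidence(model, "max")).score == 100.0
    assert infer_log2_odds(model, extreme_evidence(model, "min")).score == 0.0


def test_midpoint_normalises_to_fifty(symmetric_model):
    mid = (symmetric_model.log2_odds_min + symmetric_model.log2_odds_max) / 2.0
    assert normalize_score(symmetric_model, mid) == pytest.approx(50.0)


def test_out_of_range_odds_clamped_with_warning(symmetric_model):
    with pytest.warns(UserWarning, match="clamping"):
        score = normalize_score(symmetric_model, symmetric_model.log2_odds_max + 1.0)
    assert score == 100.0


def test_degenerate_range_rejected(std_gene):
    with pytest.raises(UninformativeModelError):
        PathwayModel(
            genes=(std_gene,), prior_active=0.5, log2_odds_min=1.0, log2_odds_max=1.0
        )


# -- serialisation -----------------------------------------------------------


def test_model_round_trip_is_lossless(tmp_path, rng, calibrated):
    _, result = calibrated
    path = tmp_path / "model.yaml"
    result.model.save(path)
    loaded = PathwayModel.load(path)
    assert loaded.platform == result.model.platform
    assert loaded.prior_active == result.model.prior_active
    for a, b in zip(loaded.genes, result.model.genes):
        for f in (
            "p_up_given_active",
            "p_up_given_inactive",
            "p_high_given_up",
            "p_high_given_down",
        ):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)
    assert loaded.log2_odds_min == pytest.approx(result.model.log2_odds_min, rel=1e-12)
    assert loaded.log2_odds_max == pytest.approx(result.model.log2_odds_max, rel=1e-12)
    assert loaded.intensity_map is not None
    for gid, entry in result.intensity_map.items():
        got = loaded.intensity_map[gid]
        assert got.mu_high == pytest.approx(entry.mu_high, rel=1e-12)
        assert got.direction == entry.direction
    # identical scoring behaviour
    ev = extreme_evidence(loaded, "max")
    assert infer_log2_odds(loaded, ev).score == 100.0
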