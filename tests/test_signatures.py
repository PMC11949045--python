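"""Signature refitting, NMF extraction and matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobec_emt import (
    CHANNELS_96,
    MutationCatalog,
    SignatureMatrix,
    apobec_fraction,
    build_catalog,
    cosine_similarity,
    example_signatures,
    fit_exposures,
    match_signatures,
    mixture_distribution,
    nmf_extract,
    relative_contribution,
    sample_variants,
)
from apobec_emt.signatures import grid_search_relative


def _catalog(columns: dict) -> MutationCatalog:
    return MutationCatalog(
        pd.DataFrame(columns, index=list(CHANNELS_96)).astype(float)
    )


def test_pure_signature_refits_to_itself(signature_set):
    counts = np.round(100 * signature_set["SBS2"])
    cat = _catalog({"s": counts})
    res = fit_exposures(cat, signature_set)
    assert res.relative.loc["s", "SBS2"] > 0.99
    assert res.reconstruction_residual["s"] < 0.05
    assert res.cosine_to_data["s"] > 0.999


def test_orthogonal_mixture_recovers_exact_weights(orthogonal_pair):
    mix = 60 * orthogonal_pair["sigA"] + 40 * orthogonal_pair["sigB"]
    res = fit_exposures(_catalog({"s": mix}), orthogonal_pair)
    np.testing.assert_allclose(
        res.relative.loc["s"].to_numpy(), [0.6, 0.4], atol=1e-9
    )
    # grid-search oracle agrees
    w = grid_search_relative(mix, orthogonal_pair, step=1e-3)
    np.testing.assert_allclose(w, [0.6, 0.4], atol=1e-3)


def test_empty_reference_rejected(signature_set):
    cat = _catalog({"s": np.ones(96)})
    empty = SignatureMatrix(signature_set.profiles[[]])
    with pytest.raises(ValueError):
        fit_exposures(cat, empty)


def test_all_zero_sample_flagged(signature_set):
    res = fit_exposures(_catalog({"s": np.zeros(96)}), signature_set)
    assert (res.absolute.loc["s"] == 0).all()
    assert res.relative.loc["s"].isna().all()
    assert np.isnan(res.reconstruction_residual["s"])


def test_relative_contribution_sums_subset(signature_set):
    counts = np.round(
        1000
        * mixture_distribution(signature_set, {"SBS2": 0.1, "SBS13": 0.1, "SBS5": 0.8})
    )
    res = fit_exposures(_catalog({"s": counts}), signature_set)
    total = relative_contribution(res, signature_set.names)
    np.testing.assert_allclose(total["s"], 1.0, atol=1e-9)
    pair = relative_contribution(res, ["SBS2", "SBS13"])
    assert pair["s"] == pytest.approx(
        res.relative.loc["s", "SBS2"] + res.relative.loc["s", "SBS13"]
    )
    with pytest.raises(KeyError):
        relative_contribution(res, ["SBS99"])


def test_grid_search_oracle_matches_nnls(reference_100kb, signature_set):
    """Exhaustive simplex enumeration at 1e-3 agrees with NNLS refitting
    within 2e-3 in every weight, for 2 and 3 signatures."""
    for names, weights in [
        (["SBS2", "SBS5"], {"SBS2": 0.3, "SBS5": 0.7}),
        (["SBS2", "SBS5", "SBS18"], {"SBS2": 0.25, "SBS5": 0.55, "SBS18": 0.2}),
    ]:
        sub = signature_set.subset(names)
        mix = mixture_distribution(signature_set, weights)
        variants = sample_variants(reference_100kb, mix, 4000, seed=17)
        cat = build_catalog(variants, reference_100kb)
        nnls_rel = fit_exposures(cat, sub).relative.iloc[0].to_numpy()
        grid_rel = grid_search_relative(cat.counts.iloc[:, 0].to_numpy(), sub)
        np.testing.assert_allclose(nnls_rel, grid_rel, atol=2e-3)


def test_refit_nesting(reference_100kb, signature_set):
    """Residual with the full reference set never exceeds the residual of
    the best single signature."""
    mix = mixture_distribution(signature_set, {"SBS2": 0.4, "SBS5": 0.6})
    variants = sample_variants(reference_100kb, mix, 2000, seed=21)
    cat = build_catalog(variants, reference_100kb)
    full = fit_exposures(cat, signature_set).reconstruction_residual.iloc[0]
    singles = [
        fit_exposures(cat, signature_set.subset([n])).reconstruction_residual.iloc[0]
        for n in signature_set.names
    ]
    assert full <= min(singles) + 1e-12


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.floats(min_value=0.1, max_value=50), st.integers(0, 2**31 - 1))
def test_scale_equivariance(scale, seed):
    """Scaling a sample's counts by c scales absolute exposures by c and
    leaves relative contributions unchanged."""
    sigs = example_signatures()
    rng = np.random.default_rng(seed)
    counts = rng.poisson(200 * mixture_distribution(sigs, {"SBS2": 0.3, "SBS5": 0.7}))
    base = fit_exposures(_catalog({"s": counts.astype(float)}), sigs)
    scaled = fit_exposures(_catalog({"s": counts * scale}), sigs)
    np.testing.assert_allclose(
        scaled.absolute.loc["s"], base.absolute.loc["s"] * scale, rtol=1e-6, atol=1e-9
    )
    np.testing.assert_allclose(
        scaled.relative.loc["s"], base.relative.loc["s"], atol=1e-9
    )


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 1, 0, 0], [1, 0, 0, 0], 1 / np.sqrt(2)),
        ([1, 0], [0, 1], 0.0),
        ([2, 3], [2, 3], 1.0),
    ],
)
def test_cosine_similarity_values(a, b, expected):
    assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)


def test_cosine_similarity_zero_vector_rejected():
    with pytest.raises(ValueError):
        cosine_similarity([0, 0], [1, 0])


def test_match_signatures_recovers_permutation(signature_set):
    permuted = SignatureMatrix(
        signature_set.profiles[["SBS5", "SBS13", "SBS1", "SBS18", "SBS2"]].set_axis(
            [f"d{i}" for i in range(5)], axis=1
        )
    )
    matches = match_signatures(permuted, signature_set)
    recovered = {d: r for d, r, _, _ in matches}
    assert recovered == {"d0": "SBS5", "d1": "SBS13", "d2": "SBS1", "d3": "SBS18", "d4": "SBS2"}
    assert all(c == pytest.approx(1.0) for _, _, c, _ in matches)


def test_match_single_denovo_takes_argmax(signature_set):
    single = SignatureMatrix(
        signature_set.profiles[["SBS13"]].set_axis(["d"], axis=1)
    )
    ref3 = signature_set.subset(["SBS2", "SBS13", "SBS5"])
    [(d, r, c, assigned)] = match_signatures(single, ref3)
    assert (d, r) == ("d", "SBS13")
    assert c == pytest.approx(1.0)
    assert assigned


def test_rank1_nmf_recovers_pooled_spectrum(reference_100kb, signature_set):
    """Rank-1 KL-NMF has a closed form: the signature is the pooled
    normalized spectrum."""
    mix = mixture_distribution(signature_set, {"SBS2": 0.5, "SBS5": 0.5})
    variants = []
    for i in range(4):
        variants += sample_variants(
            reference_100kb, mix, 1000, seed=30 + i, sample_id=f"s{i}"
        )
    cat = build_catalog(variants, reference_100kb)
    res = nmf_extract(cat, rank=1, n_restarts=3, seed=0)
    pooled = cat.matrix().sum(axis=1)
    pooled = pooled / pooled.sum()
    np.testing.assert_allclose(
        res.signatures.matrix().ravel(), pooled, atol=1e-6
    )
    # exposures recover each sample's total mutation count
    np.testing.assert_allclose(
        res.exposures.to_numpy().ravel(), cat.totals().to_numpy(), rtol=1e-6
    )


def test_nmf_objective_trace_non_increasing(reference_100kb, signature_set):
    mix = mixture_distribution(signature_set, {"SBS2": 0.5, "SBS5": 0.5})
    variants = []
    for i in range(6):
        variants += sample_variants(
            reference_100kb, mix, 800, seed=60 + i, sample_id=f"s{i}"
        )
    cat = build_catalog(variants, reference_100kb)
    res = nmf_extract(cat, rank=2, n_restarts=4, seed=1)
    diffs = np.diff(res.objective_trace)
    assert (diffs <= 1e-8 * np.maximum(np.abs(res.objective_trace[:-1]), 1.0)).all()


def test_nmf_rank_bounds(reference_100kb, signature_set):
    mix = mixture_distribution(signature_set, {"SBS5": 1.0})
    variants = sample_variants(reference_100kb, mix, 500, seed=2)
    cat = build_catalog(variants, reference_100kb)
    with pytest.raises(ValueError):
        nmf_extract(cat, rank=0)
    with pytest.raises(ValueError):
        nmf_extract(cat, rank=2)  # only one sample


def test_nmf_objective_competitive_with_sklearn(reference_100kb, signature_set):
    """Independent cross-check: our multiplicative-update KL-NMF reaches an
    objective at least as good as scikit-learn's KL-NMF (within 2%)."""
    sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
    rng = np.random.default_rng(3)
    variants = []
    for i in range(10):
        w = rng.uniform(0, 1)
        mix = mixture_distribution(signature_set, {"SBS2": w, "SBS5": 1 - w})
        variants += sample_variants(
            reference_100kb, mix, 1500, seed=int(rng.integers(2**31 - 1)), sample_id=f"s{i}"
        )
    cat = build_catalog(variants, reference_100kb)
    ours = nmf_extract(cat, rank=2, n_restarts=5, seed=4)
    V = cat.matrix()
    model = sklearn_nmf(
        n_components=2,
        beta_loss="kullback-leibler",
        solver="mu",
        init="random",
        max_iter=2000,
        random_state=0,
        tol=1e-6,
    )
    W = model.fit_transform(V)
    H = model.components_
    R = np.maximum(W @ H, 1e-12)
    mask = V > 0
    kl_sklearn = float(
        (V[mask] * np.log(V[mask] / R[mask])).sum() - V.sum() + R.sum()
    )
    assert ours.objective_trace[-1] <= kl_sklearn * 1.02 + 1e-6
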