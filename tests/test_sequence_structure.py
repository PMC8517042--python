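"""Entropy orders, Markov models and sparse PLS-DA against independent
oracles."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from usvsyntax.call_dataset import CALL_TYPES
from usvsyntax.sequence_structure import (
    EntropyProfile,
    compare_entropy,
    entropy_group_tests,
    entropy_profile,
    entropy_table,
    fit_markov,
    fit_splsda,
    score_separation,
)
from conftest import make_sequence


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def entropy_oracle(calls, k):
    """Independent tabulation: H0 from the repertoire, H1 from frequencies,
    and Hk (k>=2) as joint k-gram entropy minus the entropy of the k-gram
    prefix marginal (chain rule), all in bits."""

    def h(counter):
        total = sum(counter.values())
        return -sum(c / total * math.log2(c / total) for c in counter.values())

    if k == 0:
        return math.log2(len(set(calls)))
    if k == 1:
        return h(Counter(calls))
    if len(calls) < k:
        return float("nan")
    grams = Counter(tuple(calls[i:i + k]) for i in range(len(calls) - k + 1))
    prefixes = Counter()
    for gram, c in grams.items():
        prefixes[gram[:-1]] += c
    return h(grams) - h(prefixes)


def test_entropy_degenerate_sequence():
    """A pup repeating one call type has zero entropy at every order."""
    prof = entropy_profile(make_sequence(["F"] * 20))
    assert all(prof.H[k] == pytest.approx(0.0, abs=1e-12) for k in range(5))


def test_entropy_alternating_sequence_hand_values():
    """[F,D,F,D,F]: two types (H0=1), frequencies 0.6/0.4, deterministic
    alternation (H2=0)."""
    prof = entropy_profile(make_sequence(["F", "D", "F", "D", "F"]))
    assert prof.H[0] == pytest.approx(1.0)
    assert prof.H[1] == pytest.approx(-(0.6 * math.log2(0.6) + 0.4 * math.log2(0.4)))
    assert prof.H[2] == pytest.approx(0.0, abs=1e-12)


def test_entropy_matches_oracle_on_random_sequences(rng):
    for _ in range(100):
        n = int(rng.integers(11, 120))
        calls = [CALL_TYPES[i] for i in rng.integers(0, 12, n)]
        prof = entropy_profile(make_sequence(calls))
        for k in range(5):
            assert prof.H[k] == pytest.approx(entropy_oracle(calls, k), abs=1e-12)


def test_entropy_short_sequence_flags_missing_orders():
    prof = entropy_profile(make_sequence(["F", "D", "U"]))
    assert math.isnan(prof.H[4])
    assert not math.isnan(prof.H[3])
    with pytest.raises(ValueError):
        entropy_profile(make_sequence([]))


def _profile(pup, geno, age, h1):
    H = {0: 1.0, 1: h1, 2: h1 / 2, 3: h1 / 3, 4: h1 / 4}
    return EntropyProfile(pup_id=pup, genotype=geno, age=age, H=H)


def _profile_family(wt_h1, del_h1):
    profs = []
    for age in ("P8", "P12"):
        profs += [_profile(f"w{i}{age}", "WT", age, v) for i, v in enumerate(wt_h1)]
        profs += [_profile(f"d{i}{age}", "DEL", age, v) for i, v in enumerate(del_h1)]
    return profs


def test_compare_entropy_separated_groups():
    """Fully separated groups at order 1: U=0, exact two-sided p = 0.1."""
    profs = _profile_family([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    res, p_bh = compare_entropy(profs, order=1, age="P8")
    assert res.statistic == 0
    assert res.p == pytest.approx(0.1, abs=1e-12)
    assert p_bh >= res.p  # BH never lowers a p-value


def test_compare_entropy_family_is_bh_corrected():
    profs = _profile_family([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    table = entropy_group_tests(profs)
    assert len(table) == 10  # 5 orders x 2 ages
    from usvsyntax.stats_util import bh_adjust
    assert np.allclose(table["p_bh"], bh_adjust(table["p"].to_numpy()))
    with pytest.raises(ValueError, match="empty"):
        entropy_group_tests([p for p in profs if p.genotype == "WT"])


# ---------------------------------------------------------------------------
# Markov models
# ---------------------------------------------------------------------------

def test_fit_markov_single_repeating_sequence():
    model = fit_markov([make_sequence(["A", "A", "A"])], top_k=8, min_count=1)
    assert model.counts.loc["A", "A"] == 2
    assert model.probs.loc["A", "A"] == pytest.approx(1.0)
    assert model.probs.loc["F"].sum() == 0.0  # unused source rows stay zero


def test_fit_markov_toy_probabilities():
    """Transitions F→D x3 and F→F x1 give P(F→D) = 0.75."""
    model = fit_markov([make_sequence(["F", "D", "F", "D", "F", "F", "D"])],
                       min_count=1, top_k=20)
    assert model.counts.loc["F", "D"] == 3
    assert model.counts.loc["F", "F"] == 1
    assert model.probs.loc["F", "D"] == pytest.approx(0.75)
    rendered = [f"{a}→{b}" for a, b, _ in model.frequent_edges]
    assert "D→F" in rendered and "F→D" in rendered


def test_fit_markov_edges_respect_min_count_and_top_k():
    seqs = [make_sequence(["Ts", "Ts"] * 10 + ["U", "F"])]
    model = fit_markov(seqs, top_k=1, min_count=5)
    assert len(model.frequent_edges) == 1
    assert model.frequent_edges[0][:2] == ("Ts", "Ts")


def test_fit_markov_stable_under_pup_permutation(rng):
    from usvsyntax.synthetic_data import SimConfig, simulate_calls

    cfg = SimConfig(n_pups={"WT": 8, "DEL": 0}, ages=("P8",), seed=11)
    seqs = simulate_calls(cfg)
    a = fit_markov(seqs, group=("WT", "P8"))
    order = rng.permutation(len(seqs))
    b = fit_markov([seqs[i] for i in order], group=("WT", "P8"))
    assert a.frequent_edges == b.frequent_edges
    pd.testing.assert_frame_equal(a.counts, b.counts)


# ---------------------------------------------------------------------------
# Sparse PLS-DA
# ---------------------------------------------------------------------------

def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def test_splsda_single_informative_feature(rng):
    """With one feature equal to the class label and keepX=1, component 1
    loads on that feature only and its scores separate the classes."""
    n = 24
    y = np.array(["a"] * 12 + ["b"] * 12)
    X = rng.standard_normal((n, 8))
    X[:, 3] = (y == "b").astype(float)  # noiseless class indicator
    model = fit_splsda(pd.DataFrame(X), y, keep_x=1, n_components=2)
    support = np.nonzero(model.loadings["comp1"].to_numpy())[0]
    assert list(support) == [3]
    s = model.scores["comp1"].to_numpy()
    assert (s[y == "b"].min() > s[y == "a"].max()) or (s[y == "b"].max() < s[y == "a"].min())


def test_splsda_keepx_all_matches_svd_oracle(rng):
    """With no sparsity, component 1 equals the dominant left singular
    vector of standardized-X' x centered one-hot Y (sign convention: first
    nonzero loading positive)."""
    X = rng.standard_normal((10, 6))
    y = np.array(["a", "b"] * 5)
    model = fit_splsda(pd.DataFrame(X), y, keep_x=None, n_components=1)
    Xs = _standardize(X)
    Y = np.column_stack([(y == c).astype(float) for c in ("a", "b")])
    Y = Y - Y.mean(axis=0)
    U, _, _ = np.linalg.svd(Xs.T @ Y, full_matrices=False)
    w = U[:, 0]
    if w[np.nonzero(w)[0][0]] < 0:
        w = -w
    assert np.allclose(model.loadings["comp1"].to_numpy(), w, atol=1e-8)


def test_splsda_loadings_unit_norm_and_sparsity_budget(rng):
    X = rng.standard_normal((30, 12))
    y = np.array(["a", "b"] * 15)
    model = fit_splsda(pd.DataFrame(X), y, keep_x=4, n_components=2)
    for comp in ("comp1", "comp2"):
        w = model.loadings[comp].to_numpy()
        assert np.count_nonzero(w) <= 4
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)


def test_splsda_rejects_bad_keepx(rng):
    X = pd.DataFrame(rng.standard_normal((10, 4)))
    y = ["a", "b"] * 5
    with pytest.raises(ValueError):
        fit_splsda(X, y, keep_x=0)
    with pytest.raises(ValueError):
        fit_splsda(X, y, keep_x=5)
    with pytest.raises(ValueError):
        fit_splsda(X, ["a"] * 10)  # one class


def test_splsda_permuted_labels_within_null_band(rng):
    """Separation under one permuted labeling is not an outlier of the
    permutation null built from further shuffles."""
    X = pd.DataFrame(rng.standard_normal((24, 10)))
    y = np.array(["a", "b"] * 12)
    observed = score_separation(
        fit_splsda(X, rng.permutation(y), keep_x=3), component=1
    )
    null = np.array([
        score_separation(fit_splsda(X, rng.permutation(y), keep_x=3), component=1)
        for _ in range(200)
    ])
    lo, hi = np.quantile(null, [0.025, 0.975])
    assert lo <= observed <= hi
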