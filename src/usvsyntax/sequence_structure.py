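"""Sequence-structure analyses: multi-order entropy, Markov models, sPLS-DA.

Entropy orders quantify how nonrandomly pups compose call sequences:

* H0 — log2 of the repertoire size (number of distinct types used);
* H1 — Shannon entropy of the call-type frequencies (bits);
* Hk (k>=2) — plug-in conditional entropy of the next call given the
  preceding k-1 calls, computed from the sequence's k-gram counts.

Per-genotype first-order Markov models summarize which two-call connections
are frequent, and sparse PLS discriminant analysis projects the 144
transition-probability features into a low-dimensional space that separates
classes with a per-component cap (``keep_x``) on nonzero loadings.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .call_dataset import AGES, CALL_INDEX, CALL_TYPES, CallSequence
from .stats_util import TestResult, bh_adjust, mann_whitney

logger = logging.getLogger(__name__)

N_TYPES = len(CALL_TYPES)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyProfile:
    """Entropy orders 0..max for one pup at one age; NaN where the sequence
    is too short to supply a single k-gram."""

    pup_id: str
    genotype: str
    age: str
    H: dict[int, float]


def _entropy_bits(counts: Iterable[int]) -> float:
    n = np.array([c for c in counts if c > 0], dtype=float)
    total = n.sum()
    if total == 0:
        return 0.0
    p = n / total
    return float(-(p * np.log2(p)).sum())


def entropy_profile(seq: CallSequence, max_order: int = 4) -> EntropyProfile:
    """Compute H0..H(max_order) for one sequence.

    Conventions: 0*log0 = 0; Hk for k>=2 averages per-context entropies
    weighted by context frequency among the sequence's k-grams.
    """
    calls = seq.calls
    if len(calls) == 0:
        raise ValueError(f"pup {seq.pup_id} {seq.age}: empty sequence")
    H: dict[int, float] = {0: float(np.log2(len(set(calls))))}
    H[1] = _entropy_bits(Counter(calls).values())
    for k in range(2, max_order + 1):
        if len(calls) < k:
            H[k] = float("nan")
            continue
        grams = Counter(tuple(calls[i:i + k]) for i in range(len(calls) - k + 1))
        total = sum(grams.values())
        by_context: dict[tuple, list[int]] = {}
        for gram, c in grams.items():
            by_context.setdefault(gram[:-1], []).append(c)
        h = 0.0
        for counts in by_context.values():
            h += sum(counts) / total * _entropy_bits(counts)
        H[k] = h
    return EntropyProfile(pup_id=seq.pup_id, genotype=seq.genotype, age=seq.age, H=H)


def entropy_table(profiles: Sequence[EntropyProfile]) -> pd.DataFrame:
    """Long-format table: pup_id, genotype, age, order, H."""
    rows = [
        {"pup_id": p.pup_id, "genotype": p.genotype, "age": p.age, "order": k, "H": h}
        for p in profiles
        for k, h in sorted(p.H.items())
    ]
    return pd.DataFrame(rows, columns=["pup_id", "genotype", "age", "order", "H"])


def entropy_group_tests(
    profiles: Sequence[EntropyProfile],
    orders: Sequence[int] = (0, 1, 2, 3, 4),
    ages: Sequence[str] = AGES,
) -> pd.DataFrame:
    """Genotype comparison of each entropy order at each age.

    Two-sided Mann-Whitney per (order, age) cell, Benjamini-Hochberg
    adjusted across the whole family (|orders| x |ages| tests).
    """
    table = entropy_table(profiles)
    rows = []
    for age in ages:
        for order in orders:
            sub = table[(table["age"] == age) & (table["order"] == order)].dropna(subset=["H"])
            wt = sub.loc[sub["genotype"] == "WT", "H"].to_numpy()
            dl = sub.loc[sub["genotype"] == "DEL", "H"].to_numpy()
            if wt.size == 0 or dl.size == 0:
                raise ValueError(f"entropy comparison at ({order}, {age}): a genotype group is empty")
            res = mann_whitney(wt, dl)
            rows.append({"age": age, "order": order, "U": res.statistic,
                         "p": res.p, "method": res.method, "n_WT": wt.size, "n_DEL": dl.size})
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def compare_entropy(
    profiles: Sequence[EntropyProfile], order: int, age: str
) -> tuple[TestResult, float]:
    """Mann-Whitney genotype comparison at one (order, age); returns the test
    and its BH-adjusted p within the full 5-order x 2-age family."""
    table = entropy_group_tests(profiles)
    row = table[(table["order"] == order) & (table["age"] == age)].iloc[0]
    return (
        TestResult(statistic=float(row["U"]), p=float(row["p"]),
                   method=str(row["method"]), exact="exact" in str(row["method"])),
        float(row["p_bh"]),
    )


# ---------------------------------------------------------------------------
# Markov models
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Pooled first-order Markov model of one (genotype, age) group."""

    group: tuple[str, str]
    counts: pd.DataFrame            # 12x12 integer counts pooled over pups
    probs: pd.DataFrame             # row-normalized MLE; all-zero undefined rows
    frequent_edges: list[tuple[str, str, float]]


def fit_markov(
    seqs: Sequence[CallSequence],
    group: tuple[str, str] | None = None,
    top_k: int = 8,
    min_count: int = 5,
) -> TransitionModel:
    """Pool two-call transition counts over pups and rank frequent edges.

    ``frequent_edges`` lists the ``top_k`` transitions with count >=
    ``min_count``, sorted by conditional probability (descending), breaking
    ties by count then alphabet order — a deterministic rendering of the
    group's most frequent call connections.
    """
    if group is not None:
        seqs = [s for s in seqs if (s.genotype, s.age) == group]
    if not seqs:
        raise ValueError(f"no sequences in group {group}")
    counts = np.zeros((N_TYPES, N_TYPES), dtype=int)
    for s in seqs:
        for a, b in zip(s.calls[:-1], s.calls[1:]):
            counts[CALL_INDEX[a], CALL_INDEX[b]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    edges = [
        (CALL_TYPES[i], CALL_TYPES[j], float(probs[i, j]))
        for i in range(N_TYPES)
        for j in range(N_TYPES)
        if counts[i, j] >= min_count
    ]
    edges.sort(key=lambda e: (-e[2], -counts[CALL_INDEX[e[0]], CALL_INDEX[e[1]]],
                              CALL_INDEX[e[0]], CALL_INDEX[e[1]]))
    idx = pd.Index(CALL_TYPES, name="from")
    cols = pd.Index(CALL_TYPES, name="to")
    return TransitionModel(
        group=group if group is not None else (seqs[0].genotype, seqs[0].age),
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        probs=pd.DataFrame(probs, index=idx, columns=cols),
        frequent_edges=edges[:top_k],
    )


# ---------------------------------------------------------------------------
# Sparse PLS discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class SplsdaModel:
    """Sparse PLS-DA fit: unit-norm sparse loadings and per-sample scores."""

    loadings: pd.DataFrame          # features x components
    scores: pd.DataFrame            # samples x components
    class_labels: pd.Series
    keep_x: tuple[int, ...]
    explained: tuple[float, ...]    # fraction of X variance carried by each score


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|w| entries, soft-thresholding them by the
    largest excluded magnitude, then renormalize to unit norm.

    If the kept and excluded magnitudes tie exactly (so soft-thresholding
    would annihilate the vector) the kept entries are hard-thresholded
    instead.
    """
    if keep >= w.size:
        out = w.copy()
    else:
        mags = np.abs(w)
        # threshold = largest excluded magnitude (ties broken by index order)
        order = np.argsort(-mags, kind="stable")
        thresh = mags[order[keep]]
        out = np.sign(w) * np.maximum(mags - thresh, 0.0)
        if not np.any(out):
            out = np.zeros_like(w)
            out[order[:keep]] = w[order[:keep]]
    norm = np.linalg.norm(out)
    if norm == 0:
        raise ValueError("zero loading vector; the cross-covariance is degenerate")
    return out / norm


def fit_splsda(
    X: pd.DataFrame,
    labels: Sequence,
    keep_x: int | Sequence[int] | None = None,
    n_components: int = 2,
) -> SplsdaModel:
    """NIPALS-style sparse PLS2 of standardized X against one-hot classes.

    Per component the loading vector is the dominant left singular vector of
    X'Y, soft-thresholded to at most ``keep_x`` nonzero weights and
    renormalized; X is deflated on the component score between components.
    Sign convention: the first nonzero loading of each component is positive.
    ``keep_x=None`` keeps all features (plain PLS-DA).
    """
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    labels = pd.Series(list(labels), index=X.index, name="class")
    classes = sorted(labels.unique(), key=str)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if keep_x is None:
        keeps = [p] * n_components
    elif np.isscalar(keep_x):
        keeps = [int(keep_x)] * n_components
    else:
        keeps = [int(k) for k in keep_x]
    for k in keeps:
        if not (1 <= k <= p):
            raise ValueError(f"keep_x must be in [1, {p}], got {k}")

    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xc = (Xv - mean) / scale
    total_var = float((Xc ** 2).sum())
    Y = np.column_stack([(labels == c).to_numpy(float) for c in classes])
    Y = Y - Y.mean(axis=0)

    Xd = Xc.copy()
    load_cols, score_cols, explained = [], [], []
    sigma_first = None
    for comp in range(n_components):
        M = Xd.T @ Y
        U, svals, _ = np.linalg.svd(M, full_matrices=False)
        if sigma_first is None:
            sigma_first = svals[0]
        if svals[0] <= 1e-10 * max(sigma_first, 1.0):
            # class structure fully deflated: no further informative component
            logger.warning("fit_splsda: stopping after %d component(s); "
                           "residual cross-covariance is numerically zero", comp)
            break
        w = U[:, 0]
        nz = np.nonzero(w)[0]
        if nz.size and w[nz[0]] < 0:
            w = -w
        w = _soft_threshold_keep(w, keeps[comp])
        nz = np.nonzero(w)[0]
        if nz.size and w[nz[0]] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate component: zero score variance")
        explained.append(float((np.outer(t, (Xd.T @ t) / tt) ** 2).sum()) / total_var)
        Xd = Xd - np.outer(t, (t @ Xd) / tt)
        load_cols.append(w)
        score_cols.append(t)

    if not load_cols:
        raise ValueError("no informative component: X carries no class-correlated variance")
    comp_names = [f"comp{i + 1}" for i in range(len(load_cols))]
    return SplsdaModel(
        loadings=pd.DataFrame(np.column_stack(load_cols), index=X.columns, columns=comp_names),
        scores=pd.DataFrame(np.column_stack(score_cols), index=X.index, columns=comp_names),
        class_labels=labels,
        keep_x=tuple(keeps),
        explained=tuple(explained),
    )


def score_separation(model: SplsdaModel, component: int = 2) -> float:
    """Absolute difference of class-mean scores on one component (1-based).

    With two classes this is the between-class separation statistic used by
    permutation tests of label informativeness.
    """
    col = f"comp{component}"
    means = model.scores[col].groupby(model.class_labels).mean()
    return float(abs(means.max() - means.min()))
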