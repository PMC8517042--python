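"""Candidate explanatory variables from call sequences.

Each pup's session is summarized into the predictor set used by the
selection models: per-type call counts and ratios, two-call transition
counts and conditional probabilities over the full 12x12 transition table,
per-pup acoustic means, and the numeric genotype code.  Feature names follow
the field's labelling convention: ``U(R)`` is the ratio of U calls,
``Fs→D(#)`` the count of Fs-to-D transitions, and ``Fs→D`` the conditional
probability of D given Fs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .call_dataset import (
    BEHAVIOR_NAMES,
    CALL_INDEX,
    CALL_TYPES,
    CORE_ACOUSTICS,
    GENOTYPE_CODE,
    CallSequence,
    DependentVariables,
)

logger = logging.getLogger(__name__)

ARROW = "→"  # →


def type_count_name(code: str) -> str:
    return f"{code}(#)"


def type_ratio_name(code: str) -> str:
    return f"{code}(R)"


def trans_count_name(src: str, dst: str, ascii_arrow: bool = False) -> str:
    arrow = "->" if ascii_arrow else ARROW
    return f"{src}{arrow}{dst}(#)"


def trans_prob_name(src: str, dst: str, ascii_arrow: bool = False) -> str:
    arrow = "->" if ascii_arrow else ARROW
    return f"{src}{arrow}{dst}"


def parse_feature_name(name: str) -> tuple[str | None, str | None, str]:
    """Split a feature name into (source call, target call, kind).

    kind is one of ``trans_count``, ``trans_prob``, ``type_count``,
    ``type_ratio`` or ``other`` (acoustic / genotype).  Transition features
    return both calls; type features return the call as source only.
    """
    base, kind = name, "prob"
    if name.endswith("(#)"):
        base, kind = name[:-3], "count"
    elif name.endswith("(R)"):
        return name[:-3], None, "type_ratio"
    arrow = ARROW if ARROW in base else ("->" if "->" in base else None)
    if arrow is not None:
        src, dst = base.split(arrow, 1)
        if src in CALL_INDEX and dst in CALL_INDEX:
            return src, dst, "trans_count" if kind == "count" else "trans_prob"
    if kind == "count" and base in CALL_INDEX:
        return base, None, "type_count"
    return None, None, "other"


def feature_columns(
    acoustic_params: Sequence[str] = CORE_ACOUSTICS, ascii_arrow: bool = False
) -> list[str]:
    """Canonical column order: 12 counts, 12 ratios, 144 transition counts,
    144 transition probabilities, acoustic means, genotype."""
    cols = [type_count_name(c) for c in CALL_TYPES]
    cols += [type_ratio_name(c) for c in CALL_TYPES]
    cols += [trans_count_name(i, j, ascii_arrow) for i in CALL_TYPES for j in CALL_TYPES]
    cols += [trans_prob_name(i, j, ascii_arrow) for i in CALL_TYPES for j in CALL_TYPES]
    cols += list(acoustic_params)
    cols.append("genotype")
    return cols


@dataclass
class FeatureVector:
    """Per-pup candidate predictors extracted from one call sequence."""

    pup_id: str
    genotype: str
    age: str
    total_calls: int
    type_count: dict[str, int]
    type_ratio: dict[str, float]
    trans_count: dict[tuple[str, str], int]
    trans_prob: dict[tuple[str, str], float]
    acoustic_summary: dict[str, float]

    def value(self, name: str) -> float:
        """Look a feature up by its rendered name (``U(R)``, ``Fs→D(#)`` ...)."""
        if name == "total_calls":
            return float(self.total_calls)
        if name == "genotype":
            return float(GENOTYPE_CODE[self.genotype])
        src, dst, kind = parse_feature_name(name)
        if kind == "type_count":
            return float(self.type_count.get(src, 0))
        if kind == "type_ratio":
            return float(self.type_ratio.get(src, 0.0))
        if kind == "trans_count":
            return float(self.trans_count.get((src, dst), 0))
        if kind == "trans_prob":
            return float(self.trans_prob.get((src, dst), 0.0))
        if name in self.acoustic_summary:
            return float(self.acoustic_summary[name])
        raise KeyError(f"unknown feature name {name!r}")


def extract_features(seq: CallSequence) -> FeatureVector:
    """Compute counts, ratios, transition counts/probabilities and per-pup
    acoustic means for one sequence.

    Transition probabilities are conditional on the source call; a source
    type never emitted (or emitted only as the final call) contributes an
    all-zero row so the assembled matrix is complete.  A single-call
    sequence has empty transition maps.
    """
    n = len(seq.calls)
    type_count = {c: 0 for c in CALL_TYPES}
    for c in seq.calls:
        type_count[c] += 1
    type_ratio = {c: (type_count[c] / n if n else 0.0) for c in CALL_TYPES}

    trans_count: dict[tuple[str, str], int] = {}
    for a, b in zip(seq.calls[:-1], seq.calls[1:]):
        trans_count[(a, b)] = trans_count.get((a, b), 0) + 1
    out_totals: dict[str, int] = {}
    for (a, _), k in trans_count.items():
        out_totals[a] = out_totals.get(a, 0) + k
    trans_prob = {(a, b): k / out_totals[a] for (a, b), k in trans_count.items()}

    acoustic_summary = {
        col: float(seq.acoustics[col].mean()) for col in seq.acoustics.columns
    }
    return FeatureVector(
        pup_id=seq.pup_id,
        genotype=seq.genotype,
        age=seq.age,
        total_calls=n,
        type_count=type_count,
        type_ratio=type_ratio,
        trans_count=trans_count,
        trans_prob=trans_prob,
        acoustic_summary=acoustic_summary,
    )


def features_frame(
    features: Iterable[FeatureVector],
    acoustic_params: Sequence[str] = CORE_ACOUSTICS,
) -> pd.DataFrame:
    """Assemble feature vectors into the wide analysis matrix.

    Rows are indexed by pup id; columns follow :func:`feature_columns`.
    """
    cols = feature_columns(acoustic_params)
    rows, index = [], []
    for fv in features:
        rows.append([fv.value(c) for c in cols])
        index.append(fv.pup_id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="pup_id"), columns=cols)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated pup id(s) in feature matrix: {dups}")
    return df


class AnalysisMatrix(NamedTuple):
    """Joined predictors X and dependent variables Y, row-aligned on pup."""

    X: pd.DataFrame
    Y: pd.DataFrame


def build_matrix(
    features: Sequence[FeatureVector],
    behaviors: Mapping[str, DependentVariables],
    join_key: Mapping[str, str] | None = None,
    acoustic_params: Sequence[str] = CORE_ACOUSTICS,
) -> AnalysisMatrix:
    """Inner-join features with dependent variables.

    ``behaviors`` maps mouse id to its derived dependent variables;
    ``join_key`` maps mouse id to pup id (identity when omitted).  A mouse
    mapping onto a pup already claimed by another mouse is an error;
    unmatched rows on either side are logged and dropped.
    """
    X_all = features_frame(features, acoustic_params)
    join_key = dict(join_key) if join_key is not None else {m: m for m in behaviors}
    pup_to_mouse: dict[str, str] = {}
    for mouse, pup in join_key.items():
        if pup in pup_to_mouse:
            raise ValueError(
                f"ambiguous join: pup {pup!r} claimed by mice "
                f"{pup_to_mouse[pup]!r} and {mouse!r}"
            )
        pup_to_mouse[pup] = mouse

    kept_pups = [p for p in X_all.index if p in pup_to_mouse and pup_to_mouse[p] in behaviors]
    dropped = len(X_all) - len(kept_pups)
    if dropped:
        logger.warning("build_matrix: dropped %d pup(s) without matching behavior", dropped)
    if not kept_pups:
        logger.warning("build_matrix: empty join — no pup matches a behavior record")
    X = X_all.loc[kept_pups]
    Y = pd.DataFrame(
        [behaviors[pup_to_mouse[p]].as_dict() for p in kept_pups],
        index=X.index,
        columns=list(BEHAVIOR_NAMES),
    )
    return AnalysisMatrix(X=X, Y=Y)
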