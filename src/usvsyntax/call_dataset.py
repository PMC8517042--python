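"""Domain types, CSV I/O, validation and inclusion filtering.

Neonatal mouse ultrasonic vocalizations (USVs) arrive as per-call annotation
tables: one row per call with pup identity, genotype (wild type ``+/+`` vs
hemizygous deletion ``Del/+``), recording age (postnatal day P8 or P12), the
1-based position of the call within the 5-minute session, the call-type code
(a 12-symbol alphabet of spectrographic categories) and per-call acoustic
parameters.  Postpubertal behavior arrives as per-mouse tables of
social-interaction times (two 5-minute sessions) and olfactory sniffing
times (7 odorants x 3 trials).

This module defines the in-memory containers, the CSV dialects, the
validators, the pup-inclusion filter (pups must emit more than ten calls at
the analysis age) and the derivation of the four dependent variables used by
the predictive analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 12-symbol call-type alphabet, in canonical order.
CALL_TYPES: tuple[str, ...] = (
    "Cx", "Ts", "Fs", "Ha", "C", "H", "Sh", "D", "F", "U", "A", "Un",
)
CALL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CALL_TYPES)}

#: Spectrographic wave classes of the call types.
MULTIPLE_WAVE = frozenset({"Cx", "Ts", "Fs", "Ha", "C"})
SIMPLE_WAVE = frozenset({"H", "Sh", "D", "F", "U"})
OTHER_WAVE = frozenset({"A", "Un"})

GENOTYPES: tuple[str, str] = ("WT", "DEL")
#: Numeric coding used wherever models need a number (DEL is the positive class).
GENOTYPE_CODE: dict[str, int] = {"WT": 0, "DEL": 1}
GENOTYPE_LABELS: dict[str, str] = {"WT": "+/+", "DEL": "Del/+"}
LABEL_TO_GENOTYPE: dict[str, str] = {v: k for k, v in GENOTYPE_LABELS.items()}

AGES: tuple[str, str] = ("P8", "P12")

#: Odorant codes of the olfactory habituation assay: water, almond, banana,
#: two male urines, re-exposure to the first urine, and deletion-carrier urine.
ODORANTS: tuple[str, ...] = ("W", "Al", "Ban", "Ur1", "Ur2", "Ur1r", "DelUr")
TRIALS: tuple[int, ...] = (1, 2, 3)

#: Acoustic parameters every call table must carry.  MaFmi is the maximum
#: frequency minimum of the entire call.
CORE_ACOUSTICS: tuple[str, ...] = ("duration_ms", "MaFmi_kHz")

CALL_TABLE_META_COLUMNS = ("pup_id", "genotype", "age", "order", "call_type")

#: Upper bound (seconds) on any social session / olfactory trial time.
DEFAULT_TIME_BOUND = 300.0


def wave_class(code: str) -> str:
    """Return ``multiple``, ``simple`` or ``other`` for a call-type code."""
    if code in MULTIPLE_WAVE:
        return "multiple"
    if code in SIMPLE_WAVE:
        return "simple"
    if code in OTHER_WAVE:
        return "other"
    raise ValueError(f"unknown call type code {code!r}")


def _canon_genotype(value: str) -> str:
    if value in GENOTYPE_CODE:
        return value
    if value in LABEL_TO_GENOTYPE:
        return LABEL_TO_GENOTYPE[value]
    raise ValueError(f"unknown genotype {value!r}; expected '+/+' or 'Del/+'")


@dataclass
class CallSequence:
    """The ordered calls of one pup at one age, with aligned acoustics.

    ``acoustics`` has one row per call (same order as ``calls``) and one
    column per acoustic parameter; ``duration_ms`` and ``MaFmi_kHz`` are
    always present.
    """

    pup_id: str
    genotype: str
    age: str
    calls: list[str]
    acoustics: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotype = _canon_genotype(self.genotype)
        if self.age not in AGES:
            raise ValueError(f"unknown age {self.age!r}")

    def __len__(self) -> int:
        return len(self.calls)

    def validate(self) -> None:
        if len(self.calls) < 1:
            raise ValueError(f"pup {self.pup_id} {self.age}: empty call sequence")
        bad = [c for c in self.calls if c not in CALL_INDEX]
        if bad:
            raise ValueError(f"pup {self.pup_id} {self.age}: unknown call types {sorted(set(bad))}")
        if len(self.acoustics) != len(self.calls):
            raise ValueError(
                f"pup {self.pup_id} {self.age}: acoustics length "
                f"{len(self.acoustics)} != calls length {len(self.calls)}"
            )
        for col in CORE_ACOUSTICS:
            if col not in self.acoustics.columns:
                raise ValueError(f"pup {self.pup_id} {self.age}: missing acoustic column {col}")
        vals = self.acoustics.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"pup {self.pup_id} {self.age}: non-finite acoustic value")
        if np.any(self.acoustics["duration_ms"].to_numpy() <= 0):
            raise ValueError(f"pup {self.pup_id} {self.age}: duration_ms must be > 0")


@dataclass
class BehaviorRecord:
    """Postpubertal readouts of one mouse.

    ``olfactory`` maps ``(odorant, trial)`` to sniffing seconds; missing
    entries are allowed and propagate as NaN through the derived variables.
    """

    mouse_id: str
    genotype: str
    social_s1: float
    social_s2: float
    olfactory: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotype = _canon_genotype(self.genotype)

    def validate(self, time_bound: float = DEFAULT_TIME_BOUND) -> None:
        for name, v in (("social_s1", self.social_s1), ("social_s2", self.social_s2)):
            if not math.isnan(v) and not (0.0 <= v <= time_bound):
                raise ValueError(f"mouse {self.mouse_id}: {name}={v} outside [0, {time_bound}]")
        for (od, trial), v in self.olfactory.items():
            if od not in ODORANTS:
                raise ValueError(f"mouse {self.mouse_id}: unknown odorant {od!r}")
            if trial not in TRIALS:
                raise ValueError(f"mouse {self.mouse_id}: unknown trial {trial}")
            if not math.isnan(v) and not (0.0 <= v <= time_bound):
                raise ValueError(
                    f"mouse {self.mouse_id}: olf_{od}_t{trial}={v} outside [0, {time_bound}]"
                )


#: Names of the four derived dependent variables, in canonical order.
BEHAVIOR_NAMES: tuple[str, ...] = (
    "social_interaction",
    "social_habituation",
    "olfactory_response",
    "olfactory_habituation",
)


@dataclass(frozen=True)
class DependentVariables:
    """The four behavioral readouts the predictive models target.

    social_interaction: Session 1 time; social_habituation: Session 1 -
    Session 2; olfactory_response: urine-odorant Trial 1 time;
    olfactory_habituation: Trial 1 - Trial 3.  Missing inputs give NaN.
    """

    social_interaction: float
    social_habituation: float
    olfactory_response: float
    olfactory_habituation: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BEHAVIOR_NAMES}


def derive_dependents(b: BehaviorRecord, odorant: str = "Ur1") -> DependentVariables:
    """Derive the four dependent variables from one behavior record.

    ``odorant`` selects which olfactory stimulus defines the response and
    habituation scores (default: urine of the first male).  A missing trial
    yields NaN; nothing is imputed.
    """
    if odorant not in ODORANTS:
        raise ValueError(f"unknown odorant {odorant!r}")
    t1 = b.olfactory.get((odorant, 1), float("nan"))
    t3 = b.olfactory.get((odorant, 3), float("nan"))
    return DependentVariables(
        social_interaction=b.social_s1,
        social_habituation=b.social_s1 - b.social_s2,
        olfactory_response=t1,
        olfactory_habituation=t1 - t3,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_call_table(path: str | Path) -> list[CallSequence]:
    """Read a per-call annotation CSV into one CallSequence per (pup, age).

    Expected columns: pup_id, genotype (``+/+`` or ``Del/+``), age
    (``P8``/``P12``), order (1-based within session), call_type, then the
    acoustic columns (``duration_ms`` and ``MaFmi_kHz`` required, extras
    kept).  UTF-8 with or without BOM.  Row numbers in error messages count
    the header as line 1.
    """
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in CALL_TABLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    acoustic_cols = [c for c in df.columns if c not in CALL_TABLE_META_COLUMNS]
    for col in CORE_ACOUSTICS:
        if col not in acoustic_cols:
            raise ValueError(f"{path}: missing acoustic column {col}")

    bad = ~df["call_type"].isin(CALL_TYPES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        codes = sorted(df.loc[bad, "call_type"].unique())
        raise ValueError(f"{path}: unknown call type code(s) {codes} at row(s) {rows}")

    seqs: list[CallSequence] = []
    for (pup_id, age), g in df.groupby(["pup_id", "age"], sort=True):
        orders = g["order"].to_numpy()
        dup = g["order"].duplicated()
        if dup.any():
            rows = (g.index[dup] + 2).tolist()
            raise ValueError(
                f"{path}: duplicate (pup_id, age, order) for pup {pup_id} {age} at row(s) {rows}"
            )
        g = g.sort_values("order")
        expected = np.arange(1, len(g) + 1)
        if not np.array_equal(np.sort(orders), expected):
            raise ValueError(
                f"{path}: gap in call order for pup {pup_id} {age}: "
                f"orders run {orders.min()}..{orders.max()} over {len(g)} rows"
            )
        genotypes = g["genotype"].unique()
        if len(genotypes) != 1:
            raise ValueError(f"{path}: conflicting genotype labels for pup {pup_id}")
        seq = CallSequence(
            pup_id=str(pup_id),
            genotype=str(genotypes[0]),
            age=str(age),
            calls=g["call_type"].tolist(),
            acoustics=g[acoustic_cols].reset_index(drop=True).astype(float),
        )
        seq.validate()
        seqs.append(seq)
    return seqs


def write_call_table(seqs: Iterable[CallSequence], path: str | Path) -> None:
    """Write call sequences back to the per-call CSV dialect."""
    frames = []
    for seq in seqs:
        n = len(seq.calls)
        meta = pd.DataFrame(
            {
                "pup_id": [seq.pup_id] * n,
                "genotype": [GENOTYPE_LABELS[seq.genotype]] * n,
                "age": [seq.age] * n,
                "order": np.arange(1, n + 1),
                "call_type": seq.calls,
            }
        )
        frames.append(pd.concat([meta, seq.acoustics.reset_index(drop=True)], axis=1))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(CALL_TABLE_META_COLUMNS) + list(CORE_ACOUSTICS)
    )
    out.to_csv(path, index=False)


def _olf_col(od: str, trial: int) -> str:
    return f"olf_{od}_t{trial}"


def read_behavior_table(
    path: str | Path, time_bound: float = DEFAULT_TIME_BOUND
) -> list[BehaviorRecord]:
    """Read the per-mouse behavior CSV (social sessions + olfactory trials)."""
    df = pd.read_csv(path, encoding="utf-8-sig")
    for col in ("mouse_id", "genotype", "social_s1", "social_s2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    records: list[BehaviorRecord] = []
    for _, row in df.iterrows():
        olf = {}
        for od in ODORANTS:
            for trial in TRIALS:
                col = _olf_col(od, trial)
                if col in df.columns:
                    olf[(od, trial)] = float(row[col])
        rec = BehaviorRecord(
            mouse_id=str(row["mouse_id"]),
            genotype=str(row["genotype"]),
            social_s1=float(row["social_s1"]),
            social_s2=float(row["social_s2"]),
            olfactory=olf,
        )
        rec.validate(time_bound=time_bound)
        records.append(rec)
    if df["mouse_id"].duplicated().any():
        dups = sorted(df.loc[df["mouse_id"].duplicated(), "mouse_id"].unique())
        raise ValueError(f"{path}: duplicated mouse_id(s) {dups}")
    return records


def write_behavior_table(records: Iterable[BehaviorRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "mouse_id": r.mouse_id,
            "genotype": GENOTYPE_LABELS[r.genotype],
            "social_s1": r.social_s1,
            "social_s2": r.social_s2,
        }
        for od in ODORANTS:
            for trial in TRIALS:
                row[_olf_col(od, trial)] = r.olfactory.get((od, trial), float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

def filter_pups(
    seqs: Sequence[CallSequence], min_calls: int = 11, age: str = "P8"
) -> list[CallSequence]:
    """Keep sequences of the given age with at least ``min_calls`` calls.

    The default threshold 11 is the strict reading of the inclusion rule
    "emitted more than ten calls": a pup with exactly 10 calls is excluded,
    one with 11 is kept.  Order-preserving and idempotent.
    """
    if min_calls < 1:
        raise ValueError("min_calls must be >= 1")
    at_age = [s for s in seqs if s.age == age]
    kept = [s for s in at_age if len(s.calls) >= min_calls]
    removed = len(at_age) - len(kept)
    if removed:
        logger.info("filter_pups: removed %d of %d pups at %s (< %d calls)",
                    removed, len(at_age), age, min_calls)
    return kept
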