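"""Synthetic USV datasets with the statistical structure the analyses assume.

Call sequences are generated per pup from genotype- and age-specific
first-order Markov chains over the 12-type alphabet, with negative-binomial
session lengths and per-call-type Gaussian acoustics.  Postpubertal behavior
is generated as a linear function of planted sequence features (applied
genotype-specifically) plus Gaussian noise, and the session/trial components
are back-solved so the derived dependent variables equal the planted linear
model exactly.

Each pup draws from its own counter-based substream of the global seed, so
enlarging a group never perturbs the data of previously generated pups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .call_dataset import (
    AGES,
    BEHAVIOR_NAMES,
    CALL_INDEX,
    CALL_TYPES,
    GENOTYPE_CODE,
    GENOTYPES,
    ODORANTS,
    TRIALS,
    BehaviorRecord,
    CallSequence,
)
from .sequence_features import extract_features

N_TYPES = len(CALL_TYPES)

#: Default group sizes mirror the study's P8 cohorts (33 wild type, 16 deletion).
DEFAULT_N_PUPS: dict[str, int] = {"WT": 33, "DEL": 16}

#: Two-call connections boosted in the default transition matrices.  At P8
#: the boosted sets differ by genotype (frequent connections of each group
#: plus the shared ones); at P12 both genotypes share one softer set, which
#: creates the developmental contrast in two-call usage.
_BOOSTED_EDGES: dict[tuple[str, str], list[tuple[str, str]]] = {
    ("WT", "P8"): [
        ("Ts", "Ts"), ("Fs", "Fs"), ("U", "F"), ("A", "A"), ("A", "F"),
        ("F", "F"), ("Ha", "H"), ("Fs", "D"),
    ],
    ("DEL", "P8"): [
        ("Ha", "Ha"), ("Ts", "F"), ("H", "D"), ("C", "F"),
        ("F", "F"), ("Ha", "H"), ("Fs", "F"),
    ],
    ("WT", "P12"): [("F", "F"), ("D", "D"), ("Sh", "Sh"), ("U", "U")],
    ("DEL", "P12"): [("F", "F"), ("D", "D"), ("Sh", "Sh"), ("U", "U")],
}


def default_transition_matrix(genotype: str, age: str, boost: float = 6.0) -> np.ndarray:
    """Row-stochastic 12x12 default matrix: uniform base plus boosted edges."""
    M = np.ones((N_TYPES, N_TYPES), dtype=float)
    for src, dst in _BOOSTED_EDGES[(genotype, age)]:
        M[CALL_INDEX[src], CALL_INDEX[dst]] += boost
    return M / M.sum(axis=1, keepdims=True)


def _default_matrices() -> dict[tuple[str, str], np.ndarray]:
    return {(g, a): default_transition_matrix(g, a) for g in GENOTYPES for a in AGES}


def _default_start() -> dict[tuple[str, str], np.ndarray]:
    return {(g, a): np.full(N_TYPES, 1.0 / N_TYPES) for g in GENOTYPES for a in AGES}


def _default_acoustics() -> dict[str, dict[str, tuple[float, float]]]:
    # Per-call-type normal (mean, sd); durations in ms, MaFmi in kHz.
    dur = {
        "Cx": (45.0, 9.0), "Ts": (60.0, 12.0), "Fs": (55.0, 11.0),
        "Ha": (50.0, 10.0), "C": (40.0, 8.0), "H": (30.0, 6.0),
        "Sh": (12.0, 3.0), "D": (28.0, 6.0), "F": (35.0, 7.0),
        "U": (32.0, 7.0), "A": (20.0, 5.0), "Un": (25.0, 6.0),
    }
    mafmi = {c: (55.0 + 1.5 * i, 4.0) for i, c in enumerate(CALL_TYPES)}
    return {"duration_ms": dur, "MaFmi_kHz": mafmi}


@dataclass(frozen=True)
class Effect:
    """One planted feature→behavior link, applied only within ``genotype``."""

    feature: str
    behavior: str
    genotype: str
    beta: float


def _default_effects() -> list[Effect]:
    # Genotype-specific links of the kind the predictive models look for:
    # the A→F transition probability drives social interaction in wild types,
    # Ha→H drives it in deletion carriers.
    return [
        Effect("A→F", "social_interaction", "WT", 120.0),
        Effect("Fs→D(#)", "social_interaction", "WT", -2.0),
        Effect("Ha→H", "social_interaction", "DEL", 90.0),
        Effect("H→D", "olfactory_habituation", "DEL", 30.0),
        Effect("U→C", "olfactory_response", "WT", 60.0),
    ]


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset.

    Defaults emulate the study conditions: P8 cohorts of 33 wild-type and 16
    deletion pups (each pup recorded at P8 and P12), ~60 calls per 5-minute
    session (negative binomial, dispersion 5), genotype/age-specific
    transition matrices, and genotype-specific planted behavior effects.
    """

    n_pups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PUPS))
    ages: tuple[str, ...] = AGES
    transition_matrices: dict[tuple[str, str], np.ndarray] = field(
        default_factory=_default_matrices
    )
    start_dist: dict[tuple[str, str], np.ndarray] = field(default_factory=_default_start)
    length_mean: float = 60.0
    length_dispersion: float = 5.0
    acoustic_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_acoustics
    )
    effect_spec: list[Effect] = field(default_factory=_default_effects)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {name: 8.0 for name in BEHAVIOR_NAMES}
    )
    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "social_interaction": 80.0,
            "social_habituation": 20.0,
            "olfactory_response": 30.0,
            "olfactory_habituation": 10.0,
        }
    )
    feature_age: str = "P8"
    seed: int = 0

    def validate(self) -> None:
        for key, M in self.transition_matrices.items():
            M = np.asarray(M, dtype=float)
            if M.shape != (N_TYPES, N_TYPES):
                raise ValueError(f"transition matrix {key}: shape {M.shape} != 12x12")
            if np.any(M < 0) or np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"transition matrix {key} is not row-stochastic")
        for key, s in self.start_dist.items():
            s = np.asarray(s, dtype=float)
            if s.shape != (N_TYPES,) or np.any(s < 0) or abs(s.sum() - 1.0) > 1e-12:
                raise ValueError(f"start distribution {key} is not a probability vector")
        if self.length_mean < 1 or self.length_dispersion <= 0:
            raise ValueError("length model requires mean >= 1 and dispersion > 0")


def _pup_rng(seed: int, genotype: str, pup_index: int, lane: int) -> np.random.Generator:
    # Counter-based substream: (genotype, pup, lane) keys a SeedSequence so
    # adding pups or lanes never shifts another pup's draws.
    key = (GENOTYPE_CODE[genotype], pup_index, lane)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _sample_length(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def simulate_calls(cfg: SimConfig) -> list[CallSequence]:
    """Generate call sequences for every pup at every configured age.

    The first call is drawn from the start distribution, each subsequent
    call from the transition-matrix row of the current call, and per-call
    acoustics from the call type's Gaussian model.  Byte-identical output
    for equal configs.
    """
    cfg.validate()
    seqs: list[CallSequence] = []
    for genotype in GENOTYPES:
        for i in range(cfg.n_pups.get(genotype, 0)):
            pup_id = f"{genotype}{i + 1:03d}"
            for age_idx, age in enumerate(cfg.ages):
                rng = _pup_rng(cfg.seed, genotype, i, age_idx)
                M = np.asarray(cfg.transition_matrices[(genotype, age)], dtype=float)
                start = np.asarray(cfg.start_dist[(genotype, age)], dtype=float)
                n = _sample_length(rng, cfg.length_mean, cfg.length_dispersion)
                states = np.empty(n, dtype=int)
                states[0] = rng.choice(N_TYPES, p=start)
                for t in range(1, n):
                    states[t] = rng.choice(N_TYPES, p=M[states[t - 1]])
                calls = [CALL_TYPES[s] for s in states]
                acoustics = {}
                for param, per_type in cfg.acoustic_model.items():
                    mu = np.array([per_type[c][0] for c in calls])
                    sd = np.array([per_type[c][1] for c in calls])
                    vals = rng.normal(mu, sd)
                    if param == "duration_ms":
                        vals = np.maximum(vals, 0.5)
                    acoustics[param] = vals
                seq = CallSequence(
                    pup_id=pup_id,
                    genotype=genotype,
                    age=age,
                    calls=calls,
                    acoustics=pd.DataFrame(acoustics),
                )
                seq.validate()
                seqs.append(seq)
    return seqs


def simulate_behavior(seqs: Sequence[CallSequence], cfg: SimConfig) -> list[BehaviorRecord]:
    """Generate behavior records whose derived dependents follow the planted
    linear model.

    For each of the four dependent variables: value = baseline + sum of
    beta * feature over effects matching the pup's genotype + N(0, noise_sd).
    Session/trial components are then back-solved (s2 = s1 - habituation;
    urine Trial 3 = Trial 1 - habituation) so the derived variables equal
    the planted model exactly.  Filler trials (non-target odorants, Trial 2)
    get baseline-plus-noise values clipped to the valid time range.
    """
    by_pup: dict[str, CallSequence] = {}
    for s in seqs:
        if s.age == cfg.feature_age:
            by_pup[s.pup_id] = s
    records: list[BehaviorRecord] = []
    for genotype in GENOTYPES:
        pups = sorted(p for p, s in by_pup.items() if s.genotype == genotype)
        for i, pup_id in enumerate(pups):
            fv = extract_features(by_pup[pup_id])
            rng = _pup_rng(cfg.seed, genotype, i, 99)
            dv: dict[str, float] = {}
            for name in BEHAVIOR_NAMES:
                val = cfg.baseline[name]
                for eff in cfg.effect_spec:
                    if eff.behavior == name and eff.genotype == genotype:
                        try:
                            val += eff.beta * fv.value(eff.feature)
                        except KeyError as exc:
                            raise ValueError(
                                f"effect_spec refers to unknown feature {eff.feature!r}"
                            ) from exc
                val += rng.normal(0.0, cfg.noise_sd[name])
                dv[name] = val
            # floor/ceiling censoring mimics the assay's bounded times; the
            # planted linear model is exact wherever the bounds do not bind
            s1 = float(np.clip(dv["social_interaction"], 0.0, 300.0))
            s2 = float(np.clip(s1 - dv["social_habituation"], 0.0, 300.0))
            t1 = float(np.clip(dv["olfactory_response"], 0.0, 300.0))
            t3 = float(np.clip(t1 - dv["olfactory_habituation"], 0.0, 300.0))
            olf: dict[tuple[str, int], float] = {}
            for od in ODORANTS:
                for trial in TRIALS:
                    if od == "Ur1" and trial == 1:
                        olf[(od, trial)] = t1
                    elif od == "Ur1" and trial == 3:
                        olf[(od, trial)] = t3
                    else:
                        base = cfg.baseline["olfactory_response"] * (0.8 ** (trial - 1))
                        v = base + rng.normal(0.0, cfg.noise_sd["olfactory_response"] / 2)
                        olf[(od, trial)] = float(np.clip(v, 0.0, 300.0))
            records.append(
                BehaviorRecord(
                    mouse_id=pup_id,
                    genotype=genotype,
                    social_s1=s1,
                    social_s2=s2,
                    olfactory=olf,
                )
            )
    return records


def simulate_dataset(cfg: SimConfig) -> tuple[list[CallSequence], list[BehaviorRecord]]:
    """Generate the full synthetic dataset (calls at all ages + behavior)."""
    seqs = simulate_calls(cfg)
    return seqs, simulate_behavior(seqs, cfg)


# ---------------------------------------------------------------------------
# Config file support
# ---------------------------------------------------------------------------

def config_from_dict(d: Mapping) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML/JSON payload).

    Only the keys present are overridden; matrices may be given as nested
    lists keyed by "GENOTYPE,AGE".
    """
    cfg = SimConfig()
    if "n_pups" in d:
        cfg.n_pups = {str(k): int(v) for k, v in d["n_pups"].items()}
    if "seed" in d:
        cfg.seed = int(d["seed"])
    for scalar in ("length_mean", "length_dispersion"):
        if scalar in d:
            setattr(cfg, scalar, float(d[scalar]))
    if "feature_age" in d:
        cfg.feature_age = str(d["feature_age"])
    if "transition_matrices" in d:
        cfg.transition_matrices = {
            tuple(k.split(",")): np.asarray(v, dtype=float)
            for k, v in d["transition_matrices"].items()
        }
    if "start_dist" in d:
        cfg.start_dist = {
            tuple(k.split(",")): np.asarray(v, dtype=float)
            for k, v in d["start_dist"].items()
        }
    if "noise_sd" in d:
        cfg.noise_sd.update({str(k): float(v) for k, v in d["noise_sd"].items()})
    if "baseline" in d:
        cfg.baseline.update({str(k): float(v) for k, v in d["baseline"].items()})
    if "effect_spec" in d:
        cfg.effect_spec = [
            Effect(str(e["feature"]), str(e["behavior"]), str(e["genotype"]), float(e["beta"]))
            for e in d["effect_spec"]
        ]
    return cfg


def read_sim_config(path: str | Path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    return config_from_dict(payload)
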