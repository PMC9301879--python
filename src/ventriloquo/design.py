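"""Experimental design: apparatus geometry and trial-sequence generation.

The task presents brief auditory (A), visual (V) or audiovisual (AV) stimuli
from four azimuths (±5°, ±15°) and collects categorical localization
responses on a 12-button array spanning the speaker array.  Two blocks of
240 trials are used: Block 1 crosses all four A locations with all four V
locations on AV trials (discrepancies −30°…+30°), Block 2 holds the AV
discrepancy at a constant +10° (V right of A).

Sequence constraints for Block 1:

* 40 A, 40 V (10 per location each) and 160 AV trials (each of the 16
  location pairs 10 times);
* each unimodal trial's nearest preceding AV trial (skipping interjacent
  unimodal trials) has a discrepancy in {−20°, −10°, 0°, +10°, +20°}, with
  exactly 8 unimodal trials per modality per category;
* no unimodal trial immediately follows a ±30° AV trial.

Generation is constructive: the 160 AV trials are shuffled and the 80
unimodal trials are placed into the gaps after eligible AV trials so that
the preceding-discrepancy quota is met by construction.  A retry budget
guards the (never observed in practice) event that internal validation
fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Apparatus",
    "Trial",
    "TrialSequence",
    "ValidationReport",
    "GenerationError",
    "button_center",
    "bin_response",
    "bin_responses",
    "generate_block1",
    "generate_block2",
    "validate_sequence",
    "DEFAULT_APPARATUS",
]

SPEAKER_AZIMUTHS = (-15.0, -5.0, 5.0, 15.0)

#: preceding-AV discrepancy categories used for the immediate-aftereffect design
PRECEDING_CATEGORIES = (-20.0, -10.0, 0.0, 10.0, 20.0)


class GenerationError(RuntimeError):
    """Raised when a constrained sequence cannot be built within the retry budget."""


@dataclass(frozen=True)
class Apparatus:
    """Geometry of the response array relative to the speaker array.

    The 12 buttons are uniformly spaced with 10/3° between centers, so that
    buttons 2, 5, 8 and 11 coincide exactly with the four speakers and one
    flanking button lies beyond each outer speaker.  One response unit
    therefore equals 10/3°.
    """

    speaker_azimuths: tuple[float, ...] = SPEAKER_AZIMUTHS
    button_count: int = 12
    button_spacing: float = 10.0 / 3.0

    def __post_init__(self) -> None:
        if self.button_count < 1:
            raise ValueError("button_count must be positive")
        if self.button_spacing <= 0:
            raise ValueError("button_spacing must be positive")

    @property
    def button_centers(self) -> np.ndarray:
        idx = np.arange(1, self.button_count + 1)
        return (idx - (self.button_count + 1) / 2.0) * self.button_spacing


DEFAULT_APPARATUS = Apparatus()


def button_center(index: int, apparatus: Apparatus = DEFAULT_APPARATUS) -> float:
    """Azimuth (degrees) of a button center, buttons numbered 1..12 left to right."""
    if not (1 <= index <= apparatus.button_count):
        raise ValueError(
            f"button index {index} outside 1..{apparatus.button_count}"
        )
    return (index - (apparatus.button_count + 1) / 2.0) * apparatus.button_spacing


def bin_responses(locations: np.ndarray, apparatus: Apparatus = DEFAULT_APPARATUS) -> np.ndarray:
    """Vectorized mapping of continuous azimuths to button indices (1..n).

    Bins are half-open ``[center − spacing/2, center + spacing/2)``; the outer
    bins absorb anything beyond the array (clipping).
    """
    locations = np.asarray(locations, dtype=float)
    if not np.all(np.isfinite(locations)):
        raise ValueError("locations must be finite")
    left_edge = button_center(1, apparatus) - apparatus.button_spacing / 2.0
    idx = np.floor((locations - left_edge) / apparatus.button_spacing).astype(int) + 1
    return np.clip(idx, 1, apparatus.button_count)


def bin_response(location: float, apparatus: Apparatus = DEFAULT_APPARATUS) -> int:
    """Button index (1..12) whose bin contains ``location``; outer bins clip."""
    if not math.isfinite(location):
        raise ValueError("location must be finite")
    return int(bin_responses(np.asarray([location]), apparatus)[0])


@dataclass
class Trial:
    """One localization trial.

    ``s_A``/``s_V`` are stimulus azimuths in degrees (``None`` when the
    modality is absent); ``resp_A``/``resp_V`` are button indices 1..12
    (``None`` until a response is filled in).
    """

    index: int
    block: int
    modality: str  # "A" | "V" | "AV"
    s_A: float | None = None
    s_V: float | None = None
    resp_A: int | None = None
    resp_V: int | None = None
    response_order: str = "A-first"

    @property
    def discrepancy(self) -> float | None:
        """AV spatial discrepancy s_V − s_A (positive: V right of A)."""
        if self.s_A is None or self.s_V is None:
            return None
        return self.s_V - self.s_A


@dataclass
class TrialSequence:
    trials: list[Trial]
    block: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "block": t.block,
                "trial_index": t.index,
                "modality": t.modality,
                "s_A": t.s_A,
                "s_V": t.s_V,
                "resp_A": t.resp_A,
                "resp_V": t.resp_V,
                "response_order": t.response_order,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, block: int, seed: int = -1) -> "TrialSequence":
        trials = []
        for _, row in frame.iterrows():
            def _num(v):
                return None if pd.isna(v) else float(v)

            def _int(v):
                return None if pd.isna(v) else int(v)

            trials.append(
                Trial(
                    index=int(row["trial_index"]),
                    block=int(row["block"]),
                    modality=str(row["modality"]),
                    s_A=_num(row.get("s_A")),
                    s_V=_num(row.get("s_V")),
                    resp_A=_int(row.get("resp_A")),
                    resp_V=_int(row.get("resp_V")),
                    response_order=str(row.get("response_order", "A-first")),
                )
            )
        return cls(trials=trials, block=block, seed=seed)


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _unimodal_trials(rng: np.random.Generator, modality: str, block: int) -> list[Trial]:
    """40 unimodal trials, 10 per speaker location, in shuffled location order."""
    locs = np.repeat(SPEAKER_AZIMUTHS, 10).astype(float)
    rng.shuffle(locs)
    trials = []
    for loc in locs:
        if modality == "A":
            trials.append(Trial(index=-1, block=block, modality="A", s_A=float(loc)))
        else:
            trials.append(Trial(index=-1, block=block, modality="V", s_V=float(loc)))
    return trials


def _attempt_block1(rng: np.random.Generator) -> list[Trial]:
    # 160 AV trials: full 4x4 location cross, 10 repetitions per pair.
    av: list[Trial] = []
    for sa in SPEAKER_AZIMUTHS:
        for sv in SPEAKER_AZIMUTHS:
            av.extend(
                Trial(index=-1, block=1, modality="AV", s_A=sa, s_V=sv)
                for _ in range(10)
            )
    order = rng.permutation(len(av))
    av = [av[i] for i in order]

    a_trials = _unimodal_trials(rng, "A", block=1)
    v_trials = _unimodal_trials(rng, "V", block=1)

    # Gap g holds unimodal trials placed directly after AV trial g; every
    # trial in gap g has AV trial g as its nearest preceding AV trial.
    gaps: dict[int, list[Trial]] = {i: [] for i in range(len(av))}
    eligible = {
        c: [i for i, t in enumerate(av) if t.discrepancy == c]
        for c in PRECEDING_CATEGORIES
    }
    for pool in (a_trials, v_trials):
        pos = 0
        for c in PRECEDING_CATEGORIES:
            chosen = rng.choice(eligible[c], size=8, replace=True)
            for g in chosen:
                gaps[int(g)].append(pool[pos])
                pos += 1
    for g in gaps.values():
        rng.shuffle(g)

    seq: list[Trial] = []
    for i, t in enumerate(av):
        seq.append(t)
        seq.extend(gaps[i])
    for i, t in enumerate(seq):
        t.index = i
    return seq


def generate_block1(
    seed: int,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    retry_budget: int = 10_000,
) -> TrialSequence:
    """Generate a constrained pseudorandom Block 1 sequence (240 trials).

    Deterministic in ``seed``.  Raises :class:`GenerationError` if no valid
    sequence is produced within ``retry_budget`` attempts.
    """
    rng = np.random.default_rng(seed)
    for _ in range(retry_budget):
        trials = _attempt_block1(rng)
        seq = TrialSequence(trials=trials, block=1, seed=seed)
        if validate_sequence(seq, apparatus).passed:
            return seq
    raise GenerationError(f"no valid Block 1 sequence within {retry_budget} attempts")


BLOCK2_PAIRS = ((-15.0, -5.0, 53), (-5.0, 5.0, 54), (5.0, 15.0, 53))


def generate_block2(
    seed: int,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    retry_budget: int = 10_000,
) -> TrialSequence:
    """Generate a Block 2 sequence: constant +10° AV discrepancy, random order."""
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for sa, sv, n in BLOCK2_PAIRS:
        trials.extend(
            Trial(index=-1, block=2, modality="AV", s_A=sa, s_V=sv) for _ in range(n)
        )
    trials.extend(_unimodal_trials(rng, "A", block=2))
    trials.extend(_unimodal_trials(rng, "V", block=2))
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    for i, t in enumerate(trials):
        t.index = i
    return TrialSequence(trials=trials, block=2, seed=seed)


def preceding_av_discrepancies(seq: TrialSequence) -> list[float | None]:
    """Per trial, the discrepancy of the nearest preceding AV trial.

    Unimodal trials interjacent between an AV trial and a later unimodal
    trial are skipped; trials before the first AV trial get ``None``.
    """
    out: list[float | None] = []
    last: float | None = None
    for t in seq.trials:
        out.append(last if t.modality != "AV" else None)
        if t.modality == "AV":
            last = t.discrepancy
    return out


def _check_counts(violations: list[str], label: str, actual, expected) -> None:
    if actual != expected:
        violations.append(f"{label}: expected {expected}, got {actual}")


def validate_sequence(
    seq: TrialSequence, apparatus: Apparatus = DEFAULT_APPARATUS
) -> ValidationReport:
    """Check a sequence against the declared block's composition and ordering rules."""
    if seq.block not in (1, 2):
        raise ValueError(f"unknown block label {seq.block!r}")
    v: list[str] = []
    trials = seq.trials
    _check_counts(v, "total length", len(trials), 240)
    by_mod = {m: [t for t in trials if t.modality == m] for m in ("A", "V", "AV")}
    _check_counts(v, "unimodal count A", len(by_mod["A"]), 40)
    _check_counts(v, "unimodal count V", len(by_mod["V"]), 40)
    _check_counts(v, "AV count", len(by_mod["AV"]), 160)

    for m, attr in (("A", "s_A"), ("V", "s_V")):
        for loc in apparatus.speaker_azimuths:
            n = sum(1 for t in by_mod[m] if getattr(t, attr) == loc)
            _check_counts(v, f"{m} trials at {loc:+g}°", n, 10)

    for t in trials:
        if t.modality == "AV" and (t.s_A is None or t.s_V is None):
            v.append(f"trial {t.index}: AV trial missing a stimulus")
        if t.modality == "A" and (t.s_A is None or t.s_V is not None):
            v.append(f"trial {t.index}: malformed A trial stimuli")
        if t.modality == "V" and (t.s_V is None or t.s_A is not None):
            v.append(f"trial {t.index}: malformed V trial stimuli")
        for r in (t.resp_A, t.resp_V):
            if r is not None and not (1 <= r <= apparatus.button_count):
                v.append(f"trial {t.index}: response {r} out of range")

    if seq.block == 1:
        pair_counts: dict[tuple[float, float], int] = {}
        for t in by_mod["AV"]:
            pair_counts[(t.s_A, t.s_V)] = pair_counts.get((t.s_A, t.s_V), 0) + 1
        for sa in apparatus.speaker_azimuths:
            for sv in apparatus.speaker_azimuths:
                _check_counts(
                    v, f"AV pair ({sa:+g}, {sv:+g})", pair_counts.get((sa, sv), 0), 10
                )
        # ±30° AV trials never immediately followed by a unimodal trial
        for prev, nxt in zip(trials, trials[1:]):
            if (
                prev.modality == "AV"
                and abs(prev.discrepancy) == 30.0
                and nxt.modality != "AV"
            ):
                v.append(f"±30-before-unimodal: trial {nxt.index}")
        preceding = preceding_av_discrepancies(seq)
        for m in ("A", "V"):
            for c in PRECEDING_CATEGORIES:
                n = sum(
                    1
                    for t, p in zip(trials, preceding)
                    if t.modality == m and p == c
                )
                _check_counts(v, f"{m} preceded by {c:+g}° AV", n, 8)
            n_none = sum(
                1 for t, p in zip(trials, preceding) if t.modality == m and p is None
            )
            _check_counts(v, f"{m} with unresolved predecessor", n_none, 0)
    else:
        pair_counts = {}
        for t in by_mod["AV"]:
            pair_counts[(t.s_A, t.s_V)] = pair_counts.get((t.s_A, t.s_V), 0) + 1
        for sa, sv, n_expected in BLOCK2_PAIRS:
            _check_counts(
                v, f"AV pair ({sa:+g}, {sv:+g})", pair_counts.get((sa, sv), 0), n_expected
            )
        for t in by_mod["AV"]:
            if t.discrepancy != 10.0:
                v.append(f"trial {t.index}: Block 2 discrepancy {t.discrepancy} != +10°")

    return ValidationReport(passed=not v, violations=v)
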