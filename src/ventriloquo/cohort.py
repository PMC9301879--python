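"""Synthetic participants and cohorts generated from ground-truth observers.

A participant is simulated by (1) generating the two constrained trial
sequences, (2) answering every AV trial with the profile's observer family
(noisy sensory samples → causal inference → decision strategy → binning) and
(3) answering every unimodal trial by binning a draw from
``Normal(s + Δ_m, σ_m)`` with the block's likelihood parameters.

Group archetypes encode the minimal parameter structure that reproduces the
study-design's qualitative effect pattern:

* all groups share a causal-inference observer (CI-PM) with a wide location
  prior, an auditory likelihood much noisier than the visual one (so AV
  responses are visually dominated → positive auditory VE), and a Block 2
  auditory bias shift ``Δ_A`` toward the visual side (positive auditory
  VAEc);
* the congenital-cataract (CC) archetype additionally shifts the Block 2
  visual bias ``Δ_V`` toward the auditory side, producing the negative
  visual VAEc that distinguishes that group;
* sighted controls (SC) have the most reliable vision, developmental
  cataracts (DC) intermediate, CC the least (``σ_V`` 2° < 2.5° < 3.5°).

A static ideal observer has no trial history, so it cannot produce an
immediate aftereffect.  The generator therefore adds an explicit
trial-history term to the *unimodal* response means: a bias of
``gain_m × d × decay^g`` degrees, where ``d`` is the discrepancy of the
nearest preceding AV trial and ``g`` the number of interjacent unimodal
trials.  This term is a generator extension beyond the static observer
models (see the methods note); it is on by default so that archetype
cohorts show the full VE/VAEi/VAEc pattern, and can be disabled by setting
the gains to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    Apparatus,
    DEFAULT_APPARATUS,
    TrialSequence,
    bin_responses,
    generate_block1,
    generate_block2,
    validate_sequence,
)
from .observers import (
    FAMILIES,
    LikelihoodParams,
    ObserverSpec,
    PriorParams,
    continuous_responses,
)

__all__ = [
    "ParticipantProfile",
    "ParticipantDataset",
    "ARCHETYPES",
    "GROUP_SIZES",
    "make_profile",
    "simulate_participant",
    "simulate_cohort",
    "cohort_to_frame",
    "cohort_metadata",
]

#: study group sizes (CC, DC, SC)
GROUP_SIZES = {"CC": 11, "DC": 10, "SC": 10}

#: ground-truth archetype configuration per group (overridable, not dogma)
ARCHETYPES: dict[str, dict] = {
    "SC": {
        "family": "CI-PM",
        "likelihood": {"delta_A": 0.0, "sigma_A": 6.0, "delta_V": 0.0, "sigma_V": 2.0},
        "prior": {"mu_P": 0.0, "sigma_P": 25.0, "p_common": 0.5},
        "block2_delta_shift": {"delta_A": 3.0, "delta_V": 0.0},
    },
    "DC": {
        "family": "CI-PM",
        "likelihood": {"delta_A": 0.0, "sigma_A": 6.0, "delta_V": 0.0, "sigma_V": 2.5},
        "prior": {"mu_P": 0.0, "sigma_P": 25.0, "p_common": 0.5},
        "block2_delta_shift": {"delta_A": 2.0, "delta_V": 0.0},
    },
    "CC": {
        "family": "CI-PM",
        "likelihood": {"delta_A": 0.0, "sigma_A": 6.0, "delta_V": 0.0, "sigma_V": 3.5},
        "prior": {"mu_P": 0.0, "sigma_P": 25.0, "p_common": 0.5},
        "block2_delta_shift": {"delta_A": 3.0, "delta_V": -2.0},
    },
}

#: trial-history (immediate recalibration) defaults: degrees of unimodal bias
#: per degree of preceding AV discrepancy
DEFAULT_HISTORY = {"gain_A": 0.15, "gain_V": 0.05, "decay": 1.0}

#: relative Gaussian jitter applied to scale parameters across participants
DEFAULT_JITTER = 0.15


@dataclass(frozen=True)
class ParticipantProfile:
    """Ground truth for one simulated participant."""

    participant: str
    group: str
    family: str
    block1_likelihood: LikelihoodParams
    block2_likelihood: LikelihoodParams
    block1_prior: PriorParams | None
    block2_prior: PriorParams | None
    response_order: str = "A-first"
    seed: int = 0
    history_gain_A: float = DEFAULT_HISTORY["gain_A"]
    history_gain_V: float = DEFAULT_HISTORY["gain_V"]
    history_decay: float = DEFAULT_HISTORY["decay"]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        needs_prior = self.family not in ("FFnp", "SGnp")
        if needs_prior and (self.block1_prior is None or self.block2_prior is None):
            raise ValueError(f"{self.family} requires prior parameters in both blocks")

    def spec(self, block: int) -> ObserverSpec:
        lik = self.block1_likelihood if block == 1 else self.block2_likelihood
        prior = self.block1_prior if block == 1 else self.block2_prior
        if self.family in ("FFnp", "SGnp"):
            prior = None
        return ObserverSpec(self.family, lik, prior)


@dataclass
class ParticipantDataset:
    """Both blocks of one participant with responses filled in."""

    profile: ParticipantProfile
    block1: TrialSequence
    block2: TrialSequence

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for seq in (self.block1, self.block2):
            f = seq.to_frame()
            f.insert(0, "participant", self.profile.participant)
            f.insert(1, "group", self.profile.group)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def validate(self, apparatus: Apparatus = DEFAULT_APPARATUS) -> bool:
        return (
            validate_sequence(self.block1, apparatus).passed
            and validate_sequence(self.block2, apparatus).passed
        )


def make_profile(
    participant: str,
    group: str,
    seed: int,
    overrides: dict | None = None,
    jitter: float = DEFAULT_JITTER,
    response_order: str = "A-first",
) -> ParticipantProfile:
    """Draw one participant's ground truth from a group archetype.

    Scale parameters (σ_A, σ_V, σ_P, Pc) receive multiplicative Gaussian
    jitter of relative size ``jitter``; bias parameters and the Block 2 bias
    shifts are taken as configured.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in ARCHETYPES[group].items()}
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    rng = np.random.default_rng(seed)

    def _jit(x: float, lo: float = 1e-3, hi: float | None = None) -> float:
        y = x * (1.0 + jitter * rng.standard_normal())
        if hi is not None:
            return float(np.clip(y, lo, hi))
        return float(max(y, lo))

    lik_cfg = cfg["likelihood"]
    lik1 = LikelihoodParams(
        delta_A=lik_cfg["delta_A"],
        sigma_A=_jit(lik_cfg["sigma_A"]),
        delta_V=lik_cfg["delta_V"],
        sigma_V=_jit(lik_cfg["sigma_V"]),
    )
    shift = cfg["block2_delta_shift"]
    lik2 = replace(
        lik1,
        delta_A=lik1.delta_A + shift["delta_A"],
        delta_V=lik1.delta_V + shift["delta_V"],
    )
    family = cfg["family"]
    if family in ("FFnp", "SGnp"):
        prior1 = prior2 = None
    else:
        p_cfg = cfg["prior"]
        prior1 = PriorParams(
            mu_P=p_cfg["mu_P"],
            sigma_P=_jit(p_cfg["sigma_P"]),
            p_common=_jit(p_cfg["p_common"], lo=0.05, hi=0.95),
        )
        prior2 = cfg.get("block2_prior_override") or prior1
    hist = dict(DEFAULT_HISTORY)
    hist.update(cfg.get("history", {}))
    return ParticipantProfile(
        participant=participant,
        group=group,
        family=family,
        block1_likelihood=lik1,
        block2_likelihood=lik2,
        block1_prior=prior1,
        block2_prior=prior2,
        response_order=response_order,
        seed=int(rng.integers(0, 2**31 - 1)),
        history_gain_A=hist["gain_A"],
        history_gain_V=hist["gain_V"],
        history_decay=hist["decay"],
    )


def _fill_responses(
    seq: TrialSequence,
    profile: ParticipantProfile,
    block: int,
    rng: np.random.Generator,
    apparatus: Apparatus,
) -> None:
    spec = profile.spec(block)
    lik = spec.likelihood
    av_trials = [t for t in seq.trials if t.modality == "AV"]
    s_A = np.array([t.s_A for t in av_trials])
    s_V = np.array([t.s_V for t in av_trials])
    x_A = rng.normal(s_A + lik.delta_A, lik.sigma_A)
    x_V = rng.normal(s_V + lik.delta_V, lik.sigma_V)
    xi = rng.uniform(size=len(av_trials))
    r_A, r_V = continuous_responses(spec, x_A, x_V, xi)
    b_A = bin_responses(r_A, apparatus)
    b_V = bin_responses(r_V, apparatus)
    for t, ra, rv in zip(av_trials, b_A, b_V):
        t.resp_A, t.resp_V = int(ra), int(rv)

    last_disc: float | None = None
    gap = 0
    for t in seq.trials:
        t.response_order = profile.response_order
        if t.modality == "AV":
            last_disc = t.discrepancy
            gap = 0
            continue
        if t.modality == "A":
            gain, s, delta, sigma = profile.history_gain_A, t.s_A, lik.delta_A, lik.sigma_A
        else:
            gain, s, delta, sigma = profile.history_gain_V, t.s_V, lik.delta_V, lik.sigma_V
        bias = 0.0
        if last_disc is not None:
            bias = gain * last_disc * profile.history_decay**gap
        draw = rng.normal(s + delta + bias, sigma)
        resp = int(bin_responses(np.array([draw]), apparatus)[0])
        if t.modality == "A":
            t.resp_A = resp
        else:
            t.resp_V = resp
        gap += 1


def simulate_participant(
    profile: ParticipantProfile, apparatus: Apparatus = DEFAULT_APPARATUS
) -> ParticipantDataset:
    """Simulate both blocks for one profile; fully reproducible from its seed."""
    master = np.random.default_rng(profile.seed)
    seeds = master.integers(0, 2**31 - 1, size=4)
    block1 = generate_block1(int(seeds[0]), apparatus)
    block2 = generate_block2(int(seeds[1]), apparatus)
    _fill_responses(block1, profile, 1, np.random.default_rng(int(seeds[2])), apparatus)
    _fill_responses(block2, profile, 2, np.random.default_rng(int(seeds[3])), apparatus)
    return ParticipantDataset(profile=profile, block1=block1, block2=block2)


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    overrides: dict | None = None,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    apparatus: Apparatus = DEFAULT_APPARATUS,
) -> list[ParticipantDataset]:
    """Simulate a full cohort (defaults: 11 CC, 10 DC, 10 SC).

    ``overrides`` maps group → archetype override dict.  Response order is
    counterbalanced within group.  Deterministic in ``seed``.
    """
    n_per_group = n_per_group or dict(GROUP_SIZES)
    master = np.random.default_rng(seed)
    datasets = []
    for group, n in n_per_group.items():
        for i in range(n):
            profile = make_profile(
                participant=f"{group}{i + 1:02d}",
                group=group,
                seed=int(master.integers(0, 2**31 - 1)),
                overrides=(overrides or {}).get(group),
                jitter=jitter,
                response_order="A-first" if i % 2 == 0 else "V-first",
            )
            datasets.append(simulate_participant(profile, apparatus))
    return datasets


def cohort_to_frame(datasets: list[ParticipantDataset]) -> pd.DataFrame:
    """One tidy trial table for a whole cohort."""
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)


def cohort_metadata(datasets: list[ParticipantDataset]) -> pd.DataFrame:
    """Participant-level ground-truth metadata table."""
    rows = []
    for d in datasets:
        p = d.profile
        row = {
            "participant": p.participant,
            "group": p.group,
            "family": p.family,
            "seed": p.seed,
            "response_order": p.response_order,
            "delta_A_1": p.block1_likelihood.delta_A,
            "sigma_A_1": p.block1_likelihood.sigma_A,
            "delta_V_1": p.block1_likelihood.delta_V,
            "sigma_V_1": p.block1_likelihood.sigma_V,
            "delta_A_2": p.block2_likelihood.delta_A,
            "delta_V_2": p.block2_likelihood.delta_V,
            "history_gain_A": p.history_gain_A,
            "history_gain_V": p.history_gain_V,
        }
        if p.block1_prior is not None:
            row.update(
                mu_P=p.block1_prior.mu_P,
                sigma_P=p.block1_prior.sigma_P,
                p_common=p.block1_prior.p_common,
            )
        rows.append(row)
    return pd.DataFrame(rows)
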