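"""Bayesian ideal-observer models of audiovisual localization.

Seven observer families are implemented for the two-response localization
task (one auditory and one visual button press per AV trial):

``CI-MA``, ``CI-PM``, ``CI-MS``
    Hierarchical causal-inference observers.  On each trial the observer
    receives noisy internal samples ``x_A ~ N(s_A + Δ_A, σ_A)`` and
    ``x_V ~ N(s_V + Δ_V, σ_V)``, computes the posterior probability that the
    two cues share a common cause (against a causal prior ``Pc`` and a
    Gaussian location prior ``N(μ_P, σ_P)``), forms the fused (common-cause)
    and segregated (independent-cause) location estimates, and combines them
    by model averaging (MA), probability matching (PM) or model selection
    (MS).

``FF``, ``SG``
    Fixed-structure baselines with the location prior: forced fusion always
    integrates (the common-cause branch, effectively ``Pc = 1``); segregation
    never does (``Pc = 0``).

``FFnp``, ``SGnp``
    The same baselines without a location prior: forced fusion reduces to
    reliability-weighted averaging of the two samples, segregation to
    reporting each sample unchanged.

All location arithmetic is in degrees; conversion to the 12 discrete button
responses happens only at the final binning step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Apparatus, DEFAULT_APPARATUS, bin_responses

__all__ = [
    "FAMILIES",
    "CI_FAMILIES",
    "LikelihoodParams",
    "PriorParams",
    "ObserverSpec",
    "StimulusPair",
    "SensorySample",
    "LocationEstimates",
    "PredictedResponseDistribution",
    "joint_likelihood_common",
    "joint_likelihood_independent",
    "posterior_common_cause",
    "estimate_locations",
    "decide",
    "continuous_responses",
    "simulate_av_responses",
]

CI_FAMILIES = ("CI-MA", "CI-PM", "CI-MS")
FAMILIES = CI_FAMILIES + ("FF", "SG", "FFnp", "SGnp")

#: families whose spec carries location-prior parameters
PRIOR_FAMILIES = CI_FAMILIES + ("FF", "SG")


@dataclass(frozen=True)
class LikelihoodParams:
    """Gaussian likelihood bias and SD per modality (degrees)."""

    delta_A: float = 0.0
    sigma_A: float = 6.0
    delta_V: float = 0.0
    sigma_V: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_A <= 0 or self.sigma_V <= 0:
            raise ValueError("likelihood SDs must be positive")


@dataclass(frozen=True)
class PriorParams:
    """Gaussian location prior (μ_P, σ_P) and causal prior Pc."""

    mu_P: float = 0.0
    sigma_P: float = 25.0
    p_common: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_P <= 0:
            raise ValueError("sigma_P must be positive")
        if not (0.0 <= self.p_common <= 1.0):
            raise ValueError("p_common must lie in [0, 1]")


@dataclass(frozen=True)
class ObserverSpec:
    """A model family with its likelihood and (where applicable) prior parameters."""

    family: str
    likelihood: LikelihoodParams
    prior: PriorParams | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("FFnp", "SGnp"):
            if self.prior is not None:
                raise ValueError(f"{self.family} carries no prior parameters")
        elif self.prior is None:
            raise ValueError(f"{self.family} requires prior parameters")

    @property
    def effective_p_common(self) -> float:
        """Causal prior implied by the family (FF/FFnp → 1, SG/SGnp → 0)."""
        if self.family in ("FF", "FFnp"):
            return 1.0
        if self.family in ("SG", "SGnp"):
            return 0.0
        return self.prior.p_common


@dataclass(frozen=True)
class StimulusPair:
    s_A: float
    s_V: float

    @property
    def discrepancy(self) -> float:
        return self.s_V - self.s_A


@dataclass(frozen=True)
class SensorySample:
    x_A: float
    x_V: float


@dataclass(frozen=True)
class LocationEstimates:
    """Per-trial location estimates under the two causal structures."""

    fused: float
    seg_A: float
    seg_V: float
    posterior_c1: float | None = None
    xi: float | None = None


# ---------------------------------------------------------------------------
# closed-form joint likelihoods and the causal posterior


def _as_xy(sample) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sample, SensorySample):
        return np.asarray(sample.x_A, float), np.asarray(sample.x_V, float)
    x_A, x_V = sample
    return np.asarray(x_A, float), np.asarray(x_V, float)


def joint_likelihood_common(sample, lik: LikelihoodParams, prior: PriorParams):
    """p(x_A, x_V | C = 1): both samples generated by one source drawn from the prior.

    Closed form of the marginalization over the shared source location s:
    ∫ N(x_A; s, σ_A) N(x_V; s, σ_V) N(s; μ_P, σ_P) ds.
    """
    x_A, x_V = _as_xy(sample)
    sA2, sV2, sP2 = lik.sigma_A**2, lik.sigma_V**2, prior.sigma_P**2
    denom = sA2 * sV2 + sA2 * sP2 + sV2 * sP2
    quad = (
        (x_V - x_A) ** 2 * sP2
        + (x_A - prior.mu_P) ** 2 * sV2
        + (x_V - prior.mu_P) ** 2 * sA2
    ) / denom
    return np.exp(-0.5 * quad) / (2.0 * np.pi * np.sqrt(denom))


def joint_likelihood_independent(sample, lik: LikelihoodParams, prior: PriorParams):
    """p(x_A, x_V | C = 2): each sample generated by its own source from the prior."""
    x_A, x_V = _as_xy(sample)
    sA2, sV2, sP2 = lik.sigma_A**2, lik.sigma_V**2, prior.sigma_P**2
    vA, vV = sA2 + sP2, sV2 + sP2
    quad = (x_A - prior.mu_P) ** 2 / vA + (x_V - prior.mu_P) ** 2 / vV
    return np.exp(-0.5 * quad) / (2.0 * np.pi * np.sqrt(vA * vV))


def posterior_common_cause(sample, lik: LikelihoodParams, prior: PriorParams):
    """p(C = 1 | x_A, x_V): Bayes over the two causal structures."""
    pc = prior.p_common
    like1 = joint_likelihood_common(sample, lik, prior)
    like2 = joint_likelihood_independent(sample, lik, prior)
    num = like1 * pc
    return num / (num + like2 * (1.0 - pc))


# ---------------------------------------------------------------------------
# location estimates and decision strategies


def _fused_with_prior(x_A, x_V, lik: LikelihoodParams, prior: PriorParams):
    wA, wV, wP = lik.sigma_A**-2, lik.sigma_V**-2, prior.sigma_P**-2
    return (x_A * wA + x_V * wV + prior.mu_P * wP) / (wA + wV + wP)


def _seg_with_prior(x, sigma, prior: PriorParams):
    w, wP = sigma**-2, prior.sigma_P**-2
    return (x * w + prior.mu_P * wP) / (w + wP)


def _fused_no_prior(x_A, x_V, lik: LikelihoodParams):
    wA, wV = lik.sigma_A**-2, lik.sigma_V**-2
    return (x_A * wA + x_V * wV) / (wA + wV)


def estimate_locations(
    sample,
    lik: LikelihoodParams,
    prior: PriorParams | None = None,
    use_prior: bool = True,
    xi: float | None = None,
) -> LocationEstimates:
    """Fused and segregated location estimates for one sensory sample.

    With the prior, the fused estimate precision-weights both samples and the
    prior mean; the segregated estimates shrink each sample toward the prior.
    Without the prior, fusion is the reliability-weighted average of the two
    samples and segregation returns them unchanged.
    """
    x_A, x_V = _as_xy(sample)
    if use_prior:
        if prior is None:
            raise ValueError("prior parameters required when use_prior is set")
        fused = _fused_with_prior(x_A, x_V, lik, prior)
        seg_A = _seg_with_prior(x_A, lik.sigma_A, prior)
        seg_V = _seg_with_prior(x_V, lik.sigma_V, prior)
        post = float(posterior_common_cause(sample, lik, prior))
    else:
        fused = _fused_no_prior(x_A, x_V, lik)
        seg_A, seg_V = x_A, x_V
        post = None
    return LocationEstimates(
        fused=float(fused), seg_A=float(seg_A), seg_V=float(seg_V),
        posterior_c1=post, xi=xi,
    )


def decide(strategy: str, est: LocationEstimates) -> tuple[float, float]:
    """Combine fused and segregated estimates into the trial's (ŝ_A, ŝ_V).

    ``MA`` averages the two branches weighted by the causal posterior; ``PM``
    picks the common-cause branch when the posterior exceeds a uniform draw ξ
    (one shared ξ for both responses, so the chosen causal structure is
    consistent within a trial); ``MS`` picks it when the posterior exceeds
    0.5.  Posteriors exactly at the threshold resolve to segregation.
    """
    p = est.posterior_c1
    if p is None or not (0.0 <= p <= 1.0):
        raise ValueError("decision requires a causal posterior in [0, 1]")
    if strategy == "MA":
        return (
            p * est.fused + (1.0 - p) * est.seg_A,
            p * est.fused + (1.0 - p) * est.seg_V,
        )
    if strategy == "PM":
        if est.xi is None:
            raise ValueError("PM requires a uniform draw xi")
        common = p > est.xi
    elif strategy == "MS":
        common = p > 0.5
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if common:
        return est.fused, est.fused
    return est.seg_A, est.seg_V


def continuous_responses(
    spec: ObserverSpec,
    x_A: np.ndarray,
    x_V: np.ndarray,
    xi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized continuous (pre-binning) A and V responses for many trials.

    ``xi`` supplies the per-trial uniform draws used by CI-PM; it is ignored
    by the other families, so callers may always pass it (common random
    numbers across model families and parameter values).
    """
    lik, prior, family = spec.likelihood, spec.prior, spec.family
    if family == "FFnp":
        fused = _fused_no_prior(x_A, x_V, lik)
        return fused, fused.copy()
    if family == "SGnp":
        return np.asarray(x_A, float).copy(), np.asarray(x_V, float).copy()
    if family == "FF":
        fused = _fused_with_prior(x_A, x_V, lik, prior)
        return fused, fused.copy()
    if family == "SG":
        return (
            _seg_with_prior(x_A, lik.sigma_A, prior),
            _seg_with_prior(x_V, lik.sigma_V, prior),
        )

    # causal-inference families
    post = posterior_common_cause((x_A, x_V), lik, prior)
    fused = _fused_with_prior(x_A, x_V, lik, prior)
    seg_A = _seg_with_prior(x_A, lik.sigma_A, prior)
    seg_V = _seg_with_prior(x_V, lik.sigma_V, prior)
    if family == "CI-MA":
        return post * fused + (1 - post) * seg_A, post * fused + (1 - post) * seg_V
    if family == "CI-PM":
        if xi is None:
            raise ValueError("CI-PM requires per-trial uniform draws xi")
        common = post > xi
    else:  # CI-MS
        common = post > 0.5
    r_A = np.where(common, fused, seg_A)
    r_V = np.where(common, fused, seg_V)
    return r_A, r_V


# ---------------------------------------------------------------------------
# Monte-Carlo predicted response distributions


@dataclass(frozen=True)
class PredictedResponseDistribution:
    """12-bin predicted response histograms (proportions) for one AV pair."""

    pair: StimulusPair
    p_A: np.ndarray
    p_V: np.ndarray
    n_sim: int

    def __post_init__(self) -> None:
        for p in (self.p_A, self.p_V):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("histograms must be nonnegative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.p_A)
        return pd.DataFrame(
            {
                "s_A": self.pair.s_A,
                "s_V": self.pair.s_V,
                "modality": np.repeat(["A", "V"], n),
                "button": np.tile(np.arange(1, n + 1), 2),
                "probability": np.concatenate([self.p_A, self.p_V]),
            }
        )


def _histogram(buttons: np.ndarray, n_buttons: int) -> np.ndarray:
    counts = np.bincount(buttons - 1, minlength=n_buttons).astype(float)
    return counts / counts.sum()


def simulate_av_responses(
    spec: ObserverSpec,
    pair: StimulusPair,
    n_sim: int = 10_000,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    seed: int = 0,
) -> PredictedResponseDistribution:
    """Monte-Carlo predicted A and V response histograms for one stimulus pair.

    Draws ``n_sim`` sensory samples from the likelihoods, runs the family's
    estimate → decide chain, bins the continuous responses onto the button
    array and normalizes.  Deterministic in ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    lik = spec.likelihood
    x_A = rng.normal(pair.s_A + lik.delta_A, lik.sigma_A, size=n_sim)
    x_V = rng.normal(pair.s_V + lik.delta_V, lik.sigma_V, size=n_sim)
    xi = rng.uniform(size=n_sim)
    r_A, r_V = continuous_responses(spec, x_A, x_V, xi)
    return PredictedResponseDistribution(
        pair=pair,
        p_A=_histogram(bin_responses(r_A, apparatus), apparatus.button_count),
        p_V=_histogram(bin_responses(r_V, apparatus), apparatus.button_count),
        n_sim=n_sim,
    )
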