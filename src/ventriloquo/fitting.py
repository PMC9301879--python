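"""Maximum-likelihood fitting of observer models to categorical localization data.

The pipeline has three steps, applied per participant:

1. **Unimodal likelihood parameters.**  The Gaussian likelihood bias and SD of
   each modality (Δ_A, σ_A, Δ_V, σ_V) are estimated from the unimodal trials
   of each block by discretized-Gaussian MLE: the probability of a button
   response is the Gaussian probability mass on that button's interval, with
   the outer buttons integrating to ±∞.  Errors are pooled across the four
   stimulus locations.

2. **Prior parameters and model comparison.**  With the Step-1 likelihood
   parameters fixed, the free prior parameters of each of the seven observer
   families (CI models: Pc, μ_P, σ_P; FF/SG: μ_P, σ_P; FFnp/SGnp: none) are
   fitted to the Block 1 AV trials by maximizing the multinomial
   log-likelihood of the observed 12-bin response counts against Monte-Carlo
   predicted response proportions.  The search is initialized from a uniform
   grid over the free parameters (11 values per parameter by default, i.e.
   1,331 candidates for a CI model and 121 for FF/SG) and refined with
   bounded L-BFGS-B.  Families are compared by BIC.

3. **Block 2 refit.**  The per-participant best family from Step 2 is refit
   to the Block 2 AV trials with the Block 2 likelihood parameters; no model
   comparison takes place.

The Monte-Carlo objective uses common random numbers: a single simulation
seed per fit fixes the sensory noise and the probability-matching draws for
every parameter evaluation, making the objective deterministic in the
parameters.

The module surface follows the Model/Results convention:
:class:`UnimodalLocalizationModel` and :class:`AVObserverModel` are built
from data and their ``fit()`` returns results objects carrying estimates,
log-likelihood, BIC and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import Apparatus, DEFAULT_APPARATUS, TrialSequence, bin_responses
from .observers import (
    CI_FAMILIES,
    FAMILIES,
    LikelihoodParams,
    ObserverSpec,
    PredictedResponseDistribution,
    PriorParams,
    StimulusPair,
    continuous_responses,
    simulate_av_responses,
)

__all__ = [
    "FitConfig",
    "REDUCED_PRESET",
    "ResponseHistogram",
    "FitResult",
    "UnimodalLocalizationModel",
    "UnimodalFitResults",
    "AVObserverModel",
    "fit_unimodal",
    "fit_model",
    "fit_block2_priors",
    "fit_participant",
    "ParticipantFitReport",
    "multinomial_loglik",
    "grid_candidates",
    "bic",
    "classify_evidence",
    "select_best",
    "free_parameters",
]

#: number of prior parameters fitted in Step 2, by family
N_FREE = {"CI-MA": 3, "CI-PM": 3, "CI-MS": 3, "FF": 2, "SG": 2, "FFnp": 0, "SGnp": 0}

DEFAULT_BOUNDS = {
    "p_common": (0.0, 1.0),
    "mu_P": (-20.0, 20.0),
    "sigma_P": (1.0, 60.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings for the Monte-Carlo multinomial fits.

    ``prob_floor`` defaults to ``1 / (2 * n_sim)``: predicted proportions of
    exactly zero (possible with finite Monte-Carlo samples) are floored so
    that observed responses in empty bins contribute a large but finite
    penalty instead of −∞.
    """

    n_sim: int = 10_000
    grid_points_per_param: int = 11
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    prob_floor: float | None = None
    seed: int = 0
    maxiter: int = 200

    @property
    def floor(self) -> float:
        return self.prob_floor if self.prob_floor is not None else 0.5 / self.n_sim


#: cheaper settings for desk-scale iteration; not publication-grade
REDUCED_PRESET = FitConfig(n_sim=2_000, grid_points_per_param=5)


@dataclass
class ResponseHistogram:
    """Observed response counts over the 12 buttons for one pair and modality."""

    pair: StimulusPair
    modality: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("response counts must be nonnegative")


def multinomial_loglik(hist, predicted: np.ndarray, prob_floor: float) -> float:
    """Multinomial log-likelihood Σ n_i ln(max(p_i, floor)).

    The multinomial coefficient is a constant across models and parameter
    sets and is dropped.
    """
    counts = hist.counts if isinstance(hist, ResponseHistogram) else np.asarray(hist)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    p = np.maximum(np.asarray(predicted, dtype=float), prob_floor)
    return float(np.sum(counts * np.log(p)))


def grid_candidates(
    free_params: list[tuple[str, float, float]], points_per_param: int = 11
) -> list[tuple[float, ...]]:
    """Full Cartesian grid of evenly spaced candidate vectors, endpoints included."""
    if points_per_param < 2:
        raise ValueError("points_per_param must be >= 2")
    axes = [np.linspace(lo, hi, points_per_param) for _, lo, hi in free_params]
    return [tuple(v) for v in itertools.product(*axes)]


def bic(log_lik: float, k: int, N: int) -> float:
    """Bayesian information criterion −2·LL + k·ln N (lower is better)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * log_lik + k * math.log(N)


def classify_evidence(bic_difference: float) -> str:
    """Strength of evidence for the lower-BIC model from a BIC difference."""
    d = abs(bic_difference)
    if d < 2:
        return "weak"
    if d < 6:
        return "positive"
    if d < 10:
        return "strong"
    return "very strong"


def free_parameters(family: str, bounds: dict | None = None) -> list[tuple[str, float, float]]:
    """Ordered free prior parameters (name, lower, upper) fitted for a family."""
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    if family in CI_FAMILIES:
        names = ["p_common", "mu_P", "sigma_P"]
    elif family in ("FF", "SG"):
        names = ["mu_P", "sigma_P"]
    elif family in ("FFnp", "SGnp"):
        names = []
    else:
        raise ValueError(f"unknown family {family!r}")
    return [(n, *b[n]) for n in names]


# ---------------------------------------------------------------------------
# Step 1: discretized-Gaussian unimodal fits


class UnimodalLocalizationModel:
    """Discretized-Gaussian model of unimodal categorical localization.

    The response to a stimulus at azimuth ``s`` is a button draw with
    probability equal to the mass of ``Normal(s + Δ, σ)`` on the button's
    interval; the outer buttons absorb the tails.  ``fit`` estimates (Δ, σ)
    by maximum likelihood, pooling trials across stimulus locations.

    Parameters
    ----------
    stimuli : array of stimulus azimuths in degrees, one per trial.
    responses : array of button indices (1..12), one per trial.
    """

    def __init__(self, stimuli, responses, apparatus: Apparatus = DEFAULT_APPARATUS):
        self.stimuli = np.asarray(stimuli, dtype=float)
        self.responses = np.asarray(responses, dtype=int)
        if self.stimuli.shape != self.responses.shape:
            raise ValueError("stimuli and responses must align")
        if len(self.stimuli) == 0:
            raise ValueError("no trials")
        self.apparatus = apparatus
        sp = apparatus.button_spacing
        centers = apparatus.button_centers[self.responses - 1]
        self._left = centers - sp / 2.0
        self._right = centers + sp / 2.0
        self._left[self.responses == 1] = -np.inf
        self._right[self.responses == apparatus.button_count] = np.inf
        self.nobs = len(self.stimuli)

    @classmethod
    def from_trials(
        cls, trials, modality: str, apparatus: Apparatus = DEFAULT_APPARATUS
    ) -> "UnimodalLocalizationModel":
        frame = _as_frame(trials)
        sub = frame[frame["modality"] == modality]
        stim = sub["s_A"] if modality == "A" else sub["s_V"]
        resp = sub["resp_A"] if modality == "A" else sub["resp_V"]
        return cls(stim.to_numpy(float), resp.to_numpy(), apparatus)

    def loglike(self, params) -> float:
        delta, sigma = params
        if sigma <= 0:
            return -np.inf
        lo = stats.norm.cdf(self._left, loc=self.stimuli + delta, scale=sigma)
        hi = stats.norm.cdf(self._right, loc=self.stimuli + delta, scale=sigma)
        return float(np.sum(np.log(np.maximum(hi - lo, 1e-300))))

    def fit(
        self,
        delta_bounds: tuple[float, float] = (-20.0, 20.0),
        sigma_bounds: tuple[float, float] = (0.25, 30.0),
    ) -> "UnimodalFitResults":
        errors = self.apparatus.button_centers[self.responses - 1] - self.stimuli
        degenerate = np.ptp(errors) < 1e-9
        if degenerate:
            delta = float(np.clip(errors[0], *delta_bounds))
            sigma = sigma_bounds[0]
            return UnimodalFitResults(
                model=self, delta=delta, sigma=sigma,
                llf=self.loglike((delta, sigma)), degenerate=True, converged=True,
            )
        dgrid = np.linspace(*delta_bounds, 41)
        sgrid = np.geomspace(max(sigma_bounds[0], 0.25), sigma_bounds[1], 25)
        best, best_ll = None, -np.inf
        for d in dgrid:
            for s in sgrid:
                ll = self.loglike((d, s))
                if ll > best_ll:
                    best, best_ll = (d, s), ll
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0=np.array(best),
            method="L-BFGS-B",
            bounds=[delta_bounds, sigma_bounds],
        )
        if -res.fun >= best_ll:
            delta, sigma, llf = float(res.x[0]), float(res.x[1]), float(-res.fun)
        else:  # pragma: no cover - optimizer strictly worse than its start
            (delta, sigma), llf = best, best_ll
        return UnimodalFitResults(
            model=self, delta=delta, sigma=sigma, llf=llf,
            degenerate=False, converged=bool(res.success),
        )


@dataclass
class UnimodalFitResults:
    """MLE of the unimodal likelihood bias and SD for one modality and block."""

    model: UnimodalLocalizationModel
    delta: float
    sigma: float
    llf: float
    degenerate: bool
    converged: bool

    @property
    def params(self) -> dict:
        return {"delta": self.delta, "sigma": self.sigma}

    def summary(self) -> str:
        lines = [
            "Unimodal discretized-Gaussian fit",
            f"  n trials            {self.model.nobs:>10d}",
            f"  delta (bias, deg)   {self.delta:>10.3f}",
            f"  sigma (SD, deg)     {self.sigma:>10.3f}",
            f"  log-likelihood      {self.llf:>10.3f}",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate data (all errors identical); sigma at bound")
        return "\n".join(lines)


def fit_unimodal(trials, modality: str, apparatus: Apparatus = DEFAULT_APPARATUS):
    """Convenience Step-1 fit; returns (delta, sigma) in degrees."""
    res = UnimodalLocalizationModel.from_trials(trials, modality, apparatus).fit()
    return res.delta, res.sigma


def fit_block_likelihood(
    trials, apparatus: Apparatus = DEFAULT_APPARATUS
) -> LikelihoodParams:
    """Step-1 likelihood parameters for one block (both modalities)."""
    dA, sA = fit_unimodal(trials, "A", apparatus)
    dV, sV = fit_unimodal(trials, "V", apparatus)
    return LikelihoodParams(delta_A=dA, sigma_A=sA, delta_V=dV, sigma_V=sV)


# ---------------------------------------------------------------------------
# Steps 2 and 3: multinomial Monte-Carlo fits of the prior parameters


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    if isinstance(trials, TrialSequence):
        return trials.to_frame()
    return TrialSequence(trials=list(trials), block=0, seed=-1).to_frame()


def aggregate_av_histograms(
    trials, apparatus: Apparatus = DEFAULT_APPARATUS
) -> list[tuple[StimulusPair, np.ndarray, np.ndarray]]:
    """Observed per-pair 12-bin response counts (A and V) from AV trials."""
    frame = _as_frame(trials)
    av = frame[frame["modality"] == "AV"]
    if av[["resp_A", "resp_V"]].isna().any().any():
        raise ValueError("AV trials must carry both responses")
    out = []
    nb = apparatus.button_count
    for (sa, sv), grp in sorted(av.groupby(["s_A", "s_V"]).groups.items()):
        sub = av.loc[grp]
        counts_A = np.bincount(sub["resp_A"].astype(int) - 1, minlength=nb)
        counts_V = np.bincount(sub["resp_V"].astype(int) - 1, minlength=nb)
        out.append((StimulusPair(float(sa), float(sv)), counts_A, counts_V))
    return out


def _row_proportions(buttons: np.ndarray, n_buttons: int) -> np.ndarray:
    """Per-row normalized histograms of a 2-D array of button indices."""
    n_rows, n_cols = buttons.shape
    flat = (buttons - 1) + n_buttons * np.arange(n_rows)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_buttons)
    return counts.reshape(n_rows, n_buttons) / float(n_cols)


@dataclass
class FitResult:
    """Fitted prior parameters and fit statistics for one family.

    ``k`` counts only the prior parameters fitted in this step (the Step-1
    likelihood parameters are shared by all families and cancel in the
    comparison); ``N`` is the number of localization responses entering the
    multinomial likelihood (two per AV trial).
    """

    family: str
    fitted_prior: PriorParams | None
    fixed_likelihood: LikelihoodParams
    log_lik: float
    k: int
    N: int
    converged: bool = True
    grid_log_lik: float | None = None
    config: FitConfig | None = None

    @property
    def bic(self) -> float:
        return bic(self.log_lik, self.k, self.N)

    # statsmodels-flavored aliases
    @property
    def llf(self) -> float:
        return self.log_lik

    @property
    def nobs(self) -> int:
        return self.N

    @property
    def params(self) -> dict:
        if self.fitted_prior is None:
            return {}
        out = {"mu_P": self.fitted_prior.mu_P, "sigma_P": self.fitted_prior.sigma_P}
        if self.family in CI_FAMILIES:
            out["p_common"] = self.fitted_prior.p_common
        return out

    def spec(self) -> ObserverSpec:
        prior = None if self.family in ("FFnp", "SGnp") else self.fitted_prior
        return ObserverSpec(self.family, self.fixed_likelihood, prior)

    def predict(
        self,
        pair: StimulusPair,
        n_sim: int | None = None,
        apparatus: Apparatus = DEFAULT_APPARATUS,
        seed: int = 0,
    ) -> PredictedResponseDistribution:
        n = n_sim or (self.config.n_sim if self.config else 10_000)
        return simulate_av_responses(self.spec(), pair, n, apparatus, seed)

    def summary(self) -> str:
        lines = [
            f"Observer-model fit: {self.family}",
            f"  responses (N)       {self.N:>10d}",
            f"  free parameters (k) {self.k:>10d}",
            f"  log-likelihood      {self.log_lik:>10.3f}",
            f"  BIC                 {self.bic:>10.3f}",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<19s} {val:>10.4f}")
        if not self.converged:
            lines.append("  WARNING: refinement did not converge; best grid point kept")
        return "\n".join(lines)


class AVObserverModel:
    """One observer family to be fitted to the AV trials of one block.

    The likelihood parameters are fixed (from Step 1); only the prior
    parameters of the family are free.  The Monte-Carlo objective is
    deterministic in the parameters: the sensory noise and the
    probability-matching draws are generated once per fit from
    ``config.seed`` and reused for every parameter evaluation (common random
    numbers).
    """

    def __init__(
        self,
        trials,
        family: str,
        likelihood: LikelihoodParams,
        apparatus: Apparatus = DEFAULT_APPARATUS,
        config: FitConfig | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.likelihood = likelihood
        self.apparatus = apparatus
        self.config = config or FitConfig()
        self.histograms = aggregate_av_histograms(trials, apparatus)
        if not self.histograms:
            raise ValueError("no AV trials to fit")
        self.nobs = int(
            sum(cA.sum() + cV.sum() for _, cA, cV in self.histograms)
        )
        self._draw_noise()

    def _draw_noise(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        n = self.config.n_sim
        lik = self.likelihood
        xA, xV = [], []
        for pair, _, _ in self.histograms:
            xA.append(rng.normal(pair.s_A + lik.delta_A, lik.sigma_A, size=n))
            xV.append(rng.normal(pair.s_V + lik.delta_V, lik.sigma_V, size=n))
        self._x_A = np.vstack(xA)
        self._x_V = np.vstack(xV)
        self._xi = rng.uniform(size=self._x_A.shape)
        self._counts_A = np.vstack([cA for _, cA, _ in self.histograms])
        self._counts_V = np.vstack([cV for _, _, cV in self.histograms])

    def _prior_from_vector(self, vector) -> PriorParams | None:
        names = [n for n, _, _ in free_parameters(self.family, self.config.bounds)]
        if not names:
            return None
        values = dict(zip(names, vector))
        return PriorParams(
            mu_P=values.get("mu_P", 0.0),
            sigma_P=values.get("sigma_P", 25.0),
            p_common=values.get("p_common", 0.5),
        )

    def loglike(self, vector=()) -> float:
        """Summed multinomial log-likelihood at a free-parameter vector."""
        prior = self._prior_from_vector(vector)
        spec = ObserverSpec(self.family, self.likelihood, prior)
        r_A, r_V = continuous_responses(spec, self._x_A, self._x_V, self._xi)
        nb = self.apparatus.button_count
        p_A = _row_proportions(bin_responses(r_A, self.apparatus), nb)
        p_V = _row_proportions(bin_responses(r_V, self.apparatus), nb)
        floor = self.config.floor
        ll = np.sum(self._counts_A * np.log(np.maximum(p_A, floor)))
        ll += np.sum(self._counts_V * np.log(np.maximum(p_V, floor)))
        return float(ll)

    def fit(self) -> FitResult:
        free = free_parameters(self.family, self.config.bounds)
        k = len(free)
        if k == 0:
            ll = self.loglike(())
            return FitResult(
                family=self.family, fitted_prior=None,
                fixed_likelihood=self.likelihood, log_lik=ll, k=0, N=self.nobs,
                converged=True, grid_log_lik=ll, config=self.config,
            )
        candidates = grid_candidates(free, self.config.grid_points_per_param)
        grid_ll = [self.loglike(c) for c in candidates]
        best_idx = int(np.argmax(grid_ll))
        x0, best_ll = np.array(candidates[best_idx]), grid_ll[best_idx]
        res = optimize.minimize(
            lambda v: -self.loglike(v),
            x0=x0,
            method="L-BFGS-B",
            bounds=[(lo, hi) for _, lo, hi in free],
            options={"maxiter": self.config.maxiter, "eps": 1e-2},
        )
        # A flat (piecewise-constant) Monte-Carlo objective can make the line
        # search abort at the start; any refinement that did not fall below
        # the grid optimum counts as converged.
        if -res.fun >= best_ll:
            vector, llf, converged = res.x, float(-res.fun), True
        else:
            vector, llf, converged = x0, best_ll, False
        return FitResult(
            family=self.family,
            fitted_prior=self._prior_from_vector(vector),
            fixed_likelihood=self.likelihood,
            log_lik=llf, k=k, N=self.nobs,
            converged=converged, grid_log_lik=best_ll, config=self.config,
        )


def fit_model(
    family: str,
    av_trials,
    fixed_likelihood: LikelihoodParams,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    config: FitConfig | None = None,
) -> FitResult:
    """Step-2 fit of one family to one block's AV trials."""
    return AVObserverModel(av_trials, family, fixed_likelihood, apparatus, config).fit()


def fit_block2_priors(
    best_family: str,
    block2_av_trials,
    block2_likelihood: LikelihoodParams,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    config: FitConfig | None = None,
) -> FitResult:
    """Step-3 refit of the Block 1 winner to Block 2 (no model comparison)."""
    return fit_model(best_family, block2_av_trials, block2_likelihood, apparatus, config)


def select_best(fits: list[FitResult]) -> str:
    """Family with the lowest BIC; ties go to fewer parameters, then family order."""
    if not fits:
        raise ValueError("empty fit list")
    return min(
        fits, key=lambda f: (f.bic, f.k, FAMILIES.index(f.family))
    ).family


# ---------------------------------------------------------------------------
# per-participant three-step pipeline


@dataclass
class ParticipantFitReport:
    """All three fitting steps for one participant."""

    participant: str
    block1_likelihood: LikelihoodParams
    block2_likelihood: LikelihoodParams
    block1_fits: dict
    best_family: str
    block2_fit: FitResult

    def bic_table(self) -> pd.DataFrame:
        rows = []
        fits = sorted(self.block1_fits.values(), key=lambda f: f.bic)
        for rank, f in enumerate(fits, start=1):
            rows.append(
                {
                    "participant": self.participant,
                    "family": f.family,
                    "log_lik": f.log_lik,
                    "k": f.k,
                    "N": f.N,
                    "bic": f.bic,
                    "rank": rank,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = [
            f"Participant {self.participant}: best model {self.best_family}",
            "Block 1 BIC comparison:",
        ]
        tbl = self.bic_table()[["family", "log_lik", "k", "bic", "rank"]]
        return "\n".join(head + ["  " + line for line in tbl.to_string(index=False).splitlines()])


def fit_participant(
    block1_trials,
    block2_trials,
    participant: str = "p0",
    families=FAMILIES,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    config: FitConfig | None = None,
) -> ParticipantFitReport:
    """Run the full Step 1 → Step 2 → Step 3 pipeline for one participant."""
    config = config or FitConfig()
    lik1 = fit_block_likelihood(block1_trials, apparatus)
    lik2 = fit_block_likelihood(block2_trials, apparatus)
    fits = {
        fam: fit_model(fam, block1_trials, lik1, apparatus, config)
        for fam in families
    }
    best = select_best(list(fits.values()))
    block2_fit = fit_block2_priors(best, block2_trials, lik2, apparatus, config)
    return ParticipantFitReport(
        participant=participant,
        block1_likelihood=lik1,
        block2_likelihood=lik2,
        block1_fits=fits,
        best_family=best,
        block2_fit=block2_fit,
    )
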