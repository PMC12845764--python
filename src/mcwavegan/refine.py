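"""Metropolis-Hastings refinement of generated audio toward real features.

The refinement stage walks a Markov chain over acoustic feature vectors.
At every step a candidate feature vector ``v`` is drawn from the pool of
generated clips and a real feature vector ``r_t`` from the real set; the
proposed transition is the β-weighted combination

    θ_prop = (1 − β) (v − s_t) + β (v − r_t),        0 ≤ β ≤ 1,

where ``s_t`` is the current synthetic state's features.  The proposal
is accepted with probability α = min(1, p(θ_prop)/p(θ_t)) under a
Gaussian prior p(.) fitted to real-data transitions, using a uniform
draw u < α.  Accepted feature vectors are smoothed with an exponential
moving average; the emitted audio is the accepted candidate's waveform
(no feature-to-waveform inversion is performed — see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SegmentSet
from .features import FeatureConfig, GaussianPrior, fit_gaussian_prior, refinement_matrix

log = logging.getLogger(__name__)


@dataclass
class RefineConfig:
    """Knobs of the refinement chain.

    ``beta`` trades similarity-to-real (β→1) against smooth transitions
    from the current synthetic state (β→0).  ``prior_on`` selects
    whether the Gaussian prior is fitted on real *transition* vectors
    (differences of paired real features, the default) or on raw real
    feature vectors.
    """

    beta: float = 0.01
    n_out: int = 100
    ema_alpha: float = 0.2
    max_iters: int | None = None  # default 50 * n_out
    prior_on: str = "transitions"
    seed: int = 0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must satisfy 0 <= beta <= 1, got {self.beta}")
        if self.n_out < 1:
            raise ValueError("n_out must be >= 1")
        if not (0.0 < self.ema_alpha <= 1.0):
            raise ValueError("ema_alpha must be in (0, 1]")
        if self.prior_on not in ("transitions", "features"):
            raise ValueError("prior_on must be 'transitions' or 'features'")

    @property
    def budget(self) -> int:
        return self.max_iters if self.max_iters is not None else 50 * self.n_out


@dataclass
class ChainState:
    """Mutable state of one refinement chain."""

    theta: np.ndarray            # current chain state θ_t
    s: np.ndarray                # current synthetic feature vector s_t
    ema: np.ndarray | None       # EMA accumulator (None until first acceptance)
    rng: np.random.Generator
    t: int = 0
    accepted: list = field(default_factory=list)  # (pool index, smoothed features)
    n_proposed: int = 0
    last_alpha: float = float("nan")  # α of the most recent proposal


@dataclass
class RefinedSet:
    """Output of :func:`refine`: emitted clips plus chain metadata."""

    clips: SegmentSet
    features: np.ndarray          # smoothed feature vectors, parallel to clips
    accepted_indices: np.ndarray  # pool indices, parallel to clips
    acceptance_rate: float
    beta: float


def transition_vector(v: np.ndarray, s_t: np.ndarray, r_t: np.ndarray, beta: float) -> np.ndarray:
    """θ_prop = (1 − β)(v − s_t) + β(v − r_t), elementwise."""
    v, s_t, r_t = (np.asarray(a, dtype=np.float64) for a in (v, s_t, r_t))
    if not (v.shape == s_t.shape == r_t.shape):
        raise ValueError("v, s_t and r_t must share one dimension")
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    return (1.0 - beta) * (v - s_t) + beta * (v - r_t)


def acceptance_probability(theta_prop: np.ndarray, theta_t: np.ndarray,
                           prior: GaussianPrior) -> float:
    """α = min(1, p(θ_prop)/p(θ_t)), evaluated in log space."""
    log_ratio = prior.logpdf(theta_prop) - prior.logpdf(theta_t)
    return float(np.exp(min(0.0, log_ratio)))


def ema_smooth(prev: np.ndarray | None, new: np.ndarray, ema_alpha: float) -> np.ndarray:
    """Exponential moving average; the first sample initializes the accumulator."""
    new = np.asarray(new, dtype=np.float64)
    if prev is None:
        return new.copy()
    prev = np.asarray(prev, dtype=np.float64)
    if prev.shape != new.shape:
        raise ValueError("EMA operands must share one dimension")
    return ema_alpha * new + (1.0 - ema_alpha) * prev


def mh_step(state: ChainState, pool_features: np.ndarray, real_features: np.ndarray,
            prior: GaussianPrior, cfg: RefineConfig) -> ChainState:
    """One accept/reject step of the chain (mutates and returns ``state``).

    Candidate v is drawn uniformly (with replacement) from the pool,
    r_t uniformly from the real set; u ~ Uniform(0,1) decides
    acceptance.  On rejection nothing changes except the step counter.
    """
    j = int(state.rng.integers(len(pool_features)))
    k = int(state.rng.integers(len(real_features)))
    v = pool_features[j]
    r_t = real_features[k]
    theta_prop = transition_vector(v, state.s, r_t, cfg.beta)
    alpha = acceptance_probability(theta_prop, state.theta, prior)
    u = float(state.rng.uniform())
    state.n_proposed += 1
    state.last_alpha = alpha
    if u < alpha:
        state.theta = theta_prop
        state.s = v
        state.ema = ema_smooth(state.ema, v, cfg.ema_alpha)
        state.accepted.append((j, state.ema.copy()))
    state.t += 1
    return state


def _fit_prior(real_features: np.ndarray, cfg: RefineConfig,
               rng: np.random.Generator) -> GaussianPrior:
    if cfg.prior_on == "features":
        return fit_gaussian_prior(real_features)
    n = len(real_features)
    a = rng.integers(n, size=max(2 * n, 4))
    b = rng.integers(n, size=max(2 * n, 4))
    return fit_gaussian_prior(real_features[a] - real_features[b])


def refine_features(pool_features: np.ndarray, real_features: np.ndarray,
                    cfg: RefineConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the chain in feature space only.

    Returns ``(accepted_indices, smoothed_features, acceptance_rate)``.
    Used directly when the pool already lives in feature space (and by
    :func:`refine` after feature extraction).
    """
    pool_features = np.atleast_2d(np.asarray(pool_features, dtype=np.float64))
    real_features = np.atleast_2d(np.asarray(real_features, dtype=np.float64))
    if len(pool_features) == 0 or len(real_features) == 0:
        raise ValueError("pool and real feature sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    prior = _fit_prior(real_features, cfg, rng)

    # θ0: a transition of the same kind the chain will propose, built
    # from an initial (candidate, state, real) draw.  Initializing at a
    # real-data transition instead deadlocks the chain whenever the
    # generated pool is imperfect: the initial density is then
    # unreachably high and every proposal is rejected.
    s0 = pool_features[int(rng.integers(len(pool_features)))]
    v0 = pool_features[int(rng.integers(len(pool_features)))]
    r0 = real_features[int(rng.integers(len(real_features)))]
    theta0 = transition_vector(v0, s0, r0, cfg.beta)
    state = ChainState(theta=theta0.copy(), s=s0.copy(), ema=None, rng=rng)

    # Vectorized drive of the accept/reject walk.  Between acceptances
    # s_t is constant, so proposal densities for a whole block can be
    # evaluated at once; the strictly sequential part is then scalar
    # compares, with the block densities recomputed from the current
    # position whenever a proposal is accepted.  The per-step rule is
    # exactly the one in :func:`mh_step` (draw v, draw r_t, u < α).
    beta = cfg.beta
    const = -0.5 * np.log(2 * np.pi * prior.var_).sum()

    def block_logpdf(A, s):
        D = A - (1.0 - beta) * s - prior.mean_
        return -0.5 * np.sum(D * D / prior.var_, axis=1) + const

    block = 1024
    log_theta_t = prior.logpdf(state.theta)
    while len(state.accepted) < cfg.n_out and state.n_proposed < cfg.budget:
        if state.n_proposed:
            # size blocks so tail recomputes after acceptances stay cheap
            est = max(len(state.accepted) / state.n_proposed, 1e-4)
            block = int(np.clip(8.0 / est, 512, 16384))
        n = min(block, cfg.budget - state.n_proposed)
        js = rng.integers(len(pool_features), size=n)
        ks = rng.integers(len(real_features), size=n)
        us = rng.uniform(size=n)
        V = pool_features[js]
        A = V - beta * real_features[ks]  # theta_prop = A - (1-beta) s_t
        lps = block_logpdf(A, state.s)
        for i in range(n):
            state.n_proposed += 1
            state.t += 1
            if us[i] < np.exp(min(0.0, lps[i] - log_theta_t)):
                state.theta = A[i] - (1.0 - beta) * state.s
                log_theta_t = lps[i]
                state.s = V[i]
                state.ema = ema_smooth(state.ema, V[i], cfg.ema_alpha)
                state.accepted.append((int(js[i]), state.ema.copy()))
                if len(state.accepted) >= cfg.n_out:
                    break
                lps[i + 1 :] = block_logpdf(A[i + 1 :], state.s)

    rate = len(state.accepted) / max(state.n_proposed, 1)
    if len(state.accepted) < cfg.n_out:
        warnings.warn(
            f"refinement budget exhausted: {len(state.accepted)}/{cfg.n_out} "
            f"acceptances after {state.n_proposed} proposals "
            f"(acceptance rate {rate:.3f})",
            RuntimeWarning,
        )
    if state.accepted:
        idx = np.array([i for i, _ in state.accepted], dtype=int)
        feats = np.stack([f for _, f in state.accepted])
    else:
        idx = np.empty(0, dtype=int)
        feats = np.empty((0, pool_features.shape[1]))
    return idx, feats, rate


def refine(pool: SegmentSet, reals: SegmentSet, cfg: RefineConfig) -> RefinedSet:
    """Refine a pool of generated clips toward the real feature distribution.

    Emits the accepted candidates' waveforms (labels preserved from the
    pool) with the EMA-smoothed feature vectors as metadata.
    """
    if len(pool) == 0 or len(reals) == 0:
        raise ValueError("pool and real segment sets must be non-empty")
    fcfg = cfg.feature_config
    pool_features = refinement_matrix(pool, fcfg)
    real_features = refinement_matrix(reals, fcfg)
    idx, feats, rate = refine_features(pool_features, real_features, cfg)
    log.info("refine(beta=%g): acceptance rate %.3f, emitted %d clips", cfg.beta, rate, len(idx))
    return RefinedSet(
        clips=pool.subset(idx) if len(idx) else pool.subset(np.empty(0, dtype=int)),
        features=feats,
        accepted_indices=idx,
        acceptance_rate=rate,
        beta=cfg.beta,
    )


def sweep_beta(pool: SegmentSet, reals: SegmentSet, betas, cfg: RefineConfig,
               ref_classifier, target_label: str) -> pd.DataFrame:
    """Refine at each β and classify the result with the reference model.

    Returns one row per β with per-class counts (rows sum to the number
    of emitted clips), the acceptance rate, and a ``best`` flag on the β
    whose refined set has the highest target-class count (earliest β on
    ties).
    """
    betas = list(betas)
    if not betas:
        raise ValueError("betas must be non-empty")
    alphabet = list(ref_classifier.classes_)
    rows = []
    for beta in betas:
        run_cfg = RefineConfig(
            beta=beta, n_out=cfg.n_out, ema_alpha=cfg.ema_alpha,
            max_iters=cfg.max_iters, prior_on=cfg.prior_on, seed=cfg.seed,
            feature_config=cfg.feature_config,
        )
        refined = refine(pool, reals, run_cfg)
        pred = ref_classifier.predict(refined.clips.segments)
        counts = {c: int(np.sum(pred == c)) for c in alphabet}
        rows.append({"beta": beta, **counts, "n_out": len(refined.clips),
                     "acceptance_rate": refined.acceptance_rate})
    table = pd.DataFrame(rows)
    best_idx = int(table[target_label].to_numpy().argmax())
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


class MetropolisRefiner:
    """Estimator-style front: ``fit`` on real segments, ``transform`` a pool.

    Thin object wrapper over :func:`refine` so the refinement stage can
    sit in sklearn-style compositions; parameters mirror
    :class:`RefineConfig`.
    """

    def __init__(self, beta: float = 0.01, n_out: int = 100, ema_alpha: float = 0.2,
                 max_iters: int | None = None, prior_on: str = "transitions",
                 seed: int = 0, feature_config: FeatureConfig | None = None):
        self.beta = beta
        self.n_out = n_out
        self.ema_alpha = ema_alpha
        self.max_iters = max_iters
        self.prior_on = prior_on
        self.seed = seed
        self.feature_config = feature_config

    def _config(self) -> RefineConfig:
        return RefineConfig(
            beta=self.beta, n_out=self.n_out, ema_alpha=self.ema_alpha,
            max_iters=self.max_iters, prior_on=self.prior_on, seed=self.seed,
            feature_config=self.feature_config or FeatureConfig(),
        )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "beta", "n_out", "ema_alpha", "max_iters", "prior_on", "seed", "feature_config")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, reals: SegmentSet):
        self.reals_ = reals
        self.real_features_ = refinement_matrix(reals, self.feature_config or FeatureConfig())
        return self

    def transform(self, pool: SegmentSet) -> RefinedSet:
        if not hasattr(self, "reals_"):
            raise RuntimeError("MetropolisRefiner must be fitted on real segments first")
        return refine(pool, self.reals_, self._config())
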