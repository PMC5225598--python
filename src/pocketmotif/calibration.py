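"""Background Q-score calibration and extreme-value P-values.

Structure alignment of small local structures produces many spuriously high
scores, so raw Q is converted to a significance. The null is built
empirically: random pocket pairs are drawn from a background pocket set,
aligned, and the resulting Q-scores are fitted by a generalized extreme
value distribution with shape k, location mu and scale sigma. The P-value of
an observed Q-score x is the fitted survival function

    P(s > x) = 1 - exp(-[1 + k (x - mu) / sigma]^(-1/k))

(with the Gumbel limit 1 - exp(-exp(-(x - mu)/sigma)) as k -> 0). Pairs with
P below a significance threshold (default alpha = 0.05, strict) are called
significantly similar.

Shape-parameter sign convention: here k > 0 gives the heavy right tail
(Frechet type); scipy.stats.genextreme uses c = -k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from .nsalign import AlignmentParams, align_pockets
from .structio import InputError, NumericalError, PocketStructure

__all__ = [
    "EVDParams",
    "CalibrationModel",
    "sample_background_pairs",
    "background_q_scores",
    "fit_evd",
    "p_value",
    "calibrate",
    "benjamini_hochberg",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_PAIRS = 20_000
MIN_FIT_SAMPLES = 100
_GUMBEL_EPS = 1e-10


@dataclass(frozen=True)
class EVDParams:
    """Extreme-value null parameters (k > 0: heavy right tail)."""
    k: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not (math.isfinite(self.k) and math.isfinite(self.mu)
                and math.isfinite(self.sigma)):
            raise InputError("EVD parameters must be finite")
        if self.sigma <= 0:
            raise InputError(f"EVD sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class CalibrationModel:
    params: EVDParams
    n_samples: int
    fit_method: str
    goodness: float              # Kolmogorov-Smirnov statistic of the fit

    def __post_init__(self):
        if self.n_samples < MIN_FIT_SAMPLES:
            raise InputError(
                f"calibration needs >= {MIN_FIT_SAMPLES} samples, "
                f"got {self.n_samples}")

    def to_dict(self) -> dict:
        return {"k": self.params.k, "mu": self.params.mu,
                "sigma": self.params.sigma, "n_samples": self.n_samples,
                "fit_method": self.fit_method, "ks": self.goodness}

    @staticmethod
    def from_dict(d: dict) -> "CalibrationModel":
        return CalibrationModel(EVDParams(d["k"], d["mu"], d["sigma"]),
                                int(d["n_samples"]), d["fit_method"], d["ks"])


# ---------------------------------------------------------------------------
# Background sampling

def sample_background_pairs(background: Sequence[PocketStructure],
                            n_pairs: int, seed: int) -> list:
    """Draw ``n_pairs`` uniformly random distinct-pocket pairs (with
    replacement across pairs), reproducibly from ``seed``."""
    pockets = sorted(background, key=lambda p: p.pocket_id)
    if len(pockets) < 2:
        raise InputError(
            f"background must contain >= 2 pockets, got {len(pockets)}")
    rng = np.random.default_rng(seed)
    n = len(pockets)
    pairs = []
    for _ in range(n_pairs):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        pairs.append((pockets[i], pockets[j]))
    return pairs


def background_q_scores(background: Sequence[PocketStructure],
                        n_pairs: int, seed: int,
                        params: AlignmentParams = AlignmentParams()
                        ) -> np.ndarray:
    """Q-scores of random background pocket pairs.

    Q is deterministic per unordered pair, so alignments are computed once
    per distinct pair and reused across repeated draws.
    """
    pairs = sample_background_pairs(background, n_pairs, seed)
    cache: dict = {}
    qs = np.empty(len(pairs))
    for idx, (a, b) in enumerate(pairs):
        key = tuple(sorted((a.pocket_id, b.pocket_id)))
        if key not in cache:
            cache[key] = align_pockets(a, b, params).q
        qs[idx] = cache[key]
    return qs


# ---------------------------------------------------------------------------
# GEV fitting

def _lmoment_estimates(x: np.ndarray) -> tuple:
    """L-moment starting values (Hosking) as (k, mu, sigma) in the
    k-positive-heavy-tail convention."""
    xs = np.sort(x)
    n = len(xs)
    i = np.arange(1, n + 1)
    b0 = xs.mean()
    b1 = np.sum((i - 1) / (n - 1) * xs) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * xs) / n
    l1, l2, l3 = b0, 2 * b1 - b0, 6 * b2 - 6 * b1 + b0
    t3 = l3 / l2 if l2 != 0 else 0.0
    c = 2.0 / (3.0 + t3) - math.log(2) / math.log(3)
    kappa = 7.8590 * c + 2.9554 * c * c      # Hosking's kappa = -k (ours)
    if abs(kappa) < 1e-8:
        sigma = l2 / math.log(2)
        mu = l1 - sigma * 0.5772156649015329
        return 0.0, mu, sigma
    g = gamma_fn(1.0 + kappa)
    sigma = l2 * kappa / ((1.0 - 2.0 ** (-kappa)) * g)
    mu = l1 - sigma * (1.0 - g) / kappa
    return -kappa, mu, sigma


def fit_evd(q_samples) -> CalibrationModel:
    """Maximum-likelihood GEV fit of background Q-scores.

    Initialised with L-moment estimates; the Kolmogorov-Smirnov statistic of
    the fitted distribution against the sample is reported as goodness.
    """
    x = np.asarray(q_samples, dtype=float).ravel()
    if len(x) < MIN_FIT_SAMPLES:
        raise InputError(
            f"need >= {MIN_FIT_SAMPLES} samples to fit, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise InputError("Q-score samples contain non-finite values")
    if np.min(x) == np.max(x):
        raise InputError("degenerate (constant) Q-score samples; cannot fit")
    k0, mu0, s0 = _lmoment_estimates(x)
    try:
        # scipy's shape c = -k
        c_hat, loc_hat, scale_hat = stats.genextreme.fit(
            x, -k0, loc=mu0, scale=max(s0, 1e-12))
        if not (np.isfinite(c_hat) and np.isfinite(loc_hat)
                and np.isfinite(scale_hat) and scale_hat > 0):
            raise ValueError("non-finite MLE result")
        method = "mle (L-moment init)"
    except Exception as exc:
        err = NumericalError(
            f"GEV maximum-likelihood fit failed ({exc}); "
            f"L-moment estimates: k={k0:.6g}, mu={mu0:.6g}, sigma={s0:.6g}")
        err.lmoment_params = EVDParams(k0, mu0, s0)
        raise err from exc
    ks = float(stats.kstest(
        x, stats.genextreme(c_hat, loc=loc_hat, scale=scale_hat).cdf).statistic)
    return CalibrationModel(
        EVDParams(float(-c_hat), float(loc_hat), float(scale_hat)),
        len(x), method, ks)


# ---------------------------------------------------------------------------
# P-values

def p_value(q: float, params: EVDParams) -> float:
    """Survival value P(s > q) of the fitted extreme-value null.

    For |k| below 1e-10 the Gumbel limit is used. Outside the distribution's
    support the value is clamped: below the lower endpoint (k > 0) the
    P-value is 1; above the upper endpoint (k < 0) it is 0.
    """
    if not math.isfinite(q):
        raise InputError(f"non-finite Q-score: {q}")
    k, mu, sigma = params.k, params.mu, params.sigma
    if abs(k) < _GUMBEL_EPS:
        return 1.0 - math.exp(-math.exp(-(q - mu) / sigma))
    z = 1.0 + k * (q - mu) / sigma
    if z <= 0.0:
        return 1.0 if k > 0 else 0.0
    return 1.0 - math.exp(-z ** (-1.0 / k))


def calibrate(background: Sequence[PocketStructure],
              n_pairs: int = DEFAULT_N_PAIRS, seed: int = 1,
              params: AlignmentParams = AlignmentParams()
              ) -> CalibrationModel:
    """Sample background pairs, align, and fit the EVD null in one call."""
    return fit_evd(background_q_scores(background, n_pairs, seed, params))


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in the
    pipeline, which thresholds raw P like the underlying procedure)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj
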