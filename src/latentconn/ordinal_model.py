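"""Cumulative-logit latent-variable model with participant threshold shifts.

The ordinal responses (explicit 1-5 connectedness ratings and the 1-7 IOS
pictorial scale) are modelled as discretizations of a continuous latent
social-connection score.  For a latent score ``eta`` and an ascending
threshold vector ``c`` the probability of answering category ``k`` is

    P(Y = k) = F(c_k - eta) - F(c_{k-1} - eta),   F = logistic CDF,

with ``c_0 = -inf`` and ``c_K = +inf``.  Each participant carries one scalar
shift per construct (artist / audience) that is added uniformly to all
thresholds of that construct's instruments, letting individual response
styles slide along the latent scale while preserving threshold spacing.

Priors follow the weakly-informative scheme of the analysis this package
implements: N(0, 1) on regression coefficients, an induced Dirichlet on each
threshold vector (a Dirichlet on the category probabilities implied at an
anchor point, transported to ordered-threshold space with its Jacobian),
half-N(0, 1) on random-effect scales, and an LKJ(eta=4) prior on the 2x2
correlation between the artist and audience participant effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

CONSTRUCTS = ("artist", "audience")
#: number of response categories per instrument
INSTRUMENT_LEVELS = {"explicit5": 5, "ios7": 7}


class ConstraintError(ValueError):
    """A parameter value violates the model's constraint set."""


# ---------------------------------------------------------------------------
# core probability kernels
# ---------------------------------------------------------------------------

def _check_ascending(cut: np.ndarray) -> None:
    cut = np.asarray(cut, dtype=float)
    if cut.ndim != 1 or cut.size < 1:
        raise ConstraintError("threshold vector must be 1-D and non-empty")
    if not np.all(np.diff(cut) > 0):
        raise ConstraintError(f"thresholds must be strictly ascending, got {cut}")


def _log_cdf_diff(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """log(F(hi) - F(lo)) for the logistic CDF, stable for extreme arguments.

    Uses F(b) - F(a) = sigmoid(b) * sigmoid(-a) * (1 - exp(a - b)).
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    out = special.log_expit(hi) + special.log_expit(-lo)
    with np.errstate(invalid="ignore"):
        tail = np.where(np.isneginf(lo), 0.0, np.log(-np.expm1(np.minimum(lo - hi, -1e-300))))
    return out + tail


def category_logprobs(eta: float | np.ndarray, cut: np.ndarray) -> np.ndarray:
    """Log-probabilities of all K categories under the cumulative-logit model.

    Parameters
    ----------
    eta
        Latent score (scalar or array broadcast against the leading axis).
    cut
        Strictly ascending thresholds of length K - 1.

    Returns
    -------
    ndarray with last axis of length K; ``exp`` of it sums to 1.
    """
    _check_ascending(cut)
    cut = np.asarray(cut, dtype=float)
    eta = np.asarray(eta, dtype=float)
    padded = np.concatenate(([-np.inf], cut, [np.inf]))
    lo = padded[:-1] - eta[..., None]
    hi = padded[1:] - eta[..., None]
    return _log_cdf_diff(lo, hi)


def observed_logprob(y: np.ndarray, eta: np.ndarray, cut: np.ndarray,
                     shift: np.ndarray | float = 0.0) -> np.ndarray:
    """Vectorized log P(Y = y | eta, cut + shift) for 1-based integer responses.

    ``y`` entries < 1 are treated as missing and contribute exactly 0.
    """
    _check_ascending(cut)
    y = np.asarray(y)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), y.shape)
    shift = np.broadcast_to(np.asarray(shift, dtype=float), y.shape)
    padded = np.concatenate(([-np.inf], np.asarray(cut, dtype=float), [np.inf]))
    observed = y >= 1
    yy = np.where(observed, y, 1).astype(int)
    lo = padded[yy - 1] + shift - eta
    hi = padded[yy] + shift - eta
    return np.where(observed, _log_cdf_diff(lo, hi), 0.0)


def induced_dirichlet_logpdf(cut: np.ndarray, alpha: np.ndarray,
                             anchor: float = 0.0, *, strict: bool = True) -> float:
    """Log-density of the induced Dirichlet prior on an ordered threshold vector.

    The prior places Dirichlet(alpha) mass on the K category probabilities the
    thresholds imply at the anchor point, ``p_k = F(c_k - anchor) -
    F(c_{k-1} - anchor)``; the log-Jacobian of the cut -> p map is
    ``sum_k log f(c_k - anchor)`` with f the logistic pdf.  With a symmetric
    alpha this pools the thresholds toward equal category probabilities
    (equal spacing on the latent scale) with flexibility set by alpha.

    With ``strict=False`` a non-ascending cut returns ``-inf`` instead of
    raising, which is the behaviour samplers want.
    """
    cut = np.asarray(cut, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentration must be strictly positive")
    if alpha.size != cut.size + 1:
        raise ValueError("alpha must have length K = len(cut) + 1")
    if cut.ndim != 1 or not np.all(np.diff(cut) > 0):
        if strict:
            raise ConstraintError(f"thresholds must be strictly ascending, got {cut}")
        return -np.inf
    z = cut - anchor
    cdf = np.concatenate(([0.0], special.expit(z), [1.0]))
    p = np.diff(cdf)
    if np.any(p <= 0):
        return -np.inf
    log_jac = np.sum(special.log_expit(z) + special.log_expit(-z))
    return float(stats.dirichlet.logpdf(p / p.sum(), alpha) + log_jac)


# ---------------------------------------------------------------------------
# prior building blocks
# ---------------------------------------------------------------------------

def halfnormal_logpdf(x: np.ndarray, sd: float = 1.0) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(np.log(2.0) + stats.norm.logpdf(x, scale=sd)))


def lkj_corr_2x2_logpdf(rho: float, eta: float = 4.0) -> float:
    """LKJ(eta) log-density of a 2x2 correlation, as a density in rho.

    The bivariate LKJ marginal is (rho + 1)/2 ~ Beta(eta, eta), i.e.
    p(rho) = (1 - rho^2)^(eta - 1) / (2^(2 eta - 1) B(eta, eta)).
    """
    if not -1.0 < rho < 1.0:
        return -np.inf
    log_norm = (2.0 * eta - 1.0) * np.log(2.0) + special.betaln(eta, eta)
    return float((eta - 1.0) * np.log1p(-rho * rho) - log_norm)


def mvn2_logpdf(u: np.ndarray, sigma: np.ndarray, rho: float) -> float:
    """Sum of bivariate-normal log-densities of the rows of ``u`` (mean 0)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    s1, s2 = float(sigma[0]), float(sigma[1])
    if s1 <= 0 or s2 <= 0 or not -1.0 < rho < 1.0:
        return -np.inf
    det = (1.0 - rho * rho)
    z1 = u[:, 0] / s1
    z2 = u[:, 1] / s2
    quad = (z1 * z1 - 2.0 * rho * z1 * z2 + z2 * z2) / det
    n = u.shape[0]
    const = -np.log(2.0 * np.pi) - np.log(s1) - np.log(s2) - 0.5 * np.log(det)
    return float(n * const - 0.5 * np.sum(quad))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Weakly-informative prior settings (defaults mirror the study scheme)."""

    beta_sd: float = 1.0
    cut_alpha: float = 1.0     # symmetric Dirichlet concentration per category
    cut_anchor: float = 0.0
    sigma_sd: float = 1.0
    lkj_eta: float = 4.0

    def __post_init__(self) -> None:
        if self.cut_alpha <= 0 or self.lkj_eta <= 0:
            raise ValueError("cut_alpha and lkj_eta must be positive")


@dataclass
class Parameters:
    """One point in parameter space for the bivariate cumulative-logit model.

    beta maps construct -> coefficient vector, cut maps instrument ->
    ascending thresholds, ``u`` is the n_participants x 2 matrix of
    threshold shifts (columns artist, audience), L the lower Cholesky factor
    of their 2x2 correlation.  ``w``/``sigma_w`` are the per-concert shifts,
    present only for the pooled (overall) scope.
    """

    beta: Mapping[str, np.ndarray]
    cut: Mapping[str, np.ndarray]
    u: np.ndarray
    sigma_u: np.ndarray
    L: np.ndarray
    w: np.ndarray | None = None
    sigma_w: float | None = None

    @property
    def rho(self) -> float:
        return float(self.L[1, 0] / np.hypot(self.L[1, 0], self.L[1, 1]))

    def validate(self) -> None:
        for cut in self.cut.values():
            _check_ascending(np.asarray(cut))
        if np.any(np.asarray(self.sigma_u) <= 0):
            raise ConstraintError("sigma_u must be positive")
        L = np.asarray(self.L, dtype=float)
        if L.shape != (2, 2) or L[0, 1] != 0:
            raise ConstraintError("L must be 2x2 lower-triangular")
        diag = np.diag(L @ L.T)
        if not np.allclose(diag, 1.0, atol=1e-8):
            raise ConstraintError("L L' must have unit diagonal")
        if self.w is not None and (self.sigma_w is None or self.sigma_w <= 0):
            raise ConstraintError("sigma_w must be positive when concert shifts are present")


def corr_cholesky(rho: float) -> np.ndarray:
    """Lower Cholesky factor of [[1, rho], [rho, 1]]."""
    return np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho * rho)]])


# ---------------------------------------------------------------------------
# model data and likelihood
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Arrays the likelihood consumes, aligned row-by-row.

    ``y[construct][instrument]`` holds 1-based responses with 0 marking a
    missing answer; ``X[construct]`` the design matrix; ``participant_idx``
    maps rows to participant-effect rows, ``concert_idx`` (optional) to
    concert shifts.
    """

    X: Mapping[str, np.ndarray]
    y: Mapping[str, Mapping[str, np.ndarray]]
    participant_idx: np.ndarray
    concert_idx: np.ndarray | None = None
    predictor_names: Mapping[str, list] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return int(next(iter(self.X.values())).shape[0])

    @property
    def n_participants(self) -> int:
        return int(self.participant_idx.max()) + 1 if self.n_rows else 0

    def instruments(self, construct: str):
        return self.y[construct].keys()


def linear_predictors(params: Parameters, data: ModelData) -> dict[str, np.ndarray]:
    """Per-construct latent scores x'beta (+ concert shift in pooled scope)."""
    eta = {}
    for o in CONSTRUCTS:
        e = data.X[o] @ np.asarray(params.beta[o], dtype=float)
        if params.w is not None and data.concert_idx is not None:
            e = e + np.asarray(params.w)[data.concert_idx]
        eta[o] = e
    return eta


def loglik_row(responses: Mapping[str, Mapping[str, int]],
               eta_artist: float, eta_audience: float,
               cuts: Mapping[str, np.ndarray],
               u_p: np.ndarray) -> dict[tuple, float]:
    """Per-instrument log-likelihood terms for one participant-row.

    ``responses[construct][instrument]`` is a 1-based category or None/0/NaN
    for missing (missing terms are exactly 0).  The participant shift
    ``u_p = (u_artist, u_audience)`` is added uniformly to all thresholds of
    the construct's instruments.
    """
    eta = {"artist": eta_artist, "audience": eta_audience}
    terms: dict[tuple, float] = {}
    for i, o in enumerate(CONSTRUCTS):
        for m, y in responses.get(o, {}).items():
            if y is None or (isinstance(y, float) and np.isnan(y)) or y < 1:
                terms[(o, m)] = 0.0
                continue
            shifted = np.asarray(cuts[m], dtype=float) + float(u_p[i])
            terms[(o, m)] = float(category_logprobs(eta[o], shifted)[int(y) - 1])
    return terms


def loglik_total(params: Parameters, data: ModelData) -> float:
    """Total observed-data log-likelihood (missing responses marginalized out
    by omission)."""
    eta = linear_predictors(params, data)
    total = 0.0
    u = np.asarray(params.u, dtype=float)
    for i, o in enumerate(CONSTRUCTS):
        shift = u[data.participant_idx, i] if u.size else 0.0
        for m, y in data.y[o].items():
            total += float(np.sum(observed_logprob(y, eta[o], params.cut[m], shift)))
    return total


def log_prior(params: Parameters, priors: PriorConfig, *, strict: bool = False) -> float:
    """Joint log-prior density; -inf outside the constraint set."""
    try:
        params.validate()
    except ConstraintError:
        if strict:
            raise
        return -np.inf
    lp = 0.0
    for o in CONSTRUCTS:
        lp += float(np.sum(stats.norm.logpdf(params.beta[o], scale=priors.beta_sd)))
    for m, cut in params.cut.items():
        alpha = np.full(np.asarray(cut).size + 1, priors.cut_alpha)
        lp += induced_dirichlet_logpdf(np.asarray(cut), alpha, priors.cut_anchor,
                                       strict=False)
    lp += halfnormal_logpdf(params.sigma_u, priors.sigma_sd)
    rho = params.rho
    lp += lkj_corr_2x2_logpdf(rho, priors.lkj_eta)
    if np.asarray(params.u).size:
        lp += mvn2_logpdf(params.u, params.sigma_u, rho)
    if params.w is not None:
        lp += halfnormal_logpdf(np.asarray([params.sigma_w]), priors.sigma_sd)
        lp += float(np.sum(stats.norm.logpdf(params.w, scale=params.sigma_w)))
    return lp


def log_posterior(params: Parameters, data: ModelData | None,
                  spec=None, priors: PriorConfig | None = None) -> float:
    """Joint log-density: likelihood + all prior terms. -inf off-constraint.

    ``spec`` is accepted for interface symmetry with the fitting layer; the
    design is already baked into ``data``.
    """
    priors = priors or PriorConfig()
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    if data is not None and data.n_rows:
        lp += loglik_total(params, data)
    return lp


# ---------------------------------------------------------------------------
# participant-effect marginalization (Gauss-Hermite)
# ---------------------------------------------------------------------------

def _gh_nodes_2d(n_nodes: int, sigma: np.ndarray, rho: float):
    """Nodes/weights for E[g(u)] with u ~ MVN(0, diag(s) R diag(s))."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z1, z2 = np.meshgrid(x, x, indexing="ij")
    z = np.sqrt(2.0) * np.stack([z1.ravel(), z2.ravel()])  # (2, n^2) std-normal nodes
    L = corr_cholesky(rho) * np.asarray(sigma, dtype=float)[:, None]
    u = L @ z                                              # (2, n^2)
    weight = (np.outer(w, w) / np.pi).ravel()
    return u.T, weight                                     # (n^2, 2), (n^2,)


def marginal_loglik_by_participant(params: Parameters, data: ModelData,
                                   n_nodes: int = 15) -> np.ndarray:
    """Per-participant log-likelihood with the participant effect integrated
    out over its MVN law (Gauss-Hermite quadrature on the 2-D effect).

    This is the grouped predictive density used by leave-one-participant-out
    model comparison: new participants come with unknown effects, so the
    effect is averaged over, not conditioned on.
    """
    eta = linear_predictors(params, data)
    nodes, weights = _gh_nodes_2d(n_nodes, params.sigma_u, params.rho)
    n_p = data.n_participants
    n_nodes_sq = len(weights)
    # log integrand per (node, participant)
    acc = np.zeros((n_nodes_sq, n_p))
    onehot = np.zeros((data.n_rows, n_p))
    onehot[np.arange(data.n_rows), data.participant_idx] = 1.0
    for i, o in enumerate(CONSTRUCTS):
        shift = nodes[:, i][:, None]                       # (J, 1) vs rows
        for m, y in data.y[o].items():
            ll = observed_logprob(np.broadcast_to(y, (n_nodes_sq, len(y))),
                                  eta[o][None, :], params.cut[m], shift)
            acc += ll @ onehot                             # sum rows per participant
    return special.logsumexp(acc, axis=0, b=weights[:, None])
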