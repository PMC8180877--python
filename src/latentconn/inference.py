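"""Posterior sampling and summaries for the bivariate cumulative-logit model.

The sampler is an adaptive blocked random-walk Metropolis scheme:

* a *global* block (coefficients, thresholds in log-increment coordinates,
  random-effect scales on the log scale, the effect correlation through
  atanh) updated jointly with a proposal covariance adapted during warmup;
* a *participant* block updating all 2-D participant threshold shifts in
  parallel with independent per-participant accept/reject decisions;
* a *translation* move that shifts every threshold by +d and every
  participant effect by -d.  The likelihood is exactly invariant along this
  direction (only the priors decide), so the move decorrelates the
  threshold location from the mean of the participant effects.

Summaries use central credible intervals from empirical quantiles (linear
interpolation); convergence is judged by split-Rhat and rank-normalized
effective sample size via arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from . import ordinal_model as om
from .data_model import ModelSpec, ResponseTable, build_design
from .ordinal_model import (CONSTRUCTS, INSTRUMENT_LEVELS, ModelData, Parameters,
                            PriorConfig, corr_cholesky, observed_logprob)


class InitializationError(RuntimeError):
    """The initial point has a non-finite log-posterior."""


# ---------------------------------------------------------------------------
# model data assembly
# ---------------------------------------------------------------------------

def build_model_data(table: ResponseTable, spec: ModelSpec, **design_kwargs) -> ModelData:
    """Turn a validated response table + spec into likelihood-ready arrays."""
    design = build_design(table, spec, **design_kwargs)
    pid_codes, _ = pd.factorize(design.participant_ids)
    concert_codes = None
    if spec.random_effects == "participant+concert":
        concert_codes, _ = pd.factorize(design.concerts)
    X = {o: design.frames[o].to_numpy(dtype=float) for o in CONSTRUCTS}
    y: dict[str, dict[str, np.ndarray]] = {o: {} for o in CONSTRUCTS}
    for (o, m), series in design.outcomes.items():
        y[o][m] = np.nan_to_num(series.to_numpy(dtype=float), nan=0.0).astype(int)
    names = {o: list(design.frames[o].columns) for o in CONSTRUCTS}
    return ModelData(X=X, y=y, participant_idx=np.asarray(pid_codes),
                     concert_idx=None if concert_codes is None else np.asarray(concert_codes),
                     predictor_names=names)


# ---------------------------------------------------------------------------
# unconstrained parameterization of the global block
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """Index bookkeeping of the packed unconstrained global vector."""

    p: dict
    instruments: list
    n_cuts: dict
    n_concerts: int
    slices: dict

    @classmethod
    def for_data(cls, data: ModelData) -> "_Layout":
        p = {o: data.X[o].shape[1] for o in CONSTRUCTS}
        instruments = sorted({m for o in CONSTRUCTS for m in data.y[o]},
                             key=lambda m: INSTRUMENT_LEVELS[m])
        n_cuts = {m: INSTRUMENT_LEVELS[m] - 1 for m in instruments}
        n_concerts = 0 if data.concert_idx is None else int(data.concert_idx.max()) + 1
        slices, i = {}, 0
        for o in CONSTRUCTS:
            slices[f"beta_{o}"] = slice(i, i + p[o]); i += p[o]
        for m in instruments:
            slices[f"cut_{m}"] = slice(i, i + n_cuts[m]); i += n_cuts[m]
        slices["log_sigma_u"] = slice(i, i + 2); i += 2
        slices["atanh_rho"] = slice(i, i + 1); i += 1
        if n_concerts:
            slices["w"] = slice(i, i + n_concerts); i += n_concerts
            slices["log_sigma_w"] = slice(i, i + 1); i += 1
        return cls(p, instruments, n_cuts, n_concerts, slices)

    @property
    def size(self) -> int:
        return max(s.stop for s in self.slices.values())


def _cuts_from_raw(raw: np.ndarray) -> np.ndarray:
    """raw = (c1, log d2, ..., log dK-1) -> ascending thresholds."""
    return raw[0] + np.concatenate(([0.0], np.cumsum(np.exp(raw[1:]))))


def _raw_from_cuts(cut: np.ndarray) -> np.ndarray:
    return np.concatenate(([cut[0]], np.log(np.diff(cut))))


def _unpack(theta: np.ndarray, lay: _Layout) -> dict:
    g = {}
    for o in CONSTRUCTS:
        g[f"beta_{o}"] = theta[lay.slices[f"beta_{o}"]]
    for m in lay.instruments:
        g[f"cut_{m}"] = _cuts_from_raw(theta[lay.slices[f"cut_{m}"]])
    g["sigma_u"] = np.exp(theta[lay.slices["log_sigma_u"]])
    g["rho"] = float(np.tanh(theta[lay.slices["atanh_rho"]][0]))
    if lay.n_concerts:
        g["w"] = theta[lay.slices["w"]]
        g["sigma_w"] = float(np.exp(theta[lay.slices["log_sigma_w"]][0]))
    return g


def _row_loglik(g: dict, u: np.ndarray, data: ModelData) -> np.ndarray:
    """Per-row observed-data log-likelihood summed over instruments."""
    total = np.zeros(data.n_rows)
    for i, o in enumerate(CONSTRUCTS):
        eta = data.X[o] @ g[f"beta_{o}"]
        if "w" in g and data.concert_idx is not None:
            eta = eta + g["w"][data.concert_idx]
        shift = u[data.participant_idx, i]
        for m, y in data.y[o].items():
            total += observed_logprob(y, eta, g[f"cut_{m}"], shift)
    return total


def _global_logprior(g: dict, theta: np.ndarray, lay: _Layout,
                     priors: PriorConfig) -> float:
    """Priors of the global block as a density in the unconstrained vector
    (constrained-space priors plus transform Jacobians)."""
    lp = 0.0
    for o in CONSTRUCTS:
        b = g[f"beta_{o}"]
        lp += -0.5 * np.sum((b / priors.beta_sd) ** 2) \
            - b.size * np.log(priors.beta_sd * np.sqrt(2 * np.pi))
    for m in lay.instruments:
        cut = g[f"cut_{m}"]
        alpha = np.full(cut.size + 1, priors.cut_alpha)
        lp += om.induced_dirichlet_logpdf(cut, alpha, priors.cut_anchor, strict=False)
        lp += float(np.sum(theta[lay.slices[f"cut_{m}"]][1:]))     # log-increment Jacobian
    sigma = g["sigma_u"]
    lp += om.halfnormal_logpdf(sigma, priors.sigma_sd)
    lp += float(np.sum(np.log(sigma)))                              # log Jacobian
    rho = g["rho"]
    lp += om.lkj_corr_2x2_logpdf(rho, priors.lkj_eta)
    lp += float(np.log1p(-rho * rho))                               # tanh Jacobian
    if "w" in g:
        sw = g["sigma_w"]
        lp += om.halfnormal_logpdf(np.array([sw]), priors.sigma_sd) + np.log(sw)
        lp += float(np.sum(stats.norm.logpdf(g["w"], scale=sw)))
    return lp


def _u_logprior_rows(u: np.ndarray, sigma: np.ndarray, rho: float) -> np.ndarray:
    """Per-participant bivariate-normal log-prior of the threshold shifts."""
    det = 1.0 - rho * rho
    z1 = u[:, 0] / sigma[0]
    z2 = u[:, 1] / sigma[1]
    quad = (z1 * z1 - 2.0 * rho * z1 * z2 + z2 * z2) / det
    const = -np.log(2 * np.pi) - np.log(sigma[0]) - np.log(sigma[1]) - 0.5 * np.log(det)
    return const - 0.5 * quad


# ---------------------------------------------------------------------------
# draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Named posterior arrays indexed (chain, draw, ...) plus sampler metadata."""

    arrays: dict
    metadata: dict
    data: ModelData

    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """(chain * draw, ...) view of one parameter array."""
        a = self.arrays[name]
        return a.reshape(-1, *a.shape[2:])

    def parameters(self, chain: int, draw: int) -> Parameters:
        a = self.arrays
        lay: _Layout = self.metadata["layout"]
        return Parameters(
            beta={o: a[f"beta_{o}"][chain, draw] for o in CONSTRUCTS},
            cut={m: a[f"cut_{m}"][chain, draw] for m in lay.instruments},
            u=a["u"][chain, draw],
            sigma_u=a["sigma_u"][chain, draw],
            L=corr_cholesky(float(a["rho"][chain, draw])),
            w=a["w"][chain, draw] if "w" in a else None,
            sigma_w=float(a["sigma_w"][chain, draw]) if "sigma_w" in a else None,
        )

    def to_arviz(self):
        import arviz as az
        scalar = {k: v for k, v in self.arrays.items() if v.ndim == 2}
        lay: _Layout = self.metadata["layout"]
        named = {}
        for o in CONSTRUCTS:
            for j, nm in enumerate(self.data.predictor_names.get(o, [])):
                named[f"b_{o}_{nm}"] = self.arrays[f"beta_{o}"][:, :, j]
        named["sigma_u_artist"] = self.arrays["sigma_u"][:, :, 0]
        named["sigma_u_audience"] = self.arrays["sigma_u"][:, :, 1]
        for m in lay.instruments:
            for j in range(self.arrays[f"cut_{m}"].shape[-1]):
                named[f"cut_{m}_{j + 1}"] = self.arrays[f"cut_{m}"][:, :, j]
        return az.from_dict(posterior={**scalar, **named})


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    thin: int = 1
    init_jitter: float = 0.5
    global_updates_per_sweep: int = 3
    target_accept_global: float = 0.25
    target_accept_u: float = 0.44


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _init_state(lay: _Layout, data: ModelData, priors: PriorConfig,
                rng: np.random.Generator, jitter: float):
    theta = np.zeros(lay.size)
    for m in lay.instruments:
        k = lay.n_cuts[m] + 1
        p = np.arange(1, k) / k
        theta[lay.slices[f"cut_{m}"]] = _raw_from_cuts(np.log(p / (1 - p)))
    for o in CONSTRUCTS:
        theta[lay.slices[f"beta_{o}"]] = jitter * 0.5 * rng.standard_normal(lay.p[o])
    theta[lay.slices["log_sigma_u"]] = np.log(0.7) + jitter * 0.3 * rng.standard_normal(2)
    theta[lay.slices["atanh_rho"]] = jitter * 0.2 * rng.standard_normal(1)
    if lay.n_concerts:
        theta[lay.slices["w"]] = jitter * 0.2 * rng.standard_normal(lay.n_concerts)
        theta[lay.slices["log_sigma_w"]] = np.log(0.5)
    g = _unpack(theta, lay)
    u = 0.3 * jitter * rng.standard_normal((data.n_participants, 2))
    return theta, g, u


def _scaled_chol(g: dict) -> np.ndarray:
    """diag(sigma_u) @ corr_cholesky(rho): maps latent z rows to u rows."""
    return corr_cholesky(g["rho"]) * g["sigma_u"][:, None]


def _run_chain(data: ModelData, lay: _Layout, priors: PriorConfig,
               cfg: SamplerConfig, seed: int):
    # non-centered parameterization: u = z @ L_s' with z rows iid N(0, I_2),
    # L_s = diag(sigma_u) corr_cholesky(rho); scale/correlation updates then
    # move u along with them, which avoids the hierarchical funnel.
    rng = np.random.default_rng(seed)
    theta, g, u0 = _init_state(lay, data, priors, rng, cfg.init_jitter)
    z = u0.copy()
    u = z @ _scaled_chol(g).T
    row_ll = _row_loglik(g, u, data)
    z_prior = -0.5 * np.sum(z * z, axis=1)
    lp_global = _global_logprior(g, theta, lay, priors)
    if not np.isfinite(row_ll.sum() + lp_global):
        raise InitializationError(
            f"non-finite initial log-posterior (loglik={row_ll.sum()}, "
            f"global prior={lp_global})")

    d = lay.size
    scale = 2.38 / np.sqrt(d) * 0.5
    hier_scale = 0.3
    c_hier_scale = 0.3
    u_scale = 0.8
    cov_chol = np.eye(d)
    run_mean = theta.copy()
    run_cov = np.eye(d) * 1e-3
    n_adapt = 0
    pid = data.participant_idx
    n_p = data.n_participants
    acc_g = acc_u = 0
    n_global = 0
    n_keep = cfg.samples
    total = cfg.warmup + n_keep * cfg.thin
    store: dict[str, list] = {k: [] for k in
                              [f"beta_{o}" for o in CONSTRUCTS]
                              + [f"cut_{m}" for m in lay.instruments]
                              + ["sigma_u", "rho", "u"]
                              + (["w", "sigma_w"] if lay.n_concerts else [])}
    logpost_trace = []

    for sweep in range(total):
        warm = sweep < cfg.warmup
        # ---- global block (several sub-updates per sweep) -----------------
        for _ in range(cfg.global_updates_per_sweep):
            n_global += 1
            prop = theta + scale * (cov_chol @ rng.standard_normal(d))
            g_prop = _unpack(prop, lay)
            lp_prop = _global_logprior(g_prop, prop, lay, priors)
            accepted = False
            if np.isfinite(lp_prop):
                u_prop_g = z @ _scaled_chol(g_prop).T
                row_prop = _row_loglik(g_prop, u_prop_g, data)
                delta = lp_prop - lp_global + row_prop.sum() - row_ll.sum()
                if np.log(rng.uniform()) < delta:
                    theta, g, lp_global = prop, g_prop, lp_prop
                    row_ll, u = row_prop, u_prop_g
                    acc_g += 1
                    accepted = True
            if warm:
                # Robbins-Monro step-size + running covariance adaptation
                rate = 1.0 / (1 + n_adapt / 100)
                scale *= np.exp(rate * ((1.0 if accepted else 0.0)
                                        - cfg.target_accept_global))
                n_adapt += 1
                dm_ = theta - run_mean
                run_mean += dm_ / n_adapt
                run_cov += (np.outer(dm_, theta - run_mean) - run_cov) / n_adapt
                if n_adapt >= 200 and n_adapt % 100 == 0:
                    try:
                        cov_chol = np.linalg.cholesky(run_cov + 1e-6 * np.eye(d))
                    except np.linalg.LinAlgError:
                        pass

        # ---- hierarchy block: (log sigma_u, atanh rho) on their own -------
        # these three coordinates ride the non-centered map u = z L_s', so a
        # dedicated small block mixes them much faster than the joint proposal
        hier_idx = np.r_[np.arange(*lay.slices["log_sigma_u"].indices(d)),
                         np.arange(*lay.slices["atanh_rho"].indices(d))]
        for _ in range(2):
            prop = theta.copy()
            prop[hier_idx] += hier_scale * rng.standard_normal(hier_idx.size)
            g_prop = _unpack(prop, lay)
            lp_prop = _global_logprior(g_prop, prop, lay, priors)
            accepted = False
            if np.isfinite(lp_prop):
                u_prop_g = z @ _scaled_chol(g_prop).T
                row_prop = _row_loglik(g_prop, u_prop_g, data)
                if np.log(rng.uniform()) < (lp_prop - lp_global
                                            + row_prop.sum() - row_ll.sum()):
                    theta, g, lp_global = prop, g_prop, lp_prop
                    row_ll, u = row_prop, u_prop_g
                    accepted = True
            if warm:
                hier_scale *= np.exp((1.0 / (1 + sweep / 50))
                                     * ((1.0 if accepted else 0.0) - 0.3))

        # ---- participant block (vectorized per-participant MH on z) -------
        L_s = _scaled_chol(g)
        z_prop = z + u_scale * rng.standard_normal(z.shape)
        u_prop = z_prop @ L_s.T
        row_prop = _row_loglik(g, u_prop, data)
        ll_by_p = np.bincount(pid, weights=row_ll, minlength=n_p)
        ll_by_p_prop = np.bincount(pid, weights=row_prop, minlength=n_p)
        z_prior_prop = -0.5 * np.sum(z_prop * z_prop, axis=1)
        delta_p = (ll_by_p_prop - ll_by_p) + (z_prior_prop - z_prior)
        accept_p = np.log(rng.uniform(size=n_p)) < delta_p
        if accept_p.any():
            z[accept_p] = z_prop[accept_p]
            u[accept_p] = u_prop[accept_p]
            z_prior[accept_p] = z_prior_prop[accept_p]
            row_mask = accept_p[pid]
            row_ll[row_mask] = row_prop[row_mask]
        acc_u += accept_p.mean()
        if warm:
            u_scale *= np.exp((1.0 / (1 + sweep / 50))
                              * (accept_p.mean() - cfg.target_accept_u))

        # ---- interweaved centered update of (sigma_u, rho) ----------------
        # conditioning on u (not z) makes the scale/correlation conditional
        # likelihood-free: only the MVN prior of the u rows and the
        # hyperpriors enter.  Afterwards z is re-derived from u.
        for _ in range(2):
            prop = theta.copy()
            prop[hier_idx] += c_hier_scale * rng.standard_normal(hier_idx.size)
            g_prop = _unpack(prop, lay)
            lp_prop = _global_logprior(g_prop, prop, lay, priors)
            accepted = False
            if np.isfinite(lp_prop):
                cur = (_u_logprior_rows(u, g["sigma_u"], g["rho"]).sum())
                new = (_u_logprior_rows(u, g_prop["sigma_u"], g_prop["rho"]).sum())
                if np.log(rng.uniform()) < (lp_prop - lp_global + new - cur):
                    theta, g, lp_global = prop, g_prop, lp_prop
                    accepted = True
            if warm:
                c_hier_scale *= np.exp((1.0 / (1 + sweep / 50))
                                       * ((1.0 if accepted else 0.0) - 0.3))
        z = np.linalg.solve(_scaled_chol(g), u.T).T
        z_prior = -0.5 * np.sum(z * z, axis=1)

        # ---- translation move (likelihood-invariant direction) ------------
        d_shift = 0.3 * rng.standard_normal()
        theta_s = theta.copy()
        for m in lay.instruments:
            theta_s[lay.slices[f"cut_{m}"].start] += d_shift
        v = np.linalg.solve(_scaled_chol(g), np.ones(2))
        z_s = z - d_shift * v
        g_s = _unpack(theta_s, lay)
        lp_s = _global_logprior(g_s, theta_s, lay, priors)
        z_prior_s = -0.5 * np.sum(z_s * z_s, axis=1)
        if np.log(rng.uniform()) < (lp_s - lp_global + z_prior_s.sum() - z_prior.sum()):
            theta, g, lp_global, z, z_prior = theta_s, g_s, lp_s, z_s, z_prior_s
            u = u - d_shift

        if not warm and (sweep - cfg.warmup) % cfg.thin == 0:
            for o in CONSTRUCTS:
                store[f"beta_{o}"].append(g[f"beta_{o}"].copy())
            for m in lay.instruments:
                store[f"cut_{m}"].append(g[f"cut_{m}"].copy())
            store["sigma_u"].append(g["sigma_u"].copy())
            store["rho"].append(g["rho"])
            store["u"].append(u.copy())
            if lay.n_concerts:
                store["w"].append(g["w"].copy())
                store["sigma_w"].append(g["sigma_w"])
            logpost_trace.append(lp_global + row_ll.sum() + z_prior.sum())

    out = {k: np.asarray(v) for k, v in store.items()}
    out["lp"] = np.asarray(logpost_trace)
    info = {"accept_global": acc_g / max(n_global, 1), "accept_u": acc_u / total,
            "scale": scale, "u_scale": u_scale}
    return out, info


def fit(data: ResponseTable | ModelData, spec: ModelSpec | None = None,
        priors: PriorConfig | None = None,
        sampler_config: SamplerConfig | None = None,
        seed: int = 0) -> PosteriorDraws:
    """Sample the posterior of the hierarchical cumulative-logit model.

    ``data`` is either likelihood-ready :class:`ModelData` or a
    :class:`ResponseTable` (then ``spec`` is required and the design is built
    internally).  Chains run sequentially with per-chain seeds derived from
    ``seed``; identical seed and configuration give identical draws.
    """
    if isinstance(data, ResponseTable):
        if spec is None:
            raise ValueError("spec is required when fitting from a ResponseTable")
        data = build_model_data(data, spec)
    priors = priors or PriorConfig()
    cfg = sampler_config or SamplerConfig()
    lay = _Layout.for_data(data)
    chains, infos = [], []
    seeds = np.random.SeedSequence(seed).spawn(cfg.chains)
    for c in range(cfg.chains):
        draws, info = _run_chain(data, lay, priors, cfg,
                                 seed=int(seeds[c].generate_state(1)[0] % (2**31)))
        chains.append(draws)
        infos.append(info)
    arrays = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    metadata = {"seed": seed, "chains": cfg.chains, "warmup": cfg.warmup,
                "samples": cfg.samples, "thin": cfg.thin, "divergences": 0,
                "sampler": "adaptive blocked random-walk Metropolis",
                "chain_info": infos, "layout": lay,
                "spec_name": getattr(spec, "name", ""),
                "predictor_names": dict(data.predictor_names)}
    return PosteriorDraws(arrays=arrays, metadata=metadata, data=data)


# ---------------------------------------------------------------------------
# summaries, diagnostics, predictive checks
# ---------------------------------------------------------------------------

def summarize(draws: PosteriorDraws, prob: float = 0.90) -> pd.DataFrame:
    """Posterior mean, central credible interval, and excludes-zero flag per
    coefficient (one row per construct x predictor), plus scale/correlation
    rows.  Quantiles use linear interpolation."""
    if draws.n_chains * draws.n_draws < 100:
        warnings.warn("fewer than 100 total draws; summaries will be noisy")
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    rows = []

    def add(name, construct, samples):
        samples = np.asarray(samples).ravel()
        lo, hi = np.quantile(samples, [lo_q, hi_q])
        rows.append({"parameter": name, "construct": construct,
                     "mean": float(samples.mean()), "ci_lower": float(lo),
                     "ci_upper": float(hi),
                     "excludes_zero": bool(lo > 0 or hi < 0)})

    for o in CONSTRUCTS:
        names = draws.data.predictor_names.get(o, [])
        b = draws.stacked(f"beta_{o}")
        for j, nm in enumerate(names):
            add(nm, o, b[:, j])
    s = draws.stacked("sigma_u")
    add("sigma_u", "artist", s[:, 0])
    add("sigma_u", "audience", s[:, 1])
    add("rho_u", "artist/audience", draws.stacked("rho"))
    if "sigma_w" in draws.arrays:
        add("sigma_w", "concert", draws.stacked("sigma_w"))
    return pd.DataFrame(rows)


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.01,
                ess_threshold: float = 100.0) -> pd.DataFrame:
    """Split-Rhat and rank-normalized bulk ESS per scalar parameter.

    A single chain is split into halves (with a warning) so Rhat is still
    defined.  The ``pass`` column applies the configurable thresholds."""
    import arviz as az
    idata = draws.to_arviz()
    post = idata.posterior
    if draws.n_chains < 2:
        warnings.warn("single chain: splitting into halves for Rhat")
        half = draws.n_draws // 2
        post = post.isel(draw=slice(0, 2 * half))
        stacked = {v: np.concatenate([post[v].values[:, :half],
                                      post[v].values[:, half:]], axis=0)
                   for v in post.data_vars}
        post = az.from_dict(posterior=stacked).posterior
    rhat = az.rhat(post)
    ess = az.ess(post, method="bulk")
    rows = []
    for v in post.data_vars:
        r, e = float(rhat[v]), float(ess[v])
        rows.append({"parameter": v, "rhat": r, "ess_bulk": e,
                     "pass": bool(r < rhat_threshold and e > ess_threshold)})
    return pd.DataFrame(rows)


def posterior_predictive(draws: PosteriorDraws, data: ModelData | None = None,
                         spec=None, seed: int = 0, max_draws: int = 200,
                         band: float = 0.95) -> dict:
    """Replicate the ordinal responses under the fitted model and band the
    per-category frequencies against the observed ones.

    Returns, per (construct, instrument): observed frequencies, predictive
    band (quantiles across replicated datasets), and a global ``coverage``
    statistic (fraction of categories whose observed frequency falls inside
    its band).  Deterministic given draws and seed.
    """
    data = data or draws.data
    rng = np.random.default_rng(seed)
    n_total = draws.n_chains * draws.n_draws
    take = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    lo_q, hi_q = (1 - band) / 2, 1 - (1 - band) / 2
    lay: _Layout = draws.metadata["layout"]
    out, n_inside, n_cat = {}, 0, 0
    for o_i, o in enumerate(CONSTRUCTS):
        X = data.X[o]
        beta = draws.stacked(f"beta_{o}")[take]
        u_all = draws.stacked("u")[take]
        w_all = draws.stacked("w")[take] if "w" in draws.arrays else None
        for m, y in data.y[o].items():
            K = INSTRUMENT_LEVELS[m]
            cuts = draws.stacked(f"cut_{m}")[take]
            obs_mask = y >= 1
            n_obs = int(obs_mask.sum())
            freqs = np.zeros((len(take), K))
            for s in range(len(take)):
                eta = X @ beta[s]
                if w_all is not None and data.concert_idx is not None:
                    eta = eta + w_all[s][data.concert_idx]
                shift = u_all[s][data.participant_idx, o_i]
                cdf = special.expit(cuts[s][None, :] + shift[:, None] - eta[:, None])
                draw_y = 1 + np.sum(rng.uniform(size=eta.shape)[:, None] > cdf, axis=1)
                freqs[s] = np.bincount(draw_y[obs_mask], minlength=K + 1)[1:] / max(n_obs, 1)
            band_lo = np.quantile(freqs, lo_q, axis=0)
            band_hi = np.quantile(freqs, hi_q, axis=0)
            observed = np.bincount(y[obs_mask], minlength=K + 1)[1:] / max(n_obs, 1)
            inside = (observed >= band_lo) & (observed <= band_hi)
            n_inside += int(inside.sum())
            n_cat += K
            out[(o, m)] = {"observed": observed, "band_lower": band_lo,
                           "band_upper": band_hi, "inside": inside}
    out["coverage"] = n_inside / max(n_cat, 1)
    return out


def impute_missing(draws: PosteriorDraws, data: ModelData | None = None) -> dict:
    """Posterior predictive category distribution for every missing response.

    Returns {(construct, instrument, row_index): length-K probability vector}
    obtained by averaging the category probabilities over all draws (the
    posterior-predictive imputation distribution).
    """
    data = data or draws.data
    out = {}
    for o_i, o in enumerate(CONSTRUCTS):
        X = data.X[o]
        beta = draws.stacked(f"beta_{o}")
        u_all = draws.stacked("u")
        w_all = draws.stacked("w") if "w" in draws.arrays else None
        for m, y in data.y[o].items():
            missing_rows = np.flatnonzero(y < 1)
            if missing_rows.size == 0:
                continue
            cuts = draws.stacked(f"cut_{m}")
            S = beta.shape[0]
            probs = np.zeros((missing_rows.size, INSTRUMENT_LEVELS[m]))
            for s in range(S):
                eta = X[missing_rows] @ beta[s]
                if w_all is not None and data.concert_idx is not None:
                    eta = eta + w_all[s][data.concert_idx[missing_rows]]
                shift = u_all[s][data.participant_idx[missing_rows], o_i]
                cdf = special.expit(cuts[s][None, :] + shift[:, None] - eta[:, None])
                full = np.concatenate([np.zeros((len(missing_rows), 1)), cdf,
                                       np.ones((len(missing_rows), 1))], axis=1)
                probs += np.diff(full, axis=1)
            probs /= S
            for k, r in enumerate(missing_rows):
                out[(o, m, int(r))] = probs[k]
    return out
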