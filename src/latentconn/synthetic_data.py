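"""Synthetic three-concert questionnaire datasets with known ground truth.

The generator emulates the study design end-to-end: three concerts with the
deposited subgroup sizes (16 voted / 13 could not vote; 12 YouTube 2D /
9 YouTube 360 / 11 VR; 11 Zoom / 11 YouTube), registration covariates drawn
once per participant, psychometric items produced from latent drivers that
the experimental condition can shift, and bivariate ordinal connectedness
outcomes generated from the cumulative-logit measurement model with
correlated participant effects and per-concert shifts.  Ground-truth
parameters travel alongside the table so parameter recovery is testable
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import data_model as dm
from .data_model import ResponseTable
from .ordinal_model import CONSTRUCTS, corr_cholesky

#: subgroup sizes used for inference (physically attending group excluded)
DEFAULT_GROUPS = {
    1: {"voted": 16, "not_voted": 13},
    2: {"youtube": 12, "youtube360": 9, "vr": 11},
    3: {"zoom": 11, "youtube": 11},
}


def equal_probability_cuts(k: int) -> np.ndarray:
    """Thresholds putting equal mass on all k categories at eta = 0."""
    p = np.arange(1, k) / k
    return np.log(p / (1.0 - p))


@dataclass
class TrueParams:
    """Ground-truth generating parameters on the latent logit scale."""

    beta: dict = field(default_factory=lambda: {
        "artist": {"covid_impact": 0.9, "physical_presence": 0.8},
        "audience": {"social_presence": 0.9, "physical_presence": 0.5, "age_10": -0.6},
    })
    thresholds: dict = field(default_factory=lambda: {
        "explicit5": equal_probability_cuts(5), "ios7": equal_probability_cuts(7)})
    sigma_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    corr_u: float = 0.4
    sigma_concert: float = 0.5
    missing_rate: float = 0.0
    #: condition shifts applied to the latent psychometric drivers
    driver_effects: dict = field(default_factory=lambda: {
        "physical_presence": {"vr": 2.0, "youtube360": 0.7},
        "social_presence": {"zoom": 1.5},
        "ipq_spatial": {"vr": 2.0, "youtube360": 1.0},
        "ipq_involvement": {"vr": 1.5},
    })
    realized: dict | None = None   # filled by simulate_study (u, w, drivers)

    def __post_init__(self) -> None:
        for name, cut in self.thresholds.items():
            cut = np.asarray(cut, dtype=float)
            if not np.all(np.diff(cut) > 0):
                raise ValueError(f"thresholds[{name!r}] must be strictly ascending")
            self.thresholds[name] = cut
        self.sigma_u = np.asarray(self.sigma_u, dtype=float)
        if np.any(self.sigma_u < 0):
            raise ValueError("sigma_u must be non-negative")
        if not -1.0 < self.corr_u < 1.0:
            raise ValueError("corr_u must lie in (-1, 1)")


@dataclass
class StudyDesign:
    """Shape of the simulated study (defaults mirror the deposited design)."""

    groups: dict = field(default_factory=lambda: {c: dict(g) for c, g in DEFAULT_GROUPS.items()})
    repeat_fraction: float = 0.25      # share of later-concert seats taken by returnees
    age_mean: float = 37.0
    age_sd: float = 12.0
    age_range: tuple = (18.0, 80.0)
    empathic_mean: float = 3.5
    empathic_sd: float = 0.6
    covid_item_loading: float = 0.69   # gives ~0.74 reliability for six items
    ios_missing_concert1: int = 2      # sporadic IOS non-response

    def __post_init__(self) -> None:
        for c, g in self.groups.items():
            if any(n < 1 for n in g.values()):
                raise ValueError(f"group sizes must be >= 1, got {g} for concert {c}")
            bad = set(g) - set(dm.CONDITIONS[c])
            if bad:
                raise ValueError(f"illegal condition(s) {bad} for concert {c}")


def sample_ordinal(rng: np.random.Generator, eta, cut) -> np.ndarray:
    """Draw 1-based ordinals with P(Y=k) = F(c_k - eta) - F(c_{k-1} - eta)."""
    eta = np.asarray(eta, dtype=float)
    from scipy.special import expit
    cdf = expit(np.asarray(cut, dtype=float)[None, :] - eta[..., None])
    u = rng.uniform(size=eta.shape)
    return 1 + np.sum(u[..., None] > cdf, axis=-1).astype(int)


def _registration(rng, n, design: StudyDesign) -> pd.DataFrame:
    """Covariates collected once, at registration."""
    lo, hi = design.age_range
    age = design.age_mean + design.age_sd * rng.standard_normal(n)
    while np.any((age < lo) | (age > hi)):        # truncation by redraw
        bad = (age < lo) | (age > hi)
        age[bad] = design.age_mean + design.age_sd * rng.standard_normal(bad.sum())
    gender = rng.choice(["woman", "man", "not_reported"], size=n, p=[0.55, 0.41, 0.04])
    empathic = np.clip(design.empathic_mean + design.empathic_sd * rng.standard_normal(n),
                       1.0, 5.0)
    trait = rng.standard_normal(n)
    covid = {}
    for item in dm.COVID_ITEMS:
        raw = 3.0 + design.covid_item_loading * trait + rng.standard_normal(n)
        covid[item] = np.clip(np.round(raw), 1, 5).astype(int)
    fan = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.45, 0.25, 0.15, 0.10, 0.05])
    return pd.DataFrame({"age_years": np.round(age, 1), "gender": gender,
                         "empathic_concern": np.round(empathic, 2),
                         **covid, "fan_status": fan})


_DRIVER_ITEMS = {
    "physical_presence": [c for c in dm.MPS_ITEMS
                          if dm.DEFAULT_MPS_MAPPING[c] == "physical"],
    "social_presence": [c for c in dm.MPS_ITEMS
                        if dm.DEFAULT_MPS_MAPPING[c] == "social"],
    "ipq_spatial": [c for c in dm.IPQ_ITEMS if dm.DEFAULT_IPQ_MAPPING[c] == "spatial"],
    "ipq_involvement": [c for c in dm.IPQ_ITEMS
                        if dm.DEFAULT_IPQ_MAPPING[c] == "involvement"],
    "ipq_realism": [c for c in dm.IPQ_ITEMS if dm.DEFAULT_IPQ_MAPPING[c] == "realism"],
}


def simulate_study(design_config: StudyDesign | None = None,
                   true_params: TrueParams | None = None,
                   seed: int = 0) -> tuple[ResponseTable, TrueParams]:
    """Generate one full study-shaped dataset plus its ground truth.

    Per participant ``p`` and construct ``o`` the latent connectedness score
    is ``eta = x' beta_o + u_{p,o} + w_concert``; each instrument's ordinal
    response is drawn through its fixed thresholds with the logistic CDF.
    The same seed always yields the same table.
    """
    design = design_config or StudyDesign()
    truth = true_params or TrueParams()
    rng = np.random.default_rng(seed)
    cuts5 = truth.thresholds["explicit5"]

    # participant registry: returnees share registration covariates and u
    registry = _registration(rng, 0, design).iloc[0:0]
    rows = []
    pid_of_concert: dict[int, list[int]] = {}
    for concert in sorted(design.groups):
        sizes = design.groups[concert]
        n_c = sum(sizes.values())
        prior_pool = sorted({p for c in pid_of_concert if c < concert
                             for p in pid_of_concert[c]})
        n_repeat = min(len(prior_pool), int(round(design.repeat_fraction * n_c))) \
            if concert > min(design.groups) else 0
        repeats = list(rng.choice(prior_pool, size=n_repeat, replace=False)) \
            if n_repeat else []
        n_new = n_c - len(repeats)
        new_reg = _registration(rng, n_new, design)
        new_ids = list(range(len(registry), len(registry) + n_new))
        registry = pd.concat([registry, new_reg], ignore_index=True)
        pids = repeats + new_ids
        pid_of_concert[concert] = pids
        conditions = np.repeat(list(sizes), list(sizes.values()))
        conditions = rng.permutation(conditions)
        for pid, cond in zip(pids, conditions):
            rows.append({"participant_id": f"P{pid:04d}", "_pid": pid,
                         "concert": concert, "condition": cond})
    df = pd.DataFrame(rows)
    df = df.join(registry, on="_pid")

    n_participants = len(registry)
    L = corr_cholesky(truth.corr_u) * truth.sigma_u[:, None]
    u = (L @ rng.standard_normal((2, n_participants))).T
    w = {c: truth.sigma_concert * rng.standard_normal() for c in design.groups}

    n = len(df)
    # post-concert context variables
    df["preference_played"] = np.where(df["concert"] == 1,
                                       rng.integers(0, 2, size=n), np.nan)
    df["with_others"] = rng.poisson(0.5, size=n)
    df["know_audience"] = rng.integers(0, 2, size=n) * (rng.uniform(size=n) < 0.6)
    df["vr_experience"] = np.where(df["concert"] == 2,
                                   (rng.uniform(size=n) < 0.4).astype(float), np.nan)
    df["connectivity_problem"] = (rng.uniform(size=n) < 0.1).astype(int)
    df["time_watched_min"] = np.round(np.clip(28 + 5 * rng.standard_normal(n), 5, 35), 0)
    for col in ("concentration", "audio_quality", "video_quality"):
        df[col] = sample_ordinal(rng, 0.8 + 0.0 * np.zeros(n), cuts5)
    df["chat_used"] = np.where(df["concert"] == 3,
                               (rng.uniform(size=n) < 0.15).astype(float), np.nan)

    # psychometric drivers: latent, shifted by condition, shared across items
    drivers = {}
    for driver, items in _DRIVER_ITEMS.items():
        shift = np.zeros(n)
        for cond, eff in truth.driver_effects.get(driver, {}).items():
            shift += eff * (df["condition"] == cond).to_numpy()
        latent = shift + rng.standard_normal(n)
        drivers[driver] = latent
        for item in items:
            df[item] = sample_ordinal(rng, latent, cuts5)
    for col, driver in (("agency_self", None), ("agency_shared", None)):
        shift = np.zeros(n)
        for cond, eff in truth.driver_effects.get(col, {}).items():
            shift += eff * (df["condition"] == cond).to_numpy()
        df[col] = sample_ordinal(rng, shift + rng.standard_normal(n), cuts5)
    # emotional change after the concert: milder when social presence is high
    social = drivers["social_presence"]
    for item in dm.EMOTION_ITEMS:
        sign = 1.0 if item == "forget_covid" else -0.5
        df[item] = sample_ordinal(rng, sign * 0.4 * social + rng.standard_normal(n), cuts5)

    # ordinal connectedness outcomes through the measurement model
    derived = dm._derived_columns(df, dm.DEFAULT_MPS_MAPPING, dm.DEFAULT_IPQ_MAPPING)
    w_row = df["concert"].map(w).to_numpy()
    for i, o in enumerate(CONSTRUCTS):
        eta = w_row + u[df["_pid"].to_numpy(), i]
        for name, coef in truth.beta[o].items():
            # covariates enter centred so the fixed thresholds sit mid-scale
            x = derived[name].to_numpy(dtype=float)
            eta = eta + coef * (x - np.nanmean(x))
        df[dm.OUTCOME_COLUMNS[(o, "explicit5")]] = sample_ordinal(rng, eta, cuts5)
        df[dm.OUTCOME_COLUMNS[(o, "ios7")]] = sample_ordinal(
            rng, eta, truth.thresholds["ios7"])

    df = df.drop(columns="_pid")
    table = ResponseTable(df)
    if truth.missing_rate > 0:
        table = inject_missing(table, ["conn_artist", "conn_audience",
                                       "ios_artist", "ios_audience"],
                               truth.missing_rate, seed=int(rng.integers(2**31)))
    if design.ios_missing_concert1 and 1 in design.groups:
        table = inject_missing(table, ["ios_artist", "ios_audience"],
                               design.ios_missing_concert1,
                               seed=int(rng.integers(2**31)), concert=1)
    truth.realized = {"u": u, "w": w, "drivers": drivers,
                      "design": {c: dict(g) for c, g in design.groups.items()}}
    return table, truth


def simulate_latent_panel(n_participants: int, beta_artist, beta_audience,
                          sigma_u=(0.8, 0.8), corr_u: float = 0.4,
                          thresholds: dict | None = None, seed: int = 0,
                          missing_rate: float = 0.0):
    """Reduced study-shaped panel for recovery and calibration experiments.

    One row per participant; standard-normal predictors; both instruments
    (5-point explicit, 7-point IOS) observed for both constructs, generated
    from eta = x' beta_o + u_{p,o} through the fixed thresholds.  Returns
    likelihood-ready arrays (a :class:`~latentconn.ordinal_model.ModelData`)
    plus the ground truth, skipping the questionnaire plumbing.
    """
    from .ordinal_model import ModelData
    rng = np.random.default_rng(seed)
    beta = {"artist": np.asarray(beta_artist, dtype=float),
            "audience": np.asarray(beta_audience, dtype=float)}
    thresholds = thresholds or {"explicit5": equal_probability_cuts(5),
                                "ios7": equal_probability_cuts(7)}
    sigma_u = np.asarray(sigma_u, dtype=float)
    L = corr_cholesky(corr_u) * sigma_u[:, None]
    u = (L @ rng.standard_normal((2, n_participants))).T
    X = {o: rng.standard_normal((n_participants, beta[o].size)) for o in CONSTRUCTS}
    y: dict[str, dict[str, np.ndarray]] = {o: {} for o in CONSTRUCTS}
    for i, o in enumerate(CONSTRUCTS):
        eta = X[o] @ beta[o] + u[:, i]
        for m, cut in thresholds.items():
            resp = sample_ordinal(rng, eta, cut)
            if missing_rate > 0:
                resp = np.where(rng.uniform(size=n_participants) < missing_rate,
                                0, resp)
            y[o][m] = resp
    names = {o: [f"x{j + 1}" for j in range(beta[o].size)] for o in CONSTRUCTS}
    data = ModelData(X=X, y=y, participant_idx=np.arange(n_participants),
                     predictor_names=names)
    truth = {"beta": beta, "sigma_u": sigma_u, "corr_u": corr_u,
             "thresholds": thresholds, "u": u}
    return data, truth


def inject_missing(table: ResponseTable, items: list[str], count_or_rate,
                   seed: int = 0, concert: int | None = None) -> ResponseTable:
    """Replace responses by NA: an exact count, or an independent rate.

    With an integer count, exactly that many currently-observed cells across
    ``items`` (optionally restricted to one concert) become NA, positions
    seeded.  With a float rate in [0, 1), each cell goes missing
    independently.  Same seed, same NA positions.
    """
    missing_items = [c for c in items if c not in table.df.columns]
    if missing_items:
        raise KeyError(f"item(s) not in table: {missing_items}")
    df = table.df.copy()
    rng = np.random.default_rng(seed)
    mask_rows = np.ones(len(df), dtype=bool) if concert is None \
        else (df["concert"] == concert).to_numpy()
    if isinstance(count_or_rate, (int, np.integer)):
        cells = [(r, c) for c in items
                 for r in df.index[mask_rows & df[c].notna().to_numpy()]]
        if count_or_rate > len(cells):
            raise ValueError(f"requested {count_or_rate} missing cells, "
                             f"only {len(cells)} available")
        for k in rng.choice(len(cells), size=int(count_or_rate), replace=False):
            r, c = cells[int(k)]
            df.loc[r, c] = np.nan
    else:
        rate = float(count_or_rate)
        if not 0.0 <= rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        if rate > 0:
            for c in items:
                hit = mask_rows & (rng.uniform(size=len(df)) < rate)
                df.loc[hit, c] = np.nan
    return ResponseTable(df)
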