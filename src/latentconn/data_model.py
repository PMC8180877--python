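"""Tabular data contract for the three-concert livestream questionnaire study.

One row = one participant x concert response.  Registration covariates
(age, gender, empathic concern, six COVID-impact items, fan status) sit next
to the post-concert ordinal outcomes: explicit 1-5 connectedness to the
artist and the audience, the 1-7 IOS closeness scale, presence items
(MPS / IPQ), agency ratings, and emotional-change items.  Missing responses
are plain NA (NaN), never a numeric code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSTRUCTS = ("artist", "audience")

#: legal condition labels per concert
CONDITIONS = {
    1: ("voted", "not_voted"),
    2: ("youtube", "youtube360", "vr"),
    3: ("youtube", "zoom"),
}

COVID_ITEMS = ["covid_loneliness", "covid_lack_companionship", "covid_isolation",
               "covid_anxiety", "covid_worry_self", "covid_worry_others"]
MPS_ITEMS = [f"mps_{i:02d}" for i in range(1, 11)]
IPQ_ITEMS = [f"ipq_{i:02d}" for i in range(1, 15)]
EMOTION_ITEMS = ["emo_loneliness", "emo_lack_companionship", "emo_isolation",
                 "emo_anxiety", "forget_covid"]

#: column -> (kind, (low, high)) ; kind in {id, int, cat, float, ordinal, bool, count}
SCHEMA: dict[str, tuple] = {
    "participant_id": ("id", None),
    "concert": ("int", (1, 3)),
    "condition": ("cat", None),
    "preference_played": ("bool", None),
    "age_years": ("float", (0, np.inf)),
    "gender": ("cat", ("woman", "man", "not_reported")),
    "empathic_concern": ("float", (1, 5)),
    **{c: ("ordinal", (1, 5)) for c in COVID_ITEMS},
    "fan_status": ("ordinal", (1, 5)),
    "with_others": ("count", (0, np.inf)),
    "know_audience": ("bool", None),
    "vr_experience": ("bool", None),
    "connectivity_problem": ("bool", None),
    "time_watched_min": ("float", (0, np.inf)),
    "concentration": ("ordinal", (1, 5)),
    "audio_quality": ("ordinal", (1, 5)),
    "video_quality": ("ordinal", (1, 5)),
    "chat_used": ("bool", None),
    "conn_artist": ("ordinal", (1, 5)),
    "conn_audience": ("ordinal", (1, 5)),
    "ios_artist": ("ordinal", (1, 7)),
    "ios_audience": ("ordinal", (1, 7)),
    **{c: ("ordinal", (1, 5)) for c in MPS_ITEMS},
    **{c: ("ordinal", (1, 5)) for c in IPQ_ITEMS},
    "agency_self": ("ordinal", (1, 5)),
    "agency_shared": ("ordinal", (1, 5)),
    **{c: ("ordinal", (1, 5)) for c in EMOTION_ITEMS},
}

#: columns that must be present in every file
REQUIRED = ["participant_id", "concert", "condition", "age_years", "gender",
            "empathic_concern", *COVID_ITEMS]

#: default MPS item -> subscale map; one item (mps_06) sits on the physical
#: subscale rather than its original social home, reflecting the re-worded
#: virtual-concert items loading differently.
DEFAULT_MPS_MAPPING = {**{c: "physical" for c in MPS_ITEMS[:6]},
                       **{c: "social" for c in MPS_ITEMS[6:]}}
DEFAULT_IPQ_MAPPING = {**{c: "spatial" for c in IPQ_ITEMS[:6]},
                       **{c: "involvement" for c in IPQ_ITEMS[6:10]},
                       **{c: "realism" for c in IPQ_ITEMS[10:]}}


class SchemaError(ValueError):
    """The file header does not match the declared schema."""


class ValidationError(ValueError):
    """A value violates its declared range or a table invariant."""


@dataclass
class ResponseTable:
    """Validated participant x variable table for one concert or pooled."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        dup = df.duplicated(subset=["participant_id", "concert"])
        if dup.any():
            raise ValidationError(
                f"duplicate (participant_id, concert) pairs at rows {list(df.index[dup])}")
        for col in df.columns:
            kind, bounds = SCHEMA.get(col, (None, None))
            if kind in ("ordinal", "count", "int"):
                vals = pd.to_numeric(df[col], errors="coerce")
                ok = vals.isna() | ((vals == np.floor(vals))
                                    & (vals >= bounds[0]) & (vals <= bounds[1]))
                if not ok.all():
                    row = df.index[~ok][0]
                    raise ValidationError(
                        f"out-of-range value {df.loc[row, col]!r} in column "
                        f"{col!r} at row {row} (allowed {bounds})")
            elif kind == "bool":
                vals = df[col]
                ok = vals.isna() | vals.isin([0, 1, True, False])
                if not ok.all():
                    row = df.index[~ok][0]
                    raise ValidationError(f"non-boolean value in {col!r} at row {row}")
            elif kind == "cat" and bounds is not None:
                ok = df[col].isna() | df[col].isin(bounds)
                if not ok.all():
                    row = df.index[~ok][0]
                    raise ValidationError(
                        f"illegal label {df.loc[row, col]!r} in {col!r} at row {row}")
        if "condition" in df.columns:
            for concert, legal in CONDITIONS.items():
                sub = df.loc[df["concert"] == concert, "condition"]
                bad = ~(sub.isna() | sub.isin(legal))
                if bad.any():
                    raise ValidationError(
                        f"concert {concert} condition must be one of {legal}, "
                        f"got {sub[bad].iloc[0]!r}")

    def subset(self, concert: int | None) -> "ResponseTable":
        if concert is None:
            return self
        return ResponseTable(self.df[self.df["concert"] == concert].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


def read_responses(path, schema: dict | None = None) -> ResponseTable:
    """Read and validate a questionnaire CSV.

    Raises :class:`SchemaError` for missing headers, :class:`ValidationError`
    for out-of-range ordinals (naming row and column).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
    return ResponseTable(df)


def write_responses(table: ResponseTable, path) -> None:
    """Write a ResponseTable as CSV; NA cells become empty fields."""
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def covid_impact(items, policy: str = "propagate"):
    """Mean of the six COVID-impact ordinals, treated as continuous.

    ``items`` is a length-6 sequence, or a DataFrame holding the six item
    columns (row-wise means returned).  ``policy`` controls partial
    missingness: "propagate" (default) yields NA if any item is missing,
    "available" averages the observed items.
    """
    if policy not in ("propagate", "available"):
        raise ValueError("policy must be 'propagate' or 'available'")
    if isinstance(items, pd.DataFrame):
        sub = items[COVID_ITEMS] if set(COVID_ITEMS) <= set(items.columns) else items
        means = sub.mean(axis=1, skipna=(policy == "available"))
        return means
    arr = np.asarray(items, dtype=float)
    if arr.shape[-1] != 6:
        raise ValueError("expected six COVID-impact items")
    if np.isnan(arr).any() and policy == "propagate":
        return np.nan
    return float(np.nanmean(arr))


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of an n x K item matrix (sample variances, ddof=1)."""
    X = np.asarray(item_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete rows and 2 items")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("zero variance of row sums: alpha undefined")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def subscale_scores(items, mapping: dict[str, str]) -> dict[str, float]:
    """Per-subscale means of mapped items plus the overall scale mean.

    ``items`` maps item name -> value (dict or Series).  Every item must be
    covered by ``mapping`` exactly once.
    """
    if isinstance(items, pd.Series):
        items = items.to_dict()
    unmapped = sorted(set(items) - set(mapping))
    if unmapped:
        raise KeyError(f"unmapped item(s): {unmapped}")
    groups: dict[str, list] = {}
    for item, value in items.items():
        groups.setdefault(mapping[item], []).append(float(value))
    out = {sub: float(np.mean(v)) for sub, v in sorted(groups.items())}
    out["overall"] = float(np.mean([float(v) for v in items.values()]))
    return out


def _subscale_frame(df: pd.DataFrame, item_cols: list[str], mapping: dict[str, str],
                    prefix: str) -> pd.DataFrame:
    """Row-wise subscale means as columns ``{prefix}_{subscale}``."""
    out = {}
    for sub in sorted(set(mapping.values())):
        cols = [c for c in item_cols if mapping[c] == sub]
        out[f"{prefix}_{sub}"] = df[cols].mean(axis=1, skipna=False)
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# model specifications and design matrices
# ---------------------------------------------------------------------------

#: outcome measures: (construct, instrument) with the instrument's level count
ALL_OUTCOMES = [("artist", "explicit5"), ("artist", "ios7"),
                ("audience", "explicit5"), ("audience", "ios7")]
OUTCOME_COLUMNS = {("artist", "explicit5"): "conn_artist",
                   ("audience", "explicit5"): "conn_audience",
                   ("artist", "ios7"): "ios_artist",
                   ("audience", "ios7"): "ios_audience"}

ARTIST_ONLY = ("fan_status",)
AUDIENCE_ONLY = ("with_others", "know_audience")

SIMPLE_CONTROLS = ["age_10", "woman", "empathic_concern", "covid_impact"]
COMPLEX_CONTROLS = ["connectivity_problem", "time_watched_5", "concentration",
                    "audio_quality", "video_quality"]


@dataclass
class ModelSpec:
    """Declarative description of one fitted model."""

    concert_scope: int | str          # 1, 2, 3 or "overall"
    predictor_set: str                # "simple" | "complex"
    main_predictors: list[str]
    outcome_measures: list[tuple] = field(default_factory=lambda: list(ALL_OUTCOMES))
    random_effects: str = "participant"   # or "participant+concert"
    excluded_predictors: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.predictor_set not in ("simple", "complex"):
            raise ValueError("predictor_set must be 'simple' or 'complex'")
        if self.concert_scope not in (1, 2, 3, "overall"):
            raise ValueError("concert_scope must be 1, 2, 3 or 'overall'")
        bad = [p for p in self.main_predictors if p in ARTIST_ONLY + AUDIENCE_ONLY]
        if bad:
            raise ValueError(f"construct-specific controls cannot be main predictors: {bad}")

    def predictors(self, construct: str) -> list[str]:
        """Ordered predictor names for one construct's linear predictor."""
        cols = list(self.main_predictors) + list(SIMPLE_CONTROLS)
        if self.concert_scope == 2:
            cols.append("vr_experience")
        if construct == "artist":
            cols += list(ARTIST_ONLY)
        else:
            cols += list(AUDIENCE_ONLY)
        if self.predictor_set == "complex":
            cols += list(COMPLEX_CONTROLS)
            if self.concert_scope == 3:
                cols.append("chat_used")
        return [c for c in cols if c not in self.excluded_predictors]


#: the per-concert model menus (main predictors of interest)
_MENUS = {
    1: {"model1": ["allowed_vote"], "model2": ["preference_played"],
        "model3": ["self_agency"], "model4": ["shared_agency"],
        "model5": ["allowed_vote", "preference_played", "self_agency", "shared_agency"]},
    2: {"model1": ["youtube360", "vr"],
        "model2": ["social_presence", "physical_presence",
                   "ipq_spatial", "ipq_involvement", "ipq_realism"],
        "model3": ["youtube360", "vr", "social_presence", "physical_presence",
                   "ipq_spatial", "ipq_involvement", "ipq_realism"]},
    3: {"model1": ["zoom"], "model2": ["zoom", "social_presence", "physical_presence"]},
    "overall": {"model1": ["self_agency"], "model2": ["shared_agency"],
                "model3": ["social_presence"], "model4": ["physical_presence"],
                "model5": ["self_agency", "shared_agency",
                           "social_presence", "physical_presence"]},
}


def preset_names() -> list[str]:
    return [f"{'overall' if c == 'overall' else f'concert{c}'}-{s}-{m}"
            for c, menu in _MENUS.items() for s in ("simple", "complex") for m in menu]


def preset_spec(name: str) -> ModelSpec:
    """Resolve a preset name like ``concert1-simple-model2`` to a ModelSpec."""
    try:
        scope_s, pset, model = name.split("-")
        scope = "overall" if scope_s == "overall" else int(scope_s.removeprefix("concert"))
        main = _MENUS[scope][model]
    except (ValueError, KeyError):
        raise KeyError(f"unknown preset {name!r}; valid presets: {preset_names()}") from None
    excluded = []
    if scope == 3:
        # dropped in concert 3: one fan, one connectivity problem
        excluded = ["connectivity_problem", "fan_status"]
    re_kind = "participant+concert" if scope == "overall" else "participant"
    return ModelSpec(concert_scope=scope, predictor_set=pset, main_predictors=list(main),
                     excluded_predictors=excluded, random_effects=re_kind, name=name)


@dataclass
class DesignMatrix:
    """Per-construct predictor matrices plus the bookkeeping of how they
    were built (scaling, coding, drops)."""

    frames: dict[str, pd.DataFrame]
    outcomes: dict[tuple, pd.Series]
    participant_ids: pd.Series
    concerts: pd.Series
    scaling: dict[str, str]
    coding: dict[str, str]
    dropped_columns: list[tuple]
    n_dropped_rows: int


def _derived_columns(df: pd.DataFrame, mps_mapping: dict, ipq_mapping: dict) -> pd.DataFrame:
    """All derived predictor columns the model menus can reference."""
    out = pd.DataFrame(index=df.index)
    out["age_10"] = df["age_years"] / 10.0
    out["woman"] = (df["gender"] == "woman").astype(float)
    out["empathic_concern"] = df["empathic_concern"]
    out["covid_impact"] = covid_impact(df)
    for c in ("fan_status", "with_others", "know_audience", "vr_experience",
              "connectivity_problem", "concentration", "audio_quality",
              "video_quality", "chat_used", "preference_played"):
        if c in df.columns:
            out[c] = pd.to_numeric(df[c], errors="coerce")
    if "time_watched_min" in df.columns:
        out["time_watched_5"] = df["time_watched_min"] / 5.0
    out["allowed_vote"] = (df["condition"] == "voted").astype(float)
    out["youtube360"] = (df["condition"] == "youtube360").astype(float)
    out["vr"] = (df["condition"] == "vr").astype(float)
    out["zoom"] = (df["condition"] == "zoom").astype(float)
    out["self_agency"] = pd.to_numeric(df.get("agency_self"), errors="coerce")
    out["shared_agency"] = pd.to_numeric(df.get("agency_shared"), errors="coerce")
    if set(MPS_ITEMS) <= set(df.columns):
        mps = _subscale_frame(df, MPS_ITEMS, mps_mapping, "mps")
        out["social_presence"] = mps["mps_social"]
        out["physical_presence"] = mps["mps_physical"]
    if set(IPQ_ITEMS) <= set(df.columns):
        ipq = _subscale_frame(df, IPQ_ITEMS, ipq_mapping, "ipq")
        for sub in ("spatial", "involvement", "realism"):
            out[f"ipq_{sub}"] = ipq[f"ipq_{sub}"]
    return out


def build_design(table: ResponseTable, spec: ModelSpec,
                 mps_mapping: dict | None = None,
                 ipq_mapping: dict | None = None) -> DesignMatrix:
    """Assemble per-construct design matrices for one ModelSpec.

    Applies the documented scaling (age / 10, minutes watched / 5) and gender
    coding (woman = 1 vs men and not-reported pooled), expands condition
    labels against the reference level (concert 2: regular YouTube; concert
    3: YouTube), drops rows with missing covariates (counted), and drops
    constant predictor columns with a warning.
    """
    df = table.subset(None if spec.concert_scope == "overall" else spec.concert_scope).df
    derived = _derived_columns(df, mps_mapping or DEFAULT_MPS_MAPPING,
                               ipq_mapping or DEFAULT_IPQ_MAPPING)
    wanted = {c for o in CONSTRUCTS for c in spec.predictors(o)}
    absent = sorted(wanted - set(derived.columns))
    if absent:
        raise KeyError(f"predictor(s) not derivable from table: {absent}")
    covariates = derived[sorted(wanted)]
    complete = ~covariates.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    df, derived = df[complete], derived[complete]

    dropped_columns: list[tuple] = []
    frames = {}
    for o in CONSTRUCTS:
        cols = spec.predictors(o)
        X = derived[cols].astype(float).copy()
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        for c in constant:
            warnings.warn(f"dropping constant predictor column {c!r} "
                          f"({o} linear predictor)", stacklevel=2)
            dropped_columns.append((c, o, "constant"))
        frames[o] = X.drop(columns=constant).reset_index(drop=True)

    outcomes = {om: pd.to_numeric(df[OUTCOME_COLUMNS[om]], errors="coerce")
                    .reset_index(drop=True)
                for om in spec.outcome_measures}
    return DesignMatrix(
        frames=frames,
        outcomes=outcomes,
        participant_ids=df["participant_id"].reset_index(drop=True),
        concerts=df["concert"].astype(int).reset_index(drop=True),
        scaling={"age_10": "age_years / 10", "time_watched_5": "time_watched_min / 5"},
        coding={"woman": "1 iff gender == 'woman'; men and not_reported pooled",
                "condition": "indicators vs reference (concert 2/3: youtube)"},
        dropped_columns=dropped_columns,
        n_dropped_rows=n_dropped,
    )
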