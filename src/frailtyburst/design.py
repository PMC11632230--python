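"""Model ladder (M0-M4) and design-matrix construction for the location-scale model.

The ladder mirrors the staged analysis of a measurement-burst study:

* M0 - unconditional means, location only: fixed intercept plus individual and
  person-burst random intercepts; constant residual SD.  Its three variance
  components decompose total FI variance into between-person, between-burst
  within-person, and within-burst shares.
* M1 - unconditional growth: adds burst and (centred) within-burst wave as
  fixed time effects plus a burst-level random wave slope, de-trending the
  within-burst repeats.
* M2 - adds the scale submodel (log residual SD) with individual and
  burst-level random scale intercepts and location-scale correlations.
* M3 - adds time-stable covariates (age, sex, education, living situation,
  social support, death between bursts, interview mode) to both submodels.
* M4 - adds the time-varying event indicators (bedrest, fall, hospital stay)
  to both submodels.

Encoding is deterministic: reference categories are men / low education / low
social support / cohabiting / alive / no event / personal interview / burst 1;
age is centred at the sample mean over persons and wave at the within-burst
midpoint (wave 4 of 1..7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODEL_IDS = ("M0", "M1", "M2", "M3", "M4")

WAVE_CENTER = 4.0

#: term -> (required column, allowed levels or None for numeric)
_TERM_COLUMNS: dict[str, tuple[str | None, list[str] | None]] = {
    "intercept": (None, None),
    "wave": ("wave", None),
    "burst2": ("burst", None),
    "age_c": ("age_baseline", None),
    "women": ("sex", ["men", "women"]),
    "edu_medium": ("education", ["low", "medium", "high"]),
    "edu_high": ("education", ["low", "medium", "high"]),
    "living_alone": ("living_alone", ["no", "yes"]),
    "support_medium": ("social_support", ["low", "medium", "high"]),
    "support_high": ("social_support", ["low", "medium", "high"]),
    "dead": ("dead_between_bursts", ["no", "yes"]),
    "telephone": ("interview_mode", ["personal", "telephone"]),
    "bedrest": ("bedrest", ["no", "yes"]),
    "fall": ("fall", ["no", "yes"]),
    "hospital": ("hospital", ["no", "yes"]),
}

_PERSON_TERMS = [
    "age_c",
    "women",
    "edu_medium",
    "edu_high",
    "living_alone",
    "support_medium",
    "support_high",
    "dead",
    "telephone",
]
_EVENT_TERMS = ["bedrest", "fall", "hospital"]


@dataclass(frozen=True)
class MelsmSpec:
    """Which fixed effects and random effects a ladder model carries."""

    model_id: str
    location_fixed: tuple[str, ...]
    scale_fixed: tuple[str, ...]
    has_scale_submodel: bool
    has_scale_re: bool
    has_wave_slope: bool
    #: observation family: "normal" (the baseline model) or "truncated_normal"
    #: (FI bounded to [0, 1], matching how a proportion outcome is generated)
    family: str = "normal"

    @classmethod
    def from_model_id(cls, model_id: str, family: str = "normal") -> "MelsmSpec":
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {model_id!r}; choose from {MODEL_IDS}")
        loc: list[str] = ["intercept"]
        sc: list[str] = ["intercept"]
        if model_id >= "M1":
            loc += ["wave", "burst2"]
        if model_id >= "M2":
            sc += ["burst2"]
        if model_id >= "M3":
            loc += _PERSON_TERMS
            sc += _PERSON_TERMS
        if model_id >= "M4":
            loc += _EVENT_TERMS
            sc += _EVENT_TERMS
        has_scale = model_id >= "M2"
        if family not in ("normal", "truncated_normal"):
            raise ValueError(f"unknown observation family {family!r}")
        return cls(
            model_id=model_id,
            location_fixed=tuple(loc),
            scale_fixed=tuple(sc) if has_scale else ("intercept",),
            has_scale_submodel=has_scale,
            has_scale_re=has_scale,
            has_wave_slope=model_id >= "M1",
            family=family,
        )

    # -- random-effect bookkeeping --------------------------------------

    @property
    def person_effects(self) -> tuple[str, ...]:
        return ("loc_int", "sc_int") if self.has_scale_re else ("loc_int",)

    @property
    def burst_effects(self) -> tuple[str, ...]:
        eff = ["loc_int"]
        if self.has_wave_slope:
            eff.append("wave")
        if self.has_scale_re:
            eff.append("sc_int")
        return tuple(eff)

    @property
    def sd_names(self) -> tuple[str, ...]:
        names = ["sd_person_loc"]
        if self.has_scale_re:
            names.append("sd_person_sc")
        names.append("sd_burst_loc")
        if self.has_wave_slope:
            names.append("sd_burst_wave")
        if self.has_scale_re:
            names.append("sd_burst_sc")
        return tuple(names)

    @property
    def cor_names(self) -> tuple[str, ...]:
        names = []
        if self.has_scale_re:
            names.append("cor_person_loc_sc")
        if self.has_wave_slope:
            names.append("cor_burst_loc_wave")
        if self.has_scale_re:
            names.append("cor_burst_loc_sc")
        return tuple(names)


@dataclass
class Design:
    """Model matrices and grouping indices for one fitted data set."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    loc_names: tuple[str, ...]
    sc_names: tuple[str, ...]
    person_ids: np.ndarray
    person_codes: np.ndarray
    burst: np.ndarray
    wave_c: np.ndarray
    age_center: float
    spec: MelsmSpec
    row_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)


def _term_vector(term: str, df: pd.DataFrame, age_center: float) -> np.ndarray:
    col, levels = _TERM_COLUMNS[term]
    if col is not None and col not in df.columns:
        raise ValueError(f"model term {term!r} needs column {col!r}, absent from data")
    if col is not None:
        series = df[col]
        if series.isna().any():
            raise ValueError(f"covariate column {col!r} has missing values")
        if levels is not None:
            bad = ~series.isin(levels)
            if bad.any():
                val = series[bad].iloc[0]
                raise ValueError(f"column {col!r}: unseen category level {val!r}")
    if term == "intercept":
        return np.ones(len(df))
    if term == "wave":
        return df["wave"].to_numpy(dtype=float) - WAVE_CENTER
    if term == "burst2":
        return (df["burst"].to_numpy() == 2).astype(float)
    if term == "age_c":
        return df["age_baseline"].to_numpy(dtype=float) - age_center
    mapping = {
        "women": ("sex", "women"),
        "edu_medium": ("education", "medium"),
        "edu_high": ("education", "high"),
        "living_alone": ("living_alone", "yes"),
        "support_medium": ("social_support", "medium"),
        "support_high": ("social_support", "high"),
        "dead": ("dead_between_bursts", "yes"),
        "telephone": ("interview_mode", "telephone"),
        "bedrest": ("bedrest", "yes"),
        "fall": ("fall", "yes"),
        "hospital": ("hospital", "yes"),
    }
    col, level = mapping[term]
    return (df[col] == level).to_numpy(dtype=float)


def build_design(
    data: pd.DataFrame,
    spec: MelsmSpec | str,
    age_center: float | None = None,
    fi_column: str = "fi",
) -> Design:
    """Build location/scale model matrices and grouping indices.

    ``data`` is a long panel frame carrying the FI column; rows without a
    scored FI are dropped (unscored interviews carry no outcome).  The age
    centre defaults to the sample mean over persons and is recorded so that
    simulated and fitted intercepts refer to the same origin.
    """
    if isinstance(spec, str):
        spec = MelsmSpec.from_model_id(spec)
    if fi_column not in data.columns:
        raise ValueError(f"data lacks the outcome column {fi_column!r}")
    df = data.loc[data[fi_column].notna()].reset_index(drop=False)
    if df.empty:
        raise ValueError("no rows with a scored FI")
    for col in ("person_id", "burst", "wave"):
        if col not in df.columns:
            raise ValueError(f"data lacks key column {col!r}")

    if age_center is None:
        if "age_baseline" in df.columns:
            age_center = float(df.drop_duplicates("person_id")["age_baseline"].mean())
        else:
            age_center = 0.0

    X = np.column_stack([_term_vector(t, df, age_center) for t in spec.location_fixed])
    Z = np.column_stack([_term_vector(t, df, age_center) for t in spec.scale_fixed])

    codes, uniques = pd.factorize(df["person_id"], sort=True)
    return Design(
        y=df[fi_column].to_numpy(dtype=float),
        X=X,
        Z=Z,
        loc_names=spec.location_fixed,
        sc_names=spec.scale_fixed,
        person_ids=np.asarray(uniques),
        person_codes=codes.astype(int),
        burst=df["burst"].to_numpy(dtype=int),
        wave_c=df["wave"].to_numpy(dtype=float) - WAVE_CENTER,
        age_center=age_center,
        spec=spec,
        row_index=df["index"].to_numpy(),
    )
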