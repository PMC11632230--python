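"""Synthetic measurement-burst cohorts with known generating truth.

The generator emulates a two-burst biweekly panel of community-dwelling
adults aged 70+: covariate mix, per-wave retention, between-burst attrition
and mortality, per-interview health events, and FI values drawn from the
mixed-effects location-scale model (defaults = the fitted coefficients of
the study the package reproduces).  The latent random effects and row-level
linear predictors are returned alongside the panel so parameter-recovery
tests can compare estimates against the truth.

Defaults (sample size 426, retention 98.3->95.3% within burst 1,
94.2->76.7% then 53.5% within burst 2, 88.7% between-burst return, 11/426
deaths, events calibrated to person-level prevalences 50.9/25.4/8.9%) are
the study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .design import MelsmSpec, WAVE_CENTER, build_design
from .schema import DeficitSchema, default_schema

#: generating parameters: posterior means of the final (M4) location-scale fit.
#: Scale-submodel entries are on the log scale (log of the exponentiated,
#: multiplicative coefficients).  The individual-level scale SD is converted
#: from SD units to the log scale by the delta method at the reference
#: residual SD 0.04 (0.02 / 0.04 = 0.5); the burst-level scale SD (0.36) is
#: taken as already log-scale.
DEFAULT_GENERATING_PARAMS: dict = {
    "beta": {
        "intercept": 0.27,
        "wave": 0.0,
        "burst2": 0.01,
        "age_c": 0.01,
        "women": 0.02,
        "edu_medium": -0.04,
        "edu_high": -0.07,
        "living_alone": 0.02,
        "support_medium": -0.08,
        "support_high": -0.11,
        "dead": 0.17,
        "telephone": 0.0,
        "bedrest": 0.04,
        "fall": 0.01,
        "hospital": 0.03,
    },
    "gamma": {
        "intercept": float(np.log(0.04)),
        "burst2": float(np.log(0.98)),
        "age_c": float(np.log(1.03)),
        "women": float(np.log(1.15)),
        "edu_medium": float(np.log(0.80)),
        "edu_high": float(np.log(0.72)),
        "living_alone": float(np.log(1.12)),
        "support_medium": float(np.log(0.80)),
        "support_high": float(np.log(0.68)),
        "dead": float(np.log(1.44)),
        "telephone": 0.0,
        "bedrest": float(np.log(1.50)),
        "fall": float(np.log(1.14)),
        "hospital": float(np.log(1.50)),
    },
    "sds": {
        "sd_person_loc": 0.10,
        "sd_person_sc": 0.50,
        "sd_burst_loc": 0.03,
        "sd_burst_wave": 0.002,
        "sd_burst_sc": 0.36,
    },
    "cors": {
        "cor_person_loc_sc": 0.62,
        "cor_burst_loc_wave": -0.35,
        "cor_burst_loc_sc": 0.26,
    },
}


def _linear(a: float, b: float, n: int) -> tuple[float, ...]:
    return tuple(np.linspace(a, b, n))


@dataclass(frozen=True)
class CohortDesign:
    """Generator configuration; defaults reproduce the study conditions."""

    n_persons: int = 426
    waves_per_burst: int = 7
    #: marginal probability of being interviewed at waves 2..7 of burst 1
    retention_burst1: tuple[float, ...] = field(default_factory=lambda: _linear(0.983, 0.953, 6))
    #: waves 2..6 interpolate the reported range; the last wave is separate
    retention_burst2: tuple[float, ...] = field(
        default_factory=lambda: (*_linear(0.942, 0.767, 5), 0.535)
    )
    between_burst_retention: float = 0.887
    mortality_prob: float = 11.0 / 426.0
    p_women: float = 0.646
    age_mean: float = 77.7
    age_sd: float = 5.4
    age_range: tuple[float, float] = (70.0, 97.0)
    education_probs: tuple[float, float, float] = (0.193, 0.542, 0.265)  # low/med/high
    support_probs: tuple[float, float, float] = (0.116, 0.420, 0.463)  # low/med/high
    p_living_alone: float = 0.660
    event_prevalence: dict = field(
        default_factory=lambda: {"bedrest": 0.509, "fall": 0.254, "hospital": 0.089}
    )
    n_inperson_subsample: int = 40
    params: dict = field(default_factory=lambda: DEFAULT_GENERATING_PARAMS)
    render_deficits: bool = True
    fi_dependent_dropout: bool = False
    seed: int | None = None

    def validate(self) -> None:
        probs = [
            *self.retention_burst1,
            *self.retention_burst2,
            self.between_burst_retention,
            self.mortality_prob,
            self.p_women,
            self.p_living_alone,
            *self.event_prevalence.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for shares in (self.education_probs, self.support_probs):
            # printed shares may carry rounding error (e.g. 0.999)
            if abs(sum(shares) - 1.0) > 5e-3:
                raise ValueError("category shares must sum to 1")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("age range must be increasing")
        if len(self.retention_burst1) != self.waves_per_burst - 1:
            raise ValueError("retention_burst1 needs one probability per wave 2..W")
        if len(self.retention_burst2) != self.waves_per_burst - 1:
            raise ValueError("retention_burst2 needs one probability per wave 2..W")
        for ev, prev in self.event_prevalence.items():
            if prev <= 0:
                raise ValueError(f"event {ev!r}: prevalence must be positive")


def interview_count_pmf(design: CohortDesign) -> np.ndarray:
    """Distribution of a person's total interview count under the design.

    Wave 1 of each attended burst is certain; later waves are independent
    Bernoulli attendances; burst 2 happens with the overall between-burst
    return probability.  Used to calibrate per-interview event hazards.
    """

    def pois_binom(ps):
        pmf = np.array([1.0])
        for p in ps:
            pmf = np.convolve(pmf, [1.0 - p, p])
        return pmf

    k1 = np.convolve([0.0, 1.0], pois_binom(design.retention_burst1))  # + certain wave 1
    k2 = np.convolve([0.0, 1.0], pois_binom(design.retention_burst2))
    both = np.convolve(k1, k2)
    p_ret = design.between_burst_retention
    out = np.zeros(max(len(k1), len(both)))
    out[: len(k1)] += (1.0 - p_ret) * k1
    out[: len(both)] += p_ret * both
    return out


def calibrate_event_hazard(target_prevalence: float, design: CohortDesign) -> float:
    """Per-interview hazard such that P(>= 1 event over all interviews) hits the target."""
    pmf = interview_count_pmf(design)
    ks = np.arange(len(pmf))

    def gap(h):
        return 1.0 - float(np.sum(pmf * (1.0 - h) ** ks)) - target_prevalence

    if gap(1.0 - 1e-12) < 0:
        raise ValueError(f"prevalence {target_prevalence} unreachable under this design")
    return float(brentq(gap, 1e-10, 1.0 - 1e-10, xtol=1e-12))


# ---------------------------------------------------------------------------
# deficit rendering


def render_deficits(
    fi: float,
    schema: DeficitSchema | None = None,
    rng: np.random.Generator | None = None,
    chronic_state: dict[str, float] | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Convert a target FI into per-item deficit values whose mean matches it.

    The item sum is the target FI times the catalogue size, rounded to the
    nearest achievable half point (largest-remainder style), so the rendered
    mean is within 1/(2 n_items) of the target.  Items marked chronic keep
    the values passed in ``chronic_state`` (persistence across waves); the
    remainder is distributed over the non-chronic items with selection
    weights increasing in their volatility class, a fractional half point
    going to an item whose level grid contains 0.5.
    """
    schema = schema or default_schema()
    if not 0.0 <= fi <= 1.0:
        raise ValueError("fi must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = schema.n_items
    target = fi * n
    half_capable = [it.name for it in schema.items if 0.5 in it.levels]
    k = round(target * 2.0) / 2.0 if half_capable else float(round(target))
    k = float(min(max(k, 0.0), n))

    values = {it.name: 0.0 for it in schema.items}
    chronic = dict(chronic_state or {})
    for name, v in chronic.items():
        values[name] = v
    remaining = min(max(k - sum(chronic.values()), 0.0), float(n - len(chronic)))
    pool = [it for it in schema.items if it.name not in chronic]

    # chronic items outside the persistent state get a vanishing weight: they
    # are only drawn on overflow (all volatile items exhausted), and the
    # caller then ratchets them into the persistent state
    weights = np.array([{"none": 1e-9, "low": 1.0, "high": 4.0}[it.volatility] for it in pool])
    m = int(np.floor(remaining + 1e-9))
    frac = remaining - m
    order = rng.choice(len(pool), size=len(pool), replace=False, p=weights / weights.sum())
    for j in order[:m]:
        values[pool[j].name] = 1.0
    if frac >= 0.25:
        rest = [pool[j] for j in order[m:] if 0.5 in pool[j].levels]
        taken = [pool[j] for j in order[:m] if 0.5 in pool[j].levels]
        if rest:
            values[rest[0].name] = 0.5
        elif taken and m < len(pool):
            # all unset items are binary: demote a half-capable item to 0.5
            # and promote one more binary item, keeping the sum at m + 0.5
            values[taken[0].name] = 0.5
            values[pool[order[m]].name] = 1.0
        elif frac >= 0.5 and m < len(pool):
            values[pool[order[m]].name] = 1.0
    return values


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    design: CohortDesign | None = None,
    seed: int | None = None,
    schema: DeficitSchema | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw one synthetic cohort; returns (panel frame, ground truth).

    The frame is a valid long panel.  With ``design.render_deficits`` the
    deficit columns are rendered from the latent FI (which then lives only in
    the truth record); otherwise the frame carries the latent ``fi`` column
    directly.  The truth dict holds person- and burst-level random effects,
    row-level linear predictors, the generating parameters and the seed.
    """
    design = design or CohortDesign()
    design.validate()
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    schema = schema or default_schema()
    P = design.n_persons
    W = design.waves_per_burst

    # --- persons -------------------------------------------------------
    lo, hi = design.age_range
    a, b = (lo - design.age_mean) / design.age_sd, (hi - design.age_mean) / design.age_sd
    age = truncnorm.rvs(a, b, loc=design.age_mean, scale=design.age_sd, size=P, random_state=rng)
    sex = np.where(rng.random(P) < design.p_women, "women", "men")
    edu_p = np.asarray(design.education_probs) / sum(design.education_probs)
    sup_p = np.asarray(design.support_probs) / sum(design.support_probs)
    education = rng.choice(["low", "medium", "high"], size=P, p=edu_p)
    support = rng.choice(["low", "medium", "high"], size=P, p=sup_p)
    alone = np.where(rng.random(P) < design.p_living_alone, "yes", "no")
    person_ids = np.array([f"p{i:04d}" for i in range(P)])

    params = design.params
    sds, cors = params["sds"], params["cors"]
    cov_p = np.array(
        [
            [sds["sd_person_loc"] ** 2, cors["cor_person_loc_sc"] * sds["sd_person_loc"] * sds["sd_person_sc"]],
            [cors["cor_person_loc_sc"] * sds["sd_person_loc"] * sds["sd_person_sc"], sds["sd_person_sc"] ** 2],
        ]
    )
    ua = rng.multivariate_normal(np.zeros(2), cov_p, size=P)
    sb = np.array([sds["sd_burst_loc"], sds["sd_burst_wave"], sds["sd_burst_sc"]])
    Rb = np.array(
        [
            [1.0, cors["cor_burst_loc_wave"], cors["cor_burst_loc_sc"]],
            [cors["cor_burst_loc_wave"], 1.0, 0.0],
            [cors["cor_burst_loc_sc"], 0.0, 1.0],
        ]
    )
    cov_b = (sb[:, None] * Rb) * sb[None, :]
    wsc = rng.multivariate_normal(np.zeros(3), cov_b, size=(P, 2))  # (P, burst, 3)

    # --- mortality, return, retention ----------------------------------
    dead = rng.random(P) < design.mortality_prob
    p_ret = min(design.between_burst_retention / max(1.0 - design.mortality_prob, 1e-12), 1.0)
    ret_p = np.full(P, p_ret)
    if design.fi_dependent_dropout:
        # frailer persons (higher location intercept) drop out more often
        ret_p = np.clip(p_ret - 2.0 * np.maximum(ua[:, 0], 0.0), 0.05, 1.0)
    returns = (~dead) & (rng.random(P) < ret_p)

    attend = {1: np.ones((P, W), dtype=bool), 2: np.zeros((P, W), dtype=bool)}
    for w, p in enumerate(design.retention_burst1, start=1):
        attend[1][:, w] = rng.random(P) < p
    attend[2][:, 0] = returns
    for w, p in enumerate(design.retention_burst2, start=1):
        attend[2][:, w] = returns & (rng.random(P) < p)

    hazards = {
        ev: calibrate_event_hazard(prev, design) for ev, prev in design.event_prevalence.items()
    }
    inperson = rng.choice(P, size=min(design.n_inperson_subsample, P), replace=False)
    inperson_mask = np.zeros(P, dtype=bool)
    inperson_mask[inperson] = True

    # --- rows ------------------------------------------------------------
    rows = []
    for i in range(P):
        for burst in (1, 2):
            for w in range(W):
                if not attend[burst][i, w]:
                    continue
                wave = w + 1
                personal = wave == 1 or (burst == 1 and inperson_mask[i])
                rows.append(
                    {
                        "person_id": person_ids[i],
                        "burst": burst,
                        "wave": wave,
                        "age_baseline": round(float(age[i]), 1),
                        "sex": sex[i],
                        "education": education[i],
                        "living_alone": alone[i],
                        "social_support": support[i],
                        "interview_mode": "personal" if personal else "telephone",
                        "bedrest": "yes" if rng.random() < hazards["bedrest"] else "no",
                        "fall": "yes" if rng.random() < hazards["fall"] else "no",
                        "hospital": "yes" if rng.random() < hazards["hospital"] else "no",
                        "dead_between_bursts": "yes" if dead[i] else "no",
                        "_i": i,
                    }
                )
    frame = pd.DataFrame(rows)

    # --- linear predictors and FI ---------------------------------------
    spec = MelsmSpec.from_model_id("M4")
    des = build_design(frame.assign(fi=0.0), spec, age_center=design.age_mean)
    beta = np.array([params["beta"][t] for t in spec.location_fixed])
    gamma = np.array([params["gamma"][t] for t in spec.scale_fixed])
    ii = frame["_i"].to_numpy()
    bpos = frame["burst"].to_numpy() - 1
    wave_c = frame["wave"].to_numpy(dtype=float) - WAVE_CENTER
    mu = des.X @ beta + ua[ii, 0] + wsc[ii, bpos, 0] + wsc[ii, bpos, 1] * wave_c
    sigma = np.exp(des.Z @ gamma + ua[ii, 1] + wsc[ii, bpos, 2])

    # FI restricted to [0, 1] by resampling, i.e. exact truncated-normal draws
    # (no point mass at the bounds, unlike clipping)
    fi = truncnorm.rvs(
        (0.0 - mu) / sigma, (1.0 - mu) / sigma, loc=mu, scale=sigma, random_state=rng
    )

    truth = {
        "seed": seed,
        "params": params,
        "person": pd.DataFrame(
            {
                "person_id": person_ids,
                "u": ua[:, 0],
                "a": ua[:, 1],
                "dead": dead,
                "returned": returns,
            }
        ),
        "burst": pd.DataFrame(
            {
                "person_id": np.repeat(person_ids, 2),
                "burst": np.tile([1, 2], P),
                "w": wsc[:, :, 0].ravel(),
                "s": wsc[:, :, 1].ravel(),
                "c": wsc[:, :, 2].ravel(),
            }
        ),
        "rows": frame[["person_id", "burst", "wave"]].assign(mu=mu, sigma=sigma, fi=fi),
        "event_hazards": hazards,
    }

    frame = frame.drop(columns=["_i"])
    if not design.render_deficits:
        frame["fi"] = fi
        return frame, truth

    # --- deficit rendering ----------------------------------------------
    chronic_items = schema.chronic_names
    values = np.zeros((len(frame), schema.n_items))
    names = schema.names
    frame_fi = pd.Series(fi)
    for pid, grp in frame.groupby("person_id", sort=False):
        idxs = grp.index.to_numpy()
        k_min = float(np.floor(frame_fi[idxs].min() * schema.n_items))
        n_on = int(min(np.floor(0.6 * k_min), len(chronic_items)))
        chosen = rng.choice(len(chronic_items), size=n_on, replace=False) if n_on else []
        chronic_state = {chronic_items[j]: 1.0 for j in chosen}
        for ridx in idxs:
            rendered = render_deficits(
                float(frame_fi[ridx]), schema, rng=rng, chronic_state=chronic_state
            )
            # ratchet: keep any chronic item switched on by overflow
            for nm in chronic_items:
                if rendered[nm] == 1.0:
                    chronic_state[nm] = 1.0
            values[ridx] = [rendered[nm] for nm in names]
    for j, nm in enumerate(names):
        frame[nm] = values[:, j]
    return frame, truth
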