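"""Intraindividual variability of the frailty index and its deficit items.

Within each measurement burst a person contributes a short FI series.  Its
intraindividual mean (iMean) measures the person's frailty level and its
intraindividual standard deviation (iSD, sample denominator n-1) the size of
short-term fluctuations.  At the single-deficit level, fluctuation is
summarised by the intraindividual interquartile range (iIQR) with classes
none (= 0), some (0 < iIQR <= 0.5) and high (> 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .frailty import FISeries, fi_frame, panel_to_fi
from .panel import DeficitPanel

FRAILTY_CUTOFF = 0.25


def imean_isd(series: FISeries, ddof: int = 1) -> tuple[float, float]:
    """Intraindividual mean and standard deviation of one burst series.

    The iSD uses the sample (n-1) denominator by default and is missing (NaN),
    not zero, for a single observation.
    """
    vals = np.asarray(series.fi_values, dtype=float)
    imean = float(np.mean(vals))
    isd = float(np.std(vals, ddof=ddof)) if vals.size > 1 else float("nan")
    return imean, isd


def fluctuation_class(iiqr: float) -> str:
    if np.isnan(iiqr):
        return "undefined"
    if iiqr == 0:
        return "none"
    return "some" if iiqr <= 0.5 else "high"


def threshold_inconsistency(series: FISeries, cutoff: float = FRAILTY_CUTOFF) -> bool | None:
    """Whether a burst series crosses the robust/frail cutoff.

    True iff at least one FI value is >= cutoff and at least one is < cutoff
    (the per-assessment classification flips within the burst).  Undefined
    (None) for a single observation.
    """
    vals = np.asarray(series.fi_values, dtype=float)
    if vals.size < 2:
        return None
    return bool((vals >= cutoff).any() and (vals < cutoff).any())


class BurstVariability(TransformerMixin, BaseEstimator):
    """Per person-burst variability profile table.

    ``transform`` accepts a :class:`DeficitPanel` or a frame with an ``fi``
    column and returns one row per person-burst with n_obs, iMean, iSD,
    threshold-crossing flag and the person-level frailty class (``robust`` if
    iMean <= cutoff else ``frail``, mirroring the categorical usage where the
    person class uses the iMean and the per-assessment class the raw FI).
    """

    def __init__(self, cutoff: float = FRAILTY_CUTOFF, ddof: int = 1):
        self.cutoff = cutoff
        self.ddof = ddof

    def fit(self, X, y=None):
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be inside (0, 1)")
        self.cutoff_ = float(self.cutoff)
        return self

    def transform(self, X) -> pd.DataFrame:
        series = X if isinstance(X, list) else panel_to_fi(X)
        rows = []
        for s in series:
            imean, isd = imean_isd(s, ddof=self.ddof)
            rows.append(
                {
                    "person_id": s.person_id,
                    "burst": s.burst,
                    "n_obs": s.n_obs,
                    "iMean": imean,
                    "iSD": isd,
                    "crossed_threshold": threshold_inconsistency(s, self.cutoff_),
                    "frailty_class": "robust" if imean <= self.cutoff_ else "frail",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "person_id",
                "burst",
                "n_obs",
                "iMean",
                "iSD",
                "crossed_threshold",
                "frailty_class",
            ],
        )


def variability_profiles(panel, cutoff: float = FRAILTY_CUTOFF, ddof: int = 1) -> pd.DataFrame:
    return BurstVariability(cutoff=cutoff, ddof=ddof).fit_transform(panel)


def cohort_isd_summary(
    profiles: pd.DataFrame,
    n_items: int = 40,
    baseline_between_sd: float | None = None,
) -> dict:
    """Distribution of the iSD over person-bursts, plus deficit-unit rescaling.

    ``deficit_units`` converts the mean iSD to the equivalent number of
    deficits (mean iSD x number of FI items).  When the baseline between-person
    FI standard deviation is supplied, ``ratio_to_between_pct`` expresses the
    mean iSD as an integer percentage of it.
    """
    isd = profiles["iSD"].dropna().to_numpy(dtype=float)
    if isd.size == 0:
        raise ValueError("no profile with a defined iSD")
    out = {
        "n": int(isd.size),
        "mean": float(np.mean(isd)),
        "sd": float(np.std(isd, ddof=1)) if isd.size > 1 else float("nan"),
        "q1": float(np.quantile(isd, 0.25)),
        "median": float(np.quantile(isd, 0.50)),
        "q3": float(np.quantile(isd, 0.75)),
        "min": float(np.min(isd)),
        "max": float(np.max(isd)),
    }
    out["deficit_units"] = out["mean"] * n_items
    if baseline_between_sd is not None:
        out["ratio_to_between_pct"] = int(round(100 * out["mean"] / baseline_between_sd))
    return out


def deficit_iiqr(
    panel: DeficitPanel, person_id=None, burst: int | None = None
) -> pd.DataFrame:
    """Within-burst iIQR and fluctuation class per deficit.

    Quantiles use linear interpolation of the empirical distribution (the
    common type-7 rule); the class boundary at 0.5 is sensitive to this
    convention, so it is fixed and documented rather than configurable.
    Deficits with fewer than 2 non-missing observations get a missing iIQR.

    Returns one row per (person_id, burst, deficit); restrict with the
    optional ``person_id``/``burst`` arguments.
    """
    df = panel.df
    if person_id is not None:
        df = df[df["person_id"] == person_id]
    if burst is not None:
        df = df[df["burst"] == burst]
    if df.empty:
        raise ValueError("no rows for the requested person/burst")
    names = panel.schema.names
    rows = []
    for (pid, b), grp in df.groupby(["person_id", "burst"], sort=False):
        vals = grp[names].to_numpy(dtype=float)
        for j, name in enumerate(names):
            col = vals[:, j]
            col = col[~np.isnan(col)]
            if col.size < 2:
                iiqr = float("nan")
            else:
                iiqr = float(np.quantile(col, 0.75) - np.quantile(col, 0.25))
            rows.append(
                {
                    "person_id": pid,
                    "burst": int(b),
                    "deficit": name,
                    "n_obs": int(col.size),
                    "iIQR": iiqr,
                    "fluctuation_class": fluctuation_class(iiqr),
                }
            )
    return pd.DataFrame(rows)


class DeficitVolatility(TransformerMixin, BaseEstimator):
    """Per-deficit shares of none / some / high within-burst fluctuation.

    ``transform`` returns one row per deficit with the proportion of
    person-bursts (with a defined iIQR) in each fluctuation class.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: DeficitPanel) -> pd.DataFrame:
        table = deficit_iiqr(X)
        table = table[table["fluctuation_class"] != "undefined"]
        rows = []
        for deficit, grp in table.groupby("deficit", sort=False):
            n = len(grp)
            counts = grp["fluctuation_class"].value_counts()
            rows.append(
                {
                    "deficit": deficit,
                    "n_defined": n,
                    "none": counts.get("none", 0) / n,
                    "some": counts.get("some", 0) / n,
                    "high": counts.get("high", 0) / n,
                }
            )
        return pd.DataFrame(rows)


def group_isd_contrast(
    profiles: pd.DataFrame,
    groups: pd.Series | dict,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict:
    """Mean-iSD difference between two person-level strata.

    ``groups`` maps person_id to a binary label (bool/0-1).  Returns the
    absolute and percent difference in mean iSD (exposed minus unexposed) with
    a seeded bootstrap percentile interval resampling persons within strata.
    The paper-style usage is descriptive (e.g. disease present vs absent).
    """
    g = pd.Series(groups)
    prof = profiles.dropna(subset=["iSD"]).copy()
    prof["group"] = prof["person_id"].map(g)
    prof = prof.dropna(subset=["group"])
    person_isd = prof.groupby(["person_id", "group"], sort=False)["iSD"].mean().reset_index()
    exposed = person_isd.loc[person_isd["group"].astype(bool), "iSD"].to_numpy()
    control = person_isd.loc[~person_isd["group"].astype(bool), "iSD"].to_numpy()
    for name, arr in (("exposed", exposed), ("unexposed", control)):
        if arr.size == 0:
            raise ValueError(f"stratum {name!r} is empty")
    if min(exposed.size, control.size) < 2:
        warnings.warn(
            "a stratum has a single member; the bootstrap interval is degenerate",
            stacklevel=2,
        )
    diff = float(exposed.mean() - control.mean())
    pct = 100.0 * diff / control.mean() if control.mean() != 0 else float("inf")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        e = rng.choice(exposed, size=exposed.size, replace=True)
        c = rng.choice(control, size=control.size, replace=True)
        boots[b] = e.mean() - c.mean()
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {
        "diff": diff,
        "pct_diff": float(pct),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_exposed": int(exposed.size),
        "n_unexposed": int(control.size),
    }
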