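"""Frailty-index construction by deficit accumulation.

The frailty index (FI) of an interview is the mean of its 0-1-coded health
deficits: the sum of deficit scores divided by the number of deficits
considered.  With partially missing answers the denominator is the count of
non-missing items, provided completeness reaches a threshold (default 80%,
standard FI practice); below the threshold the FI is treated as missing
rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import DeficitPanel
from .schema import DeficitSchema, default_schema


@dataclass
class FISeries:
    """Ordered FI sequence of one person within one burst."""

    person_id: str
    burst: int
    waves: np.ndarray
    fi_values: np.ndarray
    n_items_used: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.waves = np.asarray(self.waves, dtype=int)
        self.fi_values = np.asarray(self.fi_values, dtype=float)
        self.n_items_used = np.asarray(self.n_items_used, dtype=int)
        if len(self.waves) != len(self.fi_values):
            raise ValueError("waves and fi_values must have equal length")
        if np.any(np.diff(self.waves) <= 0):
            raise ValueError("waves must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return len(self.fi_values)


def compute_fi(
    deficit_values, min_completeness: float = 0.8, n_items_total: int | None = None
) -> float:
    """FI of a single interview record.

    Parameters
    ----------
    deficit_values : sequence of float
        Item scores in [0, 1]; NaN marks a missing answer.
    min_completeness : float
        Minimum fraction of non-missing items required; below it the FI is NaN.
    n_items_total : int, optional
        Catalogue size used for the completeness check (defaults to
        ``len(deficit_values)``).
    """
    vals = np.asarray(deficit_values, dtype=float)
    n_total = n_items_total if n_items_total is not None else vals.size
    observed = ~np.isnan(vals)
    n_used = int(observed.sum())
    if n_used == 0:
        warnings.warn("all deficit items missing; FI undefined", stacklevel=2)
        return float("nan")
    if n_used / n_total < min_completeness:
        return float("nan")
    return float(vals[observed].sum() / n_used)


class FrailtyIndex(TransformerMixin, BaseEstimator):
    """Transformer adding an ``fi`` column (and ``fi_n_items``) to a panel frame.

    Parameters
    ----------
    schema : DeficitSchema, optional
        Deficit catalogue naming the item columns (default: shipped 40-item set).
    min_completeness : float
        Completeness threshold below which an interview's FI is missing.
    """

    def __init__(self, schema: DeficitSchema | None = None, min_completeness: float = 0.8):
        self.schema = schema
        self.min_completeness = min_completeness

    def fit(self, X, y=None):
        self.schema_ = self.schema or default_schema()
        if not 0.0 < self.min_completeness <= 1.0:
            raise ValueError("min_completeness must be in (0, 1]")
        self.n_items_ = self.schema_.n_items
        return self

    def transform(self, X) -> pd.DataFrame:
        df = X.df.copy() if isinstance(X, DeficitPanel) else X.copy()
        missing = [c for c in self.schema_.names if c not in df.columns]
        if missing:
            raise ValueError(f"panel lacks deficit columns: {missing[:5]}")
        vals = df[self.schema_.names].to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        n_used = observed.sum(axis=1)
        with np.errstate(invalid="ignore"):
            fi = np.nansum(vals, axis=1) / np.where(n_used > 0, n_used, np.nan)
        fi[n_used / self.n_items_ < self.min_completeness] = np.nan
        df["fi"] = fi
        df["fi_n_items"] = n_used
        return df


def panel_to_fi(
    panel: DeficitPanel | pd.DataFrame,
    schema: DeficitSchema | None = None,
    min_completeness: float = 0.8,
) -> list[FISeries]:
    """One :class:`FISeries` per person-burst with at least one scored interview.

    Accepts either a :class:`DeficitPanel` (FI computed from the deficit
    columns) or a plain frame that already carries an ``fi`` column (as
    emitted by the simulator with deficit rendering off).
    """
    if isinstance(panel, DeficitPanel):
        df = FrailtyIndex(schema=schema or panel.schema, min_completeness=min_completeness).fit_transform(panel)
    elif "fi" in panel.columns:
        df = panel.copy()
        if "fi_n_items" not in df.columns:
            df["fi_n_items"] = -1
    else:
        df = FrailtyIndex(schema=schema, min_completeness=min_completeness).fit_transform(panel)

    out: list[FISeries] = []
    df = df.sort_values(["person_id", "burst", "wave"], kind="mergesort")
    for (pid, burst), grp in df.groupby(["person_id", "burst"], sort=False):
        scored = grp[grp["fi"].notna()]
        if len(scored) == 0:
            continue
        out.append(
            FISeries(
                person_id=pid,
                burst=int(burst),
                waves=scored["wave"].to_numpy(),
                fi_values=scored["fi"].to_numpy(),
                n_items_used=scored["fi_n_items"].to_numpy(),
            )
        )
    return out


def fi_frame(
    panel: DeficitPanel | pd.DataFrame,
    schema: DeficitSchema | None = None,
    min_completeness: float = 0.8,
) -> pd.DataFrame:
    """Panel frame with an ``fi`` column, computing it only when absent."""
    if isinstance(panel, DeficitPanel):
        return FrailtyIndex(schema=schema or panel.schema, min_completeness=min_completeness).fit_transform(panel)
    if "fi" in panel.columns:
        return panel.copy()
    return FrailtyIndex(schema=schema, min_completeness=min_completeness).fit_transform(panel)
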