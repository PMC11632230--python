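"""Long-format interview panel: schema, validation, CSV round trip.

One row per interview, keyed by ``(person_id, burst, wave)``.  All downstream
stages (FI construction, variability statistics, location-scale models)
consume this canonical table.  Missing deficit answers are empty CSV cells and
stay missing — they are never silently coded as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import DeficitSchema, default_schema

KEY_COLUMNS = ["person_id", "burst", "wave"]

#: categorical covariates with their declared level order (first level is the
#: reference for model coding and the deterministic mode-imputation tie-break)
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["men", "women"],
    "education": ["low", "medium", "high"],
    "living_alone": ["no", "yes"],
    "social_support": ["low", "medium", "high"],
    "interview_mode": ["personal", "telephone"],
    "bedrest": ["no", "yes"],
    "fall": ["no", "yes"],
    "hospital": ["no", "yes"],
    "dead_between_bursts": ["no", "yes"],
}

#: covariates that must be identical on every row of a person
TIME_CONSTANT = [
    "age_baseline",
    "sex",
    "education",
    "living_alone",
    "social_support",
    "dead_between_bursts",
]

COVARIATE_COLUMNS = ["age_baseline", *CATEGORICAL_LEVELS.keys()]

MAX_WAVES = 7


class PanelError(ValueError):
    """Base class for panel problems."""


class PanelSchemaError(PanelError):
    """A required column is absent."""


class PanelValidationError(PanelError):
    """A cell value violates its domain; message carries row references."""


class PanelIntegrityError(PanelError):
    """Key structure violated (duplicate person/burst/wave, inconsistent covariates)."""


@dataclass
class DeficitPanel:
    """A validated long-format panel plus its deficit schema.

    ``df`` holds one row per interview.  Construct via :meth:`from_frame` or
    :func:`read_panel` so the invariants have been checked.
    """

    df: pd.DataFrame
    schema: DeficitSchema

    @property
    def deficit_columns(self) -> list[str]:
        return self.schema.names

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, schema: DeficitSchema | None = None
    ) -> "DeficitPanel":
        schema = schema or default_schema()
        panel = cls(df=df.copy(), schema=schema)
        panel.validate()
        return panel

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        df = self.df
        required = KEY_COLUMNS + COVARIATE_COLUMNS + self.deficit_columns
        for col in required:
            if col not in df.columns:
                raise PanelSchemaError(f"required column missing: {col!r}")

        burst = pd.to_numeric(df["burst"], errors="coerce")
        wave = pd.to_numeric(df["wave"], errors="coerce")
        bad = df.index[~burst.isin([1, 2]) | ~wave.isin(range(1, MAX_WAVES + 1))]
        if len(bad):
            raise PanelValidationError(
                f"rows {list(bad[:10])}: burst must be 1/2 and wave 1..{MAX_WAVES}"
            )
        df["burst"] = burst.astype(int)
        df["wave"] = wave.astype(int)

        dupes = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dupes.any():
            keys = df.loc[dupes, KEY_COLUMNS].drop_duplicates().values.tolist()
            raise PanelIntegrityError(f"duplicate (person, burst, wave) keys: {keys[:10]}")

        for col in self.deficit_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_cells = df.index[df[col].notna() & (vals.isna() | (vals < 0) | (vals > 1))]
            if len(bad_cells):
                i = bad_cells[0]
                raise PanelValidationError(
                    f"deficit {col!r} outside [0, 1] at row {i} "
                    f"(person {df.at[i, 'person_id']!r}, burst {df.at[i, 'burst']}, "
                    f"wave {df.at[i, 'wave']}): value {df.at[i, col]!r}"
                )
            df[col] = vals.astype(float)

        age = pd.to_numeric(df["age_baseline"], errors="coerce")
        bad_age = df.index[df["age_baseline"].notna() & (age.isna() | (age < 70))]
        if len(bad_age):
            raise PanelValidationError(
                f"age_baseline must be numeric and >= 70; first bad row {bad_age[0]}"
            )
        df["age_baseline"] = age.astype(float)

        for col, levels in CATEGORICAL_LEVELS.items():
            ok = df[col].isna() | df[col].isin(levels)
            if not ok.all():
                i = df.index[~ok][0]
                raise PanelValidationError(
                    f"column {col!r}: value {df.at[i, col]!r} at row {i} "
                    f"not in allowed levels {levels}"
                )

        for col in TIME_CONSTANT:
            per = df.groupby("person_id", sort=False)[col].nunique(dropna=True)
            unstable = per[per > 1]
            if len(unstable):
                raise PanelIntegrityError(
                    f"time-constant covariate {col!r} varies within persons "
                    f"{list(unstable.index[:5])}"
                )

        self.df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)

    # -- I/O ------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        cols = KEY_COLUMNS + COVARIATE_COLUMNS + self.deficit_columns
        extra = [c for c in self.df.columns if c not in cols]
        self.df[cols + extra].to_csv(path, index=False, lineterminator="\n")


def read_panel(path: str | Path, schema: DeficitSchema | None = None) -> DeficitPanel:
    """Read and validate a long-format panel CSV.

    Raises :class:`PanelSchemaError` when a required column is absent,
    :class:`PanelValidationError` with a row reference for out-of-domain cells,
    and :class:`PanelIntegrityError` for duplicate keys.  Empty cells become
    missing values, never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"person_id": str})
    return DeficitPanel.from_frame(df, schema=schema)


def write_panel(panel: DeficitPanel, path: str | Path) -> None:
    panel.write_csv(path)


def validate_covariate_completeness(
    panel: DeficitPanel, impute: bool = False
) -> tuple[pd.DataFrame, DeficitPanel | None]:
    """Report missing covariate cells; optionally mode-impute categoricals.

    The report has one row per missing cell (column, person, burst, wave).
    With ``impute=True`` each missing categorical cell is replaced by the
    within-sample mode; ties break deterministically to the first category in
    the declared level order.  Time-constant covariates are imputed from the
    person-level distribution (each person counted once), time-varying ones
    from the row-level distribution.  Numeric ``age_baseline`` is imputed by
    the person-level median.  Only flagged cells are touched.
    """
    df = panel.df
    rows = []
    for col in COVARIATE_COLUMNS:
        miss = df.index[df[col].isna()]
        for i in miss:
            rows.append(
                {
                    "column": col,
                    "person_id": df.at[i, "person_id"],
                    "burst": df.at[i, "burst"],
                    "wave": df.at[i, "wave"],
                }
            )
    report = pd.DataFrame(rows, columns=["column", "person_id", "burst", "wave"])
    if not impute:
        return report, None

    out = df.copy()
    for col in COVARIATE_COLUMNS:
        if not out[col].isna().any():
            continue
        if col == "age_baseline":
            out[col] = out[col].fillna(
                out.drop_duplicates("person_id")[col].median()
            )
            continue
        levels = CATEGORICAL_LEVELS[col]
        if col in TIME_CONSTANT:
            observed = out.drop_duplicates("person_id")[col].dropna()
        else:
            observed = out[col].dropna()
        counts = observed.value_counts()
        best = max(counts.max(), 0) if len(counts) else 0
        # deterministic tie-break: first declared level among the modes
        mode = next(
            (lv for lv in levels if counts.get(lv, 0) == best), levels[0]
        )
        out[col] = out[col].fillna(mode)
    imputed = DeficitPanel(df=out, schema=panel.schema)
    imputed.validate()
    return report, imputed
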