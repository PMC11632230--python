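"""Deficit-item schema: which columns form the frailty index and how they are coded.

The schema is deliberately a configuration artifact, not code: the shipped
default catalogue (40 self-report items) lives in ``data/deficits_default.yaml``
and any user study can substitute its own item list, level codings and
volatility annotations without touching the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

VOLATILITY_LEVELS = ("none", "low", "high")


class SchemaError(ValueError):
    """Raised when a deficit schema file is malformed."""


@dataclass(frozen=True)
class DeficitItem:
    """One health deficit: a named column scored on a fixed grid in [0, 1]."""

    name: str
    levels: tuple[float, ...] = (0.0, 1.0)
    group: str = "other"
    volatility: str = "low"

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("deficit item needs a non-empty name")
        lv = tuple(float(v) for v in self.levels)
        if len(lv) < 2 or any(not (0.0 <= v <= 1.0) for v in lv):
            raise SchemaError(
                f"deficit {self.name!r}: levels must be >=2 values in [0, 1], got {lv}"
            )
        if tuple(sorted(lv)) != lv:
            raise SchemaError(f"deficit {self.name!r}: levels must be sorted")
        if self.volatility not in VOLATILITY_LEVELS:
            raise SchemaError(
                f"deficit {self.name!r}: volatility must be one of {VOLATILITY_LEVELS}"
            )
        object.__setattr__(self, "levels", lv)

    @property
    def is_binary(self) -> bool:
        return self.levels == (0.0, 1.0)

    @property
    def is_chronic(self) -> bool:
        return self.volatility == "none"


@dataclass(frozen=True)
class DeficitSchema:
    """Ordered catalogue of deficit items.

    The order is meaningful: it fixes the column order of panel files and the
    deterministic tie-break of categorical mode imputation.
    """

    items: tuple[DeficitItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate deficit names: {dupes}")
        if not self.items:
            raise SchemaError("schema has no deficit items")

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def chronic_names(self) -> list[str]:
        return [it.name for it in self.items if it.is_chronic]

    def __getitem__(self, name: str) -> DeficitItem:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @classmethod
    def from_mapping(cls, spec: dict) -> "DeficitSchema":
        try:
            entries = spec["deficits"]
        except (KeyError, TypeError) as exc:
            raise SchemaError("schema file must contain a top-level 'deficits' list") from exc
        items = []
        for entry in entries:
            if isinstance(entry, str):
                items.append(DeficitItem(name=entry))
            else:
                items.append(
                    DeficitItem(
                        name=entry["name"],
                        levels=tuple(entry.get("levels", (0.0, 1.0))),
                        group=entry.get("group", "other"),
                        volatility=entry.get("volatility", "low"),
                    )
                )
        return cls(items=tuple(items))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeficitSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "DeficitSchema":
        return cls(items=tuple(DeficitItem(name=n) for n in names))


def default_schema() -> DeficitSchema:
    """The shipped 40-item self-report catalogue."""
    ref = resources.files("frailtyburst").joinpath("data/deficits_default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return DeficitSchema.from_mapping(yaml.safe_load(fh))
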