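"""Pedigree container with social and (optionally) genetic parent links.

A pedigree is a table with one row per individual: ``id``, ``sire``, ``dam``
and, for simulated dual pedigrees, ``genetic_sire``/``genetic_dam`` (the dam
is shared — extra-pair matings corrupt paternity only).  Missing parents are
``None``.  Parents that are referenced but have no row of their own are
promoted to founder rows on construction, so every named parent is always an
individual of the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from graphlib import CycleError, TopologicalSorter

import pandas as pd

from .errors import IdCollisionError, PedigreeIntegrityError

#: value used for a missing parent in files (alongside the empty string)
MISSING_TOKENS = {"", "0", "NA", None}

_OPTIONAL_COLUMNS = ("genetic_sire", "genetic_dam", "generation", "sex", "clutch")


def _clean_parent(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    value = str(value)
    return None if value in MISSING_TOKENS else value


@dataclass(frozen=True)
class Pedigree:
    """Immutable pedigree; ``dummy_ids`` marks inserted placeholder parents."""

    table: pd.DataFrame
    dummy_ids: frozenset = frozenset()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dummy_ids=()) -> "Pedigree":
        frame = frame.copy()
        if "id" not in frame.columns:
            raise PedigreeIntegrityError("pedigree frame needs an 'id' column")
        for col in ("sire", "dam"):
            if col not in frame.columns:
                frame[col] = None
        frame["id"] = frame["id"].map(str)
        parent_cols = [c for c in ("sire", "dam", "genetic_sire", "genetic_dam")
                       if c in frame.columns]
        for col in parent_cols:
            frame[col] = frame[col].map(_clean_parent)
        ids = frame["id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise IdCollisionError(f"duplicated pedigree ids: {dups}")
        known = set(ids)
        referenced = set()
        for col in parent_cols:
            referenced.update(p for p in frame[col] if p is not None)
        orphans = sorted(referenced - known)
        if orphans:  # promote referenced-only parents to founders
            extra = pd.DataFrame({"id": orphans})
            frame = pd.concat([extra, frame], ignore_index=True)
            frame = frame.where(pd.notna(frame), None)
        cols = ["id", "sire", "dam"] + [c for c in _OPTIONAL_COLUMNS if c in frame.columns]
        return cls(table=frame[cols].reset_index(drop=True),
                   dummy_ids=frozenset(str(d) for d in dummy_ids))

    @classmethod
    def from_records(cls, records, columns=("id", "sire", "dam"), dummy_ids=()):
        return cls.from_frame(pd.DataFrame(records, columns=list(columns)),
                              dummy_ids=dummy_ids)

    # -- basic access -----------------------------------------------------
    @property
    def ids(self) -> list:
        return list(self.table["id"])

    @property
    def is_dual(self) -> bool:
        return "genetic_sire" in self.table.columns

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, item) -> bool:
        return str(item) in set(self.table["id"])

    def links(self, which: str = "social") -> pd.DataFrame:
        """Trio view (id, sire, dam) through the requested link set."""
        if which == "social":
            out = self.table[["id", "sire", "dam"]].copy()
        elif which == "genetic":
            if not self.is_dual:
                out = self.table[["id", "sire", "dam"]].copy()
            else:
                out = self.table[["id", "genetic_sire", "genetic_dam"]].copy()
                out.columns = ["id", "sire", "dam"]
        else:
            raise ValueError(f"unknown link set {which!r}")
        return out

    def parent_map(self, which: str = "social") -> dict:
        frame = self.links(which)
        return {r.id: (r.sire, r.dam) for r in frame.itertuples(index=False)}

    def topological_order(self, which: str = "social") -> list:
        """Ids sorted parents-before-offspring; raises on cycles."""
        parents = self.parent_map(which)
        sorter = TopologicalSorter(
            {i: [p for p in ps if p is not None] for i, ps in parents.items()}
        )
        try:
            return list(sorter.static_order())
        except CycleError as exc:
            raise PedigreeIntegrityError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    def validate(self) -> None:
        """Check acyclicity of both link sets and dam agreement on dual pedigrees."""
        self.topological_order("social")
        if self.is_dual:
            self.topological_order("genetic")
            social = self.table["dam"]
            genetic = self.table["genetic_dam"]
            if not (social.fillna("·") == genetic.fillna("·")).all():
                raise PedigreeIntegrityError("genetic dam must equal social dam")

    def with_dummies(self, frame: pd.DataFrame, new_dummies) -> "Pedigree":
        return replace(self, table=frame.reset_index(drop=True),
                       dummy_ids=self.dummy_ids | frozenset(new_dummies))

    # -- derived sets -----------------------------------------------------
    def founders(self, which: str = "social") -> list:
        frame = self.links(which)
        return [r.id for r in frame.itertuples(index=False)
                if r.sire is None and r.dam is None]

    def ancestor_closure(self, ids, which: str = "both") -> set:
        """ids plus every ancestor reachable through the requested links."""
        maps = []
        if which in ("social", "both"):
            maps.append(self.parent_map("social"))
        if which in ("genetic", "both") and self.is_dual:
            maps.append(self.parent_map("genetic"))
        closure, stack = set(), [str(i) for i in ids]
        while stack:
            cur = stack.pop()
            if cur in closure:
                continue
            closure.add(cur)
            for pm in maps:
                for parent in pm.get(cur, (None, None)):
                    if parent is not None and parent not in closure:
                        stack.append(parent)
        return closure
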