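"""Pedigree container shared by the simulator and the heritability estimators.

Individuals are identified by string ids.  Sexes are ``"F"``/``"M"``.  The
mimicry traits (``white_rel``, ``red_rel``) are female-limited: males never
carry phenotype values.  Parent links may be absent (founders and the wild
mates of founder females).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "DanglingParentError",
    "PedigreeCycleError",
    "SexOfParentError",
    "MaleTraitError",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DanglingParentError(PedigreeError):
    """A parent id that does not belong to the pedigree."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class SexOfParentError(PedigreeError):
    """A mother that is not female, or a father that is not male."""


class MaleTraitError(PedigreeError):
    """A male carrying a value for a female-limited trait."""


@dataclass
class Individual:
    id: str
    sex: str  # "F" or "M"
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    generation: int = 0
    white_rel: Optional[float] = None
    red_rel: Optional[float] = None


@dataclass
class Pedigree:
    """A multi-generation family structure with female-limited trait values."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        self.individuals[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def mother(self, ind_id: str) -> Optional[Individual]:
        m = self.individuals[ind_id].mother_id
        return self.individuals.get(m) if m else None

    def father(self, ind_id: str) -> Optional[Individual]:
        f = self.individuals[ind_id].father_id
        return self.individuals.get(f) if f else None

    def ancestors(self, ind_id: str, depth: int) -> set[str]:
        """Ids of ancestors up to ``depth`` generations back (1 = parents)."""
        out: set[str] = set()
        frontier = {ind_id}
        for _ in range(depth):
            nxt: set[str] = set()
            for i in frontier:
                ind = self.individuals.get(i)
                if ind is None:
                    continue
                for p in (ind.mother_id, ind.father_id):
                    if p:
                        nxt.add(p)
            out |= nxt
            frontier = nxt
        return out

    def females(self) -> list[Individual]:
        return [i for i in self if i.sex == "F"]

    def validate(self) -> None:
        """Check parent links, parent sexes, female-limited traits and acyclicity."""
        for ind in self:
            if ind.sex not in ("F", "M"):
                raise PedigreeError(f"{ind.id}: unknown sex {ind.sex!r}")
            for label, pid in (("mother", ind.mother_id), ("father", ind.father_id)):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise DanglingParentError(
                        f"{ind.id}: {label} {pid!r} not in pedigree"
                    )
                want = "F" if label == "mother" else "M"
                if parent.sex != want:
                    raise SexOfParentError(
                        f"{ind.id}: {label} {pid!r} has sex {parent.sex!r}"
                    )
            if ind.sex == "M" and (ind.white_rel is not None or ind.red_rel is not None):
                raise MaleTraitError(f"{ind.id}: male with female-limited trait value")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.individuals:
            if start in state:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state.get(node) == 0:
                        raise PedigreeCycleError(f"{node} is its own ancestor")
                    if state.get(node) == 1:
                        continue
                    state[node] = 0
                    stack.append((node, 1))
                    ind = self.individuals.get(node)
                    if ind is not None:
                        for p in (ind.mother_id, ind.father_id):
                            if p and state.get(p) != 1:
                                stack.append((p, 0))
                else:
                    state[node] = 1

    # --- frame round trip -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": i.id,
                "sex": i.sex,
                "mother_id": i.mother_id or "",
                "father_id": i.father_id or "",
                "generation": i.generation,
                "white_rel": i.white_rel,
                "red_rel": i.red_rel,
            }
            for i in self
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ped = cls()
        for row in df.itertuples(index=False):
            ped.add(
                Individual(
                    id=str(row.id),
                    sex=str(row.sex),
                    mother_id=str(row.mother_id) or None
                    if not pd.isna(row.mother_id)
                    else None,
                    father_id=str(row.father_id) or None
                    if not pd.isna(row.father_id)
                    else None,
                    generation=int(row.generation),
                    white_rel=None if pd.isna(row.white_rel) else float(row.white_rel),
                    red_rel=None if pd.isna(row.red_rel) else float(row.red_rel),
                )
            )
        return ped
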