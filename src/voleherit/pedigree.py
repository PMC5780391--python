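"""Pedigrees and the additive (numerator) relationship matrix.

A pedigree is an ordered collection of parentage records over a closed
breeding colony.  From it we build the numerator relationship matrix
``A``, whose entry ``a_ij`` is twice the kinship coefficient between
animals *i* and *j* (so non-inbred full sibs have 0.5, parent-offspring
0.5, half sibs 0.25) and whose diagonal is ``1 + F_i`` with ``F_i`` the
inbreeding coefficient.  ``A`` is the covariance structure of additive
genetic effects in the animal model.

The matrix is built by the tabular method: animals are processed in
topological order (parents before offspring) and each new row is a
parental average of earlier rows.  At colony scale (a few hundred to a
few thousand animals) dense linear algebra is exact and cheap, so the
inverse needed by the Gibbs sampler is obtained by a dense Cholesky
factorisation rather than Henderson's sparse rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "additive_relationship_matrix",
    "inverse_relationship",
    "read_pedigree",
    "write_pedigree",
]

#: sentinel strings treated as "parent unknown" in pedigree CSV files
UNKNOWN_SENTINELS = {"", "0", "NA", "na", "nan", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, dangling ids, duplicates)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal's parentage entry.

    ``sire_id`` / ``dam_id`` of ``None`` mean the parent is unknown; such
    animals are treated as unrelated, non-inbred founders.
    """

    animal_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    generation: Optional[int] = None
    sex: Optional[str] = None  # "M" or "F" when known

    def __post_init__(self) -> None:
        if self.animal_id in (None, ""):
            raise PedigreeError("animal_id must be a non-empty identifier")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise PedigreeError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.animal_id in (self.sire_id, self.dam_id):
            raise PedigreeError(
                f"animal {self.animal_id!r} is recorded as its own parent"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """An ordered, validated collection of :class:`PedigreeRecord`.

    On construction, animal ids are checked for uniqueness and parents that
    appear only on the parent side of records are auto-inserted as founders
    (with a warning), so that every referenced id resolves to a record.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        if not records:
            raise PedigreeError("pedigree must contain at least one record")
        seen: set[str] = set()
        for rec in records:
            if rec.animal_id in seen:
                raise PedigreeError(f"duplicate animal id {rec.animal_id!r}")
            seen.add(rec.animal_id)
        missing: list[str] = []
        for rec in records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in seen:
                    missing.append(parent)
                    seen.add(parent)
        if missing:
            warnings.warn(
                f"{len(missing)} animal(s) appear only as parents; "
                f"inserted as founders: {missing[:5]}{'...' if len(missing) > 5 else ''}",
                stacklevel=2,
            )
            records = [PedigreeRecord(a) for a in missing] + records
        self._records: tuple[PedigreeRecord, ...] = tuple(records)
        self._index = {rec.animal_id: i for i, rec in enumerate(self._records)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PedigreeRecord]:
        return iter(self._records)

    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        return self._records[self._index[animal_id]]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        n_founders = sum(rec.is_founder for rec in self._records)
        return f"Pedigree(n={len(self)}, founders={n_founders})"

    @property
    def records(self) -> tuple[PedigreeRecord, ...]:
        return self._records

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.animal_id for rec in self._records)

    def males(self) -> list[PedigreeRecord]:
        return [rec for rec in self._records if rec.sex == "M"]

    def females(self) -> list[PedigreeRecord]:
        return [rec for rec in self._records if rec.sex == "F"]

    @property
    def is_sorted(self) -> bool:
        """True when every parent precedes its offspring."""
        for i, rec in enumerate(self._records):
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and self._index[parent] >= i:
                    return False
        return True

    # -- conversion ---------------------------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build a pedigree from a frame with columns animal, sire, dam
        (optional generation, sex); empty/"0" parent fields mean unknown."""
        required = {"animal", "sire", "dam"}
        if not required.issubset(frame.columns):
            raise PedigreeError(
                f"pedigree table needs columns {sorted(required)}, got {list(frame.columns)}"
            )

        def _clean(value: object) -> Optional[str]:
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return None
            text = str(value).strip()
            return None if text in UNKNOWN_SENTINELS else text

        def _plain(value: object) -> Optional[str]:
            # unlike parent fields, "0" is a legitimate generation value
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return None
            text = str(value).strip()
            return text or None

        records = []
        for pos, row in enumerate(frame.itertuples(index=False), start=2):
            row = row._asdict()
            animal = _clean(row["animal"])
            if animal is None:
                raise PedigreeError(f"line {pos}: missing animal id")
            try:
                records.append(
                    PedigreeRecord(
                        animal_id=animal,
                        sire_id=_clean(row["sire"]),
                        dam_id=_clean(row["dam"]),
                        generation=(
                            int(float(row["generation"]))
                            if "generation" in row and _plain(row["generation"]) is not None
                            else None
                        ),
                        sex=_plain(row["sex"]) if "sex" in row else None,
                    )
                )
            except (PedigreeError, ValueError) as exc:
                raise PedigreeError(f"line {pos}: {exc}") from exc
        return cls(records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [r.animal_id for r in self._records],
                "sire": [r.sire_id or "0" for r in self._records],
                "dam": [r.dam_id or "0" for r in self._records],
                "generation": [r.generation for r in self._records],
                "sex": [r.sex for r in self._records],
            }
        )


def validate_and_sort(pedigree: Pedigree) -> Pedigree:
    """Return the pedigree in topological order (parents before offspring).

    Content is unchanged; only record order may differ.  A stable Kahn
    traversal is used so that already-sorted pedigrees come back in their
    original order.  Raises :class:`PedigreeError` naming an offending
    animal if the parentage graph contains a cycle.
    """
    if pedigree.is_sorted:
        return pedigree
    index = {rec.animal_id: rec for rec in pedigree}
    n_unresolved_parents = {
        rec.animal_id: sum(p is not None for p in (rec.sire_id, rec.dam_id))
        for rec in pedigree
    }
    children: dict[str, list[str]] = {rec.animal_id: [] for rec in pedigree}
    for rec in pedigree:
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None:
                children[parent].append(rec.animal_id)
    ready = [rec.animal_id for rec in pedigree if n_unresolved_parents[rec.animal_id] == 0]
    ordered: list[PedigreeRecord] = []
    while ready:
        animal = ready.pop(0)
        ordered.append(index[animal])
        for child in children[animal]:
            n_unresolved_parents[child] -= 1
            if n_unresolved_parents[child] == 0:
                ready.append(child)
    if len(ordered) != len(pedigree):
        stuck = next(a for a, k in n_unresolved_parents.items() if k > 0)
        raise PedigreeError(
            f"pedigree contains a parentage cycle involving animal {stuck!r}"
        )
    return Pedigree(ordered)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix ``A`` over an ordered list of animals."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def relatedness(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def inbreeding(self, animal_id: str) -> float:
        i = self._index[animal_id]
        return float(self.values[i, i] - 1.0)

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = np.array([self._index[a] for a in ids])
        return RelationshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def inverse(self) -> np.ndarray:
        return inverse_relationship(self)


def additive_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Build ``A`` by the tabular method.

    Requires a topologically sorted pedigree (use :func:`validate_and_sort`
    first).  For animal *i* with parents *s*, *d* (indices earlier in the
    order), ``a_ii = 1 + 0.5 a_sd`` and ``a_ij = 0.5 (a_js + a_jd)`` for all
    earlier *j*; an unknown parent contributes nothing.
    """
    if not pedigree.is_sorted:
        raise PedigreeError(
            "pedigree must be topologically sorted; call validate_and_sort() first"
        )
    n = len(pedigree)
    index = {rec.animal_id: i for i, rec in enumerate(pedigree)}
    A = np.zeros((n, n))
    for i, rec in enumerate(pedigree):
        s = index[rec.sire_id] if rec.sire_id is not None else None
        d = index[rec.dam_id] if rec.dam_id is not None else None
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        if i:
            row = np.zeros(i)
            if s is not None:
                row += A[:i, s]
            if d is not None:
                row += A[:i, d]
            row *= 0.5
            A[:i, i] = row
            A[i, :i] = row
    return RelationshipMatrix(pedigree.ids, A)


def inverse_relationship(A: RelationshipMatrix | np.ndarray) -> np.ndarray:
    """Dense inverse of ``A`` via Cholesky factorisation.

    Pedigree relationship matrices are positive definite whenever no animal
    is duplicated, so the Cholesky route is both a validity check and the
    fastest exact inverse at colony scale.  Raises ``LinAlgError`` carrying
    a condition-number estimate if the factorisation fails or the matrix is
    numerically singular.
    """
    values = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, float)
    try:
        c, low = scipy.linalg.cho_factor(values)
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(values)
        raise np.linalg.LinAlgError(
            f"relationship matrix is not positive definite "
            f"(condition estimate {cond:.3e})"
        ) from exc
    inv = scipy.linalg.cho_solve((c, low), np.eye(values.shape[0]))
    return (inv + inv.T) / 2.0


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns animal, sire, dam[, generation, sex])."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return Pedigree.from_dataframe(frame)


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write a pedigree CSV in the dialect :func:`read_pedigree` accepts."""
    frame = pedigree.to_dataframe()
    frame["generation"] = frame["generation"].map(
        lambda g: "" if g is None or (isinstance(g, float) and np.isnan(g)) else int(g)
    )
    frame["sex"] = frame["sex"].map(lambda s: s or "")
    frame.to_csv(path, index=False)
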