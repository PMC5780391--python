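"""Independent reference implementations used only to check the package.

The relationship-matrix oracle is the classic recursive coancestry
(kinship) recursion: f(i, i) = 0.5 (1 + f(s_i, d_i)) and, for j preceding
i in a topological order, f(i, j) = 0.5 (f(s_i, j) + f(d_i, j)) with
unknown parents contributing zero.  The numerator relationship is twice
the kinship.  This is a different recursion from the tabular method the
package uses, so agreement is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def coancestry_matrix(records: list[tuple[str, str | None, str | None]]) -> np.ndarray:
    """2 * kinship matrix for records given as (animal, sire, dam) tuples in
    topological order (parents before offspring)."""
    position = {animal: i for i, (animal, _, _) in enumerate(records)}
    parents = {animal: (s, d) for animal, s, d in records}

    @lru_cache(maxsize=None)
    def f(a: str, b: str) -> float:
        if position[a] < position[b]:
            a, b = b, a
        sa, da = parents[a]
        if a == b:
            if sa is None or da is None:
                return 0.5
            return 0.5 * (1.0 + f(sa, da))
        return 0.5 * (
            (f(sa, b) if sa is not None else 0.0)
            + (f(da, b) if da is not None else 0.0)
        )

    n = len(records)
    A = np.empty((n, n))
    ids = [animal for animal, _, _ in records]
    for i, a in enumerate(ids):
        for j, b in enumerate(ids[: i + 1]):
            A[i, j] = A[j, i] = 2.0 * f(a, b)
    f.cache_clear()
    return A


def random_pedigree_tuples(
    rng: np.random.Generator, n: int, founder_fraction: float = 0.3
) -> list[tuple[str, str | None, str | None]]:
    """Random valid pedigree as (animal, sire, dam) tuples in topological order.

    Parents are drawn among earlier animals (possibly unknown), so cycles
    are impossible by construction; self-matings are allowed only in the
    sense that one animal can appear as both sire and dam of different
    offspring, never of the same one via itself.
    """
    records: list[tuple[str, str | None, str | None]] = []
    for i in range(n):
        name = f"x{i}"
        if i == 0 or rng.random() < founder_fraction:
            records.append((name, None, None))
            continue
        sire = f"x{rng.integers(0, i)}"
        dam = f"x{rng.integers(0, i)}"
        if sire == dam:  # a single known parent instead of an impossible selfing
            dam = None
        records.append((name, sire, dam))
    return records
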