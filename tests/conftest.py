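import numpy as np
import pandas as pd
import pytest

from voleherit import (
    Pedigree,
    PedigreeRecord,
    RelationshipMatrix,
    additive_relationship_matrix,
    generate_colony_pedigree,
)


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree(
        [
            PedigreeRecord("sire", sex="M"),
            PedigreeRecord("dam", sex="F"),
            PedigreeRecord("kid", sire_id="sire", dam_id="dam", sex="M"),
        ]
    )


@pytest.fixture(scope="session")
def family_pedigree() -> Pedigree:
    """Two founder pairs, full sibs, half sibs, and a full-sib mating."""
    return Pedigree(
        [
            PedigreeRecord("s1", sex="M"),
            PedigreeRecord("d1", sex="F"),
            PedigreeRecord("d2", sex="F"),
            PedigreeRecord("fs1", sire_id="s1", dam_id="d1", sex="M"),
            PedigreeRecord("fs2", sire_id="s1", dam_id="d1", sex="F"),
            PedigreeRecord("hs", sire_id="s1", dam_id="d2", sex="M"),
            PedigreeRecord("inbred", sire_id="fs1", dam_id="fs2", sex="M"),
        ]
    )


@pytest.fixture(scope="session")
def small_colony() -> Pedigree:
    """Three founder blocks, two bred generations (96 animals)."""
    return generate_colony_pedigree(n_founder_blocks=3, n_generations=2, litter_size=5)


@pytest.fixture(scope="session")
def small_colony_A(small_colony) -> RelationshipMatrix:
    return additive_relationship_matrix(small_colony)


@pytest.fixture(scope="session")
def identity_relationship():
    def make(n: int, prefix: str = "a") -> RelationshipMatrix:
        ids = tuple(f"{prefix}{i}" for i in range(n))
        return RelationshipMatrix(ids, np.eye(n))

    return make


@pytest.fixture()
def behaviour_table() -> pd.DataFrame:
    """Deterministic paired before/after table for three behaviours, 6 animals."""
    rng = np.random.default_rng(42)
    rows = []
    for assay, behaviour, mu_b, mu_a in [
        ("open_field", "centre", 120.0, 115.0),
        ("resident_intruder", "aggressive", 8.0, 28.0),
        ("alloparental", "licking_grooming", 38.0, 30.0),
    ]:
        for i in range(6):
            rows.append((f"v{i}", assay, behaviour, "before", mu_b + rng.normal(0, 5)))
            rows.append((f"v{i}", assay, behaviour, "after", mu_a + rng.normal(0, 5)))
    return pd.DataFrame(rows, columns=["animal", "assay", "behaviour", "phase", "value"])
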