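"""Shared fixtures: closed-form pedigrees and a random-pedigree factory."""

from __future__ import annotations

import numpy as np
import pytest

from pedloop.pedigree import AnimalRecord, validate_and_order
from pedloop.simulate import reference_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The four closed-form pedigrees (full-sib, half-sib, parent-offspring, chain)."""
    return reference_fixtures()


def make_random_pedigree(rng, n_founders=6, n=40, missing_rate=0.1):
    """Random acyclic pedigree: each non-founder draws parents from earlier animals."""
    recs = [
        AnimalRecord(id=f"F{i:03d}", sex="male" if i % 2 == 0 else "female")
        for i in range(n_founders)
    ]
    males = [r.id for r in recs if r.sex == "male"]
    females = [r.id for r in recs if r.sex == "female"]
    for k in range(n - n_founders):
        sire = males[rng.integers(len(males))] if rng.random() > missing_rate else None
        dam = females[rng.integers(len(females))] if rng.random() > missing_rate else None
        sex = "male" if rng.random() < 0.5 else "female"
        rid = f"A{k:03d}"
        recs.append(AnimalRecord(id=rid, sire=sire, dam=dam, sex=sex))
        (males if sex == "male" else females).append(rid)
    return validate_and_order(recs)


@pytest.fixture()
def random_pedigree_factory():
    return make_random_pedigree


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
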