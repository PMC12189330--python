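"""Synthetic structured pedigrees with regions, migration and inbreeding loops.

The generator emulates the demographic features a regional herdbook of an
endangered cattle breed presents to the decomposition pipeline: several
geographic subpopulations founded on region-specific pools, limited
exchange of sires between regions (the transhumance signal), occasional
deliberate matings between relatives that create inbreeding loops, and
incomplete parentage records in the earliest generations.  Generations
are discrete and non-overlapping, which keeps closed-form checks of the
decomposition possible.

Everything is a pure function of the :class:`SimulationConfig`, seed
included, so the same configuration always produces a byte-identical
pedigree CSV.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from pedloop.pedigree import AnimalRecord, Pedigree, PedigreeError, validate_and_order


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the structured-pedigree generator.

    ``migration_rate`` is the per-mating probability that a dam is mated
    to an out-of-region sire; ``loop_intensity`` the probability that a
    mating deliberately pairs relatives (full/half sibs when available);
    ``unknown_parent_rate`` the probability that a first-generation
    animal's parent link is masked, emulating incomplete early records.
    """

    seed: int
    n_regions: int = 3
    founders_per_region: int = 30
    n_generations: int = 7
    municipalities_per_region: int = 3
    mean_offspring_per_mating: float = 2.0
    migration_rate: float = 0.15
    loop_intensity: float = 0.10
    unknown_parent_rate: float = 0.10
    base_year: int = 1994
    # optional per-region override of migration_rate (dam takes an
    # out-of-region sire), e.g. (0.0, 0.3, 0.3) isolates the first region
    migration_rates: tuple[float, ...] | None = None
    # optional per-region founder pool sizes (unequal nuclei); overrides
    # founders_per_region when given
    founders_by_region: tuple[int, ...] | None = None

    def __post_init__(self):
        for name in ("migration_rate", "loop_intensity", "unknown_parent_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.migration_rates is not None:
            object.__setattr__(self, "migration_rates", tuple(self.migration_rates))
            if len(self.migration_rates) != self.n_regions:
                raise ValueError("migration_rates must list one rate per region")
            if any(not (0.0 <= v <= 1.0) for v in self.migration_rates):
                raise ValueError("migration_rates must be in [0, 1]")
        if self.founders_by_region is not None:
            object.__setattr__(
                self, "founders_by_region", tuple(self.founders_by_region)
            )
            if len(self.founders_by_region) != self.n_regions:
                raise ValueError("founders_by_region must list one count per region")
            if any(v < 2 for v in self.founders_by_region):
                raise ValueError("each region needs at least two founders")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.founders_per_region < 2:
            raise ValueError("need at least two founders per region")
        if self.mean_offspring_per_mating < 1.0:
            raise ValueError("mean_offspring_per_mating must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _region_name(r: int) -> str:
    return f"R{r + 1}"


def generate_structured_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a multi-region pedigree under the given configuration.

    Region labels go to the ``province`` field and nested sub-region
    labels to ``municipality``; generation numbers are encoded in the
    animal ids (``R1-G3-007``).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    regions = [_region_name(r) for r in range(config.n_regions)]
    munis = {
        r: [f"{r}-M{m + 1}" for m in range(config.municipalities_per_region)]
        for r in regions
    }
    records: list[AnimalRecord] = []
    # animals per (generation, region): list of (id, sex, municipality, sire, dam)
    current: dict[str, list[AnimalRecord]] = {}
    for ri, r in enumerate(regions):
        n_founders = (
            config.founders_by_region[ri]
            if config.founders_by_region is not None
            else config.founders_per_region
        )
        cohort = []
        for k in range(n_founders):
            rec = AnimalRecord(
                id=f"{r}-G0-{k + 1:03d}",
                sex="male" if k % 2 == 0 else "female",
                birth_date=_dt.date(config.base_year, 1, 1),
                municipality=munis[r][k % len(munis[r])],
                province=r,
                alive=False,
            )
            cohort.append(rec)
        current[r] = cohort
        records.extend(cohort)

    parent_of = {rec.id: (None, None) for cohort in current.values() for rec in cohort}

    for gen in range(1, config.n_generations + 1):
        new: dict[str, list[AnimalRecord]] = {r: [] for r in regions}
        males = {r: [a for a in current[r] if a.sex == "male"] for r in regions}
        for r in regions:
            dams = [a for a in current[r] if a.sex == "female"]
            if not dams:
                raise PedigreeError(f"no dams available in region {r} at generation {gen}")
            rate_r = (
                config.migration_rates[regions.index(r)]
                if config.migration_rates is not None
                else config.migration_rate
            )
            if not males[r] and rate_r == 0.0:
                raise PedigreeError(
                    f"no sires available in region {r} at generation {gen} "
                    "and migration is disabled"
                )
            counter = 0
            for dam in dams:
                sire = _choose_sire(
                    dam, r, regions, males, parent_of, config, rng
                )
                if sire is None:
                    continue
                n_off = 1 + rng.poisson(config.mean_offspring_per_mating - 1.0)
                for _ in range(n_off):
                    counter += 1
                    muni = (
                        dam.municipality
                        if rng.random() < 0.8
                        else munis[r][rng.integers(len(munis[r]))]
                    )
                    sire_id, dam_id = sire.id, dam.id
                    if gen == 1:
                        if rng.random() < config.unknown_parent_rate:
                            sire_id = None
                        if rng.random() < config.unknown_parent_rate:
                            dam_id = None
                    rec = AnimalRecord(
                        id=f"{r}-G{gen}-{counter:03d}",
                        sire=sire_id,
                        dam=dam_id,
                        sex="male" if counter % 2 == 1 else "female",
                        birth_date=_dt.date(config.base_year + gen, 1, 1),
                        municipality=muni,
                        province=r,
                        alive=gen >= config.n_generations - 1,
                    )
                    parent_of[rec.id] = (sire.id, dam.id)  # true parents, for loops
                    new[r].append(rec)
                    records.append(rec)
        current = new
    return validate_and_order(records)


def _choose_sire(dam, region, regions, males, parent_of, config, rng):
    """Pick a sire for a dam: relative, migrant, or random in-region male."""
    u = rng.random()
    pool = males[region]
    migration = (
        config.migration_rates[regions.index(region)]
        if config.migration_rates is not None
        else config.migration_rate
    )
    if u < config.loop_intensity and pool:
        dsire, ddam = parent_of.get(dam.id, (None, None))
        full_sibs, half_sibs = [], []
        for m in pool:
            if m.id == dam.id:
                continue
            msire, mdam = parent_of.get(m.id, (None, None))
            shared = sum(
                1
                for a, b in ((dsire, msire), (ddam, mdam))
                if a is not None and a == b
            )
            if shared == 2:
                full_sibs.append(m)
            elif shared == 1:
                half_sibs.append(m)
        relatives = full_sibs or half_sibs  # prefer the tighter loop
        if relatives:
            return relatives[rng.integers(len(relatives))]
    if config.loop_intensity <= u < config.loop_intensity + migration and len(regions) > 1:
        others = [r for r in regions if r != region and males[r]]
        if others:
            r2 = others[rng.integers(len(others))]
            return males[r2][rng.integers(len(males[r2]))]
    if pool:
        return pool[rng.integers(len(pool))]
    # fall back to any region with males
    others = [r for r in regions if males[r]]
    if not others:
        return None
    r2 = others[rng.integers(len(others))]
    return males[r2][rng.integers(len(males[r2]))]


def _ancestors_at_depth(pedigree: Pedigree, pos: int, depth: int) -> set[int]:
    """Positions of ancestors exactly ``depth`` generations above ``pos``."""
    frontier = {pos}
    for _ in range(depth):
        nxt = set()
        for p in frontier:
            for q in (pedigree.sire_idx[p], pedigree.dam_idx[p]):
                if q >= 0:
                    nxt.add(int(q))
        frontier = nxt
    return frontier


def inject_inbreeding_loops(
    pedigree: Pedigree,
    focal_region: str,
    depth: int,
    count: int,
    seed: int,
) -> Pedigree:
    """Append ``count`` matings whose parents share an ancestor ``depth``
    generations back, closing new inbreeding loops in ``focal_region``.

    The shared ancestors become nodal common ancestors of the new
    offspring by construction.  With ``count = 0`` the pedigree is
    returned unchanged.
    """
    if count == 0:
        return pedigree
    rng = np.random.default_rng(seed)
    males = [
        (i, r)
        for i, r in enumerate(pedigree.records)
        if r.sex == "male" and r.province == focal_region
    ]
    females = [
        (i, r)
        for i, r in enumerate(pedigree.records)
        if r.sex == "female" and r.province == focal_region
    ]
    if not males or not females:
        raise PedigreeError(f"region {focal_region!r} lacks breeding candidates")
    eligible = []
    for mi, mrec in males:
        anc_m = _ancestors_at_depth(pedigree, mi, depth)
        if not anc_m:
            continue
        for fi, frec in females:
            if anc_m & _ancestors_at_depth(pedigree, fi, depth):
                eligible.append((mrec, frec))
    if not eligible:
        raise PedigreeError(
            f"no pairs sharing an ancestor {depth} generations back in "
            f"{focal_region!r}"
        )
    records = list(pedigree.records)
    latest = max(
        (r.birth_date for r in pedigree.records if r.birth_date is not None),
        default=_dt.date(2000, 1, 1),
    )
    for k in range(count):
        sire, dam = eligible[rng.integers(len(eligible))]
        records.append(
            AnimalRecord(
                id=f"LOOP-{focal_region}-{k + 1:03d}",
                sire=sire.id,
                dam=dam.id,
                sex="male" if k % 2 == 0 else "female",
                birth_date=_dt.date(latest.year + 1, 1, 1),
                municipality=dam.municipality,
                province=focal_region,
                alive=True,
            )
        )
    return validate_and_order(records)


def reference_fixtures() -> dict[str, Pedigree]:
    """Tiny pedigrees with closed-form inbreeding and loop structure.

    * ``full_sib`` — founders A, B; S = A x B; D = A x B; X = S x D.
      F_X = 1/4; nodal common ancestors of X: {A, B}.
    * ``half_sib`` — founders A, B, C; S = A x B; D = A x C; X = S x D.
      F_X = 1/8; NCAs: {A}.
    * ``parent_offspring`` — founders A, B; D = A x B; X = A x D.
      F_X = 1/4; NCAs: {A}.
    * ``chain`` — founders A, B, C, E; M = A x B; S = M x C; D = M x E;
      X = S x D.  F_X = 1/8; common ancestors {M, A, B} but only M keeps a
      marginal (nodal) contribution: u = {M: 1/8}, pushed to founders as
      v = {A: 1/16, B: 1/16}.
    """

    def rec(id, sire=None, dam=None, sex="unknown", year=2000):
        return AnimalRecord(
            id=id,
            sire=sire,
            dam=dam,
            sex=sex,
            birth_date=_dt.date(year, 1, 1),
            municipality="R1-M1",
            province="R1",
            alive=True,
        )

    full_sib = validate_and_order(
        [
            rec("A", sex="male"),
            rec("B", sex="female"),
            rec("S", "A", "B", "male", 2002),
            rec("D", "A", "B", "female", 2002),
            rec("X", "S", "D", "male", 2004),
        ]
    )
    half_sib = validate_and_order(
        [
            rec("A", sex="male"),
            rec("B", sex="female"),
            rec("C", sex="female"),
            rec("S", "A", "B", "male", 2002),
            rec("D", "A", "C", "female", 2002),
            rec("X", "S", "D", "male", 2004),
        ]
    )
    parent_offspring = validate_and_order(
        [
            rec("A", sex="male"),
            rec("B", sex="female"),
            rec("D", "A", "B", "female", 2002),
            rec("X", "A", "D", "male", 2004),
        ]
    )
    chain = validate_and_order(
        [
            rec("A", sex="male"),
            rec("B", sex="female"),
            rec("C", sex="female"),
            rec("E", sex="female"),
            rec("M", "A", "B", "male", 2002),
            rec("S", "M", "C", "male", 2004),
            rec("D", "M", "E", "female", 2004),
            rec("X", "S", "D", "male", 2006),
        ]
    )
    return {
        "full_sib": full_sib,
        "half_sib": half_sib,
        "parent_offspring": parent_offspring,
        "chain": chain,
    }
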