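"""Pedigree reading, validation, topological ordering and subsetting.

A :class:`Pedigree` is an ordered collection of :class:`AnimalRecord`
objects in which every parent precedes its offspring.  All downstream
algebra (inbreeding, Mendelian sampling variances, indirect
relationship-vector products) relies on that ordering, so construction
always goes through :func:`validate_and_order`.

Unknown parents are represented by ``None`` in memory and by a
configurable sentinel set (``"", "0", "NA", "UNKNOWN"`` by default) in CSV
files.  Parents referenced but never declared are materialized as founder
stubs and flagged, so that contribution decompositions conserve their
totals over an explicit founder set.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN = None

DEFAULT_UNKNOWN_TOKENS = frozenset({"", "0", "NA", "UNKNOWN", "NAN", "NONE"})

_CSV_COLUMNS = [
    "id",
    "sire",
    "dam",
    "sex",
    "birth_date",
    "municipality",
    "province",
    "alive",
]


class PedigreeError(ValueError):
    """Structural pedigree problem (duplicate id, cycle, unknown id)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One pedigree entry.

    ``sire``/``dam`` are ``None`` when unknown.  ``sex`` is one of
    ``male``/``female``/``unknown``.  ``alive`` is ``None`` when the flag
    was absent from the source file.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    birth_date: _dt.date | None = None
    municipality: str | None = None
    province: str | None = None
    alive: bool | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be a non-empty token")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"animal {self.id!r} lists itself as a parent")


@dataclass(frozen=True)
class PopulationSubset:
    """A named set of animal ids selected by :func:`subset_population`."""

    name: str
    member_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.member_ids)


class Pedigree:
    """Topologically ordered pedigree with integer parent indices.

    Do not call the constructor with unordered records; use
    :func:`validate_and_order` (or :func:`read_pedigree`), which certify
    acyclicity and parent-before-offspring ordering.
    """

    def __init__(self, records: list[AnimalRecord], warnings_: list[str] | None = None):
        self.records: list[AnimalRecord] = list(records)
        self.index: dict[str, int] = {r.id: i for i, r in enumerate(self.records)}
        if len(self.index) != len(self.records):
            raise PedigreeError("duplicate animal ids in pedigree")
        n = len(self.records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire is not None:
                j = self.index.get(r.sire)
                if j is None:
                    raise PedigreeError(f"sire {r.sire!r} of {r.id!r} not in pedigree")
                if j >= i:
                    raise PedigreeError("pedigree is not parent-before-offspring ordered")
                self.sire_idx[i] = j
            if r.dam is not None:
                j = self.index.get(r.dam)
                if j is None:
                    raise PedigreeError(f"dam {r.dam!r} of {r.id!r} not in pedigree")
                if j >= i:
                    raise PedigreeError("pedigree is not parent-before-offspring ordered")
                self.dam_idx[i] = j
        self.warnings: list[str] = list(warnings_ or [])

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.index

    def __getitem__(self, animal_id: str) -> AnimalRecord:
        return self.records[self.position(animal_id)]

    def position(self, animal_id: str) -> int:
        try:
            return self.index[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def founders(self) -> list[str]:
        """Ids of animals with both parents unknown."""
        return [
            r.id
            for i, r in enumerate(self.records)
            if self.sire_idx[i] < 0 and self.dam_idx[i] < 0
        ]

    def parents(self, animal_id: str) -> tuple[str | None, str | None]:
        r = self[animal_id]
        return r.sire, r.dam

    def ancestor_positions(self, pos: int, include_self: bool = False) -> set[int]:
        """All ancestor positions of ``pos`` (optionally including it)."""
        out: set[int] = {pos} if include_self else set()
        stack = [pos]
        seen = {pos}
        while stack:
            p = stack.pop()
            for q in (self.sire_idx[p], self.dam_idx[p]):
                if q >= 0 and q not in seen:
                    seen.add(q)
                    out.add(q)
                    stack.append(q)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Record table in the canonical CSV column layout."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "sire": r.sire if r.sire is not None else "",
                    "dam": r.dam if r.dam is not None else "",
                    "sex": r.sex,
                    "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                    "municipality": r.municipality or "",
                    "province": r.province or "",
                    "alive": "" if r.alive is None else str(bool(r.alive)).lower(),
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _date_key(r: AnimalRecord):
    return (
        r.birth_date is None,
        r.birth_date or _dt.date.min,
        r.id,
    )


def validate_and_order(
    records_or_pedigree: list[AnimalRecord] | Pedigree,
) -> Pedigree:
    """Return a pedigree in stable topological (parent-first) order.

    Ties among simultaneously available animals are broken by birth date
    then id, which makes the ordering a pure function of the record set —
    reordering the input rows cannot change any downstream vector.

    Raises :class:`PedigreeError` with the offending chain if the parent
    graph contains a cycle.
    """
    if isinstance(records_or_pedigree, Pedigree):
        records = records_or_pedigree.records
        warns = list(records_or_pedigree.warnings)
    else:
        records = list(records_or_pedigree)
        warns = []

    by_id: dict[str, AnimalRecord] = {}
    for r in records:
        if r.id in by_id:
            raise PedigreeError(f"duplicate animal id {r.id!r}")
        by_id[r.id] = r

    # Materialize referenced-but-undeclared parents as founder stubs.
    stubs = []
    for r in records:
        for p in (r.sire, r.dam):
            if p is not None and p not in by_id:
                stub = AnimalRecord(id=p)
                by_id[p] = stub
                stubs.append(p)
                warns.append(
                    f"parent {p!r} referenced but not declared; inserted as founder stub"
                )
    records = list(by_id.values())

    graph = nx.DiGraph()
    graph.add_nodes_from(by_id)
    for r in records:
        for p in (r.sire, r.dam):
            if p is not None:
                graph.add_edge(p, r.id)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        chain = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise PedigreeError(f"parentage cycle detected: {chain}")

    order = list(
        nx.lexicographical_topological_sort(graph, key=lambda a: _date_key(by_id[a]))
    )
    ordered = [by_id[a] for a in order]

    # Birth-date sanity: a child must not precede its parents in time.
    for r in ordered:
        if r.birth_date is None:
            continue
        for p in (r.sire, r.dam):
            if p is None:
                continue
            pd_ = by_id[p].birth_date
            if pd_ is not None and r.birth_date < pd_:
                warns.append(
                    f"birth date of {r.id!r} ({r.birth_date}) precedes that of "
                    f"parent {p!r} ({pd_})"
                )
    return Pedigree(ordered, warns)


def _parse_bool(tok: str) -> bool | None:
    t = tok.strip().lower()
    if t in {"1", "true", "t", "yes", "y", "alive"}:
        return True
    if t in {"-1", "false", "f", "no", "n", "dead", "deceased"}:
        return False
    return None


def read_pedigree(
    path,
    dialect: dict[str, str] | None = None,
    unknown_tokens: frozenset[str] | set[str] = DEFAULT_UNKNOWN_TOKENS,
) -> Pedigree:
    """Read a pedigree CSV and return a validated, ordered :class:`Pedigree`.

    Parameters
    ----------
    path
        CSV file with at least id/sire/dam columns.
    dialect
        Mapping from canonical column names (``id``, ``sire``, ``dam``,
        ``sex``, ``birth_date``, ``municipality``, ``province``,
        ``alive``) to the column names actually present in the file.
    unknown_tokens
        Case-insensitive sentinel tokens normalized to an unknown parent.
    """
    dialect = dialect or {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    colmap = {canon: dialect.get(canon, canon) for canon in _CSV_COLUMNS}
    for required in ("id", "sire", "dam"):
        if colmap[required] not in df.columns:
            raise PedigreeError(
                f"mandatory column {colmap[required]!r} missing from {path}"
            )
    tokens_upper = {t.upper() for t in unknown_tokens}

    def norm_parent(tok: str) -> str | None:
        tok = tok.strip()
        return None if tok.upper() in tokens_upper else tok

    records = []
    for _, row in df.iterrows():
        get = lambda canon: (
            str(row[colmap[canon]]).strip() if colmap[canon] in df.columns else ""
        )
        birth = get("birth_date")
        birth_date = None
        if birth:
            try:
                birth_date = _dt.date.fromisoformat(birth)
            except ValueError:
                warnings.warn(
                    f"unparseable birth date {birth!r} for animal {get('id')!r}; "
                    "treated as missing",
                    stacklevel=2,
                )
        sex = get("sex").lower() or "unknown"
        if sex not in {"male", "female", "unknown"}:
            sex = {"m": "male", "f": "female", "bull": "male", "cow": "female"}.get(
                sex, "unknown"
            )
        records.append(
            AnimalRecord(
                id=get("id"),
                sire=norm_parent(get("sire")),
                dam=norm_parent(get("dam")),
                sex=sex,
                birth_date=birth_date,
                municipality=get("municipality") or None,
                province=get("province") or None,
                alive=_parse_bool(get("alive")) if get("alive") else None,
            )
        )
    return validate_and_order(records)


def write_pedigree(pedigree: Pedigree, path, header_comment: str | None = None) -> None:
    """Write the canonical pedigree CSV (round-trips with :func:`read_pedigree`)."""
    frame = pedigree.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def equivalent_complete_generations(
    pedigree: Pedigree, animal_id: str | None = None
) -> float | np.ndarray:
    """Equivalent complete generations t = sum over known ancestors of (1/2)^depth.

    Computed by the recursion ``t_i = 1/2 (1 + t_sire) + 1/2 (1 + t_dam)``
    with missing-parent terms contributing zero; founders have ``t = 0``.
    With ``animal_id=None`` the full per-animal vector (pedigree order) is
    returned.
    """
    n = len(pedigree)
    t = np.zeros(n)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        acc = 0.0
        if s[i] >= 0:
            acc += 0.5 * (1.0 + t[s[i]])
        if d[i] >= 0:
            acc += 0.5 * (1.0 + t[d[i]])
        t[i] = acc
    if animal_id is None:
        return t
    return float(t[pedigree.position(animal_id)])


def subset_population(
    pedigree: Pedigree,
    name: str,
    alive: bool | None = None,
    birth_window: tuple[_dt.date | None, _dt.date | None] | None = None,
    both_parents_known: bool = False,
) -> PopulationSubset:
    """Select animals by the conjunction of the given criteria.

    ``alive`` matches the record flag exactly (records without the flag
    never match); ``birth_window`` is an inclusive ``(start, end)`` date
    range, either bound optional; ``both_parents_known`` keeps animals
    whose sire and dam are both recorded.  An empty result warns rather
    than fails.
    """
    members = []
    for i, r in enumerate(pedigree.records):
        if alive is not None and r.alive is not alive:
            continue
        if birth_window is not None:
            start, end = birth_window
            if r.birth_date is None:
                continue
            if start is not None and r.birth_date < start:
                continue
            if end is not None and r.birth_date > end:
                continue
        if both_parents_known and (pedigree.sire_idx[i] < 0 or pedigree.dam_idx[i] < 0):
            continue
        members.append(r.id)
    if not members:
        warnings.warn(f"subset {name!r} is empty under the given rules", stacklevel=2)
    return PopulationSubset(name=name, member_ids=frozenset(members))


def rewire_parents(
    pedigree: Pedigree, animal_id: str, sire: str | None, dam: str | None
) -> Pedigree:
    """Return a new pedigree with ``animal_id``'s parent links replaced."""
    pos = pedigree.position(animal_id)
    records = list(pedigree.records)
    records[pos] = replace(records[pos], sire=sire, dam=dam)
    return validate_and_order(records)
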