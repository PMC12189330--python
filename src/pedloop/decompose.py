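"""Decomposition of inbreeding and coancestry into ancestral components.

Three nested representations of the same mass are produced:

``m`` — MSV contributions: the share of the target statistic (an
individual F, a group mean F, or a group mean coancestry) injected by the
Mendelian sampling variance of each ancestor, ``m_k = b_k c_k(s) c_k(d)``
with ``c`` the expected gene proportions along the pedigree.

``u`` — nodal-common-ancestor (NCA) contributions: the marginal share of
each ancestor at which an inbreeding loop actually closes.  An NCA is an
ancestor appearing on both the paternal and maternal side; when a younger
NCA sits below an older one on all connecting paths, the younger captures
the mass and the older is left with only its marginal share.  ``u`` is
computed by propagating labeled gene pairs up the pedigree and attributing
each pair to the vertex where the two lineages first coincide, which
reproduces Wright's path-counting attribution without enumerating paths.

``v`` — founder contributions: ``u`` pushed back to the founder pool
through expected gene proportions (``v = T' u``).  Animals with a missing
parent retain the unrecorded half themselves, so totals are conserved.

All three conserve the target statistic to numerical precision, which the
test suite asserts at 1e-10.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedloop.pedigree import Pedigree, PedigreeError, PopulationSubset
from pedloop.relationship import (
    compute_inbreeding,
    contribution_accumulation,
    mendelian_sampling_variances,
)

RELATIONSHIP = "relationship"
COANCESTRY = "coancestry"

_TARGETS = {"individual_F", "group_mean_F", "group_mean_coancestry"}


def _weights_series(pedigree: Pedigree, values: np.ndarray, drop_zero=True) -> pd.Series:
    ser = pd.Series(values, index=pedigree.ids, dtype=float)
    if drop_zero:
        ser = ser[ser != 0.0]
    return ser


@dataclass(frozen=True)
class ContributionVector:
    """Per-ancestor weights that conserve a target statistic."""

    target: str
    scale: str
    weights: pd.Series

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.scale not in (RELATIONSHIP, COANCESTRY):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def on_scale(self, scale: str) -> "ContributionVector":
        if scale == self.scale:
            return self
        factor = 2.0 if scale == RELATIONSHIP else 0.5
        return ContributionVector(self.target, scale, self.weights * factor)


@dataclass(frozen=True)
class NCAContribution:
    """Marginal contributions of nodal common ancestors."""

    target: str
    scale: str
    ncas: frozenset[str]
    weights: pd.Series

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def on_scale(self, scale: str) -> "NCAContribution":
        if scale == self.scale:
            return self
        factor = 2.0 if scale == RELATIONSHIP else 0.5
        return NCAContribution(self.target, scale, self.ncas, self.weights * factor)


@dataclass(frozen=True)
class FounderContribution:
    """Founder contributions ``v = T' u`` plus the gene-proportion matrix T.

    ``T`` has one row per founder-like source (true founders plus animals
    retaining an unrecorded-parent fraction) and one column per NCA; the
    entry is the expected gene proportion of that source in the NCA.
    """

    target: str
    scale: str
    v: pd.Series
    T: pd.DataFrame

    @property
    def total(self) -> float:
        return float(self.v.sum())


# ---------------------------------------------------------------------------
# genetic contributions and MSV decompositions
# ---------------------------------------------------------------------------


def genetic_contribution_vector(pedigree: Pedigree, animal_id: str) -> np.ndarray:
    """Expected gene proportion of every ancestor in ``animal_id``.

    Entry at the focal animal is 1; each ancestor receives half the value
    of each of its offspring on the paths down to the focal animal (the
    focal row of ``U^-1``).
    """
    x = np.zeros(len(pedigree))
    x[pedigree.position(animal_id)] = 1.0
    return contribution_accumulation(pedigree, x)


def _resolve_b(pedigree: Pedigree, b: np.ndarray | None) -> np.ndarray:
    if b is None:
        return mendelian_sampling_variances(pedigree, compute_inbreeding(pedigree))
    return np.asarray(b, dtype=float)


def msv_decomposition_individual(
    pedigree: Pedigree,
    b: np.ndarray | None,
    animal_id: str,
    scale: str = COANCESTRY,
) -> ContributionVector:
    """MSV contributions of ancestors to one animal's inbreeding.

    ``m_k = b_k c_k(sire) c_k(dam)`` on the relationship scale; halved on
    the coancestry scale where the total equals F of the animal.  Animals
    with an unknown parent have F = 0 and an empty vector.
    """
    b = _resolve_b(pedigree, b)
    pos = pedigree.position(animal_id)
    si, di = pedigree.sire_idx[pos], pedigree.dam_idx[pos]
    if si < 0 or di < 0:
        empty = pd.Series(dtype=float)
        return ContributionVector("individual_F", scale, empty)
    xs = np.zeros(len(pedigree))
    xs[si] = 1.0
    xd = np.zeros(len(pedigree))
    xd[di] = 1.0
    m = b * contribution_accumulation(pedigree, xs) * contribution_accumulation(
        pedigree, xd
    )
    if scale == COANCESTRY:
        m = m / 2.0
    return ContributionVector("individual_F", scale, _weights_series(pedigree, m))


def _group_positions(pedigree: Pedigree, group) -> list[int]:
    if isinstance(group, PopulationSubset):
        group = group.member_ids
    ids = sorted(group)
    if not ids:
        raise PedigreeError("group is empty")
    return [pedigree.position(a) for a in ids]


def msv_decomposition_group(
    pedigree: Pedigree,
    b: np.ndarray | None,
    group,
    target: str = "mean_coancestry",
    scale: str = COANCESTRY,
) -> ContributionVector:
    """MSV contributions to a group's mean F or mean coancestry.

    For ``mean_F`` the individual decompositions are averaged via paired
    sire/dam accumulation passes.  For ``mean_coancestry`` a single pass
    yields the mean group contribution ``cbar_k`` of every ancestor and
    ``m_k = b_k cbar_k^2``, whose relationship-scale total is
    ``x'Ax / n^2`` for the group indicator x.
    """
    b = _resolve_b(pedigree, b)
    positions = _group_positions(pedigree, group)
    n = len(positions)
    npop = len(pedigree)
    if target == "mean_coancestry":
        x = np.zeros(npop)
        for p in positions:
            x[p] += 1.0 / n
        cbar = contribution_accumulation(pedigree, x)
        m = b * cbar * cbar
    elif target == "mean_F":
        m = np.zeros(npop)
        for p in positions:
            si, di = pedigree.sire_idx[p], pedigree.dam_idx[p]
            if si < 0 or di < 0:
                continue
            xs = np.zeros(npop)
            xs[si] = 1.0
            xd = np.zeros(npop)
            xd[di] = 1.0
            m += (
                b
                * contribution_accumulation(pedigree, xs)
                * contribution_accumulation(pedigree, xd)
            )
        m /= n
    else:
        raise ValueError(f"unknown group target {target!r}")
    if scale == COANCESTRY:
        m = m / 2.0
    return ContributionVector(f"group_{target}", scale, _weights_series(pedigree, m))


# ---------------------------------------------------------------------------
# nodal common ancestors
# ---------------------------------------------------------------------------


def find_nodal_common_ancestors(pedigree: Pedigree, animal_id: str) -> frozenset[str]:
    """Ancestors on both the paternal and maternal side of an animal.

    Each side includes the parent itself.  Empty when either parent is
    unknown (no loop can close).
    """
    pos = pedigree.position(animal_id)
    si, di = pedigree.sire_idx[pos], pedigree.dam_idx[pos]
    if si < 0 or di < 0:
        return frozenset()
    sire_side = pedigree.ancestor_positions(si, include_self=True)
    dam_side = pedigree.ancestor_positions(di, include_self=True)
    return frozenset(pedigree.records[p].id for p in sire_side & dam_side)


def _propagate_pairs(
    pedigree: Pedigree,
    pairs: dict[tuple[int, int], float],
    mode: str,
    F: np.ndarray | None = None,
    b: np.ndarray | None = None,
    max_table: int = 20_000_000,
) -> np.ndarray:
    """Upward propagation of weighted gene pairs.

    Pairs are keyed by sorted position tuples.  At each step the younger
    member of a pair is replaced by its parents at half weight; weight
    routed to an unknown parent vanishes (it cannot close a loop).  When
    the two lineages coincide at an animal ``a``:

    * ``mode='nca'``: the full pair relationship ``1 + F_a`` is attributed
      to ``a`` and the pair stops — first-coalescence attribution, which
      reproduces Wright's apex attribution of non-self-intersecting loops;
    * ``mode='msv'``: the MSV ``b_a`` is attributed to ``a`` and the
      remaining mass continues to the parent pairs with quarter weights,
      yielding the MSV decomposition.

    Returns per-animal attributed weight on the relationship scale; the
    grand total equals the weighted sum of pair relationships exactly.
    """
    n = len(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    buckets: dict[int, dict[int, float]] = defaultdict(dict)
    processed = 0

    def add(i: int, j: int, w: float) -> None:
        if i > j:
            i, j = j, i
        bucket = buckets[j]
        bucket[i] = bucket.get(i, 0.0) + w

    for (i, j), w in pairs.items():
        add(i, j, w)
    contrib = np.zeros(n)
    for p in range(n - 1, -1, -1):
        bucket = buckets.pop(p, None)
        if not bucket:
            continue
        processed += len(bucket)
        if processed > max_table:
            raise PedigreeError(
                "gene-pair table exceeded the memory cap; use the MSV "
                "decomposition route for this group"
            )
        sp, dp = s[p], d[p]
        for q, w in bucket.items():
            if q == p:
                if mode == "nca":
                    contrib[p] += w * (1.0 + F[p])
                else:
                    contrib[p] += w * b[p]
                    if sp >= 0:
                        add(sp, sp, 0.25 * w)
                    if dp >= 0:
                        add(dp, dp, 0.25 * w)
                    if sp >= 0 and dp >= 0:
                        add(sp, dp, 0.5 * w)
            else:
                if sp >= 0:
                    add(q, sp, 0.5 * w)
                if dp >= 0:
                    add(q, dp, 0.5 * w)
    return contrib


def nca_contributions(
    pedigree: Pedigree,
    m: ContributionVector | None,
    animal_id: str,
    F: np.ndarray | None = None,
    scale: str = COANCESTRY,
    tol: float = 1e-8,
) -> NCAContribution:
    """Marginal NCA contributions ``u`` to one animal's inbreeding.

    Aggregates the MSV mass of every ancestor into the nearest descendant
    NCA on its loops, implemented as first-coalescence attribution of the
    sire/dam gene pair.  When the MSV vector ``m`` is supplied its total
    is checked against ``u`` (both conserve F of the animal).
    """
    if F is None:
        F = compute_inbreeding(pedigree)
    pos = pedigree.position(animal_id)
    si, di = pedigree.sire_idx[pos], pedigree.dam_idx[pos]
    ncas = find_nodal_common_ancestors(pedigree, animal_id)
    if si < 0 or di < 0:
        return NCAContribution("individual_F", scale, ncas, pd.Series(dtype=float))
    contrib = _propagate_pairs(pedigree, {(min(si, di), max(si, di)): 1.0}, "nca", F=F)
    if scale == COANCESTRY:
        contrib = contrib / 2.0
    weights = _weights_series(pedigree, contrib)
    if not set(weights.index) <= set(ncas):
        raise PedigreeError("loop mass attributed outside the NCA set")
    u = NCAContribution("individual_F", scale, ncas, weights)
    if m is not None:
        expected = m.on_scale(scale).total
        if abs(u.total - expected) > tol:
            raise PedigreeError(
                f"NCA total {u.total} inconsistent with MSV total {expected}"
            )
    return u


def _group_pairs(
    pedigree: Pedigree, group, target: str
) -> dict[tuple[int, int], float]:
    positions = _group_positions(pedigree, group)
    n = len(positions)
    pairs: dict[tuple[int, int], float] = defaultdict(float)
    if target == "mean_F":
        for p in positions:
            si, di = pedigree.sire_idx[p], pedigree.dam_idx[p]
            if si < 0 or di < 0:
                continue
            pairs[(min(si, di), max(si, di))] += 1.0 / n
    elif target == "mean_coancestry":
        w_off = 2.0 / n**2
        for i, pi in enumerate(positions):
            pairs[(pi, pi)] += 1.0 / n**2
            for pj in positions[i + 1 :]:
                pairs[(min(pi, pj), max(pi, pj))] += w_off
    else:
        raise ValueError(f"unknown group target {target!r}")
    return dict(pairs)


def nca_contributions_group(
    pedigree: Pedigree,
    group,
    target: str = "mean_coancestry",
    F: np.ndarray | None = None,
    scale: str = COANCESTRY,
) -> NCAContribution:
    """Marginal NCA contributions to a group mean F or mean coancestry.

    Per-ancestor weights are summed over all contributing members (for
    mean F) or member pairs (for mean coancestry, self-pairs included, in
    which case coalescence at a group member itself attributes to that
    member).
    """
    if F is None:
        F = compute_inbreeding(pedigree)
    pairs = _group_pairs(pedigree, group, target)
    contrib = _propagate_pairs(pedigree, pairs, "nca", F=F)
    if scale == COANCESTRY:
        contrib = contrib / 2.0
    weights = _weights_series(pedigree, contrib)
    return NCAContribution(
        f"group_{target}", scale, frozenset(weights.index), weights
    )


# ---------------------------------------------------------------------------
# founder contributions
# ---------------------------------------------------------------------------


def _push_to_founders(pedigree: Pedigree, w: np.ndarray) -> np.ndarray:
    """Propagate per-animal mass up to founder-like sources.

    Each animal forwards half its mass to each known parent; the share of
    an unrecorded parent stays with the animal itself, so the total is
    conserved over an explicit source set.
    """
    s, d = pedigree.sire_idx, pedigree.dam_idx
    w = np.array(w, dtype=float, copy=True)
    v = np.zeros(len(pedigree))
    for p in range(len(pedigree) - 1, -1, -1):
        wp = w[p]
        if wp == 0.0:
            continue
        sp, dp = s[p], d[p]
        if sp < 0 and dp < 0:
            v[p] += wp
            continue
        for par in (sp, dp):
            if par >= 0:
                w[par] += 0.5 * wp
            else:
                v[p] += 0.5 * wp
    return v


def founder_contributions(
    pedigree: Pedigree, u: NCAContribution
) -> FounderContribution:
    """Founder contributions ``v = T' u`` from NCA contributions.

    ``T`` is built by expectation gene dropping (each animal's founder
    profile is half its sire's plus half its dam's profile; founder stubs
    count as their own founder).  ``sum(v) == sum(u)`` holds exactly.
    """
    n = len(pedigree)
    u_arr = np.zeros(n)
    for aid, w in u.weights.items():
        u_arr[pedigree.position(aid)] = w
    v = _push_to_founders(pedigree, u_arr)
    v_ser = _weights_series(pedigree, v)
    # explicit T restricted to the NCAs carrying weight
    cols = {}
    for aid in u.weights.index:
        e = np.zeros(n)
        e[pedigree.position(aid)] = 1.0
        cols[aid] = _weights_series(pedigree, _push_to_founders(pedigree, e))
    T = pd.DataFrame(cols).fillna(0.0) if cols else pd.DataFrame()
    return FounderContribution(u.target, u.scale, v_ser, T)


# ---------------------------------------------------------------------------
# oracles: Wright path counting and upward exploration
# ---------------------------------------------------------------------------


def _upward_paths(pedigree: Pedigree, start: int, cap: int) -> list[tuple[int, ...]]:
    """All upward parent chains from ``start`` (positions strictly decrease)."""
    s, d = pedigree.sire_idx, pedigree.dam_idx
    out: list[tuple[int, ...]] = []
    stack: list[tuple[int, ...]] = [(start,)]
    while stack:
        path = stack.pop()
        out.append(path)
        if len(out) > cap:
            raise PedigreeError(
                f"path enumeration exceeded cap ({cap}); use the MSV/NCA route"
            )
        node = path[-1]
        for par in sorted(p for p in (s[node], d[node]) if p >= 0):
            stack.append(path + (par,))
    return out


def wright_path_counting(
    pedigree: Pedigree,
    animal_id: str,
    F: np.ndarray | None = None,
    max_paths: int = 1_000_000,
    scale: str = COANCESTRY,
) -> NCAContribution:
    """Wright's path-counting decomposition of one animal's inbreeding.

    Sums ``(1/2)^(n1 + n2 + 1) (1 + F_a)`` over all pairs of upward paths
    from the sire and the dam meeting only at their apex ``a`` (the
    non-self-intersecting loops), grouped by apex.  Intended as a
    small-pedigree oracle: enumeration is capped at ``max_paths``.
    """
    if F is None:
        F = compute_inbreeding(pedigree)
    pos = pedigree.position(animal_id)
    si, di = pedigree.sire_idx[pos], pedigree.dam_idx[pos]
    ncas = find_nodal_common_ancestors(pedigree, animal_id)
    if si < 0 or di < 0:
        return NCAContribution("individual_F", scale, ncas, pd.Series(dtype=float))
    sire_paths = _upward_paths(pedigree, si, max_paths)
    dam_paths = _upward_paths(pedigree, di, max_paths)
    by_apex_d: dict[int, list[tuple[int, ...]]] = defaultdict(list)
    for p2 in dam_paths:
        by_apex_d[p2[-1]].append(p2)
    contrib: dict[int, float] = defaultdict(float)
    for p1 in sire_paths:
        apex = p1[-1]
        set1 = set(p1)
        for p2 in by_apex_d.get(apex, ()):
            if len(set1 & set(p2)) == 1:  # intersect only at the apex
                length = (len(p1) - 1) + (len(p2) - 1) + 1
                contrib[apex] += 0.5**length * (1.0 + F[apex])
    values = np.zeros(len(pedigree))
    for p, w in contrib.items():
        values[p] = w
    if scale == RELATIONSHIP:
        values = values * 2.0
    return NCAContribution(
        "individual_F", scale, ncas, _weights_series(pedigree, values)
    )


def upward_exploration(
    pedigree: Pedigree,
    group,
    target: str = "mean_F",
    b: np.ndarray | None = None,
    scale: str = COANCESTRY,
    max_table: int = 20_000_000,
) -> ContributionVector:
    """MSV decomposition via the gene-pair frequency-table backend.

    Starts from the labeled gene pairs of the group (sire/dam pairs for a
    mean F target, all member pairs for mean coancestry), splits each
    pair's weight half/half to the parents of the younger member, and at
    every coincidence attributes the animal's MSV before continuing with
    quarter weights to the parent pairs.  An independent second backend
    for :func:`msv_decomposition_group`; memory-capped because the table
    can grow quickly on deep pedigrees.
    """
    b = _resolve_b(pedigree, b)
    pairs = _group_pairs(pedigree, group, target)
    contrib = _propagate_pairs(pedigree, pairs, "msv", b=b, max_table=max_table)
    if scale == COANCESTRY:
        contrib = contrib / 2.0
    return ContributionVector(
        f"group_{target}", scale, _weights_series(pedigree, contrib)
    )
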