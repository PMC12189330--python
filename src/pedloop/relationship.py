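"""Core pedigree algebra on the numerator relationship matrix A.

Everything here exploits the factorization ``A = U^-1 B (U^-1)^T`` where
``U`` has 1 on the diagonal and -1/2 linking each animal to each known
parent, and ``B`` is the diagonal matrix of Mendelian sampling variances
(MSVs).  Products ``A x`` therefore cost one upward pedigree pass, one
diagonal scaling and one downward pass — no dense matrix is ever formed,
except by :func:`tabular_relationship_matrix`, the classical recursive
tabular method kept as an exact small-pedigree cross-check.

Scales
------
Relationship scale refers to entries of A (diagonal ``1 + F``); the
coancestry (kinship) scale is exactly half of it.  Functions that can be
read on either scale return both explicitly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from pedloop.pedigree import Pedigree, PedigreeError, PopulationSubset


@dataclass(frozen=True)
class GroupCoancestry:
    """Mean relationship of a group on both scales.

    ``relationship`` is ``x' A x / n^2`` for the group indicator ``x``
    (self-pairs included); ``coancestry`` is half of it.
    """

    relationship: float

    @property
    def coancestry(self) -> float:
        return self.relationship / 2.0


def compute_inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F in pedigree order.

    Uses the Meuwissen & Luo style single pass: for each animal the
    diagonal element ``a_ii = sum_k c_ik^2 b_k`` is accumulated by
    climbing the pedigree from the animal, where ``c_ik`` is the expected
    gene proportion of ancestor k in i and ``b_k`` its MSV.  Animals with
    an unknown parent have ``F = 0``.
    """
    n = len(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    F = np.zeros(n)
    b = np.zeros(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            b[i] = 1.0
        elif si < 0:
            b[i] = 0.75 - 0.25 * F[di]
        elif di < 0:
            b[i] = 0.75 - 0.25 * F[si]
        else:
            b[i] = 0.5 - 0.25 * (F[si] + F[di])
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # climb: contributions of every ancestor of i (including i) to i
        contrib: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = contrib.pop(j, 0.0)
            if cj == 0.0:
                continue
            a_ii += cj * cj * b[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p not in contrib:
                        heapq.heappush(heap, -p)
                        contrib[p] = 0.0
                    contrib[p] += 0.5 * cj
        F[i] = a_ii - 1.0
    return F


def mendelian_sampling_variances(pedigree: Pedigree, F: np.ndarray) -> np.ndarray:
    """Diagonal of B given inbreeding F.

    Founders get 1; one-known-parent animals ``3/4 - F_known/4``; animals
    with both parents known ``1/2 - (F_sire + F_dam)/4``.  With this
    convention ``A = U^-1 B (U^-1)^T`` reconstructs A exactly even for
    incomplete pedigrees.
    """
    n = len(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    b = np.empty(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            b[i] = 1.0
        elif si < 0:
            b[i] = 0.75 - 0.25 * F[di]
        elif di < 0:
            b[i] = 0.75 - 0.25 * F[si]
        else:
            b[i] = 0.5 - 0.25 * (F[si] + F[di])
    return b


def contribution_accumulation(pedigree: Pedigree, x: np.ndarray) -> np.ndarray:
    """Upward pass: solve ``U' w = x``.

    ``w_k = sum_j x_j c_jk`` where ``c_jk`` is the expected gene
    proportion of ancestor k in animal j; for an indicator ``x = e_j``
    this is j's genetic-contribution profile over its ancestors.
    """
    n = len(pedigree)
    if len(x) != n:
        raise ValueError(f"vector length {len(x)} != pedigree size {n}")
    s, d = pedigree.sire_idx, pedigree.dam_idx
    w = np.array(x, dtype=float, copy=True)
    for j in range(n - 1, -1, -1):
        wj = w[j]
        if wj == 0.0:
            continue
        if s[j] >= 0:
            w[s[j]] += 0.5 * wj
        if d[j] >= 0:
            w[d[j]] += 0.5 * wj
    return w


def _downward_pass(pedigree: Pedigree, w: np.ndarray) -> np.ndarray:
    """Solve ``U y = w`` (gene dropping direction)."""
    s, d = pedigree.sire_idx, pedigree.dam_idx
    y = np.array(w, dtype=float, copy=True)
    for j in range(len(pedigree)):
        if s[j] >= 0:
            y[j] += 0.5 * y[s[j]]
        if d[j] >= 0:
            y[j] += 0.5 * y[d[j]]
    return y


def relationship_times_vector(
    pedigree: Pedigree, b: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Indirect product ``A x`` via ``U^-1 B (U^-1)^T x``.

    One upward pass, diagonal scaling by the MSVs ``b``, one downward
    pass.  For an indicator at j, the entry at j of the result is
    ``1 + F_j`` and entry i is the pairwise relationship ``a_ij``.
    """
    n = len(pedigree)
    if len(b) != n:
        raise ValueError(f"MSV vector length {len(b)} != pedigree size {n}")
    w = contribution_accumulation(pedigree, x)
    return _downward_pass(pedigree, w * b)


def tabular_relationship_matrix(pedigree: Pedigree, max_n: int = 2000) -> np.ndarray:
    """Dense A by the recursive tabular method (small-pedigree oracle).

    ``a_ii = 1 + a_{sire,dam}/2``; ``a_ij = (a_{sire_i,j} + a_{dam_i,j})/2``
    for j earlier than i.  Quadratic in memory, so refuse pedigrees larger
    than ``max_n``.
    """
    n = len(pedigree)
    if n > max_n:
        raise PedigreeError(
            f"tabular method limited to {max_n} animals (got {n}); "
            "use relationship_times_vector instead"
        )
    s, d = pedigree.sire_idx, pedigree.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def _group_indicator(pedigree: Pedigree, group) -> np.ndarray:
    if isinstance(group, PopulationSubset):
        group = group.member_ids
    ids = list(group)
    if not ids:
        raise PedigreeError("group is empty")
    x = np.zeros(len(pedigree))
    for a in ids:
        x[pedigree.position(a)] += 1.0
    return x


def group_mean_coancestry(
    pedigree: Pedigree, group, b: np.ndarray | None = None
) -> GroupCoancestry:
    """Mean (self-inclusive) relationship of a group, one indirect pass.

    Returns a :class:`GroupCoancestry` exposing both the relationship
    scale ``x'Ax / n^2`` and the coancestry scale (half of it).
    """
    x = _group_indicator(pedigree, group)
    n_group = x.sum()
    if b is None:
        b = mendelian_sampling_variances(pedigree, compute_inbreeding(pedigree))
    ax = relationship_times_vector(pedigree, b, x)
    return GroupCoancestry(relationship=float(x @ ax) / n_group**2)


def rate_of_coancestry(c_ba: float, t_b: float, t_a: float) -> float:
    """Individual rate of coancestry.

    ``dC = 1 - (1 - C_ba)^(2 / (t_b + t_a))`` where ``t_b``/``t_a`` are
    the equivalent complete generations of the two individuals.  The
    standardization makes coancestries accrued over different pedigree
    depths comparable.
    """
    if not (0.0 <= c_ba < 1.0):
        raise ValueError(f"coancestry must be in [0, 1), got {c_ba}")
    tsum = t_b + t_a
    if tsum <= 0.0:
        if c_ba == 0.0:
            return 0.0
        raise ValueError(
            "rate of coancestry undefined: zero equivalent generations with C > 0"
        )
    return 1.0 - (1.0 - c_ba) ** (2.0 / tsum)


def mean_rate_of_coancestry(
    pedigree: Pedigree, group, t: np.ndarray | None = None, max_n: int = 2000
) -> float:
    """Mean pairwise rate of coancestry over all distinct pairs in a group.

    Convenience wrapper around the pairwise primitive; pairs in which both
    members have zero equivalent generations and zero coancestry
    contribute 0.  Dense in the group size, so capped at ``max_n``.
    """
    from pedloop.pedigree import equivalent_complete_generations

    if isinstance(group, PopulationSubset):
        group = group.member_ids
    ids = sorted(group)
    if len(ids) < 2:
        raise PedigreeError("need at least two animals for a mean pairwise rate")
    if t is None:
        t = equivalent_complete_generations(pedigree)
    A = tabular_relationship_matrix(pedigree, max_n=max_n)
    pos = [pedigree.position(a) for a in ids]
    total = 0.0
    count = 0
    for i, pi in enumerate(pos):
        for pj in pos[i + 1 :]:
            c = 0.5 * A[pi, pj]
            total += rate_of_coancestry(c, t[pi], t[pj])
            count += 1
    return total / count


def nonrandom_mating_alpha(f_bar_inbreeding: float, f_bar_coancestry: float) -> float:
    """Deviation from random mating: ``(1 - F) = (1 - f)(1 - alpha)``.

    ``alpha > 0`` indicates mating between relatives in excess of random
    expectation; ``alpha < 0`` indicates avoidance of related matings.
    """
    if f_bar_coancestry >= 1.0:
        raise ValueError("mean coancestry must be < 1")
    return 1.0 - (1.0 - f_bar_inbreeding) / (1.0 - f_bar_coancestry)
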