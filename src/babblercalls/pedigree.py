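"""Pedigree relatedness and neighbour-group composition profiles.

Relatedness is the additive (numerator) relationship computed from the
pedigree by the tabular method: processing individuals in topological order
(parents before offspring),

    A(i, i) = 1 + 0.5 * A(dam_i, sire_i)
    A(i, j) = 0.5 * (A(j, dam_i) + A(j, sire_i))      for j processed earlier,

with unknown parents contributing 0.  For non-inbred pairs A(i, j) equals
the familiar coefficient of relatedness r (parent-offspring and full sibs
0.5, half sibs and grandparent-grandchild 0.25).

A neighbouring group is classified *related* to a focal caller when at least
one of its current dominants has r >= 0.25 to the caller (inclusive
threshold); a *potential breeding partner* is an unrelated (r < 0.25),
opposite-sex adult (>= 365 days post-hatch) member of a neighbouring group.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Individual, Pedigree, ValidationError

RELATEDNESS_THRESHOLD = 0.25
ADULT_AGE_DAYS = 365


@dataclass(frozen=True)
class NeighbourProfile:
    """Composition of one neighbouring group relative to a focal caller."""

    focal_caller: str
    neighbour_group: str
    related: bool
    n_adults: int
    n_potential_partners: int
    n_same_sex_unrelated_adults: int


def relatedness_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Full additive relationship matrix over the pedigree closure.

    Founders (individuals with no recorded parents) are pairwise unrelated;
    diagonal entries are 1 + the parental relationship / 2 (>= 1).
    """
    order = pedigree.topological_order
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        dam, sire = pedigree.parents(ind)
        di = idx[dam] if dam is not None else None
        si = idx[sire] if sire is not None else None
        for j in range(i):
            v = 0.0
            if di is not None:
                v += 0.5 * A[j, di]
            if si is not None:
                v += 0.5 * A[j, si]
            A[i, j] = A[j, i] = v
        A[i, i] = 1.0 + (0.5 * A[di, si] if di is not None and si is not None else 0.0)
    return pd.DataFrame(A, index=order, columns=order)


def relatedness(
    matrix_or_pedigree: pd.DataFrame | Pedigree, i: str, j: str
) -> float:
    """Pairwise relatedness r; individuals absent from the pedigree are
    treated as unrelated founders (r = 0 to everyone, 1 to themselves)."""
    if isinstance(matrix_or_pedigree, Pedigree):
        matrix = relatedness_matrix(matrix_or_pedigree)
    else:
        matrix = matrix_or_pedigree
    if i == j:
        return float(matrix.at[i, j]) if i in matrix.index else 1.0
    if i not in matrix.index or j not in matrix.columns:
        return 0.0
    return float(matrix.at[i, j])


def group_dominants(group_members: Iterable[Individual]) -> list[Individual]:
    return [m for m in group_members if m.rank == "dominant"]


def is_related_group(
    caller: str | Individual,
    group_members: Sequence[Individual],
    matrix: pd.DataFrame,
    threshold: float = RELATEDNESS_THRESHOLD,
) -> bool:
    """True iff at least one current dominant of the group is a close
    relative (r >= threshold, inclusive) of the caller."""
    caller_id = caller.id if isinstance(caller, Individual) else caller
    dominants = group_dominants(group_members)
    if not dominants:
        group = group_members[0].group_id if group_members else "<empty>"
        raise ValidationError(f"group {group} has no recorded dominants")
    return max(relatedness(matrix, caller_id, d.id) for d in dominants) >= threshold


def profile_neighbour(
    caller: Individual,
    group_members: Sequence[Individual],
    matrix: pd.DataFrame,
    reference_date: dt.date,
    threshold: float = RELATEDNESS_THRESHOLD,
    adult_age_days: int = ADULT_AGE_DAYS,
) -> NeighbourProfile:
    """Composition metrics of a neighbouring group relative to the caller.

    Adults are >= ``adult_age_days`` post-hatch on the reference date.
    Unknown-sex individuals count as adults but are excluded from the
    partner and same-sex counts.
    """
    if caller.sex not in ("male", "female"):
        raise ValidationError(f"caller {caller.id} has unknown sex")
    group_id = group_members[0].group_id if group_members else ""
    adults = [m for m in group_members if m.is_adult(reference_date, adult_age_days)]
    opposite = "female" if caller.sex == "male" else "male"
    unrelated = [
        m for m in adults if relatedness(matrix, caller.id, m.id) < threshold
    ]
    n_partners = sum(1 for m in unrelated if m.sex == opposite)
    n_same_sex = sum(1 for m in unrelated if m.sex == caller.sex)
    related = (
        is_related_group(caller, group_members, matrix, threshold)
        if group_members
        else False
    )
    return NeighbourProfile(
        focal_caller=caller.id,
        neighbour_group=group_id,
        related=related,
        n_adults=len(adults),
        n_potential_partners=n_partners,
        n_same_sex_unrelated_adults=n_same_sex,
    )
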