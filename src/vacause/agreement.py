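"""Agreement between the algorithm and a second coder.

Individual level: per-cause Cohen's kappa.  Each cause is binarized
(cause vs not-cause) for both coders and

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement proportion and p_e the chance agreement
from the marginal proportions.  The standard error is the large-sample
variance of the kappa estimate for two raters (Fleiss, Cohen & Everitt
1969).  Deaths initially assigned to multiple causes (the measles /
diarrhea / ARI group before redistribution) are excluded.  When neither
coder ever assigns the cause, chance agreement is 1 and kappa is
undefined; such results are reported as 0.00 (0.000) with a degenerate
flag rather than NaN.

Population level: per-cause CSMF differences, top-k cause lists from
both coders, their overlap and per-cause rank shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from vacause.csmf import CSMFTable, rank_top
from vacause.hierarchy_engine import CauseAssignment

_EPS = 1e-12


@dataclass
class PairedLabels:
    """Aligned cause labels from the two coders for eligible records."""

    record_ids: tuple
    algorithm: tuple
    comparator: tuple

    def __post_init__(self) -> None:
        if not (len(self.record_ids) == len(self.algorithm) == len(self.comparator)):
            raise ValueError("paired label vectors must have equal length")

    @property
    def n(self) -> int:
        return len(self.record_ids)

    def causes(self) -> list:
        return sorted(set(self.algorithm) | set(self.comparator))


@dataclass
class KappaResult:
    cause: str
    kappa: float
    se: float
    n: int
    degenerate: bool = False


def exclude_multicause(
    assignments: Sequence[CauseAssignment],
    comparator: Mapping,
) -> PairedLabels:
    """Build kappa input, dropping pre-redistribution multi-cause deaths.

    ``comparator`` maps record_id to the second coder's cause (records
    without a comparator cause are dropped as well).  Exclusion looks at
    the provisional set, so a record redistributed to a single cause is
    still excluded if it initially carried several.
    """
    ids, algo, comp = [], [], []
    for a in assignments:
        if len(a.provisional_causes) > 1:
            continue
        other = comparator.get(a.record_id)
        if other is None:
            continue
        if a.final_cause is None:  # pragma: no cover - defensive
            raise ValueError(f"record {a.record_id!r} still pending")
        ids.append(a.record_id)
        algo.append(a.final_cause)
        comp.append(str(other))
    return PairedLabels(record_ids=tuple(ids), algorithm=tuple(algo), comparator=tuple(comp))


def kappa_from_table(a: int, b: int, c: int, d: int):
    """Kappa and SE from a 2x2 agreement table.

    Cell layout: a = both assign the cause, b = coder A only, c = coder B
    only, d = neither.  Returns (kappa, se, degenerate).
    """
    n = a + b + c + d
    if n < 2:
        raise ValueError("kappa requires at least 2 records")
    p = np.array([[a, b], [c, d]], dtype=float) / n
    po = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    colm = p.sum(axis=0)
    pe = float(row @ colm)
    if 1.0 - pe < _EPS:
        # both coders constant on the same class: chance agreement is 1
        return 0.0, 0.0, True
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt large-sample variance
    diag = sum(
        p[i, i] * ((1.0 - pe) - (colm[i] + row[i]) * (1.0 - po)) ** 2 for i in range(2)
    )
    off = sum(
        p[i, j] * (colm[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    var = (diag + (1.0 - po) ** 2 * off - (po * pe - 2.0 * pe + po) ** 2) / (
        n * (1.0 - pe) ** 4
    )
    se = float(np.sqrt(max(var, 0.0)))
    return float(kappa), se, False


def cohen_kappa(labels: PairedLabels, cause: str) -> KappaResult:
    """One-vs-rest Cohen's kappa for a single cause."""
    if labels.n < 2:
        raise ValueError("kappa requires at least 2 paired records")
    a_vec = np.array([lab == cause for lab in labels.algorithm])
    b_vec = np.array([lab == cause for lab in labels.comparator])
    a = int(np.sum(a_vec & b_vec))
    b = int(np.sum(a_vec & ~b_vec))
    c = int(np.sum(~a_vec & b_vec))
    d = int(np.sum(~a_vec & ~b_vec))
    kappa, se, degenerate = kappa_from_table(a, b, c, d)
    return KappaResult(cause=cause, kappa=kappa, se=se, n=labels.n, degenerate=degenerate)


def kappa_table(labels: PairedLabels, causes: Optional[Sequence[str]] = None) -> list:
    """Kappa results for every cause either coder used (or a given list)."""
    return [cohen_kappa(labels, c) for c in (causes or labels.causes())]


# ---------------------------------------------------------------------------
# Population-level comparison
# ---------------------------------------------------------------------------


@dataclass
class PopulationComparison:
    """CSMF deltas (percentage points, A minus B) and top-k ranking overlap."""

    age_group: str
    delta_pct_points: dict
    top_a: list
    top_b: list
    overlap: int
    rank_shifts: dict


def compare_populations(
    table_a: CSMFTable,
    table_b: CSMFTable,
    k: int = 5,
    order_hint: Optional[Sequence[str]] = None,
) -> PopulationComparison:
    """Compare two CSMF tables over the same age group and cause vocabulary."""
    if table_a.age_group != table_b.age_group:
        raise ValueError(
            f"age-group mismatch: {table_a.age_group!r} vs {table_b.age_group!r}"
        )
    if set(table_a.fractions) != set(table_b.fractions):
        only_a = sorted(set(table_a.fractions) - set(table_b.fractions))
        only_b = sorted(set(table_b.fractions) - set(table_a.fractions))
        raise ValueError(f"cause vocabulary mismatch: only in A {only_a}, only in B {only_b}")
    deltas = {
        c: 100.0 * (table_a.fractions[c] - table_b.fractions[c]) for c in table_a.fractions
    }
    top_a = rank_top(table_a, k, order_hint=order_hint)
    top_b = rank_top(table_b, k, order_hint=order_hint)
    causes_a = [c for _, c in top_a]
    causes_b = [c for _, c in top_b]
    shared = set(causes_a) & set(causes_b)
    shifts = {
        c: causes_b.index(c) - causes_a.index(c) for c in shared
    }
    return PopulationComparison(
        age_group=table_a.age_group,
        delta_pct_points=deltas,
        top_a=top_a,
        top_b=top_b,
        overlap=len(shared),
        rank_shifts=shifts,
    )
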