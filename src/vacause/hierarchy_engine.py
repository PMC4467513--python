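"""Hierarchical cause assignment and multi-cause redistribution.

Each age stratum has an ordered list of causes.  Walking the order, the
first cause whose case definition fires wins and evaluation stops —
except for the multi-cause group (measles / diarrhea / ARI in the child
stratum): once a group member fires, the remaining group members are
still evaluated and every firing member enters the provisional cause
set, while non-group causes further down are skipped.  A record firing
no definition is assigned the fallback cause "unspecified".

Records left with more than one provisional cause are resolved by
:func:`redistribute`: each pending record is allocated among its
provisional causes in proportion to the pre-redistribution CSMFs of
those causes (computed from records provisionally assigned to exactly
one group cause).  Two modes are provided: the default ``fractional``
mode splits the record's survey weight deterministically, and ``sample``
mode draws a single cause with the same probabilities from a seeded RNG.
Both yield identical expected CSMFs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from vacause.case_definitions import CaseDefinition, ConfigError, evaluate
from vacause.data_model import AgeStratum, VARecord, stratify

UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class Hierarchy:
    """Evaluation order for one age stratum plus multi-cause group membership."""

    stratum: AgeStratum
    ordered_causes: tuple
    multi_cause_group: frozenset = frozenset()
    fallback_cause: str = UNSPECIFIED

    def __post_init__(self) -> None:
        if len(set(self.ordered_causes)) != len(self.ordered_causes):
            raise ConfigError(f"{self.stratum}: duplicate causes in hierarchy order")
        extra = self.multi_cause_group - set(self.ordered_causes)
        if extra:
            raise ConfigError(
                f"{self.stratum}: multi-cause group members not in order: {sorted(extra)}"
            )

    def index(self, cause: str) -> int:
        return self.ordered_causes.index(cause)


@dataclass
class CauseAssignment:
    """Per-record output of the hierarchy walk.

    ``provisional_causes`` has more than one member only when all members
    belong to the multi-cause group; such assignments are *pending*
    (``final_cause`` is None) until :func:`redistribute` resolves them.
    ``rule_trace`` lists every (cause, fired) evaluation actually
    performed, in order.  ``weight_fractions`` (set at redistribution,
    or {final_cause: 1.0} for single-cause records) gives the share of
    the record's survey weight allocated to each cause.
    """

    record_id: str
    stratum: AgeStratum
    provisional_causes: tuple
    final_cause: Optional[str]
    rule_trace: tuple = ()
    weight_fractions: Optional[dict] = None

    @property
    def pending(self) -> bool:
        return self.final_cause is None

    def fractions(self) -> dict:
        """Allocated weight share per cause (defaults to all-on-final)."""
        if self.weight_fractions is not None:
            return self.weight_fractions
        if self.final_cause is None:
            raise ValueError(f"record {self.record_id!r}: pending, no fractions yet")
        return {self.final_cause: 1.0}


# ---------------------------------------------------------------------------
# Published structural constraints on hierarchy configuration
# ---------------------------------------------------------------------------

_CHILD_PARTIAL_ORDER = ("ari", "meningitis", "malaria", "aids")
_NEONATE_FORBIDDEN = ("malaria", "aids")
_NEONATE_AFTER_SCREENS = ("neonatal_sepsis", ("diarrhea", "pneumonia"))


def validate_constraints(hierarchy: Hierarchy) -> None:
    """Enforce the published structural constraints on a hierarchy.

    Child stratum: ARI before meningitis before malaria before AIDS (for
    whichever of those causes are present).  Neonatal stratum: no malaria,
    no AIDS, and neonatal sepsis after the diarrhea and pneumonia screens.
    """
    order = hierarchy.ordered_causes
    if hierarchy.stratum is AgeStratum.CHILD:
        present = [c for c in _CHILD_PARTIAL_ORDER if c in order]
        idx = [order.index(c) for c in present]
        if idx != sorted(idx):
            raise ConfigError(
                f"child hierarchy violates required order {_CHILD_PARTIAL_ORDER}: {order}"
            )
    else:
        banned = [c for c in _NEONATE_FORBIDDEN if c in order]
        if banned:
            raise ConfigError(f"neonatal hierarchy must not contain {banned}")
        sepsis, screens = _NEONATE_AFTER_SCREENS
        if sepsis in order:
            for screen in screens:
                if screen in order and order.index(screen) > order.index(sepsis):
                    raise ConfigError(
                        f"neonatal hierarchy must place {sepsis!r} after {screen!r}"
                    )


def _check_definitions(hierarchy: Hierarchy, defs: Mapping) -> None:
    for cause in hierarchy.ordered_causes:
        if cause not in defs:
            raise ConfigError(f"{hierarchy.stratum}: cause {cause!r} has no case definition")
        if not defs[cause].applies_to(hierarchy.stratum):
            raise ConfigError(
                f"{hierarchy.stratum}: definition for {cause!r} not applicable to stratum"
            )


def default_hierarchies(validate: bool = True) -> dict:
    """The bundled hierarchies, one per age stratum."""
    text = resources.files("vacause.data").joinpath("hierarchies.yaml").read_text("utf-8")
    return _hierarchies_from_payload(yaml.safe_load(text), validate=validate)


def load_hierarchies(path, validate: bool = True) -> dict:
    """Load hierarchies from a YAML config.

    The config is rejected if it violates the published partial-order
    constraints unless ``validate=False`` is passed explicitly.
    """
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _hierarchies_from_payload(payload, validate=validate)


def _hierarchies_from_payload(payload: Mapping, validate: bool) -> dict:
    fallback = str(payload.get("fallback_cause", UNSPECIFIED))
    out = {}
    for stratum in AgeStratum:
        body = payload.get(stratum.value)
        if body is None:
            raise ConfigError(f"hierarchy config missing stratum {stratum.value!r}")
        h = Hierarchy(
            stratum=stratum,
            ordered_causes=tuple(str(c) for c in body["order"]),
            multi_cause_group=frozenset(str(c) for c in body.get("multi_cause_group", ())),
            fallback_cause=fallback,
        )
        if validate:
            validate_constraints(h)
        out[stratum] = h
    return out


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assign(record: VARecord, hierarchy: Hierarchy, defs: Mapping) -> CauseAssignment:
    """Walk the hierarchy for one (included, stratified) record.

    First-hit semantics for causes outside the multi-cause group; once a
    group member fires, only the remaining group members are evaluated
    and all firing members enter the provisional set.
    """
    _check_definitions(hierarchy, defs)
    stratum = stratify(record)
    if stratum is not hierarchy.stratum:
        raise ValueError(
            f"record {record.record_id!r} is {stratum} but hierarchy is {hierarchy.stratum}"
        )
    trace = []
    provisional = []
    group_fired = False
    for cause in hierarchy.ordered_causes:
        in_group = cause in hierarchy.multi_cause_group
        if group_fired and not in_group:
            continue  # skipped, not evaluated
        fired = evaluate(defs[cause], record)
        trace.append((cause, fired))
        if not fired:
            continue
        if in_group:
            provisional.append(cause)
            group_fired = True
        else:
            return CauseAssignment(
                record_id=record.record_id,
                stratum=stratum,
                provisional_causes=(cause,),
                final_cause=cause,
                rule_trace=tuple(trace),
            )
    if not provisional:
        provisional = [hierarchy.fallback_cause]
    final = provisional[0] if len(provisional) == 1 else None
    return CauseAssignment(
        record_id=record.record_id,
        stratum=stratum,
        provisional_causes=tuple(provisional),
        final_cause=final,
        rule_trace=tuple(trace),
    )


def assign_all(records: Sequence[VARecord], hierarchies: Mapping, defs: Mapping) -> list:
    """Assign every record using the hierarchy of its own age stratum."""
    return [assign(rec, hierarchies[stratify(rec)], defs) for rec in records]


# ---------------------------------------------------------------------------
# Redistribution of the multi-cause group
# ---------------------------------------------------------------------------


def redistribute(
    assignments: Sequence[CauseAssignment],
    weights: Mapping,
    seed: Optional[int] = None,
    mode: str = "fractional",
) -> list:
    """Resolve pending multi-cause assignments.

    Pre-redistribution CSMFs are computed per stratum from the survey
    weights of records provisionally assigned to exactly one group cause;
    each pending record is then allocated among its provisional causes in
    proportion to those CSMFs restricted to its provisional set.  In
    ``fractional`` mode (default, deterministic) the record's weight is
    split; ``final_cause`` is set to the largest share for reporting, ties
    going to the earlier provisional cause.  In ``sample`` mode a single
    cause is drawn from the seeded RNG.  If every relevant CSMF is zero
    the record is split (or drawn) equally.
    """
    if mode not in ("fractional", "sample"):
        raise ValueError(f"unknown redistribution mode {mode!r}")
    pending = [a for a in assignments if a.pending]
    if not pending:
        return list(assignments)

    # weighted totals of resolved single causes, per stratum
    base: dict = {}
    for a in assignments:
        if a.pending:
            continue
        w = float(weights[a.record_id])
        per = base.setdefault(a.stratum, {})
        per[a.final_cause] = per.get(a.final_cause, 0.0) + w

    rng = np.random.default_rng(seed)
    out = []
    for a in assignments:
        if not a.pending:
            out.append(a)
            continue
        per = base.get(a.stratum, {})
        shares = np.array([per.get(c, 0.0) for c in a.provisional_causes], dtype=float)
        if shares.sum() <= 0.0:
            shares = np.ones(len(a.provisional_causes))
        shares = shares / shares.sum()
        if mode == "fractional":
            fractions = {c: float(s) for c, s in zip(a.provisional_causes, shares)}
            best = max(range(len(shares)), key=lambda i: (shares[i], -i))
            final = a.provisional_causes[best]
            out.append(replace(a, final_cause=final, weight_fractions=fractions))
        else:
            chosen = a.provisional_causes[rng.choice(len(shares), p=shares)]
            out.append(replace(a, final_cause=chosen, weight_fractions={chosen: 1.0}))
    return out
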