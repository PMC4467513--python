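"""Truth-known synthetic VA study generator.

Emulates the structure of a national child VA study: a few hundred to a
few thousand deaths, a neonatal / post-neonatal split, survey weights and
stratum/PSU identifiers, symptom responses speaking the case-definition
vocabulary, and an optional simulated second coder.

Symptom generation is *definition-aware*: for each record a true cause is
drawn from the stratum CSMF and, with probability equal to the symptom
sensitivity, the record receives a satisfying assignment of that cause's
predicate tree, chosen uniformly among the minimal ones that the
hierarchy recovers exactly (i.e. the resulting profile fires no
definition placed earlier, so at sensitivity 1 and false-positive rate 0
the algorithm recovers the true cause for every record).  Undetected
records emit an empty profile, landing in "unspecified" exactly like
truly unspecified deaths.  Independently, every binary item not required
by the profile is flipped positive with the per-item false-positive
rate, which can create spurious earlier diagnoses — deliberately so, as
real VA case definitions have imperfect specificity.

All draws come from one seeded RNG stream with a fixed per-record draw
order (stratum, cause, weight, PSU, age, detection, profile choice,
false-positive vector, comparator), so identical scenarios and seeds
give byte-identical outputs.  Appending records re-uses the same stream,
so extending n does NOT preserve earlier records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from vacause.case_definitions import (
    AllOf,
    AnyOf,
    DurationInDays,
    ItemAtLeast,
    ItemEquals,
    NoneOf,
    predicate_items,
)
from vacause.data_model import AgeStratum, Codebook, VARecord, default_codebook
from vacause.hierarchy_engine import UNSPECIFIED, assign, default_hierarchies

# ---------------------------------------------------------------------------
# Minimal satisfying assignments of a predicate tree
# ---------------------------------------------------------------------------


def minimal_satisfying_assignments(pred) -> list:
    """Enumerate minimal ways to satisfy a predicate.

    Returns a list of (positives, forbidden) pairs: ``positives`` maps
    item id to the value to report; ``forbidden`` is the set of items
    that must stay unreported (from none_of arms).  Contradictory
    combinations (an item both required and forbidden, or required at two
    different values) are pruned.
    """
    if isinstance(pred, ItemEquals):
        return [({pred.item: pred.value}, frozenset())]
    if isinstance(pred, ItemAtLeast):
        return [({pred.item: pred.count}, frozenset())]
    if isinstance(pred, DurationInDays):
        return [({pred.item: pred.min_days}, frozenset())]
    if isinstance(pred, NoneOf):
        # satisfied by absence: forbid everything the subtree mentions
        return [({}, predicate_items(pred))]
    if isinstance(pred, AnyOf):
        out, seen = [], set()
        for child in pred.children:
            for positives, forbidden in minimal_satisfying_assignments(child):
                key = (frozenset(positives.items()), forbidden)
                if key not in seen:
                    seen.add(key)
                    out.append((positives, forbidden))
        return out
    if isinstance(pred, AllOf):
        combos = [({}, frozenset())]
        for child in pred.children:
            nxt = []
            for positives, forbidden in combos:
                for cp, cf in minimal_satisfying_assignments(child):
                    merged = dict(positives)
                    ok = True
                    for item, value in cp.items():
                        if merged.get(item, value) != value:
                            ok = False
                            break
                        merged[item] = value
                    if not ok:
                        continue
                    union_forbidden = forbidden | cf
                    if any(item in union_forbidden for item in merged):
                        continue
                    nxt.append((merged, union_forbidden))
            combos = nxt
        return combos
    raise TypeError(f"not a predicate: {pred!r}")


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass
class SimulationScenario:
    """Parameters of one synthetic VA study.

    ``csmf`` maps each age stratum to its true cause distribution
    (summing to 1; may include "unspecified").  ``sensitivity`` is the
    probability a death's symptom profile is consistent with its true
    cause; ``false_positive_rate`` is the per-binary-item probability of
    a spurious positive.  ``comparator_error`` maps a true cause to the
    distribution of causes the simulated second coder assigns (rows sum
    to 1); None means an error-free (identity) comparator.
    """

    n: int
    neonatal_proportion: float
    csmf: dict
    sensitivity: float = 0.9
    false_positive_rate: float = 0.02
    comparator_error: Optional[dict] = None
    weight_sigma: float = 0.5
    n_strata: int = 5
    n_psu_per_stratum: int = 3
    seed: int = 0
    name: str = "synthetic"

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.neonatal_proportion <= 1.0:
            raise ValueError("neonatal_proportion must be in [0, 1]")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate must be in [0, 1]")
        for stratum in AgeStratum:
            dist = self.csmf.get(stratum)
            if not dist:
                raise ValueError(f"csmf missing stratum {stratum.value!r}")
            if any(p < 0 for p in dist.values()):
                raise ValueError("csmf probabilities must be non-negative")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"csmf for {stratum.value} must sum to 1")
        if self.comparator_error is not None:
            for cause, row in self.comparator_error.items():
                if abs(sum(row.values()) - 1.0) > 1e-6:
                    raise ValueError(f"comparator_error row for {cause!r} must sum to 1")


def uniform_comparator_error(scenario_csmf: Mapping, accuracy: float) -> dict:
    """Comparator error matrix: correct with prob ``accuracy``, else uniform
    over the other causes of the same stratum."""
    matrix = {}
    for stratum, dist in scenario_csmf.items():
        causes = sorted(dist)
        for cause in causes:
            others = [c for c in causes if c != cause]
            row = {cause: accuracy}
            for other in others:
                row[other] = (1.0 - accuracy) / len(others)
            matrix[cause] = row
    return matrix


# ---------------------------------------------------------------------------
# Profile library: minimal assignments the hierarchy recovers exactly
# ---------------------------------------------------------------------------


def _probe_record(stratum: AgeStratum, responses: dict) -> VARecord:
    age = 10 if stratum is AgeStratum.NEONATE else 400
    return VARecord(record_id="probe", age_at_death_days=age, responses=responses)


def exact_recovery_profiles(defs: Mapping, hierarchies: Mapping) -> dict:
    """(stratum, cause) -> minimal profiles that assign() maps back to cause."""
    library: dict = {}
    for stratum, hierarchy in hierarchies.items():
        for cause in hierarchy.ordered_causes:
            valid = []
            for positives, forbidden in minimal_satisfying_assignments(defs[cause].predicate):
                result = assign(_probe_record(stratum, dict(positives)), hierarchy, defs)
                if result.final_cause == cause and len(result.provisional_causes) == 1:
                    valid.append((dict(positives), forbidden))
            library[(stratum, cause)] = valid
    return library


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_from(rng: np.random.Generator, labels, cumprobs) -> str:
    return labels[int(np.searchsorted(cumprobs, rng.random(), side="right"))]


def simulate(
    scenario: SimulationScenario,
    codebook: Optional[Codebook] = None,
    definitions: Optional[Mapping] = None,
    hierarchies: Optional[Mapping] = None,
):
    """Generate (records, truth) for a scenario.

    ``truth`` is a DataFrame with one row per record: record_id, stratum,
    true_cause, weight.  Raises if the scenario's CSMF names a cause with
    no case definition in the hierarchy of its stratum.
    """
    scenario.validate()
    codebook = codebook or default_codebook()
    hierarchies = hierarchies or default_hierarchies()
    if definitions is None:
        from vacause.case_definitions import builtin_definitions

        definitions = builtin_definitions(codebook)

    for stratum in AgeStratum:
        known = set(hierarchies[stratum].ordered_causes) | {hierarchies[stratum].fallback_cause}
        unknown = sorted(set(scenario.csmf[stratum]) - known)
        if unknown:
            raise ValueError(
                f"csmf for {stratum.value} names causes with no case definition: {unknown}"
            )

    library = exact_recovery_profiles(definitions, hierarchies)
    for (stratum, cause), profiles in library.items():
        if cause in scenario.csmf[stratum] and scenario.csmf[stratum][cause] > 0 and not profiles:
            raise ValueError(
                f"cause {cause!r} in {stratum.value} has no exactly-recoverable profile"
            )

    binary_items = [it.id for it in codebook.items if it.kind == "binary"]
    cause_tables = {}
    for stratum in AgeStratum:
        labels = sorted(scenario.csmf[stratum])
        probs = np.array([scenario.csmf[stratum][c] for c in labels], dtype=float)
        cause_tables[stratum] = (labels, np.cumsum(probs / probs.sum()))
    comp_tables = None
    if scenario.comparator_error is not None:
        comp_tables = {}
        for cause, row in scenario.comparator_error.items():
            labels = sorted(row)
            probs = np.array([row[c] for c in labels], dtype=float)
            comp_tables[cause] = (labels, np.cumsum(probs / probs.sum()))

    rng = np.random.default_rng(scenario.seed)
    records, truth_rows = [], []
    for i in range(scenario.n):
        stratum = (
            AgeStratum.NEONATE
            if rng.random() < scenario.neonatal_proportion
            else AgeStratum.CHILD
        )
        labels, cum = cause_tables[stratum]
        cause = _draw_from(rng, labels, cum)
        weight = float(np.exp(rng.normal(0.0, scenario.weight_sigma)))
        cluster = int(rng.integers(scenario.n_strata * scenario.n_psu_per_stratum))
        stratum_id = f"S{cluster // scenario.n_psu_per_stratum + 1}"
        psu_id = f"{stratum_id}-P{cluster % scenario.n_psu_per_stratum + 1}"
        if stratum is AgeStratum.NEONATE:
            age = int(rng.integers(0, 28))
        else:
            age = int(rng.integers(28, 1827))
        detected = rng.random() < scenario.sensitivity
        profiles = library.get((stratum, cause), [])
        choice = int(rng.integers(len(profiles))) if profiles else 0  # draw kept in stream
        responses: dict = {}
        if cause != UNSPECIFIED and detected and profiles:
            responses = dict(profiles[choice][0])
        flips = rng.random(len(binary_items))
        for item, u in zip(binary_items, flips):
            if u < scenario.false_positive_rate and item not in responses:
                responses[item] = True
        comparator = cause
        if comp_tables is not None:
            labels_c, cum_c = comp_tables[cause]
            comparator = _draw_from(rng, labels_c, cum_c)
        else:
            rng.random()  # keep draw order identical with and without comparator error
        record_id = f"{scenario.name}-{i:05d}"
        records.append(
            VARecord(
                record_id=record_id,
                live_birth="yes",
                age_at_death_days=age,
                questionnaire_type="neonatal" if stratum is AgeStratum.NEONATE else "child",
                responses=responses,
                survey_weight=weight,
                stratum_id=stratum_id,
                psu_id=psu_id,
                comparator_cause=comparator,
                interview_complete=True,
            )
        )
        truth_rows.append(
            {
                "record_id": record_id,
                "stratum": stratum.value,
                "true_cause": cause,
                "weight": weight,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["record_id", "stratum", "true_cause", "weight"])
    return records, truth


# ---------------------------------------------------------------------------
# Ready-made scenarios
# ---------------------------------------------------------------------------

#: printed under-five CSMFs (percent of all 0-59 m deaths) and sample sizes
#: of the three re-analyzed national VA studies; used as simulation
#: parameters, not as reproduction targets.
STUDY_PARAMETERS = {
    "uganda": {
        "n": 530,
        "n_neonatal": 126,
        AgeStratum.NEONATE: {
            "pneumonia": 2.8,
            "intrapartum_related": 6.7,
            "preterm_birth": 5.9,
            "congenital_abnormalities": 1.8,
            "neonatal_sepsis": 0.4,
            "other_neonatal": 2.5,
            "tetanus": 2.3,
            "diarrhea": 0.2,
            "unspecified": 2.1,
        },
        AgeStratum.CHILD: {
            "diarrhea": 15.7,
            "malaria": 23.2,
            "aids": 3.9,
            "injury": 2.8,
            "meningitis": 1.8,
            "measles": 1.6,
            "other_infections": 2.0,
            "ari": 18.3,
            "unspecified": 6.1,
        },
    },
    "rwanda": {
        "n": 360,
        "n_neonatal": 121,
        AgeStratum.NEONATE: {
            "pneumonia": 4.4,
            "intrapartum_related": 10.7,
            "preterm_birth": 4.5,
            "congenital_abnormalities": 1.9,
            "neonatal_sepsis": 0.5,
            "other_neonatal": 1.5,
            "tetanus": 0.9,
            "diarrhea": 0.6,
            "unspecified": 7.2,
        },
        AgeStratum.CHILD: {
            "diarrhea": 11.4,
            "malaria": 25.6,
            "aids": 3.0,
            "injury": 1.2,
            "meningitis": 1.2,
            "measles": 0.2,
            "other_infections": 3.3,
            "ari": 12.1,
            "unspecified": 9.6,
        },
    },
    "ghana": {
        "n": 188,
        "n_neonatal": 71,
        AgeStratum.NEONATE: {
            "pneumonia": 3.7,
            "intrapartum_related": 6.4,
            "preterm_birth": 6.3,
            "congenital_abnormalities": 3.6,
            "neonatal_sepsis": 0.0,
            "other_neonatal": 1.8,
            "tetanus": 0.7,
            "diarrhea": 0.0,
            "unspecified": 13.6,
        },
        AgeStratum.CHILD: {
            "diarrhea": 2.5,
            "malaria": 16.8,
            "aids": 8.6,
            "injury": 3.7,
            "meningitis": 1.8,
            "measles": 0.5,
            "other_infections": 3.7,
            "ari": 14.9,
            "unspecified": 11.4,
        },
    },
}


def _renormalize(dist: Mapping) -> dict:
    total = sum(dist.values())
    return {c: v / total for c, v in dist.items()}


def scenario_from_study(country: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Scenario parameterized by one of the three published study populations.

    Sample size and neonatal split come from the study's reported counts;
    true CSMFs are the published under-five fractions renormalized within
    stratum.  Keyword overrides pass through to the scenario (e.g.
    ``sensitivity=1.0, false_positive_rate=0.0``).
    """
    key = country.lower()
    if key not in STUDY_PARAMETERS:
        raise ValueError(f"unknown country {country!r}; choose from {sorted(STUDY_PARAMETERS)}")
    params = STUDY_PARAMETERS[key]
    kwargs = dict(
        n=params["n"],
        neonatal_proportion=params["n_neonatal"] / params["n"],
        csmf={s: _renormalize(params[s]) for s in AgeStratum},
        seed=seed,
        name=key,
    )
    kwargs.update(overrides)
    return SimulationScenario(**kwargs)


def default_scenario(n: int = 1000, seed: int = 0, **overrides) -> SimulationScenario:
    """A generic three-country-like scenario for testing and demos."""
    kwargs = dict(
        n=n,
        neonatal_proportion=0.25,
        csmf={
            AgeStratum.NEONATE: {
                "intrapartum_related": 0.28,
                "preterm_birth": 0.19,
                "pneumonia": 0.13,
                "congenital_abnormalities": 0.08,
                "tetanus": 0.05,
                "other_neonatal": 0.07,
                "neonatal_sepsis": 0.01,
                "diarrhea": 0.01,
                "unspecified": 0.18,
            },
            AgeStratum.CHILD: {
                "malaria": 0.28,
                "ari": 0.22,
                "diarrhea": 0.15,
                "aids": 0.05,
                "injury": 0.03,
                "meningitis": 0.02,
                "measles": 0.01,
                "other_infections": 0.06,
                "unspecified": 0.18,
            },
        },
        seed=seed,
        name="default",
    )
    kwargs.update(overrides)
    return SimulationScenario(**kwargs)
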