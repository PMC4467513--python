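"""Declarative case-definition engine.

A case definition operationally diagnoses one cause of death from VA
symptom responses: a boolean predicate tree whose leaves test individual
codebook items (equality, count thresholds, closed duration windows in
whole days) and whose internal nodes combine children with all_of /
any_of / none_of.  Evaluation is pure and uses missing-as-absent
semantics: a missing or unreported response never satisfies a leaf test,
so "don't know" answers are conservative and cannot create a diagnosis.

Default definitions ship as editable YAML under ``vacause/data``.  The
AIDS screen follows its published five-condition disjunction exactly
(jaundice; chronic diarrhea >1 month; chronic fever >1 month; wasting as
at least one of paleness / hair-colour change / leg edema / dry scaly
skin; cough or trouble breathing lasting 3-27 days with fever and no
recent tuberculosis diagnosis) and diarrhea requires loose/liquid stools
with >=6 stools on the worst day; all other definitions are reconstructed
WHO-style indicator definitions, marked as such in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from vacause.data_model import AgeStratum, Codebook, VARecord, default_codebook


class ConfigError(ValueError):
    """A case-definition or hierarchy configuration is invalid."""


# ---------------------------------------------------------------------------
# Predicate tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemEquals:
    item: str
    value: object = True

    def evaluate(self, responses: Mapping) -> bool:
        got = responses.get(self.item)
        return got is not None and got == self.value


@dataclass(frozen=True)
class ItemAtLeast:
    item: str
    count: int

    def evaluate(self, responses: Mapping) -> bool:
        got = responses.get(self.item)
        return got is not None and got >= self.count


@dataclass(frozen=True)
class DurationInDays:
    """Closed interval [min_days, max_days] in whole days; max None = unbounded."""

    item: str
    min_days: int
    max_days: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_days is not None and self.min_days > self.max_days:
            raise ConfigError(
                f"duration window on {self.item!r}: min {self.min_days} > max {self.max_days}"
            )

    def evaluate(self, responses: Mapping) -> bool:
        got = responses.get(self.item)
        if got is None:
            return False
        return got >= self.min_days and (self.max_days is None or got <= self.max_days)


@dataclass(frozen=True)
class AllOf:
    children: tuple

    def evaluate(self, responses: Mapping) -> bool:
        return all(c.evaluate(responses) for c in self.children)


@dataclass(frozen=True)
class AnyOf:
    children: tuple

    def evaluate(self, responses: Mapping) -> bool:
        return any(c.evaluate(responses) for c in self.children)


@dataclass(frozen=True)
class NoneOf:
    children: tuple

    def evaluate(self, responses: Mapping) -> bool:
        return not any(c.evaluate(responses) for c in self.children)


Predicate = (ItemEquals, ItemAtLeast, DurationInDays, AllOf, AnyOf, NoneOf)

_COMBINATORS = {"all_of": AllOf, "any_of": AnyOf, "none_of": NoneOf}


def predicate_items(pred) -> frozenset:
    """Set of item ids referenced anywhere in the tree."""
    if isinstance(pred, (AllOf, AnyOf, NoneOf)):
        out = frozenset()
        for child in pred.children:
            out |= predicate_items(child)
        return out
    return frozenset({pred.item})


def validate_predicate(pred, codebook: Codebook, where: str = "predicate") -> None:
    """Reject leaves referencing items absent from the codebook (load-time)."""
    if isinstance(pred, (AllOf, AnyOf, NoneOf)):
        if not pred.children:
            raise ConfigError(f"{where}: empty combinator")
        for i, child in enumerate(pred.children):
            validate_predicate(child, codebook, f"{where}[{i}]")
        return
    if pred.item not in codebook:
        raise ConfigError(f"{where}: item {pred.item!r} not in codebook")
    kind = codebook[pred.item].kind
    if isinstance(pred, DurationInDays) and kind != "duration_days":
        raise ConfigError(f"{where}: duration test on non-duration item {pred.item!r}")
    if isinstance(pred, ItemAtLeast) and kind not in ("count", "duration_days"):
        raise ConfigError(f"{where}: threshold test on non-numeric item {pred.item!r}")


def predicate_from_dict(node, where: str = "predicate"):
    """Deserialize a predicate tree from its nested-map form."""
    if not isinstance(node, Mapping) or len(node) != 1:
        raise ConfigError(f"{where}: predicate node must be a single-key map, got {node!r}")
    key, body = next(iter(node.items()))
    if key in _COMBINATORS:
        if not isinstance(body, list) or not body:
            raise ConfigError(f"{where}.{key}: expected a non-empty list of children")
        children = tuple(
            predicate_from_dict(child, f"{where}.{key}[{i}]") for i, child in enumerate(body)
        )
        return _COMBINATORS[key](children)
    if key == "item_equals":
        return ItemEquals(item=str(body["item"]), value=body.get("value", True))
    if key == "item_at_least":
        return ItemAtLeast(item=str(body["item"]), count=int(body["count"]))
    if key == "duration_in_days":
        max_days = body.get("max")
        return DurationInDays(
            item=str(body["item"]),
            min_days=int(body["min"]),
            max_days=None if max_days is None else int(max_days),
        )
    raise ConfigError(f"{where}: unknown predicate kind {key!r}")


def predicate_to_dict(pred) -> dict:
    """Serialize to the nested-map form; inverse of :func:`predicate_from_dict`."""
    for name, cls in _COMBINATORS.items():
        if isinstance(pred, cls):
            return {name: [predicate_to_dict(c) for c in pred.children]}
    if isinstance(pred, ItemEquals):
        return {"item_equals": {"item": pred.item, "value": pred.value}}
    if isinstance(pred, ItemAtLeast):
        return {"item_at_least": {"item": pred.item, "count": pred.count}}
    if isinstance(pred, DurationInDays):
        return {
            "duration_in_days": {
                "item": pred.item,
                "min": pred.min_days,
                "max": pred.max_days,
            }
        }
    raise TypeError(f"not a predicate: {pred!r}")


# ---------------------------------------------------------------------------
# Case definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseDefinition:
    """A cause label, its predicate, and the strata it applies to."""

    cause: str
    predicate: object
    applicable_strata: frozenset

    def applies_to(self, stratum: AgeStratum) -> bool:
        return stratum in self.applicable_strata


def evaluate(defn: CaseDefinition, record: VARecord) -> bool:
    """True iff the definition's predicate holds for the record's responses."""
    return defn.predicate.evaluate(record.responses)


_STRATUM_BY_LABEL = {s.value: s for s in AgeStratum}


def _definitions_from_payload(payload, codebook, known_causes, where):
    if not isinstance(payload, Mapping) or "definitions" not in payload:
        raise ConfigError(f"{where}: expected a map with a 'definitions' key")
    out = {}
    for cause, body in payload["definitions"].items():
        cause = str(cause)
        if known_causes is not None and cause not in known_causes:
            raise ConfigError(f"{where}: unknown cause label {cause!r}")
        strata_labels = body.get("strata")
        if not strata_labels:
            raise ConfigError(f"{where}.{cause}: missing 'strata'")
        try:
            strata = frozenset(_STRATUM_BY_LABEL[str(s)] for s in strata_labels)
        except KeyError as exc:
            raise ConfigError(f"{where}.{cause}: unknown stratum {exc.args[0]!r}") from None
        if "predicate" not in body:
            raise ConfigError(f"{where}.{cause}: missing 'predicate'")
        pred = predicate_from_dict(body["predicate"], f"{where}.{cause}.predicate")
        validate_predicate(pred, codebook, f"{where}.{cause}.predicate")
        out[cause] = CaseDefinition(cause=cause, predicate=pred, applicable_strata=strata)
    return out


def builtin_definitions(codebook: Optional[Codebook] = None) -> dict:
    """The default definition set bundled with the package.

    Covers, for neonates: tetanus, congenital abnormalities,
    intrapartum-related complications, preterm birth complications,
    pneumonia/ARI, diarrhea, neonatal sepsis and other neonatal disorders;
    for 1-59 months: measles, injury, diarrhea, ARI/pneumonia,
    meningitis/encephalitis, malaria, AIDS and other infections.
    """
    codebook = codebook or default_codebook()
    text = resources.files("vacause.data").joinpath("case_definitions.yaml").read_text("utf-8")
    return _definitions_from_payload(
        yaml.safe_load(text), codebook, known_causes=None, where="builtin"
    )


def load_definitions(
    path,
    codebook: Codebook,
    known_causes=None,
) -> dict:
    """Load (and validate) case definitions from a YAML/JSON config.

    When the config sets ``extends_builtin: true`` (the default), causes it
    does not mention keep their builtin definitions, so a config overriding
    a single threshold leaves everything else unchanged.  ``known_causes``
    restricts acceptable cause labels; it defaults to the builtin cause
    vocabulary, and may be set to None to allow novel causes.
    """
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if payload is None:
        payload = {}
    extends = payload.get("extends_builtin", True)
    base = builtin_definitions(codebook) if extends else {}
    if known_causes is None and extends:
        known_causes = set(base)
    if "definitions" not in payload:
        payload = dict(payload, definitions={})
    overrides = _definitions_from_payload(payload, codebook, known_causes, str(path))
    merged = dict(base)
    merged.update(overrides)
    if not merged:
        raise ConfigError(f"{path}: no case definitions defined")
    return merged


def dump_definitions(defs: Mapping, path) -> None:
    """Serialize definitions to YAML; load -> dump -> load is lossless."""
    payload = {
        "extends_builtin": False,
        "definitions": {
            cause: {
                "strata": sorted(s.value for s in d.applicable_strata),
                "predicate": predicate_to_dict(d.predicate),
            }
            for cause, d in sorted(defs.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
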