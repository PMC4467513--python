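"""Survey-weighted CSMF estimation, cause-category mapping and ranking.

The cause-specific mortality fraction of cause c in an age group is the
ratio of survey weight allocated to c to the total survey weight of the
group; fractionally redistributed records contribute their weight shares.
Standard errors, when requested, use Taylor linearization of the ratio
estimator with the with-replacement PSU approximation, clustering on PSU
within sampling stratum — the standard complex-survey variance for a
weighted proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from vacause.data_model import AgeStratum, VARecord
from vacause.hierarchy_engine import CauseAssignment

#: pooled 0-59 month age-group label used alongside the two strata
POOLED = "0_59m"

_AGE_GROUPS = {AgeStratum.NEONATE.value, AgeStratum.CHILD.value, POOLED}


@dataclass
class CSMFTable:
    """Cause fractions for one age group; fractions sum to 1 (±1e-9)."""

    age_group: str
    fractions: dict
    se: Optional[dict] = None
    n: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"CSMF fractions sum to {total!r}, not 1")


def design_from_records(records: Sequence[VARecord]) -> pd.DataFrame:
    """Extract the survey-design frame (weight, stratum, PSU) from records."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "weight": [r.survey_weight for r in records],
            "stratum_id": [r.stratum_id for r in records],
            "psu_id": [r.psu_id for r in records],
        }
    )


def compute_csmf(
    assignments: Sequence[CauseAssignment],
    design: pd.DataFrame,
    age_group: str = POOLED,
    with_se: bool = False,
) -> CSMFTable:
    """Weighted CSMFs for one age group.

    ``age_group`` is ``neonate_0_27d``, ``child_1_59m`` or ``0_59m``
    (both strata pooled over their combined weights).  All assignments
    must be resolved (final, or fractional after redistribution).
    """
    if age_group not in _AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    if age_group == POOLED:
        subset = list(assignments)
    else:
        subset = [a for a in assignments if a.stratum.value == age_group]
    if not subset:
        raise ValueError(f"no assignments in age group {age_group!r}")

    dsg = design.set_index("record_id")
    causes = sorted({c for a in subset for c in a.fractions()})
    weights = np.array([float(dsg.at[a.record_id, "weight"]) for a in subset])
    total = weights.sum()
    # per-record allocation matrix y[i, j] = share of record i on cause j
    y = np.zeros((len(subset), len(causes)))
    col = {c: j for j, c in enumerate(causes)}
    for i, a in enumerate(subset):
        for c, f in a.fractions().items():
            y[i, col[c]] = f
    fractions = (weights[:, None] * y).sum(axis=0) / total
    # guard against float drift so the table invariant holds exactly enough
    fractions = fractions / fractions.sum()

    se = None
    if with_se:
        strata = [str(dsg.at[a.record_id, "stratum_id"]) for a in subset]
        psus = [str(dsg.at[a.record_id, "psu_id"]) for a in subset]
        se = {
            c: _taylor_se(y[:, j], weights, strata, psus, fractions[j])
            for c, j in col.items()
        }
    return CSMFTable(
        age_group=age_group,
        fractions={c: float(fractions[j]) for c, j in col.items()},
        se=se,
        n=len(subset),
    )


def _taylor_se(y, w, strata, psus, p) -> float:
    """Linearized SE of p = sum(w*y)/sum(w), PSU-clustered within stratum."""
    total = w.sum()
    z = w * (np.asarray(y) - p) / total  # score contributions
    frame = pd.DataFrame({"z": z, "stratum": strata, "psu": psus})
    var = 0.0
    for _, grp in frame.groupby("stratum"):
        cluster_totals = grp.groupby("psu")["z"].sum().to_numpy()
        n_h = len(cluster_totals)
        if n_h < 2:
            continue  # single-PSU stratum contributes no estimable variance
        var += n_h / (n_h - 1) * ((cluster_totals - cluster_totals.mean()) ** 2).sum()
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Cause-category mapping (CHERG-comparable reporting groups)
# ---------------------------------------------------------------------------


def default_cause_map() -> dict:
    """The bundled algorithm-cause -> reporting-category map."""
    text = resources.files("vacause.data").joinpath("cause_map.yaml").read_text("utf-8")
    return {str(k): str(v) for k, v in yaml.safe_load(text)["map"].items()}


def map_causes(table: CSMFTable, cmap: Mapping) -> CSMFTable:
    """Sum fractions within categories; the map must cover every cause."""
    missing = [c for c in table.fractions if c not in cmap]
    if missing:
        raise ValueError(f"cause map does not cover: {missing}")
    out: dict = {}
    for cause, frac in table.fractions.items():
        cat = cmap[cause]
        out[cat] = out.get(cat, 0.0) + frac
    se = None
    if table.se is not None:
        # linearization does not aggregate across causes; recompute upstream
        se = None
    return CSMFTable(age_group=table.age_group, fractions=out, se=se, n=table.n)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

#: residual groups never ranked among "single causes"
DEFAULT_RANK_EXCLUDE = frozenset({"unspecified", "other", "other_neonatal", "other_infections"})


def rank_top(
    table: CSMFTable,
    k: int,
    order_hint: Optional[Sequence[str]] = None,
    exclude: frozenset = DEFAULT_RANK_EXCLUDE,
) -> list:
    """Top-k single causes as (rank, cause) pairs.

    Unspecified and residual "other" groups are excluded by default.
    Ties break by position in ``order_hint`` (typically the hierarchy
    order) and then lexicographically; zero-fraction causes never rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hint = {c: i for i, c in enumerate(order_hint)} if order_hint else {}

    def sort_key(item):
        cause, frac = item
        return (-frac, hint.get(cause, len(hint)), cause)

    eligible = [
        (c, f) for c, f in table.fractions.items() if c not in exclude and f > 0.0
    ]
    ranked = sorted(eligible, key=sort_key)[:k]
    return [(i + 1, cause) for i, (cause, _) in enumerate(ranked)]


def ranking_report(tables: Mapping, k: int = 5, **kwargs) -> pd.DataFrame:
    """Long-form ranking table (age group x rank x cause) for several tables."""
    rows = []
    for label, table in tables.items():
        for rank, cause in rank_top(table, k, **kwargs):
            rows.append({"age_group": table.age_group, "source": label, "rank": rank, "cause": cause})
    return pd.DataFrame(rows)
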