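"""Population-level chronic-condition indicators.

Given per-unit condition profiles, computes per-condition prevalence, the
multimorbidity (MCC) prevalence at a configurable threshold (default: two
or more concurrent conditions), the top-coded condition-count
distribution, and pairwise (dyad) co-occurrence counts.  Also renders the
cross-system coverage report from the registry's availability matrix.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .code_systems import ContractError, ValidationError
from .coder import ConditionProfile
from .registry import Availability, Registry

__all__ = [
    "DEFAULT_MCC_THRESHOLD",
    "IndicatorReport",
    "has_mcc",
    "compute_indicators",
    "coverage_table",
    "coverage_report",
    "compare_dialects",
]

#: Two or more concurrent chronic conditions.
DEFAULT_MCC_THRESHOLD = 2


def has_mcc(profile: ConditionProfile, threshold: int = DEFAULT_MCC_THRESHOLD) -> bool:
    """True when the unit has at least *threshold* concurrent conditions."""
    return profile.n_conditions >= threshold


@dataclass(frozen=True)
class IndicatorReport:
    dialect_id: str
    n_units: int
    per_condition_prevalence: Mapping[str, float]
    mcc_threshold: int
    mcc_prevalence: float
    count_distribution: Mapping[str, float]
    dyads: Mapping[tuple[str, str], float]
    weights_used: bool

    def to_dict(self) -> dict:
        return {
            "dialect_id": self.dialect_id,
            "n_units": self.n_units,
            "per_condition_prevalence": dict(self.per_condition_prevalence),
            "mcc_threshold": self.mcc_threshold,
            "mcc_prevalence": self.mcc_prevalence,
            "count_distribution": dict(self.count_distribution),
            "dyads": {f"{a}|{b}": v for (a, b), v in self.dyads.items()},
            "weights_used": self.weights_used,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"metric": f"prevalence:{cid}", "value": v}
            for cid, v in self.per_condition_prevalence.items()
        ]
        rows.append({"metric": "mcc_prevalence", "value": self.mcc_prevalence})
        rows += [
            {"metric": f"count:{k}", "value": v}
            for k, v in self.count_distribution.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _count_bins(top_code: int) -> list[str]:
    return [str(k) for k in range(top_code)] + [f"{top_code}+"]


def compute_indicators(
    profiles: Sequence[ConditionProfile],
    mcc_threshold: int = DEFAULT_MCC_THRESHOLD,
    weights: Optional[Sequence[float]] = None,
    *,
    top_code: int = 4,
) -> IndicatorReport:
    """Compute the indicator report for a coded population.

    Prevalences are (optionally weighted) proportions of true flags; the
    count distribution is top-coded at ``top_code``; dyad entries give the
    (weighted) number of units with both conditions flagged.
    """
    if not profiles:
        raise ContractError("profiles must be nonempty")
    dialects = {p.dialect_id for p in profiles}
    if len(dialects) != 1:
        raise ContractError(f"profiles span several dialects: {sorted(dialects)}")
    if mcc_threshold < 0:
        raise ValidationError("mcc_threshold must be nonnegative")

    n = len(profiles)
    if weights is None:
        w = np.ones(n)
        weights_used = False
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (n,):
            raise ValidationError(
                f"weights length {w.shape} does not match {n} profiles"
            )
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        if w.sum() == 0:
            raise ValidationError("weights must not be all zero")
        weights_used = True
    total = w.sum()

    condition_ids = list(profiles[0].flags)
    flag_matrix = np.array(
        [[p.flags[cid] for cid in condition_ids] for p in profiles], dtype=bool
    )
    counts = np.array([p.n_conditions for p in profiles])

    prevalence = {
        cid: float(w[flag_matrix[:, j]].sum() / total)
        for j, cid in enumerate(condition_ids)
    }
    mcc_prevalence = float(w[counts >= mcc_threshold].sum() / total)

    dist: dict[str, float] = {}
    for k in range(top_code):
        dist[str(k)] = float(w[counts == k].sum() / total)
    dist[f"{top_code}+"] = float(w[counts >= top_code].sum() / total)

    dyads: dict[tuple[str, str], float] = {}
    for j, k in itertools.combinations(range(len(condition_ids)), 2):
        both = flag_matrix[:, j] & flag_matrix[:, k]
        if both.any():
            pair = tuple(sorted((condition_ids[j], condition_ids[k])))
            dyads[pair] = float(w[both].sum())

    return IndicatorReport(
        dialect_id=profiles[0].dialect_id,
        n_units=n,
        per_condition_prevalence=prevalence,
        mcc_threshold=mcc_threshold,
        mcc_prevalence=mcc_prevalence,
        count_distribution=dist,
        dyads=dyads,
        weights_used=weights_used,
    )


def coverage_table(registry: Registry) -> pd.DataFrame:
    """Availability matrix as a DataFrame with a per-system totals row."""
    matrix = registry.availability()
    frame = matrix.to_frame()
    totals = {
        d: matrix.count_measured(d) for d in matrix.dialect_ids
    }
    frame.loc["total_measured"] = pd.Series(totals)
    return frame


def coverage_report(registry: Registry) -> str:
    """Render the 20 x 5 coverage matrix as an aligned plain-text table."""
    matrix = registry.availability()
    frame = matrix.to_frame()
    name_w = max(len(i) for i in frame.index) + 2
    col_w = max(
        max(len(d) for d in matrix.dialect_ids),
        max(len(s.value) for s in Availability),
    ) + 2
    lines = [
        "condition".ljust(name_w)
        + "".join(d.rjust(col_w) for d in matrix.dialect_ids)
    ]
    for cid in frame.index:
        lines.append(
            cid.ljust(name_w)
            + "".join(str(frame.loc[cid, d]).rjust(col_w) for d in matrix.dialect_ids)
        )
    lines.append(
        "total_measured".ljust(name_w)
        + "".join(
            str(matrix.count_measured(d)).rjust(col_w)
            for d in matrix.dialect_ids
        )
    )
    return "\n".join(lines)


def compare_dialects(
    reports: Sequence[IndicatorReport],
    registry: Optional[Registry] = None,
) -> pd.DataFrame:
    """Pairwise discordance table between dialect-level indicator reports.

    For every pair of reports, lists per-condition prevalence differences
    and the MCC-prevalence difference; conditions measurable in one dialect
    but not the other are marked structurally incomparable.
    """
    if len(reports) < 2:
        raise ContractError("at least two reports are required")
    if registry is None:
        from .registry import load_default_registry

        registry = load_default_registry()
    matrix = registry.availability()

    rows = []
    for r1, r2 in itertools.combinations(reports, 2):
        for cid in r1.per_condition_prevalence:
            s1 = matrix.state(cid, r1.dialect_id)
            s2 = matrix.state(cid, r2.dialect_id)
            incomparable = (s1 is Availability.UNAVAILABLE) != (
                s2 is Availability.UNAVAILABLE
            )
            measurable_both = (
                s1 is not Availability.UNAVAILABLE
                and s2 is not Availability.UNAVAILABLE
            )
            diff = (
                r1.per_condition_prevalence[cid]
                - r2.per_condition_prevalence[cid]
                if measurable_both
                else float("nan")
            )
            rows.append(
                {
                    "dialect_a": r1.dialect_id,
                    "dialect_b": r2.dialect_id,
                    "condition_id": cid,
                    "prevalence_diff": diff,
                    "structurally_incomparable": incomparable,
                }
            )
        rows.append(
            {
                "dialect_a": r1.dialect_id,
                "dialect_b": r2.dialect_id,
                "condition_id": "__mcc__",
                "prevalence_diff": r1.mcc_prevalence - r2.mcc_prevalence,
                "structurally_incomparable": False,
            }
        )
    return pd.DataFrame(rows)
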