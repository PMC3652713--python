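"""Applies the classification scheme to claims and survey records.

One profile is produced per analysis unit (person, visit, or
hospitalization depending on the dialect): a boolean flag per condition,
the flag count, and the matching codes or items as evidence.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .code_systems import CodeSystem, ContractError, ValidationError, normalize_code
from .registry import Availability, Registry

logger = logging.getLogger(__name__)

__all__ = [
    "ClaimRecord",
    "SurveyRecord",
    "ConditionProfile",
    "CodingConfig",
    "CodingSummary",
    "code_claims_unit",
    "code_survey_unit",
    "code_population",
    "claims_from_csv",
    "surveys_from_csv",
    "records_from_jsonl",
    "profiles_to_csv",
    "profiles_to_jsonl",
    "profiles_from_csv",
]

RESPONSES = ("yes", "no", "missing")


@dataclass(frozen=True)
class ClaimRecord:
    """One claim/discharge/visit record carrying diagnosis codes."""

    unit_id: str
    record_id: str
    codes: tuple[str, ...]
    code_system: CodeSystem

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValidationError(f"record {self.record_id}: empty code list")


@dataclass(frozen=True)
class SurveyRecord:
    """One unit's survey/checkbox responses, keyed by item label."""

    unit_id: str
    items: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.items.values() if v not in RESPONSES}
        if bad:
            raise ValidationError(f"invalid responses: {sorted(bad)}")


@dataclass(frozen=True)
class CodingConfig:
    min_records_per_condition: int = 1
    prefix_matching: bool = False
    unknown_code_policy: str = "warn"  # ignore | warn | error
    # Whether proxy kidney items set the chronic kidney disease flag.
    kidney_proxy_as_ckd: bool = True

    def __post_init__(self) -> None:
        if self.min_records_per_condition < 1:
            raise ValidationError("min_records_per_condition must be >= 1")
        if self.unknown_code_policy not in ("ignore", "warn", "error"):
            raise ValidationError(
                f"unknown_code_policy must be ignore/warn/error, "
                f"got {self.unknown_code_policy!r}"
            )


@dataclass(frozen=True)
class ConditionProfile:
    unit_id: str
    dialect_id: str
    flags: Mapping[str, bool]
    n_conditions: int
    evidence: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_conditions != sum(self.flags.values()):
            raise ValidationError(
                f"unit {self.unit_id}: n_conditions inconsistent with flags"
            )


@dataclass
class CodingSummary:
    n_units: int = 0
    n_records: int = 0
    n_quarantined: int = 0


def _match_conditions(
    code_norm: str,
    registry: Registry,
    dialect_id: str,
    prefix_matching: bool,
) -> frozenset[str]:
    hits = registry.conditions_for_code(
        normalize_code(code_norm, registry.dialect(dialect_id).code_system),
        dialect_id,
    )
    if hits or not prefix_matching:
        return hits
    out = set()
    for cid in registry.condition_ids:
        members = registry.flattened_codes(cid, dialect_id)
        if any(code_norm.startswith(m) for m in members):
            out.add(cid)
    return frozenset(out)


def code_claims_unit(
    records: Sequence[ClaimRecord],
    dialect_id: str,
    config: CodingConfig = CodingConfig(),
    *,
    registry: Registry,
    summary: Optional[CodingSummary] = None,
) -> ConditionProfile:
    """Code all claim records of a single unit into a condition profile.

    A condition flag is set when at least ``min_records_per_condition``
    distinct records carry one of its member codes; a single code may set
    several flags.
    """
    dialect = registry.dialect(dialect_id)
    if not dialect.is_code_based:
        raise ContractError(f"dialect {dialect_id} does not carry codes")
    if not records:
        raise ContractError("at least one record is required")
    unit_ids = {r.unit_id for r in records}
    if len(unit_ids) != 1:
        raise ContractError(f"mixed unit_ids in one call: {sorted(unit_ids)}")
    unit_id = records[0].unit_id

    records_per_condition: dict[str, set[str]] = defaultdict(set)
    evidence: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        quarantined = False
        for raw in rec.codes:
            try:
                norm = normalize_code(raw, dialect.code_system).normalized
            except ValidationError as exc:
                if config.unknown_code_policy == "error":
                    raise
                if config.unknown_code_policy == "warn":
                    logger.warning(
                        "unit %s record %s: %s", unit_id, rec.record_id, exc
                    )
                quarantined = True
                continue
            for cid in _match_conditions(
                norm, registry, dialect_id, config.prefix_matching
            ):
                records_per_condition[cid].add(rec.record_id)
                evidence[cid].add(norm)
        if quarantined and summary is not None:
            summary.n_quarantined += 1

    flags: dict[str, bool] = {}
    for cid in registry.condition_ids:
        measured = (
            registry.mapping(cid, dialect_id).state
            is not Availability.UNAVAILABLE
        )
        flags[cid] = (
            measured
            and len(records_per_condition.get(cid, ()))
            >= config.min_records_per_condition
        )
    return ConditionProfile(
        unit_id=unit_id,
        dialect_id=dialect_id,
        flags=flags,
        n_conditions=sum(flags.values()),
        evidence={
            cid: tuple(sorted(evidence[cid])) for cid in sorted(evidence)
            if flags[cid]
        },
    )


def code_survey_unit(
    record: SurveyRecord,
    dialect_id: str,
    config: CodingConfig = CodingConfig(),
    *,
    registry: Registry,
) -> ConditionProfile:
    """Code one unit's survey/checkbox responses into a condition profile.

    A flag is set when the condition's registered item answered yes;
    missing responses and items for conditions unavailable in the dialect
    leave the flag false.
    """
    dialect = registry.dialect(dialect_id)
    if dialect.is_code_based:
        raise ContractError(
            f"dialect {dialect_id} is code-based; use code_claims_unit"
        )
    item_map = registry.survey_items(dialect_id)
    proxy_labels = {
        label
        for label, cid in item_map.items()
        if label != cid
    }

    flags = {cid: False for cid in registry.condition_ids}
    evidence: dict[str, set[str]] = defaultdict(set)
    for label, response in record.items.items():
        cid = item_map.get(label)
        if cid is None:
            msg = (
                f"unit {record.unit_id}: item {label!r} is not registered "
                f"for dialect {dialect_id}"
            )
            if config.unknown_code_policy == "error":
                raise ValidationError(msg)
            if config.unknown_code_policy == "warn":
                logger.warning(msg)
            continue
        if label in proxy_labels and not config.kidney_proxy_as_ckd:
            logger.info(
                "unit %s: proxy item %r not mapped (kidney_proxy_as_ckd=False)",
                record.unit_id, label,
            )
            continue
        if response == "yes":
            flags[cid] = True
            evidence[cid].add(label)
        elif response == "missing":
            logger.debug(
                "unit %s: item %r missing, treated as no", record.unit_id, label
            )
    return ConditionProfile(
        unit_id=record.unit_id,
        dialect_id=dialect_id,
        flags=flags,
        n_conditions=sum(flags.values()),
        evidence={cid: tuple(sorted(v)) for cid, v in sorted(evidence.items())},
    )


Record = Union[ClaimRecord, SurveyRecord]


def code_population(
    records: Iterable[Record],
    dialect_id: str,
    config: CodingConfig = CodingConfig(),
    *,
    registry: Registry,
    unit_ids: Optional[Iterable[str]] = None,
) -> list[ConditionProfile]:
    """Code a stream of records into one profile per unit, sorted by unit_id.

    When *unit_ids* (a population roster) is given, units without any
    record receive an all-false profile, so denominators cover the whole
    population rather than only units that generated records.
    """
    claims: dict[str, list[ClaimRecord]] = defaultdict(list)
    surveys: dict[str, SurveyRecord] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        if isinstance(rec, ClaimRecord):
            claims[rec.unit_id].append(rec)
        elif isinstance(rec, SurveyRecord):
            if rec.unit_id in surveys:
                merged = dict(surveys[rec.unit_id].items)
                merged.update(rec.items)
                surveys[rec.unit_id] = SurveyRecord(rec.unit_id, merged)
            else:
                surveys[rec.unit_id] = rec
        else:  # pragma: no cover - defensive
            raise ContractError(f"unsupported record type: {type(rec)!r}")
    if claims and surveys:
        raise ContractError("cannot mix claim and survey records in one run")

    summary = CodingSummary(n_records=n_records)
    profiles: list[ConditionProfile] = []
    if claims:
        for unit_id in sorted(claims):
            profiles.append(
                code_claims_unit(
                    claims[unit_id], dialect_id, config,
                    registry=registry, summary=summary,
                )
            )
    else:
        for unit_id in sorted(surveys):
            profiles.append(
                code_survey_unit(
                    surveys[unit_id], dialect_id, config, registry=registry
                )
            )
    if unit_ids is not None:
        covered = {p.unit_id for p in profiles}
        empty_flags = {cid: False for cid in registry.condition_ids}
        for uid in unit_ids:
            if uid not in covered:
                profiles.append(
                    ConditionProfile(
                        unit_id=uid,
                        dialect_id=dialect_id,
                        flags=dict(empty_flags),
                        n_conditions=0,
                    )
                )
        profiles.sort(key=lambda p: p.unit_id)
    summary.n_units = len(profiles)
    logger.info(
        "coded %d units from %d records (%d quarantined)",
        summary.n_units, summary.n_records, summary.n_quarantined,
    )
    return profiles


# ---------------------------------------------------------------------------
# File formats: long-format CSV and JSON-lines


def claims_from_csv(path: str | Path) -> list[ClaimRecord]:
    """Read claims from CSV with columns unit_id, record_id, code, code_system.

    One row per code; rows sharing (unit_id, record_id) form one record.
    Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    required = {"unit_id", "record_id", "code", "code_system"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"claims CSV missing columns: {sorted(missing)}")
    grouped: dict[tuple[str, str, str], list[str]] = defaultdict(list)
    for row in df.itertuples(index=False):
        grouped[(row.unit_id, row.record_id, row.code_system)].append(row.code)
    return [
        ClaimRecord(
            unit_id=uid, record_id=rid, codes=tuple(codes),
            code_system=CodeSystem(system),
        )
        for (uid, rid, system), codes in grouped.items()
    ]


def surveys_from_csv(path: str | Path) -> list[SurveyRecord]:
    """Read survey responses from long CSV with columns unit_id, item, response."""
    df = pd.read_csv(path, dtype=str, comment="#").fillna("missing")
    required = {"unit_id", "item", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"survey CSV missing columns: {sorted(missing)}")
    per_unit: dict[str, dict[str, str]] = defaultdict(dict)
    for row in df.itertuples(index=False):
        per_unit[row.unit_id][row.item] = row.response
    return [SurveyRecord(uid, items) for uid, items in per_unit.items()]


def records_from_jsonl(path: str | Path) -> list[Record]:
    """Read claim or survey records from a JSON-lines file."""
    out: list[Record] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        obj = json.loads(line)
        if "codes" in obj:
            out.append(
                ClaimRecord(
                    unit_id=obj["unit_id"],
                    record_id=obj["record_id"],
                    codes=tuple(obj["codes"]),
                    code_system=CodeSystem(obj["code_system"]),
                )
            )
        else:
            out.append(SurveyRecord(obj["unit_id"], obj["items"]))
    return out


def _metadata_lines(metadata: Optional[Mapping[str, object]]) -> list[str]:
    if not metadata:
        return []
    return [f"# {k}: {v}" for k, v in metadata.items()]


def profiles_to_csv(
    profiles: Sequence[ConditionProfile],
    path: str | Path,
    *,
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    """Write profiles as CSV: one row per unit, one flag column per condition.

    Run metadata (scheme version, registry checksum, config echo, seed) is
    embedded as ``#`` comment lines before the header.
    """
    if not profiles:
        raise ContractError("no profiles to write")
    condition_ids = list(profiles[0].flags)
    rows = [
        {
            "unit_id": p.unit_id,
            "dialect_id": p.dialect_id,
            **{cid: int(p.flags[cid]) for cid in condition_ids},
            "n_conditions": p.n_conditions,
        }
        for p in profiles
    ]
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def profiles_to_jsonl(
    profiles: Sequence[ConditionProfile],
    path: str | Path,
    *,
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    """Write profiles (with evidence) as JSON-lines."""
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        for p in profiles:
            fh.write(
                json.dumps(
                    {
                        "unit_id": p.unit_id,
                        "dialect_id": p.dialect_id,
                        "flags": {k: bool(v) for k, v in p.flags.items()},
                        "n_conditions": p.n_conditions,
                        "evidence": {k: list(v) for k, v in p.evidence.items()},
                    }
                )
                + "\n"
            )


def profiles_from_csv(path: str | Path) -> list[ConditionProfile]:
    """Read back a profiles CSV written by :func:`profiles_to_csv`."""
    df = pd.read_csv(path, comment="#", dtype={"unit_id": str})
    flag_cols = [
        c for c in df.columns
        if c not in ("unit_id", "dialect_id", "n_conditions")
    ]
    out = []
    for row in df.itertuples(index=False):
        flags = {c: bool(getattr(row, c)) for c in flag_cols}
        out.append(
            ConditionProfile(
                unit_id=row.unit_id,
                dialect_id=row.dialect_id,
                flags=flags,
                n_conditions=int(row.n_conditions),
            )
        )
    return out
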