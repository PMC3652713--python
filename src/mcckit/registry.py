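"""Machine-readable registry of the 20-condition classification scheme.

The registry is loaded from a packaged JSON resource that stores every
mapping-table cell verbatim alongside structured metadata for the five
data-system dialects, the chronic-condition definition survey, and the
comparison classification schemes.  All code parsing is delegated to
:mod:`mcckit.code_systems`; the resource is the single source of truth for
condition and code literals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .code_systems import (
    CellKind,
    CodeSystem,
    CodeValue,
    ContractError,
    ParsedCell,
    ValidationError,
    normalize_code,
    parse_codeset_spec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Availability",
    "SystemDialect",
    "DefinitionRecord",
    "SchemeRecord",
    "ConditionMapping",
    "ConditionDefinition",
    "AvailabilityMatrix",
    "Registry",
    "RegistryLoadError",
    "load_default_registry",
    "N_CONDITIONS",
    "DIALECT_IDS",
]

N_CONDITIONS = 20
DIALECT_IDS = ("NHIS", "NAMCS", "MEPS", "NIS", "CMS")

# CCS category numbers are small integers; values far outside that range in
# a CCS column indicate a cross-system transcription anomaly.
_CCS_PLAUSIBLE_MAX = 1000


class RegistryLoadError(ValueError):
    """Raised when the registry resource fails validation."""


class Availability(str, Enum):
    MEASURED = "measured"
    RELATED_PROXY = "related_proxy"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class SystemDialect:
    """Measurement context of one data system."""

    dialect_id: str
    name: str
    unit_of_analysis: str
    condition_data_kind: str
    operator: str
    sampling_frame: str
    data_source: str

    @property
    def code_system(self) -> Optional[CodeSystem]:
        """Diagnosis-code vocabulary used by this dialect, if any."""
        return {
            "ccs_codes": CodeSystem.CCS,
            "icd9_codes": CodeSystem.ICD9CM,
        }.get(self.condition_data_kind)

    @property
    def is_code_based(self) -> bool:
        return self.code_system is not None


@dataclass(frozen=True)
class DefinitionRecord:
    source: str
    year: int
    duration_criterion: str
    functional_limitation: bool
    ongoing_care: bool


@dataclass(frozen=True)
class SchemeRecord:
    scheme_name: str
    source: str
    first_year: int
    n_conditions: int
    method: str


@dataclass(frozen=True)
class ConditionMapping:
    """Flattened mapping of one condition in one dialect."""

    state: Availability
    codes: frozenset[str] = frozenset()
    kind: Optional[CodeSystem] = None
    item_labels: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConditionDefinition:
    condition_id: str
    display_name: str
    scope_note: str
    sub_conditions: tuple[dict, ...]
    mappings: Mapping[str, ConditionMapping]


@dataclass(frozen=True)
class AvailabilityMatrix:
    """20 x 5 map of condition x dialect measurement states."""

    cells: Mapping[tuple[str, str], Availability]
    provenance: Mapping[tuple[str, str], str]
    condition_ids: tuple[str, ...]
    dialect_ids: tuple[str, ...]

    def state(self, condition_id: str, dialect_id: str) -> Availability:
        return self.cells[(condition_id, dialect_id)]

    def count_measured(self, dialect_id: str) -> int:
        """Conditions with a usable measure (direct or proxy) in a dialect."""
        return sum(
            1
            for c in self.condition_ids
            if self.cells[(c, dialect_id)] is not Availability.UNAVAILABLE
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            d: [self.cells[(c, d)].value for c in self.condition_ids]
            for d in self.dialect_ids
        }
        return pd.DataFrame(data, index=list(self.condition_ids))


class Registry:
    """Parsed classification scheme plus dialect and definition metadata."""

    def __init__(
        self,
        *,
        scheme: str,
        version: str,
        dialects: Mapping[str, SystemDialect],
        conditions: Mapping[str, ConditionDefinition],
        definitions: tuple[DefinitionRecord, ...],
        schemes: tuple[SchemeRecord, ...],
        mcc_threshold: int,
        checksum: str,
        warnings: tuple[str, ...] = (),
    ) -> None:
        self.scheme = scheme
        self.version = version
        self.dialects = dict(dialects)
        self.conditions = dict(conditions)
        self.definitions = definitions
        self.schemes = schemes
        self.mcc_threshold = mcc_threshold
        self.checksum = checksum
        self.warnings = warnings
        self._code_index = self._build_code_index()

    # -- basic accessors ---------------------------------------------------

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(self.conditions)

    def dialect(self, dialect_id: str) -> SystemDialect:
        try:
            return self.dialects[dialect_id]
        except KeyError:
            raise ContractError(f"unknown dialect: {dialect_id!r}") from None

    def mapping(self, condition_id: str, dialect_id: str) -> ConditionMapping:
        self.dialect(dialect_id)
        try:
            return self.conditions[condition_id].mappings[dialect_id]
        except KeyError:
            raise ContractError(
                f"unknown condition: {condition_id!r}"
            ) from None

    def flattened_codes(self, condition_id: str, dialect_id: str) -> frozenset[str]:
        """Union of normalized codes for a condition in a code-based dialect."""
        return self.mapping(condition_id, dialect_id).codes

    # -- derived views -----------------------------------------------------

    def availability(self) -> AvailabilityMatrix:
        cells: dict[tuple[str, str], Availability] = {}
        provenance: dict[tuple[str, str], str] = {}
        for cid, cond in self.conditions.items():
            for did in self.dialects:
                m = cond.mappings[did]
                cells[(cid, did)] = m.state
                provenance[(cid, did)] = "; ".join(m.provenance)
        return AvailabilityMatrix(
            cells=cells,
            provenance=provenance,
            condition_ids=self.condition_ids,
            dialect_ids=tuple(self.dialects),
        )

    def count_measured(self, dialect_id: str) -> int:
        self.dialect(dialect_id)
        return self.availability().count_measured(dialect_id)

    def conditions_for_code(
        self, code: CodeValue | str, dialect_id: str
    ) -> frozenset[str]:
        """All conditions whose code set for *dialect_id* contains *code*."""
        dialect = self.dialect(dialect_id)
        if not dialect.is_code_based:
            raise ContractError(
                f"dialect {dialect_id} has no code-based mapping"
            )
        if isinstance(code, str):
            code = normalize_code(code, dialect.code_system)
        elif code.system is not dialect.code_system:
            raise ContractError(
                f"code system {code.system.value} does not match dialect "
                f"{dialect_id} ({dialect.code_system.value})"
            )
        return frozenset(self._code_index[dialect_id].get(code.normalized, ()))

    def survey_items(self, dialect_id: str) -> dict[str, str]:
        """Map of registered item label -> condition_id for a survey dialect."""
        dialect = self.dialect(dialect_id)
        if dialect.is_code_based:
            raise ContractError(
                f"dialect {dialect_id} is code-based, not survey-based"
            )
        items: dict[str, str] = {}
        for cid, cond in self.conditions.items():
            m = cond.mappings[dialect_id]
            if m.state is Availability.UNAVAILABLE:
                continue
            for label in m.item_labels:
                items[label] = cid
        return items

    def definition_feature_matrix(self) -> pd.DataFrame:
        """One row per chronic-condition definition with its key components."""
        rows = [
            {
                "source": d.source,
                "year": d.year,
                "duration_criterion": d.duration_criterion,
                "functional_limitation": d.functional_limitation,
                "ongoing_care": d.ongoing_care,
            }
            for d in self.definitions
        ]
        return pd.DataFrame(rows)

    def scheme_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.schemes])

    def to_code_csv(self, path: str | Path) -> None:
        """Audit export: one row per condition x dialect x code/item."""
        rows = []
        for cid, cond in self.conditions.items():
            for did in self.dialects:
                m = cond.mappings[did]
                if m.codes:
                    for code in sorted(m.codes):
                        rows.append(
                            {
                                "condition_id": cid,
                                "dialect_id": did,
                                "kind": m.kind.value,
                                "code_or_item": code,
                                "state": m.state.value,
                            }
                        )
                else:
                    for label in m.item_labels:
                        rows.append(
                            {
                                "condition_id": cid,
                                "dialect_id": did,
                                "kind": m.kind.value if m.kind else "",
                                "code_or_item": label,
                                "state": m.state.value,
                            }
                        )
                    if not m.item_labels:
                        rows.append(
                            {
                                "condition_id": cid,
                                "dialect_id": did,
                                "kind": "",
                                "code_or_item": "",
                                "state": m.state.value,
                            }
                        )
        pd.DataFrame(rows).to_csv(path, index=False)

    # -- internals ---------------------------------------------------------

    def _build_code_index(self) -> dict[str, dict[str, set[str]]]:
        index: dict[str, dict[str, set[str]]] = {}
        for did, dialect in self.dialects.items():
            if not dialect.is_code_based:
                continue
            per_code: dict[str, set[str]] = {}
            for cid, cond in self.conditions.items():
                for code in cond.mappings[did].codes:
                    per_code.setdefault(code, set()).add(cid)
            index[did] = per_code
        return index


# ---------------------------------------------------------------------------
# Loading


def _resource_bytes(resource_path: Optional[str | Path]) -> bytes:
    if resource_path is not None:
        return Path(resource_path).read_bytes()
    ref = importlib_resources.files("mcckit.resources") / "oash20_registry.json"
    return ref.read_bytes()


def _parse_cell(entry: Mapping, system: CodeSystem) -> ParsedCell:
    return parse_codeset_spec(
        entry["cell"],
        system,
        lenient=bool(entry.get("lenient", False)),
        source_note=entry["cell"],
    )


def _flatten_condition(
    raw_cond: Mapping,
    dialects: Mapping[str, SystemDialect],
    warnings: list[str],
    drop_codes: Mapping[tuple[str, str], Iterable[str]],
) -> ConditionDefinition:
    cid = raw_cond["condition_id"]
    display = raw_cond["display_name"]
    overrides = raw_cond.get("availability_overrides", {})
    row_names = [r["name"] for r in raw_cond["rows"]]
    sub_conditions: list[dict] = []
    mappings: dict[str, ConditionMapping] = {}

    # Alias targets must resolve to another row of the same condition (or
    # the condition's own display name).
    resolvable = {n.lower() for n in row_names} | {display.lower(), cid}

    for did, dialect in dialects.items():
        cell_system = dialect.code_system or (
            CodeSystem.SURVEY_ITEM
            if dialect.condition_data_kind == "self_report"
            else CodeSystem.CHECKBOX
        )
        codes: set[str] = set()
        item_labels: list[str] = []
        provenance: list[str] = []
        kind: Optional[CodeSystem] = None
        for row in raw_cond["rows"]:
            entry = row["cells"][did]
            parsed = _parse_cell(entry, cell_system)
            provenance.append(f"{row['name']}: {entry['cell']}")
            for w in parsed.warnings:
                warnings.append(f"{cid}/{did}: {w}")
            if parsed.kind is CellKind.ALIAS:
                target = parsed.alias_target.lower()
                if target not in resolvable:
                    raise RegistryLoadError(
                        f"{cid}/{did}: alias target {parsed.alias_target!r} "
                        f"does not resolve within condition"
                    )
                continue
            if parsed.kind is CellKind.UNAVAILABLE:
                continue
            if parsed.kind is CellKind.CODES:
                codes.update(parsed.codeset.members)
                kind = parsed.codeset.system
            else:
                label = parsed.codeset.item_label
                if label.lower() in ("self-reported", "checkbox"):
                    label = cid
                item_labels.append(label)
                kind = parsed.codeset.system

        dropped = set(drop_codes.get((cid, did), ()))
        if dropped:
            codes -= {normalize_code(c, cell_system).normalized for c in dropped}
            provenance.append(f"codes dropped by override: {sorted(dropped)}")

        state = (
            Availability.MEASURED
            if codes or item_labels
            else Availability.UNAVAILABLE
        )

        override = overrides.get(did)
        if override:
            state = Availability(override["state"])
            provenance.append(f"override: {override['note']}")
            if override.get("synthesize_checkbox") and not item_labels:
                item_labels.append(cid)
                kind = CodeSystem.CHECKBOX
            proxy = override.get("proxy_item_label")
            if proxy:
                item_labels.append(proxy)
        if state is Availability.UNAVAILABLE:
            codes = set()
            item_labels = []

        mappings[did] = ConditionMapping(
            state=state,
            codes=frozenset(codes),
            kind=kind if (codes or item_labels) else None,
            item_labels=tuple(dict.fromkeys(item_labels)),
            provenance=tuple(provenance),
        )

    for row in raw_cond["rows"]:
        alias_of = None
        for did in dialects:
            parsed = _parse_cell(
                row["cells"][did],
                dialects[did].code_system
                or (
                    CodeSystem.SURVEY_ITEM
                    if dialects[did].condition_data_kind == "self_report"
                    else CodeSystem.CHECKBOX
                ),
            )
            if parsed.kind is CellKind.ALIAS:
                alias_of = cid
                break
        sub_conditions.append({"name": row["name"], "alias_of": alias_of})

    return ConditionDefinition(
        condition_id=cid,
        display_name=display,
        scope_note=raw_cond.get("scope_note", ""),
        sub_conditions=tuple(sub_conditions),
        mappings=mappings,
    )


def _cross_checks(
    conditions: Mapping[str, ConditionDefinition],
    dialects: Mapping[str, SystemDialect],
    warnings: list[str],
) -> None:
    for did, dialect in dialects.items():
        if not dialect.is_code_based:
            continue
        seen: dict[str, list[str]] = {}
        for cid, cond in conditions.items():
            for code in cond.mappings[did].codes:
                seen.setdefault(code, []).append(cid)
        for code, owners in sorted(seen.items()):
            if len(owners) > 1:
                warnings.append(
                    f"{did}: code {code} shared by {sorted(owners)}"
                )
        if dialect.code_system is CodeSystem.CCS:
            for cid, cond in conditions.items():
                odd = [
                    c
                    for c in cond.mappings[did].codes
                    if int(c) > _CCS_PLAUSIBLE_MAX
                ]
                if odd:
                    warnings.append(
                        f"{did}/{cid}: CCS values {sorted(odd)} exceed the "
                        f"plausible category range (possible cross-system "
                        f"transcription anomaly); stored verbatim"
                    )


def load_default_registry(
    resource_path: Optional[str | Path] = None,
    *,
    drop_codes: Optional[Mapping[tuple[str, str], Iterable[str]]] = None,
) -> Registry:
    """Load and validate the packaged (or a user-supplied) registry resource.

    Parameters
    ----------
    resource_path
        Path to an alternative registry JSON; the packaged resource is used
        when omitted.
    drop_codes
        Override hook mapping ``(condition_id, dialect_id)`` to raw codes to
        remove from that flattened set (e.g. to resolve a duplicated code in
        the printed source).

    Raises
    ------
    RegistryLoadError
        If the resource violates the registry schema or its invariants;
        the message lists the failing entries.
    """
    payload = _resource_bytes(resource_path)
    checksum = hashlib.sha256(payload).hexdigest()
    try:
        raw = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise RegistryLoadError(f"registry resource is not valid JSON: {exc}")

    errors: list[str] = []
    for key in ("scheme", "version", "dialects", "conditions", "definitions",
                "schemes"):
        if key not in raw:
            errors.append(f"missing top-level key: {key}")
    if errors:
        raise RegistryLoadError("; ".join(errors))

    dialects: dict[str, SystemDialect] = {}
    for d in raw["dialects"]:
        dialects[d["dialect_id"]] = SystemDialect(
            dialect_id=d["dialect_id"],
            name=d["name"],
            unit_of_analysis=d["unit_of_analysis"],
            condition_data_kind=d["condition_data_kind"],
            operator=d["operator"],
            sampling_frame=d["sampling_frame"],
            data_source=d["data_source"],
        )
    if tuple(dialects) != DIALECT_IDS:
        raise RegistryLoadError(
            f"expected dialects {DIALECT_IDS}, found {tuple(dialects)}"
        )

    warnings: list[str] = []
    conditions: dict[str, ConditionDefinition] = {}
    drop_codes = drop_codes or {}
    for raw_cond in raw["conditions"]:
        try:
            cond = _flatten_condition(raw_cond, dialects, warnings, drop_codes)
        except (ValidationError, KeyError) as exc:
            errors.append(f"{raw_cond.get('condition_id', '?')}: {exc}")
            continue
        if cond.condition_id in conditions:
            errors.append(f"duplicate condition_id: {cond.condition_id}")
        conditions[cond.condition_id] = cond

    if errors:
        raise RegistryLoadError("registry validation failed: " + "; ".join(errors))
    if len(conditions) != N_CONDITIONS:
        raise RegistryLoadError(
            f"registry must define exactly {N_CONDITIONS} conditions, "
            f"found {len(conditions)}"
        )

    _cross_checks(conditions, dialects, warnings)
    for w in warnings:
        logger.warning("registry: %s", w)

    definitions = tuple(
        DefinitionRecord(
            source=d["source"],
            year=int(d["year"]),
            duration_criterion=d["duration_criterion"],
            functional_limitation=bool(d["functional_limitation"]),
            ongoing_care=bool(d["ongoing_care"]),
        )
        for d in raw["definitions"]
    )
    schemes = tuple(
        SchemeRecord(
            scheme_name=s["scheme_name"],
            source=s["source"],
            first_year=int(s["first_year"]),
            n_conditions=int(s["n_conditions"]),
            method=s["method"],
        )
        for s in raw["schemes"]
    )

    return Registry(
        scheme=raw["scheme"],
        version=raw["version"],
        dialects=dialects,
        conditions=conditions,
        definitions=definitions,
        schemes=schemes,
        mcc_threshold=int(raw.get("mcc_threshold", 2)),
        checksum=checksum,
        warnings=tuple(warnings),
    )
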