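"""Diagnosis-code vocabularies: parsing, normalization, and membership.

Two code systems are supported: ICD-9-CM diagnosis codes (stored in a
compact, decimal-free form) and CCS category numbers (positive integers).
Survey items and chart checkboxes are represented as code sets with no
members and an item label instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "CodeSystem",
    "CodeValue",
    "CodeSet",
    "ParsedCell",
    "CellKind",
    "ValidationError",
    "ContractError",
    "normalize_icd9",
    "normalize_ccs",
    "normalize_code",
    "format_icd9",
    "parse_codeset_spec",
    "is_member",
]


class ValidationError(ValueError):
    """Raised when input data fails vocabulary validation."""


class ContractError(ValueError):
    """Raised when an operation is called outside its contract."""


class CodeSystem(str, Enum):
    ICD9CM = "icd9cm"
    CCS = "ccs"
    SURVEY_ITEM = "survey_item"
    CHECKBOX = "checkbox"


@dataclass(frozen=True)
class CodeValue:
    """A single normalized diagnosis code.

    ICD-9-CM codes are stored compact (no decimal point, optional leading
    ``V``, 3-5 significant characters); CCS codes are positive integers
    rendered as text.
    """

    system: CodeSystem
    normalized: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


class CellKind(str, Enum):
    CODES = "codes"
    SURVEY_ITEM = "survey_item"
    CHECKBOX = "checkbox"
    ALIAS = "alias"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class CodeSet:
    """A set of codes (or a survey/checkbox item) attached to one condition
    within one data-system dialect."""

    system: CodeSystem
    members: frozenset[str] = frozenset()
    item_label: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        code_based = self.system in (CodeSystem.ICD9CM, CodeSystem.CCS)
        if code_based and not self.members:
            raise ValidationError(
                f"code set with system={self.system.value} must have members"
            )
        if not code_based and self.members:
            raise ValidationError(
                f"code set with system={self.system.value} must be empty"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ParsedCell:
    """Outcome of parsing one mapping-table cell.

    ``kind`` discriminates between an actual code set, a survey/checkbox
    item, an alias pointing at another sub-condition, and an explicit
    unavailability marker.
    """

    kind: CellKind
    codeset: Optional[CodeSet] = None
    alias_target: str = ""
    source_note: str = ""
    warnings: tuple[str, ...] = field(default=())


# Dotted or compact ICD-9-CM diagnosis spellings.  Plain codes carry a
# 3-digit base (leading zeros significant, e.g. 016.00); V codes a 2-digit
# base.  E codes are rejected: the scheme uses none, so their appearance
# signals a data problem.
_ICD9_DOTTED = re.compile(r"^(V?)(\d+)(?:\.(\d{1,2}))?$")
_ICD9_COMPACT_PLAIN = re.compile(r"^\d{3,5}$")
_ICD9_COMPACT_V = re.compile(r"^V\d{2,4}$")

_UNAVAILABLE_SENTINELS = {"not applicable", "—", "-", "–", "n/a", "na", ""}


def normalize_icd9(raw: str) -> CodeValue:
    """Normalize an ICD-9-CM diagnosis code to compact form.

    Accepts dotted (``402.01``, ``V10.3``) and compact (``40201``,
    ``V103``) spellings; strips whitespace and case-folds a leading ``v``.

    Raises
    ------
    ValidationError
        If *raw* is not a well-formed ICD-9-CM diagnosis code (E codes are
        rejected as out of scope for the scheme).
    """
    token = raw.strip()
    if not token:
        raise ValidationError("empty ICD-9-CM code")
    if token[0] in "eE":
        raise ValidationError(f"E-code not accepted: {raw!r}")
    if token[0] == "v":
        token = "V" + token[1:]

    if "." in token:
        m = _ICD9_DOTTED.match(token)
        if m is None:
            raise ValidationError(f"malformed ICD-9-CM code: {raw!r}")
        prefix, base, frac = m.group(1), m.group(2), m.group(3) or ""
        expected_base_len = 2 if prefix else 3
        if len(base) != expected_base_len:
            raise ValidationError(
                f"malformed ICD-9-CM code (base must be "
                f"{expected_base_len} digits): {raw!r}"
            )
        return CodeValue(CodeSystem.ICD9CM, prefix + base + frac)

    if token.startswith("V"):
        if _ICD9_COMPACT_V.match(token) is None:
            raise ValidationError(f"malformed ICD-9-CM V-code: {raw!r}")
        return CodeValue(CodeSystem.ICD9CM, token)
    if _ICD9_COMPACT_PLAIN.match(token) is None:
        raise ValidationError(f"malformed ICD-9-CM code: {raw!r}")
    return CodeValue(CodeSystem.ICD9CM, token)


def format_icd9(code: CodeValue | str) -> str:
    """Render a normalized ICD-9-CM code in its dotted display form.

    Round-trips with :func:`normalize_icd9`; codes of 3 significant
    characters (e.g. ``585``, ``V10``) carry no dot.
    """
    if isinstance(code, CodeValue):
        if code.system is not CodeSystem.ICD9CM:
            raise ContractError(f"not an ICD-9-CM code: {code}")
        compact = code.normalized
    else:
        compact = normalize_icd9(code).normalized
    if len(compact) <= 3:
        return compact
    return compact[:3] + "." + compact[3:]


def normalize_ccs(raw: str) -> CodeValue:
    """Normalize a CCS category number (positive integer as text)."""
    token = raw.strip()
    if not re.fullmatch(r"\d+", token):
        raise ValidationError(f"malformed CCS category: {raw!r}")
    value = int(token)
    if value <= 0:
        raise ValidationError(f"CCS category must be positive: {raw!r}")
    return CodeValue(CodeSystem.CCS, str(value))


def normalize_code(raw: str, system: CodeSystem | str) -> CodeValue:
    """Normalize *raw* under the given code system."""
    system = CodeSystem(system)
    if system is CodeSystem.ICD9CM:
        return normalize_icd9(raw)
    if system is CodeSystem.CCS:
        return normalize_ccs(raw)
    raise ContractError(f"system {system.value} has no code normalizer")


_RANGE = re.compile(r"^(\d+)\s*[–-]\s*(\d+)$")
# Prose labels inside a code cell, e.g. "Female breast cancer: 174.0, ..."
_CELL_LABEL = re.compile(r"[A-Za-z][A-Za-z ()]*:\s*")


def _expand_range(lo: int, hi: int) -> list[str]:
    if hi < lo:
        raise ValidationError(f"descending range bounds: {lo}–{hi}")
    return [str(v) for v in range(lo, hi + 1)]


def _tokenize_cell(cell: str) -> list[str]:
    text = _CELL_LABEL.sub("", cell)
    tokens: list[str] = []
    for chunk in text.split(","):
        for piece in chunk.split():
            piece = piece.strip().rstrip(".")
            if piece:
                tokens.append(piece)
    return tokens


def parse_codeset_spec(
    cell: str,
    system: CodeSystem | str,
    *,
    lenient: bool = False,
    source_note: str = "",
) -> ParsedCell:
    """Parse one mapping-table cell into a :class:`ParsedCell`.

    A cell is either a sentinel (``Not applicable``, ``—``,
    ``Self-reported``, ``Checkbox [for ...]``, ``Included in <name>``) or a
    comma-separated list of codes and inclusive integer ranges (en-dash or
    hyphen).  Ranges are CCS-only; duplicates are removed.

    With ``lenient=True`` tokens that fail code validation are dropped and
    reported in ``warnings`` instead of raising — used for known
    transcription artifacts in the packaged scheme.
    """
    system = CodeSystem(system)
    note = source_note or cell
    stripped = cell.strip()
    low = stripped.lower()

    if low in _UNAVAILABLE_SENTINELS:
        return ParsedCell(CellKind.UNAVAILABLE, source_note=note)
    if low.startswith("self-report"):
        return ParsedCell(
            CellKind.SURVEY_ITEM,
            codeset=CodeSet(CodeSystem.SURVEY_ITEM, item_label=stripped,
                            source_note=note),
            source_note=note,
        )
    if low.startswith("checkbox"):
        label = stripped
        m = re.match(r"checkbox\s+for\s+(.+)$", low)
        if m:
            label = stripped[len(stripped) - len(m.group(1)):]
        return ParsedCell(
            CellKind.CHECKBOX,
            codeset=CodeSet(CodeSystem.CHECKBOX, item_label=label,
                            source_note=note),
            source_note=note,
        )
    if low.startswith("included in"):
        target = stripped[len("included in"):].strip()
        if not target:
            raise ValidationError(f"alias cell without target: {cell!r}")
        return ParsedCell(CellKind.ALIAS, alias_target=target,
                          source_note=note)

    if system not in (CodeSystem.ICD9CM, CodeSystem.CCS):
        raise ContractError(
            f"cell {cell!r} lists codes but system is {system.value}"
        )

    members: set[str] = set()
    warnings: list[str] = []
    for token in _tokenize_cell(cell):
        m = _RANGE.match(token)
        if m and system is CodeSystem.CCS:
            members.update(_expand_range(int(m.group(1)), int(m.group(2))))
            continue
        if m:
            raise ValidationError(
                f"ranges are only valid for CCS cells: {token!r}"
            )
        try:
            members.add(normalize_code(token, system).normalized)
        except ValidationError as exc:
            if lenient:
                warnings.append(f"dropped invalid token {token!r}: {exc}")
            else:
                raise
    if not members:
        raise ValidationError(f"cell parsed to an empty code set: {cell!r}")
    return ParsedCell(
        CellKind.CODES,
        codeset=CodeSet(system, members=frozenset(members), source_note=note),
        source_note=note,
        warnings=tuple(warnings),
    )


def is_member(
    code: CodeValue | str,
    codeset: CodeSet,
    *,
    prefix_matching: bool = False,
) -> bool:
    """Membership test for a normalized code in a code set.

    Default semantics are exact match on normalized codes.  With
    ``prefix_matching=True`` a code also matches when any listed member is
    a prefix of it (ICD-9-CM only; CCS categories are atomic).
    """
    if isinstance(code, str):
        code = normalize_code(code, codeset.system)
    if code.system is not codeset.system:
        raise ContractError(
            f"system mismatch: code is {code.system.value}, "
            f"set is {codeset.system.value}"
        )
    if code.normalized in codeset.members:
        return True
    if prefix_matching and codeset.system is CodeSystem.ICD9CM:
        return any(code.normalized.startswith(m) for m in codeset.members)
    return False


def normalize_many(raws: Iterable[str], system: CodeSystem | str) -> list[CodeValue]:
    """Normalize a sequence of raw codes, failing on the first bad token."""
    return [normalize_code(r, system) for r in raws]
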