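"""Synthetic multimorbid populations and their measurement layers.

Condition indicators are generated with a Gaussian-copula construction:
a latent multivariate standard normal with a user-supplied correlation
matrix is thresholded at the quantile matching each condition's marginal
prevalence.  Claims emission draws codes from the registry's code sets
(plus non-scheme decoy codes at a configurable extraneous rate); survey
emission applies per-item sensitivity/specificity misclassification.

All randomness is derived from a single seed; each emission layer uses its
own spawned stream so results are stable across module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, stats

from .code_systems import ContractError, ValidationError
from .coder import ClaimRecord, SurveyRecord
from .registry import Availability, Registry

__all__ = [
    "SyntheticConfig",
    "TruePopulation",
    "simulate_truth",
    "emit_claims",
    "emit_survey",
    "decoy_codes",
    "correlation_from_odds_ratio",
]

_STREAM_TRUTH, _STREAM_CLAIMS, _STREAM_SURVEY = 0, 1, 2


class SyntheticConfig(BaseModel):
    """Full parameterization of one simulated population."""

    n_units: int = Field(gt=0)
    prevalence: dict[str, float]
    association: Optional[list[list[float]]] = None
    claims_per_unit: float = Field(default=3.0, ge=0)
    extraneous_code_rate: float = Field(default=0.0, ge=0, lt=1)
    self_report_sensitivity: float = Field(default=1.0, gt=0, le=1)
    self_report_specificity: float = Field(default=1.0, gt=0, le=1)
    seed: int = 0

    @field_validator("prevalence")
    @classmethod
    def _prevalence_open_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for cid, p in v.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {cid} must be in (0, 1): {p}")
        return v

    @model_validator(mode="after")
    def _association_shape(self) -> "SyntheticConfig":
        if self.association is not None:
            k = len(self.prevalence)
            mat = np.asarray(self.association, dtype=float)
            if mat.shape != (k, k):
                raise ValueError(
                    f"association must be {k}x{k}, got {mat.shape}"
                )
        return self

    def association_matrix(self) -> np.ndarray:
        k = len(self.prevalence)
        if self.association is None:
            return np.eye(k)
        return np.asarray(self.association, dtype=float)


@dataclass(frozen=True)
class TruePopulation:
    """Per-unit true condition indicators plus the generating config."""

    unit_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    flags: np.ndarray  # bool, shape (n_units, n_conditions)
    config: SyntheticConfig

    def prevalence(self) -> dict[str, float]:
        means = self.flags.mean(axis=0)
        return {cid: float(m) for cid, m in zip(self.condition_ids, means)}

    def condition_set(self, i: int) -> frozenset[str]:
        return frozenset(
            cid for cid, f in zip(self.condition_ids, self.flags[i]) if f
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flags.astype(int),
            index=list(self.unit_ids),
            columns=list(self.condition_ids),
        ).rename_axis("unit_id")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _latent_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = corr; validates the correlation matrix."""
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("association matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValidationError("association matrix must have a unit diagonal")
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-10:
        raise ValidationError(
            f"association matrix is not positive semidefinite "
            f"(eigenvalue {eigvals.min():.3e})"
        )
    return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_truth(config: SyntheticConfig) -> TruePopulation:
    """Draw the true condition indicators for a population.

    Deterministic under a fixed config seed.  Raises a validation error for
    a non-positive-semidefinite association matrix, naming the offending
    eigenvalue.
    """
    condition_ids = tuple(config.prevalence)
    corr = config.association_matrix()
    factor = _latent_factor(corr)
    rng = _stream(config.seed, _STREAM_TRUTH)
    latent = rng.standard_normal((config.n_units, len(condition_ids))) @ factor.T
    thresholds = stats.norm.ppf(
        [config.prevalence[cid] for cid in condition_ids]
    )
    flags = latent <= thresholds
    width = max(6, len(str(config.n_units)))
    unit_ids = tuple(f"u{i:0{width}d}" for i in range(config.n_units))
    return TruePopulation(
        unit_ids=unit_ids,
        condition_ids=condition_ids,
        flags=flags,
        config=config,
    )


def decoy_codes(
    registry: Registry, dialect_id: str, n: int = 40
) -> tuple[str, ...]:
    """Valid-format codes guaranteed absent from every condition's code set.

    ICD-9-CM decoys use 3-digit bases that appear nowhere in the scheme
    (so they cannot match even under prefix matching); CCS decoys are
    category numbers outside every listed set.
    """
    dialect = registry.dialect(dialect_id)
    if not dialect.is_code_based:
        raise ContractError(f"dialect {dialect_id} has no code vocabulary")
    union: set[str] = set()
    for cid in registry.condition_ids:
        union |= registry.flattened_codes(cid, dialect_id)
    out: list[str] = []
    if dialect.code_system.value == "icd9cm":
        used_bases = {c[:3] for c in union}
        for base in range(1, 1000):
            b = f"{base:03d}"
            if b in used_bases:
                continue
            out.append(b + "99")
            if len(out) == n:
                break
    else:
        used = {int(c) for c in union}
        candidate = 300
        while len(out) < n:
            if candidate not in used:
                out.append(str(candidate))
            candidate += 1
    return tuple(out)


def emit_claims(
    truth: TruePopulation,
    dialect_id: str,
    config: Optional[SyntheticConfig] = None,
    *,
    registry: Registry,
) -> list[ClaimRecord]:
    """Emit claims records realizing the true population in a code dialect.

    Every true condition measured in the dialect contributes at least one
    claim carrying a code drawn uniformly from its registry code set;
    additional claims repeat true-condition codes up to the configured mean
    claims per unit, and decoy (non-scheme) codes are appended at the
    extraneous rate as separate claims.
    """
    config = config or truth.config
    dialect = registry.dialect(dialect_id)
    if not dialect.is_code_based:
        raise ContractError(f"dialect {dialect_id} has no code-based mapping")

    # Prefer codes listed only under this condition so that emitted claims
    # identify it unambiguously; where the printed scheme gives a condition
    # no distinctive code (e.g. a CCS category shared with another
    # condition) fall back to the full set — measurement crosstalk is then
    # a property of the scheme itself, not of the generator.
    all_codes: dict[str, frozenset[str]] = {}
    for cid in truth.condition_ids:
        mapping = registry.mapping(cid, dialect_id)
        if mapping.state is not Availability.UNAVAILABLE and mapping.codes:
            all_codes[cid] = mapping.codes
    code_pools: dict[str, list[str]] = {}
    for cid, codes in all_codes.items():
        shared = set().union(
            *(c for other, c in all_codes.items() if other != cid)
        )
        distinctive = codes - shared
        code_pools[cid] = sorted(distinctive or codes)

    decoys = decoy_codes(registry, dialect_id)
    rate = config.extraneous_code_rate
    rng = _stream(config.seed, _STREAM_CLAIMS)
    records: list[ClaimRecord] = []
    for i, unit_id in enumerate(truth.unit_ids):
        true_measured = [
            cid for cid in truth.condition_set(i) if cid in code_pools
        ]
        codes: list[str] = [
            code_pools[cid][rng.integers(len(code_pools[cid]))]
            for cid in sorted(true_measured)
        ]
        n_base = len(codes)
        if n_base:
            n_extra = rng.poisson(max(0.0, config.claims_per_unit - n_base))
            for _ in range(n_extra):
                cid = true_measured[rng.integers(len(true_measured))]
                pool = code_pools[cid]
                codes.append(pool[rng.integers(len(pool))])
        if rate > 0.0:
            n_decoy = rng.binomial(max(n_base, 1), rate / (1.0 - rate))
            codes.extend(
                decoys[rng.integers(len(decoys))] for _ in range(n_decoy)
            )
        for j, code in enumerate(codes):
            records.append(
                ClaimRecord(
                    unit_id=unit_id,
                    record_id=f"{unit_id}-c{j:03d}",
                    codes=(code,),
                    code_system=dialect.code_system,
                )
            )
    return records


def emit_survey(
    truth: TruePopulation,
    dialect_id: str,
    config: Optional[SyntheticConfig] = None,
    *,
    registry: Registry,
) -> list[SurveyRecord]:
    """Emit survey/checkbox responses with misclassification.

    Each measured condition's item answers yes with probability
    ``sensitivity`` when the condition is truly present and ``1 -
    specificity`` when absent, independently per item.
    """
    config = config or truth.config
    dialect = registry.dialect(dialect_id)
    if dialect.is_code_based:
        raise ContractError(
            f"dialect {dialect_id} is code-based; use emit_claims"
        )
    measured = [
        cid
        for cid in truth.condition_ids
        if registry.mapping(cid, dialect_id).state
        is not Availability.UNAVAILABLE
    ]
    sens = config.self_report_sensitivity
    spec = config.self_report_specificity
    rng = _stream(config.seed, _STREAM_SURVEY)
    records: list[SurveyRecord] = []
    col = {cid: j for j, cid in enumerate(truth.condition_ids)}
    for i, unit_id in enumerate(truth.unit_ids):
        items: dict[str, str] = {}
        for cid in measured:
            p_yes = sens if truth.flags[i, col[cid]] else 1.0 - spec
            items[cid] = "yes" if rng.random() < p_yes else "no"
        records.append(SurveyRecord(unit_id=unit_id, items=items))
    return records


def correlation_from_odds_ratio(
    p1: float, p2: float, odds_ratio: float
) -> float:
    """Latent correlation reproducing a target pairwise odds ratio.

    Solves for the bivariate-normal correlation whose thresholded joint
    probability yields the requested odds ratio between two binary
    indicators with marginal prevalences *p1* and *p2*.  The mapping is an
    approximation in the tails; an odds ratio of 1 maps to correlation 0.
    """
    if odds_ratio <= 0:
        raise ValidationError("odds ratio must be positive")
    if odds_ratio == 1.0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)

    def objective(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        p10 = p1 - p11
        p01 = p2 - p11
        p00 = 1.0 - p1 - p2 + p11
        return (p11 * p00) / (p10 * p01) - odds_ratio

    return float(optimize.brentq(objective, -0.99, 0.99, xtol=1e-8))
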