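"""Error-tolerant probabilistic record linkage.

Each configured field is compared with a similarity in [0, 1] (exact
match, padded-bigram Dice for names, exact comparison of decomposed date
components).  Field similarities are combined into a record score

    score = sum(w_i * s_i) / sum(w_i),   w_i = log2((1 - e_i) / f_i)

over the fields present on both sides, where ``e_i`` is the probability
that the field disagrees between records of the *same* person (data
entry errors) and ``f_i`` the probability that it agrees by chance
between *different* persons (roughly the frequency of the most common
value).  Rare, reliable fields therefore carry more weight.  Two
thresholds split the score range into non-match, tentative match
(queued for human conflict resolution) and match; the upper boundary is
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from math import log2
from typing import Mapping, Optional, Sequence

from .errors import ConfigError, EmptyIdentityError, LinkageError
from .model import Identity, Patient, PatientStore
from .normalize import DEFAULT_FIELDS

MISSING = None


class Comparator(str, Enum):
    EXACT = "EXACT"
    NGRAM_DICE = "NGRAM_DICE"
    DATE_COMPONENT = "DATE_COMPONENT"


class Decision(str, Enum):
    MATCH = "MATCH"
    TENTATIVE = "TENTATIVE"
    NON_MATCH = "NON_MATCH"


@dataclass(frozen=True)
class FieldComparatorConfig:
    """Per-field comparator with its error rate e and chance-agreement rate f."""

    field_name: str
    comparator: Comparator
    error_rate: float = 0.01
    frequency: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 1.0:
            raise ConfigError("error_rate must lie in (0, 1)")
        if not 0.0 < self.frequency < 1.0:
            raise ConfigError("frequency must lie in (0, 1)")
        if (1.0 - self.error_rate) / self.frequency <= 1.0:
            raise ConfigError("(1 - e) / f must exceed 1 so the field weight is positive")

    @property
    def weight(self) -> float:
        return log2((1.0 - self.error_rate) / self.frequency)


@dataclass(frozen=True)
class LinkageConfig:
    comparators: tuple[FieldComparatorConfig, ...]
    threshold_nonmatch: float = 0.80  # lower threshold: below it, non-match
    threshold_match: float = 0.95  # upper threshold: at or above it, match
    auto_reject_tentative: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_nonmatch <= self.threshold_match <= 1.0:
            raise ConfigError("thresholds must satisfy 0 <= lower <= upper <= 1")


#: Default chance-agreement rates for the default schema.
_DEFAULT_FREQUENCIES = {
    "first_name": 0.01,
    "last_name": 0.005,
    "birth_day": 1.0 / 31.0,
    "birth_month": 1.0 / 12.0,
    "birth_year": 1.0 / 70.0,
    "city": 0.05,
}
_DEFAULT_COMPARATORS = {
    "first_name": Comparator.NGRAM_DICE,
    "last_name": Comparator.NGRAM_DICE,
    "birth_day": Comparator.DATE_COMPONENT,
    "birth_month": Comparator.DATE_COMPONENT,
    "birth_year": Comparator.DATE_COMPONENT,
    "city": Comparator.NGRAM_DICE,
}


def default_linkage_config(
    fields: Sequence[str] = DEFAULT_FIELDS,
    threshold_nonmatch: float = 0.80,
    threshold_match: float = 0.95,
    auto_reject_tentative: bool = False,
) -> LinkageConfig:
    comparators = tuple(
        FieldComparatorConfig(
            name,
            _DEFAULT_COMPARATORS.get(name, Comparator.EXACT),
            error_rate=0.01,
            frequency=_DEFAULT_FREQUENCIES.get(name, 0.01),
        )
        for name in fields
    )
    return LinkageConfig(comparators, threshold_nonmatch, threshold_match, auto_reject_tentative)


# ---------------------------------------------------------------------------
# Field similarity
# ---------------------------------------------------------------------------


@lru_cache(maxsize=65536)
def padded_bigrams(value: str) -> tuple[tuple[str, int], ...]:
    """Multiset of overlapping bigrams of "_value_" as (gram, count) pairs."""
    padded = f"_{value}_"
    counts: dict[str, int] = {}
    for i in range(len(padded) - 1):
        gram = padded[i : i + 2]
        counts[gram] = counts.get(gram, 0) + 1
    return tuple(sorted(counts.items()))


def _dice_multiset(a: tuple[tuple[str, int], ...], b: tuple[tuple[str, int], ...]) -> float:
    counts_b = dict(b)
    shared = sum(min(n, counts_b.get(gram, 0)) for gram, n in a)
    total = sum(n for _, n in a) + sum(n for _, n in b)
    return 2.0 * shared / total if total else 1.0


def compare_field(a: Optional[str], b: Optional[str], comparator: Comparator) -> Optional[float]:
    """Similarity in [0, 1]; MISSING (None) if either side is absent."""
    if a is MISSING or b is MISSING:
        return MISSING
    if comparator is Comparator.NGRAM_DICE:
        return _dice_multiset(padded_bigrams(a), padded_bigrams(b))
    # EXACT and DATE_COMPONENT: both operate on normalized strings.
    return 1.0 if a == b else 0.0


# ---------------------------------------------------------------------------
# Record score and classification
# ---------------------------------------------------------------------------


def _as_fields(identity: Identity | Mapping[str, Optional[str]]) -> Mapping[str, Optional[str]]:
    return identity.field_values if isinstance(identity, Identity) else identity


def field_similarities(
    identity_a: Identity | Mapping[str, Optional[str]],
    identity_b: Identity | Mapping[str, Optional[str]],
    config: LinkageConfig,
) -> dict[str, float]:
    a, b = _as_fields(identity_a), _as_fields(identity_b)
    sims: dict[str, float] = {}
    for comp in config.comparators:
        sim = compare_field(a.get(comp.field_name), b.get(comp.field_name), comp.comparator)
        if sim is not MISSING:
            sims[comp.field_name] = sim
    return sims


def epilink_score(
    identity_a: Identity | Mapping[str, Optional[str]],
    identity_b: Identity | Mapping[str, Optional[str]],
    config: LinkageConfig,
) -> float:
    """Weighted-average similarity over fields non-missing on both sides."""
    sims = field_similarities(identity_a, identity_b, config)
    if not sims:
        raise LinkageError("no comparable (mutually non-missing) fields")
    weights = {c.field_name: c.weight for c in config.comparators}
    total = sum(weights[name] for name in sims)
    return sum(weights[name] * sim for name, sim in sims.items()) / total


def classify(score: float, config: LinkageConfig) -> tuple[Decision, bool]:
    """Map a score to a decision; the second element flags an auto-rejected tentative."""
    if score >= config.threshold_match:
        return Decision.MATCH, False
    if score >= config.threshold_nonmatch:
        if config.auto_reject_tentative:
            return Decision.NON_MATCH, True
        return Decision.TENTATIVE, False
    return Decision.NON_MATCH, False


@dataclass
class MatchResult:
    decision: Decision
    best_patient: Optional[Patient]
    score: float
    per_field_similarities: dict[str, float]
    rejected_tentative: bool = False


def match_candidate(
    identity: Identity | Mapping[str, Optional[str]],
    store: PatientStore,
    config: LinkageConfig,
    block_index=None,
) -> MatchResult:
    """Score an incoming identity against every identity of every candidate patient.

    Candidates come from the blocking index if one is supplied, otherwise
    all non-absorbed patients are compared.  A patient's score is the
    maximum over its MAIN and ALIAS identities; ties between patients are
    broken by the lowest internal record handle for reproducibility.
    """
    probe = identity if isinstance(identity, Identity) else Identity(dict(identity))
    if not probe.non_missing():
        raise EmptyIdentityError("cannot match an identity with no non-missing fields")

    if block_index is not None:
        candidate_keys = block_index.candidates(probe)
        candidates = [
            store.patients[key]
            for key in sorted(candidate_keys)
            if key in store.patients and store.patients[key].duplicate_of is None
        ]
    else:
        candidates = sorted(store.active_patients(), key=lambda p: p.internal_key)

    best_patient: Optional[Patient] = None
    best_score = 0.0
    best_sims: dict[str, float] = {}
    for patient in candidates:
        for ident in patient.identities:
            try:
                score = epilink_score(probe, ident, config)
            except LinkageError:
                continue
            if score > best_score or best_patient is None and score > 0.0:
                best_patient, best_score = patient, score
                best_sims = field_similarities(probe, ident, config)

    if best_patient is None:
        return MatchResult(Decision.NON_MATCH, None, 0.0, {})
    decision, rejected = classify(best_score, config)
    return MatchResult(decision, best_patient, best_score, best_sims, rejected)


# ---------------------------------------------------------------------------
# Ingestion pipeline and conflict resolution
# ---------------------------------------------------------------------------


@dataclass
class IngestOutcome:
    decision: Decision
    patient: Optional[Patient]
    score: float
    created: bool
    rejected_tentative: bool = False


def ingest_identity(
    store: PatientStore,
    fields: Mapping[str, object],
    config: LinkageConfig,
    block_index=None,
    tenant: str | None = None,
) -> IngestOutcome:
    """Normalize, match, then create / attach / queue the incoming record.

    MATCH: return the existing patient (the identity is appended as an
    alias when it differs from every stored identity).  TENTATIVE: a new
    patient is created and the pair queued for conflict resolution —
    unless auto-reject is on, in which case the record is rejected and
    nothing is stored.  NON_MATCH: a new patient is created.
    """
    probe = Identity.from_raw(fields)
    result = match_candidate(probe, store, config, block_index)

    if result.decision is Decision.MATCH:
        patient = store.resolve(result.best_patient)
        if not any(probe.same_values(ident) for ident in patient.identities):
            store.add_identity(patient, probe, as_main=False)
            if block_index is not None:
                block_index.add_identity(patient.internal_key, probe)
        if tenant:
            store.enroll(patient, tenant)
        return IngestOutcome(Decision.MATCH, patient, result.score, created=False)

    if result.rejected_tentative:
        return IngestOutcome(Decision.NON_MATCH, None, result.score, created=False,
                             rejected_tentative=True)

    patient = store.new_patient(probe, tenant=tenant)
    if block_index is not None:
        block_index.add_patient(patient)
    if result.decision is Decision.TENTATIVE and not store.is_excluded(patient, result.best_patient):
        store.record_tentative(patient, result.best_patient, result.score)
    return IngestOutcome(result.decision, patient, result.score, created=True)


class ConflictDecision(str, Enum):
    MERGE = "MERGE"
    SPLIT = "SPLIT"


def list_tentative_pairs(store: PatientStore) -> list[tuple[Patient, Patient, float]]:
    return store.list_tentative_pairs()


def resolve_conflict(
    store: PatientStore,
    pair: tuple[Patient, Patient],
    decision: ConflictDecision,
    actor: str | None = None,
):
    """Resolve a queued tentative pair by merging or splitting."""
    a, b = pair
    key = frozenset((a.internal_key, b.internal_key))
    if key not in store.tentative_pairs:
        raise LinkageError("pair is not in the tentative-match list")
    if ConflictDecision(decision) is ConflictDecision.MERGE:
        survivor, absorbed = sorted((a, b), key=lambda p: p.internal_key)
        return store.merge_patients(survivor, absorbed, actor=actor)
    return store.split_patients(a, b, actor=actor)
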