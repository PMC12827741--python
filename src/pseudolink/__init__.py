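"""pseudolink: pseudonymization, error-tolerant record linkage, and
informed-consent management for patient registries and research networks.

The package keeps personally identifiable information (PII) behind
pseudonyms, links records of the same person despite data-entry errors
(optionally on Bloom-filter-encoded fields so the matcher never sees
plaintext), manages modular informed consents with FHIR serialization,
and gates every patient operation behind a session/token delegation
model with multi-tenant role-based access control and an audit trail.
"""

from .batch import BatchJob, BatchQueue, JobState, batch_export, batch_import, run_import
from .benchmark import BenchmarkResult, run_benchmark
from .blocking import (
    BlockIndex,
    BlockingConfig,
    BlockingMethod,
    BlockingVariable,
    block_keys,
    soundex_encode,
)
from .consent import (
    Choice,
    ConsentModule,
    ConsentRecord,
    ConsentStatus,
    ConsentStore,
    ConsentTemplate,
    PolicyDecision,
    PolicyOutcome,
    Scan,
    consent_from_fhir,
    consent_to_fhir,
)
from .crypto import (
    CryptoIDConfig,
    Direction,
    TransportEnvelope,
    TransportKeyPair,
    cryptoid_derive,
    cryptoid_forward,
    cryptoid_invert,
    generate_transport_keypair,
    transport_decrypt,
    transport_encrypt,
)
from .elasticid import ElasticIDConfig, elasticid_generate
from .linkage import (
    Comparator,
    ConflictDecision,
    Decision,
    FieldComparatorConfig,
    IngestOutcome,
    LinkageConfig,
    MatchResult,
    classify,
    compare_field,
    default_linkage_config,
    epilink_score,
    ingest_identity,
    list_tentative_pairs,
    match_candidate,
    resolve_conflict,
)
from .model import (
    Identity,
    IdentityKind,
    Patient,
    PatientStore,
    Pseudonym,
    PseudonymOrigin,
    PseudonymTypeDef,
)
from .normalize import DEFAULT_FIELDS, normalize_name, normalize_record
from .pid import (
    PID_ALPHABET,
    PIDConfig,
    PIDMode,
    PIDStatus,
    VerificationResult,
    make_pid_generator,
    pid_encode,
    pid_verify,
)
from .pprl import (
    BloomField,
    BloomFilterConfig,
    bloom_encode,
    dice_cleartext,
    dice_similarity,
    extract_ngrams,
    lsh_keys,
)
from .service import (
    AuditRecord,
    ClientConfig,
    Grant,
    PseudonymizationService,
    Role,
    ServiceConfig,
    Session,
    Token,
    TokenState,
    TokenType,
)
from .synth import ErrorModel, NamePools, corrupt_record, generate_cohort

__version__ = "0.1.0"


def default_store(mixing_key: bytes, pid_mode: PIDMode = PIDMode.CORRECT1) -> PatientStore:
    """A PatientStore with the default schema and an internal ``pid`` type
    minting check-charactered identifiers under ``mixing_key``."""
    config = PIDConfig(mixing_key=mixing_key, mode=pid_mode)
    return PatientStore(
        pseudonym_types=[PseudonymTypeDef("pid", generator=make_pid_generator(config))]
    )
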