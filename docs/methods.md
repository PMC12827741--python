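# Methods

This note documents the models and procedures implemented in
`pseudolink`, the parameters that matter, the numerical and design
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Identity model

A patient is a person tracked over time; their identifying fields may
change (marriage, relocation, typo fixes). The store therefore never
overwrites PII: every snapshot is an *identity*, exactly one of which is
MAIN (shown to users) while the rest are ALIAS identities that still
participate in matching and lookups. Identities are append-only;
duplicate records discovered late are resolved by *merge* (the absorbed
record points to the survivor via `duplicate_of`, its identities become
aliases of the survivor, and its pseudonyms resolve to the survivor) or
by *split* (the pair is recorded as a permanent exclusion the matcher
consults, so the same conflict cannot recur). `duplicate_of` chains are
acyclic by construction (merging an absorbed record is refused).
Merge keeps the survivor's MAIN identity; which record survives is the
caller's choice (the built-in conflict resolver picks the lower record
handle for reproducibility). Internal record handles are opaque
integers and never leave the store — exports are keyed by pseudonyms.

## Record linkage

Normalization precedes every comparison: names are uppercased,
compatibility-decomposed, stripped of diacritics and non-alphanumerics
(ß→SS); dates are decomposed into day/month/year components compared as
separate exact fields. Field similarities: exact (0/1) for components,
Dice of padded bigram multisets for names ("ANNA" → {_A, AN, NN, NA,
A_}).

The record score is the weighted average Σw·s / Σw over fields present
on both sides, with w = log2((1−e)/f): e is the field's error rate
among true matches, f its chance-agreement rate among non-matches.
Defaults: e = 0.01 everywhere; f = 0.01 (first name), 0.005 (last
name), 1/31, 1/12, 1/70 (birth day/month/year), 0.05 (city). All are
config-overridable; the invariant (1−e)/f > 1 keeps weights positive.
Missing fields drop out of numerator and denominator, so partial
records are scored on what they share rather than penalized.

Classification uses two thresholds (defaults 0.80 / 0.95), upper
boundary inclusive; between them the pair is a *tentative match*,
stored as two separate records plus a queued pair for human merge/split
resolution. With `auto_reject_tentative` the record is instead refused
outright and nothing is stored — the submitter must correct and resend.
A candidate patient's score is the maximum over its identities (MAIN
and ALIAS); ties between patients break toward the lowest internal
handle so runs are deterministic. Which of the two thresholds the
literature letters "A"/"B" refer to is not fixed anywhere we rely on;
here the lower bound is the non-match boundary and the upper the match
boundary.

## PID check code

PIDs are 8 characters over the 32-symbol alphabet `0–9` plus the
consonant-heavy letters excluding B, I, O, S (confusable with 8, 1, 0,
5). The 30-bit counter is scrambled by a 4-round keyed Feistel
permutation (HMAC-SHA256 round function, 15-bit halves) — bijective,
deterministic, and key-dependent, so no mapping table is stored and
identifiers leak nothing about registration order. The scrambled
payload (6 symbols) is extended by 2 check symbols of a systematic
Reed-Solomon-style [8, 6] code over GF(32) (primitive polynomial
x⁵+x²+1, generator roots α, α²), minimum distance 3. Decoding computes
the two syndromes; CORRECT1 mode repairs any single substitution via
the standard one-error syndrome solution (error position log(S₂/S₁)),
DETECT2 mode refuses any nonzero syndrome, which distance 3 guarantees
for up to two substitutions. The two guarantees are mutually exclusive
at distance 3, so the mode is configuration, not runtime choice.
Verification is case-insensitive; malformed input yields INVALID, never
an exception.

## CryptoID, ElasticID, transport encryption

CryptoIDs are deterministic authenticated encryptions of a base
pseudonym in an SIV-style construction from HMAC-SHA256: a truncated
MAC of the plaintext serves as synthetic IV for an HMAC-counter
keystream and is re-verified on inversion, so a wrong key fails loudly.
Determinism is required — the value is regenerated on every access
rather than stored. Output is base-N over a configurable alphabet.

ElasticIDs expand a counter through a pattern of vocabulary and digit
slots by mixed-radix decomposition: deterministic, injective up to the
pattern capacity, with an optional maximum length (tube labels).

Transport protection of pseudonyms to a trusted third party uses hybrid
encryption: an ephemeral Diffie-Hellman exchange over the RFC 3526
2048-bit MODP group against the recipient's long-term public key,
HKDF-style key separation, an HMAC-counter stream cipher and an
encrypt-then-MAC tag. Fresh ephemeral keys and nonces make equal
plaintexts produce distinct envelopes; tag verification precedes any
decryption output. All primitives are built from the standard library's
`hmac`/`hashlib`/`secrets`; no key-management infrastructure is
included.

## PPRL

Name fields are encoded as m-bit Bloom filters: each padded bigram sets
k positions by keyed double hashing, position_i = (h1 + i·h2) mod m
with h1, h2 HMAC-SHA256 under a shared secret. Defaults m = 500,
k = 10. The Dice coefficient 2|a∧b|/(|a|+|b|) of two filters
approximates the clear-text bigram Dice and plugs into the linkage
scoring unchanged. Conventions: both filters empty → 1.0, exactly one
empty → 0.0. Serialization is lowercase hex with filter position 0 in
the most significant bit of byte 0 (a bit-exact contract).

Accuracy caveat, measured not assumed: for *same-person* name pairs
(one or two character edits) the mean |Bloom Dice − clear-text Dice| is
≈ 0.03 at the defaults. For *unrelated* pairs the filter inflates Dice
by roughly the fill fraction (~74 set bits / 500 ≈ 0.15), an inherent
property of Bloom-filter Dice at these parameters; it does not affect
decisions because unrelated pairs sit far below the thresholds either
way. The fidelity bound in the acceptance suite is therefore evaluated
on same-person pairs, where comparator accuracy actually decides
outcomes. With collisions absent (verifiable at large m), Bloom Dice
equals clear-text Dice exactly. Hardening variants (balancing, salting,
xor-folding) and attack tooling are out of scope.

## Blocking

Three default variables, union (OR) semantics: Soundex of the last
name, the birth-year value, and LSH band keys of the Bloom-encoded
first name. Union semantics mean a typo in one blocked field cannot
hide a record that agrees on another; alias identities contribute keys
too. A probe yielding no key at all falls back to exhaustive
comparison. Soundex is the classic American variant: first letter plus
three digits, H/W transparent for run-collapsing, vowels silent but
run-breaking.

LSH keys sample fixed seeded bit positions: Q bands of L bits each
(key = band index + sampled bits). Name filters are sparse (~15% fill),
so agreement on a narrow band is dominated by shared zero bits; the
default is therefore Q = 8 wide bands of L = 32 bits, which keeps
unrelated-pair band collisions at the few-percent level while a
single-typo variant still shares a band with useful probability — and
recall is carried jointly with the other two variables. The positions
derive from a fixed config seed so the index is stable across a store's
lifetime. Blocking only restricts which pairs are *scored*; it never
alters a score, so every blocked MATCH is also an exhaustive-comparison
MATCH.

## Consent

Templates model consent forms: ordered modules (one per checkbox), each
granting one or more policy identifiers, some required, with an
optional validity period. Records store a patient's per-module
PERMIT/DENY choices against a template version with monotone
versioning; re-consent supersedes, history is append-only. Full
withdrawal flips the active record to WITHDRAWN from its withdrawal
date; partial withdrawal records a successor version with the named
modules set to DENY (the two flavors are deliberately distinct).

`check_policy(patient, policy, date)` evaluates the highest applicable
version signed on or before the date: withdrawal and validity expiry
yield DENY (fail-safe — an expired legal basis is no legal basis);
PERMIT requires a covering module permitted at that date; UNKNOWN is
reserved for "never asked", so callers can distinguish absence from
refusal. Across templates covering the same policy, DENY wins.

Serialization targets structural conformance with the base FHIR
resources: a Consent resource (one provision per module, status
active/inactive, template identity in `policy.uri`, version in
`meta.versionId`), a DocumentReference with the Base64-encoded scan
(application/pdf or image/png), and a Provenance resource linking the
two — present exactly when a scan is attached. Strict national-profile
validation is out of scope.

## Sessions, tokens, permissions, audit

Clients authenticate with pre-shared API keys and open sessions
(128-bit-random ids, 10-minute default expiry, injectable clock).
Tokens are bound to their session, authorize exactly one operation
class (ADD/READ/EDIT/DELETE patient), default to single-use, and
require a logged reason when the audit trail is enabled. Redemption
validates first (invalid attempts consume nothing), then atomically
marks single-use tokens REDEEMED before executing, so a token can never
run twice; execution failures still consume the token and still audit.
ADD_PATIENT redemption runs the full ingestion pipeline, mints the
tenant's project pseudonym on enrollment, returns to the redeemer only
the pseudonym types named in the token payload, and delivers a
different set to the pre-registered (allow-listed) callback URL — the
mechanism by which the end user can see a study id while the internal
pid goes only to the backend. Callback delivery is at-least-once with
bounded retries and an HMAC-signed payload; failures are logged and
never block the redeemer's response.

Permissions are deny-by-default grant strings
`action[:qualifier][|requires-policy:<id>]` per role; tenant grants
scope patient visibility (a patient with tenants is visible only to
roles sharing one), and `requires-policy` gates a grant on a PERMIT
from the consent store. The audit trail is append-only: exactly one
record per consumed token, carrying client, role, token type, reason,
and affected pseudonyms — never raw PII.

The engine is in-process and transport-agnostic by design (callbacks
and time are injected), so the full authorization logic is testable
without networking; an HTTP layer would be a thin shell over it.

## Synthetic cohorts and the error model

The generator samples identity records from built-in pools: ~1,000
surnames composed from 40 common German surname prefixes × 25 suffixes
(ordered suffix-major so the frequency head spans many Soundex codes),
~1,000 given names (120 common seeds plus compounds), 60 cities, birth
dates uniform over 1935–2004 (70 years, matching the default
f = 1/70) with days 1–28. Frequencies follow a Zipf-Mandelbrot law
(exponent 1.07, rank shift 50; cities shift 5): the most common surname
carries ~0.7% of the mass and the most common city ~8%, consistent with
real name-frequency tables and with the linkage defaults f. Base
records are unique as full tuples; duplicates corrupt a without-
replacement sample of base records.

The error model applies, independently per field: character
substitution (rate 0.01), insertion, deletion, adjacent transposition
(0.003 each) on text fields; a redrawn date component (0.01 per
component); a blanked field (0.02). The character rates are chosen to
mirror the linkage model's default assumed per-field error probability
e = 0.01, so the generator and the matcher describe the same world.
Applied corruptions are tagged per record for stratified evaluation.
Everything is a pure function of the seed; cohort generation and the
benchmark are reproducible bit-for-bit.

What the generator does *not* emulate: swapped field contents
(first/last name exchange), nicknames and transliteration variants,
correlated household addresses, duplicate chains (three or more records
of one person), or realistic missingness structure (fields go missing
independently). Passing benchmarks therefore demonstrate the pipeline's
behavior under clean, independent typographic noise at realistic rates
— not performance on any specific real registry.

## Benchmark sizes and determinism

The shipped evaluation ingests 5,000 base + 1,000 duplicate records
with blocking enabled (a few seconds' work), measuring end-to-end
precision/recall of MATCH decisions against ground truth, blocking
recall, and the candidate-pair fraction; smaller instances (≤ 500
records) are cross-checked against an exhaustive all-pairs oracle in
the tests. Property sweeps (score contract, PID corruption
enumeration) run tens of thousands of cases. All test and script
randomness is seeded; the acceptance script derives every random source
from its `--seed` argument.

## Known limitations

* The patient store is in-memory with CSV export; durable storage is a
  caller concern.
* Bloom-filter encodings are not hardened against the published
  reconstruction attacks; for adversarial settings stronger protocols
  (e.g., secure multi-party computation) are required and out of scope.
* Exchange groups (swapped fields) are neither generated nor modeled by
  a comparator, so a first/last name swap scores low.
* FHIR output is structurally conformant but not validated against
  national profiles.
* Cross-tenant linkage policy is a boolean visibility rule, not a
  policy engine.
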