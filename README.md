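# pseudolink

Pseudonymization, error-tolerant record linkage, and informed-consent
management for patient registries, biobanks, and medical research
networks — as an importable Python toolkit.

Collaborative biomedical research routinely needs to recognize that two
records at different institutions (or different visits) belong to the
same person, without a shared unique identifier, and to keep the
identifying data (PII) separate from the medical data (MDAT).
`pseudolink` implements the building blocks of a trusted-third-party
patient list that makes this possible:

* **Pseudonyms** — short check-charactered patient identifiers (PIDs)
  that detect or even self-correct typing errors; deterministic
  key-derived CryptoIDs that never need to be stored; vocabulary-based
  ElasticIDs for human-friendly labels; hybrid (asymmetric + symmetric)
  transport encryption for handing pseudonyms to a trusted third party.
* **Record linkage** — per-field similarities combined into a weighted
  score in [0, 1], classified against two thresholds into match /
  tentative match / non-match, with alias identities, merge/split
  conflict resolution, and an auto-reject mode.
* **Privacy-preserving linkage (PPRL)** — keyed Bloom-filter encodings
  of name fields whose Dice similarity stands in for the clear-text
  comparison, so records can be linked without exchanging plaintext PII.
* **Blocking** — Soundex, birth-year, and LSH buckets that cut the
  quadratic comparison space to a few percent without losing true pairs.
* **Consent management** — modular consent templates, versioning and
  (partial) withdrawal, date-dependent policy checks, and FHIR
  Consent / DocumentReference / Provenance serialization.
* **Sessions, tokens, RBAC, audit** — every patient operation is gated
  by a single-purpose token inside an authenticated session, with
  multi-tenant deny-by-default permissions and an append-only audit
  trail.
* **Bulk operations and synthetic cohorts** — CSV import/export with
  job semantics, plus a seeded generator of realistic identity records
  with injected data-entry errors and ground-truth duplicate labels, so
  the whole stack is testable without real PII.

## The score at the core

Two identity records A and B are compared field by field (exact match
for date components, padded-bigram Dice for names), and the field
similarities s_i are combined as

    score(A, B) = Σ w_i · s_i / Σ w_i        over fields present in both,
    w_i = log2((1 − e_i) / f_i)

where e_i is the probability that field i disagrees between records of
the *same* person (data-entry error rate) and f_i the probability that
it agrees by chance between *different* persons. Rare, reliable fields
therefore dominate the score. Two thresholds split [0, 1] into
non-match, tentative match (queued for human merge/split resolution),
and match; the defaults are 0.80 and 0.95, with the upper boundary
inclusive.

The PID check code extends a 6-character payload (a keyed bijective
scrambling of a counter) by 2 check characters of a Reed-Solomon-style
[8, 6] code over GF(32), minimum distance 3: any single mistyped
character can be corrected, or any two detected — one of the two, per
configuration.

## Worked example

```python
import pseudolink as pl

store = pl.default_store(b"example-mixing-key")
config = pl.default_linkage_config()

anna = {"first_name": "Anna", "last_name": "Meier", "birth_day": 4,
        "birth_month": 7, "birth_year": 1981, "city": "Mainz"}

first = pl.ingest_identity(store, anna, config)
again = pl.ingest_identity(store, dict(anna, last_name="MEIER "), config)
typo  = pl.ingest_identity(store, dict(anna, birth_month=8), config)
print(first.decision.value, again.decision.value, typo.decision.value)
```

prints

```
NON_MATCH MATCH TENTATIVE
```

— the first registration creates a patient (nothing to match against,
and a `pid` such as `Z4C2R6AE` is minted), the exact re-entry matches at
score 1.0 despite the case/whitespace noise, and the record with the
wrong birth month scores 0.892: inside the tentative zone, so it is
queued for a trustee to merge or split rather than silently linked.

The `examples/` directory walks through each capability the same way:
PID self-correction (`01`), linkage and conflict resolution (`02`),
Bloom-filter PPRL (`03`), the blocking benchmark (`04`), consent and
FHIR (`05`), and token delegation with audit (`06`). Each script prints
what it computes and says what the numbers mean. A thin CLI
(`pseudolink pid|link|pprl|synth`) covers the shell-shaped operations;
secrets are read from the environment or key files, never from
arguments.

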