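"""End-to-end linkage evaluation on synthetic cohorts.

Runs a generated cohort (base records + corrupted duplicates) through
the full ingestion pipeline — normalize, block, score, classify,
create/match — and measures, against the generator's ground truth:

* linkage recall: fraction of true duplicate pairs whose two rows end up
  resolved to the same patient record;
* linkage precision: fraction of rows attached to an existing patient
  that were attached to the *correct* patient;
* blocking recall: fraction of true duplicate pairs sharing at least one
  blocking key (the pair survives candidate generation);
* candidate fraction: candidate pairs scored as a fraction of all
  possible record pairs (the blocking reduction ratio).

Everything is deterministic in the seed, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import blocking as blocking_mod
from .blocking import BlockIndex, BlockingConfig
from .linkage import Decision, LinkageConfig, default_linkage_config, ingest_identity
from .model import PatientStore
from .normalize import normalize_record
from .pprl import BloomFilterConfig
from .synth import ErrorModel, generate_cohort


@dataclass(frozen=True)
class BenchmarkResult:
    n_records: int
    n_truth_pairs: int
    linkage_recall: float
    linkage_precision: float
    n_match_decisions: int
    blocking_recall: float
    candidate_fraction: float


def run_benchmark(
    n_base: int = 5000,
    n_duplicates: int = 1000,
    seed: int = 1,
    error_model: Optional[ErrorModel] = None,
    linkage_config: Optional[LinkageConfig] = None,
    use_blocking: bool = True,
) -> BenchmarkResult:
    records, truth = generate_cohort(n_base, n_duplicates, error_model=error_model, seed=seed)
    config = linkage_config or default_linkage_config()
    store = PatientStore()
    index = None
    bloom_config = BloomFilterConfig(hmac_secret=b"benchmark-secret")
    if use_blocking:
        index = BlockIndex(bloom_config=bloom_config)

    row_patient: dict[int, int] = {}
    candidate_pairs = 0
    matched_rows: list[int] = []
    rows = records.to_dict("records")
    for i, row in enumerate(rows):
        if index is not None:
            candidate_pairs += len(index.candidates(normalize_record(row)))
        outcome = ingest_identity(store, row, config, index)
        row_patient[i] = outcome.patient.internal_key if outcome.patient else -1
        if outcome.decision is Decision.MATCH and not outcome.created:
            matched_rows.append(i)

    truth_map = dict(zip(truth["dup_row"], truth["base_row"]))
    recalled = sum(1 for d, b in truth_map.items() if row_patient[d] == row_patient[b])
    correct_matches = sum(
        1
        for r in matched_rows
        if r in truth_map and row_patient[r] == row_patient[truth_map[r]]
    )
    n = len(rows)
    total_pairs = n * (n - 1) / 2

    block_config = BlockingConfig()
    keysets = [
        blocking_mod.block_keys(normalize_record(r), block_config, bloom_config) for r in rows
    ]
    block_recall = (
        sum(1 for d, b in truth_map.items() if keysets[d] & keysets[b]) / len(truth_map)
        if truth_map
        else 1.0
    )

    return BenchmarkResult(
        n_records=n,
        n_truth_pairs=len(truth_map),
        linkage_recall=recalled / len(truth_map) if truth_map else 1.0,
        linkage_precision=correct_matches / len(matched_rows) if matched_rows else 1.0,
        n_match_decisions=len(matched_rows),
        blocking_recall=block_recall,
        candidate_fraction=candidate_pairs / total_pairs if use_blocking else 1.0,
    )
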