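"""Synthetic patient cohorts with injected data-entry errors.

The generator produces identity records (first/last name, decomposed
birth date, city) from frequency-weighted name pools, plus duplicate
records derived from sampled base records by a configurable corruption
model, together with a ground-truth pair list.  Everything is a pure
function of the seed, so benchmarks are bit-reproducible.

Name pools: ~1,000 surnames composed from common German surname
prefixes and suffixes, and ~1,000 given names (120 common seed names
plus compound given names), both weighted by a Zipf-Mandelbrot
rank-frequency law so that value frequencies are realistically skewed
(top name ~0.7%) and the linkage weights' f parameters are meaningful.

The default corruption rates mirror the linkage model's default assumed
per-field error probability e = 0.01: a duplicate record disagrees with
its base on any given field with probability of about one percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import BatchError
from .normalize import DEFAULT_FIELDS

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_FIRST_SEEDS = [
    "ANNA", "MARIA", "PETER", "HANS", "MICHAEL", "THOMAS", "ANDREAS", "STEFAN",
    "CHRISTIAN", "WOLFGANG", "KLAUS", "JUERGEN", "DIETER", "MANFRED", "UWE",
    "SABINE", "SUSANNE", "PETRA", "MONIKA", "KARIN", "BRIGITTE", "URSULA",
    "HELGA", "RENATE", "INGRID", "ELKE", "CHRISTA", "GISELA", "ERIKA", "HILDEGARD",
    "JAN", "LUKAS", "FELIX", "JONAS", "PAUL", "LEON", "MAX", "DAVID", "SIMON",
    "TOBIAS", "FLORIAN", "SEBASTIAN", "MARTIN", "MATTHIAS", "ALEXANDER",
    "DANIEL", "PATRICK", "MARKUS", "FRANK", "RALF", "HEINZ", "WERNER", "GERHARD",
    "HELMUT", "WALTER", "KURT", "HERBERT", "GUENTER", "KARL", "OTTO", "FRITZ",
    "EMMA", "MIA", "HANNAH", "SOFIA", "LENA", "LEONIE", "CLARA", "LAURA",
    "JULIA", "KATHARINA", "CHRISTINE", "BARBARA", "ANGELIKA", "MARTINA",
    "ANDREA", "CLAUDIA", "SILKE", "BIRGIT", "HEIKE", "GABRIELE", "KERSTIN",
    "ANJA", "NICOLE", "STEFANIE", "MELANIE", "SANDRA", "NADINE", "JESSICA",
    "LISA", "SARAH", "MARIE", "SOPHIE", "CHARLOTTE", "JOHANNA", "FRIEDA",
    "LOTTE", "GRETA", "ELLA", "IDA", "LUISE", "MATHILDA", "THEA", "ROSA",
    "BRUNO", "EMIL", "OSKAR", "ANTON", "THEO", "HENRI", "LUDWIG", "ALBERT",
    "RICHARD", "ROBERT", "ERNST", "WILHELM", "FRIEDRICH", "HERMANN", "RUDOLF",
    "BERND", "NORBERT", "VOLKER", "HARTMUT", "LOTHAR",
]

_LAST_PREFIXES = [
    "MUELL", "SCHMID", "SCHNEID", "FISCH", "WEB", "MEY", "WAGN", "BECK",
    "SCHULZ", "HOFF", "SCHAEF", "KOCH", "BAU", "RICHT", "KLEIN", "WOLF",
    "SCHROED", "NEU", "SCHWARZ", "ZIMM", "BRAUN", "KRUEG", "HOF", "HART",
    "LANG", "SCHMITT", "WERN", "KRAUS", "LEHM", "SCHUST", "HUB", "KAIS",
    "FUCHS", "HERR", "LIND", "BERG", "STEIN", "FELD", "ROSEN", "GRUEN",
]

_LAST_SUFFIXES = [
    "ER", "MANN", "ERMANN", "NER", "LER", "HARDT", "BERG", "BERGER", "STEIN",
    "FELD", "HAUS", "HAUSEN", "BACH", "HOFER", "MEIER", "MAYER", "EL", "KE",
    "ERT", "ING", "LING", "NERT", "SCHE", "WALD", "BRAND",
]

_CITIES = [
    "BERLIN", "HAMBURG", "MUENCHEN", "KOELN", "FRANKFURT", "STUTTGART",
    "DUESSELDORF", "LEIPZIG", "DORTMUND", "ESSEN", "BREMEN", "DRESDEN",
    "HANNOVER", "NUERNBERG", "DUISBURG", "BOCHUM", "WUPPERTAL", "BIELEFELD",
    "BONN", "MUENSTER", "MANNHEIM", "KARLSRUHE", "AUGSBURG", "WIESBADEN",
    "MOENCHENGLADBACH", "GELSENKIRCHEN", "AACHEN", "BRAUNSCHWEIG", "KIEL",
    "CHEMNITZ", "HALLE", "MAGDEBURG", "FREIBURG", "KREFELD", "MAINZ",
    "LUEBECK", "ERFURT", "OBERHAUSEN", "ROSTOCK", "KASSEL", "HAGEN",
    "POTSDAM", "SAARBRUECKEN", "HAMM", "LUDWIGSHAFEN", "MUELHEIM",
    "OLDENBURG", "OSNABRUECK", "LEVERKUSEN", "HEIDELBERG", "DARMSTADT",
    "SOLINGEN", "REGENSBURG", "HERNE", "PADERBORN", "NEUSS", "INGOLSTADT",
    "OFFENBACH", "FUERTH", "WUERZBURG",
]

_BIRTH_YEARS = (1935, 2004)  # 70 distinct years, matching the default f = 1/70


def _zipf_weights(n: int, exponent: float = 1.07, shift: float = 50.0) -> np.ndarray:
    """Zipf-Mandelbrot rank-frequency weights, f_r proportional to (r+shift)^-s.

    The rank shift tempers the head of the distribution: with the
    defaults the most common of 1,000 names carries ~0.7% of the mass,
    in line with real-world name frequencies (and with the linkage
    config's default chance-agreement rates f), instead of the ~17% a
    pure Zipf law over a 1,000-name pool would give."""
    ranks = np.arange(1, n + 1, dtype=float)
    weights = (ranks + shift) ** -exponent
    return weights / weights.sum()


def _compound_first_names(target: int) -> list[str]:
    """Seed names plus deterministic compound given names up to ``target``."""
    names = list(_FIRST_SEEDS)
    seen = set(names)
    for a in _FIRST_SEEDS:
        for b in _FIRST_SEEDS:
            if len(names) >= target:
                return names
            if a == b:
                continue
            compound = a + b
            if len(compound) <= 14 and compound not in seen:
                names.append(compound)
                seen.add(compound)
    return names


def _composed_last_names(target: int) -> list[str]:
    # Suffix-major order so that consecutive (high-frequency) ranks differ in
    # prefix: the Zipf head mass then spreads over many phonetic codes instead
    # of piling into one Soundex bucket.
    names = []
    seen = set()
    for suffix in _LAST_SUFFIXES:
        for prefix in _LAST_PREFIXES:
            name = prefix + suffix
            if name not in seen:
                names.append(name)
                seen.add(name)
            if len(names) >= target:
                return names
    return names


@dataclass(frozen=True)
class NamePools:
    first_names: tuple[str, ...]
    last_names: tuple[str, ...]
    cities: tuple[str, ...]

    @classmethod
    def default(cls) -> "NamePools":
        return cls(
            tuple(_compound_first_names(1000)),
            tuple(_composed_last_names(1000)),
            tuple(_CITIES),
        )


@dataclass(frozen=True)
class ErrorModel:
    """Per-field corruption rates; all probabilities, all seed-determined.

    Character-level rates apply per text field (first/last name, city);
    ``date_component_error`` applies per birth-date component;
    ``field_missing`` blanks a field entirely.
    """

    substitution: float = 0.01
    insertion: float = 0.003
    deletion: float = 0.003
    transposition: float = 0.003
    field_missing: float = 0.02
    date_component_error: float = 0.01

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion", "transposition",
                     "field_missing", "date_component_error"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise BatchError(f"{name} rate must lie in [0, 1]")


_TEXT_FIELDS = ("first_name", "last_name", "city")
_DATE_FIELDS = ("birth_day", "birth_month", "birth_year")


def _substitute(value: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(value)))
    choices = [c for c in _LETTERS if c != value[pos]]
    return value[:pos] + choices[int(rng.integers(len(choices)))] + value[pos + 1 :]


def _insert(value: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(value) + 1))
    return value[:pos] + _LETTERS[int(rng.integers(26))] + value[pos:]


def _delete(value: str, rng: np.random.Generator) -> str:
    if len(value) <= 1:
        return value
    pos = int(rng.integers(len(value)))
    return value[:pos] + value[pos + 1 :]


def _transpose(value: str, rng: np.random.Generator) -> str:
    pairs = [i for i in range(len(value) - 1) if value[i] != value[i + 1]]
    if not pairs:
        return value
    i = pairs[int(rng.integers(len(pairs)))]
    return value[:i] + value[i + 1] + value[i] + value[i + 2 :]


def corrupt_record(
    fields: dict, model: ErrorModel, rng: np.random.Generator
) -> tuple[dict, list[str]]:
    """Apply each corruption kind independently at its configured rate.

    Returns the corrupted record and the list of applied-corruption tags
    (``"substitution:last_name"`` etc.) for stratified evaluation.
    """
    out = dict(fields)
    tags: list[str] = []
    for name in _TEXT_FIELDS:
        if name not in out or not out[name]:
            continue
        for kind, op in (
            ("substitution", _substitute),
            ("insertion", _insert),
            ("deletion", _delete),
            ("transposition", _transpose),
        ):
            if rng.random() < getattr(model, kind):
                new = op(out[name], rng)
                if new != out[name]:
                    out[name] = new
                    tags.append(f"{kind}:{name}")
    for name in _DATE_FIELDS:
        if name in out and rng.random() < model.date_component_error:
            low, high = {"birth_day": (1, 28), "birth_month": (1, 12),
                         "birth_year": _BIRTH_YEARS}[name]
            new = int(rng.integers(low, high + 1))
            while new == int(out[name]):
                new = int(rng.integers(low, high + 1))
            out[name] = new
            tags.append(f"component:{name}")
    for name in list(out):
        if rng.random() < model.field_missing and sum(v is not None and v != "" for v in out.values()) > 1:
            out[name] = None
            tags.append(f"missing:{name}")
    return out, tags


def generate_cohort(
    n_base: int,
    n_duplicates: int,
    error_model: Optional[ErrorModel] = None,
    seed: int = 0,
    pools: Optional[NamePools] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n_base`` unique identities plus ``n_duplicates`` corrupted copies.

    Returns ``(records, truth)``: records has the schema columns and the
    duplicates appended after the base rows; truth lists one row per
    duplicate with ``base_row``, ``dup_row`` (0-based row indices into
    records) and the '|'-joined applied-corruption tags.
    """
    if n_base <= 0 or n_duplicates < 0 or n_duplicates > n_base:
        raise BatchError("require n_base > 0 and 0 <= n_duplicates <= n_base")
    pools = pools or NamePools.default()
    model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)

    w_first = _zipf_weights(len(pools.first_names))
    w_last = _zipf_weights(len(pools.last_names))
    # Cities are registry catchment areas: a markedly heavier head is realistic
    # (top city ~8%, consistent with the default f_city = 0.05).
    w_city = _zipf_weights(len(pools.cities), shift=5.0)

    records: list[dict] = []
    seen: set[tuple] = set()
    while len(records) < n_base:
        rec = {
            "first_name": pools.first_names[int(rng.choice(len(pools.first_names), p=w_first))],
            "last_name": pools.last_names[int(rng.choice(len(pools.last_names), p=w_last))],
            "birth_day": int(rng.integers(1, 29)),
            "birth_month": int(rng.integers(1, 13)),
            "birth_year": int(rng.integers(_BIRTH_YEARS[0], _BIRTH_YEARS[1] + 1)),
            "city": pools.cities[int(rng.choice(len(pools.cities), p=w_city))],
        }
        key = tuple(rec.values())
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)

    base_rows = rng.choice(n_base, size=n_duplicates, replace=False)
    truth_rows = []
    for offset, base_row in enumerate(base_rows):
        corrupted, tags = corrupt_record(records[int(base_row)], model, rng)
        records.append(corrupted)
        truth_rows.append(
            {"base_row": int(base_row), "dup_row": n_base + offset, "corruptions": "|".join(tags)}
        )

    records_df = pd.DataFrame(records, columns=list(DEFAULT_FIELDS))
    truth_df = pd.DataFrame(truth_rows, columns=["base_row", "dup_row", "corruptions"])
    return records_df, truth_df
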