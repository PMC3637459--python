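"""Internal helpers: deterministic seeding and table-style rounding."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds in int32 range


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as survey tables print percentages.

    Python's builtin ``round`` uses banker's rounding (71.45 -> 71.4); printed
    response-rate tables round half away from zero (71.45 -> 71.5).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def _entropy(seed: int, tags: tuple[int, ...]) -> list[int]:
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return [int(seed) & _SEED_MASK, *[int(t) & _SEED_MASK for t in tags]]


def seeded_rng(seed: int, *tags: int) -> np.random.Generator:
    """A Generator keyed by (seed, *tags); identical arguments yield identical streams."""
    return np.random.default_rng(np.random.SeedSequence(_entropy(seed, tags)))


def child_seed(seed: int, *tags: int) -> int:
    """Derive a reproducible 31-bit integer seed from (seed, *tags)."""
    ss = np.random.SeedSequence(_entropy(seed, tags))
    return int(ss.generate_state(1, np.uint32)[0]) & _SEED_MASK


def stable_person_key(person_id: str) -> int:
    """A stable 31-bit hash of a person identifier (Python's ``hash`` is salted)."""
    digest = hashlib.sha256(person_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & _SEED_MASK
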