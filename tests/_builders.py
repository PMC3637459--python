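"""Hand-built network fixtures used across test modules."""

from __future__ import annotations

import numpy as np

from shiftnet.survey_io import RELATIONS, DyadNetwork, Roster, ShiftNetworkSet

ROLE_CYCLE = ("SRN", "PCT", "CRN", "RMD", "AMD", "TRN", "HUC", "RC", "TRAMRN")


def make_roster(
    n: int, shift_id: str = "T01-day", week: int = 1, shift: str = "day"
) -> Roster:
    members = tuple((f"P{i:02d}", ROLE_CYCLE[i % len(ROLE_CYCLE)]) for i in range(n))
    return Roster(shift_id, week, shift, "2009-05-06", members)


def make_netset(
    n: int,
    arcs: dict | None = None,
    missing: tuple[int, ...] = (),
    roster: Roster | None = None,
) -> ShiftNetworkSet:
    """Build a ShiftNetworkSet from index-based arcs.

    ``arcs`` maps relation -> iterable of (i, j) or (i, j, weight) tuples;
    unlisted relations are all-zero. ``missing`` lists row indices whose
    person returned no survey (NaN rows in every relation).
    """
    roster = roster or make_roster(n)
    arcs = arcs or {}
    matrices: dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        w = np.zeros((n, n))
        for entry in arcs.get(rel, ()):
            if len(entry) == 3:
                i, j, v = entry
            else:
                (i, j), v = entry, 1
            w[i, j] = v
        for i in missing:
            w[i, :] = np.nan
        np.fill_diagonal(w, np.nan)
        matrices[rel] = w
    return ShiftNetworkSet(
        roster=roster,
        matrices=matrices,
        missing_rows=frozenset(roster.ids[i] for i in missing),
    )


def make_dyad_network(n: int, ties: set[tuple[int, int]]) -> DyadNetwork:
    roster = make_roster(n)
    ids = roster.ids
    return DyadNetwork(
        roster=roster,
        ties=frozenset((ids[min(i, j)], ids[max(i, j)]) for i, j in ties),
    )


def random_valued_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.integers(0, 11, size=(n, n)).astype(float)
    np.fill_diagonal(w, np.nan)
    return w
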