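"""Whole-network and per-node communication statistics.

Three statistics summarize each shift x relation network:

* **Density** — the percentage of possible dyads (unordered pairs) with at
  least one communication tie in either direction. High density means a
  cohesive team where most colleagues talk to each other.
* **Degree centralization** (Freeman) — how concentrated ties are on a single
  member, ``100 * sum_i(d_max - d_i) / ((n-1)(n-2))`` on the symmetrized
  binary network: 0 for regular graphs, 100 for a star.
* **In-degree centrality** — per member, the standardized count of incoming
  communication reports: who is being sought out. The network-level
  counterpart uses the directed Freeman denominator ``(n-1)^2``.

Density and centralization are dyadic (symmetrized) statistics; the in-degree
measures are directed and use the raw arc matrix. Members whose survey row is
missing cannot *send* arcs, so in-degree denominators count only potential
senders (non-missing rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError
from .survey_io import (
    RELATIONS,
    ROLES,
    DyadNetwork,
    ShiftNetworkSet,
    dichotomize_symmetrize,
)


@dataclass(frozen=True)
class ShiftMetrics:
    """All network statistics for one shift-point x relation."""

    shift_id: str
    week: int
    shift: str
    relation: str
    density_pct: float
    centralization_pct: float
    in_degree: dict[str, float]  # per-node normalized in-degree; NaN if undefined
    in_degree_centralization_pct: float
    top_in_degree_roles: tuple[str, ...]
    stars: tuple[str, ...]
    isolates: tuple[str, ...]
    excluded_dyads: int


def density(network: DyadNetwork) -> float:
    """Dyadic density as a percentage of observable dyads holding a tie."""
    n = network.roster.size
    if n < 2:
        raise UndefinedMetricError("density requires at least 2 members")
    possible = network.n_possible
    if possible == 0:
        raise UndefinedMetricError("no observable dyads; density undefined")
    return 100.0 * len(network.ties) / possible


def degree_centralization(network: DyadNetwork) -> float:
    """Freeman degree centralization of the symmetrized binary network.

    ``100 * sum_i (d_max - d_i) / ((n - 1)(n - 2))``; the denominator is the
    centralization a perfect star attains, so values live in [0, 100].
    """
    n = network.roster.size
    if n < 3:
        raise UndefinedMetricError("degree centralization requires at least 3 members")
    degrees = list(network.degrees().values())
    d_max = max(degrees)
    return 100.0 * sum(d_max - d for d in degrees) / ((n - 1) * (n - 2))


def _potential_senders(network: ShiftNetworkSet) -> dict[str, int]:
    senders = set(network.respondents)
    return {
        pid: len(senders) - (1 if pid in senders else 0) for pid in network.roster.ids
    }


def in_degree_centrality(
    network: ShiftNetworkSet, relation: str, threshold: int = 1, weighted: bool = False
) -> dict[str, float]:
    """Standardized incoming-communication centrality per member.

    Default (binary): the count of distinct senders reporting a frequency
    >= ``threshold`` toward the member, divided by the member's number of
    potential senders; values in [0, 1]. With ``weighted=True`` the numerator
    is the summed reported frequency instead of a count of senders (so values
    may exceed 1); the printed statistics in this package are the binary ones.

    Members with no potential sender get NaN (undefined), not 0.
    """
    if relation not in RELATIONS:
        raise ConfigurationError(f"unknown relation {relation!r}")
    if network.roster.size < 2:
        raise UndefinedMetricError("in-degree requires at least 2 members")
    w = network.matrices[relation]
    ids = network.roster.ids
    potential = _potential_senders(network)
    out: dict[str, float] = {}
    for j, pid in enumerate(ids):
        if potential[pid] == 0:
            out[pid] = math.nan
            continue
        col = w[:, j]
        observed = np.isfinite(col)
        if weighted:
            score = float(col[observed].sum())
        else:
            score = float((col[observed] >= threshold).sum())
        out[pid] = score / potential[pid]
    return out


def in_degree_centralization(
    network: ShiftNetworkSet, relation: str, threshold: int = 1
) -> float:
    """Freeman-style centralization of the binary in-degree distribution.

    ``100 * sum_j (din_max - din_j) / ((n - 1)^2)`` on raw incoming-arc
    counts, with missing-row senders ignored consistently with
    :func:`in_degree_centrality`.
    """
    if relation not in RELATIONS:
        raise ConfigurationError(f"unknown relation {relation!r}")
    n = network.roster.size
    if n < 3:
        raise UndefinedMetricError("in-degree centralization requires at least 3 members")
    w = network.matrices[relation]
    counts = []
    for j in range(n):
        col = w[:, j]
        observed = np.isfinite(col)
        counts.append(int((col[observed] >= threshold).sum()))
    d_max = max(counts)
    return 100.0 * sum(d_max - d for d in counts) / ((n - 1) ** 2)


def compute_shift_metrics(
    network: ShiftNetworkSet, relation: str, threshold: int = 1
) -> ShiftMetrics:
    """Assemble the full :class:`ShiftMetrics` record for one relation."""
    dyads = dichotomize_symmetrize(network, relation, threshold=threshold)
    tied = {pid for pair in dyads.ties for pid in pair}
    isolates = tuple(pid for pid in network.roster.ids if pid not in tied)
    in_deg = in_degree_centrality(network, relation, threshold=threshold)
    stars = _stars_from_in_degree(in_deg)
    roles = network.roster.roles
    top_roles = tuple(
        sorted({roles[pid] for pid in stars}, key=ROLES.index)
    )
    return ShiftMetrics(
        shift_id=network.roster.shift_id,
        week=network.roster.week,
        shift=network.roster.shift,
        relation=relation,
        density_pct=density(dyads),
        centralization_pct=degree_centralization(dyads),
        in_degree=in_deg,
        in_degree_centralization_pct=in_degree_centralization(
            network, relation, threshold=threshold
        ),
        top_in_degree_roles=top_roles,
        stars=stars,
        isolates=isolates,
        excluded_dyads=len(dyads.excluded),
    )


def _stars_from_in_degree(in_degree: dict[str, float]) -> tuple[str, ...]:
    defined = {pid: v for pid, v in in_degree.items() if not math.isnan(v)}
    if not defined:
        return ()
    best = max(defined.values())
    if best <= 0:
        return ()
    return tuple(pid for pid, v in defined.items() if v == best)


def identify_stars_and_isolates(
    metrics: ShiftMetrics,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Stars (all maximizers of in-degree; empty if no arcs) and isolates."""
    return _stars_from_in_degree(metrics.in_degree), metrics.isolates


def all_relation_metrics(
    network: ShiftNetworkSet, threshold: int = 1
) -> list[ShiftMetrics]:
    """Metrics for every relation of one shift network set."""
    return [compute_shift_metrics(network, rel, threshold=threshold) for rel in RELATIONS]
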