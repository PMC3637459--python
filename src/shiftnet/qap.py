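"""Quadratic Assignment Procedure: matrix correlation and permutation tests.

Two communication networks measured on the same roster are not bags of
independent observations — cells sharing a row or column share a sender or a
receiver. Naive significance tests on the cell-by-cell correlation are
therefore badly biased. The QAP test handles this with a *restricted*
permutation scheme: each permutation relabels the nodes of one matrix,
applying the same relabeling simultaneously to rows and columns
(``Y[pi(i), pi(j)]``), which preserves the autocorrelational structure of the
matrix while breaking its alignment with the other.

For small rosters the full permutation group is enumerated and the p-value is
the exact proportion; otherwise uniformly random relabelings are sampled and
the add-one (conservative) Monte-Carlo estimate is reported.

Missing cells (nonrespondent rows) stay attached to their node: the
permutation moves a node's missingness with it, and a cell enters the
correlation only if observed in both matrices under the permuted alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import child_seed, seeded_rng
from .errors import ConfigurationError, UndefinedCorrelationError
from .survey_io import RELATIONS, ShiftNetworkSet

#: Smallest permitted Monte-Carlo permutation count.
MIN_PERMUTATIONS = 99

#: Largest roster for which the full n! permutation group is enumerated.
EXHAUSTIVE_CAP = 7

#: Minimum jointly observed off-diagonal cells for a defined correlation.
MIN_JOINT_CELLS = 3

_EPS = 1e-12  # tolerance when counting permutation statistics at least as extreme


@dataclass(frozen=True)
class QapResult:
    """Outcome of one QAP test between two relations on one shift."""

    shift_id: str
    relation_pair: tuple[str, str]
    r_obs: float
    n_permutations: int
    p_ge: float
    p_le: float
    p_two_sided: float
    seed: int
    method: str  # "exhaustive" | "monte_carlo"
    n_nodes: int
    week: int | None = None
    shift: str | None = None


@dataclass(frozen=True)
class SkippedShift:
    """A shift-point where a QAP test could not be run, with the reason."""

    shift_id: str
    relation_pair: tuple[str, str]
    reason: str


def _as_matrix(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ConfigurationError(f"{name} must be a square matrix, got shape {x.shape}")
    return x


def _binarize(x: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    return np.where(np.isnan(x), np.nan, (x >= threshold).astype(float))


def _masked_corr(x: np.ndarray, y: np.ndarray, offdiag: np.ndarray) -> float:
    """Pearson r over jointly observed off-diagonal cells; NaN if undefined."""
    mask = offdiag & np.isfinite(x) & np.isfinite(y)
    if int(mask.sum()) < MIN_JOINT_CELLS:
        return math.nan
    xv = x[mask]
    yv = y[mask]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(xc @ yc) / denom


def matrix_correlation(X: np.ndarray, Y: np.ndarray, binary: bool = False) -> float:
    """Pearson correlation over jointly observed off-diagonal cells.

    The diagonal is excluded structurally; cells missing in either matrix are
    excluded pairwise. Raises :class:`UndefinedCorrelationError` rather than
    returning NaN when fewer than three joint cells remain or either vector
    has zero variance.
    """
    X = _as_matrix(X, "X")
    Y = _as_matrix(Y, "Y")
    if X.shape != Y.shape:
        raise ConfigurationError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if binary:
        X, Y = _binarize(X), _binarize(Y)
    offdiag = ~np.eye(X.shape[0], dtype=bool)
    r = _masked_corr(X, Y, offdiag)
    if math.isnan(r):
        raise UndefinedCorrelationError(
            "matrix correlation undefined: fewer than "
            f"{MIN_JOINT_CELLS} joint off-diagonal cells or zero variance"
        )
    return r


def qap_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    binary: bool = False,
    method: str = "auto",
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    shift_id: str = "",
    relation_pair: tuple[str, str] = ("X", "Y"),
) -> QapResult:
    """QAP permutation test of association between two same-roster matrices.

    Each permutation relabels Y's nodes, permuting rows and columns together.
    For ``n <= exhaustive_cap`` all ``n!`` relabelings are enumerated and
    p-values are exact proportions (the identity guarantees p > 0); otherwise
    ``n_permutations`` uniform relabelings are sampled and the conservative
    add-one estimate ``(1 + #extreme) / (1 + B)`` is used. The two-sided
    p-value is ``min(1, 2 * min(p_ge, p_le))``.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ConfigurationError(
            f"n_permutations must be >= {MIN_PERMUTATIONS}, got {n_permutations}"
        )
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ConfigurationError(f"unknown method {method!r}")
    X = _as_matrix(X, "X")
    Y = _as_matrix(Y, "Y")
    if X.shape != Y.shape:
        raise ConfigurationError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if binary:
        X, Y = _binarize(X), _binarize(Y)
    n = X.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    r_obs = _masked_corr(X, Y, offdiag)
    if math.isnan(r_obs):
        raise UndefinedCorrelationError(
            "observed matrix correlation undefined; cannot run QAP test"
        )
    if method == "auto":
        method = "exhaustive" if n <= exhaustive_cap else "monte_carlo"

    n_ge = n_le = 0
    if method == "exhaustive":
        total = 0
        for pi in permutations(range(n)):
            pi = np.asarray(pi)
            r = _masked_corr(X, Y[np.ix_(pi, pi)], offdiag)
            if math.isnan(r):  # degenerate alignment; drop from the reference set
                continue
            total += 1
            if r >= r_obs - _EPS:
                n_ge += 1
            if r <= r_obs + _EPS:
                n_le += 1
        p_ge = n_ge / total
        p_le = n_le / total
        effective = total
    else:
        rng = seeded_rng(seed, 17)
        valid = 0
        for _ in range(n_permutations):
            pi = rng.permutation(n)
            r = _masked_corr(X, Y[np.ix_(pi, pi)], offdiag)
            if math.isnan(r):
                continue
            valid += 1
            if r >= r_obs - _EPS:
                n_ge += 1
            if r <= r_obs + _EPS:
                n_le += 1
        p_ge = (1 + n_ge) / (1 + valid)
        p_le = (1 + n_le) / (1 + valid)
        effective = valid
    return QapResult(
        shift_id=shift_id,
        relation_pair=relation_pair,
        r_obs=r_obs,
        n_permutations=effective,
        p_ge=p_ge,
        p_le=p_le,
        p_two_sided=min(1.0, 2.0 * min(p_ge, p_le)),
        seed=int(seed),
        method=method,
        n_nodes=n,
    )


def relation_pairs(pairs: str | Sequence[tuple[str, str]] = "all") -> list[tuple[str, str]]:
    """Normalize a pair specification; ``"all"`` yields the three relation pairs."""
    if pairs == "all":
        return list(combinations(RELATIONS, 2))
    out = []
    for a, b in pairs:
        if a not in RELATIONS or b not in RELATIONS or a == b:
            raise ConfigurationError(f"invalid relation pair ({a!r}, {b!r})")
        out.append((a, b))
    if not out:
        raise ConfigurationError("no relation pairs requested")
    return out


def qap_panel(
    networks: Iterable[ShiftNetworkSet],
    pairs: str | Sequence[tuple[str, str]] = "all",
    n_permutations: int = 1000,
    seed: int = 0,
    binary: bool = False,
) -> tuple[list[QapResult], list[SkippedShift]]:
    """Run QAP tests for every shift-point x relation pair.

    Day and night shift-points are kept as separate results (the caller
    stratifies them downstream). Shift-points failing the test's
    preconditions are reported in the skipped list, never silently dropped.
    Per-test seeds are derived deterministically from ``seed``.
    """
    pair_list = relation_pairs(pairs)
    results: list[QapResult] = []
    skipped: list[SkippedShift] = []
    networks = list(networks)
    if not networks:
        raise ConfigurationError("no shift networks supplied")
    for i, net in enumerate(networks):
        for k, (rel_a, rel_b) in enumerate(pair_list):
            test_seed = child_seed(seed, i, k)
            try:
                res = qap_test(
                    net.matrices[rel_a],
                    net.matrices[rel_b],
                    n_permutations=n_permutations,
                    seed=test_seed,
                    binary=binary,
                    shift_id=net.roster.shift_id,
                    relation_pair=(rel_a, rel_b),
                )
            except (UndefinedCorrelationError, ConfigurationError) as exc:
                skipped.append(SkippedShift(net.roster.shift_id, (rel_a, rel_b), str(exc)))
                continue
            results.append(
                QapResult(
                    **{
                        **res.__dict__,
                        "week": net.roster.week,
                        "shift": net.roster.shift,
                    }
                )
            )
    return results, skipped


def results_to_frame(results: Iterable[QapResult]) -> pd.DataFrame:
    """Tabulate QAP results (one row per shift-point x pair) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "shift_id": r.shift_id,
                "week": r.week,
                "shift": r.shift,
                "pair": "~".join(r.relation_pair),
                "r_obs": r.r_obs,
                "p_two_sided": r.p_two_sided,
                "p_ge": r.p_ge,
                "p_le": r.p_le,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
                "method": r.method,
                "n_nodes": r.n_nodes,
            }
        )
    return pd.DataFrame(rows)
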