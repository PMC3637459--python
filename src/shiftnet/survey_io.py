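"""Sociometric survey ingestion: rosters, responses, matrices, response rates.

The measurement instrument is a per-shift roster survey: every person working
a shift receives a form listing all colleagues on that shift and reports, for
three relations (general problem solving, medication advice seeking, general
socializing), how many times they *initiated* communication toward each named
colleague, on a 0..10 scale whose top category "10+" means "more than 10".

This module reads the delimited-text dialect for rosters, survey responses and
attendance bookkeeping, abstracts responses into per-shift directed weighted
matrices (one per relation), derives symmetrized binary dyad networks, and
computes response-rate accounting.

Missingness convention
----------------------
A rostered person who returned no survey contributes a *missing* outgoing row
(NaN), which is distinct from a row of zeros: zeros are an observed report of
"no communication", NaN is "not observed". Incoming ties reported *toward* a
nonrespondent by respondents are retained. Dyads that are unobservable in both
directions are excluded from density denominators rather than counted as
absent.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import round_half_away
from .errors import ConfigurationError, FormatError, UndefinedNetworkError

#: Clinical and support roles eligible for the shift roster.
ROLES = ("AMD", "RMD", "SRN", "TRN", "TRAMRN", "CRN", "PCT", "HUC", "RC")

#: The three surveyed communication relations.
RELATIONS = ("problem_solving", "medication_advice", "socializing")

SHIFTS = ("day", "night")

# Overnight-shift surveys are collected in the early-morning block (AM) as the
# night shift ends; day-shift surveys in the late-afternoon block (PM).
SHIFT_TO_CSV = {"night": "AM", "day": "PM"}
CSV_TO_SHIFT = {"AM": "night", "PM": "day"}

ROSTER_HEADER = ["shift_id", "date", "shift", "person_id", "role"]
SURVEY_HEADER = ["shift_id", "respondent", "relation", "target", "frequency"]
ATTENDANCE_HEADER = ["shift_id", "completed", "refused", "not_located"]

#: Reported frequencies are capped at the survey's top category "10+".
MAX_FREQUENCY = 10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Roster:
    """The personnel present on one shift; defines the node set and node order.

    Parameters
    ----------
    shift_id:
        Opaque unique token for the shift-point, e.g. ``"W08-day"``.
    week:
        1-based week index of the study period.
    shift:
        ``"day"`` or ``"night"``.
    date:
        ISO date string of the survey-collection block.
    members:
        Ordered ``(person_id, role)`` pairs. The order is canonical: it fixes
        the row/column order of every matrix built over this roster.
    """

    shift_id: str
    week: int
    shift: str
    date: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.shift not in SHIFTS:
            raise ConfigurationError(f"shift must be one of {SHIFTS}, got {self.shift!r}")
        if len(self.members) < 1:
            raise ConfigurationError("roster must contain at least one member")
        ids = [pid for pid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate person_id in roster {self.shift_id!r}")
        for pid, role in self.members:
            if role not in ROLES:
                raise ConfigurationError(
                    f"unknown role {role!r} for person {pid!r} (valid: {', '.join(ROLES)})"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.members)

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def index(self) -> dict[str, int]:
        """Map person_id -> canonical matrix row/column index."""
        return {pid: k for k, (pid, _) in enumerate(self.members)}


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent's reported communication frequencies for one relation."""

    shift_id: str
    respondent: str
    relation: str
    targets: Mapping[str, int]  # person_id -> frequency 0..10; absent target == 0

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ConfigurationError(f"unknown relation {self.relation!r}")
        for target, freq in self.targets.items():
            if target == self.respondent:
                raise ConfigurationError("respondent may not report toward themself")
            if not 0 <= int(freq) <= MAX_FREQUENCY:
                raise ConfigurationError(
                    f"frequency {freq!r} toward {target!r} outside 0..{MAX_FREQUENCY}"
                )


@dataclass
class ShiftNetworkSet:
    """Three directed weighted matrices (one per relation) over one roster.

    ``matrices[rel][i, j]`` is the frequency respondent ``i`` reported toward
    ``j``. Rows of nonrespondents are NaN (missing, not zero); the diagonal is
    structurally NaN.
    """

    roster: Roster
    matrices: dict[str, np.ndarray]
    missing_rows: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = self.roster.size
        idx = self.roster.index()
        for pid in self.missing_rows:
            if pid not in idx:
                raise ConfigurationError(f"missing-row id {pid!r} not on roster")
        for rel in RELATIONS:
            if rel not in self.matrices:
                raise ConfigurationError(f"matrix for relation {rel!r} absent")
            w = np.asarray(self.matrices[rel], dtype=float)
            if w.shape != (n, n):
                raise ConfigurationError(
                    f"matrix for {rel!r} has shape {w.shape}, roster size is {n}"
                )
            finite = w[np.isfinite(w)]
            if finite.size and (finite.min() < 0 or finite.max() > MAX_FREQUENCY):
                raise ConfigurationError(f"{rel!r} entries outside 0..{MAX_FREQUENCY}")
            self.matrices[rel] = w

    @property
    def respondents(self) -> tuple[str, ...]:
        return tuple(pid for pid in self.roster.ids if pid not in self.missing_rows)

    def binary(self, relation: str, threshold: int = 1) -> np.ndarray:
        """0/1 arc matrix (NaN preserved for missing cells)."""
        w = self.matrices[relation]
        out = np.where(np.isnan(w), np.nan, (w >= threshold).astype(float))
        return out


@dataclass(frozen=True)
class DyadNetwork:
    """Symmetrized binary network at the dyad (unordered pair) level.

    ``ties`` holds present dyads, ``excluded`` the dyads unobservable in both
    directions (removed from density denominators). Pair members are ordered
    by roster position.
    """

    roster: Roster
    ties: frozenset[tuple[str, str]]
    excluded: frozenset[tuple[str, str]] = frozenset()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.roster.index()
        for a, b in self.ties | self.excluded:
            if a == b:
                raise ConfigurationError("self-dyad is not allowed")
            if a not in idx or b not in idx:
                raise ConfigurationError(f"dyad ({a!r}, {b!r}) off roster")
        if self.ties & self.excluded:
            raise ConfigurationError("a dyad cannot be both present and excluded")

    @property
    def n_possible(self) -> int:
        n = self.roster.size
        return n * (n - 1) // 2 - len(self.excluded)

    def degrees(self) -> dict[str, int]:
        deg = {pid: 0 for pid in self.roster.ids}
        for a, b in self.ties:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix in roster order (excluded dyads are 0)."""
        idx = self.roster.index()
        a = np.zeros((self.roster.size, self.roster.size))
        for u, v in self.ties:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a


@dataclass(frozen=True)
class ResponseRateRecord:
    """Per-shift survey accounting: completed (B), refused (C), not located (D)."""

    shift_id: str
    completed: int
    refused: int
    not_located: int

    def __post_init__(self) -> None:
        if min(self.completed, self.refused, self.not_located) < 0:
            raise ConfigurationError("attendance counts must be non-negative")
        if self.eligible < 1:
            raise ConfigurationError(
                f"shift {self.shift_id!r}: at least one eligible person required"
            )

    @property
    def eligible(self) -> int:
        return self.completed + self.refused + self.not_located

    @property
    def rate(self) -> float:
        """Response rate 100*B/(B+C+D), one decimal, ties away from zero."""
        return round_half_away(100.0 * self.completed / self.eligible, 1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_header(fieldnames: Sequence[str] | None, expected: list[str], path: Path) -> None:
    if fieldnames is None or [f.strip() for f in fieldnames] != expected:
        raise FormatError(
            f"{path}: expected header {','.join(expected)!r}, got {fieldnames!r}"
        )


def _week_ranks(dates: Iterable[str]) -> dict[str, int]:
    """Assign 1-based week indices by ISO calendar week (fallback: date-string rank)."""
    unique = sorted(set(dates))
    try:
        keys = {d: _dt.date.fromisoformat(d).isocalendar()[:2] for d in unique}
    except ValueError:
        keys = {d: d for d in unique}
    ordered = sorted(set(keys.values()))
    rank = {k: i + 1 for i, k in enumerate(ordered)}
    return {d: rank[keys[d]] for d in unique}


def read_roster(path: str | Path) -> dict[str, Roster]:
    """Read a roster CSV into one :class:`Roster` per shift_id.

    The dialect is ``shift_id,date,shift,person_id,role`` with shift in
    {AM, PM} (AM = overnight shift, PM = day shift). Member order within a
    shift follows file order and becomes the canonical matrix order. Week
    indices are assigned from the ISO calendar week of the date column.
    """
    path = Path(path)
    groups: dict[str, list[tuple[str, str]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ROSTER_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            sid = (row["shift_id"] or "").strip()
            date = (row["date"] or "").strip()
            token = (row["shift"] or "").strip()
            pid = (row["person_id"] or "").strip()
            role = (row["role"] or "").strip()
            if not sid or not pid:
                raise FormatError(f"{path}:{lineno}: empty shift_id or person_id")
            if token not in CSV_TO_SHIFT:
                raise FormatError(f"{path}:{lineno}: shift must be AM or PM, got {token!r}")
            if role not in ROLES:
                raise FormatError(f"{path}:{lineno}: unknown role {role!r}")
            members = groups.setdefault(sid, [])
            if any(pid == existing for existing, _ in members):
                raise FormatError(f"{path}:{lineno}: duplicate person_id {pid!r} in {sid!r}")
            if sid in meta and meta[sid] != (date, token):
                raise FormatError(f"{path}:{lineno}: inconsistent date/shift for {sid!r}")
            meta[sid] = (date, token)
            members.append((pid, role))
    if not groups:
        raise FormatError(f"{path}: no roster rows")
    weeks = _week_ranks(date for date, _ in meta.values())
    rosters: dict[str, Roster] = {}
    for sid, members in groups.items():
        date, token = meta[sid]
        rosters[sid] = Roster(
            shift_id=sid,
            week=weeks[date],
            shift=CSV_TO_SHIFT[token],
            date=date,
            members=tuple(members),
        )
    return rosters


def _parse_frequency(token: str, where: str) -> int:
    token = token.strip()
    if token == "10+":
        return MAX_FREQUENCY
    try:
        value = int(token)
    except ValueError:
        raise FormatError(f"{where}: unparseable frequency {token!r}") from None
    if not 0 <= value <= MAX_FREQUENCY:
        raise FormatError(f"{where}: frequency {value} outside 0..{MAX_FREQUENCY}")
    return value


def read_surveys(path: str | Path, roster: Roster) -> list[SurveyResponse]:
    """Read survey rows for one roster's shift into :class:`SurveyResponse` objects.

    Dialect: ``shift_id,respondent,relation,target,frequency``; the literal
    frequency token ``"10+"`` parses as 10. Pairs not listed default to 0.
    Rows for other shift_ids are ignored, so one file may hold a whole study.
    """
    path = Path(path)
    member_ids = set(roster.ids)
    acc: dict[tuple[str, str], dict[str, int]] = {}
    order: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SURVEY_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            if (row["shift_id"] or "").strip() != roster.shift_id:
                continue
            where = f"{path}:{lineno}"
            resp = (row["respondent"] or "").strip()
            rel = (row["relation"] or "").strip()
            target = (row["target"] or "").strip()
            if rel not in RELATIONS:
                raise FormatError(f"{where}: unknown relation {rel!r}")
            if resp not in member_ids:
                raise FormatError(f"{where}: respondent {resp!r} not on roster")
            if target not in member_ids:
                raise FormatError(f"{where}: target {target!r} not on roster")
            if resp == target:
                raise FormatError(f"{where}: respondent equals target ({resp!r})")
            freq = _parse_frequency(row["frequency"] or "", where)
            bucket = acc.setdefault((resp, rel), {})
            if (resp, rel) not in order:
                order.append((resp, rel))
            if target in bucket and bucket[target] != freq:
                raise FormatError(
                    f"{where}: conflicting duplicate row for "
                    f"({resp!r}, {rel!r}, {target!r}): {bucket[target]} vs {freq}"
                )
            bucket[target] = freq
    return [
        SurveyResponse(roster.shift_id, resp, rel, dict(acc[(resp, rel)]))
        for resp, rel in order
    ]


def build_networks(responses: Iterable[SurveyResponse], roster: Roster) -> ShiftNetworkSet:
    """Abstract survey responses into the per-shift directed weighted matrices.

    A person who returned *any* survey page is a respondent: their rows default
    to 0 in all three relations. Rostered persons with no response at all get
    NaN rows. Three matrices are always produced, even if a relation received
    no responses.
    """
    idx = roster.index()
    n = roster.size
    responses = list(responses)
    for r in responses:
        if r.shift_id != roster.shift_id:
            raise ConfigurationError(
                f"response for shift {r.shift_id!r} does not belong to {roster.shift_id!r}"
            )
        if r.respondent not in idx:
            raise ConfigurationError(f"respondent {r.respondent!r} not on roster")
    seen: dict[tuple[str, str, str], int] = {}
    for r in responses:
        for target, freq in r.targets.items():
            key = (r.respondent, r.relation, target)
            if key in seen and seen[key] != freq:
                raise ConfigurationError(
                    f"conflicting duplicate report {key}: {seen[key]} vs {freq}"
                )
            seen[key] = freq
    respondents = {r.respondent for r in responses}
    missing = frozenset(pid for pid in roster.ids if pid not in respondents)
    matrices: dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        w = np.full((n, n), np.nan)
        for pid in respondents:
            w[idx[pid], :] = 0.0
        for r in responses:
            if r.relation != rel:
                continue
            for target, freq in r.targets.items():
                w[idx[r.respondent], idx[target]] = float(freq)
        np.fill_diagonal(w, np.nan)
        matrices[rel] = w
    return ShiftNetworkSet(roster=roster, matrices=matrices, missing_rows=missing)


def dichotomize_symmetrize(
    network: ShiftNetworkSet, relation: str, threshold: int = 1
) -> DyadNetwork:
    """Collapse a directed weighted matrix to presence/absence dyads.

    A dyad {i, j} holds a tie iff either observed direction reports a
    frequency >= ``threshold`` (union rule). Dyads missing in both directions
    are excluded from the possible-dyad count and reported via ``excluded``.
    """
    if relation not in RELATIONS:
        raise ConfigurationError(f"unknown relation {relation!r}")
    if not network.respondents:
        raise UndefinedNetworkError(
            f"{network.roster.shift_id}/{relation}: every row is missing"
        )
    w = network.matrices[relation]
    ids = network.roster.ids
    ties: set[tuple[str, str]] = set()
    excluded: set[tuple[str, str]] = set()
    n = network.roster.size
    for i in range(n):
        for j in range(i + 1, n):
            forward, backward = w[i, j], w[j, i]
            if np.isnan(forward) and np.isnan(backward):
                excluded.add((ids[i], ids[j]))
            elif (np.isfinite(forward) and forward >= threshold) or (
                np.isfinite(backward) and backward >= threshold
            ):
                ties.add((ids[i], ids[j]))
    return DyadNetwork(
        roster=network.roster,
        ties=frozenset(ties),
        excluded=frozenset(excluded),
        provenance={"relation": relation, "threshold": threshold, "rule": "union"},
    )


def load_shift_networks(
    roster_path: str | Path, surveys_path: str | Path
) -> dict[str, ShiftNetworkSet]:
    """Read a roster file and a survey file and build all shift networks."""
    rosters = read_roster(roster_path)
    return {
        sid: build_networks(read_surveys(surveys_path, roster), roster)
        for sid, roster in rosters.items()
    }


# ---------------------------------------------------------------------------
# response-rate accounting
# ---------------------------------------------------------------------------


def response_rates(
    records: Iterable[ResponseRateRecord | tuple[str, int, int, int]],
) -> list[ResponseRateRecord]:
    """Normalize attendance records; each carries its one-decimal response rate."""
    out: list[ResponseRateRecord] = []
    for rec in records:
        if not isinstance(rec, ResponseRateRecord):
            rec = ResponseRateRecord(*rec)
        out.append(rec)
    if not out:
        raise ConfigurationError("no attendance records")
    return out


def pooled_response_rate(
    records: Iterable[ResponseRateRecord | tuple[str, int, int, int]],
    shift_id: str = "overall",
) -> ResponseRateRecord:
    """Pooled rate from summed counts (NOT the mean of per-shift rates)."""
    recs = response_rates(records)
    return ResponseRateRecord(
        shift_id=shift_id,
        completed=sum(r.completed for r in recs),
        refused=sum(r.refused for r in recs),
        not_located=sum(r.not_located for r in recs),
    )


def read_attendance(path: str | Path) -> list[ResponseRateRecord]:
    """Read an attendance CSV (``shift_id,completed,refused,not_located``)."""
    path = Path(path)
    out: list[ResponseRateRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        # a derived response_rate_pct column (as written by include_rate) is ignored
        fields = [f.strip() for f in (reader.fieldnames or [])]
        _check_header(fields[: len(ATTENDANCE_HEADER)], ATTENDANCE_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    ResponseRateRecord(
                        shift_id=(row["shift_id"] or "").strip(),
                        completed=int(row["completed"]),
                        refused=int(row["refused"]),
                        not_located=int(row["not_located"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no attendance rows")
    return out


# ---------------------------------------------------------------------------
# writers (the same dialects the readers accept)
# ---------------------------------------------------------------------------


def write_roster_csv(rosters: Iterable[Roster], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_HEADER)
        for roster in rosters:
            for pid, role in roster.members:
                writer.writerow(
                    [roster.shift_id, roster.date, SHIFT_TO_CSV[roster.shift], pid, role]
                )
    return path


def write_surveys_csv(networks: Iterable[ShiftNetworkSet], path: str | Path) -> Path:
    """Write survey rows that rebuild the given networks exactly on re-read.

    Nonzero reports are written one row each; a respondent whose reports are
    all zero still gets a single zero row so that re-reading recovers their
    respondent status (missing vs. zero must round-trip).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_HEADER)
        for net in networks:
            ids = net.roster.ids
            idx = net.roster.index()
            for pid in net.respondents:
                i = idx[pid]
                wrote_any = False
                for rel in RELATIONS:
                    w = net.matrices[rel]
                    for j, target in enumerate(ids):
                        if j == i:
                            continue
                        value = w[i, j]
                        if np.isfinite(value) and value >= 1:
                            writer.writerow(
                                [net.roster.shift_id, pid, rel, target, int(value)]
                            )
                            wrote_any = True
                if not wrote_any:
                    anchor = next(t for t in ids if t != pid)
                    writer.writerow(
                        [net.roster.shift_id, pid, RELATIONS[0], anchor, 0]
                    )
    return path


def write_attendance_csv(
    records: Iterable[ResponseRateRecord], path: str | Path, include_rate: bool = False
) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = list(ATTENDANCE_HEADER) + (["response_rate_pct"] if include_rate else [])
        writer.writerow(header)
        for rec in records:
            row = [rec.shift_id, rec.completed, rec.refused, rec.not_located]
            if include_rate:
                row.append(rec.rate)
            writer.writerow(row)
    return path


def write_matrices(network: ShiftNetworkSet, outdir: str | Path) -> Path:
    """Export a shift's three matrices as CSV plus a JSON manifest.

    Missing cells are written as empty fields. Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = network.roster.ids
    files = {}
    for rel in RELATIONS:
        w = network.matrices[rel]
        fname = f"{network.roster.shift_id}_{rel}.csv"
        with (outdir / fname).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["", *ids])
            for i, pid in enumerate(ids):
                writer.writerow(
                    [pid]
                    + ["" if np.isnan(w[i, j]) else int(w[i, j]) for j in range(len(ids))]
                )
        files[rel] = fname
    manifest = {
        "shift_id": network.roster.shift_id,
        "week": network.roster.week,
        "shift": network.roster.shift,
        "n": network.roster.size,
        "missing_rows": sorted(network.missing_rows),
        "files": files,
        "dialect": {"missing": "empty field", "scale": "0..10, 10 encodes 10+"},
    }
    manifest_path = outdir / f"{network.roster.shift_id}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest_path
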