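"""Synthetic shift rosters and correlated multiplex communication networks.

The study design this generator emulates: a 12-week campaign surveying one
emergency department twice a week (one day shift, one night shift), with each
shift staffed by roughly 7-20 people drawn from nine roles, and each person
reporting communication frequencies toward every rostered colleague for three
relations. Raw survey data of this kind are rarely deposited, so downstream
analysis stages are exercised against data generated here with known latent
structure.

Generative model
----------------
For ordered pair (i, j), i != j, and relation r, the tie indicator is
Bernoulli with

    logit p = base_logit[r] + s_i + s_j + lambda[r] * z_ij + night * delta

where ``s`` is a per-person latent sociability (N(0, sociability_sd), fixed
for the person across the whole study), ``z_ij = z_ji`` is a dyad-level
standard-normal factor shared by all three relations within a shift-point,
``lambda[r]`` is the relation's loading on that shared factor (the product
``lambda[r1] * lambda[r2]`` controls the inter-relation QAP correlation), and
``delta >= 0`` raises night-shift density. Present ties carry integer weights
``1 + Poisson(weight_mean - 1)`` capped at 10, mirroring the survey's "10+"
top category. Nonresponse deletes a person's outgoing rows (missing, not
zero) in all three matrices.

Personnel persist across weeks: each role has a fixed pool (``pool_multiplier``
times the per-shift head-count) from which every shift-point samples, so
repeat-respondent structure arises naturally.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from ._util import child_seed, seeded_rng, stable_person_key
from .errors import ConfigurationError
from .qap import matrix_correlation
from .survey_io import (
    MAX_FREQUENCY,
    RELATIONS,
    ROLES,
    SHIFTS,
    ResponseRateRecord,
    Roster,
    ShiftNetworkSet,
    write_attendance_csv,
    write_roster_csv,
    write_surveys_csv,
)

#: Default per-shift head-count by role (19 people across the 9 roles).
DEFAULT_ROLE_COUNTS: Mapping[str, int] = {
    "AMD": 2,
    "RMD": 3,
    "SRN": 6,
    "TRN": 1,
    "TRAMRN": 1,
    "CRN": 1,
    "PCT": 3,
    "HUC": 1,
    "RC": 1,
}

# Baseline tie log-odds per relation, chosen so that dyadic densities land in
# the ranges reported for emergency-department teams: socializing most dense,
# medication advice much sparser than the other two.
DEFAULT_BASE_LOGIT: Mapping[str, float] = {
    "problem_solving": -0.7,
    "medication_advice": -2.5,
    "socializing": -0.2,
}

DEFAULT_OVERLAP_LAMBDA: Mapping[str, float] = {
    "problem_solving": 0.8,
    "medication_advice": 0.8,
    "socializing": 0.8,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study; the seed fixes all outputs bit-for-bit."""

    n_weeks: int = 12
    role_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_COUNTS)
    )
    base_logit: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOGIT)
    )
    night_density_offset: float = 0.6
    sociability_sd: float = 0.7
    overlap_lambda: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAP_LAMBDA)
    )
    weight_mean: float = 3.0
    nonresponse_rate: float = 0.18
    pool_multiplier: float = 5.0
    start_date: str = "2009-05-06"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ConfigurationError("n_weeks must be >= 1")
        for role in self.role_counts:
            if role not in ROLES:
                raise ConfigurationError(f"unknown role {role!r} in role_counts")
        if any(c < 0 for c in self.role_counts.values()):
            raise ConfigurationError("role counts must be non-negative")
        if sum(self.role_counts.values()) < 2:
            raise ConfigurationError("role_counts must sum to at least 2")
        for mapping, name in (
            (self.base_logit, "base_logit"),
            (self.overlap_lambda, "overlap_lambda"),
        ):
            for rel in RELATIONS:
                if rel not in mapping:
                    raise ConfigurationError(f"{name} missing relation {rel!r}")
        if self.night_density_offset < 0:
            raise ConfigurationError("night_density_offset must be >= 0")
        if self.sociability_sd < 0:
            raise ConfigurationError("sociability_sd must be >= 0")
        if not 0.0 <= self.nonresponse_rate <= 1.0:
            raise ConfigurationError("nonresponse_rate must be in [0, 1]")
        if self.weight_mean < 1.0:
            raise ConfigurationError("weight_mean must be >= 1 (weights start at 1)")
        if self.pool_multiplier < 1.0:
            raise ConfigurationError("pool_multiplier must be >= 1")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n_weeks": self.n_weeks,
            "role_counts": dict(self.role_counts),
            "base_logit": dict(self.base_logit),
            "night_density_offset": self.night_density_offset,
            "sociability_sd": self.sociability_sd,
            "overlap_lambda": dict(self.overlap_lambda),
            "weight_mean": self.weight_mean,
            "nonresponse_rate": self.nonresponse_rate,
            "pool_multiplier": self.pool_multiplier,
            "start_date": self.start_date,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        return cls(**dict(data))


@dataclass(frozen=True)
class Person:
    person_id: str
    role: str
    sociability: float


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus the latent truth."""

    config: SyntheticConfig
    rosters: dict[str, Roster]
    networks: dict[str, ShiftNetworkSet]
    truth: dict
    nonrespondents: dict[str, frozenset[str]]

    def shift_points(self):
        """Yield (week, shift, roster, network set) in generation order."""
        for sid, roster in self.rosters.items():
            yield roster.week, roster.shift, roster, self.networks[sid]


def personnel_pool(config: SyntheticConfig) -> tuple[Person, ...]:
    """The fixed per-role personnel pool, with per-person latent sociability."""
    rng = seeded_rng(config.seed, 1)
    people: list[Person] = []
    for role in ROLES:
        count = config.role_counts.get(role, 0)
        if count == 0:
            continue
        pool_n = max(count, int(round(count * config.pool_multiplier)))
        for k in range(pool_n):
            people.append(
                Person(
                    person_id=f"{role}-{k + 1:03d}",
                    role=role,
                    sociability=float(rng.normal(0.0, config.sociability_sd)),
                )
            )
    return tuple(people)


def _shift_index(shift: str) -> int:
    if shift not in SHIFTS:
        raise ConfigurationError(f"shift must be one of {SHIFTS}, got {shift!r}")
    return SHIFTS.index(shift)


def _shift_date(config: SyntheticConfig, week: int) -> str:
    import datetime as _dt

    start = _dt.date.fromisoformat(config.start_date)
    return (start + _dt.timedelta(weeks=week - 1)).isoformat()


def generate_roster(config: SyntheticConfig, week: int, shift: str) -> Roster:
    """Sample one shift-point's roster from the fixed role pools.

    Deterministic in (seed, week, shift); the same call always returns the
    identical roster. Members are ordered by role then id (canonical order).
    """
    if not 1 <= week <= config.n_weeks:
        raise ConfigurationError(f"week {week} outside 1..{config.n_weeks}")
    s_idx = _shift_index(shift)
    rng = seeded_rng(config.seed, 2, week, s_idx)
    pool = personnel_pool(config)
    members: list[tuple[str, str]] = []
    for role in ROLES:
        count = config.role_counts.get(role, 0)
        if count == 0:
            continue
        candidates = [p for p in pool if p.role == role]
        chosen = rng.choice(len(candidates), size=count, replace=False)
        members.extend((candidates[i].person_id, role) for i in sorted(chosen))
    members.sort(key=lambda m: (ROLES.index(m[1]), m[0]))
    return Roster(
        shift_id=f"W{week:02d}-{shift}",
        week=week,
        shift=shift,
        date=_shift_date(config, week),
        members=tuple(members),
    )


def _sigmoid(logit: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", under="ignore"):
        out = np.where(
            logit >= 0, 1.0 / (1.0 + np.exp(-logit)), np.exp(logit) / (1.0 + np.exp(logit))
        )
    return out


def _sociability_lookup(config: SyntheticConfig) -> dict[str, float]:
    return {p.person_id: p.sociability for p in personnel_pool(config)}


def generate_networks(
    config: SyntheticConfig, roster: Roster, shift: str | None = None
) -> ShiftNetworkSet:
    """Draw the three correlated relation matrices for one roster.

    Persons outside the generator's own pool (e.g. a hand-built roster) get a
    sociability derived deterministically from a stable hash of their id, so
    the operation stays reproducible for arbitrary rosters.
    """
    if roster.size < 2:
        raise ConfigurationError("network generation requires a roster of size >= 2")
    shift = shift or roster.shift
    s_idx = _shift_index(shift)
    rng = seeded_rng(config.seed, 3, roster.week, s_idx)
    lookup = _sociability_lookup(config)
    soc = np.array(
        [
            lookup.get(
                pid,
                float(
                    seeded_rng(config.seed, 5, stable_person_key(pid)).normal(
                        0.0, config.sociability_sd
                    )
                ),
            )
            for pid in roster.ids
        ]
    )
    n = roster.size
    upper = rng.standard_normal((n, n))
    z = np.triu(upper, 1)
    z = z + z.T  # dyad-level factor, symmetric by construction
    offset = config.night_density_offset if shift == "night" else 0.0
    matrices: dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        logit = (
            config.base_logit[rel]
            + soc[:, None]
            + soc[None, :]
            + config.overlap_lambda[rel] * z
            + offset
        )
        p = _sigmoid(logit)
        ties = rng.random((n, n)) < p
        weights = 1 + rng.poisson(config.weight_mean - 1.0, size=(n, n))
        weights = np.minimum(weights, MAX_FREQUENCY)
        w = np.where(ties, weights, 0).astype(float)
        np.fill_diagonal(w, np.nan)
        matrices[rel] = w
    return ShiftNetworkSet(roster=roster, matrices=matrices, missing_rows=frozenset())


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full study: every week x {day, night} roster and network set."""
    rosters: dict[str, Roster] = {}
    networks: dict[str, ShiftNetworkSet] = {}
    shifts_truth: dict[str, dict] = {}
    for week in range(1, config.n_weeks + 1):
        for shift in SHIFTS:
            roster = generate_roster(config, week, shift)
            net = generate_networks(config, roster, shift)
            rosters[roster.shift_id] = roster
            networks[roster.shift_id] = net
            arc_density = {}
            for rel in RELATIONS:
                w = net.matrices[rel]
                observed = np.isfinite(w)
                arc_density[rel] = float((w[observed] >= 1).mean())
            shifts_truth[roster.shift_id] = {
                "week": week,
                "shift": shift,
                "n": roster.size,
                "arc_density": arc_density,
            }
    truth = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "sociability": {
            p.person_id: p.sociability for p in personnel_pool(config)
        },
        "shifts": shifts_truth,
    }
    return SyntheticDataset(
        config=config,
        rosters=rosters,
        networks=networks,
        truth=truth,
        nonrespondents={sid: frozenset() for sid in rosters},
    )


def apply_nonresponse(
    dataset: SyntheticDataset, config: SyntheticConfig | None = None
) -> SyntheticDataset:
    """Mark each rostered person nonrespondent with ``nonresponse_rate``.

    A nonrespondent's outgoing row becomes missing (NaN, not zero) in all
    three matrices; columns toward them reported by respondents are kept.
    Returns a new dataset; the input is not mutated.
    """
    config = config or dataset.config
    new_networks: dict[str, ShiftNetworkSet] = {}
    new_nonresp: dict[str, frozenset[str]] = {}
    for i, (sid, net) in enumerate(dataset.networks.items()):
        rng = seeded_rng(config.seed, 4, i)
        mask = rng.random(net.roster.size) < config.nonresponse_rate
        missing = frozenset(
            pid for pid, m in zip(net.roster.ids, mask) if m
        ) | net.missing_rows
        idx = net.roster.index()
        matrices = {}
        for rel in RELATIONS:
            w = net.matrices[rel].copy()
            for pid in missing:
                w[idx[pid], :] = np.nan
            matrices[rel] = w
        new_networks[sid] = ShiftNetworkSet(
            roster=net.roster, matrices=matrices, missing_rows=missing
        )
        new_nonresp[sid] = missing
    return SyntheticDataset(
        config=config,
        rosters=dict(dataset.rosters),
        networks=new_networks,
        truth=copy.deepcopy(dataset.truth),
        nonrespondents=new_nonresp,
    )


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full study and apply the nonresponse process."""
    return apply_nonresponse(generate_dataset(config), config)


def mean_pair_correlation(
    config: SyntheticConfig,
    pair: tuple[str, str],
    n_replicates: int = 48,
    seed: int | None = None,
) -> float:
    """Monte-Carlo mean matrix correlation between two relations.

    Simulates ``ceil(n_replicates / 2)`` weeks (day + night) under ``config``
    with the given seed and averages the observed correlations — the
    calibration oracle used by :func:`calibrate_overlap_lambda`.
    """
    n_weeks = (n_replicates + 1) // 2
    cfg = replace(config, n_weeks=n_weeks, seed=config.seed if seed is None else seed)
    ds = simulate(cfg)
    rs = []
    for _, _, _, net in ds.shift_points():
        rs.append(matrix_correlation(net.matrices[pair[0]], net.matrices[pair[1]]))
        if len(rs) == n_replicates:
            break
    return float(np.mean(rs))


def calibrate_overlap_lambda(
    config: SyntheticConfig,
    pair: tuple[str, str] = ("problem_solving", "socializing"),
    target_r: float = 0.4,
    n_replicates: int = 48,
    lo: float = 0.0,
    hi: float = 4.0,
    n_iter: int = 12,
    seed: int | None = None,
) -> float:
    """Find the shared-factor loading that yields a target inter-relation r.

    Sets both relations of ``pair`` to a common loading ``lam`` and bisects on
    the Monte-Carlo mean correlation (monotone increasing in ``lam``), using
    common random numbers across evaluations. Returns the calibrated loading;
    if the target is outside the reachable range the nearest bound is
    returned.
    """
    base_seed = config.seed if seed is None else seed
    eval_seed = child_seed(base_seed, 6)

    def mean_r(lam: float) -> float:
        lam_map = dict(config.overlap_lambda)
        lam_map[pair[0]] = lam
        lam_map[pair[1]] = lam
        cfg = replace(config, overlap_lambda=lam_map)
        return mean_pair_correlation(cfg, pair, n_replicates=n_replicates, seed=eval_seed)

    if mean_r(lo) >= target_r:
        return lo
    if mean_r(hi) <= target_r:
        return hi
    a, b = lo, hi
    for _ in range(n_iter):
        mid = 0.5 * (a + b)
        if mean_r(mid) < target_r:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------


def attendance_records(dataset: SyntheticDataset) -> list[ResponseRateRecord]:
    """Per-shift completed/refused counts implied by the nonresponse draw.

    Refusal and not-located are a single collapsed nonresponse process here;
    nonrespondents are booked under "refused" and "not_located" stays 0.
    """
    out = []
    for sid, roster in dataset.rosters.items():
        n_missing = len(dataset.nonrespondents.get(sid, frozenset()))
        out.append(
            ResponseRateRecord(
                shift_id=sid,
                completed=roster.size - n_missing,
                refused=n_missing,
                not_located=0,
            )
        )
    return out


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write roster/survey/attendance CSVs and the JSON truth file.

    The CSVs use exactly the dialect the ingestion readers accept, so a
    written dataset round-trips through ``read_roster`` / ``read_surveys`` /
    ``build_networks`` to equal matrices.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": write_roster_csv(dataset.rosters.values(), outdir / "roster.csv"),
        "surveys": write_surveys_csv(dataset.networks.values(), outdir / "surveys.csv"),
        "attendance": write_attendance_csv(
            attendance_records(dataset), outdir / "attendance.csv", include_rate=True
        ),
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth, indent=2), encoding="utf-8")
    paths["truth"] = truth_path
    return paths
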