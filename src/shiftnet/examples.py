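"""Bundled miniature example fixtures.

Two small plain-text fixtures ship with the package:

* a four-person worked example shift (one medication-advice survey round)
  whose dyad network has 5 of 6 possible ties — handy for checking the
  density and centralization arithmetic by hand;
* an attendance table for a 12-week, twice-weekly survey campaign
  (24 shift-points) exercising the response-rate accounting.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .survey_io import (
    ResponseRateRecord,
    Roster,
    ShiftNetworkSet,
    build_networks,
    read_attendance,
    read_roster,
    read_surveys,
)


def example_data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files("shiftnet").joinpath("data", name)))


def worked_example_roster() -> Roster:
    """The four-person roster (A, B, C, D) of the worked example shift."""
    rosters = read_roster(example_data_path("example_roster.csv"))
    return next(iter(rosters.values()))


def worked_example_network() -> ShiftNetworkSet:
    """The worked example shift: all four respond; C reports toward A, B, D
    and D toward A, B, so the symmetrized dyad network has 5 of 6 ties
    (only A-B absent): density 83.3%, degree centralization 33.33%."""
    roster = worked_example_roster()
    responses = read_surveys(example_data_path("example_surveys.csv"), roster)
    return build_networks(responses, roster)


def example_attendance() -> list[ResponseRateRecord]:
    """Attendance counts for the bundled 24-shift-point campaign (pooled rate 82.0%)."""
    return read_attendance(example_data_path("example_attendance.csv"))
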