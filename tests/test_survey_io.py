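"""Roster/survey ingestion, matrix abstraction and response-rate accounting."""

from __future__ import annotations

import numpy as np
import pytest

from _builders import make_netset, make_roster
from shiftnet.errors import ConfigurationError, FormatError, UndefinedNetworkError
from shiftnet.survey_io import (
    RELATIONS,
    ResponseRateRecord,
    Roster,
    build_networks,
    dichotomize_symmetrize,
    load_shift_networks,
    pooled_response_rate,
    read_roster,
    read_surveys,
    response_rates,
    write_roster_csv,
    write_surveys_csv,
)
from shiftnet.synthetic_data import write_dataset


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


ROSTER_CSV = (
    "shift_id,date,shift,person_id,role\n"
    "S1,2009-05-06,PM,n1,SRN\n"
    "S1,2009-05-06,PM,n2,SRN\n"
    "S1,2009-05-06,PM,d1,AMD\n"
    "S1,2009-05-06,PM,t1,PCT\n"
)


class TestReadRoster:
    def test_four_row_file_gives_roster_of_four(self, tmp_path):
        rosters = read_roster(_write(tmp_path, "r.csv", ROSTER_CSV))
        assert list(rosters) == ["S1"]
        roster = rosters["S1"]
        assert roster.size == 4
        assert roster.ids == ("n1", "n2", "d1", "t1")  # canonical = file order
        assert roster.shift == "day" and roster.week == 1

    def test_duplicate_person_rejected_with_row_number(self, tmp_path):
        bad = ROSTER_CSV + "S1,2009-05-06,PM,n1,SRN\n"
        with pytest.raises(FormatError, match=r":6.*n1"):
            read_roster(_write(tmp_path, "r.csv", bad))

    def test_unknown_role_rejected_naming_row(self, tmp_path):
        bad = ROSTER_CSV.replace("t1,PCT", "t1,JANITOR")
        with pytest.raises(FormatError, match="JANITOR"):
            read_roster(_write(tmp_path, "r.csv", bad))

    def test_week_indices_follow_iso_weeks(self, tmp_path):
        text = (
            "shift_id,date,shift,person_id,role\n"
            "A,2009-05-06,PM,x,SRN\n"
            "A,2009-05-06,PM,y,SRN\n"
            "B,2009-05-13,AM,x,SRN\n"
            "B,2009-05-13,AM,y,SRN\n"
        )
        rosters = read_roster(_write(tmp_path, "r.csv", text))
        assert rosters["A"].week == 1 and rosters["B"].week == 2
        assert rosters["B"].shift == "night"


class TestReadSurveys:
    @pytest.fixture
    def roster(self, tmp_path):
        return read_roster(_write(tmp_path, "r.csv", ROSTER_CSV))["S1"]

    def test_ten_plus_token_parses_as_ten(self, tmp_path, roster):
        path = _write(
            tmp_path,
            "s.csv",
            "shift_id,respondent,relation,target,frequency\n"
            "S1,n1,socializing,n2,10+\n",
        )
        (resp,) = read_surveys(path, roster)
        assert resp.targets == {"n2": 10}

    def test_empty_file_means_everyone_nonrespondent(self, tmp_path, roster):
        path = _write(
            tmp_path, "s.csv", "shift_id,respondent,relation,target,frequency\n"
        )
        net = build_networks(read_surveys(path, roster), roster)
        assert net.missing_rows == frozenset(roster.ids)
        assert np.isnan(net.matrices["problem_solving"]).all()

    @pytest.mark.parametrize(
        "row,match",
        [
            ("S1,n1,socializing,n1,3", "respondent equals target"),
            ("S1,n1,socializing,n2,11", "outside"),
            ("S1,n1,socializing,n2,-1", "outside"),
            ("S1,n1,gossip,n2,3", "unknown relation"),
            ("S1,ghost,socializing,n2,3", "not on roster"),
            ("S1,n1,socializing,ghost,3", "not on roster"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, roster, row, match):
        path = _write(
            tmp_path,
            "s.csv",
            "shift_id,respondent,relation,target,frequency\n" + row + "\n",
        )
        with pytest.raises(FormatError, match=match):
            read_surveys(path, roster)

    def test_conflicting_duplicate_rows_rejected(self, tmp_path, roster):
        path = _write(
            tmp_path,
            "s.csv",
            "shift_id,respondent,relation,target,frequency\n"
            "S1,n1,socializing,n2,3\n"
            "S1,n1,socializing,n2,4\n",
        )
        with pytest.raises(FormatError, match="conflicting duplicate"):
            read_surveys(path, roster)


class TestBuildNetworks:
    def test_nonrespondent_row_is_missing_not_zero(self, tmp_path):
        roster = Roster("S1", 1, "day", "2009-05-06", (("A", "SRN"), ("B", "SRN")))
        path = _write(
            tmp_path,
            "s.csv",
            "shift_id,respondent,relation,target,frequency\nS1,A,problem_solving,B,5\n",
        )
        net = build_networks(read_surveys(path, roster), roster)
        w = net.matrices["problem_solving"]
        assert w[0, 1] == 5.0
        assert np.isnan(w[1, 0])  # B returned nothing: missing, not zero
        assert net.missing_rows == frozenset({"B"})

    def test_three_matrices_with_roster_dimensions(self, small_dataset, tmp_path):
        paths = write_dataset(small_dataset, tmp_path)
        nets = load_shift_networks(paths["roster"], paths["surveys"])
        for sid, net in nets.items():
            n = small_dataset.rosters[sid].size
            for rel in RELATIONS:
                assert net.matrices[rel].shape == (n, n)

    def test_synthetic_round_trip_is_exact(self, small_dataset, tmp_path):
        paths = write_dataset(small_dataset, tmp_path)
        nets = load_shift_networks(paths["roster"], paths["surveys"])
        assert set(nets) == set(small_dataset.networks)
        for sid, original in small_dataset.networks.items():
            rebuilt = nets[sid]
            assert rebuilt.roster == original.roster
            assert rebuilt.missing_rows == original.missing_rows
            for rel in RELATIONS:
                assert np.array_equal(
                    rebuilt.matrices[rel], original.matrices[rel], equal_nan=True
                )


class TestDichotomize:
    def test_union_rule_one_direction_suffices(self):
        net = make_netset(2, {"problem_solving": [(0, 1, 3)]})
        dyads = dichotomize_symmetrize(net, "problem_solving")
        assert dyads.ties == frozenset({("P00", "P01")})

    def test_all_zero_matrix_gives_empty_tie_set(self):
        net = make_netset(4)
        dyads = dichotomize_symmetrize(net, "socializing")
        assert dyads.ties == frozenset() and dyads.n_possible == 6

    def test_doubly_missing_dyads_are_excluded_not_absent(self):
        net = make_netset(4, missing=(2, 3))
        dyads = dichotomize_symmetrize(net, "problem_solving")
        assert dyads.excluded == frozenset({("P02", "P03")})
        assert dyads.n_possible == 5

    def test_all_rows_missing_is_undefined(self):
        net = make_netset(3, missing=(0, 1, 2))
        with pytest.raises(UndefinedNetworkError):
            dichotomize_symmetrize(net, "problem_solving")

    def test_roster_relabeling_permutes_but_preserves_ties(self):
        arcs = {"socializing": [(0, 1, 2), (2, 0, 9), (3, 1, 1)]}
        net = make_netset(4, arcs)
        base = dichotomize_symmetrize(net, "socializing")
        # rebuild with members in reversed order; same person-level arcs
        roster = net.roster
        rev = Roster(
            roster.shift_id, roster.week, roster.shift, roster.date,
            tuple(reversed(roster.members)),
        )
        idx = {pid: k for k, pid in enumerate(rev.ids)}
        arcs_rev = {
            "socializing": [
                (idx[roster.ids[i]], idx[roster.ids[j]], v)
                for i, j, v in arcs["socializing"]
            ]
        }
        net_rev = make_netset(4, arcs_rev, roster=rev)
        unordered = lambda ties: {frozenset(pair) for pair in ties}
        assert unordered(
            dichotomize_symmetrize(net_rev, "socializing").ties
        ) == unordered(base.ties)


class TestResponseRates:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 1, 3), 71.4), ((13, 0, 0), 100.0), ((11, 4, 3), 61.1)],
    )
    def test_per_shift_rates(self, counts, expected):
        (rec,) = response_rates([("s", *counts)])
        assert rec.rate == expected

    def test_pooled_rate_uses_summed_counts(self, attendance):
        pooled = pooled_response_rate(attendance)
        assert (pooled.completed, pooled.refused, pooled.not_located) == (336, 61, 13)
        assert pooled.rate == 82.0
        # pooling is NOT the mean of the per-shift rates
        mean_of_rates = np.mean([r.rate for r in attendance])
        assert abs(mean_of_rates - pooled.rate) > 0.5

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ResponseRateRecord("s", 0, 0, 0)


def test_written_roster_and_surveys_reload_identically(tmp_path, worked_example):
    roster_path = write_roster_csv([worked_example.roster], tmp_path / "r.csv")
    surveys_path = write_surveys_csv([worked_example], tmp_path / "s.csv")
    nets = load_shift_networks(roster_path, surveys_path)
    rebuilt = nets[worked_example.roster.shift_id]
    assert rebuilt.roster == worked_example.roster
    for rel in RELATIONS:
        assert np.array_equal(
            rebuilt.matrices[rel], worked_example.matrices[rel], equal_nan=True
        )
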