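"""CSV schema validation, reference selection, quadrant tracking."""

import pandas as pd
import pytest

from braotrial import (
    NormativeProfile,
    most_affected_quadrant,
    read_thickness_table,
    select_reference,
    write_thickness_table,
)
from braotrial.thickness_io import (
    ReferenceSelectionError,
    ThicknessTableError,
)

HEADER = "patient_id,eye,status,day,ring,quadrant,layer,thickness_um"


def write_csv(tmp_path, body):
    path = tmp_path / "table.csv"
    path.write_text(HEADER + "\n" + body)
    return path


def small_profile(cells):
    return NormativeProfile(
        values=pd.DataFrame(
            [
                {"quadrant": q, "layer": l, "mean_um": m, "sd_um": s}
                for (q, l, m, s) in cells
            ]
        ),
        source_n=9,
    )


def test_well_formed_two_row_file(tmp_path):
    path = write_csv(
        tmp_path,
        "P1,OD,affected,0,inner_3mm,S,GCL,45.0\n"
        "P1,OS,reference,0,inner_3mm,S,GCL,50.0\n",
    )
    records = read_thickness_table(path)
    assert len(records) == 2
    assert records["thickness_um"].tolist() == [45.0, 50.0]
    assert records["day"].dtype.kind == "i"


@pytest.mark.parametrize(
    ("body", "fragment"),
    [
        ("P1,OD,affected,0,inner_3mm,S,GCL,50\n"
         "P1,OD,affected,3,inner_3mm,S,GCL,-5\n", "row 3"),
        ("P1,OD,affected,0,inner_3mm,X,GCL,50\n", "quadrant"),
        ("P1,OD,affected,0,inner_3mm,S,XXX,50\n", "layer"),
        ("P1,OD,affected,-1,inner_3mm,S,GCL,50\n", "day"),
        ("P1,OD,affected,0,middle,S,GCL,50\n", "ring"),
        ("P1,OD,affected,0,inner_3mm,S,GCL,50\n"
         "P1,OD,affected,0,inner_3mm,S,GCL,51\n", "duplicate"),
    ],
)
def test_malformed_rows_are_rejected_with_row_numbers(tmp_path, body, fragment):
    with pytest.raises(ThicknessTableError, match=fragment):
        read_thickness_table(write_csv(tmp_path, body))


def test_missing_column_is_named(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text("patient_id,eye,status,day\nP1,OD,affected,0\n")
    with pytest.raises(ThicknessTableError, match="thickness_um"):
        read_thickness_table(path)


def test_generated_cohort_round_trips(tmp_path, cohort):
    path = tmp_path / "cohort.csv"
    write_thickness_table(cohort.records, path)
    back = read_thickness_table(path)
    pd.testing.assert_frame_equal(back, cohort.records)


def test_fellow_eye_takes_precedence_over_normative(make_table):
    records = make_table([
        ("P1", "OD", "affected", 0, "inner_3mm", "S", "GCL", 40.0),
        ("P1", "OS", "reference", 0, "inner_3mm", "S", "GCL", 50.0),
    ])
    profile = small_profile([("S", "GCL", 48.0, 3.0)])
    refs = select_reference(records, normative=profile)
    assert len(refs) == 1
    row = refs.iloc[0]
    assert row["reference_um"] == 50.0
    assert row["source"] == "fellow_eye"


def test_normative_fallback_when_no_fellow_eye(make_table):
    records = make_table([
        ("P1", "OD", "affected", 0, "inner_3mm", "S", "GCL", 40.0),
    ])
    profile = small_profile([("S", "GCL", 48.0, 3.0)])
    refs = select_reference(records, normative=profile)
    assert refs.iloc[0]["reference_um"] == 48.0
    assert refs.iloc[0]["source"] == "normative"


def test_missing_normative_cell_is_an_error(make_table):
    records = make_table([
        ("P1", "OD", "affected", 0, "inner_3mm", "N", "GCL", 40.0),
    ])
    profile = small_profile([("S", "GCL", 48.0, 3.0)])
    with pytest.raises(ReferenceSelectionError, match="N"):
        select_reference(records, normative=profile)
    with pytest.raises(ReferenceSelectionError):
        select_reference(records, normative=None)


def _quadrant_case(changes):
    """Affected GCL thicknesses against a 100 um reference per quadrant."""
    rows = [
        ("P1", "OD", "affected", 10, "inner_3mm", q, "GCL",
         100.0 * (1.0 + pct / 100.0))
        for q, pct in zip("TSNI", changes)
    ]
    records = pd.DataFrame(
        rows,
        columns=["patient_id", "eye", "status", "day", "ring", "quadrant",
                 "layer", "thickness_um"],
    )
    references = pd.DataFrame(
        {"quadrant": list("TSNI"), "layer": "GCL", "reference_um": 100.0,
         "source": "fellow_eye"}
    )
    return records, references


@pytest.mark.parametrize(
    ("changes", "expected"),
    [
        ((-5, -31, -8, -2), "S"),
        ((-10, -10, -10, -10), "T"),   # tie-break order T < S < N < I
        ((-39, -39, -40, -10), "N"),
    ],
)
def test_most_affected_quadrant_selection(changes, expected):
    records, references = _quadrant_case(changes)
    assert most_affected_quadrant(records, references) == expected


def test_most_affected_quadrant_ignores_row_order(rng):
    records, references = _quadrant_case((-12.5, -3, -12.4, -40))
    for _ in range(5):
        shuffled = records.sample(frac=1, random_state=rng.integers(1 << 30))
        assert most_affected_quadrant(
            shuffled.reset_index(drop=True), references
        ) == "I"


def test_quadrant_chosen_at_earliest_scan(make_table):
    # later visit has a deeper loss elsewhere, but day 5 decides
    records = make_table([
        ("P1", "OD", "affected", 5, "inner_3mm", "T", "GCL", 70.0),
        ("P1", "OD", "affected", 5, "inner_3mm", "S", "GCL", 90.0),
        ("P1", "OD", "affected", 200, "inner_3mm", "T", "GCL", 80.0),
        ("P1", "OD", "affected", 200, "inner_3mm", "S", "GCL", 30.0),
    ])
    references = pd.DataFrame(
        {"quadrant": ["T", "S"], "layer": "GCL", "reference_um": 100.0,
         "source": "fellow_eye"}
    )
    assert most_affected_quadrant(records, references) == "T"
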