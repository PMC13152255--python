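"""ACMG/AMP token parsing, point arithmetic and the five-tier classifier."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sgecurate import (
    EvidenceParseError,
    ValidationError,
    aggregate_points,
    classify,
    classify_variant,
    parse_evidence_code,
    parse_evidence_list,
)
from sgecurate.evidence import CLASS_LABELS, FAMILY_DEFAULT_STRENGTH, SUFFIX_STRENGTH


@pytest.mark.parametrize(
    "token, direction, strength, points",
    [
        ("PVS1", "pathogenic", "very_strong", 8),
        ("PS1", "pathogenic", "strong", 4),
        ("PM2", "pathogenic", "moderate", 2),
        ("PP3", "pathogenic", "supporting", 1),
        ("PM2_P", "pathogenic", "supporting", 1),
        ("PM5_S", "pathogenic", "strong", 4),
        ("PP1_M", "pathogenic", "moderate", 2),
        ("PS1_P", "pathogenic", "supporting", 1),
        ("BS1", "benign", "strong", -4),
        ("BP4", "benign", "supporting", -1),
        ("BP7_S", "benign", "strong", -4),
        ("BS1_P", "benign", "supporting", -1),
        ("BP7_VS", "benign", "very_strong", -8),
    ],
)
def test_parse_token(token, direction, strength, points):
    code = parse_evidence_code(token)
    assert code.direction == direction
    assert code.strength == strength
    assert code.points == points
    assert code.render() == token


def test_parse_strips_parenthetical_comment():
    assert parse_evidence_code("BP7_S (RNA)").label == "BP7_S"
    assert parse_evidence_code("PVS1 (RNA)").points == 8


@pytest.mark.parametrize("bad", ["", "XX1", "PS", "PM2_Q", "PM_P", "ps3", "BA1_S", "PM2 P"])
def test_parse_rejects_malformed_tokens(bad):
    with pytest.raises(EvidenceParseError):
        parse_evidence_code(bad)


_VOCABULARY = st.builds(
    lambda family, number, suffix: f"{family}{number}{suffix}",
    family=st.sampled_from(["PVS", "PS", "PM", "PP", "BS", "BP"]),
    number=st.integers(1, 7),
    suffix=st.sampled_from(["", "_P", "_M", "_S", "_VS"]),
)


@given(_VOCABULARY)
def test_parser_round_trip(token):
    """Rendering a parsed code reproduces the input token."""
    code = parse_evidence_code(token)
    assert code.render() == token
    # strength agrees with the suffix, or the family default without one
    if "_" in token:
        assert code.strength == SUFFIX_STRENGTH[token.split("_")[1]]
    else:
        assert code.strength == FAMILY_DEFAULT_STRENGTH[code.base.rstrip("0123456789")]


@pytest.mark.parametrize(
    "tokens, expected",
    [
        ("PVS1; PM2_P; PM5_S", 13),
        ("BS1; BP4; BP7", -6),
        ("", 0),
        ("PS3; PM2_P; PP1_M; PP3", 8),
        ("PM2_P; BS3; BP4", -4),
    ],
)
def test_aggregate_points(tokens, expected):
    assert aggregate_points(parse_evidence_list(tokens)) == expected


def test_aggregate_rejects_duplicate_base_family():
    with pytest.raises(ValidationError, match="PS3"):
        aggregate_points(parse_evidence_list("PS3; PS3_P"))


def test_classify_thresholds_totality_and_monotonicity():
    """Every integer total maps to exactly one label; labels are monotone."""
    order = {label: rank for rank, label in enumerate(CLASS_LABELS)}
    previous = 0
    for total in range(-20, 21):
        label = classify(total)
        assert label in CLASS_LABELS
        rank = order[label]
        assert rank >= previous
        previous = rank
    # band edges
    assert [classify(t) for t in (-7, -6, -2, -1, 5, 6, 9, 10)] == [
        "BV", "LBV", "LBV", "VUS", "VUS", "LPV", "LPV", "PV",
    ]


def test_classify_variant_records_codes_and_total():
    result = classify_variant(parse_evidence_list("PVS1; PM2_P; PM5_S"))
    assert result.total_points == 13
    assert result.label == "PV"
    assert [c.label for c in result.applied_codes] == ["PVS1", "PM2_P", "PM5_S"]
    assert not result.stand_alone_applied


def test_stand_alone_benign_short_circuits_to_bv():
    result = classify_variant(parse_evidence_list("BA1"))
    assert result.label == "BV"
    assert result.stand_alone_applied
    assert result.total_points == 0  # BA1 carries no points
    # even alongside pathogenic evidence the stand-alone call wins
    mixed = classify_variant(parse_evidence_list("BA1; PM2"))
    assert mixed.label == "BV"
    assert mixed.total_points == 2
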