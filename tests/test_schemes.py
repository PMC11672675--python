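"""Position algebra, region catalogs and inter-scheme conversion."""

import random

import pytest

import igentropy as ig
from igentropy.schemes import (
    CATALOG_SCHEMES,
    CDR_REGIONS,
    SchemeError,
    equivalence_table,
    sort_positions,
)


@pytest.mark.parametrize("text,scheme,expected", [
    ("L27B", "kabat", ("L", 27, "B")),
    ("H111.1", "imgt", ("H", 111, ".1")),
    ("L5", "kabat", ("L", 5, None)),
    ("H100T", "kabat", ("H", 100, "T")),
    ("L84.6", "imgt", ("L", 84, ".6")),
])
def test_parse_position_label(text, scheme, expected):
    pos = ig.parse_position_label(text, scheme)
    assert (pos.chain, pos.number, pos.insertion) == expected
    assert pos.label == text  # lossless text round-trip


@pytest.mark.parametrize("text,scheme", [
    ("L27Z", "kabat"),      # tag beyond the enumerated L27A-L27F site
    ("L30A", "kabat"),      # Chothia site, not a Kabat one
    ("H27A", "kabat"),      # no insertion site at H27
    ("L200", "kabat"),      # beyond the chain span
    ("H129", "imgt"),       # beyond the IMGT span
    ("X12", "kabat"),       # unknown chain
    ("L", "kabat"),         # no number
    ("H111.1", "kabat"),    # fractional tag in a lettered scheme
])
def test_parse_rejects_invalid_labels(text, scheme):
    with pytest.raises(SchemeError):
        ig.parse_position_label(text, scheme)


@pytest.mark.parametrize("a,b,scheme,expected", [
    ("L27", "L27A", "kabat", -1),    # untagged precedes tagged
    ("L27A", "L27B", "kabat", -1),   # alphabetical tags
    ("H111.1", "H112.1", "imgt", -1),
    ("H111", "H111.1", "imgt", -1),
    ("H112.1", "H112", "imgt", -1),  # 112.x descends back toward 112
    ("H112.2", "H112.1", "imgt", -1),
    ("L28", "L27F", "kabat", 1),
    ("L5", "L5", "kabat", 0),
])
def test_compare_positions(a, b, scheme, expected):
    pa, pb = ig.parse_position_label(a, scheme), ig.parse_position_label(b, scheme)
    assert ig.compare_positions(pa, pb) == expected
    assert ig.compare_positions(pb, pa) == -expected


def test_imgt_cdr3_insertion_order():
    """Documented IMGT CDR3 site order: 111 < 111.1 < 112.1 < 112."""
    labels = ["H112", "H111.1", "H112.1", "H111"]
    ordered = sort_positions(ig.parse_position_label(t, "imgt")
                             for t in labels)
    assert [p.label for p in ordered] == ["H111", "H111.1", "H112.1", "H112"]


def test_compare_rejects_mixed_chains_or_schemes():
    with pytest.raises(SchemeError):
        ig.compare_positions(ig.parse_position_label("L5", "kabat"),
                             ig.parse_position_label("H5", "kabat"))
    with pytest.raises(SchemeError):
        ig.compare_positions(ig.parse_position_label("L5", "kabat"),
                             ig.parse_position_label("L5", "imgt"))


def test_sorting_is_a_total_order_on_full_inventories():
    """Shuffled full position inventories sort to a unique, stable order."""
    rng = random.Random(7)
    for scheme, chain in [("kabat", "L"), ("kabat", "H"), ("imgt", "H")]:
        inventory = [r[scheme] for r in equivalence_table()
                     if r["chain"] == chain]
        # add every allowed insertion position too
        from igentropy.schemes import INSERTION_SITES
        for (c, base), tags in INSERTION_SITES[scheme].items():
            if c == chain:
                inventory += [f"{c}{base}{t}" for t in tags]
        positions = [ig.parse_position_label(t, scheme)
                     for t in set(inventory)]
        reference = sort_positions(positions)
        for _ in range(5):
            shuffled = positions[:]
            rng.shuffle(shuffled)
            assert sort_positions(shuffled) == reference
        # strict: no two distinct positions compare equal
        keys = [p.sort_key() for p in reference]
        assert len(set(keys)) == len(keys)


# ---------------------------------------------------------------------------
# region catalog
# ---------------------------------------------------------------------------

def test_catalog_covers_chain_span_without_gaps_or_overlap():
    cat = ig.default_catalog()
    for scheme in CATALOG_SCHEMES:
        for chain in "LH":
            regs = cat.regions(scheme, chain)
            assert [r[0] for r in regs] == list(
                ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"))
            for (_, _, end_prev), (_, start, _) in zip(regs, regs[1:]):
                assert start == end_prev + 1


@pytest.mark.parametrize("label,scheme,region", [
    ("L30", "kabat", "CDR1"),
    ("L27B", "kabat", "CDR1"),   # insertion inherits the base's region
    ("H36", "kabat", "FR2"),     # first position after Kabat HCDR1
    ("H111.1", "imgt", "CDR3"),
    ("L56", "kabat", "CDR2"),
    ("H26", "chothia", "CDR1"),
])
def test_region_of(label, scheme, region):
    assert ig.region_of(ig.parse_position_label(label, scheme)) == region


def test_region_of_outside_span_errors():
    pos = ig.parse_position_label("L109", "kabat")  # valid, past catalog FR4
    with pytest.raises(SchemeError):
        ig.region_of(pos)


@pytest.mark.parametrize("label,expected", [
    ("H93", True), ("H92", False), ("L56", True), ("L57", False),
    ("H26", True), ("H25", False), ("L24", True), ("H35H", True),
])
def test_general_cdr(label, expected):
    assert ig.general_cdr(ig.parse_position_label(label, "kabat")) is expected


def test_general_cdr_requires_kabat():
    with pytest.raises(SchemeError):
        ig.general_cdr(ig.parse_position_label("H105", "imgt"))


# ---------------------------------------------------------------------------
# scheme conversion
# ---------------------------------------------------------------------------

def test_convert_identity():
    pos = ig.parse_position_label("L27B", "kabat")
    assert ig.convert_scheme(pos, "kabat") is pos


def test_convert_round_trip_over_whole_table():
    """kabat -> target -> kabat is the identity on every table column."""
    for row in equivalence_table():
        pos = ig.parse_position_label(row["kabat"], "kabat")
        for target in ("imgt", "aho", "chothia", "abm"):
            there = ig.convert_scheme(pos, target)
            assert there.label == row[target]
            assert ig.convert_scheme(there, "kabat") == pos


@pytest.mark.parametrize("src,scheme,target,expected", [
    ("L27B", "kabat", "imgt", "L29"),    # kappa CDR1 pivot column
    ("H29", "kabat", "imgt", "H30"),     # heavy pivot column
    ("H93", "kabat", "imgt", "H105"),    # general-CDR3 start
    ("L88", "kabat", "aho", "L106"),     # conserved Cys
    ("L61", "kabat", "imgt", "L75"),     # RFSGSXSG strand start
    ("L29", "imgt", "kabat", "L27B"),
])
def test_convert_anchor_correspondences(src, scheme, target, expected):
    pos = ig.parse_position_label(src, scheme)
    assert ig.convert_scheme(pos, target).label == expected


def test_convert_outside_table_is_an_error():
    # IMGT 37/38 (long-CDR1 slots) lie outside the canonical column table
    with pytest.raises(SchemeError):
        ig.convert_scheme(ig.parse_position_label("H37", "imgt"), "kabat")


def test_every_scheme_cdr_maps_into_general_cdr():
    """The general CDR is the union of all scheme CDR definitions: any
    convertible CDR position of any scheme lands inside it on Kabat
    numbering."""
    cat = ig.default_catalog()
    for scheme in ("kabat", "chothia", "consensus_chothia", "abm", "imgt"):
        for row in equivalence_table():
            pos = ig.parse_position_label(row[scheme], scheme)
            if not ig.region_of(pos, cat).startswith("CDR"):
                continue
            as_kabat = ig.convert_scheme(pos, "kabat")
            assert ig.general_cdr(as_kabat), (
                f"{scheme} CDR position {pos.label} maps to "
                f"{as_kabat.label}, outside the general CDR")


def test_catalog_export_records():
    recs = ig.default_catalog().to_records()
    assert {"scheme": "kabat", "chain": "L", "region": "CDR1",
            "start": "L24", "end": "L34"} in recs
    assert {"scheme": "general", "chain": "H", "region": "CDR3",
            "start": "H93", "end": "H102"} in recs
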