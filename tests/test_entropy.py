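"""Relative entropy, region summaries, hotspots and pivot analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import igentropy as ig
from igentropy.entropy import (
    BITS,
    FiveNumberSummary,
    UnsupportedSupportError,
    five_number_summary,
)
from igentropy.schemes import AMINO_ACIDS, SchemeError
from igentropy.frequencies import ReferenceDistribution

from conftest import random_simplex, shifted_delta


def brute_force_re(p, q, base=math.e):
    """Independent term-by-term oracle for RE(p || q)."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total / math.log(base)


# ---------------------------------------------------------------------------
# relative_entropy
# ---------------------------------------------------------------------------

def test_identity_gives_exactly_zero():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = random_simplex(rng)
        assert ig.relative_entropy(p, p) == 0.0


def test_one_hot_vs_uniform_closed_form():
    p = np.zeros(20)
    p[AMINO_ACIDS.index("W")] = 1.0
    q = ReferenceDistribution.uniform()
    assert ig.relative_entropy(p, q) == pytest.approx(math.log(20),
                                                      abs=1e-12)
    assert ig.relative_entropy(p, q, base=BITS) == pytest.approx(
        math.log2(20), abs=1e-12)


def test_matches_term_by_term_oracle():
    rng = np.random.default_rng(42)
    for _ in range(500):
        p, q = random_simplex(rng, 0.5), random_simplex(rng, 0.5)
        assert ig.relative_entropy(p, q) == pytest.approx(
            brute_force_re(p, q), abs=1e-12)


def test_bits_equals_nats_over_ln2():
    rng = np.random.default_rng(1)
    p, q = random_simplex(rng), random_simplex(rng)
    assert ig.relative_entropy(p, q, base=2) == pytest.approx(
        ig.relative_entropy(p, q) / math.log(2), abs=1e-12)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_gibbs_inequality_and_identity_of_indiscernibles(seed):
    """RE >= 0 always; RE == 0 iff p == q (within tolerance)."""
    rng = np.random.default_rng(seed)
    p, q = random_simplex(rng, 0.7), random_simplex(rng, 0.7)
    re = ig.relative_entropy(p, q)
    assert re >= 0.0
    if re < 1e-12:
        assert np.allclose(p, q, atol=1e-6)
    assert ig.relative_entropy(p, p) == 0.0


def test_zero_times_log_zero_is_zero():
    p = np.zeros(20)
    p[0] = 1.0
    q = np.full(20, 0.05)
    # p has zeros where q > 0: those terms contribute nothing
    assert ig.relative_entropy(p, q) == pytest.approx(math.log(20))


def test_unsupported_support_is_an_error():
    p = np.full(20, 0.05)
    q = np.zeros(20)
    q[:10] = 0.1
    with pytest.raises(UnsupportedSupportError):
        ig.relative_entropy(p, q)


def test_malformed_simplex_rejected():
    q = ReferenceDistribution.uniform()
    with pytest.raises(SchemeError):
        ig.relative_entropy(np.full(20, 0.06), q)  # sums to 1.2


# ---------------------------------------------------------------------------
# profiles and summaries
# ---------------------------------------------------------------------------

def test_profile_zero_when_table_matches_reference(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    for pos in table.positions[:5]:
        q = ReferenceDistribution(name="self", q=table.p(pos.label))
        assert ig.relative_entropy(table.p(pos.label), q) == 0.0


def test_profile_composes_relative_entropy(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    ref = ig.pooled_reference(table)
    profile = ig.re_profile(table, ref)
    assert len(profile) == len(table.positions)
    for pos in table.positions[::25]:
        assert profile.values[pos.label] == pytest.approx(
            brute_force_re(table.p(pos.label), ref.q), abs=1e-12)


def test_region_summary_hand_computed():
    """{1,1,1,1,5}: mean 1.8, sample SD sqrt(3.2), median 1."""
    vals = [1.0, 1.0, 1.0, 1.0, 5.0]
    arr = np.asarray(vals)
    assert arr.mean() == pytest.approx(1.8)
    assert arr.std(ddof=1) == pytest.approx(math.sqrt(3.2))
    assert np.median(arr) == 1.0


def test_summarize_regions_constant_profile(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    ref = ig.pooled_reference(table)
    profile = ig.re_profile(table, ref)
    profile.values[:] = 2.0
    summary = ig.summarize_regions(profile)
    for region in ("FR1", "CDR2", "all", "framework", "all_CDR"):
        assert summary.loc[region, "mean"] == 2.0
        assert summary.loc[region, "median"] == 2.0
        assert summary.loc[region, "sd"] == 0.0
    assert summary.loc["all", "n"] == len(profile)


def test_cdr_position_counts_differ_between_schemes():
    """Kabat LCDR1 (L24-L34) is wider than consensus Chothia (L26-L32),
    so the same light domain yields different CDR1 n per scheme."""
    n = 400
    reps = {s: ig.sample_repertoire(ig.default_spec("L", s, "human"), n, 5)
            for s in ("kabat", "consensus_chothia")}
    summaries = {}
    for scheme, rep in reps.items():
        table = ig.build_frequency_table(rep)
        ref = ig.pooled_reference(table)
        summaries[scheme] = ig.summarize_regions(ig.re_profile(table, ref))
    assert (summaries["kabat"].loc["CDR1", "n"]
            > summaries["consensus_chothia"].loc["CDR1", "n"])


# ---------------------------------------------------------------------------
# five-number summary
# ---------------------------------------------------------------------------

def test_five_number_summary_quartile_rule():
    fns = five_number_summary(range(1, 10))
    assert fns.q1 == 3.0 and fns.median == 5.0 and fns.q3 == 7.0
    assert fns.lower_whisker == 1.0 and fns.upper_whisker == 9.0
    assert fns.outliers == ()


def test_five_number_summary_constant_list():
    fns = five_number_summary([2.5] * 6)
    assert fns == FiveNumberSummary(2.5, 2.5, 2.5, 2.5, 2.5, ())


def test_five_number_summary_outlier():
    fns = five_number_summary([1, 1, 1, 1, 100])
    assert fns.outliers == (100.0,)
    assert fns.upper_whisker == 1.0


def test_five_number_summary_empty_errors():
    with pytest.raises(SchemeError):
        five_number_summary([])


# ---------------------------------------------------------------------------
# cross-species profiles and hotspots
# ---------------------------------------------------------------------------

def test_cross_species_identical_tables_all_zero(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    profile = ig.cross_species_profile(table, table)
    assert np.allclose(profile.values.to_numpy(), 0.0)


def test_cross_species_intersection_rule(heavy_rep):
    t_all = ig.build_frequency_table(heavy_rep, min_occupancy=0.0)
    t_strict = ig.build_frequency_table(heavy_rep, min_occupancy=0.9)
    profile = ig.cross_species_profile(t_all, t_strict, pseudocount=0.5)
    assert set(profile.values.index) <= set(t_strict.counts.index)


def test_hotspot_hand_example():
    """Region {1,1,1,1,5}, k=1.65: threshold ~= 4.75, only the 5 flagged."""
    vals = np.array([1, 1, 1, 1, 5.0])
    threshold = vals.mean() + 1.65 * vals.std(ddof=1)
    assert threshold == pytest.approx(4.7517, abs=1e-3)
    assert (vals > threshold).sum() == 1


def test_hotspots_constant_region_flags_nothing(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    ref = ig.pooled_reference(table)
    profile = ig.re_profile(table, ref)
    profile.values[:] = 1.5
    report = ig.detect_hotspots(profile, by="region")
    assert report.flagged.empty  # strict inequality at SD = 0


def test_hotspot_flags_reproducible_from_thresholds(heavy_rep):
    """Recomputing the flag set from the emitted thresholds reproduces it."""
    spec = ig.default_spec("H", "kabat", "human")
    a, b = ig.planted_pair(spec, [("H10", shifted_delta(spec, "H10"))])
    ta = ig.build_frequency_table(ig.sample_repertoire(a, 800, 21))
    tb = ig.build_frequency_table(ig.sample_repertoire(b, 800, 22))
    profile = ig.cross_species_profile(ta, tb, pseudocount=0.5)
    report = ig.detect_hotspots(profile, by="region")
    cat = ig.default_catalog()
    expected = set()
    for pos in profile.positions:
        group = ig.region_of(pos, cat)
        if group not in report.thresholds.index:
            continue
        if profile.values[pos.label] > report.thresholds.loc[group,
                                                             "threshold"]:
            expected.add(pos.label)
    assert set(report.flagged["position"]) == expected
    for _, row in report.flagged.iterrows():
        assert row["re"] > row["threshold"]


def test_hotspot_small_region_skipped_with_warning(heavy_rep):
    table = ig.build_frequency_table(heavy_rep)
    ref = ig.pooled_reference(table)
    profile = ig.re_profile(table, ref)
    # restrict to one position: its region has n = 1
    import pandas as pd
    tiny = ig.REProfile(values=profile.values.iloc[:1],
                        positions=profile.positions[:1],
                        reference_name=ref.name, base=profile.base,
                        scheme=profile.scheme, chain=profile.chain)
    with pytest.warns(UserWarning):
        report = ig.detect_hotspots(tiny, by="region")
    assert report.thresholds.empty


# ---------------------------------------------------------------------------
# pivot distributions
# ---------------------------------------------------------------------------

def test_kappa_pivot_hydrophobic_share(light_rep):
    """Kappa pivot drawn 60% from {I, V, L}: recovered within sampling
    error, at the scheme-appropriate label (Kabat L27B)."""
    report = ig.pivot_distribution(light_rep, cutoff=0.0)
    assert report.positions["kappa"] == "L27B"
    dist = report.distributions["kappa"]
    ivl = float(dist.get("I", 0) + dist.get("V", 0) + dist.get("L", 0))
    assert ivl == pytest.approx(0.60, abs=0.06)


def test_pivot_cutoff_zero_sums_to_one(light_rep):
    report = ig.pivot_distribution(light_rep, cutoff=0.0)
    for stratum, dist in report.distributions.items():
        if len(dist):
            assert float(dist.sum()) == pytest.approx(1.0, abs=1e-12)
            assert "other" not in dist.index


def test_pivot_cutoff_aggregates_other(light_rep):
    report = ig.pivot_distribution(light_rep, cutoff=0.04)
    dist = report.distributions["kappa"]
    assert "other" in dist.index
    assert float(dist.sum()) == pytest.approx(1.0, abs=1e-12)
    assert (dist.drop("other") >= 0.04).all()


def test_all_heavy_repertoire_has_no_light_strata(heavy_rep):
    report = ig.pivot_distribution(heavy_rep)
    assert set(report.distributions) == {"heavy"}
    assert report.positions["heavy"] == "H29"  # IMGT H30 on Kabat numbering
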