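"""Anti-SD positional profiles, group assignment, class aggregation."""

import pytest

from antisdscan.profiles import (
    AntiSDProfile,
    GroupCatalog,
    SDScarce,
    aggregate_class,
    assign_group,
    build_profile,
    position_correlation,
    profile_to_table,
)
from antisdscan.rrna_tail import CoreAnnotation, TailRecord, locate_core
from antisdscan.scan import SDCall
from antisdscan.seqio import reverse_complement
from antisdscan.thermo import CANONICAL_TAIL


def sd_call(gene_id, positions, dg=-10.0):
    return SDCall(gene_id, dg, -15, True, None, tuple(positions))


def bg_call(gene_id):
    return SDCall(gene_id, -3.0, -15, False, None, ())


@pytest.fixture(scope="module")
def tail():
    return TailRecord("org", CANONICAL_TAIL)


@pytest.fixture(scope="module")
def core(tail):
    return locate_core(tail)


class TestBuildProfile:
    def test_planted_span_and_consensus(self, tail, core):
        calls = [sd_call(f"g{i}", range(-2, 5)) for i in range(64)]
        calls += [bg_call(f"b{i}") for i in range(36)]
        prof = build_profile(calls, tail, core)
        assert isinstance(prof, AntiSDProfile)
        assert prof.span == (-2, 4)
        assert prof.consensus == "CCUCCUU"
        assert prof.sd_consensus == "AAGGAGG"
        assert prof.mode_freq == pytest.approx(0.64)

    def test_sd_scarce_signal(self, tail, core):
        calls = [sd_call("g0", range(-2, 5)), sd_call("g1", range(-2, 5))]
        calls += [bg_call(f"b{i}") for i in range(98)]  # 2% SD
        prof = build_profile(calls, tail, core)
        assert isinstance(prof, SDScarce)
        assert prof.pct_sd == pytest.approx(2.0)

    def test_exactly_5_5_pct_is_scarce(self, tail, core):
        # rule is strict ">": 5.5% exactly gets no profile
        calls = [sd_call(f"g{i}", range(-2, 5)) for i in range(11)]
        calls += [bg_call(f"b{i}") for i in range(189)]
        assert isinstance(build_profile(calls, tail, core), SDScarce)

    def test_uniform_frequencies_all_in_span(self, tail, core):
        calls = [sd_call(f"g{i}", range(-2, 5)) for i in range(20)]
        prof = build_profile(calls, tail, core)
        assert prof.span == (-2, 4) and prof.length == 7

    def test_minor_positions_below_cutoff_excluded(self, tail, core):
        calls = [sd_call(f"g{i}", range(-2, 5)) for i in range(100)]
        calls += [sd_call(f"x{i}", range(-5, 2)) for i in range(30)]
        prof = build_profile(calls, tail, core)
        # positions -5..-3 appear in 30/130 < 0.4 * mode(130/130 at -2..1)
        assert prof.span[0] == -2

    def test_freq_bounded_by_pct_sd(self, tail, core, small_calls,
                                    small_organism):
        prof = build_profile(small_calls, small_organism.tail,
                             small_organism.core)
        assert all(0 <= f <= prof.pct_sd / 100 + 1e-12
                   for f in prof.freq.values())
        # the span always contains the histogram peak
        peak = max(prof.freq, key=lambda p: (prof.freq[p], -p))
        assert prof.span[0] <= peak <= prof.span[1]


class TestGroupCatalog:
    def test_catalog_is_consistent(self):
        catalog = GroupCatalog.load()
        assert len(catalog) == 15
        for entry in catalog:
            assert reverse_complement(entry.antisd) == entry.sd
            assert len(entry.antisd) == entry.span[1] - entry.span[0] + 1

    @pytest.mark.parametrize(
        "span,expected",
        [((-2, 4), 8), ((-5, 3), 12), ((-2, 6), 1), ((-6, 1), 15)],
    )
    def test_exact_span_assignment(self, span, expected):
        prof = AntiSDProfile("x", {0: 1.0}, span, "N" * (span[1] - span[0] + 1),
                             100, 50.0)
        group, entry = assign_group(prof)
        assert group == expected and entry.group_id == expected

    def test_unassigned_reports_nearest(self):
        prof = AntiSDProfile("x", {0: 1.0}, (-7, 7), "N" * 15, 100, 50.0)
        group, nearest = assign_group(prof)
        assert group is None
        assert nearest.group_id in range(1, 16)


class TestAggregateClass:
    def members(self, tail, core, n_org=3, span=range(-2, 5)):
        out = []
        for o in range(n_org):
            calls = [sd_call(f"o{o}g{i}", span) for i in range(60)]
            calls += [bg_call(f"o{o}b{i}") for i in range(40)]
            out.append((calls, tail, core))
        return out

    def test_identical_members_equal_member_profile(self, tail, core):
        members = self.members(tail, core)
        class_prof, report = aggregate_class(members, "classA")
        member_prof = build_profile(*members[0], profile_id="m")
        assert class_prof.span == member_prof.span
        assert class_prof.freq == pytest.approx(member_prof.freq)
        assert len(report) == 3

    def test_single_member_idempotent(self, tail, core):
        members = self.members(tail, core, n_org=1)
        class_prof, _ = aggregate_class(members, "classB")
        member_prof = build_profile(*members[0])
        assert class_prof.span == member_prof.span
        assert class_prof.consensus == member_prof.consensus

    def test_pooled_frequencies_average_shifted_members(self, tail, core):
        m1 = self.members(tail, core, n_org=1, span=range(-2, 5))
        m2 = self.members(tail, core, n_org=1, span=range(-3, 4))
        class_prof, _ = aggregate_class(m1 + m2, "classC")
        # equal gene counts: pooled freq is the mean of the members'
        assert class_prof.freq[-3] == pytest.approx(0.3)   # only member 2
        assert class_prof.freq[-2] == pytest.approx(0.6)   # both members
        assert class_prof.freq[4] == pytest.approx(0.3)    # only member 1

    def test_no_profiled_member_raises(self, tail, core):
        calls = [bg_call(f"b{i}") for i in range(50)]
        with pytest.raises(ValueError):
            aggregate_class([(calls, tail, core)], "empty")

    def test_position_report_and_correlation(self, tail, core):
        members = self.members(tail, core)
        _, report = aggregate_class(members, "classD")
        assert {"mean_sd_window_position", "mean_profile_position"} <= set(
            report.columns
        )
        r = position_correlation(report)
        assert r != r or -1.0 <= r <= 1.0  # NaN allowed for degenerate input


def test_profile_table_flags_span(tail, core):
    calls = [sd_call(f"g{i}", range(-2, 5)) for i in range(10)]
    table = profile_to_table(build_profile(calls, tail, core))
    assert table["in_span"].all()
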