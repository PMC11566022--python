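"""UMI deduplication, spike-in calibration, prefix grouping and the
ppm / molecules-per-cell / picomolar unit conversions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pislice.smallrna import (
    Calibration,
    CalibrationError,
    SpikeIn,
    SpikeInSet,
    apply_detection_filter,
    calibrate,
    deduplicate,
    detectability_probability,
    group_by_prefix,
    is_undetectable_in_mutant,
    molecules_to_pm,
    pm_to_molecules,
    ppm_to_molecules,
)

INSERT = "ACGTACGTACGTACGTACGTACGTAC"


def _read(insert, umi5="AAAAAAAAA", umi3="CCCCCCCCC"):
    return umi5 + insert + umi3


class TestDeduplicate:
    def test_identical_insert_and_umis_count_once(self):
        counts = deduplicate([_read(INSERT), _read(INSERT)])
        assert counts == {INSERT: 1}

    def test_identical_insert_different_umis_count_twice(self):
        counts = deduplicate([_read(INSERT), _read(INSERT, umi5="GGGGGGGGG")])
        assert counts == {INSERT: 2}

    def test_short_reads_skipped(self):
        assert deduplicate(["ACGTACGTACGTACGTAC"]) == {}  # 18 nt: no insert

    def test_umi_collision_rate_matches_birthday_bound(self):
        # 1,000 reads drawn from 100 molecules, each re-amplified 10x with
        # its own UMI pair: deduplication recovers ~100; the only loss is
        # UMI collisions between distinct molecules, << 1 at 4^18 pairs.
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        molecules = ["".join(rng.choice(bases, 26)) for _ in range(100)]
        reads = []
        for insert in molecules:
            umi = "".join(rng.choice(bases, 18))
            reads.extend([umi[:9] + insert + umi[9:]] * 10)
        counts = deduplicate(reads)
        total = sum(counts.values())
        expected_collisions = 100 * 99 / 2 / 4**18
        assert total >= 100 - math.ceil(3 * (1 + expected_collisions))
        assert total <= 100


class TestBlocklist:
    def test_blocklisted_inserts_removed(self):
        from pislice.smallrna import apply_blocklist
        counts = {INSERT: 5, "G" * 26: 3}
        assert apply_blocklist(counts, ["G" * 26]) == {INSERT: 5}

    def test_blocklist_from_fasta(self, tmp_path):
        from pislice.smallrna import apply_blocklist
        fasta = tmp_path / "rrna.fasta"
        fasta.write_text(f">rrna1\n{'G' * 26}\n")
        assert apply_blocklist({INSERT: 5, "G" * 26: 3}, fasta) == {INSERT: 5}


class TestCalibrate:
    SPIKES = SpikeInSet(tuple(
        SpikeIn(f"s{i}", "ACGTACGTACGTACGTACGT" + b1 + b2, 100.0)
        for i, (b1, b2) in enumerate((x, y) for x in "ACG" for y in "ACG")
    ))

    def test_scale_is_molecules_over_reads(self):
        counts = {e.sequence: 100 for e in self.SPIKES.entries}  # 900 reads
        counts[INSERT] = 50
        cal = calibrate(counts, self.SPIKES)
        assert cal.molecules_per_read == pytest.approx(1.0)  # 9x100 / 900
        assert cal.molecules[INSERT] == pytest.approx(50.0)

    def test_ppm_invariant_to_doubling_all_counts(self):
        counts = {e.sequence: 7 for e in self.SPIKES.entries}
        counts.update({INSERT: 10, "G" * 26: 30})
        a = calibrate(counts, self.SPIKES)
        b = calibrate({k: 2 * v for k, v in counts.items()}, self.SPIKES)
        assert a.ppm == pytest.approx(b.ppm)

    def test_zero_spike_reads_is_an_error(self):
        with pytest.raises(CalibrationError):
            calibrate({INSERT: 10}, self.SPIKES)


class TestPrefixGroups:
    def test_shared_prefix_sums_and_representative_is_most_abundant(self):
        seqs = [INSERT[:25] + suffix for suffix in ("A", "G", "GT")]
        ppm = pd.DataFrame({"rep1": [5.0, 3.0, 2.0]}, index=seqs)
        groups = group_by_prefix(ppm)
        assert len(groups) == 1
        assert groups["rep1"].iloc[0] == pytest.approx(10.0)
        assert groups["representative"].iloc[0] == seqs[0]

    def test_distinct_prefixes_stay_separate(self):
        ppm = pd.DataFrame({"rep1": [1.0, 1.0]},
                           index=["A" * 26, "C" * 26])
        assert len(group_by_prefix(ppm)) == 2

    def test_abundance_tie_resolved_lexicographically(self):
        seqs = [INSERT[:25] + "T", INSERT[:25] + "A"]
        for order in (seqs, seqs[::-1]):
            ppm = pd.DataFrame({"rep1": [4.0, 4.0]}, index=order)
            groups = group_by_prefix(ppm)
            assert groups["representative"].iloc[0] == INSERT[:25] + "A"

    def test_short_inserts_discarded(self):
        ppm = pd.DataFrame({"rep1": [9.0, 1.0]}, index=["ACGT", "A" * 25])
        groups = group_by_prefix(ppm)
        assert list(groups.index) == ["A" * 25]


class TestDetectionFilter:
    def test_boundary_one_ppm_in_every_control_is_retained(self):
        groups = pd.DataFrame({"c1": [1.0, 0.9], "c2": [1.2, 5.0], "c3": [3.0, 5.0]},
                              index=["keep", "drop"])
        kept = apply_detection_filter(groups, ["c1", "c2", "c3"])
        assert list(kept.index) == ["keep"]

    def test_empty_group_list(self):
        empty = pd.DataFrame(columns=["c1"])
        assert apply_detection_filter(empty, ["c1"]).empty

    @pytest.mark.parametrize("values,expected", [
        ([0.05, 0.05], True),
        ([0.1, 0.1], True),     # boundary inclusive
        ([0.2, 0.2], False),
    ])
    def test_undetectable_in_mutant_uses_mean(self, values, expected):
        assert is_undetectable_in_mutant(values) is expected


class TestUnitConversions:
    def test_one_ppm_is_ten_molecules_per_spermatocyte(self):
        assert ppm_to_molecules(1.0, 1e7) == pytest.approx(10.0)

    def test_fifty_ppm_is_five_hundred_molecules(self):
        assert ppm_to_molecules(50.0, 1e7) == pytest.approx(500.0)

    def test_one_molecule_in_a_primary_spermatocyte_is_about_one_pm(self):
        pm = molecules_to_pm(1.0, 1800.0)
        assert pm == pytest.approx(1 / (1.8e-12 * 6.02214076e23) * 1e12)
        assert round(pm) == 1

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            ppm_to_molecules(1.0, 0)
        with pytest.raises(ValueError):
            molecules_to_pm(1.0, -1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e9),
           st.floats(min_value=1.0, max_value=1e6))
    def test_pm_molecule_round_trip(self, pm, volume):
        assert pm_to_molecules(molecules_to_pm(pm, volume), volume) == \
            pytest.approx(pm, rel=1e-12)


class TestDetectability:
    def test_mean_ten_exceeds_4_nines(self):
        p = detectability_probability(10.0)
        assert p == pytest.approx(1 - math.exp(-10))
        assert p >= 0.9999

    def test_zero_mean(self):
        assert detectability_probability(0.0) == 0.0

    def test_ln2_mean_gives_half(self):
        assert detectability_probability(math.log(2)) == pytest.approx(0.5)

    def test_negative_binomial_option(self):
        # NB with dispersion -> 0 approaches the Poisson answer
        nb = detectability_probability(10.0, model="nb", dispersion=1e-9)
        assert nb == pytest.approx(1 - math.exp(-10), rel=1e-6)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            detectability_probability(-1.0)


def test_end_to_end_recovery_on_synthetic_reads(default_world):
    """Measured group abundance tracks generator truth for well-expressed
    guides (>= 10 ppm): unbiased, with the typical (median) deviation
    inside 15% — the spread itself is set by the replicate NB dispersion."""
    world = default_world
    measured = world.smallrna_ppm["control"].mean(axis=1)
    truth = world.pirnas.set_index("guide_id")["ppm_true"]
    well = truth[truth >= 10].index
    rel = (measured[well] - truth[well]) / truth[well]
    assert abs(rel.mean()) < 0.05
    assert rel.abs().median() < 0.15


def test_retained_ppm_sums_below_one_million(default_world):
    ppm = default_world.smallrna_ppm["control"]
    assert (ppm.sum(axis=0) <= 1e6 + 1e-6).all()
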