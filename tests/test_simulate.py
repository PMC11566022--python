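"""The synthetic world: planted sites, kinetics, determinism, file output."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from Bio import SeqIO

from pislice.pairing import align_guide_at_site, satisfies_tier
from pislice.simulate import (
    ConfigurationError,
    SimConfig,
    TIER_PATTERNS,
    emit_reads,
    generate_world,
    plant_target_site,
)
from pislice.smallrna import deduplicate


class TestConfigValidation:
    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(k_dec_range=(0.0, 1.0))

    def test_zero_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(depth=0)

    def test_tier_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(tier_mix=(0.5, 0.5, 0.5, 0.5))


class TestPlantTargetSite:
    GUIDE = "ACGGTTACGTTGCAGGTACCGTAGCA"  # 26 nt

    def test_r2_site_is_contiguous_g3_g15(self):
        rng = np.random.default_rng(0)
        seq, p = plant_target_site(self.GUIDE, "A" * 200, "R2", rng)
        pairing = align_guide_at_site(self.GUIDE, seq, p)
        assert pairing.contiguous(3, 15)
        assert not pairing.contiguous(3, 16)

    def test_r1_minimal_site_has_exactly_20_paired_in_g2_g25(self):
        rng = np.random.default_rng(0)
        seq, p = plant_target_site(self.GUIDE, "A" * 200, "R1", rng)
        pairing = align_guide_at_site(self.GUIDE, seq, p)
        assert pairing.paired_in(2, 25) == 20
        # broken contiguity: the site is R1-only geometry
        assert not pairing.contiguous(3, 15)

    def test_r4_site_breaks_the_seed_side_windows(self):
        rng = np.random.default_rng(0)
        seq, p = plant_target_site(self.GUIDE, "A" * 200, "R4", rng)
        pairing = align_guide_at_site(self.GUIDE, seq, p)
        assert pairing.contiguous(4, 17)
        assert not pairing.contiguous(3, 16)
        assert pairing.paired_in(2, 25) < 20

    def test_same_seed_gives_identical_coordinate(self):
        a = plant_target_site(self.GUIDE, "A" * 200, "R3", np.random.default_rng(9))
        b = plant_target_site(self.GUIDE, "A" * 200, "R3", np.random.default_rng(9))
        assert a == b

    def test_too_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            plant_target_site(self.GUIDE, "A" * 20, "R2", np.random.default_rng(0))


class TestWorldInvariants:
    def test_every_planted_site_passes_its_tier_when_rescanned(self, default_world):
        world = default_world
        seqs = world.transcript_sequences
        guides = world.pirnas.set_index("guide_id")
        for row in world.truth_targets.itertuples():
            pairing = align_guide_at_site(guides.loc[row.guide_id, "sequence"],
                                          seqs[row.transcript_id], row.position)
            verdict = satisfies_tier(pairing, guides.loc[row.guide_id, "ppm_true"])
            assert row.tier in verdict.satisfied_rules

    def test_knockout_has_zero_reads_for_focal_and_dependent_guides(self, default_world):
        world = default_world
        gone = world.pirnas.loc[
            world.pirnas["locus"].isin(world.config.focal_loci)
            | world.pirnas["biogenesis_dependent"], "guide_id"]
        ko = world.smallrna_counts["knockout"].loc[gone]
        assert (ko.to_numpy() == 0).all()

    def test_steady_state_fold_change_follows_rates(self, default_world):
        rates = default_world.rates
        expected = 1 + rates["k_slice"] / rates["k_dec"]
        focal_tx = default_world.truth_targets.query("kind == 'focal'")["transcript_id"]
        observed = (rates["ss_knockout"] / rates["ss_control"]).loc[focal_tx]
        assert observed.to_numpy() == pytest.approx(expected.loc[focal_tx].to_numpy())
        # unplanted transcripts do not change
        rest = rates.index.difference(focal_tx)
        assert (rates.loc[rest, "ss_knockout"]
                == rates.loc[rest, "ss_control"]).all()

    def test_equal_rates_give_twofold_derepression(self):
        config = SimConfig(seed=2, n_transcripts=30, depth=100_000,
                           degradome_depth=1_000_000, smallrna_depth=200_000,
                           k_dec_range=(0.5, 0.5), k_slice_range=(0.5, 0.5))
        world = generate_world(config)
        focal_tx = world.truth_targets.query("kind == 'focal'")["transcript_id"]
        fc = (world.rates["ss_knockout"] / world.rates["ss_control"]).loc[focal_tx]
        assert fc.to_numpy() == pytest.approx(2.0)

    def test_tier_mix_matches_multinomial_draw(self, default_world):
        """Planted tier counts are consistent with the configured mix
        (chi-square goodness of fit at alpha = 1e-4)."""
        truth = default_world.truth_targets
        counts = truth["tier"].value_counts().reindex(
            ["R1", "R2", "R3", "R4"], fill_value=0)
        expected = np.array(default_world.config.tier_mix) * len(truth)
        stat = ((counts.to_numpy() - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(1 - 1e-4, df=3)

    def test_determinism_identical_config_identical_world(self):
        config = SimConfig(seed=33, n_transcripts=30, depth=100_000,
                           degradome_depth=1_000_000, smallrna_depth=200_000)
        w1, w2 = generate_world(config), generate_world(config)
        assert w1.transcript_sequences == w2.transcript_sequences
        pd.testing.assert_frame_equal(w1.pirnas, w2.pirnas)
        pd.testing.assert_frame_equal(w1.truth_targets, w2.truth_targets)
        for genotype in ("control", "knockout"):
            pd.testing.assert_frame_equal(w1.degradome_ppm[genotype],
                                          w2.degradome_ppm[genotype])
            pd.testing.assert_frame_equal(w1.rnaseq_counts[genotype],
                                          w2.rnaseq_counts[genotype])


class TestEmitReads:
    def test_fastq_record_count_and_insert_lengths(self, small_world, tmp_path):
        emit_reads(small_world, "smallrna", tmp_path, n_reads=10_000)
        records = list(SeqIO.parse(tmp_path / "smallrna.fastq", "fastq"))
        assert len(records) == 10_000
        inserts = {len(r.seq) - 18 for r in records}
        assert all(14 <= n <= 54 for n in inserts)

    def test_fastq_round_trips_through_deduplication(self, small_world, tmp_path):
        emit_reads(small_world, "smallrna", tmp_path, n_reads=2_000)
        reads = [str(r.seq) for r in SeqIO.parse(tmp_path / "smallrna.fastq", "fastq")]
        counts = deduplicate(reads)
        # every insert is a known guide or spike sequence
        known = set(small_world.pirnas["sequence"]) | {
            e.sequence for e in small_world.spike_set.entries}
        assert set(counts) <= known

    def test_count_tables_round_trip(self, small_world, tmp_path):
        emit_reads(small_world, "degradome", tmp_path)
        back = pd.read_csv(tmp_path / "degradome_ppm_control.tsv", sep="\t",
                           index_col=[0, 1])
        pd.testing.assert_frame_equal(
            back, small_world.degradome_ppm["control"], check_exact=False)

    def test_unknown_assay_rejected(self, small_world, tmp_path):
        with pytest.raises(ValueError):
            emit_reads(small_world, "nonsense", tmp_path)

    def test_emitted_files_are_deterministic(self, small_world, tmp_path):
        emit_reads(small_world, "smallrna", tmp_path / "a", n_reads=500)
        emit_reads(small_world, "smallrna", tmp_path / "b", n_reads=500)
        assert ((tmp_path / "a" / "smallrna.fastq").read_bytes()
                == (tmp_path / "b" / "smallrna.fastq").read_bytes())


def test_tier_patterns_satisfy_only_intended_contiguity():
    """Static sanity on the planted geometries: each pattern contains its
    own tier window and omits the position that breaks the next one."""
    assert len(TIER_PATTERNS["R1"]) == 20
    assert set(range(3, 16)) <= TIER_PATTERNS["R2"] and 16 not in TIER_PATTERNS["R2"]
    assert set(range(3, 17)) <= TIER_PATTERNS["R3"] and 17 not in TIER_PATTERNS["R3"]
    assert set(range(4, 18)) <= TIER_PATTERNS["R4"] and 3 not in TIER_PATTERNS["R4"]
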