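import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import gotoh_score, mutate, random_seq
from ripscan.io_formats import SequenceRecord
from ripscan.sv_discovery import (
    DEFAULT_SCORING,
    PairwiseAlignment,
    StructuralVariant,
    _anchored_align,
    align_locus_pair,
    discover_panel,
    extract_indels,
    unify_svs,
)


def record(id_, seq, assembly="asm"):
    return SequenceRecord(id=id_, seq=seq, assembly=assembly)


class TestAlignLocusPair:
    def test_identical_sequences_align_gap_free(self, rng):
        seq = random_seq(rng, 1000)
        aln = align_locus_pair(record("l", seq, "a"), record("l", seq, "b"))
        assert "-" not in aln.aligned_ref and "-" not in aln.aligned_alt
        assert aln.score == 2 * 1000

    def test_inserted_block_appears_as_single_gap_run(self, rng):
        ref = random_seq(rng, 1000)
        block = random_seq(rng, 300)
        alt = ref[:500] + block + ref[500:]
        aln = align_locus_pair(record("l", ref), record("l", alt))
        assert aln.aligned_ref.count("-") == 300
        assert "-" * 300 in aln.aligned_ref
        assert "-" not in aln.aligned_alt

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_exhaustive_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 500))
        ref = random_seq(rng, n)
        # related sequence: substitutions plus a small indel
        alt = mutate(ref, 0.05, rng)
        cut = int(rng.integers(10, n - 10))
        alt = alt[:cut] + random_seq(rng, int(rng.integers(0, 60))) + alt[cut:]
        aln = align_locus_pair(record("l", ref), record("l", alt))
        assert aln.score == gotoh_score(ref, alt)

    def test_gap_removal_recovers_inputs(self, rng):
        ref, alt = random_seq(rng, 200), random_seq(rng, 230)
        aln = align_locus_pair(record("l", ref), record("l", alt))
        assert aln.aligned_ref.replace("-", "") == ref
        assert aln.aligned_alt.replace("-", "") == alt

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            align_locus_pair(record("l", "ACGT"), SequenceRecord(id="l", seq=""))

    def test_high_n_content_warns(self, rng):
        noisy = "N" * 50 + random_seq(rng, 100)
        with pytest.warns(UserWarning, match="N bases"):
            align_locus_pair(record("l", noisy), record("l", noisy))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_small_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(1, 40)))
        b = random_seq(rng, int(rng.integers(1, 40)))
        aln = align_locus_pair(record("l", a), record("l", b))
        assert aln.score == gotoh_score(a, b)
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_alt.replace("-", "") == b


class TestAnchoredAlignment:
    def test_matches_full_dp_on_insertion_pair(self, rng):
        ref = random_seq(rng, 3000)
        alt = ref[:1500] + random_seq(rng, 300) + ref[1500:]
        a_ref, a_alt, score = _anchored_align(ref, alt, DEFAULT_SCORING)
        aln = align_locus_pair(record("l", ref), record("l", alt))
        assert score == aln.score
        assert a_ref.replace("-", "") == ref and a_alt.replace("-", "") == alt
        svs = extract_indels(PairwiseAlignment("l", "l", a_ref, a_alt, score))
        assert [sv.length for sv in svs] == [300]


def alignment(aligned_ref, aligned_alt):
    return PairwiseAlignment("locus", "alt", aligned_ref, aligned_alt, 0.0)


class TestExtractIndels:
    def test_gap_free_alignment_yields_nothing(self, rng):
        seq = random_seq(rng, 120)
        assert extract_indels(alignment(seq, seq)) == []

    def test_single_insertion_coordinates_follow_anchor_convention(self, rng):
        # 300-column gap in the reference after 999 reference bases
        ref_part = random_seq(rng, 1200)
        ins = random_seq(rng, 300)
        a_ref = ref_part[:999] + "-" * 300 + ref_part[999:]
        a_alt = ref_part[:999] + ins + ref_part[999:]
        (sv,) = extract_indels(alignment(a_ref, a_alt))
        assert (sv.sv_type, sv.length) == ("insertion", 300)
        assert (sv.ref_begin, sv.ref_end) == (1000, 999)
        assert sv.sv_seq == ins

    def test_gap_below_50_bp_is_dropped(self, rng):
        seq = random_seq(rng, 300)
        a_ref = seq[:100] + "-" * 49 + seq[100:]
        a_alt = seq[:100] + random_seq(rng, 49) + seq[100:]
        assert extract_indels(alignment(a_ref, a_alt)) == []

    def test_nearby_gap_runs_merge_into_one_event(self, rng):
        seq = random_seq(rng, 400)
        spacer = random_seq(rng, 5)
        a_ref = seq[:200] + "-" * 60 + spacer + "-" * 60 + seq[200:]
        a_alt = seq[:200] + random_seq(rng, 60) + spacer + random_seq(rng, 60) + seq[200:]
        (sv,) = extract_indels(alignment(a_ref, a_alt), merge_within=10)
        assert sv.length == 120
        # the two 60s separated by more than merge_within stay distinct and
        # are then individually below any 100 bp threshold
        far = random_seq(rng, 15)
        b_ref = seq[:200] + "-" * 60 + far + "-" * 60 + seq[200:]
        b_alt = seq[:200] + random_seq(rng, 60) + far + random_seq(rng, 60) + seq[200:]
        svs = extract_indels(alignment(b_ref, b_alt), merge_within=10)
        assert [s.length for s in svs] == [60, 60]

    def test_deletion_coordinates_are_inclusive_span(self, rng):
        seq = random_seq(rng, 300)
        a_ref = seq
        a_alt = seq[:100] + "-" * 60 + seq[160:]
        (sv,) = extract_indels(alignment(a_ref, a_alt))
        assert (sv.sv_type, sv.ref_begin, sv.ref_end) == ("deletion", 101, 160)
        assert sv.sv_seq == seq[100:160]


class TestUnifySvs:
    def make_sv(self, begin, length, sv_type="insertion", locus="L1"):
        end = begin - 1 if sv_type == "insertion" else begin + length - 1
        return StructuralVariant(
            locus=locus, ref_begin=begin, ref_end=end, sv_type=sv_type,
            length=length, sv_seq="A" * length,
        )

    def test_shared_insertion_across_assemblies_is_one_site(self):
        per_assembly = {f"asm{i}": [self.make_sv(1000, 281)] for i in range(8)}
        per_assembly.update({f"empty{i}": [] for i in range(4)})
        (site,) = unify_svs(per_assembly, reference="ref")
        filled = [a for a, s in site.presence.items() if s == "filled"]
        empty = [a for a, s in site.presence.items() if s == "empty"]
        assert len(filled) == 8 and len(empty) == 5  # 4 silent + reference

    def test_distant_anchors_stay_separate(self):
        per_assembly = {"a": [self.make_sv(100, 100)], "b": [self.make_sv(150, 100)]}
        sites = unify_svs(per_assembly, anchor_tol=20)
        assert len(sites) == 2

    def test_dissimilar_lengths_stay_separate(self):
        per_assembly = {"a": [self.make_sv(100, 100)], "b": [self.make_sv(105, 60)]}
        assert len(unify_svs(per_assembly, anchor_tol=20, len_sim=0.8)) == 2

    def test_mixed_loci_rejected(self):
        per_assembly = {
            "a": [self.make_sv(100, 100, locus="L1")],
            "b": [self.make_sv(100, 100, locus="L2")],
        }
        with pytest.raises(ValueError, match="mixes loci"):
            unify_svs(per_assembly)

    def test_assembly_missing_from_map_is_not_called(self):
        per_assembly = {"a": [self.make_sv(100, 100)]}
        (site,) = unify_svs(per_assembly)
        assert "b" not in site.presence


class TestPanelRecovery:
    def test_planted_panel_recovered_exactly(self, default_panel):
        config, records, truth = default_panel
        sites = discover_panel(records, reference="Sscrofa11.1")
        for locus, ins in truth.insertions.items():
            assert len(sites[locus]) == 1, locus
            (site,) = sites[locus]
            assert site.sv_type == "insertion"
            assert abs(site.length - ins.length) <= ins.tsd_length
            assert abs(site.ref_begin - (ins.insert_after + 1)) <= ins.tsd_length
            filled = {a for a, s in site.presence.items() if s == "filled"}
            assert filled == set(ins.filled_in)

    def test_zero_divergence_coordinates_round_trip(self, library):
        from ripscan.synthetic_data import LocusSpec, SimulationConfig, TraitModel, simulate_locus_panel

        config = SimulationConfig(
            seed=9,
            loci=(LocusSpec("L1", 1200, "SINEA", 300, divergence=0.0, tsd_length=0),),
            breeds=(),
            trait_model=TraitModel(baselines={}, noise_sd={}),
            assemblies=("ref", "alt"),
            filled_assemblies={"L1": ("alt",)},
        )
        records, truth = simulate_locus_panel(config, library)
        sites = discover_panel(records, reference="ref")
        (site,) = sites["L1"]
        assert site.sv_seq == truth.insertions["L1"].te_copy
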