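import numpy as np
import pytest

from fpbarcodes.io import Read, ReadSet
from fpbarcodes.nanopore import (
    LibraryProfile,
    PairCountMatrix,
    _best_reference,
    _PrescreenIndex,
    assign_read,
    assign_reads,
    completeness_check,
    filter_reads,
    orient_read,
    pair_count_matrix,
    score_alignment,
)
from fpbarcodes.synthetic import (
    ReadSimConfig,
    build_construct_references,
    make_fp_sequences,
    make_homolog,
    make_linker,
    make_promoter,
    reverse_complement,
    simulate_reads,
)

FPS = ["FPa", "FPb", "FPc", "FPd"]


@pytest.fixture(scope="module")
def toy_library():
    fp_seqs = make_fp_sequences(FPS, length=720, seed=3)
    cmv, linker = make_promoter(seed=4), make_linker(seed=5)
    refs = build_construct_references(fp_seqs, cmv=cmv, linker=linker)
    return fp_seqs, cmv, linker, refs


class TestFiltering:
    def test_length_windows_by_mode(self):
        assert LibraryProfile("single_fp").length_window == (1200, 1800)
        assert LibraryProfile("known_barcode").length_window == (2000, 2800)
        assert LibraryProfile("pooled_barcode").length_window == (2000, 3000)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            LibraryProfile("exome")

    def test_length_and_qc_rules(self):
        reads = ReadSet(
            [
                Read("in_window", "A" * 1500),
                Read("too_long", "A" * 1900),
                Read("qc_fail", "A" * 1500, qc_pass=False),
            ]
        )
        kept = filter_reads(reads, LibraryProfile("single_fp"))
        assert [r.id for r in kept] == ["in_window"]


class TestOrientation:
    def test_forward_read_kept_verbatim(self, toy_library):
        _, cmv, _, refs = toy_library
        read = next(iter(refs.values()))
        seq, orientation = orient_read(read, cmv)
        assert (seq, orientation) == (read, "forward")

    def test_reverse_read_restored(self, toy_library):
        _, cmv, _, refs = toy_library
        read = next(iter(refs.values()))
        seq, orientation = orient_read(reverse_complement(read), cmv)
        assert (seq, orientation) == (read, "reverse")

    def test_strand_symmetry(self, toy_library):
        _, cmv, _, refs = toy_library
        read = list(refs.values())[5]
        assert orient_read(read, cmv)[0] == orient_read(reverse_complement(read), cmv)[0]

    def test_random_sequence_rejected(self, toy_library):
        _, cmv, _, _ = toy_library
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 2000))
        assert orient_read(junk, cmv) is None

    def test_affine_identity_agrees_on_clear_cases(self, toy_library):
        _, cmv, _, refs = toy_library
        read = next(iter(refs.values()))
        assert orient_read(read, cmv, method="affine")[1] == "forward"


class TestScoring:
    def test_exact_read_scores_one(self, toy_library):
        *_, refs = toy_library
        ref = refs["FPa-FPb"]
        assert score_alignment(ref, ref) == 1.0
        assert score_alignment(ref, ref, method="affine") == 1.0

    def test_exact_containment_scores_one(self, toy_library):
        *_, refs = toy_library
        ref = refs["FPa-FPb"]
        read = "TTTT" + ref + "GGGG"
        assert score_alignment(read, ref) == 1.0
        assert score_alignment(read, ref, method="affine") == 1.0

    def test_substitution_ranks_below_exact_above_unrelated(self, toy_library):
        *_, refs = toy_library
        ref = refs["FPa-FPb"]
        mutated = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        for method in ("edit", "affine"):
            s_mut = score_alignment(mutated, ref, method=method)
            s_other = score_alignment(mutated, refs["FPc-FPd"], method=method)
            assert s_other < s_mut < 1.0

    def test_unrelated_sequence_floors_at_zero(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(rng.choice(list("ACGT"), 500))
        assert score_alignment(a, b, method="affine") >= 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_alignment("", "ACGT")


class TestAssignment:
    def test_exact_match_dominates_all_references(self, toy_library):
        *_, refs = toy_library
        a = assign_read(refs["FPc-FPa"], refs)
        assert a.label == "FPc-FPa" and a.normalized_score == 1.0

    def test_score_floor_gives_unassigned(self, toy_library):
        *_, refs = toy_library
        rng = np.random.default_rng(2)
        junk = "".join(rng.choice(list("ACGT"), 2100))
        assert assign_read(junk, refs).label == "unassigned"

    def test_floor_zero_always_assigns(self, toy_library):
        *_, refs = toy_library
        rng = np.random.default_rng(2)
        junk = "".join(rng.choice(list("ACGT"), 2100))
        assert assign_read(junk, refs, min_score=0.0).label != "unassigned"

    def test_prescreen_scan_matches_brute_force(self, toy_library):
        *_, refs = toy_library
        labels, seqs = list(refs), list(refs.values())
        screen = _PrescreenIndex(seqs)
        cfg = ReadSimConfig(n_reads=30, reverse_prob=0.0, fail_qc_prob=0.0, seed=9)
        reads = simulate_reads(refs, None, cfg)
        import edlib

        for r in reads:
            fast_i, fast_d = _best_reference(r.sequence, seqs, screen)
            dists = [
                edlib.align(s, r.sequence, mode="HW")["editDistance"] for s in seqs
            ]
            brute_i = int(np.argmin(dists))
            assert (fast_i, fast_d) == (brute_i, dists[brute_i])

    def test_noisy_reads_recover_source(self, toy_library):
        _, cmv, _, refs = toy_library
        cfg = ReadSimConfig(n_reads=64, seed=10)  # 5% sub + 2% indel defaults
        reads = simulate_reads(refs, None, cfg)
        out = assign_reads(reads, refs, cmv, LibraryProfile("pooled_barcode"))
        assigned = out[out["status"] == "assigned"]
        assert len(assigned) > 0
        assert (assigned["label"] == assigned["truth_label"]).mean() >= 0.95

    def test_homologous_references_still_separable(self):
        # position-2 FPs share >=80% identity, the stress case for assignment
        base = make_fp_sequences(["FPx"], length=720, seed=6)["FPx"]
        fp_seqs = {
            "FPx": base,
            "FPy": make_homolog(base, identity=0.85, seed=7),
        }
        cmv, linker = make_promoter(seed=4), make_linker(seed=5)
        refs = build_construct_references(fp_seqs, cmv=cmv, linker=linker)
        cfg = ReadSimConfig(n_reads=40, seed=11)
        reads = simulate_reads(refs, None, cfg)
        out = assign_reads(reads, refs, cmv, LibraryProfile("pooled_barcode"))
        assigned = out[out["status"] == "assigned"]
        assert (assigned["label"] == assigned["truth_label"]).mean() >= 0.95


class TestPairCounts:
    def test_single_construct_concentrates_everything(self, toy_library):
        _, cmv, _, refs = toy_library
        cfg = ReadSimConfig(
            n_reads=12, sub_rate=0, ins_rate=0, del_rate=0, fail_qc_prob=0, seed=1
        )
        reads = simulate_reads({"FPb-FPd": refs["FPb-FPd"]}, None, cfg)
        out = assign_reads(reads, refs, cmv, LibraryProfile("pooled_barcode"))
        m = pair_count_matrix(out, FPS)
        pct = m.percentages()
        assert pct.loc["FPb", "FPd"] == 100.0
        assert pct.to_numpy().sum() == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, toy_library):
        _, cmv, _, refs = toy_library
        cfg = ReadSimConfig(n_reads=48, seed=3)
        reads = simulate_reads(refs, None, cfg)
        out = assign_reads(reads, refs, cmv, LibraryProfile("pooled_barcode"))
        pct = pair_count_matrix(out, FPS).percentages()
        assert pct.to_numpy().sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_assigned_rejected(self):
        m = PairCountMatrix(counts=pair_count_matrix([], FPS).counts)
        with pytest.raises(ValueError, match="no assigned"):
            m.percentages()

    def test_catalog_aware_pair_splitting(self):
        # FP names containing the separator must still split correctly
        from fpbarcodes.nanopore import _split_pair

        fps = ["mT-Sapphire", "EGFP"]
        assert _split_pair("mT-Sapphire-EGFP", fps, "-") == ("mT-Sapphire", "EGFP")
        assert _split_pair("EGFP-mT-Sapphire", fps, "-") == ("EGFP", "mT-Sapphire")


class TestCompleteness:
    def _matrix(self, missing=()):
        import pandas as pd

        counts = pd.DataFrame(5, index=FPS, columns=FPS)
        for f1, f2 in missing:
            counts.loc[f1, f2] = 0
        return PairCountMatrix(counts=counts)

    def test_full_pool_flags_nothing(self):
        report = completeness_check(self._matrix())
        assert report["missing_ordered"] == []
        assert report["missing_combinations"] == []

    def test_one_missing_ordering_flags_pair_not_combination(self):
        report = completeness_check(self._matrix(missing=[("FPa", "FPc")]))
        assert report["missing_ordered"] == [("FPa", "FPc")]
        assert report["missing_combinations"] == []

    def test_both_orderings_missing_flags_combination(self):
        report = completeness_check(
            self._matrix(missing=[("FPa", "FPc"), ("FPc", "FPa")])
        )
        assert set(report["missing_ordered"]) == {("FPa", "FPc"), ("FPc", "FPa")}
        assert report["missing_combinations"] == [("FPa", "FPc")]
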