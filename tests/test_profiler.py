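"""Profiler: mapping vs exhaustive oracle, classification, tallies, logos."""

import math

import numpy as np
import pytest

import isomirkit as ik
from isomirkit.profiling import MapParams, reconstruct
from isomirkit import build_reference_set


# --- independent exhaustive oracle -----------------------------------------
def oracle_map(read, refset, params=MapParams()):
    """Enumerate every (precursor, start, split) and apply the documented
    score and tie-break; returns the winning tuple or None.

    Written independently of the implementation: no shared code beyond
    the parameter object.
    """
    candidates = []
    for pid in refset.precursors:
        prec = refset.precursors[pid].sequence
        for start in range(len(prec) + 1):
            for split in range(len(read) + 1):
                if split < params.min_templated:
                    continue
                if len(read) - split > params.max_nta:
                    continue
                if start + split > len(prec):
                    continue
                mm = sum(
                    1 for j in range(split) if read[j] != prec[start + j]
                )
                if mm > params.max_mismatches:
                    continue
                score = split - 2 * mm
                candidates.append(
                    (-score, len(read) - split, mm, pid, start, split)
                )
    if not candidates:
        return None
    return min(candidates)


def random_reads(refset, n, rng, min_len=16, max_len=28):
    """Reads drawn from precursor substrings with occasional tails and
    substitutions, plus some pure-random reads."""
    pids = sorted(refset.precursors)
    out = []
    bases = "ACGU"
    for _ in range(n):
        if rng.random() < 0.15:
            length = rng.integers(min_len, max_len + 1)
            out.append("".join(rng.choice(list(bases), size=length)))
            continue
        pid = pids[rng.integers(len(pids))]
        prec = refset.precursors[pid].sequence
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, max(1, len(prec) - length + 1)))
        read = list(prec[start:start + length])
        if rng.random() < 0.4:  # tail
            read += list(rng.choice(list(bases), size=rng.integers(1, 4)))
        if rng.random() < 0.4:  # substitution
            pos = int(rng.integers(len(read)))
            read[pos] = bases[(bases.index(read[pos]) + 1) % 4]
        out.append("".join(read))
    return out


@pytest.fixture
def two_precursor_refset():
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGU"))
    seqs = ["".join(rng.choice(bases, size=60)) for _ in range(2)]
    return build_reference_set([("prec-a", seqs[0]), ("prec-b", seqs[1])])


class TestMapRead:
    def test_exact_substring(self, toy_refset):
        prec = toy_refset.precursors["toy-mir-1"].sequence
        read = prec[10:32]
        aln = ik.map_read(read, toy_refset)
        assert (aln.start, aln.end) == (10, 32)
        assert aln.mismatch_positions == () and aln.nta == ""
        assert aln.score == 22

    def test_untemplated_uridine_called_as_nta(self, toy_refset):
        # base after position 32 is C, so the trailing U is untemplated
        prec = toy_refset.precursors["toy-mir-1"].sequence
        assert prec[32] != "U"
        aln = ik.map_read(prec[10:32] + "U", toy_refset)
        assert (aln.start, aln.end) == (10, 32)
        assert aln.nta == "U" and aln.mismatch_positions == ()

    def test_nta_preferred_over_terminal_mismatch(self, toy_refset):
        # with mismatch budget available, scoring must still favour the
        # NTA split (score L vs L+1-2)
        prec = toy_refset.precursors["toy-mir-1"].sequence
        aln = ik.map_read(prec[10:32] + "U", toy_refset, MapParams(max_mismatches=1))
        assert aln.nta == "U" and len(aln.mismatch_positions) == 0

    def test_unmappable_read_returns_none(self, toy_refset):
        assert ik.map_read("ACGU" * 5, toy_refset) is None

    def test_too_long_tail_rejected(self, toy_refset):
        prec = toy_refset.precursors["toy-mir-1"].sequence
        read = prec[10:32] + "UUUU"  # 4 > max_nta=3 untemplated bases
        aln = ik.map_read(read, toy_refset)
        # cannot place the full tail as NTA; only mappable if a split
        # within budget exists — here the tail region mismatches
        assert aln is None or len(read) - aln.templated_length <= 3

    def test_agrees_with_exhaustive_oracle(self, two_precursor_refset):
        rng = np.random.default_rng(7)
        reads = random_reads(two_precursor_refset, 50, rng)
        for read in reads:
            expected = oracle_map(read, two_precursor_refset)
            aln = ik.map_read(read, two_precursor_refset)
            if expected is None:
                assert aln is None
            else:
                neg_score, n_nta, n_mm, pid, start, split = expected
                assert aln is not None
                assert (aln.precursor_id, aln.start, aln.end) == (pid, start, start + split)
                assert aln.score == -neg_score
                assert len(aln.mismatch_positions) == n_mm

    def test_reconstruction_rule(self, two_precursor_refset):
        rng = np.random.default_rng(8)
        for read in random_reads(two_precursor_refset, 30, rng):
            aln = ik.map_read(read, two_precursor_refset)
            if aln is not None:
                assert reconstruct(aln, two_precursor_refset) == read

    def test_ambiguous_flag_on_identical_precursor_regions(self):
        shared = "UGAGGUAGUAGGUUGUAUAGUU"
        refset = build_reference_set([
            ("prec-a", "GGGAAACCCA" + shared + "CCGAUCGAUCAAACCCAAGG"),
            ("prec-b", "AAACCCGGGA" + shared + "GGCAUGCAUGCCAAAGGGCC"),
        ])
        aln = ik.map_read(shared, refset)
        assert aln.ambiguous
        assert aln.precursor_id == "prec-a"  # lexicographic tie-break


class TestClassify:
    def test_canonical_read(self, toy_refset):
        read = toy_refset.matures["toy-miR-1-5p"].sequence
        call = ik.classify_isomir(ik.map_read(read, toy_refset), toy_refset)
        assert (call.offset5, call.offset3, call.nta) == (0, 0, "")
        assert call.arm == "5p"

    def test_shifted_read(self, toy_refset):
        var = ik.shift_mature(toy_refset, "toy-miR-1-5p", +1, +1)
        call = ik.classify_isomir(ik.map_read(var.sequence, toy_refset), toy_refset)
        assert (call.mature_id, call.offset5, call.offset3) == ("toy-miR-1-5p", 1, 1)

    def test_three_prime_truncation(self, toy_refset):
        read = toy_refset.matures["toy-miR-1-5p"].sequence[:-4]
        call = ik.classify_isomir(ik.map_read(read, toy_refset), toy_refset)
        assert (call.offset5, call.offset3) == (0, -4)


class TestProfile:
    def test_counts_and_rpm_arithmetic(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        m3 = toy_refset.matures["toy-miR-1-3p"].sequence
        reads = [("r1", m5), ("r2", m5), ("r3", m3), ("r4", m3)]
        prof = ik.profile(reads, toy_refset)
        assert prof.class_counts[("toy-miR-1-5p", 0, 0, "")] == 2
        assert prof.class_counts[("toy-miR-1-3p", 0, 0, "")] == 2
        assert prof.rpm(("toy-miR-1-5p", 0, 0, "")) == 500000.0

    def test_rpm_sums_to_one_million(self, toy_refset):
        cfg = ik.SimulationConfig(counts={"toy-mir-1": 500}, seed=3)
        reads, _ = ik.simulate_library(toy_refset, cfg)
        prof = ik.profile(reads, toy_refset)
        total_rpm = sum(prof.rpm(k) for k in prof.class_counts)
        assert math.isclose(total_rpm, 1e6, abs_tol=1e-6)

    def test_unmapped_tallied_separately(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        reads = [(f"r{i}", m5) for i in range(9)] + [("junk", "ACGU" * 5)]
        prof = ik.profile(reads, toy_refset)
        assert prof.total_mapped_reads == 9
        assert prof.unmapped_reads == 1

    def test_short_reads_dropped(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([("r1", m5), ("tiny", "ACGUACGU")], toy_refset)
        assert prof.dropped_short_reads == 1

    def test_empty_input_errors(self, toy_refset):
        with pytest.raises(ValueError):
            ik.profile([], toy_refset)

    def test_recovery_equals_truth_summary(self, toy_refset):
        cfg = ik.SimulationConfig(
            counts={"toy-miR-1-5p": 300, "toy-miR-1-3p": 100},
            distribution=ik.IsomiRDistribution(
                offset5_probs={0: 0.8, 1: 0.2},
                offset3_probs={0: 0.6, -1: 0.2, -4: 0.2},
                nta_probs={"": 0.7, "U": 0.3},
                substitution_rate=0.0,
            ),
            seed=11,
        )
        reads, manifest = ik.simulate_library(toy_refset, cfg)
        prof = ik.profile(reads, toy_refset)
        truth = ik.truth_summary(manifest)
        assert prof.class_counts == truth.class_counts
        assert prof.total_mapped_reads == truth.total_mapped_reads

    def test_substituted_read_deviation_bounded(self, toy_refset):
        cfg = ik.SimulationConfig(
            counts={"toy-miR-1-5p": 400},
            distribution=ik.IsomiRDistribution(
                offset5_probs={0: 1.0}, offset3_probs={0: 1.0},
                nta_probs={"": 1.0}, substitution_rate=0.01,
            ),
            seed=13,
        )
        reads, manifest = ik.simulate_library(toy_refset, cfg)
        prof = ik.profile(reads, toy_refset)
        truth = ik.truth_summary(manifest)
        n_substituted = int((manifest.frame["sub_positions"] != "").sum())
        deviation = sum(
            abs(prof.class_counts.get(k, 0) - truth.class_counts.get(k, 0))
            for k in set(prof.class_counts) | set(truth.class_counts)
        )
        assert deviation <= 2 * n_substituted  # each bad read miscounts twice


class TestArmFraction:
    def test_known_mixture(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        m3 = toy_refset.matures["toy-miR-1-3p"].sequence
        reads = [(f"a{i}", m5) for i in range(76)] + [(f"b{i}", m3) for i in range(24)]
        prof = ik.profile(reads, toy_refset)
        assert ik.arm_fraction(prof, "toy-mir-1") == pytest.approx(0.76)

    def test_all_5p(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([("r", m5)], toy_refset)
        assert ik.arm_fraction(prof, "toy-mir-1") == 1.0

    def test_no_reads_missing(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([("r", m5)], toy_refset)
        assert ik.arm_fraction(prof, "absent-precursor") is None


class TestFoldChange:
    def test_transfection_scale_ratio(self, toy_refset):
        # RPM 8300 vs RPM 10 -> 830-fold, the scale seen when a mimic
        # transfection is compared with control
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        m3 = toy_refset.matures["toy-miR-1-3p"].sequence
        lib_a = [(f"a{i}", m5) for i in range(83)] + [(f"x{i}", m3) for i in range(17)]
        lib_b = [("b0", m5)] + [(f"y{i}", m3) for i in range(999)]
        fc = ik.fold_change(
            ik.profile(lib_a, toy_refset), ik.profile(lib_b, toy_refset),
            "toy-miR-1-5p",
        )
        assert fc.rpm_ratio == pytest.approx(830.0)
        assert not fc.infinite

    def test_identity(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([("r", m5)], toy_refset)
        assert ik.fold_change(prof, prof, "toy-miR-1-5p").rpm_ratio == 1.0

    def test_zero_denominator_flagged_infinite(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        m3 = toy_refset.matures["toy-miR-1-3p"].sequence
        prof_a = ik.profile([("r", m5)], toy_refset)
        prof_b = ik.profile([("r", m3)], toy_refset)
        fc = ik.fold_change(prof_a, prof_b, "toy-miR-1-5p")
        assert fc.infinite and math.isinf(fc.rpm_ratio)


class TestLogoMatrix:
    def test_identical_reads_give_point_mass_columns(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([(f"r{i}", m5) for i in range(5)], toy_refset)
        logo = ik.logo_matrix(prof, toy_refset, "toy-miR-1-5p")
        support = logo.support
        assert np.all(np.isin(logo.matrix[support > 0].max(axis=1), [1.0]))

    def test_single_position_mixture(self, toy_refset):
        ann = toy_refset.matures["toy-miR-1-5p"]
        seq = ann.sequence
        alt = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        prof = ik.profile([("r1", seq), ("r2", alt)], toy_refset)
        logo = ik.logo_matrix(prof, toy_refset, "toy-miR-1-5p")
        col = logo.matrix[ann.start + 10 - logo.window_start]
        assert sorted(col[col > 0]) == [0.5, 0.5]

    def test_columns_sum_to_one_where_supported(self, toy_refset):
        cfg = ik.SimulationConfig(
            counts={"toy-miR-1-5p": 200},
            distribution=ik.IsomiRDistribution(
                offset5_probs={0: 0.5, 1: 0.5}, nta_probs={"": 0.7, "U": 0.3},
            ),
            seed=5,
        )
        reads, _ = ik.simulate_library(toy_refset, cfg)
        prof = ik.profile(reads, toy_refset)
        logo = ik.logo_matrix(prof, toy_refset, "toy-miR-1-5p")
        sums = logo.matrix.sum(axis=1)
        assert np.allclose(sums[logo.support > 0], 1.0, atol=1e-9)

    def test_shifted_population_depletes_annotated_start(self, toy_refset):
        p_shift, n = 0.95, 1000
        cfg = ik.SimulationConfig(
            counts={"toy-miR-1-5p": n},
            distribution=ik.IsomiRDistribution(
                offset5_probs={0: 1 - p_shift, 1: p_shift},
            ),
            seed=21,
        )
        reads, _ = ik.simulate_library(toy_refset, cfg)
        prof = ik.profile(reads, toy_refset)
        ann = toy_refset.matures["toy-miR-1-5p"]
        logo = ik.logo_matrix(prof, toy_refset, "toy-miR-1-5p")
        col = ann.start - logo.window_start
        support = logo.support[col]
        first_base = "ACGU".index(ann.sequence[0])
        observed = logo.matrix[col, first_base]
        expected = (1 - p_shift)
        se = math.sqrt(p_shift * (1 - p_shift) / n)
        assert support == pytest.approx((1 - p_shift) * n, abs=3 * se * n)
        assert observed == pytest.approx(1.0, abs=1e-9)  # only canonical reads cover it

    def test_no_reads_errors(self, toy_refset):
        m5 = toy_refset.matures["toy-miR-1-5p"].sequence
        prof = ik.profile([("r", m5)], toy_refset)
        with pytest.raises(ValueError):
            ik.logo_matrix(prof, toy_refset, "toy-miR-1-3p")
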