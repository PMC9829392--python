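"""Probe-set construction, constrained oligo generation, the five-step
complementarity-chain validator, and the mismatch-signal predictor."""
import numpy as np
import pytest

from padlockrca.probe_design import (
    ARM_LEN,
    BACKBONE_LEN,
    DETECTION_LEN,
    LNA_POSITIONS,
    PADLOCK_LEN,
    DesignConstraints,
    DesignError,
    DetectionOligo,
    MiRNALNAProbe,
    SignalClass,
    design_mirna_lna_probe,
    design_mrna_assay,
    design_padlock,
    generate_unique_oligo,
    lna_plus_notation,
    order_sheet_entries,
    predict_mismatch_signal,
    simulate_rca_product,
    validate_probe_set,
    write_order_sheet,
)
from padlockrca.seq_core import (
    Alphabet,
    KmerIndex,
    MiRNARecord,
    NucSeq,
    canonical_kmer,
    count_index_hits,
    gc_content,
    reverse_complement,
)
from padlockrca.thermo import hairpin_stem

MIR20 = MiRNARecord("mir20", NucSeq("UGACAGAAGAGAGUGAGCAC", Alphabet.RNA))
EMPTY = KmerIndex.empty(15)


def full_set(mirna=MIR20, seed=0):
    probe = design_mirna_lna_probe(mirna, EMPTY, seed=seed)
    rng = np.random.default_rng(seed + 1)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
    det_site = generate_unique_oligo(DETECTION_LEN, EMPTY, seed=s1)
    backbone = generate_unique_oligo(BACKBONE_LEN, EMPTY, seed=s2)
    padlock = design_padlock(probe.linker, det_site, backbone)
    det = DetectionOligo("det", padlock.detection_site)
    return probe, padlock, det


class TestMiRNAProbe:
    def test_20nt_target_gives_50mer(self):
        probe = design_mirna_lna_probe(MIR20, EMPTY, seed=3)
        assert len(probe.full_sequence) == 50
        assert probe.hybridization_region == reverse_complement(
            MIR20.sequence, to_dna=True
        )
        assert probe.lna_positions == frozenset({2, 4, 6, 8, 10})
        assert len(probe.linker) == 30

    def test_hybridization_region_tracks_mirna_length(self):
        mir21 = MiRNARecord("mir21", NucSeq("UGACAGAAGAGAGUGAGCACA", Alphabet.RNA))
        probe = design_mirna_lna_probe(mir21, EMPTY, seed=3)
        assert len(probe.full_sequence) == 51
        assert len(probe.hybridization_region) == 21

    def test_deterministic_for_seed(self):
        a = design_mirna_lna_probe(MIR20, EMPTY, seed=9)
        b = design_mirna_lna_probe(MIR20, EMPTY, seed=9)
        assert a == b
        c = design_mirna_lna_probe(MIR20, EMPTY, seed=10)
        assert a.linker != c.linker

    def test_length_invariant_enforced(self):
        with pytest.raises(DesignError):
            MiRNALNAProbe("bad", NucSeq("ACGT" * 10), target_length=20)


class TestGenerateUniqueOligo:
    def test_outputs_revalidate_under_constraint_oracles(self):
        c = DesignConstraints()
        for seed in range(200):
            s = generate_unique_oligo(30, EMPTY, seed=seed)
            assert 0.50 <= gc_content(s) <= 0.60
            for base in "ACGT":
                assert 6 <= s.residues.count(base) <= 9
            assert max(
                len(run) for run in
                __import__("re").findall(r"(?:A+|C+|G+|T+)", s.residues)
            ) <= c.run_max
            assert hairpin_stem(s, c.min_loop) <= c.stem_max

    def test_screened_against_index(self, toy_transcriptome):
        _, index = toy_transcriptome
        s = generate_unique_oligo(30, index, seed=5)
        assert count_index_hits(s, index) == 0

    def test_unsatisfiable_uniqueness_reports_failures(self):
        # an index holding every canonical 8-mer defeats any uniqueness screen
        all8 = frozenset(
            canonical_kmer("".join(p))
            for p in __import__("itertools").product("ACGT", repeat=8)
        )
        saturated = KmerIndex(k=8, kmers=all8)
        tight = DesignConstraints(max_attempts=50)
        with pytest.raises(DesignError, match="index_hits"):
            generate_unique_oligo(30, saturated, tight, seed=0)


class TestPadlock:
    def test_layout_and_junction(self):
        probe, padlock, det = full_set()
        assert len(padlock.full_sequence) == PADLOCK_LEN == 80
        assert len(padlock.arm5) == len(padlock.arm3) == ARM_LEN == 15
        assert len(padlock.detection_site) == DETECTION_LEN == 20
        assert len(padlock.backbone) == BACKBONE_LEN == 30
        assert padlock.full_sequence.residues == (
            padlock.arm5.residues + padlock.detection_site.residues
            + padlock.backbone.residues + padlock.arm3.residues
        )
        junction = padlock.arm3.residues + padlock.arm5.residues
        assert junction == reverse_complement(probe.linker).residues

    def test_validator_passes_designed_set_with_zero_gap(self):
        probe, padlock, det = full_set()
        report = validate_probe_set(MIR20, probe, padlock, det)
        assert report.passed
        assert report.step(3).positions == ()

    def test_template_mutation_at_nick_fails_step_three(self):
        probe, padlock, det = full_set()
        linker = list(probe.linker.residues)
        # flip template position 15 (the base the arm5 5'-phosphate pairs)
        linker[14] = {"A": "C", "C": "A", "G": "T", "T": "G"}[linker[14]]
        mutated = MiRNALNAProbe(
            probe.id,
            NucSeq(probe.hybridization_region.residues + "".join(linker)),
            target_length=probe.target_length,
        )
        report = validate_probe_set(MIR20, mutated, padlock, det)
        assert not report.step(3).passed
        assert 15 in report.step(3).positions

    def test_bad_segment_lengths_rejected(self):
        with pytest.raises(DesignError):
            design_padlock(NucSeq("ACGT" * 7), NucSeq("A" * 20), NucSeq("ACGT" * 8))


class TestValidatorSensitivity:
    def test_arm_center_substitution_fails_annealing(self):
        probe, padlock, det = full_set()
        seq = list(padlock.full_sequence.residues)
        seq[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[7]]  # arm5 center
        from padlockrca.probe_design import PadlockProbe

        mutated = PadlockProbe(padlock.id, NucSeq("".join(seq)))
        report = validate_probe_set(MIR20, probe, mutated, det)
        assert not report.step(2).passed

    def test_detection_oligo_reverse_complement_fails_readout(self):
        probe, padlock, det = full_set()
        flipped = DetectionOligo("det_rc", reverse_complement(det.sequence))
        report = validate_probe_set(MIR20, probe, padlock, flipped)
        assert not report.step(5).passed

    def test_rca_product_is_tandem_complement(self):
        _, padlock, _ = full_set()
        product = simulate_rca_product(padlock, n_repeats=4)
        assert len(product) == 4 * 80
        unit = product.residues[:80]
        assert reverse_complement(NucSeq(unit)).residues == (
            padlock.full_sequence.residues
        )
        assert product.residues == unit * 4


class TestMismatchPredictor:
    @pytest.mark.parametrize(
        "pos,cls",
        [
            (0, SignalClass.REFERENCE),
            (3, SignalClass.HIGH),
            (5, SignalClass.MODERATE),
            (9, SignalClass.LOW),
            (11, SignalClass.NONE),
            (19, SignalClass.NONE),
            (1, SignalClass.UNTESTED),
            (20, SignalClass.UNTESTED),
        ],
    )
    def test_signal_classes(self, pos, cls):
        assert predict_mismatch_signal(pos).signal_class is cls

    def test_score_profile(self):
        scores = [predict_mismatch_signal(p).score for p in range(2, 20)]
        lna_region = scores[9:]  # target positions 11..19
        assert all(s == 0.0 for s in lna_region)
        graded = scores[:9]  # positions 2..10
        assert all(a > b for a, b in zip(graded, graded[1:]))
        assert graded[0] == pytest.approx(0.9)
        assert graded[-1] == pytest.approx(0.1)
        assert predict_mismatch_signal(0).score == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            predict_mismatch_signal(21)
        with pytest.raises(ValueError):
            predict_mismatch_signal(-1)


class TestMRNAAssay:
    def test_design_on_toy_transcriptome(self, toy_transcriptome):
        transcripts, _ = toy_transcriptome
        from padlockrca.seq_core import build_kmer_index

        target_id, target = transcripts[0]
        loo = build_kmer_index(transcripts[1:], k=15)
        assay = design_mrna_assay(target, loo, seed=4, transcript_id=target_id)
        # cDNA sense: arms read across the junction give the transcript window
        junction = assay.padlock.arm3.residues + assay.padlock.arm5.residues
        w0, w1 = assay.cdna_window
        assert junction == target.residues[w0 - 1 : w1]
        assert target.residues.find(junction) == w0 - 1
        # window is unique in the leave-one-out index
        assert count_index_hits(NucSeq(junction), loo) == 0
        # window reachable by reverse transcription from the primer
        assert assay.cdna_window[1] < assay.primer_site[0]
        assert assay.lna_primer == reverse_complement(
            NucSeq(target.residues[assay.primer_site[0] - 1 : assay.primer_site[1]])
        )

    def test_short_transcript_rejected(self):
        with pytest.raises(DesignError, match="shorter than minimum"):
            design_mrna_assay(NucSeq("ACGT" * 10), EMPTY)


class TestOrderSheet:
    def test_write_parse_and_determinism(self, tmp_path):
        probe, padlock, det = full_set(seed=2)
        entries = order_sheet_entries(probe=probe, padlock=padlock, det=det)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_order_sheet(entries, p1, index=EMPTY)
        write_order_sheet(entries, p2, index=EMPTY)
        assert p1.read_bytes() == p2.read_bytes()
        import pandas as pd

        df = pd.read_csv(p1, sep="\t", comment="#")
        assert list(df["type"]) == ["mirna_lna_probe", "padlock", "detection"]
        assert np.allclose(df["hyb_temp_c"], df["tm_c"] - 10)
        assert df.loc[df["type"] == "padlock", "phosphorylated"].item() == "yes"

    def test_lna_plus_notation(self):
        s = NucSeq("GTGCTC")
        assert lna_plus_notation(s, {2, 4}) == "G+TG+CTC"
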