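"""Sequence toolkit: strand ops, synonymy, QFP scanning, masses."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from Bio.SeqUtils import molecular_weight

from quadstall import seqkit
from quadstall.seqkit import (NucleicSeq, check_synonymy,
                              extinction_coefficient,
                              find_synonymous_frame, peptide_mass,
                              reverse_complement, scan_qfp,
                              scan_qfp_bruteforce, translate)

rna_seq = st.text(alphabet="ACGU", min_size=1, max_size=20)


def _rna(s, id="t"):
    return NucleicSeq(id=id, residues=s, alphabet="RNA")


class TestNucleicSeq:
    def test_rejects_empty_and_mixed_alphabets(self):
        with pytest.raises(ValueError):
            NucleicSeq(id="x", residues="", alphabet="RNA")
        with pytest.raises(ValueError, match="position 2"):
            NucleicSeq(id="x", residues="ACTU", alphabet="RNA")
        with pytest.raises(ValueError, match="mixes T and U"):
            NucleicSeq.from_string("ACTU")

    def test_alphabet_inference(self):
        assert NucleicSeq.from_string("ACGT").alphabet == "DNA"
        assert NucleicSeq.from_string("ACGU").alphabet == "RNA"
        assert NucleicSeq.from_string("ACG").alphabet == "RNA"


class TestReverseComplement:
    def test_palindrome(self):
        seq = NucleicSeq.from_string("ACGT")
        assert reverse_complement(seq).residues == "ACGT"

    @given(rna_seq)
    def test_involution(self, s):
        seq = _rna(s)
        assert reverse_complement(reverse_complement(seq)).residues == s

    def test_wildtype_primer_yields_grich_sense_window(self):
        primers = seqkit.load_qfp_primers()
        sense = reverse_complement(primers["wild-type"])
        assert sense.alphabet == "DNA"
        assert "GGGGAGGGCAGGGGTGAAGTGGGG" in sense.residues


class TestTranslate:
    def test_canonical_code(self):
        assert translate(_rna("AUGUUU")) == "MF"

    def test_stop_rendered_as_star_and_partial_dropped(self):
        assert translate(_rna("UAAGG")) == "*"

    @given(st.text(alphabet="ACGU", min_size=3, max_size=30),
           st.integers(0, 2))
    def test_length_rule(self, s, frame):
        if len(s) - frame < 3:
            return
        assert len(translate(_rna(s), frame)) == (len(s) - frame) // 3

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            translate(_rna("AUGUUU"), frame=3)
        with pytest.raises(ValueError, match="fewer than one codon"):
            translate(_rna("AUG"), frame=1)


class TestSynonymy:
    def test_self_synonymy(self):
        ref = _rna("AUGUUUGGG")
        (rep,) = check_synonymy(ref, [ref])
        assert rep.n_codons_changed == 0 and rep.is_synonymous

    def test_fourfold_degenerate_glycine(self):
        (rep,) = check_synonymy(_rna("GGG"), [_rna("GGA")])
        assert rep.n_codons_changed == 1 and rep.is_synonymous

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            check_synonymy(_rna("AUGUUU"), [_rna("AUG")])

    def test_all_printed_variants_synonymous(self, sense_windows):
        """Every mutant QFP window encodes the wild-type peptide."""
        ref = sense_windows["wild-type"]
        variants = [sense_windows[n] for n in seqkit.VARIANTS
                    if n != "wild-type"]
        frame = find_synonymous_frame(ref, variants)
        reports = check_synonymy(ref, variants, frame)
        assert all(r.is_synonymous for r in reports)
        assert all(r.n_codons_changed > 0 for r in reports)

    def test_window_peptide_matches_receptor_hinge(self, sense_windows):
        """The QFP-encoded peptide occurs in the receptor hinge region."""
        ref = sense_windows["wild-type"]
        frame = find_synonymous_frame(
            ref, [sense_windows["A-mutant"]])
        peptide = translate(ref, frame)
        assert "DGEGRGEVGS" in peptide
        protein = seqkit.load_hERalpha()
        assert "DGEGRGEVGS" in protein
        # the quadruplex codons start right after residue 273
        assert protein.index("GEGRGEVG") == 273


class TestScanQfp:
    def test_single_tract_is_no_hit(self):
        assert scan_qfp(_rna("GGGG"), min_tract=3) == []

    def test_wildtype_window_has_four_tract_hit(self, sense_windows):
        hits = scan_qfp(sense_windows["wild-type"], min_tract=3)
        assert len(hits) == 1
        (hit,) = hits
        assert len(hit.tracts) == 4
        assert all(length >= 3 for _, length in hit.tracts)
        assert all(1 <= l <= 7 for l in hit.loop_lengths)

    def test_a_mutant_window_has_no_hit(self, sense_windows):
        assert scan_qfp(sense_windows["A-mutant"], min_tract=3) == []

    def test_min_tract_validation(self):
        with pytest.raises(ValueError):
            scan_qfp(_rna("GGGG"), min_tract=1)

    @given(rna_seq, st.integers(2, 3), st.integers(1, 3))
    def test_equivalence_with_bruteforce_enumerator(self, s, min_tract,
                                                    loop_max):
        seq = _rna(s)
        assert scan_qfp(seq, min_tract, 1, loop_max) == \
            scan_qfp_bruteforce(seq, min_tract, 1, loop_max)

    def test_equivalence_exhaustive_on_purine_sequences(self):
        """Every G-run/loop structure up to length 10 is enumerated
        exactly by restricting to the {A, G} alphabet."""
        import itertools
        for n in range(1, 11):
            for combo in itertools.product("AG", repeat=n):
                seq = _rna("".join(combo))
                assert scan_qfp(seq, 2, 1, 2) == \
                    scan_qfp_bruteforce(seq, 2, 1, 2)

    @given(rna_seq)
    def test_reported_tracts_are_true_g_runs(self, s):
        seq = _rna(s)
        for hit in scan_qfp(seq, min_tract=2):
            for start, length in hit.tracts:
                assert set(s[start:start + length]) == {"G"}
                assert length >= hit.min_tract


class TestExtinctionCoefficient:
    def test_single_base(self):
        assert extinction_coefficient(_rna("A")) == \
            seqkit.EPSILON_MONO_RNA["A"]

    def test_dinucleotide_base_case(self):
        assert extinction_coefficient(_rna("AA")) == \
            2 * seqkit.EPSILON_NN_RNA["AA"]

    def test_agrees_with_positionwise_oracle(self, sense_windows):
        """Independent spreadsheet-style evaluation of the same table."""
        rng = np.random.default_rng(2013)
        seqs = ["".join(rng.choice(list("ACGU"), size=n))
                for n in rng.integers(2, 60, size=100)]
        seqs.append(sense_windows["wild-type"].residues)
        for s in seqs:
            cells = []
            for i in range(len(s)):  # one row per position, spreadsheet style
                if i < len(s) - 1:
                    cells.append(2 * seqkit.EPSILON_NN_RNA[s[i] + s[i + 1]])
                if 0 < i < len(s) - 1:
                    cells.append(-seqkit.EPSILON_MONO_RNA[s[i]])
            assert extinction_coefficient(_rna(s)) == pytest.approx(
                sum(cells), abs=1e-9)


class TestPeptideMass:
    def test_free_glycine(self):
        assert peptide_mass("G").average_mass == pytest.approx(75.07,
                                                               abs=0.01)

    def test_empty_and_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")
        with pytest.raises(ValueError, match="unknown residue"):
            peptide_mass("GX")

    def test_protonation_adds_one_hydrogen(self):
        pm = peptide_mass("ACDEFGHIKLMNPQRSTVWY", protonated=True)
        assert pm.protonated_mass - pm.average_mass == pytest.approx(
            1.00794, abs=1e-6)

    def test_cross_check_against_biopython(self):
        """Dual route: residue-table sum vs Biopython's average weight."""
        protein = seqkit.load_hERalpha()
        for fragment in (protein[:50], protein[:251], protein):
            ours = peptide_mass(fragment).average_mass
            ref = molecular_weight(fragment, seq_type="protein",
                                   monoisotopic=False)
            # the two residue tables differ in their last printed digit
            assert ours == pytest.approx(ref, rel=1e-4)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.fasta"
        seqs = [NucleicSeq(id="a", residues="ACGU", alphabet="RNA"),
                NucleicSeq(id="b", residues="ACGT", alphabet="DNA")]
        seqkit.write_fasta(seqs, path)
        back = seqkit.read_fasta(path)
        assert [(s.id, s.residues, s.alphabet) for s in back] == \
            [(s.id, s.residues, s.alphabet) for s in seqs]

    def test_bundled_primers_load(self):
        primers = seqkit.load_qfp_primers()
        assert set(seqkit.VARIANTS) <= set(primers)
        assert all(len(primers[n]) == 69 for n in seqkit.VARIANTS)
        assert len(primers["first-template"]) == 49
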