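import random

import numpy as np
import pytest

from bovig.germline import (
    GermlineDatabase,
    GermlineSegment,
    collapse_identical_v,
    expand_d_orientations,
    fr4_template,
    load_germline_fasta,
    number_functional_v,
    prepare_database,
    transfer_numbering_to_pseudogene,
)
from bovig.numbering import cattle_scheme
from bovig.simdata import _random_functional_v


SCHEME = cattle_scheme()


def make_v(seed: int) -> str:
    return _random_functional_v(np.random.default_rng(seed), SCHEME)


def v_segment(seq: str, seg_id: str = "IGHV1", functionality: str = "functional"):
    return GermlineSegment(id=seg_id, segment_class="V",
                           functionality=functionality, sequence=seq)


class TestLoadFasta:
    def test_parses_records_with_functionality(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text(
            ">IGHV1|V|functional\nACGTACGT\n"
            ">IGHV2|V|pseudogene\nACGTACGA\n"
            ">IGHV3|V|ORF\nACGTACGC\n"
        )
        db = load_germline_fasta(fasta, "V")
        assert len(db.by_class("V")) == 3
        assert db.segments["IGHV2"].functionality == "pseudogene"

    def test_wobble_codes_preserved(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text(">IGHV1|V|functional\nACGRTACGT\n")
        db = load_germline_fasta(fasta, "V")
        assert "R" in db.segments["IGHV1"].sequence

    def test_non_iub_record_rejected_by_name(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text(">IGHV9|V|functional\nACXGT\n")
        with pytest.raises(ValueError, match="IGHV9"):
            load_germline_fasta(fasta, "V")

    def test_duplicate_id_rejected(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text(">IGHV1|V|functional\nACGT\n>IGHV1|V|functional\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_germline_fasta(fasta, "V")

    def test_empty_file_rejected(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text("")
        with pytest.raises(ValueError):
            load_germline_fasta(fasta, "V")

    def test_metadata_sidecar(self, tmp_path):
        fasta = tmp_path / "v.fasta"
        fasta.write_text(">IGHV1\nACGT\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text("id\tfunctionality\tchromosome\tgenomic_start\n"
                        "IGHV1\tpseudogene\tBTA21\t1000\n")
        db = load_germline_fasta(fasta, "V", metadata=meta)
        seg = db.segments["IGHV1"]
        assert seg.functionality == "pseudogene"
        assert (seg.chromosome, seg.genomic_start) == ("BTA21", 1000)


class TestNumberFunctionalV:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_round_trip_against_generator(self, seed):
        seq = make_v(seed)
        nmap = number_functional_v(v_segment(seq), SCHEME)
        positions = SCHEME.v_positions()
        assert sorted(nmap.codon_positions) == positions
        for k, p in enumerate(positions):
            assert nmap.codon_positions[p] == (3 * k, 3 * k + 1, 3 * k + 2)
        assert set(nmap.anchor_positions) == {23, 41, 89, 104}

    def test_mutated_anchor_fails_naming_position(self):
        seq = make_v(0)
        idx = SCHEME.v_positions().index(41)
        broken = seq[: 3 * idx] + "CGG" + seq[3 * idx + 3 :]  # Trp41 -> Arg
        with pytest.raises(ValueError, match="41"):
            number_functional_v(v_segment(broken), SCHEME)

    def test_truncated_v_leaves_tail_unassigned(self):
        seq = make_v(1)
        idx = SCHEME.v_positions().index(104)
        truncated = seq[: 3 * idx]  # ends right before Cys104
        nmap = number_functional_v(v_segment(truncated), SCHEME)
        assert 104 not in nmap.codon_positions
        assert 23 in nmap.codon_positions

    def test_fr1_spans_25_codons(self):
        # one FR1H position (10) is unoccupied in cattle
        nmap = number_functional_v(v_segment(make_v(2)), SCHEME)
        fr1 = [p for p in nmap.codon_positions if p <= 26]
        assert len(fr1) == 25


class TestTransferNumbering:
    def _profiles(self, *seqs):
        out = {}
        for i, seq in enumerate(seqs, 1):
            seg = v_segment(seq, f"IGHV{i}")
            out[seg.id] = (seg, number_functional_v(seg, SCHEME))
        return out

    def test_substituted_pseudogene_keeps_parent_map(self):
        parent = make_v(3)
        rng = random.Random(7)
        seq = list(parent)
        for i in rng.sample(range(len(seq)), 5):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        pseudo = v_segment("".join(seq), "IGHV9P", "pseudogene")
        nmap = transfer_numbering_to_pseudogene(pseudo, self._profiles(parent, make_v(4)))
        parent_map = number_functional_v(v_segment(parent), SCHEME)
        assert nmap.codon_positions == parent_map.codon_positions

    def test_insertion_discarded_downstream_unchanged(self):
        parent = make_v(5)
        positions = SCHEME.v_positions()
        idx = positions.index(29)  # inside CDR1H
        mutated = parent[: 3 * idx] + "AAA" + parent[3 * idx :]
        pseudo = v_segment(mutated, "IGHV9P", "pseudogene")
        nmap = transfer_numbering_to_pseudogene(pseudo, self._profiles(parent))
        # downstream codons shifted by the 3-nt insertion, labels unchanged
        for p in positions[idx + 1 :]:
            base = 3 * positions.index(p)
            assert nmap.codon_positions[p] == (base + 3, base + 4, base + 5)

    def test_internal_stop_does_not_block(self):
        parent = make_v(6)
        idx = SCHEME.v_positions().index(70)
        seq = parent[: 3 * idx] + "TAA" + parent[3 * idx + 3 :]
        pseudo = v_segment(seq, "IGHV9P", "pseudogene")
        nmap = transfer_numbering_to_pseudogene(pseudo, self._profiles(parent))
        assert 70 in nmap.codon_positions

    def test_transfer_is_idempotent_on_self(self):
        parent = make_v(8)
        profiles = self._profiles(parent)
        seg = v_segment(parent, "IGHV9P", "pseudogene")
        nmap = transfer_numbering_to_pseudogene(seg, profiles)
        assert nmap.codon_positions == profiles["IGHV1"][1].codon_positions

    def test_no_profiles_is_an_error(self):
        with pytest.raises(ValueError):
            transfer_numbering_to_pseudogene(
                v_segment(make_v(0), "P", "pseudogene"), {}
            )


class TestCollapseIdenticalV:
    def _db(self, seqs_by_id):
        db = GermlineDatabase(SCHEME)
        for sid, seq in seqs_by_id.items():
            seg = v_segment(seq, sid)
            db.add(seg)
            db.numbering[sid] = number_functional_v(seg, SCHEME)
        return db

    def test_identical_pair_merges_with_combined_name(self):
        seq = make_v(10)
        db = collapse_identical_v(self._db({"IGHV1": seq, "IGHV2": seq}))
        assert list(db.identity_groups) == ["IGHV1/IGHV2"]
        assert db.identity_groups["IGHV1/IGHV2"] == ["IGHV1", "IGHV2"]

    def test_distinct_segments_unchanged(self):
        db = collapse_identical_v(self._db({"IGHV1": make_v(10), "IGHV2": make_v(11)}))
        assert sorted(db.identity_groups) == ["IGHV1", "IGHV2"]

    def test_three_way_identity_single_group(self):
        seq = make_v(12)
        db = collapse_identical_v(
            self._db({"IGHV1": seq, "IGHV2": seq, "IGHV3": seq})
        )
        assert list(db.identity_groups) == ["IGHV1/IGHV2/IGHV3"]

    def test_order_independent(self):
        seq_a, seq_b = make_v(13), make_v(14)
        db1 = collapse_identical_v(
            self._db({"IGHV1": seq_a, "IGHV2": seq_b, "IGHV3": seq_a})
        )
        db2 = collapse_identical_v(
            self._db({"IGHV3": seq_a, "IGHV1": seq_a, "IGHV2": seq_b})
        )
        assert sorted(db1.identity_groups) == sorted(db2.identity_groups)


class TestFr4Template:
    def test_suffix_of_long_j(self):
        j = GermlineSegment(id="IGHJ1", segment_class="J", sequence="A" * 27 + "C" * 33)
        assert fr4_template(j) == "C" * 33

    def test_exact_33_returns_whole(self):
        j = GermlineSegment(id="IGHJ1", segment_class="J", sequence="ACG" * 11)
        assert fr4_template(j) == "ACG" * 11

    def test_short_j_rejected(self):
        j = GermlineSegment(id="IGHJ1", segment_class="J", sequence="A" * 32)
        with pytest.raises(ValueError):
            fr4_template(j)


class TestExpandDOrientations:
    def _db(self, seqs):
        db = GermlineDatabase(SCHEME)
        for i, seq in enumerate(seqs, 1):
            db.add(GermlineSegment(id=f"IGHD{i}", segment_class="D", sequence=seq))
        return db

    def test_reverse_complement_variant(self):
        db = expand_d_orientations(self._db(["GGTACA"]))
        seg = db.segments["IGHD1_as"]
        assert seg.sequence == "TGTACC"
        assert seg.orientation == "antisense"

    def test_count_doubles(self):
        db = expand_d_orientations(self._db(["ACGTAGCA", "TTGACC", "GGGCAT"]))
        assert len(db.by_class("D")) == 6

    def test_palindrome_still_gets_distinct_variant(self):
        db = expand_d_orientations(self._db(["ACGT"]))
        assert db.segments["IGHD1_as"].sequence == "ACGT"
        assert db.segments["IGHD1_as"].orientation == "antisense"

    def test_ambiguity_codes_complemented(self):
        db = expand_d_orientations(self._db(["AMG"]))
        assert db.segments["IGHD1_as"].sequence == "CKT"


class TestDatabasePersistence:
    def test_save_load_round_trip(self, toy_db, tmp_path):
        toy_db.save(tmp_path / "db")
        again = GermlineDatabase.load(tmp_path / "db")
        assert set(again.segments) == set(toy_db.segments)
        assert again.identity_groups == toy_db.identity_groups
        assert again.fr4_templates == toy_db.fr4_templates
        for sid, nmap in toy_db.numbering.items():
            assert again.numbering[sid].codon_positions == nmap.codon_positions
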