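"""Local alignment, bit scores, annotation transfer and the final OR."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from atpres.io_formats import ChainRecord, STANDARD_AA
from atpres import template_transfer as tt
from oracles import smith_waterman_affine

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def random_chain(rng, length, chain_id="q", labels=False):
    seq = "".join(STANDARD_AA[i] for i in rng.integers(0, 20, length))
    lab = rng.integers(0, 2, length).astype(np.int8) if labels else None
    return ChainRecord(chain_id, seq, lab)


class TestAlignerAgainstDP:
    def test_scores_match_bruteforce_gotoh(self):
        """Raw local-alignment scores equal an independent dynamic program
        on 50 random pairs of short sequences."""
        rng = np.random.default_rng(42)
        db = tt.TemplateDB([ChainRecord("t", "GKT", np.zeros(3, np.int8))])
        aligner = tt._make_aligner(db)
        for _ in range(50):
            a = random_chain(rng, int(rng.integers(8, 31))).sequence
            b = random_chain(rng, int(rng.integers(8, 31))).sequence
            got = aligner.align(a, b).score
            want = smith_waterman_affine(a, b, BLOSUM62, tt.GAP_OPEN,
                                         tt.GAP_EXTEND)
            assert got == pytest.approx(want)

    def test_bit_score_strictly_increasing(self):
        raw = np.linspace(0, 500, 40)
        bits = [tt.bit_score(s) for s in raw]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))


class TestSearchTemplates:
    def test_identical_chain_is_full_diagonal_top_hit(self):
        rng = np.random.default_rng(0)
        target = random_chain(rng, 120, "tmpl", labels=True)
        decoy = random_chain(rng, 100, "decoy", labels=True)
        db = tt.TemplateDB([decoy, target])
        query = ChainRecord("query", target.sequence)
        hits = tt.search_templates(query, db)
        assert hits and hits[0].template_id == "tmpl"
        assert hits[0].aligned_pairs == [(i, i) for i in range(120)]

    def test_random_query_finds_nothing(self):
        """Unrelated 60-mers never reach 50 bits against a small db."""
        rng = np.random.default_rng(7)
        db = tt.TemplateDB(
            [random_chain(rng, 150, f"t{i}", labels=True) for i in range(4)]
        )
        for seed in range(5):
            q = random_chain(np.random.default_rng(1000 + seed), 60, "q")
            assert tt.search_templates(q, db, min_bit_score=50.0) == []

    def test_planted_substring_alignment_covers_it(self):
        rng = np.random.default_rng(3)
        motif = "GKSGSGKSTLLKAIMESSGG"  # 20 residues
        host = random_chain(rng, 140, "host", labels=True)
        seq = host.sequence[:60] + motif + host.sequence[80:]
        template = ChainRecord("host", seq, host.labels)
        db = tt.TemplateDB([template])
        query = ChainRecord("q", motif)
        hits = tt.search_templates(query, db, min_bit_score=20.0)
        assert hits
        assert hits[0].aligned_pairs == [(i, 60 + i) for i in range(20)]

    def test_empty_db_returns_empty(self, caplog):
        with caplog.at_level("WARNING", logger="atpres"):
            assert tt.search_templates(ChainRecord("q", "GKT"),
                                       tt.TemplateDB([])) == []

    def test_unlabeled_template_rejected(self):
        with pytest.raises(ValueError):
            tt.TemplateDB([ChainRecord("t", "GKT")])


class TestTransfer:
    def test_identity_transfer(self):
        rng = np.random.default_rng(1)
        template = random_chain(rng, 80, "t", labels=True)
        db = tt.TemplateDB([template])
        query = ChainRecord("q", template.sequence)
        hits = tt.search_templates(query, db)
        track = tt.transfer_annotations(hits, db, 80)
        np.testing.assert_array_equal(track, template.labels)

    def test_no_hits_all_zero(self):
        db = tt.TemplateDB([ChainRecord("t", "GKT",
                                        np.ones(3, np.int8))])
        assert not tt.transfer_annotations([], db, 10).any()

    def test_union_of_disjoint_hits(self):
        labels_a = np.array([1, 0, 0, 0, 0], dtype=np.int8)
        labels_b = np.array([0, 0, 0, 0, 1], dtype=np.int8)
        db = tt.TemplateDB([
            ChainRecord("a", "GKTAC", labels_a),
            ChainRecord("b", "GKTAC", labels_b),
            ChainRecord("c", "GKTAC", np.zeros(5, np.int8)),
        ])
        hits = [
            tt.TemplateHit("q", "a", 60.0, [(i, i) for i in range(5)]),
            tt.TemplateHit("q", "b", 55.0, [(i, i) for i in range(5)]),
        ]
        track = tt.transfer_annotations(hits, db, 5)
        np.testing.assert_array_equal(track, [1, 0, 0, 0, 1])

    def test_transfer_monotone_in_hits(self):
        """Adding a hit never removes a predicted binding position."""
        db = tt.TemplateDB([
            ChainRecord("a", "GKTAC", np.array([1, 1, 0, 0, 0], np.int8)),
            ChainRecord("b", "GKTAC", np.array([0, 0, 0, 1, 0], np.int8)),
        ])
        h1 = tt.TemplateHit("q", "a", 60.0, [(i, i) for i in range(5)])
        h2 = tt.TemplateHit("q", "b", 55.0, [(i, i) for i in range(5)])
        t1 = tt.transfer_annotations([h1], db, 5)
        t12 = tt.transfer_annotations([h1, h2], db, 5)
        assert (t12 >= t1).all()


class TestCombineFinal:
    def test_zero_template_equals_thresholded_ensemble(self, rng):
        probs = rng.random(30)
        final = tt.combine_final(probs, 0.5, np.zeros(30, dtype=int))
        np.testing.assert_array_equal(final, probs > 0.5)

    def test_template_only_position(self):
        probs = np.full(10, 0.1)
        template = np.zeros(10, dtype=int)
        template[5] = 1
        final = tt.combine_final(probs, 0.5, template)
        assert final[5] == 1 and final.sum() == 1

    def test_or_monotonicity(self, rng):
        for _ in range(50):
            probs = rng.random(20)
            template = rng.integers(0, 2, 20)
            base = probs > 0.4
            final = tt.combine_final(probs, 0.4, template)
            assert (final >= base).all()
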