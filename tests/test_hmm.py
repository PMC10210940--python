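"""Profile-HMM construction, glocal scoring, search and refinement."""

import numpy as np
import pytest

from oracles import enumerate_glocal_scores
from stcmine.core import AMINO_ACIDS, ProteinRecord, UNCLASSIFIED
from stcmine.hmm import (
    HmmHit,
    ProfileHmm,
    assign_by_best_score,
    build_hmm,
    hmm_search,
    read_hmm,
    refine_generation2,
    score_sequence,
    write_hmm,
)
from stcmine.msa import Msa


def toy_model(p_a=0.9):
    """L=1 model: M1 emits A with p_a, C with the rest; B->M1->E certain."""
    em = np.zeros((1, 20))
    em[0, 0] = p_a
    em[0, 1] = 1.0 - p_a
    ins = np.full((2, 20), 0.05)
    tr = np.zeros((2, 7))
    tr[0] = [1, 0, 0, 1, 0, 1, 0]
    tr[1] = [1, 0, 0, 1, 0, 1, 0]
    return ProfileHmm(
        name="toy", clade=1, match_emissions=em, insert_emissions=ins, transitions=tr
    )


def random_model(rng, L):
    """A small random but valid model for oracle comparisons."""
    em = rng.dirichlet(np.full(20, 0.5), size=L)
    ins = rng.dirichlet(np.full(20, 0.5), size=L + 1)
    tr = np.zeros((L + 1, 7))
    for k in range(L + 1):
        m_edges = 2 if k == L else 3
        m = rng.dirichlet(np.ones(m_edges))
        tr[k, :m_edges] = m if m_edges == 3 else [m[0], m[1]]
        tr[k, 3:5] = rng.dirichlet(np.ones(2))
        if k == L:
            tr[k, 5] = 1.0
        else:
            tr[k, 5:7] = rng.dirichlet(np.ones(2))
    return ProfileHmm(
        name="rand", clade=1, match_emissions=em, insert_emissions=ins, transitions=tr
    )


class TestScoring:
    def test_single_state_closed_form(self):
        m = toy_model()
        assert score_sequence(m, "A") == pytest.approx(np.log2(0.9 / 0.05))
        assert score_sequence(m, "C", mode="viterbi") == pytest.approx(
            np.log2(0.1 / 0.05)
        )

    def test_unknown_residue_scores_zero_bits(self):
        m = toy_model()
        assert score_sequence(m, "X") == pytest.approx(0.0)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = random_model(rng, int(rng.integers(1, 5)))
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, rng.integers(1, 8)))
            v = score_sequence(m, seq, mode="viterbi")
            f = score_sequence(m, seq, mode="forward")
            assert f >= v - 1e-9

    def test_scores_match_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            m = random_model(rng, int(rng.integers(1, 6)))
            seq = "".join(
                AMINO_ACIDS[i] for i in rng.integers(0, 20, rng.integers(1, 9))
            )
            ref_v, ref_f = enumerate_glocal_scores(m, seq)
            assert score_sequence(m, seq, "viterbi") == pytest.approx(ref_v, abs=1e-9)
            assert score_sequence(m, seq, "forward") == pytest.approx(ref_f, abs=1e-9)

    def test_background_flanks_change_score_little(self):
        from stcmine.simulate import make_clade_model, sample_family

        model = make_clade_model(1, 328, 12.0, seed=51)
        seq = sample_family(model, 1, 1.0, seed=52)[0]
        rng = np.random.default_rng(53)
        flank = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 200))
        base = score_sequence(model, seq.sequence)
        padded = score_sequence(model, flank + seq.sequence + flank)
        assert padded >= base - 1e-9  # extra entry points can only help
        assert abs(padded - base) < 0.5

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            score_sequence(toy_model(), "A", mode="posterior")


class TestBuild:
    def test_emission_estimator_arithmetic(self):
        msa = Msa(ids=list("abcd"), rows=["A", "A", "A", "C"])
        m = build_hmm(msa, "m", 1)
        assert m.L == 1
        assert m.match_emissions[0, 0] == pytest.approx(4 / 24)  # (3+1)/(4+20)
        assert m.match_emissions[0, 1] == pytest.approx(2 / 24)  # (1+1)/24

    def test_majority_gap_column_becomes_insert_region(self):
        msa = Msa(ids=list("abcd"), rows=["AC", "A-", "A-", "A-"])
        m = build_hmm(msa, "m", 1)
        assert m.L == 1  # second column (3/4 gaps) is not a match state

    def test_all_emission_rows_normalized(self, small_dataset):
        from stcmine.msa import progressive_align, trim_msa

        seqs = small_dataset.proteome[:6]
        m = build_hmm(trim_msa(progressive_align(seqs)), "m", 2)
        assert np.allclose(m.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(m.insert_emissions.sum(axis=1), 1.0)

    def test_no_match_states_raises(self):
        msa = Msa(ids=list("abcd"), rows=["A", "-", "-", "-"])
        with pytest.raises(ValueError, match="no match states"):
            build_hmm(msa, "m", 1)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_hmm(Msa(ids=["a"], rows=["ACD"]), "m", 1)


class TestSerialization:
    def test_round_trip_reproduces_probabilities(self, tmp_path, small_dataset):
        from stcmine.msa import progressive_align, trim_msa

        m = build_hmm(trim_msa(progressive_align(small_dataset.proteome[:5])), "m", 3)
        path = tmp_path / "m.shmm"
        write_hmm(m, path)
        back = read_hmm(path)
        assert back.name == m.name and back.clade == m.clade and back.L == m.L
        np.testing.assert_allclose(back.match_emissions, m.match_emissions, rtol=1e-14)
        np.testing.assert_allclose(back.insert_emissions, m.insert_emissions, rtol=1e-14)
        np.testing.assert_allclose(back.transitions, m.transitions, rtol=1e-14, atol=1e-300)
        # serialization itself is byte-stable
        path2 = tmp_path / "m2.shmm"
        write_hmm(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_bad_emission_sum_rejected(self, tmp_path):
        m = toy_model()
        path = tmp_path / "m.shmm"
        write_hmm(m, path)
        lines = path.read_text().splitlines()
        idx = next(i for i, l in enumerate(lines) if l.startswith("match 1"))
        parts = lines[idx].split()
        parts[2] = "%.17g" % np.log(0.7)  # 0.9 -> 0.7: row sums to 0.8
        lines[idx] = " ".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="sums to"):
            read_hmm(path)

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "m.shmm"
        path.write_text("SHMM1\nname t\nclade 1\nL 1\nbogus\n")
        with pytest.raises(ValueError, match=":5"):
            read_hmm(path)

    def test_hand_written_single_state_model_scores_closed_form(self, tmp_path):
        m = toy_model()
        path = tmp_path / "toy.shmm"
        write_hmm(m, path)
        back = read_hmm(path)
        assert score_sequence(back, "A") == pytest.approx(np.log2(0.9 / 0.05))


class TestSearchAndAssign:
    def test_family_members_hit_their_model_and_shuffles_miss(self):
        from stcmine.simulate import make_clade_model, sample_family

        model = make_clade_model(2, 336, 12.0, seed=61)
        train = sample_family(model, 40, 1.0, seed=62)
        from stcmine.msa import progressive_align, trim_msa

        built = build_hmm(trim_msa(progressive_align(train)), "c2", 2)
        held = sample_family(model, 10, 1.0, seed=63)
        rng = np.random.default_rng(64)
        shuffled = []
        for i, r in enumerate(held):
            chars = list(r.sequence)
            rng.shuffle(chars)
            shuffled.append(ProteinRecord(id=f"shuf{i}", sequence="".join(chars)))
        hits = hmm_search([built], held + shuffled, threshold=25.0)
        hit_ids = {h.protein_id for h in hits}
        assert hit_ids == {r.id for r in held}

    def test_infinite_threshold_returns_no_hits(self):
        m = toy_model()
        recs = [ProteinRecord(id="a", sequence="A")]
        assert hmm_search([m], recs, threshold=float("inf")) == []

    def test_no_models_is_an_error(self):
        with pytest.raises(ValueError, match="at least one model"):
            hmm_search([], [ProteinRecord(id="a", sequence="A")])

    def test_best_score_wins(self):
        hits = [
            HmmHit("p1", "m1", 1, 40.0),
            HmmHit("p1", "m3", 3, 55.0),
            HmmHit("p2", "m2", 2, 31.0),
        ]
        calls = {c.protein_id: c for c in assign_by_best_score(hits)}
        assert calls["p1"].clade == 3 and calls["p1"].score == 55.0
        assert calls["p2"].clade == 2

    def test_exact_cross_clade_tie_is_unclassified(self, caplog):
        hits = [HmmHit("p1", "m1", 1, 33.0), HmmHit("p1", "m4", 4, 33.0)]
        with caplog.at_level("WARNING"):
            calls = assign_by_best_score(hits)
        assert calls[0].clade == UNCLASSIFIED
        assert "tie" in caplog.text


class TestRefinement:
    def test_top_k_per_division_rule(self):
        from stcmine.msa import progressive_align, trim_msa
        from stcmine.simulate import make_clade_model, sample_family

        model = make_clade_model(1, 328, 12.0, seed=71)
        fam = sample_family(model, 30, 1.0, seed=72)  # alternating divisions
        msa = trim_msa(progressive_align(fam[:10]))
        gen1 = build_hmm(msa, "gen1-c1", 1)
        proteins = {r.id: r for r in fam}
        hits = [
            HmmHit(r.id, "gen1-c1", 1, float(score_sequence(gen1, r)))
            for r in fam
        ]
        models = refine_generation2([gen1], hits, proteins, top_k=5)
        assert len(models) == 1
        assert models[0].name == "gen2-clade1"
        # 15 basidiomycete + 15 ascomycete available, 5 + 5 used: the
        # resulting model is trained and valid
        assert models[0].L > 100

    def test_zero_top_k_rejected(self):
        with pytest.raises(ValueError, match="top_k"):
            refine_generation2([], [], {}, top_k=0)

    def test_clade_without_hits_raises(self):
        m = toy_model()
        with pytest.raises(ValueError, match="clade 1"):
            refine_generation2([m], [], {}, top_k=5)
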