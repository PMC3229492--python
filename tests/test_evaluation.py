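import numpy as np
import pytest

from _oracles import quaternion_rmsd, random_rigid_transform
from conftest import toy_structure, transform_structure
from synaln.core_io import MultipleAlignment, PairwiseAlignment, Sequence
from synaln.errors import (
    ConsistencyError,
    ParameterError,
    UndefinedResultError,
)
from synaln.evaluation import (
    StructurePairLabel,
    alignment_rmsd,
    build_outlier_set,
    irmsd,
    kabsch_rmsd,
    msa_avg_rmsd,
    precision_recall,
    q_score,
    seq_identity,
)


class TestQScore:
    def test_perfect_agreement(self):
        aln = PairwiseAlignment("a", "b", "ACDE", "ACDE")
        assert q_score(aln, aln) == 100.0

    def test_no_shared_pairs(self):
        ref = PairwiseAlignment("a", "b", "ACDE", "ACDE")
        test = PairwiseAlignment("a", "b", "ACDE----", "----ACDE")
        assert q_score(test, ref) == 0.0

    def test_partial_recovery_ratio(self):
        seq_a = Sequence("a", "ACDEFGHIKL")
        seq_b = Sequence("b", "ACDEFGHIKL")
        ref = PairwiseAlignment.from_pairs(seq_a, seq_b, [(i, i) for i in range(10)])
        test = PairwiseAlignment.from_pairs(
            seq_a, seq_b, [(i, i) for i in range(4)] + [(i, i + 1) for i in range(5, 9)]
        )
        assert q_score(test, ref) == 40.0

    def test_msa_pools_projected_pairs(self):
        ref = MultipleAlignment(rows={"a": "AC", "b": "AC", "c": "AC"})
        test = MultipleAlignment(rows={"a": "AC-", "b": "AC-", "c": "-AC"})
        # ref pairs: 3 sequence pairs x 2 columns = 6; test reproduces only a-b
        assert q_score(test, ref) == pytest.approx(100.0 * 2 / 6)

    def test_disjoint_sequence_sets_rejected(self):
        a = PairwiseAlignment("a", "b", "AC", "AC")
        c = PairwiseAlignment("x", "y", "AC", "AC")
        with pytest.raises(ConsistencyError):
            q_score(a, c)

    def test_orientation_independent(self):
        seq_a = Sequence("a", "ACDE")
        seq_b = Sequence("b", "ACD")
        ref = PairwiseAlignment.from_pairs(seq_a, seq_b, [(0, 0), (2, 1)])
        # same test alignment written with the sequences swapped
        fwd = PairwiseAlignment("a", "b", "ACDE", "ACD-")
        flipped = PairwiseAlignment("b", "a", "ACD-", "ACDE")
        assert q_score(fwd, ref) == q_score(flipped, ref)


class TestSeqIdentity:
    def test_self_alignment(self):
        assert seq_identity(PairwiseAlignment("a", "b", "ACDE", "ACDE")) == 100.0

    def test_gap_columns_excluded(self):
        assert seq_identity(PairwiseAlignment("a", "b", "AC-E", "ACDE")) == 100.0

    def test_one_in_five(self):
        assert seq_identity(PairwiseAlignment("a", "b", "AAAAA", "AWYVK")) == 20.0

    def test_no_aligned_pairs_gives_zero(self):
        assert seq_identity(PairwiseAlignment("a", "b", "A-", "-C")) == 0.0


class TestKabschRmsd:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(5, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(6, 3)) * 5
        R, t = random_rigid_transform(rng)
        assert kabsch_rmsd(pts, pts @ R.T + t) == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for trial in range(50):
            n = int(rng.integers(1, 7))
            A = rng.normal(size=(n, 3)) * 4
            B = rng.normal(size=(n, 3)) * 4
            assert kabsch_rmsd(A, B) == pytest.approx(
                quaternion_rmsd(A, B), abs=1e-8
            )

    def test_symmetry_and_nonnegativity(self, rng):
        A = rng.normal(size=(5, 3))
        B = rng.normal(size=(5, 3))
        assert kabsch_rmsd(A, B) == pytest.approx(kabsch_rmsd(B, A), abs=1e-9)
        assert kabsch_rmsd(A, B) >= 0.0

    def test_reflection_not_allowed(self):
        # mirrored helix cannot be superposed by a proper rotation
        t = np.linspace(0, 4 * np.pi, 8)
        helix = np.stack([np.cos(t), np.sin(t), t / 3], axis=1)
        mirror = helix * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(helix, mirror) > 0.1

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def identity_alignment(n, ids=("a", "b")):
    res = "A" * n
    return PairwiseAlignment(ids[0], ids[1], res, res)


class TestAlignmentRmsd:
    def test_self_is_zero(self, rng):
        st = toy_structure("a", rng.normal(size=(5, 3)) * 8)
        r, n = alignment_rmsd(identity_alignment(5), st, st)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert n == 5

    def test_rigidly_moved_copy_is_zero(self, rng):
        st = toy_structure("a", rng.normal(size=(6, 3)) * 8)
        R, t = random_rigid_transform(rng)
        r, _ = alignment_rmsd(identity_alignment(6), st, transform_structure(st, R, t))
        assert r == pytest.approx(0.0, abs=1e-8)

    def test_incomplete_backbones_excluded(self, rng):
        st = toy_structure("a", rng.normal(size=(4, 3)))
        st2 = toy_structure("b", rng.normal(size=(4, 3)))
        st2.residues[1].O = None
        _, n = alignment_rmsd(identity_alignment(4), st, st2)
        assert n == 3

    def test_matches_direct_computation_on_toy(self):
        coords_a = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        coords_b = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 1.0, 0]])
        sa = toy_structure("a", coords_a)
        sb = toy_structure("b", coords_b)
        r, n = alignment_rmsd(identity_alignment(3), sa, sb)
        pa = np.array([getattr(res, at) for res in sa.residues for at in "N CA C O".split()])
        pb = np.array([getattr(res, at) for res in sb.residues for at in "N CA C O".split()])
        assert n == 3
        assert r == pytest.approx(quaternion_rmsd(pa, pb), abs=1e-8)

    def test_zero_usable_pairs_is_undefined(self, rng):
        st = toy_structure("a", rng.normal(size=(3, 3)))
        st2 = toy_structure("b", rng.normal(size=(3, 3)))
        for res in st2.residues:
            res.CA = None
        with pytest.raises(UndefinedResultError):
            alignment_rmsd(identity_alignment(3), st, st2)


class TestMsaAvgRmsd:
    def test_two_sequences_equals_pairwise(self, rng):
        sa = toy_structure("a", rng.normal(size=(4, 3)) * 5)
        sb = toy_structure("b", rng.normal(size=(4, 3)) * 5)
        msa = MultipleAlignment(rows={"a": "AAAA", "b": "AAAA"})
        mean, skipped = msa_avg_rmsd(msa, {"a": sa, "b": sb})
        direct, _ = alignment_rmsd(msa.project("a", "b"), sa, sb)
        assert mean == pytest.approx(direct)
        assert skipped == 0

    def test_identical_structures_zero(self, rng):
        st = toy_structure("x", rng.normal(size=(4, 3)))
        structures = {k: toy_structure(k, np.array([r.CA for r in st.residues]))
                      for k in ("a", "b", "c")}
        msa = MultipleAlignment(rows={k: "AAAA" for k in structures})
        mean, _ = msa_avg_rmsd(msa, structures)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_mean_of_three_pairwise_values(self, rng):
        structures = {
            k: toy_structure(k, rng.normal(size=(4, 3)) * 6) for k in ("a", "b", "c")
        }
        msa = MultipleAlignment(rows={k: "AAAA" for k in structures})
        mean, _ = msa_avg_rmsd(msa, structures)
        vals = []
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            r, _ = alignment_rmsd(msa.project(x, y), structures[x], structures[y])
            vals.append(r)
        assert mean == pytest.approx(np.mean(vals))


class TestIrmsd:
    def chain(self, rng, n=6):
        # compact fold so CA-CA distances fall inside the 10 A radius
        return toy_structure("a", rng.normal(size=(n, 3)) * 3)

    def test_identical_structures_zero(self, rng):
        st = self.chain(rng)
        assert irmsd(identity_alignment(6), st, st) == pytest.approx(0.0)

    def test_invariant_under_independent_rigid_transforms(self, rng):
        sa = self.chain(rng)
        sb = self.chain(rng)
        base = irmsd(identity_alignment(6), sa, sb)
        R1, t1 = random_rigid_transform(rng)
        R2, t2 = random_rigid_transform(rng)
        moved = irmsd(
            identity_alignment(6),
            transform_structure(sa, R1, t1),
            transform_structure(sb, R2, t2),
        )
        assert moved == pytest.approx(base, abs=1e-8)

    def test_matches_hand_computation_on_four_residues(self):
        ca_a = np.array([[0.0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0]])
        ca_b = np.array([[0.0, 0, 0], [3, 0, 0], [6, 1, 0], [9, 0, 0]])
        sa = toy_structure("a", ca_a)
        sb = toy_structure("b", ca_b)
        acc = []
        for p in range(4):
            for q in range(p + 1, 4):
                da = np.linalg.norm(ca_a[p] - ca_a[q])
                if da < 10.0:
                    db = np.linalg.norm(ca_b[p] - ca_b[q])
                    acc.append((da - db) ** 2)
        expect = np.sqrt(np.mean(acc))
        assert irmsd(identity_alignment(4), sa, sb) == pytest.approx(expect)

    def test_no_qualifying_pairs_is_undefined(self):
        far = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        sa = toy_structure("a", far)
        with pytest.raises(UndefinedResultError):
            irmsd(identity_alignment(2), sa, sa)


class TestPrecisionRecall:
    def test_textbook_counts(self):
        records = [(30.0, "PP")] * 4 + [(30.0, "PN")] + [(5.0, "PP")] * 4
        p, r = precision_recall(records, 20.0)
        assert p == pytest.approx(80.0)
        assert r == pytest.approx(50.0)

    def test_no_predictions_precision_undefined(self):
        p, r = precision_recall([(5.0, "PP"), (2.0, "PN")], 20.0)
        assert p is None
        assert r == 0.0

    def test_threshold_is_strict(self):
        p, r = precision_recall([(20.0, "PP")], 20.0)
        assert p is None and r == 0.0

    def test_recall_non_increasing_in_threshold(self, rng):
        records = [
            (float(rng.uniform(0, 40)), "PP" if rng.random() < 0.3 else "PN")
            for _ in range(50)
        ]
        recalls = [precision_recall(records, t)[1] for t in (5, 10, 15, 20, 30)]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_label_derivation_from_tm_score(self):
        assert StructurePairLabel("a", "b", 0.5).label == "PP"
        assert StructurePairLabel("a", "b", 0.49).label == "PN"
        with pytest.raises(ParameterError):
            StructurePairLabel("a", "b", 0.0)


class TestBuildOutlierSet:
    def test_pool_of_one(self):
        out = build_outlier_set(
            ["p1", "p2"], ["c"], {("p1", "c"): 10, ("p2", "c"): 20},
            {("p1", "c"): 0.4, ("p2", "c"): 0.6},
        )
        assert out == ["p1", "p2", "c", "c"]

    def test_identity_vs_tm_tradeoff(self):
        seqidy = {("p", "c1"): 40.0, ("p", "c2"): 10.0}
        tm = {("p", "c1"): 0.2, ("p", "c2"): 0.3}
        # 0.4 - 0.2 = 0.2 beats 0.1 - 0.3 = -0.2
        assert build_outlier_set(["p"], ["c1", "c2"], seqidy, tm) == ["p", "c1"]

    def test_matches_exhaustive_argmax(self, rng):
        members = [f"p{k}" for k in range(5)]
        pool = [f"c{k}" for k in range(15)]
        seqidy = {(p, c): float(rng.uniform(0, 60)) for p in members for c in pool}
        tm = {(p, c): float(rng.uniform(0.01, 0.99)) for p in members for c in pool}
        out = build_outlier_set(members, pool, seqidy, tm)
        for k, p in enumerate(members):
            best = max(
                sorted(pool),
                key=lambda c: (seqidy[(p, c)] / 100.0 - tm[(p, c)], [-ord(x) for x in c]),
            )
            # ties broken lexicographically: recompute explicitly
            diffs = {c: seqidy[(p, c)] / 100.0 - tm[(p, c)] for c in pool}
            mx = max(diffs.values())
            expect = min(c for c, d in diffs.items() if d == mx)
            assert out[len(members) + k] == expect

    def test_raw_difference_mode(self):
        seqidy = {("p", "c1"): 40.0, ("p", "c2"): 90.0}
        tm = {("p", "c1"): 0.01, ("p", "c2"): 0.99}
        out = build_outlier_set(["p"], ["c1", "c2"], seqidy, tm, rescale_identity=False)
        assert out == ["p", "c2"]  # 89.01 beats 39.99 on the raw scale
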