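"""Inter-rater reliability: alignment, Cohen's and Fleiss' kappa."""

import itertools

import numpy as np
import pytest

from camkit.model import CAMSet
from camkit.reliability import (
    AlignedCoding,
    RaterCoding,
    align_categories,
    category_members,
    cohen_kappa,
    cohen_kappa_from_labels,
    fleiss_kappa,
    fleiss_kappa_from_counts,
    reliability_report,
    sample_training_concepts,
    total_overlap,
)
from conftest import make_cam

ITEMS = [f"item{i}" for i in range(8)]


def coding(rater_id, labels):
    return RaterCoding(rater_id, dict(zip(ITEMS[: len(labels)], labels)))


class TestSampling:
    def _cams(self, n_texts=100):
        cams = [
            make_cam(f"c{i}", {f"n{i}": (f"text{i:03d}", 0)}, [])
            for i in range(n_texts)
        ]
        return CAMSet(cams=cams)

    def test_proportion_one_returns_everything(self):
        cams = self._cams(10)
        assert len(sample_training_concepts(cams, 1.0, seed=1)) == 10

    def test_ten_percent_of_hundred(self):
        assert len(sample_training_concepts(self._cams(100), 0.1, seed=3)) == 10

    def test_deterministic_given_seed(self):
        cams = self._cams(50)
        assert sample_training_concepts(cams, 0.3, 9) == sample_training_concepts(cams, 0.3, 9)
        assert sample_training_concepts(cams, 0.3, 9) != sample_training_concepts(cams, 0.3, 10)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_training_concepts(CAMSet(cams=[]), 0.5, 0)


class TestAlignment:
    def test_identical_partitions_different_names_align_perfectly(self):
        r1 = coding("r1", ["A", "A", "B", "B", "C", "C"])
        r2 = coding("r2", ["x", "x", "y", "y", "z", "z"])
        for mode in ("exact_overlap", "max_overlap"):
            aligned = align_categories([r1, r2], mode=mode)
            assert aligned.codes[0] == aligned.codes[1]
            assert cohen_kappa(aligned, (0, 1)) == pytest.approx(1.0)

    def test_single_shared_category(self):
        r1 = coding("r1", ["A"] * 4)
        r2 = coding("r2", ["z"] * 4)
        aligned = align_categories([r1, r2])
        assert aligned.codes[0] == aligned.codes[1]

    def test_item_mismatch_lists_difference(self):
        r1 = RaterCoding("r1", {"a": "A", "b": "A"})
        r2 = RaterCoding("r2", {"a": "A", "c": "A"})
        with pytest.raises(ValueError, match="'b', 'c'"):
            align_categories([r1, r2])

    def test_max_overlap_at_least_exact_overlap_exhaustive(self):
        """Optimal assignment dominates greedy on every <=3-category table."""
        labels = ["A", "B", "C"]
        for l1 in itertools.product(labels, repeat=5):
            for l2 in itertools.product(labels, repeat=5):
                r1, r2 = coding("r1", l1), coding("r2", l2)
                greedy = total_overlap(align_categories([r1, r2], "exact_overlap"))
                optimal = total_overlap(align_categories([r1, r2], "max_overlap"))
                assert optimal >= greedy
                # verify optimality against every injective category mapping
                cats1, cats2 = sorted(set(l1)), sorted(set(l2))
                best = 0
                if len(cats1) >= len(cats2):
                    injections = (
                        dict(zip(cats2, perm))
                        for perm in itertools.permutations(cats1, len(cats2))
                    )
                else:
                    injections = (
                        {c2: c1 for c1, c2 in zip(cats1, perm)}
                        for perm in itertools.permutations(cats2, len(cats1))
                    )
                for mapping in injections:
                    best = max(best, sum(mapping.get(b) == a for a, b in zip(l1, l2)))
                assert optimal == best


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa_from_labels([1, 2, 3, 1, 2], [1, 2, 3, 1, 2]) == 1.0

    def test_hand_worked_half_agreement(self):
        # p_o = 0.5, p_e = 0.5 -> kappa = 0
        assert cohen_kappa_from_labels(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_degenerate_single_category(self):
        assert cohen_kappa_from_labels(["A"] * 5, ["A"] * 5) == 1.0

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            r1 = rng.integers(0, 4, size=30).tolist()
            r2 = rng.integers(0, 4, size=30).tolist()
            k = cohen_kappa_from_labels(r1, r2)
            perm = rng.permutation(4)
            assert cohen_kappa_from_labels(
                [int(perm[x]) for x in r1], [int(perm[x]) for x in r2]
            ) == pytest.approx(k)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(25):
            r1 = rng.integers(0, 3, size=40)
            r2 = rng.integers(0, 3, size=40)
            if len(set(r1) | set(r2)) < 2:
                continue
            assert cohen_kappa_from_labels(r1.tolist(), r2.tolist()) == pytest.approx(
                cohen_kappa_score(r1, r2)
            )


class TestFleissKappa:
    def _aligned(self, codes):
        n_raters = len(codes)
        n_items = len(codes[0])
        return AlignedCoding(
            items=tuple(f"i{k}" for k in range(n_items)),
            rater_ids=tuple(f"r{k}" for k in range(n_raters)),
            codes=tuple(tuple(row) for row in codes),
            alignment_mode="identity",
        )

    def test_unanimous_agreement(self):
        aligned = self._aligned([[0, 1, 2, 0]] * 3)
        overall, per_cat = fleiss_kappa(aligned)
        assert overall == 1.0
        assert all(v == pytest.approx(1.0) for v in per_cat.values())

    def test_hand_built_table(self):
        # 3 raters, 4 items; n_ij table evaluated by the printed formulas
        codes = [[0, 0, 1, 2], [0, 1, 1, 2], [1, 0, 1, 0]]
        aligned = self._aligned(codes)
        counts = np.zeros((4, 3))
        for row in codes:
            for i, c in enumerate(row):
                counts[i, c] += 1
        n, N = 3, 4
        P_i = (np.square(counts).sum(axis=1) - n) / (n * (n - 1))
        p_j = counts.sum(axis=0) / (N * n)
        expected = (P_i.mean() - np.square(p_j).sum()) / (1 - np.square(p_j).sum())
        overall, _ = fleiss_kappa(aligned)
        assert overall == pytest.approx(expected)
        assert overall == pytest.approx(fleiss_kappa_from_counts(counts))

    def test_two_raters_reduce_to_cohen_with_equal_marginals(self):
        """With two raters and matching marginals Fleiss equals Cohen."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            r1 = rng.integers(0, 3, size=60).tolist()
            r2 = list(r1)
            rng.shuffle(r2)  # identical marginals, permuted assignments
            aligned = self._aligned([r1, r2])
            overall, _ = fleiss_kappa(aligned)
            assert overall == pytest.approx(
                cohen_kappa_from_labels(r1, r2), abs=1e-12
            )

    def test_single_rater_rejected(self):
        aligned = AlignedCoding(
            items=("i0", "i1"),
            rater_ids=("r0",),
            codes=((0, 1),),
            alignment_mode="identity",
        )
        with pytest.raises(ValueError, match="2 raters"):
            fleiss_kappa(aligned)


class TestReport:
    def test_identical_raters_all_ones(self):
        r1 = coding("r1", ["A", "A", "B", "B"])
        r2 = coding("r2", ["g1", "g1", "g2", "g2"])
        rep = reliability_report([r1, r2])
        assert np.allclose(rep["value"], 1.0)

    def test_row_count_structure(self):
        rng = np.random.default_rng(3)
        codings = [
            RaterCoding(
                f"r{k}",
                {f"i{j}": f"c{rng.integers(0, 3)}" for j in range(20)},
            )
            for k in range(3)
        ]
        rep = reliability_report(codings)
        n_cat = (rep["coefficient"] == "category_kappa").sum()
        assert len(rep) == 3 * 2 + 1 + n_cat  # C(3,2) pairs x 2 modes + Fleiss + cats

    def test_category_members_summary(self):
        r = coding("r1", ["A", "A", "B"])
        tab = category_members(r)
        assert list(tab["n_members"]) == [2, 1]


class TestNullCalibration:
    def test_independent_raters_mean_kappa_near_zero(self):
        """Under independent coding the expected kappa is 0 (shared labels)."""
        rng = np.random.default_rng(77)
        ks = []
        for _ in range(200):
            r1 = rng.integers(0, 4, size=200).tolist()
            r2 = rng.integers(0, 4, size=200).tolist()
            ks.append(cohen_kappa_from_labels(r1, r2))
        assert abs(float(np.mean(ks))) < 0.05
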