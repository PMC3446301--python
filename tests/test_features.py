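"""RC-collapsed k-mer features, motif scores, auROC, and the origin SVM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriseq import features as ft
from oriseq.features import (
    KMER_CLASS_COUNTS,
    N_KMER_FEATURES,
    PWM,
    auroc,
    build_feature_matrix,
    cross_apply,
    extract_loci,
    feature_auroc,
    kmer_class_names,
    kmer_features,
    motif_score,
    train_svm,
    train_svm_cv,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def brute_force_class_count(k: int) -> int:
    from itertools import product

    seen = set()
    for tup in product("ACGT", repeat=k):
        s = "".join(tup)
        seen.add(min(s, revcomp(s)))
    return len(seen)


dna = st.text(alphabet="ACGT", min_size=6, max_size=60)


class TestKmerAlphabet:
    def test_class_counts_match_brute_force_enumeration(self):
        for k in range(1, 7):
            assert KMER_CLASS_COUNTS[k] == brute_force_class_count(k)
        assert N_KMER_FEATURES == 2772

    def test_class_counts_match_closed_form(self):
        for k in range(1, 7):
            expected = 4**k // 2 if k % 2 else (4**k + 4 ** (k // 2)) // 2
            assert KMER_CLASS_COUNTS[k] == expected

    def test_names_are_canonical_and_ordered(self):
        names = kmer_class_names()
        assert len(names) == N_KMER_FEATURES
        assert all(n <= revcomp(n) for n in names)
        by_k: dict[int, list[str]] = {}
        for n in names:
            by_k.setdefault(len(n), []).append(n)
        for k, block in by_k.items():
            assert block == sorted(block)


class TestKmerFeatures:
    def test_polyA_sequence_hits_only_polyA_classes(self):
        vec = kmer_features("AAAAAA")
        names = kmer_class_names()
        nonzero = {names[i] for i in np.flatnonzero(vec)}
        assert nonzero == {"A" * k for k in range(1, 7)}
        # every k has frequency 1.0 before normalization -> equal entries
        np.testing.assert_allclose(vec[vec > 0], 1 / np.sqrt(6))

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_reverse_complement(self, s):
        np.testing.assert_allclose(kmer_features(s), kmer_features(revcomp(s)), atol=1e-12)

    @given(dna)
    @settings(max_examples=30, deadline=None)
    def test_unit_euclidean_norm(self, s):
        assert np.linalg.norm(kmer_features(s)) == pytest.approx(1.0)

    def test_n_windows_skipped_denominator_kept(self):
        # "AANAAAA": k=1 -> 6 of 7 windows valid; k=2 -> 4 of 6 windows valid
        vec = kmer_features("AANAAAA")
        names = kmer_class_names()
        a1 = vec[names.index("A")]
        aa = vec[names.index("AA")]
        # raw freqs 6/7 and 4/6; the ratio survives the joint 2-norm scaling
        assert a1 / aa == pytest.approx((6 / 7) / (4 / 6))

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="length"):
            kmer_features("ACGTA")


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 10, size=n).astype(float)  # integer scores force ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 2], [1, 1])


class TestFeatureAuroc:
    def test_label_column_scores_one(self):
        m = ft.FeatureMatrix(
            X=np.array([[0.0], [1.0], [0.0], [1.0]]),
            labels=np.array([0, 1, 0, 1]),
            columns=["f"],
        )
        assert feature_auroc(m)["f"] == 1.0

    def test_sign_flip_symmetry(self, rng):
        x = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        m1 = ft.FeatureMatrix(X=x[:, None], labels=labels, columns=["f"])
        m2 = ft.FeatureMatrix(X=-x[:, None], labels=labels, columns=["f"])
        assert feature_auroc(m1)["f"] + feature_auroc(m2)["f"] == pytest.approx(1.0)


class TestMotifScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", np.full((5, 4), 0.25))
        assert motif_score("ACGTACGTACGT", pwm) == 0.0

    def test_single_consensus_site_matches_hand_logodds(self):
        pwm = PWM.from_consensus("m", "ACGTAG", weight=0.85)
        lo = pwm.log_odds()
        seq = "ACGTAG"
        fwd = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(seq))
        rc_lo = lo[::-1, ::-1]
        rev = sum(rc_lo[i, "ACGT".index(b)] for i, b in enumerate(seq))
        expected = max(0.0, fwd) + max(0.0, rev)
        assert motif_score(seq, pwm) == pytest.approx(expected)

    def test_sequence_shorter_than_motif_scores_zero(self):
        pwm = PWM.from_consensus("m", "ACGTACGT")
        assert motif_score("ACG", pwm) == 0.0

    def test_matrix_rescaling_matches_kmer_statistics(self, gc_loci):
        m = gc_loci["matrix"]
        kmer_block = m.X[:, : m.n_kmer]
        motif_col = m.X[:, -1]
        assert motif_col.mean() == pytest.approx(kmer_block.mean(), abs=1e-9)
        assert motif_col.std() == pytest.approx(kmer_block.std(), abs=1e-9)


class TestExtractLoci:
    GENOME = {"c": "ACGT" * 25_000}  # 100 kb

    def test_close_peaks_merge_to_one_locus(self):
        loci = extract_loci(
            [("c", 50_000), ("c", 51_500)], self.GENOME, [], seed=0
        )
        assert int(loci.labels.sum()) == 1

    def test_distant_peaks_stay_separate(self):
        loci = extract_loci([("c", 30_000), ("c", 60_000)], self.GENOME, [], seed=0)
        assert int(loci.labels.sum()) == 2

    def test_no_peaks_raises(self):
        with pytest.raises(ValueError, match="no peaks"):
            extract_loci([], self.GENOME, [], seed=0)

    def test_fully_genic_peak_window_dropped(self):
        genes = [("c", 0, 100_000)]
        with pytest.raises(ValueError, match="fully genic"):
            extract_loci([("c", 50_000)], self.GENOME, genes, seed=0)

    def test_background_respects_subthreshold_halo(self, polyA_loci):
        loci = polyA_loci["loci"]
        truth = polyA_loci["truth"]
        centers = np.sort(np.array([p for _, p in truth.origin_positions]))
        for prov, label in zip(loci.provenance, loci.labels):
            if label == 0:
                region = prov.split(":")[1]
                s, e = (int(x) for x in region.split("-"))
                center = (s + e) / 2
                assert np.min(np.abs(centers - center)) > 8000


class TestSVM:
    def test_linearly_separable_toy_set_scores_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        m = ft.FeatureMatrix(X=X, labels=y, columns=["a", "b"])
        assert train_svm_cv(m, folds=5, seed=0).auroc == 1.0

    def test_deterministic_under_seed(self, polyA_loci):
        m = polyA_loci["matrix"]
        a = train_svm_cv(m, seed=3)
        b = train_svm_cv(m, seed=3)
        assert a.auroc == b.auroc
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_same_species_fixture_is_learnable(self, polyA_loci):
        assert train_svm_cv(polyA_loci["matrix"], seed=5).auroc >= 0.85

    def test_planted_polyA_feature_outranks_polyG(self, polyA_loci):
        table = feature_auroc(polyA_loci["matrix"])
        assert table["AAAAAA"] > table["CCCCCC"]  # canonical class of 6G is 6C

    def test_cross_species_transfer_degrades(self, polyA_loci, gc_loci):
        """A model trained on polyA-style origins transfers poorly to GC-style ones."""
        km_gc = ft.build_feature_matrix(gc_loci["loci"])  # k-mer columns only
        model = train_svm(polyA_loci["matrix"])
        same = cross_apply(model, polyA_loci["matrix"])
        other = cross_apply(model, km_gc)
        assert other < same

    def test_apply_to_own_training_matrix_is_optimistic(self, polyA_loci):
        m = polyA_loci["matrix"]
        cv = train_svm_cv(m, seed=5)
        assert cross_apply(train_svm(m), m) >= cv.auroc - 1e-9

    def test_shuffled_labels_score_near_half(self, polyA_loci, rng):
        m = polyA_loci["matrix"]
        shuffled = ft.FeatureMatrix(
            X=m.X, labels=rng.permutation(m.labels), columns=m.columns
        )
        assert abs(cross_apply(train_svm(polyA_loci["matrix"]), shuffled) - 0.5) < 0.15

    def test_column_mismatch_names_first_difference(self, polyA_loci):
        m = polyA_loci["matrix"]
        bad = ft.FeatureMatrix(X=m.X, labels=m.labels, columns=["x"] + m.columns[1:])
        model = train_svm(m)
        with pytest.raises(ValueError, match="mismatch"):
            cross_apply(model, bad)

    def test_imbalanced_classes_refuse_stratification(self):
        X = np.ones((8, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        m = ft.FeatureMatrix(X=X, labels=y, columns=["a", "b"])
        with pytest.raises(ValueError, match="stratified"):
            train_svm_cv(m, folds=5)
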