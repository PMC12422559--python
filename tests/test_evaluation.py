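"""Variance explained, loop O/E, fold enrichment, ARI, overlaps, segments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import chromdomain as cd
from chromdomain.core import NA_LABEL, DomainAnnotation, LoopSet, SignalMatrix
from chromdomain.evaluation import (
    adjusted_rand_index,
    domain_coverage,
    fold_enrichment,
    loop_oe_ratio,
    mean_segment_length,
    normalize_ve_across_annotations,
    overlap_matrix,
    per_signal_ve,
    variance_explained,
)


def brute_force_ari(a, b):
    """Pair-agreement oracle: count concordant/discordant pairs directly."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "values,labels,expected",
        [
            ([1, 1, 2, 2], [1, 1, 2, 2], 1.0),
            ([1, 2, 1, 2], [1, 1, 2, 2], 0.0),
            ([0, 1, 2, 3], [1, 1, 2, 2], 0.8),
        ],
    )
    def test_closed_forms(self, values, labels, expected):
        assert np.isclose(
            variance_explained(np.array(values, dtype=float), np.array(labels)),
            expected,
        )

    def test_zero_variance_returns_zero(self):
        assert variance_explained(np.full(4, 3.0), np.array([1, 1, 2, 2])) == 0.0

    def test_all_na_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.full(3, np.nan), np.array([1, 1, 2]))

    def test_na_positions_dropped_pairwise(self):
        v = np.array([0.0, 1.0, 2.0, 3.0, 99.0])
        lab = np.array([1, 1, 2, 2, NA_LABEL])
        assert np.isclose(variance_explained(v, lab), 0.8)

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    @settings(deadline=None, max_examples=30)
    def test_affine_and_rename_invariance(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        v = r.normal(size=20)
        lab = r.integers(1, 4, size=20)
        ve = variance_explained(v, lab)
        assert 0.0 <= ve <= 1.0
        assert np.isclose(ve, variance_explained(scale * v + shift, lab), atol=1e-8)
        assert np.isclose(ve, variance_explained(v, 5 - lab), atol=1e-12)

    def test_null_simulation_small_ve(self):
        # independent noise, n=1000, K=6: VE stays near (K-1)/(n-1) ~ 0.005
        r = np.random.default_rng(0)
        ves = [
            variance_explained(r.normal(size=1000), r.integers(1, 7, size=1000))
            for _ in range(100)
        ]
        assert np.mean(ves) < 0.05


class TestPerSignalVE:
    def test_track_equal_to_labels_gives_one(self, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 1, 2, 2, 1]), K=2, bins=tiny_bins)
        sm = SignalMatrix(
            values=np.column_stack([ann.labels.astype(float), np.ones(5)]),
            track_names=["lab", "const"],
        )
        ve = per_signal_ve(sm, ann)
        assert len(ve) == 2
        assert np.isclose(ve[0], 1.0)
        assert ve[1] == 0.0

    def test_normalize_across_annotations(self):
        t = np.array([[0.2, 0.0], [0.4, 0.0]])
        out = normalize_ve_across_annotations(t)
        assert np.allclose(out[:, 0], [0.5, 1.0])
        assert np.allclose(out[:, 1], 0.0)

    def test_single_annotation_normalizes_to_one(self):
        out = normalize_ve_across_annotations(np.array([[0.3, 0.6]]))
        assert np.allclose(out, 1.0)


class TestLoopOE:
    def _ann(self, labels, bins=None):
        labels = np.asarray(labels)
        bins = bins or cd.bin_genome([("c1", len(labels) * 10)], 10)
        return DomainAnnotation(labels=labels, K=int(labels.max()), bins=bins)

    def _loops(self, pairs):
        anchors = [("c1", i * 10, i * 10 + 5, "c1", j * 10, j * 10 + 5) for i, j in pairs]
        return LoopSet(anchors=anchors, resolved=np.array(pairs))

    def test_single_domain_gives_exactly_one(self):
        ann = self._ann([1] * 10)
        loops = self._loops([(0, 5), (2, 7), (1, 9)])
        assert loop_oe_ratio(loops, ann, n_perm=50, seed=0) == 1.0

    def test_balanced_two_types_all_within_approaches_two(self, rng):
        labels = np.array([1] * 50 + [2] * 50)
        ann = self._ann(labels)
        within = np.flatnonzero(labels == 1)
        pairs = [tuple(rng.choice(within, 2, replace=False)) for _ in range(200)]
        oe = loop_oe_ratio(self._loops(pairs), ann, n_perm=400, seed=0)
        assert abs(oe - 2.0) < 0.15

    def test_zero_same_domain_loops_gives_zero(self):
        ann = self._ann([1] * 5 + [2] * 5)
        loops = self._loops([(0, 5), (1, 6), (2, 7)])
        assert loop_oe_ratio(loops, ann, n_perm=100, seed=0) == 0.0

    def test_permutation_agrees_with_closed_form(self, rng):
        labels = rng.integers(1, 4, size=120)
        ann = self._ann(labels)
        pairs = [tuple(rng.choice(120, 2, replace=False)) for _ in range(150)]
        loops = self._loops(pairs)
        perm = loop_oe_ratio(loops, ann, n_perm=2000, seed=1)
        closed = loop_oe_ratio(loops, ann, method="closed_form")
        assert abs(perm - closed) / closed < 0.1

    def test_unlabeled_anchors_and_self_pairs_dropped(self):
        labels = np.array([1, 1, 2, 2, NA_LABEL])
        ann = self._ann(np.where(labels == NA_LABEL, NA_LABEL, labels))
        loops = self._loops([(0, 1), (3, 4), (2, 2)])  # only (0,1) usable
        assert loop_oe_ratio(loops, ann, n_perm=100, seed=0) > 0

    def test_no_usable_loops_rejected(self):
        ann = self._ann([1, 1, 2, 2])
        loops = self._loops([(0, 0)])
        with pytest.raises(ValueError):
            loop_oe_ratio(loops, ann, n_perm=10, seed=0)


class TestFoldEnrichment:
    def test_constant_track_is_all_ones(self, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 1, 2, 2, 2]), K=2, bins=tiny_bins)
        sm = SignalMatrix(values=np.full((5, 2), 4.0), track_names=["a", "b"])
        assert np.allclose(fold_enrichment(sm, ann), 1.0)

    def test_hand_medians(self):
        bins = cd.bin_genome([("c1", 60)], 10)
        ann = DomainAnnotation(labels=np.array([1, 1, 1, 2, 2, 2]), K=2, bins=bins)
        sm = SignalMatrix(
            values=np.array([2.0, 2, 2, 1, 1, 1]).reshape(-1, 1), track_names=["t"]
        )
        fe = fold_enrichment(sm, ann)
        assert np.allclose(fe[:, 0], [4 / 3, 2 / 3])

    def test_single_domain_is_one(self):
        bins = cd.bin_genome([("c1", 40)], 10)
        ann = DomainAnnotation(labels=np.ones(4, dtype=int), K=1, bins=bins)
        sm = SignalMatrix(values=np.arange(4.0).reshape(-1, 1) + 1, track_names=["t"])
        assert np.allclose(fold_enrichment(sm, ann), 1.0)

    def test_empty_domain_gives_nan_row(self, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 1, 1, 1, 1]), K=2, bins=tiny_bins)
        sm = SignalMatrix(values=np.ones((5, 1)), track_names=["t"])
        fe = fold_enrichment(sm, ann)
        assert np.isnan(fe[1]).all()

    def test_invariant_to_positive_rescaling(self, rng, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 2, 1, 2, 1]), K=2, bins=tiny_bins)
        v = rng.uniform(1, 5, size=(5, 1))
        sm1 = SignalMatrix(values=v, track_names=["t"])
        sm2 = SignalMatrix(values=7.3 * v, track_names=["t"])
        assert np.allclose(fold_enrichment(sm1, ann), fold_enrichment(sm2, ann))


class TestARI:
    def test_identical_labelings(self):
        a = np.array([1, 1, 2, 2, 3])
        assert adjusted_rand_index(a, a) == 1.0

    def test_label_name_invariance(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([3, 3, 1, 1, 2, 2])
        assert adjusted_rand_index(a, b) == 1.0

    def test_worked_six_element_example(self):
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([1, 1, 2, 2, 2, 2])
        assert np.isclose(adjusted_rand_index(a, b), 0.324324324, atol=1e-9)

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            a = rng.integers(1, 4, size=n)
            b = rng.integers(1, 4, size=n)
            ours = adjusted_rand_index(a, b)
            assert np.isclose(ours, brute_force_ari(a, b), atol=1e-12)
            assert np.isclose(ours, adjusted_rand_score(a, b), atol=1e-12)

    def test_na_dropped_pairwise(self):
        a = np.array([1, 1, 2, 2, NA_LABEL])
        b = np.array([1, 1, 2, 2, 1])
        assert adjusted_rand_index(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(np.array([1, 2]), np.array([1, 2, 3]))


class TestOverlapMatrix:
    def test_self_overlap_is_diagonal(self, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 2, 1, 2, 1]), K=2, bins=tiny_bins)
        om = overlap_matrix(ann, ann, "row")
        assert np.allclose(om.values, np.eye(2))
        assert om.raw.sum() == 5

    def test_row_normalization_hand_example(self):
        bins = cd.bin_genome([("c1", 100)], 10)
        a = DomainAnnotation(labels=np.ones(10, dtype=int), K=1, bins=bins)
        b_lab = np.array([1] * 3 + [2] * 7)
        b = DomainAnnotation(labels=b_lab, K=2, bins=bins)
        om = overlap_matrix(a, b, "row")
        assert np.allclose(om.values, [[0.3, 0.7]])

    def test_column_normalization_sums_to_one(self, rng):
        bins = cd.bin_genome([("c1", 500)], 10)
        a = DomainAnnotation(labels=rng.integers(1, 4, 50), K=3, bins=bins)
        b = DomainAnnotation(labels=rng.integers(1, 5, 50), K=4, bins=bins)
        om = overlap_matrix(a, b, "column")
        assert np.allclose(om.values.sum(axis=0), 1.0)

    def test_na_bins_excluded(self, tiny_bins):
        a = DomainAnnotation(labels=np.array([1, 1, NA_LABEL, 2, 2]), K=2, bins=tiny_bins)
        b = DomainAnnotation(labels=np.array([1, NA_LABEL, 1, 2, 2]), K=2, bins=tiny_bins)
        om = overlap_matrix(a, b, "none")
        assert om.raw.sum() == 3  # bins 0, 3, 4

    def test_different_bin_tables_rejected(self, tiny_bins):
        other = cd.bin_genome([("c1", 50)], 10)
        a = DomainAnnotation(labels=np.ones(5, dtype=int), K=1, bins=tiny_bins)
        b = DomainAnnotation(labels=np.ones(5, dtype=int), K=1, bins=other)
        with pytest.raises(ValueError):
            overlap_matrix(a, b)


class TestSegments:
    def test_domain_coverage(self, tiny_bins):
        ann = DomainAnnotation(labels=np.array([1, 1, 2, NA_LABEL, 1]), K=2, bins=tiny_bins)
        assert np.array_equal(domain_coverage(ann), [3, 1])

    def test_coverage_all_na(self, tiny_bins):
        ann = DomainAnnotation(labels=np.full(5, NA_LABEL), K=2, bins=tiny_bins)
        assert np.array_equal(domain_coverage(ann), [0, 0])

    def test_run_enumeration(self):
        bins = cd.bin_genome([("c1", 40)], 10)
        ann = DomainAnnotation(labels=np.array([1, 1, 2, 1]), K=2, bins=bins)
        mb, mbp = mean_segment_length(ann)
        assert np.allclose(mb, [1.5, 1.0])
        assert np.allclose(mbp, [15.0, 10.0])

    def test_single_label_whole_chromosome(self):
        bins = cd.bin_genome([("c1", 70)], 10)
        ann = DomainAnnotation(labels=np.ones(7, dtype=int), K=1, bins=bins)
        assert mean_segment_length(ann)[0][0] == 7.0

    def test_chromosome_boundary_breaks_run(self, tiny_bins):
        # chr1 has bins 0-2, chr2 bins 3-4; same label across the boundary
        ann = DomainAnnotation(labels=np.array([2, 2, 1, 1, 2]), K=2, bins=tiny_bins)
        mb, _ = mean_segment_length(ann)
        # label 1: runs [1] (chr1 bin2) and [1] (chr2 bin3) -> mean 1.0
        assert mb[0] == 1.0

    def test_na_breaks_run(self):
        bins = cd.bin_genome([("c1", 50)], 10)
        ann = DomainAnnotation(labels=np.array([1, NA_LABEL, 1, 1, 1]), K=1, bins=bins)
        assert mean_segment_length(ann)[0][0] == 2.0  # runs {1, 3}
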