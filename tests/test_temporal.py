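"""Rule-based six-class labels and the fuzzy c-means route."""

import numpy as np
import pytest

from ptmdyn.temporal import (
    FcmModel,
    UNREGULATED,
    assign_fcm,
    classify_rule_based,
    classify_sites,
    fit_fcm,
    label_clusters,
    standardize_profiles,
)
from .conftest import make_profile


class TestRuleClassifier:
    @pytest.mark.parametrize(
        "m05,m2,label,conflict",
        [
            (1.5, 1.4, "fast-lasting-up", False),
            (0.2, -1.3, "slow-down", False),
            (1.2, 0.3, "fast-transient-up", False),
            (1.2, -1.1, "fast-transient-up", True),  # sign reversal tie-break
            (-1.2, 1.1, "fast-transient-down", True),
            (-1.5, -1.5, "fast-lasting-down", False),
            (0.0, 1.0, "slow-up", False),
            (0.5, 0.5, UNREGULATED, False),
        ],
    )
    def test_six_class_rules(self, m05, m2, label, conflict):
        cl = classify_rule_based(make_profile(m05, m2))
        assert cl.six_class_label == label
        assert cl.conflict_flag is conflict

    def test_label_decomposition_consistency(self):
        cl = classify_rule_based(make_profile(1.5, 1.4))
        assert (cl.speed, cl.persistence, cl.direction) == ("fast", "lasting", "up")
        cl = classify_rule_based(make_profile(0.0, -1.2))
        assert (cl.speed, cl.persistence, cl.direction) == ("slow", "n/a", "down")
        cl = classify_rule_based(make_profile(0.0, 0.0))
        assert cl.speed == "none" and cl.six_class_label == UNREGULATED

    @pytest.mark.parametrize(
        "m05,m2,label",
        [
            (1.3, None, "fast-transient-up"),
            (None, -1.4, "slow-down"),
            (None, 0.2, UNREGULATED),
        ],
    )
    def test_single_time_point_sites_flagged(self, m05, m2, label):
        cl = classify_rule_based(make_profile(m05, m2))
        assert cl.six_class_label == label
        assert cl.conflict_flag is True

    def test_regulated_sites_get_exactly_one_class(self):
        # the six regulated classes partition the regulated sites
        rng = np.random.default_rng(3)
        for _ in range(200):
            cl = classify_rule_based(
                make_profile(float(rng.uniform(-3, 3)), float(rng.uniform(-3, 3)))
            )
            regulated = cl.six_class_label != UNREGULATED
            assert regulated == (cl.speed != "none")


class TestStandardize:
    def test_shape_vectors_are_zero_mean_unit_sd(self):
        x = standardize_profiles([make_profile(1.0, 2.0), make_profile(-3.0, 0.5)])
        assert x.shape == (2, 3)
        assert np.allclose(x.mean(axis=1), 0)
        assert np.allclose(x.std(axis=1), 1)

    def test_flat_profile_maps_to_zero(self):
        x = standardize_profiles([make_profile(0.0, 0.0)])
        assert np.allclose(x, 0)

    def test_unquantified_profile_rejected(self):
        with pytest.raises(ValueError):
            standardize_profiles([make_profile(1.0, None)])


class TestFcm:
    def test_single_cluster_degenerate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (15, 2))
        model = fit_fcm(x, c=1, seed=0)
        assert np.allclose(model.memberships, 1.0)
        assert np.allclose(model.centers[0], x.mean(axis=0), atol=1e-4)

    def test_two_blobs_match_nearest_center_partition(self):
        # brute-force oracle on 20 points: argmax membership must equal
        # exhaustive nearest-center assignment
        rng = np.random.default_rng(1)
        x = np.vstack(
            [rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))]
        )
        model = fit_fcm(x, c=2, seed=1)
        hard = model.memberships.argmax(axis=1)
        nearest = np.array(
            [
                np.argmin([np.sum((p - ctr) ** 2) for ctr in model.centers])
                for p in x
            ]
        )
        assert (hard == nearest).all()
        assert len(set(hard[:10])) == 1 and len(set(hard[10:])) == 1
        assert hard[0] != hard[10]

    def test_memberships_row_normalized_and_objective_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (60, 3))
        model = fit_fcm(x, c=4, seed=2)
        assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)
        trace = model.objective_trace
        assert all(b <= a + 1e-9 * max(1, a) for a, b in zip(trace, trace[1:]))

    def test_duplicated_point_gets_identical_memberships(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 2))
        x_dup = np.vstack([x, x[5]])
        model = fit_fcm(x_dup, c=3, seed=3)
        assert np.allclose(model.memberships[5], model.memberships[-1])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (30, 2))
        a = fit_fcm(x, c=3, seed=7)
        b = fit_fcm(x, c=3, seed=7)
        assert np.array_equal(a.memberships, b.memberships)

    def test_too_few_distinct_points_rejected(self):
        x = np.tile([[1.0, 2.0], [3.0, 4.0]], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            fit_fcm(x, c=3)


class TestAssignFcm:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.61, 0.39], 0),
            ([0.60, 0.40], None),  # strictly greater than
            ([0.39, 0.61], 1),
        ],
    )
    def test_strict_membership_threshold(self, row, expected):
        model = FcmModel(
            c=2, m=2.0, centers=np.zeros((2, 2)), memberships=np.array([row])
        )
        assert assign_fcm(model, 0.6) == [expected]

    def test_uniform_memberships_unassigned(self):
        model = FcmModel(
            c=6, m=2.0, centers=np.zeros((6, 2)), memberships=np.full((1, 6), 1 / 6)
        )
        assert assign_fcm(model, 0.6) == [None]


class TestLabelClusters:
    def test_labels_from_raw_space_centers(self):
        # crisp memberships make raw-space centers the member means
        profiles = [
            make_profile(1.4, 1.5, position=1),
            make_profile(1.4, 1.5, position=2),
            make_profile(0.1, 1.2, position=3),
            make_profile(0.1, 1.2, position=4),
            make_profile(0.0, 0.0, position=5),
        ]
        memberships = np.array(
            [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        model = FcmModel(c=3, m=2.0, centers=np.zeros((3, 3)), memberships=memberships)
        labels = label_clusters(model, profiles)
        assert labels[0] == "fast-lasting-up"
        assert labels[1] == "slow-up"
        assert labels[2] == UNREGULATED  # flagged unlabeled center


def test_classify_sites_end_to_end_marks_memberships():
    rng = np.random.default_rng(5)
    profiles = []
    for m05, m2 in [(2, 2), (-2, -2), (2, 0), (-2, 0), (0, 2), (0, -2)]:
        for _ in range(10):
            profiles.append(
                make_profile(
                    m05 + rng.normal(0, 0.1),
                    m2 + rng.normal(0, 0.1),
                    position=len(profiles) + 1,
                )
            )
    profiles.append(make_profile(0.0, 0.1, position=999))
    cls = classify_sites(profiles, seed=5)
    regulated = [c for c in cls if c.six_class_label != UNREGULATED]
    assert all(c.fcm_membership > 0 for c in regulated)
    assert cls[-1].fcm_cluster is None and cls[-1].fcm_membership == 0.0
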