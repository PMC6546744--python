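import numpy as np
import pytest

from betimed.barcodes import BarcodeConfig, filter_etp, sharing_profile, surviving_fraction
from betimed.io import CountTable


def table_from(rows: dict[str, list[int]], samples: list[str]) -> CountTable:
    counts = np.array([rows[b] for b in rows])
    return CountTable(list(rows), samples, counts)


class TestEtpFilter:
    def test_boundary_of_three_reads_is_inclusive(self):
        t = table_from({"b1": [2], "b2": [3], "b3": [4]}, ["ETP"])
        assert filter_etp(t, "ETP") == {"b2", "b3"}

    def test_empty_table(self):
        t = CountTable([], ["ETP"], np.zeros((0, 1), dtype=int))
        assert filter_etp(t, "ETP") == set()

    def test_missing_etp_column_rejected(self):
        t = table_from({"b1": [1]}, ["other"])
        with pytest.raises(KeyError, match="ETP"):
            filter_etp(t, "ETP")

    def test_six_barcode_hand_enumeration(self):
        counts = {"b1": [0], "b2": [1], "b3": [2], "b4": [3], "b5": [10], "b6": [300]}
        t = table_from(counts, ["ETP"])
        assert filter_etp(t, "ETP") == {"b4", "b5", "b6"}


class TestSurvivingFraction:
    def test_everything_detected_everywhere_is_hundred_percent(self):
        t = table_from({"b1": [5, 1, 1], "b2": [5, 2, 2]}, ["ETP", "JQ1_1", "JQ1_2"])
        pct = surviving_fraction(t, {"b1", "b2"}, ["JQ1_1", "JQ1_2"])
        assert pct == 100.0

    def test_half_detected_is_fifty_percent(self):
        rows = {"b1": [5, 1], "b2": [5, 0], "b3": [5, 2], "b4": [5, 0]}
        t = table_from(rows, ["ETP", "JQ1_1"])
        cfg = BarcodeConfig(denominator="eligible")
        pct = surviving_fraction(t, set(rows), ["JQ1_1"], cfg)
        assert pct == 50.0

    def test_empty_eligible_set_rejected(self):
        t = table_from({"b1": [5, 1]}, ["ETP", "JQ1_1"])
        with pytest.raises(ValueError, match="empty"):
            surviving_fraction(t, set(), ["JQ1_1"])

    def test_union_denominator_excludes_never_detected_barcodes(self):
        # b4 passes the ETP filter but is absent from every post-treatment
        # sample, so the union convention drops it from the denominator
        rows = {"b1": [5, 1, 1], "b2": [5, 0, 1], "b3": [5, 1, 0], "b4": [5, 0, 0]}
        t = table_from(rows, ["ETP", "JQ1_1", "DMSO_1"])
        pct = surviving_fraction(t, set(rows), ["JQ1_1"],
                                 all_samples=["JQ1_1", "DMSO_1"])
        assert pct == pytest.approx(100 * 2 / 3)


class TestSharingProfile:
    def make(self, detected: dict[str, list[int]], n_rep: int):
        samples = ["ETP"] + [f"JQ1_{i}" for i in range(1, n_rep + 1)]
        rows = {b: [5] + v for b, v in detected.items()}
        return table_from(rows, samples)

    def test_identical_replicates_share_everything(self):
        t = self.make({"b1": [1, 1, 1], "b2": [2, 2, 2]}, 3)
        s = sharing_profile(t, {"b1", "b2"}, ["JQ1_1", "JQ1_2", "JQ1_3"])
        assert s.shared_across_all_percent == 100.0

    def test_disjoint_replicates_share_nothing(self):
        t = self.make({"b1": [1, 0], "b2": [0, 1]}, 2)
        s = sharing_profile(t, {"b1", "b2"}, ["JQ1_1", "JQ1_2"])
        assert s.shared_across_all_percent == 0.0
        assert s.per_replicate_sharing["JQ1_1"] == {0: 1, 1: 0}

    def test_three_of_ten_survivors_fully_shared(self):
        detected = {}
        for i in range(3):                      # shared across all 8
            detected[f"s{i}"] = [1] * 8
        for i in range(7):                      # one replicate each
            v = [0] * 8
            v[i % 8] = 1
            detected[f"u{i}"] = v
        t = self.make(detected, 8)
        s = sharing_profile(t, set(detected), [f"JQ1_{i}" for i in range(1, 9)])
        assert s.n_survivors == 10
        assert s.shared_across_all_percent == pytest.approx(30.0)

    def test_per_replicate_counts_sum_to_replicate_size(self):
        rng = np.random.default_rng(12)
        detected = {f"b{i}": list(rng.integers(0, 2, size=4)) for i in range(50)}
        t = self.make(detected, 4)
        s = sharing_profile(t, set(detected), [f"JQ1_{i}" for i in range(1, 5)])
        frame = t.to_frame()
        for rep, counts in s.per_replicate_sharing.items():
            assert sum(counts.values()) == int((frame[rep] >= 1).sum())

    def test_raising_detection_threshold_never_increases_sharing(self):
        rng = np.random.default_rng(13)
        detected = {f"b{i}": list(rng.integers(0, 5, size=4)) for i in range(60)}
        t = self.make(detected, 4)
        treated = [f"JQ1_{i}" for i in range(1, 5)]
        lo = sharing_profile(t, set(detected), treated, config=BarcodeConfig(detection_threshold=1))
        hi = sharing_profile(t, set(detected), treated, config=BarcodeConfig(detection_threshold=3))
        for rep in treated:
            assert sum(hi.per_replicate_sharing[rep].values()) <= sum(
                lo.per_replicate_sharing[rep].values()
            )

    def test_replicate_order_permutation_invariant(self):
        rng = np.random.default_rng(14)
        detected = {f"b{i}": list(rng.integers(0, 2, size=4)) for i in range(40)}
        t = self.make(detected, 4)
        treated = [f"JQ1_{i}" for i in range(1, 5)]
        s1 = sharing_profile(t, set(detected), treated)
        s2 = sharing_profile(t, set(detected), treated[::-1])
        assert s1.shared_across_all_percent == s2.shared_across_all_percent
        assert s1.surviving_percent == s2.surviving_percent

    def test_treated_only_contrast_against_vehicle(self):
        rows = {
            "b1": [5, 1, 1, 0],   # survives drug, absent from vehicle
            "b2": [5, 1, 1, 1],   # survives drug, present in vehicle
        }
        t = table_from(rows, ["ETP", "JQ1_1", "JQ1_2", "DMSO_1"])
        s = sharing_profile(t, set(rows), ["JQ1_1", "JQ1_2"], ["DMSO_1"])
        assert s.treated_only_percent == pytest.approx(50.0)
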