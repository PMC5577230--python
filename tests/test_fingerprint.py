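import numpy as np
import pytest

from actinoprint.defaults import ENZYMES
from actinoprint.dna import random_dna
from actinoprint.fingerprint import (
    Enzyme,
    GelModel,
    LaneProfile,
    apply_area_filter,
    band_matrix,
    combine_matrices,
    digest,
    lane_from_fragments,
)
from actinoprint.util import ParameterError


def naive_digest(seq, enzyme):
    """Position-by-position scanning oracle."""
    cuts = []
    for i in range(len(seq)):
        if seq[i:i + len(enzyme.site)] == enzyme.site:
            c = i + enzyme.cut_offset
            if 0 < c < len(seq):
                cuts.append(c)
    cuts = sorted(set(cuts))
    frags, prev = [], 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(seq) - prev)
    return frags


class TestDigest:
    def test_alui_single_site(self):
        assert digest("TTAGCTTT", ENZYMES["AluI"]) == [4, 4]

    def test_haeiii_single_site(self):
        assert digest("AAGGCCAA", ENZYMES["HaeIII"]) == [4, 4]

    def test_no_site_returns_whole_molecule(self):
        assert digest("AAAATTTT", ENZYMES["AluI"]) == [8]

    def test_conservation_and_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            seq = random_dna(480, rng)
            for enzyme in ENZYMES.values():
                frags = digest(seq, enzyme)
                assert sum(frags) == 480
                assert frags == naive_digest(seq, enzyme)

    def test_overlapping_sites_all_cut(self):
        # AGCT at 2 and GGCC-style overlap check with a custom enzyme AAA^A
        e = Enzyme("tandem", site="AGCTAGCT", cut_offset=2)
        seq = "AGCTAGCTAGCT"
        assert digest(seq, e) == naive_digest(seq, e)

    def test_bad_enzyme_definitions(self):
        with pytest.raises(ParameterError):
            Enzyme("x", site="AGC", cut_offset=1)
        with pytest.raises(ParameterError):
            Enzyme("x", site="AGCT", cut_offset=7)


class TestLaneFromFragments:
    def test_exact_comigration_single_band(self):
        lane = lane_from_fragments([240, 240])
        assert lane.bands == [(240.0, 1.0)]

    def test_small_fragment_dropped(self):
        lane = lane_from_fragments([300, 10])
        assert lane.bands == [(300.0, 1.0)]

    def test_resolved_bands_mass_proportional_areas(self):
        lane = lane_from_fragments([250, 230])
        sizes = [b[0] for b in lane.bands]
        areas = [b[1] for b in lane.bands]
        assert sizes == [250.0, 230.0]
        assert areas == pytest.approx([250 / 480, 230 / 480])

    def test_areas_sum_to_one(self, rng):
        for _ in range(50):
            frags = list(rng.integers(20, 400, size=rng.integers(1, 10)))
            lane = lane_from_fragments([int(f) for f in frags])
            if lane.bands:
                assert sum(a for _, a in lane.bands) == pytest.approx(1.0)
                assert [s for s, _ in lane.bands] == sorted(
                    (s for s, _ in lane.bands), reverse=True
                )

    def test_all_below_detection_empty_lane(self):
        assert lane_from_fragments([10, 20, 30]).bands == []

    def test_merged_band_size_is_mass_weighted_mean(self):
        gel = GelModel(resolution_bp=10.0, resolution_frac=0.0)
        lane = lane_from_fragments([100, 108], gel)
        (size, area), = lane.bands
        assert area == pytest.approx(1.0)
        assert size == pytest.approx((100 * 100 + 108 * 108) / 208)


class TestAreaFilter:
    def test_five_percent_rule(self):
        lane = LaneProfile("i", "AluI", [(400.0, 0.97), (50.0, 0.03)])
        assert apply_area_filter(lane).bands == [(400.0, 0.97)]

    def test_exactly_five_percent_dropped(self):
        lane = LaneProfile("i", "AluI", [(400.0, 0.95), (50.0, 0.05)])
        assert apply_area_filter(lane).bands == [(400.0, 0.95)]

    def test_uniform_digest_all_retained(self):
        lane = LaneProfile("i", "AluI", [(float(100 + k), 0.1) for k in range(10)])
        assert len(apply_area_filter(lane).bands) == 10

    def test_idempotent(self):
        lane = LaneProfile("i", "AluI", [(400.0, 0.9), (60.0, 0.04), (55.0, 0.06)])
        once = apply_area_filter(lane)
        assert apply_area_filter(once).bands == once.bands


def naive_bin_count(sizes, gel):
    """Oracle: count single-linkage clusters of pooled sizes."""
    if not sizes:
        return 0
    s = sorted(sizes, reverse=True)
    bins = 1
    for prev, cur in zip(s, s[1:]):
        if prev - cur > max(gel.resolution_bp, gel.resolution_frac * prev):
            bins += 1
    return bins


class TestBandMatrix:
    def test_identical_lanes_identical_rows(self):
        lanes = [
            LaneProfile("a", "AluI", [(300.0, 0.6), (180.0, 0.4)]),
            LaneProfile("b", "AluI", [(300.0, 0.6), (180.0, 0.4)]),
        ]
        m = band_matrix(lanes)
        assert (m.loc["a"] == m.loc["b"]).all()
        assert m.shape == (2, 2)

    def test_disjoint_sizes_one_column_per_band(self):
        lanes = [
            LaneProfile("a", "AluI", [(400.0, 1.0)]),
            LaneProfile("b", "AluI", [(200.0, 1.0)]),
        ]
        m = band_matrix(lanes)
        assert m.shape == (2, 2)
        assert m.to_numpy().sum() == 2
        # columns strictly decreasing
        assert list(m.columns) == sorted(m.columns, reverse=True)

    def test_bin_count_matches_clustering_oracle(self, rng):
        gel = GelModel()
        for _ in range(30):
            lanes = []
            pooled = []
            for k in range(int(rng.integers(2, 6))):
                sizes = sorted(
                    {float(s) for s in rng.integers(60, 480, size=rng.integers(1, 6))},
                    reverse=True,
                )
                # keep within-lane sizes resolvable so they are bands
                lanes.append(
                    LaneProfile(f"l{k}", "AluI", [(s, 0.5) for s in sizes])
                )
                pooled.extend(sizes)
            m = band_matrix(lanes, gel)
            assert m.shape[1] == naive_bin_count(pooled, gel)
            assert (m.sum(axis=0) >= 1).all()

    def test_lane_order_permutation_only_permutes_rows(self):
        lanes = [
            LaneProfile("a", "AluI", [(300.0, 0.6)]),
            LaneProfile("b", "AluI", [(200.0, 0.7)]),
            LaneProfile("c", "AluI", [(300.0, 0.5), (200.0, 0.3)]),
        ]
        m1 = band_matrix(lanes)
        m2 = band_matrix(lanes[::-1])
        assert list(m1.columns) == list(m2.columns)
        assert (m1.loc[["a", "b", "c"]] == m2.loc[["a", "b", "c"]]).all().all()

    def test_mixed_enzymes_rejected(self):
        lanes = [
            LaneProfile("a", "AluI", [(300.0, 1.0)]),
            LaneProfile("b", "HaeIII", [(300.0, 1.0)]),
        ]
        with pytest.raises(ParameterError):
            band_matrix(lanes)


class TestCombineMatrices:
    def test_shapes_concatenate(self):
        import pandas as pd

        a = pd.DataFrame(np.ones((3, 2), dtype=int), index=list("xyz"))
        b = pd.DataFrame(np.ones((3, 4), dtype=int), index=list("xyz"))
        c = combine_matrices(a, b, ("AluI", "HaeIII"))
        assert c.shape == (3, 6)
        assert all(str(col).startswith(("AluI:", "HaeIII:")) for col in c.columns)

    def test_combining_with_empty_is_identity_on_values(self):
        import pandas as pd

        a = pd.DataFrame([[1, 0], [0, 1]], index=["x", "y"], columns=[300.0, 200.0])
        empty = pd.DataFrame(index=["x", "y"])
        c = combine_matrices(a, empty)
        assert c.shape == (2, 2)
        assert (c.to_numpy() == a.to_numpy()).all()

    def test_row_mismatch_rejected(self):
        import pandas as pd

        a = pd.DataFrame([[1]], index=["x"])
        b = pd.DataFrame([[1]], index=["y"])
        with pytest.raises(ParameterError):
            combine_matrices(a, b)
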