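import numpy as np
import pandas as pd
import pytest

from tmespatial.errors import ValidationError
from tmespatial.scoring import MarkerScore
from tmespatial.spatial import (
    brute_force_counts,
    build_index,
    clustering_matrix,
    density_expression_correlation,
    neighbor_counts,
    paired_in_range,
    partition_centers_by_flag,
)
from tests.conftest import make_core, random_core


class TestSpatialIndex:
    def test_empty_core_queries_empty(self):
        index = build_index(make_core([]))
        assert index.query((0.0, 0.0), 30.0).size == 0

    def test_oracle_equivalence_random_queries(self, rng):
        core = random_core(rng, 1000)
        index = build_index(core)
        pos = core.positions()
        for _ in range(50):
            q = rng.random(2) * 500.0
            got = index.query(q, 30.0)
            dist = np.hypot(pos[:, 0] - q[0], pos[:, 1] - q[1])
            expected = np.nonzero(dist <= 30.0)[0]
            assert np.array_equal(got, expected)

    def test_duplicate_coordinates_both_returned(self):
        core = make_core([(5.0, 5.0, {}), (5.0, 5.0, {})])
        index = build_index(core)
        assert index.query((5.0, 5.0), 1.0).tolist() == [0, 1]


class TestNeighborCounts:
    def test_self_exclusion_single_cell(self):
        core = make_core([(10.0, 10.0, {"nkp46": True})])
        res = neighbor_counts(core, "NKp46", ["NKp46"])
        assert res.per_center["count_NKp46"].tolist() == [0]

    def test_inclusive_boundary_at_exactly_radius(self):
        core = make_core([(0.0, 0.0, {"cd3": True}), (30.0, 0.0, {"cd3": True})])
        res = neighbor_counts(core, "CD3", ["CD3"], radius=30.0)
        assert res.per_center["count_CD3"].tolist() == [1, 1]
        strict = neighbor_counts(core, "CD3", ["CD3"], radius=30.0, inclusive=False)
        assert strict.per_center["count_CD3"].tolist() == [0, 0]

    def test_coincident_distinct_cells_are_mutual_neighbors(self):
        core = make_core([(5.0, 5.0, {"nkp46": True}), (5.0, 5.0, {"nkp46": True})])
        res = neighbor_counts(core, "NKp46", ["NKp46"])
        assert res.per_center["count_NKp46"].tolist() == [1, 1]

    def test_unknown_phenotype_hard_error(self):
        core = make_core([(0.0, 0.0, {})])
        with pytest.raises(ValidationError, match="unknown phenotype"):
            neighbor_counts(core, "CD19", ["CD3"])

    def test_brute_force_oracle_200_cells(self, rng):
        core = random_core(rng, 200)
        phenotypes = ["CD3", "CD8", "NKp46"]
        for center in phenotypes:
            res = neighbor_counts(core, center, phenotypes, radius=30.0)
            for target in phenotypes:
                expected = brute_force_counts(core, center, target, radius=30.0)
                assert res.per_center[f"count_{target}"].tolist() == expected.tolist()

    def test_monotone_in_radius(self, rng):
        core = random_core(rng, 300)
        radii = [5.0, 15.0, 30.0, 60.0]
        results = [
            neighbor_counts(core, "CD3", ["CD8"], radius=r).per_center["count_CD8"].to_numpy()
            for r in radii
        ]
        for smaller, larger in zip(results, results[1:]):
            assert (larger >= smaller).all()

    def test_guard_margin_excludes_border_centers(self, rng):
        core = random_core(rng, 200, extent=200.0)
        core.geometry = (100.0, 100.0, 100.0)
        res = neighbor_counts(core, "CD3", ["CD3"], radius=30.0, guard_margin=True)
        pos = core.positions()
        interior = np.hypot(pos[:, 0] - 100.0, pos[:, 1] - 100.0) <= 70.0
        assert res.n_centers == int((interior & core.mask("CD3")).sum())

    def test_guard_margin_requires_geometry(self, rng):
        core = random_core(rng, 10)
        with pytest.raises(ValidationError, match="geometry"):
            neighbor_counts(core, "CD3", ["CD3"], guard_margin=True)


def pair_count_sum(cores, a, b, radius=30.0):
    total_ab = sum(
        neighbor_counts(c, a, [b], radius=radius).per_center[f"count_{b}"].sum()
        for c in cores
    )
    total_ba = sum(
        neighbor_counts(c, b, [a], radius=radius).per_center[f"count_{a}"].sum()
        for c in cores
    )
    return int(total_ab), int(total_ba)


class TestPairSymmetry:
    def test_cross_type_symmetry(self, rng):
        cores = [random_core(rng, 250, core_id=f"c{i}") for i in range(3)]
        for a, b in [("CD3", "NKp46"), ("CD8", "NKp46"), ("CD3", "CD8")]:
            ab, ba = pair_count_sum(cores, a, b)
            assert ab == ba

    def test_same_type_double_counts_pairs(self, rng):
        core = random_core(rng, 150)
        total = neighbor_counts(core, "CD3", ["CD3"]).per_center["count_CD3"].sum()
        pos = core.positions()[core.mask("CD3")]
        n_pairs = 0
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.hypot(*(pos[i] - pos[j])) <= 30.0:
                    n_pairs += 1
        assert int(total) == 2 * n_pairs


# hand-placed configuration, enumerated manually:
#   A(0,0) CD3; B(10,0) CD3+CD8; C(100,0) NK; D(105,0) NK; E(120,0) CD3; F(200,200) NK
HAND_CELLS = [
    (0.0, 0.0, {"cd3": True}),
    (10.0, 0.0, {"cd3": True, "cd8": True}),
    (100.0, 0.0, {"nkp46": True}),
    (105.0, 0.0, {"nkp46": True}),
    (120.0, 0.0, {"cd3": True}),
    (200.0, 200.0, {"nkp46": True}),
]


class TestClusteringMatrix:
    def test_hand_computation(self):
        core = make_core(HAND_CELLS)
        res = clustering_matrix([core], ("CD3", "CD8", "NKp46"), radius=30.0)
        m = res.pooled
        assert m.loc["CD3", "CD3"] == pytest.approx(2 / 3)
        assert m.loc["CD3", "CD8"] == pytest.approx(1 / 3)
        assert m.loc["CD3", "NKp46"] == pytest.approx(2 / 3)
        assert m.loc["CD8", "CD3"] == pytest.approx(1.0)
        assert m.loc["CD8", "CD8"] == pytest.approx(0.0)
        assert m.loc["CD8", "NKp46"] == pytest.approx(0.0)
        assert m.loc["NKp46", "NKp46"] == pytest.approx(2 / 3)
        assert m.loc["NKp46", "CD3"] == pytest.approx(2 / 3)
        assert m.loc["NKp46", "CD8"] == pytest.approx(0.0)

    def test_absent_phenotype_is_na_not_zero(self):
        core = make_core([(0.0, 0.0, {"cd3": True})])
        res = clustering_matrix([core], ("CD3", "NKp46"))
        assert np.isnan(res.pooled.loc["NKp46", "CD3"])
        assert ("c0", "NKp46") in res.excluded

    def test_per_patient_unweighted_mean_over_cores(self):
        core_a = make_core([(0.0, 0.0, {"cd3": True}), (10.0, 0.0, {"cd3": True})], core_id="a")
        core_b = make_core([(0.0, 0.0, {"cd3": True})], core_id="b")
        res = clustering_matrix([core_a, core_b], ("CD3",))
        # core a mean = 1 (each cell sees the other), core b mean = 0
        assert res.per_patient["p0"].loc["CD3", "CD3"] == pytest.approx(0.5)
        # pooled: 3 centers, counts (1, 1, 0)
        assert res.pooled.loc["CD3", "CD3"] == pytest.approx(2 / 3)

    def test_long_table_row_count(self, rng):
        core = random_core(rng, 100)
        phenos = ("CD3", "NKp46")
        res = clustering_matrix([core], phenos)
        n_centers = sum(int(core.mask(p).sum()) for p in phenos)
        assert len(res.long) == n_centers * len(phenos)


class TestPairedInRange:
    def test_trivial_counts(self):
        cells = [
            (0.0, 0.0, {"nkp46": True}),
            (5.0, 0.0, {"nkp46": True}),
            (10.0, 0.0, {"nkp46": True}),
            (15.0, 0.0, {"nkp46": True}),
        ]
        df = paired_in_range([make_core(cells)], "NKp46", "NKp46", "CD3")
        assert df["count_a"].tolist() == [3, 3, 3, 3]
        assert df["count_b"].tolist() == [0, 0, 0, 0]

    def test_fixture_vs_oracle(self, rng):
        core = random_core(rng, 150)
        df = paired_in_range([core], "NKp46", "CD3", "CD8")
        assert df["count_a"].tolist() == brute_force_counts(core, "NKp46", "CD3").tolist()
        assert df["count_b"].tolist() == brute_force_counts(core, "NKp46", "CD8").tolist()

    def test_degenerate_identical_targets(self, rng):
        core = random_core(rng, 80)
        df = paired_in_range([core], "CD3", "CD8", "CD8")
        assert df["count_a"].tolist() == df["count_b"].tolist()


class TestPartitionByFlag:
    def test_all_positive_leaves_negative_empty(self):
        cells = [(float(i), 0.0, {"mhc1": True, "cd3": True}) for i in range(5)]
        res = partition_centers_by_flag([make_core(cells)], ["CD3"])
        assert len(res.positive) == 5
        assert len(res.negative) == 0

    def test_partition_property(self, rng):
        core = random_core(rng, 200)
        res = partition_centers_by_flag([core], ["CD3", "NKp46"])
        assert len(res.positive) + len(res.negative) == 200
        assert res.n_excluded == 0

    def test_undefined_flags_excluded_and_reported(self):
        cells = [
            (0.0, 0.0, {"mhc1": True}),
            (1.0, 0.0, {}),  # mhc1 undefined
            (2.0, 0.0, {"mhc1": False}),
        ]
        res = partition_centers_by_flag([make_core(cells)], ["CD3"])
        assert res.n_excluded == 1
        assert len(res.positive) == 1 and len(res.negative) == 1

    def test_counts_match_oracle(self, rng):
        core = random_core(rng, 150)
        res = partition_centers_by_flag([core], ["NKp46"], radius=30.0)
        pos = core.positions()
        nk = core.mask("NKp46")
        flags = core.cells["mhc1"].fillna(False).to_numpy(dtype=bool)
        combined = pd.concat([res.positive, res.negative])
        by_id = dict(zip(combined["cell_id"], combined["count_NKp46"]))
        for i in range(150):
            d = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
            in_range = (d <= 30.0) & nk
            in_range[i] = False
            assert by_id[core.cells["cell_id"].iloc[i]] == int(in_range.sum())
        assert set(res.positive["cell_id"]) == set(core.cells["cell_id"][flags])

    def test_restrict_to_phenotype(self, rng):
        core = random_core(rng, 100)
        core.cells["tumor"] = core.cells.index < 40
        res = partition_centers_by_flag([core], ["CD3"], restrict_to="tumor")
        assert len(res.positive) + len(res.negative) == 40


class TestDensityExpressionCorrelation:
    def _cores_with_density(self, rng, densities):
        cores = []
        for i, d in enumerate(densities):
            n_pos = int(round(d))
            cells = [(rng.random() * 100, rng.random() * 100, {"cd3": j < n_pos}) for j in range(max(n_pos, 1))]
            cores.append(
                make_core(cells, area_um2=1.0e6, core_id=f"c{i}", patient_id=f"p{i}")
            )
        return cores

    def test_exact_linear_gives_r_one(self, rng):
        densities = [10, 20, 30, 40]
        cores = self._cores_with_density(rng, densities)
        scores = [
            MarkerScore(f"p{i}", "MHC1", float(d) * 2 + 1, "flow_frequency")
            for i, d in enumerate(densities)
        ]
        r, p, n = density_expression_correlation(cores, "CD3", scores)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_anti_linear_gives_r_minus_one(self, rng):
        densities = [10, 20, 30, 40]
        cores = self._cores_with_density(rng, densities)
        scores = [
            MarkerScore(f"p{i}", "MHC1", 100.0 - float(d), "flow_frequency")
            for i, d in enumerate(densities)
        ]
        r, _, _ = density_expression_correlation(cores, "CD3", scores)
        assert r == pytest.approx(-1.0)

    def test_too_few_points(self, rng):
        cores = self._cores_with_density(rng, [10, 20])
        scores = [MarkerScore(f"p{i}", "MHC1", 1.0 + i, "flow_frequency") for i in range(2)]
        with pytest.raises(ValidationError):
            density_expression_correlation(cores, "CD3", scores)

    def test_independent_scores_null_mean(self, rng):
        # r averaged over replicates of independent expression/density pairs
        rs = []
        for _ in range(200):
            densities = rng.integers(5, 50, size=12)
            cores = self._cores_with_density(rng, densities)
            scores = [
                MarkerScore(f"p{i}", "MHC1", float(rng.random() * 100), "flow_frequency")
                for i in range(12)
            ]
            r, _, _ = density_expression_correlation(cores, "CD3", scores)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
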