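import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from healthmrp.errors import (
    ConvergenceError,
    DataError,
    InfeasibleMarginsError,
    SchemaError,
)
from healthmrp.frame import (
    JointTable,
    MarginalTable,
    PostStratFrame,
    aggregate_imd,
    combine_blocks,
    estimate_joint_from_microdata,
    ipf_rake,
)
from healthmrp.schema import (
    Covariate,
    CovariateSchema,
    IMD_VARIABLE,
    default_schema,
    enumerate_cells,
)


_SCHEMA_2X2 = CovariateSchema(
    (Covariate("r", ("r0", "r1"), "r0"), Covariate("c", ("c0", "c1"), "c0"))
)


@pytest.fixture
def two_by_two():
    return _SCHEMA_2X2


class TestEstimateJoint:
    def test_relative_frequencies(self, toy_schema):
        records = pd.DataFrame({"a": ["a0", "a0", "a0", "a1"]})
        joint = estimate_joint_from_microdata(records, toy_schema, ["a"])
        assert np.allclose(joint.probs, [0.75, 0.25])

    def test_record_weights(self, toy_schema):
        records = pd.DataFrame({"a": ["a0", "a0", "a0", "a1"]})
        joint = estimate_joint_from_microdata(
            records, toy_schema, ["a"], record_weights=np.array([1, 1, 1, 3.0])
        )
        assert np.allclose(joint.probs, [0.5, 0.5])

    def test_unknown_level_names_record_and_variable(self, toy_schema):
        records = pd.DataFrame({"a": ["a0", "bogus"]})
        with pytest.raises(SchemaError, match="'a'"):
            estimate_joint_from_microdata(records, toy_schema, ["a"])

    def test_monte_carlo_recovers_known_joint(self, two_by_two):
        truth = np.array([[0.4, 0.1], [0.2, 0.3]])
        rng = np.random.default_rng(7)
        cells = rng.choice(4, size=1000, p=truth.reshape(-1))
        records = pd.DataFrame(
            {
                "r": np.array(["r0", "r0", "r1", "r1"])[cells],
                "c": np.array(["c0", "c1", "c0", "c1"])[cells],
            }
        )
        joint = estimate_joint_from_microdata(records, two_by_two, ["r", "c"])
        assert np.abs(joint.probs - truth).max() < 0.05

    def test_absent_combination_gets_zero(self, two_by_two):
        records = pd.DataFrame({"r": ["r0"], "c": ["c1"]})
        joint = estimate_joint_from_microdata(records, two_by_two, ["r", "c"])
        assert joint.probs[0, 1] == 1.0 and joint.probs.sum() == 1.0


class TestIpfRake:
    def _margins(self, schema, row, col):
        return [
            MarginalTable(schema, "r", np.asarray(row, dtype=float)),
            MarginalTable(schema, "c", np.asarray(col, dtype=float)),
        ]

    def test_independence_seed_converges_to_product(self, two_by_two):
        seed = JointTable(two_by_two, ("r", "c"), np.full((2, 2), 0.25))
        out = ipf_rake(seed, self._margins(two_by_two, (0.6, 0.4), (0.7, 0.3)))
        expected = np.outer([0.6, 0.4], [0.7, 0.3])
        assert np.abs(out.probs - expected).max() < 1e-10

    def test_feasible_seed_unchanged(self, two_by_two):
        probs = np.array([[0.4, 0.1], [0.1, 0.4]])
        seed = JointTable(two_by_two, ("r", "c"), probs)
        out = ipf_rake(seed, self._margins(two_by_two, (0.5, 0.5), (0.5, 0.5)))
        assert np.abs(out.probs - probs).max() < 1e-12

    def test_odds_ratio_preserved(self, two_by_two):
        seed = JointTable(two_by_two, ("r", "c"), np.array([[0.35, 0.15], [0.25, 0.25]]))
        out = ipf_rake(
            seed, self._margins(two_by_two, (0.6, 0.4), (0.5, 0.5)), tol=1e-12
        )
        p = out.probs
        assert np.isclose(p[0, 0] * p[1, 1] / (p[0, 1] * p[1, 0]), 0.35 * 0.25 / (0.15 * 0.25))
        assert np.abs(p.sum(axis=1) - (0.6, 0.4)).max() < 1e-10
        assert np.abs(p.sum(axis=0) - (0.5, 0.5)).max() < 1e-10

    def test_structural_zeros_preserved(self, two_by_two):
        seed = JointTable(two_by_two, ("r", "c"), np.array([[0.5, 0.0], [0.25, 0.25]]))
        out = ipf_rake(seed, self._margins(two_by_two, (0.4, 0.6), (0.5, 0.5)))
        assert out.probs[0, 1] == 0.0

    def test_infeasible_targets_raise(self, two_by_two):
        seed = JointTable(two_by_two, ("r", "c"), np.array([[0.5, 0.5], [0.0, 0.0]]))
        with pytest.raises(InfeasibleMarginsError):
            ipf_rake(seed, self._margins(two_by_two, (0.5, 0.5), (0.5, 0.5)))

    def test_nonconvergence_reports_deviation(self, two_by_two):
        # a diagonal seed forces row margin == col margin; ask for conflicting ones
        seed = JointTable(two_by_two, ("r", "c"), np.array([[0.5, 0.0], [0.0, 0.5]]))
        with pytest.raises(ConvergenceError, match="deviation"):
            ipf_rake(seed, self._margins(two_by_two, (0.9, 0.1), (0.1, 0.9)), max_iter=50)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cells=st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4),
        rm=st.floats(0.1, 0.9),
        cm=st.floats(0.1, 0.9),
    )
    def test_margins_match_and_odds_ratio_invariant(self, cells, rm, cm):
        two_by_two = _SCHEMA_2X2
        probs = np.array(cells).reshape(2, 2)
        probs = probs / probs.sum()
        seed = JointTable(two_by_two, ("r", "c"), probs)
        out = ipf_rake(
            seed, self._margins(two_by_two, (rm, 1 - rm), (cm, 1 - cm)), tol=1e-12
        )
        p = out.probs
        assert np.abs(p.sum(axis=1) - (rm, 1 - rm)).max() < 1e-10
        assert np.abs(p.sum(axis=0) - (cm, 1 - cm)).max() < 1e-10
        orig = probs[0, 0] * probs[1, 1] / (probs[0, 1] * probs[1, 0])
        new = p[0, 0] * p[1, 1] / (p[0, 1] * p[1, 0])
        assert np.isclose(orig, new, rtol=1e-8)


class TestAggregateImd:
    def _table(self, deciles, pops):
        return pd.DataFrame(
            {
                "lsoa_id": [f"L{i}" for i in range(len(deciles))],
                "imd_decile": deciles,
                "population": pops,
            }
        )

    def test_two_deciles_pool_into_first_quintile(self, schema11):
        out = aggregate_imd(self._table([1, 2], [100, 200]), schema11)
        assert np.allclose(out.proportions, [1.0, 0, 0, 0, 0])

    def test_equal_population_gives_uniform_quintiles(self, schema11):
        out = aggregate_imd(self._table(list(range(1, 11)), [50] * 10), schema11)
        assert np.allclose(out.proportions, [0.2] * 5)

    def test_concentrated_deciles_leave_extreme_quintiles_empty(self, schema11):
        rng = np.random.default_rng(3)
        deciles = rng.integers(3, 9, size=164)  # deciles 3..8 only
        out = aggregate_imd(self._table(deciles, rng.integers(500, 3000, 164)), schema11)
        # direct pooling oracle
        pops = self._table(deciles, np.ones(164))["population"]
        assert out.proportions[0] == 0.0 and out.proportions[4] == 0.0
        assert np.isclose(out.proportions.sum(), 1.0)

    def test_zero_population_rejected(self, schema11):
        with pytest.raises(DataError):
            aggregate_imd(self._table([1, 2], [0, 0]), schema11)

    def test_bad_decile_rejected(self, schema11):
        with pytest.raises(DataError):
            aggregate_imd(self._table([0, 11], [5, 5]), schema11)


class TestCombineBlocks:
    def test_two_binary_blocks(self, two_by_two):
        blocks = [
            JointTable(two_by_two, ("r",), np.array([0.3, 0.7])),
            JointTable(two_by_two, ("c",), np.array([0.5, 0.5])),
        ]
        frame = combine_blocks(blocks, two_by_two)
        assert np.allclose(frame.weights, [0.15, 0.15, 0.35, 0.35])

    def test_block_margins_recovered(self, toy_schema):
        rng = np.random.default_rng(5)
        ab = rng.random((2, 2))
        ab /= ab.sum()
        c = rng.random(3)
        c /= c.sum()
        frame = combine_blocks(
            [
                JointTable(toy_schema, ("a", "b"), ab),
                JointTable(toy_schema, ("c",), c),
            ],
            toy_schema,
        )
        assert np.abs(frame.joint(["a", "b"]).probs - ab).max() < 1e-12
        assert np.abs(frame.margin("c").proportions - c).max() < 1e-12

    def test_brute_force_product_enumeration(self, schema11):
        """Three-block frame equals the per-cell product loop."""
        rng = np.random.default_rng(11)
        from healthmrp.schema import RESIDENTS_BLOCK, LFS_BLOCK

        def rand_joint(variables):
            shape = tuple(schema11[v].n_levels for v in variables)
            p = rng.random(shape)
            return JointTable(schema11, tuple(variables), p / p.sum())

        res, lfs = rand_joint(RESIDENTS_BLOCK), rand_joint(LFS_BLOCK)
        imd = rng.random(5)
        imd_m = MarginalTable(schema11, IMD_VARIABLE, imd / imd.sum())
        frame = combine_blocks([res, lfs, imd_m], schema11)

        names = schema11.names
        res_pos = [names.index(v) for v in RESIDENTS_BLOCK]
        lfs_pos = [names.index(v) for v in LFS_BLOCK]
        imd_pos = names.index(IMD_VARIABLE)
        expected = np.empty(frame.cell_index.n_cells)
        for i, codes in enumerate(frame.cell_index.codes):
            expected[i] = (
                res.probs[tuple(codes[p] for p in res_pos)]
                * lfs.probs[tuple(codes[p] for p in lfs_pos)]
                * imd_m.proportions[codes[imd_pos]]
            )
        assert np.abs(frame.weights - expected).max() < 1e-12

    def test_overlapping_blocks_rejected(self, two_by_two):
        b = JointTable(two_by_two, ("r",), np.array([0.5, 0.5]))
        with pytest.raises(SchemaError, match="overlap"):
            combine_blocks([b, b], two_by_two)

    def test_missing_coverage_rejected(self, two_by_two):
        b = JointTable(two_by_two, ("r",), np.array([0.5, 0.5]))
        with pytest.raises(SchemaError, match="cover"):
            combine_blocks([b], two_by_two)


class TestPostStratFrame:
    def test_weights_validated(self, toy_schema):
        index = enumerate_cells(toy_schema)
        with pytest.raises(DataError):
            PostStratFrame(index, np.full(index.n_cells, 0.5))  # sums to 6

    def test_csv_roundtrip(self, tmp_path, toy_schema, make_random_frame):
        frame = make_random_frame(toy_schema, np.random.default_rng(2))
        path = tmp_path / "frame.csv"
        frame.to_csv(path)
        back = PostStratFrame.from_csv(path, toy_schema)
        assert np.array_equal(back.weights, frame.weights)
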