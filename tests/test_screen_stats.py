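"""Robust plate Z-scores, replicate aggregation, viability filter, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from asorpipe.errors import DegenerateDispersionError
from asorpipe.screen import (
    aggregate_and_rank,
    baseline_viability_z,
    robust_plate_z,
    run_screen_analysis,
)
from asorpipe.synth import QuenchModel, ScreenDesign, simulate_screen


def brute_force_z(values):
    """Two-pass median/MAD oracle with explicit sorting."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    med = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
    dev = sorted(abs(v - med) for v in vals)
    mad = dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2])
    return [(float(v) - med) / mad for v in values]


class TestRobustPlateZ:
    def test_printed_formula_direct_evaluation(self):
        z = robust_plate_z([1, 2, 3, 4, 100])
        assert np.allclose(z, [-2, -1, 0, 1, 97])

    def test_median_well_scores_zero(self):
        z = robust_plate_z([5.0, 7.0, 9.0, 11.0, 30.0])
        assert z[2] == 0.0

    def test_zero_mad_raises(self):
        with pytest.raises(DegenerateDispersionError):
            robust_plate_z([5.0, 5.0, 5.0, 5.0])

    def test_matches_brute_force_oracle_on_random_plates(self, rng):
        for _ in range(30):
            x = rng.normal(0, rng.uniform(0.1, 10), size=rng.integers(5, 400))
            assert np.allclose(robust_plate_z(x), brute_force_z(x), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 2**16),
    )
    def test_location_scale_invariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).normal(size=50)
        z = robust_plate_z(x)
        assert np.allclose(robust_plate_z(scale * x + shift), z, atol=1e-7)

    def test_standardization_median_zero_mad_one(self, rng):
        z = robust_plate_z(rng.normal(size=368))
        assert np.median(z) == pytest.approx(0.0, abs=1e-12)
        assert np.median(np.abs(z - np.median(z))) == pytest.approx(1.0, rel=1e-12)

    def test_scaled_variant_applies_consistency_factor(self, rng):
        x = rng.normal(size=101)
        assert np.allclose(robust_plate_z(x, scaled=True) * 1.4826022185056018,
                           robust_plate_z(x))


class TestBaselineViabilityZ:
    def test_direct_evaluation(self):
        z = baseline_viability_z([800.0, 950.0, 1000.0, 1050.0, 1200.0])
        assert np.allclose(z, [-4, -1, 0, 1, 4])

    def test_majority_equal_baselines_degenerate(self):
        # MAD of {100,0,0,0,100} is 0: at least half the wells must vary
        with pytest.raises(DegenerateDispersionError):
            baseline_viability_z([900.0, 1000.0, 1000.0, 1000.0, 1100.0])


def make_scores(rows):
    return pd.DataFrame(rows, columns=["gene_id", "replicate", "z", "baseline_z"])


class TestAggregateAndRank:
    def test_median_of_replicates_and_top_rank(self):
        rows = [("HIT", r, z, 0.0) for r, z in zip([1, 2, 3], [8, 7, 9])]
        rows += [("DULL", r, z, 0.0) for r, z in zip([1, 2, 3], [0.1, -0.2, 0.0])]
        table = aggregate_and_rank(make_scores(rows))
        hit = table[table.gene_id == "HIT"].iloc[0]
        assert hit.median_z == 8.0
        assert hit["rank"] == 1

    def test_viability_filter_excludes_low_baseline(self):
        rows = [("G1", r, 10.0, -0.6) for r in (1, 2, 3)]
        rows += [("G2", r, 0.0, 0.0) for r in (1, 2, 3)]
        table = aggregate_and_rank(make_scores(rows))
        g1 = table[table.gene_id == "G1"].iloc[0]
        assert not g1.viable and pd.isna(g1["rank"])
        assert table[table.gene_id == "G2"].iloc[0]["rank"] == 1

    def test_threshold_is_strict_less_than(self):
        rows = [("EDGE", r, 1.0, -0.5) for r in (1, 2, 3)]
        table = aggregate_and_rank(make_scores(rows))
        assert table.iloc[0].viable  # exactly -0.5 is kept

    def test_single_viable_gene_gets_rank_one(self):
        table = aggregate_and_rank(make_scores([("ONLY", 1, 1.0, 0.0),
                                                ("ONLY", 2, 1.2, 0.0)]))
        assert table.iloc[0]["rank"] == 1

    def test_min_replicates_required(self):
        rows = [("SPARSE", 1, 5.0, 0.0),
                ("SPARSE", 2, np.nan, 0.0), ("SPARSE", 3, np.nan, 0.0)]
        rows += [("FULL", r, 0.0, 0.0) for r in (1, 2, 3)]
        table = aggregate_and_rank(make_scores(rows))
        assert not table[table.gene_id == "SPARSE"].iloc[0].viable

    def test_ties_break_lexicographically(self):
        rows = [(g, r, 1.0, 0.0) for g in ("B", "A", "C") for r in (1, 2, 3)]
        table = aggregate_and_rank(make_scores(rows))
        assert list(table.sort_values("rank").gene_id) == ["A", "B", "C"]

    def test_direction_parameter_flips_order(self):
        rows = [("UP", r, 5.0, 0.0) for r in (1, 2, 3)]
        rows += [("DOWN", r, -5.0, 0.0) for r in (1, 2, 3)]
        loss = aggregate_and_rank(make_scores(rows), direction="loss_of_signal")
        gain = aggregate_and_rank(make_scores(rows), direction="gain_of_signal")
        assert loss[loss.gene_id == "UP"].iloc[0]["rank"] == 1
        assert gain[gain.gene_id == "DOWN"].iloc[0]["rank"] == 1

    def test_ranks_are_permutation_of_viable(self, rng):
        rows = []
        for g in range(40):
            for r in (1, 2, 3):
                rows.append((f"G{g:02d}", r, rng.normal(), rng.normal()))
        table = aggregate_and_rank(make_scores(rows))
        ranks = table.loc[table.viable, "rank"].astype(int).to_numpy()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))


class TestEndToEnd:
    def test_planted_hit_ranks_first(self, small_screen):
        _, data, _ = small_screen
        res = run_screen_analysis(data)
        assert res.rank_of("GENE42") == 1

    def test_filter_matches_direct_recomputation(self, small_screen):
        _, data, _ = small_screen
        res = run_screen_analysis(data)
        table = res.gene_table
        expected_filtered = set(
            table.loc[table.median_baseline_z < -0.5, "gene_id"]
        )
        unranked = set(table.loc[table["rank"].isna(), "gene_id"])
        # with 3 complete replicates the only exclusion route is the filter
        assert (table.n_valid == 3).all()
        assert unranked == expected_filtered

    def test_plate_standardization_holds_on_fit(self, small_screen):
        _, data, _ = small_screen
        res = run_screen_analysis(data)
        wt = res.well_table
        for (_, _), grp in wt.groupby(["replicate", "plate"]):
            z = grp.loc[grp.well_type == "candidate", "z"].dropna()
            assert np.median(z) == pytest.approx(0.0, abs=1e-9)
            assert np.median(np.abs(z)) == pytest.approx(1.0, rel=1e-9)

    def test_null_screen_candidate_scores_exchangeable(self):
        design = ScreenDesign(n_genes=300, seed=3)
        data, _ = simulate_screen(design, QuenchModel(), None, seed=11)
        res = run_screen_analysis(data)
        z = res.well_table.query("well_type == 'candidate'").z.dropna().to_numpy()
        half = len(z) // 2
        assert ks_2samp(z[:half], z[half:]).pvalue > 0.01

    def test_rerun_is_deterministic(self, small_screen):
        _, data, _ = small_screen
        a = run_screen_analysis(data).gene_table
        b = run_screen_analysis(data).gene_table
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_null_plate_is_flagged_degenerate(self):
        design = ScreenDesign(n_genes=100, seed=5)
        model = QuenchModel(noise_cv=0.0, well_gain_sd=0.0, plate_shift_sd=0.0)
        data, _ = simulate_screen(design, model, None, seed=5)
        res = run_screen_analysis(data)
        assert res.plate_qc.degenerate.all()
        assert res.well_table.z.isna().all()
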