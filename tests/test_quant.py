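"""QC filters, greedy matching (vs brute-force oracle), contact calls,
summaries and binning."""

import numpy as np
import pandas as pd
import pytest

import loopquant as lq
from loopquant import quant
from tests.conftest import run_quant


def nuc_row(nucleus_id=0, area=100.0, solidity=0.95, condition="c"):
    return {"nucleus_id": nucleus_id, "field_id": "F0",
            "condition": condition, "area_um2": area, "solidity": solidity,
            "gfp_mean": 1000.0}


class TestQCFilter:
    @pytest.mark.parametrize("area,solidity,kept", [
        (100.0, 0.95, True),    # passes both U2OS thresholds
        (89.9, 0.95, False),    # just under the 90 um^2 area floor
        (100.0, 0.89, False),   # solidity below 0.9
        (90.0, 0.9, True),      # boundary values are kept (>= comparisons)
    ])
    def test_thresholds(self, area, solidity, kept, analysis_config):
        nuclei = pd.DataFrame([nuc_row(area=area, solidity=solidity)])
        out, report = quant.qc_filter_nuclei(nuclei, analysis_config)
        assert (len(out) == 1) is kept
        assert report.n_input == 1 and report.n_kept == int(kept)

    def test_rejection_report_counts_criteria(self, analysis_config):
        nuclei = pd.DataFrame([
            nuc_row(0, 50.0, 0.95), nuc_row(1, 100.0, 0.5),
            nuc_row(2, 50.0, 0.5), nuc_row(3, 120.0, 0.99),
        ])
        _, report = quant.qc_filter_nuclei(nuclei, analysis_config)
        assert report.rejected == {"area": 1, "solidity": 1, "both": 1}

    def test_empty_input_empty_output(self, analysis_config):
        nuclei = pd.DataFrame(columns=list(nuc_row().keys()))
        out, report = quant.qc_filter_nuclei(nuclei, analysis_config)
        assert len(out) == 0 and report.n_input == 0

    def test_hela_threshold_configurable(self):
        cfg = lq.AnalysisConfig(min_area=50.0, ploidy=3)
        nuclei = pd.DataFrame([nuc_row(area=60.0)])
        out, _ = quant.qc_filter_nuclei(nuclei, cfg)
        assert len(out) == 1


def spot_rows(nucleus_id, channel, coords):
    return [{"nucleus_id": nucleus_id, "channel": channel,
             "x_um": x, "y_um": y, "intensity": 100.0} for x, y in coords]


class TestPloidyFilter:
    def make(self, counts_a, counts_b):
        nuclei = pd.DataFrame([nuc_row(0)])
        spots = pd.DataFrame(
            spot_rows(0, "dna_a", [(0.0, 0.0)] * counts_a)
            + spot_rows(0, "dna_b", [(1.0, 1.0)] * counts_b))
        return nuclei, spots

    @pytest.mark.parametrize("ploidy,ca,cb,kept", [
        (2, 2, 2, True),   # diploid, correct counts
        (2, 2, 3, False),  # extra spot in one channel
        (2, 1, 2, False),  # dropout in one channel
        (3, 3, 3, True),   # triploid, correct counts
    ])
    def test_spot_count_rule(self, ploidy, ca, cb, kept):
        cfg = lq.AnalysisConfig(ploidy=ploidy)
        nuclei, spots = self.make(ca, cb)
        out, _ = quant.ploidy_filter(nuclei, spots, cfg)
        assert (len(out) == 1) is kept

    def test_nucleus_with_no_spots_rejected(self, analysis_config):
        nuclei = pd.DataFrame([nuc_row(0), nuc_row(1)])
        spots = pd.DataFrame(spot_rows(0, "dna_a", [(0, 0), (1, 1)])
                             + spot_rows(0, "dna_b", [(0, 0), (1, 1)]))
        out, report = quant.ploidy_filter(nuclei, spots, analysis_config)
        assert list(out["nucleus_id"]) == [0]
        assert report.rejected["spot_count"] == 1

    def test_rna_spots_do_not_count(self, analysis_config):
        nuclei, spots = self.make(2, 2)
        spots = pd.concat([spots, pd.DataFrame(
            spot_rows(0, "rna", [(0, 0)] * 5))], ignore_index=True)
        out, _ = quant.ploidy_filter(nuclei, spots, analysis_config)
        assert len(out) == 1


def greedy_oracle(dist, cap):
    """Independent greedy reference: full-matrix scan, delete row/col."""
    d = np.array(dist, dtype=float)
    rows = list(range(d.shape[0]))
    cols = list(range(d.shape[1]))
    out = []
    while d.size:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        out.append((rows[i], cols[j], d[i, j]))
        d = np.delete(np.delete(d, i, axis=0), j, axis=1)
        rows.pop(i)
        cols.pop(j)
    return [(i, j, v) for i, j, v in out if v < cap]


class TestMatchSpots:
    def test_single_pair_contact(self, analysis_config):
        d = quant.match_spots([[0, 0]], [[0.1, 0]], analysis_config)
        assert d == pytest.approx([0.1])

    def test_cap_discards_far_pair(self, analysis_config):
        d = quant.match_spots([[0, 0], [5, 5]], [[0.1, 0], [5, 7.5]],
                              analysis_config)
        assert len(d) == 1 and d[0] == pytest.approx(0.1)

    def test_greedy_picks_global_minimum(self, analysis_config):
        d = quant.match_spots([[0, 0], [0.2, 0]], [[0.1, 0]], analysis_config)
        assert d == pytest.approx([0.1])

    def test_empty_channel_gives_no_pairs(self, analysis_config):
        assert len(quant.match_spots(np.empty((0, 2)), [[1, 1]],
                                     analysis_config)) == 0

    def test_agrees_with_bruteforce_oracle(self, analysis_config, rng):
        for _ in range(200):
            na, nb = rng.integers(1, 5, size=2)
            a = rng.uniform(0, 3, size=(na, 2))
            b = rng.uniform(0, 3, size=(nb, 2))
            got = np.sort(quant.match_spots(a, b, analysis_config))
            from scipy.spatial.distance import cdist
            want = np.sort([v for _, _, v in
                            greedy_oracle(cdist(a, b),
                                          analysis_config.max_pair_distance)])
            np.testing.assert_allclose(got, want)

    def test_never_reuses_a_spot(self, analysis_config, rng):
        a = rng.uniform(0, 1, size=(4, 2))
        b = rng.uniform(0, 1, size=(3, 2))
        d = quant.match_spots(a, b, analysis_config)
        assert len(d) <= 3

    def test_per_spot_min_mode(self):
        cfg = lq.AnalysisConfig(match_mode="per_spot_min")
        d = quant.match_spots([[0, 0], [0.2, 0]], [[0.1, 0]], cfg)
        np.testing.assert_allclose(np.sort(d), [0.1, 0.1])


class TestCallContacts:
    def make_pairs(self, distances):
        return pd.DataFrame({"nucleus_id": range(len(distances)),
                             "distance_um": distances})

    def test_strict_threshold(self, analysis_config):
        out = quant.call_contacts(self.make_pairs([0.27, 0.26, 0.28]),
                                  analysis_config)
        assert list(out["is_contact"]) == [False, True, False]

    def test_larger_threshold_gives_superset(self):
        pairs = self.make_pairs(np.linspace(0.01, 1.9, 50))
        narrow = quant.call_contacts(pairs, lq.AnalysisConfig(
            contact_threshold=0.27))
        wide = quant.call_contacts(pairs, lq.AnalysisConfig(
            contact_threshold=0.4))
        assert set(np.where(narrow["is_contact"])[0]) <= \
            set(np.where(wide["is_contact"])[0])

    def test_between_condition_difference_threshold_stable(self):
        """A true looping effect keeps its sign at thresholds 0.2/0.27/0.35."""
        results = {}
        for thr in (0.2, 0.27, 0.35):
            cfg = lq.AnalysisConfig(ploidy=2, contact_threshold=thr)
            fr = {}
            for label, p_loop in (("dark", 0.05), ("light", 0.3)):
                sim = lq.SimulationConfig(n_cells=800, p_loop=p_loop, seed=13)
                nuclei, spots, _ = lq.generate_fish_dataset(sim,
                                                            condition=label)
                _, pairs, _ = run_quant(nuclei, spots, cfg)
                fr[label] = quant.condition_contact_fraction(pairs) \
                    .set_index("condition")["fraction"][label]
            results[thr] = fr["light"] - fr["dark"]
        assert all(v > 0 for v in results.values())


class TestSummarizeCells:
    def test_fraction_and_rna_metrics(self):
        nuclei = pd.DataFrame([nuc_row(0), nuc_row(1)])
        pairs = pd.DataFrame({
            "nucleus_id": [0, 0], "distance_um": [0.1, 0.5],
            "is_contact": [True, False],
        })
        rna = pd.DataFrame(spot_rows(0, "rna", [(0, 0)] * 3))
        rna["intensity"] = [10.0, 20.0, 30.0]
        cells = quant.summarize_cells(nuclei, pairs, rna)
        c0 = cells.set_index("nucleus_id").loc[0]
        assert c0["fraction_close"] == pytest.approx(0.5)
        assert c0["rna_spot_count"] == 3
        assert c0["rna_total_intensity"] == pytest.approx(60.0)
        assert c0["rna_mean_intensity"] == pytest.approx(20.0)
        # nucleus 1 has no pairs: excluded from contact analyses via NaN
        assert np.isnan(cells.set_index("nucleus_id").loc[1, "fraction_close"])

    def test_total_at_least_mean_when_spots_present(self, clean_dataset,
                                                    analysis_config):
        (nuclei, spots, _), _ = clean_dataset
        _, _, cells = run_quant(nuclei, spots, analysis_config)
        has = cells["rna_spot_count"] >= 1
        assert (cells.loc[has, "rna_total_intensity"]
                >= cells.loc[has, "rna_mean_intensity"] - 1e-9).all()

    def test_idempotent_pipeline_order(self, clean_dataset, analysis_config):
        """Re-filtering already filtered tables changes nothing."""
        (nuclei, spots, _), _ = clean_dataset
        kept1, _ = quant.qc_filter_nuclei(nuclei, analysis_config)
        kept1, _ = quant.ploidy_filter(kept1, spots, analysis_config)
        kept2, _ = quant.qc_filter_nuclei(kept1, analysis_config)
        kept2, _ = quant.ploidy_filter(kept2, spots, analysis_config)
        pd.testing.assert_frame_equal(kept1, kept2)


class TestBinCells:
    def test_equal_count_bins_all_distinct(self):
        cells = pd.DataFrame({"gfp_intensity": np.arange(100.0),
                              "fraction_close": np.linspace(0.01, 1, 100)})
        out = quant.bin_cells(cells, by="gfp_intensity", n_bins=4)
        assert out["gfp_intensity_bin"].value_counts().tolist() == [25] * 4

    def test_zero_fraction_cells_form_their_own_bin(self):
        cells = pd.DataFrame({"fraction_close": [0, 0, 0, 0.5, 0.5, 1.0]})
        out = quant.bin_cells(cells, by="fraction_close", n_bins=3)
        zero_bin = out[out["fraction_close_bin"] == "0"]
        assert len(zero_bin) == 3
        assert (zero_bin["fraction_close"] == 0).all()

    def test_constant_variable_single_bin_with_warning(self):
        cells = pd.DataFrame({"gfp_intensity": [5.0] * 10,
                              "fraction_close": [0.5] * 10})
        with pytest.warns(UserWarning, match="constant"):
            out = quant.bin_cells(cells, by="gfp_intensity", n_bins=4)
        assert out["gfp_intensity_bin"].nunique() == 1

    def test_nan_fraction_gets_no_bin(self):
        cells = pd.DataFrame({"fraction_close": [np.nan, 0.0, 0.5, 1.0]})
        out = quant.bin_cells(cells, by="fraction_close", n_bins=3)
        assert pd.isna(out.loc[0, "fraction_close_bin"])

    def test_invalid_variable_rejected(self):
        with pytest.raises(ValueError, match="bin variable"):
            quant.bin_cells(pd.DataFrame({"x": [1]}), by="x")


class TestConditionAggregates:
    def test_contact_fraction_counts(self):
        pairs = pd.DataFrame({
            "condition": ["c"] * 100,
            "is_contact": [True] * 15 + [False] * 85,
            "distance_um": np.linspace(0.01, 1.0, 100),
        })
        out = lq.condition_contact_fraction(pairs)
        assert out.loc[0, "fraction"] == pytest.approx(0.15)
        assert out.loc[0, "n_alleles"] == 100

    def test_median_distance_conventions(self):
        pairs = pd.DataFrame({
            "condition": ["a"] * 3 + ["b"] * 2,
            "distance_um": [0.1, 0.5, 0.9, 0.2, 0.4],
            "is_contact": [True, False, False, True, False],
        })
        out = lq.median_pair_distance(pairs).set_index("condition")
        assert out.loc["a", "median_um"] == pytest.approx(0.5)
        assert out.loc["b", "median_um"] == pytest.approx(0.3)

    def test_free_only_median_matches_rayleigh_closed_form(self):
        """Pure free-law data: median distance ~ sigma*sqrt(2 ln 2)."""
        sigma = 0.6
        cfg = lq.SimulationConfig(n_cells=4000, p_loop=0.0, seed=17)
        nuclei, spots, _ = lq.generate_fish_dataset(cfg, condition="free")
        _, pairs, _ = run_quant(nuclei, spots, lq.AnalysisConfig(ploidy=2))
        med = lq.median_pair_distance(pairs).loc[0, "median_um"]
        expected = sigma * np.sqrt(2 * np.log(2))
        assert med == pytest.approx(expected, rel=0.03)

    def test_normalize_to_control(self):
        vals = pd.Series([1.0, 2.0, 3.0, 6.0])
        conds = pd.Series(["ctrl", "ctrl", "t", "t"])
        out = quant.normalize_to_control(vals, conds, "ctrl")
        np.testing.assert_allclose(out, [2 / 3, 4 / 3, 2.0, 4.0])
        with pytest.raises(ValueError, match="missing"):
            quant.normalize_to_control(vals, conds, "missing")
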