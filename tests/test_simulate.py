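"""Synthetic-data generator: dilution series, layouts, latent curves, phantoms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdgbo import simulate as sim

from conftest import PRINTED_SERIES_M


class TestDilutionSeries:
    def test_printed_seven_point_fourfold_series(self, dilution_series):
        # 3 significant figures, as printed in the assay description
        for got, want in zip(dilution_series, PRINTED_SERIES_M):
            assert got == pytest.approx(want, rel=2e-3)

    @pytest.mark.parametrize(
        "args, expected",
        [((10.0, 2.0, 4), [10, 5, 2.5, 1.25]), ((7e-6, 3.0, 1), [7e-6])],
    )
    def test_small_series(self, args, expected):
        assert sim.make_dilution_series(*args) == pytest.approx(expected)

    @given(
        top=st.floats(1e-9, 1e-3),
        fold=st.floats(1.5, 10),
        n=st.integers(1, 12),
    )
    @settings(max_examples=50, deadline=None)
    def test_series_is_exactly_geometric(self, top, fold, n):
        s = sim.make_dilution_series(top, fold, n)
        assert len(s) == n
        assert np.all(np.diff(s) <= 0)
        ratios = s[1:] / s[:-1]
        assert ratios == pytest.approx(np.full(n - 1, 1.0 / fold), rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 4, 7), (1e-5, 1.0, 7), (1e-5, 4, 0),
                                     (np.inf, 4, 7)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.make_dilution_series(*bad)


class TestPlateLayout:
    def test_full_screen_splits_across_two_plates(self, dilution_series):
        # 41 drugs x 7 x 2 = 574 wells exceed one 384-well plate
        layout = sim.make_plate_layout(41, dilution_series, 2)
        assert (layout["role"] == "drug").sum() == 574
        assert layout["plate_id"].nunique() == 2
        with pytest.raises(ValueError, match="multi-plate"):
            sim.make_plate_layout(41, dilution_series, 2, allow_multi_plate=False)

    def test_twenty_seven_drugs_fit_one_plate_with_six_controls(
        self, dilution_series
    ):
        layout = sim.make_plate_layout(
            27, dilution_series, 2, n_vehicle=6, positive_control=False
        )
        assert layout["plate_id"].nunique() == 1
        assert (layout["role"] == "drug").sum() == 378
        assert (layout["role"] == "vehicle").sum() == 6

    def test_every_drug_at_every_concentration_in_duplicate(self, dilution_series):
        layout = sim.make_plate_layout(5, dilution_series, 2)
        drugs = layout[layout["role"] == "drug"]
        counts = drugs.groupby(["drug_id", "concentration_M"]).size()
        assert (counts == 2).all()
        assert drugs["drug_id"].nunique() == 5
        assert (layout["role"] == "vehicle").sum() >= 8
        assert (layout["role"] == "positive_control").sum() == 14
        assert set(layout.loc[layout["role"] == "positive_control", "drug_id"]) == {
            "bortezomib"
        }

    def test_well_addresses_unique_within_plate(self, dilution_series):
        layout = sim.make_plate_layout(41, dilution_series, 2)
        assert not layout.duplicated(subset=["plate_id", "well"]).any()

    def test_oversized_single_series_rejected(self):
        series = sim.make_dilution_series(3e-5, 1.5, 200)
        with pytest.raises(ValueError, match="exceeds"):
            sim.make_plate_layout(1, series, 2)


class TestSimulateViability:
    def test_noiseless_readouts_reproduce_the_4pl_exactly(self, dilution_series):
        layout = sim.make_plate_layout(3, dilution_series, 2)
        drugs = {
            "drug_01": sim.DrugTruth(top=1.0, bottom=0.0, ic50=1e-6, hill=1.0),
            "drug_02": sim.DrugTruth(top=1.0, bottom=0.2, ic50=5e-7, hill=2.0),
            "drug_03": sim.DrugTruth(),
            "bortezomib": sim.DrugTruth(top=1.0, bottom=0.0, ic50=1e-7, hill=1.2),
        }
        truth = sim.ScreenTruth(drugs=drugs, sigma=0.0, plate_sigma=0.0, seed=0)
        out = layout.merge(sim.simulate_viability(layout, truth), on=["plate_id", "well"])
        veh = out.loc[out["role"] == "vehicle", "readout"]
        assert veh.to_numpy() == pytest.approx(truth.baseline)
        for _, row in out[out["role"] == "drug"].iterrows():
            t = drugs[row["drug_id"]]
            expected = truth.baseline * sim.four_pl(
                row["concentration_M"], t.top, t.bottom, t.ic50, t.hill
            )
            assert row["readout"] == pytest.approx(expected, rel=1e-12)

    def test_midpoint_and_limits_of_the_4pl(self):
        assert sim.four_pl(1e-6, 1.0, 0.0, 1e-6, 1.0) == pytest.approx(0.5)
        assert sim.four_pl(1e-12, 1.0, 0.0, 1e-6, 1.0) == pytest.approx(1.0, abs=1e-5)
        assert sim.four_pl(1.0, 1.0, 0.0, 1e-6, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_seed_reproducibility(self, dilution_series):
        layout = sim.make_plate_layout(4, dilution_series, 2)
        truth = sim.make_screen_truth(4, sigma=0.1, seed=11)
        a = sim.simulate_viability(layout, truth)
        b = sim.simulate_viability(layout, truth)
        pd.testing.assert_frame_equal(a, b)
        c = sim.simulate_viability(layout, truth, seed=99)
        assert not np.allclose(a["readout"], c["readout"])

    def test_missing_truth_entry_raises(self, dilution_series):
        layout = sim.make_plate_layout(2, dilution_series, 1)
        truth = sim.ScreenTruth(drugs={"drug_01": sim.DrugTruth()})
        with pytest.raises(KeyError):
            sim.simulate_viability(layout, truth)


class TestImagePhantom:
    def test_truth_mask_areas_match_analytic_counts(self):
        truth = sim.make_image_truth(n_cells=6, seed=3)
        analytic_nuclei = sum(np.pi * r**2 for r in truth.radii)
        assert truth.nuclei_mask().sum() == pytest.approx(analytic_nuclei, rel=0.05)

    def test_empty_phantom_renders_background_only(self):
        truth = sim.ImageTruth(
            centers=np.zeros((0, 2)),
            radii=np.zeros(0),
            adjacency=[],
            viability=np.zeros(0),
            shape=(64, 64, 3),
        )
        imgs = sim.render_organoid_images(truth, seed=0, read_noise_sd=0.0)
        mip = imgs.mip("calcein").astype(float)
        assert np.ptp(mip) == 0

    def test_adjacency_symmetric_no_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            sim.ImageTruth(
                centers=[[10, 10], [30, 30]],
                radii=[5, 5],
                adjacency=[(0, 0)],
                viability=[1, 1],
                shape=(64, 64, 3),
            )
        truth = sim.make_image_truth(n_cells=8, seed=1)
        for i, j in truth.adjacency:
            assert i < j and i != j

    def test_centers_must_lie_inside_image(self):
        with pytest.raises(ValueError, match="inside"):
            sim.ImageTruth(
                centers=[[100, 10]],
                radii=[5],
                adjacency=[],
                viability=[1],
                shape=(64, 64, 3),
            )


class TestCalciumPhantom:
    def test_nonparticipating_cell_noiseless_trace_is_flat(self):
        truth = sim.CalciumTruth(
            event_times=[np.array([])],
            participating=np.array([False]),
            noise_sd=0.0,
        )
        tr = sim.simulate_calcium_traces(truth, seed=0)
        assert np.ptp(tr["cell_0"].to_numpy()) == 0

    def test_single_event_noiseless_peak_at_event_frame(self):
        truth = sim.CalciumTruth(
            event_times=[np.array([100.0])],
            participating=np.array([True]),
            noise_sd=0.0,
        )
        tr = sim.simulate_calcium_traces(truth, seed=0)
        peak_frame = int(tr["cell_0"].to_numpy().argmax())
        assert abs(peak_frame - 100.0 / 1.52) <= 1

    def test_connected_cells_share_event_times_without_jitter(self):
        truth = sim.make_calcium_truth(
            n_cells=4, adjacency=[(0, 1)], jitter_frames=0.0,
            participating_fraction=1.0, seed=5,
        )
        assert np.allclose(truth.event_times[0], truth.event_times[1])

    def test_events_respect_duration_and_participation(self):
        truth = sim.make_calcium_truth(n_cells=10, seed=2)
        for flag, times in zip(truth.participating, truth.event_times):
            if not flag:
                assert times.size == 0
            if times.size:
                assert times.min() >= 0 and times.max() <= truth.duration

    def test_duration_shorter_than_frame_rejected(self):
        with pytest.raises(ValueError):
            sim.CalciumTruth(
                event_times=[np.array([])],
                participating=np.array([False]),
                duration=1.0,
                frame_interval=1.52,
            )


class TestExpressionPhantom:
    def test_null_effects_leave_samples_exchangeable(self, small_gene_sets):
        truth = sim.make_expression_truth(small_gene_sets, n_samples=6, seed=0)
        truth.pathway_effects = {
            p: np.zeros(6) for p in ("NEG_1", "POS_1")
        }
        expr, resp = sim.simulate_expression(truth, small_gene_sets, seed=1)
        # no planted signal: per-sample means agree within noise
        sample_means = expr.mean(axis=0)
        assert sample_means.std() < 0.2

    def test_planted_pathway_shift_raises_member_genes(self, small_gene_sets):
        truth = sim.make_expression_truth(small_gene_sets, n_samples=4, seed=0)
        effect = np.array([3.0, 0.0, 0.0, 0.0])
        truth.pathway_effects = {"POS_1": effect}
        truth.drug_links = {"d1": {"POS_1": 1.0}}
        expr, resp = sim.simulate_expression(truth, small_gene_sets, seed=1)
        members = small_gene_sets["POS_1"]
        others = [g for g in expr.index if g not in members]
        delta = expr.loc[members, "S01"].mean() - expr.loc[others, "S01"].mean()
        assert delta == pytest.approx(3.0, abs=0.7)
        # linked drug response shifts with the effect
        assert resp.loc["d1", "S01"] > resp.loc["d1", "S02"]

    def test_unknown_planted_pathway_rejected(self, small_gene_sets):
        with pytest.raises(KeyError):
            sim.make_expression_truth(
                small_gene_sets, n_samples=4, pos_pathways=["NOT_A_PATHWAY"]
            )
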