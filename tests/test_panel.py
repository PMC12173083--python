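"""Three-step panel normalisation against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from chronotox.cohort import PanelLaneTruth, generate_panel_counts
from chronotox.panel import (
    PanelCountMatrix,
    housekeeping_normalise,
    log2_transform,
    negative_control_subtract,
    normalise_panel,
    positive_control_scale,
)


def make_matrix(counts: dict, classes: dict) -> PanelCountMatrix:
    frame = pd.DataFrame(counts).T  # rows = lanes
    return PanelCountMatrix(frame, pd.Series(classes))


@pytest.fixture
def two_lane():
    # positive means: L1 = 100, L2 = 200 -> reference 150
    counts = {
        "L1": {"pos1": 90.0, "pos2": 110.0, "neg1": 20.0, "hk1": 400.0, "g1": 100.0},
        "L2": {"pos1": 190.0, "pos2": 210.0, "neg1": 10.0, "hk1": 360.0, "g1": 50.0},
    }
    classes = {
        "pos1": "positive", "pos2": "positive", "neg1": "negative",
        "hk1": "housekeeping", "g1": "endogenous",
    }
    return make_matrix(counts, classes)


class TestPositiveControlScale:
    def test_identical_lanes_unchanged(self):
        m = make_matrix(
            {
                "L1": {"p": 100.0, "n": 5.0, "h": 50.0, "g": 20.0},
                "L2": {"p": 100.0, "n": 7.0, "h": 60.0, "g": 30.0},
            },
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out, factors = positive_control_scale(m)
        assert np.allclose(factors, 1.0)
        assert out.counts.equals(m.counts)

    def test_double_mean_gets_half_factor(self, two_lane):
        # L2 positive mean is 200 vs reference 150 -> factor 0.75; check formula
        _, factors = positive_control_scale(two_lane)
        assert factors["L1"] == pytest.approx(150.0 / 100.0)
        assert factors["L2"] == pytest.approx(150.0 / 200.0)

    def test_hand_computed_two_lane_oracle(self, two_lane):
        out, factors = positive_control_scale(two_lane)
        for lane in ("L1", "L2"):
            for probe in two_lane.counts.columns:
                assert out.counts.loc[lane, probe] == pytest.approx(
                    two_lane.counts.loc[lane, probe] * factors[lane]
                )

    def test_zero_positive_mean_lane_flagged(self):
        m = make_matrix(
            {
                "L1": {"p": 0.0, "n": 1.0, "h": 10.0, "g": 5.0},
                "L2": {"p": 100.0, "n": 1.0, "h": 10.0, "g": 5.0},
            },
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        with pytest.warns(UserWarning):
            out, factors = positive_control_scale(m)
        assert "L1" in out.flagged_lanes
        assert np.isnan(factors["L1"])


class TestNegativeControlSubtract:
    def test_background_subtracted(self):
        m = make_matrix(
            {"L1": {"p": 50.0, "n": 20.0, "h": 120.0, "g": 100.0}},
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out = negative_control_subtract(m)
        assert out.counts.loc["L1", "g"] == pytest.approx(80.0)
        assert out.counts.loc["L1", "n"] == pytest.approx(20.0)  # negatives untouched

    def test_floor_rule(self):
        m = make_matrix(
            {"L1": {"p": 50.0, "n": 20.0, "h": 120.0, "g": 10.0}},
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out = negative_control_subtract(m)
        assert out.counts.loc["L1", "g"] == pytest.approx(1.0)

    def test_zero_background_is_identity(self):
        m = make_matrix(
            {"L1": {"p": 50.0, "n": 0.0, "h": 120.0, "g": 100.0}},
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out = negative_control_subtract(m)
        assert out.counts.equals(m.counts)


class TestHousekeepingNormalise:
    def test_identical_housekeeping_factors_one(self):
        m = make_matrix(
            {
                "L1": {"p": 10.0, "n": 1.0, "h1": 4.0, "h2": 16.0, "g": 5.0},
                "L2": {"p": 10.0, "n": 1.0, "h1": 4.0, "h2": 16.0, "g": 9.0},
            },
            {"p": "positive", "n": "negative", "h1": "housekeeping",
             "h2": "housekeeping", "g": "endogenous"},
        )
        _, factors = housekeeping_normalise(m)
        assert np.allclose(factors, 1.0)

    def test_geomean_arithmetic(self):
        # L1 geomean sqrt(4*16) = 8, L2 geomean 16 -> reference 12
        m = make_matrix(
            {
                "L1": {"p": 10.0, "n": 1.0, "h1": 4.0, "h2": 16.0, "g": 5.0},
                "L2": {"p": 10.0, "n": 1.0, "h1": 16.0, "h2": 16.0, "g": 9.0},
            },
            {"p": "positive", "n": "negative", "h1": "housekeeping",
             "h2": "housekeeping", "g": "endogenous"},
        )
        _, factors = housekeeping_normalise(m)
        assert factors["L1"] == pytest.approx(12.0 / 8.0)
        assert factors["L2"] == pytest.approx(12.0 / 16.0)

    def test_housekeeping_geomeans_agree_after_step(self, two_lane):
        out, _ = housekeeping_normalise(two_lane)
        hk = out.counts[["hk1"]]
        geo = np.exp(np.log(hk).mean(axis=1))
        assert geo["L1"] == pytest.approx(geo["L2"], rel=1e-9)


class TestLog2Transform:
    def test_floor_one_maps_to_zero(self):
        m = make_matrix(
            {"L1": {"p": 1.0, "n": 1.0, "h": 1.0, "g": 1.0}},
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out = log2_transform(m, pseudo=0.0)
        assert np.allclose(out.counts, 0.0)

    def test_pseudo_count(self):
        m = make_matrix(
            {"L1": {"p": 7.0, "n": 7.0, "h": 7.0, "g": 7.0}},
            {"p": "positive", "n": "negative", "h": "housekeeping", "g": "endogenous"},
        )
        out = log2_transform(m, pseudo=1.0)
        assert np.allclose(out.counts, 3.0)

    def test_monotone(self, two_lane):
        out = log2_transform(two_lane, pseudo=1.0)
        raw = two_lane.counts.to_numpy().ravel()
        trans = out.counts.to_numpy().ravel()
        order = np.argsort(raw)
        assert np.all(np.diff(trans[order]) >= 0)


class TestFullPipeline:
    def test_housekeeping_reference_reached_to_1e9(self, two_lane):
        result, meta = normalise_panel(two_lane, log2=False)
        hk = result.counts[["hk1"]]
        geo = np.exp(np.log(hk).mean(axis=1))
        assert geo["L1"] == pytest.approx(geo["L2"], rel=1e-9)

    def test_lane_scale_removed_by_positive_step(self):
        """A lane that is a pure c-times rescale of another (background
        included) ends up with identical endogenous values after the three
        steps, and relative lane structure is invariant to rescaling."""
        base_lane = {"p": 100.0, "n": 10.0, "h": 200.0, "g": 150.0}
        classes = {"p": "positive", "n": "negative", "h": "housekeeping",
                   "g": "endogenous"}
        counts = {
            "L1": dict(base_lane),
            "L2": {probe: 3.0 * v for probe, v in base_lane.items()},
        }
        out, _ = normalise_panel(make_matrix(counts, classes), log2=False)
        assert out.counts.loc["L1", "g"] == pytest.approx(
            out.counts.loc["L2", "g"], rel=1e-6
        )

    def test_step_order_is_fixed(self, two_lane):
        """Permuting the steps on the same fixture changes the endogenous
        output, so the positive -> negative -> housekeeping order cannot
        silently drift."""
        canonical, _ = normalise_panel(two_lane, log2=False)
        # permuted order: negative subtraction before positive scaling
        alt = negative_control_subtract(two_lane.copy())
        alt, _ = positive_control_scale(alt)
        alt, _ = housekeeping_normalise(alt)
        assert not np.allclose(
            canonical.counts["g1"].to_numpy(), alt.counts["g1"].to_numpy()
        )

    def test_missing_control_class_rejected(self):
        m = make_matrix(
            {"L1": {"h": 5.0, "g": 10.0}},
            {"h": "housekeeping", "g": "endogenous"},
        )
        with pytest.raises(ValueError, match="positive"):
            normalise_panel(m)


class TestGeneratedPanelRoundTrip:
    def test_identity_lane_counts_equal_rounded_abundance(self):
        truth = PanelLaneTruth(
            positive_scale=[1.0],
            background=[0.0],
            housekeeping_factor=[1.0],
            gene_log2_abundance={"hkA": 6.0, "geneB": 5.3},
        )
        classes = pd.Series(
            {"posA": "positive", "negA": "negative",
             "hkA": "housekeeping", "geneB": "endogenous"}
        )
        matrix, _ = generate_panel_counts(truth, classes)
        assert matrix.counts.loc["L01", "hkA"] == pytest.approx(64.0)
        assert matrix.counts.loc["L01", "geneB"] == pytest.approx(round(2**5.3))

    def test_three_lane_fixture_matches_hand_executed_oracle(self):
        """Generate a 3-lane fixture from known factors and check the full
        three-step pipeline cell by cell against a hand-written oracle that
        applies the formulas independently."""
        truth = PanelLaneTruth(
            positive_scale=[1.0, 2.0, 0.5],
            background=[10.0, 30.0, 5.0],
            housekeeping_factor=[1.0, 1.5, 0.8],
            gene_log2_abundance={"hk1": 8.0, "hk2": 9.0, "g1": 7.0, "g2": 10.0},
        )
        classes = pd.Series(
            {"pos1": "positive", "pos2": "positive", "neg1": "negative",
             "hk1": "housekeeping", "hk2": "housekeeping",
             "g1": "endogenous", "g2": "endogenous"}
        )
        matrix, _ = generate_panel_counts(truth, classes)
        result, _ = normalise_panel(matrix, log2=False)

        # independent hand-executed oracle on the raw counts
        raw = matrix.counts.copy()
        pos_mean = raw[["pos1", "pos2"]].mean(axis=1)
        f_pos = pos_mean.mean() / pos_mean
        step1 = raw.mul(f_pos, axis=0)
        bg = step1[["neg1"]].mean(axis=1)
        step2 = step1.copy()
        non_neg = [c for c in raw.columns if c != "neg1"]
        step2[non_neg] = step1[non_neg].sub(bg, axis=0).clip(lower=1.0)
        geo = np.sqrt(step2["hk1"] * step2["hk2"])
        f_hk = geo.mean() / geo
        expected = step2.copy()
        for col in ("hk1", "hk2", "g1", "g2"):
            expected[col] = step2[col] * f_hk
        for col in ("g1", "g2", "hk1", "hk2"):
            assert np.allclose(result.counts[col], expected[col], rtol=1e-12)

    def test_scale_invariant_lanes_agree_after_normalisation(self):
        truth = PanelLaneTruth(
            positive_scale=[1.0, 2.0],
            background=[0.0, 0.0],
            housekeeping_factor=[1.0, 1.0],
            gene_log2_abundance={"hk1": 8.0, "g1": 7.0},
        )
        classes = pd.Series(
            {"pos1": "positive", "neg1": "negative",
             "hk1": "housekeeping", "g1": "endogenous"}
        )
        matrix, _ = generate_panel_counts(truth, classes)
        result, _ = normalise_panel(matrix, log2=False)
        assert result.counts.loc["L01", "g1"] == pytest.approx(
            result.counts.loc["L02", "g1"], rel=1e-3  # integer rounding of counts
        )

    def test_missing_control_class_in_manifest_rejected(self):
        truth = PanelLaneTruth(
            positive_scale=[1.0], background=[0.0], housekeeping_factor=[1.0],
            gene_log2_abundance={"g1": 5.0},
        )
        with pytest.raises(ValueError, match="negative"):
            generate_panel_counts(
                truth, pd.Series({"pos1": "positive", "g1": "endogenous"})
            )

    def test_tidy_round_trip(self):
        truth = PanelLaneTruth(
            positive_scale=[1.0, 1.3], background=[2.0, 4.0],
            housekeeping_factor=[1.0, 0.9],
            gene_log2_abundance={"hk1": 8.0, "g1": 7.0},
        )
        classes = pd.Series(
            {"pos1": "positive", "neg1": "negative",
             "hk1": "housekeeping", "g1": "endogenous"}
        )
        matrix, _ = generate_panel_counts(truth, classes)
        again = PanelCountMatrix.from_tidy(matrix.to_tidy())
        assert again.counts.loc[matrix.counts.index, matrix.counts.columns].equals(
            matrix.counts
        )
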