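"""Tests of normalization factors, baseline scaling and CV reduction."""

import numpy as np
import pandas as pd
import pytest

from refnorm import (
    DesignError,
    DomainError,
    ReferenceNormalizer,
    SimulationConfig,
    build_report,
    cv,
    cv_reduction,
    geometric_mean_nf,
    make_panel_truth,
    normalize_series,
    quantify_wells,
    scale_to_day0,
    simulate_ddpcr_panel,
)
from refnorm.datasets import senescence_cv_reduction_table


class TestNormalizationFactor:
    def test_single_gene_identity(self):
        ref = pd.DataFrame([[2.0, 3.0, 4.0]], index=["g"], columns=list("xyz"))
        assert geometric_mean_nf(ref, ["g"]).to_numpy() == pytest.approx(
            [2.0, 3.0, 4.0])

    def test_two_gene_sqrt(self):
        ref = pd.DataFrame([[1.0], [4.0]], index=["a", "b"], columns=["s"])
        assert geometric_mean_nf(ref).iloc[0] == pytest.approx(2.0)

    def test_four_gene_value(self):
        ref = pd.DataFrame([[2.0], [3.0], [4.0], [6.0]],
                           index=list("abcd"), columns=["s"])
        assert geometric_mean_nf(ref).iloc[0] == pytest.approx(144 ** 0.25)
        assert geometric_mean_nf(ref).iloc[0] == pytest.approx(3.4641, abs=1e-4)

    def test_nonpositive_value_names_gene_and_sample(self):
        ref = pd.DataFrame([[2.0, 0.0]], index=["gx"], columns=["s1", "s2"])
        with pytest.raises(DomainError, match="gx.*s2"):
            geometric_mean_nf(ref)


class TestNormalizeSeries:
    def test_constant_nf_preserves_cv(self, rng):
        raw = pd.Series(rng.lognormal(size=6), index=list("abcdef"))
        nf = pd.Series(3.7, index=raw.index)
        assert cv(normalize_series(raw, nf)) == pytest.approx(cv(raw))

    def test_self_normalization_gives_unit_series(self):
        raw = pd.Series([2.0, 5.0, 9.0], index=list("abc"))
        normed = normalize_series(raw, raw)
        assert (normed == 1.0).all()
        assert cv(normed) == 0.0

    def test_missing_sample_errors(self):
        raw = pd.Series([1.0], index=["a"])
        with pytest.raises(DesignError):
            normalize_series(raw, pd.Series([1.0], index=["b"]))

    def test_true_scale_factors_recover_trajectory(self):
        """Dividing by the simulated scale factors removes sample variation."""
        cfg = SimulationConfig(biological_noise_sd=0.0, sample_scale_sd=0.4,
                               cq_noise_sd=0.0, seed=13)
        truth = make_panel_truth(cfg, markers={"m": (100.0, 3.0)})
        wells = simulate_ddpcr_panel(truth, cfg)
        quant = quantify_wells(wells, droplet_volume=cfg.droplet_volume,
                               background_correction=False)
        m_rows = quant[quant["target"] == "m"]
        normed = (m_rows["conc"].to_numpy()
                  / truth.scale_factors[m_rows["sample"]].to_numpy())
        expected = truth.trajectories.loc["m", m_rows["day"]].to_numpy()
        # residual is droplet-sampling noise only (a few % per well)
        rel_err = np.abs(normed - expected) / expected
        assert rel_err.mean() < 0.05
        assert rel_err.max() < 0.2


class TestScaleToDay0:
    def test_constant_series_all_ones(self):
        s = pd.DataFrame({"day": [0, 0, 3, 3], "replicate": list("abab"),
                          "value": [5.0] * 4})
        out = scale_to_day0(s)
        assert (out["fold"] == 1.0).all()

    def test_per_replicate_doubling(self, tidy_series):
        out = scale_to_day0(tidy_series, "per_replicate")
        d10a = out[(out["day"] == 10) & (out["replicate"] == "a")]["fold"]
        assert d10a.iloc[0] == pytest.approx(2.0)

    def test_mean_mode(self, tidy_series):
        out = scale_to_day0(tidy_series, "mean")
        assert out.loc[out["day"] == 10, "fold"].iloc[0] == pytest.approx(
            200.0 / 75.0)

    def test_zero_baseline_errors(self):
        s = pd.DataFrame({"day": [0, 3], "replicate": ["a", "a"],
                          "value": [0.0, 1.0]})
        with pytest.raises(DomainError):
            scale_to_day0(s)


class TestCV:
    def test_identical_values(self):
        assert cv([7.0, 7.0, 7.0]) == 0.0

    def test_hand_computed(self):
        assert cv([90, 100, 110]) == pytest.approx(0.1)

    def test_scale_invariance(self, rng):
        x = rng.lognormal(size=5)
        assert cv(3.1 * x) == pytest.approx(cv(x))

    def test_all_zero_errors(self):
        with pytest.raises(DomainError):
            cv([0.0, 0.0, 0.0])


class TestCVReduction:
    def test_published_day10_pair(self):
        assert cv_reduction(0.65, 0.10) == pytest.approx(84.6, abs=0.05)

    def test_published_day12_pair(self):
        assert cv_reduction(0.98, 0.24) == pytest.approx(75.5, abs=0.05)

    def test_no_change_is_zero(self):
        assert cv_reduction(0.4, 0.4) == 0.0

    def test_worsening_goes_negative(self):
        assert cv_reduction(0.16, 0.18) < 0

    def test_zero_raw_cv_errors(self):
        with pytest.raises(DomainError):
            cv_reduction(0.0, 0.1)


def _synthetic_measurements(seed=0, scale_sd=0.3, noise_sd=0.05):
    cfg = SimulationConfig(biological_noise_sd=noise_sd,
                           sample_scale_sd=scale_sd, seed=seed)
    truth = make_panel_truth(cfg)
    wells = simulate_ddpcr_panel(truth, cfg)
    quant = quantify_wells(wells, droplet_volume=cfg.droplet_volume)
    meas = quant.rename(columns={"target": "gene", "conc_bg": "value"})
    return meas[["gene", "day", "replicate", "value"]]


class TestReport:
    COMBOS = [("ref_A", "ref_B"), ("ref_A", "ref_D"),
              ("ref_A", "ref_B", "ref_D", "ref_E")]

    def test_dimensions(self):
        meas = _synthetic_measurements()
        rep = build_report(meas, targets=["ref_C", "marker_up"],
                           references=["ref_A", "ref_B", "ref_D", "ref_E"],
                           combos=self.COMBOS)
        assert len(rep.cv_table) == 2 * 6 * len(self.COMBOS)
        assert len(rep.profiles) == 2 * 6 * 3  # per-replicate profiles

    def test_cv_reduce_identity_to_machine_precision(self):
        meas = _synthetic_measurements(seed=5)
        rep = build_report(meas, targets=["ref_C"],
                           references=["ref_A", "ref_B", "ref_D", "ref_E"],
                           combos=self.COMBOS)
        recomputed = 100 * (rep.cv_table["cv_raw"] - rep.cv_table["cv_norm"]) \
            / rep.cv_table["cv_raw"]
        assert np.allclose(recomputed, rep.cv_table["cv_reduce_pct"],
                           rtol=0, atol=1e-12)

    def test_target_in_its_own_combo_gives_zero_cv(self):
        meas = _synthetic_measurements(seed=6)
        rep = build_report(meas, targets=["ref_A"],
                           references=["ref_A"], combos=[("ref_A",)])
        assert np.allclose(rep.cv_table["cv_norm"], 0.0, atol=1e-12)
        assert np.allclose(rep.cv_table["cv_reduce_pct"], 100.0)

    def test_unknown_combo_gene_rejected(self):
        meas = _synthetic_measurements(seed=7)
        with pytest.raises(DesignError):
            build_report(meas, targets=["ref_C"], references=["ref_A"],
                         combos=[("ref_A", "nope")])

    def test_baseline_profile_is_one_per_replicate(self):
        meas = _synthetic_measurements(seed=8)
        rep = build_report(meas, targets=["marker_up"],
                           references=["ref_A", "ref_B"], combos=[("ref_A",)])
        base = rep.profiles[rep.profiles["day"] == 0]
        assert np.allclose(base["raw_fold"], 1.0)
        assert np.allclose(base["norm_fold"], 1.0)

    def test_cv_reduce_invariant_to_units(self):
        meas = _synthetic_measurements(seed=9)
        scaled = meas.assign(value=meas["value"] * 20.0 / 100.0)  # copies/ng
        r1 = build_report(meas, ["ref_C"], ["ref_A", "ref_B"], [("ref_A", "ref_B")])
        r2 = build_report(scaled, ["ref_C"], ["ref_A", "ref_B"], [("ref_A", "ref_B")])
        assert np.allclose(r1.cv_table["cv_reduce_pct"],
                           r2.cv_table["cv_reduce_pct"], atol=1e-9)

    def test_no_scale_variation_means_no_benefit(self):
        """Without sample-level variation, normalization cannot help on average."""
        reductions = []
        for seed in range(200):
            meas = _synthetic_measurements(seed=seed, scale_sd=0.0,
                                           noise_sd=0.05)
            rep = build_report(meas, targets=["ref_C"],
                               references=["ref_A", "ref_B", "ref_D", "ref_E"],
                               combos=[("ref_A", "ref_B", "ref_D", "ref_E")])
            reductions.append(rep.cv_table["cv_reduce_pct"].mean())
        assert np.mean(reductions) < 10.0


class TestPublishedTable:
    def test_printed_cv_pairs_reproduce_printed_percentages(self):
        """Recomputing CV_reduce from the printed CV pairs matches the
        printed percentages within the rounding of the two-decimal CVs."""
        table = senescence_cv_reduction_table()
        for row in table.itertuples():
            got = cv_reduction(row.cv_raw, row.cv_norm)
            # half-ULP propagation of the two printed 0.01-rounded CVs
            tol = 100 * 0.005 * (1 / row.cv_raw
                                 + row.cv_norm / row.cv_raw ** 2) + 0.05
            assert got == pytest.approx(row.cv_reduce_pct, abs=tol)


class TestReferenceNormalizer:
    def test_transform_divides_by_row_gmean(self):
        X = pd.DataFrame({"r1": [1.0, 4.0], "r2": [4.0, 16.0],
                          "t": [10.0, 10.0]})
        norm = ReferenceNormalizer(reference_genes=["r1", "r2"]).fit(X)
        out = norm.transform(X)
        assert out["t"].to_numpy() == pytest.approx([5.0, 1.25])
        assert np.allclose(np.sqrt(out["r1"] * out["r2"]), 1.0)

    def test_unknown_reference_rejected(self):
        X = pd.DataFrame({"a": [1.0]})
        with pytest.raises(DesignError):
            ReferenceNormalizer(reference_genes=["zz"]).fit(X)
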