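"""Synthetic network generator: determinism, physical consistency, truth ledger."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from baycarb import carbonate as cb
from baycarb import qaqc, synth
from baycarb.pipeline import run_trend_pipeline


def small_config(seed=0, **kwargs):
    """Two stations, four years, no outliers: fast enough for unit tests."""
    cfg = synth.nb_like(seed=seed, outlier_rate=0.0)
    cfg.stations = [synth.StationSpec("GD", year_round=True),
                    synth.StationSpec("NP", salinity_offset=0.5)]
    cfg.start_year, cfg.end_year = 2010, 2013
    for key, value in kwargs.items():
        setattr(cfg, key, value)
    return cfg


def silence(cfg):
    """Zero every stochastic and biological term."""
    for layer in cfg.climate:
        cfg.climate[layer] = {
            p: dataclasses.replace(s, ar1_sd=0, shared_sd=0, daily_sd=0)
            for p, s in cfg.climate[layer].items()}
    cfg.do = {l: dataclasses.replace(d, ar1_sd=0, shared_sd=0, daily_sd=0,
                                     chl_coupling=0, temp_bio_coupling=0)
              for l, d in cfg.do.items()}
    cfg.dic_noise = {l: dataclasses.replace(d, ar1_sd=0, shared_sd=0)
                     for l, d in cfg.dic_noise.items()}
    return cfg


def flatten(cfg):
    """Additionally remove trends, harmonics and excursions."""
    silence(cfg)
    for layer in cfg.climate:
        cfg.climate[layer] = {
            p: dataclasses.replace(s, amp1=0, amp2=0, trend=0, excursion_amp=0)
            for p, s in cfg.climate[layer].items()}
    cfg.do = {l: dataclasses.replace(d, trend=0) for l, d in cfg.do.items()}
    cfg.ph_trend = {l: 0.0 for l in cfg.ph_trend}
    return cfg


class TestDeterminism:
    def test_identical_seeds_bitwise_identical(self):
        a, la = synth.generate_network(small_config(seed=5))
        b, lb = synth.generate_network(small_config(seed=5))
        pd.testing.assert_frame_equal(a, b)
        assert la.to_dict() == lb.to_dict()

    def test_different_seeds_differ(self):
        a, _ = synth.generate_network(small_config(seed=5))
        b, _ = synth.generate_network(small_config(seed=6))
        assert not a["temperature"].equals(b["temperature"])


class TestStructure:
    def test_network_layout_matches_reader_expectations(self):
        records, _ = synth.generate_network(small_config())
        assert list(records.columns) == ["station", "timestamp", "layer",
                                         "temperature", "salinity", "do_mgL",
                                         "pH", "chl", "depth"]
        assert set(records["layer"]) == {"surface", "bottom"}

    def test_bottom_layer_has_no_chlorophyll(self):
        records, _ = synth.generate_network(small_config())
        assert records.loc[records.layer == "bottom", "chl"].isna().all()
        assert records.loc[records.layer == "surface", "chl"].notna().all()

    def test_seasonal_station_samples_may_to_october(self):
        records, _ = synth.generate_network(small_config())
        months = pd.to_datetime(
            records.loc[records.station == "NP", "timestamp"]).dt.month
        assert set(months) == set(range(5, 11))
        gd_months = pd.to_datetime(
            records.loc[records.station == "GD", "timestamp"]).dt.month
        assert set(gd_months) == set(range(1, 13))

    def test_subdaily_cadence_collapses_to_daily_means(self):
        cfg = small_config(cadence=4)
        cfg.start_year = cfg.end_year = 2010
        records, _ = synth.generate_network(cfg)
        renamed = records.rename(columns={"station": "station_id",
                                          "pH": "pH_nbs"})
        daily = qaqc.daily_means(renamed)
        assert (daily["n_temperature"] == 4).all()


class TestPhysicalConsistency:
    def test_generated_ph_closes_carbonate_system(self):
        """With biology and DIC noise off, pH must equal speciation of
        TA(S), DIC(S) at in-situ T — closure by construction."""
        cfg = silence(small_config())
        records, _ = synth.generate_network(cfg)
        sub = records.sample(200, random_state=0)
        # the generator adds its calibrated DIC trend; reproduce it
        mid = pd.Timestamp("2012-01-01")
        t_years = (pd.to_datetime(sub["timestamp"]) - mid).dt.days / 365.25
        cal = synth._calibrate(cfg)
        # net linear DIC rate: the calibrated rate minus the DO-coupled
        # biological rate (the only surviving terms with noise silenced)
        rate = {layer: cal[layer]["dic_rate"]
                - cal[layer]["dic_per_do"] * cal[layer]["do_bio_rate"]
                for layer in ("surface", "bottom")}
        dic = (cfg.endmembers.dic(sub["salinity"].to_numpy())
               + np.where(sub["layer"] == "surface", rate["surface"],
                          rate["bottom"]) * t_years.to_numpy())
        ph_expect = cb.solve_ph_from_ta_dic(
            cfg.endmembers.ta(sub["salinity"].to_numpy()), dic,
            sub["temperature"].to_numpy(), sub["salinity"].to_numpy())
        assert np.abs((sub["pH"] - cb.NBS_TOTAL_OFFSET) - ph_expect).max() < 2e-3

    def test_without_biology_observations_sit_on_mixing_curve(self):
        from baycarb import mixing as mx
        cfg = flatten(small_config())
        records, _ = synth.generate_network(cfg)
        curve = mx.build_mixing_curve(cfg.endmembers, 17.0)
        obs = records.rename(columns={"pH": "pH_nbs"}).sample(
            100, random_state=1)[["salinity", "temperature", "pH_nbs"]]
        out = mx.mixing_deviation(obs, curve)
        assert np.abs(out["delta_ph"]).max() < 1e-3

    def test_zero_everything_means_zero_trends_and_no_removals(self):
        cfg = flatten(small_config())
        records, _ = synth.generate_network(cfg)
        renamed = records.rename(columns={"station": "station_id",
                                          "pH": "pH_nbs"})
        result = run_trend_pipeline(renamed, min_years=1)
        assert result.outlier_report.n_days_removed == 0
        for t in result.trends:
            assert abs(t.slope) < 1e-10


class TestInjectOutliers:
    def test_zero_rate_is_identity(self):
        values = np.random.default_rng(0).normal(10, 1, 500)
        out, idx = synth.inject_outliers(values, 0.0, 1.0, 3)
        assert np.array_equal(out, values) and idx.size == 0

    def test_count_and_reproducibility(self):
        values = np.random.default_rng(0).normal(10, 1, 1000)
        out1, idx1 = synth.inject_outliers(values, 0.02, 1.0, 42)
        out2, idx2 = synth.inject_outliers(values, 0.02, 1.0, 42)
        assert idx1.size == 20
        assert np.array_equal(idx1, idx2) and np.array_equal(out1, out2)

    def test_injected_days_lie_outside_clean_fences(self):
        values = np.random.default_rng(1).normal(10, 1, 800)
        fences = qaqc.iqr_fences(values)
        out, idx = synth.inject_outliers(values, 0.03, 1.0, 7)
        assert ((out[idx] > fences.upper) | (out[idx] < fences.lower)).all()

    def test_valid_range_respected(self):
        values = np.random.default_rng(2).normal(8.0, 0.1, 500)
        out, idx = synth.inject_outliers(values, 0.05, 2.0, 11,
                                         valid_range=(5.05, 9.95))
        assert out[idx].min() >= 5.05 and out[idx].max() <= 9.95

    def test_rate_cap(self):
        with pytest.raises(ValueError):
            synth.inject_outliers(np.ones(100), 0.5, 1.0, 0)


class TestTruthLedger:
    def test_ledger_records_trends_couplings_and_outliers(self, nb_network,
                                                          nb_config):
        _, ledger = nb_network
        assert ledger.seed == nb_config.seed
        assert ledger.trends["GD"]["bottom"]["ph_nbs"] == 0.0021
        assert ledger.trends["GD"]["surface"]["do_umolkg"] == -0.69
        assert ledger.couplings["surface"]["ph_per_do"] == 0.00156
        # the effective DO-temperature coupling is the annual-mean solubility
        # slope plus the configured biological response
        cal = ledger.calibration["surface"]
        assert ledger.couplings["surface"]["do_per_degC_total"] == pytest.approx(
            cal["dsol_dT"] + 0.95)
        assert cal["dsol_dT"] < -4.0  # solubility steepens in cold months
        assert len(ledger.outliers) > 100

    def test_ledger_serializes_to_json(self, nb_network, tmp_path):
        _, ledger = nb_network
        path = tmp_path / "truth.json"
        ledger.to_json(path)
        import json
        assert json.loads(path.read_text())["seed"] == ledger.seed


class TestCouplingRecovery:
    """Injected couplings are recovered by the anomaly regressions when the
    generator isolates them (no interannual salinity excursion, which in the
    full profile adds a real mixing covariance to both regressions)."""

    @staticmethod
    def isolating_config(seed=11, t_amp=None):
        cfg = synth.nb_like(seed=seed, outlier_rate=0.0)
        for layer in cfg.climate:
            newc = {}
            for p, s in cfg.climate[layer].items():
                s = dataclasses.replace(s, excursion_amp=0.0)
                if p == "salinity":
                    s = dataclasses.replace(s, ar1_sd=0.02, shared_sd=0.02)
                if p == "temperature" and t_amp is not None:
                    s = dataclasses.replace(s, amp1=t_amp, amp2=0.0)
                newc[p] = s
            cfg.climate[layer] = newc
        return cfg

    def run(self, cfg):
        records, ledger = synth.generate_network(cfg)
        renamed = records.rename(columns={"station": "station_id",
                                          "pH": "pH_nbs"})
        result = run_trend_pipeline(
            renamed, skip_outlier_screen=True,
            analysis_stations=[s.station_id for s in cfg.stations
                               if s.station_id != "PD"])
        return result.baywide, ledger

    def test_ph_do_coupling_recovered(self):
        from baycarb import trends as tr
        bay, ledger = self.run(self.isolating_config())
        fit = tr.regress_anomalies(bay, "pH_nbs", "do_umolkg",
                                   layer_mode="mean-of-layers")
        truth = ledger.couplings["surface"]["ph_per_do"]
        assert fit.ci_low <= truth <= fit.ci_high

    def test_do_temperature_coupling_recovered(self):
        from baycarb import trends as tr
        # a gentle seasonal cycle keeps the local solubility slope nearly
        # constant, so the ledger's effective coupling is the estimand
        bay, ledger = self.run(self.isolating_config(seed=12, t_amp=2.0))
        fit = tr.regress_anomalies(bay, "do_umolkg", "temperature",
                                   layer_mode="mean-of-layers")
        truth = np.mean([ledger.couplings[l]["do_per_degC_total"]
                         for l in ("surface", "bottom")])
        assert fit.ci_low <= truth <= fit.ci_high
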