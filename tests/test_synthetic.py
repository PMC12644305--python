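import numpy as np
import pandas as pd
import pytest

from hdps import LatentEffects, SimConfig, synthetic as syn


def null_config(n=20_000, seed=3, **kw):
    """All structural effects switched off."""
    return SimConfig(n_patients=n, seed=seed, true_log_hr=0.0,
                     latent_effects=LatentEffects(0, 0, 0, 0), **kw)


class TestCohortGeneration:
    def test_same_seed_gives_identical_tables(self, small_sim):
        a = syn.generate_cohort(small_sim)
        b = syn.generate_cohort(small_sim)
        pd.testing.assert_frame_equal(a, b)
        ea = syn.emit_code_events(a, small_sim)
        eb = syn.emit_code_events(b, small_sim)
        pd.testing.assert_frame_equal(ea, eb)

    def test_marginal_exposure_prevalence_near_target(self):
        cohort = syn.generate_cohort(SimConfig(n_patients=10_000, seed=11))
        assert abs(cohort["exposure"].mean() - 0.4) < 0.05

    def test_null_structure_gives_equal_risks_between_arms(self):
        cohort = syn.generate_cohort(null_config())
        # covariate effects on exposure/outcome remain; switch them off by
        # comparing within the null latent structure via two-proportion z
        r1 = cohort.loc[cohort.exposure == 1, "event"].mean()
        r0 = cohort.loc[cohort.exposure == 0, "event"].mean()
        n1 = (cohort.exposure == 1).sum()
        n0 = (cohort.exposure == 0).sum()
        p = cohort["event"].mean()
        se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n0))
        # measured covariates still confound mildly; allow 4 SE
        assert abs(r1 - r0) < 4 * se

    def test_latent_confounding_biases_unadjusted_hr_upward(self):
        # latent severity raises both exposure odds and outcome hazard with
        # a null conditional effect, so the crude HR exceeds 1 on average
        from hdps.outcomes import weighted_cox_hr
        logs = []
        for seed in range(5):
            cfg = SimConfig(n_patients=8000, seed=seed,
                            latent_effects=LatentEffects(1.0, 1.0, 0.0, 0.0))
            cohort = syn.generate_cohort(cfg)
            est = weighted_cox_hr(cohort["time_to_event"], cohort["event"],
                                  cohort["exposure"])
            logs.append(est.extra["log_point"])
        assert np.mean(logs) > 0

    def test_followup_bounds_and_event_flags(self, small_study, small_sim):
        cohort, _, _ = small_study
        assert ((cohort["time_to_event"] >= 1)
                & (cohort["time_to_event"] <= small_sim.followup_days)).all()
        assert set(cohort["event"].unique()) <= {0, 1}

    def test_nonfinite_effect_rejected_with_parameter_name(self):
        cfg = SimConfig(latent_effects=LatentEffects(np.inf, 0.5, 0.3, 0.5))
        with pytest.raises(ValueError, match="severity_exposure"):
            syn.generate_cohort(cfg)
        with pytest.raises(ValueError, match="true_log_hr"):
            syn.generate_cohort(SimConfig(true_log_hr=np.nan))

    def test_estimation_view_withholds_latents(self, small_study):
        cohort, _, _ = small_study
        view = syn.estimation_view(cohort)
        assert not set(syn.LATENT_COLUMNS) & set(view.columns)


class TestCodeEmission:
    def test_severity_proxies_increase_with_latent(self, small_study, small_sim):
        cohort, events, _ = small_study
        reg = syn.code_registry(small_sim)
        sev_codes = reg.loc[(reg.kind == "confounder")
                            & (reg.latent == "severity")
                            & (reg.dimension == "observation")]
        raws = {raw for _, row in sev_codes.iterrows()
                for raw in syn._raw_variants(row.dimension, "confounder",
                                             int(row.code[1:3]))}
        counts = (events[events.raw_code.isin(raws)]
                  .groupby("patient_id").size()
                  .reindex(cohort.patient_id, fill_value=0))
        sev = cohort.set_index("patient_id")["latent_severity"]
        hi = counts[sev >= sev.quantile(0.95)].mean()
        lo = counts[sev <= sev.quantile(0.05)].mean()
        assert hi > lo

    def test_noise_codes_independent_of_exposure(self):
        sim = SimConfig(n_patients=20_000, seed=21)
        cohort = syn.generate_cohort(sim)
        events = syn.emit_code_events(cohort, sim)
        reg = syn.code_registry(sim)
        noise = reg[reg.kind == "noise"].iloc[0]
        raws = set(syn._raw_variants(noise.dimension, "noise", 0))
        has_code = (events[events.raw_code.isin(raws)]
                    .groupby("patient_id").size() > 0)
        has = cohort["patient_id"].isin(has_code[has_code].index)
        p1 = has[cohort.exposure == 1].mean()
        p0 = has[cohort.exposure == 0].mean()
        p = has.mean()
        se = np.sqrt(p * (1 - p) * (1 / (cohort.exposure == 1).sum()
                                    + 1 / (cohort.exposure == 0).sum()))
        assert abs(p1 - p0) < 3 * se

    def test_no_instrument_codes_when_count_zero(self, small_sim):
        import dataclasses
        cfg = dataclasses.replace(small_sim, n_instrument_codes=0)
        cohort = syn.generate_cohort(cfg)
        events = syn.emit_code_events(cohort, cfg)
        instrument_raws = {raw for dim in syn.DIMENSIONS for j in range(10)
                           for raw in syn._raw_variants(dim, "instrument", j)}
        assert not events["raw_code"].isin(instrument_raws).any()

    def test_event_dates_at_least_one_day_before_index(self, small_study):
        _, events, _ = small_study
        assert (events["event_date"] >= 1).all()
        assert set(events["dimension"].unique()) <= set(syn.DIMENSIONS)


class TestMappingTables:
    def test_zero_unmapped_fraction_resolves_every_raw_code(self):
        import dataclasses
        sim = SimConfig(n_patients=500, seed=5, fraction_unmapped=0.0,
                        n_true_confounder_codes=3, n_instrument_codes=1,
                        n_noise_codes=3)
        cohort = syn.generate_cohort(sim)
        events = syn.emit_code_events(cohort, sim)
        tables = syn.make_mapping_tables(sim)
        known = (set(tables["observation"].source_code)
                 | set(tables["prescription"].source_code)
                 | set(tables["prescription_fallback"].source_code))
        raw = events.loc[events.dimension != "hospitalisation", "raw_code"]
        assert set(raw.unique()) <= known

    def test_unmapped_fraction_withholds_exact_count(self):
        sim = SimConfig(seed=5, fraction_unmapped=0.1,
                        n_true_confounder_codes=20, n_instrument_codes=10,
                        n_noise_codes=20)  # 50 concepts -> 100 raw variants
        tables = syn.make_mapping_tables(sim)
        n_obs = len(tables["observation"])
        assert n_obs == 90  # exactly 10% of the 100 observation variants absent
        n_rx = (len(tables["prescription"]) - 3  # 3 fixed drug-class rows
                + len(tables["prescription_fallback"]))
        assert n_rx == 90

    def test_many_raw_codes_map_to_one_harmonized_code(self):
        sim = SimConfig(seed=5, fraction_unmapped=0.0)
        tables = syn.make_mapping_tables(sim)
        targets = tables["observation"]["target_code"].str.slice(0, 3)
        assert (targets.value_counts() == 2).all()

    def test_registry_covers_emitted_harmonized_codes(self, small_study, small_sim):
        from hdps.code_mapping import map_all_dimensions
        cohort, events, tables = small_study
        mapped = map_all_dimensions(events, tables)
        reg_codes = set(syn.code_registry(small_sim)["code"])
        assert set(mapped.events["harmonized_code"].unique()) <= reg_codes


class TestCsvRoundTrip:
    def test_cohort_events_and_mappings_round_trip(self, small_study, tmp_path):
        cohort, events, tables = small_study
        syn.write_cohort(cohort, tmp_path / "c.csv")
        back = syn.read_cohort(tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back, cohort, check_dtype=False)
        syn.write_events(events, tmp_path / "e.csv")
        back_e = syn.read_events(tmp_path / "e.csv")
        pd.testing.assert_frame_equal(back_e, events, check_dtype=False)
        syn.write_mapping(tables["observation"], tmp_path / "m.csv")
        back_m = syn.read_mapping(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back_m, tables["observation"])
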