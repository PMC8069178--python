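"""Generator contracts: determinism, calibration, planted effects, censoring,
and the clamp forward model's closed-form behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metsynkit as mk
from metsynkit.cohort import _annotations

from conftest import noise_free_config


class TestClinical:
    def test_empty_cohort(self):
        records, truth = mk.gen_clinical(mk.SimConfig(n_subjects=0))
        assert records == [] and truth.ir_labels.size == 0

    def test_determinism_byte_level(self, small_config):
        a = mk.generate_cohort(small_config)
        b = mk.generate_cohort(small_config)
        pd.testing.assert_frame_equal(mk.clinical_frame(a[0]), mk.clinical_frame(b[0]))
        pd.testing.assert_frame_equal(a[2].abundances, b[2].abundances)
        for sa, sb in zip(a[3], b[3]):
            np.testing.assert_array_equal(sa.C, sb.C)
            np.testing.assert_array_equal(sa.E, sb.E)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mk.SimConfig(ir_fraction=1.2)
        with pytest.raises(ValueError):
            mk.SimConfig(missing_rate=-0.1)
        with pytest.raises(ValueError):
            mk.SimConfig(clamp_true_suppression=120)

    def test_effect_indices_validated(self):
        with pytest.raises(ValueError):
            mk.SimConfig(n_metabolites=10, ir_effect_metabolites=(11,),
                         fram_effect_metabolites=(), supp_effect_metabolites=())
        with pytest.raises(ValueError):  # overlap between effect sets
            mk.SimConfig(n_metabolites=10, ir_effect_metabolites=(1, 2),
                         fram_effect_metabolites=(2, 3), supp_effect_metabolites=())

    def test_bmi_median_calibration(self):
        # large calibration draw: cohort BMI median near the target 33.91 kg/m²
        cfg = mk.SimConfig(n_subjects=10_000, n_metabolites=5, seed=0,
                           ir_effect_metabolites=(), fram_effect_metabolites=(),
                           supp_effect_metabolites=())
        records, _ = mk.gen_clinical(cfg)
        bmi = np.array([r.bmi for r in records])
        assert abs(np.median(bmi) - 33.91) < 1.0

    def test_records_all_male_and_valid(self, small_cohort):
        records, truth = small_cohort[0], small_cohort[1]
        assert all(r.sex == "male" for r in records)
        assert all(r.sbp > r.dbp for r in records)
        # Rd consistent with planted labels through the classifier
        for r, ir in zip(records, truth.ir_labels):
            assert (mk.classify_ir(r.rd) == "IR") == bool(ir)

    def test_suppression_in_range(self, small_cohort):
        truth = small_cohort[1]
        assert np.all((truth.true_suppression >= 0) & (truth.true_suppression <= 100))


class TestMetabolites:
    def test_default_panel_shape(self):
        cfg = mk.SimConfig(n_subjects=20, seed=4)
        records, truth = mk.gen_clinical(cfg)
        table = mk.gen_metabolites(records, truth, cfg)
        assert table.n_metabolites == 917
        assert (table.annotations["superpathway"] == "Lipid").sum() == 451

    def test_annotation_blocks_cover_any_size(self):
        for n in (1, 7, 917, 1200):
            ann = _annotations(n)
            assert len(ann) == n and ann["superpathway"].notna().all()

    def test_left_censoring_invariant(self, small_cohort, small_config):
        _, truth, table, _ = small_cohort
        missing = table.missing_mask.to_numpy()
        latent = truth.latent_abundances.to_numpy()
        limits = truth.detection_limits.to_numpy()
        assert missing.any()
        assert np.all(latent[missing] < np.broadcast_to(limits, latent.shape)[missing])
        # observed cells match the latent values exactly
        obs = ~missing
        np.testing.assert_array_equal(table.abundances.to_numpy()[obs], latent[obs])

    def test_null_false_positive_calibration(self):
        # no planted effects: per-column Mann-Whitney p<0.05 rate matches alpha
        flat = []
        for rep in range(200):
            cfg = mk.SimConfig(n_subjects=40, n_metabolites=50, seed=1000 + rep,
                               ir_effect_metabolites=(), fram_effect_metabolites=(),
                               supp_effect_metabolites=(), missing_rate=0.0)
            records, truth = mk.gen_clinical(cfg)
            table = mk.gen_metabolites(records, truth, cfg)
            labels = np.where(truth.ir_labels, "IR", "N-IR")
            if np.unique(labels).size < 2:
                continue
            x = table.abundances.to_numpy()
            res = stats.mannwhitneyu(x[truth.ir_labels], x[~truth.ir_labels],
                                     axis=0, method="asymptotic")
            flat.append(np.asarray(res.pvalue) < 0.05)
        rate = np.concatenate(flat).mean()
        assert abs(rate - 0.05) < 0.01

    def test_planted_shift_realized(self):
        # 1-SD planted log shift is realized within 0.1 SD on average
        diffs = []
        for rep in range(100):
            cfg = mk.SimConfig(n_subjects=60, n_metabolites=20, seed=2000 + rep,
                               ir_effect_metabolites=tuple(range(14)),
                               ir_effect_size=1.0,
                               fram_effect_metabolites=(), supp_effect_metabolites=(),
                               missing_rate=0.0)
            records, truth = mk.gen_clinical(cfg)
            table = mk.gen_metabolites(records, truth, cfg)
            if truth.ir_labels.all() or not truth.ir_labels.any():
                continue
            logx = np.log(table.abundances.to_numpy()[:, :14])
            a, b = logx[truth.ir_labels], logx[~truth.ir_labels]
            pooled = np.sqrt(((a.std(axis=0, ddof=1) ** 2) + (b.std(axis=0, ddof=1) ** 2)) / 2)
            diffs.append((a.mean(axis=0) - b.mean(axis=0)) / pooled)
        assert abs(np.mean(diffs) - 1.0) < 0.1

    def test_empty_records_rejected(self, small_config):
        with pytest.raises(ValueError):
            mk.gen_metabolites([], mk.SimTruth(), small_config)


class TestClamp:
    def test_zero_noise_determinism(self):
        cfg = noise_free_config(68.1)
        records, truth = mk.gen_clinical(cfg)
        a = mk.gen_clamp(records, truth, cfg)
        b = mk.gen_clamp(records, truth, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.C, sb.C)
            np.testing.assert_array_equal(sa.E, sb.E)

    def test_terminal_enrichment_closed_form(self):
        # constant Ra, long equilibration: E -> F/(Ra+F)
        cfg = noise_free_config(0.0, times=(-10.0, 0.0, 1000.0, 2000.0))
        records, truth = mk.gen_clinical(cfg)
        series = mk.gen_clamp(records, truth, cfg)
        for i, s in enumerate(series):
            expected = cfg.clamp_tracer_rate / (truth.ra_basal[i] + cfg.clamp_tracer_rate)
            assert abs(s.E[-1] - expected) / expected < 1e-6

    def test_tracer_mass_conservation(self):
        # d(tracer amount)/dt = F − E·(total disposal), checked by central
        # differences on a dense noise-free trajectory
        cfg = noise_free_config(68.1, times=tuple(np.arange(-60.0, 241.0, 1.0)))
        records, truth = mk.gen_clinical(cfg)
        s = mk.gen_clamp(records, truth, cfg)[0]
        V, F = cfg.clamp_v_dist, cfg.clamp_tracer_rate
        k = (truth.ra_basal[0] + F) / (cfg.clamp_basal_concentration * V)
        qt = s.E * s.C * V                    # tracer amount per kg
        disposal = k * s.C * V                # total disposal = CL·C
        dqt_dt = np.gradient(qt, s.time)
        residual = dqt_dt - (F - s.E * disposal)
        interior = slice(2, -2)
        assert np.max(np.abs(residual[interior])) < 1e-3 * F + 1e-3 * np.abs(dqt_dt[interior]).max()

    def test_phase_labels_and_units(self):
        cfg = noise_free_config(50.0)
        records, truth = mk.gen_clinical(cfg)
        s = mk.gen_clamp(records, truth, cfg)[0]
        assert set(s.phase[s.time <= 0]) == {"basal"}
        assert set(s.phase[s.time > 0]) == {"step1"}
        assert np.all((s.E > 0) & (s.E < 1)) and np.all(s.C > 0)


def test_write_cohort_round_trip(tmp_path, small_config):
    paths = mk.write_cohort(tmp_path, small_config)
    table = mk.MetaboliteTable.from_tsv(paths["abundances"], paths["annotations"])
    assert table.n_samples == small_config.n_subjects
    clamps = mk.read_clamp_csv(paths["clamp"])
    assert len(clamps) == small_config.n_subjects
    clin = pd.read_csv(paths["clinical"], index_col="subject_id")
    records = mk.records_from_frame(clin)
    assert len(records) == small_config.n_subjects
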