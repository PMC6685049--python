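"""Label masses, channel aggregation, ratios and differential classification."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.SeqUtils import molecular_weight

from mitotails import (
    DifferentialAbundance,
    DifferentialClass,
    FilterConfig,
    PeptideObservation,
    Stage,
    aggregate_areas,
    classify_differential,
    default_design,
    dimethyl_mass_delta,
    log2_ratios,
    peptide_mass,
)
from mitotails.types import AMINO_ACIDS

from conftest import make_observation


class TestDimethylMasses:
    def test_light_delta_from_atomic_masses(self):
        assert dimethyl_mass_delta("light") == pytest.approx(28.0313, abs=5e-5)
        assert round(dimethyl_mass_delta("light"), 2) == 28.03

    def test_heavy_delta_from_atomic_masses(self):
        assert dimethyl_mass_delta("heavy") == pytest.approx(34.0631, abs=5e-5)
        assert round(dimethyl_mass_delta("heavy"), 2) == 34.06

    def test_heavy_light_difference(self):
        diff = dimethyl_mass_delta("heavy") - dimethyl_mass_delta("light")
        assert diff == pytest.approx(6.0318, abs=5e-5)


class TestPeptideMass:
    def test_glycine_monoisotopic(self):
        assert peptide_mass("G") == pytest.approx(75.0320, abs=5e-5)

    def test_nterm_label_additivity(self):
        base = peptide_mass("SAMPLEGITR")
        labeled = peptide_mass("SAMPLEGITR", nterm_label="light")
        assert labeled - base == pytest.approx(dimethyl_mass_delta("light"), abs=1e-9)

    def test_lysines_are_co_labeled(self):
        base = peptide_mass("AKDVKF")
        labeled = peptide_mass("AKDVKF", nterm_label="heavy")
        assert labeled - base == pytest.approx(3 * dimethyl_mass_delta("heavy"), abs=1e-9)

    def test_carbamidomethyl_nominal_delta(self):
        delta = peptide_mass("ACR", mods=[(2, "carbamidomethyl")]) - peptide_mass("ACR")
        assert round(delta, 2) == 57.02

    def test_mod_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError, match="carbamidomethyl"):
            peptide_mass("AGR", mods=[(2, "carbamidomethyl")])

    def test_mass_additivity_against_independent_oracle(self, rng):
        # independent summation route: Biopython's monoisotopic protein mass
        for _ in range(25):
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(2, 25))))
            oracle = molecular_weight(pep, seq_type="protein", monoisotopic=True)
            assert peptide_mass(pep) == pytest.approx(oracle, abs=1e-3)


class TestAggregation:
    def test_duplicate_rows_sum_per_channel(self, design7):
        obs = [
            make_observation("MARGK", "R1", light=100.0, heavy=10.0),
            make_observation("MARGK", "R1", light=50.0, heavy=None),
        ]
        agg = aggregate_areas(obs, design7)
        assert len(agg) == 1
        # R1 labels CTRL light
        assert agg.iloc[0]["area_ctrl"] == 150.0
        assert agg.iloc[0]["area_da"] == 10.0

    def test_orientation_maps_heavy_to_ctrl_on_swapped_replicate(self, design7):
        # R7 labels DA light / CTRL heavy
        obs = [make_observation("MARGK", "R7", light=None, heavy=100.0)]
        agg = aggregate_areas(obs, design7)
        assert agg.iloc[0]["area_ctrl"] == 100.0
        assert np.isnan(agg.iloc[0]["area_da"])

    def test_unknown_replicate_is_configuration_error(self, design7):
        from mitotails.types import ConfigurationError

        with pytest.raises(ConfigurationError):
            aggregate_areas([make_observation("MARGK", "R99", light=1.0)], design7)


class TestRatios:
    def _ratio(self, design, light, heavy, replicate="R1"):
        agg = aggregate_areas(
            [make_observation("MARGK", replicate, light=light, heavy=heavy)], design
        )
        return log2_ratios(agg, design).iloc[0]

    def test_equal_areas_give_zero(self, design7):
        assert self._ratio(design7, 100.0, 100.0)["log2_ratio"] == pytest.approx(0.0)

    def test_threefold_da(self, design7):
        # R1: light=CTRL, heavy=DA
        row = self._ratio(design7, 100.0, 300.0)
        assert row["log2_ratio"] == pytest.approx(math.log2(3))

    def test_zero_area_treated_as_missing(self, design7):
        row = self._ratio(design7, 0.0, 300.0)
        assert not row["ctrl_detected"] and row["da_detected"]
        assert np.isnan(row["log2_ratio"])

    def test_injected_ratio_recovered_within_sem(self, design7, rng):
        # 7 replicates, true fold 1.5x, log-normal noise
        obs = []
        for i, rep in enumerate(design7.replicate_ids):
            ctrl = 1e6 * 2 ** rng.normal(0, 0.3)
            da = 1.5e6 * 2 ** rng.normal(0, 0.3)
            orient = design7.orientation(rep)
            light, heavy = (ctrl, da) if orient.light_condition.value == "CTRL" else (da, ctrl)
            obs.append(make_observation("MARGK", rep, light=light, heavy=heavy))
        res = DifferentialAbundance(obs, design7).fit().results[0]
        assert res.mean_log2 == pytest.approx(math.log2(1.5), abs=3 * res.sem_log2)


def _ratio_rows(values, design):
    rows = []
    for rep, v in zip(design.replicate_ids, values):
        if v is None:
            continue
        rows.append(
            {"replicate_id": rep, "log2_ratio": v, "da_detected": True, "ctrl_detected": True}
        )
    return pd.DataFrame(rows)


def _exclusive_rows(design, n_da, n_ctrl=0):
    rows = []
    reps = design.replicate_ids
    for rep in reps[:n_da]:
        rows.append({"replicate_id": rep, "log2_ratio": np.nan, "da_detected": True, "ctrl_detected": False})
    for rep in reps[n_da : n_da + n_ctrl]:
        rows.append({"replicate_id": rep, "log2_ratio": np.nan, "da_detected": False, "ctrl_detected": True})
    return pd.DataFrame(rows)


class TestClassification:
    def test_seven_identical_positive_ratios_are_over(self, design7):
        jitter = [1.0, 1.01, 0.99, 1.0, 1.02, 0.98, 1.0]
        res = classify_differential("S", "A", _ratio_rows(jitter, design7), design7, FilterConfig())
        assert res.differential_class is DifferentialClass.over
        assert res.p_value < 0.05

    def test_da_exclusive_six_of_seven_is_da_only(self, design7):
        res = classify_differential("S", "A", _exclusive_rows(design7, 6), design7, FilterConfig())
        assert res.differential_class is DifferentialClass.da_only
        assert res.mean_log2 is None and res.p_value is None

    def test_small_mean_fails_magnitude_gate(self, design7):
        vals = [0.30, 0.31, 0.29, 0.30, 0.30, 0.31, 0.29]
        res = classify_differential("S", "A", _ratio_rows(vals, design7), design7, FilterConfig())
        assert res.p_value < 0.05  # significant but too small
        assert res.differential_class is DifferentialClass.not_significant

    def test_threshold_is_log2_of_fold_change(self):
        assert round(FilterConfig().log2_threshold, 2) == 0.58

    def test_too_many_missing_is_insufficient(self, design7):
        vals = [1.0, 1.1, None, None, None, 0.9, None]
        res = classify_differential("S", "A", _ratio_rows(vals, design7), design7, FilterConfig())
        assert res.differential_class is DifferentialClass.insufficient_data

    def test_mixed_detection_is_not_qualitative(self, design7):
        rows = _exclusive_rows(design7, 5, 2)
        res = classify_differential("S", "A", rows, design7, FilterConfig())
        assert res.differential_class is DifferentialClass.insufficient_data


class TestDesignSymmetries:
    def _fit(self, observations, design):
        return DifferentialAbundance(observations, design).fit()

    def test_swap_invariance_of_full_experiment(self, small_experiment):
        """Flipping every orientation together with its channel areas is a no-op."""
        post = [o for o in small_experiment.post if o.stage is Stage.POSTsel]
        base = self._fit(post, small_experiment.design)
        flipped_obs = [
            PeptideObservation(
                sequence=o.sequence, accession=o.accession, replicate_id=o.replicate_id,
                stage=o.stage, nterm_mod=o.nterm_mod,
                area_light=o.area_heavy, area_heavy=o.area_light,
            )
            for o in post
        ]
        flipped = self._fit(flipped_obs, small_experiment.design.swapped())
        for a, b in zip(base.results, flipped.results):
            assert (a.sequence, a.differential_class) == (b.sequence, b.differential_class)
            if a.mean_log2 is not None:
                assert a.mean_log2 == pytest.approx(b.mean_log2, abs=1e-12)

    def test_antisymmetry_under_condition_exchange(self, small_experiment):
        """Exchanging CTRL and DA negates ratios and swaps over/under calls."""
        post = [o for o in small_experiment.post if o.stage is Stage.POSTsel]
        base = self._fit(post, small_experiment.design)
        # exchanging the conditions = keeping areas but flipping the design roles
        exchanged = self._fit(
            [
                PeptideObservation(
                    sequence=o.sequence, accession=o.accession, replicate_id=o.replicate_id,
                    stage=o.stage, nterm_mod=o.nterm_mod,
                    area_light=o.area_heavy, area_heavy=o.area_light,
                )
                for o in post
            ],
            small_experiment.design,
        )
        swap = {
            DifferentialClass.over: DifferentialClass.under,
            DifferentialClass.under: DifferentialClass.over,
            DifferentialClass.da_only: DifferentialClass.ctrl_only,
            DifferentialClass.ctrl_only: DifferentialClass.da_only,
        }
        for a, b in zip(base.results, exchanged.results):
            assert b.differential_class is swap.get(a.differential_class, a.differential_class)
            if a.mean_log2 is not None:
                assert b.mean_log2 == pytest.approx(-a.mean_log2, abs=1e-12)


class TestParameterRecovery:
    @staticmethod
    def _simulate_calls(fold, n_peptides, design, rng, sigma=0.3):
        over = 0
        bias = []
        for _ in range(n_peptides):
            vals = math.log2(fold) + rng.normal(0, sigma, size=design.n_replicates)
            res = classify_differential(
                "S", "A", _ratio_rows(vals.tolist(), design), design, FilterConfig()
            )
            bias.append(res.mean_log2 - math.log2(fold))
            over += res.differential_class is DifferentialClass.over
        return over / n_peptides, float(np.mean(bias))

    def test_sensitivity_monotone_and_unbiased(self, design7):
        rng = np.random.default_rng(7)
        sens_null, bias_null = self._simulate_calls(1.0, 170, design7, rng)
        sens_15, _ = self._simulate_calls(1.5, 170, design7, rng)
        sens_20, bias_20 = self._simulate_calls(2.0, 170, design7, rng)
        assert sens_20 > sens_15 > sens_null
        assert abs(bias_null) < 0.05 and abs(bias_20) < 0.05


def test_summary_mentions_thresholds(small_experiment):
    res = DifferentialAbundance(small_experiment.post, small_experiment.design).fit()
    text = res.summary()
    assert "0.58" in text and "over" in text
    frame = res.frame
    assert {"sequence", "mean_log2", "p_value", "class"} <= set(frame.columns)
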