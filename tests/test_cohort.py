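"""Synthetic-cohort generator: planted precision, intakes, covariates, outcomes."""

import numpy as np
import pandas as pd
import pytest

import dietnet as dn
from dietnet.cohort import _SATFAT_FIG
from dietnet.groups import CANONICAL_GROUPS


class TestPlantedPrecision:
    def test_zero_blocks_gives_identity(self):
        structure = dn.PlantedStructure(blocks=())
        omega = dn.build_planted_precision(structure)
        assert np.allclose(omega.to_numpy(), np.eye(39))
        rho = dn.precision_to_partial(omega)
        off = rho.to_numpy()[~np.eye(39, dtype=bool)]
        assert np.all(off == 0)

    def test_saturated_fats_block_reproduces_printed_edges(self):
        """Planted butter-margarine 0.06 and butter-animal fat 0.03 come back exactly."""
        structure = dn.PlantedStructure(blocks=(dn.Block("saturated_fats", _SATFAT_FIG),))
        omega = dn.build_planted_precision(structure)
        rho = dn.precision_to_partial(omega)
        assert rho.loc["butter", "margarine"] == pytest.approx(0.06, abs=1e-10)
        assert rho.loc["butter", "animal_fat"] == pytest.approx(0.03, abs=1e-10)
        assert rho.loc["margarine", "animal_fat"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("rho_target", [-0.8, -0.3, 0.06, 0.5, 0.95])
    def test_single_pair_matches_inversion_oracle(self, rho_target):
        """2x2 block: invert the covariance numerically and read the correlation back."""
        structure = dn.PlantedStructure(blocks=(dn.Block("pair", (("a", "b", rho_target),)),))
        omega = dn.build_planted_precision(structure, groups=("a", "b"))
        cov = np.linalg.inv(omega.to_numpy())
        corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert corr == pytest.approx(rho_target, abs=1e-12)

    def test_infeasible_block_rejected_by_name(self):
        bad = dn.Block("overloaded", (("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9)))
        structure = dn.PlantedStructure(blocks=(bad,))
        with pytest.raises(dn.NotPositiveDefiniteError, match="overloaded"):
            dn.build_planted_precision(structure, groups=("a", "b", "c"))

    def test_boost_recovers_spd_with_shrunken_edges(self):
        bad = dn.Block("overloaded", (("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9)))
        structure = dn.PlantedStructure(blocks=(bad,))
        omega = dn.build_planted_precision(structure, groups=("a", "b", "c"), boost=True)
        assert np.linalg.eigvalsh(omega.to_numpy()).min() > 0
        rho = dn.precision_to_partial(omega)
        # boosting shrinks edges, so magnitudes drop below request
        assert 0 < rho.loc["a", "b"] < 0.9

    def test_unknown_group_rejected(self):
        structure = dn.PlantedStructure(blocks=(dn.Block("x", (("nope", "butter", 0.1),)),))
        with pytest.raises(dn.ValidationError, match="nope"):
            dn.build_planted_precision(structure)

    def test_partial_correlation_out_of_range_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.PlantedStructure(blocks=(dn.Block("x", (("a", "b", 1.0),)),))


class TestSimulateIntakes:
    def test_planted_pair_recovered_from_sample(self, pair_structure):
        """At n=10000 the sample partial correlation sits within 0.03 of 0.30."""
        structure, groups, marginals = pair_structure
        omega = dn.build_planted_precision(structure, groups)
        cfg = dn.CohortConfig(n_subjects=10_000, seed=3, marginals=marginals)
        intakes = dn.simulate_intakes(cfg, omega)
        x = intakes.to_numpy()
        prec = np.linalg.inv(np.cov(x, rowvar=False))
        rho_hat = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert rho_hat == pytest.approx(0.30, abs=0.03)

    def test_identity_precision_gives_independent_columns(self):
        groups = tuple("abcde")
        omega = pd.DataFrame(np.eye(5), index=groups, columns=groups)
        cfg = dn.CohortConfig(
            n_subjects=10_000, seed=5, marginals={g: (0.0, 1.0) for g in groups}
        )
        intakes = dn.simulate_intakes(cfg, omega)
        corr = np.corrcoef(intakes.to_numpy(), rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_butter_marginal_matches_configuration(self):
        """Mean 3.50 and SD 11.5 g/day within 5% at n=10000, no truncation."""
        omega = dn.build_planted_precision(dn.PlantedStructure(blocks=()))
        cfg = dn.CohortConfig(n_subjects=10_000, seed=11)
        intakes = dn.simulate_intakes(cfg, omega)
        butter = intakes["butter"]
        assert butter.mean() == pytest.approx(3.50, rel=0.05)
        assert butter.std(ddof=0) == pytest.approx(11.5, rel=0.05)

    def test_truncation_clips_at_zero(self):
        omega = dn.build_planted_precision(dn.PlantedStructure(blocks=()))
        cfg = dn.CohortConfig(n_subjects=2000, seed=11, truncate_at_zero=True)
        intakes = dn.simulate_intakes(cfg, omega)
        assert (intakes.to_numpy() >= 0).all()

    def test_dimension_mismatch_is_reported(self, pair_structure):
        structure, groups, marginals = pair_structure
        omega = dn.build_planted_precision(structure, groups)
        cfg = dn.CohortConfig(n_subjects=100, seed=0, marginals={"a": (1, 1)})
        with pytest.raises(dn.ValidationError):
            dn.simulate_intakes(cfg, omega)

    def test_seed_determinism_bit_identical(self):
        cfg = lambda: dn.CohortConfig(n_subjects=150, seed=99)
        a = dn.simulate_cohort(cfg())
        b = dn.simulate_cohort(cfg())
        for ta, tb in [(a.intakes, b.intakes), (a.covariates, b.covariates), (a.biomarkers, b.biomarkers)]:
            pd.testing.assert_frame_equal(ta, tb, check_exact=True)


class TestRoundTrip:
    def test_empirical_precision_converges_to_planted(self):
        """Inverse sample covariance approaches the planted 39-group precision."""
        structure = dn.recovery_structure()
        omega = dn.build_planted_precision(structure)
        cfg = dn.CohortConfig(n_subjects=10_000, seed=21)
        intakes = dn.simulate_intakes(cfg, omega)
        z, _ = dn.standardize(intakes)
        x = z.to_numpy()
        S = (x.T @ x) / len(x)
        prec_hat = np.linalg.inv(S)
        d = np.sqrt(np.diag(prec_hat))
        rho_hat = -prec_hat / np.outer(d, d)
        np.fill_diagonal(rho_hat, 1.0)
        rho_true = dn.precision_to_partial(omega).to_numpy()
        assert np.max(np.abs(rho_hat - rho_true)) <= 0.05


class TestSimulateCovariates:
    def test_female_proportion_near_config(self):
        cfg = dn.CohortConfig(n_subjects=850, seed=13)
        cov = dn.simulate_covariates(cfg)
        assert (cov["sex"] == "female").mean() == pytest.approx(0.69, abs=0.03)

    def test_no_male_has_menopause(self):
        cfg = dn.CohortConfig(n_subjects=2000, seed=17)
        cov = dn.simulate_covariates(cfg)
        assert int(cov.loc[cov["sex"] == "male", "menopause"].sum()) == 0

    def test_degenerate_config_yields_constant_columns(self):
        cm = dn.cohort.CovariateModel(
            p_female=1.0,
            education_p=(1.0, 0.0, 0.0),
            occupation_p=(1.0, 0.0, 0.0, 0.0),
            marital_p=(0.0, 1.0, 0.0),
            smoking_p=(1.0, 0.0, 0.0),
            activity_p=(1.0, 0.0, 0.0),
            menopause_p=0.0,
        )
        cfg = dn.CohortConfig(n_subjects=50, seed=1)
        cfg.covariates = cm
        cov = dn.simulate_covariates(cfg)
        for col in ("sex", "education", "occupation", "marital", "smoking", "activity", "menopause"):
            assert cov[col].nunique() == 1

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(dn.ValidationError):
            dn.cohort.CovariateModel(education_p=(0.5, 0.2, 0.2))


class TestSimulateOutcomes:
    def test_unknown_network_name_lists_available(self, small_cohort):
        cfg = dn.CohortConfig(
            n_subjects=100,
            seed=2,
            outcome_model=dn.OutcomeModel(network_effects={"mystery": dn.NetworkEffect()}),
        )
        structure = dn.recovery_structure()
        omega = dn.build_planted_precision(structure)
        intakes = dn.simulate_intakes(cfg, omega)
        cov = dn.simulate_covariates(cfg)
        with pytest.raises(dn.ValidationError, match="saturated_fats"):
            dn.simulate_outcomes(intakes, cov, cfg, structure)

    def test_low_intercept_drives_prevalence_to_zero(self):
        cfg = dn.CohortConfig(
            n_subjects=2000, seed=4, outcome_model=dn.OutcomeModel(intercept=-10.0)
        )
        cohort = dn.simulate_cohort(cfg)
        assert cohort.truth["mets"].mean() < 0.005

    def test_null_effect_gives_or_near_one(self):
        """Planted log-OR 0: crude tertile ORs center on 1 over replicates."""
        ors = []
        for seed in range(10):
            cfg = dn.CohortConfig(
                n_subjects=3000,
                seed=200 + seed,
                outcome_model=dn.OutcomeModel(
                    intercept=-1.1,
                    network_effects={"saturated_fats": dn.NetworkEffect()},
                ),
            )
            cohort = dn.simulate_cohort(cfg)
            t = cohort.truth["network_tertiles"]["saturated_fats"]
            m = cohort.truth["mets"]
            p1, p3 = m[t == "T1"].mean(), m[t == "T3"].mean()
            ors.append((p3 / (1 - p3)) / (p1 / (1 - p1)))
        assert np.mean(ors) == pytest.approx(1.0, abs=0.12)

    def test_prevalence_matches_intercept_when_no_effects(self):
        """All effects zero: empirical prevalence within 2 SE of sigmoid(intercept)."""
        cfg = dn.CohortConfig(n_subjects=5000, seed=31, outcome_model=dn.OutcomeModel(intercept=-1.1))
        cohort = dn.simulate_cohort(cfg)
        p = 1 / (1 + np.exp(1.1))
        se = np.sqrt(p * (1 - p) / 5000)
        assert abs(cohort.truth["mets"].mean() - p) <= 2 * se

    def test_biomarkers_imply_the_drawn_mets_state(self, small_cohort):
        """ATP III classification of the generated biomarkers returns the planted flags."""
        result = dn.classify(small_cohort.biomarkers, small_cohort.covariates["sex"])
        assert (result["mets"].to_numpy() == small_cohort.truth["mets"].to_numpy()).all()
        flags = small_cohort.truth["component_flags"]
        assert (result[flags.columns].to_numpy() == flags.to_numpy()).all()


def test_write_cohort_outputs_tables_and_truth(tmp_path, small_cohort):
    paths = dn.write_cohort(small_cohort, tmp_path)
    assert sorted(p.name for p in tmp_path.iterdir()) == [
        "biomarkers.csv",
        "covariates.csv",
        "intakes.csv",
        "truth.json",
    ]
    import json

    truth = json.loads(paths["truth"].read_text())
    assert {b["name"] for b in truth["blocks"]} == {"healthy", "unhealthy", "saturated_fats"}
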