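import numpy as np
import pandas as pd
import pytest

from gfblup_kit.evaluation import (
    ReliabilityEntry,
    ValidationPlan,
    corrected_phenotypes,
    desaturation_indexes,
    filter_dim,
    make_validation_plan,
    prediction_reliability,
    residual_diagnostics,
    summarize_replicates,
    variance_proportions,
)
from gfblup_kit.mixedmodel import VarianceComponents


class TestFilterDim:
    def test_threshold_inclusive(self):
        ph = pd.DataFrame({"animal_id": list("abcd"), "dim": [3, 59, 60, 278]})
        out = filter_dim(ph, 60)
        assert out["dim"].tolist() == [60, 278]

    def test_zero_is_identity(self):
        ph = pd.DataFrame({"animal_id": list("ab"), "dim": [3, 59]})
        out = filter_dim(ph, 0)
        assert len(out) == 2

    def test_all_removed_flagged(self, caplog):
        ph = pd.DataFrame({"animal_id": list("ab"), "dim": [3, 9]})
        out = filter_dim(ph, 60)
        assert out.empty


class TestDesaturationIndexes:
    def test_formula(self):
        fa = pd.DataFrame(
            {
                "C14:0": [9.0],
                "C14:1": [1.0],
                "C16:0": [30.0],
                "C16:1": [0.0],
                "C18:0": [2.0],
                "C18:1c9": [2.0],
            }
        )
        out = desaturation_indexes(fa)
        assert out["C14_index"].iloc[0] == pytest.approx(10.0)
        assert out["C16_index"].iloc[0] == pytest.approx(0.0)
        assert out["C18_index"].iloc[0] == pytest.approx(50.0)

    def test_zero_denominator_missing(self):
        fa = pd.DataFrame(
            {
                "C14:0": [0.0],
                "C14:1": [0.0],
                "C16:0": [1.0],
                "C16:1": [1.0],
                "C18:0": [1.0],
                "C18:1c9": [1.0],
            }
        )
        out = desaturation_indexes(fa)
        assert np.isnan(out["C14_index"].iloc[0])
        assert out["C16_index"].iloc[0] == pytest.approx(50.0)

    def test_range(self):
        rng = np.random.default_rng(0)
        fa = pd.DataFrame(
            {
                name: rng.uniform(0.1, 30, 50)
                for name in ["C14:0", "C14:1", "C16:0", "C16:1", "C18:0", "C18:1c9"]
            }
        )
        out = desaturation_indexes(fa)
        assert ((out > 0) & (out < 100)).all().all()


class _FakeFit:
    """Minimal stand-in carrying fitted values and residuals."""

    def __init__(self, fitted, residuals):
        self.fitted = np.asarray(fitted, dtype=float)
        self.residuals = np.asarray(residuals, dtype=float)


class TestResidualDiagnostics:
    def test_heteroscedastic_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fitted = rng.uniform(5, 20, 500)
            resid = rng.normal(0, 0.3 * fitted)  # SD proportional to mean
            verdict = residual_diagnostics(_FakeFit(fitted, resid))
            hits += verdict["recommend_log_transform"]
        assert hits == 10

    def test_homoscedastic_keep(self):
        keeps = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            fitted = rng.uniform(5, 20, 500)
            resid = rng.normal(0, 1.0, 500)
            verdict = residual_diagnostics(_FakeFit(fitted, resid))
            keeps += not verdict["recommend_log_transform"]
        assert keeps >= 9

    def test_insufficient_data(self):
        verdict = residual_diagnostics(_FakeFit([1, 2, 3], [0.1, -0.1, 0.2]))
        assert verdict["verdict"] == "insufficient_data"
        assert verdict["recommend_log_transform"] is None

    def test_degenerate_residuals(self):
        verdict = residual_diagnostics(_FakeFit(np.arange(20), np.zeros(20)))
        assert verdict["verdict"] == "degenerate"

    def test_plot_emitted(self, tmp_path):
        rng = np.random.default_rng(0)
        path = tmp_path / "resid.png"
        residual_diagnostics(
            _FakeFit(rng.uniform(0, 1, 50), rng.normal(size=50)), plot_path=path
        )
        assert path.exists()


def _pedigree_phenos(n_groups=6, group_size=150):
    rows = []
    for g in range(n_groups):
        for i in range(group_size):
            rows.append(
                {
                    "animal_id": f"s{g}_c{i}",
                    "sire_id": f"sire{g}",
                    "dam_id": f"dam_{g}_{i}",
                    "population": "pop1",
                }
            )
    return pd.DataFrame(rows)


class TestValidationPlans:
    def test_sire_group_holdout_structure(self):
        ph = _pedigree_phenos()
        plans = make_validation_plan(ph, "sire_group_holdout", n_val=100, n_reps=5, seed=1)
        sire_of = dict(zip(ph["animal_id"], ph["sire_id"]))
        for plan in plans:
            val_sires = {sire_of[i] for i in plan.validation_ids}
            assert len(val_sires) == 1  # all validation cows share one sire
            assert len(plan.validation_ids) == 100
            assert len(plan.excluded_ids) == 50  # rest of the 150-cow group
            (the_sire,) = val_sires
            # no cow of that sire remains in the reference
            assert all(sire_of[i] != the_sire for i in plan.reference_ids)
            assert len(plan.reference_ids) == 5 * 150

    def test_unrelated_subset(self):
        # 120 singleton-sire cows plus two big sib groups
        singles = pd.DataFrame(
            {
                "animal_id": [f"u{i}" for i in range(120)],
                "sire_id": [f"us{i}" for i in range(120)],
                "dam_id": [f"ud{i}" for i in range(120)],
                "population": "pop1",
            }
        )
        ph = pd.concat([_pedigree_phenos(2, 100), singles], ignore_index=True)
        plans = make_validation_plan(ph, "unrelated_subset", n_val=100, n_reps=5, seed=2)
        for plan in plans:
            assert len(plan.validation_ids) == 100
            assert all(str(i).startswith("u") for i in plan.validation_ids)
            # everyone else is reference (eligible non-sampled return)
            assert len(plan.reference_ids) == len(ph) - 100
            assert len(plan.excluded_ids) == 0

    def test_unrelated_subset_guard(self):
        ph = _pedigree_phenos(3, 50)  # every cow has half sibs
        with pytest.raises(ValueError, match="eligible"):
            make_validation_plan(ph, "unrelated_subset", n_val=10, n_reps=1, seed=0)

    def test_sire_group_guard(self):
        ph = _pedigree_phenos(6, 30)
        with pytest.raises(ValueError, match="sire group"):
            make_validation_plan(ph, "sire_group_holdout", n_val=100, n_reps=1, seed=0)

    def test_deterministic(self):
        ph = _pedigree_phenos()
        a = make_validation_plan(ph, "sire_group_holdout", 100, 5, seed=9)
        b = make_validation_plan(ph, "sire_group_holdout", 100, 5, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.validation_ids, pb.validation_ids)
            np.testing.assert_array_equal(pa.reference_ids, pb.reference_ids)

    def test_plan_invariants_mass(self):
        ph = _pedigree_phenos()
        for strategy in ("sire_group_holdout",):
            plans = make_validation_plan(ph, strategy, 100, 50, seed=3)
            for plan in plans:
                assert not set(plan.validation_ids) & set(plan.reference_ids)
                assert not set(plan.excluded_ids) & set(plan.reference_ids)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            ValidationPlan(
                replicate=1,
                strategy="sire_group_holdout",
                validation_ids=np.array(["a", "b"], dtype=object),
                reference_ids=np.array(["b", "c"], dtype=object),
                excluded_ids=np.array([], dtype=object),
            )


class TestCorrectedPhenotypes:
    def test_construction_oracle(self, medium_dataset):
        from gfblup_kit.kinship import vanraden_grm
        from gfblup_kit.mixedmodel import blup_solve, build_fixed_design, reml_fit

        cfg, (geno, phen, tgv, _) = medium_dataset
        grm = vanraden_grm(geno)
        X = build_fixed_design(phen)
        y = phen["trait"].to_numpy()
        vc = reml_fit(y, X, [grm], names=["g"])
        fit = blup_solve(y, X, [grm], vc, names=["g"])
        y_corr = corrected_phenotypes(phen, "trait", fit)
        # corrected phenotype should track g + e; at these sizes the fixed
        # effects are well estimated, so correlation is very high
        assert len(y_corr) == len(phen)
        # reconstruct g+e as y minus the true fixed part up to the mean:
        # use correlation with (y - fitted fixed part of the truth) proxy g
        r = np.corrcoef(y_corr.to_numpy(), tgv.total)[0, 1]
        assert r > 0.5  # contains the genetic signal

    def test_zero_fit_identity(self):
        from gfblup_kit.mixedmodel import FixedDesign, ModelFit, VarianceComponents

        n = 10
        ids = np.array([f"a{i}" for i in range(n)], dtype=object)
        X = FixedDesign(np.ones((n, 1)), ["mu"], ids)
        fit = ModelFit(
            beta=pd.Series([0.0], index=["mu"]),
            gbv={"g": np.zeros(n)},
            individual_ids=ids,
            vc=VarianceComponents(genetic={"g": 1.0}, residual=1.0),
            fitted=np.zeros(n),
            residuals=np.zeros(n),
            observed_ids=ids,
            design=X,
        )
        ph = pd.DataFrame({"animal_id": ids, "trait": np.arange(n, dtype=float)})
        y_corr = corrected_phenotypes(ph, "trait", fit)
        np.testing.assert_allclose(y_corr.to_numpy(), np.arange(n, dtype=float))

    def test_translation_invariance(self, medium_dataset):
        from gfblup_kit.kinship import vanraden_grm
        from gfblup_kit.mixedmodel import blup_solve, build_fixed_design, reml_fit

        cfg, (geno, phen, tgv, _) = medium_dataset
        grm = vanraden_grm(geno)
        X = build_fixed_design(phen)
        y = phen["trait"].to_numpy()
        vc = reml_fit(y, X, [grm], names=["g"])
        fit_a = blup_solve(y, X, [grm], vc, names=["g"])
        yc_a = corrected_phenotypes(phen, "trait", fit_a)

        phen_b = phen.assign(trait=phen["trait"] + 50.0)
        vc_b = reml_fit(y + 50.0, X, [grm], names=["g"])
        fit_b = blup_solve(y + 50.0, X, [grm], vc_b, names=["g"])
        yc_b = corrected_phenotypes(phen_b, "trait", fit_b)
        np.testing.assert_allclose(yc_a.to_numpy(), yc_b.to_numpy(), atol=1e-6)

    def test_absent_cow_raises(self):
        from gfblup_kit.mixedmodel import FixedDesign, ModelFit, VarianceComponents

        ids = np.array(["a1", "a2", "a3"], dtype=object)
        X = FixedDesign(np.ones((3, 1)), ["mu"], ids)
        fit = ModelFit(
            beta=pd.Series([1.0], index=["mu"]),
            gbv={"g": np.zeros(3)},
            individual_ids=ids,
            vc=VarianceComponents(genetic={"g": 1.0}, residual=1.0),
            fitted=np.zeros(3),
            residuals=np.zeros(3),
            observed_ids=ids,
            design=X,
        )
        ph = pd.DataFrame({"animal_id": ["a1", "zz"], "trait": [1.0, 2.0]})
        with pytest.raises(KeyError):
            corrected_phenotypes(ph, "trait", fit)


class TestPredictionReliability:
    def test_exact_one(self):
        rng = np.random.default_rng(0)
        # construct y with sample correlation exactly 0.5 to gbv:
        # mix the standardized gbv with an exactly orthogonal unit vector
        gbv = np.array([0.0, 1.0, 2.0, 3.0] * 10)
        u = gbv - gbv.mean()
        u /= u.std()
        w = rng.normal(size=len(gbv))
        w -= w.mean()
        w -= (w @ u) / (u @ u) * u
        w /= w.std()
        y = 0.5 * u + np.sqrt(1 - 0.25) * w
        entry = prediction_reliability(gbv, y, h2=0.25)
        assert entry.correlation == pytest.approx(0.5, abs=1e-10)
        assert entry.reliability == pytest.approx(1.0, abs=1e-9)

    def test_null_gbv(self):
        rng = np.random.default_rng(1)
        small = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            gbv = r.normal(size=100)
            y = r.normal(size=100)
            entry = prediction_reliability(gbv, y, h2=0.4)
            small += entry.reliability < 0.1
        assert small >= 9

    def test_perfect_prediction(self):
        y = np.arange(10, dtype=float)
        entry = prediction_reliability(y, y, h2=1.0)
        assert entry.reliability == pytest.approx(1.0)
        assert entry.slope == pytest.approx(1.0)
        assert not entry.flagged_above_one

    def test_above_one_flagged(self):
        y = np.arange(10, dtype=float)
        entry = prediction_reliability(y, y, h2=0.5)
        assert entry.reliability == pytest.approx(2.0)
        assert entry.flagged_above_one

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        gbv = rng.normal(size=50)
        y = gbv + rng.normal(size=50)
        e1 = prediction_reliability(gbv, y, 0.4)
        e2 = prediction_reliability(3.0 * gbv - 7.0, y, 0.4)
        assert e2.reliability == pytest.approx(e1.reliability, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            prediction_reliability(np.ones(10), np.arange(10.0), 0.4)

    def test_bad_h2(self):
        with pytest.raises(ValueError):
            prediction_reliability(np.arange(10.0), np.arange(10.0), 0.0)


class TestVarianceProportions:
    def test_eq3_arithmetic(self):
        vc = VarianceComponents(
            genetic={"c14": 2.0, "c19": 1.0, "c26": 1.0, "rest": 4.0}, residual=1.0
        )
        table = variance_proportions(vc)
        assert table.proportions == pytest.approx(
            {"c14": 25.0, "c19": 12.5, "c26": 12.5, "rest": 50.0}
        )

    def test_single_component(self):
        vc = VarianceComponents(genetic={"c14": 0.7, "rest": 0.0}, residual=1.0)
        assert variance_proportions(vc).proportions["c14"] == pytest.approx(100.0)

    def test_scale_invariance(self):
        a = VarianceComponents(genetic={"x": 1.0, "y": 3.0}, residual=1.0)
        b = VarianceComponents(genetic={"x": 3.0, "y": 9.0}, residual=1.0)
        assert variance_proportions(a).proportions == pytest.approx(
            variance_proportions(b).proportions
        )

    def test_zero_total_raises(self):
        vc = VarianceComponents(genetic={"x": 0.0}, residual=1.0)
        with pytest.raises(ValueError):
            variance_proportions(vc)


class TestSummarizeReplicates:
    def _entry(self, rep, r, rel=None):
        return ReliabilityEntry(
            replicate=rep,
            correlation=r,
            reliability=rel if rel is not None else r ** 2 / 0.4,
            slope=1.0,
            n_validation=100,
        )

    def test_constant_correlations_zero_mad(self):
        entries = [self._entry(i, 0.3) for i in range(1, 6)]
        report = summarize_replicates(entries, h2=0.4)
        assert report.mad_correlation == pytest.approx(0.0)

    def test_two_values(self):
        entries = [self._entry(1, 0.2), self._entry(2, 0.4)]
        report = summarize_replicates(entries, h2=0.4)
        assert report.mean_correlation == pytest.approx(0.3)
        assert report.mad_correlation == pytest.approx(0.1)

    def test_mean_reliability(self):
        entries = [
            self._entry(1, 0.1, rel=0.1),
            self._entry(2, 0.1, rel=0.2),
            self._entry(3, 0.1, rel=0.3),
        ]
        report = summarize_replicates(entries, h2=0.4)
        assert report.mean_reliability == pytest.approx(0.2)
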