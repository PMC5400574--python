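import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpmeta.contingency import GeneticModel, model_tables
from snpmeta.pooling import (
    EffectEstimate,
    PoolingMethod,
    meta_analyse,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
    study_effect,
)
from conftest import make_fourfold


def iv_textbook(thetas, ses):
    """Independent plain-Python inverse-variance pooling (the textbook way)."""
    w = [1.0 / s**2 for s in ses]
    pooled = sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)
    se = math.sqrt(1.0 / sum(w))
    Q = sum(wi * (ti - pooled) ** 2 for wi, ti in zip(w, thetas))
    return pooled, se, Q


class TestStudyEffect:
    def test_saudi_homozygote_table(self):
        table = make_fourfold(2, 53, 5, 58, GeneticModel.HOMOZYGOTE)
        effect = study_effect(table)
        assert effect.or_value == pytest.approx(116 / 265)
        assert effect.se == pytest.approx(
            math.sqrt(1 / 2 + 1 / 53 + 1 / 5 + 1 / 58)
        )

    def test_balanced_table_has_unit_odds_ratio(self):
        effect = study_effect(make_fourfold(10, 10, 10, 10))
        assert effect.log_or == pytest.approx(0.0)
        assert effect.or_value == pytest.approx(1.0)
        assert effect.se == pytest.approx(math.sqrt(0.4))

    def test_ci_is_log_symmetric_around_estimate(self):
        effect = study_effect(make_fourfold(12, 34, 56, 78))
        lo, hi = effect.ci95
        assert lo < effect.or_value < hi
        assert math.sqrt(lo * hi) == pytest.approx(effect.or_value)

    def test_zero_cell_without_correction_is_undefined(self):
        with pytest.raises(ValueError, match="zero cell"):
            study_effect(make_fourfold(0, 10, 10, 10))


class TestFixedIV:
    def test_single_effect_identity(self):
        effect = EffectEstimate(log_or=0.3, se=0.1)
        pooled = pool_fixed_iv([effect])
        assert pooled.log_or == pytest.approx(0.3)
        assert pooled.se == pytest.approx(0.1)
        assert pooled.Q == pytest.approx(0.0)

    def test_two_opposed_unit_effects(self):
        effects = [EffectEstimate(1.0, 1.0), EffectEstimate(-1.0, 1.0)]
        pooled = pool_fixed_iv(effects)
        assert pooled.log_or == pytest.approx(0.0)
        assert pooled.Q == pytest.approx(2.0)
        # P(chi2_1 > 2) = 0.15729...
        assert pooled.p_Q == pytest.approx(0.1572992, abs=1e-6)

    def test_equal_weights_give_arithmetic_mean(self):
        effects = [EffectEstimate(t, 0.5) for t in (0.1, 0.4, 0.7)]
        pooled = pool_fixed_iv(effects)
        assert pooled.log_or == pytest.approx(0.4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            pool_fixed_iv([])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-2, max_value=2),
                st.floats(min_value=0.05, max_value=2.0),
            ),
            min_size=1,
            max_size=3,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_oracle(self, pairs):
        effects = [EffectEstimate(t, s) for t, s in pairs]
        pooled = pool_fixed_iv(effects)
        exp_theta, exp_se, exp_Q = iv_textbook(
            [t for t, _ in pairs], [s for _, s in pairs]
        )
        assert pooled.log_or == pytest.approx(exp_theta, abs=1e-12)
        assert pooled.se == pytest.approx(exp_se, abs=1e-12)
        assert pooled.Q == pytest.approx(exp_Q, abs=1e-12)


class TestFixedMH:
    def test_single_study_identity(self):
        table = make_fourfold(2, 53, 5, 58, GeneticModel.HOMOZYGOTE)
        pooled = pool_fixed_mh([table])
        assert pooled.or_value == pytest.approx(116 / 265)
        assert pooled.k == 1
        assert pooled.I2 == 0.0

    def test_identical_balanced_studies(self):
        tables = [make_fourfold(10, 10, 10, 10)] * 2
        pooled = pool_fixed_mh(tables)
        assert pooled.or_value == pytest.approx(1.0)
        assert pooled.Q == pytest.approx(0.0)
        assert pooled.I2 == 0.0

    def test_single_study_variance_reduces_to_woolf(self):
        # With one stratum the Robins-Breslow-Greenland variance equals
        # the plain 1/a + 1/b + 1/c + 1/d.
        table = make_fourfold(12, 34, 56, 78)
        pooled = pool_fixed_mh([table])
        assert pooled.se == pytest.approx(study_effect(table).se)

    def test_agrees_with_iv_on_fixture_all_models(self, fixture_table):
        for model in GeneticModel:
            tables, _ = model_tables(fixture_table, model)
            mh = pool_fixed_mh(tables)
            iv = pool_fixed_iv([study_effect(t) for t in tables])
            assert abs(mh.or_value - iv.or_value) < 0.02
            # identical heterogeneity by construction
            assert mh.Q == pytest.approx(iv.Q)


class TestRandomDL:
    def test_two_opposed_unit_effects_give_unit_tau2(self):
        effects = [EffectEstimate(1.0, 1.0), EffectEstimate(-1.0, 1.0)]
        pooled = pool_random_dl(effects)
        # Q=2, k=2, sum w = 2, sum w^2/sum w = 1 -> tau2 = (2-1)/1 = 1
        assert pooled.tau2 == pytest.approx(1.0)
        assert pooled.log_or == pytest.approx(0.0)

    def test_homogeneous_effects_collapse_to_fixed_iv(self):
        effects = [EffectEstimate(0.2, 0.3), EffectEstimate(0.2, 0.4)]
        random = pool_random_dl(effects)
        fixed = pool_fixed_iv(effects)
        assert random.tau2 == 0.0
        assert random.log_or == pytest.approx(fixed.log_or)
        assert random.se == pytest.approx(fixed.se)

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pool_random_dl([EffectEstimate(0.0, 1.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-2, max_value=2),
                st.floats(min_value=0.05, max_value=2.0),
            ),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_random_ci_never_narrower_than_fixed(self, pairs):
        effects = [EffectEstimate(t, s) for t, s in pairs]
        random = pool_random_dl(effects)
        fixed = pool_fixed_iv(effects)
        assert random.tau2 >= 0.0
        assert random.se >= fixed.se - 1e-12
        assert 0.0 <= random.I2 <= 100.0


class TestSelectModel:
    @pytest.mark.parametrize(
        "p_Q, I2, expected",
        [
            (0.286, 15.3, PoolingMethod.FIXED_IV),
            (0.002, 59.3, PoolingMethod.RANDOM_DL),
            (0.05, 10.0, PoolingMethod.RANDOM_DL),
            (0.5, 80.0, PoolingMethod.RANDOM_DL),
            # boundary: the rule uses strict inequalities
            (0.1, 50.0, PoolingMethod.FIXED_IV),
        ],
    )
    def test_heterogeneity_rule(self, p_Q, I2, expected):
        assert select_model(p_Q, I2) == expected


class TestMetaAnalyse:
    def test_fixture_homozygote_reproduces_published_pool(self, fixture_table):
        tables, _ = model_tables(fixture_table, GeneticModel.HOMOZYGOTE)
        pooled = meta_analyse(tables)
        assert pooled.method is PoolingMethod.FIXED_MH
        lo, hi = pooled.ci95
        assert round(pooled.or_value, 2) == 0.55
        assert round(lo, 2) == 0.49
        assert round(hi, 2) == 0.61

    def test_fixture_allele_reproduces_published_pool(self, fixture_table):
        tables, _ = model_tables(fixture_table, GeneticModel.ALLELE)
        pooled = meta_analyse(tables)
        assert pooled.method is PoolingMethod.RANDOM_DL
        lo, hi = pooled.ci95
        assert round(pooled.or_value, 2) == 0.79
        assert round(lo, 2) == 0.72
        assert round(hi, 2) == 0.87

    def test_significance_matches_ci_exclusion_of_unity(self, fixture_table):
        for model in GeneticModel:
            tables, _ = model_tables(fixture_table, model)
            pooled = meta_analyse(tables)
            lo, hi = pooled.ci95
            assert (pooled.p < 0.05) == (hi < 1.0 or lo > 1.0)

    def test_force_method_overrides_selection(self, fixture_table):
        tables, _ = model_tables(fixture_table, GeneticModel.HOMOZYGOTE)
        forced = meta_analyse(tables, force_method=PoolingMethod.RANDOM_DL)
        assert forced.method is PoolingMethod.RANDOM_DL


METAFOR_TABLES = [(12, 30, 20, 25), (8, 40, 15, 35), (25, 50, 30, 45)]


@pytest.fixture(scope="module")
def metafor_results():
    import json
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    ai = ",".join(str(t[0]) for t in METAFOR_TABLES)
    bi = ",".join(str(t[1]) for t in METAFOR_TABLES)
    ci = ",".join(str(t[2]) for t in METAFOR_TABLES)
    di = ",".join(str(t[3]) for t in METAFOR_TABLES)
    script = (
        "suppressMessages(library(metafor));"
        f"ai<-c({ai});bi<-c({bi});ci<-c({ci});di<-c({di});"
        "mh<-rma.mh(ai=ai,bi=bi,ci=ci,di=di,measure='OR',add=0,to='none',correct=FALSE);"
        "dl<-rma(measure='OR',ai=ai,bi=bi,ci=ci,di=di,method='DL',add=0,to='none');"
        "cat(jsonlite::toJSON(list(mh_b=mh$beta[1],dl_b=dl$beta[1],"
        "dl_tau2=dl$tau2,Q=dl$QE),digits=12,auto_unbox=TRUE))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    if out.returncode != 0:
        pytest.skip(f"metafor unavailable: {out.stderr[-200:]}")
    return json.loads(out.stdout)


class TestMetaforCrossCheck:
    """Independent validation against R's metafor on a toy 3-study set."""

    def test_mantel_haenszel_point_estimate(self, metafor_results):
        tables = [make_fourfold(*t) for t in METAFOR_TABLES]
        pooled = pool_fixed_mh(tables)
        assert pooled.log_or == pytest.approx(metafor_results["mh_b"], abs=1e-8)

    def test_dersimonian_laird_estimate_and_tau2(self, metafor_results):
        effects = [study_effect(make_fourfold(*t)) for t in METAFOR_TABLES]
        pooled = pool_random_dl(effects)
        assert pooled.log_or == pytest.approx(metafor_results["dl_b"], abs=1e-8)
        assert pooled.tau2 == pytest.approx(metafor_results["dl_tau2"], abs=1e-8)
        assert pooled.Q == pytest.approx(metafor_results["Q"], abs=1e-8)
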