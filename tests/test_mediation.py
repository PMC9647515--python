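"""Moderated mediation: path assembly, indirect effects, contrasts, P_M."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from esm_mediation import (
    ConfigurationError,
    EstimationError,
    GROUPS,
    GeneratorConfig,
    GroupPaths,
    ModeratedMediation,
    MonteCarloEngine,
    PathEstimates,
    apply_compliance_filter,
    apply_lateness_filter,
    conditional_indirect,
    contrast_indirect,
    fit_moderated_mediation,
    fit_two_level,
    generate_dataset,
    proportion_mediated,
)


def _pe(a, b, var=1e-6):
    """Hand-built PathEstimates with diagonal covariances."""
    eye = pd.DataFrame(np.eye(3) * var, index=GROUPS, columns=GROUPS)
    return PathEstimates(
        direction="x2y",
        a=dict(zip(GROUPS, a)),
        b=dict(zip(GROUPS, b)),
        c_prime={g: 0.1 for g in GROUPS},
        c_total={g: 0.3 for g in GROUPS},
        cov_a=eye, cov_b=eye, cov_c_prime=eye, cov_c_total=eye,
    )


def _sim(paths, n=40, seed=7, **kw):
    cfg = GeneratorConfig(
        n_subjects={"control": n, "relative": n, "patient": n},
        paths=paths,
        seed=seed,
        **kw,
    )
    ds, truth = generate_dataset(cfg)
    return apply_compliance_filter(apply_lateness_filter(ds)), truth


class TestPointArithmetic:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.0, 0.9, 0.0), (0.5, 0.4, 0.2), (-0.3, 0.2, -0.06)]
    )
    def test_conditional_indirect_is_product(self, a, b, expected):
        pe = _pe([a] * 3, [b] * 3)
        assert conditional_indirect(pe, "control") == pytest.approx(expected)

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown group"):
            conditional_indirect(_pe([0.1] * 3, [0.1] * 3), "sibling")

    @pytest.mark.parametrize(
        "indirect,total,pm,flag",
        [
            (0.2, 0.29, 0.69, False),
            (0.2, 0.15, 4 / 3, True),   # direct = -0.05, opposite sign
            (0.0, 0.5, 0.0, False),
        ],
    )
    def test_proportion_mediated(self, indirect, total, pm, flag):
        got_pm, got_flag = proportion_mediated(indirect, total)
        assert got_pm == pytest.approx(pm, abs=0.005)
        assert got_flag is flag

    def test_proportion_mediated_zero_total_undefined(self):
        pm, flag = proportion_mediated(0.2, 0.0)
        assert np.isnan(pm) and flag is False

    @given(
        indirect=st.floats(-2, 2, allow_subnormal=False),
        direct=st.floats(-2, 2, allow_subnormal=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_proportion_mediated_decomposition_properties(self, indirect, direct):
        """P_M reconstructs the decomposition; the flag marks sign conflict."""
        total = indirect + direct
        assume(abs(total) > 1e-6)
        pm, flag = proportion_mediated(indirect, total)
        assert pm * total == pytest.approx(indirect, rel=1e-9, abs=1e-12)
        if flag:
            assert indirect * direct < 0
            # under suppression P_M leaves [0, 1]: negative when the direct
            # effect dominates, above 1 when the indirect effect does
            assert pm < 1e-9 or pm > 1.0 - 1e-9


class TestContrasts:
    def test_point_is_exact_difference_of_products(self):
        pe = _pe([0.52, 0.475, 0.4], [1.0, 1.0, 1.0])
        eng = MonteCarloEngine(reps=2000, seed=0)
        c = contrast_indirect(pe, "patient", "control", eng)
        assert c.point == pytest.approx(
            conditional_indirect(pe, "patient") - conditional_indirect(pe, "control")
        )

    def test_antisymmetry(self):
        pe = _pe([0.5, 0.3, 0.2], [0.4, 0.4, 0.4])
        eng = MonteCarloEngine(reps=2000, seed=5)
        ab = contrast_indirect(pe, "patient", "relative", eng)
        ba = contrast_indirect(pe, "relative", "patient", eng)
        assert ab.point == pytest.approx(-ba.point)

    def test_same_group_rejected(self):
        pe = _pe([0.1] * 3, [0.1] * 3)
        with pytest.raises(ConfigurationError, match="distinct"):
            contrast_indirect(pe, "control", "control", MonteCarloEngine(seed=0))


class TestDecompositionOracle:
    def test_total_equals_direct_plus_indirect_in_ols_reduction(self, rng):
        # classic single-level identity c = c' + a*b, exact for OLS fits
        # sharing regressors; serves as oracle for the path assembly
        n = 600
        x = rng.normal(size=n)
        age = rng.normal(40, 10, n)
        m = 1.0 + 0.5 * x + 0.02 * age + rng.normal(size=n)
        y = 0.5 + 0.3 * x + 0.4 * m + 0.01 * age + rng.normal(size=n)
        df = pd.DataFrame(
            {"x": x, "m": m, "y": y, "age": age, "subject_id": np.arange(n)}
        )
        fm = fit_two_level("m ~ x + age", df, re_formula=None)
        fo = fit_two_level("y ~ x + m + age", df, re_formula=None)
        ft = fit_two_level("y ~ x + age", df, re_formula=None)
        a, b = fm.params["x"], fo.params["m"]
        c_prime, c = fo.params["x"], ft.params["x"]
        assert c == pytest.approx(c_prime + a * b, abs=1e-6)


class TestModelFitting:
    def test_direction_swap_exchanges_roles(self):
        paths = {g: GroupPaths(a=0.5, b=0.4, c_prime=0.1) for g in GROUPS}
        ds, truth = _sim(paths, n=30)
        m_fwd = ModeratedMediation(ds, direction="x2y")
        m_rev = ModeratedMediation(ds, direction="y2x")
        # forward: source is stress; reverse: source is psychotic experiences
        assert m_fwd.frame["src"].equals(
            ds.valid_frame()["stress"].rename("src")
        )
        assert m_rev.frame["src"].equals(
            ds.valid_frame()["psychotic_experiences"].rename("src")
        )

    def test_recovers_group_difference_in_a_path(self):
        paths = {
            "control": GroupPaths(a=0.2, b=0.4, c_prime=0.1),
            "relative": GroupPaths(a=0.4, b=0.4, c_prime=0.1),
            "patient": GroupPaths(a=0.6, b=0.4, c_prime=0.1),
        }
        ds, truth = _sim(paths, n=60, seed=13)
        pe = fit_moderated_mediation(ds, direction="x2y")
        diff = pe.a["patient"] - pe.a["control"]
        se = np.sqrt(
            pe.cov_a.loc["patient", "patient"]
            + pe.cov_a.loc["control", "control"]
            - 2 * pe.cov_a.loc["patient", "control"]
        )
        assert diff == pytest.approx(0.4, abs=3 * se)
        assert abs(diff - 0.4) < 0.1

    def test_homogeneous_paths_give_null_interactions(self):
        paths = {g: GroupPaths(a=0.4, b=0.35, c_prime=0.1) for g in GROUPS}
        ds, _ = _sim(paths, n=50, seed=21)
        pe = fit_moderated_mediation(ds, direction="x2y")
        fmed = pe.fits["mediator"]
        for term in ("src:W[T.relative]", "src:W[T.patient]"):
            est = fmed.params[term]
            se = fmed.bse()[term]
            assert abs(est) < 4 * se

    def test_missing_group_is_estimation_error(self):
        paths = {g: GroupPaths(a=0.4, b=0.3) for g in GROUPS}
        ds, _ = _sim(paths, n=12, seed=2)
        frame = ds.valid_frame()
        frame = frame[frame["group"] != "relative"]
        with pytest.raises(EstimationError, match="relative"):
            ModeratedMediation(frame, direction="x2y")

    def test_suppression_flagged_and_pm_above_one(self):
        from esm_mediation import scenario

        cfg = scenario(
            "suppression",
            n_subjects={"control": 40, "relative": 30, "patient": 40},
            seed=31,
        )
        ds, _ = generate_dataset(cfg)
        ds = apply_compliance_filter(apply_lateness_filter(ds))
        res = ModeratedMediation(ds, direction="x2y").fit(
            MonteCarloEngine(reps=2000, seed=1)
        )
        # true indirect 0.16 vs direct -0.08: P_M = 2 with the flag set
        pm, flag = res.prop_mediated["control"]
        assert flag
        assert pm > 1.0
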