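"""Adjusted association models, partial eta-squared, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainage import (
    PanelVariable,
    default_panel,
    fdr_adjust,
    fit_association,
    partial_eta_squared,
    run_panel,
)


def test_partial_eta_squared_formula():
    # t=10.208 with 14693 residual df -> eta_p^2 ~ 0.0070
    assert partial_eta_squared(10.208, 14693) == pytest.approx(0.00704, abs=5e-5)
    assert partial_eta_squared(0.0, 100) == 0.0


def _cohort_frame(rng, n=2000, effect=2.0):
    age = rng.uniform(45, 80, n)
    sex = rng.choice(["F", "M"], n)
    height = np.where(sex == "F", 162, 176) + rng.normal(0, 6, n)
    diabetes = (rng.random(n) < 0.3).astype(int)
    delta = rng.normal(0, 4, n) + effect * diabetes
    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "height": height,
            "vol_scaling": rng.normal(1.3, 0.1, n),
            "head_motion": rng.lognormal(np.log(0.12), 0.25, n),
            "diabetes": diabetes,
            "alcohol_freq": rng.choice([1, 2, 3, 4, 5, 6, -3], n, p=[0.2, 0.2, 0.2, 0.15, 0.1, 0.1, 0.05]),
            "noise_var": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    pad = pd.Series(delta, index=df.index, name="brain_pad")
    return df, pad


def test_binary_effect_recovered_within_2se(rng):
    df, pad = _cohort_frame(rng, effect=2.0)
    res = fit_association(pad, df, PanelVariable("diabetes", kind="binary"))
    assert abs(res.estimate - 2.0) < 2 * res.std_error
    assert res.p_value < 1e-6
    assert res.partial_eta_sq == pytest.approx(
        res.t_value**2 / (res.t_value**2 + (res.n_used - 8)), rel=1e-6
    )


def test_null_variable_estimate_near_zero(rng):
    hits = 0
    for rep in range(40):
        r = np.random.default_rng(1000 + rep)
        df, pad = _cohort_frame(r, n=400, effect=0.0)
        res = fit_association(pad, df, PanelVariable("noise_var"))
        if abs(res.estimate) <= 2 * res.std_error:
            hits += 1
    assert hits >= 35  # ~95% coverage of zero across replicates


def test_special_codes_excluded_complete_case(rng):
    df, pad = _cohort_frame(rng)
    res = fit_association(
        pad, df, PanelVariable("alcohol_freq", kind="ordinal", missing_codes=(-3,))
    )
    n_refused = int((df["alcohol_freq"] == -3).sum())
    assert n_refused > 0
    assert res.n_used == len(df) - n_refused


def test_orthogonal_covariates_leave_group_difference_unchanged(rng):
    """With covariates orthogonal to the variable, adjustment changes nothing."""
    n = 64
    group = np.repeat([0.0, 1.0], n // 2)
    cov = np.tile([-1.5, -0.5, 0.5, 1.5], n // 4)  # balanced within both groups
    pad_vals = 1.7 * group + 0.8 * cov + rng.normal(0, 0.1, n)
    df = pd.DataFrame(
        {"grp": group, "cov": cov}, index=[f"s{i}" for i in range(n)]
    )
    pad = pd.Series(pad_vals, index=df.index)
    adjusted = fit_association(pad, df, PanelVariable("grp", kind="binary"), covariates=("cov",))
    unadjusted = pad_vals[group == 1].mean() - pad_vals[group == 0].mean()
    assert adjusted.estimate == pytest.approx(unadjusted, abs=1e-10)


def test_constant_variable_rejected(rng):
    df, pad = _cohort_frame(rng, n=100)
    df["flat"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        fit_association(pad, df, PanelVariable("flat"))


def test_missing_variable_or_covariate_named(rng):
    df, pad = _cohort_frame(rng, n=100)
    with pytest.raises(KeyError, match="nope"):
        fit_association(pad, df, PanelVariable("nope"))
    df2 = df.drop(columns=["height"])
    with pytest.raises(KeyError, match="height"):
        fit_association(pad, df2, PanelVariable("diabetes"))


def brute_force_bh(p):
    """Direct step-up definition: p_adj(i) = min(1, min_{j>=i} p_(j)*m/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_single_and_hand_example():
    assert fdr_adjust([0.03]) == pytest.approx([0.03])
    adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
)
def test_bh_matches_brute_force_definition(p):
    adj = fdr_adjust(p)
    assert np.allclose(adj, brute_force_bh(p), atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


def test_panel_runs_and_fdr_spans_panel(rng):
    df, pad = _cohort_frame(rng)
    panel = (
        PanelVariable("diabetes", kind="binary"),
        PanelVariable("noise_var"),
        PanelVariable("alcohol_freq", kind="ordinal", missing_codes=(-3,)),
    )
    out = run_panel(pad, df, panel)
    assert list(out.index) == ["diabetes", "noise_var", "alcohol_freq"]
    assert (out["fdr_p"] >= out["p_value"] - 1e-15).all()
    single = run_panel(pad, df, (PanelVariable("diabetes", kind="binary"),))
    assert single.loc["diabetes", "fdr_p"] == pytest.approx(
        single.loc["diabetes", "p_value"]
    )


def test_default_panel_has_18_variables():
    panel = default_panel()
    assert len(panel) == 18
    assert any(v.name == "alcohol_freq" and -3 in v.missing_codes for v in panel)
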