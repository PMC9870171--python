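import math

import numpy as np
import pytest
from scipy.stats import kstest

from trawlsel import (
    CatchDataset,
    CatchSimConfig,
    ModelSpec,
    ParamVector,
    fit,
    fit_all,
    goodness_of_fit,
    neg_log_likelihood,
    retention,
    select_model,
    simulate_catch,
)

from conftest import make_haul, random_small_dataset


def brute_force_nll(dataset, spec, params):
    """Independent double-loop implementation of the pooled objective."""
    total = 0.0
    for h in dataset:
        for l, nR, nE in zip(h.length_classes, h.n_codend, h.n_cover):
            r = retention(spec, params, float(l))
            r = min(max(r, 1e-12), 1.0 - 1e-12)
            if nR:
                total -= nR / h.q_codend * math.log(r)
            if nE:
                total -= nE / h.q_cover * math.log(1.0 - r)
    return total


def test_half_retention_single_class_gives_10_ln2():
    ds = CatchDataset(
        [make_haul(lengths=(20,), n_codend=(5,), n_cover=(5,))]
    )
    val = neg_log_likelihood(ds, ModelSpec("logit"), ParamVector(20.0, 4.0))
    assert val == pytest.approx(10 * math.log(2), abs=1e-12)


def test_objective_linear_in_raised_counts():
    spec, params = ModelSpec("logit"), ParamVector(20.0, 3.0)
    ds_full = CatchDataset([make_haul(q_codend=0.5, q_cover=0.5)])
    ds_half = CatchDataset([make_haul(q_codend=1.0, q_cover=1.0)])
    # doubling both subsample fractions halves the raised counts
    assert neg_log_likelihood(ds_half, spec, params) == pytest.approx(
        0.5 * neg_log_likelihood(ds_full, spec, params), rel=1e-12
    )


def test_objective_matches_double_loop_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        ds = random_small_dataset(rng)
        spec = ModelSpec(
            str(rng.choice(["logit", "probit", "gompertz", "richard"])),
            contact=bool(rng.integers(0, 2)),
        )
        params = ParamVector(
            float(rng.uniform(14, 26)),
            float(rng.uniform(1, 8)),
            inv_delta=float(rng.uniform(0.3, 3)) if spec.family == "richard" else None,
            c=float(rng.uniform(0.2, 1.0)) if spec.contact else None,
        )
        assert neg_log_likelihood(ds, spec, params) == pytest.approx(
            brute_force_nll(ds, spec, params), abs=1e-10
        )


def test_recovery_on_one_synthetic_dataset():
    ds, truth = simulate_catch(CatchSimConfig(seed=5))
    res = fit(ds, ModelSpec("logit"))
    assert res.converged
    assert res.params.l50 == pytest.approx(truth.params.l50, abs=0.3)
    assert res.params.sr == pytest.approx(truth.params.sr, abs=0.6)


def test_all_fish_in_cover_is_flagged_boundary_fit():
    ds = CatchDataset(
        [make_haul(n_codend=(0, 0, 0, 0, 0), n_cover=(5, 9, 12, 9, 5))]
    )
    res = fit(ds, ModelSpec("logit"), with_gof=False)
    # retention is driven toward zero across all observed lengths
    r = retention(res.spec, res.params, ds.length_classes.astype(float))
    assert np.all(r < 0.05)
    assert res.at_boundary


def test_deviance_zero_when_curve_passes_through_proportions():
    # class proportions 0.25 / 0.5 / 0.75 lie exactly on a logistic curve
    ds = CatchDataset(
        [
            make_haul(
                lengths=(18, 20, 22),
                n_codend=(25, 50, 75),
                n_cover=(75, 50, 25),
            )
        ]
    )
    res = fit(ds, ModelSpec("logit"))
    dev, dof, p = goodness_of_fit(res, ds)
    assert dev == pytest.approx(0.0, abs=1e-6)
    assert dof == 1
    assert p == pytest.approx(1.0, abs=1e-4)


def test_dof_counts_occupied_classes_minus_k(toy_dataset):
    res3 = fit(toy_dataset, ModelSpec("richard"))
    assert res3.spec.n_params == 3
    assert res3.dof == len(toy_dataset.length_classes) - 3
    resc = fit(toy_dataset, ModelSpec("gompertz", contact=True))
    assert resc.spec.n_params == 3
    assert resc.dof == res3.dof


def test_gof_not_assessable_when_dof_nonpositive():
    ds = CatchDataset(
        [make_haul(lengths=(19, 21), n_codend=(4, 16), n_cover=(16, 4))]
    )
    res = fit(ds, ModelSpec("logit"))
    dev, dof, p = goodness_of_fit(res, ds)
    assert dof == 0 and p is None


def test_gof_pvalues_uniform_under_well_specified_model():
    """On well-specified data with ample counts per class the deviance
    p-values should be approximately U(0,1) across replicates."""
    cfg = dict(
        params=ParamVector(20.0, 4.0),
        length_mean=20.0,
        length_sd=3.0,
        length_range=(15.0, 25.0),
        n_hauls=10,
        fish_per_haul=2000,
    )
    pvals = []
    for seed in range(200):
        ds, _ = simulate_catch(CatchSimConfig(seed=seed, **cfg))
        res = fit(ds, ModelSpec("logit"))
        pvals.append(res.p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_select_model_orders_by_aic(toy_dataset):
    fits = fit_all(toy_dataset, [ModelSpec("logit"), ModelSpec("probit")])
    best, table = select_model(fits)
    assert best.aic == min(f.aic for f in fits)
    assert list(table["aic"]) == sorted(table["aic"])
    assert table["delta_aic"].iloc[0] == 0.0


def test_fit_is_deterministic(toy_dataset):
    r1 = fit(toy_dataset, ModelSpec("logit", contact=True))
    r2 = fit(toy_dataset, ModelSpec("logit", contact=True))
    assert r1.aic == r2.aic
    assert r1.params == r2.params


def test_nested_contact_model_never_fits_worse():
    ds, _ = simulate_catch(CatchSimConfig(seed=3, n_hauls=4, fish_per_haul=500))
    f0 = fit(ds, ModelSpec("logit"), with_gof=False)
    f1 = fit(ds, ModelSpec("logit", contact=True), with_gof=False)
    # the classical curve is (essentially) nested at C = 1
    assert f1.neg_log_lik <= f0.neg_log_lik + 1e-3


def test_contact_model_selected_when_contact_is_real():
    """With a true retention floor of 1 - C = 0.5, contact variants must
    beat every classical family by AIC (checked over seeded replicates in
    the acceptance suite at larger scale)."""
    cfg = CatchSimConfig(
        spec=ModelSpec("gompertz", contact=True),
        params=ParamVector(22.0, 3.0, c=0.5),
        n_hauls=10,
        fish_per_haul=2000,
        seed=0,
    )
    ds, _ = simulate_catch(cfg)
    fits = fit_all(ds)
    best, table = select_model(fits)
    assert best.spec.contact
    cg = table[table["model"] == "CGompertz"]["aic"].iloc[0]
    assert cg <= best.aic + 2.0


def test_contact_estimate_spread_covers_truth_at_small_m():
    """At 4 hauls the contact parameter is weakly identified: its
    replicate spread is wide but should cover the true C = 0.5."""
    ests = []
    for seed in range(30):
        cfg = CatchSimConfig(
            spec=ModelSpec("gompertz", contact=True),
            params=ParamVector(22.0, 3.0, c=0.5),
            n_hauls=4,
            fish_per_haul=800,
            seed=seed,
        )
        ds, _ = simulate_catch(cfg)
        res = fit(ds, ModelSpec("gompertz", contact=True), with_gof=False)
        ests.append(res.params.c)
    lo, hi = np.percentile(ests, [2.5, 97.5])
    assert lo <= 0.5 <= hi
    assert hi - lo > 0.02
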