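"""Objective construction, joint fitting, profiles, bands, specificity."""

import numpy as np
import pandas as pd
import pytest

import labelflux as lf
from labelflux.inference import Stream, _Objective

from conftest import preprocess


def noise_free_datasets(truth, designs, names=("tie2-like", "fgd5-like"),
                        freq_sem=0.01, count_sem_frac=0.05):
    """Exact model expectations packaged as fit datasets with nominal SEMs."""
    from labelflux.synth import _expected_observables
    rates, init = truth
    out = []
    for name in names:
        d = designs[name]
        times = np.asarray(d.times, dtype=float)
        exp = _expected_observables(rates, init.n0, np.asarray(d.f0), times)
        f_hsc = exp["HSC"][0]
        streams = [
            Stream("HSC", "frequency", times, f_hsc, np.full_like(times, freq_sem)),
            Stream("ST-HSC", "norm_frequency", times, exp["ST-HSC"][0] / f_hsc,
                   np.full_like(times, freq_sem * 2)),
            Stream("MPP", "norm_frequency", times, exp["MPP"][0] / f_hsc,
                   np.full_like(times, freq_sem * 2)),
        ]
        for comp in ("HSC", "ST-HSC", "MPP"):
            streams.append(Stream(comp, "count", times, exp[comp][1],
                                  count_sem_frac * exp[comp][1]))
        out.append(lf.FitDataset(dataset_id=d.dataset_id, streams=tuple(streams)))
    return out


def truth_values(truth, designs, names=("tie2-like", "fgd5-like")):
    rates, init = truth
    comps = lf.DEFAULT_COMPARTMENTS
    vals = {}
    for i, c in enumerate(comps[:-1]):
        vals[f"alpha.{c}"] = rates.alpha[i]
    for i, c in enumerate(comps):
        vals[f"kappa.{c}"] = rates.kappa[i]
        vals[f"n0.{c}"] = init.n0[i]
    for name in names:
        d = designs[name]
        for i, c in enumerate(comps):
            vals[f"f0.{d.dataset_id}.{c}"] = d.f0[i]
    return vals


class TestWeightedSSR:
    def test_zero_at_exact_model(self, truth, designs):
        fds = noise_free_datasets(truth, designs)
        spec = lf.make_fitspec([d.dataset_id for d in fds])
        vals = truth_values(truth, designs)
        assert lf.weighted_ssr(vals, fds, spec) < 1e-16

    def test_single_two_sigma_residual_scores_four(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        s0 = fds[0].streams[0]
        mean = s0.mean.copy()
        mean[0] += 2 * s0.sem[0]
        bumped = lf.FitDataset(fds[0].dataset_id, (Stream(
            s0.compartment, s0.quantity, s0.times, mean, s0.sem),) + fds[0].streams[1:])
        spec = lf.make_fitspec([bumped.dataset_id])
        vals = truth_values(truth, designs, names=("tie2-like",))
        assert lf.weighted_ssr(vals, [bumped], spec) == pytest.approx(4.0, abs=1e-9)

    def test_hand_summed_toy_instance(self):
        # 2 bins, model == 0.5, data (0.4, 0.7) with SEM (0.1, 0.2):
        # residuals -1 and +1 -> SSR = 2 ... computed via the objective core
        times = np.array([0.0, 10.0])
        stream = Stream("HSC", "frequency", times, np.array([0.4, 0.7]),
                        np.array([0.1, 0.2]))
        ds = lf.FitDataset("d", (stream,))
        spec = lf.make_fitspec(["d"])
        obj = _Objective(spec, [ds])
        vals = spec.values()
        pred = obj.stream_prediction(vals, "d", "HSC", "frequency", times)
        expected = float(np.sum(((pred - stream.mean) / stream.sem) ** 2))
        assert obj.ssr(vals) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_model_penalized_not_silent(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        spec = lf.make_fitspec(["tie2"])
        vals = truth_values(truth, designs, names=("tie2-like",))
        vals["kappa.HSC-U"] = -5.0  # population explodes -> overflow
        obj = _Objective(spec, fds)
        ssr = obj.ssr(vals)
        assert np.isfinite(ssr) and ssr > 1e6
        assert obj.penalty_hits > 0


class TestFitJoint:
    def test_noise_free_self_consistency(self, truth, designs):
        fds = noise_free_datasets(truth, designs)
        spec = lf.make_fitspec([d.dataset_id for d in fds],
                               values=truth_values(truth, designs))
        fit = lf.fit_joint(fds, spec, n_starts=1, seed=0,
                           use_informed_start=False)
        assert fit.objective < 1e-10

    def test_dataset_order_invariance(self, truth, designs):
        fds = noise_free_datasets(truth, designs)
        spec = lf.make_fitspec([d.dataset_id for d in fds])
        f1 = lf.fit_joint(fds, spec, n_starts=4, seed=0)
        f2 = lf.fit_joint(fds[::-1], spec, n_starts=4, seed=0)
        assert f1.objective == pytest.approx(f2.objective, rel=1e-6, abs=1e-9)

    def test_optimizer_never_worsens_starts(self, joint_fit):
        for initial, final in joint_fit.start_objectives:
            assert final <= initial + 1e-9

    def test_reparameterization_invariance(self, truth, designs):
        # kappa-block and beta-block fits describe the same model family
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        rates, _ = truth
        vals = truth_values(truth, designs, names=("tie2-like",))
        spec_k = lf.make_fitspec(["tie2"], values=vals)
        beta_vals = {k: v for k, v in vals.items() if not k.startswith("kappa")}
        for i, c in enumerate(lf.DEFAULT_COMPARTMENTS):
            alpha_i = rates.alpha[i] if i < 3 else 0.1
            beta_vals[f"beta.{c}"] = alpha_i - rates.kappa[i]
        spec_b = lf.make_fitspec(["tie2"], kinetics="beta", alpha_last=0.1,
                                 values=beta_vals)
        fit_k = lf.fit_joint(fds, spec_k, n_starts=1, use_informed_start=False)
        fit_b = lf.fit_joint(fds, spec_b, n_starts=1, use_informed_start=False)
        assert fit_b.objective == pytest.approx(fit_k.objective, abs=1e-6)

    def test_deterministic_given_seed(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        spec = lf.make_fitspec(["tie2"])
        f1 = lf.fit_joint(fds, spec, n_starts=4, seed=7)
        f2 = lf.fit_joint(fds, spec, n_starts=4, seed=7)
        assert np.array_equal(f1.x_free, f2.x_free)


class TestFixedKinetics:
    def test_recovers_third_dataset_labeling(self, truth, designs):
        fds = noise_free_datasets(truth, designs,
                                  names=("tie2-like", "fgd5-like", "krt18-like"))
        vals = truth_values(truth, designs,
                            names=("tie2-like", "fgd5-like", "krt18-like"))
        fit = lf.fit_fixed_kinetics(fds[2], vals, n_starts=4, seed=0)
        d = designs["krt18-like"]
        for i, c in enumerate(lf.DEFAULT_COMPARTMENTS):
            assert fit.values[f"f0.krt18.{c}"] == pytest.approx(d.f0[i], abs=5e-3)
        assert fit.objective < 1e-8

    def test_empty_free_block_returns_fixed_objective(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("krt18-like",))
        vals = truth_values(truth, designs, names=("krt18-like",))
        spec = lf.make_fitspec(["krt18"], values=vals)
        spec = spec.with_fixed(list(spec.params))
        fit = lf.fit_joint(fds, spec)
        assert fit.n_free == 0 and fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_boundary_truth_handled_by_logit(self, truth, designs):
        # true downstream labeling of zero: estimate pinned near the boundary
        from dataclasses import replace
        d = replace(designs["krt18-like"], f0=(0.3, 0.01, 0.0, 0.0))
        fds = noise_free_datasets(truth, {"krt18-like": d}, names=("krt18-like",))
        vals = truth_values(truth, {"krt18-like": d}, names=("krt18-like",))
        fit = lf.fit_fixed_kinetics(fds[0], vals, n_starts=4, seed=1)
        assert fit.values["f0.krt18.MPP"] <= 0.01

    def test_missing_kinetics_rejected(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("krt18-like",))
        with pytest.raises(ValueError, match="missing"):
            lf.fit_fixed_kinetics(fds[0], {"alpha.HSC-U": 0.003})


class TestProfiles:
    def test_linear_gaussian_profile_matches_analytic(self):
        # with all rates zero and equal gate sizes the HSC frequency is the
        # plain average of the two gate labelings; profiling the single free
        # labeling must reproduce the analytic mean +/- 1.96 SE interval
        times = np.array([0.0, 1.0, 2.0, 3.0])
        obs = np.array([0.30, 0.34, 0.28, 0.32])
        sem = np.full(4, 0.02)
        ds = lf.FitDataset("d", (Stream("HSC", "frequency", times, obs, sem),))
        spec = lf.make_fitspec(["d"])
        spec.set_values({n: 0.0 for n in spec.params
                         if n.startswith(("alpha.", "kappa."))})
        spec.set_values({"n0.HSC-U": 1e4, "n0.HSC-D": 1e4, "f0.d.HSC-D": 0.30})
        spec = spec.with_fixed([n for n in spec.params if n != "f0.d.HSC-U"])
        fit = lf.fit_joint([ds], spec, n_starts=4, seed=0,
                           use_informed_start=False)
        p = lf.profile_likelihood_ci(fit, "f0.d.HSC-U")
        # model: f_HSC = (f0_U + 0.30) / 2, so SE(f0_U) = 2 * 0.02 / sqrt(4)
        se = 2 * 0.02 / np.sqrt(4)
        assert fit.values["f0.d.HSC-U"] == pytest.approx(2 * 0.31 - 0.30, abs=1e-4)
        assert (p.upper - p.lower) / 2 == pytest.approx(1.96 * se, rel=0.01)

    def test_unidentifiable_parameter_unbounded_both_sides(self, truth, designs):
        # downstream labeling cannot influence the upstream HSC gate: with
        # only the HSC frequency observed, f0 of MPP is fully unidentified
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        hsc_only = lf.FitDataset("tie2", tuple(
            s for s in fds[0].streams
            if (s.compartment, s.quantity) == ("HSC", "frequency")))
        vals = truth_values(truth, designs, names=("tie2-like",))
        spec = lf.make_fitspec(["tie2"], values=vals)
        spec = spec.with_fixed([n for n in spec.params if n != "f0.tie2.MPP"])
        fit = lf.fit_joint([hsc_only], spec, n_starts=2, seed=0,
                           use_informed_start=False)
        p = lf.profile_likelihood_ci(fit, "f0.tie2.MPP", span=6.0)
        assert p.lower_unbounded and p.upper_unbounded

    def test_profile_curve_above_optimum_and_contains_best(self, joint_fit):
        p = lf.profile_likelihood_ci(joint_fit, "alpha.HSC-D")
        assert (p.curve["objective"] >= joint_fit.objective - 1e-6).all()
        best = joint_fit.values["alpha.HSC-D"]
        if not p.lower_unbounded:
            assert p.lower <= best
        if not p.upper_unbounded:
            assert p.upper >= best
        assert p.has_finite_bound


class TestPredictionBands:
    def test_band_contains_best_fit_prediction(self, joint_fit):
        obj = _Objective(joint_fit.spec, joint_fit.datasets)
        for t in (10.0, 100.0):
            lo, hi = lf.prediction_profile_band(joint_fit, "tie2", "HSC",
                                                "frequency", t)
            pred = float(obj.stream_prediction(joint_fit.values, "tie2", "HSC",
                                               "frequency", [t])[0])
            assert lo - 1e-9 <= pred <= hi + 1e-9
            assert hi - lo < 0.2

    def test_zero_noise_band_collapses(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("tie2-like",),
                                  freq_sem=1e-4, count_sem_frac=1e-4)
        spec = lf.make_fitspec(["tie2"], values=truth_values(
            truth, designs, names=("tie2-like",)))
        fit = lf.fit_joint(fds, spec, n_starts=1, use_informed_start=False)
        lo, hi = lf.prediction_profile_band(fit, "tie2", "HSC", "frequency", 50.0)
        assert hi - lo < 2e-3

    def test_validation_band_covers_held_out_bin_means(self, truth, designs):
        # new noisy replicates' bin means should fall inside noise-inflated
        # bands at roughly the nominal rate
        rates, init = truth
        inside = total = 0
        for seed in range(12):
            tabs = lf.generate_multi_dataset(
                rates, init, [designs["tie2-like"], designs["fgd5-like"]],
                seed=900 + seed)
            pooled = preprocess(tabs)
            fds = lf.fit_datasets_from_pooled(pooled)
            spec = lf.make_fitspec([d.dataset_id for d in fds])
            fit = lf.fit_joint(fds, spec, n_starts=6, seed=seed)
            held, = lf.fit_datasets_from_pooled(
                preprocess([lf.generate_cohort(rates, init, designs["tie2-like"],
                                               rng=5000 + seed)]))
            stream = next(s for s in held.streams
                          if (s.compartment, s.quantity) == ("HSC", "frequency"))
            for t, m in zip(stream.times[::3], stream.mean[::3]):
                lo, hi = lf.prediction_profile_band(
                    fit, "tie2", "HSC", "frequency", float(t),
                    include_observation_noise=True)
                inside += int(lo <= m <= hi)
                total += 1
        assert total >= 30 and inside / total >= 0.85


class TestSpecificity:
    def test_equal_labeling_gives_unit_ratio(self, truth, designs):
        from dataclasses import replace
        d = replace(designs["fgd5-like"], f0=(0.3, 0.3, 0.01, 0.01))
        fds = noise_free_datasets(truth, {"fgd5-like": d}, names=("fgd5-like",))
        vals = truth_values(truth, {"fgd5-like": d}, names=("fgd5-like",))
        spec = lf.make_fitspec(["fgd5"], values=vals)
        fit = lf.fit_joint(fds, spec, n_starts=1, use_informed_start=False)
        out = lf.labeling_specificity(fit)
        assert out.loc["fgd5", "ratio"] == pytest.approx(1.0, abs=1e-3)

    def test_zero_downstream_labeling_unbounded_ratio(self, truth, designs):
        fds = noise_free_datasets(truth, designs, names=("tie2-like",))
        vals = truth_values(truth, designs, names=("tie2-like",))
        vals["f0.tie2.HSC-D"] = 0.0
        spec = lf.make_fitspec(["tie2"], values=vals)
        spec = spec.with_fixed(list(spec.params))
        fit = lf.fit_joint(fds, spec)
        assert np.isinf(lf.labeling_specificity(fit).loc["tie2", "ratio"])

    def test_ratio_of_ratios_recovered(self, joint_fit):
        out = lf.labeling_specificity(joint_fit)
        # generator truths: tie2 21:1, fgd5 4:1 -> specificity 5.25
        assert out.loc["tie2", "ratio"] > out.loc["fgd5", "ratio"]
        assert out.loc["tie2", "specificity_vs_fgd5"] == pytest.approx(5.25, rel=0.6)
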