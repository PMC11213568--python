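"""Time-resolved MI / II / TE estimators and their permutation nulls."""

import numpy as np
import pytest
import xarray as xr

from infolearn import dynamics, synth
from infolearn.dynamics import DelayWindow
from infolearn.synth import CouplingSpec


def _latency_index(epochs, latency=0.5):
    return int(np.argmin(np.abs(epochs["time"].values - latency)))


def _exp_transform(epochs):
    out = epochs.copy()
    out.values = np.exp(out.values / out.values.std())
    return out


class TestMI:
    def test_trial_count_precondition(self, pe_table):
        ep = synth.generate_epochs(pe_table, seed=1)
        short = pe_table.iloc[:30]
        with pytest.raises(ValueError):
            dynamics.mi_timecourse(ep.isel(trial=slice(30)), short, "RPE")

    def test_monotone_invariance(self, pe_table):
        ep = synth.generate_epochs(pe_table, CouplingSpec(target="RPE"), seed=2)
        a = dynamics.mi_timecourse(ep, pe_table, "RPE")
        b = dynamics.mi_timecourse(_exp_transform(ep), pe_table, "RPE")
        assert np.allclose(a.values.values, b.values.values)

    def test_null_determinism_and_mean(self, pe_table):
        ep = synth.generate_epochs(pe_table, CouplingSpec(target="RPE"), seed=3)
        a = dynamics.mi_timecourse(ep, pe_table, "RPE", n_perm=200, seed=9)
        b = dynamics.mi_timecourse(ep, pe_table, "RPE", n_perm=200, seed=9)
        assert np.array_equal(a.null.values, b.null.values)
        # bias-corrected null MI is centred near zero
        assert abs(float(a.null.mean())) < 0.005
        # observed coupled MI exceeds its null 95th percentile at latency
        i = _latency_index(ep)
        thr = np.percentile(a.null.values[0, i], 95)
        assert a.values.values[0, i] > thr


class TestII:
    def test_symmetry_and_subject_guard(self, pe_table):
        ep = synth.make_redundant_pair(pe_table, seed=4)
        ab = dynamics.interaction_information(ep, pe_table, (0, 1), "RPE")
        ba = dynamics.interaction_information(ep, pe_table, (1, 0), "RPE")
        assert np.allclose(ab.values.values, ba.values.values)
        ep2 = ep.assign_coords(subject=("contact", [0, 1]))
        with pytest.raises(ValueError):
            dynamics.interaction_information(ep2, pe_table, (0, 1), "RPE")

    def test_monotone_invariance(self, pe_table):
        ep = synth.make_redundant_pair(pe_table, seed=5)
        a = dynamics.interaction_information(ep, pe_table, (0, 1), "RPE")
        b = dynamics.interaction_information(_exp_transform(ep), pe_table, (0, 1), "RPE")
        assert np.allclose(a.values.values, b.values.values)

    def test_duplicate_source_identity(self, pe_table, rng):
        """gamma2 = gamma1 + jitter makes II collapse to -I(gamma1; S)."""
        ep = synth.generate_epochs(pe_table, CouplingSpec(target="RPE"), seed=6)
        dup = xr.concat([ep, ep + 0.05 * rng.normal(size=ep.shape)], dim="contact")
        dup = dup.assign_coords(contact=[0, 1])
        dup.attrs.update(ep.attrs)
        i = _latency_index(ep)
        ii = dynamics.interaction_information(dup, pe_table, (0, 1), "RPE")
        mi = dynamics.mi_timecourse(ep, pe_table, "RPE")
        assert ii.values.values[0, i] == pytest.approx(
            -mi.values.values[0, i], rel=0.10
        )

    def test_gaussian_closed_form(self, rng):
        """II on jointly Gaussian amplitudes matches analytic co-information."""
        n = 10_000
        z = rng.normal(size=n)
        x1 = z + rng.normal(size=n)
        x2 = 0.8 * z + rng.normal(size=n)

        def analytic_mi(cov, ix, iy):
            cxx = cov[np.ix_(ix, ix)]
            cyy = cov[np.ix_(iy, iy)]
            cfull = cov[np.ix_(ix + iy, ix + iy)]
            return 0.5 * np.log2(
                np.linalg.det(cxx) * np.linalg.det(cyy) / np.linalg.det(cfull)
            )

        cov = np.cov(np.stack([x1, x2, z]))
        ii_true = (
            analytic_mi(cov, [0, 1], [2])
            - analytic_mi(cov, [0], [2])
            - analytic_mi(cov, [1], [2])
        )
        from infolearn.gcmi import batch_mi_1d, batch_mi_2d_1d, copula_normalize

        c1, c2, cz = (copula_normalize(v) for v in (x1, x2, z))
        ii_est = (
            batch_mi_2d_1d(c1, c2, cz) - batch_mi_1d(c1, cz) - batch_mi_1d(c2, cz)
        )
        assert ii_est == pytest.approx(ii_true, abs=0.02)


class TestTE:
    def test_directionality_and_time_reversal(self):
        ep = synth.make_directed_pair(seed=7)
        fwd = dynamics.transfer_entropy(ep, (0, 1))
        rev = dynamics.transfer_entropy(ep, (1, 0))
        assert np.nanmean(fwd.values.values) > np.nanmean(rev.values.values)
        flipped = ep.isel(time=slice(None, None, -1)).assign_coords(
            time=ep["time"].values
        )
        flipped.attrs.update(ep.attrs)
        f2 = dynamics.transfer_entropy(flipped, (0, 1))
        r2 = dynamics.transfer_entropy(flipped, (1, 0))
        assert np.nanmean(r2.values.values) > np.nanmean(f2.values.values)

    def test_invalid_times_marked(self):
        ep = synth.make_directed_pair(seed=8)
        te = dynamics.transfer_entropy(ep, (0, 1))
        d_max = DelayWindow().samples(256.0).max()
        vals = te.values.values[0]
        assert np.isnan(vals[:d_max]).all()
        assert np.isfinite(vals[d_max:]).all()

    def test_monotone_invariance(self):
        ep = synth.make_directed_pair(seed=9)
        a = dynamics.transfer_entropy(ep, (0, 1))
        b = dynamics.transfer_entropy(_exp_transform(ep), (0, 1))
        va, vb = a.values.values, b.values.values
        assert np.allclose(va[np.isfinite(va)], vb[np.isfinite(vb)])

    def test_null_shuffles_source(self):
        ep = synth.make_directed_pair(seed=10)
        te = dynamics.transfer_entropy(ep, (0, 1), n_perm=50, seed=11)
        obs = np.nanmean(te.values.values)
        null = np.nanmean(te.null.values, axis=(0, 1))
        assert obs > np.percentile(null, 95)

    def test_independent_pair_within_null(self):
        ep = synth.make_directed_pair(
            CouplingSpec(mode="directed_pair", directed_gain=0.0), seed=12
        )
        te = dynamics.transfer_entropy(ep, (0, 1), n_perm=100, seed=13)
        obs = np.nanmean(te.values.values)
        null = np.nanmean(te.null.values, axis=(0, 1))
        assert obs < np.percentile(null, 99)

    def test_delay_profile_argmax(self):
        ep = synth.make_directed_pair(seed=14)
        prof = dynamics.te_delay_profile(ep, (0, 1))
        assert abs(prof.attrs["argmax_delay"] - 0.15) <= 2 / 256.0

    def test_delay_profile_bimodal(self):
        """Two lagged couplings produce two local maxima in the profile."""
        spec = CouplingSpec(mode="directed_pair", lag=0.1)
        ep = synth.make_directed_pair(spec, n_trials=300, seed=15)
        x = ep.values[0]
        lag2 = int(round(0.2 * 256))
        y = ep.values[1].copy()
        y[:, lag2:] += 0.8 * x[:, :-lag2]
        ep.values[1] = y
        prof = dynamics.te_delay_profile(
            ep, (0, 1), delays_s=np.arange(0.05, 0.30, 1 / 256.0)
        )
        d = prof["delay"].values
        v = prof.values
        local_max = [
            d[i] for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]
        ]
        near = lambda x0: any(abs(m - x0) < 0.03 for m in local_max)
        assert near(0.1) and near(0.2)

    def test_gaussian_granger_closed_form(self, rng):
        """TE at the generating lag matches the analytic Gaussian CMI."""
        n = 20_000
        coef, a = 0.9, 0.8
        # x is AR(1) across a short time axis; y = a*x(t-d) + white noise
        T, d = 12, 4
        x = np.zeros((n, T))
        x[:, 0] = rng.normal(size=n)
        for t in range(1, T):
            x[:, t] = coef * x[:, t - 1] + np.sqrt(1 - coef**2) * rng.normal(size=n)
        y = rng.normal(size=(n, T))
        y[:, d:] += a * x[:, :-d]
        # analytic I(x_{t-d}; y_t | y_{t-d}) from the true joint covariance
        t = T - 1
        rho = coef**d
        cov = np.array(
            [
                [1.0, a, a * rho],  # x_{t-d}
                [a, 1 + a * a, a * a * rho],  # y_t
                [a * rho, a * a * rho, 1 + a * a],  # y_{t-d}
            ]
        )
        def mi3(c, ix, iy, iz):
            xz = np.ix_(ix + iz, ix + iz)
            yz = np.ix_(iy + iz, iy + iz)
            zz = np.ix_(iz, iz)
            return 0.5 * np.log2(
                np.linalg.det(c[xz]) * np.linalg.det(c[yz])
                / (np.linalg.det(c) * np.linalg.det(c[zz]))
            )

        true = mi3(cov, [0], [1], [2])
        from infolearn.gcmi import batch_cmi_1d, copula_normalize

        cx = copula_normalize(x[:, t - d])
        cy = copula_normalize(y[:, t])
        cz = copula_normalize(y[:, t - d])
        assert batch_cmi_1d(cx, cy, cz) == pytest.approx(true, abs=0.02)


def test_build_permutation_null_dispatch(pe_table):
    ep = synth.generate_epochs(pe_table, seed=20)
    s = dynamics.build_permutation_null("MI", ep, pe_table, n_perm=10, seed=1,
                                        target="RPE")
    assert s.n_perm == 10
    with pytest.raises(ValueError):
        dynamics.build_permutation_null("MI", ep, pe_table, n_perm=0)
    with pytest.raises(ValueError):
        dynamics.build_permutation_null("XX", ep, pe_table, n_perm=5)


def test_concat_series(pe_table):
    ep = synth.generate_epochs(pe_table, n_contacts=2, seed=21)
    a = dynamics.mi_timecourse(ep, pe_table, "RPE", n_perm=5, seed=2)
    cat = dynamics.concat_series([a, a])
    assert cat.values.shape[0] == 4
    assert cat.null.shape == (4, ep.sizes["time"], 5)
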