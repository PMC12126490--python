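"""Isotherm, CSP and FRAP operations against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervscape import (
    TitrationSeries,
    csp_euclidean,
    csp_weighted_abs,
    fit_binding_isotherm,
    frap_dip_depth,
    match_and_classify_peaks,
    predict_delta_i,
    simulate_frap_curve,
    simulate_peak_lists,
    simulate_titration,
    summarize_replicates,
)


class TestIsothermForward:
    def test_saturation_identity(self):
        assert predict_delta_i(2.0, 2.0, 0.0, 1.5) == pytest.approx(1.5, abs=1e-12)

    def test_zero_ligand(self):
        assert predict_delta_i(0.0, 1.0, 0.3, 1.0) == 0.0

    def test_hand_evaluated_point(self):
        assert predict_delta_i(1.0, 1.0, 1.0, 1.0) == pytest.approx((3 - np.sqrt(5)) / 2, abs=1e-12)

    def test_monotone_and_bounded(self):
        L = np.linspace(0, 50, 200)
        di = predict_delta_i(L, 1.0, 0.7, 1.0)
        assert np.all(np.diff(di) >= -1e-12)
        assert np.all(di <= 1.0 + 1e-12)

    def test_kd_to_zero_limit_is_stoichiometric(self):
        L = np.array([0.25, 0.5, 0.75, 1.0, 2.0, 5.0])
        di = predict_delta_i(L, 1.0, 1e-12, 1.0)
        assert np.allclose(di, np.minimum(1.0, L / 1.0), atol=1e-5)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            predict_delta_i(1.0, 0.0, 1.0, 1.0)


class TestIsothermFit:
    @pytest.mark.parametrize("kd", [5e-3, 5e-2, 0.5, 5.0, 50.0])
    def test_noiseless_self_consistency(self, kd):
        L = np.linspace(0, 10, 13)[1:]
        series = simulate_titration(kd, 1.0, 1.0, L, noise_sd=0.0)
        fit = fit_binding_isotherm(series)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.delta_i_max == pytest.approx(1.0, rel=1e-6)

    def test_noisy_recovery_median_error(self):
        errors = []
        for seed in range(100):
            series = simulate_titration(0.5, 1.0, 1.0, np.linspace(0, 8, 12)[1:],
                                        noise_sd=0.01, seed=seed)
            errors.append(abs(fit_binding_isotherm(series).kd - 0.5) / 0.5)
        assert np.median(errors) < 0.05

    def test_replicate_summary(self):
        fits = [fit_binding_isotherm(simulate_titration(0.5, 1.0, 1.0,
                np.linspace(0, 8, 12)[1:], noise_sd=0.02, seed=s)) for s in (1, 2, 3)]
        rep = summarize_replicates(fits)
        kds = [f.kd for f in fits]
        assert rep["n"] == 3
        assert rep["kd_mean"] == pytest.approx(np.mean(kds))
        assert rep["kd_sd"] == pytest.approx(np.std(kds, ddof=1))

    def test_flat_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_binding_isotherm(TitrationSeries(np.arange(1.0, 6.0), np.ones(5), 1.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_binding_isotherm(TitrationSeries([1.0, 2.0], [0.1, 0.2], 1.0))


class TestCSPMetrics:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.1, 0.0, 0.1), (0.0, 0.5, 0.1), (0.0, 0.0, 0.0), (0.1, 0.5, np.sqrt(0.02))],
    )
    def test_euclidean_examples(self, dh, dn, expected):
        assert csp_euclidean(dh, dn) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.1, 1.0, 0.205), (-0.1, -1.0, 0.205), (0.0, 0.0, 0.0)],
    )
    def test_weighted_abs_examples(self, dh, dn, expected):
        assert csp_weighted_abs(dh, dn, 0.105) == pytest.approx(expected, abs=1e-15)

    @given(
        st.floats(-2, 2), st.floats(-20, 20),
        st.floats(min_value=0, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_absolute_homogeneity(self, dh, dn, c):
        assert csp_euclidean(c * dh, c * dn) == pytest.approx(c * csp_euclidean(dh, dn), rel=1e-9, abs=1e-12)
        assert csp_weighted_abs(c * dh, c * dn) == pytest.approx(c * csp_weighted_abs(dh, dn), rel=1e-9, abs=1e-12)


def exhaustive_assignment_oracle(apo, bound, tol_h, tol_n):
    """Search all injective apo->bound assignments; maximize matches, then
    minimize total Euclidean-CSP distance.  Returns residue -> bound index."""
    feas = []
    for _, p in apo.iterrows():
        cands = []
        for j, q in bound.iterrows():
            dh, dn = q.delta_h - p.delta_h, q.delta_n - p.delta_n
            if (dh / tol_h) ** 2 + (dn / tol_n) ** 2 <= 1.0:
                cands.append((j, np.sqrt(dh**2 + (dn / 5.0) ** 2)))
        feas.append(cands)

    best = {"key": None, "assign": None}

    def rec(i, used, n_matched, cost, assign):
        if i == len(feas):
            key = (-n_matched, cost)
            if best["key"] is None or key < best["key"]:
                best["key"], best["assign"] = key, dict(assign)
            return
        rec(i + 1, used, n_matched, cost, assign)  # leave i unmatched
        for j, d in feas[i]:
            if j not in used:
                assign[i] = j
                rec(i + 1, used | {j}, n_matched + 1, cost + d, assign)
                del assign[i]

    rec(0, frozenset(), 0, 0.0, {})
    return best["assign"]


class TestPeakMatching:
    TOL = dict(tol_h=0.15, tol_n=1.0)

    def test_identical_lists_all_matched_zero_csp(self):
        apo, bound = simulate_peak_lists(8, seed=2)
        recs = match_and_classify_peaks(apo, bound, **self.TOL)
        assert all(r.status == "matched" for r in recs)
        assert all(r.csp_euclidean == pytest.approx(0.0, abs=1e-12) for r in recs)

    def test_one_disappeared_record(self):
        apo, bound = simulate_peak_lists(8, disappeared_set={5}, seed=2)
        recs = match_and_classify_peaks(apo, bound, **self.TOL)
        gone = [r for r in recs if r.status == "disappeared"]
        assert len(gone) == 1 and gone[0].residue_id == 5

    def test_planted_shift_recovered(self):
        apo, bound = simulate_peak_lists(8, shifted_set={3}, shift_magnitudes=(0.1, 0.5), seed=2)
        recs = {r.residue_id: r for r in match_and_classify_peaks(apo, bound, **self.TOL)}
        assert recs[3].csp_euclidean == pytest.approx(np.sqrt(0.01 + 0.01), abs=1e-12)
        assert recs[3].csp_weighted == pytest.approx(0.1 + 0.105 * 0.5, abs=1e-12)

    def test_duplicate_residues_rejected(self):
        apo, bound = simulate_peak_lists(4, seed=2)
        bad = pd.concat([apo, apo.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            match_and_classify_peaks(bad, bound, **self.TOL)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_crowded_lists(self, seed, rng=None):
        # random dense instances with <= 10 peaks and ambiguous candidates
        r = np.random.default_rng(1000 + seed)
        n = int(r.integers(3, 10))
        apo = pd.DataFrame({
            "residue_id": np.arange(1, n + 1),
            "delta_h": r.uniform(8.0, 8.3, n),
            "delta_n": r.uniform(118.0, 120.0, n),
            "intensity": np.ones(n),
        })
        bound = apo.copy()
        bound["delta_h"] += r.normal(0, 0.05, n)
        bound["delta_n"] += r.normal(0, 0.3, n)
        drop = r.integers(0, n)
        bound = bound.drop(index=drop).reset_index(drop=True)

        oracle = exhaustive_assignment_oracle(apo, bound, 0.15, 1.0)
        recs = match_and_classify_peaks(apo, bound, tol_h=0.15, tol_n=1.0)
        got = {}
        for i, rec in enumerate(recs):
            if rec.status == "matched":
                # recover which bound row was chosen from the displacement
                j = np.argmin(
                    np.abs(bound.delta_h - (apo.delta_h[i] + rec.d_h))
                    + np.abs(bound.delta_n - (apo.delta_n[i] + rec.d_n))
                )
                got[i] = int(j)
        assert len(got) == len(oracle)
        cost_got = sum(
            np.sqrt((bound.delta_h[j] - apo.delta_h[i]) ** 2 + ((bound.delta_n[j] - apo.delta_n[i]) / 5) ** 2)
            for i, j in got.items()
        )
        cost_oracle = sum(
            np.sqrt((bound.delta_h[j] - apo.delta_h[i]) ** 2 + ((bound.delta_n[j] - apo.delta_n[i]) / 5) ** 2)
            for i, j in oracle.items()
        )
        assert cost_got == pytest.approx(cost_oracle, abs=1e-9)


class TestFrapDip:
    def test_constant_curve_zero_dip(self):
        c = simulate_frap_curve(0.0, 15.0, noise_sd=0.0)
        dips = frap_dip_depth(c, probe_times=[1.0, 15.0])
        assert all(d == pytest.approx(0.0, abs=1e-9) for d in dips.values())

    def test_planted_depth_recovered(self):
        c = simulate_frap_curve(0.25, 15.0, noise_sd=0.01, seed=5)
        dips = frap_dip_depth(c, probe_times=[15.0])
        assert dips[15.0] == pytest.approx(0.25, abs=0.02)

    def test_null_depth_bounded_by_noise(self):
        noise = 0.01
        c = simulate_frap_curve(0.0, 15.0, noise_sd=noise, seed=6)
        dips = frap_dip_depth(c, probe_times=[15.0])
        assert dips[15.0] <= 3 * noise

    def test_window_too_large_rejected(self):
        c = simulate_frap_curve(0.1, 1.0, n_frames=20)
        with pytest.raises(ValueError, match="sg_window"):
            frap_dip_depth(c, sg_window=21, probe_times=[1.0])

    def test_probe_outside_span_rejected(self):
        c = simulate_frap_curve(0.1, 5.0)
        with pytest.raises(ValueError, match="outside"):
            frap_dip_depth(c, probe_times=[1e5])
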