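"""Occupancy model, expected counts, likelihood, denominators, and the fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

import bindnseq as bq
from bindnseq.affinity import (
    ConcentrationSeries,
    Denominators,
    FitData,
    _per_sequence_nll,
    _poisson_nll_terms,
)


class TestOccupancy:
    @pytest.mark.parametrize(
        "K, C, expected",
        [(1e-3, 1000.0, 0.5), (123.0, 0.0, 0.0), (1e-2, 1000.0, 10 / 11)],
    )
    def test_closed_forms(self, K, C, expected):
        assert bq.occupancy(K, C) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "K, C, w, expected",
        [(1e-3, 1000.0, 0.0, 0.5), (1e-3, 1000.0, 1.0, 0.0), (1e-3, 1000.0, 0.2, 0.4)],
    )
    def test_well_retention(self, K, C, w, expected):
        assert bq.occupancy_with_well(K, C, w) == pytest.approx(expected)

    @given(
        logK=st.floats(-6, 0), C=st.floats(1, 5000),
        dlogK=st.floats(0.01, 2), dC=st.floats(1, 2000), w=st.floats(0, 0.99),
        dw=st.floats(0.005, 0.5),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotonicity(self, logK, C, dlogK, dC, w, dw):
        K = 10.0 ** logK
        assert bq.occupancy(10.0 ** (logK + dlogK), C) > bq.occupancy(K, C)
        assert bq.occupancy(K, C + dC) > bq.occupancy(K, C)
        if w + dw <= 1:
            assert bq.occupancy_with_well(K, C, w + dw) < bq.occupancy_with_well(K, C, w)


def tiny_fit_data(f, K, w, concs, N=1e6, n_override=None):
    """Minimal single-replicate FitData with expected counts as observations."""
    f = np.asarray(f, float)
    S, J = len(f), len(concs)
    concs = np.asarray(concs, float)
    data = FitData(
        sequences=[(f"rs{i}", "A") for i in range(S)],
        concentrations=concs,
        replicates=["R1"],
        n_bound=np.zeros((S, J, 1)), n_unbound=np.zeros((S, J, 1)),
        n_library=(f * N)[:, None],
        N_bound=np.full((J, 1), N), N_unbound=np.full((J, 1), N),
        N_library=np.array([N]),
        library_fraction=f[:, None],
    )
    if n_override is not None:
        data.n_bound, data.n_unbound = n_override
    return data


class TestExpectedCounts:
    def test_plug_in_arithmetic(self):
        # w=0, K*C=1, f=1e-4, N_B=1e6, D=0.5 -> lambda_B = 100
        data = tiny_fit_data([1e-4], K=[1e-3], w=[0.0], concs=[1000.0])
        den = Denominators(bound={1000.0: 0.5}, unbound={1000.0: 1.0})
        exp = bq.expected_counts(np.array([1e-3]), np.array([0.0]), data, den)
        assert exp.lambda_bound[0, 0, 0] == pytest.approx(100.0)
        assert exp.lambda_unbound[0, 0, 0] == pytest.approx(1e6 * 1e-4 * 0.5)
        assert exp.lambda_library[0, 0] == pytest.approx(100.0)

    def test_zero_concentration(self):
        data = tiny_fit_data([1e-4], K=[1e-3], w=[0.0], concs=[0.0])
        den = Denominators(bound={0.0: 0.3}, unbound={0.0: 0.7})
        exp = bq.expected_counts(np.array([1e-3]), np.array([0.0]), data, den)
        assert exp.lambda_bound[0, 0, 0] == 0.0
        assert exp.lambda_unbound[0, 0, 0] == pytest.approx(1e6 * 1e-4 / 0.7)

    def test_normalization_identity(self):
        """With self-consistent denominators the bound lambdas sum to N_B."""
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(5))
        K = 10.0 ** rng.uniform(-4, -2, 5)
        w = np.zeros(5)
        concs = [100.0, 1000.0, 3000.0]
        data = tiny_fit_data(f, K, w, concs)
        den = Denominators(
            bound={c: float(np.sum(f * bq.occupancy(K, c))) for c in concs},
            unbound={c: float(np.sum(f * (1 - bq.occupancy(K, c)))) for c in concs},
        )
        exp = bq.expected_counts(K, w, data, den)
        np.testing.assert_allclose(exp.lambda_bound.sum(axis=0)[:, 0], 1e6, rtol=1e-6)
        np.testing.assert_allclose(exp.lambda_unbound.sum(axis=0)[:, 0], 1e6, rtol=1e-6)

    def test_zero_denominator_rejected(self):
        data = tiny_fit_data([1e-4], K=[1e-3], w=[0.0], concs=[100.0])
        den = Denominators(bound={100.0: 0.0}, unbound={100.0: 1.0})
        with pytest.raises(ValueError, match="positive"):
            bq.expected_counts(np.array([1e-3]), np.array([0.0]), data, den)


class TestNegLogLikelihood:
    def test_single_term_hand_value(self):
        got = _poisson_nll_terms(np.array([4.0]), np.array([4.0]))[0]
        assert got == pytest.approx(-(4 * np.log(4) - 4), abs=1e-10)

    def test_empty_cell_convention(self):
        assert _poisson_nll_terms(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_zero_lambda_with_counts_is_penalized(self):
        assert _poisson_nll_terms(np.array([3.0]), np.array([0.0]))[0] >= 1e29

    def test_matches_brute_force_poisson_logpmf(self):
        """Joint NLL equals -sum(logpmf) minus the dropped log(n!) constants."""
        rng = np.random.default_rng(8)
        f = rng.dirichlet(np.ones(3))
        K = np.array([1e-3, 3e-3, 5e-4])
        w = np.array([0.0, 0.1, 0.3])
        concs = [500.0, 2000.0]
        data = tiny_fit_data(f, K, w, concs, N=1e5)
        den = Denominators(
            bound={c: 0.2 for c in concs}, unbound={c: 0.9 for c in concs}
        )
        exp = bq.expected_counts(K, w, data, den)
        data.n_bound = rng.poisson(exp.lambda_bound).astype(float)
        data.n_unbound = rng.poisson(exp.lambda_unbound).astype(float)
        data.n_library = rng.poisson(exp.lambda_library).astype(float)
        got = bq.neg_log_likelihood(data, exp)
        brute = 0.0
        for n, lam in (
            (data.n_bound, exp.lambda_bound),
            (data.n_unbound, exp.lambda_unbound),
            (data.n_library, exp.lambda_library),
        ):
            brute += -poisson.logpmf(n.astype(int), lam).sum()
            from scipy.special import gammaln
            brute -= gammaln(n + 1).sum()  # re-drop the data-only constants
        assert got == pytest.approx(brute, abs=1e-8)


class TestDenominatorInit:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows, columns=["rsid", "allele", "tf", "concentration_nM", "replicate", "enrichment"]
        )

    def test_point_nine_over_max(self):
        enr = self.frame(
            [("rs1", "A", "T", 100.0, "R1", 9.0), ("rs2", "A", "T", 100.0, "R1", 2.0)]
        )
        series = ConcentrationSeries(values=(100.0,))
        den, _ = bq.initialize_denominators(enr, series)
        assert den.bound[100.0] == pytest.approx(0.1)
        assert den.unbound[100.0] == 1.0

    def test_max_below_one(self):
        enr = self.frame([("rs1", "A", "T", 100.0, "R1", 0.9)])
        den, _ = bq.initialize_denominators(enr, ConcentrationSeries(values=(100.0,)))
        assert den.bound[100.0] == pytest.approx(1.0)

    def test_replicate_averaging_before_max(self):
        enr = self.frame(
            [("rs1", "A", "T", 100.0, "R1", 8.0), ("rs1", "A", "T", 100.0, "R2", 10.0)]
        )
        den, _ = bq.initialize_denominators(enr, ConcentrationSeries(values=(100.0,)))
        assert den.bound[100.0] == pytest.approx(0.1)

    def test_empty_concentration_auto_excluded(self):
        enr = self.frame([("rs1", "A", "T", 100.0, "R1", 2.0)])
        series = ConcentrationSeries(values=(100.0, 500.0))
        with pytest.warns(UserWarning, match="500"):
            den, out = bq.initialize_denominators(enr, series)
        assert 500.0 in out.excluded and 500.0 not in den.bound


class TestConcentrationExclusion:
    def test_low_bound_total_excluded(self, variants3):
        from conftest import make_table
        from bindnseq import SampleKey

        rows = {}
        for c, tot in ((100.0, 500_000), (500.0, 3_000), (1000.0, 200_000)):
            rows[SampleKey("T", "bound", c, "R1")] = {("rs1", "A"): tot}
        table = make_table(rows)
        series = ConcentrationSeries(values=(0.0, 100.0, 500.0, 1000.0))
        out = bq.exclude_low_coverage_concentrations(table, series, min_bound_total=1e4)
        assert out.excluded == {500.0: "insufficient bound counts"}

    def test_manual_union(self, variants3):
        from conftest import make_table
        from bindnseq import SampleKey

        table = make_table({SampleKey("T", "bound", 100.0, "R1"): {("rs1", "A"): 10**6}})
        series = ConcentrationSeries(values=(100.0, 200.0))
        out = bq.exclude_low_coverage_concentrations(
            table, series, min_bound_total=1, manual=[100.0]
        )
        # 200 nM has no bound sample at all -> zero counts -> auto-excluded
        assert set(out.excluded) == {100.0, 200.0}


@pytest.fixture(scope="module")
def small_sim():
    truth = bq.simulate_truth(n_variants=8, seed=21, depth=2e5)
    counts = bq.simulate_counts(truth)
    flags = bq.apply_filters(counts)
    return truth, counts, flags


class TestFit:
    def test_reproducible_bit_for_bit(self, small_sim):
        truth, counts, flags = small_sim
        fits1, den1 = bq.fit(counts, flags, truth.series)
        fits2, den2 = bq.fit(counts, flags, truth.series)
        pd.testing.assert_frame_equal(fits1, fits2)
        assert den1.bound == den2.bound and den1.unbound == den2.unbound

    def test_zero_nM_counts_never_influence_the_fit(self, small_sim):
        truth, counts, flags = small_sim
        baseline, _ = bq.fit(counts, flags, truth.series)
        tampered = bq.ReadCountTable(dict(counts.counts), counts.discarded)
        for (rsid, allele, key) in list(tampered.counts):
            if key.concentration_nM == 0.0:
                tampered.counts[(rsid, allele, key)] += 1234
        refit, _ = bq.fit(tampered, flags, truth.series)
        pd.testing.assert_frame_equal(refit, baseline)

    def test_shared_K_recovers_tight_spread(self):
        """All sequences generated at one K: fitted spread collapses."""
        truth = bq.simulate_truth(
            n_variants=8, seed=5, depth=2e5, K_law=("constant", 1e-3),
            allele_mode="shared",
        )
        counts = bq.simulate_counts(truth)
        flags = bq.apply_filters(counts)
        fits, _ = bq.fit(counts, flags, truth.series)
        logk = np.log10(fits.loc[fits["converged"], "K_nM_inv"])
        q75, q25 = np.percentile(logk, [75, 25])
        assert q75 - q25 <= 0.2

    def test_well_retention_identifiable_at_depth(self):
        """A strongly bound sequence simulated with w=0.5 fits w near 0.5."""
        truth = bq.simulate_truth(
            n_variants=6, seed=13, depth=5e6, K_law=("constant", 5e-3),
            w_law=("constant", 0.0), allele_mode="shared",
        )
        target = truth.sequences[0]
        truth.w[target] = 0.5
        counts = bq.simulate_counts(truth)
        flags = bq.apply_filters(counts)
        fits, _ = bq.fit(counts, flags, truth.series)
        got = fits.set_index(["rsid", "allele"]).loc[target, "w"]
        assert got == pytest.approx(0.5, abs=0.15)

    def test_local_optimality_at_generating_parameters(self):
        """On noise-free data the generating K beats +-50% perturbations."""
        rng = np.random.default_rng(17)
        f = rng.dirichlet(np.ones(4))
        K = np.array([2e-4, 8e-4, 3e-3, 9e-3])
        w = np.zeros(4)
        concs = [100.0, 500.0, 1500.0, 3000.0]
        data = tiny_fit_data(f, K, w, concs)
        den = Denominators(
            bound={c: float(np.sum(f * bq.occupancy(K, c))) for c in concs},
            unbound={c: float(np.sum(f * (1 - bq.occupancy(K, c)))) for c in concs},
        )
        exp = bq.expected_counts(K, w, data, den)
        data.n_bound = np.round(exp.lambda_bound)
        data.n_unbound = np.round(exp.lambda_unbound)
        data.n_library = np.round(exp.lambda_library)
        base = _per_sequence_nll(data, bq.expected_counts(K, w, data, den))
        for factor in (0.5, 0.75, 1.25, 1.5):
            pert = _per_sequence_nll(data, bq.expected_counts(K * factor, w, data, den))
            assert np.all(base <= pert + 1e-9)

    def test_no_qc_passers_is_an_error(self, small_sim):
        truth, counts, flags = small_sim
        none = flags.copy()
        none["overall_pass"] = False
        with pytest.raises(ValueError, match="no sequences"):
            bq.fit(counts, none, truth.series)
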