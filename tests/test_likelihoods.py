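"""Cell probabilities, multinomial kernels, and forward recursions,
checked against closed forms and exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from deadrecovery import (
    CaptureHistoryMatrix,
    Encoding,
    MArray,
    ParamSet,
    StudyDesign,
    ValidationError,
    build_marray,
    detection_matrix,
    forward_loglik_multistate,
    forward_loglik_single_dr,
    forward_loglik_single_joint,
    marray_cell_probs,
    multinomial_loglik,
    multistate_cell_probs,
    observation_matrix_bpa,
    observation_matrix_classical,
    pool,
    recode,
    simulate_dr,
    transition_matrix_bpa,
    transition_matrix_classical,
)
from deadrecovery._kernels import forward_two_state


class TestCellProbs:
    def test_single_state_schematic_values(self):
        # release occ 1, T=4: (1-s)r, s(1-s)r, ss(1-s)r, complement
        pi = marray_cell_probs(ParamSet(s=0.5, r=0.2), T=4)
        assert pi[0].tolist() == pytest.approx([0.1, 0.05, 0.025, 0.825])
        assert pi[1].tolist() == pytest.approx([0.0, 0.1, 0.05, 0.85])

    def test_zero_recovery_prob_puts_all_mass_in_never(self):
        pi = marray_cell_probs(ParamSet(s=0.7, r=0.0), T=6)
        assert pi[:, -1].tolist() == pytest.approx([1.0] * 5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(100):
            T = int(rng.integers(2, 9))
            pi = marray_cell_probs(
                ParamSet(s=rng.uniform(), r=rng.uniform()), T
            )
            assert pi.sum(axis=1) == pytest.approx([1.0] * (T - 1), abs=1e-12)

    def test_too_few_occasions_rejected(self):
        with pytest.raises(ValidationError):
            marray_cell_probs(ParamSet(s=0.5, r=0.2), T=1)

    def test_multistate_matches_single_state_cells(self):
        s, r, T = 0.5, 0.2, 6
        tau, tau_never = multistate_cell_probs(
            transition_matrix_classical(s), detection_matrix(r), T
        )
        pi = marray_cell_probs(ParamSet(s=s, r=r), T)
        # alive releases re-encountered dead = the single-state cells
        assert tau[:, 0, :, 1] == pytest.approx(pi[:, :-1], abs=1e-12)
        assert tau[:, 0, :, 0] == pytest.approx(0.0)  # no live detection
        assert tau_never[:, 0] == pytest.approx(pi[:, -1], abs=1e-12)

    def test_zero_detection_all_mass_never(self):
        tau, tau_never = multistate_cell_probs(
            transition_matrix_classical(0.6), np.zeros((3, 3)), 5
        )
        assert tau.sum() == 0.0
        assert tau_never[:, 0] == pytest.approx([1.0] * 4)

    def test_joint_detection_reduces_to_cjs_when_r_zero(self):
        s, p, T = 0.7, 0.4, 6
        tau, _ = multistate_cell_probs(
            transition_matrix_classical(s), detection_matrix(0.0, p), T
        )
        for t in range(T - 1):
            for k in range(t, T - 1):
                expected = (s * (1 - p)) ** (k - t) * s * p
                assert tau[t, 0, k, 0] == pytest.approx(expected, abs=1e-12)
                assert tau[t, 0, k, 1] == 0.0

    def test_non_stochastic_transition_rejected(self):
        bad = np.full((3, 3), 0.5)
        with pytest.raises(ValidationError):
            multistate_cell_probs(bad, detection_matrix(0.2), 4)


class TestMultinomialLoglik:
    def test_empty_marray_gives_zero(self):
        ma = MArray(m=np.zeros((3, 4), dtype=int), R=np.zeros(3, dtype=int))
        assert multinomial_loglik(ma, marray_cell_probs(ParamSet(s=0.5, r=0.2), 4)) == 0.0

    def test_single_recovery_hand_value(self):
        m = np.zeros((3, 4), dtype=int)
        m[0, 0] = 1  # released occ 1, recovered occ 2
        ma = MArray(m=m, R=np.array([1, 0, 0]))
        ll = multinomial_loglik(ma, marray_cell_probs(ParamSet(s=0.5, r=0.2), 4))
        assert ll == pytest.approx(np.log(0.1))

    def test_count_in_zero_probability_cell(self):
        m = np.zeros((3, 4), dtype=int)
        m[0, 0] = 1
        ma = MArray(m=m, R=np.array([1, 0, 0]))
        ll = multinomial_loglik(ma, marray_cell_probs(ParamSet(s=0.5, r=0.0), 4))
        assert ll == -np.inf

    def test_mle_recovers_truth_on_large_marray(self):
        truth = ParamSet(s=0.55, r=0.25)
        design = StudyDesign(T=8, releases=(2000,) * 7 + (0,))
        data = simulate_dr(truth, design, np.random.default_rng(5))
        ma = build_marray(data)

        def nll(x):
            return -multinomial_loglik(ma, marray_cell_probs(ParamSet(*x), 8))

        fit = minimize(nll, x0=[0.4, 0.15], method="L-BFGS-B", bounds=[(0.01, 0.99)] * 2)
        se = np.sqrt(np.diag(fit.hess_inv.todense()))
        assert abs(fit.x[0] - truth.s) < 3 * se[0]
        assert abs(fit.x[1] - truth.r) < 3 * se[1]


def enumerate_dr_patterns(T):
    """All binary recovery patterns on occasions 2..T (valid or not)."""
    return [np.array((0,) + bits) for bits in itertools.product((0, 1), repeat=T - 1)]


class TestForwardSingleDR:
    def test_never_recovered_two_occasions(self):
        # (1-s)(1-r) + s with s=0.6, r=0.2 -> 0.92
        y = CaptureHistoryMatrix.from_codes([[1, 0]], Encoding.DR_BINARY)
        ll = forward_loglik_single_dr(ParamSet(s=0.6, r=0.2), y)
        assert ll == pytest.approx(np.log(0.92))

    def test_recovered_first_interval(self):
        y = CaptureHistoryMatrix.from_codes([[1, 1]], Encoding.DR_BINARY)
        ll = forward_loglik_single_dr(ParamSet(s=0.6, r=0.2), y)
        assert ll == pytest.approx(np.log(0.4 * 0.2))

    def test_certain_survival_limit(self):
        y = CaptureHistoryMatrix.from_codes([[1, 0, 0, 0]], Encoding.DR_BINARY)
        assert forward_loglik_single_dr(ParamSet(s=1.0, r=0.3), y) == 0.0

    def test_exhaustive_patterns_sum_to_one(self, rng):
        # all 2^(T-1) post-release recovery patterns; impossible ones
        # (second recovery) must carry probability 0
        T = 4
        f0 = np.zeros(1, dtype=np.int64)
        live = np.zeros((1, T), dtype=np.int64)
        for _ in range(100):
            s, r = rng.uniform(), rng.uniform()
            total = 0.0
            for pat in enumerate_dr_patterns(T):
                ll = forward_two_state(live, pat[None, :], f0, s, r, 0.0)[0]
                total += np.exp(ll)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_row_order(self, small_dr_data, dr_params):
        perm = np.random.default_rng(0).permutation(small_dr_data.n_individuals)
        shuffled = CaptureHistoryMatrix.from_codes(
            small_dr_data.codes[perm], Encoding.DR_BINARY
        )
        assert forward_loglik_single_dr(dr_params, shuffled) == pytest.approx(
            forward_loglik_single_dr(dr_params, small_dr_data), abs=1e-9
        )


class TestForwardJoint:
    def test_exhaustive_joint_patterns_sum_to_one(self, rng):
        # all 3^(T-1) post-release {none, live, dead} patterns
        T = 4
        from deadrecovery._kernels import forward_two_state as fwd

        f0 = np.zeros(1, dtype=np.int64)
        for _ in range(50):
            s, r, p = rng.uniform(size=3)
            total = 0.0
            for pat in itertools.product((0, 1, 2), repeat=T - 1):
                row = np.array((0,) + pat)
                live = (row == 1).astype(np.int64)[None, :]
                dead = (row == 2).astype(np.int64)[None, :]
                total += np.exp(fwd(live, dead, f0, s, r, p)[0])
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_fully_observed_history_is_explicit_product(self):
        # seen alive at occasions 2,3 then recovered at 4:
        # (sp)(sp)((1-s)r)
        y = CaptureHistoryMatrix.from_codes([[1, 1, 1, 2]], Encoding.JOINT)
        params = ParamSet(s=0.6, r=0.3, p=0.4)
        expected = (0.6 * 0.4) ** 2 * 0.4 * 0.3
        assert forward_loglik_single_joint(params, y) == pytest.approx(np.log(expected))

    def test_p_zero_reduces_to_dead_recovery_likelihood(self, small_dr_data):
        v = recode(small_dr_data, Encoding.DR_MULTISTATE)
        joint_coded = recode(v, Encoding.MULTISTATE_ZERO)
        y_joint = CaptureHistoryMatrix.from_codes(joint_coded.codes, Encoding.JOINT)
        params = ParamSet(s=0.45, r=0.3, p=0.0)
        assert forward_loglik_single_joint(params, y_joint) == pytest.approx(
            forward_loglik_single_dr(ParamSet(s=0.45, r=0.3), small_dr_data),
            abs=1e-10,
        )


class TestEquivalenceWeb:
    """Single-state, multistate, BPA, pooled, and multinomial routes agree."""

    def test_dr_formulations_agree(self, dr_data, rng):
        v = recode(dr_data, Encoding.DR_MULTISTATE)
        ma = build_marray(dr_data)
        pooled = pool(dr_data)
        for _ in range(20):
            s, r = rng.uniform(0.05, 0.95, size=2)
            ll = forward_loglik_single_dr(ParamSet(s=s, r=r), dr_data)
            ll_ms = forward_loglik_multistate(
                transition_matrix_classical(s), observation_matrix_classical(r), v
            )
            ll_bpa = forward_loglik_multistate(
                transition_matrix_bpa(s, r), observation_matrix_bpa(), v
            )
            ll_pool = forward_loglik_single_dr(ParamSet(s=s, r=r), pooled)
            ll_multi = multinomial_loglik(ma, marray_cell_probs(ParamSet(s=s, r=r), 8))
            for other in (ll_ms, ll_bpa, ll_pool, ll_multi):
                assert other == pytest.approx(ll, abs=1e-8 * abs(ll))

    def test_joint_formulations_agree(self, joint_data, rng):
        from deadrecovery import build_multistate_marray

        vj = recode(joint_data, Encoding.JOINT_MULTISTATE)
        w = recode(vj, Encoding.MULTISTATE_ZERO)
        msma = build_multistate_marray(w)
        pooled = pool(joint_data)
        for _ in range(20):
            s, r, p = rng.uniform(0.05, 0.95, size=3)
            ll = forward_loglik_single_joint(ParamSet(s=s, r=r, p=p), joint_data)
            ll_ms = forward_loglik_multistate(
                transition_matrix_classical(s),
                observation_matrix_classical(r, p),
                vj,
            )
            ll_bpa = forward_loglik_multistate(
                transition_matrix_bpa(s, r), observation_matrix_bpa(p), vj
            )
            ll_pool = forward_loglik_single_joint(ParamSet(s=s, r=r, p=p), pooled)
            ll_multi = multinomial_loglik(
                msma,
                multistate_cell_probs(
                    transition_matrix_classical(s), detection_matrix(r, p), 8
                ),
            )
            for other in (ll_ms, ll_bpa, ll_pool, ll_multi):
                assert other == pytest.approx(ll, abs=1e-8 * abs(ll))

    def test_multistate_enumeration_sums_to_one(self, rng):
        # all valid 3-coded observation patterns for one release, T=4
        T = 4
        valid = []
        for pat in itertools.product((1, 2, 3), repeat=T - 1):
            try:
                valid.append(
                    CaptureHistoryMatrix.from_codes(
                        [(1,) + pat], Encoding.DR_MULTISTATE
                    )
                )
            except ValidationError:
                continue
        for _ in range(20):
            s, r = rng.uniform(size=2)
            total = sum(
                np.exp(
                    forward_loglik_multistate(
                        transition_matrix_classical(s),
                        observation_matrix_classical(r),
                        h,
                    )
                )
                for h in valid
            )
            assert total == pytest.approx(1.0, abs=1e-12)
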