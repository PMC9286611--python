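import numpy as np
import pytest
from scipy.special import comb

from scrhybrid import (
    AvailabilityMatrix,
    DataBundle,
    Detector,
    DetectionParams,
    GeneticHistory,
    LatentState,
    MarkedResightHistory,
    MarkingHistory,
    ModelSpec,
    OperationMatrix,
    StateSpace,
    TelemetrySet,
    UnmarkedCountMatrix,
    align_bundle,
    log_joint,
    loglik_genetic_scr,
    loglik_marking,
    loglik_resight_marked,
    loglik_spa,
    loglik_telemetry,
    loglik_unmarked_counts,
)
from scrhybrid.detection import inv_logit
from scrhybrid.models import log_prior

SS = StateSpace(-5000.0, 5000.0, -5000.0, 5000.0)


def logit(p):
    return np.log(p / (1 - p))


def state(z, s, psi=0.5, g=None):
    z = np.asarray(z)
    return LatentState(
        z=z, s=np.asarray(s, dtype=float),
        g=np.zeros(len(z), dtype=int) if g is None else np.asarray(g),
        psi=psi,
    )


class TestGeneticLik:
    def _gen(self, y, cell_xy, effort=None, K=1):
        cell_xy = np.asarray(cell_xy, dtype=float)
        J = cell_xy.shape[0]
        eff = np.zeros(J) if effort is None else np.asarray(effort, dtype=float)
        ids = [f"g{i}" for i in range(np.asarray(y).shape[0])]
        return GeneticHistory(ids, [f"c{j}" for j in range(J)], cell_xy, eff, y, n_occasions=K)

    def test_single_detection_at_center(self):
        # kernel = 1 at the cell center, baseline p = 0.3 => log 0.3
        gen = self._gen([[1]], [[0.0, 0.0]])
        params = DetectionParams(sigma=[1000.0], alpha0=[logit(0.3)])
        st = state([1], [[0.0, 0.0]])
        assert loglik_genetic_scr(st, params, gen) == pytest.approx(np.log(0.3), abs=1e-12)

    def test_detection_with_z_zero_impossible(self):
        gen = self._gen([[1]], [[0.0, 0.0]])
        params = DetectionParams(sigma=[1000.0], alpha0=[logit(0.3)])
        st = state([0], [[0.0, 0.0]])
        assert loglik_genetic_scr(st, params, gen) == -np.inf

    def test_independence_product(self):
        # two cells with p = 0.3 and 0.1, y = (1, 0) => log 0.3 + log 0.9
        a0 = logit(0.3)
        a1 = logit(0.1) - logit(0.3)  # effort 1 in the second cell
        gen = self._gen([[1, 0]], [[0.0, 0.0], [0.0, 0.0]], effort=[0.0, 1.0])
        params = DetectionParams(sigma=[1000.0], alpha0=[a0], alpha1=a1)
        st = state([1], [[0.0, 0.0]])
        expected = np.log(0.3) + np.log(0.9)
        assert loglik_genetic_scr(st, params, gen) == pytest.approx(expected, abs=1e-12)

    def test_augmented_all_zero_row(self):
        gen = self._gen([[1]], [[0.0, 0.0]])
        params = DetectionParams(sigma=[1000.0], alpha0=[logit(0.3)])
        st = state([1, 1], [[0.0, 0.0], [0.0, 0.0]])
        # second (augmented) individual at the center contributes log 0.7
        expected = np.log(0.3) + np.log(0.7)
        assert loglik_genetic_scr(st, params, gen) == pytest.approx(expected, abs=1e-12)


class TestMarkingLik:
    def _mk(self, y3, traps):
        ids = [f"m{i}" for i in range(np.asarray(y3).shape[0])]
        return MarkingHistory(ids, [t.id for t in traps], y3), traps

    def test_binomial_pmf(self):
        traps = [Detector("t1", 0.0, 0.0, "live_trap")]
        y3 = np.zeros((1, 1, 5), dtype=int)
        y3[0, 0, 0] = 1
        mk, traps = self._mk(y3, traps)
        params = DetectionParams(sigma=[1000.0], p0_marking=[0.2])
        st = state([1], [[0.0, 0.0]])
        expected = np.log(comb(5, 1)) + np.log(0.2) + 4 * np.log(0.8)
        assert loglik_marking(st, params, mk, traps) == pytest.approx(expected, abs=1e-12)

    def test_augmented_far_away_contributes_zero(self):
        traps = [Detector("t1", 0.0, 0.0, "live_trap")]
        mk, traps = self._mk(np.zeros((1, 1, 5), dtype=int), traps)
        params = DetectionParams(sigma=[100.0], p0_marking=[0.2])
        st = state([1, 1], [[0.0, 0.0], [1e7, 1e7]])
        # far individual's capture probability underflows to 0 -> term 0
        near_only = loglik_marking(state([1], [[0.0, 0.0]]), params, mk, traps)
        both = loglik_marking(st, params, mk, traps)
        assert both == pytest.approx(near_only, abs=1e-12)

    def test_z_zero_contributes_nothing(self):
        traps = [Detector("t1", 0.0, 0.0, "live_trap")]
        mk, traps = self._mk(np.zeros((1, 1, 5), dtype=int), traps)
        params = DetectionParams(sigma=[1000.0], p0_marking=[0.9])
        base = loglik_marking(state([1], [[0.0, 0.0]]), params, mk, traps)
        withz0 = loglik_marking(state([1, 0], [[0.0, 0.0], [10.0, 10.0]]), params, mk, traps)
        assert withz0 == pytest.approx(base, abs=1e-12)

    def test_poisson_variant(self):
        traps = [Detector("t1", 0.0, 0.0, "live_trap")]
        y3 = np.zeros((1, 1, 5), dtype=int)
        y3[0, 0, 0] = 1
        mk, traps = self._mk(y3, traps)
        params = DetectionParams(sigma=[1000.0], lambda0_marking=[0.1])
        st = state([1], [[0.0, 0.0]])
        lam = 0.1 * 5  # rate * kernel(0) * K
        expected = np.log(lam) - lam
        assert loglik_marking(st, params, mk, traps, poisson=True) == pytest.approx(expected, abs=1e-12)


class TestResightLik:
    def _setup(self, y, avail=None, K=1):
        cams = [Detector("cam1", 0.0, 0.0)]
        res = MarkedResightHistory(["A"], ["cam1"], np.asarray(y).reshape(1, 1, K))
        op = OperationMatrix(["cam1"], np.ones((1, K)))
        av = None if avail is None else AvailabilityMatrix(["A"], np.asarray(avail).reshape(1, K))
        return res, cams, op, av

    def test_poisson_at_zero(self):
        res, cams, op, _ = self._setup([0])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.4])
        st = state([1], [[0.0, 0.0]])
        assert loglik_resight_marked(st, params, res, cams, op) == pytest.approx(-0.4, abs=1e-12)

    def test_poisson_pmf_value(self):
        # y = 2 with mean 2: log(2^2 e^-2 / 2!) = ln 2 - 2
        res, cams, op, _ = self._setup([2])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[2.0])
        st = state([1], [[0.0, 0.0]])
        expected = np.log(2.0) - 2.0
        assert loglik_resight_marked(st, params, res, cams, op) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.3069, abs=1e-4)

    def test_unavailable_occasion_skipped(self):
        res, cams, op, av = self._setup([0, 0], avail=[0, 1], K=2)
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.4])
        st = state([1], [[0.0, 0.0]])
        assert loglik_resight_marked(st, params, res, cams, op, av) == pytest.approx(-0.4, abs=1e-12)

    def test_positive_count_zero_exposure_errors(self):
        res, cams, op, av = self._setup([1, 0], avail=[0, 1], K=2)
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.4])
        st = state([1], [[0.0, 0.0]])
        with pytest.raises(ValueError):
            loglik_resight_marked(st, params, res, cams, op, av)


class TestUnmarkedCounts:
    def _setup(self, n, K=1):
        cams = [Detector("cam1", 0.0, 0.0)]
        counts = UnmarkedCountMatrix(["cam1"], np.asarray(n).reshape(1, K))
        op = OperationMatrix(["cam1"], np.ones((1, K)))
        return counts, cams, op

    def test_empty_population_zero_counts(self):
        counts, cams, op = self._setup([0])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.1])
        st = state([0], [[0.0, 0.0]])
        assert loglik_unmarked_counts(st, params, counts, cams, op) == 0.0

    def test_one_individual_at_detector(self):
        counts, cams, op = self._setup([0])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.1])
        st = state([1], [[0.0, 0.0]])
        assert loglik_unmarked_counts(st, params, counts, cams, op) == pytest.approx(-0.1, abs=1e-12)

    def test_unexplained_count_impossible(self):
        counts, cams, op = self._setup([3])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.1])
        st = state([0], [[0.0, 0.0]])
        assert loglik_unmarked_counts(st, params, counts, cams, op) == -np.inf

    def test_marked_individuals_excluded_from_sum(self):
        counts, cams, op = self._setup([0])
        params = DetectionParams(sigma=[1000.0], lambda0_resight=[0.1])
        st = state([1, 1], [[0.0, 0.0], [0.0, 0.0]])
        marked = np.array([True, False])
        assert loglik_unmarked_counts(st, params, counts, cams, op, marked) == pytest.approx(-0.1)


class TestSpaLik:
    def _setup(self, det, K=1):
        cams = [Detector("cam1", 0.0, 0.0)]
        d = UnmarkedCountMatrix(["cam1"], np.asarray(det).reshape(1, K))
        op = OperationMatrix(["cam1"], np.ones((1, K)))
        return d, cams, op

    def test_two_individuals_half(self):
        det, cams, op = self._setup([1])
        params = DetectionParams(sigma=[1000.0], p0=[0.5])
        st = state([1, 1], [[0.0, 0.0], [0.0, 0.0]])
        assert loglik_spa(st, params, det, cams, op) == pytest.approx(np.log(0.75), abs=1e-12)

    def test_single_individual_reduces_to_p(self):
        det, cams, op = self._setup([1])
        params = DetectionParams(sigma=[1000.0], p0=[0.37])
        st = state([1], [[0.0, 0.0]])
        assert loglik_spa(st, params, det, cams, op) == pytest.approx(np.log(0.37), abs=1e-12)

    def test_nobody_included_detection_impossible(self):
        det, cams, op = self._setup([1])
        params = DetectionParams(sigma=[1000.0], p0=[0.5])
        st = state([0], [[0.0, 0.0]])
        assert loglik_spa(st, params, det, cams, op) == -np.inf

    def test_non_binary_rejected(self):
        det, cams, op = self._setup([2])
        params = DetectionParams(sigma=[1000.0], p0=[0.5])
        with pytest.raises(ValueError):
            loglik_spa(state([1], [[0.0, 0.0]]), params, det, cams, op)

    def test_spa_detection_prob_matches_sc_with_matched_rate(self):
        """Cross-model consistency: with p = 1 - exp(-lambda) pointwise, the
        single-individual SPA detection probability equals the SC probability
        of a nonzero count."""
        lam0, sigma = 0.7, 900.0
        for d in (0.0, 300.0, 1200.0, 2500.0):
            lam = lam0 * np.exp(-(d**2) / (2 * sigma**2))
            p_match = 1.0 - np.exp(-lam)
            det, cams, op = self._setup([1])
            spa_params = DetectionParams(sigma=[sigma], p0=[p_match])
            st = state([1], [[d, 0.0]])
            # kernel applies twice on the SPA side; undo it to match pointwise
            spa_params.p0[0] = p_match / np.exp(-(d**2) / (2 * sigma**2))
            if spa_params.p0[0] >= 1:
                continue
            ll_spa = loglik_spa(st, spa_params, det, cams, op)
            counts = UnmarkedCountMatrix(["cam1"], np.array([[0]]))
            sc_params = DetectionParams(sigma=[sigma], lambda0_resight=[lam0])
            ll0 = loglik_unmarked_counts(st, sc_params, counts, cams, op)
            assert np.exp(ll_spa) == pytest.approx(1.0 - np.exp(ll0), rel=1e-10)


class TestTelemetryLik:
    def test_density_at_mean(self):
        tel = TelemetrySet({"A": np.array([[0.0, 0.0]])})
        params = DetectionParams(sigma=[1000.0])
        st = state([1], [[0.0, 0.0]])
        expected = np.log(1.0 / (2.0 * np.pi * 1e6))
        assert loglik_telemetry(st, params, tel, {"A": 0}) == pytest.approx(expected, abs=1e-12)

    def test_doubling_sigma_quarters_density_at_mean(self):
        tel = TelemetrySet({"A": np.array([[0.0, 0.0]])})
        st = state([1], [[0.0, 0.0]])
        l1 = loglik_telemetry(st, DetectionParams(sigma=[1000.0]), tel, {"A": 0})
        l2 = loglik_telemetry(st, DetectionParams(sigma=[2000.0]), tel, {"A": 0})
        assert np.exp(l1) / np.exp(l2) == pytest.approx(4.0, rel=1e-12)

    def test_maximized_at_fix_centroid(self):
        rng = np.random.default_rng(1)
        fixes = rng.normal(0.0, 500.0, size=(40, 2)) + np.array([300.0, -200.0])
        tel = TelemetrySet({"A": fixes})
        params = DetectionParams(sigma=[500.0])
        centroid = fixes.mean(axis=0)
        best = loglik_telemetry(state([1], [centroid]), params, tel, {"A": 0})
        for delta in ([100.0, 0.0], [0.0, -150.0], [80.0, 80.0]):
            other = loglik_telemetry(state([1], [centroid + delta]), params, tel, {"A": 0})
            assert other < best


# ---------------------------------------------------------------------------
# Joint density composition and reduction identities
# ---------------------------------------------------------------------------


def _hybrid_bundle(rng, n_occ=3):
    cams = [Detector(f"cam{j}", 500.0 * j - 1000.0, 0.0) for j in range(4)]
    traps = [Detector(f"trap{j}", 700.0 * j - 700.0, 300.0, "live_trap") for j in range(3)]
    cells_xy = np.array([[-800.0, -500.0], [0.0, -500.0], [800.0, -500.0]])
    marked = ["A", "B"]
    res = MarkedResightHistory(marked, [c.id for c in cams], rng.poisson(0.4, (2, 4, n_occ)))
    counts = UnmarkedCountMatrix([c.id for c in cams], rng.poisson(0.6, (4, n_occ)))
    op = OperationMatrix([c.id for c in cams], np.ones((4, n_occ)))
    avail = AvailabilityMatrix.always_available(marked, n_occ)
    mk = MarkingHistory(marked, [t.id for t in traps], rng.binomial(1, 0.3, (2, 3, 2)))
    gen = GeneticHistory(
        ["A", "C"], ["c0", "c1", "c2"], cells_xy, np.array([1.5, 1.8, 1.6]),
        np.array([[1, 0, 0], [0, 1, 1]]),
    )
    tel = TelemetrySet({"A": rng.normal(0, 800, (10, 2)), "B": rng.normal(0, 800, (10, 2))})
    return DataBundle(
        state_space=SS, cameras=cams, resights=res, counts=counts, operation=op,
        availability=avail, traps=traps, marking=mk, genetic=gen, telemetry=tel,
    )


def _rand_state_params(rng, M, spec):
    z = np.ones(M, dtype=int)
    z[4:] = rng.integers(0, 2, M - 4)
    s = rng.uniform(-4000, 4000, (M, 2))
    st = LatentState(z=z, s=s, g=np.zeros(M, dtype=int), psi=rng.uniform(0.2, 0.8))
    params = DetectionParams(
        sigma=[rng.uniform(500, 2000)],
        lambda0_resight=[rng.uniform(0.1, 0.8)],
        p0_marking=[rng.uniform(0.05, 0.4)],
        alpha0=[rng.normal(-1.5, 0.5)],
        alpha1=rng.normal(0, 0.3),
    )
    return st, params


class TestLogJoint:
    def test_hybrid_is_sum_of_components_plus_priors(self):
        rng = np.random.default_rng(3)
        bundle = _hybrid_bundle(rng)
        spec = ModelSpec("hybrid", M=8, use_telemetry=True)
        aln = align_bundle(bundle, spec)
        st, params = _rand_state_params(rng, 8, spec)
        total = log_joint(spec, st, params, bundle)
        manual = (
            log_prior(spec, st, params, bundle)
            + loglik_genetic_scr(st, params, bundle.genetic, aln.genetic_slots)
            + loglik_marking(st, params, bundle.marking, bundle.traps, aln.marking_slots)
            + loglik_resight_marked(
                st, params, bundle.resights, bundle.cameras, bundle.operation,
                bundle.availability, aln.resight_slots,
            )
            + loglik_unmarked_counts(
                st, params, bundle.counts, bundle.cameras, bundle.operation, aln.marked_mask
            )
            + loglik_telemetry(st, params, bundle.telemetry, aln.telemetry_slots)
        )
        assert total == pytest.approx(manual, abs=1e-9)

    def test_center_outside_state_space_impossible(self):
        rng = np.random.default_rng(4)
        bundle = _hybrid_bundle(rng)
        spec = ModelSpec("hybrid", M=8, use_telemetry=True)
        st, params = _rand_state_params(rng, 8, spec)
        st.s[5] = [99999.0, 0.0]
        assert log_joint(spec, st, params, bundle) == -np.inf

    def test_known_individual_z_zero_impossible(self):
        rng = np.random.default_rng(5)
        bundle = _hybrid_bundle(rng)
        spec = ModelSpec("hybrid", M=8, use_telemetry=True)
        st, params = _rand_state_params(rng, 8, spec)
        st.z[0] = 0  # marked individual: known to exist
        assert log_joint(spec, st, params, bundle) == -np.inf

    def test_missing_stream_rejected(self):
        rng = np.random.default_rng(6)
        bundle = _hybrid_bundle(rng)
        bundle.marking = None
        spec = ModelSpec("hybrid", M=8, use_telemetry=True)
        with pytest.raises(ValueError, match="marking"):
            align_bundle(bundle, spec)

    def test_detector_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        bundle = _hybrid_bundle(rng)
        spec = ModelSpec("hybrid", M=8, use_telemetry=True)
        st, params = _rand_state_params(rng, 8, spec)
        before = log_joint(spec, st, params, bundle)
        perm = [2, 0, 3, 1]
        bundle2 = _hybrid_bundle(np.random.default_rng(7))
        bundle2.cameras = [bundle.cameras[j] for j in perm]
        bundle2.resights.y = bundle.resights.y[:, perm, :]
        bundle2.resights.detector_ids = [bundle.resights.detector_ids[j] for j in perm]
        bundle2.counts.n = bundle.counts.n[perm, :]
        bundle2.counts.detector_ids = [bundle.counts.detector_ids[j] for j in perm]
        bundle2.operation.values = bundle.operation.values[perm, :]
        bundle2.operation.detector_ids = [bundle.operation.detector_ids[j] for j in perm]
        after = log_joint(spec, st, params, bundle2)
        assert after == pytest.approx(before, abs=1e-9)


class TestReductions:
    def test_smr_with_zero_marked_equals_sc(self):
        rng = np.random.default_rng(11)
        cams = [Detector(f"cam{j}", 600.0 * j - 900.0, 0.0) for j in range(4)]
        counts = UnmarkedCountMatrix([c.id for c in cams], rng.poisson(0.5, (4, 3)))
        op = OperationMatrix([c.id for c in cams], np.ones((4, 3)))
        empty_res = MarkedResightHistory([], [c.id for c in cams], np.zeros((0, 4, 3), dtype=int))
        smr_bundle = DataBundle(state_space=SS, cameras=cams, resights=empty_res,
                                counts=counts, operation=op)
        sc_bundle = DataBundle(state_space=SS, cameras=cams, counts=counts, operation=op)
        M = 6
        smr = ModelSpec("SMR", M=M)
        sc = ModelSpec("SC", M=M)
        for trial in range(5):
            st, params = _rand_state_params(np.random.default_rng(100 + trial), M, sc)
            a = log_joint(smr, st, params, smr_bundle)
            b = log_joint(sc, st, params, sc_bundle)
            assert a == b

    def test_hybrid_with_only_genetic_reduces_to_scr(self):
        """With empty camera/marking streams the hybrid joint equals the
        genetic-SCR joint up to the constant prior mass of the unused
        resighting rate (one Uniform(0,5) normalization; the binomial marking
        probability has a Beta(1,1) prior with unit density)."""
        rng = np.random.default_rng(12)
        gen = GeneticHistory(
            ["A", "B"], ["c0", "c1"], np.array([[-500.0, 0.0], [500.0, 0.0]]),
            np.array([1.5, 1.8]), np.array([[1, 0], [0, 1]]),
        )
        M = 5
        empty_res = MarkedResightHistory([], [], np.zeros((0, 0, 2), dtype=int))
        empty_counts = UnmarkedCountMatrix([], np.zeros((0, 2), dtype=int))
        empty_mk = MarkingHistory([], [], np.zeros((0, 0, 2), dtype=int))
        hyb_bundle = DataBundle(
            state_space=SS, cameras=[], resights=empty_res, counts=empty_counts,
            operation=OperationMatrix([], np.zeros((0, 2))), traps=[], marking=empty_mk,
            genetic=gen,
        )
        scr_bundle = DataBundle(state_space=SS, genetic=gen)
        hyb = ModelSpec("hybrid", M=M)
        scr = ModelSpec("SCR", M=M)
        expected_const = -np.log(5.0)
        for trial in range(5):
            st, params = _rand_state_params(np.random.default_rng(200 + trial), M, scr)
            diff = log_joint(hyb, st, params, hyb_bundle) - log_joint(scr, st, params, scr_bundle)
            assert diff == pytest.approx(expected_const, abs=1e-9)

    def test_binary_components_nonpositive(self):
        rng = np.random.default_rng(13)
        bundle = _hybrid_bundle(rng)
        spec = ModelSpec("hybrid", M=8, use_telemetry=False)
        aln = align_bundle(bundle, spec)
        for trial in range(10):
            st, params = _rand_state_params(np.random.default_rng(300 + trial), 8, spec)
            assert loglik_genetic_scr(st, params, bundle.genetic, aln.genetic_slots) <= 0.0
            assert loglik_marking(st, params, bundle.marking, bundle.traps, aln.marking_slots) <= 0.0
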