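"""Shell-scan and propagative scan against the voxel oracle."""

import numpy as np
import pytest

import episcan as ep
from episcan.scans import ScanState, nn_predict, select_new_acquisitions
from conftest import constant_background_model, flat_shell


def brute_force_nn_predict(state, shell, beta):
    """Exhaustive pairwise-distance NN search: the independent oracle for
    the production prediction (same layer, min xy distance, ties to the
    highest normalized intensity, cutoff at beta)."""
    pred = np.full_like(state.values, np.nan)
    valid = state.layer_valid
    nlay, nx, ny = state.values.shape
    for li in range(nlay):
        cand = np.argwhere(np.isfinite(state.values[li]))
        if len(cand) == 0:
            continue
        cvals = state.values[li][cand[:, 0], cand[:, 1]]
        for x in range(nx):
            for y in range(ny):
                if not valid[li, x, y] or np.isfinite(state.values[li, x, y]):
                    continue
                d2 = (cand[:, 0] - x) ** 2 + (cand[:, 1] - y) ** 2
                best = d2.min()
                if best > beta * beta:
                    continue
                tied = cvals[d2 == best]
                pred[li, x, y] = tied.max()
    return pred


def make_state(shell, coords, values, model=None):
    model = model or constant_background_model(100.0, 0.05)
    state = ScanState(shell)
    raw = 100.0 * (1 + 0.05 * np.asarray(values, dtype=float))
    samples = ep.SampleSet(coords=coords, raw=raw).with_normalized(values)
    state.ingest(samples)
    return state


class TestNNPredict:
    def test_single_candidate_predicts_its_layer_only(self):
        shell = flat_shell(20, 20, 50, plane=25)
        state = make_state(shell, np.array([[10, 10, 25]]), [5.0])
        pred = nn_predict(state, shell, beta=5)
        k = shell.half_layers
        gx, gy = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        within = (gx - 10) ** 2 + (gy - 10) ** 2 <= 25
        within[10, 10] = False  # already acquired, not predicted
        assert np.array_equal(np.isfinite(pred[k]), within)
        assert np.all(pred[k][within] == 5.0)
        assert not np.isfinite(pred[k - 1]).any()
        assert not np.isfinite(pred[k + 1]).any()

    def test_tie_takes_highest_normalized_intensity(self):
        shell = flat_shell(9, 9, 50, plane=25)
        state = make_state(shell, np.array([[4, 2, 25], [4, 6, 25]]), [2.0, 4.0])
        pred = nn_predict(state, shell, beta=2)
        assert pred[shell.half_layers, 4, 4] == 4.0

    @pytest.mark.parametrize("beta", [1, 3, 7.5])
    def test_matches_brute_force(self, beta):
        rng = np.random.default_rng(42)
        surf = ep.SurfaceModel(z=rng.uniform(4.5, 5.5, size=(30, 30)),
                               support=rng.random((30, 30)) > 0.1)
        shell = ep.build_shell(surf, 1.5, 20, 0.5)  # 3 layers
        coords = shell.all_coords()
        pick = rng.choice(len(coords), size=60, replace=False)
        state = make_state(shell, coords[pick], rng.normal(0, 3, size=60))
        fast = nn_predict(state, shell, beta)
        slow = brute_force_nn_predict(state, shell, beta)
        assert np.array_equal(np.isfinite(fast), np.isfinite(slow))
        assert np.allclose(fast[np.isfinite(fast)], slow[np.isfinite(slow)])


class TestSelectNewAcquisitions:
    def setup_method(self):
        self.shell = flat_shell(6, 6, 50, plane=25)
        self.state = ScanState(self.shell)
        self.k = self.shell.half_layers

    def test_all_below_threshold_selects_nothing(self):
        pred = np.full_like(self.state.values, np.nan)
        pred[self.k, 1, 1] = 2.0
        assert len(select_new_acquisitions(pred, self.state, self.shell, 2.33)) == 0

    def test_column_keeps_only_highest_prediction(self):
        pred = np.full_like(self.state.values, np.nan)
        pred[self.k, 2, 2] = 2.5
        pred[self.k + 1, 2, 2] = 3.0
        coords = select_new_acquisitions(pred, self.state, self.shell, 2.33)
        assert coords.tolist() == [[2, 2, 26]]

    def test_column_blocked_by_brighter_acquisition(self):
        state = make_state(self.shell, np.array([[2, 2, 25]]), [3.5])
        pred = np.full_like(state.values, np.nan)
        pred[self.k + 1, 2, 2] = 3.0
        assert len(select_new_acquisitions(pred, state, self.shell, 2.33)) == 0
        # equality also blocks
        state2 = make_state(self.shell, np.array([[2, 2, 25]]), [3.0])
        assert len(select_new_acquisitions(pred, state2, self.shell, 2.33)) == 0
        # a dimmer acquisition does not
        state3 = make_state(self.shell, np.array([[2, 2, 25]]), [2.9])
        assert len(select_new_acquisitions(pred, state3, self.shell, 2.33)) == 1


class TestSeedInShell:
    def test_counts_and_determinism(self):
        shell = flat_shell(10, 10, 50, plane=25)
        assert len(ep.seed_in_shell(shell, 0, 0)) == 0
        a = ep.seed_in_shell(shell, 50, 3)
        b = ep.seed_in_shell(shell, 50, 3)
        assert np.array_equal(a, b)
        assert shell.contains(a).all()
        full = ep.seed_in_shell(shell, shell.n_voxels(), 0)
        assert len(np.unique(full, axis=0)) == shell.n_voxels()

    def test_too_many_seeds(self):
        shell = flat_shell(4, 4, 50, plane=25)
        with pytest.raises(ValueError):
            ep.seed_in_shell(shell, shell.n_voxels() + 1, 0)


class TestShellScan:
    def test_flat_shell_dose_arithmetic(self):
        rng = np.random.default_rng(0)
        vol = ep.Volume(data=rng.uniform(50, 150, (30, 30, 50)).astype(np.float32),
                        pitch=(0.27, 0.27, 0.5))
        shell = flat_shell(30, 30, 50, plane=25)
        ledger = ep.DoseLedger(vol.shape)
        model = constant_background_model(100.0, 0.2)
        res = ep.shell_scan(ep.oracle_from_stack(vol), shell, model, ledger)
        assert res.dose["dose_fraction"] == pytest.approx(7 / 50)
        # emulation fidelity: acquired values equal stack values exactly
        c = res.samples.coords
        assert np.array_equal(res.samples.raw, vol.data[c[:, 0], c[:, 1], c[:, 2]])
        assert np.all(res.acquisitions_per_column == 7)

    def test_empty_shell_rejected(self):
        surf = ep.SurfaceModel(z=np.full((4, 4), np.nan),
                               support=np.zeros((4, 4), dtype=bool))
        shell = ep.build_shell(surf, 3.0, 10, 0.5)
        vol = ep.Volume(data=np.ones((4, 4, 10), dtype=np.float32),
                        pitch=(0.27, 0.27, 0.5))
        with pytest.raises(ValueError):
            ep.shell_scan(ep.oracle_from_stack(vol), shell,
                          constant_background_model(1.0, 0.1),
                          ep.DoseLedger(vol.shape))


def _dark_setup(nx=24, ny=24, nz=20, plane=10):
    vol = ep.Volume(data=np.full((nx, ny, nz), 100.0, dtype=np.float32),
                    pitch=(0.27, 0.27, 0.5))
    shell = flat_shell(nx, ny, nz, plane=plane)
    model = constant_background_model(100.0, 0.05, shape=(nx, ny, nz))
    oracle = ep.oracle_from_stack(vol)
    ledger = ep.DoseLedger(vol.shape)
    prescan_coords = ep.draw_prescan(vol.shape, 0.01, seed=5)
    prescan = ep.normalize(ep.acquire(oracle, prescan_coords, ledger, 0), model)
    return vol, shell, model, oracle, ledger, prescan


class TestPropagativeScan:
    def test_dark_volume_converges_at_iteration_two(self):
        vol, shell, model, oracle, ledger, prescan = _dark_setup()
        params = ep.PropagativeParams(T=2.33, beta=1, n0=30, seed=0)
        res = ep.propagative_scan(oracle, shell, model, params, ledger, prescan)
        assert res.converged
        assert res.per_iteration_counts[-1] == 0
        assert len(res.per_iteration_counts) == 2  # seeds, then nothing
        assert ledger.n_unique <= len(prescan) + 30

    def test_requires_normalized_prescan(self):
        vol, shell, model, oracle, ledger, prescan = _dark_setup()
        bare = ep.SampleSet(coords=prescan.coords, raw=prescan.raw)
        with pytest.raises(ValueError, match="normaliz"):
            ep.propagative_scan(oracle, shell, model,
                                ep.PropagativeParams(T=2.33), ledger, bare)

    def test_acquisitions_confined_to_shell_and_prescan(self, small_curved_gt,
                                                        small_curved_estimate):
        est = small_curved_estimate
        ledger = ep.DoseLedger(small_curved_gt.config.shape)
        ledger.record(est.prescan.coords)
        params = ep.PropagativeParams(T=est.params.T, beta=3, seed=2)
        res = ep.propagative_scan(est.oracle, est.shell, est.model, params,
                                  ledger, est.prescan)
        new = res.samples.iteration > 0
        assert est.shell.contains(res.samples.coords[new]).all()
        # dose bound relative to the exhaustive shell-scan
        n0 = len(est.prescan)
        assert ledger.n_unique <= est.shell.n_voxels() + 2 * n0
        # iteration counts decrease to zero at convergence
        assert res.converged and res.per_iteration_counts[-1] == 0

    def test_determinism(self, small_curved_gt, small_curved_estimate):
        est = small_curved_estimate
        runs = []
        for _ in range(2):
            ledger = ep.DoseLedger(small_curved_gt.config.shape)
            params = ep.PropagativeParams(T=est.params.T, beta=1, seed=9)
            res = ep.propagative_scan(est.oracle, est.shell, est.model, params,
                                      ledger, est.prescan)
            runs.append(res)
        assert np.array_equal(runs[0].samples.coords, runs[1].samples.coords)
        assert runs[0].per_iteration_counts == runs[1].per_iteration_counts

    def test_propagation_follows_a_bright_line(self):
        # noise-free contour: every line voxel xy-connected to the seed is
        # eventually acquired
        nx, ny, nz = 40, 9, 20
        data = np.full((nx, ny, nz), 100.0, dtype=np.float32)
        line_y, line_z = 4, 10
        data[:, line_y, line_z] = 300.0
        vol = ep.Volume(data=data, pitch=(0.27, 0.27, 0.5))
        shell = flat_shell(nx, ny, nz, plane=line_z)
        model = constant_background_model(100.0, 0.05, shape=(nx, ny, nz))
        oracle = ep.oracle_from_stack(vol)
        ledger = ep.DoseLedger(vol.shape)
        seed_sample = ep.normalize(
            ep.acquire(oracle, np.array([[0, line_y, line_z]]), ledger, 0), model)
        params = ep.PropagativeParams(T=2.33, beta=1, n0=0, seed=0)
        res = ep.propagative_scan(oracle, shell, model, params, ledger, seed_sample)
        acquired = ledger.acquired_mask
        assert acquired[:, line_y, line_z].all()
        counts = res.per_iteration_counts
        assert counts[-1] == 0 and max(counts) >= 1


class TestMaxIntensityProjection:
    def test_values_and_missing_flags(self):
        shell = flat_shell(5, 5, 50, plane=25)
        s = ep.SampleSet(coords=np.array([[1, 1, 25], [1, 1, 26], [3, 3, 24]]),
                         raw=np.ones(3),
                         normalized=np.array([2.0, 4.0, 1.0]))
        mip = ep.max_intensity_projection(s, shell)
        assert mip[1, 1] == 4.0
        assert mip[3, 3] == 1.0
        assert np.isnan(mip[0, 0])

    def test_requires_acquisitions(self):
        shell = flat_shell(5, 5, 50, plane=25)
        with pytest.raises(ValueError):
            ep.max_intensity_projection(ep.SampleSet.empty(), shell)
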