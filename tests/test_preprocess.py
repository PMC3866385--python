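"""Filtering, nuisance extraction and the four regression schemes."""

import dataclasses

import numpy as np
import pytest

import gsrnet as g
from gsrnet.preprocess import CollinearRegressorsError
from gsrnet.synth import TimeSeriesDataset


def _dataset_from(data, phantom, tr=2.5, motion=None):
    t = data.shape[1]
    if motion is None:
        rng = np.random.default_rng(0)
        motion = rng.standard_normal((6, t))
    aux = {"white_matter_sphere": data[:1] * 0.0,
           "ventricle": data[:1] * 0.0}
    return TimeSeriesDataset(data=data, tr=tr, phantom=phantom,
                             motion=motion, aux=aux)


class TestBandpass:
    @pytest.mark.parametrize("design", ["butterworth", "ideal"])
    def test_inband_sinusoid_passes(self, small_phantom, design):
        t = np.arange(240) * 2.5
        x = np.sin(2 * np.pi * 0.04 * t)
        data = np.tile(x, (small_phantom.n_nodes, 1))
        ds = _dataset_from(data, small_phantom)
        out = g.bandpass(ds, 0.009, 0.08, design=design)
        assert out.data[0].var() >= 0.9 * x.var()

    @pytest.mark.parametrize("design", ["butterworth", "ideal"])
    def test_stopband_sinusoid_attenuated(self, small_phantom, design):
        t = np.arange(240) * 2.5
        x = np.sin(2 * np.pi * 0.15 * t)  # inside Nyquist 0.2, outside band
        data = np.tile(x, (small_phantom.n_nodes, 1))
        out = g.bandpass(_dataset_from(data, small_phantom), 0.009, 0.08,
                         design=design)
        assert out.data[0].var() <= 0.1 * x.var()

    def test_constant_series_removed(self, small_phantom):
        data = np.full((small_phantom.n_nodes, 120), 3.7)
        out = g.bandpass(_dataset_from(data, small_phantom), 0.009, 0.08)
        assert np.abs(out.data).max() < 1e-6

    def test_invalid_band_errors(self, shared_signal_dataset):
        with pytest.raises(ValueError, match="(?i)band|nyquist"):
            g.bandpass(shared_signal_dataset, 0.08, 0.009)
        with pytest.raises(ValueError):
            g.bandpass(shared_signal_dataset, 0.01, 0.3)

    def test_provenance_recorded(self, shared_signal_dataset):
        out = g.bandpass(shared_signal_dataset, 0.009, 0.08)
        assert any("bandpass" in step for step in out.provenance)


class TestExtractNuisance:
    def test_single_voxel_mask_returns_that_series(self, small_phantom):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((small_phantom.n_nodes, 50))
        ds = _dataset_from(data, small_phantom)
        ds.aux["white_matter_sphere"] = rng.standard_normal((1, 50))
        nuis = g.extract_nuisance(ds)
        assert np.allclose(nuis.white_matter,
                           ds.aux["white_matter_sphere"][0])

    def test_opposite_series_cancel(self, small_phantom):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((small_phantom.n_nodes, 50))
        ds = _dataset_from(data, small_phantom)
        x = rng.standard_normal(50)
        ds.aux["ventricle"] = np.vstack([x, -x])
        nuis = g.extract_nuisance(ds)
        assert np.allclose(nuis.ventricle, 0.0)

    def test_whole_brain_tracks_latent_global(self, small_phantom):
        model = g.SignalModel(var_module=0, var_local=0, var_noise=0.1,
                              var_global=1, var_wm=0.0,
                              module_loading_spread=0, hub_global_loading=1,
                              seed=9)
        ds = g.simulate_timeseries(small_phantom, model)
        nuis = g.extract_nuisance(ds)
        # the node mean is dominated by G when var_global dominates noise
        node_mean = ds.data.mean(axis=0)
        r = np.corrcoef(nuis.whole_brain, node_mean)[0, 1]
        assert r > 0.99

    def test_empty_mask_errors(self, small_phantom):
        data = np.random.default_rng(0).standard_normal(
            (small_phantom.n_nodes, 40))
        ds = _dataset_from(data, small_phantom)
        ds.aux.pop("ventricle")
        with pytest.raises(ValueError, match="(?i)mask"):
            g.extract_nuisance(ds)


class TestRegressOut:
    def test_residuals_orthogonal_to_all_regressors(self, shared_signal_dataset):
        nuis = g.extract_nuisance(shared_signal_dataset)
        out = g.regress_out(shared_signal_dataset, g.FULL, nuis)
        rows, _ = nuis.stack(g.FULL.regressors)
        rows = rows - rows.mean(axis=1, keepdims=True)
        for reg in rows:
            dots = np.abs(out.data @ reg)
            norms = np.linalg.norm(out.data, axis=1) * np.linalg.norm(reg)
            assert (dots <= 1e-8 * np.maximum(norms, 1e-30)).all()
        assert np.abs(out.data.sum(axis=1)).max() < 1e-8

    def test_idempotent(self, shared_signal_dataset):
        nuis = g.extract_nuisance(shared_signal_dataset)
        once = g.regress_out(shared_signal_dataset, g.NOWB, nuis)
        twice = g.regress_out(once, g.NOWB, nuis)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_exact_global_regressor_restores_intrinsic_structure(self,
                                                                 small_phantom):
        # W = Y + G with independent Y; feeding G itself as the
        # whole-brain regressor must leave Y's null correlations
        rng = np.random.default_rng(4)
        t = 200
        y = rng.standard_normal((small_phantom.n_nodes, t))
        gsig = rng.standard_normal(t)
        ds = _dataset_from(y + gsig, small_phantom,
                           motion=rng.standard_normal((6, t)) * 1e-6)
        nuis = g.NuisanceSet(motion=ds.motion, whole_brain=gsig,
                             white_matter=np.zeros(t) + rng.standard_normal(t),
                             ventricle=rng.standard_normal(t))
        out = g.regress_out(ds, g.WBONLY, nuis)
        summ = g.summarize_distribution(g.correlation_matrix(out))
        assert abs(summ.mean) < 0.02

    def test_nocorr_with_zero_motion_only_demeans(self, small_phantom):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((small_phantom.n_nodes, 80))
        ds = _dataset_from(data, small_phantom, motion=np.zeros((6, 80)))
        out = g.regress_out(ds, g.NOCORR, g.extract_nuisance(ds))
        demeaned = data - data.mean(axis=1, keepdims=True)
        assert np.allclose(out.data, demeaned, atol=1e-9)

    def test_collinear_regressors_error_names_columns(self, small_phantom):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((small_phantom.n_nodes, 60))
        motion = rng.standard_normal((6, 60))
        motion[1] = 2.0 * motion[0]  # exact collinearity
        ds = _dataset_from(data, small_phantom, motion=motion)
        with pytest.raises(CollinearRegressorsError, match="motion"):
            g.regress_out(ds, g.NOCORR, g.extract_nuisance(ds))

    def test_method_regressor_sets_fixed(self):
        assert g.NOCORR.regressors == ("motion",)
        assert g.NOWB.regressors == ("motion", "white_matter", "ventricle")
        assert g.WBONLY.regressors == ("motion", "whole_brain")
        assert g.FULL.regressors == ("motion", "white_matter", "ventricle",
                                     "whole_brain")
        with pytest.raises(ValueError):
            g.CorrectionMethod(name="NoCorr",
                               regressors=("motion", "whole_brain"))

    def test_bias_ordering_single_seed(self, small_phantom):
        """NoCorr >= NoWB >= Full mean correlation on a shared-signal
        phantom (the full multi-seed ordering runs in the study tests)."""
        model = g.SignalModel(seed=123)
        ds = g.bandpass(g.simulate_timeseries(small_phantom, model),
                        0.009, 0.08)
        nuis = g.extract_nuisance(ds)
        means = {}
        for meth in (g.NOCORR, g.NOWB, g.FULL):
            out = g.regress_out(ds, meth, nuis)
            means[meth.name] = g.summarize_distribution(
                g.correlation_matrix(out)).mean
        assert means["NoCorr"] > means["NoWB"] > means["Full"]
        assert abs(means["Full"]) < 0.1
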