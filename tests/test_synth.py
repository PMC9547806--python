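"""Generators: planted truth consistency, noise model, determinism, round-trips."""

import numpy as np
import pytest

from clusterlab import io as clio
from clusterlab.crosslink import (
    AntibodySpecies, BindingParams, make_receptor_pool, place_receptors,
    simulate_binding,
)
from clusterlab.errors import InvalidArgumentError
from clusterlab.synth import (
    OpticsParams,
    render_simulated_field,
    synth_calcium_traces,
    synth_cluster_timelapse,
    synth_flow_events,
    synth_nmj_image,
)

NOISE_FREE = OpticsParams(background_level=10.0, read_noise_sd=0.0, psf_sigma=0.0)


class TestClusterTimelapse:
    def test_zero_slopes_give_constant_truth_count(self):
        _, truth = synth_cluster_timelapse(n_pre=3, n_post=5, count_slope=0.0,
                                           initial_count=4, shape=(192, 192), seed=1)
        post = truth.counts[truth.n_pre:]
        assert (post == 4).all()
        assert (truth.counts[: truth.n_pre] == 0).all()

    def test_truth_count_follows_rounded_linear_law(self):
        _, truth = synth_cluster_timelapse(n_pre=2, n_post=10, count_slope=1.5,
                                           initial_count=2, shape=(256, 256),
                                           apply_noise=False, seed=2)
        expected = [round(2 + 1.5 * k) for k in range(10)]
        assert truth.counts[2:].tolist() == expected

    def test_noise_free_frame_sum_matches_closed_form(self):
        optics = NOISE_FREE
        stack, truth = synth_cluster_timelapse(
            n_pre=2, n_post=3, count_slope=0.0, initial_count=3,
            shape=(192, 192), optics=optics, diffuse_fraction=0.1,
            apply_noise=False, seed=3,
        )
        frame = stack.channel("BTX")[-1].astype(float)
        npix = frame.size
        planted_px = (truth.label_masks[-1] > 0).sum()
        expected = npix * (optics.background_level + 0.1 * optics.photon_scale) \
            + optics.photon_scale * planted_px
        assert frame.sum() == pytest.approx(expected, rel=0.01)

    def test_noisy_frame_sum_within_poisson_band(self):
        optics = OpticsParams(psf_sigma=0.0, read_noise_sd=0.0)
        stack, truth = synth_cluster_timelapse(
            n_pre=2, n_post=2, count_slope=0.0, initial_count=3,
            shape=(192, 192), optics=optics, diffuse_fraction=0.1, seed=4,
        )
        frame = stack.channel("BTX")[-1].astype(float)
        planted_px = (truth.label_masks[-1] > 0).sum()
        mean = frame.size * (optics.background_level + 0.1 * optics.photon_scale) \
            + optics.photon_scale * planted_px
        assert abs(frame.sum() - mean) < 3 * np.sqrt(mean)

    def test_truth_consistent_with_noise_free_render(self):
        stack, truth = synth_cluster_timelapse(n_pre=2, n_post=3, shape=(192, 192),
                                               optics=NOISE_FREE, apply_noise=False,
                                               seed=5)
        frame = stack.channel("BTX")[-1].astype(float)
        mask = truth.label_masks[-1] > 0
        assert frame[mask].min() > frame[~mask].max() * 0.9 + 1  # clusters brighter
        for lab in range(1, truth.counts[-1] + 1):
            area = (truth.label_masks[-1] == lab).sum() * stack.pixel_size**2
            assert area == pytest.approx(truth.areas_um2[-1][lab - 1])

    def test_seed_determinism_bit_identical(self):
        s1, _ = synth_cluster_timelapse(n_pre=2, n_post=2, shape=(128, 128), seed=6)
        s2, _ = synth_cluster_timelapse(n_pre=2, n_post=2, shape=(128, 128), seed=6)
        assert np.array_equal(s1.data, s2.data)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_cluster_timelapse(n_pre=1, n_post=5)


class TestNMJImage:
    def test_full_retention_single_fragment_gives_unit_ratio(self):
        stack, truth = synth_nmj_image(1, 1.0, 50.0, optics=NOISE_FREE,
                                       apply_noise=False, seed=0)
        btx = stack.channel("BTX")[0].astype(float) - NOISE_FREE.background_level
        sv2a = stack.channel("SV2A")[0].astype(float) - NOISE_FREE.background_level
        ratio = btx[truth.mask].mean() / sv2a[truth.mask].mean()
        assert ratio == pytest.approx(1.0, abs=1e-6)
        assert truth.retention == pytest.approx(1.0)

    @pytest.mark.parametrize("nfrag", [0, 1, 2, 4, 8])
    def test_fragment_labels_match_requested_count(self, nfrag):
        _, truth = synth_nmj_image(nfrag, 0.7, 80.0, apply_noise=False, seed=nfrag)
        assert truth.n_fragments == nfrag
        labels = set(np.unique(truth.fragment_labels)) - {0}
        assert len(labels) == nfrag

    def test_planted_retention_exact_in_clean_render(self):
        stack, truth = synth_nmj_image(4, 0.5, 60.0, optics=NOISE_FREE,
                                       apply_noise=False, seed=3)
        btx = stack.channel("BTX")[0].astype(float) - NOISE_FREE.background_level
        sv2a = stack.channel("SV2A")[0].astype(float) - NOISE_FREE.background_level
        assert btx[truth.mask].mean() / sv2a[truth.mask].mean() == \
            pytest.approx(0.5, abs=1e-6)
        assert truth.retention == pytest.approx(0.5, abs=1e-6)

    def test_c3_channel_carries_planted_level(self):
        stack, truth = synth_nmj_image(2, 0.8, 123.0, optics=NOISE_FREE,
                                       apply_noise=False, seed=4)
        c3 = stack.channel("C3")[0].astype(float) - NOISE_FREE.background_level
        assert c3[truth.mask].mean() == pytest.approx(123.0, abs=1e-6)

    def test_invalid_retention_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_nmj_image(1, 1.5, 50.0)
        with pytest.raises(InvalidArgumentError):
            synth_nmj_image(-1, 0.5, 50.0)


class TestFlowEvents:
    def test_population_split_within_binomial_bound(self):
        df = synth_flow_events(n_events=1000, frac_transfected=0.5, seed=1)
        n_pos = (df["population"] == "transfected").sum()
        assert abs(n_pos - 500) < 3 * np.sqrt(250)

    def test_unit_ratio_means_equal_geometric_means(self):
        df = synth_flow_events(n_events=20000, binding_ratio=1.0, seed=2)
        pos = df[df.population == "transfected"]["igg"]
        neg = df[df.population == "untransfected"]["igg"]
        ratio = np.exp(np.log(pos).mean() - np.log(neg).mean())
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_flow_events(frac_transfected=1.0)


class TestCalciumTraces:
    def test_noise_free_peak_is_exactly_amplitude(self):
        ts = synth_calcium_traces(n_wells=3, peak_amplitude=4.2, noise_sd=0.0, seed=0)
        from clusterlab.metrics import trace_peak

        for trace in ts.traces:
            assert trace_peak(trace, ts.stim_index) == pytest.approx(4.2, abs=1e-12)

    def test_zero_amplitude_peak_within_noise(self):
        ts = synth_calcium_traces(n_wells=5, peak_amplitude=0.0, noise_sd=0.1, seed=1)
        from clusterlab.metrics import trace_peak

        for trace in ts.traces:
            assert abs(trace_peak(trace, ts.stim_index)) < 0.5

    def test_stim_index_validated(self):
        with pytest.raises(InvalidArgumentError):
            synth_calcium_traces(stim_index=0)


class TestRenderSimulatedField:
    def _graph(self, seed=0):
        pool = place_receptors(make_receptor_pool(50), density_per_um2=500.0, seed=seed)
        specs = [AntibodySpecies(id="a", target_subunit="alpha", molecule_count=50),
                 AntibodySpecies(id="d", target_subunit="delta", molecule_count=50)]
        return simulate_binding(pool, specs,
                                BindingParams(mode="geometric", capture_radius=60.0),
                                seed=seed)

    def test_integrated_intensity_matches_emitter_count(self):
        optics = OpticsParams(background_level=0.0, read_noise_sd=0.0)
        stack, truth = render_simulated_field(self._graph(), optics=optics,
                                              apply_noise=False, seed=1)
        total = stack.data.astype(float).sum()
        assert total == pytest.approx(truth["n_emitters"] * optics.photon_scale, rel=0.02)

    def test_requires_positions(self):
        graph = simulate_binding(make_receptor_pool(5), [], seed=0)
        with pytest.raises(InvalidArgumentError):
            render_simulated_field(graph)


class TestImageIO:
    def test_ome_tiff_round_trip(self, tmp_path):
        stack, _ = synth_nmj_image(2, 0.6, 90.0, seed=7)
        path = clio.save_image_stack(stack, tmp_path / "nmj.ome.tif")
        loaded = clio.load_image_stack(path)
        assert np.array_equal(loaded.data, stack.data)
        assert loaded.pixel_size == pytest.approx(stack.pixel_size)
        assert loaded.channel_names == stack.channel_names
        assert np.allclose(loaded.frame_times, stack.frame_times)

    def test_ome_metadata_alone_suffices(self, tmp_path):
        stack, _ = synth_nmj_image(1, 0.6, 90.0, seed=8)
        path = clio.save_image_stack(stack, tmp_path / "x.ome.tif")
        (tmp_path / "x.ome.tif.json").unlink()
        loaded = clio.load_image_stack(path)
        assert np.array_equal(loaded.data, stack.data)
        assert loaded.pixel_size == pytest.approx(stack.pixel_size)
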