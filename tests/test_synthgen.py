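"""Synthetic generators and on-disk formats."""

import numpy as np
import pytest

from ctmonitor import synthgen as sg


class TestMovingGlyphs:
    def test_shapes_and_range(self):
        seqs = sg.generate_moving_glyphs(5, n_frames=20, size=64, seed=1)
        assert len(seqs) == 5
        for s in seqs:
            assert s.frames.shape == (20, 64, 64, 1)
            assert s.frames.min() >= 0.0 and s.frames.max() <= 1.0

    def test_seed_determinism(self):
        a = sg.generate_moving_glyphs(3, size=32, seed=9)
        b = sg.generate_moving_glyphs(3, size=32, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.frames, sb.frames)
        c = sg.generate_moving_glyphs(3, size=32, seed=10)
        assert not np.array_equal(a[0].frames, c[0].frames)

    def test_reflection_rule(self):
        # at column size-1 moving +2: reflect to size-3, velocity flips
        size = 64
        p, v = sg.reflect_position(size - 1, 2.0, 0.0, size - 1)
        assert p == size - 3 and v == -2.0

    def test_reflection_lower_bound(self):
        p, v = sg.reflect_position(1.0, -3.0, 0.0, 63.0)
        assert p == 2.0 and v == 3.0

    def test_zero_velocity_static_frames(self):
        seqs = sg.generate_moving_glyphs(2, size=32, seed=4, glyphs_per_seq=1,
                                         speed_range=(0.0, 1e-9))
        for s in seqs:
            for t in range(1, s.n_frames):
                np.testing.assert_array_equal(s.frames[t], s.frames[0])

    def test_single_glyph_mass_conserved(self):
        seqs = sg.generate_moving_glyphs(4, size=32, seed=2, glyphs_per_seq=1)
        for s in seqs:
            masses = s.frames.sum(axis=(1, 2, 3))
            np.testing.assert_allclose(masses, masses[0])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sg.generate_moving_glyphs(0)
        with pytest.raises(ValueError):
            sg.generate_moving_glyphs(1, n_frames=1)
        with pytest.raises(ValueError):
            sg.generate_moving_glyphs(1, size=8)

    def test_external_sprites(self, rng):
        sprites = [rng.random((28, 28))]
        seqs = sg.generate_moving_glyphs(1, size=64, seed=0, sprites=sprites,
                                         glyphs_per_seq=1)
        assert seqs[0].frames.max() <= 1.0 and seqs[0].frames.sum() > 0


class TestSequenceAnomalies:
    def test_frames_before_onset_unchanged(self, glyph_sequences):
        seq = glyph_sequences[0]
        out = sg.inject_sequence_anomaly(seq, onset=10, mode="appear-blob")
        np.testing.assert_array_equal(out.frames[:10], seq.frames[:10])
        assert not np.array_equal(out.frames[10:], seq.frames[10:])

    def test_last_frame_only(self, glyph_sequences):
        seq = glyph_sequences[1]
        out = sg.inject_sequence_anomaly(seq, onset=seq.n_frames - 1)
        np.testing.assert_array_equal(out.frames[:-1], seq.frames[:-1])

    def test_blob_is_pixelwise_max_and_bounded(self, glyph_sequences):
        seq = glyph_sequences[2]
        out = sg.inject_sequence_anomaly(seq, onset=5, mode="appear-blob")
        assert out.frames.max() <= 1.0
        assert np.all(out.frames[5:] >= seq.frames[5:])

    def test_sudden_growth_bounded(self, glyph_sequences):
        out = sg.inject_sequence_anomaly(glyph_sequences[3], onset=8,
                                         mode="sudden-growth")
        assert out.frames.max() <= 1.0
        assert out.frames[8:].sum() >= glyph_sequences[3].frames[8:].sum()

    def test_onset_out_of_range(self, glyph_sequences):
        with pytest.raises(ValueError, match="onset"):
            sg.inject_sequence_anomaly(glyph_sequences[0], onset=20)
        with pytest.raises(ValueError, match="onset"):
            sg.inject_sequence_anomaly(glyph_sequences[0], onset=-1)


class TestPhantoms:
    def test_corner_is_air(self, small_phantom):
        assert small_phantom.voxels[0, 0, 0] == sg.AIR_HU

    def test_shape_contract(self):
        vol = sg.generate_ct_phantom((32, 32, 32), seed=0)
        assert vol.shape == (32, 32, 32)

    def test_nodule_difference_is_exactly_the_sphere(self, small_phantom,
                                                     nodule_phantom):
        diff = small_phantom.voxels != nodule_phantom.voxels
        spec = nodule_phantom.meta["nodule"]
        zz, yy, xx = np.ogrid[0:32, 0:32, 0:32]
        sphere = ((zz - spec["center"][0]) ** 2 + (yy - spec["center"][1]) ** 2
                  + (xx - spec["center"][2]) ** 2) <= spec["radius"] ** 2
        np.testing.assert_array_equal(diff, sphere)

    def test_hu_histogram_modes(self, nodule_phantom):
        modes = np.array([sg.AIR_HU, sg.LUNG_HU, sg.BODY_HU, sg.NODULE_HU])
        nearest = np.abs(nodule_phantom.voxels[..., None] - modes).argmin(axis=-1)
        counts = np.bincount(nearest.ravel(), minlength=4)
        assert np.all(counts > 0)
        # without a nodule the +50 mode is empty
        clean = sg.generate_ct_phantom((32, 32, 32), seed=7)
        nearest = np.abs(clean.voxels[..., None] - modes).argmin(axis=-1)
        assert np.bincount(nearest.ravel(), minlength=4)[3] == 0

    def test_nodule_outside_lung_rejected(self):
        bad = sg.NoduleSpec(center=(2, 2, 2), radius=3.0)
        with pytest.raises(ValueError, match="lung"):
            sg.generate_ct_phantom((32, 32, 32), with_nodule=True, nodule_spec=bad)

    def test_size_too_small_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            sg.generate_ct_phantom((4, 32, 32))


class TestLabeledVolumes:
    def test_half_rate_counts(self):
        ds = sg.generate_labeled_volumes(10, 0.5, size=(16, 16, 16), seed=3)
        assert ds.labels.sum() == 5 and len(ds) == 10

    def test_zero_rate(self):
        ds = sg.generate_labeled_volumes(6, 0.0, size=(16, 16, 16), seed=3)
        assert ds.labels.sum() == 0

    def test_round_half_even(self):
        # 7 * 0.5 = 3.5 rounds to the even neighbour 4
        ds = sg.generate_labeled_volumes(7, 0.5, size=(16, 16, 16), seed=0)
        assert ds.labels.sum() == 4
        # 5 * 0.5 = 2.5 rounds to 2
        ds = sg.generate_labeled_volumes(5, 0.5, size=(16, 16, 16), seed=0)
        assert ds.labels.sum() == 2

    def test_deterministic(self):
        a = sg.generate_labeled_volumes(4, 0.5, size=(16, 16, 16), seed=8)
        b = sg.generate_labeled_volumes(4, 0.5, size=(16, 16, 16), seed=8)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.volumes[0].voxels, b.volumes[0].voxels)

    def test_positive_volumes_have_nodules(self):
        ds = sg.generate_labeled_volumes(8, 0.5, size=(32, 32, 32), seed=5)
        for vol, label in zip(ds.volumes, ds.labels):
            assert vol.meta["with_nodule"] == bool(label)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_labeled_volumes(0)


class TestIO:
    def test_nifti_round_trip(self, tmp_path, nodule_phantom):
        path = tmp_path / "vol.nii.gz"
        sg.write_nifti(nodule_phantom, path)
        back = sg.read_nifti(path)
        np.testing.assert_allclose(back.voxels, nodule_phantom.voxels, rtol=1e-6)
        assert back.spacing == nodule_phantom.spacing
        assert back.meta["source_axes"] == "xyz"

    def test_nifti_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sg.read_nifti(tmp_path / "missing.nii")

    def test_nifti_malformed(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti header at all")
        with pytest.raises(sg.FormatError):
            sg.read_nifti(bad)

    def test_png_round_trip_quantization(self, tmp_path, glyph_sequences):
        seq = glyph_sequences[0]
        sg.write_png_frames(seq, tmp_path / "seq")
        back = sg.read_png_frames(tmp_path / "seq")
        assert back.frames.shape == seq.frames.shape
        assert np.abs(back.frames - seq.frames).max() <= 1.0 / 255.0 + 1e-12

    def test_png_missing_dir(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sg.read_png_frames(tmp_path / "nowhere")

    def test_labels_json_round_trip(self, tmp_path):
        ds = sg.generate_labeled_volumes(4, 0.5, size=(16, 16, 16), seed=1)
        path = tmp_path / "labels.json"
        sg.write_labels_json(ds, path)
        labels = sg.read_labels_json(path)
        assert labels == {v.id: int(l) for v, l in zip(ds.volumes, ds.labels)}

    def test_labels_json_bad_value(self, tmp_path):
        path = tmp_path / "labels.json"
        path.write_text('{"vol-000": 2}')
        with pytest.raises(sg.FormatError, match="vol-000"):
            sg.read_labels_json(path)
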