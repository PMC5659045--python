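import numpy as np
import pytest

from retinascreen.core_io import BinaryMask, ChannelImage, PipelineConfig
from retinascreen.red_lesions import (CascadeModel, classify_hemorrhages,
                                      cross_section_profiles, detect_mas,
                                      extract_features, kmeans_segment,
                                      LesionCandidate, ma_accept, ma_score,
                                      region_grow, remove_vessels,
                                      train_cascade)


def _dot_image(shape=(64, 64), center=(32, 32), amp=0.3, sigma=1.6, base=0.3):
    """Inverted-green-style image: an MA is a bright bump."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return base + amp * np.exp(-d2 / (2 * sigma ** 2))


class TestProfiles:
    def test_radially_symmetric_peak_gives_identical_profiles(self):
        img = _dot_image(amp=0.5, sigma=3.0, base=0.2)
        ps = cross_section_profiles(img, (32, 32), 15)
        peak = ps.profiles.max()
        # identical up to nearest-neighbor sampling error along oblique rays
        spread = np.abs(ps.profiles[:, None, :] - ps.profiles[None, :, :]).max()
        assert spread < 0.08 * peak

    def test_vertical_ridge_peaks_only_across(self):
        img = np.full((64, 64), 0.3)
        img[:, 31:34] = 0.6
        ps = cross_section_profiles(img, (32, 32), 15)
        horiz = ps.profiles[0]          # 0 deg: scans along the row, across the ridge
        vert = ps.profiles[4]           # 90 deg: scans along the ridge
        assert np.ptp(vert) < 0.05
        assert np.ptp(horiz) > 0.2

    def test_border_center_rejected(self):
        img = _dot_image()
        with pytest.raises(ValueError, match="border"):
            cross_section_profiles(img, (3, 32), 15)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            cross_section_profiles(_dot_image(), (32, 32), 14)


class TestMAScore:
    def test_flat_window_scores_zero(self):
        img = np.full((64, 64), 0.4)
        ps = cross_section_profiles(img, (32, 32), 15)
        assert ma_score(ps) == 0

    def test_ideal_dot_scores_maximum(self):
        ps = cross_section_profiles(_dot_image(amp=0.4, sigma=1.5), (32, 32), 15)
        assert ma_score(ps) == 56

    def test_ridge_fails_along_directions(self):
        img = np.full((64, 64), 0.3)
        img[30:35, :] = 0.6             # horizontal ridge through the center
        ps = cross_section_profiles(img, (32, 32), 15)
        score = ma_score(ps)
        assert ps.hits[0] == 0          # the along-ridge profile has no peak
        assert score < 56               # strictly below an ideal dot
        assert score <= 48

    def test_score_invariant_to_intensity_gain(self):
        img = _dot_image(amp=0.3, sigma=1.5)
        s1 = ma_score(cross_section_profiles(img, (32, 32), 15))
        img2 = img * 1.4                # gain without clipping
        s2 = ma_score(cross_section_profiles(img2, (32, 32), 15))
        assert s1 == s2

    def test_accept_modes(self):
        cfg = PipelineConfig()
        assert cfg.ma_accept_mode == "threshold"
        assert ma_accept(56, cfg)
        assert not ma_accept(12, cfg)
        cfg.ma_accept_mode = "range"
        assert ma_accept(25, cfg)
        assert not ma_accept(56, cfg)   # the closed published window


class TestKMeans:
    def test_two_cluster_exact(self):
        D = ChannelImage(data=np.array([[0.0, 0.0], [10 / 255, 10 / 255]]),
                         domain="difference")
        model, labels = kmeans_segment(D, K=2)
        assert sorted(model.centers) == pytest.approx([0.0, 10 / 255], abs=1e-5)
        assert model.objective == pytest.approx(0.0, abs=1e-12)

    def test_objective_non_increasing_everywhere(self, rng):
        for _ in range(10):
            D = ChannelImage(data=rng.uniform(-0.5, 0.5, (40, 40)),
                             domain="difference")
            model, _ = kmeans_segment(D, K=5)
            h = model.objective_history
            assert all(b <= a + 1e-8 for a, b in zip(h, h[1:]))

    def test_fewer_distinct_values_reduces_k(self):
        D = ChannelImage(data=np.tile(np.array([0.0, 0.1, 0.2]), (3, 1)),
                         domain="difference")
        with pytest.warns(UserWarning, match="reducing K"):
            model, _ = kmeans_segment(D, K=5)
        assert model.K == 3

    def test_agrees_with_sklearn_on_1d(self, rng):
        from sklearn.cluster import KMeans
        x = np.concatenate([rng.normal(-0.2, 0.02, 500),
                            rng.normal(0.0, 0.02, 500),
                            rng.normal(0.25, 0.02, 500)])
        D = ChannelImage(data=x.reshape(50, 30), domain="difference")
        model, _ = kmeans_segment(D, K=3)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(x[:, None])
        assert sorted(model.centers) == pytest.approx(
            sorted(ref.cluster_centers_.ravel()), abs=0.01)


class TestRegionGrow:
    def test_printed_toy_blob_exactly_recovered(self):
        """5x5 field, background 200/255, a 4-px dark blob at 50/255: the
        grown region is exactly the blob (checked against exhaustive
        enumeration of the growth criterion)."""
        f = np.full((5, 5), 200 / 255)
        blob = [(2, 2), (2, 3), (3, 2), (3, 3)]
        for (r, c) in blob:
            f[r, c] = 50 / 255
        green = ChannelImage(data=f)
        region = region_grow(green, (2, 2), t0=100 / 255)
        got = {tuple(p) for p in region}
        assert got == set(blob)
        # enumeration oracle: every blob pixel satisfies the criterion
        # against the final mean, every non-blob pixel fails it
        m = np.mean([f[p] for p in blob])
        from skimage.filters import threshold_otsu
        T = threshold_otsu(f)
        for r in range(5):
            for c in range(5):
                ok = abs(f[r, c] - m) < 100 / 255 and f[r, c] < T
                assert ok == ((r, c) in got)

    def test_uniform_image_returns_seed_or_cap(self):
        green = ChannelImage(data=np.full((20, 20), 0.5))
        region = region_grow(green, (10, 10), area_cap=50)
        assert 1 <= len(region) <= 50

    def test_growth_stops_at_darker_vessel(self):
        f = np.full((30, 30), 0.9)
        f[10:20, 10:20] = 0.42          # blob (below the local Otsu split)
        f[:, 20:23] = 0.02              # vessel differing from the blob mean
        green = ChannelImage(data=f)    # by more than T0 = 100/255
        region = region_grow(green, (15, 15), t0=100 / 255,
                             bbox=(10, 10, 20, 20))
        cols = {c for (_r, c) in map(tuple, region)}
        assert cols.isdisjoint({20, 21, 22})
        assert len(region) >= 50        # the blob itself was grown

    def test_final_region_satisfies_criterion(self, phantom_green):
        """Re-check the growth criterion against the final region mean."""
        region = region_grow(phantom_green, (300, 300), t0=100 / 255,
                             bbox=(290, 290, 310, 310))
        vals = phantom_green.data[region[:, 0], region[:, 1]]
        m = vals.mean()
        violations = (np.abs(vals - m) >= 100 / 255).mean()
        assert violations < 0.05


class TestRemoveVessels:
    def test_candidate_on_vessel_removed_entirely(self):
        v = np.zeros((50, 50), bool)
        v[20:25, :] = True
        c = np.zeros((50, 50), bool)
        c[21:24, 10:14] = True
        out = remove_vessels(BinaryMask(data=c, label="candidate"),
                             BinaryMask(data=v, label="vessels"))
        assert not out.data.any()

    def test_disjoint_candidate_untouched(self):
        v = np.zeros((50, 50), bool)
        v[40:45, :] = True
        c = np.zeros((50, 50), bool)
        c[5:10, 5:10] = True
        out = remove_vessels(BinaryMask(data=c, label="candidate"),
                             BinaryMask(data=v, label="vessels"))
        assert np.array_equal(out.data, c)

    def test_straddling_candidate_keeps_off_vessel_part(self):
        v = np.zeros((50, 50), bool)
        v[24:26, :] = True
        c = np.zeros((50, 50), bool)
        c[14:30, 10:20] = True          # half on the dilated vessel band
        out = remove_vessels(BinaryMask(data=c, label="candidate"),
                             BinaryMask(data=v, label="vessels"))
        assert out.data.any()
        assert not (out.data & v).any()


class TestFeatures:
    def test_disc_circularity_near_one(self):
        rr, cc = np.mgrid[0:60, 0:60]
        disc = np.column_stack(np.nonzero(np.hypot(rr - 30, cc - 30) <= 12))
        green = ChannelImage(data=np.full((60, 60), 0.5))
        f = extract_features(disc, green)
        assert f["circularity"] == pytest.approx(1.0, abs=0.25)
        assert f["axis_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_strip_circularity_grows_with_length(self):
        green = ChannelImage(data=np.full((40, 120), 0.5))
        short = np.array([(r, c) for r in (20, 21) for c in range(20, 40)])
        long = np.array([(r, c) for r in (20, 21) for c in range(20, 100)])
        f_short = extract_features(short, green)
        f_long = extract_features(long, green)
        assert f_long["circularity"] > f_short["circularity"] > 1.5

    def test_contrast_feature(self):
        data = np.full((40, 40), 200 / 255)
        rr, cc = np.mgrid[0:40, 0:40]
        blob = np.hypot(rr - 20, cc - 20) <= 6
        data[blob] = 50 / 255
        region = np.column_stack(np.nonzero(blob))
        f = extract_features(region, ChannelImage(data=data))
        assert f["m_d"] == pytest.approx(150 / 255, abs=0.01)
        assert f["m_d"] == pytest.approx(f["m_out"] - f["m_in"], abs=1e-12)

    def test_tiny_region_rejected(self):
        green = ChannelImage(data=np.full((20, 20), 0.5))
        with pytest.raises(ValueError):
            extract_features(np.array([[5, 5], [5, 6]]), green)


class TestCascade:
    def _toy_table(self, sep=True, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            lab = ["hemorrhage", "vessel", "background"][i % 3]
            base = {"hemorrhage": 0.0, "vessel": 4.0, "background": -4.0}[lab]
            if not sep:
                base = 0.0
            rows.append({
                "eccentricity": base + rng.normal(), "circularity": base + rng.normal(),
                "axis_ratio": base + rng.normal(), "m_in": base + rng.normal(),
                "m_out": base + rng.normal(), "m_d": base + rng.normal(),
                "label": lab})
        return rows

    def test_separable_table_reaches_perfect_cv(self):
        model = train_cascade(self._toy_table(sep=True, n=90), seed=0)
        assert model.cv_accuracy[0] == pytest.approx(1.0)
        assert model.cv_accuracy[1] == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        rows = self._toy_table(sep=True, n=120)
        labels = [r["label"] for r in rows]
        rng.shuffle(labels)
        for r, lab in zip(rows, labels):
            r["label"] = lab
        model = train_cascade(rows, seed=0)
        assert 0.3 <= model.cv_accuracy[0] <= 0.75

    def test_untrained_model_rejected(self):
        cand = LesionCandidate(mask=np.zeros((4, 2), int), centroid=(0, 0),
                               features={k: 0.0 for k in
                                         ("eccentricity", "circularity",
                                          "axis_ratio", "m_in", "m_out", "m_d")})
        with pytest.raises(ValueError, match="not trained"):
            classify_hemorrhages([cand], CascadeModel())

    def test_empty_candidate_list(self, models):
        assert classify_hemorrhages([], models.cascade) == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 5 samples"):
            train_cascade(self._toy_table(n=6), seed=0)


def test_phantom_ma_detection_bounds(phantom1, phantom_green, vessels1, cfg):
    """Most planted microaneurysms are found, with few spurious dots."""
    img, gt = phantom1
    mas = detect_mas(phantom_green, vessels1.mask, None,
                     img.field_of_view_mask, cfg)
    hits = sum(1 for (r, c) in gt.ma_centroids
               if any(np.hypot(r - m.centroid[0], c - m.centroid[1]) <= 3
                      for m in mas))
    assert hits >= 0.8 * len(gt.ma_centroids)
    fp = len(mas) - hits
    assert fp <= 10
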