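"""Structural invariants of the phantom, bundle and DWI generators, and the
statistical structure of the synthetic cohorts."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import erfi

from slf_maturation import synthetic_data as sd
from slf_maturation import watson
from slf_maturation.errors import LayoutError, SelectionError


class TestPhantom:
    def test_all_rois_present_and_disjoint(self, phantom):
        layout, labels = phantom
        counts = {
            name: int(np.sum(labels.data == lid))
            for name, lid in layout.label_ids.items()
        }
        assert set(counts) == set(sd.ROI_NAMES)
        assert all(c > 0 for c in counts.values())
        # single-valued label map means boxes cannot overlap except by
        # overwriting; verify totals match the box volumes
        for name, ((x0, x1), (y0, y1), (z0, z1)) in layout.boxes.items():
            assert counts[name] == (x1 - x0 + 1) * (y1 - y0 + 1) * (z1 - z0 + 1)

    def test_left_right_mirror_symmetry(self, phantom):
        layout, labels = phantom
        mx = layout.shape[0] // 2
        flipped = np.zeros_like(labels.data)
        # mirror across the mid-sagittal voxel column
        for x in range(layout.shape[0]):
            xm = 2 * mx - x
            if 0 <= xm < layout.shape[0]:
                flipped[xm] = labels.data[x]
        swap = {}
        for left, right in (
            ("SFgL", "SFgR"), ("MFgL", "MFgR"), ("PrgL", "PrgR"),
            ("PaL", "PaR"), ("TeL", "TeR"), ("MFgL-P", "MFgR-P"),
        ):
            swap[layout.label_ids[left]] = layout.label_ids[right]
            swap[layout.label_ids[right]] = layout.label_ids[left]
        for a, b in swap.items():
            assert np.array_equal(flipped == b, labels.data == a)

    def test_coronal_plane_ordering(self, phantom):
        layout, _ = phantom
        ac, pc = layout.ac_index, layout.pc_index
        assert ac > pc
        for name in ("SFgL", "MFgL", "PrgL"):
            assert layout.boxes[name][1][0] > ac  # frontal: anterior to AC
        assert layout.boxes["PaL"][1][1] < pc  # parietal: posterior to PC
        y0, y1 = layout.boxes["MFgL-P"][1]
        assert pc < y0 <= y1 < ac  # strictly between the commissures

    def test_midsag_is_one_voxel_slab(self, phantom):
        layout, _ = phantom
        (x0, x1), (y0, y1), (z0, z1) = layout.boxes["Midsag"]
        assert x0 == x1
        assert (y0, y1) == (0, layout.shape[1] - 1)
        assert (z0, z1) == (0, layout.shape[2] - 1)

    def test_determinism(self):
        _, a = sd.make_phantom(seed=3)
        _, b = sd.make_phantom(seed=3)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("shape", [(30, 48, 48), (48, 20, 48), (47, 48, 48)])
    def test_bad_shapes_rejected(self, shape):
        with pytest.raises(LayoutError):
            sd.make_phantom(shape=shape)


def vertices_hit_roi(streamline, layout, labels, name):
    """Brute-force vertex membership: nearest-voxel map of every vertex."""
    inv = np.linalg.inv(layout.affine)
    idx = np.floor(streamline @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(layout.shape)), axis=1)
    hits = labels.data[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return np.any(hits == layout.label_ids[name])


class TestBundles:
    def test_every_streamline_visits_waypoints(self, phantom):
        layout, labels = phantom
        t = sd.simulate_bundle(layout, ("PaL", "SFgL"), n=100, seed=1)
        assert len(t) == 100
        for s in t.streamlines:
            assert vertices_hit_roi(s, layout, labels, "PaL")
            assert vertices_hit_roi(s, layout, labels, "SFgL")

    def test_zero_jitter_is_deterministic_geometry(self, phantom):
        layout, _ = phantom
        t = sd.simulate_bundle(layout, ("PaL", "MFgL"), n=5, jitter=0.0, seed=2)
        for s in t.streamlines[1:]:
            np.testing.assert_array_equal(s, t.streamlines[0])

    def test_temporal_route_always_touches_te(self, phantom):
        """A parietal-temporal bundle leaves a vertex in TeL on every
        streamline, so an exclude-TeL rule removes all of it."""
        layout, labels = phantom
        t = sd.simulate_bundle(layout, ("PaL", "TeL"), n=50, seed=3)
        assert all(
            vertices_hit_roi(s, layout, labels, "TeL") for s in t.streamlines
        )

    def test_unknown_roi_rejected(self, phantom):
        layout, _ = phantom
        with pytest.raises(SelectionError):
            sd.simulate_bundle(layout, ("PaL", "Nope"), n=1)

    def test_mix_counts_and_provenance_partition(self, adult_mix):
        tractogram, provenance = adult_mix
        mix = sd.default_bundle_mix("adult")
        assert len(tractogram) == sum(c.n for c in mix)
        assert len(provenance) == len(tractogram)
        from collections import Counter

        counts = Counter(provenance)
        for comp in mix:
            assert counts[comp.name] == comp.n

    def test_empty_mix_rejected(self, phantom):
        layout, _ = phantom
        with pytest.raises(ValueError):
            sd.simulate_tractogram(
                layout, [sd.BundleComponent("x", ("PaL", "SFgL"), 0)]
            )


class TestWatson:
    @pytest.mark.parametrize("kappa", [0.25, 1.0, 4.0, 16.0, 64.0, 128.0])
    def test_normalization_matches_closed_form(self, kappa):
        """The quadrature Z(kappa) equals the erfi closed form to 1e-6,
        i.e. the dispersed-stick kernel integrates to 1 over the sphere."""
        closed = 2 * np.pi * np.sqrt(np.pi / kappa) * erfi(np.sqrt(kappa))
        assert watson.watson_normalization(kappa) == pytest.approx(
            closed, rel=1e-6
        )

    def test_odi_kappa_mapping(self):
        assert watson.odi_from_kappa(1.0) == pytest.approx(0.5)
        assert watson.kappa_from_odi(0.5) == pytest.approx(1.0)
        odi = np.array([0.05, 0.3, 0.9])
        np.testing.assert_allclose(
            watson.odi_from_kappa(watson.kappa_from_odi(odi)), odi, rtol=1e-12
        )

    def test_tau1_limits(self):
        assert watson.watson_tau1(1e-9) == pytest.approx(1 / 3, abs=1e-6)
        assert watson.watson_tau1(300.0) > 0.99


class TestDwi:
    def test_b0_signal_is_exactly_one(self, dhcp):
        params = sd.NoddiParams(
            ndi=np.array(0.4), odi=np.array(0.3), f_iso=np.array(0.2),
            mu=np.array([0.0, 0.0, 1.0]),
        )
        sig = sd.simulate_dwi(params, dhcp)
        np.testing.assert_array_equal(sig[dhcp.b0_indices], 1.0)
        assert np.all(sig > 0) and np.all(sig <= 1)

    def test_free_water_collapse(self, dhcp):
        """f_iso = 1 leaves a mono-exponential isotropic decay regardless of
        the tissue parameters."""
        expected = np.exp(-dhcp.bvals * 3.0e-3)
        for ndi, odi in ((0.1, 0.9), (0.9, 0.1)):
            params = sd.NoddiParams(
                ndi=np.array(ndi), odi=np.array(odi), f_iso=np.array(1.0),
                mu=np.array([0.0, 0.0, 1.0]),
            )
            np.testing.assert_allclose(
                sd.simulate_dwi(params, dhcp), expected, rtol=1e-12
            )

    def test_coherent_stick_has_no_perpendicular_attenuation(self):
        """As dispersion vanishes, a pure stick measured perpendicular to its
        axis approaches unit signal."""
        bd = np.array([2600 * 1.7e-3])
        perp = np.array([0.0])
        values = [
            watson.dispersed_stick_attenuation(
                bd, perp, float(watson.kappa_from_odi(o))
            ).item()
            for o in (0.2, 0.05, 0.01)
        ]
        assert values[0] < values[1] < values[2]
        assert values[2] > 0.96

    def test_deterministic_given_seed(self, dhcp):
        params = sd.NoddiParams(
            ndi=np.array(0.5), odi=np.array(0.2), f_iso=np.array(0.1),
            mu=np.array([1.0, 0.0, 0.0]),
        )
        a = sd.simulate_dwi(params, dhcp, snr=25, seed=11)
        b = sd.simulate_dwi(params, dhcp, snr=25, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sd.NoddiParams(
                ndi=np.zeros((2, 2)) + 0.5, odi=np.zeros((2, 2)) + 0.2,
                f_iso=np.zeros((2, 2)), mu=np.zeros((3, 3)),
            )


class TestCohorts:
    def test_group_mean_matches_intercept(self):
        """With zero age slope, the generated tract-mean NDI averages to the
        specified intercept within 3 standard errors (n = 200)."""
        spec = sd.default_cohort_spec(n_neonates=200, n_adults=0)
        spec.slope = {m: 0.0 for m in sd.METRICS}
        neo, _ = sd.simulate_cohort_tables(spec, seed=9)
        values = neo["SLF_I_NDI_LR"].to_numpy()
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - spec.neonate_intercept["SLF_I"]["NDI"]) < 3 * se

    def test_between_subject_sd_within_20_percent(self):
        spec = sd.default_cohort_spec(n_neonates=200, n_adults=0)
        neo, _ = sd.simulate_cohort_tables(spec, seed=5)
        expected = np.sqrt(
            spec.factor_loading["ODI"] ** 2
            + spec.subject_sd["ODI"] ** 2
            + spec.hemi_sd["ODI"] ** 2 / 2
        )
        observed = neo["SLF_I_ODI_LR"].std(ddof=1)
        assert abs(observed - expected) / expected < 0.20

    def test_positive_ndi_trend_recovered_reliably(self):
        """Across 200 replicates at n = 40, the sample Pearson r between NDI
        and PMA is positive in at least 99% of draws."""
        spec = sd.default_cohort_spec(n_adults=0)
        positive = 0
        for k in range(200):
            neo, _ = sd.simulate_cohort_tables(spec, seed=1000 + k)
            r = np.corrcoef(neo["SLF_I_NDI_LR"], neo["age"])[0, 1]
            positive += r > 0
        assert positive >= 198

    def test_zero_variability_gives_identical_maps(self, phantom):
        layout, _ = phantom
        spec = sd.default_cohort_spec(n_neonates=2, n_adults=0)
        spec.slope = {m: 0.0 for m in sd.METRICS}
        spec.subject_sd = {m: 0.0 for m in sd.METRICS}
        spec.factor_loading = {m: 0.0 for m in sd.METRICS}
        spec.hemi_sd = {m: 0.0 for m in sd.METRICS}
        spec.voxel_sd = {m: 0.0 for m in sd.METRICS}
        subjects = list(sd.simulate_cohorts(spec, layout, seed=2))
        assert len(subjects) == 2
        for metric in sd.METRICS:
            np.testing.assert_array_equal(
                subjects[0][1][metric].data, subjects[1][1][metric].data
            )

    def test_age_ranges_validated(self):
        with pytest.raises(ValueError):
            sd.default_cohort_spec(neonate_age_range=(30.0, 44.0))
        with pytest.raises(ValueError):
            sd.default_cohort_spec(adult_age_range=(22.0, 60.0))
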