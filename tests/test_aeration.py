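"""Aeration classification, masks, dorsoventral split, global metrics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from lungstrain import (
    AerationThresholds,
    BinaryMask,
    CTImage,
    aerated_mask,
    classify_aeration,
    compartment_fractions,
    dorsoventral_split,
    global_metrics,
)
from lungstrain.core import Compartment
from lungstrain.phantom import make_compartment_layout, make_ct_from_labels, make_lung_mask


def _uniform_ct(shape, hu, spacing=0.1):
    return CTImage(np.full(shape, hu, np.float32), spacing)


def _full_mask(shape, spacing=0.1):
    return BinaryMask(np.ones(shape, bool), spacing)


class TestClassification:
    @pytest.mark.parametrize(
        "hu,expected",
        [
            (-950.0, Compartment.HYPER_AERATED),
            (-700.0, Compartment.NORMALLY_AERATED),
            (-300.0, Compartment.POORLY_AERATED),
            (-100.0, Compartment.NON_AERATED),  # boundary: lower-closed
            (-900.0, Compartment.NORMALLY_AERATED),
            (-500.0, Compartment.POORLY_AERATED),
            (50.0, Compartment.NON_AERATED),
        ],
    )
    def test_interval_membership(self, hu, expected):
        am = classify_aeration(_uniform_ct((4, 4, 4), hu), _full_mask((4, 4, 4)))
        assert (am.labels == expected).all()

    def test_out_of_range_clamped_and_counted(self):
        am = classify_aeration(_uniform_ct((2, 2, 2), -1500.0), _full_mask((2, 2, 2)))
        assert (am.labels == Compartment.HYPER_AERATED).all()
        assert am.n_clamped == 8

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            classify_aeration(_uniform_ct((4, 4, 4), -700), _full_mask((5, 4, 4)))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            AerationThresholds(hyper_normal=-500, normal_poor=-900, poor_non=-100)

    def test_zero_noise_phantom_label_agreement(self, small_spec):
        spec = replace(small_spec, hu_noise_sd=0.0)
        mask = make_lung_mask(spec)
        layout = make_compartment_layout(mask, (0.1, 0.2, 0.6, 0.1), np.random.default_rng(2))
        ct = make_ct_from_labels(layout, spec, rng=0)
        am = classify_aeration(ct, mask)
        assert (am.labels == layout).all()

    def test_noisy_recovery_matches_gaussian_flow_oracle(self, small_spec):
        """At HU noise sd 50 the classified fractions equal the layout
        fractions corrected by the analytic Gaussian boundary spill.

        With compartment means (-50, -300, -700, -950) and boundaries
        (-100, -500, -900) the only non-negligible spill is non -> poor:
        P(N(-50, 50) < -100) = Phi(-1).  The spilled mass must be added to
        the poor compartment and removed from non.
        """
        spec = replace(small_spec, hu_noise_sd=50.0)
        fractions = np.array([0.13, 0.17, 0.65, 0.05])
        mask = make_lung_mask(spec)
        layout = make_compartment_layout(mask, tuple(fractions), np.random.default_rng(4))
        ct = make_ct_from_labels(layout, spec, rng=8)
        measured = compartment_fractions(classify_aeration(ct, mask))
        spill = fractions[0] * norm.cdf(-1)  # non below -100 HU
        expected = {
            Compartment.NON_AERATED: fractions[0] - spill,
            Compartment.POORLY_AERATED: fractions[1] + spill,
            Compartment.NORMALLY_AERATED: fractions[2],
            Compartment.HYPER_AERATED: fractions[3],
        }
        for comp, exp in expected.items():
            assert abs(measured[comp] - exp) < 0.01, comp


class TestFractionsAndMasks:
    def test_all_normal_gives_unit_fraction(self):
        labels = np.full((4, 4, 4), int(Compartment.NORMALLY_AERATED), np.uint8)
        from lungstrain.core import AerationMap

        f = compartment_fractions(AerationMap(labels, 0.1))
        assert f[Compartment.NORMALLY_AERATED] == 1.0
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_equal_quarters(self):
        from lungstrain.core import AerationMap

        labels = np.zeros((4, 4, 4), np.uint8)
        for i, c in enumerate(
            [Compartment.NON_AERATED, Compartment.POORLY_AERATED,
             Compartment.NORMALLY_AERATED, Compartment.HYPER_AERATED]
        ):
            labels[i] = int(c)
        f = compartment_fractions(AerationMap(labels, 0.1))
        assert all(v == pytest.approx(0.25) for v in f.values())

    def test_empty_map_rejected(self):
        from lungstrain.core import AerationMap

        with pytest.raises(ValueError, match="empty"):
            compartment_fractions(AerationMap(np.zeros((3, 3, 3), np.uint8), 0.1))

    def test_aerated_mask_excludes_non_aerated(self):
        am = classify_aeration(_uniform_ct((4, 4, 4), -700), _full_mask((4, 4, 4)))
        assert aerated_mask(am).voxel_count == 64
        am_non = classify_aeration(_uniform_ct((4, 4, 4), 0.0), _full_mask((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty"):
            assert aerated_mask(am_non).voxel_count == 0

    def test_aerated_volume_complements_collapse(self, small_spec):
        spec = replace(small_spec, hu_noise_sd=0.0)
        mask = make_lung_mask(spec)
        layout = make_compartment_layout(mask, (0.3, 0.2, 0.45, 0.05), np.random.default_rng(6))
        ct = make_ct_from_labels(layout, spec, rng=0)
        am = classify_aeration(ct, mask)
        aer = aerated_mask(am)
        non = compartment_fractions(am)[Compartment.NON_AERATED]
        assert aer.volume_mm3() == pytest.approx(mask.volume_mm3() * (1 - non), rel=1e-9)


class TestDorsoventralSplit:
    def test_symmetric_sphere_splits_at_center(self):
        coords = np.indices((30, 30, 30)) - 14.5
        sphere = (coords**2).sum(axis=0) <= 10**2
        d, v, info = dorsoventral_split(BinaryMask(sphere, 0.1))
        assert abs(info["cut_index"] - 15) <= 1
        assert d.voxel_count + v.voxel_count == sphere.sum()

    def test_imbalance_bounded_by_largest_slab(self, sb_subject):
        mask = sb_subject.mask_ee
        d, v, info = dorsoventral_split(mask)
        largest_slab = int(mask.data.sum(axis=(0, 2)).max())
        assert abs(d.voxel_count - v.voxel_count) <= largest_slab

    def test_single_slab_flagged_degenerate(self):
        m = np.zeros((8, 8, 8), bool)
        m[:, 3, :] = True
        _, _, info = dorsoventral_split(BinaryMask(m, 0.1))
        assert info["degenerate"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dorsoventral_split(BinaryMask(np.zeros((4, 4, 4), bool), 0.1))


class TestGlobalMetrics:
    def _mask_with_ml(self, ml, spacing=1.0):
        # spacing 1 mm: 1 voxel = 1 mm^3 = 0.001 ml -> need 1000*ml voxels
        n = int(round(1000 * ml))
        m = np.zeros((120, 100, 100), bool)
        m.ravel()[:n] = True
        return BinaryMask(m, spacing)

    def test_vt_and_strain_arithmetic(self):
        # EELV 20 ml/kg, EILV 25 ml/kg at 1 kg -> Vt 5 ml/kg, strain 25 %
        gm = global_metrics(self._mask_with_ml(20), self._mask_with_ml(25), 1.0, rr_per_min=90)
        assert gm.vt_ml_kg == pytest.approx(5.0)
        assert gm.global_strain_pct == pytest.approx(25.0)
        assert gm.vmin_ml_min_kg == pytest.approx(450.0)

    def test_voxel_volume_conversion(self):
        m = np.zeros((20, 10, 10), bool)
        m.ravel()[:1000] = True
        gm = global_metrics(BinaryMask(m, 0.1), BinaryMask(m, 0.1), 1.0, 60)
        assert gm.eelv_ml_kg == pytest.approx(0.001)  # 1000 voxels -> 1 mm^3

    def test_zero_eelv_rejected(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool), 0.1)
        with pytest.raises(ValueError, match="EELV"):
            global_metrics(empty, self._mask_with_ml(1), 1.0, 60)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            global_metrics(self._mask_with_ml(1), self._mask_with_ml(1), 0.0, 60)
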