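"""SDC/DDVD/ADC map formulas, invalid-voxel policy, ROI aggregation."""

import math

import numpy as np
import pytest

from sdc_glioma import (
    DWISeries,
    ROIMask,
    compute_adc,
    compute_ddvd,
    compute_maps,
    compute_sdc,
    roi_aggregate,
)
from sdc_glioma.metrics import MetricTriplet, ADC_E4, ADC_MM2S
from sdc_glioma.synthetic import (
    MUTANT_LIKE,
    WILDTYPE_LIKE,
    default_phantom_spec,
    ivim_signal,
    simulate_phantom,
)

from conftest import make_tissue, mono_exp_series


def series_from_signals(signals: dict[float, float], shape=(3, 3, 2)):
    b = np.array(sorted(signals), dtype=float)
    data = np.stack(
        [np.full(shape, signals[k]) for k in sorted(signals)], axis=-1)
    return DWISeries(b_values=b, data=data)


class TestSDC:
    def test_direct_difference_quotient(self):
        s = series_from_signals({500: 250.0, 750: 200.0})
        assert np.allclose(compute_sdc(s), (250 - 200) / 250)

    def test_equal_signals_give_zero(self):
        s = series_from_signals({500: 300.0, 750: 300.0})
        assert np.all(compute_sdc(s) == 0.0)

    def test_mono_exponential_closed_form(self):
        """S0=1000, D=1e-3: SDC = (606.531-472.367)/250 = 0.53666 au/s."""
        s = mono_exp_series(s0=1000.0, d=1.0e-3)
        assert np.allclose(compute_sdc(s), 0.53666, atol=5e-6)

    def test_negative_values_preserved(self):
        s = series_from_signals({500: 200.0, 750: 260.0})
        assert np.all(compute_sdc(s) < 0)

    def test_bad_b_pair_rejected(self):
        s = mono_exp_series()
        with pytest.raises(ValueError, match="b1 must be smaller"):
            compute_sdc(s, 750, 500)
        with pytest.raises(KeyError):
            compute_sdc(s, 500, 800)


class TestADC:
    @pytest.mark.parametrize("b1,b2", [(0, 1000), (0, 500), (10, 750),
                                       (500, 1000)])
    def test_recovers_d_exactly_for_any_pair(self, b1, b2):
        s = mono_exp_series(s0=1234.5, d=1.7e-3)
        adc = compute_adc(s, b1, b2)
        assert np.allclose(adc, 1.7e-3, rtol=1e-12)

    def test_ln_e_spot_value(self):
        s = series_from_signals({0: 1000.0, 1000: 367.879441})
        assert np.allclose(compute_adc(s), 1.0e-3, rtol=1e-8)

    def test_equal_signals_zero(self):
        s = series_from_signals({0: 500.0, 1000: 500.0})
        assert np.all(compute_adc(s) == 0.0)

    def test_nonpositive_signal_flagged_invalid_locally(self):
        s = series_from_signals({0: 1000.0, 1000: 400.0}, shape=(4, 4, 2))
        s.data[1, 1, 0, -1] = 0.0
        adc = compute_adc(s)
        assert np.isnan(adc[1, 1, 0])
        rest = np.delete(adc.ravel(), np.ravel_multi_index((1, 1, 0),
                                                           (4, 4, 2)))
        assert np.all(np.isfinite(rest))


class TestDDVD:
    def test_roi_sum_example(self):
        """100-pixel ROI, mean b0 signal 100, mean b10 signal 90 -> 10."""
        s = series_from_signals({0: 100.0, 10: 90.0}, shape=(10, 10, 1))
        mask = ROIMask(mask=np.ones((10, 10, 1), dtype=bool))
        r = compute_ddvd(s, mask)
        assert r.scalar == pytest.approx(10.0)
        assert r.n_pixels == 100

    def test_identical_volumes_zero(self):
        s = series_from_signals({0: 77.0, 10: 77.0})
        mask = ROIMask(mask=np.ones((3, 3, 2), dtype=bool))
        assert compute_ddvd(s, mask).scalar == 0.0

    def test_ivim_closed_form(self):
        """f=0.2, D*=50e-3, Dt=1e-3, S0=1000:
        DDVD = 1000*[0.2*(1-e^-0.5) + 0.8*(1-e^-0.01)] = 86.654 au/pixel."""
        p = make_tissue(f=0.2, d_star=50e-3, d_t=1.0e-3)
        want = 1000.0 * (0.2 * (1 - math.exp(-0.5))
                         + 0.8 * (1 - math.exp(-0.01)))
        assert want == pytest.approx(86.654, abs=5e-4)
        sig = {b: float(ivim_signal(b, p)) for b in (0, 10, 500, 750, 1000)}
        s = series_from_signals(sig)
        mask = ROIMask(mask=np.ones((3, 3, 2), dtype=bool))
        assert compute_ddvd(s, mask).scalar == pytest.approx(want,
                                                             rel=1e-12)

    def test_scalar_equals_roi_mean_of_pixelwise_map(self, rng):
        """Exact identity for any mask, including noisy inhomogeneous data."""
        data = rng.uniform(10, 1000, size=(8, 8, 4, 5))
        s = DWISeries(b_values=[0, 10, 500, 750, 1000], data=data)
        m = rng.random((8, 8, 4)) > 0.6
        m[0, 0, 0] = True
        mask = ROIMask(mask=m)
        r = compute_ddvd(s, mask)
        assert r.scalar == pytest.approx(r.pixelwise[m].mean(), rel=1e-12)


class TestScaleBehaviour:
    def test_scale_covariance_exact(self, rng):
        """Signals x c: SDC and DDVD scale by c, ADC is unchanged."""
        data = rng.uniform(50, 1000, size=(6, 6, 3, 5))
        s1 = DWISeries(b_values=[0, 10, 500, 750, 1000], data=data)
        c = 4.0   # dyadic scale keeps the identity exact in floating point
        s2 = DWISeries(b_values=s1.b_values, data=data * c)
        mask = ROIMask(mask=np.ones((6, 6, 3), dtype=bool))
        assert np.array_equal(compute_sdc(s2), compute_sdc(s1) * c)
        assert compute_ddvd(s2, mask).scalar == pytest.approx(
            compute_ddvd(s1, mask).scalar * c, rel=1e-12)
        assert np.allclose(compute_adc(s2), compute_adc(s1), rtol=1e-12)


class TestNormalization:
    def test_b0_roi_mean_normalization_rescales_difference_metrics(self, rng):
        """Normalized series: ADC unchanged, SDC/DDVD divided by ROI-mean
        b0 signal; the b=0 ROI mean becomes exactly 1."""
        from sdc_glioma.metrics import normalize_by_b0_roi_mean
        data = rng.uniform(100, 1000, size=(6, 6, 3, 5))
        s = DWISeries(b_values=[0, 10, 500, 750, 1000], data=data)
        mask = ROIMask(mask=rng.random((6, 6, 3)) > 0.4)
        ref = s.volume(0)[mask.mask].mean()
        ns = normalize_by_b0_roi_mean(s, mask)
        assert ns.volume(0)[mask.mask].mean() == pytest.approx(1.0)
        assert np.allclose(compute_sdc(ns), compute_sdc(s) / ref)
        assert np.allclose(compute_adc(ns), compute_adc(s), rtol=1e-12)


class TestROIAggregate:
    def test_uniform_maps_triplet_with_unit_conversion(self):
        s = mono_exp_series()
        maps = compute_maps(s)
        maps.sdc[:] = 0.4
        maps.ddvd[:] = 30.0
        maps.adc[:] = 1.1e-3
        st = roi_aggregate(maps, ROIMask(np.ones(s.grid_shape, dtype=bool)))
        assert st.triplet.sdc == pytest.approx(0.4)
        assert st.triplet.ddvd == pytest.approx(30.0)
        assert st.triplet.adc == pytest.approx(11.0)   # 1e-4 mm2/s
        assert st.triplet.adc_unit == ADC_E4

    def test_two_voxel_mean(self):
        s = mono_exp_series(shape=(2, 1, 1))
        maps = compute_maps(s)
        maps.sdc[0, 0, 0], maps.sdc[1, 0, 0] = 0.3, 0.5
        m = np.ones((2, 1, 1), dtype=bool)
        st = roi_aggregate(maps, ROIMask(m))
        assert st.triplet.sdc == pytest.approx(0.4)

    def test_invalid_voxels_excluded_and_counted(self):
        s = series_from_signals({0: 1000.0, 10: 990.0, 500: 600.0,
                                 750: 470.0, 1000: 360.0}, shape=(4, 4, 1))
        s.data[0, 0, 0, -1] = 0.0   # ADC undefined there
        maps = compute_maps(s)
        st = roi_aggregate(maps, ROIMask(np.ones((4, 4, 1), dtype=bool)))
        assert st.n_excluded == {"sdc": 0, "ddvd": 0, "adc": 1}
        assert np.isfinite(st.triplet.adc)

    def test_all_invalid_names_metric(self):
        s = series_from_signals({0: 1000.0, 10: 990.0, 500: 600.0,
                                 750: 470.0, 1000: 360.0}, shape=(2, 2, 1))
        s.data[..., -1] = 0.0
        maps = compute_maps(s)
        with pytest.raises(ValueError, match="'adc'"):
            roi_aggregate(maps, ROIMask(np.ones((2, 2, 1), dtype=bool)))

    def test_noisy_roi_mean_matches_noiseless_oracle(self):
        """Mutant-like region at snr=50: ROI SDC within 3 SE of noiseless."""
        spec = default_phantom_spec(snr=50.0, seed=14)
        series, labels = simulate_phantom(spec)
        maps = compute_maps(series)
        sel = labels == MUTANT_LIKE
        assert sel.sum() >= 310
        p = spec.regions[MUTANT_LIKE]
        oracle = float((ivim_signal(500.0, p) - ivim_signal(750.0, p)) / 250)
        vals = maps.sdc[sel]
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean() - oracle) < 3 * se + 1e-3


class TestPhantomDirections:
    def test_wildtype_like_lower_sdc_higher_ddvd(self, noiseless_phantom):
        """Hypervascular dense insert: lower SDC, higher DDVD, lower ADC."""
        _, series, labels = noiseless_phantom
        maps = compute_maps(series)
        wt, mut = labels == WILDTYPE_LIKE, labels == MUTANT_LIKE
        assert maps.sdc[wt].mean() < maps.sdc[mut].mean()
        assert maps.ddvd[wt].mean() > maps.ddvd[mut].mean()
        assert maps.adc[wt].mean() < maps.adc[mut].mean()


class TestMetricTriplet:
    def test_unit_tag_mandatory_and_convertible(self):
        t = MetricTriplet(sdc=0.4, ddvd=30.0, adc=1.1e-3, adc_unit=ADC_MM2S)
        assert t.adc_in(ADC_E4) == pytest.approx(11.0)
        with pytest.raises(ValueError, match="unit"):
            MetricTriplet(sdc=0.4, ddvd=30.0, adc=11.0, adc_unit="cm2/s")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            MetricTriplet(sdc=np.nan, ddvd=0.0, adc=1.0)
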