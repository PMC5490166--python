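"""Phase wrapping, unwrapping, decoding and offset anchoring."""

import dataclasses

import numpy as np
import pytest

import cardiodense as cd
from cardiodense.dense import wrap_phase
from conftest import decode_phantom


class TestWrap:
    def test_wrap_convention_half_open_interval(self):
        assert wrap_phase(np.pi) == pytest.approx(np.pi)
        assert wrap_phase(-np.pi) == pytest.approx(np.pi)
        assert wrap_phase(1.2 * np.pi) == pytest.approx(-0.8 * np.pi)
        assert wrap_phase(0.0) == 0.0

    def test_wrap_is_2pi_periodic(self):
        x = np.linspace(-10, 10, 1001)
        assert np.allclose(wrap_phase(x + 2 * np.pi), wrap_phase(x), atol=1e-9)


def _strip_pair(phase_x, mask=None, spacing=1.0, k_e=0.1):
    phase_x = np.asarray(phase_x, float)
    return cd.PhasePair(
        phase_x=wrap_phase(phase_x),
        phase_y=np.zeros_like(phase_x),
        pixel_spacing_mm=spacing,
        k_e=k_e,
    )


class TestUnwrap:
    def test_smooth_in_range_phase_returned_unchanged(self):
        phase = np.tile(np.linspace(-1.0, 1.0, 30), (5, 1))
        pair = _strip_pair(phase)
        mask = np.ones_like(phase, bool)
        out = cd.unwrap_phase(pair, mask)
        # already consistent: result equals input up to the component constant
        offset = out.phase_x[0, 0] - phase[0, 0]
        assert np.allclose(out.phase_x - offset, phase, atol=1e-12)

    def test_wrapped_ramp_recovered_up_to_component_constant(self):
        """A 0 -> 3*pi ramp wrapped at +/-pi unwraps back to the true ramp."""
        true = np.tile(np.linspace(0.0, 3 * np.pi, 60), (6, 1))
        pair = _strip_pair(true)
        mask = np.ones_like(true, bool)
        out = cd.unwrap_phase(pair, mask)
        offset = out.phase_x[0, 0] - true[0, 0]
        assert offset == pytest.approx(round(offset / (2 * np.pi)) * 2 * np.pi, abs=1e-9)
        assert np.allclose(out.phase_x - offset, true, atol=1e-9)

    def test_adjacent_differences_within_wrap_interval_after_unwrap(self):
        rng = np.random.default_rng(0)
        # smooth 2D field: separable ramps with sub-pi increments
        row = np.cumsum(rng.uniform(-2.0, 2.5, 50))
        col = np.cumsum(rng.uniform(-1.0, 1.5, 8))
        true = col[:, None] + row[None, :]
        pair = _strip_pair(true)
        mask = np.ones_like(true, bool)
        out = cd.unwrap_phase(pair, mask)
        dx = np.diff(out.phase_x, axis=1)
        assert dx.max() <= np.pi + 1e-9 and dx.min() > -np.pi - 1e-9

    def test_two_components_unwrapped_independently(self):
        """Separate strips may differ by their own 2*pi constants."""
        true = np.zeros((10, 21))
        true[:4] = np.linspace(0, 2.5 * np.pi, 21)
        true[6:] = np.linspace(0, 2.5 * np.pi, 21) + 4 * np.pi
        mask = np.zeros_like(true, bool)
        mask[:4] = True
        mask[6:] = True
        pair = _strip_pair(true)
        out = cd.unwrap_phase(pair, mask)
        assert out.meta["n_components"] == 2
        for rows in (slice(0, 4), slice(6, 10)):
            sub = out.phase_x[rows] - true[rows]
            assert np.allclose(sub, sub.flat[0], atol=1e-9)  # one constant each
            assert sub.flat[0] == pytest.approx(
                round(sub.flat[0] / (2 * np.pi)) * 2 * np.pi, abs=1e-9
            )

    def test_agrees_with_skimage_reference_unwrapper(self, default_spec):
        """Independent cross-check: our flood fill matches the reliability-
        sorting unwrapper on a wrapped multi-wrap phantom, per component."""
        from skimage.restoration import unwrap_phase as sk_unwrap

        ph = cd.make_phantom_pair(default_spec, cd.uniform_stretch(2.2, axis=(0, 1)))
        out = cd.unwrap_phase(ph.pair, ph.mask)
        masked = np.ma.array(ph.pair.phase_y, mask=~ph.mask)
        ref = sk_unwrap(masked)
        comps = out.meta["components"]
        for label in (1, 2):
            sel = comps == label
            diff = (out.phase_y - ref.filled(np.nan))[sel]
            # equal up to one 2-pi constant per component
            assert np.allclose(diff, diff.flat[0], atol=1e-9)
            assert abs(diff.flat[0] / (2 * np.pi) - round(diff.flat[0] / (2 * np.pi))) < 1e-9

    def test_empty_or_tiny_mask_rejected(self):
        pair = _strip_pair(np.zeros((12, 12)))
        with pytest.raises(ValueError, match="empty"):
            cd.unwrap_phase(pair, np.zeros((12, 12), bool))
        tiny = np.zeros((12, 12), bool)
        tiny[0, :3] = True
        with pytest.raises(ValueError, match="10 pixels"):
            cd.unwrap_phase(pair, tiny)


class TestDecode:
    def test_decode_closed_form(self):
        phase = np.full((4, 12), np.pi / 2)
        pair = cd.PhasePair(phase, np.zeros_like(phase), 1.0, 0.1, unwrapped=True)
        mask = np.ones_like(phase, bool)
        out = cd.decode_displacement(pair, mask)
        assert np.allclose(out.u_x, 2.5)  # pi/2 / (2 pi * 0.1) = 2.5 mm
        assert np.allclose(out.u_y, 0.0)

    def test_decode_post_unwrap_value_beyond_range(self):
        phase = np.full((4, 12), 1.2 * np.pi)
        pair = cd.PhasePair(phase, np.zeros_like(phase), 1.0, 0.1, unwrapped=True)
        out = cd.decode_displacement(pair, np.ones_like(phase, bool))
        assert np.allclose(out.u_x, 6.0)

    def test_decode_requires_unwrapped_pair_and_positive_ke(self):
        phase = np.zeros((4, 12))
        pair = cd.PhasePair(phase, phase, 1.0, 0.1)
        with pytest.raises(ValueError, match="unwrapped"):
            cd.decode_displacement(pair, np.ones_like(phase, bool))
        with pytest.raises(ValueError):
            cd.PhasePair(phase, phase, 1.0, k_e=-0.1, unwrapped=True).k_e
            cd.decode_displacement(
                cd.PhasePair(phase, phase, 1.0, k_e=-0.1, unwrapped=True),
                np.ones_like(phase, bool),
            )

    def test_decoding_is_linear_in_phase(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-2, 2, (6, 9))
        mask = np.ones_like(phase, bool)
        u1 = cd.decode_displacement(
            cd.PhasePair(phase, phase, 1.0, 0.1, unwrapped=True), mask
        )
        u2 = cd.decode_displacement(
            cd.PhasePair(3 * phase, 3 * phase, 1.0, 0.1, unwrapped=True), mask
        )
        assert np.allclose(u2.u_x, 3 * u1.u_x)


class TestAnchor:
    def _field(self, ux, components=None):
        ux = np.asarray(ux, float)
        mask = np.ones_like(ux, bool)
        return cd.DisplacementField(
            u_x=ux, u_y=np.zeros_like(ux), mask=mask, pixel_spacing_mm=1.0,
            components=components, provenance={"k_e": 0.1},
        )

    def test_injected_wrap_offset_removed_exactly(self):
        true = np.tile(np.linspace(-2, 2, 40), (5, 1))  # median ~0
        field = self._field(true + 10.0)  # one wrap = 1/k_e = 10 mm
        out = cd.anchor_component_offsets(field)
        assert np.allclose(out.u_x, true, atol=1e-12)

    def test_anchor_pixel_rule_zeroes_known_pixel(self):
        true = np.full((5, 40), 20.0)  # two wraps everywhere
        field = self._field(true)
        out = cd.anchor_component_offsets(field, rule="anchor", anchor_px=(2, 3))
        assert out.u_x[2, 3] == pytest.approx(0.0)

    def test_already_anchored_field_unchanged(self):
        true = np.tile(np.linspace(-2, 2, 40), (5, 1))
        out = cd.anchor_component_offsets(self._field(true))
        assert np.allclose(out.u_x, true)

    def test_anchor_off_mask_rejected(self):
        ux = np.zeros((5, 5))
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        field = cd.DisplacementField(ux, ux, mask, 1.0, provenance={"k_e": 0.1})
        with pytest.raises(ValueError, match="off the tissue mask"):
            cd.anchor_component_offsets(field, rule="anchor", anchor_px=(0, 0))


class TestRoundTrip:
    @pytest.mark.parametrize("e_ll", [-0.10, -0.22])
    def test_noiseless_phantom_roundtrip_below_1e9_mm(self, default_spec, e_ll):
        """decode(unwrap(encode(u))) == u on the strained crescent."""
        ph = cd.make_phantom_pair(default_spec, cd.imposed_strain_field(default_spec, e_ll))
        field = decode_phantom(ph)
        err = np.abs(field.u_x - ph.truth_ux)[ph.rv_mask].max()
        err = max(err, np.abs(field.u_y - ph.truth_uy)[ph.rv_mask].max())
        assert err < 1e-9

    def test_multi_wrap_ramp_recovered_exactly_after_anchoring(self):
        """A ramp spanning several wrap transitions decodes to the truth."""
        spec = cd.PhantomSpec()
        # stretch along y: both walls are symmetric about y=0, so each
        # component has ~zero median displacement and anchors exactly
        ph = cd.make_phantom_pair(spec, cd.uniform_stretch(2.2, axis=(0, 1)))
        raw = 2 * np.pi * spec.k_e * ph.truth_uy
        assert np.ptp(raw[ph.rv_mask]) > 3 * 2 * np.pi  # >= 3 wrap transitions
        field = decode_phantom(ph)
        for m in (ph.rv_mask, ph.lv_mask):
            assert np.abs(field.u_x - ph.truth_ux)[m].max() < 1e-9
            assert np.abs(field.u_y - ph.truth_uy)[m].max() < 1e-9
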