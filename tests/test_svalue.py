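"""Phantom geometry, Monte Carlo transport and S-value properties."""

import math

import numpy as np
import pytest

from ritdose.nuclides import KEV_TO_J, mean_energy_per_decay
from ritdose.svalue import (
    PhantomValidationError,
    analytic_selfdose,
    build_phantom,
    csda_range_g_cm2,
    default_phantom,
    energy_balance,
    mc_svalue,
    svalue_matrix,
)


def _sphere(name, r, center=(0.0, 0.0, 0.0), material="soft_tissue", **kw):
    return dict(
        name=name, shape="sphere", material=material, center_mm=list(center),
        radius_mm=r, **kw,
    )


class TestPhantom:
    def test_sphere_mass_from_volume_times_density(self):
        ph = build_phantom({"regions": [_sphere("ball", 6.2035)]})
        # (4/3) pi (0.62035 cm)^3 * 1.04 g/cm^3 = 1.04 g
        assert ph.regions[0].mass_g == pytest.approx(1.04, rel=1e-3)

    def test_material_densities(self):
        ph = build_phantom(
            {"regions": [_sphere("a", 3.0), _sphere("b", 3.0, center=(10, 0, 0), material="lung")]}
        )
        assert ph.region("a").density == 1.04
        assert ph.region("b").density == 0.296

    def test_empty_spec_rejected(self):
        with pytest.raises(PhantomValidationError):
            build_phantom({"regions": []})

    def test_unknown_material_rejected(self):
        with pytest.raises(PhantomValidationError, match="material"):
            build_phantom({"regions": [_sphere("a", 3.0, material="adamantium")]})

    def test_overlapping_named_regions_rejected(self):
        with pytest.raises(PhantomValidationError, match="overlap"):
            build_phantom(
                {"regions": [_sphere("a", 3.0), _sphere("b", 3.0, center=(4, 0, 0))]}
            )

    def test_background_mass_excludes_organs(self):
        ph = build_phantom(
            {
                "regions": [
                    _sphere("organ", 5.0),
                    {
                        "name": "body",
                        "shape": "box",
                        "material": "soft_tissue",
                        "center_mm": [0, 0, 0],
                        "size_mm": [40, 40, 40],
                        "background": True,
                    },
                ]
            }
        )
        v_org = (4.0 / 3.0) * math.pi * 0.5**3
        assert ph.region("body").volume_cm3 == pytest.approx(64.0 - v_org, rel=1e-9)

    def test_default_phantom_has_study_organs(self):
        ph = default_phantom()
        assert set(ph.region_names) == {
            "tumor", "spleen", "kidneys", "liver", "heart", "lungs", "brain",
            "rest_of_body",
        }
        assert ph.region("lungs").density == 0.296


class TestRangeTable:
    def test_monotone_in_energy(self):
        e = np.linspace(5.0, 2500.0, 400)
        r = csda_range_g_cm2(e)
        assert np.all(np.diff(r) > 0)

    def test_tabulated_anchor_points(self):
        assert csda_range_g_cm2(100.0) == pytest.approx(1.431e-2, rel=1e-9)
        assert csda_range_g_cm2(1000.0) == pytest.approx(4.367e-1, rel=1e-9)


class TestAnalyticSelfdose:
    def test_unit_arithmetic(self, lu177):
        delta = mean_energy_per_decay(lu177)
        s = analytic_selfdose(1.0, lu177)
        assert s == pytest.approx(delta * KEV_TO_J / 1e-3, rel=1e-12)

    def test_doubling_mass_halves_s(self, lu177):
        assert analytic_selfdose(2.0, lu177) == pytest.approx(
            analytic_selfdose(1.0, lu177) / 2.0, rel=1e-12
        )

    def test_nonpositive_mass_rejected(self, lu177):
        with pytest.raises(ValueError):
            analytic_selfdose(0.0, lu177)


class TestMonteCarlo:
    def test_large_sphere_selfdose_matches_delta_over_m(self, lu177):
        """Full-absorption limit: S * m = Delta within 3 batch sigma."""
        ph = build_phantom({"regions": [_sphere("ball", 400.0)]})
        res = mc_svalue(ph, "ball", "ball", lu177, n_particles=60_000, seed=9)
        s_ref = analytic_selfdose(ph.regions[0].mass_g, lu177)
        assert abs(res.s_value - s_ref) <= 3.0 * res.rel_uncertainty * res.s_value

    def test_cross_svalue_zero_beyond_range(self, lu177):
        # Lu-177 max CSDA range ~1.7 mm in soft tissue; 30 mm of tissue between
        ph = build_phantom(
            {
                "regions": [
                    _sphere("a", 2.0, center=(-17, 0, 0)),
                    _sphere("b", 2.0, center=(17, 0, 0)),
                    {
                        "name": "body",
                        "shape": "box",
                        "material": "soft_tissue",
                        "center_mm": [0, 0, 0],
                        "size_mm": [44, 10, 10],
                        "background": True,
                    },
                ]
            }
        )
        res = mc_svalue(ph, "a", "b", lu177, n_particles=5_000, seed=1)
        assert res.s_value == 0.0

    def test_symmetric_twin_targets_get_equal_dose(self, y90):
        ph = build_phantom(
            {
                "regions": [
                    _sphere("src", 1.5),
                    _sphere("left", 2.0, center=(-6, 0, 0)),
                    _sphere("right", 2.0, center=(6, 0, 0)),
                ]
            }
        )
        mat = svalue_matrix(ph, y90, n_particles=60_000, seed=4)
        by = {(r.source, r.target): r for r in mat}
        left = by[("src", "left")]
        right = by[("src", "right")]
        sigma = math.hypot(
            left.rel_uncertainty * left.s_value,
            right.rel_uncertainty * right.s_value,
        )
        assert left.s_value > 0 and right.s_value > 0
        assert abs(left.s_value - right.s_value) <= 3.0 * sigma

    def test_matrix_rerun_is_bit_identical(self, lu177):
        ph = build_phantom(
            {"regions": [_sphere("a", 2.0), _sphere("b", 2.0, center=(10, 0, 0))]}
        )
        m1 = svalue_matrix(ph, lu177, n_particles=2_000, seed=13)
        m2 = svalue_matrix(ph, lu177, n_particles=2_000, seed=13)
        assert [(r.source, r.target, r.s_value) for r in m1] == [
            (r.source, r.target, r.s_value) for r in m2
        ]

    def test_energy_conservation_enclosed_and_leaky(self, lu177):
        ph = default_phantom()
        enclosed = energy_balance(ph, "liver", lu177, n_particles=20_000, seed=3)
        assert enclosed["deposited_kev"] == pytest.approx(
            enclosed["sampled_kev"], rel=1e-12
        )
        leaky = energy_balance(ph, "rest_of_body", lu177, n_particles=20_000, seed=3)
        assert leaky["deposited_kev"] < leaky["sampled_kev"]

    def test_sum_s_times_m_bounded_by_sampled_energy(self, lu177):
        """Conservation: per source, sum_t S(s->t) m_t <= sampled energy/decay."""
        ph = default_phantom()
        mat = svalue_matrix(ph, lu177, n_particles=5_000, seed=6)
        masses = {r.name: r.mass_g for r in ph.regions}
        delta = mean_energy_per_decay(lu177)
        for src in ph.region_names:
            total_kev = sum(
                r.s_value * masses[r.target] * 1e-3 / KEV_TO_J
                for r in mat
                if r.source == src
            )
            # bounded by the spectrum mean up to MC fluctuation of the mean
            assert total_kev <= delta * 1.05

    def test_self_dose_dominates_cross_dose(self, lu177):
        ph = default_phantom()
        mat = svalue_matrix(ph, lu177, n_particles=10_000, seed=8)
        by = {(r.source, r.target): r.s_value for r in mat}
        for src in ("tumor", "liver", "kidneys"):
            self_s = by[(src, src)]
            for tgt in ph.region_names:
                if tgt != src:
                    assert by[(src, tgt)] <= self_s

    def test_too_few_particles_rejected(self, lu177):
        ph = build_phantom({"regions": [_sphere("a", 2.0)]})
        with pytest.raises(ValueError):
            mc_svalue(ph, "a", "a", lu177, n_particles=10, seed=0)

    def test_non_beta_source_rejected(self, in111):
        ph = build_phantom({"regions": [_sphere("a", 2.0)]})
        from ritdose.nuclides import UnsupportedNuclideError

        with pytest.raises(UnsupportedNuclideError):
            mc_svalue(ph, "a", "a", in111, n_particles=2_000, seed=0)
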