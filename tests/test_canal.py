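"""Reduced hiatus-ring model: kinematics, materials, force projection."""

import numpy as np
import pytest

from vadsim.canal import (
    PERINEUM_MATERIAL,
    PFM_MATERIAL,
    HeadGeometry,
    HiatusRing,
    PfmMaterial,
    cup_force,
    default_materials,
    ring_stretch_at,
    simulate_vad,
)
from vadsim.constitutive import MartinsParams
from vadsim.errors import ConfigurationError, GeometryError
from vadsim.protocol import PullProtocol


PROTOCOL = PullProtocol(60.0, 60.0, 2, engagement_duration=600.0,
                        engagement_dt=60.0)


def sphere(radius=47.5):
    return HeadGeometry.spheroid(radius=radius)


def test_ring_stretch_geometry():
    head = sphere()
    ring = HiatusRing("levator", C0=2 * np.pi * 25.0, z_station=10.0)
    # apex not yet at the ring plane: no contact
    assert ring_stretch_at(5.0, head, ring) == 1.0
    # sphere section 20 mm from the equator plane
    d_equator = ring.z_station + head.L / 2.0
    lam = ring_stretch_at(d_equator - 20.0, head, ring)
    assert lam == pytest.approx(np.sqrt(47.5 ** 2 - 20 ** 2) / 25.0, rel=1e-3)
    # equator at the ring plane: global maximum R / r0
    assert ring_stretch_at(d_equator, head, ring) == pytest.approx(47.5 / 25.0)
    sweep = ring_stretch_at(np.linspace(0, 120, 2401), head, ring)
    assert sweep.max() == pytest.approx(47.5 / 25.0)


def test_invalid_ring_station():
    with pytest.raises(GeometryError):
        ring_stretch_at(1.0, sphere(), HiatusRing("levator", C0=100.0,
                                                  z_station=-5.0))


def test_head_scale_doubles_peak_stretch():
    ring = HiatusRing("levator", C0=150.0, z_station=20.0)
    d = np.linspace(0.0, 250.0, 5001)
    small = ring_stretch_at(d, sphere(40.0), ring).max()
    large = ring_stretch_at(d, HeadGeometry.spheroid(radius=80.0, length=160.0),
                            ring).max()
    assert large == pytest.approx(2.0 * small, rel=1e-9)


def _tiny_anatomy(lambda_eng=1.3):
    head = HeadGeometry.spheroid(radius=47.5, n=501)
    rings = [
        HiatusRing("levator", C0=2 * np.pi * 47.5 / 2.09, z_station=22.41,
                   material=PFM_MATERIAL, lambda_eng=lambda_eng,
                   area_mm2=300.0),
        HiatusRing("urogenital", C0=2 * np.pi * 47.5 / 3.01, z_station=32.01,
                   material=PERINEUM_MATERIAL, lambda_eng=lambda_eng,
                   area_mm2=150.0),
    ]
    return head, rings


def test_stretch_is_purely_kinematic():
    """The stretch series does not depend on the material configuration."""
    head, rings = _tiny_anatomy()
    stiff = {
        PFM_MATERIAL: PfmMaterial(params=MartinsParams(c=0.05, b=2.0)),
        PERINEUM_MATERIAL: default_materials()[PERINEUM_MATERIAL],
    }
    a = simulate_vad(PROTOCOL, head, rings, default_materials())
    b = simulate_vad(PROTOCOL, head, rings, stiff)
    for name in ("levator", "urogenital"):
        assert np.array_equal(a.stretch[name], b.stretch[name])
    assert not np.array_equal(a.sigma1["levator"], b.sigma1["levator"])


def test_simulation_invariants_and_determinism():
    head, rings = _tiny_anatomy()
    a = simulate_vad(PROTOCOL, head, rings)
    b = simulate_vad(PROTOCOL, head, rings)
    for name in ("levator", "urogenital"):
        assert np.array_equal(a.sigma1[name], b.sigma1[name])
        assert np.all(a.stretch[name] >= 1.0)
    assert np.all(a.force >= 0.0)
    assert np.array_equal(a.force, b.force)
    # engagement: no head contact, so no cup force
    assert np.all(a.force[a.phase == "engagement"] == 0.0)


def test_head_never_reaching_ring_is_warned_and_stress_free():
    """A ring the head cannot distend stays at unit stretch with zero stress
    (the degenerate no-load path)."""
    head, _ = _tiny_anatomy()
    rings = [HiatusRing("levator", C0=2 * np.pi * 500.0, z_station=22.41,
                        material=PFM_MATERIAL, lambda_eng=1.0, area_mm2=300.0)]
    with pytest.warns(UserWarning, match="never stretches"):
        res = simulate_vad(PROTOCOL, head, rings)
    assert np.all(res.stretch["levator"] == 1.0)
    assert np.allclose(res.sigma1["levator"], 0.0, atol=1e-15)
    assert np.all(res.force == 0.0)


def test_viscoelastic_ring_relaxes_elastic_ring_does_not():
    head, rings = _tiny_anatomy()
    res = simulate_vad(PROTOCOL, head, rings)
    for lab, blk in res.phase_blocks():
        if lab.startswith("rest"):
            pfm = res.sigma1["levator"][blk.start - 1:blk.stop]
            uro = res.sigma1["urogenital"][blk.start - 1:blk.stop]
            assert pfm[-1] < pfm[0]
            assert np.all(uro == uro[0])


def test_total_stress_at_least_equilibrium_while_loading():
    """During monotone stretch growth the viscous ring stress never drops
    below the equilibrium hyperelastic response."""
    from vadsim.constitutive import martins_uniaxial_stress

    head, rings = _tiny_anatomy()
    res = simulate_vad(PROTOCOL, head, rings)
    lam = res.stretch["levator"]
    sig = res.sigma1["levator"]
    growing = np.concatenate([[True], np.diff(lam) >= 0])
    eq = np.array([martins_uniaxial_stress(l, MartinsParams()) for l in lam])
    assert np.all(sig[growing] >= eq[growing] - 1e-12)


def test_cup_force_projection():
    head, rings = _tiny_anatomy()
    res = simulate_vad(PROTOCOL, head, rings)
    # recomputation from the stored series matches the stored force
    assert np.allclose(cup_force(res, rings, head), res.force)
    # missing area config
    bad = [HiatusRing("levator", C0=140.0, z_station=22.41, area_mm2=None)]
    with pytest.raises(ConfigurationError):
        cup_force(res, bad, head)


def test_cylindrical_segment_contributes_no_axial_force():
    """Where the profile slope is zero (cylinder), sin(alpha) = 0."""
    s = np.linspace(0.0, 60.0, 301)
    head = HeadGeometry(s=s, rho=np.full_like(s, 30.0))
    assert head.sin_slope_at(30.0) == pytest.approx(0.0, abs=1e-12)
    ring = HiatusRing("levator", C0=2 * np.pi * 20.0, z_station=10.0,
                      area_mm2=300.0)
    res = simulate_vad(PROTOCOL, head, [ring])
    inside = (res.displacement > 12.0) & (res.displacement < 60.0)
    assert np.any(res.sigma1["levator"][inside] > 0.1)
    assert np.all(np.abs(res.force[inside]) < 1e-9)


def test_spheroid_profile_validation():
    with pytest.raises(GeometryError):
        HeadGeometry(s=np.array([0.0, 1.0]), rho=np.array([1.0, 1.0]))
    with pytest.raises(GeometryError):
        HeadGeometry(s=np.array([0.0, 1.0, 0.5]), rho=np.ones(3))
    with pytest.raises(GeometryError):
        HeadGeometry(s=np.linspace(0, 1, 5), rho=-np.ones(5))
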