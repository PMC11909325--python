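"""Simulator physics: binding models, library generation, screen assembly."""

import math

import numpy as np
import pytest

from ndscreen import (
    InjectionProtocol,
    Pathology,
    SimConfig,
    capture_decay,
    default_surfaces,
    generate_library,
    langmuir_response,
    partition_response,
    simulate_screen,
)
from ndscreen.datatypes import CapturedSpecies, Lipid, Role, SurfaceDefinition
from ndscreen.exceptions import ConfigError
from ndscreen.sim import DEFAULT_LEACH_RATE


class TestLangmuir:
    def test_half_saturation_at_kd(self):
        # C = K_D saturates half the sites at equilibrium
        r = langmuir_response(1e6, C=10.0, kon=0.1, koff=1.0, rmax=50.0)
        assert r == pytest.approx(25.0, rel=1e-12)

    def test_zero_concentration_gives_zero(self):
        t = np.linspace(0, 100, 11)
        r = langmuir_response(t, C=0.0, kon=0.1, koff=1.0, rmax=50.0)
        assert np.all(r == 0.0)

    def test_dissociation_half_life(self):
        koff = 0.3
        r = langmuir_response(math.log(2) / koff, C=0.0, kon=0.1, koff=koff,
                              rmax=50.0, phase="dissociation", r0=8.0)
        assert r == pytest.approx(4.0, rel=1e-12)

    def test_association_monotone_and_bounded(self):
        t = np.linspace(0, 60, 200)
        r = langmuir_response(t, C=30.0, kon=0.05, koff=0.5, rmax=20.0)
        assert np.all(np.diff(r) >= 0)
        assert r.max() <= 20.0 and r.min() >= 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            langmuir_response(1.0, C=-1.0, kon=0.1, koff=1.0, rmax=5.0)


class TestPartition:
    def test_zero_concentration(self):
        assert partition_response(0.0, 2.0, Lipid.POPC, 5000.0,
                                  SimConfig()) == 0.0

    def test_lipid_ratio_is_kappa_ratio(self):
        cfg = SimConfig()
        a = partition_response(100.0, 1.0, Lipid.POPC, 5000.0, cfg)
        b = partition_response(100.0, 1.0, Lipid.DMPC, 5000.0, cfg)
        expected = cfg.kappa_lipid[Lipid.POPC] / cfg.kappa_lipid[Lipid.DMPC]
        assert a / b == pytest.approx(expected, rel=1e-12)

    def test_clogp_increment_scales_by_beta_decade(self):
        cfg = SimConfig(beta_clogp=0.5)
        a = partition_response(100.0, 2.0, Lipid.POPC, 5000.0, cfg)
        b = partition_response(100.0, 1.0, Lipid.POPC, 5000.0, cfg)
        assert a / b == pytest.approx(10.0 ** 0.5, rel=1e-12)

    def test_unknown_lipid_is_config_error(self):
        cfg = SimConfig(kappa_lipid={Lipid.POPC: 1e-3})
        with pytest.raises(ConfigError):
            partition_response(100.0, 1.0, Lipid.DMPC, 5000.0, cfg)


class TestCaptureDecay:
    def test_no_leaching_is_constant(self):
        assert capture_decay(1e6, 5000.0, 0.0) == 5000.0

    def test_half_life(self):
        lam = 1e-4
        assert capture_decay(math.log(2) / lam, 1000.0, lam) == pytest.approx(
            500.0, rel=1e-12)

    def test_default_rate_matches_30pct_loss_over_34h(self):
        assert capture_decay(34 * 3600.0, 1.0, DEFAULT_LEACH_RATE) == \
            pytest.approx(0.7, rel=1e-12)


class TestLibrary:
    def test_reproducible_under_seed(self):
        a = generate_library(n=140, seed=42)
        b = generate_library(n=140, seed=42)
        assert len(a) == 140
        assert all(x == y for x, y in zip(a, b))

    def test_no_pathologies_when_fraction_zero(self):
        lib = generate_library(n=50, seed=1, frac_pathological=0.0)
        assert all(f.pathology is Pathology.NONE for f in lib)

    def test_degenerate_clogp_spread(self):
        lib = generate_library(n=10, seed=1, clogp_sd=0.0, clogp_mean=1.7)
        assert all(f.clogp == pytest.approx(1.7) for f in lib)

    def test_property_bounds_and_planting(self):
        lib = generate_library(n=140, seed=5)
        assert all(100.0 <= f.mw <= 300.0 for f in lib)
        assert all(-2.0 <= f.clogp <= 4.0 for f in lib)
        n_path = sum(f.pathology is not Pathology.NONE for f in lib)
        assert n_path == round(0.05 * 140)
        clean_binders = [f for f in lib if f.true_kd is not None
                         and f.pathology is Pathology.NONE]
        assert len(clean_binders) == round(0.10 * 140)
        # planted 1:1 occupancy at 500 uM falls in the requested band
        for f in clean_binders:
            occ = 100.0 * 500.0 / (f.true_kd + 500.0)
            assert 60.0 - 1e-9 <= occ <= 95.0 + 1e-9


def _tiny_screen(noise=0.0, seed=0, **proto_kw):
    lib = generate_library(n=5, seed=seed, frac_pathological=0.0)
    proto = InjectionProtocol(concentrations=(500.0,), **proto_kw)
    cfg = SimConfig(seed=seed, noise_sigma=noise)
    return lib, simulate_screen(lib, default_surfaces(), cfg, proto)


class TestSimulateScreen:
    def test_noiseless_blank_on_empty_chip_is_zero(self):
        _, screen = _tiny_screen()
        blanks = [r.cycle_index for r in screen.sample_sheet
                  if r.role is Role.BLANK]
        trace = next(sg for sg in screen.sensorgrams
                     if sg.cycle_index == blanks[0] and sg.channel_id == "ch1")
        assert np.all(trace.response == 0.0)

    def test_nonbinder_on_protein_only_surface_is_silent(self):
        # protein captured without an ND: no lipid term, no specific site
        surfaces = [
            SurfaceDefinition("ch1", CapturedSpecies.EMPTY_CHIP, Lipid.NONE,
                              None, 0.0, None),
            SurfaceDefinition("ch2", CapturedSpecies.PROTEIN, Lipid.NONE,
                              57000.0, 4000.0, "ch1"),
        ]
        lib = generate_library(n=5, seed=2, frac_pathological=0.0,
                               frac_binders=0.0)
        screen = simulate_screen(lib, surfaces,
                                 SimConfig(seed=2, noise_sigma=0.0),
                                 InjectionProtocol(concentrations=(500.0,)))
        frag_cycles = {r.cycle_index: r for r in screen.sample_sheet
                       if r.role is Role.FRAGMENT and r.dmso_pct == 1.0}
        for sg in screen.sensorgrams:
            if sg.channel_id == "ch2" and sg.cycle_index in frag_cycles:
                # any residual is pure DMSO bulk, absent when matched at 1%
                assert np.allclose(sg.response, 0.0)

    def test_doubling_concentration_doubles_partition(self):
        lib = generate_library(n=3, seed=4, frac_pathological=0.0,
                               frac_binders=0.0)
        surfaces = default_surfaces()
        cfg = SimConfig(seed=4, noise_sigma=0.0)
        screen = simulate_screen(
            lib, surfaces, cfg,
            InjectionProtocol(concentrations=(250.0, 500.0)))
        t = screen.truth
        for frag in lib:
            lo = t[(t.analyte_id == frag.analyte_id) & (t.channel_id == "ch2")
                   & (t.concentration_um == 250.0)].partition_ru.iloc[0]
            hi = t[(t.analyte_id == frag.analyte_id) & (t.channel_id == "ch2")
                   & (t.concentration_um == 500.0)].partition_ru.iloc[0]
            assert hi == pytest.approx(2.0 * lo, rel=1e-12)

    def test_cycle_count_arithmetic(self):
        lib = generate_library(n=140, seed=0)
        screen = simulate_screen(lib, default_surfaces(), SimConfig(seed=0))
        # per series: 1 leading + 28 interleaved/trailing blanks,
        # 1 leading + 14 controls; plus 5 solvent cycles
        expected = 5 + 2 * (140 + 29 + 15)
        assert len(screen.sample_sheet) == expected
        assert len(screen.sensorgrams) == expected * 7

    def test_equal_seeds_identical_sensorgrams(self):
        _, a = _tiny_screen(noise=0.1, seed=9)
        _, b = _tiny_screen(noise=0.1, seed=9)
        for sa, sb in zip(a.sensorgrams, b.sensorgrams):
            np.testing.assert_array_equal(sa.response, sb.response)

    def test_empty_nd_partition_ordering_follows_kappa(self):
        lib = [f for f in generate_library(n=30, seed=6,
                                           frac_pathological=0.0)]
        screen = simulate_screen(lib, default_surfaces(),
                                 SimConfig(seed=6, noise_sigma=0.0),
                                 InjectionProtocol(concentrations=(500.0,)))
        t = screen.truth
        lipophilic = [f.analyte_id for f in lib if f.clogp > 1.0]
        means = {
            ch: t[(t.channel_id == ch) & t.analyte_id.isin(lipophilic)
                  ]["true_occupancy_pct"].mean()
            for ch in ("ch2", "ch3", "ch4", "ch5")
        }
        assert means["ch2"] > means["ch3"] > means["ch4"] > means["ch5"]
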