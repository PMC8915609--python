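import math

import numpy as np
import pytest
from scipy import integrate

from ljfit.constants import R_GAS
from ljfit.forcefield import (
    AtomTypeDef,
    MoleculeSpec,
    ParameterSet,
    SiteSpec,
    SystemSpec,
    lj_energy,
)
from ljfit.toysim import (
    Configuration,
    GeometryError,
    MCEngine,
    SimSettings,
    block_sem,
    build_particle_system,
    metropolis_accept,
    run_npt_density,
    run_nvt,
    total_energy,
    widom_mu_excess,
)


def _ideal_params(name="G"):
    p = ParameterSet()
    p.add_type(AtomTypeDef(name, 0.0, 0.3))
    return p


def _ideal_system(n=64, t=300.0, name="G", mass=40.0):
    mol = MoleculeSpec(name, (SiteSpec(name),), molar_mass=mass)
    return SystemSpec("ideal", ((mol, n, "solvent"),), temperature=t, pressure=1.0)


class TestTotalEnergy:
    def test_two_particles_at_sigma(self, simple_params, mono_a):
        system = SystemSpec("two", ((mono_a, 2, "solvent"),), temperature=100.0,
                            box_edge=2.0)
        pos = np.array([[0.5, 0.5, 0.5], [0.5 + 0.34, 0.5, 0.5]])
        settings = SimSettings(n_steps=10, equil_steps=0, r_cut=0.9,
                               tail_correction=False)
        e = total_energy(Configuration(pos, 2.0), system, simple_params, settings)
        assert e == pytest.approx(0.0, abs=1e-10)

    def test_all_epsilon_zero(self):
        system = _ideal_system(n=8)
        system = SystemSpec(system.name, system.molecules, 300.0, 1.0, box_edge=2.0)
        pos = np.random.default_rng(0).random((8, 3)) * 2.0
        settings = SimSettings(n_steps=10, equil_steps=0, r_cut=0.9)
        e = total_energy(Configuration(pos, 2.0), system, _ideal_params(), settings)
        assert e == 0.0

    def test_matches_naive_double_loop(self, simple_params, mono_a):
        system = SystemSpec("five", ((mono_a, 5, "solvent"),), temperature=100.0,
                            box_edge=2.0)
        rng = np.random.default_rng(3)
        pos = rng.random((5, 3)) * 2.0
        settings = SimSettings(n_steps=10, equil_steps=0, r_cut=0.9,
                               tail_correction=False)
        e = total_energy(Configuration(pos, 2.0), system, simple_params, settings)
        naive = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                d = pos[i] - pos[j]
                d -= 2.0 * np.round(d / 2.0)
                r = float(np.sqrt(np.sum(d * d)))
                if r < 0.9:
                    naive += lj_energy(0.65, 0.34, r)
        assert e == pytest.approx(naive, rel=1e-12)

    def test_cutoff_exceeding_half_box_rejected(self, simple_params, mono_a):
        system = SystemSpec("two", ((mono_a, 2, "solvent"),), temperature=100.0,
                            box_edge=1.0)
        settings = SimSettings(n_steps=10, equil_steps=0, r_cut=0.9)
        with pytest.raises(GeometryError):
            total_energy(
                Configuration(np.zeros((2, 3)), 1.0), system, simple_params, settings
            )


class TestMetropolisRule:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.5, 1.0, rng) for _ in range(100))

    def test_uphill_probability(self):
        rng = np.random.default_rng(7)
        beta, dw = 0.4, 3.0
        target = math.exp(-beta * dw)
        n = 40000
        acc = sum(metropolis_accept(dw, beta, rng) for _ in range(n)) / n
        assert acc == pytest.approx(target, abs=3.0 * math.sqrt(target / n) + 0.003)


class TestRunNvt:
    def test_ideal_gas_acceptance_unity(self):
        system = SystemSpec("ig", _ideal_system(27).molecules, 300.0, 1.0,
                            box_edge=3.0)
        settings = SimSettings(n_steps=3000, equil_steps=500, r_cut=1.2,
                               sample_interval=100, seed=4)
        stats = run_nvt(system, _ideal_params(), settings)
        assert stats.acceptance["move"] == 1.0

    def test_same_seed_identical_series(self, simple_params, mono_a):
        system = SystemSpec("liq", ((mono_a, 20, "solvent"),), temperature=300.0,
                            box_edge=1.2)
        settings = SimSettings(n_steps=4000, equil_steps=1000, r_cut=0.55,
                               tail_correction=False, sample_interval=50, seed=9)
        s1 = run_nvt(system, simple_params, settings)
        s2 = run_nvt(system, simple_params, settings)
        assert np.array_equal(s1.energies, s2.energies)

    def test_two_particle_mean_energy_matches_quadrature(self):
        eps, sig = 1.0, 0.30
        params = ParameterSet()
        params.add_type(AtomTypeDef("Q", eps, sig))
        mol = MoleculeSpec("Q", (SiteSpec("Q"),), molar_mass=40.0)
        box, rc, temp = 1.2, 0.55, 150.0
        system = SystemSpec("pair", ((mol, 2, "solvent"),), temperature=temp,
                            box_edge=box)
        settings = SimSettings(n_steps=150000, equil_steps=10000, r_cut=rc,
                               tail_correction=False, sample_interval=7,
                               max_displacement=0.3, seed=11)
        stats = run_nvt(system, params, settings)
        beta = 1.0 / (R_GAS * temp)

        def boltz(r):
            u = lj_energy(eps, sig, r)
            return math.exp(-beta * min(u, 700.0 / beta))

        num, _ = integrate.quad(
            lambda r: 4 * math.pi * r * r * lj_energy(eps, sig, r) * boltz(r),
            1e-4, rc, limit=300,
        )
        den, _ = integrate.quad(
            lambda r: 4 * math.pi * r * r * boltz(r), 1e-4, rc, limit=300
        )
        v_out = box**3 - 4.0 / 3.0 * math.pi * rc**3
        mean_exact = num / (den + v_out)
        sem = block_sem(stats.energies, 10)
        assert np.mean(stats.energies) == pytest.approx(
            mean_exact, abs=max(5.0 * sem, 0.02)
        )


class TestRunNptDensity:
    def test_ideal_gas_density(self):
        system = _ideal_system(n=256)
        settings = SimSettings(n_steps=30000, equil_steps=6000, r_cut=0.4,
                               tail_correction=False, sample_interval=10,
                               volume_move_freq=0.25, seed=21)
        rho, sem, stats = run_npt_density(system, _ideal_params(), settings)
        molar = rho / (40.0 / 1000.0)  # mol/m^3
        molar_sem = sem / (40.0 / 1000.0)
        ideal = 1e5 / (8.314462618 * 300.0)
        assert molar == pytest.approx(ideal, abs=3.0 * molar_sem + 0.01 * ideal)

    def test_seed_determinism(self):
        system = _ideal_system(n=32)
        settings = SimSettings(n_steps=5000, equil_steps=1000, r_cut=0.4,
                               sample_interval=20, volume_move_freq=0.3, seed=2)
        r1 = run_npt_density(system, _ideal_params(), settings)
        r2 = run_npt_density(system, _ideal_params(), settings)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_block_sem_matches_direct_formula(self, simple_params, mono_a):
        system = SystemSpec("liq", ((mono_a, 30, "solvent"),), temperature=300.0,
                            pressure=200.0, box_edge=1.3)
        settings = SimSettings(n_steps=8000, equil_steps=2000, r_cut=0.6,
                               sample_interval=10, seed=3, n_blocks=5)
        rho, sem, stats = run_npt_density(system, simple_params, settings)
        series = stats.densities[: len(stats.densities) - len(stats.densities) % 5]
        blocks = series.reshape(5, -1).mean(axis=1)
        expected = np.std(blocks, ddof=1) / math.sqrt(5)
        assert sem == pytest.approx(expected, rel=1e-12)

    def test_zero_pressure_rejected(self):
        system = SystemSpec("ig", _ideal_system(8).molecules, 300.0, pressure=0.0,
                            box_edge=3.0)
        settings = SimSettings(n_steps=100, equil_steps=10, r_cut=0.4)
        with pytest.raises(ValueError):
            run_npt_density(system, _ideal_params(), settings)


class TestWidom:
    def test_ideal_gas_insertion_is_zero(self, mono_a):
        system = SystemSpec("ig", _ideal_system(27, name="G").molecules, 300.0,
                            1.0, box_edge=3.0)
        params = _ideal_params()
        params.add_type(AtomTypeDef("A", 0.0, 0.3))
        settings = SimSettings(n_steps=2000, equil_steps=500, r_cut=1.2,
                               sample_interval=100, seed=4)
        stats = run_nvt(system, params, settings)
        mu = widom_mu_excess(stats, mono_a, params, settings, n_insertions=50)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_dilute_fluid_matches_virial_expansion(self):
        eps, sig, temp = 2.0, 0.34, 300.0
        params = ParameterSet()
        params.add_type(AtomTypeDef("V", eps, sig))
        mol = MoleculeSpec("V", (SiteSpec("V"),), molar_mass=40.0)
        n, box, rc = 20, 3.0, 1.2
        system = SystemSpec("gas", ((mol, n, "solvent"),), temperature=temp,
                            box_edge=box)
        settings = SimSettings(n_steps=60000, equil_steps=10000, r_cut=rc,
                               tail_correction=False, sample_interval=100,
                               max_displacement=0.4, seed=17)
        stats = run_nvt(system, params, settings)
        mu, sem = widom_mu_excess(stats, mol, params, settings,
                                  n_insertions=800, seed=5, full_output=True)
        beta = 1.0 / (R_GAS * temp)
        b2, _ = integrate.quad(
            lambda r: -2.0 * math.pi * r * r
            * (math.exp(-beta * min(lj_energy(eps, sig, r), 700.0 / beta)) - 1.0),
            1e-4, rc, limit=300,
        )
        rho = n / box**3
        mu_virial = 2.0 * rho * b2 / beta
        assert mu == pytest.approx(mu_virial, abs=max(4.0 * sem, 0.12))

    def test_seed_reproducibility(self, simple_params, mono_a, mono_b):
        system = SystemSpec("liq", ((mono_a, 20, "solvent"),), temperature=300.0,
                            box_edge=1.3)
        settings = SimSettings(n_steps=4000, equil_steps=1000, r_cut=0.6,
                               sample_interval=50, seed=9)
        stats = run_nvt(system, simple_params, settings)
        mu1 = widom_mu_excess(stats, mono_b, simple_params, settings, seed=3)
        mu2 = widom_mu_excess(stats, mono_b, simple_params, settings, seed=3)
        assert mu1 == mu2


class TestIncrementalEnergy:
    def test_running_total_does_not_drift(self, simple_params, mono_a):
        system = SystemSpec("liq", ((mono_a, 30, "solvent"),), temperature=300.0,
                            box_edge=1.3)
        settings = SimSettings(n_steps=100, equil_steps=0, r_cut=0.6,
                               tail_correction=False, max_displacement=0.1, seed=5)
        psys = build_particle_system(system, simple_params)
        engine = MCEngine(psys, 1.3, settings, np.random.default_rng(5))
        for _ in range(10000):
            engine.attempt_move()
        assert engine.energy == pytest.approx(engine.full_energy(), abs=1e-6)


class TestSettingsValidation:
    def test_step_ordering(self):
        with pytest.raises(ValueError):
            SimSettings(n_steps=10, equil_steps=10)

    def test_block_count(self):
        with pytest.raises(ValueError):
            SimSettings(n_blocks=1)
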