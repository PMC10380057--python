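import numpy as np
import pytest

from tnkit import (
    DescriptorSpec,
    Macrostate,
    MacrostateSpec,
    abeta_like_spec,
    autocorrelation,
    build_transition_matrix,
    compute_descriptors,
    detect_communities,
    fit_stretched_exponential,
    generate_hbond_traces,
    generate_markov_series,
    generate_water_configuration,
    orientational_order,
    project_trajectory,
    realize_trajectory,
    stationary_distribution,
    summarize_communities,
)
from tnkit.descriptors import dihedral_angle
from tnkit.synthetic_data import GeometryEngine


class TestMarkov:
    def test_identity_matrix_freezes_the_chain(self):
        s = generate_markov_series(np.eye(3), 50, seed=0)
        assert len(set(s)) == 1

    def test_symmetric_two_state_frequencies(self):
        P = np.full((2, 2), 0.5)
        s = generate_markov_series(P, 100_000, seed=1)
        trans = np.zeros((2, 2))
        np.add.at(trans, (s[:-1], s[1:]), 1)
        freq = trans / trans.sum(axis=1, keepdims=True)
        assert np.abs(freq - 0.5).max() < 0.01

    def test_seed_reproducibility(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        a = generate_markov_series(P, 500, seed=7)
        b = generate_markov_series(P, 500, seed=7)
        assert np.array_equal(a, b)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            generate_markov_series(np.array([[0.5, 0.2], [0.3, 0.7]]), 10, seed=0)

    def test_stationary_distribution_of_detailed_balance_matrix(self):
        spec = abeta_like_spec()
        pi = stationary_distribution(spec.transition_matrix)
        assert pi == pytest.approx([0.6, 0.3, 0.1], abs=1e-12)


class TestGeometryEngine:
    def test_bonded_distances_match_ideals(self, engine):
        coords = engine.build_backbone([-70.0] * 6, [140.0] * 6)
        for r in range(6):
            n_i, ca_i, c_i = coords[3 * r], coords[3 * r + 1], coords[3 * r + 2]
            assert np.linalg.norm(ca_i - n_i) == pytest.approx(engine.bond_n_ca, abs=1e-3)
            assert np.linalg.norm(c_i - ca_i) == pytest.approx(engine.bond_ca_c, abs=1e-3)
            if r < 5:
                assert np.linalg.norm(coords[3 * r + 3] - c_i) == pytest.approx(
                    engine.bond_c_n, abs=1e-3
                )

    def test_rebuild_from_measured_dihedrals_is_rigid_motion(self, engine):
        """Measuring (φ, ψ) off a built chain and rebuilding reproduces the
        chain up to rigid-body motion (RMSD < 1e-3 Å)."""
        rng = np.random.default_rng(3)
        phi = rng.uniform(-150, -50, 10)
        psi = rng.uniform(-60, 150, 10)
        coords = engine.build_backbone(phi, psi)
        phi_m = np.full(10, np.nan)
        psi_m = np.full(10, np.nan)
        for r in range(10):
            if r > 0:
                phi_m[r] = dihedral_angle(
                    coords[3 * r - 1], coords[3 * r], coords[3 * r + 1], coords[3 * r + 2]
                )
            if r < 9:
                psi_m[r] = dihedral_angle(
                    coords[3 * r], coords[3 * r + 1], coords[3 * r + 2], coords[3 * r + 3]
                )
        phi_m[0], psi_m[-1] = phi[0], psi[-1]  # unused by the builder
        rebuilt = engine.build_backbone(phi_m, psi_m)
        # Kabsch superposition
        a = coords - coords.mean(axis=0)
        b = rebuilt - rebuilt.mean(axis=0)
        u, _, vt = np.linalg.svd(a.T @ b)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1, 1, d]) @ vt
        rmsd = np.sqrt(((a - b @ rot.T) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-3


class TestRealizedTrajectories:
    def test_pure_helix_macrostate_is_strongly_helical(self):
        helix = Macrostate.from_pattern("helix", "H" * 42)
        spec = MacrostateSpec([helix], np.ones((1, 1)), n_frames=25, seed=2)
        ens, _ = realize_trajectory(spec)
        for f in range(ens.n_frames):
            na, nb, _ = compute_descriptors(ens, f)
            assert na >= 30

    def test_hairpin_beats_coil_in_compactness(self):
        """Hairpin frames: Nβ ≥ 8 and dNC below every coil frame's dNC."""
        spec = abeta_like_spec(n_frames=60, seed=5)
        ens, truth = realize_trajectory(spec)
        dnc = {0: [], 2: []}
        for f in range(ens.n_frames):
            na, nb, d = compute_descriptors(ens, f)
            if truth[f] == 2:
                assert nb >= 8
                dnc[2].append(d)
            elif truth[f] == 0:
                dnc[0].append(d)
        if dnc[2] and dnc[0]:
            assert max(dnc[2]) < min(dnc[0])

    def test_descriptor_pipeline_recovers_macrostate_boundaries(self):
        spec = abeta_like_spec(n_frames=150, seed=9)
        ens, truth = realize_trajectory(spec)
        series = project_trajectory(ens)
        # every descriptor state must be visited by exactly one macrostate
        for s in range(series.n_states):
            owners = set(truth[series.states == s])
            assert len(owners) == 1

    def test_seed_reproducibility(self):
        e1, t1 = realize_trajectory(abeta_like_spec(n_frames=20, seed=3))
        e2, t2 = realize_trajectory(abeta_like_spec(n_frames=20, seed=3))
        assert np.array_equal(e1.frames, e2.frames)
        assert np.array_equal(t1, t2)


class TestWaterConfigurations:
    def test_diamond_lattice_is_perfectly_tetrahedral(self):
        coords, box = generate_water_configuration("diamond_lattice", 512, seed=0)
        op = orientational_order(coords, box)
        assert np.abs(op.q_values - 1.0).max() < 1e-10

    def test_ideal_gas_mean_q_near_zero(self):
        coords, box = generate_water_configuration("ideal_gas", 10_000, seed=1)
        op = orientational_order(coords, box)
        assert abs(op.Q) < 0.01

    def test_disorder_grows_with_jitter(self):
        qs = []
        for sigma in (0.0, 0.1, 0.25, 0.5):
            coords, box = generate_water_configuration(
                "perturbed_lattice", 512, jitter_sigma=sigma, seed=6
            )
            qs.append(orientational_order(coords, box).Q)
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_lattice_size_rounded_to_unit_cells(self, caplog):
        with caplog.at_level("WARNING", logger="tnkit"):
            coords, _ = generate_water_configuration("diamond_lattice", 600, seed=0)
        assert len(coords) == 512
        assert any("8·m³" in r.message for r in caplog.records)


class TestHbondTraces:
    def test_same_seed_identical(self):
        a = generate_hbond_traces(20, 300, seed=4)
        b = generate_hbond_traces(20, 300, seed=4)
        assert np.array_equal(a.h, b.h)

    def test_on_fraction_matches_renewal_reward(self):
        """Long-run on-fraction ≈ E[on]/(E[on]+E[off]) with E[on] = τ·Γ(1+1/β)."""
        from scipy.special import gamma

        beta, tau, off = 0.7, 10.0, 40.0
        tr = generate_hbond_traces(400, 4000, dt=0.5, on_shape=beta, on_scale=tau,
                                   off_scale=off, seed=8)
        expected = tau * gamma(1 + 1 / beta) / (tau * gamma(1 + 1 / beta) + off)
        # discrete sampling clips sub-frame episodes, so allow a few percent
        assert tr.h.mean() == pytest.approx(expected, abs=0.04)

    def test_exponential_limit_fits_beta_one(self):
        tr = generate_hbond_traces(300, 2000, dt=0.5, on_shape=1.0, on_scale=10.0,
                                   off_scale=1000.0, seed=0)
        c = autocorrelation(tr, 500, origins="formation")
        fit = fit_stretched_exponential(c, 0.5)
        assert fit.beta > 0.9


def test_end_to_end_macrostate_population_recovery():
    """Community populations of the transition network built on a synthetic
    three-macrostate run match the generating chain's empirical macrostate
    fractions within 0.02 (community → macrostate by majority vote)."""
    spec = abeta_like_spec(n_frames=1200, seed=17)
    ens, truth = realize_trajectory(spec)
    series = project_trajectory(ens)
    net = build_transition_matrix(series, ens.segments)
    detect_communities(net, seed=0)
    df = summarize_communities(net, series)
    frame_comm = np.array([net.communities[s] for s in series.states])
    recovered = np.zeros(3)
    for comm in df.index:
        mask = frame_comm == comm
        majority = np.bincount(truth[mask]).argmax()
        recovered[majority] += df.loc[comm, "population_fraction"]
    empirical = np.bincount(truth, minlength=3) / len(truth)
    assert np.abs(recovered - empirical).max() <= 0.02
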