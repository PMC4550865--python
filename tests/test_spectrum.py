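"""Eigensystem, Boltzmann weighting, spectrum normalization."""

import numpy as np
import pytest

import holespec as hs
from tests.conftest import random_duplex_sequence

EPS = {"G": 7.75, "C": 8.87, "A": 8.24, "T": 9.14}


def _spectrum_for(bases, kBT=0.047, **params):
    dup = hs.build_duplex(hs.BaseSequence(bases))
    es = hs.diagonalize(hs.build_hamiltonian(dup, hs.ModelParams(**params)))
    return es, hs.hole_spectrum(es, kBT)


def _oracle_probabilities(bases, kBT, t_par=1.0, t_perp=0.5, periodic=True):
    """Brute-force reference: assemble the ladder as an explicit edge list
    and Boltzmann-average with plain numpy."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(bases)
    sites = [(m, c) for c in (0, 1) for m in range(n)]
    chain = {0: bases, 1: "".join(comp[b] for b in bases)}
    h = np.zeros((2 * n, 2 * n))
    for k, (m, c) in enumerate(sites):
        h[k, k] = EPS[chain[c][m]]
    edges = []
    for c in (0, 1):
        edges += [((m, c), (m + 1, c), t_par) for m in range(n - 1)]
        if periodic:
            edges.append(((0, c), (n - 1, c), t_par))
    edges += [((m, 0), (m, 1), t_perp) for m in range(n)]
    idx = {s: k for k, s in enumerate(sites)}
    for a, b, t in edges:
        h[idx[a], idx[b]] = h[idx[b], idx[a]] = t
    e, v = np.linalg.eigh(h)
    w = np.exp(-(e - e[0]) / kBT)
    w /= w.sum()
    p = (v**2) @ w
    out = np.empty((n, 2))
    for (m, c), k in idx.items():
        out[m, c] = p[k]
    return out


def test_diagonalize_completeness_and_norms():
    es, _ = _spectrum_for("GAT")
    assert es.n_states == 6
    assert np.all(np.diff(es.energies) >= 0)
    norms = es.densities.sum(axis=(1, 2))
    assert np.allclose(norms, 1.0, atol=1e-10)


def test_diagonalize_rejects_asymmetric():
    ham = hs.build_hamiltonian(hs.build_duplex(hs.BaseSequence("GAT")))
    ham.matrix[0, 1] = 123.0  # break symmetry on purpose
    with pytest.raises(ValueError, match="not symmetric"):
        hs.diagonalize(ham)


def test_decoupled_limit_recovers_on_site_energies():
    es, _ = _spectrum_for("GATC", t_par=0.0, t_perp=0.0, periodic=False)
    onsite = sorted(EPS[b] for b in "GATC") + sorted(EPS[b] for b in "CTAG")
    assert np.allclose(es.energies, sorted(onsite), atol=1e-12)
    # each eigenvector is a unit site vector
    assert np.allclose(np.sort(es.densities.max(axis=(1, 2))), 1.0)


def test_nd1_has_1912_states(nd1_spectrum):
    es, _ = nd1_spectrum
    assert es.n_states == 1912


class TestBoltzmannWeights:
    def test_two_level_closed_form(self):
        es, _ = _spectrum_for("GAT")
        fake = hs.EigenSystem(
            energies=np.array([0.0, 0.047]),
            densities=es.densities[:2],
            start=1, periodic=True)
        w = hs.boltzmann_weights(fake, kBT=0.047)
        z = 1 + np.exp(-1)
        assert w == pytest.approx([1 / z, np.exp(-1) / z], abs=1e-12)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_degenerate_doublet_splits_evenly(self):
        es, _ = _spectrum_for("GAT")
        fake = hs.EigenSystem(
            energies=np.array([1.5, 1.5]),
            densities=es.densities[:2],
            start=1, periodic=True)
        assert hs.boltzmann_weights(fake, 0.01) == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_and_decrease(self, nd1_spectrum):
        es, spec = nd1_spectrum
        w = spec.weights
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(w) <= 1e-15)

    def test_infinite_temperature_equal_weights(self):
        es, _ = _spectrum_for("GATCC")
        w = hs.boltzmann_weights(es, kBT=1e9)
        assert np.allclose(w, 1 / es.n_states, atol=1e-10)

    def test_nonpositive_kbt_rejected(self):
        es, _ = _spectrum_for("GAT")
        for bad in (0.0, -0.047):
            with pytest.raises(ValueError):
                hs.boltzmann_weights(es, bad)


class TestHoleSpectrum:
    def test_probability_conservation(self, nd1_spectrum):
        _, spec = nd1_spectrum
        assert spec.P.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(spec.P >= 0)

    def test_infinite_temperature_uniform_by_completeness(self):
        es, _ = _spectrum_for("GATTACAGC")
        spec = hs.hole_spectrum(es, kBT=1e7)
        assert np.abs(spec.P - 1 / (2 * es.n_sites)).max() < 1e-8

    def test_zero_temperature_ground_state_density(self, rng):
        bases = random_duplex_sequence(rng, 21)
        es, _ = _spectrum_for(bases)
        gap = es.energies[1] - es.energies[0]
        assert gap > 1e-6  # generic sequence: unique ground state
        spec = hs.hole_spectrum(es, kBT=1e-6)
        assert np.abs(spec.P - es.densities[0]).max() < 1e-8

    def test_uniform_poly_g_duplex_is_flat_with_l_excess(self):
        es, spec = _spectrum_for("G" * 12)
        for c in (0, 1):
            col = spec.P[:, c]
            assert np.ptp(col) < 1e-10  # translation symmetry
        # holes prefer the guanine chain (lower on-site energy)
        assert spec.strand("L").mean() > spec.strand("H").mean()

    def test_planted_guanine_traps_the_hole(self):
        k = 48  # 1-based position of the lone G in a poly-A ring
        bases = "A" * (k - 1) + "G" + "A" * (101 - k)
        es, spec = _spectrum_for(bases)
        m, c = np.unravel_index(np.argmax(spec.P), spec.P.shape)
        assert (m + 1, c) == (k, 0)

    @pytest.mark.parametrize("n", [8, 23, 64])
    def test_matches_dense_oracle_on_random_duplexes(self, rng, n):
        bases = random_duplex_sequence(rng, n)
        _, spec = _spectrum_for(bases)
        assert np.abs(spec.P - _oracle_probabilities(bases, 0.047)).max() < 1e-8

    def test_g_run_hosts_top_peak(self):
        bases = "A" * 40 + "GGG" + "A" * 40
        es, spec = _spectrum_for(bases)
        track = hs.normalize_track(spec, "L_only")
        top = hs.top_k_peaks(track, "L", 1)[0]
        assert 41 <= top.position <= 43


class TestNormalizeTrack:
    def test_both_strands_mean_is_one(self, nd1_tracks):
        track = nd1_tracks["both"]
        assert track.values.mean() == pytest.approx(1.0, abs=1e-10)
        assert track.baseline == pytest.approx(1 / 1912, rel=1e-10)

    @pytest.mark.parametrize("mode,strand", [("L_only", "L"), ("H_only", "H")])
    def test_single_strand_baseline_mean_is_one(self, nd1_tracks, mode, strand):
        track = nd1_tracks[strand]
        assert track.mode == mode
        assert track.strand(strand).mean() == pytest.approx(1.0, abs=1e-10)

    def test_two_to_one_strand_imbalance(self):
        """P_L uniformly twice P_H gives N_L = 4/3, N_H = 2/3 under the
        both-strand baseline."""
        n = 5
        p = np.empty((n, 2))
        p[:, 0] = 2 / (3 * n)
        p[:, 1] = 1 / (3 * n)
        spec = hs.HoleSpectrum(P=p, kBT=0.047, start=1, periodic=True,
                               weights=np.ones(2 * n) / (2 * n))
        track = hs.normalize_track(spec, "both_strands")
        assert np.allclose(track.strand("L"), 4 / 3)
        assert np.allclose(track.strand("H"), 2 / 3)

    def test_unknown_mode_rejected(self, nd1_spectrum):
        with pytest.raises(ValueError):
            hs.normalize_track(nd1_spectrum[1], "Z_only")
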