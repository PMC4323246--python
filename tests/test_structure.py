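"""Structural checks: geometry oracles, rigid-transform invariance, ranking."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import burial_bruteforce, count_cross_chain_polar_bruteforce

from exomefunnel.simulate import make_synthetic_trimer
from exomefunnel.structure import (
    Chain,
    RmsdSeries,
    TrimerModel,
    assess_convergence,
    c_terminus_exposed,
    count_polar_interface_contacts,
    kabsch,
    rank_models,
    read_trimer_pdb,
    residue_rmsd_series,
    write_trimer_pdb,
)


def _rigid_copy(model, rng):
    rot = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31))))
    r = rot.as_matrix()
    t = rng.uniform(-50, 50, size=3)
    chains = tuple(
        Chain(
            chain_id=c.chain_id,
            res_ids=c.res_ids.copy(),
            res_names=c.res_names.copy(),
            atom_names=c.atom_names.copy(),
            elements=c.elements.copy(),
            coords=c.coords @ r.T + t,
            c_term_index=c.c_term_index,
        )
        for c in model.chains
    )
    return TrimerModel(chains=chains, external_score=model.external_score, name=model.name)


def _plain_chains(model):
    return [(list(c.elements), c.coords) for c in model.chains]


def _ca_positions(model):
    out = []
    for c in model.chains:
        sel = (c.res_ids == c.c_term_index) & (c.atom_names == "CA")
        out.append(c.coords[np.nonzero(sel)[0][0]])
    return out


class TestExposure:
    def test_outward_c_termini_exposed(self):
        m, truth = make_synthetic_trimer(preset="exposed", seed=1)
        assert c_terminus_exposed(m) == (True, True, True)
        assert truth["exposed"]

    def test_dense_core_c_termini_buried(self):
        m, truth = make_synthetic_trimer(preset="buried", seed=1)
        assert c_terminus_exposed(m) == (False, False, False)
        assert not truth["exposed"]

    def test_missing_c_terminal_ca_raises(self):
        m, _ = make_synthetic_trimer(seed=2)
        c0 = m.chains[0]
        names = c0.atom_names.copy()
        names[(c0.res_ids == c0.c_term_index) & (names == "CA")] = "CB"
        bad = TrimerModel(
            chains=(
                Chain(c0.chain_id, c0.res_ids, c0.res_names, names, c0.elements,
                      c0.coords, c0.c_term_index),
                m.chains[1],
                m.chains[2],
            )
        )
        with pytest.raises(ValueError, match="CA"):
            c_terminus_exposed(bad)

    def test_verdicts_equal_bruteforce_distance_count(self, rng):
        for seed in range(30):
            preset = "exposed" if seed % 2 == 0 else "buried"
            m, _ = make_synthetic_trimer(
                preset=preset, n_residues=int(rng.integers(10, 25)),
                noise=float(rng.uniform(0, 1.0)), seed=seed,
            )
            got = list(c_terminus_exposed(m))
            want = burial_bruteforce(_plain_chains(m), _ca_positions(m))
            assert got == want


class TestPolarContacts:
    def test_planted_pairs_counted_exactly(self):
        m, truth = make_synthetic_trimer(preset="exposed", n_polar_pairs=5, seed=3)
        assert count_polar_interface_contacts(m) == truth["n_polar_pairs"] == 5

    def test_pair_beyond_cutoff_not_counted(self):
        m, _ = make_synthetic_trimer(preset="exposed", n_polar_pairs=2,
                                     polar_distance=4.0, seed=4)
        assert count_polar_interface_contacts(m, cutoff=3.5) == 0
        assert count_polar_interface_contacts(m, cutoff=4.1) == 2

    def test_unknown_element_warned_and_skipped(self):
        m, _ = make_synthetic_trimer(preset="exposed", n_polar_pairs=1, seed=5)
        c0 = m.chains[0]
        elements = c0.elements.copy()
        elements[-1] = "Xx"  # the planted N atom of the pair
        patched = TrimerModel(
            chains=(
                Chain(c0.chain_id, c0.res_ids, c0.res_names, c0.atom_names,
                      elements, c0.coords, c0.c_term_index),
                m.chains[1],
                m.chains[2],
            )
        )
        with pytest.warns(UserWarning, match="unknown element"):
            assert count_polar_interface_contacts(patched) == 0

    def test_counts_equal_bruteforce_pairs(self, rng):
        for seed in range(20):
            m, _ = make_synthetic_trimer(
                preset="exposed", n_polar_pairs=int(rng.integers(0, 6)),
                ring_radius=float(rng.uniform(12, 25)), noise=0.3, seed=seed,
            )
            assert count_polar_interface_contacts(m) == (
                count_cross_chain_polar_bruteforce(_plain_chains(m))
            )


class TestRigidInvariance:
    def test_exposure_contacts_invariant_under_rigid_transforms(self, rng):
        m, _ = make_synthetic_trimer(preset="exposed", n_polar_pairs=3, seed=6)
        base_exp = c_terminus_exposed(m)
        base_cnt = count_polar_interface_contacts(m)
        for _ in range(5):
            moved = _rigid_copy(m, rng)
            assert c_terminus_exposed(moved) == base_exp
            assert count_polar_interface_contacts(moved) == base_cnt

    def test_rmsd_zero_after_superposition_on_rigidly_moved_frame(self, rng):
        m, _ = make_synthetic_trimer(seed=7)
        coords = np.vstack([c.coords for c in m.chains])
        moved = _rigid_copy(m, rng)
        frame = np.vstack([c.coords for c in moved.chains])
        idx = np.arange(len(coords))
        series = residue_rmsd_series(frame[None], coords, idx, idx)
        assert series.values[0] == pytest.approx(0.0, abs=1e-6)


class TestRanking:
    def _models(self, n, rng, distinct=True):
        models = []
        scores = rng.permutation(n).astype(float) if distinct else rng.integers(0, 3, n)
        for i in range(n):
            m, _ = make_synthetic_trimer(
                preset="exposed", n_polar_pairs=int(rng.integers(0, 4)),
                seed=100 + i, external_score=float(scores[i]), name=f"m{i}",
            )
            models.append(m)
        return models

    def test_shortlist_size_is_ceil_of_fraction(self, rng):
        models = self._models(40, rng)
        entries = rank_models(models, top_fraction=0.1)
        assert len(entries) == 4  # all exposed, ceil(0.1 * 40)

    def test_all_buried_yields_empty_shortlist_with_warning(self):
        models = [
            make_synthetic_trimer(preset="buried", seed=s, external_score=float(s))[0]
            for s in range(5)
        ]
        with pytest.warns(UserWarning, match="buried"):
            assert rank_models(models, top_fraction=1.0) == []

    def test_missing_score_raises(self):
        m, _ = make_synthetic_trimer(seed=8)
        with pytest.raises(ValueError, match="score"):
            rank_models([m])

    def test_permutation_invariance_with_distinct_scores(self, rng):
        models = self._models(30, rng, distinct=True)
        ref = [e.model.name for e in rank_models(models, top_fraction=0.5)]
        for _ in range(5):
            perm = list(rng.permutation(len(models)))
            shuffled = [models[i] for i in perm]
            got = [e.model.name for e in rank_models(shuffled, top_fraction=0.5)]
            assert got == ref

    def test_ordering_by_score_then_contacts(self, rng):
        models = self._models(20, rng)
        entries = rank_models(models, top_fraction=1.0)
        keys = [(e.score, -e.polar_contacts) for e in entries]
        assert keys == sorted(keys)


class TestRmsdSeries:
    def test_identical_frame_gives_zero(self):
        ref = np.random.default_rng(0).normal(size=(30, 3))
        idx = np.arange(30)
        s = residue_rmsd_series(ref[None], ref, idx, idx)
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_atom_displaced_two_angstrom(self):
        # rigid scaffold held fixed; one distant target atom moved 2 A
        rng = np.random.default_rng(1)
        scaffold = rng.normal(size=(40, 3)) * 5
        target = np.array([[30.0, 0.0, 0.0]])
        ref = np.vstack([scaffold, target])
        frame = ref.copy()
        frame[-1] += np.array([0.0, 2.0, 0.0])
        s = residue_rmsd_series(frame[None], ref, np.array([40]), np.arange(40))
        assert s.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_atom_count_mismatch_raises(self):
        ref = np.zeros((10, 3))
        with pytest.raises(ValueError, match="mismatch"):
            residue_rmsd_series(np.zeros((2, 9, 3)), ref, np.arange(3), np.arange(3))

    def test_kabsch_recovers_random_rotations(self, rng):
        pts = rng.normal(size=(25, 3))
        for _ in range(10):
            r = Rotation.random(
                random_state=np.random.RandomState(int(rng.integers(2**31)))
            ).as_matrix()
            t = rng.uniform(-10, 10, size=3)
            moved = pts @ r.T + t
            rot, trans = kabsch(moved, pts)
            back = moved @ rot.T + trans
            assert np.allclose(back, pts, atol=1e-8)


class TestConvergence:
    def test_constant_series_converges_at_its_level(self):
        s = RmsdSeries(np.arange(40.0), np.full(40, 5.0))
        res = assess_convergence(s)
        assert res.converged and res.mean == pytest.approx(5.0)

    def test_wide_oscillation_does_not_converge(self):
        vals = 5.0 + 2.0 * np.sin(np.arange(60) * 1.3)  # wanders across 3-7
        res = assess_convergence(RmsdSeries(np.arange(60.0), np.clip(vals, 3, 7)))
        assert not res.converged and res.spread > 1.0

    def test_too_few_frames_raises(self):
        s = RmsdSeries(np.arange(12.0), np.full(12, 5.0))
        with pytest.raises(ValueError, match="frames"):
            assess_convergence(s, window_fraction=0.5)

    def test_verdict_monotone_in_spread_tolerance(self, rng):
        vals = 5.0 + rng.normal(0, 0.4, size=80).cumsum() * 0.05
        vals = np.abs(vals)
        s = RmsdSeries(np.arange(80.0), vals)
        verdicts = [assess_convergence(s, spread_tol=tol).converged
                    for tol in (0.1, 0.5, 1.0, 2.0, 5.0)]
        assert verdicts == sorted(verdicts)

    def test_ar1_series_match_direct_window_recomputation(self, rng):
        for _ in range(10):
            n = int(rng.integers(30, 100))
            phi = float(rng.uniform(0.5, 0.99))
            x = np.empty(n)
            x[0] = 5.0
            for i in range(1, n):
                x[i] = 5.0 + phi * (x[i - 1] - 5.0) + float(rng.normal(0, 0.3))
            x = np.abs(x)
            s = RmsdSeries(np.arange(float(n)), x)
            res = assess_convergence(s, window_fraction=0.5, spread_tol=1.0)
            w = math.ceil(0.5 * n)
            window = x[-w:]
            assert res.spread == pytest.approx(window.max() - window.min())
            assert res.converged == (window.max() - window.min() <= 1.0)
            assert res.mean == pytest.approx(window.mean())


class TestPdbIO:
    def test_trimer_pdb_round_trip(self, tmp_path):
        m, _ = make_synthetic_trimer(preset="exposed", n_polar_pairs=2, seed=9)
        path = tmp_path / "trimer.pdb"
        write_trimer_pdb(m, path)
        back = read_trimer_pdb(path, external_score=-12.5)
        assert len(back.chains) == 3
        assert back.external_score == -12.5
        # geometry-derived verdicts survive the round trip
        assert count_polar_interface_contacts(back) == 2
        assert c_terminus_exposed(
            back, max_neighbors=10
        ) == c_terminus_exposed(m, max_neighbors=10) == (True, True, True)
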