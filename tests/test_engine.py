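"""Simulation engine: life cycle, conservation laws, determinism, oracle."""

import numpy as np
import pytest

from kinsim._match import match_loop, match_loop_py
from kinsim.engine import (age_and_cull, initialize_world, match_marriages,
                           reproduce, run_simulation, split_and_select, step)
from kinsim.params import ModelParams

from conftest import make_society


class TestInitializeWorld:
    def test_layout_and_zero_vectors(self):
        params = ModelParams(N_s=3, N_f=5)
        world = initialize_world(params)
        assert len(world.societies) == 3
        for soc in world.societies:
            assert soc.n == 5
            assert not soc.extinct
            np.testing.assert_array_equal(soc.t, 0.0)
            np.testing.assert_array_equal(soc.p, 0.0)
            assert soc.pending.all()
        ids = np.concatenate([s.family_id for s in world.societies])
        assert len(np.unique(ids)) == 15

    def test_same_seed_gives_identical_worlds(self):
        params = ModelParams(N_s=2, N_f=4, seed=9)
        a, b = initialize_world(params), initialize_world(params)
        assert a.rng.bit_generator.state == b.rng.bit_generator.state


class TestMatchLoopImplementations:
    def test_numba_and_python_agree_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            n_men = int(rng.integers(0, 30))
            man_fams = rng.integers(0, n, n_men)
            u = rng.random(n_men)
            W = np.exp(-rng.random((n, n)) * 5)
            women = rng.integers(0, 4, n)
            g1, b1 = match_loop(man_fams, u, W, women)
            g2, b2 = match_loop_py(man_fams, u, W, women)
            np.testing.assert_array_equal(g1, g2)
            np.testing.assert_array_equal(b1, b2)

    def test_underflow_falls_back_to_uniform_choice(self):
        W = np.zeros((2, 2))
        g, b = match_loop_py(np.array([0]), np.array([0.9]), W,
                             np.array([1, 1], np.int64))
        assert len(g) == 1 and b[0] == 1  # 0.9 * 2 -> family index 1


class TestReproduce:
    def test_poisson_mean_without_selection(self, rng):
        params = ModelParams(d_c=0.0, d_m=0.0, b=5.0)
        soc = make_society(np.zeros((400, 2)), np.zeros((400, 2)),
                           pending=np.ones(400, bool))
        reproduce(soc, params, rng)
        mean = soc.men[:, 0].mean()
        se = np.sqrt(5.0 / 400)
        assert abs(mean - 5.0) < 3 * se

    def test_mean_reduced_by_competition_when_all_identical(self, rng):
        params = ModelParams(d_c=2.0, d_m=0.8, b=5.0)
        counts = []
        for _ in range(10):
            soc = make_society(np.zeros((200, 2)), np.zeros((200, 2)),
                               pending=np.ones(200, bool))
            reproduce(soc, params, rng)  # friend = rival = 1
            counts.append(soc.men[:, 0])
        mean = np.concatenate(counts).mean()
        expect = 5.0 * np.exp(-0.8)
        assert abs(mean - expect) < 3 * np.sqrt(expect / 2000)

    def test_men_and_women_uncorrelated(self, rng):
        params = ModelParams(d_c=0.0, d_m=0.0, b=5.0)
        men, women = [], []
        for _ in range(25):
            soc = make_society(np.zeros((400, 2)), np.zeros((400, 2)),
                               pending=np.ones(400, bool))
            reproduce(soc, params, rng)
            men.append(soc.men[:, 0])
            women.append(soc.women[:, 0])
        corr = np.corrcoef(np.concatenate(men), np.concatenate(women))[0, 1]
        assert abs(corr) < 0.05

    def test_only_pending_families_reproduce(self, rng):
        params = ModelParams()
        soc = make_society(np.zeros((4, 2)), np.zeros((4, 2)),
                           pending=[True, False, True, False])
        reproduce(soc, params, rng)
        assert soc.men[1].sum() == 0 and soc.men[3].sum() == 0
        assert not soc.pending.any()


class TestMatchMarriages:
    def test_single_family_marries_itself(self, rng):
        params = ModelParams()
        soc = make_society([[0, 0]], [[0, 0]], men=[[1, 0]], women=[[1, 0]])
        block = match_marriages(soc, params, rng, id_start=100)
        assert block is not None and len(block) == 1
        assert soc.n == 2 and soc.pending[1]
        assert soc.men.sum() == 0 and soc.women.sum() == 0

    def test_marriages_bounded_by_scarcer_sex(self, rng):
        params = ModelParams()
        soc = make_society(np.zeros((6, 2)), np.zeros((6, 2)),
                           men=np.tile([3, 0], (6, 1)),
                           women=np.tile([1, 0], (6, 1)))
        block = match_marriages(soc, params, rng, id_start=0)
        assert len(block) <= 6  # 6 women total, 18 men

    def test_offers_follow_preference_weights(self, rng):
        """Bride family whose p equals the groom trait wins ~ always."""
        params = ModelParams()
        chosen = []
        for _ in range(2000):
            soc = make_society(
                t=[[0, 0], [50, 50], [60, 60]],
                p=[[99, 99], [0, 0], [10, 10]],  # family 1 matches groom t
                men=[[1, 0], [0, 0], [0, 0]],
                women=[[0, 0], [5, 0], [5, 0]],
            )
            block = match_marriages(soc, params, rng, id_start=0)
            if block is not None:
                chosen.append(block._brides[0])
        frac = np.mean(np.array(chosen) == 1)
        assert frac > 0.99

    def test_child_inherits_paternal_and_maternal_components(self, rng):
        # bride family's preference sits exactly on the groom trait, the
        # groom family's own preference is far away: offer goes to family 1
        params = ModelParams(mu=0.0)
        soc = make_society(t=[[1, 9], [3, 4]], p=[[50, 60], [1, 9]],
                           men=[[1, 0], [0, 0]], women=[[0, 0], [1, 0]])
        block = match_marriages(soc, params, rng, id_start=7)
        assert len(block) == 1
        g, b = block._grooms[0], block._brides[0]
        assert (g, b) == (0, 1)
        np.testing.assert_array_equal(soc.t[2], [1, 4])   # (t1 groom, t2 bride)
        np.testing.assert_array_equal(soc.p[2], [50, 9])  # (p1 groom, p2 bride)
        assert block.child_id[0] == 7

    def test_no_men_no_marriages(self, rng):
        soc = make_society([[0, 0]], [[0, 0]], women=[[3, 0]])
        assert match_marriages(soc, ModelParams(), rng) is None


class TestAgeAndCull:
    def test_aging_and_lifespan_death(self):
        params = ModelParams(unmarried_lifespan=2)
        soc = make_society(np.zeros((3, 2)), np.zeros((3, 2)),
                           men=[[2, 1], [0, 1], [0, 0]],
                           women=[[0, 0], [0, 0], [0, 0]],
                           pending=[False, False, True])
        age_and_cull(soc, params)
        # family 0: 2 age-0 men -> age 1; its age-1 man died
        assert soc.n == 2
        np.testing.assert_array_equal(soc.men[0], [0, 2])
        # family 1 lost its only member and was dropped; pending family 2 kept
        assert soc.pending[1]

    def test_emptied_society_flagged_extinct(self):
        params = ModelParams(unmarried_lifespan=2)
        soc = make_society([[0, 0]], [[0, 0]], men=[[0, 1]])
        age_and_cull(soc, params)
        assert soc.extinct


class TestSplitAndSelect:
    def _world_with_oversized(self, seed=0, n_fam=10):
        params = ModelParams(N_s=4, N_f=5, seed=seed)
        world = initialize_world(params)
        big = make_society(np.zeros((n_fam, 2)), np.zeros((n_fam, 2)),
                           pending=np.ones(n_fam, bool))
        world.societies[0] = big
        return params, world

    def test_no_threshold_no_change(self):
        params = ModelParams(N_s=3, N_f=5, seed=1)
        world = initialize_world(params)
        before = [s.society_id for s in world.societies]
        split_and_select(world, params, world.rng)
        assert [s.society_id for s in world.societies] == before

    def test_split_conserves_families_and_society_count(self):
        params, world = self._world_with_oversized(n_fam=11)
        total_before = world.total_families()
        split_and_select(world, params, world.rng)
        assert len(world.societies) == 4
        # halves of 11 differ by one; the victim was one of the originals
        assert sorted(s.n for s in world.societies) == [5, 5, 5, 6]
        assert world.total_families() == total_before - 5  # one victim removed

    def test_removal_victim_uniform_over_other_societies(self):
        counts = {1: 0, 2: 0, 3: 0}
        n_rep = 3000
        for seed in range(n_rep):
            params, world = self._world_with_oversized(seed=seed)
            survivors_before = {id(s): s.society_id for s in world.societies}
            ids_before = [s.society_id for s in world.societies[1:]]
            split_and_select(world, params, np.random.default_rng(seed))
            ids_after = [s.society_id for s in world.societies]
            gone = set(ids_before) - set(ids_after)
            assert len(gone) == 1
            counts[gone.pop()] += 1
        for c in counts.values():
            p = c / n_rep
            assert abs(p - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n_rep)


class TestStep:
    def test_society_count_and_size_invariants(self):
        params = ModelParams(N_s=5, N_f=8, d_c=0.3, d_m=0.5, n_steps=0, seed=3)
        world = initialize_world(params)
        for _ in range(15):
            step(world, params)
            assert len(world.societies) == 5
            for soc in world.societies:
                assert soc.n < params.split_threshold

    def test_fused_step_matches_standalone_phases(self):
        """One engine step equals reproduce/match/cull/split called in
        sequence with an identically seeded generator."""
        params = ModelParams(N_s=3, N_f=4, d_c=0.4, d_m=0.6, seed=21)
        w1 = initialize_world(params)
        for _ in range(3):
            step(w1, params)
        w2 = initialize_world(params)
        for _ in range(3):
            nf = w2.next_family_id
            for soc in w2.societies:
                if soc.extinct:
                    continue
                reproduce(soc, params, w2.rng)
                blk = match_marriages(soc, params, w2.rng, id_start=nf)
                if blk is not None:
                    soc.born_step[soc.pending] = w2.step
                    nf += len(blk)
                age_and_cull(soc, params)
            w2.next_family_id = nf
            split_and_select(w2, params, w2.rng)
            w2.step += 1
        assert w1.next_family_id == w2.next_family_id
        for a, b in zip(w1.societies, w2.societies):
            np.testing.assert_array_equal(a.t, b.t)
            np.testing.assert_array_equal(a.p, b.p)
            np.testing.assert_array_equal(a.men, b.men)
            np.testing.assert_array_equal(a.family_id, b.family_id)


class TestRunSimulation:
    def test_zero_steps_returns_initial_world(self):
        params = ModelParams(N_s=2, N_f=3, n_steps=0)
        res = run_simulation(params)
        assert res.outcome == "completed"
        assert len(res.total_families) == 0
        assert res.world.step == 0

    def test_determinism_of_full_runs(self):
        params = ModelParams(N_s=4, N_f=6, d_c=0.3, d_m=0.5, n_steps=25, seed=17)
        a, b = run_simulation(params), run_simulation(params)
        np.testing.assert_array_equal(a.total_families, b.total_families)
        np.testing.assert_array_equal(a.final_points(), b.final_points())
        ea = [(bl.step, bl.society_id, bl.child_id.tolist()) for bl in a.events]
        eb = [(bl.step, bl.society_id, bl.child_id.tolist()) for bl in b.events]
        assert ea == eb

    def test_no_noise_no_selection_stays_at_origin(self):
        params = ModelParams(N_s=3, N_f=5, d_c=0.0, d_m=0.0, mu=0.0,
                             n_steps=12, seed=5)
        res = run_simulation(params)
        for soc in res.world.societies:
            if soc.n:
                np.testing.assert_array_equal(soc.t, 0.0)
                np.testing.assert_array_equal(soc.p, 0.0)

    def test_extreme_pressures_drive_extinction(self):
        extinct = 0
        for seed in range(5):
            params = ModelParams(N_s=4, N_f=6, d_c=10.0, d_m=10.0,
                                 n_steps=40, seed=seed)
            if run_simulation(params).outcome == "extinct":
                extinct += 1
        assert extinct >= 4

    def test_monogamy_no_individual_in_two_marriages(self):
        """Marriage counts never exceed the members a family held."""
        params = ModelParams(N_s=3, N_f=5, d_c=0.3, d_m=0.5, n_steps=15,
                             seed=2, event_log_window=100)
        res = run_simulation(params)
        assert res.outcome == "completed"
        # every step: marriages consume one man + one woman each; counts
        # stay non-negative throughout (enforced in arrays)
        for soc in res.world.societies:
            assert (soc.men >= 0).all() and (soc.women >= 0).all()

    def test_divergence_under_dual_pressures(self):
        """With both pressures on, trait variance grows far beyond mu^2."""
        high = 0
        for seed in range(10):
            params = ModelParams(N_s=10, N_f=20, d_c=0.3, d_m=1.0,
                                 n_steps=200, seed=seed)
            res = run_simulation(params)
            if res.outcome == "extinct":
                continue
            var = res.final_points().var(axis=0)
            if var.max() > 10 * params.mu ** 2:
                high += 1
        assert high >= 8


class TestOracleTransliteration:
    """A 2-society, 3-family micro-run against a naive straight-line
    implementation of the interaction, marriage and inheritance rules."""

    def _oracle_run(self, params, n_steps):
        tau2 = params.tau ** 2
        rng = np.random.default_rng(params.seed)
        L = params.unmarried_lifespan

        societies = []
        fid = 0
        for sid in range(params.N_s):
            fams = [{"id": fid + i, "t": np.zeros(2), "p": np.zeros(2),
                     "men": [0] * L, "women": [0] * L, "pending": True}
                    for i in range(params.N_f)]
            societies.append(fams)
            fid += params.N_f
        next_sid = params.N_s

        for step_no in range(n_steps):
            for fams in societies:
                n = len(fams)
                if n == 0:
                    continue
                pend = [i for i, f in enumerate(fams) if f["pending"]]
                if pend:
                    lam = []
                    for i in pend:
                        sf = sr = 0.0
                        for j in range(n):
                            dtt = np.sum((fams[i]["t"] - fams[j]["t"]) ** 2)
                            dtp = np.sum((fams[i]["t"] - fams[j]["p"]) ** 2)
                            dpt = np.sum((fams[i]["p"] - fams[j]["t"]) ** 2)
                            sf += np.exp(-min(dtt, dtp, dpt) / tau2)
                            sr += np.exp(-np.sum(
                                (fams[i]["p"] - fams[j]["p"]) ** 2) / tau2)
                        lam.append(params.b * np.exp(
                            -params.d_c * (1 - sf / n) - params.d_m * sr / n))
                    men0 = rng.poisson(np.array(lam))
                    women0 = rng.poisson(np.array(lam))
                    for k, i in enumerate(pend):
                        fams[i]["men"][0] += int(men0[k])
                        fams[i]["women"][0] += int(women0[k])
                        fams[i]["pending"] = False
                man_fams = [i for i, f in enumerate(fams)
                            for _ in range(sum(f["men"]))]
                if man_fams:
                    order = rng.permutation(len(man_fams))
                    man_fams = [man_fams[o] for o in order]
                    u = rng.random(len(man_fams))
                    W = np.array([[np.exp(-np.sum(
                        (fams[g]["t"] - fams[j]["p"]) ** 2) / tau2)
                        for j in range(n)] for g in range(n)])
                    avail = [sum(f["women"]) for f in fams]
                    n_women = sum(avail)
                    marriages = []
                    for m, g in enumerate(man_fams):
                        if n_women == 0:
                            break
                        tot = W[g].sum()
                        if tot > 1e-300:
                            target = u[m] * tot
                            acc, chosen = 0.0, n - 1
                            for j in range(n):
                                acc += W[g, j]
                                if acc >= target:
                                    chosen = j
                                    break
                        else:
                            chosen = min(int(u[m] * n), n - 1)
                        if avail[chosen] == 0:
                            continue
                        avail[chosen] -= 1
                        n_women -= 1
                        marriages.append((g, chosen))
                    if marriages:
                        noise = rng.normal(0.0, params.mu, (len(marriages), 4))
                        for (g, b), eta in zip(marriages, noise):
                            for ages in (fams[g]["men"],):
                                for a in range(L - 1, -1, -1):
                                    if ages[a] > 0:
                                        ages[a] -= 1
                                        break
                            for a in range(L - 1, -1, -1):
                                if fams[b]["women"][a] > 0:
                                    fams[b]["women"][a] -= 1
                                    break
                            fams.append({
                                "id": None,
                                "t": np.array([fams[g]["t"][0],
                                               fams[b]["t"][1]]) + eta[:2],
                                "p": np.array([fams[g]["p"][0],
                                               fams[b]["p"][1]]) + eta[2:],
                                "men": [0] * L, "women": [0] * L,
                                "pending": True})
                # age and cull
                for f in fams:
                    for a in range(L - 1, 0, -1):
                        f["men"][a] = f["men"][a - 1]
                        f["women"][a] = f["women"][a - 1]
                    f["men"][0] = f["women"][0] = 0
                fams[:] = [f for f in fams
                           if f["pending"] or sum(f["men"]) + sum(f["women"]) > 0]
            # split phase
            thr = params.split_threshold
            while True:
                oversized = [i for i, fams in enumerate(societies)
                             if len(fams) >= thr]
                if not oversized:
                    break
                idx = oversized[int(rng.integers(len(oversized)))]
                fams = societies[idx]
                perm = rng.permutation(len(fams))
                h1 = sorted(perm[: len(fams) // 2])
                h2 = sorted(perm[len(fams) // 2:])
                societies[idx] = [fams[i] for i in h1]
                societies.append([fams[i] for i in h2])
                next_sid += 1
                candidates = [i for i in range(len(societies))
                              if i != idx and i != len(societies) - 1]
                victim = candidates[int(rng.integers(len(candidates)))]
                del societies[victim]
        return societies

    def test_two_step_micro_run_matches_engine(self):
        params = ModelParams(N_s=2, N_f=3, b=3.0, mu=0.05, d_c=0.5, d_m=0.4,
                             n_steps=2, seed=123)
        res = run_simulation(params)
        oracle = self._oracle_run(params, 2)
        assert len(oracle) == len(res.world.societies)
        for soc, fams in zip(res.world.societies, oracle):
            assert soc.n == len(fams)
            np.testing.assert_allclose(
                soc.t, np.array([f["t"] for f in fams]).reshape(-1, 2),
                atol=1e-12)
            np.testing.assert_allclose(
                soc.p, np.array([f["p"] for f in fams]).reshape(-1, 2),
                atol=1e-12)
            np.testing.assert_array_equal(
                soc.men, np.array([f["men"] for f in fams]).reshape(-1, 2))
            np.testing.assert_array_equal(
                soc.women, np.array([f["women"] for f in fams]).reshape(-1, 2))
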