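"""Agent algebra (GAE, PPO/A2C losses), network contracts, checkpoints."""

import numpy as np
import pytest
from rdkit import Chem

from torsionrl import chem
from torsionrl.agents import (
    A2CAgent,
    AgentConfig,
    PPOAgent,
    RandomAgent,
    TrajectoryBatch,
    compute_gae,
    evaluate,
    load_checkpoint,
    save_checkpoint,
    train,
)
from torsionrl.env import ConformerEnv, EnvConfig
from torsionrl.nn import BatchedGraphs, PolicyValueNet
from torsionrl.observations import build_observation


def _gae_recursive_oracle(rewards, values, next_value, gamma, lam):
    """Direct recursive evaluation, independent of the vectorized path."""
    T = len(rewards)
    vs = list(values) + [next_value]
    def adv(t):
        if t >= T:
            return 0.0
        delta = rewards[t] + gamma * vs[t + 1] - vs[t]
        return delta + gamma * lam * adv(t + 1)
    return [adv(t) for t in range(T)]


class TestComputeGAE:
    def test_gamma_zero_closed_form(self):
        r = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 0.2, 0.1])
        adv, ret = compute_gae(r, v, np.zeros(3, bool), gamma=0.0, lam=0.7)
        assert np.allclose(adv, r - v)
        assert np.allclose(ret, r)

    def test_lambda_one_discounted_return_identity(self):
        rng = np.random.default_rng(2)
        r = rng.normal(size=6)
        v = rng.normal(size=6)
        gamma = 0.9
        adv, _ = compute_gae(r, v, np.zeros(6, bool), gamma=gamma, lam=1.0)
        discounted = [
            sum(gamma**k * r[t + k] for k in range(6 - t)) - v[t] for t in range(6)
        ]
        assert np.allclose(adv, discounted)

    def test_three_step_hand_case_matches_recursion(self):
        r = [1.0, 0.0, 2.0]
        v = [0.5, 0.5, 0.5]
        adv, ret = compute_gae(
            np.array(r), np.array(v), np.zeros(3, bool), gamma=0.9, lam=0.8,
            last_value=0.0,
        )
        expected = _gae_recursive_oracle(r, v, 0.0, 0.9, 0.8)
        assert np.allclose(adv, expected)
        assert np.allclose(ret, np.array(expected) + v)

    def test_done_stops_bootstrap(self):
        r = np.array([1.0, 1.0])
        v = np.array([10.0, 20.0])
        adv, _ = compute_gae(r, v, np.array([True, True]), gamma=0.99, lam=0.95)
        assert np.allclose(adv, r - v)  # no leakage across episode boundaries

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_gae(np.ones(3), np.ones(2), np.zeros(3, bool), 0.9, 0.9)


class TestPolicyValueNet:
    def test_output_shapes(self, pentane):
        obs = build_observation(pentane.molecule, pentane.reference)
        net = PolicyValueNet(11, 6, 6, seed=0)
        out = net.forward_single(obs)
        assert out.logits.shape == (2, 6)
        assert out.value.shape == (1,)

    def test_softmax_rows_sum_to_one(self, pentane):
        obs = build_observation(pentane.molecule, pentane.reference)
        net = PolicyValueNet(11, 6, 6, seed=0)
        probs = net.forward_single(obs).logits.softmax(axis=1).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_value_invariant_to_atom_relabeling(self, pentane):
        """Message passing + sum pooling make the value head permutation
        invariant (same molecule, permuted atom order)."""
        net = PolicyValueNet(11, 6, 6, seed=1)
        obs = build_observation(pentane.molecule, pentane.reference)
        v0 = float(net.forward_single(obs).value.data[0])
        perm = list(range(pentane.molecule.n_atoms))[::-1]
        renumbered = Chem.RenumberAtoms(pentane.molecule.rdkit_mol, perm)
        spec2 = chem.mol_spec_from_rdkit(renumbered)
        # same coordinates, permuted rows
        conf2 = chem.Conformer(pentane.reference.coordinates[perm])
        obs2 = build_observation(spec2.molecule, conf2)
        v1 = float(net.forward_single(obs2).value.data[0])
        assert v1 == pytest.approx(v0, abs=1e-5)

    def test_variable_molecule_sizes_share_parameters(self):
        net = PolicyValueNet(11, 6, 6, seed=0)
        for smiles in ("CCCC", "CCCCCC", "CCCCCCCC"):
            spec = chem.mol_spec_from_smiles(smiles)
            out = net.forward_single(build_observation(spec.molecule, spec.reference))
            assert out.logits.shape == (spec.molecule.n_torsions, 6)


def _tiny_batch(pentane, net, n=6, seed=0):
    rng = np.random.default_rng(seed)
    obs = build_observation(pentane.molecule, pentane.reference)
    batch = TrajectoryBatch()
    for _ in range(n):
        action = rng.integers(0, 6, 2)
        out = net.forward_single(obs)
        logp_all = out.logits.log_softmax(axis=1).data
        batch.observations.append(obs)
        batch.actions.append(action)
        batch.log_probs.append(float(logp_all[np.arange(2), action].sum()))
        batch.rewards.append(float(rng.normal()))
        batch.values.append(float(out.value.data[0]))
        batch.dones.append(False)
    batch.dones[-1] = True
    batch.finalize(0.9, 0.8)
    return batch


class TestUpdates:
    def test_ppo_loss_is_negative_mean_advantage_at_rho_one(self, pentane):
        """Before any parameter change ρ = 1, so the clipped surrogate reduces
        to -mean(normalized A)."""
        cfg = AgentConfig(seed=0, epochs=1, minibatch_size=64, learning_rate=0.0)
        agent = PPOAgent(11, 6, 6, cfg)
        batch = _tiny_batch(pentane, agent.net)
        stats = agent.update(batch)
        adv = batch.advantages
        adv_norm = (adv - adv.mean()) / (adv.std() + 1e-8)
        assert stats["policy_loss"] == pytest.approx(-adv_norm.mean(), abs=1e-8)

    def test_ppo_clip_bounds_ratio_contribution(self):
        """Hand case: A>0 and ρ=1+2ε contributes the clipped (1+ε)·A."""
        from torsionrl.autodiff import Tensor, clip, minimum
        eps = 0.2
        A = Tensor(np.array([2.0]))
        rho = Tensor(np.array([1.0 + 2 * eps]))
        surr = minimum(rho * A, clip(rho, 1 - eps, 1 + eps) * A)
        assert surr.data[0] == pytest.approx((1 + eps) * 2.0)

    def test_a2c_two_step_hand_loss(self, pentane):
        """A2C policy loss equals -mean(logp·A_norm) evaluated directly."""
        cfg = AgentConfig(algorithm="a2c", seed=0, learning_rate=0.0)
        agent = A2CAgent(11, 6, 6, cfg)
        batch = _tiny_batch(pentane, agent.net, n=2)
        adv = batch.advantages
        adv_norm = (adv - adv.mean()) / (adv.std() + 1e-8)
        expected = -np.mean([lp * a for lp, a in zip(batch.log_probs, adv_norm)])
        stats = agent.update(batch)
        assert stats["policy_loss"] == pytest.approx(expected, abs=1e-8)

    def test_updates_keep_parameters_finite(self, pentane):
        cfg = AgentConfig(seed=0, epochs=2, minibatch_size=4)
        agent = PPOAgent(11, 6, 6, cfg)
        for _ in range(3):
            agent.update(_tiny_batch(pentane, agent.net))
        assert all(np.all(np.isfinite(p.data)) for p in agent.net.parameters())


class TestRandomAgent:
    def test_uniform_over_buckets(self, butane):
        obs = build_observation(butane.molecule, butane.reference)
        agent = RandomAgent(n_buckets=6, seed=0)
        draws = np.concatenate([agent.act(obs) for _ in range(6000)])
        counts = np.bincount(draws, minlength=6)
        # binomial CI: p=1/6, n=6000, 4 sigma
        sigma = np.sqrt(6000 * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - 1000) < 4 * sigma)

    def test_seeded_reproducibility(self, pentane):
        obs = build_observation(pentane.molecule, pentane.reference)
        a = RandomAgent(6, seed=42)
        b = RandomAgent(6, seed=42)
        for _ in range(10):
            assert np.array_equal(a.act(obs), b.act(obs))

    def test_respects_n_torsions(self, pentane, butane):
        agent = RandomAgent(6, seed=1)
        assert len(agent.act(build_observation(pentane.molecule, pentane.reference))) == 2
        assert len(agent.act(build_observation(butane.molecule, butane.reference))) == 1


class TestTrainLoop:
    def test_metrics_and_eval_column(self, butane, tmp_path):
        env = ConformerEnv(EnvConfig(mol_specs=[butane], max_steps=2, seed=0))
        eval_env = ConformerEnv(EnvConfig(mol_specs=[butane], max_steps=2, seed=9))
        agent = PPOAgent.for_env(env, AgentConfig(seed=0, rollout_steps=8, epochs=1))
        history = train(agent, env, total_steps=24, eval_env=eval_env, eval_interval=3)
        assert len(history) == 3
        assert "eval_reward" in history[2] and "eval_reward" not in history[0]
        history2 = train(agent, env, total_steps=8)
        assert "eval_reward" not in history2[0]

    def test_bucket_mismatch_rejected(self, butane):
        env = ConformerEnv(
            EnvConfig(mol_specs=[butane], max_steps=2, seed=0, granularity_deg=30.0)
        )
        agent = PPOAgent(11, 6, 6, AgentConfig(seed=0))  # 6 buckets vs env's 12
        with pytest.raises(ValueError):
            train(agent, env, total_steps=4)

    def test_checkpoint_resume_reproduces_metrics(self, butane, tmp_path):
        def fresh_env():
            return ConformerEnv(EnvConfig(mol_specs=[butane], max_steps=2, seed=5))
        cfg = AgentConfig(seed=3, rollout_steps=6, epochs=1)
        agent = PPOAgent.for_env(fresh_env(), cfg)
        env = fresh_env()
        train(agent, env, total_steps=6)
        path = tmp_path / "ckpt.pkl"
        save_checkpoint(path, agent, iteration=1, env_steps=6)
        # continue the original
        next_a = train(agent, fresh_env(), total_steps=6)
        # reload and continue the copy under identical seeds
        clone, _, _ = load_checkpoint(path)
        next_b = train(clone, fresh_env(), total_steps=6)
        for key in ("policy_loss", "value_loss", "entropy", "mean_episode_reward"):
            va, vb = next_a[0][key], next_b[0][key]
            if np.isnan(va) and np.isnan(vb):
                continue
            assert va == pytest.approx(vb, abs=1e-9)

    def test_evaluate_runs_greedy_episodes(self, butane):
        env = ConformerEnv(EnvConfig(mol_specs=[butane], max_steps=2, seed=0))
        agent = PPOAgent.for_env(env, AgentConfig(seed=0))
        val = evaluate(agent, env, n_episodes=2)
        assert np.isfinite(val)
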