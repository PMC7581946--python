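import numpy as np
import pytest
from scipy import stats as sps

from boolsynergy.ga_optimizer import (
    EmptyEnsembleError,
    GAConfig,
    TrainingProfile,
    evolve,
    fitness,
    mutate,
    read_training_profile,
    restrict_to_common,
)
from boolsynergy.logic_engine import fixed_points
from boolsynergy.network_io import (
    AND_NOT,
    OR_NOT,
    LogicalNetwork,
    SignedEdge,
    default_model,
)
from boolsynergy.synthetic_data import generate_network, make_instance


def net_from(edges):
    nodes = []
    for s, t, _ in edges:
        for n in (s, t):
            if n not in nodes:
                nodes.append(n)
    return LogicalNetwork(nodes=nodes, edges=[SignedEdge(*e) for e in edges])


class TestTrainingProfile:
    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            TrainingProfile(observations={})

    def test_rejects_nonbinary_and_bad_weight(self):
        with pytest.raises(ValueError):
            TrainingProfile(observations={"A": 2})
        with pytest.raises(ValueError):
            TrainingProfile(observations={"A": 1}, weights={"A": 0.0})

    def test_restrict_to_common(self):
        a = TrainingProfile(observations={"A": 1, "B": 0, "C": 1}, weights={"A": 2.0})
        b = TrainingProfile(observations={"A": 0, "C": 0})
        r = restrict_to_common(a, b)
        assert r.observations == {"A": 1, "C": 1} and r.weights == {"A": 2.0}
        with pytest.raises(ValueError, match="no observed node"):
            restrict_to_common(a, TrainingProfile(observations={"Z": 1}))

    def test_reader(self, tmp_path):
        p = tmp_path / "profile.tsv"
        p.write_text("node\tstate\tweight\nA\t1\t2.0\nB\t0\n")
        prof = read_training_profile(p)
        assert prof.observations == {"A": 1, "B": 0} and prof.weight("A") == 2.0


class TestFitness:
    def bistable(self):
        return net_from([("A", "B", 1), ("B", "A", 1)])

    def test_perfect_match_on_unique_fixed_point(self):
        # clamp-free chain: A input free makes 2 fps; use profile on both fps
        net = net_from([("A", "B", 1), ("B", "A", 1)])
        model = default_model(net)
        prof = TrainingProfile(observations={"A": 1, "B": 1})
        # fps: 00 and 11 -> matches 0.0 and 1.0, mean 0.5, max 1.0
        assert fitness(model, prof) == pytest.approx(0.5)
        assert fitness(model, prof, aggregate="max") == 1.0

    def test_fraction_of_matching_nodes(self):
        net = net_from([("I", "B", 1), ("I", "C", -1)])
        model = default_model(net)
        prof = TrainingProfile(observations={"B": 1, "C": 1})
        # under I=1 branch: B=1, C=0 -> 0.5; under I=0: B=0, C=1 -> 0.5
        assert fitness(model, prof) == pytest.approx(0.5)

    def test_weight_scaling_is_irrelevant(self):
        net = net_from([("I", "B", 1), ("I", "C", -1)])
        model = default_model(net)
        p1 = TrainingProfile(observations={"B": 1, "C": 1}, weights={"B": 1.0, "C": 3.0})
        p2 = TrainingProfile(observations={"B": 1, "C": 1}, weights={"B": 2.0, "C": 6.0})
        assert fitness(model, p1) == pytest.approx(fitness(model, p2))

    def test_no_fixed_point_scores_zero(self):
        model = default_model(net_from([("A", "B", 1), ("B", "A", -1)]))
        assert fitness(model, TrainingProfile(observations={"A": 1})) == 0.0

    def test_unknown_profile_node_rejected(self):
        model = default_model(net_from([("A", "B", 1)]))
        with pytest.raises(ValueError, match="not in network"):
            fitness(model, TrainingProfile(observations={"Z": 1}))


class TestMutate:
    def one_locus_model(self):
        return default_model(net_from([("A", "B", 1), ("C", "B", -1)]))

    def test_single_locus_flip_and_copy_semantics(self):
        model = self.one_locus_model()
        child = mutate(model, 1, np.random.default_rng(0))
        assert child.equations["B"].link_operator == OR_NOT
        assert model.equations["B"].link_operator == AND_NOT

    def test_double_hit_is_involution(self):
        model = self.one_locus_model()
        child = mutate(model, 2, np.random.default_rng(0))
        assert child.equations["B"].link_operator == AND_NOT

    def test_no_mutable_locus_errors(self):
        model = default_model(net_from([("A", "B", 1)]))
        with pytest.raises(ValueError, match="no mutable equation"):
            mutate(model, 1, np.random.default_rng(0))

    def test_locus_choice_is_uniform(self):
        """Chi-square on 10,000 single-locus draws over 4 loci."""
        edges = []
        for i in range(4):
            edges += [(f"a{i}", f"x{i}", 1), (f"b{i}", f"x{i}", -1)]
        model = default_model(net_from(edges))
        loci = model.mutable_targets()
        assert len(loci) == 4
        rng = np.random.default_rng(7)
        counts = dict.fromkeys(loci, 0)
        for _ in range(10_000):
            child = mutate(model, 1, rng)
            hit = [t for t in loci
                   if child.equations[t].link_operator != model.equations[t].link_operator]
            counts[hit[0]] += 1
        freqs = np.array(list(counts.values())) / 10_000
        assert np.all(np.abs(freqs - 0.25) < 0.02)
        chi2 = ((np.array(list(counts.values())) - 2500) ** 2 / 2500).sum()
        assert chi2 < sps.chi2.ppf(0.999, df=3)


class TestEvolve:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(elite=0)
        with pytest.raises(ValueError):
            GAConfig(elite=30, population=20)
        with pytest.raises(ValueError):
            GAConfig(generations=0)

    def small_instance(self):
        net = generate_network(n_nodes=20, seed=11, n_pro=3, n_anti=3)
        return make_instance(network=net, seed=11, flip_prob=0.0, obs_fraction=1.0)

    def test_same_seed_gives_identical_ensembles(self):
        inst = self.small_instance()
        cfg = GAConfig(population=8, generations=4, elite=2, runs=2, seed=5)
        e1 = evolve(inst.network, inst.training_profile, cfg)
        e2 = evolve(inst.network, inst.training_profile, cfg)
        assert [m.operator_signature() for m in e1.models] == \
               [m.operator_signature() for m in e2.models]
        assert e1.fitnesses == e2.fitnesses

    def test_degenerate_ga_returns_single_init_model(self):
        inst = self.small_instance()
        cfg = GAConfig(population=1, generations=1, elite=1, runs=1, seed=3)
        ens = evolve(inst.network, inst.training_profile, cfg)
        assert len(ens) == 1

    def test_elitist_monotonicity(self):
        """Best fitness never decreases across generations within a run."""
        inst = self.small_instance()
        cfg = GAConfig(population=10, generations=8, elite=2, runs=3, seed=9)
        ens = evolve(inst.network, inst.training_profile, cfg)
        for run_hist in ens.provenance["best_fitness_history"]:
            assert all(b >= a for a, b in zip(run_hist, run_hist[1:]))

    def test_unreachable_threshold_raises_with_best_fitness(self):
        # B = A always; asking for A=1 with B=0 caps any model at 0.5
        net = net_from([("A", "B", 1), ("A", "X", 1), ("C", "X", -1)])
        prof = TrainingProfile(observations={"A": 1, "B": 0})
        cfg = GAConfig(population=2, generations=2, elite=1, runs=1, seed=0,
                       fitness_threshold=0.9, fitness_aggregate="max")
        with pytest.raises(EmptyEnsembleError, match="best achieved fitness"):
            evolve(net, prof, cfg)

    def test_recovery_on_noiseless_instance(self):
        """GA refits a profile drawn from a hidden model's own attractor."""
        net = generate_network(n_nodes=20, seed=2, n_pro=3, n_anti=3)
        inst = make_instance(network=net, seed=2, flip_prob=0.0, obs_fraction=1.0)
        cfg = GAConfig(population=16, generations=12, elite=3, runs=4, seed=17,
                       fitness_aggregate="max")
        ens = evolve(inst.network, inst.training_profile, cfg)
        assert ens.mean_fitness >= 0.95


class TestOperatorRecovery:
    def test_recovered_operators_beat_chance(self):
        """Identifiable link operators are recovered above the 50% baseline."""
        agree = total = 0
        for seed in range(20):
            net = generate_network(n_nodes=15, seed=seed, n_pro=3, n_anti=3)
            inst = make_instance(network=net, seed=seed, flip_prob=0.0,
                                 obs_fraction=1.0)
            cfg = GAConfig(population=10, generations=8, elite=2, runs=2,
                           seed=100 + seed, fitness_aggregate="max")
            ens = evolve(inst.network, inst.training_profile, cfg)
            truth_sig = inst.truth_model.operator_signature()
            for m in ens.models:
                sig = m.operator_signature()
                agree += sum(a == b for a, b in zip(sig, truth_sig))
                total += len(sig)
        assert total > 100
        # strictly above chance with a comfortable margin
        assert agree / total > 0.55
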