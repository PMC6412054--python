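"""Outbreak simulator, NJ rebuilding, and the insertion procedures.

Unit tests run on a shrunken population (30-60 individuals, 12-20
samples) so the whole file stays in the seconds range; the full-size
study conditions are exercised by the acceptance suite.
"""

import numpy as np
import pytest

from homoplasy.core import find_homoplasies, fitch_site_lengths
from homoplasy.errors import InputError, SimulationError
from homoplasy.io import Alignment, Node, PhyloTree
from homoplasy.simulate import (
    SimulationConfig,
    build_nj_tree,
    insert_homoplasies,
    insert_recombination,
    nj_tree_from_distances,
    run_detection_experiment,
    simulate_outbreak,
    true_transmission_tree,
)

SMALL = dict(n_individuals=40, stop_after_sampled=15, infectiousness=0.01)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"infectiousness": 1.5},
            {"sampling_prob": -0.1},
            {"mutation_rate": -1},
            {"stop_after_sampled": 300},
            {"n_individuals": 0},
            {"n_recombination_events": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InputError):
            SimulationConfig(**kwargs)


class TestSimulateOutbreak:
    def test_zero_mutation_rate_gives_identical_sequences(self):
        config = SimulationConfig(mutation_rate=0.0, rng_seed=3, **SMALL)
        outbreak = simulate_outbreak(config)
        assert len(set(outbreak.alignment.sequences.values())) == 1

    def test_forced_single_sample_run(self):
        # sampling removes patient zero immediately; quota of 1 is met
        config = SimulationConfig(
            n_individuals=5, infectiousness=0.0, sampling_prob=1.0,
            stop_after_sampled=1, rng_seed=1,
        )
        outbreak = simulate_outbreak(config)
        assert outbreak.alignment.n_sequences == 1

    def test_unreachable_quota_raises_after_restarts(self):
        # with no transmission the epidemic always ends after one sample
        config = SimulationConfig(
            n_individuals=5, infectiousness=0.0, sampling_prob=1.0,
            stop_after_sampled=2, rng_seed=1,
        )
        with pytest.raises(SimulationError, match="died out"):
            simulate_outbreak(config)

    def test_mutation_counts_match_poisson_mean(self):
        config = SimulationConfig(rng_seed=11)
        outbreak = simulate_outbreak(config)
        mean = outbreak.n_mutation_events / outbreak.n_infected_steps
        se = np.sqrt(config.mutation_rate / outbreak.n_infected_steps)
        assert abs(mean - config.mutation_rate) < 3 * se

    def test_reaches_sampling_quota_exactly(self):
        outbreak = simulate_outbreak(SimulationConfig(rng_seed=5, **SMALL))
        assert outbreak.alignment.n_sequences == 15
        assert len(outbreak.samples) == 15

    def test_deterministic_under_fixed_seed(self):
        config = SimulationConfig(rng_seed=8, **SMALL)
        a, b = simulate_outbreak(config), simulate_outbreak(config)
        assert a.alignment == b.alignment
        assert a.transmission == b.transmission

    def test_true_tree_sees_no_homoplasy_in_clean_data(self):
        outbreak = simulate_outbreak(SimulationConfig(rng_seed=21, **SMALL))
        tree = true_transmission_tree(outbreak)
        assert sorted(tree.tip_labels()) == sorted(outbreak.alignment.labels)
        result = find_homoplasies(tree, outbreak.alignment)
        assert result.flagged_positions == []


def _path_distances(tree: PhyloTree) -> dict[frozenset, float]:
    """Tip-to-tip path lengths via root-to-tip depths."""
    depth = {}

    def walk(node: Node, acc: float) -> None:
        acc += node.length or 0.0
        if node.is_tip:
            depth[node.label] = acc
        for child in node.children:
            walk(child, acc)

    walk(tree.root, 0.0)

    def mrca_depth(a: str, b: str) -> float:
        best = 0.0

        def descend(node: Node, acc: float) -> None:
            nonlocal best
            tips = {t.label for t in node.postorder() if t.is_tip}
            if {a, b} <= tips:
                best = max(best, acc + (node.length or 0.0))
                for child in node.children:
                    descend(child, acc + (node.length or 0.0))

        descend(tree.root, -(tree.root.length or 0.0))
        return best

    labels = sorted(depth)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[frozenset((a, b))] = depth[a] + depth[b] - 2 * mrca_depth(a, b)
    return out


class TestNJ:
    def test_additive_distances_recovered_exactly(self):
        # distances from a 5-tip tree with distinct branch lengths
        source = PhyloTree(
            Node(children=[
                Node(children=[Node(label="A", length=2.0), Node(label="B", length=3.0)],
                     length=1.0),
                Node(children=[
                    Node(children=[Node(label="C", length=4.0), Node(label="D", length=5.0)],
                         length=2.0),
                    Node(label="E", length=7.0)], length=1.5),
            ])
        )
        want = _path_distances(source)
        labels = sorted(source.tip_labels())
        D = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    D[i, j] = want[frozenset((a, b))]
        rebuilt = nj_tree_from_distances(labels, D)
        got = _path_distances(rebuilt)
        for pair, value in want.items():
            assert got[pair] == pytest.approx(value, abs=1e-9)

    def test_generating_topology_recovered(self, quartet_tree):
        aln = Alignment([
            ("A", "AAAACCCC" + "ACGT"),
            ("B", "AAAACCCC" + "ACGA"),
            ("C", "TTTTGGGG" + "TCGT"),
            ("D", "TTTTGGGG" + "TGGT"),
        ])
        tree = build_nj_tree(aln)
        clades = {frozenset(t.label for t in n.postorder() if t.is_tip)
                  for n in tree.internal_nodes()}
        assert frozenset("AB") in clades or frozenset("CD") in clades

    def test_identical_sequences_star_with_zero_lengths(self):
        aln = Alignment([(lab, "ACGTACGT") for lab in "ABCDE"])
        tree = build_nj_tree(aln)
        assert all((n.length or 0.0) == 0.0 for n in tree.postorder())

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(InputError):
            build_nj_tree(Alignment([("A", "ACGT"), ("B", "ACGA")]))

    def test_no_negative_branch_lengths(self):
        outbreak = simulate_outbreak(SimulationConfig(rng_seed=13, **SMALL))
        tree = build_nj_tree(outbreak.alignment)
        assert all((n.length or 0.0) >= 0.0 for n in tree.postorder())


@pytest.fixture(scope="module")
def small_outbreak():
    outbreak = simulate_outbreak(SimulationConfig(rng_seed=17, **SMALL))
    return outbreak, build_nj_tree(outbreak.alignment)


class TestInsertHomoplasies:
    def test_count_zero_is_identity(self, small_outbreak):
        outbreak, tree = small_outbreak
        rng = np.random.default_rng(0)
        modified, records = insert_homoplasies(tree, outbreak.alignment, 0, rng)
        assert modified == outbreak.alignment
        assert records == []

    def test_inserted_site_flagged_on_original_tree(self, small_outbreak):
        outbreak, tree = small_outbreak
        for seed in range(5):
            rng = np.random.default_rng(seed)
            modified, records = insert_homoplasies(tree, outbreak.alignment, 1, rng)
            assert len(records) == 1
            rec = records[0]
            assert not (rec.donor_tips & rec.recipient_tips)
            result = find_homoplasies(tree, modified)
            assert rec.position in result.flagged_positions

    def test_insertion_changes_exactly_the_recorded_sites(self, small_outbreak):
        outbreak, tree = small_outbreak
        rng = np.random.default_rng(2)
        modified, records = insert_homoplasies(tree, outbreak.alignment, 5, rng)
        positions = {r.position for r in records}
        assert len(positions) == 5  # without replacement
        diff_sites = {
            i + 1
            for i in range(outbreak.alignment.length)
            for lab in outbreak.alignment.labels
            if outbreak.alignment[lab][i] != modified[lab][i]
        }
        assert diff_sites <= positions

    def test_eligibility_exhaustion_reports_progress(self):
        from homoplasy.io import read_newick_string

        # pairs exist (e.g. {A,B} with {D,E}) but identical sequences
        # leave no clade-private site anywhere
        tree = read_newick_string("(((A,B),C),((D,E),F));")
        aln = Alignment([(lab, "ACGT") for lab in "ABCDEF"])
        with pytest.raises(SimulationError, match="0 of 1"):
            insert_homoplasies(tree, aln, 1, np.random.default_rng(0))


class TestInsertRecombination:
    def test_zero_events_is_identity(self, small_outbreak):
        outbreak, tree = small_outbreak
        out = insert_recombination(tree, outbreak.alignment, 0,
                                   rng=np.random.default_rng(0))
        assert out == outbreak.alignment

    def test_recipient_gets_donor_consensus(self, small_outbreak):
        outbreak, tree = small_outbreak
        region = min(50, outbreak.alignment.length)
        rng = np.random.default_rng(4)
        out = insert_recombination(tree, outbreak.alignment, 1,
                                   region_length=region, rng=rng)
        changed = [
            lab for lab in out.labels if out[lab] != outbreak.alignment[lab]
        ]
        # every changed sequence now matches every other changed one in
        # some contiguous window (they all received the same consensus)
        if changed:
            diffs = [
                i for i in range(out.length)
                if out[changed[0]][i] != outbreak.alignment[changed[0]][i]
            ]
            assert max(diffs) - min(diffs) < region
            for lab in changed[1:]:
                assert out[lab][min(diffs): max(diffs) + 1] == \
                    out[changed[0]][min(diffs): max(diffs) + 1]

    def test_monomorphic_donor_region_copied_verbatim(self):
        # quartet where the donor clade is monomorphic across the region
        tree = PhyloTree(Node(children=[
            Node(children=[Node(label="A"), Node(label="B")]),
            Node(children=[Node(label="C"), Node(label="D")]),
            Node(label="E"),
        ]))
        aln = Alignment([
            ("A", "AAAA"), ("B", "AAAA"), ("C", "TTTT"), ("D", "TTTT"),
            ("E", "GGGG"),
        ])
        rng = np.random.default_rng(1)
        out = insert_recombination(tree, aln, 1, region_length=4, rng=rng)
        changed = {lab for lab in out.labels if out[lab] != aln[lab]}
        assert changed in ({"A", "B"}, {"C", "D"})
        donor = "TTTT" if changed == {"A", "B"} else "AAAA"
        for lab in changed:
            assert out[lab] == donor

    def test_short_alignment_rejected(self, quartet_tree):
        aln = Alignment([(lab, "ACGT") for lab in "ABCD"])
        with pytest.raises(InputError, match="shorter"):
            insert_recombination(quartet_tree, aln, 1, region_length=100,
                                 rng=np.random.default_rng(0))


class TestDetectionExperiment:
    def test_reproducible_from_master_seed(self):
        config = SimulationConfig(rng_seed=23, n_inserted_homoplasies=2, **SMALL)
        a = run_detection_experiment(config, 3)
        b = run_detection_experiment(config, 3)
        assert a.table.equals(b.table)

    def test_zero_insertion_replicates_excluded_from_mean(self):
        config = SimulationConfig(rng_seed=23, n_inserted_homoplasies=0, **SMALL)
        summary = run_detection_experiment(config, 2)
        assert summary.n_scored == 0
        assert np.isnan(summary.mean_detection_pct)
        assert summary.table["proportion"].isna().all()
        assert (summary.table["false_positives"] >= 0).all()

    def test_replicate_count_validated(self):
        with pytest.raises(InputError):
            run_detection_experiment(SimulationConfig(), 0)

    def test_pre_insertion_tree_detects_everything(self):
        config = SimulationConfig(rng_seed=29, n_inserted_homoplasies=3, **SMALL)
        summary = run_detection_experiment(config, 3, detect_on="original")
        assert (summary.table["proportion"] == 1.0).all()
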