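import math

import numpy as np
import pytest

from duplexkit import families
from duplexkit.simulator import (
    FamilySizeDist,
    PcrNode,
    PcrTree,
    SimConfig,
    apply_errors,
    build_pcr_tree,
    apply_variants,
    draw_family_sizes,
    emit_reads,
    mutate_reference,
    random_reference,
    revcomp,
    sample_fragments,
    simulate_run,
    singleton_fraction_experiment,
    tagged_molecule,
    _mutate_branch,
)


class TestFamilySizeDist:
    def test_default_shape(self):
        dist = FamilySizeDist.default()
        assert math.isclose(dist.probs.sum(), 1.0)
        assert dist.sizes[dist.probs.argmax()] == 9  # empirical peak
        assert dist.probs[0] == pytest.approx(0.012)  # singleton mass

    def test_exact_singleton_assignment(self, rng):
        dist = FamilySizeDist.default()
        sizes = draw_family_sizes(10000, dist, rng, exact_singleton_fraction=0.012)
        assert (sizes == 1).sum() == 120
        assert sizes.min() >= 1

    def test_rejects_bad_probs(self):
        with pytest.raises(ValueError):
            FamilySizeDist(np.array([1, 2]), np.array([0.4, 0.4]))


class TestMutateReference:
    def test_zero_sites_identity(self, small_ref, rng):
        mut, truth = mutate_reference(small_ref, 0, 600, rng)
        assert mut == small_ref and truth == []

    def test_spacing_and_roundtrip(self, rng):
        ref = random_reference(16600, rng)
        mut, truth = mutate_reference(ref, 21, 600, rng)
        positions = [p for p, _, _ in truth]
        assert len(truth) == 21
        assert positions[0] >= 600 and len(ref) - 1 - positions[-1] >= 600
        assert all(b - a >= 600 for a, b in zip(positions, positions[1:]))
        assert apply_variants(ref, truth) == mut
        assert sum(x != y for x, y in zip(ref, mut)) == 21

    def test_infeasible_spacing_reports_max(self, small_ref, rng):
        with pytest.raises(ValueError, match="at most"):
            mutate_reference(small_ref, 21, 600, rng)


class TestSampleFragments:
    def test_whole_reference(self, rng):
        starts, strands = sample_fragments(100, 1, 100, rng)
        assert starts[0] == 0

    def test_bounds(self, rng):
        starts, _ = sample_fragments(3000, 1000, 600, rng)
        assert starts.min() >= 0 and starts.max() <= 2400

    def test_empty(self, rng):
        starts, strands = sample_fragments(3000, 0, 600, rng)
        assert len(starts) == 0


class TestPcrTree:
    @pytest.mark.parametrize("size", [1, 2, 3, 9, 25])
    def test_leaf_count(self, size, rng):
        tree = build_pcr_tree(size, 30, rng)
        assert tree.leaf_count() == size

    def test_single_read_single_leaf(self, rng):
        tree = build_pcr_tree(1, 30, rng)
        leaves = [d for d in tree.daughters if d is not None]
        assert len(leaves) == 1

    def test_pairwise_coalescence_follows_two_to_minus_cycle(self):
        """Empirical merge-cycle frequencies for 2 lineages match the model.

        P(merge at cycle c) = 2^-c * prod_{k=c+1..30} (1 - 2^-k), computed
        independently from the stated per-cycle pairing probability.
        """
        rng = np.random.default_rng(123)
        n_trials = 20000
        counts = {}
        for _ in range(n_trials):
            tree = build_pcr_tree(2, 30, rng)
            nodes = [d for d in tree.daughters if d is not None]
            if len(nodes) == 1 and nodes[0].leaf_id is None and len(nodes[0].children) == 2:
                c = nodes[0].split_cycle + 1  # merge happened at this cycle
                counts[c] = counts.get(c, 0) + 1

        def expected(c):
            p = 2.0**-c
            for k in range(c + 1, 31):
                p *= 1 - 2.0**-k
            return p

        # cycle 2 is skipped: unmerged lineages attached to one daughter are
        # indistinguishable from a cycle-2 merge in the tree encoding
        for c in (3, 4, 5):
            exp = expected(c)
            obs = counts.get(c, 0) / n_trials
            sd = math.sqrt(exp * (1 - exp) / n_trials)
            assert abs(obs - exp) < 4 * sd + 1e-9, (c, obs, exp)


class TestApplyErrors:
    def test_zero_rate_identity(self, rng):
        cfg = SimConfig(fragment_length=200, read_length=100, per_base_per_cycle_error=0.0)
        tree = build_pcr_tree(5, 30, rng)
        template = random_reference(234, rng)
        leaves = apply_errors(tree, template, cfg, rng)
        assert len(leaves) == 5
        assert all(seq == template for _, _, seq in leaves)

    def test_substitution_count_binomial(self, rng):
        """One error round at p=0.1 on 10 kb: mutations ~ Binomial(10000, 0.1)."""
        cfg = SimConfig(
            fragment_length=10000,
            read_length=100,
            per_base_per_cycle_error=0.1,
            indel_fraction_of_errors=0.0,
        )
        template = random_reference(10000, rng)
        seq = list(template)
        _mutate_branch(seq, 1, cfg, rng)
        n_mut = sum(x != y for x, y in zip(template, seq))
        # mean 1000, sd ~30; 5 sigma; resampling the same site can hide a few
        assert 800 < n_mut <= 1100

    def test_trunk_mutations_inherited_by_descendants_only(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(
            fragment_length=400,
            read_length=100,
            per_base_per_cycle_error=0.004,
            indel_fraction_of_errors=0.0,
        )
        # daughter 0: internal split at cycle 15 over two leaves; daughter 1: one leaf
        tree = PcrTree(
            daughters=[
                PcrNode(15, children=[PcrNode(30, leaf_id=0), PcrNode(30, leaf_id=1)]),
                PcrNode(1, children=[PcrNode(30, leaf_id=2)]),
            ]
        )
        template = random_reference(434, rng)
        leaves = {lid: seq for lid, _, seq in apply_errors(tree, template, cfg, rng)}
        shared01 = {
            i
            for i, (x, y, t) in enumerate(zip(leaves[0], leaves[1], template))
            if x == y != t
        }
        # the 15-cycle trunk is shared by leaves 0 and 1 but not leaf 2
        assert len(shared01) >= 5
        leaked = {i for i in shared01 if leaves[2][i] == leaves[0][i]}
        assert len(leaked) < len(shared01) / 2


class TestEmitReads:
    def test_read_construction(self):
        alpha, beta, linker = "A" * 12, "C" * 12, "TGACT"
        insert = "ACGTACGTACGTACGTACGTACGTACGT"  # 28 bp
        mol = tagged_molecule(insert, alpha, beta, linker)
        leaves = [(0, 0, mol), (1, 1, mol)]
        pairs, n_ab, n_ba = emit_reads(leaves, 7, read_length=30, fixed_phred=40)
        assert (n_ab, n_ba) == (1, 1)
        ab, ba = pairs
        assert ab.seq1[:12] == alpha and ab.seq1[12:17] == linker
        assert ab.seq1[17:30] == insert[:13]
        assert ab.seq2[:12] == beta
        assert ab.seq2[17:30] == revcomp(insert)[:13]
        # the opposite strand swaps the mates
        assert ba.seq1 == ab.seq2 and ba.seq2 == ab.seq1
        assert set(ab.qual1) == {"I"}

    def test_zero_error_family_recovers_fragment_via_pipeline(self, small_ref, rng):
        from duplexkit.pipeline import PipelineConfig, call_consensi

        cfg = SimConfig(fragment_length=400, read_length=100, per_base_per_cycle_error=0.0)
        res = simulate_run(cfg, [("ref", small_ref, 12)], 3)
        rows, _ = families.make_family_table(res.pairs)
        out = call_consensi(families.group_families(rows), PipelineConfig())
        byfrag = {f.canonical: f for f in res.fragments}
        assert out.dcs, "no duplex families formed"
        for dcs in out.dcs:
            frag = byfrag[dcs.canonical_barcode]
            insert = small_ref[frag.start : frag.end]
            if frag.strand == "-":
                insert = revcomp(insert)
            fwd = (frag.alpha <= frag.beta) == (dcs.mate == 1)
            expect = insert if fwd else revcomp(insert)
            assert dcs.seq == expect[: cfg.payload_length]


class TestSimulateRun:
    def test_distinct_barcodes_per_fragment(self, small_ref):
        cfg = SimConfig(fragment_length=400, read_length=100, per_base_per_cycle_error=0.0)
        res = simulate_run(cfg, [("ref", small_ref, 100)], 9)
        assert len({f.canonical for f in res.fragments}) == 100
        rows, _ = families.make_family_table(res.pairs)
        assert len(list(families.group_families(rows))) == 100

    def test_seed_determinism(self, small_ref):
        cfg = SimConfig(fragment_length=400, read_length=100)
        a = simulate_run(cfg, [("ref", small_ref, 20)], 77)
        b = simulate_run(cfg, [("ref", small_ref, 20)], 77)
        assert [(p.name, p.seq1, p.seq2) for p in a.pairs] == [
            (p.name, p.seq1, p.seq2) for p in b.pairs
        ]
        assert a.fragments == b.fragments

    def test_truth_accounts_every_pair(self, small_ref):
        cfg = SimConfig(fragment_length=400, read_length=100)
        res = simulate_run(cfg, [("ref", small_ref, 30)], 5)
        assert sum(f.family_size for f in res.fragments) == len(res.pairs)
        assert all(f.n_ab + f.n_ba == f.family_size for f in res.fragments)


class TestSingletonExperiment:
    def test_zero_error_exact_fraction_small(self, small_ref):
        cfg = SimConfig(
            fragment_length=400, read_length=100, exact_singleton_fraction=0.012
        )
        rows = singleton_fraction_experiment([0.0], cfg, small_ref, 500, seed=4)
        assert rows[0]["n_unique_barcodes"] == 500
        assert rows[0]["singleton_fraction"] == pytest.approx(6 / 500)

    def test_no_singleton_sizes_zero_fraction(self, small_ref):
        dist = FamilySizeDist.from_mapping({3: 0.5, 4: 0.5})
        cfg = SimConfig(
            fragment_length=400, read_length=100, family_size_dist=dist
        )
        rows = singleton_fraction_experiment([0.0], cfg, small_ref, 300, seed=4)
        assert rows[0]["singleton_fraction"] == 0.0
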