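"""Consensus NMF, robust-program selection, meta-program clustering and
hypergeometric annotation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import NMF

from metaniche import (
    ConfigError,
    GeneProgram,
    GeneSetCollection,
    MetaProgram,
    ProgramSetConfig,
    annotate_mp,
    cluster_metaprograms,
    consensus_nmf,
    jaccard,
    programs_for_sample,
    select_robust,
)
from metaniche.programs import reconstruction_error

from conftest import make_matrix

UNIVERSE = [f"G{i:03d}" for i in range(400)]


def toy_program(sample, k, index, top, n_top=None):
    """A GeneProgram whose spectrum puts descending weight on ``top``."""
    top = list(top)
    spectrum = np.zeros(len(UNIVERSE))
    for rank, g in enumerate(top):
        spectrum[UNIVERSE.index(g)] = float(len(top) - rank)
    return GeneProgram(
        sample_id=sample, k=k, program_index=index, genes=list(UNIVERSE),
        spectrum=spectrum, top_genes=top[: n_top or len(top)],
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            (set(), set(), 0.0),
            (set("abcdefghij"), set("abcdefghij") | set(map(str, range(40))), 0.2),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetric_bounded(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b and len(a) > 0) or (not a and not b and j == 0.0)


class TestConsensusNMF:
    def test_block_diagonal_two_programs(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((40, 60), dtype=int)
        counts[:20, :30] = rng.integers(5, 20, size=(20, 30))
        counts[20:, 30:] = rng.integers(5, 20, size=(20, 30))
        m = make_matrix(counts)
        progs, usage = consensus_nmf(m, k=2, n_replicates=8, seed=1,
                                     top_genes_per_program=20, preprocess=False)
        blocks = [set(m.gene_ids[:20]), set(m.gene_ids[20:])]
        for p in progs:
            top = set(p.top_genes)
            assert top <= blocks[0] or top <= blocks[1]

    def test_rank_one_recovery(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 4.0, 3.0, 5.0, 6.0])
        X = np.outer(u, v)
        m = make_matrix(X.astype(int) * 0 + X)  # exact rank-1, nonneg
        progs, usage = consensus_nmf(m, k=1, n_replicates=5, seed=0,
                                     preprocess=False)
        W = usage.to_numpy()
        H = np.vstack([p.spectrum for p in progs])
        err = reconstruction_error(X.T, W, H)
        assert err < 1e-6 * np.linalg.norm(X)

    def test_determinism(self, small_cohort):
        _, m, _ = small_cohort
        sub = m.subset_cells((m.cell_meta["sample"] == "S01").to_numpy())
        p1, u1 = consensus_nmf(sub, k=4, n_replicates=5, seed=9)
        p2, u2 = consensus_nmf(sub, k=4, n_replicates=5, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.spectrum, b.spectrum)
            assert a.top_genes == b.top_genes
        assert u1.equals(u2)

    def test_k_too_large_rejected(self):
        m = make_matrix(np.ones((5, 6)))
        with pytest.raises(ConfigError, match="k=5"):
            consensus_nmf(m, k=5, n_replicates=3, preprocess=False)

    def test_consensus_error_not_worse_than_worst_replicate(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2.0, 1.0, size=(25, 35))
        m = make_matrix(X)
        progs, usage = consensus_nmf(m, k=3, n_replicates=8, seed=2,
                                     preprocess=False)
        H = np.vstack([p.spectrum for p in progs])
        consensus_err = reconstruction_error(X.T, usage.to_numpy(), H)
        worst = 0.0
        for rs in range(8):
            model = NMF(n_components=3, init="random", random_state=rs,
                        max_iter=500, tol=1e-4)
            W = model.fit_transform(X.T)
            worst = max(worst, reconstruction_error(X.T, W, model.components_))
        assert consensus_err <= worst + 1e-9


@pytest.fixture(scope="module")
def sample_matrix(small_cohort):
    _, m, _ = small_cohort
    return m.subset_cells((m.cell_meta["sample"] == "S01").to_numpy())


class TestProgramsForSample:
    def test_full_k_range_gives_72(self, sample_matrix):
        cfg = ProgramSetConfig(k_min=4, k_max=12, n_replicates=3, seed=0)
        progs, usages = programs_for_sample(sample_matrix, cfg)
        assert len(progs) == 72
        assert sorted(usages) == list(range(4, 13))

    def test_small_k_range_gives_sum_of_k(self, sample_matrix):
        cfg = ProgramSetConfig(k_min=2, k_max=3, n_replicates=3, seed=0)
        progs, _ = programs_for_sample(sample_matrix, cfg)
        assert len(progs) == 5

    def test_provenance(self, sample_matrix):
        cfg = ProgramSetConfig(k_min=2, k_max=3, n_replicates=3, seed=0)
        progs, _ = programs_for_sample(sample_matrix, cfg)
        keys = [(p.sample_id, p.k, p.program_index) for p in progs]
        assert keys == [("S01", 2, 0), ("S01", 2, 1),
                        ("S01", 3, 0), ("S01", 3, 1), ("S01", 3, 2)]


class TestSelectRobust:
    def test_default_thresholds_retain_recurrent_program(self):
        base = UNIVERSE[:50]
        # program sharing 40/50 with same-sample other-K and 15/50 cross-sample
        p = toy_program("S1", 4, 0, base)
        q = toy_program("S1", 5, 0, base[:40] + UNIVERSE[100:110])
        r = toy_program("S2", 4, 0, base[:15] + UNIVERSE[200:235])
        kept = select_robust([p, q, r], intra_overlap_min=35, inter_overlap_min=10)
        assert p in kept

    def test_single_k_per_sample_empty(self):
        p = toy_program("S1", 4, 0, UNIVERSE[:50])
        q = toy_program("S2", 4, 0, UNIVERSE[:50])
        assert select_robust([p, q]) == []

    def test_single_sample_warns_empty(self):
        p = toy_program("S1", 4, 0, UNIVERSE[:50])
        q = toy_program("S1", 5, 0, UNIVERSE[:50])
        with pytest.warns(UserWarning, match="two samples"):
            assert select_robust([p, q]) == []

    def test_matches_brute_force_oracle(self):
        progs = [
            toy_program("S1", 4, 0, UNIVERSE[0:50]),
            toy_program("S1", 5, 0, UNIVERSE[10:60]),
            toy_program("S1", 5, 1, UNIVERSE[200:250]),
            toy_program("S2", 4, 0, UNIVERSE[0:50]),
            toy_program("S2", 5, 0, UNIVERSE[5:55]),
            toy_program("S2", 4, 1, UNIVERSE[300:350]),
        ]
        intra, inter = 35, 10
        expected = []
        for p in progs:
            a = any(
                len(set(p.top_genes) & set(q.top_genes)) >= intra
                for q in progs
                if q is not p and q.sample_id == p.sample_id and q.k != p.k
            )
            b = any(
                len(set(p.top_genes) & set(q.top_genes)) >= inter
                for q in progs if q.sample_id != p.sample_id
            )
            if a and b:
                expected.append(p)
        assert select_robust(progs, intra, inter) == expected

    def test_subset_and_monotone_in_evidence(self):
        progs = [
            toy_program("S1", 4, 0, UNIVERSE[0:50]),
            toy_program("S1", 5, 0, UNIVERSE[10:60]),
            toy_program("S2", 4, 0, UNIVERSE[0:50]),
            toy_program("S2", 5, 0, UNIVERSE[5:55]),
        ]
        kept = select_robust(progs)
        assert all(p in progs for p in kept)
        dup = toy_program("S3", 6, 0, UNIVERSE[0:50])
        kept_more = select_robust(progs + [dup])
        assert all(p in kept_more for p in kept)


def planted_groups():
    """Three program groups with high within- and low between-overlap."""
    rng = np.random.default_rng(7)
    groups, progs = [], []
    for g in range(3):
        base = UNIVERSE[g * 60 : g * 60 + 50]
        groups.append(set(base))
        for i, sample in enumerate(["S1", "S2", "S3", "S1"]):
            core = list(rng.choice(base, size=45, replace=False))
            noise = list(rng.choice(UNIVERSE[240:], size=5, replace=False))
            progs.append(toy_program(sample, 4 + i, g, core + noise))
    return groups, progs


class TestClusterMetaprograms:
    def test_planted_partition_recovered(self):
        groups, progs = planted_groups()
        mps = cluster_metaprograms(progs)
        assert len(mps) == 3
        for mp in mps:
            best = max(range(3), key=lambda g: jaccard(set(mp.signature), groups[g]))
            assert len(set(mp.signature) & groups[best]) >= 25
            assert len(mp.member_programs) == 4

    def test_signatures_have_30_genes(self):
        _, progs = planted_groups()
        for mp in cluster_metaprograms(progs):
            assert len(mp.signature) == 30
            assert len(set(mp.signature)) == 30

    def test_single_sample_cluster_excluded(self):
        progs = [
            toy_program("S1", 4, 0, UNIVERSE[0:50]),
            toy_program("S1", 5, 0, UNIVERSE[0:50]),
            toy_program("S1", 6, 0, UNIVERSE[0:50]),
            toy_program("S2", 4, 0, UNIVERSE[100:150]),
            toy_program("S3", 4, 0, UNIVERSE[100:150]),
        ]
        mps = cluster_metaprograms(progs)
        assert len(mps) == 1
        assert mps[0].member_samples == {"S2", "S3"}

    def test_members_partition(self):
        _, progs = planted_groups()
        mps = cluster_metaprograms(progs)
        seen = [p.key for mp in mps for p in mp.member_programs]
        assert len(seen) == len(set(seen))
        assert set(seen) <= {p.key for p in progs}

    def test_truncated_signature_warns(self):
        progs = [
            toy_program("S1", 4, 0, UNIVERSE[:10]),
            toy_program("S2", 5, 0, UNIVERSE[:10]),
        ]
        with pytest.warns(UserWarning, match="truncated"):
            mps = cluster_metaprograms(progs, min_join_overlap=5)
        assert len(mps[0].signature) == 10


class TestAnnotateMp:
    def make_mp(self, signature):
        return MetaProgram("MP1", [toy_program("S1", 4, 0, signature)],
                           list(signature))

    def test_worked_hypergeometric_example(self):
        # universe of 10 genes, one set of 5, signature of 3, overlap 3:
        # p = C(5,3)/C(10,3) = 10/120
        mp = self.make_mp(UNIVERSE[:3])
        sets = GeneSetCollection(sets={"S": UNIVERSE[:5]})
        out = annotate_mp(mp, sets, universe_size=10)
        assert out.loc[0, "overlap"] == 3
        assert out.loc[0, "p"] == pytest.approx(10 / 120)

    def test_zero_overlap_gives_p_one(self):
        mp = self.make_mp(UNIVERSE[:3])
        sets = GeneSetCollection(sets={"S": UNIVERSE[100:102]})
        out = annotate_mp(mp, sets, universe_size=200)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_signature_inside_full_universe_set(self):
        mp = self.make_mp(UNIVERSE[:3])
        sets = GeneSetCollection(sets={"S": UNIVERSE[:10]})
        out = annotate_mp(mp, sets, universe_size=10)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_column_present_and_monotone(self):
        mp = self.make_mp(UNIVERSE[:10])
        sets = GeneSetCollection(sets={
            "hit": UNIVERSE[:12], "miss": UNIVERSE[300:340]})
        out = annotate_mp(mp, sets, universe_size=400)
        assert {"p", "p_adj"} <= set(out.columns)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_genes_outside_universe_counted_out(self):
        mp = self.make_mp(UNIVERSE[:3])
        sets = GeneSetCollection(sets={"S": UNIVERSE[1:6]},
                                 universe=UNIVERSE[1:200])
        with pytest.warns(UserWarning, match="absent from the universe"):
            out = annotate_mp(mp, sets, universe_size=199)
        assert out.loc[0, "overlap"] == 2
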