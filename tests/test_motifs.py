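"""Motif classification against brute-force oracles and hand-built
transformation scenarios."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pollinet import (
    AssemblyConfig,
    BinaryNetwork,
    MotifGroup,
    SpeciesRecord,
    classify,
    evaluate_trajectory,
    indirect_partners,
    run_assembly,
    summarize,
)
from pollinet.assembly import EventSnapshot
from pollinet.motifs import analyze_assembly


def net_from(M, time=None):
    M = np.asarray(M, dtype=bool)
    return BinaryNetwork(
        plant_ids=[f"p{i}" for i in range(M.shape[0])],
        poll_ids=[f"a{j}" for j in range(M.shape[1])],
        adjacency=M,
        time=time,
    )


def oracle_indirect(M, guild, idx):
    """Two-step breadth-first enumeration of same-guild indirect partners."""
    g = nx.Graph()
    n_p, n_a = M.shape
    for i in range(n_p):
        for j in range(n_a):
            if M[i, j]:
                g.add_edge(("p", i), ("a", j))
    node = ("p", idx) if guild == "plant" else ("a", idx)
    if node not in g:
        return set()
    out = set()
    for mid in g.neighbors(node):
        for nb in g.neighbors(mid):
            if nb != node and nb[0] == node[0]:
                out.add(nb)
    return out


def oracle_classify(M, guild, idx):
    """Independent re-derivation of the motif group from first principles."""
    M = np.asarray(M, dtype=bool)
    deg = M[idx].sum() if guild == "plant" else M[:, idx].sum()
    if deg == 0:
        return None
    partners = oracle_indirect(M, guild, idx)
    if not partners:
        return MotifGroup.NO_INDIRECT
    def degree(node):
        _, k = node
        return M[k].sum() if node[0] == "p" else M[:, k].sum()
    any_spec = any(degree(p) == 1 for p in partners)
    if deg == 1:
        return MotifGroup.SPEC_SPEC if any_spec else MotifGroup.SPEC_GEN
    return MotifGroup.GEN_SPEC if any_spec else MotifGroup.GEN_GEN


class TestIndirectPartners:
    def test_two_plants_sharing_one_pollinator(self):
        net = net_from([[1], [1]])
        assert indirect_partners(net, "p0") == {"p1"}
        assert indirect_partners(net, "p1") == {"p0"}

    def test_isolated_module_has_no_indirect_partners(self):
        net = net_from([[1, 0], [0, 1]])
        assert indirect_partners(net, "p0") == set()

    def test_missing_species_raises(self):
        with pytest.raises(KeyError):
            indirect_partners(net_from([[1]]), "p9")

    def test_matches_breadth_first_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            M = rng.random((8, 8)) < 0.3
            net = net_from(M)
            for i in range(8):
                if M[i].any():
                    expect = {f"p{k}" for (_, k) in oracle_indirect(M, "plant", i)}
                    assert indirect_partners(net, f"p{i}") == expect
            for j in range(8):
                if M[:, j].any():
                    expect = {f"a{k}" for (_, k) in oracle_indirect(M, "pollinator", j)}
                    assert indirect_partners(net, f"a{j}") == expect


class TestClassify:
    def test_specialist_with_indirect_specialist(self):
        # p0 and p1 both specialist on a0
        net = net_from([[1, 0], [1, 0], [0, 1]])
        assert classify(net, "p0") is MotifGroup.SPEC_SPEC

    def test_specialist_with_only_generalist_neighbors(self):
        # p0 specialist on a0; p1 visits a0 and a1 (generalist)
        net = net_from([[1, 0], [1, 1]])
        assert classify(net, "p0") is MotifGroup.SPEC_GEN

    def test_isolated_module_excluded(self):
        net = net_from([[1, 0], [0, 1]])
        assert classify(net, "p0") is MotifGroup.NO_INDIRECT

    def test_degree_zero_rejected(self):
        net = net_from([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            classify(net, "p0")

    def test_exhaustive_small_matrices(self):
        """All 3x3 binary matrices, every focal in both guilds."""
        for bits in range(2**9):
            M = np.array([(bits >> k) & 1 for k in range(9)]).reshape(3, 3)
            net = net_from(M)
            for i in range(3):
                if M[i].any():
                    assert classify(net, f"p{i}") is oracle_classify(M, "plant", i)
            for j in range(3):
                if M[:, j].any():
                    assert classify(net, f"a{j}") is oracle_classify(M, "pollinator", j)

    def test_random_5x5_sample_against_oracle(self, rng):
        for _ in range(2000):
            M = rng.random((5, 5)) < rng.uniform(0.15, 0.6)
            if M.sum() > 12:
                continue
            net = net_from(M)
            for i in range(5):
                if M[i].any():
                    assert classify(net, f"p{i}") is oracle_classify(M, "plant", i)


def scenario(arrival_M, post_M, post2_M, focal_links):
    """Build snapshots and a record for a focal plant 'p0' arriving event 0."""
    snaps = [
        EventSnapshot(0, net_from(arrival_M, 0.0), net_from(post_M, 2000.0)),
        EventSnapshot(1, net_from(post2_M, 2000.0), net_from(post2_M, 4000.0)),
    ]
    rec = SpeciesRecord(
        sid="p0",
        guild="plant",
        niche_type="specialist" if len(focal_links) == 1 else "generalist",
        arrival_time=0.0,
        arrival_event=0,
        links_at_arrival=focal_links,
        established=True,
    )
    return snaps, rec


class TestTrajectoryTransformations:
    """The four canonical motif transformations: specialist exclusion
    (Spec-Spec -> Spec-Gen, Gen-Spec -> Gen-Gen) and subsequent specialist
    establishment (Spec-Gen -> Spec-Spec, Gen-Gen -> Gen-Spec)."""

    def test_spec_spec_to_spec_gen_flags_exclusion(self):
        # p0, p1 specialists on a0; p2 generalist on a0+a1; p1 dies by +2000
        arrival = [[1, 0], [1, 0], [1, 1]]
        post = [[1, 0], [0, 0], [1, 1]]
        snaps, rec = scenario(arrival, post, post, ["a0"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_at_arrival is MotifGroup.SPEC_SPEC
        assert traj.group_post_extinction is MotifGroup.SPEC_GEN
        assert traj.specialist_exclusion_detected
        assert not traj.subsequent_specialist_establishment_detected

    def test_gen_spec_to_gen_gen_flags_exclusion(self):
        # p0 generalist on a0+a1; p1 specialist on a0 dies; p2 generalist stays
        arrival = [[1, 1], [1, 0], [1, 1]]
        post = [[1, 1], [0, 0], [1, 1]]
        snaps, rec = scenario(arrival, post, post, ["a0", "a1"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_at_arrival is MotifGroup.GEN_SPEC
        assert traj.group_post_extinction is MotifGroup.GEN_GEN
        assert traj.specialist_exclusion_detected

    def test_spec_gen_to_spec_spec_flags_subsequent_establishment(self):
        # p0 specialist on a0 beside generalist p1; new specialist p2
        # attaches to a0 during the subsequent event
        arrival = [[1, 0], [1, 1]]
        post = [[1, 0], [1, 1]]
        post2 = [[1, 0], [1, 1], [1, 0]]
        snaps, rec = scenario(arrival, post, post2, ["a0"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_at_arrival is MotifGroup.SPEC_GEN
        assert traj.group_post_extinction is MotifGroup.SPEC_GEN
        assert traj.group_post_subsequent is MotifGroup.SPEC_SPEC
        assert traj.subsequent_specialist_establishment_detected
        assert not traj.specialist_exclusion_detected

    def test_gen_gen_to_gen_spec_flags_subsequent_establishment(self):
        arrival = [[1, 1], [1, 1]]
        post = [[1, 1], [1, 1]]
        post2 = [[1, 1], [1, 1], [1, 0]]
        snaps, rec = scenario(arrival, post, post2, ["a0", "a1"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_at_arrival is MotifGroup.GEN_GEN
        assert traj.group_post_subsequent is MotifGroup.GEN_SPEC
        assert traj.subsequent_specialist_establishment_detected

    def test_unchanged_network_sets_no_flags(self):
        arrival = [[1, 0], [1, 1]]
        snaps, rec = scenario(arrival, arrival, arrival, ["a0"])
        traj = evaluate_trajectory(snaps, rec)
        assert not traj.specialist_exclusion_detected
        assert not traj.subsequent_specialist_establishment_detected

    def test_focal_niche_frozen_when_degree_changes(self):
        """Links gained from opposite-guild colonizers do not reclassify
        the focal as generalist at later timepoints."""
        arrival = [[1, 0], [1, 1]]
        post2 = [[1, 1], [1, 1]]  # focal p0 gained a1
        snaps, rec = scenario(arrival, post2, post2, ["a0"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_at_arrival is MotifGroup.SPEC_GEN
        assert traj.group_post_extinction is MotifGroup.SPEC_GEN
        assert traj.focal_type_changed  # drift is still reported separately

    def test_focal_extinct_at_later_time_truncates(self):
        arrival = [[1, 0], [1, 1]]
        post = [[0, 0], [1, 1]]
        snaps, rec = scenario(arrival, post, post, ["a0"])
        traj = evaluate_trajectory(snaps, rec)
        assert traj.group_post_extinction is None
        assert traj.truncated

    def test_last_event_trajectory_incomplete(self):
        arrival = [[1, 0], [1, 1]]
        snaps = [EventSnapshot(0, net_from(arrival, 0.0), net_from(arrival, 2000.0))]
        rec = SpeciesRecord("p0", "plant", "specialist", 0.0, 0, ["a0"], established=True)
        traj = evaluate_trajectory(snaps, rec)
        assert traj.incomplete and traj.group_post_subsequent is None


@pytest.fixture(scope="module")
def result():
    return run_assembly(AssemblyConfig(n_events=8, seed=13))


class TestSummarize:

    def test_partition_into_exactly_one_group(self, result):
        """Each considered colonizer lands in exactly one of the five
        categories at every evaluation time."""
        trajs = analyze_assembly(result)
        for traj in trajs.values():
            for g in (traj.group_at_arrival, traj.group_post_extinction):
                assert g is None or isinstance(g, MotifGroup)

    def test_counts_sum_to_eligible_colonizers(self, result):
        summary = summarize(result)
        for guild in ("plant", "pollinator"):
            sub = summary[summary.guild == guild]
            n_eligible = len(result.records_of(guild)) - 9
            considered = sub.attempted.sum() + sub.excluded_no_indirect.iloc[0]
            # failed attachments are part of the excluded bucket
            assert considered == n_eligible

    def test_first_nine_excluded_per_guild(self, result):
        summary = summarize(result)
        trajs = analyze_assembly(result)
        first9 = {r.sid for g in ("plant", "pollinator") for r in result.records_of(g)[:9]}
        classified = sum(
            1
            for sid, t in trajs.items()
            if sid not in first9 and t.group_at_arrival not in (None, MotifGroup.NO_INDIRECT)
        )
        assert summary.attempted.sum() == classified

    def test_rates_bounded(self, result):
        summary = summarize(result)
        assert ((summary.establishment_rate >= 0) & (summary.establishment_rate <= 1)).all()

    def test_empty_input_gives_zero_summary(self):
        res = run_assembly(AssemblyConfig(n_events=1, seed=0))
        summary = summarize(res)  # all colonizers are within the first nine
        assert summary.attempted.sum() == 0 and summary.established.sum() == 0
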