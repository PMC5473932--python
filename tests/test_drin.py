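import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdrin.drin import (
    DRINGraph,
    combine_drins,
    compile_drin,
    differential_drin,
    export_graph,
    load_graphml,
    max_lifetime,
    read_drin_tsv,
    threshold_merge,
    write_drin_tsv,
)
from mdrin.rin import AdjacencySeries


def longest_run_oracle(seq):
    best = run = 0
    for v in seq:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def all_windows_oracle(seq):
    """Literal scan of every (start, length) window for all-ones."""
    n = len(seq)
    best = 0
    for t0 in range(n):
        for t1 in range(t0, n):
            if all(seq[t0 : t1 + 1]):
                best = max(best, t1 - t0 + 1)
            else:
                break
    return best


class TestMaxLifetime:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([0, 0, 0], 0),
            ([1] * 17, 17),
            ([1, 1, 0, 1, 1, 1, 0, 1], 3),
            ([], 0),
            ([1], 1),
        ],
    )
    def test_known_sequences(self, seq, expected):
        assert max_lifetime(seq) == expected
        assert all_windows_oracle(seq) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            max_lifetime([0, 2, 1])

    @given(seq=st.lists(st.integers(0, 1), min_size=0, max_size=200))
    @settings(max_examples=500, deadline=None)
    def test_equals_brute_force_on_random_sequences(self, seq):
        assert max_lifetime(seq) == longest_run_oracle(seq)

    @given(
        seq=st.lists(st.integers(0, 1), min_size=1, max_size=100),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_bit_flips(self, seq, data):
        """Turning any 0 into a 1 never decreases the lifetime."""
        before = max_lifetime(seq)
        zeros = [i for i, v in enumerate(seq) if v == 0]
        if not zeros:
            return
        i = data.draw(st.sampled_from(zeros))
        flipped = list(seq)
        flipped[i] = 1
        assert max_lifetime(flipped) >= before


def series(kind, pair, bits):
    return AdjacencySeries(kind=kind, pair=pair, values=np.array(bits, dtype=np.uint8))


class TestCompile:
    def test_empty_input_empty_graph(self):
        assert compile_drin([], state="ox") == {}

    def test_scripted_runs_zero_lifetime_dropped(self):
        from mdrin.synthetic import make_adjacency_schedule

        specs = {(1, 4): 7, (11, 14): 0, (21, 24): 100}
        ser = [
            series("hbond", pair, make_adjacency_schedule(100, lr, seed=pair[0]))
            for pair, lr in specs.items()
        ]
        graphs = compile_drin(ser, state="ox")
        assert graphs["hbond"].edges == {(1, 4): 7, (21, 24): 100}

    def test_random_series_match_oracle(self, rng):
        ser = [
            series("vdw", (2 * i + 1, 2 * i + 4), rng.integers(0, 2, size=60))
            for i in range(20)
        ]
        graphs = compile_drin(ser, state="red")
        for s in ser:
            want = longest_run_oracle(s.values)
            assert graphs["vdw"].gamma(*s.pair) == want

    def test_length_mismatch_rejected(self):
        ser = [series("hbond", (1, 4), [1, 0]), series("hbond", (2, 5), [1, 0, 1])]
        with pytest.raises(ValueError, match="lengths"):
            compile_drin(ser, state="ox")

    def test_combine_takes_max_across_trajectories(self):
        g1 = DRINGraph(state="ox", kind="hbond", n_frames=50,
                       edges={(1, 4): 10, (2, 6): 3})
        g2 = DRINGraph(state="ox", kind="hbond", n_frames=50, edges={(1, 4): 7})
        combined = combine_drins([g1, g2])
        assert combined.edges == {(1, 4): 10, (2, 6): 3}


class TestDifferential:
    def test_equal_persistence_gives_zero(self):
        ox = DRINGraph(state="ox", kind="hbond", n_frames=100, edges={(1, 4): 10})
        red = DRINGraph(state="red", kind="hbond", n_frames=100, edges={(1, 4): 10})
        for eps in (0.5, 1.0, 3.0):
            diff = differential_drin(ox, red, eps=eps)
            assert diff.edges[(1, 4)].delta == 0.0

    def test_direct_evaluation_sixteen_vs_zero(self):
        ox = DRINGraph(state="ox", kind="hbond", n_frames=100, edges={(1, 4): 16})
        red = DRINGraph(state="red", kind="hbond", n_frames=100, edges={})
        diff = differential_drin(ox, red, eps=1.0)
        assert diff.edges[(1, 4)].delta == pytest.approx(math.log2(17), abs=1e-12)

    def test_antisymmetry_under_state_swap(self, rng):
        pairs = [(2 * i + 1, 2 * i + 5) for i in range(30)]
        ox = DRINGraph(
            state="ox", kind="vdw", n_frames=200,
            edges={p: int(g) for p, g in zip(pairs, rng.integers(1, 200, 30))
                   if rng.random() > 0.3},
        )
        red = DRINGraph(
            state="red", kind="vdw", n_frames=200,
            edges={p: int(g) for p, g in zip(pairs, rng.integers(1, 200, 30))
                   if rng.random() > 0.3},
        )
        fwd = differential_drin(ox, red, eps=1.0)
        rev = differential_drin(red, ox, eps=1.0)
        assert set(fwd.edges) == set(rev.edges)
        for pair, e in fwd.edges.items():
            assert rev.edges[pair].delta == -e.delta
            assert (e.delta == 0.0) == (e.gamma_ox == e.gamma_red)

    def test_monotone_in_each_argument(self):
        def delta(g_ox, g_red):
            ox = DRINGraph(state="ox", kind="hbond", n_frames=100,
                           edges={(1, 4): g_ox} if g_ox else {})
            red = DRINGraph(state="red", kind="hbond", n_frames=100,
                            edges={(1, 4): g_red} if g_red else {})
            return differential_drin(ox, red, eps=1.0).edges[(1, 4)].delta

        for g in range(0, 99):
            assert delta(g + 1, 10) > delta(g, 10)
            assert delta(10, g + 1) < delta(10, g)

    def test_nonpositive_eps_rejected(self):
        ox = DRINGraph(state="ox", kind="hbond", n_frames=10, edges={(1, 4): 5})
        red = DRINGraph(state="red", kind="hbond", n_frames=10, edges={})
        with pytest.raises(ValueError, match="eps"):
            differential_drin(ox, red, eps=0.0)

    def test_type_mismatch_rejected(self):
        ox = DRINGraph(state="ox", kind="hbond", n_frames=10, edges={(1, 4): 5})
        red = DRINGraph(state="red", kind="vdw", n_frames=10, edges={})
        with pytest.raises(ValueError, match="types differ"):
            differential_drin(ox, red)


def two_type_diffs():
    ox_h = DRINGraph(state="ox", kind="hbond", n_frames=100,
                     edges={(1, 4): 50, (2, 6): 10, (3, 8): 9})
    red_h = DRINGraph(state="red", kind="hbond", n_frames=100,
                      edges={(1, 4): 2, (2, 6): 9, (3, 8): 40})
    ox_s = DRINGraph(state="ox", kind="salt_bridge", n_frames=100,
                     edges={(1, 4): 60})
    red_s = DRINGraph(state="red", kind="salt_bridge", n_frames=100, edges={})
    return [
        differential_drin(ox_h, red_h, eps=1.0),
        differential_drin(ox_s, red_s, eps=1.0),
    ]


class TestMergeAndExport:
    def test_cutoff_filters_edges(self):
        diffs = two_type_diffs()
        # hand count: |Delta| >= 1 keeps (1,4) hbond, (3,8) hbond, (1,4) salt
        merged = threshold_merge(diffs, cutoff=1.0)
        assert merged.number_of_edges() == 3

    def test_cutoff_zero_keeps_all(self):
        diffs = two_type_diffs()
        total = sum(len(d.edges) for d in diffs)
        assert threshold_merge(diffs, cutoff=0.0).number_of_edges() == total

    def test_parallel_typed_edges_survive(self):
        merged = threshold_merge(two_type_diffs(), cutoff=1.0)
        kinds = {d["kind"] for _, _, d in merged.edges(1, data=True)}
        assert kinds == {"hbond", "salt_bridge"}

    def test_node_size_is_max_incident_delta(self):
        merged = threshold_merge(two_type_diffs(), cutoff=1.0)
        deltas = [abs(d["delta"]) for _, _, d in merged.edges(1, data=True)]
        assert merged.nodes[1]["size"] == pytest.approx(max(deltas))

    def test_display_weight_sigmoid(self):
        ox = DRINGraph(state="ox", kind="hbond", n_frames=10, edges={(1, 4): 5})
        red = DRINGraph(state="red", kind="hbond", n_frames=10, edges={(1, 4): 5})
        merged = threshold_merge([differential_drin(ox, red)], cutoff=0.0)
        (_, _, d), = merged.edges(data=True)
        assert d["delta"] == 0.0
        assert d["display_weight"] == 0.0  # zero fold change draws thin/grey

    def test_graphml_round_trip_preserves_deltas(self, tmp_path):
        merged = threshold_merge(two_type_diffs(), cutoff=0.0)
        path = export_graph(merged, tmp_path / "diff.graphml")
        back = load_graphml(path)
        assert back.number_of_edges() == merged.number_of_edges()
        want = sorted(
            (u, v, d["kind"], d["delta"]) for u, v, d in merged.edges(data=True)
        )
        got = sorted(
            (u, v, d["kind"], d["delta"]) for u, v, d in back.edges(data=True)
        )
        for w, g in zip(want, got):
            assert w[:3] == g[:3]
            assert abs(w[3] - g[3]) < 1e-9

    def test_sif_export_with_attribute_tables(self, tmp_path):
        merged = threshold_merge(two_type_diffs(), cutoff=1.0)
        path = export_graph(merged, tmp_path / "diff.sif", fmt="sif")
        assert len(path.read_text().splitlines()) == 3
        edges = path.with_suffix(".edges.tsv").read_text().splitlines()
        nodes = path.with_suffix(".nodes.tsv").read_text().splitlines()
        assert len(edges) == 4  # header + 3
        assert "delta" in edges[0] and "size" in nodes[0]

    def test_empty_graph_export_rejected(self, tmp_path):
        import networkx as nx

        with pytest.raises(ValueError, match="empty"):
            export_graph(nx.MultiGraph(), tmp_path / "x.graphml")

    def test_drin_tsv_round_trip(self, tmp_path):
        graphs = {
            "hbond": DRINGraph(state="ox", kind="hbond", n_frames=100,
                               edges={(1, 4): 50, (2, 6): 10}),
            "vdw": DRINGraph(state="ox", kind="vdw", n_frames=100,
                             edges={(3, 9): 4}),
        }
        path = write_drin_tsv(graphs, tmp_path / "drin.tsv")
        assert read_drin_tsv(path) == graphs
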