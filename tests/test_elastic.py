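"""Elastic-network construction, the common-constraints filter, topology I/O."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from comdyn.elastic import (
    ENParams,
    TopologyError,
    build_network,
    comdyn_filter,
    read_topology,
    write_topology,
)
from comdyn.structures import map_residues


def brute_force_pairs(s, params):
    """Independent all-pairs enumeration oracle."""
    out = set()
    for i in range(s.n_beads):
        for j in range(i + 1, s.n_beads):
            d = np.linalg.norm(s.coords[i] - s.coords[j])
            if not params.lower_cutoff <= d <= params.upper_cutoff:
                continue
            if (
                s.chain_ids[i] == s.chain_ids[j]
                and abs(int(s.resids[i]) - int(s.resids[j])) < params.min_seq_sep
            ):
                continue
            out.add((i, j))
    return out


class TestBuildNetwork:
    def test_three_collinear_beads(self, chain_factory):
        s = chain_factory([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0]])
        params = ENParams(lower_cutoff=0.3, upper_cutoff=0.7, min_seq_sep=1)
        net = build_network(s, params)
        assert net.pairs == {(0, 1), (1, 2)}
        np.testing.assert_allclose(net.d0, [0.38, 0.38])

    def test_empty_when_upper_below_spacing(self, chain_factory):
        s = chain_factory([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        net = build_network(s, ENParams(lower_cutoff=0.5, upper_cutoff=0.9))
        assert len(net) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_clouds(self, chain_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        s = chain_factory(rng.uniform(0, 3.0, size=(n, 3)))
        params = ENParams()
        net = build_network(s, params)
        assert net.pairs == brute_force_pairs(s, params)

    def test_min_seq_sep_ignored_across_chains(self, chain_factory):
        import numpy as np
        from comdyn.structures import BeadStructure

        s = BeadStructure(
            chain_ids=np.array(["A", "B"], dtype=object),
            resids=np.array([1, 1]),
            resnames=np.array(["ALA", "ALA"], dtype=object),
            coords=np.array([[0.0, 0, 0], [0.6, 0, 0]]),
        )
        net = build_network(s, ENParams())
        assert net.pairs == {(0, 1)}


class TestComdynFilter:
    def test_identical_states_keep_everything(self, chain_factory):
        rng = np.random.default_rng(7)
        s = chain_factory(rng.uniform(0, 2.5, size=(40, 3)))
        rmap = map_residues(s, s, mode="identity")
        net = build_network(s)
        res = comdyn_filter(net, s, s, rmap)
        assert res.n_kept == res.n_input == len(net)
        assert res.kept_fraction == 1.0

    def test_rigid_body_transform_keeps_everything(self, chain_factory):
        rng = np.random.default_rng(8)
        s = chain_factory(rng.uniform(0, 2.5, size=(40, 3)))
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        other = s.with_coords(s.coords @ rot.T + np.array([1.0, -2.0, 3.0]))
        res = comdyn_filter(
            build_network(s), s, other, map_residues(s, other, mode="identity")
        )
        assert res.kept_fraction == 1.0

    def test_six_bead_fixture_with_known_deltas(self, chain_factory):
        # beads on a line, spaced 0.6 nm; state B stretches the two end
        # gaps so exactly the constraints touching bead 0 change > 0.1 nm
        a = chain_factory([[0.6 * k, 0, 0] for k in range(4)])
        b_coords = np.array([[0.0, 0, 0], [0.8, 0, 0], [1.4, 0, 0], [2.0, 0, 0]])
        b = a.with_coords(b_coords)
        params = ENParams(lower_cutoff=0.5, upper_cutoff=0.7, min_seq_sep=1)
        net = build_network(a, params)  # (0,1),(1,2),(2,3) at 0.6
        res = comdyn_filter(net, a, b, map_residues(a, b, mode="identity"), params)
        assert res.n_input == 3
        assert res.n_kept == 2
        assert set(zip(res.dropped.i, res.dropped.j)) == {(0, 1)}
        assert res.dropped.delta.iloc[0] == pytest.approx(0.2)

    def test_kept_count_monotone_in_threshold(self, bundle):
        net = build_network(bundle.state_a)
        kept = [
            comdyn_filter(
                net, bundle.state_a, bundle.state_b, bundle.residue_map,
                ENParams(comdyn_threshold=thr),
            ).n_kept
            for thr in (0.02, 0.05, 0.1, 0.2, 0.5)
        ]
        assert kept == sorted(kept)
        assert kept[-1] == len(net)

    def test_filter_output_is_subset(self, bundle):
        net = build_network(bundle.state_a)
        res = comdyn_filter(net, bundle.state_a, bundle.state_b, bundle.residue_map)
        assert res.filtered.pairs <= net.pairs
        assert res.n_kept + len(res.dropped) == res.n_input

    def test_unmapped_endpoints_dropped_by_default(self, chain_factory):
        rng = np.random.default_rng(9)
        a = chain_factory(rng.uniform(0, 2.0, size=(30, 3)))
        b = a.with_coords(a.coords)
        # map only the first 20 residues
        rmap = map_residues(
            a, b, mode="explicit", spans=[("A", 1, 20, "A", 1)]
        )
        net = build_network(a)
        involves_unmapped = sum(
            1 for i, j in zip(net.i, net.j) if i >= 20 or j >= 20
        )
        res_drop = comdyn_filter(net, a, b, rmap, unmapped="drop")
        res_keep = comdyn_filter(net, a, b, rmap, unmapped="keep")
        assert res_drop.n_kept == len(net) - involves_unmapped
        assert res_keep.n_kept == len(net)


class TestTopologyIO:
    def test_formatting_contract(self, chain_factory, tmp_path):
        s = chain_factory([[0, 0, 0], [0.38, 0, 0]])
        net = build_network(s, ENParams(lower_cutoff=0.3, upper_cutoff=0.5,
                                        min_seq_sep=1))
        p = tmp_path / "net.itp"
        write_topology(net, p)
        data_lines = [
            l for l in p.read_text().splitlines()
            if l and not l.startswith((";", "["))
        ]
        assert data_lines == ["1 2 1 0.38000 500"]

    def test_roundtrip_random_network(self, chain_factory, tmp_path):
        rng = np.random.default_rng(11)
        s = chain_factory(rng.uniform(0, 2.5, size=(80, 3)))
        net = build_network(s)
        assert len(net) >= 100
        p = tmp_path / "net.itp"
        write_topology(net, p)
        back = read_topology(p)
        assert back.pairs == net.pairs
        np.testing.assert_allclose(back.d0, net.d0, atol=1e-5)
        np.testing.assert_allclose(back.k, net.k)
        assert back.params == net.params

    def test_empty_section(self, tmp_path):
        p = tmp_path / "empty.itp"
        p.write_text("[ bonds ]\n")
        assert len(read_topology(p)) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.itp"
        p.write_text("[ bonds ]\n1 2 1 0.38000 500\n1 2 badness\n")
        with pytest.raises(TopologyError, match=":3"):
            read_topology(p)

    def test_unknown_funct_rejected(self, tmp_path):
        p = tmp_path / "funct.itp"
        p.write_text("1 2 9 0.38000 500\n")
        with pytest.raises(TopologyError, match="funct"):
            read_topology(p)
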