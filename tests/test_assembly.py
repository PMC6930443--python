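"""Assembly construction, validation rules, and kill-graph reduction."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clicksim as cs
from clicksim.assembly import Assembly, KillEdge, MaturationEdge, Population, Stage


def _pops(n, lineage="x", stage=Stage.YOUNG):
    return tuple(
        Population(id=f"n{i}", lineage=lineage, stage=stage, growth_rate=1.0)
        for i in range(n))


def _kill_assembly(n, edges):
    return Assembly(populations=_pops(n),
                    kill_edges=tuple(KillEdge(f"n{i}", f"n{j}") for i, j in edges))


class TestValidation:
    def test_canonical_4click_is_strict_valid(self, canonical):
        report = cs.validate_assembly(canonical, strict=True)
        assert report.valid
        assert report.violations == ()

    def test_mutual_kill_edges_violate_directionality(self):
        a = _kill_assembly(2, [(0, 1), (1, 0)])
        report = cs.validate_assembly(a)
        assert not report.valid
        assert any(v.rule == "click-exclusivity" for v in report.violations)

    def test_cross_lineage_maturation_is_a_lineage_violation(self):
        pops = (
            Population(id="hy", lineage="helper", stage=Stage.YOUNG),
            Population(id="cm", lineage="cytotoxic", stage=Stage.MATURE),
        )
        a = Assembly(populations=pops,
                     maturation_edges=(MaturationEdge("hy", "cm", 0.1),))
        report = cs.validate_assembly(a, strict=True)
        assert not report.valid
        assert any(v.rule == "maturation-lineage" for v in report.violations)

    def test_strict_flags_backwards_within_lineage_kill(self):
        pops = (
            Population(id="y", lineage="l", stage=Stage.YOUNG),
            Population(id="m", lineage="l", stage=Stage.MATURE),
        )
        a = Assembly(populations=pops, kill_edges=(KillEdge("m", "y"),))
        assert cs.validate_assembly(a, strict=False).valid
        report = cs.validate_assembly(a, strict=True)
        assert any(v.rule == "canonical-wiring" for v in report.violations)

    def test_dangling_reference_is_reported_not_raised(self):
        a = Assembly(populations=_pops(1), kill_edges=(KillEdge("n0", "ghost"),))
        report = cs.validate_assembly(a)
        assert not report.valid
        assert any(v.rule == "dangling-reference" for v in report.violations)

    def test_validation_is_idempotent(self, canonical):
        r1 = cs.validate_assembly(canonical, strict=True)
        r2 = cs.validate_assembly(canonical, strict=True)
        assert r1 == r2

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_bad_rates_are_violations(self, bad):
        pops = (Population(id="p", lineage="l", stage=Stage.YOUNG, growth_rate=bad),)
        report = cs.validate_assembly(Assembly(populations=pops))
        assert not report.valid


class TestSmallestCycle:
    def test_canonical_kill_cycle_has_length_four(self, canonical):
        cycle = cs.smallest_directed_cycle(canonical)
        assert len(cycle) == 4
        # killer -> victim orientation around the click cycle
        assert cycle == ["Tc", "Tnk", "Th", "Tr1"]

    def test_embedded_three_cycle_beats_six_cycle(self):
        edges = [(i, (i + 1) % 6) for i in range(6)]  # 6-cycle
        edges += [(0, 2), (2, 4), (4, 0)]             # embedded 3-cycle
        a = _kill_assembly(6, edges)
        cycle = cs.smallest_directed_cycle(a)
        assert len(cycle) == 3
        assert sorted(cycle) == ["n0", "n2", "n4"]

    def test_directed_path_is_acyclic(self):
        a = _kill_assembly(3, [(0, 1), (1, 2)])
        assert cs.smallest_directed_cycle(a) == []

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(3, 8))
    def test_matches_exhaustive_enumeration(self, seed, n):
        """BFS reduction agrees with brute-force simple-cycle enumeration."""
        rng = np.random.default_rng(seed)
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                u = rng.random()
                if u < 0.35:
                    edges.append((i, j))
                elif u < 0.7:
                    edges.append((j, i))
        a = _kill_assembly(n, edges)
        got = cs.smallest_directed_cycle(a)
        g = nx.DiGraph([(f"n{i}", f"n{j}") for i, j in edges])
        g.add_nodes_from(f"n{i}" for i in range(n))
        cycles = list(nx.simple_cycles(g))
        if not cycles:
            assert got == []
        else:
            shortest = min(len(c) for c in cycles)
            assert len(got) == shortest
            assert len(got) >= 3  # one edge per unordered pair forbids 2-cycles
            # reported cycle is a real cycle of the graph
            assert all(g.has_edge(got[k], got[(k + 1) % len(got)])
                       for k in range(len(got)))
            # tie-break: no shortest cycle sorts lexicographically earlier
            assert sorted(got) == min(
                sorted(sorted(c) for c in cycles if len(c) == shortest))


class TestCanonicalBuilder:
    def test_shipped_structure(self, canonical):
        assert len(canonical.populations) == 4
        assert len(canonical.kill_edges) == 4
        assert len(canonical.maturation_edges) == 2
        assert any(b.target == "Th" for b in canonical.bystander_inputs)

    def test_builder_is_deterministic(self):
        assert cs.build_canonical_4click() == cs.build_canonical_4click()

    def test_zero_kill_override_stays_valid(self):
        a = cs.build_canonical_4click({
            f"{e.killer}>{e.victim}.kill_rate": 0.0
            for e in cs.build_canonical_4click().kill_edges})
        assert all(e.kill_rate == 0.0 for e in a.kill_edges)
        assert cs.validate_assembly(a, strict=True).valid

    def test_unknown_override_key_raises(self):
        with pytest.raises(KeyError):
            cs.build_canonical_4click({"foo": 1.0})
        with pytest.raises(KeyError):
            cs.build_canonical_4click({"Tc.foo": 1.0})


class TestRandomAssembly:
    def test_two_lineages_pass_strict_validation(self):
        a = cs.random_assembly(2, rng_seed=1)
        assert len(a.populations) == 4
        assert cs.validate_assembly(a, strict=True).valid

    def test_three_lineages_have_cycle_length_at_least_three(self):
        a = cs.random_assembly(3, rng_seed=7)
        assert len(a.populations) == 6
        assert len(cs.smallest_directed_cycle(a)) >= 3

    def test_single_lineage_rejected(self):
        with pytest.raises(ValueError):
            cs.random_assembly(1, rng_seed=0)

    def test_same_seed_reproduces_assembly(self):
        assert cs.random_assembly(3, rng_seed=5) == cs.random_assembly(3, rng_seed=5)


class TestSerialization:
    def test_round_trip(self, canonical, tmp_path):
        path = tmp_path / "a.json"
        cs.save_assembly(canonical, path)
        assert cs.load_assembly(path) == canonical

    def test_reader_rejects_malformed(self, tmp_path):
        with pytest.raises(ValueError):
            cs.assembly_from_dict({"kill_edges": []})
        with pytest.raises(ValueError):
            cs.assembly_from_dict({"populations": [{"lineage": "x"}]})
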