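"""Terminology engine: snapshots, descendants, expansion, membership."""

from __future__ import annotations

from collections import deque

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microfhir import codes, systems
from microfhir.errors import (
    ConfigurationError,
    SnapshotParseError,
    StructuralError,
    UnknownConceptError,
)
from microfhir.terminology import (
    CodeSystemSnapshot,
    ConceptRef,
    IncludeRoot,
    IntensionalRule,
    SnapshotRegistry,
    ValueSetDef,
    contains,
    descendants,
    expand,
    load_snapshot,
)


class TestConceptRef:
    def test_identity_ignores_display(self):
        a = ConceptRef(system=systems.SNOMED, code="260373001", display="Detected")
        b = ConceptRef(system=systems.SNOMED, code="260373001")
        assert a == b and hash(a) == hash(b)

    @pytest.mark.parametrize("code", ["", "a b", "x\t", " "])
    def test_rejects_bad_codes(self, code):
        with pytest.raises(ValueError):
            ConceptRef(system=systems.SNOMED, code=code)

    def test_rejects_unregistered_system(self):
        with pytest.raises(ValueError):
            ConceptRef(system="http://not-a-real-terminology.invalid", code="1")


class TestSnapshotLoading:
    def test_concept_count_equals_row_count(self, registry, tmp_path):
        from microfhir.synth import SNOMED_FIXTURE_ROWS, LOINC_FIXTURE_ROWS

        assert len(registry.get(systems.SNOMED).codes) == len(SNOMED_FIXTURE_ROWS)
        assert len(registry.get(systems.LOINC).codes) == len(LOINC_FIXTURE_ROWS)

    def test_tabular_snapshot_has_no_edges(self, registry):
        snap = registry.get(systems.LOINC)
        assert snap.dialect == "tabular"
        assert snap.graph is None and snap.parts is not None

    def test_cycle_is_rejected(self, tmp_path):
        path = tmp_path / "cyclic.tsv"
        path.write_text(
            "#system=https://example.org/fhir/microbiology/CodeSystem/toy\n"
            "code\tdisplay\tparent_codes\nA\ta\tB\nB\tb\tA\n"
        )
        with pytest.raises(StructuralError, match="cycle"):
            load_snapshot(path, "hierarchical")

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#system=https://example.org/fhir/microbiology/CodeSystem/toy\n"
            "code\tdisplay\tparent_codes\nA\ta\t\nB\n"
        )
        with pytest.raises(SnapshotParseError) as exc:
            load_snapshot(path, "hierarchical")
        assert exc.value.line == 4

    def test_undeclared_parent_is_rejected(self, tmp_path):
        path = tmp_path / "orphan.tsv"
        path.write_text(
            "#system=https://example.org/fhir/microbiology/CodeSystem/toy\n"
            "code\tdisplay\tparent_codes\nA\ta\tZZZ\n"
        )
        with pytest.raises(SnapshotParseError, match="ZZZ"):
            load_snapshot(path, "hierarchical")

    def test_missing_file_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_snapshot(tmp_path / "nope.tsv", "tabular")


class TestDescendants:
    def test_strict_descendants_exclude_root(self, registry):
        snap = registry.get(systems.SNOMED)
        out = descendants(snap, codes.ORGANISM_ROOT, include_self=False)
        assert codes.ORGANISM_ROOT not in out
        assert codes.E_COLI in out

    def test_leaf_has_no_descendants(self, registry):
        snap = registry.get(systems.SNOMED)
        assert descendants(snap, codes.E_COLI) == set()

    def test_resistance_chain_is_transitive(self, registry):
        # 409793007 -> 707497007 -> 726492000 (chained children)
        snap = registry.get(systems.SNOMED)
        out = descendants(snap, codes.RESISTANT_BACTERIA_ROOT)
        assert {codes.CARBAPENEM_RESISTANT, codes.CARBAPENEM_RESISTANT_PA} <= out

    def test_unknown_root_raises(self, registry):
        with pytest.raises(UnknownConceptError):
            descendants(registry.get(systems.SNOMED), "000000000")

    @given(data=st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bfs_oracle_on_random_dags(self, data):
        """descendants() equals breadth-first reachability on random DAGs."""
        n = data.draw(st.integers(min_value=2, max_value=200))
        raw = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)),
                max_size=3 * n,
            )
        )
        # orient every edge low->high: guaranteed acyclic
        edges = {(f"N{min(a, b)}", f"N{max(a, b)}") for a, b in raw if a != b}
        displays = {f"N{i}": f"node {i}" for i in range(n)}
        graph = nx.DiGraph()
        graph.add_nodes_from(displays)
        graph.add_edges_from(edges)
        snap = CodeSystemSnapshot(
            system=systems.NAMESPACE + "CodeSystem/random-dag",
            displays=displays,
            graph=graph,
        )
        adj: dict[str, set[str]] = {c: set() for c in displays}
        for parent, child in edges:
            adj[parent].add(child)
        root = f"N{data.draw(st.integers(0, n - 1))}"
        seen, queue = set(), deque([root])
        while queue:
            for child in adj[queue.popleft()]:
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
        assert descendants(snap, root) == seen
        assert descendants(snap, root, include_self=True) == seen | {root}


class TestExpand:
    def test_colony_count_vs_is_exactly_four_codes(self, registry, catalog):
        out = expand(catalog.resolve("colony-count-codes"), registry)
        assert {c.code for c in out} == {"49223-1", "564-5", "38436-2", "20774-6"}

    def test_organism_vs_excludes_kingdom_subtrees(self, registry, catalog):
        out = {c.code for c in expand(catalog.resolve("organism"), registry)}
        assert codes.E_COLI in out and codes.P_AERUGINOSA in out
        # excluded roots and everything below them are gone (or-self semantics)
        for excluded in codes.ORGANISM_EXCLUSIONS:
            assert excluded not in out
        assert "990000102" not in out  # child of Kingdom Animalia

    def test_genotyping_method_is_excluded_from_susceptibility_vs(self, registry, catalog):
        out = {c.code for c in expand(catalog.resolve("susceptibility-tests"), registry)}
        assert "18945-6" in out
        assert "99998-9" not in out  # Method = Genotyping

    def test_extensional_expansion_is_duplicate_free_and_order_insensitive(self, registry):
        members = tuple(
            ConceptRef(system=systems.SNOMED, code=c) for c in ("10828004", "260385009")
        )
        vs_a = ValueSetDef(url="urn:a", kind="extensional", members=members)
        vs_b = ValueSetDef(url="urn:b", kind="extensional", members=members[::-1] + members)
        assert expand(vs_a, registry) == expand(vs_b, registry)
        assert len(expand(vs_b, registry)) == 2

    def test_missing_snapshot_is_configuration_error(self, catalog):
        with pytest.raises(ConfigurationError):
            expand(catalog.resolve("organism"), SnapshotRegistry())


class TestContains:
    def test_detection_vs_membership(self, registry, catalog):
        vs = catalog.resolve("detection-result")
        assert contains(vs, ConceptRef(system=systems.SNOMED, code="260373001"), registry)
        # 10828004 Positive belongs to the molecular/serology result VS instead
        assert not contains(vs, ConceptRef(system=systems.SNOMED, code="10828004"), registry)

    def test_empty_extensional_vs_contains_nothing(self, registry):
        vs = ValueSetDef(url="urn:empty", kind="extensional", members=())
        assert not contains(vs, codes.DETECTED, registry)

    def test_unknown_code_raises_for_intensional_vs(self, registry, catalog):
        with pytest.raises(UnknownConceptError):
            contains(
                catalog.resolve("organism"),
                ConceptRef(system=systems.SNOMED, code="000000000"),
                registry,
            )

    def test_agrees_with_expand_for_every_vs_and_fixture_concept(self, registry, catalog):
        """contains(vs, c) <=> c in expand(vs), exhaustively on the fixtures."""
        concepts = [
            registry.get(system).ref(code)
            for system in (systems.SNOMED, systems.LOINC)
            for code in sorted(registry.get(system).codes)
        ]
        for vs in catalog.values():
            expansion = expand(vs, registry)
            for concept in concepts:
                assert contains(vs, concept, registry) == (concept in expansion), (
                    vs.name,
                    concept.code,
                )

    def test_exclusion_dominates_inclusion(self, registry, catalog):
        # under the organism include root AND under an excluded kingdom
        vs = catalog.resolve("organism")
        inside_excluded = ConceptRef(system=systems.SNOMED, code="990000102")
        assert not contains(vs, inside_excluded, registry)
        assert inside_excluded not in expand(vs, registry)


class TestRuleShapes:
    def test_rule_needs_exactly_one_family(self):
        with pytest.raises(ValueError):
            IntensionalRule(system=systems.SNOMED)
        with pytest.raises(ValueError):
            IntensionalRule(
                system=systems.SNOMED,
                include_roots=(IncludeRoot(code="1"),),
                part_constraints=(
                    {"part": "property", "op": "equals", "value": "Susc"},
                ),
            )

    def test_valueset_kind_must_match_payload(self):
        with pytest.raises(ValueError):
            ValueSetDef(url="urn:x", kind="extensional")
        with pytest.raises(ValueError):
            ValueSetDef(url="urn:x", kind="intensional", members=())
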