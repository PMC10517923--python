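"""Synthetic data: fixture generation, LIS tables, conversion, end-to-end."""

from __future__ import annotations

import pytest

from microfhir import codes, fhir_io, validation
from microfhir.mrgn import classify
from microfhir.synth import (
    SynthConfig,
    generate_lab_table,
    generate_snapshot_fixtures,
    susceptibility_panels,
    table_to_observations,
)
from microfhir.terminology import (
    ancestors,
    default_catalog,
    default_registry,
    load_snapshot,
)
from microfhir import systems


class TestSnapshotFixtures:
    def test_regeneration_is_byte_identical(self, tmp_path):
        first = generate_snapshot_fixtures(tmp_path / "a")
        second = generate_snapshot_fixtures(tmp_path / "b")
        for key in first:
            assert first[key].read_bytes() == second[key].read_bytes()

    def test_bundled_data_equals_generator_output(self, tmp_path):
        from importlib import resources

        generated = generate_snapshot_fixtures(tmp_path)
        data_dir = resources.files("microfhir").joinpath("data")
        for path in generated.values():
            assert path.read_bytes() == data_dir.joinpath(path.name).read_bytes()

    def test_carbapenem_resistance_chain_is_wired(self, tmp_path):
        paths = generate_snapshot_fixtures(tmp_path)
        snap = load_snapshot(paths["snomed_mini"], "hierarchical")
        lineage = ancestors(snap, codes.CARBAPENEM_RESISTANT_PA)
        assert codes.CARBAPENEM_RESISTANT in lineage
        assert codes.RESISTANT_BACTERIA_ROOT in lineage

    def test_methicillin_row_enables_the_susceptibility_rule(self, tmp_path):
        paths = generate_snapshot_fixtures(tmp_path)
        snap = load_snapshot(paths["loinc_mini"], "tabular")
        assert snap.parts["18945-6"]["property"] == "Susc"
        assert snap.parts["99998-9"]["method"] == "Genotyping"


class TestLabTable:
    def test_same_seed_same_table(self):
        cfg = SynthConfig(seed=1, n_results=100)
        a, b = generate_lab_table(cfg), generate_lab_table(cfg)
        assert a.equals(b)

    def test_different_seed_different_table(self):
        a = generate_lab_table(SynthConfig(seed=1, n_results=100))
        b = generate_lab_table(SynthConfig(seed=2, n_results=100))
        assert not a.equals(b)

    def test_all_ten_kinds_present_at_fifty_rows(self):
        from microfhir.synth import kind_for_test_code

        table = generate_lab_table(SynthConfig(seed=4, n_results=50))
        kinds = {
            kind_for_test_code(r["test_code"], r["test_system"])
            for r in table.to_dict("records")
        }
        assert len(kinds - {None}) == 10

    def test_zero_positivity_means_no_detected_or_positive_rows(self):
        table = generate_lab_table(SynthConfig(seed=5, n_results=200, positivity_rate=0))
        forbidden = {codes.DETECTED.code, codes.POSITIVE.code, codes.WEAKLY_POSITIVE.code}
        assert not table["result_code_or_value"].isin(forbidden).any()

    def test_susceptibility_rows_always_carry_scheme_and_version(self):
        table = generate_lab_table(SynthConfig(seed=6, n_results=300))
        susc = table[table["interpretation"] != ""]
        assert len(susc) > 0
        assert (susc["scheme"] != "").all()
        assert (susc["scheme_version"] != "").all()

    def test_full_resistance_classifies_every_panel_4mrgn(self):
        cfg = SynthConfig(
            seed=7, n_results=300, positivity_rate=0.6, resistance_rate=1.0,
            carbapenemase_rate=0.0,
            species_pool=(codes.E_COLI, codes.K_PNEUMONIAE),  # non-P.-aeruginosa
        )
        panels = susceptibility_panels(generate_lab_table(cfg))
        assert len(panels) > 0
        assert all(classify(p).category == "4MRGN" for p in panels.values())

    def test_invalid_block_mix_is_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(block_mix={"culture": 0.9, "molecular": 0.2,
                                   "serology": 0.0, "further_properties": 0.0})


class TestTableToObservations:
    def test_counts_are_conserved(self):
        table = generate_lab_table(SynthConfig(seed=8, n_results=100))
        result = table_to_observations(table)
        assert len(result.observations) == 100
        assert result.errors == []

    def test_children_are_wired_to_their_culture(self):
        table = generate_lab_table(
            SynthConfig(seed=9, n_results=200, positivity_rate=0.8)
        )
        result = table_to_observations(table)
        cultures = {o.id: o for o in result.observations if o.kind == "culture"}
        child_ids = {c for o in cultures.values() for c in o.children}
        kinds_of_children = {
            o.kind for o in result.observations if o.id in child_ids
        }
        assert child_ids, "expected at least one linked child"
        assert kinds_of_children <= {"colony_count", "susceptibility"}

    def test_dangling_isolate_reference_is_collected_not_fatal(self):
        table = generate_lab_table(SynthConfig(seed=10, n_results=60))
        # orphan a susceptibility row by pointing it at an absent isolate
        idx = table.index[table["interpretation"] != ""][0]
        table.loc[idx, "isolate_id"] = "ISO-9999"
        result = table_to_observations(table)
        assert len(result.observations) == 60
        assert any("ISO-9999" in e.message for e in result.errors)

    def test_unknown_test_code_is_collected_not_fatal(self):
        table = generate_lab_table(SynthConfig(seed=11, n_results=20))
        table.loc[table.index[-1], "test_code"] = "99990-0"
        result = table_to_observations(table)
        assert len(result.observations) == 19
        assert any("99990-0" in e.message for e in result.errors)

    def test_corrupted_rows_become_observations_that_fail_validation(self):
        cfg = SynthConfig(seed=12, n_results=200, fault_injection=True, fault_rate=0.2)
        table = generate_lab_table(cfg)
        n_faults = int(table["flags"].str.contains("fault=").sum())
        assert n_faults > 0
        result = table_to_observations(table)
        assert len(result.observations) == 200  # built anyway
        n_invalid = sum(
            1
            for o in result.observations
            if any(
                i.severity == "error"
                for i in validation.validate(fhir_io.to_fhir(o).body)
            )
        )
        assert n_invalid == n_faults


class TestEndToEnd:
    def test_pipeline_yields_zero_error_issues_without_fault_injection(self):
        """generate -> convert -> to_fhir -> validate: the master property."""
        table = generate_lab_table(SynthConfig(seed=13, n_results=250))
        result = table_to_observations(table)
        envelopes = [fhir_io.to_fhir(o) for o in result.observations]
        siblings = {e.body["id"]: e.body for e in envelopes}
        for env in envelopes:
            issues = validation.validate(env, siblings=siblings)
            assert [i for i in issues if i.severity == "error"] == [], env.body["id"]

    def test_whole_chain_is_byte_deterministic(self):
        def run() -> str:
            table = generate_lab_table(SynthConfig(seed=14, n_results=120))
            return fhir_io.to_ndjson(table_to_observations(table).observations)

        assert run() == run()
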