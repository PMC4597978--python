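import numpy as np
import pandas as pd
import pytest

from cerepep import (
    Datastore,
    EpitopeRecord,
    ProteinRecord,
    build_datastore,
    epitope_density,
    export_csv,
    filter_chain,
    import_csv,
    mass_search,
    parse_workflow,
    peptide_count_matrix,
    peptide_specificity_summary,
)

MARKER = "FQQPQPQQ"  # [M+H]+ 1000.4847


@pytest.fixture(scope="module")
def marker_store():
    """Tiny store in which thermolysin releases the marker peptide."""
    proteins = [
        ProteinRecord(
            accession="P1",
            sequence=f"GGG{MARKER}{MARKER}LGGG",
            protein_type="alpha gliadin",
            organism="Triticum aestivum",
            genotype="Chinese Spring",
            genome="A",
        ),
        ProteinRecord(
            accession="P2",
            sequence=f"GGG{MARKER}LGGG",
            protein_type="gamma gliadin",
            organism="Triticum aestivum",
            genome="B",
        ),
    ]
    epitopes = [
        EpitopeRecord(
            # spans the junction of P1's two adjacent marker repeats,
            # so it occurs in P1 but not in P2
            epitope_id="E1", sequence="QQFQQ", cell_type="T cell", disease="celiac disease"
        )
    ]
    return build_datastore(proteins, epitopes, workflows=[parse_workflow("TLN")])


class TestBuild:
    def test_shared_peptide_deduplicated(self, rules):
        proteins = [
            ProteinRecord(accession="P1", sequence="AAKGG"),
            ProteinRecord(accession="P2", sequence="AAKGG"),
        ]
        store = build_datastore(proteins, workflows=[parse_workflow("TR")])
        assert sorted(store.peptides.sequence) == ["AAK", "GG"]
        assert len(store.digestion_events) == 4

    def test_duplicate_accessions_rejected(self):
        proteins = [
            ProteinRecord(accession="P1", sequence="AAK"),
            ProteinRecord(accession="P1", sequence="GGK"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_datastore(proteins)

    def test_empty_epitope_set(self):
        store = build_datastore(
            [ProteinRecord(accession="P1", sequence="AAKGG")],
            workflows=[parse_workflow("TR")],
        )
        assert store.protein_epitope_matches.empty
        assert store.peptide_epitope_matches.empty
        assert not store.peptides.empty

    def test_undefined_masses_flagged_not_zero(self):
        store = build_datastore(
            [ProteinRecord(accession="P1", sequence="AXAKGG")],
            workflows=[parse_workflow("TR")],
        )
        row = store.peptides.set_index("sequence").loc["AXAK"]
        assert np.isnan(row.monoisotopic_mass)
        assert row.unrecognized_count == 1

    def test_referential_integrity_and_conservation(self, store, fixture_set, rules):
        store.validate()
        from cerepep import default_workflows, run_workflow

        total = sum(
            len(run_workflow(p, w, rules))
            for p in fixture_set.proteins
            for w in default_workflows()
        )
        assert len(store.digestion_events) == total  # distinct accessions: no dedup loss
        assert len(store.peptides) <= len(store.digestion_events)


class TestFilterChain:
    def test_counts_monotonically_non_increasing(self, store):
        joined = store.protein_epitope_matches.merge(
            store.epitopes, on="epitope_id"
        ).merge(store.proteins, left_on="target_id", right_on="accession")
        _, counts = filter_chain(
            joined,
            [
                ("organism", "Triticum"),
                ("disease", "celiac"),
                ("cell_type", "T cell"),
                ("protein_type", "gliadin"),
            ],
        )
        assert counts == sorted(counts, reverse=True)

    def test_empty_filter_list_is_identity(self, store):
        result, counts = filter_chain(store.proteins, [])
        pd.testing.assert_frame_equal(result, store.proteins)
        assert counts == []

    def test_equivalent_to_single_conjunctive_pass(self, store):
        filters = [("protein_type", "gliadin"), ("genome", "D")]
        chained, _ = filter_chain(store.proteins, filters)
        mask = store.proteins.protein_type.str.contains(
            "gliadin", case=False
        ) & store.proteins.genome.str.contains("D", case=False)
        pd.testing.assert_frame_equal(chained, store.proteins[mask])

    def test_exact_mode(self, store):
        result, _ = filter_chain(store.proteins, [("genome", "a", True)])
        assert set(result.genome) <= {"A"}

    def test_unknown_column_rejected(self, store):
        with pytest.raises(KeyError):
            filter_chain(store.proteins, [("no_such_column", "x")])


class TestMassSearch:
    def test_printed_mass_finds_marker_peptide(self, marker_store):
        hits = mass_search(marker_store, 1000.4847)
        assert MARKER in set(hits.sequence)

    def test_zero_mass_matches_nothing(self, marker_store):
        assert mass_search(marker_store, 0.0).empty

    def test_ppm_window_contains_display_hits(self, marker_store):
        display = set(mass_search(marker_store, 1000.4847).sequence)
        ppm = set(
            mass_search(marker_store, 1000.4847, mode="ppm", tolerance=10).sequence
        )
        assert display <= ppm

    def test_negative_tolerance_rejected(self, marker_store):
        with pytest.raises(ValueError):
            mass_search(marker_store, 1000.0, mode="absolute", tolerance=-1)


class TestSpecificitySummary:
    def test_counts_across_proteins_and_copies(self, marker_store):
        rows = peptide_specificity_summary(marker_store, MARKER)
        assert list(rows.workflow_id) == ["TLN"]
        row = rows.iloc[0]
        assert row.n_proteins == 2          # P1 and P2 both yield it
        assert row.n_peptides_in_protein == 2  # twice within P1
        assert row.n_species == 1
        assert row.n_types == 2
        assert row.n_genotypes == 1         # P2 has no genotype recorded

    def test_unknown_peptide_rejected(self, marker_store):
        with pytest.raises(KeyError):
            peptide_specificity_summary(marker_store, "WWWWW")

    def test_agrees_with_brute_force_recount(self, store):
        seq = store.digestion_events.peptide_sequence.iloc[0]
        rows = peptide_specificity_summary(store, seq)
        events = store.digestion_events
        proteins = store.proteins.set_index("accession")
        for row in rows.itertuples(index=False):
            sub = events[
                (events.peptide_sequence == seq) & (events.workflow_id == row.workflow_id)
            ]
            accs = sorted(set(sub.protein_accession))
            assert row.n_proteins == len(accs)
            assert row.n_peptides_in_protein == max(
                sub[sub.protein_accession == a].start.nunique() for a in accs
            )
            assert row.n_species == len({proteins.loc[a, "organism"] for a in accs})
            assert row.n_types == len({proteins.loc[a, "protein_type"] for a in accs})


class TestCountMatrix:
    def test_margins_equal_cell_sums(self, store):
        m = peptide_count_matrix(store)
        inner = m.drop(index="Grand Total", columns="Grand Total")
        assert (inner.sum(axis=1) == m.loc[inner.index, "Grand Total"]).all()
        assert (inner.sum(axis=0) == m.loc["Grand Total", inner.columns]).all()
        assert m.loc["Grand Total", "Grand Total"] == len(store.digestion_events)

    def test_empty_scope_all_zero(self, store):
        m = peptide_count_matrix(store, scope=[("organism", "Zea mays")])
        assert m.to_numpy().sum() == 0

    def test_hand_counted_fixture(self, marker_store):
        m = peptide_count_matrix(marker_store)
        # P1 (GGG|F..Q|F..Q|LGGG) -> 4 fragments, P2 -> 3 fragments
        assert m.loc["alpha gliadin", "TLN"] == 4
        assert m.loc["gamma gliadin", "TLN"] == 3
        assert m.loc["Grand Total", "Grand Total"] == 7

    def test_unique_peptides_mode_not_larger(self, store):
        events = peptide_count_matrix(store)
        unique = peptide_count_matrix(store, unique_peptides=True)
        shared = events.index.intersection(unique.index)
        assert (unique.loc[shared, "Grand Total"] <= events.loc[shared, "Grand Total"]).all()


class TestEpitopeDensity:
    def test_definition_on_constructed_group(self):
        proteins = [
            ProteinRecord(accession="P1", sequence="QQQQQQQ", protein_type="t", genome="A"),
            ProteinRecord(accession="P2", sequence="AAAAAAA", protein_type="t", genome="A"),
        ]
        epitopes = [
            EpitopeRecord(epitope_id="E1", sequence="QQ", cell_type="T cell")
        ]
        store = build_datastore(proteins, epitopes, workflows=[parse_workflow("TR")])
        result = epitope_density(store, group_by=("protein_type", "genome"))
        assert len(result) == 1
        row = result.iloc[0]
        # 6 overlapping QQ matches in P1, none in P2: density counts only
        # proteins that have at least one match in the denominator
        assert row.n_matches == 6
        assert row.n_proteins_with_match == 1
        assert row.density == 6.0

    def test_group_without_matches_absent(self, marker_store):
        result = epitope_density(marker_store, group_by=("protein_type",))
        assert "gamma gliadin" not in set(result.protein_type)  # no QPQPQ in P2

    def test_invariant_under_zero_match_protein_duplication(self):
        base = [
            ProteinRecord(accession="P1", sequence="QQQQ", protein_type="t", genome="A"),
            ProteinRecord(accession="P2", sequence="AAAA", protein_type="t", genome="A"),
        ]
        extra = base + [
            ProteinRecord(accession="P3", sequence="AAAA", protein_type="t", genome="A")
        ]
        epitopes = [EpitopeRecord(epitope_id="E1", sequence="QQ", cell_type="T cell")]
        wf = [parse_workflow("TR")]
        d1 = epitope_density(build_datastore(base, epitopes, workflows=wf))
        d2 = epitope_density(build_datastore(extra, epitopes, workflows=wf))
        pd.testing.assert_frame_equal(d1, d2)

    def test_distinct_epitope_mode(self, store):
        rows = epitope_density(store, distinct_epitopes=True)
        counted = epitope_density(store)
        merged = rows.merge(counted, on=["protein_type", "genome"], suffixes=("_d", "_r"))
        assert (merged.n_matches_d <= merged.n_matches_r).all()


class TestExportCsv:
    def test_round_trip(self, store, tmp_path):
        path = tmp_path / "proteins.csv"
        export_csv(store.proteins, path)
        back = import_csv(path)
        pd.testing.assert_frame_equal(back, store.proteins)

    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_csv(pd.DataFrame(columns=["a", "b"]), path)
        assert path.read_text() == "a,b\n"

    def test_comma_fields_quoted(self, tmp_path):
        path = tmp_path / "q.csv"
        export_csv(pd.DataFrame({"name": ["x, y"]}), path)
        assert '"x, y"' in path.read_text()


class TestPersistence:
    def test_sqlite_round_trip(self, store, tmp_path):
        path = tmp_path / "store.sqlite"
        store.save(path)
        loaded = Datastore.load(path)
        for name in (
            "proteins",
            "peptides",
            "epitopes",
            "digestion_events",
            "protein_epitope_matches",
            "peptide_epitope_matches",
        ):
            pd.testing.assert_frame_equal(store.table(name), loaded.table(name))
        assert loaded.metadata == store.metadata
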