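"""Domain types, reaction classification, SBML/GenBank I/O, workspaces."""

import textwrap

import pytest

from gsmkit.fixtures import random_model
from gsmkit.genbank import read_genbank_cds, translate_cds
from gsmkit.gpr import parse_gpr
from gsmkit.model import (
    IntegrityError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    classify_reaction,
    format_equation,
    models_equal,
    parse_equation,
)
from gsmkit.sbml_io import SBMLParseError, read_sbml, write_sbml
from gsmkit.workspace import (
    Workspace,
    WorkspaceError,
    clone_workspace,
    load_workspace,
    save_workspace,
)


def _model_with(reactions, mets):
    model = MetabolicModel(id="m", boundary_compartment="e")
    model.compartments |= {"c", "e", "p"}
    for met_id, comp in mets:
        model.add_metabolite(Metabolite(id=met_id, compartment=comp))
    for rxn in reactions:
        model.add_reaction(rxn)
    return model


class TestClassification:
    def test_exchange_boundary_species(self):
        model = _model_with(
            [Reaction(id="EX_glc", stoichiometry={"glc_e": -1.0}, reversible=True,
                      lower_bound=-1000.0)],
            [("glc_e", "e")],
        )
        assert classify_reaction(model.reactions["EX_glc"], model) == ReactionKind.EXCHANGE

    def test_transport_crossing_metabolite(self):
        rxn = Reaction(
            id="PTS",
            stoichiometry={"glc_e": -1.0, "pep_c": -1.0, "glc_c": 1.0, "pyr_c": 1.0},
        )
        model = _model_with(
            [rxn], [("glc_e", "e"), ("pep_c", "c"), ("glc_c", "c"), ("pyr_c", "c")]
        )
        assert classify_reaction(rxn, model) == ReactionKind.TRANSPORT

    def test_single_compartment_internal(self):
        rxn = Reaction(
            id="ATPase",
            stoichiometry={"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0},
        )
        model = _model_with(
            [rxn], [("atp_c", "c"), ("h2o_c", "c"), ("adp_c", "c"), ("pi_c", "c")]
        )
        assert classify_reaction(rxn, model) == ReactionKind.INTERNAL

    def test_sink_vs_demand_by_reversibility(self):
        sink = Reaction(id="SK_x", stoichiometry={"x_c": -1.0}, reversible=True,
                        lower_bound=-1000.0)
        demand = Reaction(id="DM_y", stoichiometry={"y_c": -1.0})
        model = _model_with([sink, demand], [("x_c", "c"), ("y_c", "c")])
        assert classify_reaction(sink, model) == ReactionKind.SINK
        assert classify_reaction(demand, model) == ReactionKind.DEMAND

    def test_multi_compartment_without_crossing_is_internal(self):
        rxn = Reaction(id="R", stoichiometry={"a_c": -1.0, "b_p": 1.0})
        model = _model_with([rxn], [("a_c", "c"), ("b_p", "p")])
        assert classify_reaction(rxn, model) == ReactionKind.INTERNAL

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_matches_independent_rules(self, seed):
        """Every reaction gets exactly one kind, agreeing with a literal
        restatement of the classification rules."""
        model = random_model(seed)
        for rxn in model.reactions.values():
            mets = [model.metabolites[m] for m in rxn.stoichiometry]
            if len(mets) == 1:
                if (mets[0].compartment == model.boundary_compartment
                        or rxn.id.startswith(model.exchange_prefix)):
                    expected = ReactionKind.EXCHANGE
                elif rxn.reversible:
                    expected = ReactionKind.SINK
                else:
                    expected = ReactionKind.DEMAND
            else:
                crossing = False
                subs = {(model.metabolites[m].base_id(), model.metabolites[m].compartment)
                        for m, c in rxn.stoichiometry.items() if c < 0}
                prods = {(model.metabolites[m].base_id(), model.metabolites[m].compartment)
                         for m, c in rxn.stoichiometry.items() if c > 0}
                if len({m.compartment for m in mets}) >= 2:
                    for base, comp in prods:
                        if any(b == base and c != comp for b, c in subs):
                            crossing = True
                expected = ReactionKind.TRANSPORT if crossing else ReactionKind.INTERNAL
            assert classify_reaction(rxn, model) == expected


class TestInvariants:
    def test_duplicate_ids_rejected(self):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        with pytest.raises(IntegrityError):
            model.add_metabolite(Metabolite(id="a_c", compartment="c"))

    def test_case_insensitive_locus_tags(self):
        from gsmkit.model import Gene

        model = MetabolicModel(id="m")
        model.add_gene(Gene(locus_tag="abc_1"))
        with pytest.raises(IntegrityError):
            model.add_gene(Gene(locus_tag="ABC_1"))

    def test_zero_coefficient_rejected(self):
        with pytest.raises(IntegrityError):
            Reaction(id="r", stoichiometry={"a": 0.0}).validate()

    def test_reversible_needs_negative_lower_bound(self):
        with pytest.raises(IntegrityError):
            Reaction(id="r", stoichiometry={"a": -1.0}, reversible=True,
                     lower_bound=0.0).validate()

    def test_gpr_citing_unknown_gene_rejected(self):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        with pytest.raises(IntegrityError, match="gX"):
            model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0},
                                        gpr=parse_gpr("gX")))


def test_equation_round_trip():
    stoich, reversible = parse_equation("2 a + b -> 3 c")
    assert stoich == {"a": -2.0, "b": -1.0, "c": 3.0}
    assert not reversible
    assert parse_equation(format_equation(stoich, True))[0] == stoich


class TestSBML:
    def test_toy_template_counts(self, toy_world, manifest):
        model = read_sbml(toy_world / "template.xml")
        assert len(model.reactions) == manifest["n_reactions"]
        assert len(model.genes) == manifest["n_genes"]

    @pytest.mark.parametrize("level_version", ["3.1", "3.2"])
    def test_round_trip_structural_equality(self, tmp_path, level_version):
        model = random_model(42)
        path = tmp_path / "m.xml"
        write_sbml(model, path, level_version)
        assert models_equal(model, read_sbml(path))

    def test_second_read_is_stable(self, tmp_path):
        model = random_model(7)
        write_sbml(model, tmp_path / "a.xml", "3.1")
        first = read_sbml(tmp_path / "a.xml")
        write_sbml(first, tmp_path / "b.xml", "3.1")
        assert models_equal(first, read_sbml(tmp_path / "b.xml"))

    def test_gpr_round_trip_structure(self, tmp_path):
        from gsmkit.gpr import gpr_equal
        from gsmkit.model import Gene

        model = MetabolicModel(id="m")
        model.compartments.add("c")
        for g in ("g1", "g2", "g3"):
            model.add_gene(Gene(locus_tag=g))
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        model.add_metabolite(Metabolite(id="b_c", compartment="c"))
        rule = parse_gpr("(g1 and g2) or g3")
        model.add_reaction(Reaction(id="r1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                    gpr=rule))
        write_sbml(model, tmp_path / "m.xml", "3.2")
        assert gpr_equal(read_sbml(tmp_path / "m.xml").reactions["r1"].gpr, rule)

    def test_bounds_read_back_exactly(self, tmp_path):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0},
                                    reversible=True, lower_bound=-1000.0,
                                    upper_bound=1000.0))
        write_sbml(model, tmp_path / "m.xml", "3.1")
        rxn = read_sbml(tmp_path / "m.xml").reactions["r"]
        assert (rxn.lower_bound, rxn.upper_bound) == (-1000.0, 1000.0)

    def test_empty_model_is_valid(self, tmp_path):
        model = MetabolicModel(id="empty")
        model.compartments.add("c")
        write_sbml(model, tmp_path / "e.xml", "3.1")
        assert len(read_sbml(tmp_path / "e.xml").reactions) == 0

    def test_malformed_xml_names_line(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model></sbml>")
        with pytest.raises(SBMLParseError, match="line"):
            read_sbml(bad)

    def test_dangling_gene_reference_reported(self, tmp_path):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0}))
        path = tmp_path / "m.xml"
        write_sbml(model, path, "3.1")
        # splice a GPR citing an undeclared gene product into the document
        text = path.read_text().replace(
            "</fbc:listOfFluxObjectives>", "</fbc:listOfFluxObjectives>"
        )
        text = text.replace(
            "<reaction ",
            "<reaction ",
        )
        text = text.replace(
            "</reaction>",
            "<fbc:geneProductAssociation>"
            "<fbc:geneProductRef fbc:geneProduct=\"G_gX\"/>"
            "</fbc:geneProductAssociation></reaction>",
            1,
        )
        path.write_text(text)
        with pytest.raises(IntegrityError, match="gX"):
            read_sbml(path)

    def test_cross_check_with_independent_reader(self, tmp_path):
        """cobrapy, as an independent SBML implementation, sees the same
        entity counts and bounds."""
        cobra_io = pytest.importorskip("cobra.io")
        model = random_model(13)
        path = tmp_path / "m.xml"
        write_sbml(model, path, "3.1")
        seen = cobra_io.read_sbml_model(str(path))
        assert len(seen.reactions) == len(model.reactions)
        assert len(seen.metabolites) == len(model.metabolites)
        assert len(seen.genes) == len(model.genes)
        for rxn in model.reactions.values():
            mirror = seen.reactions.get_by_id(
                rxn.id if not rxn.id[0].isdigit() else "R_" + rxn.id
            )
            assert mirror.bounds == (rxn.lower_bound, rxn.upper_bound)


GENBANK_MINIMAL = textwrap.dedent("""\
    LOCUS       unit                      19 bp    DNA     linear   UNK 01-JAN-2000
    DEFINITION  synthetic test record.
    ACCESSION   unit
    VERSION     unit
    KEYWORDS    .
    SOURCE      .
      ORGANISM  .
                .
    FEATURES             Location/Qualifiers
         CDS             1..9
                         /locus_tag="gA"
         CDS             10..19
                         /locus_tag="gB"
    ORIGIN
            1 atggcttaaa tgtttaaac
    //
    """)


class TestGenBank:
    def test_toy_world_locus_tags(self, toy_world, manifest):
        records = read_genbank_cds(toy_world / "genome.gb")
        assert [r.locus_tag for r in records] == sorted(manifest["gene_ec"])
        assert not any(r.partial for r in records)

    def test_translation_and_partial_flag(self, tmp_path):
        path = tmp_path / "g.gb"
        path.write_text(GENBANK_MINIMAL)
        records = read_genbank_cds(path)
        assert records[0].protein == "MA"  # ATG GCT TAA, stop dropped
        assert not records[0].partial
        assert records[1].partial  # 10 bp CDS

    def test_no_cds_warns_not_errors(self, tmp_path):
        path = tmp_path / "empty.gb"
        path.write_text(GENBANK_MINIMAL.replace("CDS", "domain"))
        with pytest.warns(UserWarning, match="no CDS"):
            assert read_genbank_cds(path) == []

    def test_translate_cds_standard_code(self):
        assert translate_cds("ATGGCTTAA") == "MA"


class TestWorkspace:
    def test_round_trip(self, tmp_path):
        ws = Workspace(name="demo", model=random_model(3), config={"alpha": 0.5}, seed=3)
        save_workspace(ws, tmp_path / "w")
        loaded = load_workspace(tmp_path / "w")
        assert models_equal(ws.model, loaded.model)
        assert loaded.config == {"alpha": 0.5}
        assert loaded.seed == 3

    def test_clone_is_independent(self, tmp_path):
        ws = Workspace(name="demo", model=random_model(3))
        save_workspace(ws, tmp_path / "orig")
        clone_workspace(tmp_path / "orig", tmp_path / "copy")
        cloned = load_workspace(tmp_path / "copy")
        cloned.model.reactions.clear()
        assert len(load_workspace(tmp_path / "orig").model.reactions) > 0

    def test_missing_manifest(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(WorkspaceError, match="manifest"):
            load_workspace(tmp_path / "empty")

    def test_version_mismatch_warns(self, tmp_path):
        ws = Workspace(name="demo")
        save_workspace(ws, tmp_path / "w")
        manifest = (tmp_path / "w" / "manifest.yaml")
        manifest.write_text(manifest.read_text().replace("0.1.0", "0.0.1"))
        with pytest.warns(UserWarning, match="version"):
            load_workspace(tmp_path / "w")
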