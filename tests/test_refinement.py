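"""Localization parsing, compartment integration and network audits."""

import textwrap

import pytest

from gsmkit.fixtures import random_model
from gsmkit.gpr import parse_gpr
from gsmkit.model import Gene, MetabolicModel, Metabolite, Reaction
from gsmkit.refinement import (
    LocalizationParseError,
    LocalizationReport,
    check_mass_balance,
    find_blocked_reactions,
    find_dead_ends,
    integrate_compartments,
    parse_formula,
    parse_localization_report,
)

PSORTB_LONG = textwrap.dedent("""\
    SeqID: g1
      Analysis Report:
        CMSVM-            Unknown
      Localization Scores:
        Cytoplasmic              9.97
        CytoplasmicMembrane      0.01
      Final Prediction:
        Cytoplasmic              9.97
    SeqID: g2
      Localization Scores:
        Periplasmic              7.50
        Cytoplasmic              2.50
      Final Prediction:
        Periplasmic              7.50
    """)


class TestLocalizationParsing:
    def test_psortb_long_rescaled(self, tmp_path):
        path = tmp_path / "psortb.txt"
        path.write_text(PSORTB_LONG)
        report = parse_localization_report(path, "psortb_long")
        assert report.top("g1") == ("cytoplasmic", pytest.approx(0.997))
        assert report.top("g2")[0] == "periplasmic"

    def test_generic_tsv_pass_through(self, tmp_path):
        path = tmp_path / "loc.tsv"
        path.write_text("g1\tcytoplasm\t0.9\ng2\tmembrane\t0.4\n")
        report = parse_localization_report(path, "generic_tsv")
        assert report.top("g1") == ("cytoplasm", 0.9)

    def test_wolfpsort_votes_normalised(self, tmp_path):
        path = tmp_path / "wolf.txt"
        path.write_text("g1 cyto 10, mito 4\n")
        report = parse_localization_report(path, "wolfpsort")
        assert report.top("g1") == ("cyto", pytest.approx(10 / 14))

    def test_loctree3_percent_scale(self, tmp_path):
        path = tmp_path / "loctree.tsv"
        path.write_text("g1\t92\tcytosol\tannotation text\n")
        report = parse_localization_report(path, "loctree3")
        assert report.top("g1") == ("cytosol", pytest.approx(0.92))

    def test_truncated_file_errors_with_line(self, tmp_path):
        path = tmp_path / "loc.tsv"
        path.write_text("g1\tcytoplasm\t0.9\ng2\tmembrane\n")
        with pytest.raises(LocalizationParseError, match="line 2"):
            parse_localization_report(path, "generic_tsv")

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "psortb.txt"
        path.write_text("SeqID: g1\n  Localization Scores:\n    Cytoplasmic 11.0\n")
        with pytest.raises(LocalizationParseError, match="0-10"):
            parse_localization_report(path, "psortb_long")


def _gpr_model():
    model = MetabolicModel(id="m", boundary_compartment="e")
    model.compartments |= {"c", "e"}
    for g in ("g1", "g2", "g3"):
        model.add_gene(Gene(locus_tag=g))
    for mid in ("a_c", "b_c", "x_c", "y_c"):
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    model.add_reaction(Reaction(id="r1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                gpr=parse_gpr("g1")))
    model.add_reaction(Reaction(id="r2", stoichiometry={"x_c": -1.0, "y_c": 1.0},
                                gpr=parse_gpr("g2 or g3")))
    return model


class TestCompartmentIntegration:
    def test_confident_gene_moves_reaction(self):
        model = _gpr_model()
        report = LocalizationReport({"g1": [("cytoplasm", 0.997)]})
        out = integrate_compartments(model, report, 0.5, "c")
        assert set(out.reactions["r1"].stoichiometry) == {"a_cytoplasm", "b_cytoplasm"}
        assert out.metabolites["a_cytoplasm"].compartment == "cytoplasm"

    def test_below_threshold_uses_default(self):
        model = _gpr_model()
        report = LocalizationReport({"g1": [("periplasm", 0.3)]})
        out = integrate_compartments(model, report, 0.5, "c")
        assert set(out.reactions["r1"].stoichiometry) == {"a_c", "b_c"}

    def test_split_vote_falls_back_to_default(self):
        model = _gpr_model()
        report = LocalizationReport({
            "g2": [("periplasm", 0.9)], "g3": [("mitochondrion", 0.9)],
        })
        out = integrate_compartments(model, report, 0.5, "c")
        assert set(out.reactions["r2"].stoichiometry) == {"x_c", "y_c"}

    def test_idempotent(self):
        from gsmkit.model import models_equal

        model = _gpr_model()
        report = LocalizationReport({"g1": [("periplasm", 0.8)],
                                     "g2": [("periplasm", 0.8)]})
        once = integrate_compartments(model, report, 0.5, "c")
        twice = integrate_compartments(once, report, 0.5, "c")
        assert models_equal(once, twice)

    def test_unknown_default_compartment(self):
        with pytest.raises(ValueError, match="nowhere"):
            integrate_compartments(_gpr_model(), LocalizationReport({}), 0.5, "nowhere")


def _balance_model(entries, reactions):
    model = MetabolicModel(id="m")
    model.compartments.add("c")
    for mid, formula in entries:
        model.add_metabolite(Metabolite(id=mid, compartment="c", formula=formula))
    for rid, stoich in reactions:
        model.add_reaction(Reaction(id=rid, stoichiometry=stoich))
    return model


class TestMassBalance:
    def test_balanced_combustion(self):
        model = _balance_model(
            [("h2_c", "H2"), ("o2_c", "O2"), ("h2o_c", "H2O")],
            [("r", {"h2_c": -2.0, "o2_c": -1.0, "h2o_c": 2.0})],
        )
        assert check_mass_balance(model) == []

    def test_fermentation_deficit(self):
        model = _balance_model(
            [("glc_c", "C6H12O6"), ("etoh_c", "C2H6O")],
            [("r", {"glc_c": -1.0, "etoh_c": 2.0})],
        )
        (issue,) = check_mass_balance(model)
        assert issue.status == "unbalanced"
        # two CO2 missing on the product side
        assert issue.element_imbalance == {"C": pytest.approx(-2.0),
                                           "O": pytest.approx(-4.0)}

    def test_missing_formula_reported_unknown(self):
        model = _balance_model(
            [("a_c", "CH4"), ("b_c", None)],
            [("r", {"a_c": -1.0, "b_c": 1.0})],
        )
        (issue,) = check_mass_balance(model)
        assert issue.status == "unknown"
        assert "b_c" in issue.detail

    def test_boundary_reactions_skipped(self):
        model = MetabolicModel(id="m", boundary_compartment="e")
        model.compartments |= {"c", "e"}
        model.add_metabolite(Metabolite(id="glc_e", compartment="e", formula="C6H12O6"))
        model.add_reaction(Reaction(id="EX_glc", stoichiometry={"glc_e": -1.0},
                                    reversible=True, lower_bound=-1000.0))
        assert check_mass_balance(model) == []

    def test_charge_imbalance_detected(self):
        model = _balance_model([("a_c", "H"), ("b_c", "H")], [])
        model.metabolites["a_c"].charge = 1
        model.metabolites["b_c"].charge = 0
        model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0, "b_c": 1.0}))
        (issue,) = check_mass_balance(model)
        assert issue.charge_imbalance == pytest.approx(-1.0)

    def test_formula_parser(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula("H") == {"H": 1}
        assert parse_formula("C2H3NaO2") == {"C": 2, "H": 3, "Na": 1, "O": 2}
        with pytest.raises(ValueError):
            parse_formula("C6(H2O)6")


def _chain_model(with_exchanges):
    model = MetabolicModel(id="m", boundary_compartment="e")
    model.compartments |= {"c", "e"}
    for mid in ("a_c", "b_c", "c_c"):
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    model.add_reaction(Reaction(id="r1", stoichiometry={"a_c": -1.0, "b_c": 1.0}))
    model.add_reaction(Reaction(id="r2", stoichiometry={"b_c": -1.0, "c_c": 1.0}))
    if with_exchanges:
        for base in ("a", "c"):
            model.add_metabolite(Metabolite(id=f"{base}_e", compartment="e"))
            model.add_reaction(Reaction(
                id=f"EX_{base}", stoichiometry={f"{base}_e": -1.0},
                reversible=True, lower_bound=-1000.0,
            ))
            model.add_reaction(Reaction(
                id=f"T_{base}",
                stoichiometry={f"{base}_e": -1.0, f"{base}_c": 1.0},
                reversible=True, lower_bound=-1000.0,
            ))
    return model


class TestDeadEndsAndBlocked:
    def test_linear_pair(self):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        model.add_metabolite(Metabolite(id="b_c", compartment="c"))
        model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0, "b_c": 1.0}))
        never_produced, never_consumed = find_dead_ends(model)
        assert never_produced == {"a_c"}
        assert never_consumed == {"b_c"}

    def test_reversible_pair_has_no_dead_ends(self):
        model = MetabolicModel(id="m")
        model.compartments.add("c")
        model.add_metabolite(Metabolite(id="a_c", compartment="c"))
        model.add_metabolite(Metabolite(id="b_c", compartment="c"))
        model.add_reaction(Reaction(id="r", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                    reversible=True, lower_bound=-1000.0))
        assert find_dead_ends(model) == (set(), set())

    def test_chain_without_boundaries_is_blocked(self):
        assert find_blocked_reactions(_chain_model(False)) == {"r1", "r2"}

    def test_chain_with_boundaries_is_open(self):
        assert find_blocked_reactions(_chain_model(True)) == set()

    def test_empty_model(self):
        model = MetabolicModel(id="m")
        assert find_blocked_reactions(model) == set()
        assert find_dead_ends(model) == (set(), set())

    @pytest.mark.parametrize("seed", range(8))
    def test_universal_exchanges_unblock_everything(self, seed):
        model = random_model(seed, with_exchanges=False)
        for mid in list(model.metabolites):
            model.add_reaction(Reaction(
                id=f"EX_{mid}", stoichiometry={mid: -1.0},
                reversible=True, lower_bound=-1000.0,
            ))
        assert find_blocked_reactions(model) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_blocked_reactions_carry_no_lp_flux(self, seed):
        """Cross-check the topological audit against an LP feasibility
        oracle: every flagged reaction has zero flux range."""
        pytest.importorskip("scipy")
        from tests._lp_oracle import flux_range

        model = random_model(seed, with_exchanges=False)
        blocked = find_blocked_reactions(model)
        for rid in blocked:
            lo, hi = flux_range(model, rid)
            assert abs(lo) < 1e-9 and abs(hi) < 1e-9
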