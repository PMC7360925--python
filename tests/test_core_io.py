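"""Model container, validation, serialization and SBML import."""

import json

import numpy as np
import pytest

from symbiofba import (
    FormatError,
    Medium,
    Metabolite,
    OrganismModel,
    Reaction,
    ReactionKind,
    ValidationError,
    load_medium,
    load_model,
    stoichiometric_matrix,
    write_medium,
    write_model,
)
from symbiofba.synth import random_network


def simple_model(**overrides):
    kwargs = dict(
        id="demo",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("conv", {"A": -1.0, "B": 1.0}, lb=0.0, ub=10.0),
            Reaction("EX_A", {"A": -1.0}, lb=-5.0, ub=5.0, kind=ReactionKind.EXCHANGE),
        ],
    )
    kwargs.update(overrides)
    return OrganismModel.from_parts(**kwargs)


class TestValidation:
    def test_dangling_metabolite_rejected(self):
        with pytest.raises(ValidationError, match="undeclared metabolite"):
            simple_model(
                reactions=[Reaction("bad", {"A": -1.0, "ghost": 1.0})]
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError, match="lb=.*>.*ub"):
            simple_model(reactions=[Reaction("bad", {"A": -1.0}, lb=1.0, ub=-1.0)])

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ValidationError, match="exactly one"):
            simple_model(
                reactions=[
                    Reaction("EX_bad", {"A": -1.0, "B": 1.0}, kind=ReactionKind.EXCHANGE)
                ]
            )

    def test_undeclared_compartment_rejected(self):
        with pytest.raises(ValidationError, match="undeclared compartment"):
            simple_model(
                metabolites=[Metabolite("A", compartment="x"), Metabolite("B")],
                compartments={"c"},
            )

    def test_empty_reaction_set_rejected_on_write(self, tmp_path):
        model = simple_model()
        model.reactions.clear()
        with pytest.raises(ValidationError, match="no reactions"):
            write_model(model, tmp_path / "m.json")

    def test_negative_medium_rate_rejected(self):
        with pytest.raises(ValidationError):
            Medium({"glc": -1.0})


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,name", [("native-json", "m.json"), ("tsv-pair", "m_dir")])
    def test_toy_models_round_trip_unchanged(self, toy, fmt, name, tmp_path):
        for model in (toy.host, toy.buchnera, toy.hamiltonella):
            path = tmp_path / f"{model.id}_{name}"
            write_model(model, path, fmt)
            assert load_model(path, fmt) == model

    @pytest.mark.parametrize("fmt", ["native-json", "tsv-pair"])
    def test_rational_stoichiometry_survives(self, fmt, tmp_path):
        model = simple_model(
            reactions=[Reaction("thirds", {"A": -1.0 / 3.0, "B": 1.0}, lb=0.0, ub=1.0)]
        )
        path = tmp_path / "m"
        write_model(model, path, fmt)
        back = load_model(path, fmt)
        assert back.reactions["thirds"].stoich["A"] == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_objective_biomass_and_flags_survive(self, tmp_path):
        model = simple_model(
            reactions=[
                Reaction("growth", {"A": -1.0}, lb=0.0, ub=10.0, kind=ReactionKind.BIOMASS),
                Reaction("conv", {"A": -1.0, "B": 1.0}, gene_rule="g1 and g2"),
            ],
            metabolites=[Metabolite("A", transportable=True), Metabolite("B", charge=-2, formula="C6H12O6")],
            biomass_id="growth",
            objective={"growth": 1.0},
        )
        for fmt, name in [("native-json", "m.json"), ("tsv-pair", "m_dir")]:
            write_model(model, tmp_path / name, fmt)
            assert load_model(tmp_path / name, fmt) == model

    def test_medium_tsv_round_trip(self, tmp_path):
        medium = Medium({"prpp": 10.0, "glc": 0.0})
        path = write_medium(medium, tmp_path / "medium.tsv")
        assert load_medium(path).entries == medium.entries

    def test_malformed_json_names_file(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(FormatError, match="bad.json"):
            load_model(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        smat = stoichiometric_matrix(simple_model())
        S = smat.matrix.toarray()
        j = smat.rxn_index["conv"]
        assert S[smat.met_index["A"], j] == -1.0
        assert S[smat.met_index["B"], j] == 1.0

    def test_toy_hisd_column_matches_declared_stoichiometry(self, toy):
        smat = stoichiometric_matrix(toy.buchnera)
        col = smat.matrix.toarray()[:, smat.rxn_index["HisD"]]
        expected = {"prpp": -1.0, "his": 1.0, "aicar": 1.0}
        for met, coef in expected.items():
            assert col[smat.met_index[met]] == coef
        assert np.count_nonzero(col) == 3

    @pytest.mark.parametrize("seed", [1, 7])
    def test_shape_and_no_empty_columns(self, seed):
        model = random_network(seed, n_mets=6, n_rxns=8)
        smat = stoichiometric_matrix(model)
        assert smat.matrix.shape == (len(model.metabolites), len(model.reactions))
        col_mass = np.abs(smat.matrix.toarray()).sum(axis=0)
        assert np.all(col_mass > 0)


# ---------------------------------------------------------------------------
# SBML import

SBML_NO_BOUNDS = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="mini">
  <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
   <species id="B" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="rev" reversible="true" fast="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
   </reaction>
   <reaction id="irrev" reversible="false" fast="false">
    <listOfReactants><speciesReference species="B" stoichiometry="1" constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="A" stoichiometry="1" constant="true"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


class TestSBMLImport:
    def test_default_bounds_when_unstated(self, tmp_path):
        path = tmp_path / "mini.xml"
        path.write_text(SBML_NO_BOUNDS)
        model = load_model(path, "sbml")
        assert (model.reactions["rev"].lb, model.reactions["rev"].ub) == (-1000.0, 1000.0)
        assert (model.reactions["irrev"].lb, model.reactions["irrev"].ub) == (0.0, 1000.0)

    def test_parse_failure_names_offending_content(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><model></sbml>")
        with pytest.raises(FormatError):
            load_model(path, "sbml")

    def test_cobra_written_file_round_trips_structure(self, toy, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("Buchnera")
        mets = {
            mid: cobra.Metabolite(mid, compartment="c")
            for mid in toy.buchnera.metabolites
        }
        for rid, rx in toy.buchnera.reactions.items():
            cr = cobra.Reaction(rid)
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c for m, c in rx.stoich.items()})
            cr.bounds = (rx.lb, rx.ub)
        path = tmp_path / "buchnera.xml"
        cobra.io.write_sbml_model(cm, str(path), f_replace={})
        back = load_model(path, "sbml")
        assert len(back.reactions) == len(toy.buchnera.reactions)
        assert "HisD" in back.reactions
        hisd = back.reactions["HisD"]
        assert hisd.stoich == {"prpp": -1.0, "his": 1.0, "aicar": 1.0}
        assert (hisd.lb, hisd.ub) == (0.0, 1000.0)
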