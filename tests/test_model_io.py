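"""Model-definition format, Modelica-subset importer and result tables."""

import pandas as pd
import pytest

from hepanet.core import build_network
from hepanet.model_io import (
    HEADER,
    ModelSyntaxError,
    import_modelica_subset,
    read_model_definition,
    write_model_definition,
    write_results,
)

SMALL_MODEL = """\
hepanet-model v1

compartment liver
compartment blood

metabolite glc blood
metabolite g6p liver
metabolite pyr liver

enzyme GK liver regulated_by=gk_m
enzyme PK liver

reaction R1: glc -> g6p enzyme=GK r=0.5 w=2
reaction R2: g6p -> pyr enzyme=PK
transport T1: pyr -> glc r=0.2   # recycling carrier

branch pyr: T1=0.4 snk=0.6

source src -> glc phi=1.5
sink snk <- pyr

gene gk_m: regulators=pyr:- Qmax=5 Qc_hat=10 kd=0.02
"""

MODELICA_MODEL = """\
model TinyNet
  SysBio.Metabolite glc(comp="blood");
  SysBio.Metabolite g6p(comp="liver");
  SysBio.Enzyme GK;
  SysBio.Reaction R1(r=0.5, w=2);
  SysBio.Source feed(phi=1.0);
  SysBio.Sink drain;
  Some.Unknown widget;
equation
  connect(feed.O, glc.I);
  connect(glc.O, R1.S);
  connect(R1.P, g6p.I);
  connect(GK.E, R1.E);
  connect(g6p.O, drain.I);
end TinyNet;
"""

MODELICA_LIBRARY = """\
package SysBio
  class Metabolite end Metabolite;
  class Enzyme end Enzyme;
  class Reaction end Reaction;
  class Source end Source;
  class Sink end Sink;
  class mRNA end mRNA;
  class Translation end Translation;
end SysBio;
"""


class TestReadModelDefinition:
    def test_empty_text_gives_empty_definition(self):
        d = read_model_definition("")
        assert d.metabolites == () and d.reactions == ()

    def test_small_model_parses_and_builds(self):
        d = read_model_definition(SMALL_MODEL)
        assert len(d.metabolites) == 3
        assert d.reactions[0].r == 0.5 and d.reactions[0].w == 2.0
        assert d.reactions[2].enzyme is None  # transport
        assert d.genes[0].regulators == (("pyr", -1),)
        net = build_network(d)
        assert net.baseline_flux["R1"] == pytest.approx(1.5 / 0.6)

    def test_provenance_lines_recorded(self):
        d = read_model_definition(SMALL_MODEL)
        assert d.provenance["glc"] == 6
        assert d.provenance["R1"] == 13

    def test_duplicate_id_names_both_lines(self):
        text = SMALL_MODEL + "\nmetabolite glc blood\n"
        with pytest.raises(ModelSyntaxError, match="line 6"):
            read_model_definition(text)

    def test_missing_header_rejected(self):
        with pytest.raises(ModelSyntaxError, match="header"):
            read_model_definition("metabolite x liver\n")

    @pytest.mark.parametrize("line,msg", [
        ("branch pyr: T1=abc snk=0.6", "malformed fraction"),
        ("frobnicate x", "unknown directive"),
        ("gene g: regulators=x:*", "needs :"),
        ("branch pyr: T1=0.6 snk=0.3", "residual"),
    ])
    def test_syntax_errors_carry_line_numbers(self, line, msg):
        text = SMALL_MODEL + line + "\n"
        with pytest.raises(ModelSyntaxError, match=msg) as err:
            read_model_definition(text)
        assert err.value.line is not None


class TestRoundTrip:
    def test_small_model_roundtrip(self):
        d = read_model_definition(SMALL_MODEL)
        d2 = read_model_definition(write_model_definition(d))
        assert d2.metabolites == d.metabolites
        assert d2.enzymes == d.enzymes
        assert d2.reactions == d.reactions
        assert d2.branches == d.branches
        assert d2.sources == d.sources and d2.sinks == d.sinks
        assert d2.genes == d.genes

    def test_liver_network_roundtrip(self, liver_net):
        d = liver_net.definition
        d2 = read_model_definition(write_model_definition(d))
        for attr in ("metabolites", "enzymes", "reactions", "branches",
                     "sources", "sinks", "genes", "proteins", "switches"):
            assert getattr(d2, attr) == getattr(d, attr), attr


class TestModelicaImport:
    def test_tiny_fixture_resolves_reaction(self):
        d, report = import_modelica_subset(MODELICA_MODEL, MODELICA_LIBRARY)
        assert len(d.reactions) == 1
        rxn = d.reactions[0]
        assert rxn.substrates == {"glc": 1.0}
        assert rxn.products == {"g6p": 1.0}
        assert rxn.enzyme == "GK"
        assert rxn.r == 0.5 and rxn.w == 2.0
        assert d.sources[0].target == "glc"
        assert d.sinks[0].target == "g6p"
        net = build_network(d)
        assert net.baseline_flux["R1"] == pytest.approx(1.0)

    def test_nothing_silently_dropped(self):
        _, report = import_modelica_subset(MODELICA_MODEL, MODELICA_LIBRARY)
        assert report.n_recognized == 6
        assert len(report.unrecognized) == 1
        assert "widget" in report.unrecognized[0][1]
        assert report.n_total == 7

    def test_empty_model_empty_report(self):
        d, report = import_modelica_subset("", MODELICA_LIBRARY)
        assert d.metabolites == ()
        assert report.n_total == 0

    def test_transcriptional_regulation_edges(self):
        model = """\
model RegNet
  SysBio.Metabolite s;
  SysBio.Metabolite p;
  SysBio.Enzyme E1;
  SysBio.Reaction R1;
  SysBio.Source feed(phi=1);
  SysBio.Sink drain;
  SysBio.mRNA e1_m(Qmax=8);
  SysBio.Translation tr1;
  SysBio.TranscriptionalInhibition ti;
equation
  connect(feed.O, s.I);
  connect(s.O, R1.S);
  connect(R1.P, p.I);
  connect(E1.E, R1.E);
  connect(p.O, drain.I);
  connect(p.O, ti.C);
  connect(ti.O, e1_m.I);
  connect(e1_m.O, tr1.I);
  connect(tr1.O, E1.O);
end RegNet;
"""
        lib = MODELICA_LIBRARY.replace(
            "class Translation end Translation;",
            "class Translation end Translation;\n"
            "  class TranscriptionalInhibition end TranscriptionalInhibition;")
        d, report = import_modelica_subset(model, lib)
        assert d.genes[0].regulators == (("p", -1),)
        assert d.genes[0].q_max == 8.0
        assert d.enzymes[0].regulated_by == "e1_m"


class TestWriteResults:
    def test_empty_table_header_only(self, tmp_path):
        paths = write_results({"empty": pd.DataFrame(columns=["a", "b"])},
                              tmp_path)
        assert paths[0].read_text() == "a\tb\n"

    def test_roundtrip_bit_exact(self, tmp_path):
        df = pd.DataFrame({"variable": ["x", "y"],
                           "fold": [1.2345678901234567, 0.1]})
        write_results({"folds": df}, tmp_path)
        back = pd.read_csv(tmp_path / "folds.tsv", sep="\t")
        assert (back.fold == df.fold).all()
        assert (back.variable == df.variable).all()
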