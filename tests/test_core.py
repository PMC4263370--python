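"""Network building, validation and normalized-state parameter derivation."""

import numpy as np
import pytest

from hepanet.core import (
    BranchPoint,
    Enzyme,
    FluxSource,
    Metabolite,
    ModelDefinition,
    Reaction,
    Sink,
    StructuralError,
    ValidationError,
    build_network,
    derive_rate_constants,
    initialize_state,
    parameter_set,
    structure_stats,
)
from hepanet.dynamics import assemble_rhs


def single_reaction_definition(r=0.0, w=1.0):
    return ModelDefinition(
        metabolites=(Metabolite("S", "blood"), Metabolite("P")),
        enzymes=(Enzyme("E1"),),
        reactions=(Reaction("R1", {"S": 1.0}, {"P": 1.0}, enzyme="E1",
                            r=r, w=w),),
        sources=(FluxSource("src", "S", 1.0),),
        sinks=(Sink("snk", "P"),),
    )


class TestBuildNetwork:
    def test_minimal_network_states(self):
        net = build_network(single_reaction_definition())
        # 2 metabolites + 1 free enzyme + 1 complex
        assert len(net.index) == 4
        assert set(net.index.labels) == {"S", "P", "enz.E1", "cx.R1"}
        assert net.baseline_flux["R1"] == pytest.approx(1.0)

    def test_branch_fraction_residual_reported(self):
        with pytest.raises(ValidationError, match=r"residual \+0\.1"):
            BranchPoint("X", {"a": 0.6, "b": 0.3})

    def test_dangling_enzyme_reference(self):
        d = single_reaction_definition()
        bad = ModelDefinition(
            metabolites=d.metabolites,
            enzymes=(),
            reactions=d.reactions,
            sources=d.sources, sinks=d.sinks)
        with pytest.raises(StructuralError, match="E1"):
            build_network(bad)

    def test_duplicate_id_rejected(self):
        d = single_reaction_definition()
        bad = ModelDefinition(
            metabolites=d.metabolites + (Metabolite("E1"),),
            enzymes=d.enzymes, reactions=d.reactions,
            sources=d.sources, sinks=d.sinks)
        with pytest.raises(ValidationError, match="duplicate id"):
            build_network(bad)

    def test_metabolite_with_two_consumers_needs_branch(self):
        d = single_reaction_definition()
        bad = ModelDefinition(
            metabolites=d.metabolites, enzymes=d.enzymes,
            reactions=d.reactions,
            sources=d.sources,
            sinks=d.sinks + (Sink("snk2", "S"),))
        with pytest.raises(ValidationError, match="no declared branch"):
            build_network(bad)

    def test_unused_enzyme_warned_not_fatal(self):
        d = single_reaction_definition()
        net = build_network(ModelDefinition(
            metabolites=d.metabolites,
            enzymes=d.enzymes + (Enzyme("idle"),),
            reactions=d.reactions, sources=d.sources, sinks=d.sinks))
        assert any("idle" in w for w in net.warnings)

    def test_inconsistent_fractions_rejected(self, liver_net):
        # pin the structurally-balanced glycerol-3-P branch to wrong numbers
        d = liver_net.definition.replace_branch(
            "g3p_l", {"R_GPAT": 0.1, "snk_g3p": 0.9})
        with pytest.raises(ValidationError, match="inconsistent"):
            build_network(d)


class TestRateConstants:
    def test_irreversible_has_zero_reverse_constants(self):
        rxn = Reaction("R", {"S": 1.0}, {"P": 1.0}, enzyme="E", r=0.0, w=1.0)
        rc = derive_rate_constants(rxn, throughput=1.0)
        assert rc.k_CR == 0.0 and rc.k_PR == 0.0
        assert rc.k_C == pytest.approx(1.0) and rc.k_P == pytest.approx(1.0)

    @pytest.mark.parametrize("r,w", [(0.5, 1.0), (0.3, 2.5), (0.9, 0.2)])
    def test_reverse_forward_ratio_realized(self, r, w):
        """At the normalized state each elementary step carries ratio r."""
        rxn = Reaction("R", {"S": 1.0}, {"P": 1.0}, enzyme="E", r=r, w=w)
        rc = derive_rate_constants(rxn, throughput=1.7)
        # step 1: forward k_C*S*E, reverse k_CR*C with C = w
        assert rc.k_CR * w / rc.k_C == pytest.approx(r, abs=1e-12)
        # step 2: forward k_P*C, reverse k_PR*P*E
        assert rc.k_PR / (rc.k_P * w) == pytest.approx(r, abs=1e-12)
        # net throughput through both steps
        assert rc.k_C - rc.k_CR * w == pytest.approx(1.7, abs=1e-12)
        assert rc.k_P * w - rc.k_PR == pytest.approx(1.7, abs=1e-12)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValidationError):
            Reaction("R", {"S": 1}, {"P": 1}, enzyme="E", r=1.0)
        with pytest.raises(ValidationError):
            Reaction("R", {"S": 1}, {"P": 1}, enzyme="E", w=0.0)
        rxn = Reaction("R", {"S": 1}, {"P": 1}, enzyme="E")
        with pytest.raises(ValidationError):
            derive_rate_constants(rxn, throughput=0.0)


class TestInitializeState:
    def test_all_ones_with_unit_w(self, branch2):
        x = initialize_state(branch2)
        assert np.all(x == 1.0)

    def test_complex_initialized_to_w(self):
        net = build_network(single_reaction_definition(r=0.2, w=0.3))
        x = initialize_state(net)
        assert x[net.index["cx.R1"]] == 0.3
        assert np.all(np.delete(x, net.index["cx.R1"]) == 1.0)

    @pytest.mark.parametrize("r,w", [(0.0, 1.0), (0.5, 1.0), (0.7, 4.0)])
    def test_fixed_point_residual(self, r, w):
        """The core correctness oracle: dx/dt vanishes at the initialized state."""
        net = build_network(single_reaction_definition(r=r, w=w))
        rhs = assemble_rhs(net)
        assert np.max(np.abs(rhs(0.0, initialize_state(net)))) < 1e-12

    def test_liver_network_fixed_point(self, liver_net):
        rhs = assemble_rhs(liver_net)
        res = np.max(np.abs(rhs(0.0, initialize_state(liver_net))))
        assert res < 1e-10


class TestStructureStats:
    def test_single_reaction_counts(self):
        s = structure_stats(build_network(single_reaction_definition()))
        assert (s.n_reactions, s.n_metabolites, s.n_enzymes,
                s.n_regulatory_proteins) == (1, 2, 1, 0)

    def test_counts_match_independent_walk(self, liver_net):
        """Stats agree with a direct walk over the definition tuples."""
        d = liver_net.definition
        s = structure_stats(liver_net)
        assert s.n_reactions == len(d.reactions)
        assert s.n_metabolites == len(d.metabolites)
        assert s.n_enzymes == len(d.enzymes)
        assert s.n_regulatory_proteins == len(d.proteins) + len(d.switches)
        n_complexes = sum(1 for r in d.reactions if r.enzyme)
        assert s.n_states == (len(d.metabolites) + len(d.enzymes) + n_complexes
                              + len(d.genes) + len(d.proteins)
                              + 2 * len(d.switches))

    def test_liver_network_manifest(self, liver_net):
        """Frozen hand-count of the bundled multi-tissue fixture."""
        s = structure_stats(liver_net)
        assert s.n_reactions == 33
        assert s.n_metabolites == 27
        assert s.n_enzymes == 25
        assert s.n_regulatory_proteins == 7  # 3 proteins + 4 switches
        # 27 met + 25 enz + 25 complexes + 17 mRNA + 3 proteins + 4*2 switch pools
        assert s.n_states == 105

    def test_parameter_taxonomy_consistency(self, liver_net):
        pset = parameter_set(liver_net)
        counts = pset.counts
        n_indep = sum(v for k, v in counts.items()
                      if k != "set_at_initialization")
        assert n_indep == len(pset.independent)
        assert counts["set_at_initialization"] == len(pset.dependent)
        # every dependent constant is recomputable: spot-check one reaction
        rc = liver_net.rate_constants["R_GK"]
        F = liver_net.baseline_flux["R_GK"]
        assert pset.dependent["kC[R_GK]"] == pytest.approx(F / (1 - 0.0))


class TestBranchRenormalization:
    def test_sibling_fractions_sum_to_one(self, liver_net):
        net2 = liver_net.with_branch_fraction("fa_b", "R_FAT_L", 0.52)
        b = next(b for b in net2.definition.branches if b.parent == "fa_b")
        assert sum(b.fractions.values()) == pytest.approx(1.0, abs=1e-15)
        assert b.fractions["R_FAT_L"] == pytest.approx(0.52)
        # siblings keep their relative proportions
        assert b.fractions["R_FAT_A"] / b.fractions["snk_fa_p"] == \
            pytest.approx(0.35 / 0.25)

    def test_rebuilt_network_keeps_fixed_point(self, branch2):
        net2 = branch2.with_branch_fraction("X", "RA", 0.9)
        rhs = assemble_rhs(net2)
        assert np.max(np.abs(rhs(0.0, initialize_state(net2)))) < 1e-12
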