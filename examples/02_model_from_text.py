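"""Declare a small network in the text format, validate it and inspect it.

The definition below is a glucose -> G6P -> pyruvate chain with a recycling
carrier and product repression of glucokinase.  Validation solves the
flux-balance system, derives every rate constant and checks that the
normalized reference state is an exact equilibrium.
"""

from hepanet import build_network, read_model_definition, validate_model
from hepanet.model_io import write_model_definition

TEXT = """\
hepanet-model v1

compartment liver
compartment blood

metabolite glc blood
metabolite g6p liver
metabolite pyr liver

enzyme GK liver regulated_by=gk_m
enzyme PK liver

reaction R_GK: glc -> g6p enzyme=GK r=0.5
reaction R_PK: g6p -> pyr enzyme=PK
transport T_recycle: pyr -> glc r=0.2

branch pyr: T_recycle=0.4 use=0.6

source diet -> glc phi=1.0
sink use <- pyr

gene gk_m: regulators=pyr:- Qmax=5
"""

definition = read_model_definition(TEXT)
report = validate_model(build_network(definition))
print(report)
print()
print("round-tripped definition:")
print(write_model_definition(definition))
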