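# Model-definition format (`hepanet-model v1`)

A line-oriented UTF-8 text format.  `#` starts a comment (to end of line);
blank lines are ignored.  The first non-comment line must be the header
`hepanet-model v1`.  Identifiers match `[A-Za-z_][A-Za-z0-9_]*`.

## Grammar (EBNF)

```ebnf
file        = header { line } ;
header      = "hepanet-model v1" ;
line        = compartment | metabolite | enzyme | reaction | transport
            | branch | source | sink | gene | protein | switch ;

compartment = "compartment" ident ;
metabolite  = "metabolite" ident ident ;                      (* id, compartment *)
enzyme      = "enzyme" ident ident { keyval } ;               (* id, compartment *)
reaction    = "reaction" ident ":" species "->" species { keyval } ;
transport   = "transport" ident ":" species "->" species { keyval } ;
species     = term { "+" term } ;
term        = [ number ] ident ;                              (* stoichiometric multiplier *)
branch      = "branch" ident ":" child { child } ;
child       = ident "=" ( number | "*" ) ;                    (* "*" = balance fraction *)
source      = "source" ident "->" ident [ "phi=" number ] ;
sink        = "sink" ident "<-" ident ;
gene        = "gene" ident ":" [ "regulators=" reglist ]
              [ "Qmax=" number ] [ "Qc_hat=" number ] [ "kd=" number ] ;
reglist     = reg { "," reg } ;
reg         = ident ":" ( "+" | "-" ) ;
protein     = "protein" ident ":" "mrna=" ident [ "kd=" number ] ;
switch      = "switch" ident ":" [ "act=" ident ] [ "inact=" ident ]
              [ "ki=" number ] [ "kd=" number ] [ "synth=" ident ] ;
keyval      = ident "=" value ;
```

## Semantics

- `reaction` declares an enzymatic step (`enzyme=` required); recognized
  keys: `enzyme`, `r` (reversibility, default 0), `w` (bound/free enzyme
  ratio, default 1).  `transport` is the enzyme-free first-order carrier
  variant (keys: `r`).
- `branch` must list *all* consumers (reactions and sinks) of the parent
  metabolite.  Declared fractions must sum to 1; a child may instead carry
  `*` (balance) when its throughput is already pinned elsewhere, e.g. the
  secondary substrate of a multi-substrate reaction.
- `source` injects a constant normalized influx `phi` (default 1); `sink`
  is a first-order demand whose rate constant is set at initialization so
  the baseline balances.
- `gene` declares an mRNA pool; regulator references may name a metabolite,
  a protein, a switch (its active pool) or another mRNA.  `enzyme ...
  regulated_by=<gene-or-protein>` ties enzyme synthesis to that node.
- `switch` declares a two-pool (active/inactive) post-translational
  regulator; `act`/`inact` name the driver states, `ki`/`kd` the
  inactivation/degradation constants (`ka = ki + kd` is derived).

Duplicate ids, unknown references, fractions outside (0, 1], and branch
sums away from 1 are rejected with the offending line number(s).
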