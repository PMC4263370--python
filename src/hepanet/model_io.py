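"""Readers and writers for model definitions and result tables.

Two input dialects are supported:

* the native line-oriented model-definition format (see
  ``docs/model_format.md`` for the grammar);
* a restricted subset of Modelica source as used by object-oriented
  systems-biology libraries: component declarations with modifiers plus
  ``connect`` statements.  Only the library's biological object classes are
  interpreted; any construct outside the subset is reported, never executed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    BranchPoint,
    COMPARTMENTS,
    Enzyme,
    FluxSource,
    GeneNode,
    Metabolite,
    ModelDefinition,
    ProteinNode,
    Reaction,
    Sink,
    SwitchNode,
    ValidationError,
)

__all__ = [
    "ModelSyntaxError",
    "read_model_definition",
    "load_model_definition",
    "write_model_definition",
    "ImportReport",
    "import_modelica_subset",
    "write_results",
]

HEADER = "hepanet-model v1"


class ModelSyntaxError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


def _parse_kv(tokens: list[str], line: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in tokens:
        if "=" not in tok:
            raise ModelSyntaxError(f"expected key=value, got {tok!r}", line)
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _num(text: str, line: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ModelSyntaxError(f"malformed {what} {text!r}", line) from None


_SPECIES_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z_]\w*)$")


def _parse_species(expr: str, line: int) -> dict[str, float]:
    """Parse ``2 a + b`` into {a: 2.0, b: 1.0}."""
    out: dict[str, float] = {}
    for term in expr.split("+"):
        m = _SPECIES_RE.match(term.strip())
        if not m:
            raise ModelSyntaxError(f"malformed species term {term.strip()!r}", line)
        mult = float(m.group(1)) if m.group(1) else 1.0
        out[m.group(2)] = mult
    return out


def read_model_definition(text: str) -> ModelDefinition:
    """Parse the native model-definition format.

    Returns a :class:`ModelDefinition` with per-entity source-line
    provenance; syntax errors carry the offending line number.  An empty
    file yields an empty definition.
    """
    compartments: list[str] = []
    metabolites: list[Metabolite] = []
    enzymes: list[Enzyme] = []
    reactions: list[Reaction] = []
    branches: list[BranchPoint] = []
    sources: list[FluxSource] = []
    sinks: list[Sink] = []
    genes: list[GeneNode] = []
    proteins: list[ProteinNode] = []
    switches: list[SwitchNode] = []
    provenance: dict[str, int] = {}
    seen_lines: dict[str, int] = {}
    header_seen = False

    def note(eid: str, ln: int) -> None:
        if eid in seen_lines:
            raise ModelSyntaxError(
                f"duplicate id {eid!r} (first declared on line {seen_lines[eid]})",
                ln)
        seen_lines[eid] = ln
        provenance[eid] = ln

    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if line != HEADER:
                raise ModelSyntaxError(
                    f"missing header {HEADER!r}; got {line!r}", ln)
            header_seen = True
            continue
        head, _, rest = line.partition(" ")
        rest = rest.strip()
        try:
            if head == "compartment":
                compartments.append(rest)
            elif head == "metabolite":
                parts = rest.split()
                if len(parts) != 2:
                    raise ModelSyntaxError(
                        "expected: metabolite <id> <compartment>", ln)
                note(parts[0], ln)
                metabolites.append(Metabolite(parts[0], parts[1]))
            elif head == "enzyme":
                parts = rest.split()
                if len(parts) < 2:
                    raise ModelSyntaxError(
                        "expected: enzyme <id> <compartment> [key=value ...]", ln)
                kv = _parse_kv(parts[2:], ln)
                note(parts[0], ln)
                enzymes.append(Enzyme(
                    parts[0], parts[1],
                    regulated_by=kv.get("regulated_by"),
                    turnover=_num(kv["turnover"], ln, "turnover")
                    if "turnover" in kv else 0.01))
            elif head in ("reaction", "transport"):
                name, _, body = rest.partition(":")
                name = name.strip()
                if "->" not in body:
                    raise ModelSyntaxError("expected '<subs> -> <prods>'", ln)
                lhs, rhs_part = body.split("->", 1)
                rhs_tokens = rhs_part.split()
                prod_toks: list[str] = []
                kv_toks: list[str] = []
                for tok in rhs_tokens:
                    (kv_toks if "=" in tok else prod_toks).append(tok)
                kv = _parse_kv(kv_toks, ln)
                note(name, ln)
                reactions.append(Reaction(
                    name,
                    substrates=_parse_species(lhs.strip(), ln),
                    products=_parse_species(" ".join(prod_toks), ln),
                    enzyme=kv.get("enzyme") if head == "reaction" else None,
                    r=_num(kv.get("r", "0"), ln, "reversibility"),
                    w=_num(kv.get("w", "1"), ln, "w"),
                ))
            elif head == "branch":
                parent, _, body = rest.partition(":")
                fracs: dict[str, float | None] = {}
                for tok in body.split():
                    child, _, val = tok.partition("=")
                    if not val:
                        raise ModelSyntaxError(
                            f"branch child needs <id>=<fraction|*>, got {tok!r}",
                            ln)
                    fracs[child] = (None if val == "*"
                                    else _num(val, ln, "fraction"))
                branches.append(BranchPoint(parent.strip(), fracs))
            elif head == "source":
                m = re.match(r"^(\w+)\s*->\s*(\w+)(.*)$", rest)
                if not m:
                    raise ModelSyntaxError(
                        "expected: source <id> -> <metabolite> [phi=..]", ln)
                kv = _parse_kv(m.group(3).split(), ln)
                note(m.group(1), ln)
                sources.append(FluxSource(
                    m.group(1), m.group(2),
                    phi=_num(kv.get("phi", "1"), ln, "phi")))
            elif head == "sink":
                m = re.match(r"^(\w+)\s*<-\s*(\w+)$", rest)
                if not m:
                    raise ModelSyntaxError(
                        "expected: sink <id> <- <metabolite>", ln)
                note(m.group(1), ln)
                sinks.append(Sink(m.group(1), m.group(2)))
            elif head == "gene":
                name, _, body = rest.partition(":")
                kv = _parse_kv(body.split(), ln)
                regs: list[tuple[str, int]] = []
                for item in filter(None, kv.get("regulators", "").split(",")):
                    ref, _, sign = item.partition(":")
                    if sign not in ("+", "-"):
                        raise ModelSyntaxError(
                            f"regulator {item!r} needs :+ or :-", ln)
                    regs.append((ref, 1 if sign == "+" else -1))
                note(name.strip(), ln)
                genes.append(GeneNode(
                    name.strip(), regulators=tuple(regs),
                    q_max=_num(kv.get("Qmax", "10"), ln, "Qmax"),
                    qc_hat=_num(kv.get("Qc_hat", "10"), ln, "Qc_hat"),
                    k_d=_num(kv.get("kd", "0.01"), ln, "kd")))
            elif head == "protein":
                name, _, body = rest.partition(":")
                kv = _parse_kv(body.split(), ln)
                if "mrna" not in kv:
                    raise ModelSyntaxError("protein needs mrna=<gene>", ln)
                note(name.strip(), ln)
                proteins.append(ProteinNode(
                    name.strip(), mrna=kv["mrna"],
                    k_d=_num(kv.get("kd", "0.01"), ln, "kd")))
            elif head == "switch":
                name, _, body = rest.partition(":")
                kv = _parse_kv(body.split(), ln)
                note(name.strip(), ln)
                switches.append(SwitchNode(
                    name.strip(),
                    act_driver=kv.get("act"), inact_driver=kv.get("inact"),
                    k_i=_num(kv.get("ki", "0.01"), ln, "ki"),
                    k_d=_num(kv.get("kd", "0.01"), ln, "kd"),
                    synth=kv.get("synth")))
            else:
                raise ModelSyntaxError(f"unknown directive {head!r}", ln)
        except ValidationError as exc:
            raise ModelSyntaxError(str(exc), ln) from exc

    return ModelDefinition(
        compartments=tuple(compartments) or COMPARTMENTS,
        metabolites=tuple(metabolites), enzymes=tuple(enzymes),
        reactions=tuple(reactions), branches=tuple(branches),
        sources=tuple(sources), sinks=tuple(sinks), genes=tuple(genes),
        proteins=tuple(proteins), switches=tuple(switches),
        provenance=provenance)


def load_model_definition(path: str | Path) -> ModelDefinition:
    return read_model_definition(Path(path).read_text(encoding="utf-8"))


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_model_definition(definition: ModelDefinition) -> str:
    """Serialize a definition; ``read(write(d))`` reproduces ``d``."""
    d = definition
    out = [HEADER, ""]
    for c in d.compartments:
        out.append(f"compartment {c}")
    out.append("")
    for m in d.metabolites:
        out.append(f"metabolite {m.id} {m.compartment}")
    out.append("")
    for e in d.enzymes:
        line = f"enzyme {e.id} {e.compartment}"
        if e.regulated_by:
            line += f" regulated_by={e.regulated_by}"
        if e.turnover != 0.01:
            line += f" turnover={_fmt(e.turnover)}"
        out.append(line)
    out.append("")

    def species(side: Mapping[str, float]) -> str:
        return " + ".join(
            (f"{_fmt(mu)} {mid}" if mu != 1.0 else mid)
            for mid, mu in side.items())

    for r in d.reactions:
        kind = "reaction" if r.enzyme else "transport"
        line = f"{kind} {r.id}: {species(r.substrates)} -> {species(r.products)}"
        if r.enzyme:
            line += f" enzyme={r.enzyme}"
        if r.r:
            line += f" r={_fmt(r.r)}"
        if r.w != 1.0:
            line += f" w={_fmt(r.w)}"
        out.append(line)
    out.append("")
    for b in d.branches:
        kids = " ".join(
            f"{cid}={'*' if f is None else _fmt(f)}"
            for cid, f in b.fractions.items())
        out.append(f"branch {b.parent}: {kids}")
    for s in d.sources:
        out.append(f"source {s.id} -> {s.target} phi={_fmt(s.phi)}")
    for s in d.sinks:
        out.append(f"sink {s.id} <- {s.target}")
    out.append("")
    for g in d.genes:
        line = f"gene {g.id}:"
        if g.regulators:
            regs = ",".join(f"{ref}:{'+' if sign > 0 else '-'}"
                            for ref, sign in g.regulators)
            line += f" regulators={regs}"
        line += (f" Qmax={_fmt(g.q_max)} Qc_hat={_fmt(g.qc_hat)}"
                 f" kd={_fmt(g.k_d)}")
        out.append(line)
    for p in d.proteins:
        out.append(f"protein {p.id}: mrna={p.mrna} kd={_fmt(p.k_d)}")
    for s in d.switches:
        line = f"switch {s.id}:"
        if s.act_driver:
            line += f" act={s.act_driver}"
        if s.inact_driver:
            line += f" inact={s.inact_driver}"
        line += f" ki={_fmt(s.k_i)} kd={_fmt(s.k_d)}"
        if s.synth:
            line += f" synth={s.synth}"
        out.append(line)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Modelica subset importer
# ---------------------------------------------------------------------------


#: canonical object classes (cf. the systems-biology object library:
#: metabolite, enzyme, regulatory protein, mRNA, translation, reaction,
#: activation, inhibition, transcriptional activation/inhibition, source)
_CLASS_KINDS = {
    "metabolite": "metabolite",
    "enzyme": "enzyme",
    "reaction": "reaction",
    "source": "source",
    "sink": "sink",
    "mrna": "mrna",
    "translation": "translation",
    "regulatoryprotein": "regulatory_protein",
    "transcriptionalactivation": "transcriptional_activation",
    "transcriptionalinhibition": "transcriptional_inhibition",
    "activation": "activation",
    "inhibition": "inhibition",
}


@dataclass
class ImportReport:
    recognized: dict[str, int] = field(default_factory=dict)
    unrecognized: list[tuple[int, str]] = field(default_factory=list)
    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_recognized(self) -> int:
        return sum(self.recognized.values())

    @property
    def n_total(self) -> int:
        return self.n_recognized + len(self.unrecognized)


_COMPONENT_RE = re.compile(
    r"^\s*([A-Za-z_][\w.]*)\s+([A-Za-z_]\w*)\s*(?:\((.*)\))?\s*;\s*$")
_CONNECT_RE = re.compile(
    r"^\s*connect\s*\(\s*([A-Za-z_]\w*)\.([A-Za-z_]\w*)\s*,"
    r"\s*([A-Za-z_]\w*)\.([A-Za-z_]\w*)\s*\)\s*;\s*$")
_CLASS_DEF_RE = re.compile(
    r"^\s*(?:class|model|block|connector)\s+([A-Za-z_]\w*)")


def _library_classes(library_text: str) -> dict[str, str]:
    """Map class names defined in the library to canonical kinds."""
    kinds: dict[str, str] = {}
    for line in library_text.splitlines():
        m = _CLASS_DEF_RE.match(line)
        if not m:
            continue
        name = m.group(1)
        key = name.lower().replace("_", "")
        if key in _CLASS_KINDS:
            kinds[name] = _CLASS_KINDS[key]
    return kinds


def _parse_modifiers(text: str | None) -> dict[str, str]:
    if not text:
        return {}
    out = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = v.strip().strip('"')
    return out


def import_modelica_subset(model_text: str, library_text: str
                           ) -> tuple[ModelDefinition, ImportReport]:
    """Build a :class:`ModelDefinition` from restricted Modelica source.

    Only component declarations whose class is defined (or aliased) in the
    library, plus ``connect`` statements, are interpreted.  Port semantics:
    S/P -> reaction substrate/product edges, E -> enzyme edge, C ->
    transcriptional-regulation edge, A/I -> active/inactive switch pools,
    O/I on metabolites and sources -> flux direction.  Everything else is
    listed in the report with its line number; nothing is silently dropped.
    """
    classes = _library_classes(library_text)
    report = ImportReport()
    instances: dict[str, tuple[str, dict[str, str]]] = {}
    connects: list[tuple[str, str, str, str]] = []

    in_equation = False
    for ln, raw in enumerate(model_text.splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith(("model ", "end ", "within ", "annotation")):
            continue
        if low == "equation":
            in_equation = True
            continue
        m = _CONNECT_RE.match(line)
        if m:
            connects.append(m.groups())
            continue
        if not in_equation:
            m = _COMPONENT_RE.match(line)
            if m:
                cls, name, mods = m.group(1), m.group(2), m.group(3)
                cls_short = cls.split(".")[-1]
                kind = classes.get(cls_short) or _CLASS_KINDS.get(
                    cls_short.lower().replace("_", ""))
                if kind is None:
                    report.unrecognized.append((ln, line))
                    continue
                instances[name] = (kind, _parse_modifiers(mods))
                report.recognized[kind] = report.recognized.get(kind, 0) + 1
                continue
        report.unrecognized.append((ln, line))

    if not instances and not connects:
        return ModelDefinition(), report

    def of_kind(kind: str) -> list[str]:
        return [n for n, (k, _) in instances.items() if k == kind]

    metabolites = [
        Metabolite(n, instances[n][1].get("comp", "liver"))
        for n in of_kind("metabolite")
    ]
    enzymes = {n: Enzyme(n, instances[n][1].get("comp", "liver"))
               for n in of_kind("enzyme")}

    # connect bookkeeping, keyed by (instance, port)
    by_target: dict[str, list[tuple[str, str, str]]] = {}
    for a, pa, b, pb in connects:
        by_target.setdefault(a, []).append((pa, b, pb))
        by_target.setdefault(b, []).append((pb, a, pa))

    def peers(inst: str, port: str) -> list[str]:
        return [other for p, other, _ in by_target.get(inst, []) if p == port]

    reactions: list[Reaction] = []
    rxn_fraction: dict[str, float | None] = {}
    for n in of_kind("reaction"):
        _, mods = instances[n]
        subs = {m: 1.0 for m in peers(n, "S")}
        prods = {m: 1.0 for m in peers(n, "P")}
        enz = peers(n, "E")
        if not subs or not prods:
            report.unrecognized.append((0, f"reaction {n}: unresolved S/P ports"))
            continue
        reactions.append(Reaction(
            n, subs, prods, enzyme=enz[0] if enz else None,
            r=float(mods.get("r", 0.0)), w=float(mods.get("w", 1.0))))
        rxn_fraction[n] = float(mods["f"]) if "f" in mods else None
        report.mapping[n] = ("reaction", n)

    sources = []
    for n in of_kind("source"):
        _, mods = instances[n]
        targets = peers(n, "O")
        if targets:
            sources.append(FluxSource(n, targets[0],
                                      phi=float(mods.get("phi", 1.0))))
    sinks = [Sink(n, peers(n, "I")[0]) for n in of_kind("sink")
             if peers(n, "I")]

    genes: list[GeneNode] = []
    for n in of_kind("mrna"):
        _, mods = instances[n]
        regs: list[tuple[str, int]] = []
        for reg_obj in of_kind("transcriptional_activation"):
            if n in peers(reg_obj, "O"):
                for tf in peers(reg_obj, "C"):
                    regs.append((tf, 1))
        for reg_obj in of_kind("transcriptional_inhibition"):
            if n in peers(reg_obj, "O"):
                for tf in peers(reg_obj, "C"):
                    regs.append((tf, -1))
        genes.append(GeneNode(
            n, regulators=tuple(regs),
            q_max=float(mods.get("Qmax", 10.0)),
            qc_hat=float(mods.get("Qc", 10.0)),
            k_d=float(mods.get("kd", 0.01))))

    proteins: list[ProteinNode] = []
    for tr in of_kind("translation"):
        mrnas = peers(tr, "I")
        prots = peers(tr, "O")
        if mrnas and prots:
            proteins.append(ProteinNode(prots[0], mrna=mrnas[0]))
    protein_ids = {p.id for p in proteins}

    switches: list[SwitchNode] = []
    for n in of_kind("regulatory_protein"):
        if n in protein_ids:
            continue
        act = inact = None
        for obj in of_kind("activation"):
            if n in peers(obj, "I"):     # I port: the inactive protein pool
                drivers = peers(obj, "M") or peers(obj, "S")
                if drivers:
                    act = drivers[0]
        for obj in of_kind("inhibition"):
            if n in peers(obj, "I"):
                drivers = peers(obj, "M") or peers(obj, "S")
                if drivers:
                    inact = drivers[0]
        switches.append(SwitchNode(n, act_driver=act, inact_driver=inact))

    # hook enzymes to their mRNA where a translation object targets them
    for tr in of_kind("translation"):
        mrnas = peers(tr, "I")
        targets = peers(tr, "O")
        for t in targets:
            if t in enzymes and mrnas:
                enzymes[t] = Enzyme(t, enzymes[t].compartment,
                                    regulated_by=mrnas[0])

    # branches from metabolites with several consumers
    consumed_by: dict[str, list[str]] = {}
    for r in reactions:
        for mid in r.substrates:
            consumed_by.setdefault(mid, []).append(r.id)
    for s in sinks:
        consumed_by.setdefault(s.target, []).append(s.id)
    branches = []
    for mid, consumers in consumed_by.items():
        if len(consumers) > 1:
            branches.append(BranchPoint(mid, {
                c: rxn_fraction.get(c) for c in consumers}))

    for n, (kind, _) in instances.items():
        report.mapping.setdefault(n, (kind, n))

    definition = ModelDefinition(
        metabolites=tuple(metabolites), enzymes=tuple(enzymes.values()),
        reactions=tuple(reactions), branches=tuple(branches),
        sources=tuple(sources), sinks=tuple(sinks), genes=tuple(genes),
        proteins=tuple(proteins), switches=tuple(switches))
    return definition, report


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results(tables: Mapping[str, pd.DataFrame], path: str | Path
                  ) -> list[Path]:
    """Write tidy TSVs with stable column order and deterministic rows.

    ``tables`` maps a base name to a DataFrame; each is written to
    ``<path>/<name>.tsv``.  Empty tables produce header-only files.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = outdir / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
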