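"""Domain types and normalized steady-state parameter initialization.

A network is declared in terms of four kinds of independent parameters:

* ``r``  -- reversibility: the ratio of reverse to forward flux through each
  elementary step of a reaction at the reference steady state (0 = irreversible);
* ``f``  -- flux fractions: how a metabolite's total efflux is distributed
  among the reactions that consume it;
* ``w``  -- the ratio of enzyme-substrate complex to free enzyme at the
  reference state (affects transients only, never steady-state levels);
* ``phi`` -- normalized boundary influxes.

Every concentration is dimensionless and equals 1 at the reference state
(complexes equal ``w``).  All kinetic rate constants are *derived* from
(r, f, w, phi) so that the all-ones state is an exact equilibrium of the
assembled ODE system; no measured kinetic constant is ever required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Enzyme",
    "Reaction",
    "BranchPoint",
    "FluxSource",
    "Sink",
    "GeneNode",
    "ProteinNode",
    "SwitchNode",
    "ModelDefinition",
    "ValidationError",
    "StructuralError",
    "RateConstants",
    "ParameterSet",
    "StructureStats",
    "StateIndex",
    "NetworkModel",
    "build_network",
    "derive_rate_constants",
    "initialize_state",
    "structure_stats",
]

#: Recognized tissue compartments.
COMPARTMENTS = (
    "liver",
    "adipose",
    "blood",
    "pancreas",
    "peripheral",
    "macrophage",
)

#: Default enzyme turnover (synthesis = degradation at baseline), per time unit.
#: Sets how fast expression changes propagate to enzyme levels; steady states
#: do not depend on it when expression is constant.
DEFAULT_ENZYME_TURNOVER = 0.01


class ValidationError(ValueError):
    """A definition is syntactically fine but semantically inconsistent."""


class StructuralError(ValidationError):
    """A reference in the definition does not resolve."""


# ---------------------------------------------------------------------------
# Declarative entities (what a model definition contains)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "liver"


@dataclass(frozen=True)
class Enzyme:
    """A catalytic protein pool.

    ``regulated_by`` optionally names a gene-expression node (mRNA or protein)
    whose level drives enzyme synthesis; otherwise synthesis is constant and
    exactly balances degradation at baseline.
    """

    id: str
    compartment: str = "liver"
    regulated_by: str | None = None
    turnover: float = DEFAULT_ENZYME_TURNOVER  # k_dE = phi_EI at baseline


@dataclass(frozen=True)
class Reaction:
    """An enzymatic conversion, or an enzyme-free (carrier) transport step.

    ``substrates``/``products`` map metabolite ids to stoichiometric flux
    multipliers (default 1).  ``enzyme is None`` declares a first-order
    carrier step with no explicit catalyst.
    """

    id: str
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    enzyme: str | None = None
    r: float = 0.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.id!r} needs at least one substrate and one product"
            )
        if not (0.0 <= self.r < 1.0):
            raise ValidationError(
                f"reaction {self.id!r}: reversibility r={self.r} outside [0, 1)"
            )
        if self.w <= 0.0:
            raise ValidationError(f"reaction {self.id!r}: w={self.w} must be > 0")


@dataclass(frozen=True)
class BranchPoint:
    """Distribution of a parent metabolite's efflux among >= 2 consumers.

    ``fractions`` maps consumer (reaction or sink) ids to flux fractions.
    A fraction may be ``None`` ("balance"): that child's share is whatever
    flux-balance requires, used when a child's throughput is already pinned
    elsewhere (e.g. the secondary substrate of a multi-substrate reaction).
    Declared fractions must sum to 1 when no balance children are present.
    """

    parent: str
    fractions: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValidationError(
                f"branch at {self.parent!r} needs >= 2 children"
            )
        declared = [v for v in self.fractions.values() if v is not None]
        for v in declared:
            if not (0.0 < v <= 1.0):
                raise ValidationError(
                    f"branch at {self.parent!r}: fraction {v} outside (0, 1]"
                )
        total = sum(declared)
        if len(declared) == len(self.fractions) and abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"branch at {self.parent!r}: fractions sum to {total}, "
                f"residual {1.0 - total:+.6g}"
            )
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"branch at {self.parent!r}: declared fractions exceed 1 ({total})"
            )


@dataclass(frozen=True)
class FluxSource:
    id: str
    target: str
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValidationError(f"source {self.id!r}: phi must be > 0")


@dataclass(frozen=True)
class Sink:
    """A first-order demand; its rate constant is set so baseline flux balances."""

    id: str
    target: str


@dataclass(frozen=True)
class GeneNode:
    """An mRNA pool under sigmoidal transcriptional control.

    ``regulators`` is a list of (state id, sign) pairs with sign ``+1``
    (activation) or ``-1`` (repression).  ``q_max`` is the maximal relative
    expression; ``qc_hat`` the activator level at which expression saturates
    at ``q_max``.
    """

    id: str
    regulators: tuple[tuple[str, int], ...] = ()
    q_max: float = 10.0
    qc_hat: float = 10.0
    k_d: float = 0.01

    def __post_init__(self) -> None:
        if self.q_max <= 1.0:
            raise ValidationError(
                f"gene {self.id!r}: q_max={self.q_max} gives no dynamic range"
            )
        if self.qc_hat <= 1.0:
            raise ValidationError(f"gene {self.id!r}: qc_hat must exceed 1")
        if self.k_d <= 0:
            raise ValidationError(f"gene {self.id!r}: k_d must be > 0")
        for _, sign in self.regulators:
            if sign not in (1, -1):
                raise ValidationError(f"gene {self.id!r}: sign must be +1 or -1")


@dataclass(frozen=True)
class ProteinNode:
    """A translated protein pool (linear translation / degradation)."""

    id: str
    mrna: str
    k_d: float = 0.01

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValidationError(f"protein {self.id!r}: k_d must be > 0")


@dataclass(frozen=True)
class SwitchNode:
    """A post-translationally switched regulator with active/inactive pools.

    Activation transfers mass from the inactive to the active pool at rate
    ``k_a * D_act * Q_CI``; inactivation symmetrically at ``k_i * D_inact *
    Q_CA``.  Both pools degrade at ``k_d`` and the inactive pool is fed by
    constant synthesis (optionally scaled by a gene-expression node).  At the
    baseline (all drivers 1, both pools 1), ``k_a = k_i + k_d`` is enforced
    so the partition is an exact fixed point.
    """

    id: str
    act_driver: str | None = None
    inact_driver: str | None = None
    k_i: float = 0.01
    k_d: float = 0.01
    synth: str | None = None  # optional gene/protein node scaling synthesis

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValidationError(f"switch {self.id!r}: k_d must be > 0")
        if self.k_i < 0:
            raise ValidationError(f"switch {self.id!r}: k_i must be >= 0")

    @property
    def k_a(self) -> float:
        return self.k_i + self.k_d


@dataclass(frozen=True)
class ModelDefinition:
    """The declarative content of a model-definition file."""

    compartments: tuple[str, ...] = COMPARTMENTS
    metabolites: tuple[Metabolite, ...] = ()
    enzymes: tuple[Enzyme, ...] = ()
    reactions: tuple[Reaction, ...] = ()
    branches: tuple[BranchPoint, ...] = ()
    sources: tuple[FluxSource, ...] = ()
    sinks: tuple[Sink, ...] = ()
    genes: tuple[GeneNode, ...] = ()
    proteins: tuple[ProteinNode, ...] = ()
    switches: tuple[SwitchNode, ...] = ()
    #: optional provenance: entity id -> source line number
    provenance: Mapping[str, int] = field(default_factory=dict)

    def replace_branch(self, parent: str, fractions: Mapping[str, float | None]
                       ) -> "ModelDefinition":
        """Return a copy with the branch at ``parent`` re-declared."""
        new = tuple(
            BranchPoint(parent, dict(fractions)) if b.parent == parent else b
            for b in self.branches
        )
        if all(b.parent != parent for b in self.branches):
            raise StructuralError(f"no branch point at {parent!r}")
        return replace(self, branches=new)


# ---------------------------------------------------------------------------
# Derived (dependent) parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """Per-reaction rate constants derived from (r, w) and the baseline flux.

    For an enzymatic reaction with baseline throughput ``F``::

        k_C  = F / (1 - r)            complex formation
        k_CR = r F / ((1 - r) w)      complex dissociation (reverse)
        k_P  = F / ((1 - r) w)        product formation
        k_PR = r F / (1 - r)          product reversion (reverse)

    so that at S_N = E_N = P_N = 1, C_N = w each elementary step carries net
    flux F and a reverse/forward ratio of exactly r.  Enzyme-free carriers
    use only (k_C, k_CR) as first-order forward/reverse constants.
    """

    k_C: float
    k_P: float
    k_CR: float
    k_PR: float


def derive_rate_constants(reaction: Reaction, throughput: float) -> RateConstants:
    """Rate constants making the normalized state an exact equilibrium.

    ``throughput`` is the reaction's net baseline flux: the branch fraction f
    times the parent metabolite's total steady-state efflux.
    """
    r, w = reaction.r, reaction.w
    if not (0.0 <= r < 1.0):
        raise ValidationError(f"infeasible reversibility r={r} (must be in [0,1))")
    if w <= 0:
        raise ValidationError(f"w={w} must be > 0")
    if throughput <= 0:
        raise ValidationError(
            f"reaction {reaction.id!r}: baseline throughput {throughput} must be > 0"
        )
    F = throughput
    if reaction.enzyme is None:
        # first-order carrier: flux = k_C * prod(S) - k_CR * prod(P)
        return RateConstants(k_C=F / (1 - r), k_P=0.0, k_CR=r * F / (1 - r), k_PR=0.0)
    return RateConstants(
        k_C=F / (1 - r),
        k_P=F / ((1 - r) * w),
        k_CR=r * F / ((1 - r) * w),
        k_PR=r * F / (1 - r),
    )


@dataclass(frozen=True)
class ParameterSet:
    """Independent parameters and the constants derived from them.

    Mirrors the independent/dependent taxonomy: fractions, reversibilities,
    w ratios, boundary fluxes and regulation constants are independent;
    every rate constant is recomputable from them plus the flux balance.
    """

    independent: dict[str, float]
    dependent: dict[str, float]
    counts: dict[str, int]


@dataclass(frozen=True)
class StructureStats:
    n_reactions: int
    n_metabolites: int
    n_enzymes: int
    n_regulatory_proteins: int
    n_states: int
    n_parameters_by_category: dict[str, int]


# ---------------------------------------------------------------------------
# State indexing
# ---------------------------------------------------------------------------


class StateIndex:
    """Maps state labels to positions in the assembled state vector.

    Label conventions: metabolites use their bare id; enzymes ``enz.<id>``;
    complexes ``cx.<reaction id>``; mRNAs ``mrna.<id>``; proteins their bare
    id; switch pools ``<id>.active`` / ``<id>.inactive``.
    """

    def __init__(self, definition: ModelDefinition) -> None:
        labels: list[str] = []
        labels += [m.id for m in definition.metabolites]
        labels += [f"enz.{e.id}" for e in definition.enzymes]
        labels += [f"cx.{r.id}" for r in definition.reactions if r.enzyme is not None]
        labels += [f"mrna.{g.id}" for g in definition.genes]
        labels += [p.id for p in definition.proteins]
        for s in definition.switches:
            labels += [f"{s.id}.active", f"{s.id}.inactive"]
        self.labels: tuple[str, ...] = tuple(labels)
        self._pos = {lab: i for i, lab in enumerate(labels)}
        if len(self._pos) != len(labels):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise ValidationError(f"duplicate state label {lab!r}")
                seen.add(lab)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> int:
        try:
            return self._pos[label]
        except KeyError:
            raise StructuralError(f"unknown state {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._pos

    def resolve(self, name: str) -> int:
        """Resolve a user-facing name, trying bare ids across namespaces."""
        if name in self._pos:
            return self._pos[name]
        for prefix in ("enz.", "mrna."):
            if prefix + name in self._pos:
                return self._pos[prefix + name]
        if name + ".active" in self._pos:
            return self._pos[name + ".active"]
        raise StructuralError(f"unknown variable {name!r}")

    def resolve_label(self, name: str) -> str:
        return self.labels[self.resolve(name)]


# ---------------------------------------------------------------------------
# The compiled network
# ---------------------------------------------------------------------------


@dataclass
class NetworkModel:
    """A validated network with its baseline fluxes and derived constants."""

    definition: ModelDefinition
    index: StateIndex
    #: baseline net throughput per consumer (reaction or sink) id
    baseline_flux: dict[str, float]
    #: baseline total efflux per metabolite id
    total_efflux: dict[str, float]
    #: derived constants per reaction id
    rate_constants: dict[str, RateConstants]
    #: first-order sink rate constants (= baseline sink flux)
    sink_rates: dict[str, float]
    #: realized baseline fraction per (branch parent, child)
    branch_fractions: dict[str, dict[str, float]]
    warnings: tuple[str, ...] = ()

    # -- convenience lookups ------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn[rid]

    def enzyme(self, eid: str) -> Enzyme:
        return self._enz[eid]

    def __post_init__(self) -> None:
        d = self.definition
        self._met = {m.id: m for m in d.metabolites}
        self._rxn = {r.id: r for r in d.reactions}
        self._enz = {e.id: e for e in d.enzymes}
        self.genes = {g.id: g for g in d.genes}
        self.proteins = {p.id: p for p in d.proteins}
        self.switches = {s.id: s for s in d.switches}
        self.sources = {s.id: s for s in d.sources}
        self.sinks = {s.id: s for s in d.sinks}

    def with_branch_fraction(self, parent: str, child: str, f_new: float
                             ) -> "NetworkModel":
        """Rebuild the network with one branch fraction moved to ``f_new``.

        Sibling fractions are rescaled by a common factor so the declared
        fractions still sum to one (proportional renormalization).
        """
        branch = next((b for b in self.definition.branches if b.parent == parent), None)
        if branch is None:
            raise StructuralError(f"no branch point at {parent!r}")
        if child not in branch.fractions:
            raise StructuralError(f"{child!r} is not a child of branch {parent!r}")
        if any(v is None for v in branch.fractions.values()):
            raise ValidationError(
                f"branch at {parent!r} has balance children; its fractions are "
                "structurally pinned and cannot be re-declared"
            )
        if not (0.0 < f_new < 1.0):
            raise ValidationError(f"new fraction {f_new} outside (0, 1)")
        f_old = branch.fractions[child]
        scale = (1.0 - f_new) / (1.0 - f_old)
        new_fracs = {
            c: (f_new if c == child else v * scale)
            for c, v in branch.fractions.items()
        }
        # exact renormalization against float drift
        total = sum(new_fracs.values())
        new_fracs = {c: v / total for c, v in new_fracs.items()}
        return build_network(self.definition.replace_branch(parent, new_fracs))


# ---------------------------------------------------------------------------
# Building & validation
# ---------------------------------------------------------------------------


def _check_references(d: ModelDefinition) -> list[str]:
    """Return warnings; raise StructuralError on dangling references."""
    met_ids = {m.id for m in d.metabolites}
    enz_ids = {e.id for e in d.enzymes}
    node_ids = (
        {f"g:{g.id}" for g in d.genes}
        | {f"p:{p.id}" for p in d.proteins}
        | {f"s:{s.id}" for s in d.switches}
    )
    gene_like = {g.id for g in d.genes} | {p.id for p in d.proteins}
    all_ids: dict[str, str] = {}
    for kind, items in (
        ("metabolite", d.metabolites), ("enzyme", d.enzymes),
        ("reaction", d.reactions), ("source", d.sources), ("sink", d.sinks),
        ("gene", d.genes), ("protein", d.proteins), ("switch", d.switches),
    ):
        for it in items:
            if it.id in all_ids:
                raise ValidationError(
                    f"duplicate id {it.id!r} ({all_ids[it.id]} and {kind})"
                )
            all_ids[it.id] = kind

    index = StateIndex(d)

    for m in d.metabolites:
        if m.compartment not in d.compartments:
            raise ValidationError(
                f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
            )
    for rxn in d.reactions:
        for mid in list(rxn.substrates) + list(rxn.products):
            if mid not in met_ids:
                raise StructuralError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        if rxn.enzyme is not None and rxn.enzyme not in enz_ids:
            raise StructuralError(
                f"reaction {rxn.id!r} references unknown enzyme {rxn.enzyme!r}"
            )
    for e in d.enzymes:
        if e.regulated_by is not None and e.regulated_by not in gene_like:
            raise StructuralError(
                f"enzyme {e.id!r} regulated by unknown node {e.regulated_by!r}"
            )
    consumer_ids = {r.id for r in d.reactions} | {s.id for s in d.sinks}
    for b in d.branches:
        if b.parent not in met_ids:
            raise StructuralError(f"branch parent {b.parent!r} is not a metabolite")
        for child in b.fractions:
            if child not in consumer_ids:
                raise StructuralError(
                    f"branch at {b.parent!r}: unknown consumer {child!r}"
                )
            if child in {r.id for r in d.reactions}:
                rxn = next(r for r in d.reactions if r.id == child)
                if b.parent not in rxn.substrates:
                    raise StructuralError(
                        f"branch at {b.parent!r}: child {child!r} does not "
                        f"consume the parent"
                    )
            else:
                snk = next(s for s in d.sinks if s.id == child)
                if snk.target != b.parent:
                    raise StructuralError(
                        f"branch at {b.parent!r}: sink {child!r} drains "
                        f"{snk.target!r}, not the parent"
                    )
    for s in d.sources:
        if s.target not in met_ids:
            raise StructuralError(f"source {s.id!r} targets unknown {s.target!r}")
    for s in d.sinks:
        if s.target not in met_ids:
            raise StructuralError(f"sink {s.id!r} drains unknown {s.target!r}")
    for g in d.genes:
        for ref, _ in g.regulators:
            try:
                index.resolve(ref)
            except StructuralError:
                raise StructuralError(
                    f"gene {g.id!r}: unknown regulator {ref!r}"
                ) from None
    for p in d.proteins:
        if p.mrna not in {g.id for g in d.genes}:
            raise StructuralError(f"protein {p.id!r}: unknown mRNA {p.mrna!r}")
    for s in d.switches:
        for ref in (s.act_driver, s.inact_driver):
            if ref is not None:
                try:
                    index.resolve(ref)
                except StructuralError:
                    raise StructuralError(
                        f"switch {s.id!r}: unknown driver {ref!r}"
                    ) from None
        if s.synth is not None and s.synth not in gene_like:
            raise StructuralError(f"switch {s.id!r}: unknown synth node {s.synth!r}")

    warnings: list[str] = []
    used_enzymes = {r.enzyme for r in d.reactions if r.enzyme is not None}
    for e in d.enzymes:
        if e.id not in used_enzymes:
            warnings.append(f"enzyme {e.id!r} is not used by any reaction")
    consumed = {m for r in d.reactions for m in r.substrates} | {
        s.target for s in d.sinks
    }
    produced = {m for r in d.reactions for m in r.products} | {
        s.target for s in d.sources
    }
    for m in d.metabolites:
        if m.id not in consumed and m.id not in produced:
            warnings.append(f"metabolite {m.id!r} is unreferenced")
    return warnings


def _solve_baseline_fluxes(d: ModelDefinition) -> tuple[dict[str, float],
                                                        dict[str, float]]:
    """Solve the linear flux-balance system for baseline throughputs.

    Unknowns are the net throughput of every consumer (reaction/sink) and the
    total efflux of every metabolite.  Equations: (i) per-metabolite balance
    ``T_x = sum(sources) + sum(production)``, (ii) per-metabolite efflux
    ``T_x = sum(consumption)``, (iii) one fraction constraint per declared
    branch fraction.  Solved with least squares; any residual means the
    declared fractions are mutually inconsistent.
    """
    consumers: list[tuple[str, Mapping[str, float], bool]] = []
    for r in d.reactions:
        consumers.append((r.id, r.substrates, True))
    for s in d.sinks:
        consumers.append((s.id, {s.target: 1.0}, False))

    n_c = len(consumers)
    mets = [m.id for m in d.metabolites]
    n_m = len(mets)
    c_pos = {cid: i for i, (cid, _, _) in enumerate(consumers)}
    m_pos = {mid: n_c + i for i, mid in enumerate(mets)}
    nvar = n_c + n_m

    rows: list[np.ndarray] = []
    rhs: list[float] = []

    source_in: dict[str, float] = {m: 0.0 for m in mets}
    for s in d.sources:
        source_in[s.target] += s.phi

    produced_by: dict[str, list[tuple[str, float]]] = {m: [] for m in mets}
    consumed_by: dict[str, list[tuple[str, float]]] = {m: [] for m in mets}
    for r in d.reactions:
        for mid, mult in r.products.items():
            produced_by[mid].append((r.id, mult))
        for mid, mult in r.substrates.items():
            consumed_by[mid].append((r.id, mult))
    for s in d.sinks:
        consumed_by[s.target].append((s.id, 1.0))

    for mid in mets:
        # influx balance: T_x - sum(m_j F_j) = sum(phi)
        row = np.zeros(nvar)
        row[m_pos[mid]] = 1.0
        for rid, mult in produced_by[mid]:
            row[c_pos[rid]] -= mult
        rows.append(row)
        rhs.append(source_in[mid])
        # efflux balance: T_x - sum(m_c F_c) = 0
        row = np.zeros(nvar)
        row[m_pos[mid]] = 1.0
        for cid, mult in consumed_by[mid]:
            row[c_pos[cid]] -= mult
        rows.append(row)
        rhs.append(0.0)

    branch_parents = {b.parent for b in d.branches}
    for mid in mets:
        if len(consumed_by[mid]) > 1 and mid not in branch_parents:
            raise ValidationError(
                f"metabolite {mid!r} has {len(consumed_by[mid])} consumers but "
                "no declared branch point"
            )
    for b in d.branches:
        declared_children = set(b.fractions)
        actual_children = {cid for cid, _ in consumed_by[b.parent]}
        if declared_children != actual_children:
            raise ValidationError(
                f"branch at {b.parent!r}: declared children {sorted(declared_children)} "
                f"!= actual consumers {sorted(actual_children)}"
            )
        mult_of = dict(consumed_by[b.parent])
        for child, frac in b.fractions.items():
            if frac is None:
                continue
            # m_c F_c - f T_x = 0
            row = np.zeros(nvar)
            row[c_pos[child]] = mult_of[child]
            row[m_pos[b.parent]] = -frac
            rows.append(row)
            rhs.append(0.0)

    A = np.array(rows)
    b_vec = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b_vec, rcond=None)
    residual = float(np.max(np.abs(A @ sol - b_vec))) if len(rows) else 0.0
    if residual > 1e-9:
        raise ValidationError(
            "flux-balance system is inconsistent (declared fractions / "
            f"stoichiometry conflict); max residual {residual:.3g}"
        )
    flux = {cid: float(sol[c_pos[cid]]) for cid, _, _ in consumers}
    efflux = {mid: float(sol[m_pos[mid]]) for mid in mets}
    for cid, val in flux.items():
        if val <= 1e-12:
            raise ValidationError(
                f"consumer {cid!r} carries non-positive baseline flux "
                f"({val:.3g}); every reaction needs positive throughput"
            )
    return flux, efflux


def build_network(definition: ModelDefinition) -> NetworkModel:
    """Validate a definition, solve baseline fluxes and derive all constants."""
    warnings = _check_references(definition)
    flux, efflux = _solve_baseline_fluxes(definition)
    rate_constants = {
        r.id: derive_rate_constants(r, flux[r.id]) for r in definition.reactions
    }
    sink_rates = {s.id: flux[s.id] for s in definition.sinks}

    consumed_by: dict[str, list[str]] = {}
    for r in definition.reactions:
        for mid in r.substrates:
            consumed_by.setdefault(mid, []).append(r.id)
    for s in definition.sinks:
        consumed_by.setdefault(s.target, []).append(s.id)
    branch_fractions: dict[str, dict[str, float]] = {}
    for b in definition.branches:
        tot = efflux[b.parent]
        mult = {}
        for r in definition.reactions:
            if b.parent in r.substrates:
                mult[r.id] = r.substrates[b.parent]
        for s in definition.sinks:
            if s.target == b.parent:
                mult[s.id] = 1.0
        branch_fractions[b.parent] = {
            child: mult[child] * flux[child] / tot for child in b.fractions
        }

    return NetworkModel(
        definition=definition,
        index=StateIndex(definition),
        baseline_flux=flux,
        total_efflux=efflux,
        rate_constants=rate_constants,
        sink_rates=sink_rates,
        branch_fractions=branch_fractions,
        warnings=tuple(warnings),
    )


def initialize_state(network: NetworkModel) -> np.ndarray:
    """The normalized reference state: every pool 1, complexes at their w."""
    x = np.ones(len(network.index))
    for r in network.definition.reactions:
        if r.enzyme is not None:
            x[network.index[f"cx.{r.id}"]] = r.w
    return x


def parameter_set(network: NetworkModel) -> ParameterSet:
    """Enumerate independent parameters and the constants derived from them."""
    d = network.definition
    indep: dict[str, float] = {}
    dep: dict[str, float] = {}
    counts: dict[str, int] = {
        "flux_distribution": 0,
        "reaction_reversibility": 0,
        "free_bound_enzyme_ratio": 0,
        "gene_expression_control": 0,
        "stoichiometric": 0,
        "boundary_flux": 0,
        "set_at_initialization": 0,
    }
    for b in d.branches:
        for child, frac in b.fractions.items():
            if frac is not None:
                indep[f"f[{b.parent}->{child}]"] = frac
                counts["flux_distribution"] += 1
    for r in d.reactions:
        indep[f"r[{r.id}]"] = r.r
        counts["reaction_reversibility"] += 1
        if r.enzyme is not None:
            indep[f"w[{r.id}]"] = r.w
            counts["free_bound_enzyme_ratio"] += 1
        for mid, mult in list(r.substrates.items()) + list(r.products.items()):
            indep[f"m[{r.id}:{mid}]"] = mult
            counts["stoichiometric"] += 1
    for s in d.sources:
        indep[f"phi[{s.id}]"] = s.phi
        counts["boundary_flux"] += 1
    for g in d.genes:
        for name, val in (("Qmax", g.q_max), ("Qc_hat", g.qc_hat), ("kd", g.k_d)):
            indep[f"{name}[{g.id}]"] = val
            counts["gene_expression_control"] += 1
    for p in d.proteins:
        indep[f"kd[{p.id}]"] = p.k_d
        counts["gene_expression_control"] += 1
    for s in d.switches:
        indep[f"ki[{s.id}]"] = s.k_i
        indep[f"kd[{s.id}]"] = s.k_d
        counts["gene_expression_control"] += 2
    for e in d.enzymes:
        indep[f"turnover[{e.id}]"] = e.turnover
        counts["gene_expression_control"] += 1

    for rid, rc in network.rate_constants.items():
        rxn = network.reaction(rid)
        if rxn.enzyme is None:
            dep[f"kC[{rid}]"] = rc.k_C
            dep[f"kCR[{rid}]"] = rc.k_CR
            counts["set_at_initialization"] += 2
        else:
            for name, val in (("kC", rc.k_C), ("kP", rc.k_P),
                              ("kCR", rc.k_CR), ("kPR", rc.k_PR)):
                dep[f"{name}[{rid}]"] = val
                counts["set_at_initialization"] += 1
    for sid, rate in network.sink_rates.items():
        dep[f"ksink[{sid}]"] = rate
        counts["set_at_initialization"] += 1
    for s in d.switches:
        dep[f"ka[{s.id}]"] = s.k_a
        dep[f"phiP[{s.id}]"] = 2.0 * s.k_d
        counts["set_at_initialization"] += 2
    return ParameterSet(independent=indep, dependent=dep, counts=counts)


def structure_stats(network: NetworkModel) -> StructureStats:
    d = network.definition
    pset = parameter_set(network)
    return StructureStats(
        n_reactions=len(d.reactions),
        n_metabolites=len(d.metabolites),
        n_enzymes=len(d.enzymes),
        n_regulatory_proteins=len(d.proteins) + len(d.switches),
        n_states=len(network.index),
        n_parameters_by_category=pset.counts,
    )
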