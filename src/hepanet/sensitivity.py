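"""Metabolic control analysis over branch-point flux distributions.

The central statistic is the concentration control coefficient of a branch
fraction f with respect to a target metabolite TG::

    C^TG_f = ((TG* - TG) / (f* - f)) * (f / TG)

where TG and TG* are converged steady-state concentrations at the baseline
and perturbed flux distribution (both evaluated under the same background
perturbation, e.g. a high-calorie diet), f is the baseline fraction and f*
the realized fraction at the perturbed steady state.  The f/TG factor makes
the coefficient dimensionless (a relative sensitivity).

Branch points are classified by |C|: high (> 1), moderate (0.1..0.99),
low (< 0.1); values in the printed gap (0.99, 1] classify as high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NetworkModel, StructuralError, ValidationError
from .dynamics import (
    PerturbationSpec,
    SteadyStateResult,
    find_steady_state,
    realized_flux_fractions,
)

__all__ = [
    "SensitivityRecord",
    "ToleranceRange",
    "concentration_control_coefficient",
    "scan_branches",
    "classify_impact",
    "tolerance_range",
    "regulator_sensitivity",
    "records_to_frame",
]


@dataclass(frozen=True)
class SensitivityRecord:
    branch: str              # parent metabolite of the branch point
    child: str               # consumer whose fraction was varied
    f: float                 # baseline fraction
    delta: float             # imposed relative change of f
    f_perturbed: float       # imposed fraction f (1 + delta)
    f_star: float | None     # realized fraction at the perturbed steady state
    target: str
    target_baseline: float | None   # TG under background, baseline fractions
    target_perturbed: float | None  # TG* under background, perturbed fractions
    coefficient: float       # NaN when either run failed to settle
    impact: str              # high | moderate | low | unclassified
    stable: bool
    mode: str = "none"       # failure mode of the perturbed run
    background: PerturbationSpec | None = field(default=None, compare=False)


@dataclass(frozen=True)
class ToleranceRange:
    branch: str
    child: str
    f_baseline: float
    f_lo: float
    f_hi: float
    mode_lo: str             # instability mode just below f_lo (or "none")
    mode_hi: str             # instability mode just above f_hi (or "none")
    grid: tuple[float, ...] = ()
    stable: tuple[bool, ...] = ()


def classify_impact(coefficient: float) -> str:
    """Impact class from the absolute coefficient (sign reported separately)."""
    if not math.isfinite(coefficient):
        return "unclassified"
    c = abs(coefficient)
    if c < 0.1:
        return "low"
    if c <= 0.99:
        return "moderate"
    return "high"


def _declared_fraction(network: NetworkModel, parent: str, child: str) -> float:
    branch = next((b for b in network.definition.branches if b.parent == parent),
                  None)
    if branch is None:
        raise StructuralError(f"no branch point at {parent!r}")
    if child not in branch.fractions:
        raise StructuralError(f"{child!r} is not a child of branch {parent!r}")
    f = branch.fractions[child]
    if f is None:
        raise ValidationError(
            f"branch {parent!r} child {child!r} has a structurally pinned "
            "(balance) fraction and cannot be scanned"
        )
    return f


def concentration_control_coefficient(
    network: NetworkModel,
    branch: str,
    child: str,
    target: str,
    delta: float = 0.1,
    background: PerturbationSpec | None = None,
    base_result: SteadyStateResult | None = None,
    response: str | None = None,
    **integrate_kwargs,
) -> SensitivityRecord:
    """One branch-point sensitivity evaluation.

    The child's fraction is multiplied by (1 + delta) with siblings
    renormalized proportionally; both the baseline and perturbed systems are
    integrated to steady state under the same ``background`` and the
    dimensionless control coefficient is formed from the two converged
    states.  ``response`` defaults to ``target`` (pass a regulator state to
    compute regulator sensitivities).  A precomputed ``base_result`` for this
    network/background is reused when given.
    """
    f = _declared_fraction(network, branch, child)
    f_pert = f * (1.0 + delta)
    if not (0.0 < f_pert < 1.0):
        raise ValidationError(
            f"perturbed fraction {f_pert:.4g} outside (0, 1) at branch {branch!r}"
        )
    response = response or target
    network.index.resolve(response)  # fail fast on unknown targets

    if base_result is None:
        base_result = find_steady_state(network, background, **integrate_kwargs)
    pert_net = network.with_branch_fraction(branch, child, f_pert)
    pert_result = find_steady_state(pert_net, background, **integrate_kwargs)

    stable = base_result.converged and pert_result.converged
    f_star = None
    tg = tg_star = None
    coeff = float("nan")
    if base_result.converged:
        tg = float(base_result.state[network.index.resolve(response)])
    if pert_result.converged:
        tg_star = float(pert_result.state[pert_net.index.resolve(response)])
        f_star = realized_flux_fractions(pert_net, pert_result.state, branch)[child]
    if stable:
        df = f_star - f
        if abs(df) < 1e-12:
            df = f_pert - f  # fraction held by construction; fall back
        coeff = (tg_star - tg) / df * (f / tg)
    return SensitivityRecord(
        branch=branch, child=child, f=f, delta=delta, f_perturbed=f_pert,
        f_star=f_star, target=target, target_baseline=tg,
        target_perturbed=tg_star, coefficient=coeff,
        impact=classify_impact(coeff) if stable else "unclassified",
        stable=stable, mode=pert_result.mode, background=background,
    )


def scannable_branches(network: NetworkModel) -> list[tuple[str, str]]:
    """(parent, child) pairs whose fractions are declared (not balance)."""
    out = []
    for b in sorted(network.definition.branches, key=lambda b: b.parent):
        for child in sorted(b.fractions):
            if b.fractions[child] is not None:
                out.append((b.parent, child))
    return out


def scan_branches(network: NetworkModel, target: str,
                  deltas: Sequence[float] = (-0.1, 0.1),
                  background: PerturbationSpec | None = None,
                  branches: Sequence[tuple[str, str]] | None = None,
                  **integrate_kwargs) -> list[SensitivityRecord]:
    """Scan every (branch, child, delta) combination against one target.

    Records are ordered deterministically (branch, child, delta); per-record
    non-convergence is flagged on the record, never raised, so one unstable
    grid point does not abort the scan.
    """
    pairs = list(branches) if branches is not None else scannable_branches(network)
    base = find_steady_state(network, background, **integrate_kwargs)
    records = []
    for parent, child in pairs:
        for delta in sorted(deltas):
            try:
                rec = concentration_control_coefficient(
                    network, parent, child, target, delta=delta,
                    background=background, base_result=base, **integrate_kwargs)
            except ValidationError:
                # fraction pushed outside (0,1) or rebuild infeasible
                f = _declared_fraction(network, parent, child)
                rec = SensitivityRecord(
                    branch=parent, child=child, f=f, delta=delta,
                    f_perturbed=f * (1 + delta), f_star=None, target=target,
                    target_baseline=None, target_perturbed=None,
                    coefficient=float("nan"), impact="unclassified",
                    stable=False, mode="infeasible", background=background)
            records.append(rec)
    return records


def tolerance_range(network: NetworkModel, branch: str, child: str,
                    background: PerturbationSpec | None = None,
                    resolution: float = 0.1,
                    **integrate_kwargs) -> ToleranceRange:
    """Maximal contiguous interval of stable flux fractions around baseline.

    The child's fraction is swept over a grid of width ``resolution`` in
    (0, 1); at each point the re-parameterized network is integrated under
    ``background`` and classed stable iff it reaches a steady state.  The
    instability mode just outside each end of the stable interval is
    reported (``none`` when the interval reaches the grid edge).
    """
    if not (0.0 < resolution < 0.5):
        raise ValidationError("resolution must divide (0,1) into a finite grid")
    f0 = _declared_fraction(network, branch, child)
    grid = sorted({round(g, 12) for g in
                   list(np.arange(resolution, 1.0 - resolution / 2, resolution))
                   + [f0]})
    modes = []
    stable = []
    for g in grid:
        if abs(g - f0) < 1e-12:
            net_g = network
        else:
            try:
                net_g = network.with_branch_fraction(branch, child, g)
            except ValidationError:
                stable.append(False)
                modes.append("infeasible")
                continue
        res = find_steady_state(net_g, background, **integrate_kwargs)
        stable.append(res.converged)
        modes.append(res.mode)
    i0 = grid.index(f0)
    if not stable[i0]:
        raise ValidationError(
            f"baseline fraction {f0} at branch {branch!r} is itself unstable "
            f"({modes[i0]}); the model is misconfigured"
        )
    lo = i0
    while lo > 0 and stable[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(grid) - 1 and stable[hi + 1]:
        hi += 1
    mode_lo = modes[lo - 1] if lo > 0 else "none"
    mode_hi = modes[hi + 1] if hi < len(grid) - 1 else "none"
    return ToleranceRange(
        branch=branch, child=child, f_baseline=f0,
        f_lo=grid[lo], f_hi=grid[hi], mode_lo=mode_lo, mode_hi=mode_hi,
        grid=tuple(grid), stable=tuple(stable),
    )


def regulator_sensitivity(network: NetworkModel, branch: str, child: str,
                          regulators: Sequence[str],
                          delta: float = 0.1,
                          background: PerturbationSpec | None = None,
                          **integrate_kwargs) -> pd.DataFrame:
    """Control coefficients of one branch with respect to regulator states.

    Returns a one-row-per-regulator table (branch, child, regulator,
    coefficient, impact, stable).
    """
    base = find_steady_state(network, background, **integrate_kwargs)
    rows = []
    for reg in regulators:
        rec = concentration_control_coefficient(
            network, branch, child, target=reg, response=reg, delta=delta,
            background=background, base_result=base, **integrate_kwargs)
        rows.append({
            "branch": branch, "child": child, "regulator": reg,
            "coefficient": rec.coefficient, "impact": rec.impact,
            "stable": rec.stable,
        })
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    """Scan results as a tidy table, sorted (branch, child, delta)."""
    rows = [{
        "branch": r.branch, "child": r.child, "f": r.f, "delta": r.delta,
        "target": r.target, "TG": r.target_baseline, "TG_star": r.target_perturbed,
        "coefficient": r.coefficient, "class": r.impact, "stable": r.stable,
        "mode": r.mode,
    } for r in records]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["branch", "child", "delta"]).reset_index(drop=True)
    return df
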