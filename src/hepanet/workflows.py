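"""High-level entry points tying the modules into reproducible runs.

These functions are the package's "commands": validate a model file, run a
scenario with exported tables, scan branch points, import Modelica sources
and summarize structure.  Each accepts either a :class:`NetworkModel` or a
path to a definition file, and optionally writes tidy TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    NetworkModel,
    StructureStats,
    ValidationError,
    build_network,
    initialize_state,
    structure_stats,
)
from .dynamics import PerturbationSpec, assemble_rhs
from .model_io import load_model_definition, write_results
from .scenarios import ScenarioReport, ScenarioSpec, run_scenario
from .sensitivity import SensitivityRecord, records_to_frame, scan_branches

__all__ = [
    "ValidationReport",
    "as_network",
    "validate_model",
    "simulate_scenario",
    "run_scan",
    "import_model",
    "model_stats",
]

#: fixed-point acceptance threshold for validation
RESIDUAL_TOL = 1e-10


@dataclass
class ValidationReport:
    ok: bool
    residual: float
    messages: tuple[str, ...]
    stats: StructureStats | None = None

    def __str__(self) -> str:
        lines = [f"valid: {self.ok}", f"baseline residual: {self.residual:.3e}"]
        lines += list(self.messages)
        if self.stats:
            s = self.stats
            lines.append(
                f"{s.n_reactions} reactions, {s.n_metabolites} metabolites, "
                f"{s.n_enzymes} enzymes, {s.n_regulatory_proteins} "
                "regulatory proteins")
        return "\n".join(lines)


def as_network(model: NetworkModel | str | Path) -> NetworkModel:
    if isinstance(model, NetworkModel):
        return model
    return build_network(load_model_definition(model))


def validate_model(model: NetworkModel | str | Path) -> ValidationReport:
    """Structural validation plus the baseline fixed-point residual check."""
    try:
        net = as_network(model)
    except (ValueError, OSError) as exc:  # validation, syntax or I/O failure
        return ValidationReport(False, float("nan"), (str(exc),))
    rhs = assemble_rhs(net)
    residual = float(np.max(np.abs(rhs(0.0, initialize_state(net)))))
    ok = residual < RESIDUAL_TOL
    messages = tuple(net.warnings)
    if not ok:
        messages += (f"baseline residual {residual:.3e} exceeds "
                     f"{RESIDUAL_TOL:.0e}",)
    return ValidationReport(ok, residual, messages, structure_stats(net))


def simulate_scenario(model: NetworkModel | str | Path, spec: ScenarioSpec,
                      outdir: str | Path | None = None,
                      margin: float = 0.05,
                      **integrate_kwargs) -> ScenarioReport:
    """Run a scenario; optionally export trajectory and fold-change TSVs."""
    net = as_network(model)
    report = run_scenario(net, spec, margin=margin, **integrate_kwargs)
    if outdir is not None:
        tables: dict[str, pd.DataFrame] = {
            f"{spec.name}_verdicts": report.verdicts}
        for i, (traj, res) in enumerate(
                zip(report.trajectories, report.phase_results)):
            folds = pd.DataFrame({
                "variable": net.index.labels,
                "baseline": initialize_state(net),
                "value": res.state,
            })
            folds["fold"] = folds["value"] / folds["baseline"]
            folds["direction"] = np.where(
                folds["fold"] > 1 + margin, "up",
                np.where(folds["fold"] < 1 - margin, "down", "unchanged"))
            tables[f"{spec.name}_phase{i}_folds"] = folds
            tables[f"{spec.name}_phase{i}_trajectory"] = traj.to_frame()
        write_results(tables, outdir)
    return report


def run_scan(model: NetworkModel | str | Path, target: str,
             deltas=(-0.1, 0.1),
             background: PerturbationSpec | None = None,
             outdir: str | Path | None = None,
             branches=None,
             **integrate_kwargs) -> tuple[list[SensitivityRecord], pd.DataFrame]:
    """Branch-point sensitivity scan with a per-impact-class summary."""
    net = as_network(model)
    records = scan_branches(net, target, deltas=deltas, background=background,
                            branches=branches, **integrate_kwargs)
    table = records_to_frame(records)
    summary = (table.groupby("class", as_index=False)
               .agg(n=("coefficient", "size"),
                    max_abs_coefficient=("coefficient",
                                         lambda c: float(np.nanmax(np.abs(c))
                                                         if len(c) else np.nan)))
               .sort_values("class").reset_index(drop=True))
    if outdir is not None:
        write_results({"scan": table, "scan_summary": summary}, outdir)
    return records, table


def import_model(model_path: str | Path, library_path: str | Path):
    """Import restricted Modelica sources; returns (network, report)."""
    from .model_io import import_modelica_subset

    definition, report = import_modelica_subset(
        Path(model_path).read_text(encoding="utf-8"),
        Path(library_path).read_text(encoding="utf-8"))
    return build_network(definition), report


def model_stats(model: NetworkModel | str | Path) -> StructureStats:
    return structure_stats(as_network(model))
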