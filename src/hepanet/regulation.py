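"""Rate laws for transcriptional and post-translational regulation.

Transcription is a bounded, monotone (sigmoid-class) function of each
regulator level, normalized so that every regulation node contributes zero
net rate when all drivers sit at their baseline of 1 -- adding regulation to
a network never moves the global all-ones fixed point.

Repression uses a hyperbolic law::

    g_neg(q) = Q_max / (1 + (Q_max - 1) q)

with g_neg(1) = 1 exactly, g_neg(0) = Q_max and a lower asymptote of 0.
Activation uses a saturating ramp that reaches the maximal fold-change
Q_max exactly at the regulator level ``qc_hat``::

    g_pos(q) = clip(1 + (Q_max - 1) (q - 1) / (qc_hat - 1), 0, Q_max)

Both laws are the package's own reconstruction of the sigmoidal control
published for this formalism; the test suite pins down the contract
(baseline neutrality, bounds, monotonicity, saturation at qc_hat) rather
than one algebraic form.
"""

from __future__ import annotations

from typing import Iterable

from .core import GeneNode, ProteinNode, SwitchNode

__all__ = [
    "repression_factor",
    "activation_factor",
    "transcription_production",
    "transcription_rate",
    "translation_rate",
    "switch_rates",
]


def repression_factor(q: float, q_max: float) -> float:
    """Fold-change multiplier for a negative regulator at level ``q``."""
    if q < 0:
        raise ValueError("regulator level must be >= 0")
    return q_max / (1.0 + (q_max - 1.0) * q)


def activation_factor(q: float, q_max: float, qc_hat: float) -> float:
    """Fold-change multiplier for a positive regulator at level ``q``."""
    if q < 0:
        raise ValueError("regulator level must be >= 0")
    g = 1.0 + (q_max - 1.0) * (q - 1.0) / (qc_hat - 1.0)
    return min(max(g, 0.0), q_max)


def transcription_production(node: GeneNode, regulator_levels: Iterable[float]
                             ) -> float:
    """Production term of the mRNA balance (rate of synthesis).

    Independent regulators combine multiplicatively; the combined fold-change
    is capped at ``q_max`` so the steady-state mRNA level stays within
    [0, q_max] for any constant regulator levels.  The transcription flux is
    ``k_d`` so that production equals degradation at baseline.
    """
    g = 1.0
    for (ref, sign), q in zip(node.regulators, regulator_levels):
        if sign > 0:
            g *= activation_factor(q, node.q_max, node.qc_hat)
        else:
            g *= repression_factor(q, node.q_max)
    g = min(g, node.q_max)
    return node.k_d * g


def transcription_rate(node: GeneNode, q_mrna: float,
                       regulator_levels: Iterable[float]) -> float:
    """Net rate of the mRNA pool: sigmoidal production minus degradation."""
    return transcription_production(node, regulator_levels) - node.k_d * q_mrna


def translation_rate(node: ProteinNode, q_p: float, q_mrna: float,
                     deg_mult: float = 1.0) -> float:
    """Linear translation: ``k_t Q_mRNA - k_d Q_P`` with ``k_t = k_d``.

    Equal constants make the baseline (both pools at 1) an exact fixed point;
    at a clamped mRNA level m the protein settles at m / deg_mult.
    """
    return node.k_d * q_mrna - node.k_d * deg_mult * q_p


def switch_rates(node: SwitchNode, q_active: float, q_inactive: float,
                 act_level: float = 1.0, inact_level: float = 1.0,
                 synth_level: float = 1.0, deg_mult: float = 1.0
                 ) -> tuple[float, float]:
    """Rates of the (active, inactive) pools of a regulatory switch.

    Mass moves from inactive to active at ``k_a * D_act * Q_CI`` and back at
    ``k_i * D_inact * Q_CA``; both pools degrade at ``k_d`` and the inactive
    pool receives synthesis ``2 k_d * synth_level``.  With ``k_a = k_i + k_d``
    the all-ones partition is an exact fixed point.  Switching conserves the
    transferred mass: total protein is governed by synthesis and degradation
    only.
    """
    k_a = node.k_a
    transfer = k_a * act_level * q_inactive - node.k_i * inact_level * q_active
    d_active = transfer - node.k_d * deg_mult * q_active
    d_inactive = (2.0 * node.k_d * synth_level - transfer
                  - node.k_d * deg_mult * q_inactive)
    return d_active, d_inactive
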