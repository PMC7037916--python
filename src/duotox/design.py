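"""Derivative-screening arithmetic: change rates and log-level toxicity ratios.

Two change-rate conventions exist because the source tables report a positive
"increase" for quantities that grow more negative (DFT total energy, docking
binding energy): the signed convention is 100*(d - p)/|p| and the magnitude
convention is 100*(|d| - |p|)/|p|.  The convention is auto-selected per
metric by :data:`METRIC_CONVENTIONS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import UsageError

SIGNED = "signed"
MAGNITUDE = "magnitude"

#: which convention reproduces the published per-metric change rates
METRIC_CONVENTIONS = {
    "composite": SIGNED,
    "frequency": SIGNED,
    "total_energy": MAGNITUDE,
    "log_kow": SIGNED,
    "t_half_river": SIGNED,
    "dock_total_score": SIGNED,
    "dock_binding_energy": MAGNITUDE,
}


def change_rate(parent: float, derivative: float, convention: str = SIGNED) -> float:
    """Percent change of ``derivative`` relative to ``parent``."""
    if parent == 0:
        raise UsageError("change rate undefined for a zero parent value")
    if convention == SIGNED:
        return 100.0 * (derivative - parent) / abs(parent)
    if convention == MAGNITUDE:
        return 100.0 * (abs(derivative) - abs(parent)) / abs(parent)
    raise UsageError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class ToxicityChange:
    """Change of both raw toxicities and their log-level ratio.

    ``ec50_change_pct`` and ``loec_change_pct`` are the percent decreases of
    the raw effective concentrations (a decrease means higher toxicity).
    ``rel_dp_ec50``/``rel_dp_loec`` are the relative changes of the log-level
    values pEC50 = log10(EC50) and pLOEC = -log10(LOEC), each taken as
    |delta p| / p_parent; ``ratio`` divides the former by the latter.  The
    ratio is None when the genotoxicity log-level change is zero.
    """

    ec50_change_pct: float
    loec_change_pct: float
    rel_dp_ec50: float
    rel_dp_loec: float
    ratio: float | None


def toxicity_log_ratio(
    parent: tuple[float, float], derivative: tuple[float, float]
) -> ToxicityChange:
    """Log-level toxicity-change arithmetic from raw (EC50, LOEC) pairs.

    Note the denominators of the relative log-level changes are the parent's
    log values, so the ratio is *not* invariant to re-expressing the raw
    concentrations in other units; the formula is documented as-is.
    """
    p_ec, p_lo = parent
    d_ec, d_lo = derivative
    if min(p_ec, p_lo, d_ec, d_lo) <= 0:
        raise UsageError("EC50 and LOEC values must be strictly positive")
    p_pec, d_pec = math.log10(p_ec), math.log10(d_ec)
    p_plo, d_plo = -math.log10(p_lo), -math.log10(d_lo)
    rel_ec = abs(d_pec - p_pec) / p_pec
    rel_lo = abs(d_plo - p_plo) / p_plo
    ratio = rel_ec / rel_lo if rel_lo != 0 else None
    return ToxicityChange(
        ec50_change_pct=100.0 * (p_ec - d_ec) / p_ec,
        loec_change_pct=100.0 * (p_lo - d_lo) / p_lo,
        rel_dp_ec50=rel_ec,
        rel_dp_loec=rel_lo,
        ratio=ratio,
    )


@dataclass
class ModificationReport:
    """Change-rate record for one candidate derivative and one metric."""

    parent_id: str
    derivative_id: str
    metric_name: str
    parent_value: float
    derivative_value: float
    change_rate_pct: float
    convention: str
    improved: bool | None = None
    extra: dict | None = None


def property_change_report(
    parent_id: str,
    derivative_id: str,
    metric_name: str,
    parent_value: float,
    derivative_value: float,
    convention: str | None = None,
) -> ModificationReport:
    """Change-rate report with the metric's documented convention."""
    if convention is None:
        convention = METRIC_CONVENTIONS.get(metric_name, SIGNED)
    rate = change_rate(parent_value, derivative_value, convention)
    return ModificationReport(
        parent_id=parent_id,
        derivative_id=derivative_id,
        metric_name=metric_name,
        parent_value=parent_value,
        derivative_value=derivative_value,
        change_rate_pct=rate,
        convention=convention,
    )


def screen_derivatives(
    parent_id: str,
    parent_composite: float,
    candidates: Sequence[tuple[str, float]],
) -> list[ModificationReport]:
    """Rank candidate derivatives by composite change rate, descending.

    Candidates whose composite does not increase are kept in the ranking but
    marked ``improved=False`` (rejected).
    """
    if parent_composite == 0:
        raise UsageError("parent composite must be nonzero to compute change rates")
    reports = []
    for cand_id, composite in candidates:
        rate = change_rate(parent_composite, composite, SIGNED)
        reports.append(
            ModificationReport(
                parent_id=parent_id,
                derivative_id=cand_id,
                metric_name="composite",
                parent_value=parent_composite,
                derivative_value=composite,
                change_rate_pct=rate,
                convention=SIGNED,
                improved=rate > 0,
            )
        )
    reports.sort(key=lambda r: r.change_rate_pct, reverse=True)
    return reports
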