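"""AND/OR fusion of the two binary heads into three risk levels.

Both-negative -> no risk (NOR); both-positive -> high risk (AND); exactly
one positive -> low risk.  Raising either head's probability can never
lower the fused level (monotonicity).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .focal import DecisionRule, decide


class RiskLevel(str, Enum):
    NO_RISK = "no_risk"
    LOW_RISK = "low_risk"
    HIGH_RISK = "high_risk"


_ORDER = {RiskLevel.NO_RISK: 0, RiskLevel.LOW_RISK: 1, RiskLevel.HIGH_RISK: 2}


def fuse(physio_pred: int, factor_pred: int) -> RiskLevel:
    """Combine the physiological-head and factor-head decisions."""
    if physio_pred not in (0, 1) or factor_pred not in (0, 1):
        raise ValueError("head outputs must be binary 0/1")
    if physio_pred and factor_pred:
        return RiskLevel.HIGH_RISK
    if physio_pred or factor_pred:
        return RiskLevel.LOW_RISK
    return RiskLevel.NO_RISK


def fuse_batch(
    physio_probs,
    factor_probs,
    rule: DecisionRule | None = None,
    factor_rule: DecisionRule | None = None,
) -> tuple[list[RiskLevel], pd.DataFrame]:
    """Vectorised fusion with a per-subject audit table.

    Both heads share ``rule`` unless ``factor_rule`` overrides the second
    head's threshold.  Returns (levels, audit DataFrame with columns
    physio_prob, factor_prob, physio_decision, factor_decision, risk_level).
    """
    rule = rule if rule is not None else DecisionRule()
    factor_rule = factor_rule if factor_rule is not None else rule
    p1 = np.asarray(physio_probs, dtype=float)
    p2 = np.asarray(factor_probs, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("head probability vectors must have equal length")
    d1 = decide(p1, rule)
    d2 = decide(p2, factor_rule)
    d1 = np.atleast_1d(d1)
    d2 = np.atleast_1d(d2)
    levels = [fuse(int(a), int(b)) for a, b in zip(d1, d2)]
    audit = pd.DataFrame(
        {
            "physio_prob": np.atleast_1d(p1),
            "factor_prob": np.atleast_1d(p2),
            "physio_decision": d1,
            "factor_decision": d2,
            "risk_level": [lv.value for lv in levels],
        }
    )
    return levels, audit


def risk_rank(level: RiskLevel) -> int:
    """Ordinal position of a level (no < low < high)."""
    return _ORDER[level]
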