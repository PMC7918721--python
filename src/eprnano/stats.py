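"""Condition comparison of condensed domain groups.

Replicate experiments (independent spectra, each fitted and condensed
separately) yield per-replicate GHOST groups. This module matches domains
across conditions by their order-parameter rank, expresses each
parameter's difference as a relative change against the control, and
tests it with a two-sample Student's t-test on the replicate values
(Welch's correction available as a flag; no multiple-testing correction
by default, each parameter is tested at alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ghost import GhostGroup
from .spin_model import ValidationError

__all__ = ["ConditionResult", "DomainMismatchError", "match_domains",
           "relative_change", "compare_conditions", "COMPARED_PARAMS"]

COMPARED_PARAMS = ("S", "tau_c", "pA", "d")


class DomainMismatchError(ValueError):
    """Conditions resolved different numbers of domain groups."""


@dataclass
class ConditionResult:
    """GHOST groups of one replicate measurement of one condition."""

    condition: str
    replicate: int
    groups: list[GhostGroup] = dc_field(default_factory=list)

    def ordered_groups(self) -> list[GhostGroup]:
        return sorted(self.groups, key=lambda g: -g.mean["S"])


def match_domains(groups_a: list[GhostGroup],
                  groups_b: list[GhostGroup]) -> list[tuple[GhostGroup, GhostGroup]]:
    """Pair domain groups across two conditions by descending-S rank.

    Raises :class:`DomainMismatchError` (listing the group order
    parameters) when the group counts differ.
    """
    if len(groups_a) != len(groups_b):
        sa = [round(g.mean["S"], 3) for g in groups_a]
        sb = [round(g.mean["S"], 3) for g in groups_b]
        raise DomainMismatchError(
            f"cannot match {len(groups_a)} groups (S={sa}) "
            f"with {len(groups_b)} groups (S={sb})")
    a = sorted(groups_a, key=lambda g: -g.mean["S"])
    b = sorted(groups_b, key=lambda g: -g.mean["S"])
    return list(zip(a, b))


def relative_change(values_condition: np.ndarray,
                    values_control: np.ndarray) -> tuple[float, float]:
    """Relative change of replicate means, (cond - ctrl) / ctrl, with SE.

    The standard error propagates the two replicate-level standard errors
    of the mean to first order:
    SE^2 = (SE_c / m_k)^2 + (m_c * SE_k / m_k^2)^2.
    """
    vc = np.asarray(values_condition, dtype=float)
    vk = np.asarray(values_control, dtype=float)
    if vc.size < 1 or vk.size < 1:
        raise ValidationError("need at least one replicate per condition")
    m_c, m_k = vc.mean(), vk.mean()
    if m_k == 0:
        raise ValidationError("control mean is zero; relative change undefined")
    change = (m_c - m_k) / m_k
    se_c = vc.std(ddof=1) / np.sqrt(vc.size) if vc.size > 1 else 0.0
    se_k = vk.std(ddof=1) / np.sqrt(vk.size) if vk.size > 1 else 0.0
    se = float(np.sqrt((se_c / m_k) ** 2 + (m_c * se_k / m_k ** 2) ** 2))
    return float(change), se


def _replicate_values(replicates: list[ConditionResult], rank: int,
                      param: str) -> np.ndarray:
    out = []
    for rep in replicates:
        g = rep.ordered_groups()[rank]
        out.append(g.mean["d"] if param == "d" else g.mean[param])
    return np.array(out)


def compare_conditions(replicates_cond: list[ConditionResult],
                       replicates_ctrl: list[ConditionResult],
                       alpha: float = 0.05,
                       welch: bool = False,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Per-domain, per-parameter comparison table of two conditions.

    Every replicate must carry the same number of domain groups (the
    condition's and control's first replicates are matched to verify
    this). The table holds, for each (domain, parameter in S/tau_c/pA/d):
    the relative change of the condition vs. the control, its propagated
    SE, the two-sided two-sample t statistic and p value on replicate
    values, and a significance flag at ``alpha``. With fewer than two
    replicates on either side the tests are flagged not computable
    (NaN statistics, significant=False).
    """
    if not replicates_cond or not replicates_ctrl:
        raise ValidationError("need at least one replicate per condition")
    counts = {len(r.groups) for r in replicates_cond + replicates_ctrl}
    if len(counts) != 1:
        raise DomainMismatchError(
            f"replicates disagree on group count: {sorted(counts)}")
    match_domains(replicates_cond[0].groups, replicates_ctrl[0].groups)
    n_domains = counts.pop()
    n_tests = n_domains * len(COMPARED_PARAMS)
    testable = len(replicates_cond) >= 2 and len(replicates_ctrl) >= 2
    rows = []
    for rank in range(n_domains):
        for param in COMPARED_PARAMS:
            vc = _replicate_values(replicates_cond, rank, param)
            vk = _replicate_values(replicates_ctrl, rank, param)
            change, se = relative_change(vc, vk)
            if testable:
                t, p = sps.ttest_ind(vc, vk, equal_var=not welch)
                p_eff = min(p * n_tests, 1.0) if bonferroni else p
                sig = bool(p_eff < alpha)
            else:
                t, p_eff, sig = float("nan"), float("nan"), False
            rows.append({"domain": rank + 1, "parameter": param,
                         "relative_change": change, "se": se,
                         "t_statistic": float(t), "p_value": float(p_eff),
                         "significant": sig,
                         "tests_computable": testable})
    return pd.DataFrame(rows)
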