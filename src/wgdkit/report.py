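"""Cohort-level summaries and the statistical tests used to compare them.

Groups of lines (crosses, ploidy classes) are compared with
distribution-free tests: a Kruskal-Wallis omnibus across groups, with
pairwise two-sided Mann-Whitney-Wilcoxon tests reported alongside
regardless of the omnibus outcome, and a two-sided paired t-test for
before/after designs (spore viability or growth rate around a WGD).
No multiple-testing correction is applied; pairwise p-values are raw.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FertilityRecord",
    "GroupComparison",
    "spore_viability",
    "compare_groups",
    "build_report",
    "write_report_json",
    "read_report_json",
]

#: below this per-group size Mann-Whitney uses exact enumeration
EXACT_TEST_MAX_N = 50


@dataclass
class FertilityRecord:
    """Spore-viability observation for one line at one stage."""

    line_id: str
    stage: str  # "diploid_before_wgd" | "tetraploid_after_wgd"
    spores_dissected: int
    colonies: int

    def __post_init__(self) -> None:
        if not (0 <= self.colonies <= self.spores_dissected):
            raise ValueError("colonies must be between 0 and spores_dissected")

    @property
    def viability(self) -> float:
        return self.colonies / self.spores_dissected


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    omnibus_statistic: float | None = None
    omnibus_p: float | None = None
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    paired_statistic: float | None = None
    paired_p: float | None = None
    note: str = ""


def spore_viability(
    records: list[FertilityRecord],
) -> tuple[pd.DataFrame, GroupComparison]:
    """Per-line spore viability and a paired before/after-WGD comparison.

    Viability is colonies / spores dissected. Lines with both a
    diploid-before and tetraploid-after record enter a two-sided paired
    t-test; unpaired lines are excluded from the test with a warning
    (they remain in the viability table).
    """
    table = pd.DataFrame(
        [
            {
                "line_id": r.line_id,
                "stage": r.stage,
                "spores_dissected": r.spores_dissected,
                "colonies": r.colonies,
                "viability": r.viability,
            }
            for r in records
        ]
    )
    before = {r.line_id: r.viability for r in records if r.stage == "diploid_before_wgd"}
    after = {r.line_id: r.viability for r in records if r.stage == "tetraploid_after_wgd"}
    paired_ids = sorted(set(before) & set(after))
    unpaired = (set(before) | set(after)) - set(paired_ids)
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} line(s) lack a before/after pair and are "
            "excluded from the paired test"
        )
    b = np.array([before[i] for i in paired_ids])
    a = np.array([after[i] for i in paired_ids])
    comparison = GroupComparison(groups={"before": b, "after": a})
    if paired_ids:
        deltas = a - b
        if np.allclose(deltas, 0):
            comparison.note = "no-change: all paired differences are zero"
        elif len(paired_ids) < 2:
            comparison.note = "insufficient pairs for a paired t-test"
        else:
            t, p = stats.ttest_rel(a, b)
            comparison.paired_statistic = float(t)
            comparison.paired_p = float(p)
    return table, comparison


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    method = (
        "exact" if max(len(x), len(y)) <= EXACT_TEST_MAX_N else "asymptotic"
    )
    try:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        )
    except ValueError:
        # exact method refuses ties in some versions: midranks + normal approx
        return float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
        )


def compare_groups(
    values_by_group: dict[str, np.ndarray], design: str = "independent"
) -> GroupComparison:
    """Rank-based comparison of labelled value sets.

    design="independent": Kruskal-Wallis omnibus over all groups plus
    two-sided Mann-Whitney-Wilcoxon p-values for every pair (exact
    enumeration for small samples, midranks/normal approximation above
    ``EXACT_TEST_MAX_N`` per group).

    design="paired": two-sided paired t-test over exactly two
    equal-length groups; all-zero differences are reported as a
    "no-change" note rather than a p-value.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    comparison = GroupComparison(groups=groups)
    if design == "independent":
        if len(groups) < 2:
            raise ValueError("independent design needs at least 2 groups")
        h, p = stats.kruskal(*groups.values())
        comparison.omnibus_statistic = float(h)
        comparison.omnibus_p = float(p)
        for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
            comparison.pairwise[(na, nb)] = _mannwhitney_p(va, vb)
    elif design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design needs exactly 2 groups")
        (na, va), (nb, vb) = groups.items()
        if va.size != vb.size:
            raise ValueError("paired groups must have equal length")
        deltas = vb - va
        if np.allclose(deltas, 0):
            comparison.note = "no-change: all paired differences are zero"
        else:
            t, p = stats.ttest_rel(vb, va)
            comparison.paired_statistic = float(t)
            comparison.paired_p = float(p)
    else:
        raise ValueError(f"unknown design {design!r}")
    return comparison


_REPORT_SECTIONS = (
    "wgd",
    "aneuploidy",
    "loh",
    "fitness",
    "fertility",
)


def build_report(
    wgd: dict | None = None,
    aneuploidy: dict | None = None,
    loh: dict | None = None,
    fitness: dict | None = None,
    fertility: dict | None = None,
) -> dict:
    """Assemble per-cross summary tables into one machine-readable report.

    Each section is a dict of plain values / lists / records produced by
    the corresponding module (e.g. ``wgd`` holds per-cross rates and the
    cumulative tetraploid curve). Missing sections are recorded under
    ``gaps`` and the report stays schema-valid.
    """
    supplied = {
        "wgd": wgd,
        "aneuploidy": aneuploidy,
        "loh": loh,
        "fitness": fitness,
        "fertility": fertility,
    }
    report: dict = {"sections": {}, "gaps": []}
    for name in _REPORT_SECTIONS:
        value = supplied[name]
        if value is None:
            report["gaps"].append(name)
        else:
            report["sections"][name] = value
    return report


def write_report_json(report: dict, path) -> None:
    """Write a report deterministically (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, separators=(",", ": "))
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
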