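"""Summary statistics and hypothesis-testing conventions for condition comparisons.

Follows the reporting conventions of the emulated study: values are
mean +/- SEM over cells, with the number of animals (n) and cells (c)
carried alongside; groups are screened with the D'Agostino-Pearson omnibus
normality test and compared with Student's t (paired or unpaired) or a
one-way ANOVA; p-values map to the usual star code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    mean: float
    sem: float
    n_animals: int | None = None
    n_cells: int | None = None


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p: float
    stars: str
    normality_p: tuple[float | None, ...] = ()
    non_normal: bool = False
    flags: tuple[str, ...] = ()


def summarize(
    values,
    animal_ids=None,
    cell_ids=None,
) -> GroupSummary:
    """Mean and SEM of per-cell values, with the n/c bookkeeping.

    ``sem`` is the sample SD over the supplied values divided by the square
    root of their count (cells are the summarised unit).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("summarize needs >= 2 values")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size))
    n_animals = len(set(animal_ids)) if animal_ids is not None else None
    n_cells = len(set(cell_ids)) if cell_ids is not None else values.size
    return GroupSummary(mean=mean, sem=sem, n_animals=n_animals, n_cells=n_cells)


def star_code(p: float) -> str:
    """Map a p-value to the asterisk convention (strict inequalities)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


_MIN_NORMALITY_N = 8  # omnibus test needs at least 8 observations


def compare(*groups, paired: bool = False) -> TestResult:
    """Compare 2+ groups of per-cell values.

    Two groups: Student's t-test (two-sided; ``paired`` selects the paired
    form and requires equal lengths).  More than two: one-way ANOVA.  Each
    group is screened with the D'Agostino-Pearson omnibus test; failures at
    0.05 set ``non_normal`` but the parametric test is still run (matching
    the emulated study's practice).  Groups too small for the omnibus test
    skip normality screening with a flag.

    A paired contrast of identical groups (all-zero differences) reports
    p = 1 with a ``zero_differences`` flag instead of NaN.
    """
    if len(groups) < 2:
        raise ValueError("compare needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 3 for a in arrays):
        raise ValueError("each group needs >= 3 values")

    flags: list[str] = []
    norm_p: list[float | None] = []
    non_normal = False
    for a in arrays:
        if a.size < _MIN_NORMALITY_N:
            norm_p.append(None)
            if "normality_skipped" not in flags:
                flags.append("normality_skipped")
            continue
        p = float(sps.normaltest(a).pvalue)
        norm_p.append(p)
        if p < 0.05:
            non_normal = True

    if len(arrays) > 2:
        if paired:
            raise ValueError("paired comparison is defined for exactly 2 groups")
        stat, p = sps.f_oneway(*arrays)
        name = "one-way ANOVA"
    elif paired:
        a, b = arrays
        if a.size != b.size:
            raise ValueError("paired groups must have equal lengths")
        diffs = a - b
        if np.allclose(diffs, 0.0):
            stat, p = 0.0, 1.0
            flags.append("zero_differences")
        else:
            stat, p = sps.ttest_rel(a, b)
        name = "paired t-test"
    else:
        stat, p = sps.ttest_ind(*arrays)
        name = "t-test"

    p = float(np.nan_to_num(p, nan=1.0))
    return TestResult(
        test_name=name,
        statistic=float(stat),
        p=p,
        stars=star_code(p),
        normality_p=tuple(norm_p),
        non_normal=non_normal,
        flags=tuple(flags),
    )
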