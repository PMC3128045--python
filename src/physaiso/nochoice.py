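"""Analysis of no-choice crossing experiments.

Each experiment pairs ten juveniles between two populations (the outcross
set) alongside two sets of ten within-population control pairs.  Pairs are
inspected weekly: embryos are counted as fecundity, hatchlings of each egg
cohort are counted as viability (attributed to the oviposition week of their
cohort), and observation of a pair stops at the first parental death.

In a hermaphrodite every paired snail can also self-fertilize, so apparent
reproduction never proves hybridization; this module only quantifies the
demography (onset of reproduction, fecundity, F1 viability, F1 x F1
fertility).  Classifying progeny as selfed or outcrossed is the job of
:mod:`physaiso.hybridity`.

Timing convention: weeks are 1-based calendar indices.  "Week 1" of the
fecundity/viability window is anchored separately for each set of ten pairs
as the first calendar week in which three or more pairs oviposit, and the
analysis window runs ten weeks from that anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CROSS_TYPES",
    "NoChoicePairRecord",
    "ExperimentSet",
    "F2CrossRecord",
    "F2Summary",
    "DepressionTest",
    "anchor_week_one",
    "first_oviposition_ages",
    "first_reproduction_test",
    "delay_test",
    "pair_mean_fecundity",
    "pair_f1_viability",
    "depressed_outcross_test",
    "f2_fertility_summary",
]

CROSS_TYPES = ("outcross", "control_a", "control_b")


@dataclass(frozen=True)
class NoChoicePairRecord:
    """Weekly observations for one parental pair.

    ``embryos[w]`` and ``hatchlings[w]`` are the counts for calendar week
    ``w + 1``; hatchlings are attributed to the oviposition week of their
    cohort, so ``hatchlings[w] <= embryos[w]``.  ``alive[w]`` is True while
    both parents were alive through that week; weeks after the first death
    are censored (postmortem zeros are never data).
    """

    pair_id: str
    cross: str
    embryos: tuple
    hatchlings: tuple
    alive: tuple

    def __post_init__(self) -> None:
        if not (len(self.embryos) == len(self.hatchlings) == len(self.alive)):
            raise ValueError("weekly series must have equal length")
        dead = False
        for w, (e, h, a) in enumerate(zip(self.embryos, self.hatchlings, self.alive)):
            if e < 0 or h < 0:
                raise ValueError(f"negative count in week {w + 1}")
            if h > e:
                raise ValueError(
                    f"week {w + 1}: cohort hatchlings ({h}) exceed embryos ({e})"
                )
            if dead and a:
                raise ValueError("parents cannot come back to life")
            if dead and e > 0:
                raise ValueError(f"week {w + 1}: oviposition after parental death")
            dead = dead or not a
        object.__setattr__(self, "embryos", tuple(int(e) for e in self.embryos))
        object.__setattr__(self, "hatchlings", tuple(int(h) for h in self.hatchlings))
        object.__setattr__(self, "alive", tuple(bool(a) for a in self.alive))

    @property
    def weeks(self) -> int:
        return len(self.embryos)

    @property
    def first_oviposition_week(self) -> Optional[int]:
        """1-based calendar week of first oviposition, None if never."""
        for w, e in enumerate(self.embryos):
            if e > 0:
                return w + 1
        return None

    @property
    def last_alive_week(self) -> int:
        """Last 1-based week with both parents alive (0 = dead before week 1)."""
        last = 0
        for w, a in enumerate(self.alive):
            if a:
                last = w + 1
            else:
                break
        return last


@dataclass
class ExperimentSet:
    """One no-choice experiment: outcross pairs plus the two incross controls."""

    label: str
    outcross: list
    control_a: list
    control_b: list

    def records(self, cross: str) -> list:
        if cross not in CROSS_TYPES:
            raise ValueError(f"unknown cross type {cross!r}")
        return getattr(self, cross)


@dataclass(frozen=True)
class F2CrossRecord:
    """Outcome of one F1 x F1 cross in the early/middle/late time series."""

    pair_id: str
    series: str
    oviposited: bool
    viable_f2: bool

    def __post_init__(self) -> None:
        if self.viable_f2 and not self.oviposited:
            raise ValueError("viable F2 implies oviposition")


@dataclass(frozen=True)
class F2Summary:
    n_records: int
    n_ovipositing: int
    n_with_viable_f2: int
    sterile: bool
    complete: bool


@dataclass(frozen=True)
class DepressionTest:
    """One-sided comparison of outcross values against both controls.

    ``p_vs_a`` / ``p_vs_b`` are exact one-sided Mann-Whitney p-values for
    "outcross < control", already Bonferroni-doubled for the two control
    comparisons; ``kruskal_p`` is the 3-group omnibus for reference.  The
    outcross set is called depressed only when significant against *both*
    controls.
    """

    p_vs_a: float
    p_vs_b: float
    kruskal_p: float
    n_dropped: int

    def depressed(self, alpha: float = 0.05) -> bool:
        return self.p_vs_a < alpha and self.p_vs_b < alpha


def anchor_week_one(records: Sequence[NoChoicePairRecord], min_pairs: int = 3):
    """First calendar week in which >= ``min_pairs`` pairs oviposit.

    Returns the 1-based week index, or None when the threshold is never
    reached ("no anchor"; the set is then excluded from fecundity and
    viability testing).
    """
    if not records:
        return None
    horizon = max(r.weeks for r in records)
    for week in range(1, horizon + 1):
        n = sum(1 for r in records if week <= r.weeks and r.embryos[week - 1] > 0)
        if n >= min_pairs:
            return week
    return None


def first_oviposition_ages(records: Sequence[NoChoicePairRecord]) -> np.ndarray:
    """Week of first oviposition per pair; +inf for pairs that never laid.

    Infinity keeps non-reproducing pairs above any finite median, the most
    conservative reading of a delayed-reproduction test.
    """
    return np.array(
        [
            r.first_oviposition_week if r.first_oviposition_week is not None else np.inf
            for r in records
        ],
        dtype=float,
    )


def first_reproduction_test(exp_ages, ctrl_ages) -> float:
    """Median-split Fisher exact test for delayed first reproduction.

    Pools the two groups, takes the combined median, excludes ties at the
    median, and tests one-tailed whether experimental pairs fall above the
    median (reproduce later) more often than control pairs.
    """
    exp = np.asarray(exp_ages, dtype=float)
    ctrl = np.asarray(ctrl_ages, dtype=float)
    combined = np.concatenate([exp, ctrl])
    finite = combined[np.isfinite(combined)]
    if finite.size == 0:
        return 1.0  # nobody reproduced in either group
    # Non-reproducers rank above every finite age; cap them one week past the
    # latest observed onset so the median stays finite and splits the sample.
    cap = finite.max() + 1.0
    exp = np.minimum(exp, cap)
    ctrl = np.minimum(ctrl, cap)
    med = np.median(np.concatenate([exp, ctrl]))
    table = np.array(
        [
            [np.count_nonzero(exp > med), np.count_nonzero(exp < med)],
            [np.count_nonzero(ctrl > med), np.count_nonzero(ctrl < med)],
        ]
    )
    if table.sum() == 0:  # everything tied at the median
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])


def delay_test(
    exp_ages,
    ctrl_a_ages,
    ctrl_b_ages,
    conditioning: str = "slower",
):
    """Delay of outcross reproduction behind the *slower* control.

    Evidence of prezygotic-plus-early-postzygotic trouble requires the
    outcross pairs to lag behind the slower (later-median) of the two control
    sets.  ``conditioning="both"`` instead tests against each control and
    returns the larger (least favourable) p-value.
    """
    exp = np.asarray(exp_ages, dtype=float)
    a = np.asarray(ctrl_a_ages, dtype=float)
    b = np.asarray(ctrl_b_ages, dtype=float)
    if conditioning == "slower":
        slower = a if np.median(a) >= np.median(b) else b
        return first_reproduction_test(exp, slower)
    if conditioning == "both":
        return max(first_reproduction_test(exp, a), first_reproduction_test(exp, b))
    raise ValueError("conditioning must be 'slower' or 'both'")


def _window_end(record: NoChoicePairRecord, anchor: int, window: int) -> int:
    return min(anchor + window - 1, record.last_alive_week, record.weeks)


def pair_mean_fecundity(
    record: NoChoicePairRecord, anchor: int, window: int = 10
) -> Optional[float]:
    """Mean weekly embryo production of one pair inside the anchored window.

    Leading (pre-first-oviposition) zeros are ignored as immaturity, weeks
    after parental death are censored, interior zero weeks count as true
    reproductive failures, and a pair that survives into the window without
    ever ovipositing scores 0.  Returns None (excluded) for a pair dead
    before the window opens.
    """
    if anchor < 1:
        raise ValueError("anchor week must be >= 1")
    end = _window_end(record, anchor, window)
    if record.last_alive_week < anchor or end < anchor:
        return None  # dead before the window: no exposure
    first = record.first_oviposition_week
    if first is None or first > end:
        return 0.0  # viable, mature, never reproduced in the window
    start = max(anchor, first)
    vals = record.embryos[start - 1 : end]
    return float(np.mean(vals))


def pair_f1_viability(
    record: NoChoicePairRecord, anchor: int, window: int = 10
) -> Optional[float]:
    """Per-pair F1 viability: mean cohort hatchlings over mean cohort embryos.

    Only weeks with embryo production (cohort weeks) enter either mean —
    hatchling zeros in weeks without a cohort carry no information.  With
    cohort-attributed hatchling counts the ratio lies in [0, 1].  Undefined
    (None) for a pair with no embryo production in the window.
    """
    end = _window_end(record, anchor, window)
    if record.last_alive_week < anchor or end < anchor:
        return None
    weeks = [w for w in range(anchor, end + 1) if record.embryos[w - 1] > 0]
    if not weeks:
        return None  # zero fecundity: viability undefined
    mean_h = float(np.mean([record.hatchlings[w - 1] for w in weeks]))
    mean_e = float(np.mean([record.embryos[w - 1] for w in weeks]))
    return mean_h / mean_e


def _clean(values) -> tuple:
    kept = [float(v) for v in values if v is not None and np.isfinite(v)]
    return kept, len(list(values)) - len(kept)


def depressed_outcross_test(
    exp_values, ctrl_a_values, ctrl_b_values
) -> DepressionTest:
    """Test whether outcross pair values are depressed below both controls.

    Implemented as two exact one-sided Mann-Whitney tests (the two-group
    special case of a Kruskal-Wallis ANOVA, given a direction), each
    Bonferroni-doubled for the two control comparisons; the 3-group omnibus
    Kruskal-Wallis p accompanies them for reference.  Undefined (None/NaN)
    pair values are dropped and counted.
    """
    exp, d1 = _clean(list(exp_values))
    a, d2 = _clean(list(ctrl_a_values))
    b, d3 = _clean(list(ctrl_b_values))
    for name, grp in (("experiment", exp), ("control_a", a), ("control_b", b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} has fewer than two defined values")

    def one_sided(x, y) -> float:
        try:
            p = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        except ValueError:
            p = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        return min(1.0, 2.0 * float(p))

    pooled = exp + a + b
    if len(set(pooled)) == 1:
        kw = 1.0  # identical samples: no evidence of any group difference
    else:
        kw = float(stats.kruskal(exp, a, b).pvalue)
    return DepressionTest(
        p_vs_a=one_sided(exp, a),
        p_vs_b=one_sided(exp, b),
        kruskal_p=kw,
        n_dropped=d1 + d2 + d3,
    )


def f2_fertility_summary(
    records: Sequence[F2CrossRecord], expected: int = 9
) -> F2Summary:
    """Tally F1 x F1 crosses: how many oviposited, how many left viable F2.

    Nine crosses (three sibships x early/middle/late series) are expected per
    experiment; fewer triggers a completeness warning but tallies are still
    returned.  "Sterile" flags experiments where pairs laid eggs but none
    produced a viable second generation.
    """
    records = list(records)
    if len(records) < expected:
        warnings.warn(
            f"only {len(records)} of {expected} expected F1 x F1 records",
            stacklevel=2,
        )
    n_ovi = sum(1 for r in records if r.oviposited)
    n_f2 = sum(1 for r in records if r.viable_f2)
    return F2Summary(
        n_records=len(records),
        n_ovipositing=n_ovi,
        n_with_viable_f2=n_f2,
        sterile=(n_f2 == 0 and n_ovi >= 1),
        complete=(len(records) >= expected),
    )
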