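"""Sexual-isolation statistics for mate-choice contest data.

A mate-choice trial places equal numbers of adults from two populations in a
common arena and records, for each individual, its first successful copulation
in the male role.  Pooling trials gives a 2x2 table of counts
``n(male population x female population)`` that measures positive-assortative
mating.  This module computes the pair sexual isolation (PSI) coefficients and
the IPSI index of Rolan-Alvarez & Caballero from such tables, attaches a
multinomial-bootstrap significance test, checks heterogeneity across replicate
trials with a margin-fixed Monte-Carlo exact test, and applies Holm's
step-down (sequential Bonferroni) correction across a family of comparisons.

Because every individual acts once as a focal "male" choosing uniformly among
the other ``2n - 1`` snails in the arena, random mating does not give 1:1
homogametic:heterogametic pairings but ``(n-1):n`` — 9:10 in a 10 + 10 trial;
:func:`null_pairing_odds` returns that design constant.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CELLS",
    "PairTable",
    "PsiSet",
    "IsolationResult",
    "MateChoiceTrial",
    "psi_coefficients",
    "ipsi",
    "ipsi_bootstrap_test",
    "heterogeneity_test",
    "pool_trials",
    "sequential_bonferroni",
    "holm_adjusted_p",
    "null_pairing_odds",
    "null_homogametic_fraction",
]

#: Cell order used throughout: male population first, female second.
CELLS = ("aa", "ab", "ba", "bb")


@dataclass(frozen=True)
class PairTable:
    """First-copulation counts for one population pair.

    ``n_xy`` counts recorded copulations with an ``x`` male and a ``y``
    female, where ``a`` and ``b`` refer to ``pop_a`` and ``pop_b``.
    """

    pop_a: str
    pop_b: str
    n_aa: int
    n_ab: int
    n_ba: int
    n_bb: int

    def __post_init__(self) -> None:
        if self.pop_a == self.pop_b:
            raise ValueError("population labels must be distinct")
        for cell in CELLS:
            if getattr(self, f"n_{cell}") < 0:
                raise ValueError(f"count n_{cell} must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        """2x2 array of counts, rows = male population, columns = female."""
        return np.array(
            [[self.n_aa, self.n_ab], [self.n_ba, self.n_bb]], dtype=float
        )

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_ba + self.n_bb

    def swapped(self) -> "PairTable":
        """The same observations with the two population labels exchanged."""
        return PairTable(
            self.pop_b, self.pop_a, self.n_bb, self.n_ba, self.n_ab, self.n_aa
        )


@dataclass(frozen=True)
class PsiSet:
    """PSI coefficients (observed / expected pair frequency) for one table.

    A coefficient is NaN where its expected count is zero (an empty row or
    column marginal); such coefficients are *undefined*, not zero.
    """

    psi: dict
    expected: dict

    @property
    def undefined_cells(self) -> tuple:
        return tuple(c for c in CELLS if not np.isfinite(self.psi[c]))

    @property
    def all_defined(self) -> bool:
        return not self.undefined_cells


@dataclass(frozen=True)
class IsolationResult:
    """Bootstrap test of IPSI against the no-isolation null."""

    ipsi: float
    se_boot: float
    t_stat: float
    p_one_tailed: float
    n_boot: int
    n_dropped: int
    seed: int
    reference: str = "normal"


@dataclass(frozen=True)
class MateChoiceTrial:
    """One arena trial: the list of first copulations in the male role.

    ``events`` are ``(male population, female population)`` labels.  Each of
    the ``2 * n_per_type`` snails is recorded at most once as a male, so a
    population contributes at most ``n_per_type`` events as male.
    """

    pop_a: str
    pop_b: str
    events: tuple
    n_per_type: int = 10

    def __post_init__(self) -> None:
        if self.pop_a == self.pop_b:
            raise ValueError("population labels must be distinct")
        males = Counter(m for m, _ in self.events)
        valid = {self.pop_a, self.pop_b}
        for m, f in self.events:
            if m not in valid or f not in valid:
                raise ValueError(f"event ({m}, {f}) has an unknown population label")
        for pop, k in males.items():
            if k > self.n_per_type:
                raise ValueError(
                    f"{k} males recorded for {pop!r} but only "
                    f"{self.n_per_type} individuals per population"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def table(self) -> PairTable:
        c = Counter(self.events)
        a, b = self.pop_a, self.pop_b
        return PairTable(
            a, b, c[(a, a)], c[(a, b)], c[(b, a)], c[(b, b)]
        )


def psi_coefficients(table: PairTable) -> PsiSet:
    """PSI coefficients: observed over expected pair frequencies.

    Expected counts come from the marginal products ``row_i * col_j / N``
    (the random-mating expectation conditional on who mated how often in each
    role).  PSI = 1 means a pair type occurs exactly as often as expected,
    > 1 an excess, < 1 a deficit.
    """
    if table.total == 0:
        raise ValueError("no copulations observed")
    n = table.counts
    rows = n.sum(axis=1)
    cols = n.sum(axis=0)
    e = np.outer(rows, cols) / table.total
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(e > 0, n / np.where(e > 0, e, 1.0), np.nan)
    flat_psi = dict(zip(CELLS, psi.ravel()))
    flat_e = dict(zip(CELLS, e.ravel()))
    return PsiSet(psi=flat_psi, expected=flat_e)


def ipsi(table: PairTable) -> float:
    """Index of Pair Sexual Isolation.

    ``IPSI = (PSI_aa + PSI_bb - PSI_ab - PSI_ba) / (sum of all four PSI)``;
    0 under random mating, +1 under complete positive assortment, negative
    under disassortative mating.  Requires all four PSI coefficients to be
    defined (no empty marginal).
    """
    psis = psi_coefficients(table)
    if not psis.all_defined:
        rows = table.counts.sum(axis=1)
        cols = table.counts.sum(axis=0)
        empty = []
        for label, tot in zip(
            (
                f"male {table.pop_a}",
                f"male {table.pop_b}",
                f"female {table.pop_a}",
                f"female {table.pop_b}",
            ),
            np.concatenate([rows, cols]),
        ):
            if tot == 0:
                empty.append(label)
        raise ValueError(f"IPSI undefined: empty marginal(s): {', '.join(empty)}")
    p = psis.psi
    num = p["aa"] + p["bb"] - p["ab"] - p["ba"]
    den = p["aa"] + p["bb"] + p["ab"] + p["ba"]
    return float(num / den)


def _ipsi_array(counts: np.ndarray) -> np.ndarray:
    """Vectorised IPSI over an array of 2x2 tables (shape ``(..., 2, 2)``).

    Returns NaN for tables with an empty row or column marginal.
    """
    counts = np.asarray(counts, dtype=float)
    rows = counts.sum(axis=-1)
    cols = counts.sum(axis=-2)
    total = rows.sum(axis=-1)
    e = rows[..., :, None] * cols[..., None, :] / total[..., None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = counts / e
    num = psi[..., 0, 0] + psi[..., 1, 1] - psi[..., 0, 1] - psi[..., 1, 0]
    den = psi.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    bad = (rows == 0).any(axis=-1) | (cols == 0).any(axis=-1)
    return np.where(bad, np.nan, out)


def ipsi_bootstrap_test(
    table: PairTable,
    n_boot: int = 10_000,
    seed: int = 0,
    reference: str = "normal",
) -> IsolationResult:
    """One-tailed bootstrap t-test of IPSI > 0 (positive assortment).

    ``N`` pairings are resampled multinomially from the observed cell
    proportions; the bootstrap standard deviation of IPSI gives the standard
    error, ``t = IPSI / SE`` is referred one-tailed to a standard normal
    (``reference="normal"``, default) or to a t distribution with
    ``n_valid - 1`` df (``reference="t"``).  Replicates with an empty marginal
    have no defined IPSI; they are dropped and counted in ``n_dropped``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if reference not in ("normal", "t"):
        raise ValueError("reference must be 'normal' or 't'")
    observed = ipsi(table)
    rng = np.random.default_rng(seed)
    p = table.counts.ravel() / table.total
    draws = rng.multinomial(table.total, p, size=n_boot).reshape(n_boot, 2, 2)
    values = _ipsi_array(draws)
    valid = values[np.isfinite(values)]
    n_dropped = n_boot - valid.size
    se = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0
    if se == 0.0:
        # Degenerate bootstrap distribution: decided by the point estimate.
        t_stat = 0.0 if observed == 0 else float(np.sign(observed)) * np.inf
        p_one = 0.5 if observed == 0 else (0.0 if observed > 0 else 1.0)
    else:
        t_stat = observed / se
        if reference == "normal":
            p_one = float(stats.norm.sf(t_stat))
        else:
            p_one = float(stats.t.sf(t_stat, df=valid.size - 1))
    return IsolationResult(
        ipsi=observed,
        se_boot=se,
        t_stat=float(t_stat),
        p_one_tailed=p_one,
        n_boot=n_boot,
        n_dropped=int(n_dropped),
        seed=seed,
        reference=reference,
    )


def _check_same_pair(trials: Sequence[MateChoiceTrial]) -> None:
    first = trials[0]
    for t in trials[1:]:
        if (t.pop_a, t.pop_b) != (first.pop_a, first.pop_b):
            raise ValueError(
                f"mismatched labels: ({t.pop_a}, {t.pop_b}) vs "
                f"({first.pop_a}, {first.pop_b})"
            )


def heterogeneity_test(
    trials: Sequence[MateChoiceTrial],
    n_shuffles: int = 20_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test of homogeneity across replicate trials.

    Builds the trials x 4-pairing-category contingency table and compares its
    Pearson chi-square statistic with tables sampled uniformly under fixed
    margins (Patefield's algorithm), which gives an exact conditional p-value
    up to Monte-Carlo error.  Trials with zero events are excluded with a
    warning.  A large p means the trials look like draws from one multinomial
    and pooling is safe.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need at least two trials of the same population pair")
    _check_same_pair(trials)
    used = [t for t in trials if t.n_events > 0]
    if len(used) < len(trials):
        warnings.warn(
            f"excluded {len(trials) - len(used)} trial(s) with zero events",
            stacklevel=2,
        )
    if len(used) < 2:
        raise ValueError("fewer than two non-empty trials")
    tab = np.array([t.table().counts.ravel() for t in used])
    tab = tab[:, tab.sum(axis=0) > 0]  # drop never-observed pairing categories
    if tab.shape[1] < 2:
        return 1.0  # a single occupied category cannot be heterogeneous
    rows = tab.sum(axis=1).astype(int)
    cols = tab.sum(axis=0).astype(int)
    expected = np.outer(rows, cols) / tab.sum()
    chi2_obs = float(((tab - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    samples = stats.random_table(rows, cols, seed=rng).rvs(n_shuffles)
    chi2_null = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
    hits = int(np.count_nonzero(chi2_null >= chi2_obs - 1e-9))
    return float((hits + 1) / (n_shuffles + 1))


def pool_trials(trials: Sequence[MateChoiceTrial]) -> PairTable:
    """Cellwise sum of per-trial tables for one population pair.

    Trials with zero events are excluded with a warning (they carry no
    information and, in practice, mark failed arenas).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to pool")
    _check_same_pair(trials)
    used = [t for t in trials if t.n_events > 0]
    if len(used) < len(trials):
        warnings.warn(
            f"excluded {len(trials) - len(used)} empty trial(s) from pooling",
            stacklevel=2,
        )
    if not used:
        raise ValueError("no copulations observed in any trial")
    total = np.sum([t.table().counts for t in used], axis=0).astype(int)
    first = trials[0]
    return PairTable(
        first.pop_a,
        first.pop_b,
        int(total[0, 0]),
        int(total[0, 1]),
        int(total[1, 0]),
        int(total[1, 1]),
    )


def sequential_bonferroni(
    p_values: Iterable[float], alpha: float = 0.05
) -> list:
    """Holm step-down decisions; ``True`` = reject at family-wise ``alpha``.

    Sort p-values ascending and compare the k-th smallest with
    ``alpha / (m - k + 1)``, stopping at the first failure.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p, alpha=alpha, method="holm")[0]
    return [bool(r) for r in reject]


def holm_adjusted_p(p_values: Iterable[float]) -> list:
    """Holm-adjusted p-values (monotone step-down adjustment)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    return [float(q) for q in multipletests(p, method="holm")[1]]


def null_pairing_odds(n_per_type: int) -> float:
    """Homogametic:heterogametic odds under random pairing, as a ratio.

    A focal snail in an ``n + n`` arena chooses uniformly among the other
    ``2n - 1`` snails: ``n - 1`` of its own population against ``n`` of the
    other, hence odds ``(n - 1):n`` — 9:10 for the standard 10 + 10 design.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    return (n_per_type - 1) / n_per_type


def null_homogametic_fraction(n_per_type: int) -> float:
    """Expected fraction of homogametic pairings under random pairing:
    ``(n - 1) / (2n - 1)`` (9/19 for the 10 + 10 design)."""
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    return (n_per_type - 1) / (2 * n_per_type - 1)
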