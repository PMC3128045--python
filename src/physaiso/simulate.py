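"""Synthetic data generators with known ground truth.

Every analysis stage in this package can be exercised without the original
laboratory records: these generators emulate the three experimental designs
— arena mate-choice trials with first-male-copulation recording, no-choice
crossing experiments with weekly embryo/hatchling counts, and Mendelian
codominant marker genotypes for broods of known selfed/outcross composition
— and return the true parameters alongside the records.

Design choices that mirror the experiments:

* A mate-choice trial holds ``n + n`` snails; a focal snail (drawn among
  those not yet recorded as male, weighted by its population's mating
  propensity) approaches a partner uniform among the other ``2n - 1``, so
  random mating yields homogametic:heterogametic odds of ``(n-1):n``.
  Isolation acts on pairing acceptance — a heterogametic approach succeeds
  with probability ``w`` — not on encounter rates, reflecting rejection in
  the female role rather than differences in activity.
* Weekly fecundity is an overdispersed (negative-binomial) count; observed
  per-pair ranges in such experiments are far wider than Poisson.
* Offspring of an outcross pair are a mixture of self-by-A, self-by-B and
  true hybrids with configurable probabilities, because a paired hermaphrodite
  always retains the option to self-fertilize.

All generators take a :class:`numpy.random.Generator` (or an integer seed)
and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .hybridity import MarkerGenotypeSet
from .nochoice import ExperimentSet, NoChoicePairRecord
from .sexual_isolation import MateChoiceTrial, PairTable, pool_trials

__all__ = [
    "MateChoiceSimParams",
    "NoChoiceSimParams",
    "MarkerSimParams",
    "simulate_mate_choice_trial",
    "simulate_mate_choice_comparison",
    "simulate_nochoice_experiment",
    "simulate_offspring_markers",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class MateChoiceSimParams:
    """Parameters of one arena mate-choice trial.

    ``w`` is the heterogametic acceptance weight: 1 = no isolation, 0 =
    complete isolation.  A mapping ``{(male_pop, female_pop): w}`` gives
    directional weights.  ``propensity`` scales how often each population's
    snails act as the focal male.
    """

    pop_a: str = "A"
    pop_b: str = "B"
    n_per_type: int = 10
    w: Union[float, Mapping] = 1.0
    propensity: tuple = (1.0, 1.0)
    n_trials: int = 3
    max_attempts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        ws = (
            self.w.values() if isinstance(self.w, Mapping) else (self.w,)
        )
        if any(not 0.0 <= float(v) <= 1.0 for v in ws):
            raise ValueError("acceptance weight w must lie in [0, 1]")
        if any(p <= 0 for p in self.propensity):
            raise ValueError("mating propensities must be positive")

    def accept_weight(self, male_pop: str, female_pop: str) -> float:
        if isinstance(self.w, Mapping):
            return float(self.w[(male_pop, female_pop)])
        return float(self.w)


def simulate_mate_choice_trial(
    params: MateChoiceSimParams, rng=None
) -> MateChoiceTrial:
    """Simulate one trial; each snail is recorded at most once as male.

    Repeatedly draws an unrecorded focal snail (propensity-weighted), a
    partner uniform among the other ``2n - 1`` snails, and realises the
    pairing with probability 1 if homogametic or ``w`` if heterogametic.
    Stops when every snail has been recorded as male or the attempt budget
    (default ``400 * 2n``) is exhausted — with strong isolation some snails
    may never be recorded, as in real arenas.
    """
    rng = _rng(rng)
    n = params.n_per_type
    size = 2 * n
    pops = np.repeat([0, 1], n)
    labels = (params.pop_a, params.pop_b)
    weights = np.array([params.propensity[p] for p in pops], dtype=float)
    uniform = params.propensity[0] == params.propensity[1]
    recorded = np.zeros(size, dtype=bool)
    unrecorded = list(range(size))
    events = []
    cap = params.max_attempts if params.max_attempts is not None else 400 * size
    attempts = 0
    while unrecorded and attempts < cap:
        attempts += 1
        if uniform:
            focal = unrecorded[rng.integers(len(unrecorded))]
        else:
            w = weights[unrecorded]
            focal = unrecorded[rng.choice(len(unrecorded), p=w / w.sum())]
        partner = int(rng.integers(size - 1))
        if partner >= focal:
            partner += 1
        male, female = labels[pops[focal]], labels[pops[partner]]
        if pops[focal] == pops[partner] or rng.random() < params.accept_weight(
            male, female
        ):
            events.append((male, female))
            recorded[focal] = True
            unrecorded.remove(focal)
    return MateChoiceTrial(
        pop_a=params.pop_a,
        pop_b=params.pop_b,
        events=tuple(events),
        n_per_type=n,
    )


def simulate_mate_choice_comparison(
    params: MateChoiceSimParams, rng=None
) -> tuple:
    """Simulate ``n_trials`` trials of one pair and their pooled table."""
    rng = _rng(rng)
    trials = [simulate_mate_choice_trial(params, rng) for _ in range(params.n_trials)]
    return trials, pool_trials(trials)


def _per_cross(value, cross: str):
    if isinstance(value, Mapping):
        return value[cross]
    return value


@dataclass(frozen=True)
class NoChoiceSimParams:
    """Parameters of one simulated no-choice experiment (30 pairs).

    Scalar parameters apply to all three cross types; mappings keyed by
    ``outcross`` / ``control_a`` / ``control_b`` give per-type values.
    Defaults reflect healthy laboratory physids: onset of reproduction
    around week 5, roughly 60 embryos per pair-week with strong
    overdispersion, 70% hatch success, occasional never-reproducing pairs,
    and excellent parental survival over a 16-week observation.
    """

    label: str = "experiment"
    n_pairs: int = 10
    weeks: int = 16
    onset_mean: Union[float, Mapping] = 5.0
    fecundity_mean: Union[float, Mapping] = 60.0
    dispersion: float = 5.0
    hatch_p: Union[float, Mapping] = 0.7
    prob_reproduce: Union[float, Mapping] = 0.9
    weekly_survival: float = 0.998
    selfing: tuple = (0.25, 0.56)  # (P(self by A), P(self by B)) per outcross offspring

    def __post_init__(self) -> None:
        probs = []
        for v in (self.hatch_p, self.prob_reproduce):
            probs.extend(v.values() if isinstance(v, Mapping) else [v])
        probs.append(self.weekly_survival)
        probs.extend(self.selfing)
        if any(not 0.0 <= float(p) <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.selfing) > 1.0:
            raise ValueError("selfing probabilities sum above 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _simulate_pair(
    pair_id: str, cross: str, params: NoChoiceSimParams, rng: np.random.Generator
):
    onset_mean = float(_per_cross(params.onset_mean, cross))
    onset = 1 + int(rng.poisson(max(onset_mean - 1.0, 0.0)))
    reproduces = rng.random() < float(_per_cross(params.prob_reproduce, cross))
    hatch_p = float(_per_cross(params.hatch_p, cross))
    fec_mean = float(_per_cross(params.fecundity_mean, cross))
    embryos, hatchlings, alive = [], [], []
    both_alive = True
    classes = []
    for week in range(1, params.weeks + 1):
        if both_alive and rng.random() > params.weekly_survival:
            both_alive = False
        alive.append(both_alive)
        if both_alive and reproduces and week >= onset:
            e = _negbin(rng, fec_mean, params.dispersion)
            h = int(rng.binomial(e, hatch_p)) if e else 0
        else:
            e = h = 0
        embryos.append(e)
        hatchlings.append(h)
        if cross == "outcross" and h:
            p_a, p_b = params.selfing
            draws = rng.random(h)
            for u in draws:
                if u < p_a:
                    classes.append("self_a")
                elif u < p_a + p_b:
                    classes.append("self_b")
                else:
                    classes.append("hybrid")
    record = NoChoicePairRecord(
        pair_id=pair_id,
        cross=cross,
        embryos=tuple(embryos),
        hatchlings=tuple(hatchlings),
        alive=tuple(alive),
    )
    truth = {"onset": onset, "reproduces": reproduces, "classes": tuple(classes)}
    return record, truth


def simulate_nochoice_experiment(params: NoChoiceSimParams, rng=None):
    """Simulate an experiment set (outcross + two controls) with ground truth.

    Returns ``(ExperimentSet, truth)`` where ``truth`` records the simulation
    parameters and, per pair, the drawn onset week, whether the pair ever
    reproduces, and (for outcross pairs) the true class of every hatchling.
    """
    rng = _rng(rng)
    sets = {}
    truth = {"params": params, "pairs": {}}
    for cross in ("outcross", "control_a", "control_b"):
        records = []
        for i in range(params.n_pairs):
            pair_id = f"{params.label}-{cross}-{i + 1}"
            record, pair_truth = _simulate_pair(pair_id, cross, params, rng)
            records.append(record)
            truth["pairs"][pair_id] = pair_truth
        sets[cross] = records
    exp = ExperimentSet(
        label=params.label,
        outcross=sets["outcross"],
        control_a=sets["control_a"],
        control_b=sets["control_b"],
    )
    return exp, truth


@dataclass(frozen=True)
class MarkerSimParams:
    """Parental genotypes per locus for marker simulation.

    ``loci`` maps locus name to ``(parent_a_genotype, parent_b_genotype)``,
    each an unordered allele pair.
    """

    loci: Mapping

    def __post_init__(self) -> None:
        for locus, (ga, gb) in self.loci.items():
            if len(tuple(ga)) != 2 or len(tuple(gb)) != 2:
                raise ValueError(f"locus {locus}: genotypes must be allele pairs")


def _gamete(genotype, rng: np.random.Generator) -> str:
    return str(genotype[int(rng.integers(2))])


def simulate_offspring_markers(
    params: MarkerSimParams, classes: Sequence, rng=None
) -> MarkerGenotypeSet:
    """Simulate Mendelian marker genotypes for offspring of known classes.

    A selfed offspring unites two independent gametes of one parent; a hybrid
    takes one gamete from each parent.  Genotypes are unordered.
    """
    rng = _rng(rng)
    valid = {"self_a", "self_b", "hybrid"}
    bad = set(classes) - valid
    if bad:
        raise ValueError(f"unknown offspring class(es): {sorted(bad)}")
    parent_a = {locus: tuple(ga) for locus, (ga, _) in params.loci.items()}
    parent_b = {locus: tuple(gb) for locus, (_, gb) in params.loci.items()}
    offspring = []
    for cls in classes:
        geno = {}
        for locus in params.loci:
            ga, gb = parent_a[locus], parent_b[locus]
            if cls == "self_a":
                pair = (_gamete(ga, rng), _gamete(ga, rng))
            elif cls == "self_b":
                pair = (_gamete(gb, rng), _gamete(gb, rng))
            else:
                pair = (_gamete(ga, rng), _gamete(gb, rng))
            geno[locus] = tuple(sorted(pair))
        offspring.append(geno)
    return MarkerGenotypeSet(
        parent_a=parent_a, parent_b=parent_b, offspring=offspring
    )
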