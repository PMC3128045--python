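"""Selfed-versus-outcrossed classification of F1 progeny.

In a no-choice cross between two hermaphroditic snails, any offspring may be
the product of outcrossing or of self-fertilization by either parent.  With
codominant Mendelian markers (allozyme loci such as Lap, Isdh1, Est6, Pgm1)
each hypothesis — self by parent A, self by parent B, outcross — predicts
which offspring genotypes are producible at each locus; a hypothesis is
rejected as soon as one locus shows a genotype it cannot produce.  Selfing is
modelled as a random union of two gametes from the same parent, so a
heterozygous selfer a/b can yield a/a, a/b or b/b offspring.

An offspring is called *hybrid* only when outcrossing is the sole surviving
hypothesis, *self_a*/*self_b* when selfing by that parent is, and *ambiguous*
when more than one hypothesis remains.  A fixed difference between the
parents at any one locus (A = a/a, B = b/b) removes all ambiguity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "HYPOTHESES",
    "MarkerGenotypeSet",
    "OffspringClassification",
    "ClassProportions",
    "classify_offspring",
    "classification_proportions",
]

HYPOTHESES = ("self_a", "self_b", "outcross")


def _norm(genotype) -> tuple:
    """Unordered genotype as a sorted 2-tuple of allele labels."""
    if genotype is None:
        return None
    x, y = genotype
    return tuple(sorted((str(x), str(y))))


@dataclass(frozen=True)
class MarkerGenotypeSet:
    """Multi-locus genotypes for both parents and a brood of offspring.

    ``parent_a`` / ``parent_b`` map locus name to an unordered allele pair;
    each entry of ``offspring`` maps locus name to an allele pair or None for
    missing data.
    """

    parent_a: Mapping
    parent_b: Mapping
    offspring: Sequence
    offspring_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "parent_a", {k: _norm(v) for k, v in self.parent_a.items()}
        )
        object.__setattr__(
            self, "parent_b", {k: _norm(v) for k, v in self.parent_b.items()}
        )
        object.__setattr__(
            self,
            "offspring",
            tuple({k: _norm(v) for k, v in o.items()} for o in self.offspring),
        )
        ids = self.offspring_ids
        if ids is None:
            ids = tuple(f"offspring_{i + 1}" for i in range(len(self.offspring)))
        elif len(ids) != len(self.offspring):
            raise ValueError("offspring_ids length mismatch")
        object.__setattr__(self, "offspring_ids", tuple(str(i) for i in ids))


@dataclass(frozen=True)
class OffspringClassification:
    """Classification of one offspring with its per-locus evidence trace.

    ``label`` is one of self_a / self_b / hybrid / ambiguous; ``evidence``
    maps each informative locus to the hypotheses compatible with the
    offspring genotype there.
    """

    label: str
    retained: tuple
    evidence: Mapping

    @property
    def definite(self) -> bool:
        return self.label != "ambiguous"

    @property
    def supporting_loci(self) -> tuple:
        """Loci at which at least one hypothesis was excluded."""
        return tuple(
            locus
            for locus, hyps in self.evidence.items()
            if len(hyps) < len(HYPOTHESES)
        )


@dataclass(frozen=True)
class ClassProportions:
    counts: Mapping
    n_total: int
    n_definite: int

    def proportion(self, label: str) -> float:
        """Share of *definite* calls in the given class."""
        if self.n_definite == 0:
            return float("nan")
        return self.counts.get(label, 0) / self.n_definite

    @property
    def ambiguous_fraction(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.counts.get("ambiguous", 0) / self.n_total


def _compatible(genotype, hypothesis, ga, gb) -> bool:
    x, y = genotype
    a, b = set(ga), set(gb)
    if hypothesis == "self_a":
        return x in a and y in a
    if hypothesis == "self_b":
        return x in b and y in b
    return (x in a and y in b) or (y in a and x in b)


def classify_offspring(
    offspring: Mapping,
    parent_a: Mapping,
    parent_b: Mapping,
    max_incompatible_loci: int = 0,
) -> OffspringClassification:
    """Classify one offspring as selfed, hybrid, or ambiguous.

    A hypothesis is retained iff the offspring genotype is producible from
    the corresponding gamete pairs at every informative locus (loci with
    missing data in offspring or either parent are skipped and contribute no
    evidence).  ``max_incompatible_loci`` relaxes the veto for genotyping
    error; the default is strict.

    Raises ValueError when an offspring allele occurs in neither parent
    (non-Mendelian inheritance or a labelling error), or when every
    hypothesis is excluded.
    """
    off = {k: _norm(v) for k, v in offspring.items()}
    pa = {k: _norm(v) for k, v in parent_a.items()}
    pb = {k: _norm(v) for k, v in parent_b.items()}
    informative = [
        locus
        for locus, g in off.items()
        if g is not None and pa.get(locus) is not None and pb.get(locus) is not None
    ]
    if not informative:
        raise ValueError("no informative loci: all offspring genotypes missing")
    evidence = {}
    misses = Counter()
    for locus in informative:
        g = off[locus]
        pool = set(pa[locus]) | set(pb[locus])
        foreign = [al for al in g if al not in pool]
        if foreign:
            raise ValueError(
                f"locus {locus}: allele(s) {foreign} absent from both parents "
                "(non-Mendelian or mislabelled)"
            )
        ok = tuple(
            h for h in HYPOTHESES if _compatible(g, h, pa[locus], pb[locus])
        )
        evidence[locus] = ok
        for h in HYPOTHESES:
            if h not in ok:
                misses[h] += 1
    retained = tuple(h for h in HYPOTHESES if misses[h] <= max_incompatible_loci)
    if not retained:
        raise ValueError(
            "offspring genotype incompatible with selfing by either parent "
            "and with outcrossing (non-Mendelian or mislabelled)"
        )
    if retained == ("outcross",):
        label = "hybrid"
    elif len(retained) == 1:
        label = retained[0]
    else:
        label = "ambiguous"
    return OffspringClassification(label=label, retained=retained, evidence=evidence)


def classification_proportions(
    classifications: Iterable,
) -> ClassProportions:
    """Counts and proportions per class across a brood.

    Proportions are computed over definite calls; ambiguous offspring are
    counted but reported separately via ``ambiguous_fraction``.
    """
    labels = [
        c.label if isinstance(c, OffspringClassification) else str(c)
        for c in classifications
    ]
    if not labels:
        raise ValueError("no classifications supplied")
    counts = Counter(labels)
    n_total = len(labels)
    n_def = n_total - counts.get("ambiguous", 0)
    return ClassProportions(counts=dict(counts), n_total=n_total, n_definite=n_def)
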