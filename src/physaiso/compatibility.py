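"""Dobzhansky-Muller compatibility models on a rooted species tree.

Reproductive isolation between population pairs is modelled with a small
number of compatibility loci at which opaque alleles 1, 2, 3, ... segregate;
populations are treated as fixed at each locus, so the phenotype of a cross
is a deterministic function of which loci *match* (carry the same allele):

* viability — epistatic two-locus rule over a "complete" locus J and a
  "partial" locus K: a J match gives fully viable hybrids regardless of K, a
  J mismatch with a K match gives partial viability, a double mismatch none;
* mating — complementary two-locus rule: a match at either J or K suffices
  for unrestricted mating;
* F1 fertility — a single locus: match means fertile hybrids.

Given a rooted species tree whose root is assumed fully compatible (the
ancestral allele everywhere), the historical cost of an allele assignment is
the minimum number of independent allele origins on branches — small
parsimony with a fixed root state, computed by dynamic programming.
:func:`search_minimal_model` enumerates all allele assignments (as set
partitions of the populations with a marked ancestral block, so relabelled
models are never counted twice), keeps those that reproduce an observed
pairwise phenotype matrix exactly, and returns the minimal-origin ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import dendropy
from sympy.utilities.iterables import multiset_partitions

__all__ = [
    "SpeciesTree",
    "RuleSet",
    "PhenotypeMatrix",
    "ConsistencyResult",
    "SearchResult",
    "VIABILITY_EPISTATIC",
    "VIABILITY_SINGLE",
    "MATING_EITHER",
    "MATING_SINGLE",
    "FERTILITY_SINGLE",
    "RULES",
    "read_newick",
    "predict_viability",
    "predict_mating",
    "predict_fertility",
    "predict",
    "model_consistency",
    "count_origins",
    "search_minimal_model",
]

_INF = float("inf")


class SpeciesTree:
    """A rooted tree with uniquely labelled tips (populations)."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise ValueError(f"duplicate tip label(s): {', '.join(dupes)}")
        self._tree = tree
        self.tip_labels = tuple(labels)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return read_newick(text)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self):
        return self._tree.seed_node

    def postorder(self):
        return self._tree.postorder_node_iter()

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def restrict(self, labels) -> "SpeciesTree":
        """Induced subtree on a subset of the tips (labels kept as-is)."""
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise ValueError(f"tip(s) not on the tree: {', '.join(sorted(missing))}")
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        sub.is_rooted = True
        return SpeciesTree(sub)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({', '.join(self.tip_labels)})"


def read_newick(source: str) -> SpeciesTree:
    """Parse a newick string (or a path to a newick file) into a SpeciesTree."""
    text = source
    if not source.lstrip().startswith("(") and "(" not in source:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree)


@dataclass(frozen=True)
class RuleSet:
    """Deterministic phenotype rule over per-locus match patterns.

    ``classify`` maps a tuple of booleans (did the two genotypes match at
    each locus, in ``loci`` order) to an output class.  Rules are total
    functions with no penetrance parameter: the models are qualitative.
    """

    kind: str
    loci: tuple
    classify: Callable
    name: str = ""

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def classes(self) -> tuple:
        return tuple(
            dict.fromkeys(
                self.classify(pattern)
                for pattern in itertools.product((True, False), repeat=self.n_loci)
            )
        )


VIABILITY_EPISTATIC = RuleSet(
    kind="viability",
    loci=("J", "K"),
    classify=lambda m: "full" if m[0] else ("partial" if m[1] else "none"),
    name="viability_epistatic",
)
VIABILITY_SINGLE = RuleSet(
    kind="viability",
    loci=("J",),
    classify=lambda m: "full" if m[0] else "none",
    name="viability_single",
)
MATING_EITHER = RuleSet(
    kind="mating",
    loci=("J", "K"),
    classify=lambda m: "compatible" if any(m) else "isolated",
    name="mating_either",
)
MATING_SINGLE = RuleSet(
    kind="mating",
    loci=("J",),
    classify=lambda m: "compatible" if m[0] else "isolated",
    name="mating_single",
)
FERTILITY_SINGLE = RuleSet(
    kind="fertility",
    loci=("F",),
    classify=lambda m: "fertile" if m[0] else "sterile",
    name="fertility_single",
)

#: Named rules, for configuration files and the CLI.
RULES = {
    r.name: r
    for r in (
        VIABILITY_EPISTATIC,
        VIABILITY_SINGLE,
        MATING_EITHER,
        MATING_SINGLE,
        FERTILITY_SINGLE,
    )
}

#: Default rule families by phenotype kind and locus count, used by the
#: minimal-model search.
RULE_FAMILIES = {
    "viability": {1: VIABILITY_SINGLE, 2: VIABILITY_EPISTATIC},
    "mating": {1: MATING_SINGLE, 2: MATING_EITHER},
    "fertility": {1: FERTILITY_SINGLE},
}


def _match_pattern(g_a: Mapping, g_b: Mapping, loci) -> tuple:
    pattern = []
    for locus in loci:
        if locus not in g_a or locus not in g_b:
            raise ValueError(f"genotype missing locus {locus!r}")
        pattern.append(g_a[locus] == g_b[locus])
    return tuple(pattern)


def predict(rule: RuleSet, g_a: Mapping, g_b: Mapping) -> str:
    """Predicted phenotype class for a cross between two genotypes."""
    return rule.classify(_match_pattern(g_a, g_b, rule.loci))


def predict_viability(g_a: Mapping, g_b: Mapping) -> str:
    """Hybrid viability under the epistatic J/K rule: full / partial / none."""
    return predict(VIABILITY_EPISTATIC, g_a, g_b)


def predict_mating(g_a: Mapping, g_b: Mapping) -> str:
    """Mating compatibility: a match at either locus suffices."""
    return predict(MATING_EITHER, g_a, g_b)


def predict_fertility(g_a: Mapping, g_b: Mapping) -> str:
    """F1 fertility under the single-locus rule: fertile / sterile."""
    return predict(FERTILITY_SINGLE, g_a, g_b)


class PhenotypeMatrix:
    """Observed (or predicted) pairwise phenotype classes over populations.

    Symmetric by construction: entries are keyed by unordered population
    pairs; the diagonal is implicitly the compatible class and not stored.
    Pairs that were never scored (e.g. fertility where no hybrids exist) are
    simply absent and ignored by consistency checks.
    """

    def __init__(self, kind: str, classes: Mapping):
        self.kind = kind
        store = {}
        for pair, cls in classes.items():
            key = frozenset(pair)
            if len(key) != 2:
                raise ValueError(f"pair {tuple(pair)} is not two distinct populations")
            if key in store and store[key] != cls:
                raise ValueError(f"conflicting classes for pair {sorted(key)}")
            store[key] = str(cls)
        self._classes = store

    @property
    def populations(self) -> tuple:
        return tuple(sorted({p for pair in self._classes for p in pair}))

    def pairs(self):
        """Iterate ``((pop_a, pop_b), class)`` in a deterministic order."""
        for key in sorted(self._classes, key=sorted):
            a, b = sorted(key)
            yield (a, b), self._classes[key]

    def get(self, pop_a: str, pop_b: str) -> str:
        return self._classes[frozenset((pop_a, pop_b))]

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._classes

    def __len__(self) -> int:
        return len(self._classes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PhenotypeMatrix)
            and self.kind == other.kind
            and self._classes == other._classes
        )


@dataclass(frozen=True)
class ConsistencyResult:
    consistent: bool
    mismatches: tuple  # of (pair, predicted, observed)

    def __bool__(self) -> bool:
        return self.consistent


def model_consistency(
    assignments: Mapping, rule: RuleSet, observed: PhenotypeMatrix
) -> ConsistencyResult:
    """Do the model's predictions match every observed off-diagonal pair?

    ``assignments`` maps population -> {locus: allele} and must cover every
    population in the matrix.
    """
    missing = [p for p in observed.populations if p not in assignments]
    if missing:
        raise ValueError(f"assignments missing population(s): {', '.join(missing)}")
    mismatches = []
    for (a, b), obs_cls in observed.pairs():
        pred = predict(rule, assignments[a], assignments[b])
        if pred != obs_cls:
            mismatches.append(((a, b), pred, obs_cls))
    return ConsistencyResult(consistent=not mismatches, mismatches=tuple(mismatches))


def count_origins(tree: SpeciesTree, tip_states: Mapping, ancestral) -> int:
    """Minimum number of allele origins on the tree, root fixed to ancestral.

    Small parsimony by dynamic programming: for every node and state, the
    minimal number of state changes in its subtree; the answer is the root's
    cost at the ancestral state.  Any change of state along a branch counts
    as one origin (unit cost, state-symmetric).
    """
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"unassigned tip(s): {', '.join(missing)}")
    states = sorted({str(s) for s in tip_states.values()} | {str(ancestral)})
    index = {s: i for i, s in enumerate(states)}
    cost = {}
    for node in tree.postorder():
        if node.is_leaf():
            vec = [_INF] * len(states)
            vec[index[str(tip_states[node.taxon.label])]] = 0.0
        else:
            vec = []
            for i in range(len(states)):
                total = 0.0
                for child in node.child_nodes():
                    c = cost[id(child)]
                    total += min(c[j] + (0.0 if j == i else 1.0) for j in range(len(states)))
                vec.append(total)
        cost[id(node)] = vec
    return int(cost[id(tree.root)][index[str(ancestral)]])


def _locus_assignments(populations: Sequence, max_alleles: Optional[int], ancestral: str):
    """All distinct allele assignments for one locus, canonicalised.

    An assignment is a set partition of the populations into allele classes
    plus the choice of which class (possibly none) carries the ancestral
    allele.  The ancestral class is labelled with ``ancestral``; derived
    classes get "2", "3", ... in a canonical order, so relabelled duplicates
    never appear.
    """
    pops = sorted(populations)
    for partition in multiset_partitions(pops):
        blocks = sorted((tuple(sorted(b)) for b in partition), key=lambda b: b[0])
        for anc_idx in range(-1, len(blocks)):  # -1: ancestral allele at no tip
            n_alleles = len(blocks) + (1 if anc_idx == -1 else 0)
            if max_alleles is not None and n_alleles > max_alleles:
                continue
            assignment = {}
            nxt = 2
            for i, block in enumerate(blocks):
                if i == anc_idx:
                    label = str(ancestral)
                else:
                    label = str(nxt)
                    nxt += 1
                for pop in block:
                    assignment[pop] = label
            yield assignment


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an exhaustive minimal-origins model search."""

    min_origins: Optional[int]
    models: tuple  # of {"rule": name, "assignments": ..., "origins": {locus: int}}
    n_consistent: int
    n_searched: int
    max_loci: int
    max_alleles: Optional[int]

    @property
    def found(self) -> bool:
        return self.min_origins is not None


def search_minimal_model(
    tree: SpeciesTree,
    observed: PhenotypeMatrix,
    rules_by_loci: Optional[Mapping] = None,
    max_loci: int = 2,
    max_alleles: Optional[int] = None,
    ancestral: str = "1",
) -> SearchResult:
    """Exhaustive search for minimal-origin models consistent with the data.

    Enumerates, for each locus count up to ``max_loci`` with a rule defined
    in ``rules_by_loci`` (default: the family for ``observed.kind``), every
    combination of canonical per-locus allele assignments over the matrix's
    populations, keeps the combinations whose predictions reproduce the
    observed matrix exactly, and returns those minimising the total number of
    allele origins on the tree.  All ties at the minimum are reported;
    assignments differing only by allele relabelling are counted once.
    """
    pops = observed.populations
    if len(pops) > 8:
        raise ValueError("exhaustive search is bounded at 8 populations")
    missing = [p for p in pops if p not in tree.tip_labels]
    if missing:
        raise ValueError(f"population(s) not on the tree: {', '.join(missing)}")
    if set(pops) != set(tree.tip_labels):
        tree = tree.restrict(pops)  # origins counted on the induced subtree
    if rules_by_loci is None:
        rules_by_loci = RULE_FAMILIES.get(observed.kind, {})
    best = None
    best_models = []
    n_consistent = 0
    n_searched = 0
    for n_loci in range(1, max_loci + 1):
        rule = rules_by_loci.get(n_loci)
        if rule is None:
            continue
        options = list(_locus_assignments(pops, max_alleles, ancestral))
        for combo in itertools.product(options, repeat=n_loci):
            n_searched += 1
            genotypes = {
                p: {locus: combo[i][p] for i, locus in enumerate(rule.loci)}
                for p in pops
            }
            if not model_consistency(genotypes, rule, observed).consistent:
                continue
            n_consistent += 1
            origins = {
                locus: count_origins(tree, combo[i], ancestral)
                for i, locus in enumerate(rule.loci)
            }
            total = sum(origins.values())
            if best is None or total < best:
                best = total
                best_models = []
            if total == best:
                best_models.append(
                    {"rule": rule.name, "assignments": genotypes, "origins": origins}
                )
    return SearchResult(
        min_origins=best,
        models=tuple(best_models),
        n_consistent=n_consistent,
        n_searched=n_searched,
        max_loci=max_loci,
        max_alleles=max_alleles,
    )
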