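"""Published study inputs for the five-population *Physa* system.

Printed summaries from the mate-choice and no-choice studies of five
populations — *P. acuta* from Charleston (``acuta-c``) and Philadelphia
(``acuta-p``), *P. carolinae*, *P. pomilia* and *P. gyrina* — encoded as
package data: the species-tree topology, the pooled mate-choice table
reconstructible from the printed directional counts, the pooled copulation
totals and IPSI values, the observed pairwise phenotype matrices (hybrid
viability, F1 fertility, mating compatibility), the proposed compatibility
models, and the progeny classification counts.  Everything here is a printed
number, not a computation.
"""

from __future__ import annotations

from .compatibility import PhenotypeMatrix, SpeciesTree, read_newick
from .sexual_isolation import PairTable

__all__ = [
    "POPULATIONS",
    "SPECIES_TREE_NEWICK",
    "species_tree",
    "acuta_pomilia_pair_table",
    "pooled_copulation_totals",
    "ipsi_values",
    "starred_pairs",
    "observed_viability_matrix",
    "observed_mating_matrix",
    "observed_fertility_matrix",
    "viability_model_genotypes",
    "mating_model_genotypes",
    "fertility_model_genotypes",
    "progeny_classification_counts",
]

POPULATIONS = ("acuta-c", "acuta-p", "carolinae", "pomilia", "gyrina")

#: Rooted species-tree topology: the two acuta populations are sisters,
#: carolinae joins them, then pomilia, with gyrina most distant.
SPECIES_TREE_NEWICK = "(gyrina,(pomilia,(carolinae,(acuta-c,acuta-p))));"


def species_tree() -> SpeciesTree:
    return read_newick(SPECIES_TREE_NEWICK)


def acuta_pomilia_pair_table() -> PairTable:
    """Pooled acuta-p x pomilia mate-choice table from the directional counts.

    Of 22 first copulations by Philadelphia acuta as male, 14 were with
    pomilia females; of 28 by pomilia as male, 10 were with acuta females —
    hence counts (aa=8, ab=14, ba=10, bb=18) with a = acuta-p, b = pomilia.
    """
    return PairTable("acuta-p", "pomilia", 8, 14, 10, 18)


def pooled_copulation_totals() -> dict:
    """Total first copulations pooled over the three trials, per pair."""
    totals = {
        ("acuta-c", "acuta-p"): 52,
        ("acuta-c", "carolinae"): 49,
        ("acuta-c", "pomilia"): 41,
        ("acuta-c", "gyrina"): 43,
        ("acuta-p", "carolinae"): 44,
        ("acuta-p", "pomilia"): 50,
        ("acuta-p", "gyrina"): 41,
        ("carolinae", "pomilia"): 38,
        ("carolinae", "gyrina"): 51,
        ("pomilia", "gyrina"): 54,
    }
    return {frozenset(k): v for k, v in totals.items()}


def ipsi_values() -> dict:
    """Published IPSI per pair (two decimals)."""
    values = {
        ("acuta-c", "acuta-p"): 0.19,
        ("acuta-c", "carolinae"): 0.13,
        ("acuta-p", "carolinae"): 0.23,
        ("acuta-c", "pomilia"): 0.46,
        ("acuta-p", "pomilia"): 0.01,
        ("carolinae", "pomilia"): 0.45,
        ("acuta-c", "gyrina"): 0.71,
        ("acuta-p", "gyrina"): 0.51,
        ("carolinae", "gyrina"): 0.51,
        ("pomilia", "gyrina"): 0.37,
    }
    return {frozenset(k): v for k, v in values.items()}


def starred_pairs() -> set:
    """Pairs whose IPSI was significant after sequential Bonferroni."""
    starred = [
        ("acuta-c", "pomilia"),
        ("carolinae", "pomilia"),
        ("acuta-c", "gyrina"),
        ("acuta-p", "gyrina"),
        ("carolinae", "gyrina"),
        ("pomilia", "gyrina"),
    ]
    return {frozenset(p) for p in starred}


def observed_viability_matrix() -> PhenotypeMatrix:
    """Hybrid-viability classes from the no-choice experiments.

    ``full``: 100% hybrid F1 in high frequency; ``partial``: hybrids
    recovered mixed with selfed progeny; ``none``: no hybrids at all.
    """
    classes = {
        ("acuta-c", "acuta-p"): "full",
        ("acuta-c", "carolinae"): "full",
        ("acuta-p", "carolinae"): "full",
        ("acuta-c", "pomilia"): "partial",
        ("acuta-p", "pomilia"): "partial",
        ("carolinae", "pomilia"): "none",
        ("acuta-c", "gyrina"): "none",
        ("acuta-p", "gyrina"): "none",
        ("carolinae", "gyrina"): "none",
        ("pomilia", "gyrina"): "none",
    }
    return PhenotypeMatrix("viability", classes)


def observed_mating_matrix() -> PhenotypeMatrix:
    """Mating-compatibility classes, encoded from the starred IPSI pattern."""
    classes = {}
    for i, a in enumerate(POPULATIONS):
        for b in POPULATIONS[i + 1 :]:
            cls = "isolated" if frozenset((a, b)) in starred_pairs() else "compatible"
            classes[(a, b)] = cls
    return PhenotypeMatrix("mating", classes)


def observed_fertility_matrix() -> PhenotypeMatrix:
    """F1-fertility classes for the four hybrid-producing populations.

    gyrina pairs and carolinae x pomilia produced no hybrids to score, so
    those pairs are absent rather than assigned a class.
    """
    classes = {
        ("acuta-c", "acuta-p"): "fertile",
        ("acuta-c", "carolinae"): "sterile",
        ("acuta-p", "carolinae"): "sterile",
        ("acuta-c", "pomilia"): "sterile",
        ("acuta-p", "pomilia"): "sterile",
    }
    return PhenotypeMatrix("fertility", classes)


def viability_model_genotypes() -> dict:
    """Proposed two-locus viability model from a J1 K1 ancestor."""
    return {
        "gyrina": {"J": "2", "K": "2"},
        "pomilia": {"J": "3", "K": "1"},
        "carolinae": {"J": "1", "K": "3"},
        "acuta-c": {"J": "1", "K": "1"},
        "acuta-p": {"J": "1", "K": "1"},
    }


def mating_model_genotypes() -> dict:
    """Proposed two-locus mating model (match at either locus suffices)."""
    return {
        "gyrina": {"J": "2", "K": "2"},
        "pomilia": {"J": "3", "K": "1"},
        "carolinae": {"J": "1", "K": "3"},
        "acuta-c": {"J": "1", "K": "4"},
        "acuta-p": {"J": "1", "K": "1"},
    }


def fertility_model_genotypes() -> dict:
    """Single-locus F1-fertility model over the hybrid-producing populations.

    One unique incompatibility allele arose independently on the carolinae
    and pomilia branches; both acuta populations retain the ancestral allele.
    gyrina is outside the model's scope (no hybrids exist to score).
    """
    return {
        "acuta-c": {"F": "1"},
        "acuta-p": {"F": "1"},
        "carolinae": {"F": "2"},
        "pomilia": {"F": "3"},
    }


def progeny_classification_counts() -> dict:
    """Marker-based F1 classifications from the two mixed-progeny crosses.

    Counts per class; the acuta-p x pomilia brood (n = 68) was published as
    25% self-acuta, 56% self-pomilia, 19% outcrossed, the acuta-c x pomilia
    brood (n = 36) as 25% / 25% / 50%.
    """
    return {
        ("acuta-p", "pomilia"): {"self_a": 17, "self_b": 38, "hybrid": 13},
        ("acuta-c", "pomilia"): {"self_a": 9, "self_b": 9, "hybrid": 18},
    }
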