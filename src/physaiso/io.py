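"""Readers and writers for the package's plain-text formats.

All tabular inputs are UTF-8 comma-separated files with a header row; weeks
are 1-based calendar indices.  Dialects:

* mate-choice events — ``trial_id, male_pop, female_pop`` (one row per first
  copulation);
* pre-tabulated pair tables — ``pop_a, pop_b, n_aa, n_ab, n_ba, n_bb``;
* no-choice records — ``experiment_id, cross_type, pair_id, week, embryos,
  hatchlings, parent_a_alive, parent_b_alive``;
* marker genotypes — ``individual_id, role, locus, allele_1, allele_2``
  (blank alleles = missing);
* phenotype matrices — ``pop_a, pop_b, phenotype_class``;
* trees — newick;
* models — JSON with ``rule``, ``ancestral`` and ``genotypes``.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from .compatibility import PhenotypeMatrix, RULES, RuleSet
from .hybridity import MarkerGenotypeSet
from .nochoice import CROSS_TYPES, ExperimentSet, NoChoicePairRecord
from .sexual_isolation import MateChoiceTrial, PairTable

__all__ = [
    "read_trial_events_csv",
    "read_pair_tables_csv",
    "write_pair_tables_csv",
    "read_nochoice_csv",
    "write_nochoice_csv",
    "read_markers_csv",
    "write_markers_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_model_json",
    "write_model_json",
    "write_json_report",
]


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_trial_events_csv(path, n_per_type: int = 10) -> dict:
    """Read per-event trial records, grouped into trials per population pair.

    Returns ``{(pop_a, pop_b): [MateChoiceTrial, ...]}`` with the pair
    inferred from the populations appearing in each trial's events (exactly
    two are required) and labels ordered alphabetically.
    """
    df = pd.read_csv(path, dtype=str)
    _require(df, ("trial_id", "male_pop", "female_pop"), path)
    out = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        pops = sorted(set(grp["male_pop"]) | set(grp["female_pop"]))
        if len(pops) > 2:
            raise ValueError(
                f"{path}: trial {trial_id} mixes more than two populations: {pops}"
            )
        if len(pops) < 2:
            raise ValueError(
                f"{path}: trial {trial_id} names only one population; "
                "the pair cannot be inferred"
            )
        events = tuple(zip(grp["male_pop"], grp["female_pop"]))
        trial = MateChoiceTrial(
            pop_a=pops[0], pop_b=pops[1], events=events, n_per_type=n_per_type
        )
        out.setdefault((pops[0], pops[1]), []).append(trial)
    return out


def read_pair_tables_csv(path) -> list:
    """Read pre-tabulated 2x2 pair tables, one per row."""
    df = pd.read_csv(path)
    _require(df, ("pop_a", "pop_b", "n_aa", "n_ab", "n_ba", "n_bb"), path)
    tables = []
    for i, row in df.iterrows():
        try:
            tables.append(
                PairTable(
                    str(row["pop_a"]),
                    str(row["pop_b"]),
                    int(row["n_aa"]),
                    int(row["n_ab"]),
                    int(row["n_ba"]),
                    int(row["n_bb"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return tables


def write_pair_tables_csv(tables, path) -> None:
    pd.DataFrame(
        [
            {
                "pop_a": t.pop_a,
                "pop_b": t.pop_b,
                "n_aa": t.n_aa,
                "n_ab": t.n_ab,
                "n_ba": t.n_ba,
                "n_bb": t.n_bb,
            }
            for t in tables
        ]
    ).to_csv(path, index=False)


def _bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "t", "yes")
    return bool(value)


def read_nochoice_csv(path) -> dict:
    """Read weekly no-choice records into experiment sets.

    Returns ``{experiment_id: ExperimentSet}``.  Both parents must be alive
    for a week to count as uncensored.
    """
    df = pd.read_csv(path)
    cols = (
        "experiment_id",
        "cross_type",
        "pair_id",
        "week",
        "embryos",
        "hatchlings",
        "parent_a_alive",
        "parent_b_alive",
    )
    _require(df, cols, path)
    bad = set(df["cross_type"]) - set(CROSS_TYPES)
    if bad:
        raise ValueError(f"{path}: unknown cross_type value(s): {sorted(bad)}")
    out = {}
    for exp_id, exp_grp in df.groupby("experiment_id", sort=True):
        sets = {c: [] for c in CROSS_TYPES}
        for (cross, pair_id), grp in exp_grp.groupby(
            ["cross_type", "pair_id"], sort=True
        ):
            grp = grp.sort_values("week")
            weeks = grp["week"].to_numpy()
            if not np.array_equal(weeks, np.arange(1, len(weeks) + 1)):
                raise ValueError(
                    f"{path}: pair {pair_id}: weeks must run 1..{len(weeks)} "
                    "without gaps"
                )
            alive = [
                _bool(a) and _bool(b)
                for a, b in zip(grp["parent_a_alive"], grp["parent_b_alive"])
            ]
            record = NoChoicePairRecord(
                pair_id=str(pair_id),
                cross=str(cross),
                embryos=tuple(int(e) for e in grp["embryos"]),
                hatchlings=tuple(int(h) for h in grp["hatchlings"]),
                alive=tuple(alive),
            )
            sets[cross].append(record)
        out[str(exp_id)] = ExperimentSet(
            label=str(exp_id),
            outcross=sets["outcross"],
            control_a=sets["control_a"],
            control_b=sets["control_b"],
        )
    return out


def write_nochoice_csv(experiments: Mapping, path) -> None:
    rows = []
    for exp_id, exp in experiments.items():
        for cross in CROSS_TYPES:
            for record in exp.records(cross):
                for w in range(record.weeks):
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "cross_type": cross,
                            "pair_id": record.pair_id,
                            "week": w + 1,
                            "embryos": record.embryos[w],
                            "hatchlings": record.hatchlings[w],
                            "parent_a_alive": record.alive[w],
                            "parent_b_alive": record.alive[w],
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerGenotypeSet:
    """Read a marker genotype table for one brood.

    Requires exactly one ``parent_a`` and one ``parent_b`` individual; every
    other row belongs to offspring.  Blank alleles mean missing data.
    """
    df = pd.read_csv(path, dtype=str)
    _require(df, ("individual_id", "role", "locus", "allele_1", "allele_2"), path)
    bad = set(df["role"]) - {"parent_a", "parent_b", "offspring"}
    if bad:
        raise ValueError(f"{path}: unknown role(s): {sorted(bad)}")

    def genotypes(grp) -> dict:
        out = {}
        for _, row in grp.iterrows():
            a1, a2 = row["allele_1"], row["allele_2"]
            if pd.isna(a1) or pd.isna(a2) or a1 == "" or a2 == "":
                out[row["locus"]] = None
            else:
                out[row["locus"]] = (str(a1), str(a2))
        return out

    parents = {}
    for role in ("parent_a", "parent_b"):
        grp = df[df["role"] == role]
        if grp["individual_id"].nunique() != 1:
            raise ValueError(f"{path}: expected exactly one {role} individual")
        parents[role] = genotypes(grp)
    off = df[df["role"] == "offspring"]
    ids = sorted(off["individual_id"].unique())
    offspring = [genotypes(off[off["individual_id"] == i]) for i in ids]
    return MarkerGenotypeSet(
        parent_a=parents["parent_a"],
        parent_b=parents["parent_b"],
        offspring=offspring,
        offspring_ids=ids,
    )


def write_markers_csv(markers: MarkerGenotypeSet, path) -> None:
    rows = []

    def emit(ind_id, role, genotypes):
        for locus, g in genotypes.items():
            a1, a2 = ("", "") if g is None else g
            rows.append(
                {
                    "individual_id": ind_id,
                    "role": role,
                    "locus": locus,
                    "allele_1": a1,
                    "allele_2": a2,
                }
            )

    emit("PA", "parent_a", markers.parent_a)
    emit("PB", "parent_b", markers.parent_b)
    for ind_id, geno in zip(markers.offspring_ids, markers.offspring):
        emit(ind_id, "offspring", geno)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrix_csv(path, kind: str) -> PhenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    _require(df, ("pop_a", "pop_b", "phenotype_class"), path)
    classes = {
        (row["pop_a"], row["pop_b"]): row["phenotype_class"]
        for _, row in df.iterrows()
    }
    return PhenotypeMatrix(kind, classes)


def write_matrix_csv(matrix: PhenotypeMatrix, path) -> None:
    pd.DataFrame(
        [
            {"pop_a": a, "pop_b": b, "phenotype_class": cls}
            for (a, b), cls in matrix.pairs()
        ]
    ).to_csv(path, index=False)


def read_model_json(path):
    """Read a compatibility model: returns ``(rule, genotypes, ancestral)``."""
    with open(path) as fh:
        spec = json.load(fh)
    for key in ("rule", "genotypes"):
        if key not in spec:
            raise ValueError(f"{path}: model JSON lacks key {key!r}")
    rule_name = spec["rule"]
    if rule_name not in RULES:
        raise ValueError(
            f"{path}: unknown rule {rule_name!r}; known: {sorted(RULES)}"
        )
    genotypes = {
        pop: {locus: str(allele) for locus, allele in loci.items()}
        for pop, loci in spec["genotypes"].items()
    }
    return RULES[rule_name], genotypes, str(spec.get("ancestral", "1"))


def write_model_json(rule: RuleSet, genotypes: Mapping, path, ancestral="1") -> None:
    with open(path, "w") as fh:
        json.dump(
            {"rule": rule.name, "ancestral": ancestral, "genotypes": genotypes},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def write_json_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
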