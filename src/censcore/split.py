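"""Dataset curation: affinity-qualifier filtering and cluster-aware k-folds.

Affinity annotations are kept when measured precisely ("=") or approximately
("~"); weaker-than (">") entries are dropped as ambiguous, and stronger-than
("<") entries are kept only when the bound is at most 1 uM (trained on as
exact values). Cross-validation folds are built on sequence clusters so that
no cluster ever straddles two folds, with greedy size balancing (largest
cluster first into the currently smallest fold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import AffinityRecord

__all__ = ["SplitPlan", "filter_affinities", "remove_ambiguous_cluster_entries",
           "clustered_kfold", "read_affinity_table", "read_cluster_table"]

WEAK_BOUND_MOLAR = 1e-6  # "<" entries retained at or below 1 uM


@dataclass
class SplitPlan:
    """Entry-to-fold assignment with cluster provenance and removal log."""

    fold_of_entry: dict[str, int]
    cluster_of_entry: dict[str, object]
    removed_entries: list[tuple[str, str]] = field(default_factory=list)
    k: int = 0
    seed: int = 0

    def fold_entries(self, fold: int) -> list[str]:
        return sorted(e for e, f in self.fold_of_entry.items() if f == fold)

    def validate(self) -> None:
        clusters_per_fold: dict[int, set] = {}
        for entry, fold in self.fold_of_entry.items():
            clusters_per_fold.setdefault(fold, set()).add(self.cluster_of_entry[entry])
        folds = sorted(clusters_per_fold)
        for i in folds:
            for j in folds:
                if i < j and clusters_per_fold[i] & clusters_per_fold[j]:
                    raise AssertionError(f"cluster straddles folds {i} and {j}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k, "seed": self.seed,
            "fold_of_entry": self.fold_of_entry,
            "cluster_of_entry": {k: str(v) for k, v in self.cluster_of_entry.items()},
            "removed_entries": self.removed_entries}, indent=1))


def filter_affinities(records: list[AffinityRecord]) -> list[AffinityRecord]:
    """Keep "=" and "~" entries; drop ">"; keep "<" iff the bound is <= 1 uM.

    Order-independent and idempotent; unknown qualifiers raise at record
    construction.
    """
    kept = []
    for rec in records:
        if rec.qualifier in {"=", "~"}:
            kept.append(rec)
        elif rec.qualifier == "<" and rec.value <= WEAK_BOUND_MOLAR:
            kept.append(rec)
    return kept


def remove_ambiguous_cluster_entries(
        entries: list[str],
        cluster_table: dict[str, list]) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop entries whose chains map to two or more distinct clusters.

    ``cluster_table`` maps an entry id to the cluster ids of its chains.
    Entries absent from the table are removed with reason "unclustered".
    """
    retained, removed = [], []
    for entry in entries:
        clusters = set(cluster_table.get(entry, []))
        if not clusters:
            removed.append((entry, "unclustered"))
        elif len(clusters) > 1:
            removed.append((entry, f"multi-cluster:{sorted(map(str, clusters))}"))
        else:
            retained.append(entry)
    return retained, removed


def clustered_kfold(entries: list[str], cluster_of_entry: dict[str, object],
                    k: int, seed: int = 0) -> SplitPlan:
    """Assign whole clusters to folds, greedily balancing fold sizes.

    Clusters are sorted by size (largest first; ties broken by a seeded
    shuffle, reproducibly) and each is placed into the currently smallest
    fold. Every entry must be clustered.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    missing = [e for e in entries if e not in cluster_of_entry]
    if missing:
        raise ValueError(f"unclustered entries: {missing[:3]}")
    members: dict[object, list[str]] = {}
    for entry in entries:
        members.setdefault(cluster_of_entry[entry], []).append(entry)
    if len(members) < k:
        raise ValueError(f"only {len(members)} clusters for k={k} folds")

    rng = np.random.default_rng(seed)
    cluster_ids = sorted(members, key=str)
    rng.shuffle(cluster_ids)
    cluster_ids.sort(key=lambda c: -len(members[c]))  # stable: keeps shuffled tie order

    fold_sizes = [0] * k
    fold_of_entry: dict[str, int] = {}
    for cid in cluster_ids:
        fold = int(np.argmin(fold_sizes))
        for entry in members[cid]:
            fold_of_entry[entry] = fold
        fold_sizes[fold] += len(members[cid])
    plan = SplitPlan(fold_of_entry=fold_of_entry,
                     cluster_of_entry={e: cluster_of_entry[e] for e in entries},
                     k=k, seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Tables

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9,
                  "pM": 1e-12, "fM": 1e-15}


def read_affinity_table(path) -> list[AffinityRecord]:
    """TSV with columns entry_id, measure, qualifier, value, unit."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        unit = str(row.unit)
        if unit not in _UNIT_TO_MOLAR:
            raise ValueError(f"{row.entry_id}: unknown unit {unit!r}")
        records.append(AffinityRecord(entry_id=str(row.entry_id),
                                      measure=str(row.measure),
                                      qualifier=str(row.qualifier),
                                      value=float(row.value) * _UNIT_TO_MOLAR[unit]))
    return records


def read_cluster_table(path) -> dict[str, list]:
    """TSV with columns entry_id (or entry_id:chain) and cluster_id."""
    df = pd.read_csv(path, sep="\t")
    table: dict[str, list] = {}
    for row in df.itertuples(index=False):
        entry = str(row.entry_id).split(":")[0]
        table.setdefault(entry, []).append(row.cluster_id)
    return table
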