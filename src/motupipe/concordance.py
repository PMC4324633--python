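"""Agreement between genotypic clusters (MOTUs) and morpho-species labels.

Reverse taxonomy delimits units genetically first; the quality control is
whether the genotypic clusters coincide with the phenotypic clusters
(morpho-species) assigned afterwards.  Only MOTUs represented by more than
one specimen enter the comparison (a singleton constrains nothing), and
members without a usable label ("species indet", damaged vouchers) are
skipped with a warning.

A multi-member MOTU is *concordant* when all its labeled members share one
morpho-label AND that label occurs in no other multi-member MOTU
(one-to-one matching; a weaker purity-only notion would mask lumping).  A
MOTU whose members carry several labels is *lumped*; a pure MOTU whose
label spans several MOTUs is *split* (a morpho-species divided into deep
genetic lineages -- the classic cryptic-species signature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterConfig, MotuTable, greedy_cluster
from .seq_io import SequenceRecord

__all__ = ["ConcordanceReport", "compare_partitions", "threshold_sweep"]

INDET_LABELS = {"", "species indet", "indet", "na", "n/a"}


@dataclass
class ConcordanceReport:
    verdicts: dict[int, str]  # cluster_id -> concordant | split | lumped
    n_concordant: int
    n_split: int
    n_lumped: int
    ari: float
    conflicts: list[tuple[int, str]] = field(default_factory=list)
    n_skipped_members: int = 0

    @property
    def n_examined(self) -> int:
        return len(self.verdicts)

    def summary_text(self) -> str:
        lines = [
            f"{self.n_examined} multi-member MOTUs examined: "
            f"{self.n_concordant} concordant, {self.n_split} split, "
            f"{self.n_lumped} lumped (ARI {self.ari:.3f})"
        ]
        for cid, why in self.conflicts:
            lines.append(f"  cluster {cid}: {why}")
        return "\n".join(lines)


def _usable(label: str | None) -> bool:
    return label is not None and label.strip().lower() not in INDET_LABELS


def compare_partitions(
    motus: MotuTable, labels: Mapping[str, str | None]
) -> ConcordanceReport:
    """Score genotypic vs phenotypic partitions over multi-member MOTUs."""
    multi = [c for c in motus.clusters if c.size > 1]
    member_labels: dict[int, list[str]] = {}
    skipped = 0
    for c in multi:
        lab = []
        for m in c.member_ids:
            l = labels.get(m)
            if _usable(l):
                lab.append(l.strip())
            else:
                skipped += 1
        member_labels[c.cluster_id] = lab
    if skipped:
        warnings.warn(f"{skipped} members without usable morpho-label skipped")

    # which labels occur in which multi-member MOTUs
    label_clusters: dict[str, set[int]] = {}
    for cid, labs in member_labels.items():
        for l in set(labs):
            label_clusters.setdefault(l, set()).add(cid)

    verdicts: dict[int, str] = {}
    conflicts: list[tuple[int, str]] = []
    for c in multi:
        labs = member_labels[c.cluster_id]
        uniq = sorted(set(labs))
        if not uniq:
            continue  # nothing labeled -> no verdict possible
        if len(uniq) > 1:
            verdicts[c.cluster_id] = "lumped"
            conflicts.append(
                (c.cluster_id, f"members span morpho-labels {uniq} (lumped)")
            )
        elif len(label_clusters[uniq[0]]) > 1:
            verdicts[c.cluster_id] = "split"
            others = sorted(label_clusters[uniq[0]] - {c.cluster_id})
            conflicts.append(
                (
                    c.cluster_id,
                    f"morpho-species {uniq[0]!r} also in cluster(s) {others} (split)",
                )
            )
        else:
            verdicts[c.cluster_id] = "concordant"

    # ARI over labeled members of multi-member MOTUs
    assign = motus.assignment()
    ids = [
        m
        for c in multi
        for m in c.member_ids
        if _usable(labels.get(m))
    ]
    if ids:
        ari = float(
            adjusted_rand_score(
                [labels[m].strip() for m in ids], [assign[m] for m in ids]
            )
        )
    else:
        ari = float("nan")
    counts = pd.Series(list(verdicts.values()))
    return ConcordanceReport(
        verdicts=verdicts,
        n_concordant=int((counts == "concordant").sum()) if len(counts) else 0,
        n_split=int((counts == "split").sum()) if len(counts) else 0,
        n_lumped=int((counts == "lumped").sum()) if len(counts) else 0,
        ari=ari,
        conflicts=conflicts,
        n_skipped_members=skipped,
    )


def threshold_sweep(
    records: Sequence[SequenceRecord],
    labels: Mapping[str, str | None],
    thresholds: Sequence[float] = (0.97, 0.90, 0.80),
    min_overlap: int = 400,
) -> pd.DataFrame:
    """Re-cluster at each threshold and score concordance.

    Thresholds must be in (0, 1], descending; the cluster count is monotone
    non-increasing down the sweep.  Returns a table with columns
    threshold, n_clusters, n_multi, ari, n_concordant, n_split, n_lumped.
    """
    ts = list(thresholds)
    if any(not 0 < t <= 1 for t in ts):
        raise ValueError("thresholds must lie in (0, 1]")
    if ts != sorted(ts, reverse=True):
        raise ValueError("thresholds must be descending")
    rows = []
    for t in ts:
        motus = greedy_cluster(
            records, ClusterConfig(threshold=t, min_overlap=min_overlap)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compare_partitions(motus, labels)
        rows.append(
            {
                "threshold": t,
                "n_clusters": motus.n_motus,
                "n_multi": sum(1 for c in motus.clusters if c.size > 1),
                "ari": rep.ari,
                "n_concordant": rep.n_concordant,
                "n_split": rep.n_split,
                "n_lumped": rep.n_lumped,
            }
        )
    return pd.DataFrame(rows)
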