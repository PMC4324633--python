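"""Pairwise alignment-based identity and evolutionary distances.

Distances are computed from pairwise-aligned columns with *pairwise
deletion*: only columns where both entries are unambiguous bases (A/C/G/T)
are compared; gaps and IUPAC ambiguity codes never count as matches and are
excluded from site counts.

Two distances are exposed:

* uncorrected p-distance, the proportion of differing compared sites, and
* the Kimura 2-parameter (K2P) distance, which corrects for multiple hits
  separately for transitions (proportion P) and transversions (Q):

      d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Saturated pairs (1-2P-Q <= 0 or 1-2Q <= 0) get a NaN sentinel; downstream
consumers (e.g. neighbor joining) refuse matrices containing sentinels.

Identity follows the greedy-clustering convention: the number of identical
unambiguous columns divided by the unambiguous length of the *shorter*
sequence, so a short fragment nested in a longer sequence can still reach
identity 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seq_io import SequenceRecord, UNAMBIGUOUS

__all__ = [
    "Scoring",
    "AlignedPair",
    "SiteCounts",
    "DistanceMatrix",
    "align_pair",
    "pair_from_columns",
    "pairs_from_msa",
    "site_counts",
    "pairwise_identity",
    "p_distance",
    "k2p_distance",
    "k2p_from_pair",
    "build_distance_matrix",
    "group_mean_distances",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class Scoring:
    """Global-alignment scoring (match, mismatch, affine gap)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class AlignedPair:
    """Columns of one pairwise alignment.

    ``a`` and ``b`` are equal-length gapped strings; ``overlap`` counts the
    columns where both entries are unambiguous bases.
    """

    a: str
    b: str
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned strings must have equal length")

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.a, self.b))

    @property
    def overlap(self) -> int:
        return sum(
            1 for x, y in zip(self.a, self.b) if x in UNAMBIGUOUS and y in UNAMBIGUOUS
        )


@dataclass(frozen=True)
class SiteCounts:
    """Compared-site and substitution counts of one aligned pair."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites if self.n_sites else math.nan

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites if self.n_sites else math.nan


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_pair(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = Scoring(),
) -> AlignedPair:
    """Global (Needleman-Wunsch, affine-gap) alignment of two sequences.

    Gaps are stripped from the inputs first; the first optimal alignment
    reported by the engine is used, so the result is deterministic for a
    fixed input.
    """
    sa = a.ungapped() if isinstance(a, SequenceRecord) else a.upper().replace("-", "")
    sb = b.ungapped() if isinstance(b, SequenceRecord) else b.upper().replace("-", "")
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    aln = aligner.align(sa, sb)[0]
    return AlignedPair(a=str(aln[0]), b=str(aln[1]), score=aln.score)


def pair_from_columns(a: str, b: str) -> AlignedPair:
    """Wrap two pre-aligned (gapped) strings as an AlignedPair."""
    return AlignedPair(a=a.upper(), b=b.upper())


def pairs_from_msa(
    msa: Mapping[str, str], id_a: str, id_b: str
) -> AlignedPair:
    """Extract the pairwise columns of two sequences from a multiple alignment.

    Columns gapped in both sequences are dropped.
    """
    ga, gb = msa[id_a].upper(), msa[id_b].upper()
    if len(ga) != len(gb):
        raise ValueError("MSA rows differ in length")
    keep = [(x, y) for x, y in zip(ga, gb) if not (x in "-." and y in "-.")]
    return AlignedPair(a="".join(x for x, _ in keep), b="".join(y for _, y in keep))


def site_counts(pair: AlignedPair) -> SiteCounts:
    """Count compared sites, transitions and transversions (pairwise deletion)."""
    n = ts = tv = 0
    for x, y in zip(pair.a, pair.b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            n += 1
            if x != y:
                if (x, y) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    return SiteCounts(n_sites=n, n_transitions=ts, n_transversions=tv)


def pairwise_identity(pair: AlignedPair) -> tuple[float, int]:
    """(identity, overlap) of an aligned pair.

    identity = identical unambiguous columns / unambiguous length of the
    shorter sequence.  Zero overlap yields NaN (treated as below any
    threshold by callers).
    """
    matches = sum(
        1
        for x, y in zip(pair.a, pair.b)
        if x == y and x in UNAMBIGUOUS
    )
    denom = min(
        sum(1 for c in pair.a if c in UNAMBIGUOUS),
        sum(1 for c in pair.b if c in UNAMBIGUOUS),
    )
    overlap = pair.overlap
    if denom == 0 or overlap == 0:
        return math.nan, overlap
    return matches / denom, overlap


def p_distance(pair: AlignedPair) -> float:
    """Uncorrected proportion of differing compared sites (NaN if none)."""
    c = site_counts(pair)
    if c.n_sites == 0:
        return math.nan
    return (c.n_transitions + c.n_transversions) / c.n_sites


def k2p_distance(c: SiteCounts) -> float:
    """Kimura 2-parameter distance from site counts; NaN when saturated."""
    if c.n_sites == 0:
        return math.nan
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_from_pair(pair: AlignedPair) -> float:
    return k2p_distance(site_counts(pair))


# ---------------------------------------------------------------------------
# Labeled matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Labeled symmetric matrix over sequences or samples.

    ``kind`` is "distance" (zero diagonal) or "similarity" (unit diagonal).
    NaN entries are the sentinel for undefined values (e.g. saturated K2P
    pairs); symmetry and the diagonal are validated on construction.
    """

    def __init__(
        self,
        labels: Sequence[str],
        values,
        metric_name: str = "",
        kind: str = "distance",
    ) -> None:
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        diag_target = 0.0 if kind == "distance" else 1.0
        if not np.allclose(np.diag(values), diag_target):
            raise ValueError(f"diagonal must be {diag_target} for kind={kind!r}")
        with np.errstate(invalid="ignore"):
            if kind == "distance" and np.any(values < 0):
                raise ValueError("negative distances")
        self.labels = labels
        self.values = values
        self.metric_name = metric_name
        self.kind = kind
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._index[pair[0]], self._index[pair[1]]
        return float(self.values[i, j])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        ii, jj = np.where(np.isnan(self.values))
        for i, j in zip(ii, jj):
            if i < j:
                out.append((self.labels[i], self.labels[j]))
        return out

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (i>j) order."""
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, metric_name: str = "", kind: str = "distance"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.values, metric_name, kind)

    def to_skbio(self):
        import skbio

        if self.has_undefined:
            raise ValueError("matrix contains undefined (NaN) entries")
        return skbio.DistanceMatrix(self.values, ids=self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.metric_name, self.kind
        )


_METRICS: dict[str, Callable[[AlignedPair], float]] = {
    "p": p_distance,
    "k2p": k2p_from_pair,
    "identity_complement": lambda pair: 1.0 - pairwise_identity(pair)[0],
}

# A,C,G,T -> 0..3; ambiguity/gap -> 255.  With this coding the two
# transition pairs (A<->G, C<->T) are exactly the mismatches differing by 2.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _equal_length_matrix(seqs: list[str], metric: str) -> np.ndarray:
    """Vectorized all-pairs p/K2P/identity over equal-length ungapped sequences."""
    x = np.vstack(
        [_ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in seqs]
    )
    good = x != 255
    n = len(seqs)
    vals = np.zeros((n, n))
    n_good = good.sum(axis=1)
    for i in range(n - 1):
        a, ga = x[i], good[i]
        b, gb = x[i + 1 :], good[i + 1 :]
        both = ga[None, :] & gb
        n_sites = both.sum(axis=1)
        mism = (a[None, :] != b) & both
        if metric == "p":
            with np.errstate(invalid="ignore"):
                d = np.where(n_sites > 0, mism.sum(axis=1) / n_sites, np.nan)
        elif metric == "k2p":
            ts = (np.abs(a.astype(np.int16)[None, :] - b.astype(np.int16)) == 2) & mism
            with np.errstate(invalid="ignore", divide="ignore"):
                P = ts.sum(axis=1) / n_sites
                Q = (mism.sum(axis=1) - ts.sum(axis=1)) / n_sites
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                d = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                    - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                    np.nan,
                )
                d = np.where(n_sites > 0, d, np.nan)
        elif metric == "identity_complement":
            matches = ((a[None, :] == b) & both).sum(axis=1)
            denom = np.minimum(n_good[i], n_good[i + 1 :])
            with np.errstate(invalid="ignore"):
                d = np.where(denom > 0, 1.0 - matches / denom, np.nan)
        else:  # pragma: no cover
            raise ValueError(metric)
        vals[i, i + 1 :] = d
        vals[i + 1 :, i] = d
    return vals


def build_distance_matrix(
    records: Sequence[SequenceRecord],
    metric: str = "p",
    msa: Mapping[str, str] | None = None,
    scoring: Scoring = Scoring(),
) -> DistanceMatrix:
    """All-pairs distance matrix under one metric ("p", "k2p", "identity_complement").

    If ``msa`` is given, pairwise columns come from the multiple alignment;
    otherwise each pair is aligned internally (equal-length ungapped pairs
    are compared column-wise directly, which is the global alignment when no
    indels separate them; unequal lengths go through the affine-gap
    aligner).  The two modes are never mixed within one matrix.  Undefined
    pairs are recorded as NaN with a warning.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    fn = _METRICS[metric]
    n = len(records)
    undefined = []
    ungapped = [r.ungapped() for r in records]
    if msa is None and len(set(map(len, ungapped))) == 1:
        vals = _equal_length_matrix(ungapped, metric)
        ii, jj = np.where(np.isnan(np.triu(vals, k=1)))
        undefined = [
            (records[i].id, records[j].id) for i, j in zip(ii, jj) if i < j
        ]
    else:
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if msa is not None:
                    pair = pairs_from_msa(msa, records[i].id, records[j].id)
                else:
                    pair = align_pair(records[i], records[j], scoring)
                d = fn(pair)
                vals[i, j] = vals[j, i] = d
                if math.isnan(d):
                    undefined.append((records[i].id, records[j].id))
    if undefined:
        warnings.warn(
            f"{len(undefined)} undefined {metric} pairs (sentinel NaN recorded), "
            f"first: {undefined[0]}"
        )
    return DistanceMatrix([r.id for r in records], vals, metric_name=metric)


def group_mean_distances(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Within- and between-group mean distances, in percent.

    Returns a square DataFrame over groups: the diagonal holds within-group
    means (average over unordered intra-group pairs; NaN for singleton
    groups, the blank cells of a published distance table), off-diagonals
    hold means over all cross-group pairs.
    """
    missing = [l for l in dm.labels if l not in labels]
    if missing:
        raise ValueError(f"unlabeled ids: {missing[:5]}")
    groups = sorted(set(labels[l] for l in dm.labels))
    gidx = {g: [i for i, l in enumerate(dm.labels) if labels[l] == g] for g in groups}
    out = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for gi, g in enumerate(groups):
        for h in groups[gi:]:
            if g == h:
                idx = gidx[g]
                if len(idx) < 2:
                    out.loc[g, g] = math.nan
                    continue
                pairs = [
                    dm.values[a, b]
                    for k, a in enumerate(idx)
                    for b in idx[k + 1 :]
                ]
            else:
                pairs = [dm.values[a, b] for a in gidx[g] for b in gidx[h]]
            mean = float(np.nanmean(pairs)) * 100.0
            out.loc[g, h] = mean
            out.loc[h, g] = mean
    return out
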