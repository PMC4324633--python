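"""Sequence, station-table and tree I/O plus pseudogene screening.

The pipeline works on COI barcode fragments (~400-660 bp) carried as
:class:`SequenceRecord` objects: the bare FASTA record plus the specimen
metadata (taxon group, sampling station, optional morpho-species label) that
every downstream stage needs.  Stations live in a :class:`StationRecord`
table mirroring a cruise station list (license area, coordinates, depth).

Nuclear copies of mitochondrial genes (pseudogenes) are screened out the
standard way: a genuine COI fragment translates without internal stop codons
in at least one forward reading frame under the invertebrate mitochondrial
code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "StationRecord",
    "SampleMap",
    "read_fasta",
    "write_fasta",
    "read_sequence_metadata",
    "join_metadata",
    "read_station_table",
    "write_station_table",
    "screen_pseudogenes",
    "read_newick",
    "write_newick",
    "TAXON_GROUPS",
    "INVERTEBRATE_MITO_TABLE",
]

TAXON_GROUPS = ("polychaete", "isopod", "other")

#: NCBI translation table 5 (invertebrate mitochondrial).
INVERTEBRATE_MITO_TABLE = 5

GAP_CHARS = set("-.")
IUPAC_DNA = set("ACGTRYSWKMBDHVN") | GAP_CHARS
UNAMBIGUOUS = set("ACGT")

STATION_COLUMNS = ("station_id", "license_area", "latitude", "longitude", "depth_m")


@dataclass
class SequenceRecord:
    """One COI sequence plus its specimen metadata."""

    id: str
    residues: str
    taxon_group: str = "other"
    station_id: str | None = None
    morpho_label: str | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.length < 1:
            raise ValueError(f"record {self.id!r}: no non-gap residues")

    @property
    def length(self) -> int:
        """Number of non-gap characters."""
        return sum(1 for c in self.residues if c not in GAP_CHARS)

    @property
    def n_unambiguous(self) -> int:
        """Number of unambiguous (A/C/G/T) residues."""
        return sum(1 for c in self.residues if c in UNAMBIGUOUS)

    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)


@dataclass(frozen=True)
class StationRecord:
    """One epibenthic-sledge deployment (station)."""

    station_id: str
    license_area: str
    latitude: float
    longitude: float
    depth_m: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"station {self.station_id!r}: latitude {self.latitude} out of [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"station {self.station_id!r}: longitude {self.longitude} out of [-180, 180]"
            )
        if not self.depth_m > 0:
            raise ValueError(f"station {self.station_id!r}: depth must be positive")


@dataclass
class SampleMap:
    """Plumbing between sequences, stations and license areas.

    Every sequence id maps to exactly one station, every station to exactly
    one license area.
    """

    station_of: dict[str, str] = field(default_factory=dict)
    area_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls, records: Iterable[SequenceRecord], stations: Iterable[StationRecord]
    ) -> "SampleMap":
        area_of = {s.station_id: s.license_area for s in stations}
        station_of: dict[str, str] = {}
        for rec in records:
            if rec.station_id is None:
                raise ValueError(f"record {rec.id!r} has no station_id")
            if rec.station_id not in area_of:
                raise ValueError(
                    f"record {rec.id!r}: unknown station {rec.station_id!r}"
                )
            station_of[rec.id] = rec.station_id
        return cls(station_of=station_of, area_of=area_of)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords, in file order.

    The record id is the header token up to the first whitespace.  Metadata
    fields are left at their defaults until joined with a metadata table.
    Duplicate ids and empty sequences are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def read_sequence_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sequence metadata table (id, taxon_group, station_id, morpho_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "taxon_group", "station_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sequence metadata {path}: missing columns {sorted(missing)}")
    if "morpho_label" not in df.columns:
        df["morpho_label"] = ""
    return df


def join_metadata(
    records: Sequence[SequenceRecord], meta: pd.DataFrame
) -> list[SequenceRecord]:
    """Attach taxon_group/station_id/morpho_label to records by id."""
    by_id = meta.set_index("id")
    if by_id.index.has_duplicates:
        dups = by_id.index[by_id.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids in metadata: {dups}")
    out = []
    for rec in records:
        if rec.id not in by_id.index:
            raise KeyError(f"no metadata row for sequence {rec.id!r}")
        row = by_id.loc[rec.id]
        out.append(
            replace(
                rec,
                taxon_group=row["taxon_group"] or "other",
                station_id=row["station_id"] or None,
                morpho_label=row["morpho_label"] or None,
            )
        )
    return out


def read_station_table(path: str | Path) -> list[StationRecord]:
    """Read the station table (TSV/CSV with a header).

    Expected columns: station_id, license_area, latitude, longitude, depth_m.
    Longitudes are signed decimal degrees (west negative).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station table {path}: missing columns {sorted(missing)}")
    stations = []
    for i, row in df.iterrows():
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
            depth = float(row["depth_m"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"station table {path}, row {i + 1}: non-numeric value ({exc})")
        stations.append(
            StationRecord(
                station_id=str(row["station_id"]),
                license_area=str(row["license_area"]),
                latitude=lat,
                longitude=lon,
                depth_m=depth,
            )
        )
    ids = [s.station_id for s in stations]
    if len(set(ids)) != len(ids):
        raise ValueError(f"station table {path}: duplicate station ids")
    return stations


def write_station_table(stations: Iterable[StationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "station_id": s.station_id,
                "license_area": s.license_area,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "depth_m": s.depth_m,
            }
            for s in stations
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pseudogene screen
# ---------------------------------------------------------------------------

def _internal_stops(protein: str) -> int:
    """Stops before the final codon of the frame."""
    if not protein:
        return 0
    internal = protein[:-1]
    return internal.count("*")


def screen_pseudogenes(
    records: Sequence[SequenceRecord],
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, dict[int, int]]]]:
    """Split records into (pass, fail) by the stop-codon screen.

    Each record is translated in the three forward reading frames (gaps
    stripped first); it passes if at least one frame contains no internal
    stop codon.  Failures are returned with the per-frame internal stop
    counts.  Reverse-complement frames are not tried: PCR primers fix the
    orientation of barcode reads.
    """
    passed: list[SequenceRecord] = []
    failed: list[tuple[SequenceRecord, dict[int, int]]] = []
    for rec in records:
        seq = rec.ungapped()
        if len(seq) < 3:
            failed.append((rec, {0: -1, 1: -1, 2: -1}))
            continue
        stops: dict[int, int] = {}
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                stops[frame] = -1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partial-codon warnings
                prot = str(Seq(sub).translate(table=genetic_code))
            stops[frame] = _internal_stops(prot)
        if any(v == 0 for v in stops.values()):
            passed.append(rec)
        else:
            failed.append((rec, stops))
    return passed, failed


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path_or_handle) -> TreeNode:
    """Read a newick tree (scikit-bio TreeNode)."""
    return TreeNode.read(str(path_or_handle) if isinstance(path_or_handle, Path) else path_or_handle, format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
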