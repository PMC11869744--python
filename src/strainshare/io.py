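"""Readers and writers for the pipeline's tabular formats.

All formats are plain TSV/CSV:

* allele profiles: ``sample_id  species_id  scaffold  position  A  C  G  T``
  (one row per covered site; positions 0-based within the scaffold), with a
  genome-length sidecar ``species_id  scaffold  length``. Multi-scaffold
  genomes are concatenated in sidecar order into 0-based per-genome
  coordinates.
* sample metadata: ``sample_id  host_id  date  group  role  timepoint
  designated_donor`` (ISO-8601 dates, empty fields for n/a).
* taxon annotations: ``species_id  family  genus  oxygen  host_range``.
* dyads: ``sample_a  sample_b  category``; square distance matrices as
  labelled TSV; diet as ``group  year  food_type  proportion``; rainfall as
  ``date,millimeters`` CSV; simulation truth as ``sample_id  species_id
  strain_label  origin  source_sample``.

An inStrain-style SNV table (columns scaffold, position, A, C, G, T) can be
ingested per sample via :func:`read_instrain_snvs`.
"""

from __future__ import annotations

import csv
import datetime as dt
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .profiles import AlleleProfile, PairwiseComparison, PresenceCall
from .sharing import SampleRecord
from .enrichment import TaxonAnnotation


class TableFormatError(ValueError):
    """A malformed row, reported with its line number."""


def write_genome_lengths(
    lengths: Mapping[str, int] | Mapping[str, Mapping[str, int]], path: str | Path
) -> None:
    """Sidecar table. Values may be plain ints (single scaffold named after
    the species) or scaffold->length mappings."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_id", "scaffold", "length"])
        for species, value in lengths.items():
            if isinstance(value, Mapping):
                for scaffold, length in value.items():
                    w.writerow([species, scaffold, length])
            else:
                w.writerow([species, species, value])


def read_genome_lengths(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """species -> ordered [(scaffold, offset, length)]; offsets are cumulative."""
    out: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["species_id", "scaffold", "length"]:
            raise TableFormatError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                species, scaffold, length = row[0], row[1], int(row[2])
            except (IndexError, ValueError) as err:
                raise TableFormatError(f"{path}:{lineno}: {row!r}: {err}") from err
            if length <= 0:
                raise TableFormatError(f"{path}:{lineno}: non-positive length")
            offset = sum(entry[2] for entry in out[species])
            out[species].append((scaffold, offset, length))
    return dict(out)


def write_profile_table(profiles: Iterable[AlleleProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "species_id", "scaffold", "position", "A", "C", "G", "T"])
        for p in profiles:
            for pos, counts in zip(p.positions, p.counts):
                w.writerow([p.sample_id, p.species_id, p.species_id, int(pos), *map(int, counts)])


def read_profile_table(
    path: str | Path, genome_lengths_path: str | Path
) -> list[AlleleProfile]:
    """Read and validate an allele-profile table.

    Malformed rows (unknown species/scaffold, negative counts, position at
    or beyond the scaffold length) raise :class:`TableFormatError` naming the
    offending line.
    """
    scaffolds = read_genome_lengths(genome_lengths_path)
    genome_length = {sp: sum(e[2] for e in entries) for sp, entries in scaffolds.items()}
    offsets = {
        (sp, scaffold): (offset, length)
        for sp, entries in scaffolds.items()
        for scaffold, offset, length in entries
    }
    acc: dict[tuple[str, str], list[tuple[int, tuple[int, int, int, int]]]] = defaultdict(list)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        expected = ["sample_id", "species_id", "scaffold", "position", "A", "C", "G", "T"]
        if header != expected:
            raise TableFormatError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                sample, species, scaffold = row[0], row[1], row[2]
                pos = int(row[3])
                counts = tuple(int(c) for c in row[4:8])
            except (IndexError, ValueError) as err:
                raise TableFormatError(f"{path}:{lineno}: {row!r}: {err}") from err
            if species not in genome_length:
                raise TableFormatError(
                    f"{path}:{lineno}: unknown species {species!r}"
                )
            if (species, scaffold) not in offsets:
                raise TableFormatError(
                    f"{path}:{lineno}: unknown scaffold {scaffold!r} for {species!r}"
                )
            offset, length = offsets[(species, scaffold)]
            if not 0 <= pos < length:
                raise TableFormatError(
                    f"{path}:{lineno}: position {pos} outside scaffold of length {length}"
                )
            if any(c < 0 for c in counts):
                raise TableFormatError(f"{path}:{lineno}: negative base count")
            acc[(sample, species)].append((offset + pos, counts))

    profiles = []
    for (sample, species), rows in sorted(acc.items()):
        rows.sort(key=lambda r: r[0])
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        counts = np.array([r[1] for r in rows], dtype=np.int64)
        profiles.append(
            AlleleProfile(sample, species, genome_length[species], positions, counts)
        )
    return profiles


def read_instrain_snvs(
    path: str | Path,
    genome_lengths_path: str | Path,
    sample_id: str,
) -> list[AlleleProfile]:
    """Ingest a per-sample inStrain-style SNV table.

    Dialect: a TSV with at least the columns ``scaffold``, ``position``
    (0-based within scaffold) and per-base read counts ``A``, ``C``, ``G``,
    ``T``; extra columns are ignored. Scaffolds are assigned to species via
    the genome-length sidecar, so only positions with reported allele counts
    contribute (typical of SNV tables, which omit invariant sites).
    """
    scaffolds = read_genome_lengths(genome_lengths_path)
    genome_length = {sp: sum(e[2] for e in entries) for sp, entries in scaffolds.items()}
    scaffold_map = {
        scaffold: (sp, offset, length)
        for sp, entries in scaffolds.items()
        for scaffold, offset, length in entries
    }
    df = pd.read_csv(path, sep="\t")
    required = {"scaffold", "position", "A", "C", "G", "T"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: inStrain SNV table needs columns {sorted(required)}"
        )
    acc: dict[str, list[tuple[int, tuple[int, int, int, int]]]] = defaultdict(list)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        scaffold = getattr(row, "scaffold")
        if scaffold not in scaffold_map:
            raise TableFormatError(f"{path}:{i}: unknown scaffold {scaffold!r}")
        species, offset, length = scaffold_map[scaffold]
        pos = int(getattr(row, "position"))
        if not 0 <= pos < length:
            raise TableFormatError(f"{path}:{i}: position {pos} outside scaffold")
        counts = tuple(int(getattr(row, b)) for b in "ACGT")
        if any(c < 0 for c in counts):
            raise TableFormatError(f"{path}:{i}: negative base count")
        acc[species].append((offset + pos, counts))
    profiles = []
    for species, rows in sorted(acc.items()):
        rows.sort(key=lambda r: r[0])
        profiles.append(
            AlleleProfile(
                sample_id,
                species,
                genome_length[species],
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
            )
        )
    return profiles


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "host_id", "date", "group", "role", "timepoint", "designated_donor"]
        )
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.host_id,
                    r.date.isoformat() if r.date else "",
                    r.group or "",
                    r.role,
                    r.timepoint,
                    r.designated_donor or "",
                ]
            )


def read_metadata(path: str | Path) -> list[SampleRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        host_id=row["host_id"],
                        date=dt.date.fromisoformat(row["date"]) if row["date"] else None,
                        group=row["group"] or None,
                        role=row["role"] or "none",
                        timepoint=row["timepoint"] or "none",
                        designated_donor=row["designated_donor"] or None,
                    )
                )
            except (KeyError, ValueError) as err:
                raise TableFormatError(f"{path}:{lineno}: {err}") from err
    return out


def write_annotations(
    annotations: Mapping[str, TaxonAnnotation] | Iterable[TaxonAnnotation],
    path: str | Path,
) -> None:
    if isinstance(annotations, Mapping):
        annotations = annotations.values()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_id", "family", "genus", "oxygen", "host_range"])
        for a in annotations:
            w.writerow([a.species_id, a.family, a.genus, a.oxygen, a.host_range])


def read_annotations(path: str | Path) -> dict[str, TaxonAnnotation]:
    out = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                a = TaxonAnnotation(
                    species_id=row["species_id"],
                    family=row["family"],
                    genus=row["genus"],
                    oxygen=row.get("oxygen") or "unknown",
                    host_range=row.get("host_range") or "unknown",
                )
            except (KeyError, ValueError) as err:
                raise TableFormatError(f"{path}:{lineno}: {err}") from err
            out[a.species_id] = a
    return out


def write_dyads(dyads: pd.DataFrame, path: str | Path) -> None:
    dyads.to_csv(path, sep="\t", index=False)


def read_dyads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_a", "sample_b"}.issubset(df.columns):
        raise TableFormatError(f"{path}: dyad table needs sample_a and sample_b")
    return df


def write_distance_matrix(dist: pd.DataFrame, path: str | Path) -> None:
    dist.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_rainfall(daily: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"date": pd.DatetimeIndex(daily.index).strftime("%Y-%m-%d"),
         "millimeters": daily.to_numpy()}
    ).to_csv(path, index=False)


def read_rainfall(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"date", "millimeters"}.issubset(df.columns):
        raise TableFormatError(f"{path}: rainfall CSV needs date and millimeters")
    return pd.Series(
        df["millimeters"].to_numpy(), index=pd.DatetimeIndex(df["date"]), name="rainfall_mm"
    )


def write_diet(diet: pd.DataFrame, path: str | Path) -> None:
    diet.to_csv(path, sep="\t", index=False)


def read_diet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"group", "year", "food_type", "proportion"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"{path}: diet table needs columns {sorted(required)}")
    return df


def write_presence(
    presence: Mapping[tuple[str, str], PresenceCall], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "species_id": c.species_id,
            "breadth": c.breadth,
            "mean_depth": c.mean_depth,
            "present": int(c.present),
        }
        for c in presence.values()
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "species_id", "breadth", "mean_depth", "present"]
    ).to_csv(path, sep="\t", index=False)


def read_presence(path: str | Path) -> dict[tuple[str, str], PresenceCall]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.sample_id, r.species_id): PresenceCall(
            r.sample_id, r.species_id, float(r.breadth), float(r.mean_depth), bool(r.present)
        )
        for r in df.itertuples()
    }


def write_comparisons(comparisons: Iterable[PairwiseComparison], path: str | Path) -> None:
    rows = [
        {
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "species_id": c.species_id,
            "n_compared": c.n_compared,
            "n_pop_subs": c.n_pop_subs,
            "n_con_subs": c.n_con_subs,
            "popani": c.popani,
            "conani": c.conani,
        }
        for c in comparisons
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "species_id", "n_compared",
            "n_pop_subs", "n_con_subs", "popani", "conani",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> list[PairwiseComparison]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairwiseComparison(
            r.sample_a,
            r.sample_b,
            r.species_id,
            int(r.n_compared),
            int(r.n_pop_subs),
            int(r.n_con_subs),
        )
        for r in df.itertuples()
    ]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
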