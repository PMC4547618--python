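"""Readers and writers for every external format the tool touches.

Supported formats, all plain text:

* FASTA marker/genome sequences (via Biopython; wrapped or unwrapped,
  description after the first whitespace ignored).  Genome 16S files may hold
  multiple copies per organism as records ``organism/copy1``, ``organism/copy2``
  ...; everything before the first ``/`` is the organism identifier.
* QIIME classic OTU tables: tab-separated, header line beginning ``#OTU ID``,
  optional trailing ``taxonomy`` column, lines above the header starting with
  ``#`` treated as comments.
* SILVAngs-style assignment exports: delimited text whose first header field
  is ``reference_id`` followed by one count column per sample; comma and
  semicolon dialects auto-detected from the header.
* KO count tables (``organism_id<TAB>ko_id<TAB>count``), copy-number tables
  (``organism_id<TAB>copy_number``), KO profile TSVs
  (``ko_id<TAB>relative_abundance``, lexicographic order, 17 significant
  digits so doubles round-trip losslessly).
* Reference-database directories (``association.tsv`` sparse triplets,
  ``ref_profiles.tsv`` triplets, ``copy_numbers.tsv``, two FASTA files,
  ``metadata.json``); serialization is canonical, so identical databases
  serialize byte-identically.

Readers fail loudly with line numbers; no row is ever silently dropped.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio import SeqIO

from .errors import (AmplifunError, DialectError, EmptyProfileError,
                     FormatError)
from .profiles import AbundanceProfile
from .reference import (AssociationMatrix, CopyNumberTable, ReferenceDatabase,
                        ReferenceProfileSet)
from scipy import sparse

_KO_RE = re.compile(r"^K\d{5}$")


def _fmt(x: float) -> str:
    """17 significant digits: lossless double round-trip."""
    return format(float(x), ".17g")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id→sequence dict (uppercased).

    The record identifier is the first whitespace-delimited token; duplicate
    identifiers are an error.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"duplicate FASTA identifier {record.id!r}",
                              path=path)
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {record.id!r}",
                              path=path)
        out[record.id] = seq
    if not out:
        raise FormatError("no FASTA records found", path=path)
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    """Write sequences sorted by identifier, wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_genome_markers(path) -> dict[str, tuple[str, ...]]:
    """Read genome 16S sequences, grouping ``organism/copyN`` records."""
    grouped: dict[str, list[str]] = {}
    for rec_id, seq in read_fasta(path).items():
        grouped.setdefault(rec_id.split("/", 1)[0], []).append(seq)
    return {org: tuple(seqs) for org, seqs in grouped.items()}


def write_genome_markers(genomes: Mapping[str, tuple[str, ...]], path) -> None:
    flat: dict[str, str] = {}
    for org in sorted(genomes):
        copies = genomes[org]
        if "/" in org:
            raise AmplifunError(f"organism id {org!r} may not contain '/'")
        if len(copies) == 1:
            flat[org] = copies[0]
        else:
            for i, seq in enumerate(copies, start=1):
                flat[f"{org}/copy{i}"] = seq
    write_fasta(flat, path)


# --------------------------------------------------------------------------
# QIIME classic OTU tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OtuTable:
    """Community OTU-by-sample count table with optional taxonomy labels."""

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: Optional[dict[str, str]] = None

    def __post_init__(self):
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise AmplifunError("OTU table shape does not match labels")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise AmplifunError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AmplifunError("duplicate sample ids")
        if c.size and c.min() < 0:
            raise AmplifunError("OTU counts must be nonnegative")
        c.setflags(write=False)

    def sample_profile(self, sample_id: str) -> AbundanceProfile:
        j = self.sample_ids.index(sample_id)
        return AbundanceProfile(self.otu_ids, self.counts[:, j], "otu")


def read_qiime_classic(path) -> OtuTable:
    """Parse a QIIME classic (pre-BIOM, tab-separated) OTU table."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header_idx = i
            break
        if line.strip() and not line.startswith("#"):
            raise DialectError(
                "expected a header line beginning '#OTU ID' before data",
                line=i + 1, path=path)
    if header_idx is None:
        raise DialectError("no '#OTU ID' header line found", path=path)
    header = lines[header_idx].split("\t")
    has_taxonomy = len(header) > 1 and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1:-1] if has_taxonomy else header[1:]
    if not sample_ids:
        raise DialectError("OTU table has no sample columns",
                           line=header_idx + 1, path=path)
    otu_ids: list[str] = []
    rows: list[list[float]] = []
    taxonomy: dict[str, str] = {}
    seen: set[str] = set()
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"ragged row: {len(fields)} fields, expected {len(header)}",
                line=lineno, path=path)
        otu = fields[0]
        if otu in seen:
            raise FormatError(f"duplicate OTU id {otu!r}", line=lineno, path=path)
        seen.add(otu)
        raw = fields[1:-1] if has_taxonomy else fields[1:]
        try:
            values = [float(v) for v in raw]
        except ValueError as exc:
            raise FormatError(f"non-numeric count: {exc}", line=lineno,
                              path=path) from None
        if any(v < 0 for v in values):
            raise FormatError(f"negative count for OTU {otu!r}", line=lineno,
                              path=path)
        otu_ids.append(otu)
        rows.append(values)
        if has_taxonomy:
            taxonomy[otu] = fields[-1]
    if not otu_ids:
        raise FormatError("OTU table contains no data rows", path=path)
    counts = np.array(rows, dtype=float)
    return OtuTable(tuple(otu_ids), tuple(sample_ids), counts,
                    taxonomy if has_taxonomy else None)


def write_qiime_classic(table: OtuTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if table.taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for i, otu in enumerate(table.otu_ids):
            row = [otu, *(_fmt(v) for v in table.counts[i])]
            if table.taxonomy is not None:
                row.append(table.taxonomy.get(otu, ""))
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# SILVAngs-style assignment exports
# --------------------------------------------------------------------------

_SILVANGS_FIRST_FIELD = "reference_id"


def read_silvangs_export(path) -> dict[str, AbundanceProfile]:
    """Parse a SILVAngs-style per-reference assignment-count export.

    Accepted dialects (auto-detected from the header line): comma- or
    semicolon-separated, first column ``reference_id``, one count column per
    sample.  Returns one otu-kind profile per sample, keyed by sample id.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DialectError("empty file", path=path)
    header = lines[0]
    if header.count(";") > header.count(","):
        delim = ";"
    elif "," in header:
        delim = ","
    else:
        delim = None
    fields = header.split(delim) if delim else [header]
    if delim is None or fields[0].strip() != _SILVANGS_FIRST_FIELD or len(fields) < 2:
        raise DialectError(
            "unrecognized assignment-export header; accepted dialects are "
            "comma- or semicolon-separated with columns "
            "'reference_id,<sample>,...'", line=1, path=path)
    sample_ids = [f.strip() for f in fields[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample ids in header", line=1, path=path)
    refs: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) != len(fields):
            raise FormatError(
                f"ragged row: {len(parts)} fields, expected {len(fields)}",
                line=lineno, path=path)
        ref = parts[0]
        if ref in seen:
            raise FormatError(f"duplicate reference id {ref!r}", line=lineno,
                              path=path)
        seen.add(ref)
        try:
            values = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"non-numeric count: {exc}", line=lineno,
                              path=path) from None
        if any(v < 0 for v in values):
            raise FormatError(f"negative count for {ref!r}", line=lineno,
                              path=path)
        refs.append(ref)
        rows.append(values)
    if not refs:
        raise FormatError("no assignment rows found", path=path)
    counts = np.array(rows, dtype=float)
    profiles: dict[str, AbundanceProfile] = {}
    for j, sample in enumerate(sample_ids):
        if counts[:, j].sum() <= 0:
            raise EmptyProfileError(
                f"sample {sample!r} has an empty (all-zero) count column")
        profiles[sample] = AbundanceProfile(tuple(refs), counts[:, j], "otu")
    return profiles


def write_silvangs_export(profiles: Mapping[str, AbundanceProfile], path,
                          delimiter: str = ",") -> None:
    if delimiter not in (",", ";"):
        raise AmplifunError("delimiter must be ',' or ';'")
    path = Path(path)
    samples = sorted(profiles)
    refs = sorted({f for p in profiles.values() for f in p.feature_ids})
    with path.open("w") as fh:
        fh.write(delimiter.join([_SILVANGS_FIRST_FIELD, *samples]) + "\n")
        maps = {s: profiles[s].as_dict() for s in samples}
        for ref in refs:
            row = [ref, *(_fmt(maps[s].get(ref, 0.0)) for s in samples)]
            fh.write(delimiter.join(row) + "\n")


# --------------------------------------------------------------------------
# simple TSV tables
# --------------------------------------------------------------------------

def read_tsv_table(path, n_columns: int, skip_header_if=None
                   ) -> list[tuple[int, list[str]]]:
    """Read a TSV into (line number, fields) pairs; ragged rows are errors."""
    path = Path(path)
    out: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != n_columns:
            raise FormatError(
                f"ragged row: {len(fields)} fields, expected {n_columns}",
                line=lineno, path=path)
        if lineno == 1 and skip_header_if is not None and \
                fields[0].strip() == skip_header_if:
            continue
        out.append((lineno, fields))
    if not out:
        raise FormatError("no data rows found", path=path)
    return out


def read_ko_counts(path) -> dict[str, dict[str, float]]:
    """Read per-organism KO counts (``organism_id  ko_id  count``)."""
    path = Path(path)
    tables: dict[str, dict[str, float]] = {}
    for lineno, (org, ko, raw) in read_tsv_table(path, 3,
                                                 skip_header_if="organism_id"):
        if not _KO_RE.match(ko):
            raise FormatError(f"KO id {ko!r} does not match K#####",
                              line=lineno, path=path)
        try:
            count = float(raw)
        except ValueError:
            raise FormatError(f"non-numeric count {raw!r}", line=lineno,
                              path=path) from None
        if count < 0:
            raise FormatError(f"negative count for {org!r}/{ko!r}",
                              line=lineno, path=path)
        org_table = tables.setdefault(org, {})
        if ko in org_table:
            raise FormatError(f"duplicate entry for {org!r}/{ko!r}",
                              line=lineno, path=path)
        org_table[ko] = count
    return tables


def write_ko_counts(tables: Mapping[str, Mapping[str, float]], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("organism_id\tko_id\tcount\n")
        for org in sorted(tables):
            for ko in sorted(tables[org]):
                fh.write(f"{org}\t{ko}\t{_fmt(tables[org][ko])}\n")


def read_copy_numbers(path) -> CopyNumberTable:
    """Read a copy-number table (``organism_id  copy_number``)."""
    path = Path(path)
    mapping: dict[str, int] = {}
    for lineno, (org, raw) in read_tsv_table(path, 2,
                                             skip_header_if="organism_id"):
        if org in mapping:
            raise FormatError(f"duplicate organism id {org!r}", line=lineno,
                              path=path)
        try:
            value = int(raw)
        except ValueError:
            raise FormatError(f"copy number {raw!r} is not an integer",
                              line=lineno, path=path) from None
        if value < 1:
            raise FormatError(f"copy number for {org!r} must be >= 1",
                              line=lineno, path=path)
        mapping[org] = value
    return CopyNumberTable.from_mapping(mapping)


def write_copy_numbers(table: CopyNumberTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("organism_id\tcopy_number\n")
        for org, cn in sorted(table.as_dict().items()):
            fh.write(f"{org}\t{cn}\n")


# --------------------------------------------------------------------------
# KO profiles
# --------------------------------------------------------------------------

def write_ko_profile(profile: AbundanceProfile, path) -> None:
    """Write a KO profile TSV, lexicographic KO order, full double precision."""
    if profile.kind != "ko":
        raise AmplifunError(f"expected a ko profile, got {profile.kind!r}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("ko_id\trelative_abundance\n")
        for ko, v in sorted(profile.as_dict().items()):
            fh.write(f"{ko}\t{_fmt(v)}\n")


def read_ko_profile(path) -> AbundanceProfile:
    path = Path(path)
    mapping: dict[str, float] = {}
    for lineno, (ko, raw) in read_tsv_table(path, 2, skip_header_if="ko_id"):
        if ko in mapping:
            raise FormatError(f"duplicate KO id {ko!r}", line=lineno, path=path)
        try:
            mapping[ko] = float(raw)
        except ValueError:
            raise FormatError(f"non-numeric abundance {raw!r}", line=lineno,
                              path=path) from None
    total = sum(mapping.values())
    normalized = abs(total - 1.0) <= 1e-9
    return AbundanceProfile.from_mapping(mapping, "ko", normalized=normalized)


# --------------------------------------------------------------------------
# reference-database directories
# --------------------------------------------------------------------------

_DB_FILES = ("association.tsv", "ref_profiles.tsv", "copy_numbers.tsv",
             "marker_sequences.fasta", "genome_16s.fasta", "metadata.json")


def save_database(db: ReferenceDatabase, directory) -> Path:
    """Serialize a reference database to a directory of plain-text files.

    Output is canonical (sorted, fixed float formatting), so the same
    database always serializes byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(db.marker_sequences, directory / "marker_sequences.fasta")
    write_genome_markers(db.genome_marker_sequences, directory / "genome_16s.fasta")
    assoc = db.association
    coo = assoc.weights.tocoo()
    triplets = sorted(
        (assoc.organism_ids[i], assoc.reference_ids[j], float(v))
        for i, j, v in zip(coo.row, coo.col, coo.data))
    with (directory / "association.tsv").open("w") as fh:
        fh.write("organism_id\treference_id\tweight\n")
        for org, ref, w in triplets:
            fh.write(f"{org}\t{ref}\t{_fmt(w)}\n")
    with (directory / "ref_profiles.tsv").open("w") as fh:
        fh.write("organism_id\tko_id\trelative_abundance\n")
        profs = db.reference_profiles
        for i, org in enumerate(profs.organism_ids):
            for j, ko in enumerate(profs.ko_ids):
                v = profs.profiles[i, j]
                if v != 0.0:
                    fh.write(f"{org}\t{ko}\t{_fmt(v)}\n")
    write_copy_numbers(db.copy_numbers, directory / "copy_numbers.tsv")
    meta = dict(db.metadata)
    meta.setdefault("min_identity", repr(float(assoc.min_identity)))
    meta["reference_ids"] = json.dumps(list(assoc.reference_ids))
    with (directory / "metadata.json").open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory


def load_database(directory) -> ReferenceDatabase:
    """Load a reference database previously written by :func:`save_database`."""
    directory = Path(directory)
    for name in _DB_FILES:
        if not (directory / name).exists():
            raise FormatError(f"missing database file {name!r}", path=directory)
    meta = json.loads((directory / "metadata.json").read_text())
    marker = read_fasta(directory / "marker_sequences.fasta")
    genomes = read_genome_markers(directory / "genome_16s.fasta")
    copy_table = read_copy_numbers(directory / "copy_numbers.tsv")
    organisms = tuple(sorted(genomes))

    # reference columns: recorded in metadata so unmapped references survive
    ref_ids = tuple(json.loads(meta["reference_ids"]))
    org_index = {o: i for i, o in enumerate(organisms)}
    ref_index = {r: j for j, r in enumerate(ref_ids)}
    rows, cols, data = [], [], []
    for lineno, (org, ref, raw) in read_tsv_table(directory / "association.tsv",
                                                  3, skip_header_if="organism_id"):
        if org not in org_index or ref not in ref_index:
            raise FormatError(f"unknown label in association row {org!r}/{ref!r}",
                              line=lineno, path=directory / "association.tsv")
        rows.append(org_index[org])
        cols.append(ref_index[ref])
        data.append(float(raw))
    weights = sparse.csc_matrix((data, (rows, cols)),
                                shape=(len(organisms), len(ref_ids)))
    association = AssociationMatrix(organisms, ref_ids, weights,
                                    float(meta["min_identity"]))

    prof_tables: dict[str, dict[str, float]] = {o: {} for o in organisms}
    for lineno, (org, ko, raw) in read_tsv_table(directory / "ref_profiles.tsv",
                                                 3, skip_header_if="organism_id"):
        if org not in prof_tables:
            raise FormatError(f"unknown organism {org!r} in reference profiles",
                              line=lineno, path=directory / "ref_profiles.tsv")
        prof_tables[org][ko] = float(raw)
    ko_ids = tuple(sorted({k for t in prof_tables.values() for k in t}))
    ko_index = {k: i for i, k in enumerate(ko_ids)}
    mat = np.zeros((len(organisms), len(ko_ids)))
    for i, org in enumerate(organisms):
        for ko, v in prof_tables[org].items():
            mat[i, ko_index[ko]] = v
    profiles = ReferenceProfileSet(organisms, ko_ids, mat)
    metadata = {k: v for k, v in meta.items() if k != "reference_ids"}
    return ReferenceDatabase(marker, genomes, association, copy_table,
                             profiles, metadata)


# --------------------------------------------------------------------------
# sidecar key/value text
# --------------------------------------------------------------------------

def write_key_values(mapping: Mapping[str, object], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key in mapping:
            value = mapping[key]
            if isinstance(value, float):
                value = _fmt(value)
            fh.write(f"{key}\t{value}\n")


def read_key_values(path) -> dict[str, str]:
    return {f[0]: f[1] for _, f in read_tsv_table(path, 2)}
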