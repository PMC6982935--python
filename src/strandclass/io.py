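"""Readers and writers for every external representation the pipeline touches.

Formats handled:

* FASTA protein sequences (via Bio.SeqIO);
* PSI-BLAST ASCII position-specific scoring matrices (the first 20-column
  log-odds block, raw integer scores);
* per-residue tabular predictor outputs (NetSurfP-style 6-column, DisEMBL-style
  3-column, or generic TSV with a header);
* property tables (residue- or k-mer-keyed TSV configs);
* feature matrices as TSV with one header row (lossless round-trip).

Parsers never silently drop rows: the number of input residue rows always
equals the profile length, or an error naming the offending line is raised.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .types import (
    AMBIGUITY_CODES,
    AMINO_ACIDS,
    FeatureMatrix,
    PropertyTable,
    ProteinRecord,
    ResidueProfile,
    StrandclassError,
)

#: Column order of the log-odds block in PSI-BLAST ASCII PSSM output.
PSSM_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: NetSurfP per-residue numeric channels, in file order.
NETSURFP_COLUMNS = [
    "rsa",
    "asa",
    "zscore",
    "p_alpha",
    "p_beta",
    "p_coil",
]

#: DisEMBL per-residue disorder propensities, in file order.
DISEMBL_COLUMNS = ["coils", "rem465", "hotloops"]


def normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, strip whitespace, map tolerated ambiguity codes to X."""
    seq = "".join(raw.split()).upper()
    out = []
    for ch in seq:
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in AMBIGUITY_CODES:
            out.append("X")
        else:
            raise StrandclassError(
                f"record {record_id!r}: invalid residue character {ch!r}"
            )
    return "".join(out)


def read_fasta(path) -> List[ProteinRecord]:
    """Read a FASTA file into protein records.

    Sequences are uppercased and whitespace-joined; ambiguity codes B/Z/U are
    mapped to X.  Raises on empty files, duplicate ids and characters outside
    the tolerated alphabet, always naming the offending record.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise StrandclassError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise StrandclassError(f"record {rec.id!r}: empty sequence in {path}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise StrandclassError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _int_tokens(tokens: Sequence[str]) -> Optional[List[int]]:
    try:
        return [int(t) for t in tokens]
    except ValueError:
        return None


def read_pssm(path, protein_id: Optional[str] = None) -> ResidueProfile:
    """Parse a PSI-BLAST ASCII PSSM into a 20 x L residue profile.

    Takes the first 20-column log-odds block (columns in PSI-BLAST order
    A R N D C Q E G H I L K M F P S T W Y V), raw integer scores.  Rows whose
    score count falls short of 20 raise a parse error naming the line.
    """
    path = Path(path)
    rows: List[List[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 3:
                continue
            # data rows: position index, residue letter, then integer scores
            if not tokens[0].isdigit():
                continue
            if len(tokens[1]) != 1 or not tokens[1].isalpha():
                continue
            scores = _int_tokens(tokens[2:22])
            if scores is None or len(scores) < 20:
                raise StrandclassError(
                    f"{path}:{lineno}: expected 20 integer scores, "
                    f"got {0 if scores is None else len(scores)}"
                )
            rows.append(scores)
    if not rows:
        raise StrandclassError(f"{path}: no PSSM residue rows found (truncated file?)")
    values = np.asarray(rows, dtype=float).T  # 20 properties x L positions
    return ResidueProfile(
        protein_id=protein_id or path.stem,
        property_names=[f"pssm_{aa}" for aa in PSSM_COLUMN_ORDER],
        values=values,
    )


def read_residue_table(
    path, format: str = "generic_tsv", protein_id: Optional[str] = None
) -> ResidueProfile:
    """Read a per-residue tabular predictor output into a residue profile.

    ``format`` selects the column contract: ``netsurfp`` expects the 6 numeric
    channels (RSA, absolute surface accessibility, z-score, p-alpha, p-beta,
    p-coil), ``disembl`` the 3 disorder propensities (COILS, REM465, HOTLOOPS),
    ``generic_tsv`` takes every column of a headered TSV.  Positions follow
    file order.
    """
    path = Path(path)
    if format not in {"netsurfp", "disembl", "generic_tsv"}:
        raise StrandclassError(f"unknown residue-table format {format!r}")
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise StrandclassError(f"{path}: empty residue table")

    if format == "generic_tsv":
        header, data = rows[0], rows[1:]
        names = [h.strip() for h in header]
        expected = len(names)
    else:
        names = list(NETSURFP_COLUMNS if format == "netsurfp" else DISEMBL_COLUMNS)
        expected = len(names)
        # tolerate a header line of non-numeric tokens
        data = rows
        if data and not _is_numeric_row(data[0][-expected:]):
            data = data[1:]

    values = []
    for i, row in enumerate(data, start=1):
        cells = [c for c in row if c.strip()]
        if format != "generic_tsv":
            # predictor outputs may carry leading position/residue columns
            cells = cells[-expected:]
        if len(cells) != expected:
            raise StrandclassError(
                f"{path}: row {i} has {len(cells)} columns, expected {expected}"
            )
        try:
            values.append([float(c) for c in cells])
        except ValueError as exc:
            raise StrandclassError(f"{path}: row {i}: non-numeric cell ({exc})")
    if not values:
        raise StrandclassError(f"{path}: residue table has a header but no rows")
    return ResidueProfile(
        protein_id=protein_id or path.stem,
        property_names=names,
        values=np.asarray(values, dtype=float).T,
    )


def _is_numeric_row(cells: Sequence[str]) -> bool:
    if not cells:
        return False
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def read_property_table(path) -> PropertyTable:
    """Read a property table TSV: header ``key<TAB>prop1<TAB>...``, one row
    per residue (or k-mer for the local-structural-entropy table)."""
    path = Path(path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r]
    if len(rows) < 2:
        raise StrandclassError(f"{path}: property table needs a header and rows")
    names = [h.strip() for h in rows[0][1:]]
    entries = {}
    for i, row in enumerate(rows[1:], start=2):
        key = row[0].strip().upper()
        if len(row) - 1 != len(names):
            raise StrandclassError(
                f"{path}: row {i} has {len(row) - 1} values, expected {len(names)}"
            )
        try:
            entries[key] = [float(c) for c in row[1:]]
        except ValueError as exc:
            raise StrandclassError(f"{path}: row {i}: non-numeric cell ({exc})")
    return PropertyTable(property_names=names, entries=entries)


def write_property_table(table: PropertyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("key\t" + "\t".join(table.property_names) + "\n")
        for key in sorted(table.entries):
            vals = "\t".join(repr(float(v)) for v in table.entries[key])
            fh.write(f"{key}\t{vals}\n")


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV: header row, then one row per sample with
    sample id, class label and feature values (full float precision)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\t" + "\t".join(matrix.columns) + "\n")
        for sid, lab, row in zip(matrix.sample_ids, matrix.labels, matrix.values):
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{sid}\t{lab}\t{cells}\n" if matrix.n_columns else f"{sid}\t{lab}\n")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a TSV feature matrix written by :func:`write_feature_matrix`.

    Round-trip identity holds: ``read(write(m)) == m`` including column
    labels, sample ids and class labels.
    """
    path = Path(path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise StrandclassError(f"{path}: empty feature matrix file")
    header = rows[0]
    if len(header) < 2 or header[0] != "sample_id" or header[1] != "label":
        raise StrandclassError(
            f"{path}: feature matrix header must start with 'sample_id\\tlabel'"
        )
    columns = header[2:]
    sample_ids, labels, values = [], [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise StrandclassError(
                f"{path}: row {i} has {len(row) - 2} feature values, "
                f"expected {len(columns)}"
            )
        sample_ids.append(row[0])
        labels.append(row[1])
        values.append([float(c) for c in row[2:]])
    return FeatureMatrix(
        sample_ids=sample_ids,
        labels=labels,
        columns=columns,
        values=np.asarray(values, dtype=float).reshape(len(sample_ids), len(columns)),
    )


def write_column_list(columns: Sequence[str], path) -> None:
    """Persist a retained-column list (one name per line) so a selection made
    on training data can be re-applied verbatim to new data."""
    with open(path, "w") as fh:
        for c in columns:
            fh.write(c + "\n")


def read_column_list(path) -> List[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
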