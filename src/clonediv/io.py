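"""Readers and writers for the pipeline's plain-text formats.

Count tables and stage censuses travel as TSV; sequences as FASTA. Clone
FASTA headers carry the library label as a ``library|clone_id`` prefix so a
single file can hold all libraries; a bare header is assigned the library
label passed by the caller (one-file-per-library dialect).

The package ships one fixture: the phylotype-by-library clone-count table of
the six-library copepod study, with the three count cells that contradicted
the stated 30-clones-per-library design reconciled from their printed
percentages (count = round(frequency * 30 / 100) wherever a column did not
sum to 30).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .development import StageCensus
from .phylotyping import SequenceRecord

__all__ = [
    "packaged_count_table",
    "read_count_table",
    "write_count_table",
    "read_fasta",
    "write_fasta",
    "read_stage_census",
    "write_tsv",
]

LIBRARY_SEPARATOR = "|"


def packaged_count_table() -> pd.DataFrame:
    """The shipped six-library phylotype count table (reconciled to 30 clones)."""
    with resources.files("clonediv.data").joinpath("table1_counts.tsv").open() as fh:
        return read_count_table(fh)


def read_count_table(path_or_buffer) -> pd.DataFrame:
    """Phylotype-by-library counts from TSV; ``nd`` and blanks read as 0."""
    df = pd.read_csv(
        path_or_buffer, sep="\t", index_col=0, comment="#", na_values=["nd", ""]
    )
    df = df.fillna(0)
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise ValueError(f"count table has non-integer cells: {exc}") from exc
    if (df < 0).any().any():
        raise ValueError("count table has negative cells")
    return df


def write_count_table(
    df: pd.DataFrame, path: "str | Path", header_lines: Iterable[str] = ()
) -> None:
    write_tsv(df, path, header_lines=header_lines, index=True)


def write_tsv(
    df: pd.DataFrame,
    path: "str | Path",
    header_lines: Iterable[str] = (),
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with optional ``#``-prefixed provenance lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_fasta(path: "str | Path", library: str = "") -> list[SequenceRecord]:
    """Load sequences, decoding ``library|id`` headers when present."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if LIBRARY_SEPARATOR in rec.id:
            lib, _, seq_id = rec.id.partition(LIBRARY_SEPARATOR)
        else:
            lib, seq_id = library, rec.id
        records.append(SequenceRecord(id=seq_id, residues=str(rec.seq), library=lib))
    return records


def write_fasta(records: list[SequenceRecord], path: "str | Path") -> None:
    """Write sequences, encoding non-empty library labels into the header."""
    bio_records = []
    for r in records:
        header = f"{r.library}{LIBRARY_SEPARATOR}{r.id}" if r.library else r.id
        bio_records.append(BioSeqRecord(Seq(r.residues), id=header, description=""))
    SeqIO.write(bio_records, str(path), "fasta")


def read_stage_census(path_or_buffer) -> list[StageCensus]:
    """Stage censuses from a TSV with columns
    treatment, replicate, n_start, n_nauplii, n_copepodites."""
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#")
    required = {"treatment", "replicate", "n_start", "n_nauplii", "n_copepodites"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stage-census table missing columns: {sorted(missing)}")
    return [
        StageCensus(
            replicate=str(row.replicate),
            treatment=str(row.treatment),
            n_start=int(row.n_start),
            n_nauplii=int(row.n_nauplii),
            n_copepodites=int(row.n_copepodites),
        )
        for row in df.itertuples()
    ]
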