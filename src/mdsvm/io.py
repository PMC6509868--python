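"""Readers and writers for probe tables and FASTA.

The probe table is the tab-delimited export format of PBM experiments:
one probe per line as ``sequence<TAB>binding_intensity``, with an optional
header line. ``trim_flank`` removes a constant number of bases from each
end of every probe before use — PBM probes carry constant flanking
sequence around the variable region, and callers may want to scan only
the variable part.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _trim(sequence: str, trim_flank: int) -> str:
    if trim_flank < 0:
        raise ValueError("trim_flank must be >= 0")
    if trim_flank == 0:
        return sequence
    if len(sequence) <= 2 * trim_flank:
        raise ValueError(
            f"sequence of length {len(sequence)} too short to trim "
            f"{trim_flank} bases from each end"
        )
    return sequence[trim_flank:-trim_flank]


def read_probe_table(path: str | os.PathLike, trim_flank: int = 0) -> pd.DataFrame:
    """Read a ``sequence<TAB>intensity`` table into a DataFrame.

    A first line whose second field is not numeric is treated as a header.
    Malformed lines raise a :class:`ValueError` carrying the line number.
    """
    rows: list[tuple[str, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            seq, raw = fields
            try:
                intensity = float(raw)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: intensity {raw!r} is not numeric"
                ) from None
            rows.append((_trim(seq.strip().upper(), trim_flank), intensity))
    if not rows:
        raise ValueError(f"{path}: no probes found")
    return pd.DataFrame(rows, columns=["sequence", "intensity"])


def write_probe_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame[["sequence", "intensity"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fasta(path: str | os.PathLike, trim_flank: int = 0) -> pd.DataFrame:
    """Read FASTA probes; record ids become bag ids."""
    rows = [
        (rec.id, _trim(str(rec.seq).upper(), trim_flank))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not rows:
        raise ValueError(f"{path}: no FASTA records found")
    return pd.DataFrame(rows, columns=["id", "sequence"])


def write_fasta(
    sequences: Iterable[str], ids: Iterable[str], path: str | os.PathLike
) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for seq, name in zip(sequences, ids)
    ]
    SeqIO.write(records, str(path), "fasta")
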