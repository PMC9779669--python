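"""Readers and writers for the plain-text formats used across the package.

FASTA goes through Biopython; tables are TSV via pandas. Planted or detected
binding sites are exchanged as BED6 (0-based, half-open, score column =
number of mismatches). Occupancy tracks are bedGraph.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns (Biopython default)."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(sites: pd.DataFrame, path: str | Path) -> None:
    sites[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph intervals: chrom, start, end, value (0-based, half-open)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_motif_table(path: str | Path) -> list[tuple[str, str]]:
    """Motif TSV: two columns, TF id and consensus (IUPAC allowed)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(r[0]), str(r[1]).upper()) for r in df.itertuples(index=False)]
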