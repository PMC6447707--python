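"""FASTA/FASTQ/TSV readers and writers (Biopython + pandas backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable, path: str | Path) -> None:
    """Write AmpliconRead-like objects (id, bases, quals) as Sanger FASTQ."""
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fastq(path: str | Path):
    from .amplicon import AmpliconRead

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            AmpliconRead(
                id=rec.id,
                bases=str(rec.seq),
                quals=np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
            )
        )
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
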