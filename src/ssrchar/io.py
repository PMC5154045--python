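"""FASTA input/output and tabular locus reports."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .discovery import SequenceRecord, SsrLocus


def read_fasta(path_or_handle) -> list[SequenceRecord]:
    """Read a multi-record FASTA (wrapped or unwrapped) into SequenceRecords."""
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path_or_handle) -> None:
    bio = [
        BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(bio, path_or_handle, "fasta")


def loci_to_table(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """Detected-locus report: sequence_id, start, end, motif_string, kind, length."""
    return pd.DataFrame(
        [
            {
                "sequence_id": l.sequence_id,
                "start": l.start,
                "end": l.end,
                "motif_string": l.motif_string(),
                "kind": l.kind,
                "length": l.length,
            }
            for l in loci
        ],
        columns=["sequence_id", "start", "end", "motif_string", "kind", "length"],
    )
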