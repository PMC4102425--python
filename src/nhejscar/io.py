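"""Plain-text input/output: junction FASTA, events/summary TSV, configs."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import JunctionRead, parse_read_id

PathLike = Union[str, Path]


def read_junction_fasta(path: PathLike) -> list[JunctionRead]:
    """Read junction reads; ids of the form ``cohort|mouse|reaction|clone``
    populate ``source_reaction`` (fields after the first ``|`` optional)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        # SeqIO splits ids at whitespace; '|' fields survive intact
        fields = parse_read_id(rec.id)
        reaction = None
        if fields["reaction"] is not None:
            reaction = f"{fields['cohort']}|{fields['reaction']}"
        reads.append(
            JunctionRead(id=rec.id, sequence=str(rec.seq).upper(), source_reaction=reaction)
        )
    return reads


def write_junction_fasta(reads: Iterable[JunctionRead], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_construct_fasta(name: str, sequence: str, path: PathLike) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
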