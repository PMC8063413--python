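"""Readers and writers for the standard formats the pipeline consumes.

Conventions: FASTA wrapped at 60 columns (Biopython); GFF3 1-based closed
intervals on disk, converted to the package's internal 0-based half-open
transcript coordinates on read (start0 = start - 1, end0 = end); TSV
tab-delimited with a header row and '#'-prefixed metadata lines carrying
the generator seed and config hash.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthio import TranscriptRecord

GFF3_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
                "phase", "attributes"]


def write_fasta(transcripts: Sequence[TranscriptRecord], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"class={t.rna_class}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(transcripts: Sequence[TranscriptRecord], path) -> None:
    """One 'transcript' feature per record (rna_class attribute) plus a
    'pre_miR' feature for pri-miRs; coordinates converted 0-based half-open
    -> 1-based closed."""
    rows = []
    for t in transcripts:
        rows.append(
            dict(seqid=t.id, source="mipepscan", type="transcript", start=1,
                 end=len(t.sequence), score=".", strand="+", phase=".",
                 attributes=f"ID={t.id};rna_class={t.rna_class}")
        )
        if t.premir_interval is not None:
            s0, e0 = t.premir_interval
            rows.append(
                dict(seqid=t.id, source="mipepscan", type="pre_miR", start=s0 + 1,
                     end=e0, score=".", strand="+", phase=".",
                     attributes=f"Parent={t.id}")
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        pd.DataFrame(rows, columns=GFF3_COLUMNS).to_csv(
            fh, sep="\t", header=False, index=False
        )


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> pd.DataFrame:
    """GFF3 as a table with internal 0-based half-open start0/end0 columns."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS)
    df["start0"] = df["start"].astype(int) - 1
    df["end0"] = df["end"].astype(int)
    return df


def read_transcripts(fasta_path, gff3_path=None, classes_tsv=None) -> list[TranscriptRecord]:
    """Assemble TranscriptRecords from FASTA plus either a GFF3 (transcript
    class + pre_miR features) or a two-column (transcript_id, rna_class) TSV."""
    seqs = dict(read_fasta(fasta_path))
    classes: dict[str, str] = {}
    premirs: dict[str, tuple[int, int]] = {}
    if gff3_path is not None:
        gff = read_gff3(gff3_path)
        for _, row in gff.iterrows():
            if row["type"] == "transcript":
                classes[row["seqid"]] = _parse_attributes(row["attributes"]).get(
                    "rna_class", "lncRNA"
                )
            elif row["type"] == "pre_miR":
                premirs[row["seqid"]] = (int(row["start0"]), int(row["end0"]))
    elif classes_tsv is not None:
        cls_df = read_tsv(classes_tsv)
        classes = dict(zip(cls_df["transcript_id"], cls_df["rna_class"]))
    else:
        raise ValueError("need a GFF3 or a class TSV")
    return [
        TranscriptRecord(tid, classes.get(tid, "lncRNA"), seq,
                         premir_interval=premirs.get(tid))
        for tid, seq in seqs.items()
    ]


def write_tsv(df: pd.DataFrame, path, metadata: Optional[dict] = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
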