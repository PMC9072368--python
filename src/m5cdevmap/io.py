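"""File-format adapters: FASTA, annotation/truth/ortholog TSVs, dot-bracket."""
from __future__ import annotations

from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import TranscriptModel, TruthSite

ANNOT_COLUMNS = ["transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len"]
ORTHOLOG_COLUMNS = ["tidA", "posA", "tidB", "posB", "baseA", "baseB"]


def write_fasta(transcriptome: Sequence[TranscriptModel], path: str) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcriptome
    ]
    SeqIO.write(records, path, "fasta")


def write_annotation(transcriptome: Sequence[TranscriptModel], path: str) -> None:
    pd.DataFrame(
        [
            (t.transcript_id, t.gene_id, t.utr5_len, t.cds_len, t.utr3_len)
            for t in transcriptome
        ],
        columns=ANNOT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_transcriptome(fasta_path: str, annot_path: str) -> list[TranscriptModel]:
    annot = pd.read_csv(annot_path, sep="\t", comment="#")
    missing = set(ANNOT_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"{annot_path}: missing columns {sorted(missing)}")
    rows = {r.transcript_id: r for r in annot.itertuples(index=False)}
    out = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if rec.id not in rows:
            raise ValueError(f"{rec.id} present in FASTA but not annotated")
        r = rows[rec.id]
        out.append(
            TranscriptModel(
                transcript_id=rec.id,
                gene_id=r.gene_id,
                sequence=str(rec.seq).upper().replace("T", "U"),
                utr5_len=int(r.utr5_len),
                cds_len=int(r.cds_len),
                utr3_len=int(r.utr3_len),
            )
        )
    return out


def write_truth(truth: Sequence[TruthSite], path: str) -> None:
    pd.DataFrame(
        [(s.transcript_id, s.position, s.true_level, s.planted_type) for s in truth],
        columns=["transcript_id", "position", "true_level", "planted_type"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> list[TruthSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TruthSite(r.transcript_id, int(r.position), float(r.true_level), r.planted_type)
        for r in df.itertuples(index=False)
    ]


def read_ortholog_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_ortholog_map(df: pd.DataFrame, path: str) -> None:
    df[ORTHOLOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dotbracket(path: str) -> dict[str, tuple[str, str]]:
    """Vienna-style triplet records: '>id' line, sequence line, structure line."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise ValueError(f"{path}: expected triplets of id/sequence/structure lines")
    for i in range(0, len(lines), 3):
        header, seq, struct = lines[i : i + 3]
        if not header.startswith(">"):
            raise ValueError(f"{path}: record {i // 3}: missing '>' header")
        if len(seq) != len(struct):
            raise ValueError(f"{path}: {header[1:]}: sequence/structure length mismatch")
        out[header[1:].split()[0]] = (seq, struct)
    return out


def write_dotbracket(records: dict[str, tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, (seq, struct) in records.items():
            fh.write(f">{name}\n{seq}\n{struct}\n")
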