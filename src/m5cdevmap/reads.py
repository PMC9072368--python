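"""Columnar container for read-level cytosine observations.

The filter cascade operates on per-read cytosine observations (the C-cutoff
filter is read-global), so reads are stored as two aligned column sets: one
row per read and one row per observed reference-C position.  The record-stream
view of :class:`~m5cdevmap.models.ReadCytosineRecord` is preserved through
``from_records`` / ``__iter__``; large simulations construct the columns
directly.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .models import ReadCytosineRecord, TranscriptModel, transcript_index

_COMPLEMENT_DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}


def _rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


class ReadTable:
    """Reads and their reference-C observations in columnar form."""

    def __init__(
        self,
        transcript_ids: Sequence[str],
        read_tid: np.ndarray,
        obs_read: np.ndarray,
        obs_pos: np.ndarray,
        obs_state_c: np.ndarray,
        obs_qual: np.ndarray,
        read_ids: Sequence[str] | None = None,
        read_start: np.ndarray | None = None,
        read_span: np.ndarray | None = None,
    ):
        self.transcript_ids = list(transcript_ids)
        self.read_tid = np.asarray(read_tid, dtype=np.int32)
        self.obs_read = np.asarray(obs_read, dtype=np.int64)
        self.obs_pos = np.asarray(obs_pos, dtype=np.int32)
        self.obs_state_c = np.asarray(obs_state_c, dtype=bool)
        self.obs_qual = np.asarray(obs_qual, dtype=np.int16)
        self._read_ids = list(read_ids) if read_ids is not None else None
        self.read_start = (
            np.asarray(read_start, dtype=np.int32) if read_start is not None else None
        )
        self.read_span = (
            np.asarray(read_span, dtype=np.int32) if read_span is not None else None
        )
        if len(self.obs_read) and self.obs_read.max() >= self.n_reads:
            raise ValueError("observation refers to a read index out of range")

    # ------------------------------------------------------------------ core
    @property
    def n_reads(self) -> int:
        return len(self.read_tid)

    @property
    def n_obs(self) -> int:
        return len(self.obs_pos)

    def read_id(self, i: int) -> str:
        if self._read_ids is not None:
            return self._read_ids[i]
        return f"r{i:08d}"

    @property
    def obs_tid(self) -> np.ndarray:
        """Transcript code per observation."""
        return self.read_tid[self.obs_read]

    def per_read_c_counts(self) -> np.ndarray:
        """Number of unconverted (state C) observations per read."""
        return np.bincount(
            self.obs_read, weights=self.obs_state_c, minlength=self.n_reads
        ).astype(np.int64)

    def subset_reads(self, keep: np.ndarray) -> "ReadTable":
        """Restrict to reads where ``keep`` is True (read-global filtering)."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_reads,):
            raise ValueError("mask length must equal number of reads")
        new_index = np.cumsum(keep) - 1
        obs_keep = keep[self.obs_read]
        return ReadTable(
            self.transcript_ids,
            self.read_tid[keep],
            new_index[self.obs_read[obs_keep]],
            self.obs_pos[obs_keep],
            self.obs_state_c[obs_keep],
            self.obs_qual[obs_keep],
            read_ids=(
                [rid for rid, k in zip(self._read_ids, keep) if k]
                if self._read_ids is not None
                else None
            ),
            read_start=self.read_start[keep] if self.read_start is not None else None,
            read_span=self.read_span[keep] if self.read_span is not None else None,
        )

    # ----------------------------------------------------------- conversions
    @classmethod
    def from_records(cls, records: Iterable[ReadCytosineRecord]) -> "ReadTable":
        tids: list[str] = []
        tid_code: dict[str, int] = {}
        read_tid, read_ids = [], []
        obs_read, obs_pos, obs_c, obs_q = [], [], [], []
        for i, rec in enumerate(records):
            code = tid_code.get(rec.transcript_id)
            if code is None:
                code = tid_code[rec.transcript_id] = len(tids)
                tids.append(rec.transcript_id)
            read_tid.append(code)
            read_ids.append(rec.read_id)
            for pos, state, qual in rec.obs:
                obs_read.append(i)
                obs_pos.append(pos)
                obs_c.append(state == "C")
                obs_q.append(qual)
        return cls(
            tids,
            np.array(read_tid, dtype=np.int32),
            np.array(obs_read, dtype=np.int64),
            np.array(obs_pos, dtype=np.int32),
            np.array(obs_c, dtype=bool),
            np.array(obs_q, dtype=np.int16),
            read_ids=read_ids,
        )

    def __iter__(self) -> Iterator[ReadCytosineRecord]:
        order = np.argsort(self.obs_read, kind="stable")
        bounds = np.searchsorted(self.obs_read[order], np.arange(self.n_reads + 1))
        for i in range(self.n_reads):
            sel = order[bounds[i] : bounds[i + 1]]
            sel = sel[np.argsort(self.obs_pos[sel], kind="stable")]
            yield ReadCytosineRecord(
                read_id=self.read_id(i),
                transcript_id=self.transcript_ids[self.read_tid[i]],
                obs=[
                    (int(self.obs_pos[j]), "C" if self.obs_state_c[j] else "T",
                     int(self.obs_qual[j]))
                    for j in sel
                ],
            )

    # ------------------------------------------------------------------- TSV
    def write_tsv(self, path: str) -> None:
        """Canonical read TSV: read_id, transcript_id, start, 'pos:state:qual;...'."""
        with open(path, "w") as fh:
            fh.write("read_id\ttranscript_id\tstart\tobs\n")
            for i, rec in enumerate(self):
                start = (
                    int(self.read_start[i])
                    if self.read_start is not None
                    else (rec.obs[0][0] if rec.obs else 0)
                )
                obs = ";".join(f"{p}:{s}:{q}" for p, s, q in rec.obs)
                fh.write(f"{rec.read_id}\t{rec.transcript_id}\t{start}\t{obs}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ReadTable":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["read_id", "transcript_id"]:
                raise ValueError(f"{path}: not a read TSV (header {header})")
            for line_no, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{line_no}: expected 4 columns")
                rid, tid, _start, obs_field = parts
                obs = []
                if obs_field:
                    for item in obs_field.split(";"):
                        try:
                            p, s, q = item.split(":")
                            obs.append((int(p), s, int(q)))
                        except ValueError as exc:
                            raise ValueError(
                                f"{path}:{line_no}: malformed observation {item!r} "
                                f"in read {rid}"
                            ) from exc
                records.append(ReadCytosineRecord(rid, tid, obs))
        return cls.from_records(records)

    # ------------------------------------------------------------------- SAM
    def write_sam(self, path: str, transcriptome: Sequence[TranscriptModel]) -> None:
        """Write reads as SAM alignments against the C-to-T converted reference.

        Requires read_start/read_span (full read extent); read sequences are
        reconstructed from the reference with each observed C's state.
        """
        if self.read_start is None or self.read_span is None:
            raise ValueError("SAM export needs read_start and read_span")
        index = transcript_index(transcriptome)
        order = np.argsort(self.obs_read, kind="stable")
        bounds = np.searchsorted(self.obs_read[order], np.arange(self.n_reads + 1))
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for tid in self.transcript_ids:
                fh.write(f"@SQ\tSN:{tid}\tLN:{len(index[tid])}\n")
            for i in range(self.n_reads):
                tid = self.transcript_ids[self.read_tid[i]]
                start = int(self.read_start[i])
                span = int(self.read_span[i])
                ref_dna = _rna_to_dna(index[tid].sequence[start : start + span])
                seq = list(ref_dna.replace("C", "T"))  # converted by default
                quals = np.full(span, 37, dtype=np.int16)
                for j in order[bounds[i] : bounds[i + 1]]:
                    off = int(self.obs_pos[j]) - start
                    seq[off] = "C" if self.obs_state_c[j] else "T"
                    quals[off] = self.obs_qual[j]
                qual_str = "".join(chr(q + 33) for q in quals)
                fh.write(
                    f"{self.read_id(i)}\t0\t{tid}\t{start + 1}\t60\t{span}M\t*\t0\t0\t"
                    f"{''.join(seq)}\t{qual_str}\n"
                )

    @classmethod
    def from_sam(cls, path: str, transcriptome: Sequence[TranscriptModel]) -> "ReadTable":
        """Ingest sense-strand SAM alignments against the converted reference.

        The original (unconverted) transcript sequences recover each covered
        reference-C's status: read base C = unconverted, T = converted; other
        bases (sequencing errors) are skipped. Reverse-strand alignments are
        rejected: the caller operates in transcript (sense) space.
        """
        index = transcript_index(transcriptome)
        c_positions = {
            tid: np.frombuffer(t.sequence.encode(), dtype=np.uint8) == ord("C")
            for tid, t in index.items()
        }
        tids: list[str] = []
        tid_code: dict[str, int] = {}
        read_tid, read_ids, starts, spans = [], [], [], []
        obs_read, obs_pos, obs_c, obs_q = [], [], [], []
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped:
                    continue
                if aln.is_reverse:
                    raise ValueError(
                        f"read {aln.query_name}: reverse-strand alignment; "
                        "only sense-strand transcriptome alignments are accepted"
                    )
                tid = aln.reference_name
                if tid not in index:
                    raise ValueError(f"read {aln.query_name}: unknown reference {tid}")
                code = tid_code.get(tid)
                if code is None:
                    code = tid_code[tid] = len(tids)
                    tids.append(tid)
                i = len(read_tid)
                read_tid.append(code)
                read_ids.append(aln.query_name)
                starts.append(aln.reference_start)
                spans.append(aln.reference_end - aln.reference_start)
                seq = aln.query_sequence
                quals = aln.query_qualities
                is_c = c_positions[tid]
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                    if not is_c[rpos]:
                        continue
                    base = seq[qpos]
                    if base not in ("C", "T"):
                        continue
                    obs_read.append(i)
                    obs_pos.append(rpos)
                    obs_c.append(base == "C")
                    obs_q.append(quals[qpos] if quals is not None else 37)
        return cls(
            tids,
            np.array(read_tid, dtype=np.int32),
            np.array(obs_read, dtype=np.int64),
            np.array(obs_pos, dtype=np.int32),
            np.array(obs_c, dtype=bool),
            np.array(obs_q, dtype=np.int16),
            read_ids=read_ids,
            read_start=np.array(starts, dtype=np.int32),
            read_span=np.array(spans, dtype=np.int32),
        )
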