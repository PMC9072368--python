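"""Targeted bisulfite amplicon analysis of synthesized substrate pools.

Reads from a mutagenesis pool (all motif variants of a substrate backbone)
are assigned to variants by best match against the appropriate reference
(C-to-T converted for bisulfite reads), deduplicated on barcodes required to
be unique in both the DNA and BS libraries, and per-variant methylation
levels are quantified as C / (C + T) at the assayed site.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SubstrateVariant:
    """One synthesized substrate (~140 nt) with its assayed C and motif."""

    variant_id: str
    sequence: str  # RNA alphabet
    site_offset: int
    motif_signature: str
    n_motif_G: int
    mutation_tags: list[str] = field(default_factory=list)
    planted_level: float | None = None  # synthetic pools only

    def __post_init__(self) -> None:
        if self.sequence[self.site_offset] != "C":
            raise ValueError(f"{self.variant_id}: base at site_offset is not C")
        if self.n_motif_G != self.motif_signature.count("G"):
            raise ValueError(f"{self.variant_id}: n_motif_G inconsistent with motif")


@dataclass
class AmpliconRead:
    read_id: str
    barcode: str
    variant_id: str
    site_call: str  # 'C', 'T', or '.' (neither)


@dataclass(frozen=True)
class AssignConfig:
    barcode_len: int = 12
    max_distance: int = 5


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _converted_reference(variant: SubstrateVariant) -> str:
    """DNA-alphabet reference with every C except the assayed site converted."""
    dna = variant.sequence.replace("U", "T")
    out = bytearray(dna.replace("C", "T").encode())
    out[variant.site_offset] = ord("C")
    return out.decode()


def validate_pool(variants: Sequence[SubstrateVariant]) -> None:
    """Converted references must be mutually distinguishable."""
    refs = {}
    collisions = []
    for v in variants:
        key = _converted_reference(v)
        if key in refs:
            collisions.append((refs[key], v.variant_id))
        refs[key] = v.variant_id
    if collisions:
        raise ValueError(
            f"converted-reference collisions between variants: {collisions[:5]}"
        )


def assign_reads(
    bs_reads: Sequence[tuple[str, str]],
    variants: Sequence[SubstrateVariant],
    config: AssignConfig = AssignConfig(),
) -> tuple[list[AmpliconRead], int]:
    """Assign bisulfite reads to variants by best Hamming match.

    Each read (read_id, barcode + amplicon sequence) is compared to every
    variant's C-to-T converted reference; the unique best match within
    ``max_distance`` wins, ties and distant reads are discarded and counted.
    Returns assigned reads (with the C/T call at the assayed site) and the
    unassigned count.
    """
    validate_pool(variants)
    ref_len = len(variants[0].sequence)
    if any(len(v.sequence) != ref_len for v in variants):
        raise ValueError("all variant references must have equal length")
    ref_mat = np.stack([_encode(_converted_reference(v)) for v in variants])
    exact = { _converted_reference(v): i for i, v in enumerate(variants) }
    # a methylated read differs from the converted reference only by C at
    # unconverted positions; precompute site offsets
    site_offsets = np.array([v.site_offset for v in variants])

    assigned: list[AmpliconRead] = []
    unassigned = 0
    bl = config.barcode_len
    pending_idx, pending_mat, pending_meta = [], [], []
    for rid, seq in bs_reads:
        barcode, amplicon = seq[:bl], seq[bl:]
        if len(amplicon) != ref_len:
            unassigned += 1
            continue
        hit = exact.get(amplicon)
        if hit is not None:
            v = variants[hit]
            base = amplicon[v.site_offset]
            assigned.append(AmpliconRead(rid, barcode, v.variant_id,
                                         base if base in "CT" else "."))
            continue
        pending_idx.append(len(pending_mat))
        pending_mat.append(_encode(amplicon))
        pending_meta.append((rid, barcode))
    if pending_mat:
        reads_arr = np.stack(pending_mat)
        chunk = 512
        for lo in range(0, len(reads_arr), chunk):
            block = reads_arr[lo : lo + chunk]
            # Hamming distance, ignoring the assayed-site column per variant
            dists = (block[:, None, :] != ref_mat[None, :, :]).sum(axis=2)
            site_mismatch = (
                block[:, site_offsets] != ref_mat[np.arange(len(variants)), site_offsets]
            )
            dists = dists - site_mismatch.astype(int)
            best = dists.argmin(axis=1)
            best_d = dists[np.arange(len(block)), best]
            dists[np.arange(len(block)), best] = np.iinfo(dists.dtype).max
            second_d = dists.min(axis=1)
            for i in range(len(block)):
                rid, barcode = pending_meta[lo + i]
                if best_d[i] > config.max_distance or second_d[i] == best_d[i]:
                    unassigned += 1
                    continue
                v = variants[int(best[i])]
                base = chr(block[i, v.site_offset])
                assigned.append(AmpliconRead(rid, barcode, v.variant_id,
                                             base if base in "CT" else "."))
    return assigned, unassigned


def dedupe_barcodes(
    dna_reads: Sequence[tuple[str, str]],
    bs_reads: Sequence[AmpliconRead],
    barcode_len: int = 12,
) -> list[AmpliconRead]:
    """Retain BS reads whose barcode occurs exactly once in the BS library
    and exactly once in the DNA library."""
    dna_counts: dict[str, int] = {}
    for _, seq in dna_reads:
        bc = seq[:barcode_len]
        dna_counts[bc] = dna_counts.get(bc, 0) + 1
    bs_counts: dict[str, int] = {}
    for r in bs_reads:
        bs_counts[r.barcode] = bs_counts.get(r.barcode, 0) + 1
    return [
        r
        for r in bs_reads
        if bs_counts[r.barcode] == 1 and dna_counts.get(r.barcode, 0) == 1
    ]


def variant_level(reads: Sequence[AmpliconRead]) -> float | None:
    """Methylation level C / (C + T) at the assayed site; None when no read
    is informative."""
    c = sum(1 for r in reads if r.site_call == "C")
    t = sum(1 for r in reads if r.site_call == "T")
    if c + t == 0:
        return None
    return c / (c + t)


def variant_level_table(
    reads: Sequence[AmpliconRead], variants: Sequence[SubstrateVariant]
) -> pd.DataFrame:
    by_variant: dict[str, list[AmpliconRead]] = {v.variant_id: [] for v in variants}
    for r in reads:
        by_variant.setdefault(r.variant_id, []).append(r)
    rows = []
    for v in variants:
        vs = by_variant[v.variant_id]
        rows.append(
            {
                "variant_id": v.variant_id,
                "motif": v.motif_signature,
                "n_motif_G": v.n_motif_G,
                "n_reads": len(vs),
                "n_informative": sum(1 for r in vs if r.site_call in "CT"),
                "level": variant_level(vs),
                "planted_level": v.planted_level,
            }
        )
    return pd.DataFrame(rows)


def motif_series(level_table: pd.DataFrame, variants: Sequence[SubstrateVariant]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped level summaries by motif G count and by mutation tag."""
    defined = level_table.dropna(subset=["level"])
    by_g = (
        defined.groupby("n_motif_G")["level"]
        .agg(n="count", median="median",
             q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    tag_rows = []
    levels = dict(zip(level_table.variant_id, level_table.level))
    tag_map: dict[str, list[float]] = {}
    for v in variants:
        lv = levels.get(v.variant_id)
        if lv is None or (isinstance(lv, float) and np.isnan(lv)):
            continue
        for tag in v.mutation_tags:
            tag_map.setdefault(tag, []).append(lv)
    for tag in sorted(tag_map):
        vals = pd.Series(tag_map[tag])
        tag_rows.append(
            {
                "mutation_tag": tag,
                "n": len(vals),
                "median": vals.median(),
                "q1": vals.quantile(0.25),
                "q3": vals.quantile(0.75),
            }
        )
    return by_g, pd.DataFrame(tag_rows)
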