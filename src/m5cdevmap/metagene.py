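"""Metagene density and GC profiles over region-proportional bins.

Transcripts are scaled into a fixed number of 5'UTR, CDS and 3'UTR bins
(e.g. 10:50:40 for a transcriptome with mean region lengths 100/500/400);
per-bin density is the number of m5C sites over the number of background
covered Cs falling in that bin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .models import BinLayout, TranscriptModel, transcript_index


def overall_density(n_sites: int, n_covered_c: int) -> float:
    """m5C sites per thousand covered Cs."""
    if n_covered_c <= 0:
        raise ValueError("background C count must be positive")
    return 1000.0 * n_sites / n_covered_c


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def derive_layout(transcriptome: Sequence[TranscriptModel], n_utr5: int = 10) -> BinLayout:
    """Fix the 5'UTR at ``n_utr5`` bins; scale CDS and 3'UTR bin counts by
    their mean lengths relative to the mean 5'UTR length."""
    if n_utr5 < 1:
        raise ValueError("n_utr5 must be >= 1")
    transcripts = list(transcriptome)
    if not transcripts:
        raise ValueError("no annotated transcripts")
    mean_utr5 = float(np.mean([t.utr5_len for t in transcripts]))
    if mean_utr5 <= 0:
        raise ValueError("mean 5'UTR length must be positive")
    mean_cds = float(np.mean([t.cds_len for t in transcripts]))
    mean_utr3 = float(np.mean([t.utr3_len for t in transcripts]))
    return BinLayout(
        n_utr5=n_utr5,
        n_cds=max(1, _round_half_away(n_utr5 * mean_cds / mean_utr5)),
        n_utr3=max(1, _round_half_away(n_utr5 * mean_utr3 / mean_utr5)),
    )


class UnbinnablePosition(ValueError):
    """Position lies in a zero-length annotated region."""


def assign_bin(position: int, transcript: TranscriptModel, layout: BinLayout) -> int:
    """Map a transcript position to its metagene bin.

    The region-local fractional coordinate f = offset / region_length maps to
    floor(f * n_region_bins), clamped into the region's bin range so region
    bins stay disjoint.
    """
    region = transcript.region_of(position)
    if region == "utr5":
        offset, length, n, base = position, transcript.utr5_len, layout.n_utr5, 0
    elif region == "cds":
        offset = position - transcript.utr5_len
        length, n, base = transcript.cds_len, layout.n_cds, layout.n_utr5
    else:
        offset = position - transcript.utr5_len - transcript.cds_len
        length, n, base = transcript.utr3_len, layout.n_utr3, layout.n_utr5 + layout.n_cds
    if length <= 0:
        raise UnbinnablePosition(
            f"{transcript.transcript_id}:{position} lies in zero-length {region}"
        )
    return base + min(n - 1, int(offset / length * n))


def density_profile(
    site_positions: Sequence[tuple[str, int]],
    background_positions: Sequence[tuple[str, int]],
    transcriptome: Sequence[TranscriptModel],
    layout: BinLayout,
) -> pd.DataFrame:
    """Per-bin m5C density (sites / background Cs) with a max-normalized column.

    Positions in transcripts lacking UTR annotation (zero-length region) are
    excluded and tallied in the ``n_skipped`` attribute of the result.
    """
    index = transcript_index(transcriptome)
    site_counts = np.zeros(layout.n_bins, dtype=int)
    bg_counts = np.zeros(layout.n_bins, dtype=int)
    skipped = 0
    for counts, positions in ((site_counts, site_positions), (bg_counts, background_positions)):
        for tid, pos in positions:
            try:
                counts[assign_bin(pos, index[tid], layout)] += 1
            except UnbinnablePosition:
                skipped += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(bg_counts > 0, site_counts / np.maximum(bg_counts, 1), np.nan)
    finite = density[np.isfinite(density)]
    peak = finite.max() if finite.size else np.nan
    region = sum(
        ([name] * len(r) for name, r in layout.region_slices().items()), []
    )
    df = pd.DataFrame(
        {
            "bin": np.arange(layout.n_bins),
            "region": region,
            "m5c_count": site_counts,
            "background_c": bg_counts,
            "density": density,
            "density_normalized": density / peak if np.isfinite(peak) and peak > 0 else np.full(layout.n_bins, np.nan),
        }
    )
    df.attrs["n_skipped"] = skipped
    return df


def gc_profile(
    transcriptome: Sequence[TranscriptModel], layout: BinLayout
) -> pd.DataFrame:
    """Per-bin GC fraction over all transcript nucleotides falling in the bin."""
    gc = np.zeros(layout.n_bins, dtype=np.int64)
    total = np.zeros(layout.n_bins, dtype=np.int64)
    for t in transcriptome:
        for pos, base in enumerate(t.sequence):
            try:
                b = assign_bin(pos, t, layout)
            except UnbinnablePosition:
                continue
            total[b] += 1
            if base in "GC":
                gc[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, gc / np.maximum(total, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(layout.n_bins), "gc": frac, "n_nt": total})


@dataclass(frozen=True)
class DensityGCCorrelation:
    r: float
    r_squared: float
    n_bins: int


def density_gc_correlation(
    density: Sequence[float], gc: Sequence[float]
) -> DensityGCCorrelation:
    """Pearson correlation (and r^2) between per-bin density and GC content."""
    d = np.asarray(density, dtype=float)
    g = np.asarray(gc, dtype=float)
    ok = np.isfinite(d) & np.isfinite(g)
    d, g = d[ok], g[ok]
    if len(d) < 3:
        raise ValueError("need at least three bins for a correlation")
    if np.ptp(d) == 0 or np.ptp(g) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r, _ = _scipy_stats.pearsonr(d, g)
    return DensityGCCorrelation(r=float(r), r_squared=float(r * r), n_bins=len(d))
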