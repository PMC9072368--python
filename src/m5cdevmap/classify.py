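"""Type I / Type II classification of called sites by downstream motif.

Type II sites (NSUN6-dependent, hairpin-loop located) carry a downstream
U,C,N,A context: positions +1..+4 relative to the methylated C read U, C,
any base, A.  Everything else is Type I (NSUN2-dependent, downstream G-rich,
5' end of hairpin stems).  An alternative registration, reading the motif as
C,U,[site],N,A across positions -2..+2, is available via ``registration``
for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .models import TranscriptModel, transcript_index

FLANK = 25
Registration = Literal["downstream", "centered"]


@dataclass(frozen=True)
class SiteContext:
    """A site's clipped 25-nt flanks; ``core`` must be C."""

    transcript_id: str
    position: int
    upstream: str
    core: str
    downstream: str

    def __post_init__(self) -> None:
        if self.core != "C":
            raise ValueError(
                f"{self.transcript_id}:{self.position}: core base is "
                f"{self.core!r}, expected C"
            )


def extract_context(
    transcript: TranscriptModel, position: int, flank: int = FLANK
) -> SiteContext:
    """Flanks are clipped (never padded) at transcript ends."""
    seq = transcript.sequence
    if not 0 <= position < len(seq):
        raise IndexError(f"position {position} outside {transcript.transcript_id}")
    return SiteContext(
        transcript_id=transcript.transcript_id,
        position=position,
        upstream=seq[max(0, position - flank) : position],
        core=seq[position],
        downstream=seq[position + 1 : position + 1 + flank],
    )


def classify_site(context: SiteContext, registration: Registration = "downstream") -> str:
    """Return 'TypeII' for the U,C,N,A downstream motif, else 'TypeI'."""
    if registration == "downstream":
        d = context.downstream
        if len(d) >= 4 and d[0] == "U" and d[1] == "C" and d[3] == "A":
            return "TypeII"
        return "TypeI"
    if registration == "centered":
        u, d = context.upstream, context.downstream
        if len(u) >= 2 and len(d) >= 2 and u[-2] == "C" and u[-1] == "U" and d[1] == "A":
            return "TypeII"
        return "TypeI"
    raise ValueError(f"unknown registration {registration!r}")


def classify_sites(
    sites,
    transcriptome: Sequence[TranscriptModel],
    registration: Registration = "downstream",
) -> list[str]:
    """Classify MethylationSite objects in place (fills ``site_type``)."""
    index = transcript_index(transcriptome)
    labels = []
    for s in sites:
        ctx = extract_context(index[s.transcript_id], s.position)
        s.site_type = classify_site(ctx, registration)
        labels.append(s.site_type)
    return labels


def position_frequency_matrix(contexts: Sequence[SiteContext]) -> pd.DataFrame:
    """Base counts at positions -25..+25 (0 = site).

    Each column (position) counts only the contexts whose flank actually
    reaches it, so column sums equal the number of contributing sites.
    """
    if not contexts:
        raise ValueError("need at least one context")
    positions = np.arange(-FLANK, FLANK + 1)
    counts = {b: np.zeros(len(positions), dtype=int) for b in "ACGU"}
    for ctx in contexts:
        for i, base in enumerate(reversed(ctx.upstream)):
            counts[base][FLANK - 1 - i] += 1
        counts[ctx.core][FLANK] += 1
        for i, base in enumerate(ctx.downstream):
            counts[base][FLANK + 1 + i] += 1
    df = pd.DataFrame(counts, index=pd.Index(positions, name="position"))
    return df
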