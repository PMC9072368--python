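"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open internally; exported tables use 1-based
inclusive positions. Sequences are RNA-alphabet strings (A/C/G/U) in sense
(transcript) orientation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

RNA_ALPHABET = frozenset("ACGU")

SiteType = Literal["TypeI", "TypeII"]


@dataclass
class TranscriptModel:
    """A transcript with its coding-region annotation.

    ``utr5_len + cds_len + utr3_len`` must equal the sequence length and the
    CDS must be non-empty.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.cds_len <= 0:
            raise ValueError(f"{self.transcript_id}: cds_len must be > 0")
        if min(self.utr5_len, self.utr3_len) < 0:
            raise ValueError(f"{self.transcript_id}: negative region length")
        total = self.utr5_len + self.cds_len + self.utr3_len
        if total != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: region lengths sum to {total}, "
                f"sequence length is {len(self.sequence)}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.transcript_id}: non-RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, position: int) -> str:
        """Region name ('utr5'/'cds'/'utr3') containing a 0-based position."""
        if not 0 <= position < len(self.sequence):
            raise IndexError(f"position {position} outside {self.transcript_id}")
        if position < self.utr5_len:
            return "utr5"
        if position < self.utr5_len + self.cds_len:
            return "cds"
        return "utr3"


@dataclass(frozen=True)
class TruthSite:
    """A planted methylation site with its ground-truth level and type."""

    transcript_id: str
    position: int  # 0-based, a C in the transcript
    true_level: float
    planted_type: SiteType

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_level <= 1.0:
            raise ValueError("true_level outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the bisulfite read simulator.

    ``conversion_rate`` is the per-gene probability that an unmethylated C is
    read as T; ``bad_read_fraction`` is the fraction of reads drawn from the
    all-or-none conversion-failure mode (every covered C left unconverted),
    the failure mode the C-cutoff read filter targets.
    """

    n_genes: int = 200
    coverage_mean: float = 60.0
    conversion_rate: float = 0.995
    bad_read_fraction: float = 0.02
    read_len: int = 100
    seed: int = 0
    # base-quality two-point mixture: Phred 37 w.p. 0.99 else Phred 20,
    # exercising the Q>=30 filter.
    qual_hi: int = 37
    qual_lo: int = 20
    qual_hi_prob: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in (0, 1]")
        if not 0.0 <= self.bad_read_fraction < 1.0:
            raise ValueError("bad_read_fraction must be in [0, 1)")
        if self.read_len < 1 or self.coverage_mean <= 0:
            raise ValueError("read_len and coverage_mean must be positive")


@dataclass
class ReadCytosineRecord:
    """One aligned bisulfite read's observations at reference-C positions.

    ``obs`` is an ordered list of (position, state, qual) with state 'C'
    (unconverted, i.e. methylation signal) or 'T' (converted); positions are
    0-based transcript coordinates and strictly increasing.
    """

    read_id: str
    transcript_id: str
    obs: list[tuple[int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = -1
        for pos, state, qual in self.obs:
            if state not in ("C", "T"):
                raise ValueError(f"read {self.read_id}: bad state {state!r}")
            if qual < 0:
                raise ValueError(f"read {self.read_id}: negative quality")
            if pos <= last:
                raise ValueError(
                    f"read {self.read_id}: positions not strictly increasing"
                )
            last = pos

    @property
    def n_unconverted(self) -> int:
        return sum(1 for _, state, _ in self.obs if state == "C")


@dataclass(frozen=True)
class BinLayout:
    """Number of metagene bins for 5'UTR, CDS and 3'UTR."""

    n_utr5: int
    n_cds: int
    n_utr3: int

    def __post_init__(self) -> None:
        if min(self.n_utr5, self.n_cds, self.n_utr3) < 1:
            raise ValueError("all bin counts must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.n_utr5 + self.n_cds + self.n_utr3

    def region_slices(self) -> dict[str, range]:
        return {
            "utr5": range(0, self.n_utr5),
            "cds": range(self.n_utr5, self.n_utr5 + self.n_cds),
            "utr3": range(self.n_utr5 + self.n_cds, self.n_bins),
        }


def transcript_index(transcriptome: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in transcriptome}
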