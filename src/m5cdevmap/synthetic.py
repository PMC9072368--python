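"""Synthetic data with planted truth for every pipeline stage.

The generators emulate the statistical structure of mRNA bisulfite
sequencing of maternal transcriptomes: per-gene conversion rates around
99-99.9%, a small minority of conversion-failure reads (every covered C
left unconverted), planted methylation levels >= 10% in Type I (downstream
G-rich) and Type II (downstream U,C,N,A) sequence contexts, two replicates
per sample, and paired "species" transcriptomes related by point
substitutions whose methylation gain/loss follows a logistic model over
sequence and structure features.

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import (
    ReadCytosineRecord,
    SimulationConfig,
    TranscriptModel,
    TruthSite,
    transcript_index,
)
from .reads import ReadTable

_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)


class CapacityError(ValueError):
    """Requested more planted sites than eligible positions exist."""


# --------------------------------------------------------------------------
# transcriptome generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthParams:
    """Region-length spec: each field is a fixed int or an inclusive
    (low, high) uniform range."""

    utr5: int | tuple[int, int] = (50, 250)
    cds: int | tuple[int, int] = (600, 2000)
    utr3: int | tuple[int, int] = (200, 900)

    def draw(self, region: str, rng: np.random.Generator) -> int:
        spec = getattr(self, region)
        if isinstance(spec, int):
            value = spec
        else:
            low, high = spec
            if low > high:
                raise ValueError(f"{region}: degenerate range {spec}")
            value = int(rng.integers(low, high + 1))
        if value < 0 or (region == "cds" and value < 1):
            raise ValueError(f"{region}: invalid length {value}")
        return value


def _random_sequence(length: int, gc: float | np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random RNA sequence as uint8 codes with per-position GC probability."""
    gc = np.broadcast_to(np.asarray(gc, dtype=float), (length,))
    u = rng.random(length)
    is_gc = u < gc
    second = rng.random(length) < 0.5  # C vs G, U vs A
    out = np.where(
        is_gc,
        np.where(second, ord("C"), ord("G")),
        np.where(second, ord("U"), ord("A")),
    )
    return out.astype(np.uint8)


def make_transcriptome(
    n_genes: int,
    length_params: LengthParams | None = None,
    gc_gradient: Sequence[float] | None = None,
    seed: int = 0,
    gc_content: float = 0.5,
) -> list[TranscriptModel]:
    """Generate ``n_genes`` annotated transcripts (one per gene).

    ``gc_gradient`` gives per-bin GC targets applied 5'->3' along each
    transcript (equal-width bins); without it a flat ``gc_content`` is used.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = length_params or LengthParams()
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_genes):
        lens = {r: params.draw(r, rng) for r in ("utr5", "cds", "utr3")}
        total = sum(lens.values())
        if gc_gradient is not None:
            targets = np.asarray(gc_gradient, dtype=float)
            if targets.ndim != 1 or len(targets) < 1 or (targets < 0).any() or (targets > 1).any():
                raise ValueError("gc_gradient must be a 1-D sequence of fractions")
            edges = np.linspace(0, total, len(targets) + 1)
            per_pos = targets[
                np.clip(np.searchsorted(edges, np.arange(total), side="right") - 1,
                        0, len(targets) - 1)
            ]
        else:
            per_pos = gc_content
        codes = _random_sequence(total, per_pos, rng)
        out.append(
            TranscriptModel(
                transcript_id=f"tx{g:05d}",
                gene_id=f"gene{g:05d}",
                sequence=codes.tobytes().decode(),
                utr5_len=lens["utr5"],
                cds_len=lens["cds"],
                utr3_len=lens["utr3"],
            )
        )
    return out


# --------------------------------------------------------------------------
# truth planting
# --------------------------------------------------------------------------

def _as_level_sampler(
    level_dist: float | tuple[float, float] | Callable[[np.random.Generator, int], np.ndarray],
) -> Callable[[np.random.Generator, int], np.ndarray]:
    if callable(level_dist):
        return level_dist
    if isinstance(level_dist, tuple):
        lo, hi = level_dist
        return lambda rng, n: rng.uniform(lo, hi, n)
    value = float(level_dist)
    return lambda rng, n: np.full(n, value)


def plant_truth(
    transcriptome: list[TranscriptModel],
    n_sites: int,
    type_mix: float = 0.237,
    level_dist: float | tuple[float, float] | Callable = (0.2, 0.8),
    seed: int = 0,
    min_spacing: int = 120,
) -> list[TruthSite]:
    """Plant ``n_sites`` methylation sites, editing sequences in place.

    ``type_mix`` is the fraction of Type II sites (downstream +1..+4 set to
    U,C,N,A); the remainder are Type I (downstream +1..+3 set to G,G,G).
    The planted base at the site itself is set to C.  Sites are spaced at
    least ``min_spacing`` nt apart (default 120, a few sites per mRNA as in
    heavily methylated maternal transcriptomes) so that single reads rarely
    span several methylated sites and motifs never overlap.
    """
    if not 0.0 <= type_mix <= 1.0:
        raise ValueError("type_mix must be a fraction")
    if min_spacing < 8:
        raise ValueError("min_spacing must be >= 8 (motif width plus core)")
    rng = np.random.default_rng(seed)
    sampler = _as_level_sampler(level_dist)

    eligible: list[tuple[int, int]] = []  # (transcript index, position)
    for ti, t in enumerate(transcriptome):
        # need room for the downstream 4-mer and 2 nt of upstream context;
        # random phase so positions are not synchronized across transcripts
        if len(t) < 12:
            continue
        phase = int(rng.integers(0, min(min_spacing, max(1, len(t) - 11))))
        for pos in range(2 + phase, len(t) - 5, min_spacing):
            eligible.append((ti, pos))
    if n_sites > len(eligible):
        raise CapacityError(
            f"requested {n_sites} sites but only {len(eligible)} eligible positions"
        )
    chosen = rng.choice(len(eligible), size=n_sites, replace=False)
    is_type2 = rng.random(n_sites) < type_mix
    levels = np.clip(sampler(rng, n_sites), 0.10, 1.0)

    seqs = {ti: bytearray(transcriptome[ti].sequence.encode()) for ti in
            {eligible[c][0] for c in chosen}}
    truth = []
    for k, ci in enumerate(chosen):
        ti, pos = eligible[ci]
        seq = seqs[ti]
        seq[pos] = ord("C")
        if is_type2[k]:
            n_base = _BASES[rng.integers(0, 4)]
            seq[pos + 1 : pos + 5] = bytes([ord("U"), ord("C"), n_base, ord("A")])
            stype = "TypeII"
        else:
            seq[pos + 1 : pos + 4] = b"GGG"
            stype = "TypeI"
        truth.append(
            TruthSite(transcriptome[ti].transcript_id, pos, float(levels[k]), stype)
        )
    for ti, seq in seqs.items():
        transcriptome[ti].sequence = seq.decode()
    truth.sort(key=lambda s: (s.transcript_id, s.position))
    return truth


def plant_sites_proportional(
    transcriptome: list[TranscriptModel],
    layout,
    total_sites: int,
    bin_weights: Sequence[float],
    level: float = 0.5,
    seed: int = 0,
) -> list[TruthSite]:
    """Plant Type I sites whose per-bin *density* tracks ``bin_weights``.

    Densities are sites over background Cs, so the number of sites placed in
    a bin is proportional to ``weight * available C count``; used to
    construct data whose metagene density follows a chosen per-bin signal
    (e.g. local GC content).  Sites are placed on existing Cs; no motif
    editing is performed.
    """
    from .metagene import assign_bin  # local import: metagene does not import us

    rng = np.random.default_rng(seed)
    weights = np.asarray(bin_weights, dtype=float)
    if len(weights) != layout.n_bins or (weights < 0).any() or weights.sum() == 0:
        raise ValueError("bin_weights must be non-negative, one per bin")

    by_bin: dict[int, list[tuple[str, int]]] = {b: [] for b in range(layout.n_bins)}
    for t in transcriptome:
        for pos, base in enumerate(t.sequence):
            if base == "C":
                by_bin[assign_bin(pos, t, layout)].append((t.transcript_id, pos))
    alloc = weights * np.array([len(by_bin[b]) for b in range(layout.n_bins)])
    if alloc.sum() == 0:
        raise CapacityError("no C positions available in weighted bins")
    per_bin = np.floor(alloc / alloc.sum() * total_sites).astype(int)
    truth = []
    for b, want in enumerate(per_bin):
        pool = by_bin[b]
        if want > len(pool):
            raise CapacityError(f"bin {b}: {want} sites requested, {len(pool)} Cs available")
        for i in rng.choice(len(pool), size=want, replace=False):
            tid, pos = pool[i]
            truth.append(TruthSite(tid, pos, level, "TypeI"))
    return truth


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def simulate_reads(
    transcriptome: list[TranscriptModel],
    truth: Sequence[TruthSite],
    config: SimulationConfig,
    seed: int | None = None,
) -> ReadTable:
    """Simulate single-end bisulfite reads in transcript (sense) space.

    At a truth site the expected unconverted fraction among good reads is
    ``level + (1 - level) * (1 - conversion_rate)``; elsewhere it is
    ``1 - conversion_rate``.  A ``bad_read_fraction`` of reads model
    conversion failure: every covered C is left unconverted.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    index = {t.transcript_id: i for i, t in enumerate(transcriptome)}
    truth_by_tx: dict[int, list[TruthSite]] = {}
    for s in truth:
        truth_by_tx.setdefault(index[s.transcript_id], []).append(s)

    tids = [t.transcript_id for t in transcriptome]
    all_read_tid, all_start, all_span = [], [], []
    all_obs_read, all_obs_pos, all_obs_c, all_obs_q = [], [], [], []
    read_offset = 0
    for ti, t in enumerate(transcriptome):
        L = len(t)
        span = min(config.read_len, L)
        n_reads = max(1, round(config.coverage_mean * L / span))
        conv = config.conversion_rate
        c_pos = np.flatnonzero(
            np.frombuffer(t.sequence.encode(), dtype=np.uint8) == ord("C")
        ).astype(np.int32)

        starts = rng.integers(0, L - span + 1, n_reads).astype(np.int32)
        bad = rng.random(n_reads) < config.bad_read_fraction
        lo = np.searchsorted(c_pos, starts).astype(np.int64)
        hi = np.searchsorted(c_pos, starts + span).astype(np.int64)
        counts = hi - lo
        total = int(counts.sum())
        obs_read_local = np.repeat(np.arange(n_reads), counts)
        # concatenated ranges lo[i]..hi[i] without a Python loop
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        c_idx = np.repeat(lo, counts) + offsets
        obs_pos = c_pos[c_idx]

        level_at = np.zeros(len(c_pos))
        is_site = np.zeros(len(c_pos), dtype=bool)
        for s in truth_by_tx.get(ti, []):
            where = np.searchsorted(c_pos, s.position)
            if where >= len(c_pos) or c_pos[where] != s.position:
                raise ValueError(
                    f"truth site {s.transcript_id}:{s.position} is not a C"
                )
            level_at[where] = s.true_level
            is_site[where] = True
        p_c = np.where(is_site[c_idx],
                       level_at[c_idx] + (1.0 - level_at[c_idx]) * (1.0 - conv),
                       1.0 - conv)
        unconverted = rng.random(total) < p_c
        unconverted |= bad[obs_read_local]
        quals = np.where(
            rng.random(total) < config.qual_hi_prob, config.qual_hi, config.qual_lo
        ).astype(np.int16)

        all_read_tid.append(np.full(n_reads, ti, dtype=np.int32))
        all_start.append(starts)
        all_span.append(np.full(n_reads, span, dtype=np.int32))
        all_obs_read.append(obs_read_local + read_offset)
        all_obs_pos.append(obs_pos)
        all_obs_c.append(unconverted)
        all_obs_q.append(quals)
        read_offset += n_reads

    return ReadTable(
        tids,
        np.concatenate(all_read_tid),
        np.concatenate(all_obs_read),
        np.concatenate(all_obs_pos),
        np.concatenate(all_obs_c),
        np.concatenate(all_obs_q),
        read_start=np.concatenate(all_start),
        read_span=np.concatenate(all_span),
    )


def simulate_replicates(
    transcriptome: list[TranscriptModel],
    truth: Sequence[TruthSite],
    config: SimulationConfig,
    n_replicates: int = 2,
) -> list[ReadTable]:
    """Independent replicate libraries from one root seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates)
    return [
        simulate_reads(transcriptome, truth, config, seed=int(s % (2**31)))
        for s in seeds
    ]


# --------------------------------------------------------------------------
# minimal structure folder (maximum base pairing)
# --------------------------------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def fold_minimal(seq: str, min_loop: int = 3) -> str:
    """Maximum base-pairing dot-bracket by dynamic programming.

    A combinatorial stand-in for thermodynamic folding: maximizes the number
    of AU/GC/GU pairs with hairpin loops of at least ``min_loop`` nt. Not a
    free-energy model; the pipeline accepts externally computed dot-brackets
    wherever structures matter.
    """
    bad = set(seq) - {"A", "C", "G", "U"}
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)}")
    n = len(seq)
    if n == 0:
        return ""
    can_pair = lambda i, j: (seq[i], seq[j]) in _PAIRS and j - i > min_loop
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in _PAIRS:
                    cand = (dp[i][k - 1] if k > i else 0) + 1 + \
                        (dp[k + 1][j - 1] if k + 1 <= j - 1 else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in _PAIRS:
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if dp[i][j] == left + 1 + inner:
                    struct[k], struct[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return "".join(struct)


def random_hairpin(half_width: int, rng: np.random.Generator, min_loop: int = 3) -> str:
    """A stochastic single-stem hairpin dot-bracket over ``2*half_width+1`` nt.

    Loop center, loop size and stem length vary; used to give species-pair
    structure features realistic per-position variance without folding.
    """
    L = 2 * half_width + 1
    struct = ["."] * L
    center = half_width + int(rng.integers(-5, 6))
    half_loop = int(rng.integers(max(2, (min_loop + 1) // 2), 6))
    stem = int(rng.integers(4, 16))
    for k in range(1, stem + 1):
        i, j = center - half_loop - k, center + half_loop + k
        if i < 0 or j >= L:
            break
        struct[i], struct[j] = "(", ")"
    return "".join(struct)


# --------------------------------------------------------------------------
# species pair with gain/loss labels from a logistic model
# --------------------------------------------------------------------------

@dataclass
class PairedSiteRecord:
    """One truth site viewed in both species of a synthetic pair."""

    transcript_id: str
    position: int
    true_level: float
    planted_type: str
    base_b: str
    retained: bool
    forced_lost: bool
    level_b: float
    cov_b: int
    context_a: str
    context_b: str
    struct_a: str
    struct_b: str
    features: dict[str, float] = field(default_factory=dict)


@dataclass
class SpeciesPair:
    transcriptome_b: list[TranscriptModel]
    ortholog_map: pd.DataFrame
    sites: list[PairedSiteRecord]
    window: int


def _parse_feature(name: str) -> tuple[str, int, str | None]:
    """'pair+3' -> ('pair', 3, None); 'base+1_U' -> ('base', 1, 'U')."""
    if name.startswith("pair"):
        return "pair", int(name[4:]), None
    if name.startswith("base"):
        offset_part, base = name[4:].split("_")
        return "base", int(offset_part), base
    raise ValueError(f"unknown feature name {name!r}")


def make_species_pair(
    transcriptome: list[TranscriptModel],
    truth: Sequence[TruthSite],
    sub_rate: float = 0.0,
    glm_coefs: dict[str, float] | None = None,
    seed: int = 0,
    window: int = 20,
) -> SpeciesPair:
    """Derive a second "species" by point substitutions and draw per-site
    methylation retention from a logistic model.

    ``glm_coefs`` maps feature names ('intercept', 'pair{offset:+d}',
    'base{offset:+d}_{B}') to coefficients; the linear predictor is applied
    to the species-B context's features (pairing status from a synthesized
    hairpin structure, base identities from the substituted sequence) and
    retention is Bernoulli(sigmoid).  A substitution of the site C itself
    forces loss.  Retained sites receive a species-B level near the truth
    level; lost sites receive a level < 5% with certifying coverage.
    """
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError("sub_rate must be in [0, 1)")
    coefs = dict(glm_coefs or {})
    intercept = coefs.pop("intercept", 0.0)
    parsed = {name: _parse_feature(name) for name in coefs}
    rng = np.random.default_rng(seed)

    transcriptome_b = []
    map_frames = []
    seq_b_by_tid: dict[str, str] = {}
    for t in transcriptome:
        codes = np.frombuffer(t.sequence.encode(), dtype=np.uint8).copy()
        mutate = rng.random(len(codes)) < sub_rate
        if mutate.any():
            # substitute to one of the three other bases, uniformly
            current = codes[mutate]
            shift = rng.integers(1, 4, mutate.sum())
            base_idx = np.searchsorted(np.sort(_BASES), current)
            order = np.argsort(_BASES)  # codes sorted: A,C,G,U already sorted
            codes[mutate] = np.sort(_BASES)[(base_idx + shift) % 4]
            del current, order
        seq_b = codes.tobytes().decode()
        tid_b = t.transcript_id + ".sp2"
        seq_b_by_tid[t.transcript_id] = seq_b
        transcriptome_b.append(
            TranscriptModel(tid_b, t.gene_id + ".sp2", seq_b,
                            t.utr5_len, t.cds_len, t.utr3_len)
        )
        positions = np.arange(len(t))
        map_frames.append(
            pd.DataFrame(
                {
                    "tidA": t.transcript_id,
                    "posA": positions,
                    "tidB": tid_b,
                    "posB": positions,
                    "baseA": list(t.sequence),
                    "baseB": list(seq_b),
                }
            )
        )
    ortholog_map = pd.concat(map_frames, ignore_index=True)

    index_a = transcript_index(transcriptome)
    sites = []
    for s in truth:
        seq_a = index_a[s.transcript_id].sequence
        seq_b = seq_b_by_tid[s.transcript_id]
        pos = s.position
        ctx_a = _window_seq(seq_a, pos, window)
        ctx_b = _window_seq(seq_b, pos, window)
        struct_a = random_hairpin(window, rng)
        struct_b = random_hairpin(window, rng)
        base_b = seq_b[pos]
        forced_lost = base_b != "C"

        feats: dict[str, float] = {}
        pair_b = np.array([c != "." for c in struct_b], dtype=float)
        eta = intercept
        for name, beta in coefs.items():
            kind, offset, basew = parsed[name]
            col = window + offset
            if kind == "pair":
                value = pair_b[col] if 0 <= col < len(pair_b) else 0.0
            else:
                ref_pos = pos + offset
                value = float(0 <= ref_pos < len(seq_b) and seq_b[ref_pos] == basew)
            feats[name] = value
            eta += beta * value
        p_keep = 1.0 / (1.0 + math.exp(-eta))
        retained = (not forced_lost) and bool(rng.random() < p_keep)
        if retained:
            level_b = float(np.clip(s.true_level + rng.normal(0, 0.03), 0.10, 1.0))
        else:
            level_b = float(rng.uniform(0.0, 0.02))
        cov_b = int(rng.poisson(30) + 20)
        sites.append(
            PairedSiteRecord(
                transcript_id=s.transcript_id,
                position=pos,
                true_level=s.true_level,
                planted_type=s.planted_type,
                base_b=base_b,
                retained=retained,
                forced_lost=forced_lost,
                level_b=level_b,
                cov_b=cov_b,
                context_a=ctx_a,
                context_b=ctx_b,
                struct_a=struct_a,
                struct_b=struct_b,
                features=feats,
            )
        )
    return SpeciesPair(transcriptome_b, ortholog_map, sites, window)


def _window_seq(seq: str, pos: int, w: int) -> str:
    """Sequence window pos +/- w, N-padded at transcript ends to fixed width."""
    lo, hi = pos - w, pos + w + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    return "N" * left_pad + seq[max(0, lo) : min(len(seq), hi)] + "N" * right_pad


# --------------------------------------------------------------------------
# targeted mutagenesis substrate pools
# --------------------------------------------------------------------------

def make_substrate_pool(
    seed: int = 0,
    ref_len: int = 140,
    site_offset: int = 70,
    motif_offsets: tuple[int, ...] = (1, 2, 3, 4),
    tag_offset: int = 10,
    tag_len: int = 8,
    level_fn: Callable[[int], float] | None = None,
):
    """All 4**len(motif_offsets) motif variants of one substrate backbone.

    Each variant carries a unique A/G identification tag (invariant under
    C-to-T conversion) so converted references stay mutually distinguishable.
    The planted methylation level rises with the number of Gs in the motif
    (``level_fn(n_motif_G)``, default 0.08 + 0.17 * n_G), emulating the
    G-count dependence of Type I substrates.
    """
    from .mutagenesis import SubstrateVariant

    n_variants = 4 ** len(motif_offsets)
    if n_variants > 2**tag_len:
        raise ValueError("tag_len too short to distinguish all variants")
    if level_fn is None:
        level_fn = lambda n_g: 0.08 + 0.17 * n_g
    rng = np.random.default_rng(seed)
    backbone = bytearray(_random_sequence(ref_len, 0.5, rng).tobytes())
    backbone[site_offset] = ord("C")

    variants = []
    bases = "ACGU"
    for v in range(n_variants):
        seq = bytearray(backbone)
        motif = []
        x = v
        for off in motif_offsets:
            b = bases[x % 4]
            x //= 4
            seq[site_offset + off] = ord(b)
            motif.append(b)
        tag = "".join("AG"[(v >> k) & 1] for k in range(tag_len))
        seq[tag_offset : tag_offset + tag_len] = tag.encode()
        motif_sig = "".join(motif)
        n_g = motif_sig.count("G")
        variants.append(
            SubstrateVariant(
                variant_id=f"var{v:04d}",
                sequence=seq.decode(),
                site_offset=site_offset,
                motif_signature=motif_sig,
                n_motif_G=n_g,
                mutation_tags=[
                    f"motif+{off}:{b}" for off, b in zip(motif_offsets, motif) if b != "G"
                ],
                planted_level=float(level_fn(n_g)),
            )
        )
    return variants


def simulate_amplicon_reads(
    variants,
    reads_per_variant: int = 200,
    conversion_rate: float = 0.999,
    barcode_len: int = 12,
    duplicate_fraction: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired DNA-library and BS-library reads for a substrate pool.

    Returns ``(dna_reads, bs_reads)`` as (read_id, sequence) tuples; each
    sequence is barcode + amplicon in DNA alphabet. Matched DNA/BS reads
    share a barcode; a ``duplicate_fraction`` of BS barcodes are reused to
    exercise deduplication.
    """
    rng = np.random.default_rng(seed)
    dna_reads, bs_reads = [], []
    counter = 0
    prev_barcode = None
    for var in variants:
        amp_dna = var.sequence.replace("U", "T")
        c_positions = [i for i, b in enumerate(var.sequence) if b == "C"]
        for r in range(reads_per_variant):
            if prev_barcode is not None and rng.random() < duplicate_fraction:
                barcode = prev_barcode
            else:
                barcode = "".join("ACGT"[i] for i in rng.integers(0, 4, barcode_len))
            prev_barcode = barcode
            bs = bytearray(amp_dna.encode())
            for p in c_positions:
                if p == var.site_offset:
                    methylated = rng.random() < var.planted_level
                    keep_c = methylated or (rng.random() >= conversion_rate)
                else:
                    keep_c = rng.random() >= conversion_rate
                if not keep_c:
                    bs[p] = ord("T")
            rid = f"{var.variant_id}.r{r:04d}"
            dna_reads.append((f"{rid}.dna", barcode + amp_dna))
            bs_reads.append((f"{rid}.bs", barcode + bs.decode()))
            counter += 1
    return dna_reads, bs_reads
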