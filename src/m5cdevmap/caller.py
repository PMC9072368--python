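"""m5C site calling from bisulfite read observations.

The filter cascade, in order: high-quality coverage >= 20, at least three
unconverted reads at Q >= 30, mismatch level >= 0.1, survival of the
Gini-selected C-cutoff read filter, signal ratio >= 0.9, host gene not
conversion-resistant, one-sided binomial p < 0.001 against the gene-specific
non-conversion rate; finally replicate agreement (presence in both replicates
with Stouffer combined p < 0.001, or at least five unconverted reads when
only one replicate covers the site).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel
from .reads import ReadTable

FILTER_ORDER = [
    "coverage",
    "variant_count",
    "level",
    "c_cutoff",
    "signal_ratio",
    "resistant_gene",
    "binomial_p",
    "replicate",
]


@dataclass(frozen=True)
class CallerConfig:
    min_coverage: int = 20
    min_level: float = 0.1
    min_variant_reads: int = 3
    min_base_qual: int = 30
    c_cutoff: int = 3
    min_signal_ratio: float = 0.9
    p_threshold: float = 0.001
    combined_p_threshold: float = 0.001
    single_rep_min_variant: int = 5
    # a gene is conversion-resistant when its non-conversion exceeds this
    # over at least min_gene_obs informative observations
    resistant_gene_max_nonconversion: float = 0.05
    min_gene_obs: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_level < 1 or not 0 < self.min_signal_ratio <= 1:
            raise ValueError("thresholds out of range")
        if self.min_coverage < 1 or self.min_variant_reads < 1 or self.c_cutoff < 0:
            raise ValueError("count thresholds out of range")


@dataclass
class SitePileup:
    transcript_id: str
    position: int
    c_count_hq: int = 0
    t_count_hq: int = 0
    c_count_all: int = 0
    t_count_all: int = 0
    c_count_postfilter: int = 0
    t_count_postfilter: int = 0

    @property
    def coverage_hq(self) -> int:
        return self.c_count_hq + self.t_count_hq


@dataclass
class GeneConversionStats:
    gene_id: str
    converted: int
    unconverted: int
    resistant: bool
    low_confidence: bool
    rate_used: float

    @property
    def conversion_rate(self) -> float:
        n = self.converted + self.unconverted
        return self.converted / n if n else float("nan")


@dataclass
class MethylationSite:
    transcript_id: str
    position: int
    gene_id: str
    level: float
    coverage: int
    c_count: int
    p_value: float
    combined_p: float | None
    replicate_levels: list[float]
    passed_filters: dict[str, bool] = field(default_factory=dict)
    site_type: str | None = None


@dataclass
class CutoffRemovalLog:
    cutoff: int
    removed_read_indices: np.ndarray

    @property
    def n_removed(self) -> int:
        return len(self.removed_read_indices)


# --------------------------------------------------------------------------
# statistical kernels
# --------------------------------------------------------------------------

def gini_coefficient(values: Sequence[float]) -> float:
    """Gini coefficient: mean absolute pairwise difference over twice the mean."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("gini of empty input is undefined")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini of all-zero input is undefined")
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * x).sum() / (n * total) - (n + 1) / n)


def binomial_site_test(c_count: int, coverage: int, nonconversion_rate: float) -> float:
    """Exact one-sided upper-tail P(X >= c_count), X ~ Binomial(coverage, rate)."""
    if not 0 <= c_count <= coverage:
        raise ValueError("c_count must be within [0, coverage]")
    if not 0.0 < nonconversion_rate < 1.0:
        raise ValueError("nonconversion_rate must be in (0, 1)")
    return float(stats.binom.sf(c_count - 1, coverage, nonconversion_rate))


def stouffer_combine(p1: float, p2: float) -> float:
    """Stouffer's Z-score combination of two one-sided p-values."""
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("p-values must lie strictly in (0, 1)")
    z = (stats.norm.isf(p1) + stats.norm.isf(p2)) / np.sqrt(2.0)
    return float(stats.norm.sf(z))


# --------------------------------------------------------------------------
# read-level operations
# --------------------------------------------------------------------------

def _as_table(reads) -> ReadTable:
    if isinstance(reads, ReadTable):
        return reads
    return ReadTable.from_records(reads)


def pileup_from_reads(
    reads: Iterable | ReadTable, min_base_qual: int = 30
) -> dict[tuple[str, int], SitePileup]:
    """Exact per-position tallies of C/T observations (all and Q-filtered)."""
    table = _as_table(reads)
    out: dict[tuple[str, int], SitePileup] = {}
    if table.n_obs == 0:
        return out
    tid_codes = table.obs_tid
    hq = table.obs_qual >= min_base_qual
    df = pd.DataFrame(
        {
            "tid": tid_codes,
            "pos": table.obs_pos,
            "c_all": table.obs_state_c,
            "t_all": ~table.obs_state_c,
            "c_hq": table.obs_state_c & hq,
            "t_hq": (~table.obs_state_c) & hq,
        }
    )
    agg = df.groupby(["tid", "pos"], sort=True).sum().reset_index()
    for row in agg.itertuples(index=False):
        tid = table.transcript_ids[row.tid]
        out[(tid, int(row.pos))] = SitePileup(
            transcript_id=tid,
            position=int(row.pos),
            c_count_hq=int(row.c_hq),
            t_count_hq=int(row.t_hq),
            c_count_all=int(row.c_all),
            t_count_all=int(row.t_all),
            c_count_postfilter=int(row.c_hq),
            t_count_postfilter=int(row.t_hq),
        )
    return out


def apply_c_cutoff(reads, cutoff: int) -> tuple[ReadTable, CutoffRemovalLog]:
    """Remove reads carrying more than ``cutoff`` unconverted Cs (read-global)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    table = _as_table(reads)
    removed = table.per_read_c_counts() > cutoff
    return table.subset_reads(~removed), CutoffRemovalLog(
        cutoff=cutoff, removed_read_indices=np.flatnonzero(removed)
    )


def signal_ratio(
    position: tuple[str, int], reads, cutoff: int, min_base_qual: int = 30
) -> float:
    """Fraction of a site's high-quality methylation signal surviving the
    C-cutoff read filter: c_count_postfilter / c_count_hq."""
    table = _as_table(reads)
    tid, pos = position
    try:
        code = table.transcript_ids.index(tid)
    except ValueError:
        raise ValueError(f"no reads for transcript {tid}") from None
    at = (table.obs_tid == code) & (table.obs_pos == pos)
    hq_c = at & table.obs_state_c & (table.obs_qual >= min_base_qual)
    denom = int(hq_c.sum())
    if denom == 0:
        raise ValueError(f"no high-quality C observations at {tid}:{pos}")
    kept_reads = table.per_read_c_counts() <= cutoff
    numer = int((hq_c & kept_reads[table.obs_read]).sum())
    return numer / denom


def select_c_cutoff(
    reads,
    candidate_cutoffs: Sequence[int],
    min_coverage: int = 20,
    min_level: float = 0.1,
    min_base_qual: int = 30,
    tolerance: float = 0.02,
) -> tuple[int | None, pd.DataFrame]:
    """Pick the smallest C-cutoff at which the Gini of candidate-site
    methylation levels stabilizes (successive difference < ``tolerance``).

    The diagnostic table lists, per cutoff, the Gini coefficient of the
    candidate sites' levels recomputed after that cutoff's read filtering.
    Candidates are positions with pre-filter coverage >= min_coverage and
    level >= min_level.  If no adjacent pair stabilizes, the largest cutoff
    is returned; if no candidate site survives any cutoff the chosen value
    is None and only the diagnostic is meaningful.
    """
    if len(candidate_cutoffs) < 2:
        raise ValueError("need at least two candidate cutoffs")
    table = _as_table(reads)
    cutoffs = sorted(set(int(c) for c in candidate_cutoffs))
    hq = table.obs_qual >= min_base_qual
    key = table.obs_tid.astype(np.int64) * (table.obs_pos.max() + 1 if table.n_obs else 1) + table.obs_pos
    # pre-filter candidate selection
    uniq, inv = np.unique(key, return_inverse=True)
    c_hq = np.bincount(inv, weights=(table.obs_state_c & hq), minlength=len(uniq))
    cov_hq = np.bincount(inv, weights=hq, minlength=len(uniq))
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov_hq > 0, c_hq / np.maximum(cov_hq, 1), 0.0)
    cand = (cov_hq >= min_coverage) & (level >= min_level)
    cand_idx = np.flatnonzero(cand)

    ccounts = table.per_read_c_counts()
    rows = []
    ginis: dict[int, float] = {}
    for cutoff in cutoffs:
        kept = ccounts[table.obs_read] <= cutoff
        sel = hq & kept
        c_f = np.bincount(inv, weights=(table.obs_state_c & sel), minlength=len(uniq))
        cov_f = np.bincount(inv, weights=sel, minlength=len(uniq))
        covered = cand & (cov_f > 0)
        lv = c_f[np.flatnonzero(covered)] / cov_f[np.flatnonzero(covered)]
        if lv.size and lv.sum() > 0:
            g = gini_coefficient(lv)
        else:
            g = float("nan")
        ginis[cutoff] = g
        rows.append({"cutoff": cutoff, "n_candidates": int(covered.sum()), "gini": g})
    diag = pd.DataFrame(rows)

    chosen: int | None = None
    finite = [c for c in cutoffs if np.isfinite(ginis[c])]
    for a, b in zip(finite, finite[1:]):
        if abs(ginis[a] - ginis[b]) < tolerance:
            chosen = a
            break
    if chosen is None and finite:
        chosen = finite[-1]
    return chosen, diag


# --------------------------------------------------------------------------
# gene conversion statistics
# --------------------------------------------------------------------------

def estimate_gene_conversion(
    reads,
    candidate_positions: set[tuple[str, int]],
    gene_of: Mapping[str, str],
    config: CallerConfig = CallerConfig(),
    apply_cutoff: bool = True,
) -> dict[str, GeneConversionStats]:
    """Per-gene bisulfite conversion over high-quality observations outside
    candidate positions; genes with fewer than ``config.min_gene_obs``
    informative observations inherit the library-wide rate."""
    table = _as_table(reads)
    if apply_cutoff:
        table, _ = apply_c_cutoff(table, config.c_cutoff)
    hq = table.obs_qual >= config.min_base_qual
    tid_codes = table.obs_tid
    cand_mask = np.zeros(table.n_obs, dtype=bool)
    if candidate_positions:
        cand_keys = {
            (tid, pos) for tid, pos in candidate_positions
        }
        for code, tid in enumerate(table.transcript_ids):
            on_tid = tid_codes == code
            if not on_tid.any():
                continue
            positions = {p for t, p in cand_keys if t == tid}
            if positions:
                cand_mask[on_tid] = np.isin(
                    table.obs_pos[on_tid], np.fromiter(positions, dtype=np.int64)
                )
    informative = hq & ~cand_mask
    genes = [gene_of[t] for t in table.transcript_ids]
    gene_names = sorted(set(gene_of.values()))
    gene_code = {g: i for i, g in enumerate(gene_names)}
    obs_gene = np.array([gene_code[genes[c]] for c in tid_codes], dtype=np.int64) \
        if table.n_obs else np.zeros(0, dtype=np.int64)
    unconv = np.bincount(
        obs_gene[informative], weights=table.obs_state_c[informative],
        minlength=len(gene_names),
    )
    total = np.bincount(obs_gene[informative], minlength=len(gene_names))
    conv = total - unconv
    g_total = total.sum()
    global_rate = float(conv.sum() / g_total) if g_total else 1.0 - 1e-3

    out = {}
    for g, name in enumerate(gene_names):
        n = int(total[g])
        low_conf = n < config.min_gene_obs
        rate = float(conv[g] / n) if n else float("nan")
        # strict inequality with an epsilon so a rate exactly at the
        # threshold is not flagged through binary rounding
        resistant = (not low_conf) and (
            (1.0 - rate) > config.resistant_gene_max_nonconversion + 1e-12
        )
        out[name] = GeneConversionStats(
            gene_id=name,
            converted=int(conv[g]),
            unconverted=int(unconv[g]),
            resistant=resistant,
            low_confidence=low_conf,
            rate_used=global_rate if low_conf else rate,
        )
    return out


# --------------------------------------------------------------------------
# the full cascade
# --------------------------------------------------------------------------

def _gene_map(annotation) -> dict[str, str]:
    if isinstance(annotation, Mapping):
        return dict(annotation)
    return {t.transcript_id: t.gene_id for t in annotation}


def _rep_frame(table: ReadTable, tid_of: dict[str, int], config: CallerConfig) -> pd.DataFrame:
    """Per-(transcript, position) counts for one replicate, pre and post
    C-cutoff, high-quality only plus totals."""
    hq = table.obs_qual >= config.min_base_qual
    kept = (table.per_read_c_counts() <= config.c_cutoff)[table.obs_read]
    gtid = np.array([tid_of[t] for t in table.transcript_ids], dtype=np.int64)
    df = pd.DataFrame(
        {
            "tid": gtid[table.obs_tid],
            "pos": table.obs_pos.astype(np.int64),
            "c_all": table.obs_state_c,
            "t_all": ~table.obs_state_c,
            "c_hq": table.obs_state_c & hq,
            "t_hq": (~table.obs_state_c) & hq,
            "c_pf": table.obs_state_c & hq & kept,
            "t_pf": (~table.obs_state_c) & hq & kept,
        }
    )
    agg = df.groupby(["tid", "pos"], sort=True).sum().reset_index()
    agg["cov_all"] = agg.c_all + agg.t_all
    agg["cov_hq"] = agg.c_hq + agg.t_hq
    agg["cov_pf"] = agg.c_pf + agg.t_pf
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["level_all"] = np.where(agg.cov_all > 0, agg.c_all / agg.cov_all.clip(lower=1), 0.0)
        agg["level_hq"] = np.where(agg.cov_hq > 0, agg.c_hq / agg.cov_hq.clip(lower=1), 0.0)
        agg["level_pf"] = np.where(agg.cov_pf > 0, agg.c_pf / agg.cov_pf.clip(lower=1), 0.0)
    return agg


def call_sites(
    replicate_reads: Sequence,
    annotation,
    config: CallerConfig = CallerConfig(),
) -> tuple[list[MethylationSite], pd.DataFrame]:
    """Run the full filter cascade over one or two replicate read sets.

    Returns the emitted high-confidence sites and a per-candidate audit
    table recording, for every rejected candidate, the first failing filter.
    """
    if not 1 <= len(replicate_reads) <= 2:
        raise ValueError("expected one or two replicates")
    tables = [_as_table(r) for r in replicate_reads]
    gene_of = _gene_map(annotation)
    for t in tables:
        unknown = set(t.transcript_ids) - set(gene_of)
        if unknown:
            raise ValueError(f"reads reference unannotated transcripts {sorted(unknown)[:3]}")

    tid_names = sorted({tid for t in tables for tid in t.transcript_ids})
    tid_of = {tid: i for i, tid in enumerate(tid_names)}
    frames = [_rep_frame(t, tid_of, config) for t in tables]

    # candidate universe: the all-quality variant-support gate in any
    # replicate; looser than every cascade filter so that near-miss
    # positions are audited with their true first-failing filter
    cand_frames = []
    for f in frames:
        c = f[
            (f.c_all >= config.min_variant_reads)
            & (f.level_all >= config.min_level)
        ]
        cand_frames.append(c[["tid", "pos"]])
    candidates = (
        pd.concat(cand_frames).drop_duplicates().sort_values(["tid", "pos"])
        if cand_frames
        else pd.DataFrame(columns=["tid", "pos"])
    )
    cand_positions = {
        (tid_names[int(r.tid)], int(r.pos)) for r in candidates.itertuples(index=False)
    }

    gene_stats = [
        estimate_gene_conversion(t, cand_positions, gene_of, config) for t in tables
    ]

    merged = candidates.copy()
    for i, f in enumerate(frames):
        merged = merged.merge(f, on=["tid", "pos"], how="left", suffixes=("", f"_r{i}"))
        merged = merged.rename(
            columns={
                c: f"{c}_r{i}"
                for c in ("c_all", "t_all", "cov_all", "level_all",
                          "c_hq", "t_hq", "c_pf", "t_pf", "cov_hq", "cov_pf",
                          "level_hq", "level_pf")
                if c in merged.columns
            }
        )
    merged = merged.fillna(0.0)

    sites: list[MethylationSite] = []
    audit_rows = []
    n_reps = len(tables)
    for row in merged.itertuples(index=False):
        tid = tid_names[int(row.tid)]
        pos = int(row.pos)
        gene = gene_of[tid]
        per_rep = []
        for i in range(n_reps):
            stats_i = gene_stats[i].get(gene)
            rate = stats_i.rate_used if stats_i else 1.0 - 1e-3
            noncv = min(max(1.0 - rate, 1e-9), 1.0 - 1e-9)
            c_hq = int(getattr(row, f"c_hq_r{i}"))
            cov_hq = int(getattr(row, f"cov_hq_r{i}"))
            c_pf = int(getattr(row, f"c_pf_r{i}"))
            cov_pf = int(getattr(row, f"cov_pf_r{i}"))
            level_hq = float(getattr(row, f"level_hq_r{i}"))
            level_pf = float(getattr(row, f"level_pf_r{i}"))
            p = binomial_site_test(c_pf, cov_pf, noncv) if cov_pf else 1.0
            checks = [
                ("coverage", cov_hq >= config.min_coverage),
                ("variant_count", c_hq >= config.min_variant_reads),
                ("level", level_hq >= config.min_level),
                (
                    "c_cutoff",
                    cov_pf >= config.min_coverage
                    and c_pf >= config.min_variant_reads
                    and level_pf >= config.min_level,
                ),
                ("signal_ratio", c_hq > 0 and c_pf / c_hq >= config.min_signal_ratio),
                ("resistant_gene", not (stats_i and stats_i.resistant)),
                ("binomial_p", p < config.p_threshold),
            ]
            stage = len(checks)
            first_fail = None
            for s, (name, ok) in enumerate(checks):
                if not ok:
                    stage, first_fail = s, name
                    break
            per_rep.append(
                dict(
                    stage=stage, first_fail=first_fail, p=p, c_pf=c_pf,
                    cov_pf=cov_pf, level_pf=level_pf, cov_hq=cov_hq,
                    covered=cov_hq >= config.min_coverage,
                )
            )

        best = max(range(n_reps), key=lambda i: (per_rep[i]["stage"], -i))
        b = per_rep[best]
        emitted = False
        fail_name = b["first_fail"]
        combined_p = None
        if b["stage"] == 7:  # passed filters 1..7 in the best replicate
            others = [per_rep[i] for i in range(n_reps) if i != best]
            other = others[0] if others else None
            if other is not None and other["covered"]:
                present = other["level_pf"] >= config.min_level
                p1 = float(np.clip(b["p"], 1e-300, 1.0 - 1e-12))
                p2 = float(np.clip(other["p"], 1e-300, 1.0 - 1e-12))
                combined_p = stouffer_combine(p1, p2)
                emitted = present and combined_p < config.combined_p_threshold
            else:
                emitted = b["c_pf"] >= config.single_rep_min_variant
            if not emitted:
                fail_name = "replicate"

        covered_reps = [r for r in per_rep if r["covered"]]
        pool_c = sum(r["c_pf"] for r in covered_reps)
        pool_cov = sum(r["cov_pf"] for r in covered_reps)
        level = pool_c / pool_cov if pool_cov else 0.0
        if emitted:
            sites.append(
                MethylationSite(
                    transcript_id=tid,
                    position=pos,
                    gene_id=gene,
                    level=level,
                    coverage=pool_cov,
                    c_count=pool_c,
                    p_value=b["p"],
                    combined_p=combined_p,
                    replicate_levels=[r["level_pf"] for r in covered_reps],
                    passed_filters={name: True for name in FILTER_ORDER},
                )
            )
        audit_rows.append(
            {
                "transcript_id": tid,
                "position": pos,
                "gene_id": gene,
                "emitted": emitted,
                "first_fail": None if emitted else fail_name,
                "level": level,
                "coverage": pool_cov,
                "p_value": b["p"],
                "combined_p": combined_p,
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "transcript_id", "position", "gene_id", "emitted", "first_fail",
            "level", "coverage", "p_value", "combined_p",
        ],
    )
    return sites, audit


def sites_to_frame(sites: Sequence[MethylationSite]) -> pd.DataFrame:
    """Site table with 1-based positions for export."""
    return pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "pos": s.position + 1,
                "gene_id": s.gene_id,
                "coverage": s.coverage,
                "c_count": s.c_count,
                "level": s.level,
                "p_value": s.p_value,
                "combined_p": s.combined_p,
                "type": s.site_type,
            }
            for s in sites
        ],
        columns=[
            "transcript_id", "pos", "gene_id", "coverage", "c_count",
            "level", "p_value", "combined_p", "type",
        ],
    )


def sites_to_bed(sites: Sequence[MethylationSite]) -> pd.DataFrame:
    """Six-column BED-like export: half-open interval, name, level-scaled
    score (0-1000), sense strand."""
    return pd.DataFrame(
        [
            {
                "chrom": s.transcript_id,
                "start": s.position,
                "end": s.position + 1,
                "name": f"{s.gene_id}:{s.site_type or 'm5C'}",
                "score": int(round(min(1.0, s.level) * 1000)),
                "strand": "+",
            }
            for s in sites
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
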