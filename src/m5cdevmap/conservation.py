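"""Cross-species methylation conservation over an ortholog position map.

A pair of orthologous cytosines is *conserved* when one species shows a
methylation level >= 10% and the other > 5%, with both covered by at least
``min_pair_coverage`` reads; a site is certifiably *unmethylated* only with
coverage >= 20 and level < 5%.  Pairs where either base is not C at the DNA
level are excluded from the methylation comparison (but kept for
substitution-rate analysis).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

METHYLATED_MIN_LEVEL = 0.10
CONSERVED_PARTNER_MIN_LEVEL = 0.05  # exclusive: partner level must exceed this
UNMETHYLATED_MAX_LEVEL = 0.05  # exclusive upper bound
UNMETHYLATED_MIN_COVERAGE = 20


@dataclass(frozen=True)
class OrthologPairRecord:
    tidA: str
    posA: int
    tidB: str
    posB: int
    baseA: str
    baseB: str
    levelA: float | None = None
    covA: int | None = None
    levelB: float | None = None
    covB: int | None = None


@dataclass(frozen=True)
class ConservationCall:
    status: str  # conserved | A_specific | B_specific | unmethylated_both | indeterminate
    reason: str


def methylation_status(level: float | None, cov: int | None) -> str:
    """'methylated' (level >= 10%), 'unmethylated' (cov >= 20 and level < 5%),
    else 'indeterminate'."""
    if level is not None and level < 0:
        raise ValueError("negative level")
    if cov is not None and cov < 0:
        raise ValueError("negative coverage")
    if level is None or cov is None:
        return "indeterminate"
    if level >= METHYLATED_MIN_LEVEL:
        return "methylated"
    if cov >= UNMETHYLATED_MIN_COVERAGE and level < UNMETHYLATED_MAX_LEVEL:
        return "unmethylated"
    return "indeterminate"


def _classify_pair(rec: OrthologPairRecord, min_pair_coverage: int) -> ConservationCall:
    if rec.baseA != "C" or rec.baseB != "C":
        return ConservationCall("indeterminate", "non-C base in at least one species")
    if (
        rec.covA is None or rec.covB is None
        or rec.covA < min_pair_coverage or rec.covB < min_pair_coverage
        or rec.levelA is None or rec.levelB is None
    ):
        return ConservationCall("indeterminate", "pair coverage below threshold")
    la, lb = rec.levelA, rec.levelB
    if (la >= METHYLATED_MIN_LEVEL and lb > CONSERVED_PARTNER_MIN_LEVEL) or (
        lb >= METHYLATED_MIN_LEVEL and la > CONSERVED_PARTNER_MIN_LEVEL
    ):
        return ConservationCall("conserved", "methylated in one, >5% in the other")
    sa = methylation_status(la, rec.covA)
    sb = methylation_status(lb, rec.covB)
    if sa == "methylated" and sb == "unmethylated":
        return ConservationCall("A_specific", "methylated in A, unmethylated in B")
    if sb == "methylated" and sa == "unmethylated":
        return ConservationCall("B_specific", "methylated in B, unmethylated in A")
    if sa == "unmethylated" and sb == "unmethylated":
        return ConservationCall("unmethylated_both", "unmethylated in both species")
    return ConservationCall("indeterminate", f"statuses {sa}/{sb}")


def pair_sites(
    sitesA: Mapping[tuple[str, int], tuple[float, int]],
    sitesB: Mapping[tuple[str, int], tuple[float, int]],
    ortholog_map: pd.DataFrame,
    min_pair_coverage: int = 10,
) -> list[tuple[OrthologPairRecord, ConservationCall]]:
    """Join per-species (level, coverage) maps over the ortholog map and
    classify each C/C pair.

    ``sitesA``/``sitesB`` map (transcript_id, 0-based position) to
    (level, coverage); positions absent from a map are treated as uncovered.
    Duplicate ortholog-map rows raise with the offending keys.
    """
    dup = ortholog_map.duplicated(subset=["tidA", "posA"]) | ortholog_map.duplicated(
        subset=["tidB", "posB"]
    )
    if dup.any():
        bad = ortholog_map.loc[dup, ["tidA", "posA", "tidB", "posB"]].head(5)
        raise ValueError(f"duplicate ortholog map entries:\n{bad}")
    out = []
    for row in ortholog_map.itertuples(index=False):
        la, ca = sitesA.get((row.tidA, int(row.posA)), (None, None))
        lb, cb = sitesB.get((row.tidB, int(row.posB)), (None, None))
        rec = OrthologPairRecord(
            tidA=row.tidA, posA=int(row.posA), tidB=row.tidB, posB=int(row.posB),
            baseA=row.baseA, baseB=row.baseB,
            levelA=la, covA=ca, levelB=lb, covB=cb,
        )
        out.append((rec, _classify_pair(rec, min_pair_coverage)))
    return out


def conservation_summary(
    calls: Sequence[tuple[OrthologPairRecord, ConservationCall]],
    types: Mapping[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Counts and conserved percentages per site type and overall.

    Two denominators are reported: determinate pairs (conserved + specific)
    and all paired C/C records.
    """
    rows = []
    labels = ["overall"]
    if types:
        labels += sorted(set(types.values()))
    for label in labels:
        n = {s: 0 for s in
             ("conserved", "A_specific", "B_specific", "unmethylated_both", "indeterminate")}
        n_pairs = 0
        for rec, call in calls:
            if label != "overall":
                t = types.get((rec.tidA, rec.posA)) if types else None
                if t != label:
                    continue
            n_pairs += 1
            n[call.status] += 1
        specific = n["A_specific"] + n["B_specific"]
        determinate = n["conserved"] + specific
        rows.append(
            {
                "type": label,
                "n_pairs": n_pairs,
                "conserved": n["conserved"],
                "specific": specific,
                "unmethylated_both": n["unmethylated_both"],
                "indeterminate": n["indeterminate"],
                "pct_conserved_of_determinate": (
                    100.0 * n["conserved"] / determinate if determinate else float("nan")
                ),
                "pct_conserved_of_paired": (
                    100.0 * n["conserved"] / n_pairs if n_pairs else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
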