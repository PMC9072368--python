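"""Structure metaprofiles, bootstrap comparison, substitution-rate profiles
and the logistic model of methylation gain/loss.

Gain/loss modelling follows a case-control construction over orthologous
sites methylated in exactly one species: the methylated species' context is
a positive example, the unmethylated species' context a negative one.
Features are dummy-coded base identities at positions -2..+5 (Type I) and
per-position base-pairing bits (+/-50 nt for Type I, +/-20 nt for Type II);
interactions are not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Mode = Literal["TypeI", "TypeII"]

PAIRING_WINDOW = {"TypeI": 50, "TypeII": 20}
BASE_OFFSETS = tuple(o for o in range(-2, 6) if o != 0)  # site position omitted


@dataclass(frozen=True)
class StructureContext:
    """Sequence window around a site with its dot-bracket structure.

    ``sequence`` and ``dotbracket`` have equal odd length with the site at
    the center; ``fold_temperature`` is carried as metadata for external
    thermodynamic folders and ignored by the combinatorial stand-in.
    """

    sequence: str
    dotbracket: str
    fold_temperature: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence/structure length mismatch")
        if len(self.sequence) % 2 == 0:
            raise ValueError("window length must be odd (site at center)")
        _check_balanced(self.dotbracket)

    @property
    def half_width(self) -> int:
        return len(self.sequence) // 2

    @property
    def pairing(self) -> np.ndarray:
        return pairing_vector(self.dotbracket)


def _check_balanced(dotbracket: str) -> None:
    depth = 0
    for ch in dotbracket:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket")


def pairing_vector(dotbracket: str) -> np.ndarray:
    """1 at paired (bracket) positions, 0 at dots."""
    _check_balanced(dotbracket)
    return np.array([ch != "." for ch in dotbracket], dtype=np.int8)


def pairing_metaprofile(
    contexts: Sequence[StructureContext], window: int
) -> pd.DataFrame:
    """Per-position pairing frequency over contexts aligned on the site.

    Contexts whose flank does not reach a position are excluded from that
    position's denominator.
    """
    if not contexts:
        raise ValueError("need at least one context")
    offsets = np.arange(-window, window + 1)
    paired = np.zeros(len(offsets), dtype=np.int64)
    present = np.zeros(len(offsets), dtype=np.int64)
    for ctx in contexts:
        hw = ctx.half_width
        pv = ctx.pairing
        lo, hi = max(-window, -hw), min(window, hw)
        sl = slice(lo + window, hi + window + 1)
        present[sl] += 1
        paired[sl] += pv[lo + hw : hi + hw + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(present > 0, paired / np.maximum(present, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "paired_frequency": freq, "n": present})


def _pairing_matrix(contexts: Sequence[StructureContext], window: int) -> np.ndarray:
    mat = np.zeros((len(contexts), 2 * window + 1), dtype=np.int8)
    for i, ctx in enumerate(contexts):
        if ctx.half_width < window:
            raise ValueError(
                f"context {i} half-width {ctx.half_width} < window {window}"
            )
        c = ctx.half_width
        mat[i] = ctx.pairing[c - window : c + window + 1]
    return mat


def bootstrap_pairing_test(
    group_a: Sequence[StructureContext],
    group_b: Sequence[StructureContext],
    window: int = 20,
    n_sample: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Bootstrap comparison of per-position pairing frequencies.

    Each bootstrap replicate down-samples ``n_sample`` contexts without
    replacement from each group and records the per-position pairing
    frequency; the two length-``n_boot`` frequency samples are compared per
    position with a one-sided two-sample t-test whose direction is the sign
    of the full-data frequency difference (A minus B). Both one- and
    two-sided p-values are reported, with the replicate frequency arrays.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < n_sample:
            raise ValueError(
                f"group {name} has {len(grp)} contexts < n_sample={n_sample}; "
                "reduce n_sample"
            )
    rng = np.random.default_rng(seed)
    mat_a = _pairing_matrix(group_a, window)
    mat_b = _pairing_matrix(group_b, window)
    boot_a = np.empty((n_boot, mat_a.shape[1]))
    boot_b = np.empty((n_boot, mat_b.shape[1]))
    for r in range(n_boot):
        boot_a[r] = mat_a[rng.choice(len(mat_a), n_sample, replace=False)].mean(axis=0)
        boot_b[r] = mat_b[rng.choice(len(mat_b), n_sample, replace=False)].mean(axis=0)
    diff_full = mat_a.mean(axis=0) - mat_b.mean(axis=0)
    t, p_two = stats.ttest_ind(boot_a, boot_b, axis=0)
    df = 2 * n_boot - 2
    greater = diff_full >= 0
    p_one = np.where(greater, stats.t.sf(t, df), stats.t.cdf(t, df))
    # degenerate positions (zero variance in both groups) are non-informative
    p_one = np.where(np.isnan(t), 1.0, p_one)
    p_two = np.where(np.isnan(t), 1.0, p_two)
    table = pd.DataFrame(
        {
            "offset": np.arange(-window, window + 1),
            "freq_a": mat_a.mean(axis=0),
            "freq_b": mat_b.mean(axis=0),
            "direction": np.where(greater, "A>B", "A<B"),
            "p_one_sided": p_one,
            "p_two_sided": p_two,
        }
    )
    return table, boot_a, boot_b


# --------------------------------------------------------------------------
# substitution-rate profiles
# --------------------------------------------------------------------------

def substitution_rate_profile(
    groups: dict[str, Sequence[tuple[str, str]]],
    window: int,
) -> pd.DataFrame:
    """Per-offset base substitution rates for groups of aligned site windows.

    ``groups`` maps a group label (e.g. 'conserved', 'lost') to aligned
    (species-A window, species-B window) sequence pairs, site at center.
    Pad characters ('N') are excluded from denominators.
    """
    rows = []
    for label, pairs in groups.items():
        sub = np.zeros(2 * window + 1, dtype=np.int64)
        n = np.zeros(2 * window + 1, dtype=np.int64)
        for seq_a, seq_b in pairs:
            if len(seq_a) != len(seq_b) or len(seq_a) % 2 == 0:
                raise ValueError("windows must be aligned, equal odd length")
            c = len(seq_a) // 2
            for off in range(-min(window, c), min(window, c) + 1):
                a, b = seq_a[c + off], seq_b[c + off]
                if a == "N" or b == "N":
                    continue
                n[off + window] += 1
                sub[off + window] += a != b
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n > 0, sub / np.maximum(n, 1), np.nan)
        for i, off in enumerate(range(-window, window + 1)):
            rows.append(
                {"group": label, "offset": off, "rate": rate[i], "n_pairs": int(n[i])}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

def feature_names(mode: Mode) -> list[str]:
    """Pairing feature names for a mode (sequence dummies are data-dependent)."""
    w = PAIRING_WINDOW[mode]
    return [f"pair{o:+d}" for o in range(-w, w + 1)]


def design_from_contexts(
    contexts: Sequence[tuple[str, str]],
    mode: Mode,
    drop_reference_base: bool = True,
) -> pd.DataFrame:
    """Feature matrix for (sequence window, dot-bracket) contexts.

    Type I: base identities at positions -2..+5 (one-hot, the most frequent
    base per position dropped as reference when ``drop_reference_base``) plus
    pairing bits over +/-50; Type II: pairing bits over +/-20 only.
    """
    if mode not in PAIRING_WINDOW:
        raise ValueError(f"unknown mode {mode!r}")
    w = PAIRING_WINDOW[mode]
    cols: dict[str, np.ndarray] = {}
    n = len(contexts)
    if mode == "TypeI":
        for off in BASE_OFFSETS:
            bases = []
            for seq, _ in contexts:
                c = len(seq) // 2
                p = c + off
                bases.append(seq[p] if 0 <= p < len(seq) else "N")
            bases = np.array(bases)
            present = [b for b in "ACGU" if (bases == b).any()]
            if drop_reference_base and len(present) > 1:
                counts = {b: int((bases == b).sum()) for b in present}
                ref = max(sorted(present), key=lambda b: counts[b])
                present = [b for b in present if b != ref]
            for b in present:
                cols[f"base{off:+d}_{b}"] = (bases == b).astype(float)
    structs = [StructureContext(seq, db) for seq, db in contexts]
    pair_mat = _pairing_matrix(structs, w).astype(float)
    for i, o in enumerate(range(-w, w + 1)):
        cols[f"pair{o:+d}"] = pair_mat[:, i]
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def build_design(
    pairs, mode: Mode, drop_reference_base: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Case-control design over sites methylated in exactly one species.

    Each pair contributes two rows: the methylated species' context with
    label 1 and the unmethylated species' context with label 0.  ``pairs``
    are records with context_a/context_b, struct_a/struct_b, base_b and
    retained attributes (species A is the methylated reference); retained
    (conserved) pairs and pairs whose species-B base is not C are excluded.
    """
    contexts, labels = [], []
    for p in pairs:
        if p.retained or p.base_b != "C":
            continue
        contexts.append((p.context_a, p.struct_a))
        labels.append(1)
        contexts.append((p.context_b, p.struct_b))
        labels.append(0)
    if not labels or len(set(labels)) < 2:
        raise ValueError("need non-conserved pairs providing both classes")
    X = design_from_contexts(contexts, mode, drop_reference_base)
    return X, np.array(labels, dtype=float)


# --------------------------------------------------------------------------
# logistic fit (IRLS)
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    params: pd.Series
    bse: pd.Series
    converged: bool
    n_iter: int
    n_pos: int
    n_neg: int

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    labels: Sequence[float],
    ridge_epsilon: float = 1e-6,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Bernoulli GLM with logit link by iteratively reweighted least squares.

    ``ridge_epsilon`` adds a small L2 penalty that stabilizes
    quasi-separated designs; set it to 0 for the exact maximum-likelihood
    fit.  Complete separation without ridge is reported as non-convergence,
    never as a silent estimate.
    """
    X = np.asarray(design, dtype=float)
    names = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design/labels shape mismatch")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
        names = ["intercept"] + names

    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    it = 0
    fisher = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        fisher = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        lhs = fisher + ridge_epsilon * np.eye(p)
        try:
            step = np.linalg.solve(lhs, score - ridge_epsilon * beta)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 1e3:
        converged = False  # diverging estimates: (quasi-)separation
    try:
        cov = np.linalg.inv(fisher + ridge_epsilon * np.eye(p))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return GLMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        converged=converged,
        n_iter=it,
        n_pos=n_pos,
        n_neg=n_neg,
    )
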