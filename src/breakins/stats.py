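"""Feature enrichment by permutation, G4/GC association, exact tests.

Donor locations (with retroelement, mtDNA, rDNA, break-locus and 2-micron
donors excluded) are compared against genomic feature sets by a one-sided
permutation test: control locations of identical sizes are placed uniformly at
random on the eligible territory, the overlap (or proximity) statistic is
recomputed per shuffle, and p = (1 + #{null >= observed}) / (n_shuffles + 1).
The plus-one convention keeps p-values in (0, 1].

Edge distance between half-open intervals is 0 when they overlap; otherwise it
is the nearest-base distance (start of the later interval) - (end of the
earlier, exclusive) + 1, so adjacency gives 1.

Fisher's exact test is computed by direct hypergeometric enumeration. The
rank-sum and chi-square engines wrap scipy's exact Mann-Whitney U and the
Pearson formula; independent enumeration oracles check all of them in tests.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from breakins.model import FeatureSet, ReferenceGenome, intervals_overlap

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]  # (sequence, start, end), half-open


def edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """0 when intervals overlap; else nearest-base distance (adjacency -> 1)."""
    if intervals_overlap(a_start, a_end, b_start, b_end):
        return 0
    if a_end <= b_start:
        return b_start - a_end + 1
    return a_start - b_end + 1


def overlap_and_distance(
    donors: list[Interval],
    feature_intervals: list[tuple[str, int, int, str]],
) -> tuple[int, list[int]]:
    """(count of donors overlapping any feature by >= 1 bp, per-donor edge distances).

    Distances are to the nearest feature edge, 0 for overlaps; donors on
    sequences without any feature get no distance entry.
    """
    if not donors:
        log.warning("empty donor set for overlap/distance analysis")
        return 0, []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq, s, e, *_ in feature_intervals:
        by_seq.setdefault(seq, []).append((s, e))
    count = 0
    distances: list[int] = []
    for seq, ds, de in donors:
        feats = by_seq.get(seq)
        if not feats:
            continue
        dists = [edge_distance(ds, de, fs, fe) for fs, fe in feats]
        d = min(dists)
        distances.append(d)
        if d == 0:
            count += 1
    return count, distances


def eligible_territory(
    genome: ReferenceGenome,
    excluded_sources: tuple[str, ...],
    extra_excluded: list[tuple[str, int, int]] | None = None,
) -> list[Interval]:
    """Blocks where shuffled control locations may be placed.

    Whole sequences whose source class is excluded are removed, as are the
    interval-defined territories (Ty, rDNA) of excluded classes and any extra
    intervals (e.g. the amplicon locus).
    """
    blocked: dict[str, list[tuple[int, int]]] = {}
    for cls in ("Ty", "rDNA"):
        if cls in excluded_sources:
            for seq, s, e in genome.class_intervals.get(cls, []):
                blocked.setdefault(seq, []).append((s, e))
    for seq, s, e in extra_excluded or []:
        blocked.setdefault(seq, []).append((s, e))
    blocks: list[Interval] = []
    for name, seq in genome.sequences.items():
        if genome.source_class_map[name] in excluded_sources:
            continue
        cursor = 0
        for s, e in sorted(blocked.get(name, [])):
            if s > cursor:
                blocks.append((name, cursor, s))
            cursor = max(cursor, e)
        if cursor < len(seq):
            blocks.append((name, cursor, len(seq)))
    return blocks


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    p_value: float
    n_shuffles: int


def permutation_test(
    donors: list[Interval],
    feature_intervals: list[tuple[str, int, int, str]],
    territory: list[Interval],
    n_shuffles: int = 100_000,
    seed: int = 0,
    proximity_bp: int | None = None,
    statistic: str = "overlap",
) -> PermutationResult:
    """One-sided permutation test for feature overlap or proximity.

    Each shuffle places intervals of the same sizes as the observed donors
    uniformly at random on the eligible territory. With the default
    ``overlap`` statistic the per-shuffle statistic is the number of intervals
    overlapping (or within ``proximity_bp`` of) the feature and the p-value is
    (1 + #{null >= observed}) / (n_shuffles + 1). With ``median_distance`` the
    statistic is the median edge distance to the nearest feature (association
    means *smaller*), so the tail flips: (1 + #{null <= observed}) / (n + 1).
    The plus-one convention keeps p in (0, 1].
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not donors:
        raise ValueError("no donor intervals to test")
    if statistic not in ("overlap", "median_distance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    pad = (proximity_bp or 0) if statistic == "overlap" else 0

    # features, padded by the proximity window, as prefix-max arrays per sequence
    seq_names = sorted(
        {name for name, _, _ in territory}
        | {name for name, _, _ in donors}
        | {f[0] for f in feature_intervals}
    )
    seq_idx = {name: i for i, name in enumerate(seq_names)}
    feat_starts: dict[int, np.ndarray] = {}
    feat_maxend: dict[int, np.ndarray] = {}
    for name in seq_names:
        ivals = sorted(
            (max(0, s - pad), e + pad)
            for seq, s, e, *_ in feature_intervals
            if seq == name
        )
        if ivals:
            starts = np.array([s for s, _ in ivals])
            ends = np.maximum.accumulate(np.array([e for _, e in ivals]))
            feat_starts[seq_idx[name]] = starts
            feat_maxend[seq_idx[name]] = ends

    def hit(seq_i: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Vector overlap test for placed intervals [start, start+len)."""
        out = np.zeros(len(starts), dtype=bool)
        for si in np.unique(seq_i):
            if si not in feat_starts:
                continue
            mask = seq_i == si
            s = starts[mask]
            e = s + lengths[mask]
            idx = np.searchsorted(feat_starts[si], e, side="left")
            res = np.zeros(mask.sum(), dtype=bool)
            nz = idx > 0
            res[nz] = feat_maxend[si][idx[nz] - 1] > s[nz]
            out[mask] = res
        return out

    def distance(seq_i: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Vector nearest-feature edge distance (0 for overlap, inf if none)."""
        out = np.full(len(starts), np.inf)
        for si in np.unique(seq_i):
            if si not in feat_starts:
                continue
            mask = seq_i == si
            s = starts[mask]
            e = s + lengths[mask]
            fs, pm = feat_starts[si], feat_maxend[si]
            n_before_e = np.searchsorted(fs, e, side="left")
            n_at_or_before_s = np.searchsorted(fs, s, side="right")
            pmv = np.where(n_at_or_before_s > 0,
                           pm[np.maximum(n_at_or_before_s - 1, 0)], -np.inf)
            overlap = (pmv > s) | (n_before_e > n_at_or_before_s)
            left = np.where(np.isfinite(pmv), s - pmv + 1, np.inf)
            right = np.where(n_before_e < len(fs),
                             fs[np.minimum(n_before_e, len(fs) - 1)] - e + 1, np.inf)
            out[mask] = np.where(overlap, 0.0, np.minimum(left, right))
        return out

    stat_fn = hit if statistic == "overlap" else distance

    def summarize(values: np.ndarray, k: int) -> np.ndarray:
        arr = values.reshape(-1, k)
        if statistic == "overlap":
            return arr.sum(axis=1)
        return np.median(arr, axis=1)

    obs_seq = np.array([seq_idx.get(name, -1) for name, _, _ in donors])
    obs_start = np.array([s for _, s, _ in donors])
    obs_len = np.array([e - s for _, s, e in donors])
    observed = float(summarize(stat_fn(obs_seq, obs_start, obs_len), len(donors))[0])

    block_seq = np.array([seq_idx[name] for name, _, _ in territory])
    block_start = np.array([s for _, s, _ in territory])
    block_len = np.array([e - s for _, s, e in territory])
    rng = np.random.default_rng(seed)
    per_donor = np.empty((n_shuffles, len(donors)))
    col = 0
    for L in np.unique(obs_len):
        k = int((obs_len == L).sum())
        valid = np.maximum(0, block_len - L + 1)
        total = int(valid.sum())
        if total <= 0:
            raise ValueError(f"eligible territory smaller than interval of {L} bp")
        cum = np.cumsum(valid)
        u = rng.integers(0, total, size=(n_shuffles, k))
        b = np.searchsorted(cum, u, side="right")
        offset = u - (cum[b - 1] * (b > 0))
        starts = block_start[b] + offset
        lengths = np.full(u.size, L)
        vals = stat_fn(block_seq[b].ravel(), starts.ravel(), lengths).reshape(n_shuffles, k)
        per_donor[:, col : col + k] = vals
        col += k
    if statistic == "overlap":
        null = per_donor.sum(axis=1)
        extreme = int((null >= observed).sum())
    else:
        null = np.median(per_donor, axis=1)
        extreme = int((null <= observed).sum())
    p = (1 + extreme) / (n_shuffles + 1)
    return PermutationResult(observed=observed, null_mean=float(null.mean()),
                             p_value=p, n_shuffles=n_shuffles)


_G4_PATTERN = re.compile(r"(?=(G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}[ACGT]{1,7}G{3,}))")
_G4_PATTERN_MINUS = re.compile(r"(?=(C{3,}[ACGT]{1,7}C{3,}[ACGT]{1,7}C{3,}[ACGT]{1,7}C{3,}))")


def g4_motifs(seq: str) -> list[tuple[int, int]]:
    """Canonical G-quadruplex motifs on both strands: four tracts of >= 3 G
    (or C on the minus strand) with 1-7 nt loops."""
    out = []
    for pat in (_G4_PATTERN, _G4_PATTERN_MINUS):
        for m in pat.finditer(seq.upper()):
            out.append((m.start(1), m.end(1)))
    return sorted(out)


def g4_gc_association(
    n_t: np.ndarray,
    subject_seq: str,
    window_bp: int = 100,
) -> tuple[float, float]:
    """(one-sided rank-sum p for lower density in G4 windows, GC rank correlation).

    The subject is tiled into non-overlapping windows; per-window insert
    density (mean n_t) is compared between G4-containing and G4-free windows
    with a one-sided exact rank-sum test (alternative: G4 windows lower), and
    associated with per-window GC fraction by Spearman correlation.
    Returns (nan, rho) when either window group has fewer than 2 members.
    """
    if window_bp < 50:
        raise ValueError("window_bp must be >= 50")
    seq = subject_seq.upper()
    n_win = len(seq) // window_bp
    if n_win < 2:
        raise ValueError("subject shorter than two windows")
    motifs = g4_motifs(seq)
    g4_flag = np.zeros(n_win, dtype=bool)
    for s, e in motifs:
        for w in range(max(0, s // window_bp), min(n_win, e // window_bp + 1)):
            ws, we = w * window_bp, (w + 1) * window_bp
            if s < we and e > ws:
                g4_flag[w] = True
    density = np.array([n_t[w * window_bp : (w + 1) * window_bp].mean() for w in range(n_win)])
    gc = np.array([
        (seq[w * window_bp : (w + 1) * window_bp].count("G")
         + seq[w * window_bp : (w + 1) * window_bp].count("C")) / window_bp
        for w in range(n_win)
    ])
    if len(set(gc)) > 1 and len(set(density)) > 1:
        rho = float(sps.spearmanr(gc, density).statistic)
    else:
        rho = float("nan")
    g4_d, free_d = density[g4_flag], density[~g4_flag]
    if len(g4_d) < 2 or len(free_d) < 2:
        return float("nan"), rho
    method = "exact" if (len(g4_d) <= 12 and len(free_d) <= 12 and
                         len(set(density)) == len(density)) else "auto"
    p = float(sps.mannwhitneyu(g4_d, free_d, alternative="less", method=method).pvalue)
    return p, rho


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    Returns (one-sided p for the 'greater' tail of the top-left cell,
    two-sided p summing tables no more probable than the observed one).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0, 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    one_sided = sum(p for x, p in pmf.items() if x >= a)
    cutoff = pmf[a] * (1 + 1e-9)
    two_sided = sum(p for p in pmf.values() if p <= cutoff)
    return min(one_sided, 1.0), min(two_sided, 1.0)


def category_chisq(counts_a, counts_b) -> tuple[float, float]:
    """Pearson chi-square comparing two category count vectors (2 x k).

    Categories with pooled count 0 are dropped with a warning; expected counts
    come from the pooled margins. Returns (statistic, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("category vectors must have the same length")
    if a.sum() + b.sum() == 0:
        raise ValueError("all-zero contingency table")
    pooled = a + b
    if (pooled == 0).any():
        log.warning("dropping %d categories with pooled count 0", int((pooled == 0).sum()))
        keep = pooled > 0
        a, b = a[keep], b[keep]
    obs = np.vstack([a, b])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    if df == 0:
        return stat, 1.0
    return stat, float(sps.chi2.sf(stat, df))


def fold_change_report(
    clusters_by_condition: dict[str, list],
    n_colonies_by_condition: dict[str, int],
    reference: str,
) -> pd.DataFrame:
    """Per-class insertion frequencies (per 100,000 NHEJ products) and folds.

    A class absent in the reference condition but present elsewhere gets a
    minimal-bound fold (computed against a floor of one insertion in the
    reference) annotated as '>= x-fold (minimal)'.
    """
    for cond, n in n_colonies_by_condition.items():
        if n <= 0:
            raise ValueError(f"n_colonies for condition {cond!r} must be positive")
    if reference not in clusters_by_condition:
        raise ValueError(f"reference condition {reference!r} missing")

    def class_counts(clusters) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cl in clusters:
            rep = cl.representative
            classes = {seg.source_class or "nuclear" for seg in rep.segments}
            cls = classes.pop() if len(classes) == 1 else "mixed"
            counts[cls] = counts.get(cls, 0) + 1
            counts["all"] = counts.get("all", 0) + 1
        return counts

    per_cond = {cond: class_counts(cl) for cond, cl in clusters_by_condition.items()}
    classes = sorted({c for counts in per_cond.values() for c in counts})
    ref_counts = per_cond[reference]
    ref_n = n_colonies_by_condition[reference]
    rows = []
    for cond, counts in per_cond.items():
        n_col = n_colonies_by_condition[cond]
        for cls in classes:
            count = counts.get(cls, 0)
            freq = 1e5 * count / n_col
            ref_count = ref_counts.get(cls, 0)
            ref_freq = 1e5 * ref_count / ref_n
            if ref_count > 0:
                fold, note = freq / ref_freq, ""
            elif count > 0:
                fold = freq / (1e5 * 1 / ref_n)
                note = f">= {fold:.0f}-fold (minimal)"
            else:
                fold, note = float("nan"), "NA"
            rows.append({
                "condition": cond, "source_class": cls, "n_unique": count,
                "frequency_per_1e5": freq, "fold_vs_reference": fold, "note": note,
            })
    return pd.DataFrame(rows)
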