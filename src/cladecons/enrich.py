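"""Enrichment and downstream statistics.

* GAT-style interval permutation: each query segment is re-placed
  uniformly at random inside the workspace (length preserved, segments
  never cross workspace gaps) and the nucleotide overlap with an
  annotation is recomputed per simulation; empirical p-values carry the
  +1 pseudocount so they are never exactly 0.
* Chi-square term (GO-style) enrichment over a gene background with BH
  FDR across terms.
* Fisher's exact test, the tau expression-specificity index, and the
  cross-species (>5-fold / <2-fold) candidate-gene filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .clade import bh_fdr
from .intervals import IntervalSet

__all__ = [
    "EnrichmentResult",
    "permute_interval_overlap",
    "chi2_term_enrichment",
    "fisher_2x2",
    "tau_specificity",
    "stage_specific_calls",
    "cross_species_candidate_filter",
]


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    sd: float
    fold: float
    p_enriched: float
    p_depleted: float
    n_sims: int
    seed: int


def _workspace_layout(workspace: IntervalSet):
    """Flatten workspace intervals into one concatenated coordinate axis."""
    chroms, starts, ends = [], [], []
    for chrom, a, b in workspace:
        chroms.append(chrom)
        starts.append(a)
        ends.append(b)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    sizes = ends - starts
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return chroms, starts, ends, sizes, offsets


def _to_global(chroms, ws_starts, ws_ends, offsets, iv: IntervalSet):
    """Map an interval set (already within the workspace) to global coords."""
    seg_by_chrom: dict[str, list[int]] = {}
    for k, c in enumerate(chroms):
        seg_by_chrom.setdefault(c, []).append(k)
    pieces = []
    for chrom, a, b in iv:
        for k in seg_by_chrom.get(chrom, []):
            lo = max(a, int(ws_starts[k]))
            hi = min(b, int(ws_ends[k]))
            if lo < hi:
                g = int(offsets[k]) + (lo - int(ws_starts[k]))
                pieces.append((g, g + hi - lo))
    pieces.sort()
    return np.asarray(pieces, dtype=np.int64).reshape(-1, 2)


def _coverage_fn(pieces: np.ndarray):
    """Prefix-coverage function over global coordinates for merged pieces."""
    if len(pieces) == 0:
        return lambda x: np.zeros_like(np.asarray(x, dtype=np.int64))
    bounds = pieces.ravel()  # s0,e0,s1,e1,... strictly increasing after merge
    lens = pieces[:, 1] - pieces[:, 0]
    cum = np.zeros(len(bounds) + 1, dtype=np.int64)
    cum[2::2] = np.cumsum(lens)  # coverage up to each end
    cum[1::2] = cum[:-1:2]       # coverage up to each start

    def cov(x):
        x = np.asarray(x, dtype=np.int64)
        idx = np.searchsorted(bounds, x, side="right")
        base = cum[idx]
        inside = (idx % 2) == 1  # x falls inside piece (idx-1)//2
        extra = np.where(inside, x - bounds[np.maximum(idx - 1, 0)], 0)
        return base + extra

    return cov


def permute_interval_overlap(
    query: IntervalSet,
    annotation: IntervalSet,
    workspace: IntervalSet,
    n_sims: int = 100_000,
    seed: int = 0,
    chunk: int = 2_000_000,
) -> EnrichmentResult:
    """Permutation test of query/annotation overlap within a workspace.

    Every simulation re-places each query segment uniformly among all
    positions where it fits inside a single workspace interval; overlap is
    the summed nucleotide intersection with the annotation (intersected
    with the workspace first).  Deterministic given ``seed``.
    """
    if query.intersect(workspace).total_length != query.total_length:
        raise ValueError("query must lie within the workspace")
    ann = annotation.intersect(workspace)
    observed = query.overlap_bp(ann)

    chroms, ws_starts, ws_ends, sizes, offsets = _workspace_layout(workspace)
    ann_g = _to_global(chroms, ws_starts, ws_ends, offsets, ann)
    cov = _coverage_fn(ann_g)

    seg_lengths = np.array([b - a for _, a, b in query], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sims = np.zeros(n_sims, dtype=np.int64)
    for ln in np.unique(seg_lengths):
        k = int(np.sum(seg_lengths == ln))
        fit = sizes >= ln
        if not fit.any():
            raise ValueError(f"no workspace interval can hold a segment of {ln} bp")
        counts = (sizes[fit] - ln + 1).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(counts)])
        seg_offsets = offsets[:-1][fit]
        total = cum[-1]
        done = 0
        while done < n_sims:
            take = min(n_sims - done, max(1, chunk // max(k, 1)))
            u = rng.integers(0, total, size=(take, k))
            wi = np.searchsorted(cum, u, side="right") - 1
            gstart = seg_offsets[wi] + (u - cum[wi])
            ov = cov(gstart + ln) - cov(gstart)
            sims[done:done + take] += ov.sum(axis=1)
            done += take
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1)) if n_sims > 1 else 0.0
    p_enr = (1 + int(np.sum(sims >= observed))) / (n_sims + 1)
    p_dep = (1 + int(np.sum(sims <= observed))) / (n_sims + 1)
    fold = observed / mean if mean > 0 else float("inf") if observed else 1.0
    return EnrichmentResult(int(observed), mean, sd, float(fold),
                            float(p_enr), float(p_dep), n_sims, seed)


# --------------------------------------------------------------------- #
def chi2_term_enrichment(
    gene_list: set[str] | list[str],
    term_genes: dict[str, set[str]],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Per-term chi-square enrichment of a gene list against a background.

    Returns a DataFrame (term, in_list, in_term, chi2, p, direction, q)
    with BH FDR across terms; terms with no background members are
    skipped.
    """
    gl = set(gene_list)
    bg = set(background)
    if not gl <= bg:
        raise ValueError("gene list must be a subset of the background")
    rows = []
    for term, members in term_genes.items():
        m = set(members) & bg
        if not m:
            continue
        a = len(gl & m)
        b = len(gl) - a
        c = len(m) - a
        d = len(bg) - len(gl) - c
        table = np.array([[a, b], [c, d]])
        expected_a = len(gl) * len(m) / len(bg)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            stat, p = 0.0, 1.0
        else:
            use_yates = bool(
                (np.outer(table.sum(1), table.sum(0)) / table.sum() < 5).any()
            )
            stat, p, _, _ = chi2_contingency(table, correction=use_yates)
        rows.append(
            {
                "term": term,
                "in_list": a,
                "in_term": len(m),
                "expected": expected_a,
                "chi2": float(stat),
                "p": float(p),
                "direction": "enriched" if a >= expected_a else "depleted",
            }
        )
    df = pd.DataFrame(rows, columns=["term", "in_list", "in_term", "expected",
                                     "chi2", "p", "direction"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Degenerate tables (a zero margin) return p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


# --------------------------------------------------------------------- #
def tau_specificity(expression) -> float:
    """Tau expression-specificity index of one gene across conditions.

    tau = sum_i (1 - x_i / max(x)) / (N - 1); 1 for single-condition
    expression, 0 for a uniform profile.  Requires >= 2 non-negative
    values, not all zero.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need an expression vector over >= 2 conditions")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        raise ValueError("all-zero expression vector: tau undefined")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def stage_specific_calls(
    expression: pd.DataFrame, tau_threshold: float = 0.8
) -> pd.DataFrame:
    """Per-gene tau with the argmax stage; specific where tau >= threshold."""
    x = expression.to_numpy(dtype=float)
    ok = x.max(axis=1) > 0
    tau = np.full(len(x), np.nan)
    tau[ok] = (1.0 - x[ok] / x[ok].max(axis=1, keepdims=True)).sum(axis=1) / (
        x.shape[1] - 1
    )
    return pd.DataFrame(
        {
            "tau": tau,
            "stage": expression.columns.to_numpy()[np.argmax(x, axis=1)],
            "specific": tau >= tau_threshold,
        },
        index=expression.index,
    )


def cross_species_candidate_filter(
    fc_species1: pd.DataFrame,
    deg_species1: pd.DataFrame,
    fc_species2: pd.DataFrame,
    orthology: dict[str, str],
    fold_high: float = 5.0,
    fold_low: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Candidate genes: strong change in species 1, flat in species 2.

    Keep genes that are species-1 DEGs with fold change strictly above
    ``fold_high`` in at least one contrast and whose species-2 ortholog
    has fold change strictly below ``fold_low`` in the corresponding
    contrast.  Fold changes are ratios (> 0).  Returns (candidates,
    no_ortholog) — genes passing the species-1 criterion but lacking an
    ortholog are reported separately, not kept.
    """
    if (fc_species1.to_numpy() <= 0).any() or (fc_species2.to_numpy() <= 0).any():
        raise ValueError("fold changes must be positive ratios")
    candidates, no_ortholog = [], []
    for gene in fc_species1.index:
        hits = [
            c
            for c in fc_species1.columns
            if bool(deg_species1.loc[gene, c]) and fc_species1.loc[gene, c] > fold_high
        ]
        if not hits:
            continue
        ortho = orthology.get(gene)
        if ortho is None or ortho not in fc_species2.index:
            no_ortholog.append(gene)
            continue
        if any(fc_species2.loc[ortho, c] < fold_low for c in hits):
            candidates.append(gene)
    return candidates, no_ortholog
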