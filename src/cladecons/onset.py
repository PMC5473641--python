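"""Dating the onset of conservation on a clade's stem branch.

Model: an element evolved neutrally on the stem branch (per-Myr rate r)
until an onset time T, then at the conserved rate rho*r; crown ingroup
branches evolve at rho*r throughout.  The expected element-specific stem
branch length is therefore

    b(T) = r*(t0 - T) + rho*r*(T - t1),      t1 <= T <= t0,

with t0 the ingroup/outgroup split age and t1 the ingroup crown age.  b is
affine and strictly decreasing in T for rho < 1, so the estimator inverts
it in closed form at the ML stem length of the element; estimates falling
outside [t1, t0] are clamped with a flag.  Uncertainty comes from a
nonparametric bootstrap over alignment columns (resampling column-pattern
counts), refitting branch lengths and the rho ratio per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import MultipleAlignment
from .likelihood import compress_patterns, fit_branch_lengths, leaf_row_map
from .models import SubstitutionModel
from .tree import PhyloTree

__all__ = ["StemBranchModel", "OnsetEstimate", "expected_stem_length", "invert_onset",
           "estimate_onset"]


@dataclass(frozen=True)
class StemBranchModel:
    t0: float  # stem start age (ingroup/outgroup split), Myr
    t1: float  # stem end age (ingroup crown), Myr
    rate: float  # neutral substitutions/site/Myr on the stem
    rho: float  # conserved branch scale in (0, 1)

    def __post_init__(self):
        if not self.t1 < self.t0:
            raise ValueError("need t1 < t0")
        if self.rate <= 0:
            raise ValueError("neutral rate must be positive")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1) for onset dating")


def expected_stem_length(model: StemBranchModel, T: float) -> float:
    """Expected stem substitutions/site when conservation began at age T."""
    if not model.t1 <= T <= model.t0:
        raise ValueError(f"onset {T} outside the stem interval [{model.t1}, {model.t0}]")
    return model.rate * (model.t0 - T) + model.rho * model.rate * (T - model.t1)


def invert_onset(model: StemBranchModel, b_hat: float) -> tuple[float, bool]:
    """Onset age whose expected stem length equals ``b_hat``; clamped to the
    stem interval.  Returns (T_hat, clamped)."""
    r, rho = model.rate, model.rho
    T = (r * model.t0 - rho * r * model.t1 - b_hat) / (r * (1.0 - rho))
    if T < model.t1:
        return model.t1, True
    if T > model.t0:
        return model.t0, True
    return float(T), False


@dataclass
class OnsetEstimate:
    onset: float  # T-hat, Myr before present
    se: float
    ci_low: float
    ci_high: float
    rho: float
    rate: float
    stem_length: float
    clamped: bool
    boot_clamped_fraction: float
    n_boot: int
    seed: int
    boot_onsets: np.ndarray = field(repr=False, default=None)


def estimate_onset(
    element: MultipleAlignment,
    tree: PhyloTree,
    ingroup: list[str],
    model: SubstitutionModel,
    neutral_tree: PhyloTree | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> OnsetEstimate:
    """Date conservation onset on the ingroup stem for one element.

    ``tree`` must carry node ages; ``neutral_tree`` (defaults to ``tree``)
    supplies the genome-wide neutral branch lengths from which the stem
    rate r and the ingroup conservation scale rho are derived.  The
    element must include at least one outgroup species to anchor the stem.
    """
    neutral = neutral_tree or tree
    if tree.ages is None:
        raise ValueError("tree must carry node ages")
    if not any(sp not in ingroup for sp in element.species):
        raise ValueError("element alignment must include an outgroup species")
    if n_boot < 20:
        warnings.warn(f"n_boot={n_boot} is small; the s.e. will be unstable")
    m = tree.mrca(ingroup)
    t0 = float(tree.ages[tree.parent[m]])
    t1 = float(tree.ages[m])
    stem_neutral = float(neutral.lengths[m])
    r = stem_neutral / (t0 - t1)
    if r <= 0:
        raise ValueError("neutral stem rate is zero: cannot date onset")
    crown = np.array([v for v in tree.subtree_nodes(m)
                      if v != m and tree.parent[v] != -1], dtype=np.int64)

    patterns, counts, _ = compress_patterns(element.matrix)
    rows = leaf_row_map(tree, element.species)
    init = np.maximum(neutral.lengths[:-1], 1e-4)
    # free only the stem and crown ingroup edges: outgroup branches evolve
    # neutrally under the dating model, and fixing them pins the root split
    free = np.concatenate([[m], crown])
    lengths, _ = fit_branch_lengths(patterns, counts, tree, model, rows,
                                    init=init, free_edges=free)
    b_hat = float(lengths[m])
    rho = float(lengths[crown].sum() / neutral.lengths[crown].sum())
    if rho >= 1:
        raise ValueError("element not conserved in ingroup (rho >= 1)")
    rho = max(rho, 1e-9)  # a perfectly invariant crown sits on the boundary
    frame = StemBranchModel(t0, t1, r, rho)
    T_hat, clamped = invert_onset(frame, b_hat)

    rng = np.random.default_rng(seed)
    total = int(counts.sum())
    boots = np.empty(n_boot)
    n_clamped = 0
    for i in range(n_boot):
        w = rng.multinomial(total, counts / total).astype(float)
        bl, _ = fit_branch_lengths(patterns, w, tree, model, rows,
                                   init=np.maximum(lengths[:-1], 1e-4),
                                   free_edges=free)
        rho_b = float(bl[crown].sum() / neutral.lengths[crown].sum())
        rho_b = float(np.clip(rho_b, 1e-9, 1.0 - 1e-9))
        Tb, cl = invert_onset(StemBranchModel(t0, t1, r, rho_b), float(bl[m]))
        boots[i] = Tb
        n_clamped += int(cl)
    se = float(boots.std(ddof=1)) if n_boot > 1 else 0.0
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if n_boot > 1 else (T_hat, T_hat))
    return OnsetEstimate(
        onset=T_hat, se=se, ci_low=float(lo), ci_high=float(hi),
        rho=rho, rate=r, stem_length=b_hat, clamped=clamped,
        boot_clamped_fraction=n_clamped / n_boot, n_boot=n_boot, seed=seed,
        boot_onsets=boots,
    )
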