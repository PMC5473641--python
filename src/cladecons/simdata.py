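"""Synthetic data generators with recorded ground truth.

Every generator is a pure function of its parameters and a seed.  A single
global seed is expanded into independent substreams (one per generator
call) through :func:`numpy.random.SeedSequence.spawn`, so the pipeline's
stages draw from non-interfering streams.

The generators emulate the statistical structure of a comparative-genomics
study of clade-restricted conservation: neutral sequence evolution along a
calibrated tree, planted conserved elements (shared, clade-specific with
outgroup acceleration, or clade-specific with no aligned outgroup), SNPs
at element-dependent density, random interval annotations, and expression
tables with stage-specific genes.  They do not model indels (planted
"unaligned" elements gap whole outgroup rows), context-dependent
substitution, or alignment error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, MultipleAlignment
from .models import SubstitutionModel
from .tree import PhyloTree, parse_newick

__all__ = [
    "SimGroundTruth",
    "simulate_alignment",
    "plant_elements",
    "simulate_stem_onset",
    "simulate_snps",
    "simulate_intervals",
    "simulate_expression",
    "stem_onset_tree",
]

ELEMENT_TYPES = ("shared-conserved", "clade-specific-II", "clade-specific-I")


@dataclass
class SimGroundTruth:
    """Planted structure of a simulated dataset."""

    elements: list[tuple[str, int, int, str]] = field(default_factory=list)
    # (chrom, start, end, type)
    rho: float | None = None
    onset_time: float | None = None
    snp_positions: np.ndarray | None = None
    enriched_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    stage_specific: dict[str, str] = field(default_factory=dict)  # gene -> stage

    def elements_of_type(self, kind: str) -> list[tuple[str, int, int, str]]:
        return [e for e in self.elements if e[3] == kind]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams of one global seed, in documented order."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------- #
def _evolve(tree: PhyloTree, model: SubstitutionModel, lengths: np.ndarray,
            n: int, rng: np.random.Generator) -> np.ndarray:
    """States (tree leaves order) simulated down the tree; (n_leaves, n)."""
    pmats = model.transition_matrices(lengths)
    states = np.empty((tree.n_nodes, n), dtype=np.uint8)
    states[tree.root] = rng.choice(4, size=n, p=model.pi)
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder = reverse postorder
        parent_states = states[tree.parent[v]]
        u = rng.random(n)
        cdf = np.cumsum(pmats[v], axis=1)
        states[v] = (u[:, None] > cdf[parent_states]).sum(axis=1).astype(np.uint8)
    return states[tree.leaf_indices]


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    length: int,
    seed,
    chrom: str = "chr1",
    ref_start: int = 0,
    reference: str | None = None,
) -> MultipleAlignment:
    """Forward-simulate an ungapped alignment under the neutral model.

    Root states are drawn from the model's equilibrium frequencies and
    propagated along each branch with the CTMC transition kernel.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    mat = _evolve(tree, model, tree.lengths, length, rng)
    names = tree.leaf_names
    return MultipleAlignment(
        names, mat, reference=reference or names[0], chrom=chrom, ref_start=ref_start
    )


def plant_elements(
    aln: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    spec: Sequence[tuple[int, int, float, str, Sequence[str]]],
    seed,
) -> tuple[MultipleAlignment, SimGroundTruth]:
    """Replace intervals of a neutral alignment with conserved elements.

    ``spec`` rows are (start_column, length, rho, type, clade_species):

    * ``shared-conserved`` — every branch scaled by rho;
    * ``clade-specific-II`` — only branches inside the clade (stem included)
      scaled by rho, the rest neutral;
    * ``clade-specific-I`` — as II, plus every non-clade row replaced by
      gaps across the element (no outgroup sequence aligned).
    """
    rng = _rng(seed)
    iv = sorted((s, s + ln) for s, ln, *_ in spec)
    for (a, b), (c, d) in zip(iv, iv[1:]):
        if c < b:
            raise ValueError(f"overlapping planted intervals [{a},{b}) and [{c},{d})")
    if iv and (iv[0][0] < 0 or iv[-1][1] > aln.n_columns):
        raise ValueError("planted interval outside alignment")

    mat = aln.matrix.copy()
    truth = SimGroundTruth()
    leaf_order = {name: i for i, name in enumerate(tree.leaf_names)}
    row_of_leafname = {sp: i for i, sp in enumerate(aln.species)}
    for start, length, rho, kind, clade in spec:
        if kind not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {kind!r}")
        if kind == "clade-specific-I" and aln.reference not in clade:
            raise ValueError("reference species must be inside the clade for type I")
        lengths = tree.lengths.copy()
        if kind == "shared-conserved":
            lengths *= rho
        else:
            edges = tree.clade_edges(clade, include_stem=True)
            lengths[edges] *= rho
        sub = _evolve(tree, model, lengths, length, rng)
        for name, li in leaf_order.items():
            mat[row_of_leafname[name], start:start + length] = sub[li]
        if kind == "clade-specific-I":
            for sp in aln.species:
                if sp not in clade:
                    mat[row_of_leafname[sp], start:start + length] = GAP
        p = aln.ref_positions
        truth.elements.append(
            (aln.chrom, int(p[start]), int(p[start + length - 1]) + 1, kind)
        )
        truth.rho = rho
    out = MultipleAlignment(aln.species, mat, aln.reference, aln.chrom, aln.ref_start)
    return out, truth


# --------------------------------------------------------------------- #
def stem_onset_tree(
    t0: float = 100.0,
    t1: float = 66.0,
    n_ingroup: int = 4,
    rate: float = 0.002,
    t_root: float | None = None,
) -> tuple[PhyloTree, list[str]]:
    """Calibrated demo tree for onset dating: an ingroup crown of age ``t1``
    attached by a stem to the outgroup side diverging at ``t0``.

    The outgroup side carries a small radiation shortly after the split
    (three lineages, ages 0.95*t0 and 0.6*t0) plus a deep anchor at
    ``t_root`` (default 1.5*t0).  Dense sampling near the split is what
    real alignments provide, and it is what makes the state of the stem's
    parent node — and hence the element-specific stem length —
    well determined; a single distant outgroup leaves the stem length
    badly resolved.

    Branch lengths are neutral (``rate`` substitutions/site/Myr times
    duration).  Returns (tree_with_ages, ingroup_leaf_names).
    """
    if not 0 < t1 < t0:
        raise ValueError("need 0 < t1 < t0")
    if n_ingroup < 2:
        raise ValueError("need at least 2 ingroup leaves to anchor the crown")
    t_root = 1.5 * t0 if t_root is None else t_root
    if not t_root > t0:
        raise ValueError("t_root must exceed t0")
    names = [f"in{i+1}" for i in range(n_ingroup)]
    # ladder inside the crown with evenly spaced internal ages
    sub_ages = np.linspace(t1, t1 / n_ingroup, n_ingroup - 1)
    nwk = names[0]
    ages = {}
    for k in range(1, n_ingroup):
        lab = f"crown{k}" if k < n_ingroup - 1 else "crown"
        nwk = f"({names[k]},{nwk}){lab}"
        ages[lab] = float(sub_ages[n_ingroup - 1 - k])
    ages["crown"] = t1
    nwk = f"((((out1a,out1b)og2,out1c)og1,{nwk})split,out2)root;"
    ages["og1"] = 0.95 * t0
    ages["og2"] = 0.6 * t0
    ages["split"] = t0
    ages["root"] = t_root
    tree = parse_newick(nwk).with_ages(ages)
    lengths = tree.durations() * rate
    lengths[-1] = 0.0
    return tree.copy(lengths=lengths), names


def simulate_stem_onset(
    tree: PhyloTree,
    model: SubstitutionModel,
    ingroup: Sequence[str],
    onset: float,
    rate: float,
    rho: float,
    columns: int,
    seed,
) -> MultipleAlignment:
    """Element alignment in which ingroup conservation started at ``onset`` Myr.

    The stem branch accumulates ``rate*(t0-onset) + rho*rate*(onset-t1)``
    expected substitutions per site (neutral before onset, conserved
    after); crown ingroup branches evolve at ``rho*rate`` per Myr and all
    other branches at the neutral ``rate``.
    """
    if tree.ages is None:
        raise ValueError("tree must carry node ages")
    if not (0 < rho <= 1) or rate <= 0:
        raise ValueError("need rate > 0 and 0 < rho <= 1")
    m = tree.mrca(ingroup)
    t1 = float(tree.ages[m])
    t0 = float(tree.ages[tree.parent[m]])
    if not (t1 <= onset <= t0):
        raise ValueError(f"onset {onset} outside the stem interval [{t1}, {t0}]")
    dur = tree.durations()
    lengths = dur * rate
    crown = [v for v in tree.subtree_nodes(m) if v != m]
    lengths[crown] = dur[crown] * rate * rho
    lengths[m] = rate * (t0 - onset) + rho * rate * (onset - t1)
    lengths[-1] = 0.0
    rng = _rng(seed)
    mat = _evolve(tree, model, lengths, columns, rng)
    names = tree.leaf_names
    return MultipleAlignment(names, mat, reference=ingroup[0])


# --------------------------------------------------------------------- #
def simulate_snps(
    genome_length: int,
    elements: Sequence[tuple[int, int]],
    density_in: float,
    density_out: float,
    seed,
) -> np.ndarray:
    """Poisson-placed SNP positions with element-dependent density per kb.

    Returns sorted unique 0-based positions.
    """
    if density_in < 0 or density_out < 0:
        raise ValueError("densities must be non-negative")
    rng = _rng(seed)
    inside = np.zeros(genome_length, dtype=bool)
    for a, b in elements:
        inside[a:b] = True
    p_in, p_out = density_in / 1000.0, density_out / 1000.0
    u = rng.random(genome_length)
    hit = np.where(inside, u < p_in, u < p_out)
    return np.flatnonzero(hit).astype(np.int64)


def simulate_intervals(
    workspace: Sequence[tuple[int, int]],
    n: int,
    length: int | tuple[int, int],
    targets: Sequence[tuple[int, int]],
    fraction_inside: float,
    seed,
    chrom: str = "chr1",
) -> list[tuple[str, int, int]]:
    """Random annotation intervals, a set fraction placed inside targets.

    Each interval start is uniform over the admissible region (whole
    workspace, or the target set), with the interval kept inside one
    workspace segment.
    """
    rng = _rng(seed)
    out = []
    ws = sorted(workspace)
    tg = sorted(targets)
    for _ in range(n):
        ln = length if isinstance(length, int) else int(rng.integers(length[0], length[1] + 1))
        region = tg if (tg and rng.random() < fraction_inside) else ws
        spots = [(a, b - ln) for a, b in region if b - a >= ln]
        if not spots:
            raise ValueError(f"no region can hold an interval of length {ln}")
        weights = np.array([hi - lo + 1 for lo, hi in spots], dtype=float)
        k = rng.choice(len(spots), p=weights / weights.sum())
        s = int(rng.integers(spots[k][0], spots[k][1] + 1))
        out.append((chrom, s, s + ln))
    return sorted(out)


def simulate_expression(
    genes: Sequence[str],
    stages: Sequence[str],
    n_specific_per_stage: int,
    fold: float = 10.0,
    noise: float = 0.0,
    base_level: float = 10.0,
    seed=0,
) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Gene-by-stage expression with planted stage-specific genes.

    Stage-specific genes express ``base_level * fold`` in exactly one stage
    and 0 elsewhere (tau index 1 at zero noise); the rest are uniform at
    ``base_level`` (tau 0).  Multiplicative log-normal noise of s.d.
    ``noise`` is applied when nonzero.
    """
    rng = _rng(seed)
    genes = list(genes)
    stages = list(stages)
    truth = SimGroundTruth()
    mat = np.full((len(genes), len(stages)), base_level, dtype=float)
    gi = 0
    for s_idx, stage in enumerate(stages):
        for _ in range(n_specific_per_stage):
            if gi >= len(genes):
                break
            mat[gi, :] = 0.0
            mat[gi, s_idx] = base_level * fold
            truth.stage_specific[genes[gi]] = stage
            gi += 1
    if noise > 0:
        mat *= np.exp(rng.normal(0.0, noise, size=mat.shape))
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=stages)
    return df, truth


def simulate_fold_changes(
    genes: Sequence[str],
    contrasts: Sequence[str],
    n_candidates: int,
    seed,
    ortholog_fraction: float = 1.0,
    candidate_fc: float = 8.0,
    background_fc: float = 1.2,
    turtle_candidate_fc: float = 1.3,
    turtle_background_fc: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, str], set[str]]:
    """Cross-species fold-change fixture for the candidate-gene filter.

    Planted candidate genes are differentially expressed in the first
    species with fold change ``candidate_fc`` (> 5) in at least one
    contrast while their orthologs in the second species stay below
    twofold; background genes either lack the first-species signal or show
    a concordant (> 2-fold) second-species change.  Returns
    (species1_fc, species1_deg_flags, species2_fc, orthology, truth_set).
    """
    rng = _rng(seed)
    genes = list(genes)
    contrasts = list(contrasts)
    fc1 = pd.DataFrame(background_fc, index=pd.Index(genes, name="gene"), columns=contrasts)
    deg = pd.DataFrame(False, index=fc1.index, columns=contrasts)
    orthology = {}
    fc2_rows = {}
    truth: set[str] = set()
    for i, g in enumerate(genes):
        has_ortholog = rng.random() < ortholog_fraction
        if has_ortholog:
            orthology[g] = f"t_{g}"
        if i < n_candidates:
            c = contrasts[int(rng.integers(len(contrasts)))]
            fc1.loc[g, c] = candidate_fc
            deg.loc[g, c] = True
            if has_ortholog:
                fc2_rows[f"t_{g}"] = {k: turtle_candidate_fc for k in contrasts}
                truth.add(g)
        elif i < 2 * n_candidates:
            # discordant control: strong in species 1 but also > 2-fold in 2
            c = contrasts[int(rng.integers(len(contrasts)))]
            fc1.loc[g, c] = candidate_fc
            deg.loc[g, c] = True
            if has_ortholog:
                fc2_rows[f"t_{g}"] = {k: turtle_background_fc for k in contrasts}
        else:
            if has_ortholog:
                fc2_rows[f"t_{g}"] = {k: turtle_candidate_fc for k in contrasts}
    fc2 = pd.DataFrame.from_dict(fc2_rows, orient="index").reindex(columns=contrasts)
    fc2.index.name = "gene"
    return fc1, deg, fc2, orthology, truth
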