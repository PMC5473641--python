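"""Lineage-specific classification of conserved elements.

An element called conserved in the ingroup (e.g. birds) is

* **Type I** when no outgroup species has any aligned sequence across the
  element (fewer than 10% resolved characters for every outgroup species);
* **Type II** when outgroup sequence is present and the outgroup side of
  the tree evolves significantly faster than the ingroup within the
  element — a one-sided subtree-rate likelihood-ratio test, required to be
  significant (BH q < 0.01) in all configured outgroup sets;
* **non-specific** otherwise.

The test compares H0 (one rate scale shared by all branches) against H1
(separate scales for the ingroup, stem included, and the outgroup side);
the acceleration p-value is 0.5*P(chi2_1 > LRT) when the outgroup scale
exceeds the ingroup scale and 1 otherwise, the usual one-sided boundary
mixture.  FDR is controlled per outgroup set across all testable elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import GAP, MultipleAlignment
from .hmm import ConservedElement
from .likelihood import compress_patterns, fit_scale_groups, leaf_row_map
from .models import SubstitutionModel
from .tree import PhyloTree

__all__ = [
    "OutgroupScheme",
    "CladeTestResult",
    "outgroup_presence",
    "subtree_rate_lrt",
    "bh_fdr",
    "classify_ashce",
]


@dataclass
class OutgroupScheme:
    """Ingroup species plus an ordered family of outgroup sets.

    The default configuration of the avian analysis uses three nested sets
    (closest outgroup only; several non-ingroup reptiles; reptiles plus
    further vertebrates), and a Type II call must be supported in every
    set.
    """

    ingroup: list[str]
    outgroup_sets: dict[str, list[str]] = field(default_factory=dict)

    def validate(self, tree: PhyloTree) -> None:
        leaves = set(tree.leaf_names)
        ing = set(self.ingroup)
        if not ing <= leaves:
            raise ValueError(f"ingroup species not in tree: {sorted(ing - leaves)}")
        for name, og in self.outgroup_sets.items():
            so = set(og)
            if so & ing:
                raise ValueError(f"outgroup set {name!r} overlaps the ingroup")
            if not so <= leaves:
                raise ValueError(
                    f"outgroup set {name!r} species not in tree: {sorted(so - leaves)}"
                )

    @property
    def all_outgroups(self) -> list[str]:
        out: list[str] = []
        for og in self.outgroup_sets.values():
            out.extend(s for s in og if s not in out)
        return out


@dataclass
class CladeTestResult:
    element_id: int
    set_id: str
    lambda_in: float
    lambda_out: float
    lrt: float
    p: float
    q: float = float("nan")
    testable: bool = True


# --------------------------------------------------------------------- #
def outgroup_presence(
    element: MultipleAlignment,
    outgroup: list[str],
    presence_threshold: float = 0.10,
) -> bool:
    """True when at least one outgroup species is aligned over the element.

    A species counts as aligned when at least ``presence_threshold`` of the
    element's columns carry a resolved (non-gap, non-N) character for it;
    species missing from the alignment count as fully gapped.
    """
    n = element.n_columns
    for sp in outgroup:
        if sp not in element.species:
            continue
        resolved = int(np.sum(element.row(sp) < GAP))
        if resolved / n >= presence_threshold:
            return True
    return False


def subtree_rate_lrt(
    element: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    ingroup: list[str],
    outgroup: list[str],
    element_id: int = 0,
    set_id: str = "",
    min_columns: int = 5,
) -> CladeTestResult:
    """One-sided test for outgroup acceleration within an element.

    The tree is restricted to ingroup plus this outgroup set; under H1 the
    ingroup clade (stem branch included) and the remaining branches get
    separate rate scales on the fixed neutral branch lengths.
    """
    if element.n_columns < min_columns:
        return CladeTestResult(element_id, set_id, np.nan, np.nan, np.nan, np.nan,
                               testable=False)
    species = [s for s in ingroup + outgroup if s in element.species]
    present_out = [s for s in outgroup if s in species]
    if not present_out:
        return CladeTestResult(element_id, set_id, np.nan, np.nan, np.nan, np.nan,
                               testable=False)
    sub = tree.induced_subtree(ingroup + present_out)
    aln = element.subset_species([s for s in species])
    patterns, counts, _ = compress_patterns(aln.matrix)
    rows = leaf_row_map(sub, aln.species)

    groups = np.ones(sub.n_nodes, dtype=np.int64)
    in_edges = sub.clade_edges(ingroup, include_stem=True)
    groups[in_edges] = 0
    groups[-1] = 0  # root has no edge; any group index is fine

    (lam0,), ll0 = fit_scale_groups(patterns, counts, sub, model, rows,
                                    np.zeros(sub.n_nodes, np.int64), 1)
    scales, ll1 = fit_scale_groups(patterns, counts, sub, model, rows, groups, 2)
    lam_in, lam_out = float(scales[0]), float(scales[1])
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    if lam_out <= lam_in:
        p = 1.0
    else:
        p = float(0.5 * chi2.sf(lrt, df=1))
    return CladeTestResult(element_id, set_id, lam_in, lam_out, lrt, p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------- #
def classify_ashce(
    elements: list[ConservedElement],
    aln: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    scheme: OutgroupScheme,
    q_threshold: float = 0.01,
    presence_threshold: float = 0.10,
    min_length: int = 20,
) -> tuple[list[ConservedElement], pd.DataFrame]:
    """Label each element HCE / ASHCE-I / ASHCE-II / non-specific.

    Type I requires absence of every outgroup species (across the union of
    all sets); Type II requires presence in at least one set and q below
    ``q_threshold`` in *all* sets, with BH FDR computed within each set
    across its testable elements.  Elements shorter than ``min_length``
    keep the plain HCE label.  Returns the relabelled elements (new list,
    input untouched) plus the per-set test table.
    """
    scheme.validate(tree)
    labeled = [ConservedElement(e.chrom, e.start, e.end, e.score,
                                e.mean_posterior, "HCE") for e in elements]
    sub_alns = {}
    for i, e in enumerate(labeled):
        try:
            sub_alns[i] = aln.extract_ref_interval(e.start, e.end)
        except ValueError:
            sub_alns[i] = None

    results: list[CladeTestResult] = []
    present: dict[tuple[int, str], bool] = {}
    for set_id, og in scheme.outgroup_sets.items():
        for i, e in enumerate(labeled):
            sa = sub_alns[i]
            if sa is None:
                present[(i, set_id)] = False
                continue
            pres = outgroup_presence(sa, og, presence_threshold)
            present[(i, set_id)] = pres
            if pres:
                results.append(
                    subtree_rate_lrt(sa, tree, model, scheme.ingroup, og,
                                     element_id=i, set_id=set_id)
                )
        # per-set FDR over the testable elements
        batch = [r for r in results if r.set_id == set_id and r.testable]
        if batch:
            qs = bh_fdr([r.p for r in batch])
            for r, q in zip(batch, qs):
                r.q = float(q)

    by_key = {(r.element_id, r.set_id): r for r in results}
    set_ids = list(scheme.outgroup_sets)
    for i, e in enumerate(labeled):
        if e.length < min_length or sub_alns[i] is None:
            continue
        any_present = any(present[(i, s)] for s in set_ids)
        if not any_present:
            # absent for every outgroup species in the union of sets
            e.label = "ASHCE-I"
            continue
        ok = True
        for s in set_ids:
            r = by_key.get((i, s))
            if r is None or not r.testable or not (r.q < q_threshold):
                ok = False
                break
        e.label = "ASHCE-II" if ok else "non-specific"

    table = pd.DataFrame(
        [
            {
                "element_id": r.element_id,
                "set_id": r.set_id,
                "lambda_in": r.lambda_in,
                "lambda_out": r.lambda_out,
                "lrt": r.lrt,
                "p": r.p,
                "q": r.q,
                "testable": r.testable,
            }
            for r in results
        ]
    )
    return labeled, table
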