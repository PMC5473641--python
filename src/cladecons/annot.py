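"""Genomic context of conserved elements: annotation class, gene
association, ranked candidate genes, SNP-density contrast.

Annotation classes follow a fixed priority — coding > 5'/3' 10 kb windows
> intronic > intergenic — with the 10 kb windows anchored at the
*translation* start/stop (CDS ends), strand-aware.  Gene association uses
the nearest protein-coding gene within 10 kb of the *transcript* span, the
two anchors the upstream analyses respectively call for.  GFF3 is parsed
through gffutils; internally everything is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .hmm import ConservedElement
from .intervals import IntervalSet

__all__ = [
    "GeneModel",
    "read_gff3",
    "classify_region",
    "associate_genes",
    "rank_associated_genes",
    "snp_density_test",
]

REGION_CLASSES = ("coding", "five_prime_10kb", "three_prime_10kb", "intronic", "intergenic")


@dataclass
class GeneModel:
    """A protein-coding gene reduced to one transcript (longest CDS)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # transcript span, 0-based half-open
    tx_end: int
    cds: list[tuple[int, int]]  # sorted, non-overlapping

    def __post_init__(self):
        self.cds = sorted(self.cds)
        for (a, b), (c, d) in zip(self.cds, self.cds[1:]):
            if c < b:
                raise ValueError(f"overlapping CDS in {self.gene_id}")
        if self.cds and (self.cds[0][0] < self.tx_start or self.cds[-1][1] > self.tx_end):
            raise ValueError(f"CDS outside transcript span in {self.gene_id}")

    @property
    def translation_start(self) -> int:
        """Genomic coordinate of the start codon's first base."""
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    @property
    def translation_stop(self) -> int:
        return self.cds[-1][1] - 1 if self.strand == "+" else self.cds[0][0]


def read_gff3(path) -> list[GeneModel]:
    """Load gene/mRNA/CDS features; one model per gene (longest total CDS)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        best: tuple[int, list] | None = None
        for mrna in db.children(g, featuretype="mRNA"):
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            total = sum(b - a for a, b in cds)
            if cds and (best is None or total > best[0]):
                best = (total, cds)
        if best is None:  # gene without mRNA children: CDS directly under gene
            cds = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS")]
            best = (sum(b - a for a, b in cds), cds) if cds else None
        genes.append(
            GeneModel(
                gene_id=g.attributes.get("ID", [g.id])[0],
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                tx_start=g.start - 1,
                tx_end=g.end,
                cds=sorted(best[1]) if best else [],
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcladecons\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tcladecons\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tcladecons\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds{i + 1};Parent={mid}\n"
                )


# --------------------------------------------------------------------- #
def _overlaps(a: int, b: int, c: int, d: int) -> bool:
    return max(a, c) < min(b, d)


def classify_region(
    element: ConservedElement, genes: list[GeneModel], window: int = 10_000
) -> str:
    """Highest-priority annotation class overlapped by the element."""
    s, e = element.start, element.end
    hit = set()
    for g in genes:
        if g.chrom != element.chrom or not g.cds:
            continue
        if any(_overlaps(s, e, a, b) for a, b in g.cds):
            hit.add("coding")
            continue
        ts, tt = g.translation_start, g.translation_stop
        if g.strand == "+":
            w5 = (max(ts - window, 0), ts)
            w3 = (tt + 1, tt + 1 + window)
        else:
            w5 = (ts + 1, ts + 1 + window)
            w3 = (max(tt - window, 0), tt)
        if _overlaps(s, e, *w5):
            hit.add("five_prime_10kb")
        if _overlaps(s, e, *w3):
            hit.add("three_prime_10kb")
        if _overlaps(s, e, g.tx_start, g.tx_end):
            hit.add("intronic")
    for cls in REGION_CLASSES[:-1]:
        if cls in hit:
            return cls
    return "intergenic"


def associate_genes(
    elements: list[ConservedElement],
    genes: list[GeneModel],
    window: int = 10_000,
) -> dict[int, str]:
    """element index -> nearest gene id within ``window`` bp of its
    transcript span (distance 0 inside the span); ties break to the
    smaller distance then the lexicographically smaller gene id."""
    out: dict[int, str] = {}
    for i, e in enumerate(elements):
        best: tuple[int, str] | None = None
        for g in genes:
            if g.chrom != e.chrom:
                continue
            if _overlaps(e.start, e.end, g.tx_start, g.tx_end):
                d = 0
            elif e.end <= g.tx_start:
                d = g.tx_start - e.end  # bases strictly between the intervals
            else:
                d = e.start - g.tx_end
            if d > window:
                continue
            cand = (d, g.gene_id)
            if best is None or cand < best:
                best = cand
        if best is not None:
            out[i] = best[1]
    return out


def rank_associated_genes(
    elements: list[ConservedElement],
    association: dict[int, str],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Genes ranked by the highest log-odds score of their elements.

    Returns a DataFrame (gene, score, n_elements) in descending score
    order, ties broken by gene id; truncated to ``top_n`` when given.
    """
    scores: dict[str, list[float]] = {}
    for i, gene in association.items():
        scores.setdefault(gene, []).append(elements[i].score)
    rows = [
        {"gene": g, "score": max(v), "n_elements": len(v)} for g, v in scores.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "score", "n_elements"])
    df = df.sort_values(["score", "gene"], ascending=[False, True], ignore_index=True)
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return df


# --------------------------------------------------------------------- #
def snp_density_test(
    snps: np.ndarray,
    target: IntervalSet,
    workspace_length: int,
    chrom: str = "chr1",
) -> dict:
    """Contrast SNP density inside a target set against the rest.

    Builds the 2x2 table (SNP / non-SNP positions) x (inside / outside the
    target) and applies Pearson's chi-square with 1 df (Yates-corrected
    only when an expected cell drops below 5).  Densities are per kb.
    """
    snps = np.asarray(snps, dtype=np.int64)
    if snps.size == 0:
        raise ValueError("no variants supplied")
    bp_in = target.total_length
    bp_out = workspace_length - bp_in
    if bp_in == 0 or bp_out <= 0:
        raise ValueError("target must cover part, not all, of the workspace")
    inside = target.contains_points(chrom, snps)
    n_in = int(inside.sum())
    n_out = int(len(snps) - n_in)
    table = np.array([[n_in, bp_in - n_in], [n_out, bp_out - n_out]])
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    use_yates = bool((expected < 5).any())
    if (table.sum(axis=0) == 0).any():  # degenerate margin
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = chi2_contingency(table, correction=use_yates)
    return {
        "density_in": 1000.0 * n_in / bp_in,
        "density_out": 1000.0 * n_out / bp_out,
        "n_in": n_in,
        "n_out": n_out,
        "chi2": float(stat),
        "p": float(p),
        "yates": use_yates,
    }
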