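"""End-to-end orchestration: neutral fit -> element calling ->
classification -> annotation -> statistics, driven by a JSON config.

Every stage writes its outputs into the run directory; a manifest records
the config, input checksums, package version and seeds, and re-running
the same config reproduces all seeded outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import read_fasta, read_maf
from .annot import associate_genes, classify_region, rank_associated_genes, read_gff3, snp_density_test
from .clade import OutgroupScheme, classify_ashce
from .enrich import permute_interval_overlap, stage_specific_calls
from .hmm import PhyloHMMParams, emission_table, estimate_rho, forward_backward, viterbi_elements, write_bed, write_wig
from .intervals import IntervalSet, read_bed
from .likelihood import fit_neutral_model
from .models import SubstitutionModel
from .tree import read_newick

__all__ = ["RunConfig", "run_pipeline", "write_demo_dataset"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds of one pipeline run."""

    alignment: str
    tree: str
    neutral_sites: str | None = None
    genes: str | None = None
    snps: str | None = None
    expression: str | None = None
    annotation_bed: str | None = None

    reference: str | None = None
    family: str = "HKY85"
    ingroup: list[str] = field(default_factory=list)
    outgroup_sets: dict[str, list[str]] = field(default_factory=dict)

    rho: float = 0.3
    expected_element_length: float = 45.0
    conserved_coverage: float = 0.05
    fit_rho: bool = False

    min_element_length: int = 20
    q_threshold: float = 0.01
    presence_threshold: float = 0.10
    tau_threshold: float = 0.8
    fold_high: float = 5.0
    fold_low: float = 2.0
    n_sims: int = 100_000
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: getattr(config, k)
        for k in ("alignment", "tree", "neutral_sites", "genes", "snps",
                  "expression", "annotation_bed")
        if getattr(config, k)
    }
    for k, p in inputs.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"{k} input not found: {p}")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {k: {"path": p, "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": [],
    }
    stage = "setup"
    try:
        tree = read_newick(config.tree)
        blocks = read_maf(config.alignment, reference=config.reference)
        if not blocks:
            raise ValueError(f"alignment {config.alignment} contains no blocks")
        ingroup = config.ingroup or tree.leaf_names
        scheme = OutgroupScheme(list(ingroup), dict(config.outgroup_sets))

        # ---- neutral model ------------------------------------------- #
        stage = "fit_neutral_model"
        if config.neutral_sites:
            neutral_aln = read_fasta(config.neutral_sites)
        else:
            neutral_aln = blocks[0]
        model, neutral_tree = fit_neutral_model(neutral_aln, tree, config.family)
        model.to_json(out / "neutral_model.json")
        neutral_tree.write(out / "neutral_tree.nwk")
        manifest["outputs"] += ["neutral_model.json", "neutral_tree.nwk"]

        # ---- element calling (on the ingroup) ------------------------ #
        stage = "call_elements"
        in_tree = neutral_tree.induced_subtree(ingroup)
        params = PhyloHMMParams.from_tuning(
            config.rho, config.expected_element_length, config.conserved_coverage
        )
        elements = []
        emission_cache = []
        for block in blocks:
            in_aln = block.subset_species([s for s in ingroup if s in block.species])
            if config.fit_rho:
                params, _ = estimate_rho(in_aln, in_tree, model, init=params)
            E = emission_table(in_aln, in_tree, model, params.rho)
            post, _ = forward_backward(E, params)
            els = viterbi_elements(
                E, params, block.ref_positions, block.chrom,
                min_length=config.min_element_length, posterior=post,
            )
            emission_cache.append((block, E, post))
            elements.extend(els)
        if emission_cache:
            block0, _, post0 = emission_cache[0]
            write_wig(post0, block0.ref_positions, block0.chrom, out / "posterior.wig")
            manifest["outputs"].append("posterior.wig")

        # ---- classification ------------------------------------------ #
        stage = "classify"
        labeled = elements
        tables = []
        if scheme.outgroup_sets:
            labeled = []
            offset = 0
            for block, _, _ in emission_cache:
                blk_els = [e for e in elements if e.chrom == block.chrom
                           and block.ref_start <= e.start < block.ref_end]
                lab, tab = classify_ashce(
                    blk_els, block, neutral_tree, model, scheme,
                    q_threshold=config.q_threshold,
                    presence_threshold=config.presence_threshold,
                    min_length=config.min_element_length,
                )
                if len(tab):
                    tab["element_id"] += offset
                offset += len(blk_els)
                labeled.extend(lab)
                tables.append(tab)
        write_bed(labeled, out / "elements.bed")
        manifest["outputs"].append("elements.bed")
        if tables:
            pd.concat(tables, ignore_index=True).to_csv(
                out / "clade_tests.tsv", sep="\t", index=False
            )
            manifest["outputs"].append("clade_tests.tsv")

        ashce = [e for e in labeled if e.label.startswith("ASHCE")]
        ashce_iv = IntervalSet((e.chrom, e.start, e.end) for e in ashce) if ashce else IntervalSet()

        # ---- genomic annotation -------------------------------------- #
        if config.genes:
            stage = "annotate"
            genes = read_gff3(config.genes)
            cls = [classify_region(e, genes) for e in labeled]
            pd.DataFrame(
                {
                    "chrom": [e.chrom for e in labeled],
                    "start": [e.start for e in labeled],
                    "end": [e.end for e in labeled],
                    "label": [e.label for e in labeled],
                    "region_class": cls,
                }
            ).to_csv(out / "annotation_classes.tsv", sep="\t", index=False)
            assoc = associate_genes(ashce, genes)
            ranking = rank_associated_genes(ashce, assoc)
            ranking.to_csv(out / "gene_ranking.tsv", sep="\t", index=False)
            manifest["outputs"] += ["annotation_classes.tsv", "gene_ranking.tsv"]

        # ---- SNP density --------------------------------------------- #
        if config.snps and len(ashce_iv):
            stage = "snp_density"
            snp_df = pd.read_csv(config.snps, sep="\t", names=["chrom", "pos"],
                                 comment="#")
            ref_len = max(b.ref_end for b in blocks)
            res = snp_density_test(
                snp_df["pos"].to_numpy() - 1, ashce_iv, ref_len,
                chrom=blocks[0].chrom,
            )
            with open(out / "snp_density.json", "w") as fh:
                json.dump(res, fh, indent=1)
            manifest["outputs"].append("snp_density.json")

        # ---- interval enrichment ------------------------------------- #
        if config.annotation_bed and len(ashce_iv):
            stage = "enrichment"
            ann = read_bed(config.annotation_bed)
            ref_len = max(b.ref_end for b in blocks)
            workspace = IntervalSet([(blocks[0].chrom, 0, ref_len)])
            res = permute_interval_overlap(
                ashce_iv, ann, workspace, n_sims=config.n_sims, seed=config.seed
            )
            with open(out / "enrichment.json", "w") as fh:
                json.dump(dataclasses.asdict(res), fh, indent=1)
            manifest["outputs"].append("enrichment.json")

        # ---- expression specificity ---------------------------------- #
        if config.expression:
            stage = "expression"
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
            calls = stage_specific_calls(expr, config.tau_threshold)
            calls.to_csv(out / "tau.tsv", sep="\t")
            manifest["outputs"].append("tau.tsv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    config.to_json(out / "config.json")
    manifest["outputs"].append("config.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


# --------------------------------------------------------------------- #
def write_demo_dataset(
    outdir,
    seed: int = 0,
    length: int = 200_000,
    n_each: int = 10,
    rho: float = 0.2,
    snp_density_in: float = 1.27,
    snp_density_out: float = 2.59,
) -> tuple[Path, "RunConfig"]:
    """Simulate a complete demo dataset with ground truth and its config.

    Eight ingroup species plus three successively deeper outgroups;
    ``n_each`` planted elements of each type (shared-conserved,
    clade-specific-II, clade-specific-I) with branch scale ``rho``; SNPs
    at the study's densities inside/outside the clade-specific elements;
    a toy gene annotation and a stage-specific expression table.
    """
    from .annot import GeneModel, write_gff3
    from .simdata import (
        plant_elements,
        simulate_alignment,
        simulate_expression,
        simulate_snps,
        spawn_rngs,
    )
    from .tree import parse_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    nwk = (
        "((((((b1:0.12,b2:0.12):0.1,(b3:0.12,b4:0.12):0.1):0.09,"
        "((b5:0.12,b6:0.12):0.1,(b7:0.12,b8:0.12):0.1):0.09):0.25,og1:0.45):0.15,"
        "og2:0.55):0.1,og3:0.6);"
    )
    tree = parse_newick(nwk)
    ingroup = [f"b{i}" for i in range(1, 9)]
    model = SubstitutionModel.hky85(3.0, [0.3, 0.2, 0.2, 0.3])
    r_aln, r_neutral, r_plant, r_snp, r_expr = spawn_rngs(seed, 5)

    aln = simulate_alignment(tree, model, length, r_aln)
    gap = length // (3 * n_each + 1)
    spec = []
    kinds = ["shared-conserved", "clade-specific-II", "clade-specific-I"] * n_each
    rng_len = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])
    pos = gap
    for kind in kinds:
        ln = int(rng_len.integers(60, 250))
        spec.append((pos, ln, rho, kind, ingroup))
        pos += gap
    aln, truth = plant_elements(aln, tree, model, spec, r_plant)
    aln.write_maf(out / "alignment.maf")

    neutral = simulate_alignment(tree, model, 20_000, r_neutral)
    neutral.write_fasta(out / "neutral_4d.fa")

    with open(out / "truth.bed", "w") as fh:
        for chrom, a, b, kind in truth.elements:
            fh.write(f"{chrom}\t{a}\t{b}\t{kind}\t0\t+\n")

    clade_specific = [(a, b) for _, a, b, k in truth.elements if k != "shared-conserved"]
    snps = simulate_snps(length, clade_specific, snp_density_in, snp_density_out, r_snp)
    with open(out / "snps.tsv", "w") as fh:
        for p in snps:
            fh.write(f"{aln.chrom}\t{p + 1}\n")

    genes = []
    g_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(7)[6])
    for i in range(40):
        s = int(g_rng.integers(0, length - 3000))
        strand = "+" if g_rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene{i + 1:03d}", aln.chrom, strand, s, s + 2400,
                      [(s + 200, s + 800), (s + 1600, s + 2200)])
        )
    genes.sort(key=lambda g: g.tx_start)
    write_gff3(genes, out / "genes.gff3")

    stages = ["PS", "HH6", "HH11", "HH14", "HH16", "HH19", "HH28", "HH38"]
    expr, _ = simulate_expression(
        [g.gene_id for g in genes] + [f"x{i}" for i in range(160)],
        stages, n_specific_per_stage=5, seed=r_expr,
    )
    expr.to_csv(out / "expression.tsv", sep="\t")

    tree.write(out / "tree.nwk")
    cfg = RunConfig(
        alignment=str(out / "alignment.maf"),
        tree=str(out / "tree.nwk"),
        neutral_sites=str(out / "neutral_4d.fa"),
        genes=str(out / "genes.gff3"),
        snps=str(out / "snps.tsv"),
        expression=str(out / "expression.tsv"),
        reference="b1",
        ingroup=ingroup,
        outgroup_sets={
            "closest": ["og1"],
            "reptiles": ["og1", "og2"],
            "vertebrates": ["og1", "og2", "og3"],
        },
        rho=0.25,
        n_sims=10_000,
        seed=seed,
    )
    cfg.to_json(out / "config.json")
    return out, cfg
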