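"""Pipeline driver binding the stages into the two headline workflows:
PAV (genotype-specific gene) discovery and the SNV landscape, plus the
clock-dating and tissue-expression side analyses.

Every stage writes its table under the output directory and contributes to
a machine-readable summary recording every effective parameter, so a rerun
with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from . import alignment, expression, molevo, specific, synteny, variants
from .config import PipelineConfig
from .io import write_fasta, write_fastq, write_gff3, write_tsv
from .simulate import simulate_counts, simulate_genome_pair, simulate_ltr_pairs, simulate_reads

log = logging.getLogger("wildcomp")


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a study and run every stage; returns the summary dict."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    summary: dict = {"parameters": config.as_dict(), "stages": {}}
    sim = config.simulation

    _stage("simulate")
    genome_a, genome_b, truth = simulate_genome_pair(sim)
    write_fasta(genome_a.sequences, f"{out}/genome_A.fasta")
    write_fasta(genome_b.sequences, f"{out}/genome_B.fasta")
    write_gff3(genome_a, f"{out}/genome_A.gff3")
    write_gff3(genome_b, f"{out}/genome_B.gff3")
    reads_a = simulate_reads(genome_a, sim)
    reads_b = simulate_reads(genome_b, sim)
    write_fastq(reads_a, f"{out}/reads_A.fastq")
    write_fastq(reads_b, f"{out}/reads_B.fastq")
    summary["stages"]["simulate"] = {
        "genes_A": len(genome_a),
        "genes_B": len(genome_b),
        "planted_specific_A": len(truth.specific_genes_A),
        "planted_specific_B": len(truth.specific_genes_B),
        "planted_snvs": truth.n_snvs(),
        "reads_A": len(reads_a),
        "reads_B": len(reads_b),
    }

    _stage("homology")
    cdnas_a = genome_a.cdna_set()
    cdnas_b = genome_b.cdna_set()
    pairs = alignment.all_vs_all_homologs(
        cdnas_a, cdnas_b,
        min_score=config.homolog_min_score,
        min_identity=config.homolog_min_identity,
        min_coverage=config.min_coverage,
    )
    pairs.to_csv(f"{out}/homolog_pairs.tsv", sep="\t", index=False)
    summary["stages"]["homology"] = {"n_pairs": int(len(pairs))}

    _stage("synteny")
    order_a = synteny.GeneOrderIndex(genome_a)
    order_b = synteny.GeneOrderIndex(genome_b)
    blocks = synteny.call_blocks(
        pairs, order_a, order_b,
        min_block_genes=config.min_block_genes,
        max_gap=config.max_gap,
        allow_inversions=config.allow_inversions,
    )
    synteny.validate_blocks(blocks, order_a, order_b, config.min_block_genes, config.max_gap)
    synteny.blocks_table(blocks, genome_a, genome_b).to_csv(
        f"{out}/syntenic_blocks.tsv", sep="\t", index=False
    )
    summ = synteny.block_summary(blocks)
    syn_a, syn_b = synteny.syntenic_gene_set(blocks)
    summary["stages"]["synteny"] = {
        "n_blocks": summ.n_blocks,
        "n_genes_total": summ.n_genes_total,
        "mean_genes_per_block": round(summ.mean_genes_per_block, 4),
    }

    _stage("specific_genes")
    spec_counts = {}
    for direction, cdnas, other_genome, self_genome, syn_set, other_reads in (
        ("A", cdnas_a, genome_b, genome_a, syn_a, reads_b),
        ("B", cdnas_b, genome_a, genome_b, syn_b, reads_a),
    ):
        calls = specific.find_candidates(
            cdnas, other_genome,
            min_identity=config.min_identity, min_coverage=config.min_coverage,
        )
        calls = specific.exclude_syntenic(calls, syn_set)
        calls = specific.coverage_confirm(
            calls, other_reads, self_genome,
            covered_site_min_depth=config.covered_site_min_depth,
            max_covered_fraction=config.max_covered_fraction,
            max_substitutions=config.max_substitutions,
        )
        write_tsv(
            [
                {
                    "gene_id": c.gene_id,
                    "status": c.status,
                    "best_identity": "." if c.best_identity is None else f"{c.best_identity:.4f}",
                    "best_coverage": "." if c.best_coverage is None else f"{c.best_coverage:.4f}",
                    "covered_fraction": "."
                    if c.covered_fraction is None
                    else f"{c.covered_fraction:.4f}",
                }
                for c in calls
            ],
            f"{out}/specific_genes_{direction}.tsv",
            ["gene_id", "status", "best_identity", "best_coverage", "covered_fraction"],
        )
        hc = specific.specific_gene_ids(calls)
        write_fasta(
            {g: self_genome.gene_sequence(g) for g in sorted(hc)},
            f"{out}/specific_genes_{direction}.fasta",
        )
        spec_counts[direction] = len(hc)
    summary["stages"]["specific_genes"] = {
        "high_confidence_A": spec_counts["A"],
        "high_confidence_B": spec_counts["B"],
    }

    _stage("dating")
    best_pairs: dict[str, tuple[str, float]] = {}
    for row in pairs.itertuples():
        cur = best_pairs.get(row.gene_A)
        if cur is None or row.score > cur[1]:
            best_pairs[row.gene_A] = (row.gene_B, row.score)
    ks_values = []
    ks_rows = []
    for gene_a, (gene_b, _) in sorted(best_pairs.items()):
        try:
            aln = molevo.CodonAlignment(cdnas_a[gene_a], cdnas_b[gene_b])
            ka, ks, ratio = molevo.ng86_kaks(aln)
        except molevo.WildcompError:
            continue  # stop-containing or saturated pair: excluded from dating
        ks_values.append(ks)
        ks_rows.append(
            {"gene_A": gene_a, "gene_B": gene_b, "Ka": f"{ka:.6f}", "Ks": f"{ks:.6f}",
             "ratio": "." if ratio is None else f"{ratio:.4f}"}
        )
    write_tsv(ks_rows, f"{out}/ortholog_kaks.tsv", ["gene_A", "gene_B", "Ka", "Ks", "ratio"])
    mean_ks = float(np.mean(ks_values)) if ks_values else 0.0
    summary["stages"]["dating"] = {
        "n_pairs_dated": len(ks_values),
        "mean_ks": round(mean_ks, 6),
        "divergence_mya": round(molevo.divergence_time(mean_ks, config.ks_rate), 4),
    }

    _stage("ltr")
    ltr_seqs, ltr_truth = simulate_ltr_pairs(sim)
    write_fasta(ltr_seqs, f"{out}/ltr_pairs.fasta")
    ltr_rows = []
    ages = []
    for name in sorted(ltr_truth.ltr_true_ages):
        est = molevo.ltr_insertion_time(
            ltr_seqs[f"{name}_5p"], ltr_seqs[f"{name}_3p"], rate=config.ltr_rate
        )
        ages.append(est.time_mya)
        ltr_rows.append(
            {"element": name, "p": f"{est.p_distance:.6f}", "K": f"{est.distance:.6f}",
             "T_MYA": f"{est.time_mya:.4f}"}
        )
    write_tsv(ltr_rows, f"{out}/ltr_ages.tsv", ["element", "p", "K", "T_MYA"])
    summary["stages"]["ltr"] = {
        "n_elements": len(ages),
        "mean_age_mya": round(float(np.mean(ages)), 4) if ages else 0.0,
    }

    _stage("variants")
    placements = variants.map_reads(reads_a, genome_b, max_substitutions=config.max_substitutions)
    snvs = variants.call_snvs(
        placements, genome_b,
        min_depth=config.snv_min_depth, min_alt_fraction=config.min_alt_fraction,
    )
    variants.write_vcf(snvs, genome_b.scaffold_lengths(), f"{out}/snvs.vcf")
    dens = variants.window_density(snvs, genome_b.scaffold_lengths(), window=config.window)
    variants.write_bedgraph(dens, f"{out}/snv_density.bedgraph")
    summary["stages"]["variants"] = {
        "n_placed_reads": int(len(placements)),
        "n_snvs": len(snvs),
        "n_windows": len(dens),
    }

    _stage("expression")
    counts, tissue_of, expr_truth = simulate_counts(sim, gene_ids=[g.gene_id for g in genome_a.genes])
    counts.to_csv(f"{out}/counts.tsv", sep="\t", index_label="gene_id")
    write_tsv(
        [{"sample": s, "tissue": t} for s, t in tissue_of.items()],
        f"{out}/sample_tissues.tsv", ["sample", "tissue"],
    )
    calls = expression.tissue_specific(
        counts, tissue_of,
        fold_threshold=config.fold_threshold, padj_threshold=config.padj_threshold,
    )
    expression.calls_table(calls).to_csv(f"{out}/tissue_specific.tsv", sep="\t", index=False)
    summary["stages"]["expression"] = {
        "n_called": sum(c.tissue is not None for c in calls),
        "n_planted": len(expr_truth),
    }

    with open(f"{out}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
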