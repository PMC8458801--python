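"""End-to-end orchestration: phenotypes -> differential -> composition ->
ternary -> network -> promoters, from one config, with a run manifest and
a plain-text report.

Outputs are TSV files with fixed column order; a run is fully determined
by (config, seed) and the manifest records input digests, thresholds and
per-stage row counts so any run can be reproduced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coabundance, composition, differential, phenotype_stats, promoter_genome, ternary_bias
from .io_core import (
    DOUBLE_MUTANTS,
    GENOTYPES,
    AbundanceMatrix,
    Config,
    PhenotypeTable,
    ProteinRecord,
    default_design,
    logger,
    write_abundance_table,
    write_fasta,
    write_genome_fasta,
    write_locus_table,
    write_phenotype_table,
)
from .synthetic_data import (
    GeneratorParams,
    GroundTruth,
    generate_abundances,
    generate_phenotypes,
    generate_promoters,
    generate_proteome,
)

#: The study's contrasts: each double mutant vs wild type, and DM vs DM.
WT_DM_CONTRASTS = tuple((dm, "WT") for dm in DOUBLE_MUTANTS)
DM_DM_CONTRASTS = (("BC", "CD"), ("BC", "BD"), ("CD", "BD"))
ALL_CONTRASTS = WT_DM_CONTRASTS + DM_DM_CONTRASTS

#: Ternary panel layouts: DM vs its two single-mutant parents, and
#: DM vs WT vs one parent.
TERNARY_PANELS = (
    ("BC", "B", "C"),
    ("CD", "C", "D"),
    ("BD", "B", "D"),
    ("BC", "WT", "B"),
    ("CD", "WT", "C"),
    ("BD", "WT", "D"),
)


@dataclass
class PipelineInputs:
    proteome: list[ProteinRecord]
    matrix: AbundanceMatrix
    phenotypes: PhenotypeTable
    genome: dict[str, str]
    loci: dict
    truth: GroundTruth | None = None
    manifest_rows: list[dict] = field(default_factory=list)


def synthetic_inputs(params: GeneratorParams | None = None) -> PipelineInputs:
    """Generate a complete synthetic study under one seed."""
    params = params or GeneratorParams()
    proteome, truth = generate_proteome(params)
    design = default_design(params.n_replicates)
    matrix = generate_abundances(proteome, truth, design, params)
    genome, loci, manifest = generate_promoters(proteome, truth, params)
    phenotypes = generate_phenotypes(truth, params)
    return PipelineInputs(proteome, matrix, phenotypes, genome, loci, truth, manifest)


def write_synthetic_inputs(inputs: PipelineInputs, outdir: str | Path) -> dict[str, Path]:
    """Emit the generated study in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "abundance": outdir / "abundance.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "genome": outdir / "genome.fasta",
        "loci": outdir / "loci.tsv",
        "manifest": outdir / "motif_manifest.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_fasta(inputs.proteome, paths["proteome"])
    write_abundance_table(inputs.matrix, paths["abundance"])
    write_phenotype_table(inputs.phenotypes, paths["phenotypes"])
    write_genome_fasta(inputs.genome, paths["genome"])
    write_locus_table(inputs.loci, paths["loci"])
    pd.DataFrame(inputs.manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)
    if inputs.truth is not None:
        truth_rows = [
            {
                "protein_id": pid,
                "class": inputs.truth.class_of[pid],
                "module": inputs.truth.module_of[pid],
                **{f"effect_{g}": inputs.truth.effects[pid][g] for g in GENOTYPES},
            }
            for pid in inputs.truth.class_of
        ]
        pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def run_pipeline(
    inputs: PipelineInputs,
    outdir: str | Path,
    config: Config | None = None,
) -> dict:
    """Run all stages, write stage TSVs, a manifest and a text report.

    Returns a summary dict mirroring the report contents.
    """
    config = config or Config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    # --- phenotypes ------------------------------------------------------
    pheno = phenotype_stats.phenotype_report(inputs.phenotypes)
    pheno.to_csv(outdir / "phenotype_comparisons.tsv", sep="\t", index=False)
    summary["phenotypes"] = pheno.to_dict("records")

    # --- differential ----------------------------------------------------
    imputed = differential.impute_half_minimum(inputs.matrix)
    normalized = differential.normalize(imputed)
    all_results = {}
    diff_frames = []
    summary["contrasts"] = {}
    for mutant, reference in ALL_CONTRASTS:
        res = differential.contrast_test(imputed, mutant, reference, config)
        all_results[(mutant, reference)] = res
        frame = differential.results_frame(res)
        diff_frames.append(frame)
        n_up, n_down, n_changed, pct = differential.summarize_counts(
            res, n_quantified=len(inputs.matrix.protein_ids)
        )
        summary["contrasts"][f"{mutant}_vs_{reference}"] = {
            "n_up": n_up, "n_down": n_down, "n_changed": n_changed, "percent_changed": pct,
        }
    pd.concat(diff_frames).to_csv(outdir / "differential.tsv", sep="\t", index=False)

    pca_summary = differential.pca(normalized, n_components=3)
    pca_frame = pd.DataFrame(
        pca_summary.scores,
        index=pca_summary.sample_ids,
        columns=[f"PC{i+1}" for i in range(pca_summary.scores.shape[1])],
    )
    pca_frame.index.name = "sample_id"
    pca_frame.to_csv(outdir / "pca_scores.tsv", sep="\t")
    summary["pca_variance_fraction"] = pca_summary.variance_fraction.tolist()

    # PLS-DA: BC-mutant class vs WT + single-mutant parents (the supervised
    # layout used to rank proteins driving the double-mutant proteome)
    plsda_samples = [s for s in normalized.design if s.genotype in ("WT", "B", "C", "BC")]
    sub = AbundanceMatrix.__new__(AbundanceMatrix)
    cols = [i for i, s in enumerate(normalized.design) if s.genotype in ("WT", "B", "C", "BC")]
    sub.protein_ids = normalized.protein_ids
    sub.design = plsda_samples
    sub.values = normalized.values[:, cols]
    labels = {s.sample_id: (1 if s.genotype == "BC" else 0) for s in plsda_samples}
    vip = differential.plsda_vip(sub, labels, config)
    vip_frame = pd.DataFrame(
        {"protein_id": vip.protein_ids, "vip": vip.vip, "selected": vip.selected}
    ).sort_values("vip", ascending=False)
    vip_frame.to_csv(outdir / "vip.tsv", sep="\t", index=False)
    summary["n_vip_selected"] = int(vip.selected.sum())

    # --- composition -----------------------------------------------------
    by_id = {r.protein_id: r for r in inputs.proteome}
    background = composition.background_composition(inputs.proteome)
    shift_frames = []
    summary["composition_shift"] = {}
    for mutant, reference in WT_DM_CONTRASTS:
        res = all_results[(mutant, reference)]
        ups = [by_id[r.protein_id] for r in res if r.status == "up" and r.protein_id in by_id]
        downs = [by_id[r.protein_id] for r in res if r.status == "down" and r.protein_id in by_id]
        if not ups or not downs:
            logger.warning("contrast %s vs %s: empty up or down set; shift skipped", mutant, reference)
            continue
        shifts = composition.composition_shift(ups, downs)
        frame = composition.shift_frame(shifts)
        frame.insert(0, "contrast", f"{mutant}_vs_{reference}")
        shift_frames.append(frame)
        summary["composition_shift"][f"{mutant}_vs_{reference}"] = {
            s.residue: s.ratio for s in shifts if s.ratio is not None
        }
    if shift_frames:
        pd.concat(shift_frames).to_csv(outdir / "composition_shift.tsv", sep="\t", index=False)
    rich = composition.residue_rich_table(inputs.proteome, background)
    rich.to_csv(outdir / "residue_rich.tsv", sep="\t", index=False)
    summary["n_lysine_rich"] = int(rich[(rich.residue == "K") & rich.rich].shape[0])

    # --- ternary ---------------------------------------------------------
    panel_frames = []
    for panel in TERNARY_PANELS:
        points = ternary_bias.ternary_panel(inputs.matrix, panel)
        panel_frames.append(ternary_bias.panel_frame(points, panel))
    ternary_frame = pd.concat(panel_frames)
    ternary_frame.to_csv(outdir / "ternary.tsv", sep="\t", index=False)

    # --- network ---------------------------------------------------------
    selected = coabundance.select_network_input(
        list(all_results.values()), use_q=config.use_q_for_network, config=config
    )
    network = coabundance.build_network(imputed, selected, config)
    coabundance.edge_frame(network).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    node_table, global_measures = coabundance.network_measures(network)
    node_table.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    coabundance.write_graphml(network, outdir / "network.graphml")
    module_sizes = node_table[node_table.module > 0].groupby("module").size().to_dict()
    summary["network"] = {**global_measures, "module_sizes": {int(k): int(v) for k, v in module_sizes.items()}}

    # --- promoters -------------------------------------------------------
    mapped, unmapped = promoter_genome.map_proteins(inputs.proteome, inputs.loci)
    hits_per_gene = {}
    hit_rows = []
    for pid, locus in mapped.items():
        upstream = promoter_genome.extract_upstream(locus, inputs.genome, config.upstream_length)
        hits = promoter_genome.scan_motifs(pid, upstream, strand=locus.strand)
        hits_per_gene[pid] = hits
        hit_rows.extend(
            {"gene_id": h.gene_id, "motif": h.motif, "pattern": h.pattern,
             "offset": h.offset, "strand": h.strand}
            for h in hits
        )
    pd.DataFrame(hit_rows, columns=["gene_id", "motif", "pattern", "offset", "strand"]).to_csv(
        outdir / "motif_hits.tsv", sep="\t", index=False
    )
    classes, counts = promoter_genome.classify_promoters(hits_per_gene)
    classes.to_csv(outdir / "promoter_classes.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "promoter_class_counts.tsv", sep="\t", index=False)
    summary["promoter_classes"] = dict(zip(counts.promoter_class, counts.n_genes.astype(int)))
    summary["n_unmapped"] = len(unmapped)

    # circos tracks: per-genotype mean log2 abundance of network proteins
    log2_means = pd.DataFrame(
        {g: np.log2(np.maximum(inputs.matrix.genotype_means(g), 1e-12)) for g in GENOTYPES},
        index=inputs.matrix.protein_ids,
    )
    net_ids = [p for p in network.nodes if p in mapped]
    promoter_genome.circos_export(
        {p: mapped[p] for p in net_ids},
        log2_means.loc[net_ids],
        coabundance.edge_frame(network),
        outdir / "circos",
    )

    # --- manifest + report ----------------------------------------------
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_proteins": len(inputs.matrix.protein_ids),
        "n_samples": len(inputs.matrix.design),
        "stage_rows": {
            "phenotype_comparisons": len(pheno),
            "differential": sum(len(r) for r in all_results.values()),
            "ternary": len(ternary_frame),
            "network_edges": len(network.edges),
            "motif_hits": len(hit_rows),
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(make_report(summary))
    return summary


def make_report(summary: dict) -> str:
    """Plain-text report with the derived quantities tabulated."""
    lines = ["# Pipeline report", ""]
    lines.append("## Phenotype changes vs wild type")
    for row in summary.get("phenotypes", []):
        star = " *" if row["significant"] else ""
        lines.append(
            f"- {row['trait']} {row['genotype']}: {row['percent_change_vs_wt']:+.1f}%{star}"
        )
    lines.append("")
    lines.append("## Differential abundance")
    for name, c in summary.get("contrasts", {}).items():
        lines.append(
            f"- {name}: {c['n_changed']} changed ({c['percent_changed']:.1f}%) = "
            f"{c['n_up']} up + {c['n_down']} down"
        )
    if not summary.get("contrasts"):
        lines.append("- no differential results")
    lines.append("")
    if "pca_variance_fraction" in summary:
        fracs = ", ".join(f"{100*f:.0f}%" for f in summary["pca_variance_fraction"])
        lines.append(f"PCA variance fractions: {fracs}")
    lines.append(f"VIP-selected proteins: {summary.get('n_vip_selected', 0)}")
    lines.append(f"Lysine-rich proteins: {summary.get('n_lysine_rich', 0)}")
    lines.append("")
    net = summary.get("network", {})
    if net:
        lines.append(
            f"Network: {net['n_nodes']} nodes, {net['n_edges']} edges, "
            f"{net['n_components']} components"
        )
        sizes = net.get("module_sizes", {})
        if sizes:
            lines.append(
                "Module sizes: " + ", ".join(f"{k}:{v}" for k, v in sorted(sizes.items()))
            )
    lines.append("")
    lines.append("## Promoter classes")
    for label, n in summary.get("promoter_classes", {}).items():
        lines.append(f"- {label}: {n}")
    lines.append("")
    return "\n".join(lines)
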