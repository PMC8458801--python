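"""Chromosome mapping, upstream extraction, cis-element scanning and
Circos-ready export.

Proteins are mapped to genomic loci by an exact id join against a locus
table, with an optional sequence fallback: a shared amino-acid 5-mer
best-hit against reference translations (ties broken by lowest
(chromosome, start)), requiring at least half of the query's 5-mers to be
shared. The 1,000 bp window 5' of each gene is extracted on the coding
strand and scanned for the prolamin/pyrimidine/GA-MYB/GA box motifs at
100% identity; genes are then classed by which motif families their
promoter contains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import GENOTYPES, GenomicLocus, ProteinRecord, logger
from .synthetic_data import reverse_complement

#: Motif patterns scanned at 100% identity, and the family each belongs to.
MOTIFS: tuple[tuple[str, str, str], ...] = (
    ("Prolamin box", "TGTAAAG", "Pbox"),
    ("Prolamin box long", "TGTAAAGT", "Pbox"),
    ("Pyrimidine box", "CTTTT", "Pyr"),
    ("GA-MYB", "AACA", "GAMyb"),
    ("GA", "TAACAAA", "GA"),
)
#: Family order used for combination labels.
FAMILY_ORDER = ("Pyr", "Pbox", "GAMyb", "GA")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    pattern: str
    offset: int  # 1-based within the upstream window; 1 = most upstream
    strand: str


def _kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def map_proteins(
    proteins: Sequence[ProteinRecord],
    locus_table: Mapping[str, GenomicLocus],
    reference: Sequence[ProteinRecord] | None = None,
    k: int = 5,
    min_shared_fraction: float = 0.5,
) -> tuple[dict[str, GenomicLocus], list[str]]:
    """Exact id join, then a naive shared-k-mer best hit for the rest.

    Returns (mapping, unmapped ids). A fallback hit requires at least
    ``min_shared_fraction`` of the query's k-mers shared with the winning
    reference; ties break toward the lowest (chromosome, start).
    """
    mapped: dict[str, GenomicLocus] = {}
    unmapped: list[str] = []
    ref_index = []
    if reference:
        for ref in reference:
            if ref.locus is None:
                continue
            ref_index.append((ref, _kmers(ref.sequence, k)))
    for rec in proteins:
        if rec.protein_id in locus_table:
            mapped[rec.protein_id] = locus_table[rec.protein_id]
            continue
        best = None
        query = _kmers(rec.sequence, k)
        if query and ref_index:
            for ref, ref_kmers in ref_index:
                shared = len(query & ref_kmers)
                key = (-shared, ref.locus.chromosome, ref.locus.start)
                if best is None or key < best[0]:
                    best = (key, shared, ref.locus)
        if best is not None and best[1] >= min_shared_fraction * len(query):
            mapped[rec.protein_id] = best[2]
        else:
            unmapped.append(rec.protein_id)
    if unmapped:
        logger.info("map_proteins: %d proteins unmapped", len(unmapped))
    return mapped, unmapped


def extract_upstream(
    locus: GenomicLocus,
    genome: Mapping[str, str],
    length: int = 1000,
) -> str:
    """The ``length`` bases 5' of the gene, 5'->3' on the coding strand.

    For a + strand gene these are genome bases [start-length, start-1] in
    genome order; for a - strand gene, the reverse complement of bases
    [end+1, end+length]. Windows are truncated at chromosome boundaries
    with a log entry. Offset 1 of the returned string is the most-upstream
    base.
    """
    if locus.chromosome not in genome:
        raise KeyError(f"chromosome {locus.chromosome!r} absent from the genome")
    chrom = genome[locus.chromosome]
    if locus.strand == "+":
        lo = max(locus.start - length, 1)
        hi = locus.start - 1
        if lo > hi:
            logger.info("no upstream sequence for locus at chromosome start")
            return ""
        if locus.start - length < 1:
            logger.info("upstream window truncated at chromosome start (%d bp)", hi - lo + 1)
        return chrom[lo - 1 : hi]
    lo = locus.end + 1
    hi = min(locus.end + length, len(chrom))
    if lo > hi:
        logger.info("no upstream sequence for locus at chromosome end")
        return ""
    if locus.end + length > len(chrom):
        logger.info("upstream window truncated at chromosome end (%d bp)", hi - lo + 1)
    return reverse_complement(chrom[lo - 1 : hi])


def scan_motifs(
    gene_id: str,
    upstream: str,
    motifs: Iterable[tuple[str, str, str]] = MOTIFS,
    strand: str = "+",
    both_strands: bool = False,
) -> list[MotifHit]:
    """Every exact occurrence of every motif, overlaps included.

    By default scanning is on the provided coding-strand sequence only
    (the motifs are directional promoter elements); ``both_strands`` also
    scans the reverse complement, reporting hits at the coding-strand
    offset of their first base with the opposite strand symbol. Characters
    outside ACGT (e.g. N) never match.
    """
    hits: list[MotifHit] = []
    opposite = {"+": "-", "-": "+"}[strand]
    for name, pattern, _family in motifs:
        start = upstream.find(pattern)
        while start != -1:
            hits.append(MotifHit(gene_id, name, pattern, start + 1, strand))
            start = upstream.find(pattern, start + 1)
        if both_strands:
            rc = reverse_complement(pattern)
            start = upstream.find(rc)
            while start != -1:
                hits.append(MotifHit(gene_id, name, pattern, start + 1, opposite))
                start = upstream.find(rc, start + 1)
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


_FAMILY_OF = {name: family for name, _pattern, family in MOTIFS}


def combination_label(hits: Iterable[MotifHit]) -> str:
    """Combination class from motif-family presence, e.g. 'Pyr-Pbox-GAMyb'."""
    present = {_FAMILY_OF[h.motif] for h in hits}
    label = "-".join(f for f in FAMILY_ORDER if f in present)
    return label or "none"


def classify_promoters(
    hits_per_gene: Mapping[str, list[MotifHit]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene combination labels plus UpSet-style intersection counts."""
    rows = [
        {"gene_id": gene, "promoter_class": combination_label(hits)}
        for gene, hits in hits_per_gene.items()
    ]
    classes = pd.DataFrame(rows, columns=["gene_id", "promoter_class"])
    counts = (
        classes.groupby("promoter_class").size().rename("n_genes").reset_index()
        .sort_values(["n_genes", "promoter_class"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return classes, counts


def circos_export(
    loci: Mapping[str, GenomicLocus],
    log2_abundance: pd.DataFrame,
    edges: pd.DataFrame,
    outdir,
    genotype_order: Sequence[str] = GENOTYPES,
) -> dict[str, "pathlib.Path"]:
    """Write Circos plain-text band, heatmap and link track files.

    ``log2_abundance`` is a proteins x genotypes frame; the heatmap value
    list follows ``genotype_order`` (wild type innermost). Proteins without
    a locus are omitted with a logged count.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bands": outdir / "circos_bands.txt",
        "heatmap": outdir / "circos_heatmap.txt",
        "links": outdir / "circos_links.txt",
    }
    n_skipped = 0
    with open(paths["bands"], "w") as fh:
        for pid, loc in sorted(loci.items(), key=lambda kv: (kv[1].chromosome, kv[1].start)):
            fh.write(f"band {loc.chromosome} {pid} {pid} {loc.start} {loc.end} grey\n")
    with open(paths["heatmap"], "w") as fh:
        for pid in log2_abundance.index:
            if pid not in loci:
                n_skipped += 1
                continue
            loc = loci[pid]
            values = ",".join(
                f"{log2_abundance.loc[pid, g]:.4f}" for g in genotype_order
            )
            fh.write(f"{loc.chromosome} {loc.start} {loc.end} {values}\n")
    with open(paths["links"], "w") as fh:
        for row in edges.itertuples(index=False):
            if row.source not in loci or row.target not in loci:
                n_skipped += 1
                continue
            a, b = loci[row.source], loci[row.target]
            fh.write(
                f"{a.chromosome} {a.start} {a.end} "
                f"{b.chromosome} {b.start} {b.end} sign={row.sign}\n"
            )
    if n_skipped:
        logger.info("circos_export: omitted %d records without a mapped locus", n_skipped)
    return paths
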