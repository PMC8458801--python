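"""Domain types, file readers/writers, configuration and logging.

All tabular formats are plain TSV; sequences are FASTA (read and written
through Biopython). Genomic coordinates are 1-based and inclusive at both
ends throughout the package, matching the EnsemblPlants convention; the
conversion to Python slices happens only at the point of slicing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hordeomics")

GENOTYPES = ("WT", "B", "C", "D", "BC", "CD", "BD")
DOUBLE_MUTANTS = ("BC", "CD", "BD")

#: 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: Residues accepted in input sequences. "X" (unknown) is tolerated but
#: excluded from composition denominators.
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """One quantified sample: a genotype and its biological replicate index."""

    sample_id: str
    genotype: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check sample-id uniqueness and that every genotype present has >=2 replicates."""
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    counts: dict[str, int] = {}
    for s in design:
        counts[s.genotype] = counts.get(s.genotype, 0) + 1
    thin = [g for g, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"genotypes with fewer than 2 replicates: {sorted(thin)}")


def default_design(n_replicates: int = 3) -> list[SampleDesign]:
    """The study layout: 7 genotypes x n biological replicates."""
    return [
        SampleDesign(f"{g}_{r}", g, r)
        for g in GENOTYPES
        for r in range(1, n_replicates + 1)
    ]


@dataclass(frozen=True)
class GenomicLocus:
    """1-based inclusive span on a named chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1 (1-based convention), got {self.start}")
        if self.end < self.start:
            raise ValueError(f"locus end {self.end} precedes start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, optionally anchored to a genomic locus."""

    protein_id: str
    sequence: str
    description: str = ""
    locus: GenomicLocus | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in SEQUENCE_ALPHABET]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"protein {self.protein_id!r}: illegal residue {char!r} at position {pos}"
            )


class AbundanceMatrix:
    """Proteins x samples peak-area matrix with its sample design.

    Values are non-negative peak areas; missing measurements are stored as
    NaN, never silently as zero. Column order always matches the design.
    """

    def __init__(
        self,
        protein_ids: Sequence[str],
        design: Sequence[SampleDesign],
        values: np.ndarray,
    ) -> None:
        protein_ids = list(protein_ids)
        if len(set(protein_ids)) != len(protein_ids):
            dupes = sorted({p for p in protein_ids if protein_ids.count(p) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        validate_design(design)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(protein_ids), len(design)):
            raise ValueError(
                f"value shape {values.shape} does not match "
                f"{len(protein_ids)} proteins x {len(design)} samples"
            )
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("peak areas must be non-negative")
        self.protein_ids = protein_ids
        self.design = list(design)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.design]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def genotype_columns(self, genotype: str) -> np.ndarray:
        """Column indices of a genotype's replicates, in design order."""
        idx = np.array([i for i, s in enumerate(self.design) if s.genotype == genotype])
        if idx.size == 0:
            raise ValueError(f"genotype {genotype!r} not present in the design")
        return idx

    def genotype_values(self, genotype: str) -> np.ndarray:
        return self.values[:, self.genotype_columns(genotype)]

    def genotype_means(self, genotype: str) -> np.ndarray:
        return np.nanmean(self.genotype_values(genotype), axis=1)

    def restrict(self, protein_ids: Sequence[str]) -> "AbundanceMatrix":
        index = {p: i for i, p in enumerate(self.protein_ids)}
        missing = [p for p in protein_ids if p not in index]
        if missing:
            raise KeyError(f"proteins absent from matrix: {missing[:5]}")
        rows = [index[p] for p in protein_ids]
        return AbundanceMatrix(list(protein_ids), self.design, self.values[rows])


@dataclass(frozen=True)
class PhenotypeGroup:
    genotype: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2 for any genotype entering ANOVA")


@dataclass
class PhenotypeTable:
    """Per-trait genotype summaries (units g/100 g dry weight)."""

    traits: dict[str, dict[str, PhenotypeGroup]] = field(default_factory=dict)

    def add(self, trait: str, group: PhenotypeGroup) -> None:
        self.traits.setdefault(trait, {})[group.genotype] = group

    def trait_groups(self, trait: str) -> dict[str, PhenotypeGroup]:
        return self.traits[trait]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Pipeline thresholds; defaults are the study's operating points."""

    fold_change: float = 2.0          # volcano FC gate (up if FC > fc, down if < 1/fc)
    p_threshold: float = 0.05         # raw-p significance gate
    q_threshold: float = 0.05         # BH gate for downstream protein sets
    use_q_for_network: bool = True    # gate the network input set on BH q
    correlation_cutoff: float = 0.95  # |r| cutoff for co-abundance edges
    vip_threshold: float = 1.2        # VIP selection threshold
    vip_top_n: int = 100              # cap on selected VIP proteins
    n_pls_components: int = 2
    enrichment_factor: float = 1.5    # residue-rich rule (inclusive)
    upstream_length: int = 1000       # promoter window, bp
    n_modules: int = 12               # hierarchical module count
    ttest: str = "student"            # student (pooled) | welch
    linkage_method: str = "average"
    correlation_transform: str = "log10"  # log10 | raw | zscore
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_cutoff <= 1:
            raise ValueError("correlation_cutoff must be in (0, 1]")
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be non-negative")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")
        if self.upstream_length < 1:
            raise ValueError("upstream_length must be positive")
        if self.n_modules < 1 or self.n_pls_components < 1:
            raise ValueError("n_modules and n_pls_components must be positive")
        if self.ttest not in ("student", "welch"):
            raise ValueError("ttest must be 'student' or 'welch'")
        if self.linkage_method not in ("average", "single", "complete"):
            raise ValueError("linkage_method must be average, single or complete")
        if self.correlation_transform not in ("log10", "raw", "zscore"):
            raise ValueError("correlation_transform must be log10, raw or zscore")


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML key-value config; unknown keys are rejected.

    An absent or empty file yields the full default set.
    """
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of parameter names to values")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return Config(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_abundance_table(path: str | Path, design: Sequence[SampleDesign]) -> AbundanceMatrix:
    """Read a proteins x samples TSV (header = sample ids, first column = protein id).

    Columns are reordered to match the design; design samples missing from
    the file raise. Empty cells and "NA" are read as missing (NaN).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate protein ids in {path}: {dupes}")
    missing_cols = [s.sample_id for s in design if s.sample_id not in df.columns]
    if missing_cols:
        raise ValueError(f"design samples absent from {path}: {missing_cols}")
    df = df[[s.sample_id for s in design]]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric abundance {cell!r} at protein {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    matrix = AbundanceMatrix(list(df.index), design, values)
    logger.info("read abundance matrix %s: %d proteins x %d samples", path, *matrix.shape)
    return matrix


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "protein_id"
    frame.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; id = first header token, description = remainder."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a DNA FASTA into a chromosome -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_locus_table(path: str | Path) -> dict[str, GenomicLocus]:
    """Read a TSV of protein_id, chromosome, start, end, strand (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "chromosome", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"locus table {path} missing columns: {missing}")
    loci: dict[str, GenomicLocus] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid in loci:
            raise ValueError(f"duplicate protein id in locus table: {pid!r}")
        loci[pid] = GenomicLocus(row.chromosome, int(row.start), int(row.end), row.strand)
    return loci


def write_locus_table(loci: Mapping[str, GenomicLocus], path: str | Path) -> None:
    rows = [
        {
            "protein_id": pid,
            "chromosome": loc.chromosome,
            "start": loc.start,
            "end": loc.end,
            "strand": loc.strand,
        }
        for pid, loc in loci.items()
    ]
    pd.DataFrame(rows, columns=["protein_id", "chromosome", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read trait summaries: columns trait, genotype, mean, sd, n."""
    df = pd.read_csv(path, sep="\t")
    table = PhenotypeTable()
    for row in df.itertuples(index=False):
        table.add(row.trait, PhenotypeGroup(row.genotype, float(row.mean), float(row.sd), int(row.n)))
    return table


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    rows = [
        {"trait": trait, "genotype": g.genotype, "mean": g.mean, "sd": g.sd, "n": g.n}
        for trait, groups in table.traits.items()
        for g in groups.values()
    ]
    pd.DataFrame(rows, columns=["trait", "genotype", "mean", "sd", "n"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
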