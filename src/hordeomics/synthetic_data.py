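"""Genotype-structured synthetic grain proteomes with known ground truth.

The generator emulates the study system: a barley wild type plus three
hordein single mutants (B, C, D) and their double-mutant combinations
(BC, CD, BD), measured as peak-area abundance matrices over biological
triplicates. It plants:

* protein classes with controlled amino-acid composition — Q/P-rich
  hordein-like storage proteins, K-rich LEA-like proteins, and neutral
  metabolic/housekeeping proteins;
* genotype-specific hordein suppression (near-total loss of the targeted
  class in its cognate mutants, with an attenuated trans-effect of the
  lys3/C mutation on B-hordeins) and compensation of lysine-rich and
  fatty-acid-metabolism proteins in the BC and CD backgrounds;
* log-normal multiplicative replicate noise on the log2 scale;
* hordein loci clustered in two disjoint windows on chromosome 1H, other
  classes scattered over 2H-7H;
* promoters with cis-element motifs planted at recorded offsets in the
  1,000 bp upstream window of each gene.

Everything is driven by a single integer seed; two runs with the same
parameters produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_core import (
    AMINO_ACIDS,
    DOUBLE_MUTANTS,
    GENOTYPES,
    AbundanceMatrix,
    GenomicLocus,
    PhenotypeGroup,
    PhenotypeTable,
    ProteinRecord,
    SampleDesign,
    logger,
)

PROTEIN_CLASSES = (
    "hordein_B",
    "hordein_C",
    "hordein_D",
    "gamma_hordein",
    "lys_rich",
    "fa_metabolism",
    "starch_metabolism",
    "housekeeping",
)
HORDEIN_CLASSES = ("hordein_B", "hordein_C", "hordein_D", "gamma_hordein")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Motifs planted in promoters; families as used for combination classes.
PLANT_MOTIFS = {
    "Prolamin box": "TGTAAAG",
    "Prolamin box long": "TGTAAAGT",
    "Pyrimidine box": "CTTTT",
    "GA-MYB": "AACA",
    "GA": "TAACAAA",
}

# Promoter motif combinations per class (storage proteins carry the full
# GA-responsive complex; lysine-rich genes carry Pyr + DOF-core Prolamin box).
_CLASS_MOTIFS: dict[str, tuple[str, ...]] = {
    "hordein_B": ("Pyrimidine box", "Prolamin box", "GA-MYB"),
    "hordein_C": ("Pyrimidine box", "Prolamin box long", "GA-MYB"),
    "hordein_D": ("Pyrimidine box", "Prolamin box"),
    "gamma_hordein": ("Pyrimidine box", "Prolamin box", "GA-MYB"),
    "lys_rich": ("Pyrimidine box", "Prolamin box"),
    "fa_metabolism": ("Pyrimidine box", "GA-MYB"),
    "starch_metabolism": ("Pyrimidine box", "GA-MYB", "GA"),
}
# Housekeeping promoters cycle through sparse combinations, including none.
_HK_MOTIFS: tuple[tuple[str, ...], ...] = ((), ("GA-MYB",), ("Pyrimidine box",), ("GA",))


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_proteins: Mapping[str, int] = field(
        default_factory=lambda: {
            "hordein_B": 12,
            "hordein_C": 10,
            "hordein_D": 3,
            "gamma_hordein": 5,
            "lys_rich": 15,
            "fa_metabolism": 15,
            "starch_metabolism": 15,
            "housekeeping": 125,
        }
    )
    suppression_log2fc: float = -6.0       # hordein loss in cognate mutants
    attenuation: float = 1.0 / 3.0         # lys3 trans-effect on B-hordeins
    compensation_log2fc: float = 1.5       # lys-rich / FA classes in BC and CD
    starch_log2fc: float = -1.0            # starch metabolism in BC and CD
    replicate_noise_sd: float = 0.25       # log2-scale sd of replicate noise
    n_replicates: int = 3
    hordein_qp_fraction: float = 0.48      # Q+P target for hordein-like sequences
    lys_k_fraction: float = 0.12           # K target for lys-rich sequences
    upstream_length: int = 1000
    phenotype_sampling: bool = False       # draw replicates instead of exact means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        unknown = set(self.n_proteins) - set(PROTEIN_CLASSES)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")
        if any(v < 1 for v in self.n_proteins.values()):
            raise ValueError("class counts must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    class_of: dict[str, str]
    effects: dict[str, dict[str, float]]       # protein -> genotype -> log2 effect
    module_of: dict[str, int]
    baseline: dict[str, float]
    motif_manifest: list[dict] = field(default_factory=list)
    phenotype_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    hordein_windows: tuple[tuple[int, int], tuple[int, int]] | None = None

    def proteins_of_class(self, label: str) -> list[str]:
        return [p for p, c in self.class_of.items() if c == label]


# Per-class residue frequency profiles. Sequences are built with exact
# residue counts drawn from these profiles (then shuffled), so composition
# constraints hold by construction, not in expectation.
def _class_profile(label: str, params: GeneratorParams) -> dict[str, float]:
    uniform = {aa: 1.0 / 20 for aa in AMINO_ACIDS}
    if label in HORDEIN_CLASSES:
        qp = params.hordein_qp_fraction
        prof = {aa: (1.0 - qp - 0.01) / 17 for aa in AMINO_ACIDS}
        prof["Q"] = qp * 0.625
        prof["P"] = qp * 0.375
        prof["K"] = 0.01
        return prof
    if label == "lys_rich":
        k = params.lys_k_fraction
        prof = {aa: (1.0 - k - 0.08) / 18 for aa in AMINO_ACIDS}
        prof["K"] = k
        prof["E"] = 0.08
        return prof
    prof = dict(uniform)
    prof["K"] = 0.055
    prof["L"] = 0.05 + (1.0 / 20 - 0.055)  # keep the profile summing to 1
    return prof


def _expected_background_k(params: GeneratorParams) -> float:
    total = sum(params.n_proteins.values())
    return (
        sum(
            n * _class_profile(label, params)["K"]
            for label, n in params.n_proteins.items()
        )
        / total
    )


def _sequence_from_profile(
    profile: Mapping[str, float], length: int, rng: np.random.Generator
) -> str:
    """Exact-count sequence: residue counts rounded from the profile, shuffled.

    Counts are apportioned by the largest-remainder rule so every residue
    lands within 1/length of its target fraction.
    """
    counts = {aa: int(np.floor(profile[aa] * length)) for aa in AMINO_ACIDS}
    remainder = length - sum(counts.values())
    fractional = sorted(
        AMINO_ACIDS, key=lambda aa: (profile[aa] * length) % 1.0, reverse=True
    )
    for aa in fractional[:remainder]:
        counts[aa] += 1
    letters = np.array([aa for aa in AMINO_ACIDS for _ in range(counts[aa])])
    rng.shuffle(letters)
    return "".join(letters)


_CLASS_LENGTH = {
    "hordein_B": (260, 300),
    "hordein_C": (300, 340),
    "hordein_D": (600, 700),
    "gamma_hordein": (280, 310),
    "lys_rich": (150, 450),
    "fa_metabolism": (200, 500),
    "starch_metabolism": (300, 800),
    "housekeeping": (120, 600),
}

# Hordein loci cluster in two disjoint windows on the 1H short arm; the
# coordinates are scaled-down stand-ins, not reference-genome positions.
_WINDOW1_START = 24_000
_WINDOW_GAP = 12_000
_GENE_SLOT = 5_000  # spacing between planted genes, leaves >=1 kb flanks


def _class_effects(label: str, params: GeneratorParams) -> dict[str, float]:
    s = params.suppression_log2fc
    a = s * params.attenuation
    c = params.compensation_log2fc
    eff = {g: 0.0 for g in GENOTYPES}
    if label == "hordein_B":
        eff.update({"B": s, "BC": s, "BD": s, "C": a, "CD": a})
    elif label == "hordein_C":
        eff.update({"C": s, "BC": s, "CD": s})
    elif label == "hordein_D":
        eff.update({"D": s, "BD": s, "CD": s})
    elif label == "gamma_hordein":
        # compensation for B-hordein loss in B-mutant backgrounds
        eff.update({"B": 1.0, "BC": 1.0, "BD": 1.0})
    elif label == "lys_rich":
        eff.update({"BC": c, "CD": c})
    elif label == "fa_metabolism":
        eff.update({"BC": c, "CD": c})
    elif label == "starch_metabolism":
        eff.update({"BC": params.starch_log2fc, "CD": params.starch_log2fc})
    return eff


def generate_proteome(params: GeneratorParams) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate sequences, loci and per-genotype true effects for every class.

    Hordein-like sequences are Q/P-rich by construction; lysine-rich
    sequences carry a K fraction at least 1.5x the generated background mean.
    """
    bg_k = _expected_background_k(params)
    if params.lys_k_fraction < 1.5 * bg_k:
        raise ValueError(
            f"impossible composition constraint: lys_k_fraction "
            f"{params.lys_k_fraction:.3f} is below 1.5x the background mean K "
            f"({1.5 * bg_k:.3f})"
        )
    if params.hordein_qp_fraction < 0.40:
        raise ValueError("hordein_qp_fraction must be >= 0.40 (Q/P-rich constraint)")

    rng = np.random.default_rng(params.seed)
    records: list[ProteinRecord] = []
    truth = GroundTruth(class_of={}, effects={}, module_of={}, baseline={})

    # chromosome layout: hordeins on 1H in two windows, others on 2H-7H
    hordein_ids: list[str] = []
    other_ids: list[str] = []

    module_ids = {label: i + 1 for i, label in enumerate(PROTEIN_CLASSES)}
    for label in PROTEIN_CLASSES:
        n = params.n_proteins.get(label, 0)
        profile = _class_profile(label, params)
        lo, hi = _CLASS_LENGTH[label]
        for i in range(n):
            pid = f"{label}_{i + 1:03d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _sequence_from_profile(profile, length, rng)
            records.append(ProteinRecord(pid, seq, description=f"synthetic {label}"))
            truth.class_of[pid] = label
            truth.effects[pid] = _class_effects(label, params)
            truth.module_of[pid] = module_ids[label]
            base = 10.0 ** rng.uniform(4.5, 6.5) if label in HORDEIN_CLASSES else 10.0 ** rng.uniform(3.5, 6.0)
            truth.baseline[pid] = base
            (hordein_ids if label in HORDEIN_CLASSES else other_ids).append(pid)

    # loci: alternate hordeins between two disjoint 1H windows sized from counts
    seq_len = {r.protein_id: len(r.sequence) for r in records}
    loci: dict[str, GenomicLocus] = {}
    n_w1 = (len(hordein_ids) + 1) // 2
    n_w2 = len(hordein_ids) - n_w1
    w1 = (_WINDOW1_START, _WINDOW1_START + n_w1 * _GENE_SLOT + params.upstream_length)
    w2_start = w1[1] + _WINDOW_GAP
    w2 = (w2_start, w2_start + max(n_w2, 1) * _GENE_SLOT + params.upstream_length)
    truth.hordein_windows = (w1, w2)
    window_cursor = [w1[0] + params.upstream_length + 100, w2[0] + params.upstream_length + 100]
    for i, pid in enumerate(hordein_ids):
        w = i % 2
        start = window_cursor[w]
        gene_len = 3 * seq_len[pid]
        strand = "+" if rng.random() < 0.5 else "-"
        loci[pid] = GenomicLocus("1H", start, start + gene_len - 1, strand)
        window_cursor[w] = start + _GENE_SLOT
    chroms = [f"{i}H" for i in range(2, 8)]
    cursors = {c: params.upstream_length + 100 for c in chroms}
    for i, pid in enumerate(other_ids):
        chrom = chroms[i % len(chroms)]
        start = cursors[chrom]
        gene_len = 3 * seq_len[pid]
        strand = "+" if rng.random() < 0.5 else "-"
        loci[pid] = GenomicLocus(chrom, start, start + gene_len - 1, strand)
        cursors[chrom] = start + _GENE_SLOT

    records = [
        ProteinRecord(r.protein_id, r.sequence, r.description, loci[r.protein_id])
        for r in records
    ]
    logger.info(
        "generated proteome: %d proteins in %d classes (background K %.2f%%)",
        len(records), len(params.n_proteins), 100 * bg_k,
    )
    return records, truth


def generate_abundances(
    proteome: list[ProteinRecord],
    truth: GroundTruth,
    design: list[SampleDesign],
    params: GeneratorParams,
) -> AbundanceMatrix:
    """Peak areas: baseline x 2^(genotype effect) x 2^Normal(0, noise_sd)."""
    genotypes_present = {s.genotype for s in design}
    for pid in (r.protein_id for r in proteome):
        missing = genotypes_present - set(truth.effects[pid])
        if missing:
            raise ValueError(f"no true effect for genotypes {sorted(missing)} (protein {pid})")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    values = np.empty((len(proteome), len(design)))
    for i, rec in enumerate(proteome):
        base = truth.baseline[rec.protein_id]
        eff = truth.effects[rec.protein_id]
        for j, sample in enumerate(design):
            noise = rng.normal(0.0, params.replicate_noise_sd) if params.replicate_noise_sd else 0.0
            values[i, j] = base * 2.0 ** (eff[sample.genotype] + noise)
    return AbundanceMatrix([r.protein_id for r in proteome], design, values)


def generate_promoters(
    proteome: list[ProteinRecord],
    truth: GroundTruth,
    params: GeneratorParams,
) -> tuple[dict[str, str], dict[str, GenomicLocus], list[dict]]:
    """Synthetic genome with motifs planted in each gene's upstream window.

    Background sequence is uniform over {A,C,G,T}; accidental motif
    occurrences are left in place — the manifest records planted positions
    only. Offsets are 1-based within the upstream window, offset 1 being
    the most-upstream base on the coding strand.
    """
    max_motif = max(len(p) for p in PLANT_MOTIFS.values())
    if params.upstream_length < max_motif:
        raise ValueError("upstream length shorter than the longest motif")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    loci = {r.protein_id: r.locus for r in proteome if r.locus is not None}

    chrom_len: dict[str, int] = {}
    for loc in loci.values():
        need = loc.end + params.upstream_length + 200
        chrom_len[loc.chromosome] = max(chrom_len.get(loc.chromosome, 0), need)
    bases = np.array(list("ACGT"))
    genome_arrays = {
        c: rng.choice(bases, size=n) for c, n in sorted(chrom_len.items())
    }

    manifest: list[dict] = []
    hk_cycle = 0
    for rec in proteome:
        loc = loci[rec.protein_id]
        label = truth.class_of[rec.protein_id]
        if label == "housekeeping":
            motif_names = _HK_MOTIFS[hk_cycle % len(_HK_MOTIFS)]
            hk_cycle += 1
        else:
            motif_names = _CLASS_MOTIFS[label]
        # build the coding-strand upstream window, plant motifs at
        # non-overlapping random offsets, then write it into the genome
        window = rng.choice(bases, size=params.upstream_length)
        taken: list[tuple[int, int]] = []
        for name in motif_names:
            pattern = PLANT_MOTIFS[name]
            for _ in range(200):
                off = int(rng.integers(1, params.upstream_length - len(pattern) + 2))
                span = (off, off + len(pattern) - 1)
                if all(span[1] < a or span[0] > b for a, b in taken):
                    taken.append(span)
                    break
            else:  # pragma: no cover - window far larger than motif budget
                raise RuntimeError("could not place motif without overlap")
            window[off - 1 : off - 1 + len(pattern)] = list(pattern)
            manifest.append(
                {
                    "gene_id": rec.protein_id,
                    "motif": name,
                    "pattern": pattern,
                    "offset": off,
                    "strand": loc.strand,
                }
            )
        window_str = "".join(window)
        arr = genome_arrays[loc.chromosome]
        if loc.strand == "+":
            # window occupies [start-length, start-1] in genome order
            arr[loc.start - 1 - params.upstream_length : loc.start - 1] = list(window_str)
        else:
            # coding-strand window maps to [end+1, end+length] reverse-complemented
            arr[loc.end : loc.end + params.upstream_length] = list(
                reverse_complement(window_str)
            )

    genome = {c: "".join(a) for c, a in genome_arrays.items()}
    truth.motif_manifest = manifest
    return genome, loci, manifest


# Trait means emulate the study's wild-type operating points (g/100 g DW)
# with genotype percent effects in the observed directions.
_DEFAULT_TRAITS: dict[str, tuple[float, dict[str, float], float]] = {
    "fatty_acid": (3.15, {"B": -1.0, "C": 82.9, "D": -12.4, "BC": 67.6, "CD": 82.2, "BD": 10.2}, 0.04),
    "tag": (1.39, {"B": 5.8, "C": 131.7, "D": -9.4, "BC": 110.1, "CD": 127.3, "BD": 12.9}, 0.10),
    "starch": (51.65, {"B": -12.8, "C": -24.8, "D": -4.8, "BC": -25.6, "CD": -31.0, "BD": -16.9}, 0.03),
    "beta_glucan": (3.29, {"B": -22.8, "C": -63.5, "D": 2.1, "BC": -57.4, "CD": -62.3, "BD": -36.5}, 0.03),
}


def generate_phenotypes(
    truth: GroundTruth,
    params: GeneratorParams,
    traits: Mapping[str, tuple[float, Mapping[str, float], float]] | None = None,
) -> PhenotypeTable:
    """Trait summaries (mean, sd, n) per genotype.

    By default means are the configured values exactly (sd = cv x mean), so
    percent changes recompute to the planted effects; with
    ``phenotype_sampling`` replicates are drawn from the true normal
    distribution and summarised, for power/null simulations.
    """
    traits = dict(traits) if traits is not None else dict(_DEFAULT_TRAITS)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    table = PhenotypeTable()
    truth.phenotype_effects = {t: dict(spec[1]) for t, spec in traits.items()}
    for trait, (wt_mean, effects, cv) in traits.items():
        for genotype in GENOTYPES:
            pct = 0.0 if genotype == "WT" else float(effects.get(genotype, 0.0))
            true_mean = wt_mean * (1.0 + pct / 100.0)
            true_sd = cv * wt_mean
            if params.phenotype_sampling:
                reps = rng.normal(true_mean, true_sd, size=params.n_replicates)
                table.add(
                    trait,
                    PhenotypeGroup(genotype, float(np.mean(reps)), float(np.std(reps, ddof=1)), params.n_replicates),
                )
            else:
                table.add(trait, PhenotypeGroup(genotype, true_mean, true_sd, params.n_replicates))
    return table
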