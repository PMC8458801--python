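import numpy as np
import pytest

from hordeomics.io_core import GenomicLocus, ProteinRecord
from hordeomics.promoter_genome import (
    MOTIFS,
    circos_export,
    classify_promoters,
    combination_label,
    extract_upstream,
    map_proteins,
    scan_motifs,
)
from hordeomics.synthetic_data import reverse_complement


def sliding_window_scan(seq, pattern):
    """Naive O(n*m) oracle: all exact match offsets (1-based)."""
    return [
        i + 1
        for i in range(len(seq) - len(pattern) + 1)
        if seq[i : i + len(pattern)] == pattern
    ]


class TestMapProteins:
    def test_direct_table_entry_wins(self):
        loc = GenomicLocus("1H", 100, 200, "+")
        mapped, unmapped = map_proteins([ProteinRecord("p1", "KKK")], {"p1": loc})
        assert mapped["p1"] == loc and not unmapped

    def test_identical_sequence_maps_to_reference_model(self):
        seq = "MKQLVRPASDE"
        ref = ProteinRecord("ref1", seq, locus=GenomicLocus("3H", 500, 900, "+"))
        mapped, unmapped = map_proteins([ProteinRecord("q", seq)], {}, reference=[ref])
        assert mapped["q"] == ref.locus and not unmapped

    def test_dissimilar_sequence_stays_unmapped(self):
        ref = ProteinRecord("ref1", "M" + "K" * 30, locus=GenomicLocus("3H", 500, 900, "+"))
        mapped, unmapped = map_proteins([ProteinRecord("q", "A" * 30)], {}, reference=[ref])
        assert unmapped == ["q"]

    def test_fallback_equals_bruteforce_kmer_argmax(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        refs = []
        for i in range(15):
            seq = "".join(rng.choice(alphabet, size=60))
            refs.append(
                ProteinRecord(
                    f"ref{i}", seq,
                    locus=GenomicLocus(f"{(i % 7) + 1}H", 1000 + i, 2000 + i, "+"),
                )
            )
        for _ in range(10):
            donor = refs[rng.integers(0, len(refs))]
            # mutate a few positions so fallback is non-trivial
            q = list(donor.sequence)
            for j in rng.choice(len(q), size=3, replace=False):
                q[j] = str(rng.choice(alphabet))
            query = ProteinRecord("q", "".join(q))
            mapped, unmapped = map_proteins([query], {}, reference=refs)

            def kmers(s):
                return {s[i : i + 5] for i in range(len(s) - 4)}

            qk = kmers(query.sequence)
            shared = max(len(qk & kmers(r.sequence)) for r in refs)
            candidates = [r for r in refs if len(qk & kmers(r.sequence)) == shared]
            best = min(candidates, key=lambda r: (r.locus.chromosome, r.locus.start))
            if shared >= 0.5 * len(qk):
                assert mapped["q"] == best.locus
            else:
                assert unmapped == ["q"]


class TestExtractUpstream:
    def test_plus_strand_coordinate_arithmetic(self):
        genome = {"1H": "".join("ACGT"[i % 4] for i in range(6000))}
        locus = GenomicLocus("1H", 5001, 5500, "+")
        upstream = extract_upstream(locus, genome, length=1000)
        assert upstream == genome["1H"][4000:5000]  # bases 4001..5000

    def test_minus_strand_reverse_complement(self):
        genome = {"1H": "".join("ACGT"[i % 4] for i in range(8000))}
        locus = GenomicLocus("1H", 5500, 6000, "-")
        upstream = extract_upstream(locus, genome, length=1000)
        assert upstream == reverse_complement(genome["1H"][6000:7000])  # bases 6001..7000

    def test_truncation_at_chromosome_start(self):
        genome = {"2H": "A" * 500 + "C" * 100}
        locus = GenomicLocus("2H", 501, 600, "+")
        assert extract_upstream(locus, genome, length=1000) == "A" * 500

    def test_planted_marker_recovered_on_both_strands(self, study):
        """Generator manifest round trip: extraction contains every planted
        motif at its recorded offset."""
        for entry in study.manifest_rows[:200]:
            locus = study.loci[entry["gene_id"]]
            upstream = extract_upstream(locus, study.genome, length=1000)
            off, pat = entry["offset"], entry["pattern"]
            assert upstream[off - 1 : off - 1 + len(pat)] == pat

    def test_missing_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extract_upstream(GenomicLocus("9H", 2000, 3000, "+"), {"1H": "ACGT" * 1000})

    def test_reembedding_reproduces_genome_slice(self):
        genome = {"1H": "".join("ACGT"[(i * 7) % 4] for i in range(4000))}
        locus = GenomicLocus("1H", 3001, 3500, "-")
        upstream = extract_upstream(locus, genome, length=500)
        assert reverse_complement(upstream) == genome["1H"][3000:3500]


class TestScanMotifs:
    def test_tandem_pyrimidine_boxes(self):
        hits = scan_motifs("g", "CTTTTCTTTT", [("Pyrimidine box", "CTTTT", "Pyr")])
        assert [h.offset for h in hits] == [1, 6]

    def test_overlapping_hits_reported(self):
        hits = scan_motifs("g", "AACAACA", [("GA-MYB", "AACA", "GAMyb")])
        assert [h.offset for h in hits] == [1, 4]

    def test_poly_g_has_no_hits(self):
        assert scan_motifs("g", "G" * 500) == []

    def test_n_never_matches(self):
        assert scan_motifs("g", "CTTNT", [("Pyrimidine box", "CTTTT", "Pyr")]) == []

    def test_equals_sliding_window_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=1000))
            hits = scan_motifs("g", seq)
            for name, pattern, _family in MOTIFS:
                got = sorted(h.offset for h in hits if h.motif == name)
                assert got == sliding_window_scan(seq, pattern)

    def test_both_strands_flag_adds_reverse_complement_hits(self):
        # CTTTT on the given strand, AAAAG is its reverse complement
        hits = scan_motifs("g", "CTTTTGGAAAAG", both_strands=True)
        pyr = [(h.offset, h.strand) for h in hits if h.motif == "Pyrimidine box"]
        assert (1, "+") in pyr and (8, "-") in pyr
        default = scan_motifs("g", "CTTTTGGAAAAG")
        assert all(h.strand == "+" for h in default)

    def test_long_pbox_hit_implies_short_pbox_hit(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            seq = "".join(rng.choice(bases, size=2000)) + "TGTAAAGT"
            hits = scan_motifs("g", seq)
            short = {h.offset for h in hits if h.motif == "Prolamin box"}
            long = {h.offset for h in hits if h.motif == "Prolamin box long"}
            assert long <= short


class TestClassifyPromoters:
    def test_pyr_pbox_combination(self):
        hits = scan_motifs("g", "CTTTT" + "G" * 20 + "TGTAAAG")
        assert combination_label(hits) == "Pyr-Pbox"

    def test_no_hits_is_none_class(self):
        classes, counts = classify_promoters({"g1": []})
        assert classes.promoter_class.iloc[0] == "none"
        assert counts.n_genes.sum() == 1

    def test_planted_combinations_counted_exactly(self, study):
        """Promoter classes recomputed from the genome match the classes
        implied by the generator's planted motif manifest."""
        from collections import defaultdict

        planted = defaultdict(set)
        family = {name: fam for name, _p, fam in MOTIFS}
        for entry in study.manifest_rows:
            planted[entry["gene_id"]].add(family[entry["motif"]])
        hits_per_gene = {}
        for pid, locus in study.loci.items():
            upstream = extract_upstream(locus, study.genome, 1000)
            hits_per_gene[pid] = scan_motifs(pid, upstream, strand=locus.strand)
        classes, _counts = classify_promoters(hits_per_gene)
        observed = dict(zip(classes.gene_id, classes.promoter_class))
        for pid in study.loci:
            got = set(observed[pid].split("-")) - {"none"}
            # scanning can only add accidental families on top of planted ones
            assert planted[pid] <= got


class TestCircosExport:
    def test_single_protein_single_edge_tracks(self, tmp_path):
        import pandas as pd

        loci = {"p1": GenomicLocus("1H", 100, 200, "+"), "p2": GenomicLocus("2H", 300, 400, "-")}
        abundance = pd.DataFrame(
            np.ones((2, 7)), index=["p1", "p2"],
            columns=["WT", "B", "C", "D", "BC", "CD", "BD"],
        )
        edges = pd.DataFrame({"source": ["p1"], "target": ["p2"], "r": [0.99], "sign": ["+"]})
        paths = circos_export(loci, abundance, edges, tmp_path)
        assert len(paths) == 3
        bands = paths["bands"].read_text().strip().splitlines()
        heat = paths["heatmap"].read_text().strip().splitlines()
        links = paths["links"].read_text().strip().splitlines()
        assert len(bands) == 2 and len(heat) == 2 and len(links) == 1
        assert "1H 100 200" in links[0] and "2H 300 400" in links[0]

    def test_track_coordinates_round_trip(self, tmp_path):
        import pandas as pd

        loci = {"p1": GenomicLocus("5H", 12345, 23456, "+")}
        abundance = pd.DataFrame(
            [[1.0] * 7], index=["p1"], columns=["WT", "B", "C", "D", "BC", "CD", "BD"]
        )
        paths = circos_export(loci, abundance, pd.DataFrame(columns=["source", "target", "r", "sign"]), tmp_path)
        heat = paths["heatmap"].read_text().split()
        assert heat[0] == "5H" and heat[1] == "12345" and heat[2] == "23456"
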