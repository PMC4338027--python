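"""Transcript models, coding consequences, lookups and the cache."""

import pytest

from adviser.annotation_engine import (ModelError,
                                       PreAnnotationCache, TranscriptModel,
                                       annotate, coding_effect,
                                       max_allele_frequency, region_overlaps)
from adviser.variant_io import VariantRecord, revcomp


def snp(start, ref, alt):
    return VariantRecord("chrT", start, start + 1, "snp", ref, alt)


# toy + strand transcript: single exon at 4..22, CDS = ACGTACGTACGTACGTAC
TOY_GENOME = "NNNN" + "ACGTACGTACGTACGTAC" + "NNNN"
TOY_TX = TranscriptModel("G", "G.t1", "chrT", "+", [(4, 22)], 4, 22)


class TestCodingEffect:
    def test_synonymous_third_position(self):
        # CDS position 2: codon ACG -> ACT, both Thr
        ce = coding_effect(snp(6, "G", "T"), TOY_TX, TOY_GENOME)
        assert ce.effect == "synonymous" and ce.protein_change == "p.(T1=)"

    def test_missense_first_position(self):
        # ACG -> CCG: Thr -> Pro
        ce = coding_effect(snp(4, "A", "C"), TOY_TX, TOY_GENOME)
        assert ce.effect == "missense" and ce.protein_change == "p.T1P"

    def test_inframe_deletion_of_one_codon(self):
        rec = VariantRecord("chrT", 7, 10, "del", "TAC", "")
        assert coding_effect(rec, TOY_TX, TOY_GENOME).effect == "inframe_del"

    def test_frameshift_deletion(self):
        rec = VariantRecord("chrT", 7, 9, "del", "TA", "")
        ce = coding_effect(rec, TOY_TX, TOY_GENOME)
        assert ce.effect == "frameshift" and ce.stop_residue == 2

    def test_frameshift_insertion(self):
        rec = VariantRecord("chrT", 7, 7, "ins", "", "TT")
        assert coding_effect(rec, TOY_TX, TOY_GENOME).effect == "frameshift"

    def test_inframe_insertion(self):
        rec = VariantRecord("chrT", 7, 7, "ins", "", "AAA")
        assert coding_effect(rec, TOY_TX, TOY_GENOME).effect == "inframe_ins"

    def test_nonsense(self):
        # codon 2 TAC -> TAA (stop)
        ce = coding_effect(snp(9, "C", "A"), TOY_TX, TOY_GENOME)
        assert ce.effect == "nonsense" and ce.stop_residue == 2

    def test_fixture_gene_effects(self, reference):
        """Splice windows classified on a real multi-exon fixture gene."""
        tx = reference.transcripts[0]
        g = reference.genome
        i_start, i_end = tx.introns[0]

        def eff(pos):
            alt = [b for b in "ACGT" if b != g[pos]][0]
            return coding_effect(snp(pos, g[pos], alt), tx, g).effect

        assert eff(i_start) == "splice_donor"
        assert eff(i_start + 1) == "splice_donor"
        assert eff(i_end - 1) == "splice_acceptor"
        assert eff(i_start + 2) == "splice_region"      # intronic +3
        assert eff(i_start + 7) == "splice_region"      # intronic +8
        mid = (i_start + i_end) // 2
        assert eff(mid) == "intronic"

    def test_minus_strand_mirror(self, reference):
        """A minus-strand CDS variant yields a protein-level change
        consistent with hand translation of the reverse complement."""
        tx = next(t for t in reference.transcripts if t.strand == "-")
        g = reference.genome
        cds = tx.spliced_cds(g)
        prot = tx.protein(g)
        assert prot.startswith("M") and prot.endswith("*")
        # mutate the first base of codon 2 (genomic position = CDS index 3)
        gpos = next(p for p in range(tx.cds_start, tx.cds_end)
                    if tx.cds_index_of(p) == 3)
        # choose an alt producing a missense on the transcript strand
        for alt in "ACGT":
            if alt == g[gpos]:
                continue
            ce = coding_effect(snp(gpos, g[gpos], alt), tx, g)
            tx_base = revcomp(alt)
            expected_codon = tx_base + cds[4:6]
            from Bio.Seq import Seq
            expected_aa = str(Seq(expected_codon).translate())
            if expected_aa == prot[1]:
                assert ce.effect in ("synonymous", "splice_region")
            elif expected_aa == "*":
                assert ce.effect == "nonsense"
            else:
                assert ce.effect == "missense"
                assert ce.protein_change == f"p.{prot[1]}2{expected_aa}"

    def test_utr_classification(self, reference):
        tx = reference.transcripts[0]       # plus strand, 9 nt UTRs
        g = reference.genome
        p5 = tx.start       # first transcribed base: 5' UTR
        alt = [b for b in "ACGT" if b != g[p5]][0]
        assert coding_effect(snp(p5, g[p5], alt), tx, g).effect == "utr5"
        p3 = tx.end - 1
        alt = [b for b in "ACGT" if b != g[p3]][0]
        assert coding_effect(snp(p3, g[p3], alt), tx, g).effect == "utr3"

    def test_invalid_transcript_model_rejected(self):
        with pytest.raises(ModelError):
            TranscriptModel("G", "bad", "chrT", "+", [(4, 22)], 4, 21)
        with pytest.raises(ModelError):
            TranscriptModel("G", "bad", "chrT", "+", [(4, 10), (8, 22)], 4, 22)


class TestLookups:
    def test_max_af_over_populations(self):
        rec = snp(4, "A", "C")
        tables = {"popA": {rec.key: 0.004}, "popB": {rec.key: 0.03}}
        assert max_allele_frequency(rec, tables) == 0.03

    def test_absent_everywhere_is_null(self):
        assert max_allele_frequency(snp(4, "A", "C"), {"popA": {}}) is None

    def test_single_population(self):
        rec = snp(4, "A", "C")
        assert max_allele_frequency(rec, {"popA": {rec.key: 0.2}}) == 0.2

    def test_region_overlap_containment(self):
        regions = {"tfbs": [(10, 18, "M0")]}
        assert region_overlaps(snp(12, "A", "C"), regions) == \
            [("tfbs", "M0", (10, 18))]

    def test_span_hits_adjacent_features(self):
        regions = {"cons": [(10, 12, "E1"), (12, 14, "E2")]}
        rec = VariantRecord("chrT", 11, 13, "del", "AC", "")
        hits = region_overlaps(rec, regions)
        assert [h[1] for h in hits] == ["E1", "E2"]

    def test_insertion_at_feature_end_not_returned(self):
        regions = {"tfbs": [(10, 18, "M0")]}
        ins = VariantRecord("chrT", 18, 18, "ins", "", "A")
        assert region_overlaps(ins, regions) == []
        ins_start = VariantRecord("chrT", 10, 10, "ins", "", "A")
        assert region_overlaps(ins_start, regions) != []

    def test_brute_force_interval_agreement(self, reference):
        import numpy as np
        rng = np.random.default_rng(7)
        feats = sorted(
            (int(s), int(s) + int(w), f"F{i}") for i, (s, w) in enumerate(
                zip(rng.integers(0, 800, 40), rng.integers(1, 30, 40))))
        regions = {"r": feats}
        for _ in range(200):
            s = int(rng.integers(0, 820))
            e = s + int(rng.integers(1, 25))
            rec = VariantRecord("chrT", s, e, "del", "A" * (e - s), "")
            got = {h[1] for h in region_overlaps(rec, regions)}
            expected = {fid for fs, fe, fid in feats if fs < e and s < fe}
            assert got == expected


class TestAnnotateAndCache:
    def test_cache_hit_returns_identical_row(self, reference, sources):
        tx = reference.transcripts[0]
        p = tx.cds_start + 4
        g = reference.genome
        rec = snp(p, g[p], [b for b in "ACGT" if b != g[p]][0])
        cache = PreAnnotationCache()
        row1, computed1 = annotate(rec, sources, cache, g, "1")
        row2, computed2 = annotate(rec, sources, cache, g, "2")
        assert computed1 and not computed2
        assert row1.columns == row2.columns

    def test_cache_transparency(self, reference, sources, variant_file,
                                ref_genome):
        """Cached and de-novo annotation agree value-for-value."""
        from adviser.validator import validate_file
        from adviser.variant_io import read_variants

        path, _ = variant_file
        records, _, _ = read_variants(path)
        accepted = validate_file(records, ref_genome).accepted
        g = reference.genome
        cache = PreAnnotationCache()
        warm = [annotate(r, sources, cache, g)[0] for r in accepted]
        again = [annotate(r, sources, cache, g)[0] for r in accepted]
        cold = [annotate(r, sources, None, g)[0] for r in accepted]
        for a, b, c in zip(warm, again, cold):
            assert a.columns == b.columns == c.columns

    def test_cache_persistence_round_trip(self, reference, sources, tmp_path):
        tx = reference.transcripts[0]
        g = reference.genome
        p = tx.cds_start + 4
        rec = snp(p, g[p], [b for b in "ACGT" if b != g[p]][0])
        cache = PreAnnotationCache(tmp_path / "cache")
        row1, _ = annotate(rec, sources, cache, g)
        cache.save()
        reloaded = PreAnnotationCache(tmp_path / "cache")
        row2, computed = annotate(rec, sources, reloaded, g)
        assert not computed and row1.columns == row2.columns

    def test_cache_never_stores_genotypes(self, reference, sources):
        g = reference.genome
        rec = snp(5, g[5], [b for b in "ACGT" if b != g[5]][0]) \
            .replace(genotypes=("0/1",))
        cache = PreAnnotationCache()
        annotate(rec, sources, cache, g)
        stored = cache.get(rec)
        assert "genotypes" not in stored and "zygosity" not in stored
        with pytest.raises(ValueError):
            cache.put(rec, {"zygosity": "het"})

    def test_intergenic_variant_dashes(self, reference, sources, tmp_path):
        from adviser.variant_io import write_annotation_table
        g = reference.genome
        # last base of the genome is far from every gene and TFBS site
        p = len(g) - 2
        rec = snp(p, g[p], [b for b in "ACGT" if b != g[p]][0])
        row, _ = annotate(rec, sources, None, g, "7")
        assert row.columns["gene"] == []
        assert row.columns["region"] == "intergenic"
        assert row.variant_block[1] == str(p)
        out = tmp_path / "t.tsv"
        write_annotation_table([row], out)
        header = out.read_text().splitlines()[0].split("\t")
        cells = out.read_text().splitlines()[1].split("\t")
        assert cells[header.index("gene")] == "-"
        assert cells[header.index("effect")] == "-"

    def test_two_isoforms_give_two_parallel_entries(self, reference, sources):
        """GENE0 has two isoforms; every transcript column has 2 entries."""
        tx = reference.transcripts[0]
        g = reference.genome
        p = tx.cds_start + 4
        rec = snp(p, g[p], [b for b in "ACGT" if b != g[p]][0])
        row, _ = annotate(rec, sources, None, g)
        assert len(row.columns["gene"]) == 2
        for col in ("transcript", "effect", "proteinChange",
                    "truncationScore", "missenseDamaging"):
            val = row.columns[col]
            assert val == [] or len(val) == 2, col
        row.check_parallel()

    def test_parallel_integrity_across_fixture_file(self, reference, sources,
                                                    variant_file, ref_genome):
        from adviser.validator import validate_file
        from adviser.variant_io import read_variants

        path, _ = variant_file
        records, _, _ = read_variants(path)
        accepted = validate_file(records, ref_genome).accepted
        for rec in accepted:
            row, _ = annotate(rec, sources, None, reference.genome)
            row.check_parallel()
            n_tx = len(sources.overlapping_transcripts(rec))
            assert len(row.columns["effect"]) == n_tx
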