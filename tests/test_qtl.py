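"""Allele harmonization, rsID assignment, target annotation, BH FDR and
variant-type/significance splitting."""

import numpy as np
import pytest

from fgharmonize.qtl import (QTLRecord, annotate_target, assign_rsid,
                             compute_fdr, harmonize_alleles, split_outputs)


def make_rec(ref="C", alt="G", start=5, end=6, beta=0.5, af=0.3, p=0.01,
             target="GENEPLUS", fdr=None, tissue="liver"):
    return QTLRecord(
        chrom="chr1", start=start, end=end, variant_id=f"chr1_{start + 1}_{ref}_{alt}",
        ref_allele=ref, alt_allele=alt, beta=beta, pvalue=p, fdr=fdr,
        alt_allele_freq=af, target_id=target, tissue=tissue,
    )


def bh_oracle(pvals):
    """Independent step-up implementation of Benjamini–Hochberg.

    adjusted_i = min over j >= rank(i) of (p_(j) * m / j), clamped to <= 1.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestHarmonizeAlleles:
    def test_matching_orientation_unchanged(self, mini_ref):
        rec = harmonize_alleles(make_rec(ref="C", alt="G", start=5, end=6), mini_ref)
        assert rec.flip_status == "match"
        assert (rec.ref_allele, rec.alt_allele, rec.beta, rec.alt_allele_freq) == \
            ("C", "G", 0.5, 0.3)

    def test_swapped_orientation_flips_statistics(self, mini_ref):
        # reference site rs777 is T>C; record arrives as C/T (swapped)
        rec = harmonize_alleles(
            make_rec(ref="C", alt="T", start=7, end=8, beta=0.5, af=0.3), mini_ref)
        assert rec.flip_status == "flipped"
        assert (rec.ref_allele, rec.alt_allele) == ("T", "C")
        assert rec.beta == -0.5
        assert rec.alt_allele_freq == pytest.approx(0.7)
        assert rec.effect_allele == rec.alt_allele

    def test_genome_fallback_direct_and_swapped(self, mini_ref):
        # position 9 (genome base C) has no site in the table
        direct = harmonize_alleles(make_rec(ref="C", alt="A", start=9, end=10),
                                   mini_ref)
        assert direct.flip_status == "genome_resolved"
        assert direct.beta == 0.5
        swapped = harmonize_alleles(make_rec(ref="A", alt="C", start=9, end=10,
                                             beta=0.5, af=0.3), mini_ref)
        assert swapped.flip_status == "genome_resolved"
        assert (swapped.ref_allele, swapped.alt_allele) == ("C", "A")
        assert swapped.beta == -0.5

    def test_unresolvable_alleles(self, mini_ref):
        # in-table site with incompatible alleles
        rec = harmonize_alleles(make_rec(ref="A", alt="G", start=7, end=8), mini_ref)
        assert rec.flip_status == "unresolved"
        # off-table site where neither allele matches the genome base (C at 9)
        rec = harmonize_alleles(make_rec(ref="G", alt="T", start=9, end=10), mini_ref)
        assert rec.flip_status == "unresolved"

    def test_multiallelic_site_matches_any_alt(self, mini_ref):
        rec = harmonize_alleles(make_rec(ref="T", alt="G", start=11, end=12),
                                mini_ref)
        assert rec.flip_status == "match"

    def test_idempotence_on_harmonized_record(self, mini_ref):
        rec = harmonize_alleles(
            make_rec(ref="C", alt="T", start=7, end=8, beta=0.5, af=0.3), mini_ref)
        again = harmonize_alleles(rec, mini_ref)
        assert again.flip_status == "match"
        assert (again.ref_allele, again.alt_allele, again.beta) == ("T", "C", -0.5)

    def test_statistic_conservation(self, mini_ref):
        rec = make_rec(ref="C", alt="T", start=7, end=8, beta=-1.25, p=0.007)
        out = harmonize_alleles(rec, mini_ref)
        assert abs(out.beta) == 1.25
        assert out.pvalue == 0.007


class TestAssignRsid:
    def test_present_in_reference(self, mini_ref):
        rec = harmonize_alleles(make_rec(ref="C", alt="G", start=5, end=6), mini_ref)
        assert assign_rsid(rec, mini_ref).rsid == "rs555"

    def test_flipped_record_gets_site_rsid(self, mini_ref):
        rec = harmonize_alleles(make_rec(ref="C", alt="T", start=7, end=8), mini_ref)
        assert assign_rsid(rec, mini_ref).rsid == "rs777"

    def test_genome_fallback_keeps_variant_id(self, mini_ref):
        rec = harmonize_alleles(make_rec(ref="C", alt="A", start=9, end=10), mini_ref)
        rec = assign_rsid(rec, mini_ref)
        assert rec.rsid is None
        assert rec.variant_id == "chr1_10_C_A"


class TestAnnotateTarget:
    def test_plus_strand_downstream_positive(self, mini_genes):
        rec = make_rec(start=1499, end=1500, target="GENEPLUS")
        rec = annotate_target(rec, mini_genes)
        assert (rec.gene_symbol, rec.target_strand) == ("SYMP", "+")
        assert rec.tss_distance == 500  # TSS at 1000, variant at 1500

    def test_minus_strand_sign_convention(self, mini_genes):
        rec = make_rec(start=1499, end=1500, target="GENEMINUS")
        rec = annotate_target(rec, mini_genes)
        assert rec.target_strand == "-"
        assert rec.tss_distance == 500  # TSS at 2000, transcription leftward

    def test_unknown_target(self, mini_genes):
        rec = annotate_target(make_rec(target="NOSUCH"), mini_genes)
        assert rec.gene_symbol == "."
        assert rec.tss_distance is None


class TestComputeFdr:
    def test_uniform_spacing_group(self):
        # brute-force oracle gives 0.04 for every member of this group
        recs = [make_rec(p=p) for p in (0.01, 0.02, 0.03, 0.04)]
        compute_fdr(recs)
        assert [r.fdr for r in recs] == pytest.approx([0.04] * 4)
        assert [r.fdr for r in recs] == pytest.approx(bh_oracle([0.01, 0.02, 0.03, 0.04]))

    def test_single_record_group_identity(self):
        recs = [make_rec(p=0.2)]
        compute_fdr(recs)
        assert recs[0].fdr == pytest.approx(0.2)

    def test_preexisting_fdr_passes_through(self):
        recs = [make_rec(p=0.01, fdr=0.9), make_rec(p=0.02)]
        compute_fdr(recs)
        assert recs[0].fdr == 0.9

    def test_grouping_is_per_target_tissue(self):
        recs = [make_rec(p=0.05, target="A"), make_rec(p=0.05, target="A"),
                make_rec(p=0.05, target="B")]
        compute_fdr(recs)
        assert recs[2].fdr == pytest.approx(0.05)   # singleton group
        assert recs[0].fdr == pytest.approx(0.05)   # ties: p * 2/2

    def test_matches_independent_oracle_on_random_groups(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pvals = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 50))).tolist()
            recs = [make_rec(p=p) for p in pvals]
            compute_fdr(recs)
            expected = bh_oracle(pvals)
            for rec, exp in zip(recs, expected):
                assert abs(rec.fdr - exp) < 1e-12
                assert rec.fdr >= rec.pvalue - 1e-15


class TestSplitOutputs:
    def test_counts_and_empty_tracks(self):
        recs = ([make_rec(fdr=0.01)] * 3 + [make_rec(fdr=0.5)] * 7
                + [make_rec(ref="A", alt="AT", fdr=0.5),
                   make_rec(ref="AT", alt="A", fdr=0.9)])
        split = split_outputs(recs, threshold=0.05)
        sizes = {k: len(v) for k, v in split.items()}
        assert sizes == {("SNP", "full"): 10, ("INDEL", "full"): 2,
                         ("SNP", "significant"): 3, ("INDEL", "significant"): 0}

    def test_boundary_is_strict(self):
        recs = [make_rec(fdr=0.05)]
        split = split_outputs(recs, threshold=0.05)
        assert split[("SNP", "significant")] == []

    def test_threshold_one_keeps_everything(self):
        recs = [make_rec(fdr=p) for p in (0.1, 0.5, 1.0)]
        split = split_outputs(recs, threshold=1.0)
        # fdr == 1.0 is excluded by the strict inequality
        assert len(split[("SNP", "significant")]) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        recs = [make_rec(ref="A", alt="AT" if rng.random() < 0.3 else "G",
                         fdr=float(rng.uniform(0, 1))) for _ in range(100)]
        split = split_outputs(recs)
        full = split[("SNP", "full")] + split[("INDEL", "full")]
        assert sorted(id(r) for r in full) == sorted(id(r) for r in recs)
        for vt in ("SNP", "INDEL"):
            assert set(id(r) for r in split[(vt, "significant")]) <= \
                set(id(r) for r in split[(vt, "full")])
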