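import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haploscan import (
    classify_variant,
    lineage_dnds,
    pairwise_divergence,
    potential_sites,
    simulate_coding_gene,
)
from haploscan.balancing_signature import PartitionSignature
from haploscan.coding_dnds import (
    CdsConsistencyError,
    SENSE_CODONS,
    STOP_CODONS,
    TranscriptCDS,
    revcomp,
)
from haploscan.variant_io import VariantTable

from _oracles import biopython_codon_class


def plus_transcript(cds, start=101, chrom="I", tid="T1", gene="srx-1"):
    return TranscriptCDS(
        transcript_id=tid, gene=gene, chrom=chrom,
        exons=[(start, start + len(cds) - 1)], strand="+", cds=cds,
    )


class TestClassifyVariant:
    def test_third_position_synonymous(self):
        tx = plus_transcript("ATGGGG")
        eff = classify_variant(("I", 106, "G", "A"), tx)  # GGG -> GGA, Gly
        assert eff.classification == "synonymous"
        assert (eff.ref_codon, eff.alt_codon) == ("GGG", "GGA")

    def test_missense(self):
        tx = plus_transcript("ATGGGG")
        # position 103 is CDS offset 2: ATG -> ATT (Met -> Ile)
        eff = classify_variant(("I", 103, "G", "T"), tx)
        assert eff.classification == "nonsynonymous"

    def test_nonsense_counts_as_nonsynonymous(self):
        tx = plus_transcript("ATGTGG")
        eff = classify_variant(("I", 105, "G", "A"), tx)  # TGG -> TAG stop
        assert eff.classification == "nonsynonymous"
        assert eff.alt_codon == "TAG"

    def test_outside_exons_is_noncoding(self):
        tx = plus_transcript("ATGGGG")
        assert classify_variant(("I", 99, "A", "T"), tx).classification == "noncoding"
        assert classify_variant(("X", 103, "A", "T"), tx).classification == "noncoding"

    def test_reference_mismatch_raises(self):
        tx = plus_transcript("ATGGGG")
        with pytest.raises(CdsConsistencyError, match="I:103"):
            classify_variant(("I", 103, "C", "T"), tx)

    def test_minus_strand_alleles_complemented(self):
        # genomic CCCCAT (minus strand) -> CDS ATGGGG
        tx = TranscriptCDS(
            transcript_id="T1", gene="g", chrom="I",
            exons=[(101, 106)], strand="-", cds="ATGGGG",
        )
        # genomic pos 101 'C' is CDS offset 5 base 'G'
        eff = classify_variant(("I", 101, "C", "T"), tx)  # GGG -> GGA
        assert eff.classification == "synonymous"

    def test_agrees_with_biopython_on_all_sense_codon_changes(self):
        """All 549 single-base changes of the 61 sense codons."""
        checked = 0
        for codon in SENSE_CODONS:
            cds = "ATG" + codon + "GGG"
            tx = plus_transcript(cds)
            for within, alt in itertools.product(range(3), "ACGT"):
                if alt == codon[within]:
                    continue
                eff = classify_variant(("I", 101 + 3 + within, codon[within], alt), tx)
                mutant = codon[:within] + alt + codon[within + 1:]
                assert eff.classification == biopython_codon_class(codon, mutant)
                checked += 1
        assert checked == 549


class TestPotentialSites:
    def test_ttt_enumeration(self):
        """Of TTT's nine changes only TTT->TTC is synonymous; none hit stops."""
        n, s = potential_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_fourfold_site(self):
        n, s = potential_sites("GGG")
        assert s >= 1.0  # third position fully synonymous

    def test_internal_stop_rejected_unless_permissive(self):
        with pytest.raises(ValueError, match="internal stop"):
            potential_sites("TAAGGG")
        n, s = potential_sites("TAAGGG", permissive=True)
        assert n + s > 0

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_conservation_with_stop_exclusions(self, codons):
        """N + S + stop-excluded fractional sites = 3 x codon count exactly."""
        cds = "".join(codons)
        n, s = potential_sites(cds)
        excluded = 0.0
        for ci in range(len(codons)):
            codon = cds[3 * ci: 3 * ci + 3]
            for within, b in itertools.product(range(3), "ACGT"):
                if b != codon[within]:
                    mutant = codon[:within] + b + codon[within + 1:]
                    if mutant in STOP_CODONS:
                        excluded += 1 / 3
        assert n + s + excluded == pytest.approx(3 * len(codons), abs=1e-9)


class TestLineageDnds:
    def test_planted_counts_recovered_exactly(self):
        tx, table, truth = simulate_coding_gene(5, 20, n_codons=300, seed=1)
        sig = PartitionSignature(
            gene=tx.gene, n_snps=25,
            best_partition=truth["lineage_split"], support=25, shared_fraction=1.0,
        )
        res = lineage_dnds(sig, table, tx)
        assert (res.n_obs, res.s_obs) == (5, 20)
        n_sites, s_sites = potential_sites(tx.cds)
        assert res.ratio == pytest.approx((5 / n_sites) / (20 / s_sites))

    def test_analytic_ratio_example(self):
        """dN = 5/600, dS = 20/200 gives a ratio near 0.0833."""
        from haploscan.coding_dnds import DnDsResult

        res = DnDsResult(gene="g", n_obs=5, s_obs=20, n_sites=600.0, s_sites=200.0)
        assert res.dn == pytest.approx(0.008333, abs=1e-6)
        assert res.ds == pytest.approx(0.100, abs=1e-9)
        assert res.ratio == pytest.approx(0.0833, abs=5e-4)

    def test_no_substitutions_gives_undefined_ratio(self):
        tx, table, truth = simulate_coding_gene(0, 0, n_codons=50, seed=2)
        sig = PartitionSignature(
            gene=tx.gene, n_snps=0,
            best_partition=((0, 1, 2, 3, 4, 5, 6, 7), tuple(range(8, 16))),
            support=0, shared_fraction=math.nan,
        )
        res = lineage_dnds(sig, table, tx)
        assert (res.n_obs, res.s_obs) == (0, 0)
        assert math.isnan(res.ratio)

    def test_only_partition_supporting_snps_counted(self):
        """A SNP off the best partition does not enter the counts."""
        tx, table, truth = simulate_coding_gene(2, 3, n_codons=100, seed=3)
        # append a singleton SNP inside the CDS at an unused offset
        used = {pos for _, pos, _, _ in
                ((0, p, 0, 0) for p in table.pos)}
        offset = next(o for o in range(len(tx.cds)) if 1001 + o not in set(table.pos))
        row = np.zeros(16, dtype=np.int8)
        row[0] = 1
        records = list(
            zip(table.chrom, (int(p) for p in table.pos), table.ref, table.alt,
                table.genotypes)
        )
        records.append(("I", 1001 + offset, tx.cds[offset],
                        "A" if tx.cds[offset] != "A" else "G", row))
        bigger = VariantTable.from_records(table.strain_ids, records)
        sig = PartitionSignature(
            gene=tx.gene, n_snps=6, best_partition=truth["lineage_split"],
            support=5, shared_fraction=5 / 6,
        )
        res = lineage_dnds(sig, bigger, tx)
        assert (res.n_obs, res.s_obs) == (2, 3)

    def test_recovery_over_random_plants(self):
        """Planted (n, s) in [0..6]x[0..15] come back exactly."""
        rng = np.random.default_rng(9)
        for seed in range(25):
            n_plant = int(rng.integers(0, 7))
            s_plant = int(rng.integers(0, 16))
            tx, table, truth = simulate_coding_gene(
                n_plant, s_plant, n_codons=200, seed=seed
            )
            sig = PartitionSignature(
                gene=tx.gene, n_snps=n_plant + s_plant,
                best_partition=truth["lineage_split"],
                support=n_plant + s_plant, shared_fraction=1.0,
            )
            res = lineage_dnds(sig, table, tx)
            assert (res.n_obs, res.s_obs) == (n_plant, s_plant)

    def test_strand_reversal_preserves_classification(self):
        """Reverse-complementing transcript and variants changes nothing."""
        tx, table, truth = simulate_coding_gene(4, 7, n_codons=120, seed=5)
        start, end = tx.exons[0]
        flipped_tx = TranscriptCDS(
            transcript_id=tx.transcript_id, gene=tx.gene, chrom=tx.chrom,
            exons=tx.exons, strand="-", cds=tx.cds,
        )
        records = []
        for chrom, pos, ref, alt, row in zip(
            table.chrom, table.pos, table.ref, table.alt, table.genotypes
        ):
            # mirror the genomic coordinate and complement the alleles
            new_pos = start + (end - int(pos))
            records.append(
                (str(chrom), new_pos, revcomp(str(ref)), revcomp(str(alt)), row)
            )
        flipped_table = VariantTable.from_records(table.strain_ids, records)
        sig = PartitionSignature(
            gene=tx.gene, n_snps=11, best_partition=truth["lineage_split"],
            support=11, shared_fraction=1.0,
        )
        plus = lineage_dnds(sig, table, tx)
        minus = lineage_dnds(sig, flipped_table, flipped_tx)
        assert (plus.n_obs, plus.s_obs) == (minus.n_obs, minus.s_obs)


class TestPairwiseDivergence:
    def test_planted_mismatches(self):
        assert pairwise_divergence("ACGTACGTAC", "ACGAACGTTC") == (2, 10, 0.2)

    def test_identical_sequences(self):
        assert pairwise_divergence("ACGT", "ACGT") == (0, 4, 0.0)

    def test_promoter_scale_example(self):
        """35 mismatches over 515 aligned bases is a 6.8% divergence."""
        rng = np.random.default_rng(12)
        a = "".join(rng.choice(list("ACGT"), size=515))
        idx = rng.choice(515, size=35, replace=False)
        b = list(a)
        for i in idx:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        diff, length, frac = pairwise_divergence(a, "".join(b))
        assert (diff, length) == (35, 515)
        assert frac == pytest.approx(35 / 515, abs=1e-9)

    def test_gaps_excluded_from_both_counts(self):
        diff, length, frac = pairwise_divergence("AC-T", "ACG-")
        assert (diff, length) == (0, 2)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_divergence("ACG", "AC")
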