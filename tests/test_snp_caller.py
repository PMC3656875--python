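import numpy as np
import pytest

from gbskit.demux_tagger import Tag, TagCountMatrix
from gbskit.snp_caller import (
    MISSING,
    AlignedTag,
    FilterConfig,
    SNPTable,
    anchor_tags,
    anchor_tags_from_sam,
    discover_and_genotype,
    exclude_samples,
    filter_sites,
    group_loci,
    select_unlinked,
    site_statistics,
)


def pad(seq, n=64):
    return seq.ljust(n, ".")


def make_matrix(rows, samples):
    """rows: {tag sequence: [counts per sample]} (auto-padded to 64)."""
    tags, counts = [], []
    for seq in sorted(pad(s) for s in rows):
        eff = len(seq.rstrip("."))
        tags.append(Tag(sequence=seq, effective_length=eff))
        counts.append(rows[seq[:eff]] if seq[:eff] in rows else rows[seq])
    return TagCountMatrix(tags=tags, samples=samples, counts=np.array(counts))


class TestAnchorTags:
    def test_unique_forward_anchor(self, pstI, rng):
        left = "".join(rng.choice(list("ACGT"), 1000))
        right = "".join(rng.choice(list("ACGT"), 1000))
        genome = {"chr1": left + "CTGCAG" + right}
        cut = 1001  # site start 1000 + cut offset 1
        tagseq = genome["chr1"][cut : cut + 64]
        matrix = make_matrix({tagseq: [3]}, ["s1"])
        aligned = anchor_tags(matrix.tags, genome, pstI)
        assert len(aligned) == 1
        at = aligned[0]
        assert (at.chrom, at.pos, at.strand, at.unique) == ("chr1", cut, "+", True)

    def test_duplicated_tag_nonunique(self, pstI, rng):
        block = "".join(rng.choice(list("ACGT"), 300))
        genome = {"chr1": block + "CTGCAG" + block + "TT" + "CTGCAG" + block}
        cut = len(block) + 1
        tagseq = genome["chr1"][cut : cut + 64]
        matrix = make_matrix({tagseq: [3]}, ["s1"])
        aligned = anchor_tags(matrix.tags, genome, pstI)
        assert len(aligned) == 1
        assert not aligned[0].unique
        assert group_loci(aligned) == []

    def test_reverse_anchor(self, pstI, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000)) + "CTGCAG" + "".join(
            rng.choice(list("ACGT"), 200)
        )
        genome = {"chr1": seq}
        from gbskit.restriction_digest import reverse_complement

        rev_cut = 2000 + 5  # site start + len(recognition) - cut_offset
        tagseq = reverse_complement(seq[rev_cut - 64 : rev_cut])
        matrix = make_matrix({tagseq: [2]}, ["s1"])
        aligned = anchor_tags(matrix.tags, genome, pstI)
        assert len(aligned) == 1
        assert (aligned[0].pos, aligned[0].strand) == (rev_cut, "-")

    def test_simulated_tags_anchor_to_emitting_fragment(
        self, small_sim, small_sim_called
    ):
        matrix, _, aligned = small_sim_called
        starts = {f.start for f in small_sim.retained}
        anchored = [a for a in aligned if a.unique]
        assert len(anchored) / matrix.n_tags > 0.99
        ok = sum(a.pos in starts for a in anchored)
        assert ok / len(anchored) > 0.99

    def test_sam_round_trip(self, tmp_path, pstI, rng):
        left = "".join(rng.choice(list("ACGT"), 500))
        genome = {"chr1": left + "CTGCAG" + "".join(rng.choice(list("ACGT"), 500))}
        cut = 501
        tagseq = genome["chr1"][cut : cut + 64]
        matrix = make_matrix({tagseq: [1]}, ["s1"])
        sam = tmp_path / "tags.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:chr1\tLN:1006\n"
            f"tag0000000\t0\tchr1\t{cut + 1}\t60\t64M\t*\t0\t0\t{tagseq}\t*\tNM:i:0\n"
        )
        aligned = anchor_tags_from_sam(matrix.tags, sam, genome)
        assert len(aligned) == 1
        at = aligned[0]
        assert (at.chrom, at.pos, at.strand, at.unique) == ("chr1", cut, "+", True)
        assert at.ref_seq == tagseq


def toy_locus(n_het=4, n_samples=10, depth=5):
    """One locus, SNP at offset 1: tags AC... vs AG...; n_het samples carry
    both alleles, the rest only the reference tag."""
    base = "A" + "C" + "T" * 62
    alt = "A" + "G" + "T" * 62
    samples = [f"s{i}" for i in range(n_samples)]
    ref_counts = [depth] * n_samples
    alt_counts = [depth if i < n_het else 0 for i in range(n_samples)]
    matrix = make_matrix({base: ref_counts, alt: alt_counts}, samples)
    ref_seq = base  # reference carries the C allele
    aligned = [
        AlignedTag(i, "chr1", 1000, "+", True, 0, ref_seq=ref_seq)
        for i in range(matrix.n_tags)
    ]
    return matrix, aligned, samples


class TestDiscoverAndGenotype:
    def test_toy_locus_maf_and_genotypes(self):
        matrix, aligned, samples = toy_locus(n_het=4)
        table = discover_and_genotype(matrix, aligned, min_minor_individuals=3)
        assert table.n_sites == 1
        assert table.pos[0] == 1001
        assert (table.ref[0], table.alt[0]) == ("C", "G")
        assert (table.gt[0] == 1).sum() == 4
        assert (table.gt[0] == 0).sum() == 6
        assert table.maf[0] == pytest.approx(4 / 20)  # 4 het among 10 diploids
        assert not table.tightly_linked[0]

    def test_monomorphic_locus_no_snps(self):
        matrix = make_matrix({"A" + "T" * 63: [3, 3]}, ["s1", "s2"])
        aligned = [AlignedTag(0, "chr1", 0, "+", True, 0, ref_seq="A" + "T" * 63)]
        table = discover_and_genotype(matrix, aligned, min_minor_individuals=1)
        assert table.n_sites == 0

    def test_triallelic_discarded(self):
        seqs = {"AC" + "T" * 62: [5, 0, 0], "AG" + "T" * 62: [0, 5, 0],
                "AT" + "T" * 62: [0, 0, 5]}
        matrix = make_matrix(seqs, ["s1", "s2", "s3"])
        aligned = [
            AlignedTag(i, "chr1", 0, "+", True, 0, ref_seq="AC" + "T" * 62)
            for i in range(3)
        ]
        table = discover_and_genotype(matrix, aligned, min_minor_individuals=1)
        assert table.n_sites == 0

    def test_min_minor_individuals(self):
        matrix, aligned, _ = toy_locus(n_het=2)
        assert discover_and_genotype(matrix, aligned, 3).n_sites == 0
        assert discover_and_genotype(matrix, aligned, 2).n_sites == 1

    def test_missing_when_uncovered(self):
        base = "A" + "C" + "T" * 62
        alt = "A" + "G" + "T" * 62
        matrix = make_matrix({base: [5, 0, 5, 5], alt: [5, 0, 5, 0]},
                             ["s1", "s2", "s3", "s4"])
        aligned = [AlignedTag(i, "chr1", 0, "+", True, 0, ref_seq=base)
                   for i in range(2)]
        table = discover_and_genotype(matrix, aligned, min_minor_individuals=2)
        assert table.gt[0].tolist() == [1, MISSING, 1, 0]
        assert table.call_rate[0] == pytest.approx(0.75)

    def test_doubling_counts_invariant(self):
        matrix, aligned, _ = toy_locus(n_het=4)
        t1 = discover_and_genotype(matrix, aligned, 3)
        doubled = TagCountMatrix(matrix.tags, matrix.samples, matrix.counts * 2)
        t2 = discover_and_genotype(doubled, aligned, 3)
        assert np.array_equal(t1.gt, t2.gt)
        assert t1.maf.tolist() == t2.maf.tolist()

    def test_tightly_linked_flag(self):
        # two SNPs inside one tag span
        base = "ACT" + "T" * 61
        alt = "AGT" + "A" * 1 + "T" * 60  # differs at offsets 1 and 3
        matrix = make_matrix({base: [5] * 8, alt: [5] * 4 + [0] * 4},
                             [f"s{i}" for i in range(8)])
        aligned = [AlignedTag(i, "chr1", 0, "+", True, 0, ref_seq=base)
                   for i in range(2)]
        table = discover_and_genotype(matrix, aligned, min_minor_individuals=3)
        assert table.n_sites == 2
        assert table.tightly_linked.all()
        one = select_unlinked(table)
        assert one.n_sites == 1
        assert one.pos[0] == min(table.pos)  # call-rate tie -> lower coord

    def test_deep_simulated_concordance(self, small_sim, small_sim_called, key48):
        matrix, _, aligned = small_sim_called
        table = discover_and_genotype(matrix, aligned, samples=key48.dna_samples)
        truth = small_sim.truth
        tidx = truth.site_index()
        sidx = {s: i for i, s in enumerate(truth.samples)}
        keys = dict(zip(table.site_keys(), range(table.n_sites)))
        het_n = het_ok = 0
        for (c, p), i in keys.items():
            j = tidx.get((c, p))
            if j is None or table.ref[i] != truth.sites[j].ref:
                continue
            for k, s in enumerate(table.samples):
                if truth.genotypes[sidx[s], j] == 1 and table.gt[i, k] != MISSING:
                    het_n += 1
                    het_ok += table.gt[i, k] == 1
        assert het_n > 500
        assert het_ok / het_n >= 0.98


class TestSiteStatistics:
    def test_closed_form_example(self):
        # 10 samples: 2 het, 8 hom-major -> MAF .1, Ho .2, He .18, F = -1/9
        gt = np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]], dtype=np.int8)
        table = _table_from_gt(gt)
        assert table.maf[0] == pytest.approx(0.1)
        assert table.ho[0] == pytest.approx(0.2)
        assert table.he[0] == pytest.approx(0.18)
        assert table.f[0] == pytest.approx(1 - 0.2 / 0.18)

    def test_all_het_paralog_signature(self):
        gt = np.ones((1, 10), dtype=np.int8)
        table = _table_from_gt(gt)
        assert table.f[0] == pytest.approx(-1.0)

    def test_monomorphic_f_undefined(self):
        gt = np.zeros((1, 10), dtype=np.int8)
        table = _table_from_gt(gt)
        assert table.maf[0] == 0
        assert np.isnan(table.f[0])

    def test_call_rate_with_missing(self):
        gt = np.array([[0, 1, MISSING, MISSING, 2]], dtype=np.int8)
        table = _table_from_gt(gt)
        assert table.call_rate[0] == pytest.approx(0.6)


def _table_from_gt(gt):
    n_sites, n_samples = gt.shape
    return site_statistics(
        SNPTable(
            samples=[f"s{i}" for i in range(n_samples)],
            chrom=["chr1"] * n_sites,
            pos=np.arange(n_sites, dtype=np.int64) * 100,
            ref=["A"] * n_sites,
            alt=["C"] * n_sites,
            offset=np.zeros(n_sites, dtype=np.int64),
            strand=["+"] * n_sites,
            locus_id=np.arange(n_sites, dtype=np.int64),
            tightly_linked=np.zeros(n_sites, dtype=bool),
            gt=gt,
            ad_ref=np.where(gt >= 0, 5, 0).astype(np.int32),
            ad_alt=np.where(gt >= 1, 5, 0).astype(np.int32),
        )
    )


class TestFilterCascade:
    def test_call_rate_filter(self):
        gt = np.full((1, 20), MISSING, dtype=np.int8)
        gt[0, :13] = [0] * 7 + [1] * 6  # call rate 0.65
        table = _table_from_gt(gt)
        kept, ledger = filter_sites(table, FilterConfig(mnF=-10))
        assert kept.n_sites == 0
        assert ledger["call_rate"] == 1

    def test_f_filter_removes_all_het(self):
        gt = np.ones((1, 12), dtype=np.int8)
        kept, ledger = filter_sites(_table_from_gt(gt), FilterConfig())
        assert kept.n_sites == 0
        assert ledger["f"] == 1

    def test_thresholds_zero_identity(self):
        gt = np.array(
            [[1, 1, 1, 0, 0, 0, 2, 2, 0, 0], [1, 0, 0, 0, 0, 0, 0, 0, 0, 2]],
            dtype=np.int8,
        )
        table = _table_from_gt(gt)
        cfg = FilterConfig(mnMAF=0, mnF=-np.inf, min_minor_individuals=0,
                           min_site_call_rate=0)
        kept, _ = filter_sites(table, cfg)
        assert kept.n_sites == table.n_sites

    def test_monotone_in_thresholds(self, rng):
        gt = rng.integers(-1, 3, size=(120, 30)).astype(np.int8)
        table = _table_from_gt(gt)
        prev = table.n_sites + 1
        for maf in (0.0, 0.05, 0.1, 0.2, 0.3):
            kept, _ = filter_sites(
                table, FilterConfig(mnMAF=maf, mnF=-np.inf,
                                    min_minor_individuals=0,
                                    min_site_call_rate=0)
            )
            assert kept.n_sites <= prev
            prev = kept.n_sites

    def test_ledger_counts_every_failed_filter(self):
        gt = np.ones((1, 12), dtype=np.int8)  # fails F only
        gt2 = np.full((1, 12), MISSING, dtype=np.int8)
        gt2[0, 0] = 0  # fails maf, minor, call rate
        table = _table_from_gt(np.vstack([gt, gt2]))
        _, ledger = filter_sites(table, FilterConfig())
        assert ledger["input"] == 2 and ledger["kept"] == 0
        assert ledger["f"] >= 1 and ledger["call_rate"] == 1
        assert ledger["maf"] == 1

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(min_site_call_rate=1.5)


class TestExcludeSamples:
    def test_low_coverage_sample_excluded(self):
        gt = np.zeros((10, 4), dtype=np.int8)
        gt[:7, 3] = MISSING  # sample 3 covers 30%
        table = _table_from_gt(gt)
        out, report = exclude_samples(table, 0.5)
        assert report.excluded == ["s3"]
        assert out.samples == ["s0", "s1", "s2"]
        assert report.call_rates["s3"] == pytest.approx(0.3)

    def test_threshold_zero_keeps_all(self):
        gt = np.zeros((5, 3), dtype=np.int8)
        out, report = exclude_samples(_table_from_gt(gt), 0.0)
        assert report.excluded == []
        assert out.n_samples == 3

    def test_simulated_low_depth_sample_excluded(self, key48, pstI):
        from gbskit.demux_tagger import demultiplex_and_count
        from gbskit.gbs_simulator import SimSpec, simulate_experiment

        spec = SimSpec(
            chrom_sizes={"chr1": 600_000}, mean_site_spacing=2600,
            size_window=(600, 1100), n_sites=60, fst=0.2, inbreeding=0.2,
            maf_range=(0.25, 0.5), mean_reads_per_sample=2500, cv_reads=0.2,
            depth_multipliers={"Muturu01": 0.008},
        )
        sim = simulate_experiment(spec, key48, seed=31)
        matrix, _ = demultiplex_and_count(sim.records, key48, pstI)
        aligned = anchor_tags(matrix.tags, sim.genome, pstI)
        table = discover_and_genotype(matrix, aligned, samples=key48.dna_samples)
        _, report = exclude_samples(table, 0.5)
        assert "Muturu01" in report.excluded
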