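"""Tag anchoring, SNP discovery/genotyping and the filter cascade.

Tags are anchored to reference cut positions either with the built-in
exact/1-mismatch seed matcher (meant for synthetic genomes) or from a SAM
file produced by any external aligner.  Unique anchored tags sharing a cut
position form a locus; aligned tag sequences are compared position-wise to
find biallelic sites, samples are genotyped by allele presence/absence (the
behaviour implied by very low mean tag depth), and sites then pass through
the MAF / inbreeding-F / minor-individuals / call-rate cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .demux_tagger import PAD, Tag, TagCountMatrix
from .restriction_digest import (
    RestrictionEnzyme,
    find_sites,
    reverse_complement,
)

__all__ = [
    "AlignedTag",
    "Locus",
    "SNPTable",
    "FilterConfig",
    "ReferenceAnchorIndex",
    "anchor_tags",
    "anchor_tags_from_sam",
    "group_loci",
    "discover_and_genotype",
    "site_statistics",
    "filter_sites",
    "exclude_samples",
    "select_unlinked",
]

MISSING = -1
_SEED_LEN = 16


@dataclass
class AlignedTag:
    """A tag anchored to a reference cut position.

    ``pos`` is the 0-based cut coordinate: the first base of the tag for a
    forward anchor, one past the last covered base for a reverse anchor.
    Non-unique tags are retained (for depth profiling) but never genotyped.
    """

    tag_index: int
    chrom: str
    pos: int
    strand: str
    unique: bool
    mismatches: int
    ref_seq: str | None = None


@dataclass
class Locus:
    """Tags sharing one (chrom, cut position, strand) anchor."""

    chrom: str
    pos: int
    strand: str
    members: list[AlignedTag]


class ReferenceAnchorIndex:
    """Seeded lookup of candidate cut-site anchors in a reference genome.

    Anchors are enumerated at every recognition site on both strands; each
    reference tag is indexed by four 16-nt seeds so a query within one
    mismatch of the reference is guaranteed to hit at least one seed exactly.
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        enzyme: RestrictionEnzyme,
        tag_length: int = 64,
    ):
        self.tag_length = tag_length
        self.anchors: list[tuple[str, int, str, str]] = []  # chrom,pos,strand,seq
        self._seeds: dict[tuple[int, str], list[int]] = {}
        rl = len(enzyme.recognition)
        for chrom in sorted(genome):
            seq = genome[chrom].upper()
            for s in find_sites(seq, enzyme):
                fwd_cut = s + enzyme.cut_offset
                fwd = seq[fwd_cut : fwd_cut + tag_length]
                if len(fwd) >= _SEED_LEN:
                    self._add(chrom, fwd_cut, "+", fwd)
                rev_cut = s + rl - enzyme.cut_offset
                rev = reverse_complement(seq[max(0, rev_cut - tag_length) : rev_cut])
                if len(rev) >= _SEED_LEN:
                    self._add(chrom, rev_cut, "-", rev)

    def _add(self, chrom: str, pos: int, strand: str, seq: str) -> None:
        idx = len(self.anchors)
        self.anchors.append((chrom, pos, strand, seq))
        for slot in range(4):
            start = slot * _SEED_LEN
            seed = seq[start : start + _SEED_LEN]
            if len(seed) == _SEED_LEN:
                self._seeds.setdefault((slot, seed), []).append(idx)

    def lookup(self, seq: str, max_mismatch: int = 3) -> list[tuple[int, int]]:
        """Return [(anchor index, mismatches)] for matches within tolerance,
        comparing over the query's length."""
        candidates: set[int] = set()
        for slot in range(4):
            start = slot * _SEED_LEN
            seed = seq[start : start + _SEED_LEN]
            if len(seed) == _SEED_LEN:
                candidates.update(self._seeds.get((slot, seed), ()))
        hits = []
        for idx in candidates:
            ref = self.anchors[idx][3]
            if len(ref) < len(seq):
                continue
            mm = sum(a != b for a, b in zip(seq, ref))
            if mm <= max_mismatch:
                hits.append((idx, mm))
        return sorted(hits, key=lambda t: (t[1], t[0]))


def anchor_tags(
    tags: Sequence[Tag],
    reference: Mapping[str, str] | None = None,
    enzyme: RestrictionEnzyme | None = None,
    index: ReferenceAnchorIndex | None = None,
    max_mismatch: int = 3,
) -> list[AlignedTag]:
    """Anchor tags with the built-in matcher.

    Tags matching more than one anchor are flagged non-unique (excluded from
    calling, kept for depth profiling); tags matching nothing are dropped.
    """
    if index is None:
        if reference is None or enzyme is None:
            raise ValueError("need a reference+enzyme or a prebuilt index")
        index = ReferenceAnchorIndex(reference, enzyme)
    out: list[AlignedTag] = []
    for i, tag in enumerate(tags):
        core = tag.sequence[: tag.effective_length]
        hits = index.lookup(core, max_mismatch=max_mismatch)
        if not hits:
            continue
        positions = {index.anchors[idx][:3] for idx, _ in hits}
        idx, mm = hits[0]
        chrom, pos, strand, ref_seq = index.anchors[idx]
        out.append(
            AlignedTag(
                tag_index=i,
                chrom=chrom,
                pos=pos,
                strand=strand,
                unique=len(positions) == 1,
                mismatches=mm,
                ref_seq=ref_seq,
            )
        )
    return out


def anchor_tags_from_sam(
    tags: Sequence[Tag],
    sam_path,
    reference: Mapping[str, str] | None = None,
) -> list[AlignedTag]:
    """Anchor tags from a SAM file of tag alignments.

    Read names must be ``tag<index>`` as written by
    :meth:`TagCountMatrix.to_fasta`.  Reverse-strand alignments are
    re-oriented so the stored anchor is the cut position on the reference.
    Secondary/supplementary records or repeated names mark a tag non-unique.
    """
    import pysam

    primary: dict[int, AlignedTag] = {}
    multi: set[int] = set()
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            name = rec.query_name or ""
            if not name.startswith("tag"):
                import warnings

                warnings.warn(f"SAM record {name!r} matches no tag")
                continue
            idx = int(name[3:])
            if idx >= len(tags):
                import warnings

                warnings.warn(f"SAM record {name!r} matches no tag")
                continue
            if rec.is_secondary or rec.is_supplementary or idx in primary:
                multi.add(idx)
                if rec.is_secondary or rec.is_supplementary:
                    continue
            if rec.is_reverse:
                strand, pos = "-", rec.reference_end
                core = reverse_complement(rec.query_sequence or "")
            else:
                strand, pos = "+", rec.reference_start
                core = rec.query_sequence or ""
            ref_seq = None
            if reference is not None:
                chrom_seq = reference.get(rec.reference_name, "")
                if strand == "+":
                    ref_seq = chrom_seq[pos : pos + len(core)]
                else:
                    ref_seq = reverse_complement(chrom_seq[max(0, pos - len(core)) : pos])
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            primary[idx] = AlignedTag(
                tag_index=idx,
                chrom=rec.reference_name,
                pos=int(pos),
                strand=strand,
                unique=rec.mapping_quality > 0,
                mismatches=int(mm),
                ref_seq=ref_seq,
            )
    out = []
    for idx, at in sorted(primary.items()):
        if idx in multi:
            at = replace(at, unique=False)
        out.append(at)
    return out


def group_loci(aligned: Iterable[AlignedTag]) -> list[Locus]:
    """Group unique anchored tags into loci by shared anchor."""
    groups: dict[tuple[str, int, str], list[AlignedTag]] = {}
    for at in aligned:
        if at.unique:
            groups.setdefault((at.chrom, at.pos, at.strand), []).append(at)
    return [
        Locus(chrom=c, pos=p, strand=s, members=m)
        for (c, p, s), m in sorted(groups.items())
    ]


@dataclass
class FilterConfig:
    """Thresholds for the site filter cascade and sample exclusion."""

    mnMAF: float = 0.05
    mnF: float = 0.05
    min_minor_individuals: int = 3
    min_site_call_rate: float = 0.70
    high_confidence_call_rate: float = 0.90
    min_individual_call_rate: float = 0.50

    def __post_init__(self) -> None:
        for name in (
            "mnMAF",
            "min_site_call_rate",
            "high_confidence_call_rate",
            "min_individual_call_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SNPTable:
    """Discovered biallelic sites with per-sample calls, depths and per-site
    statistics.  Positions are 0-based internally (1-based in VCF output)."""

    samples: list[str]
    chrom: list[str]
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    offset: np.ndarray
    strand: list[str]
    locus_id: np.ndarray
    tightly_linked: np.ndarray
    gt: np.ndarray  # (n_sites, n_samples) int8: 0 hom-ref, 1 het, 2 hom-alt, -1 missing
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    ho: np.ndarray = field(default=None)  # type: ignore[assignment]
    he: np.ndarray = field(default=None)  # type: ignore[assignment]
    f: np.ndarray = field(default=None)  # type: ignore[assignment]
    call_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_sites
        for name in ("maf", "ho", "he", "f", "call_rate"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, mask_or_index) -> "SNPTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SNPTable(
            samples=list(self.samples),
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            offset=self.offset[idx],
            strand=[self.strand[i] for i in idx],
            locus_id=self.locus_id[idx],
            tightly_linked=self.tightly_linked[idx],
            gt=self.gt[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            maf=self.maf[idx],
            ho=self.ho[idx],
            he=self.he[idx],
            f=self.f[idx],
            call_rate=self.call_rate[idx],
        )

    def drop_samples(self, drop: Sequence[str]) -> "SNPTable":
        keep = [i for i, s in enumerate(self.samples) if s not in set(drop)]
        return SNPTable(
            samples=[self.samples[i] for i in keep],
            chrom=list(self.chrom),
            pos=self.pos.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            offset=self.offset.copy(),
            strand=list(self.strand),
            locus_id=self.locus_id.copy(),
            tightly_linked=self.tightly_linked.copy(),
            gt=self.gt[:, keep],
            ad_ref=self.ad_ref[:, keep],
            ad_alt=self.ad_alt[:, keep],
        )

    def sample_call_rates(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.gt != MISSING).mean(axis=0)

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom, (int(p) for p in self.pos)))


def _empty_table(samples: list[str]) -> SNPTable:
    z = np.zeros(0, dtype=np.int64)
    return SNPTable(
        samples=list(samples),
        chrom=[],
        pos=z,
        ref=[],
        alt=[],
        offset=z.copy(),
        strand=[],
        locus_id=z.copy(),
        tightly_linked=np.zeros(0, dtype=bool),
        gt=np.zeros((0, len(samples)), dtype=np.int8),
        ad_ref=np.zeros((0, len(samples)), dtype=np.int32),
        ad_alt=np.zeros((0, len(samples)), dtype=np.int32),
    )


def discover_and_genotype(
    matrix: TagCountMatrix,
    aligned: Sequence[AlignedTag],
    min_minor_individuals: int = 3,
    min_allele_individuals: int | None = None,
    samples: Sequence[str] | None = None,
) -> SNPTable:
    """Discover biallelic SNPs within loci and genotype every sample.

    Within a locus, member tag sequences are compared position-wise over
    their effective spans (pad and N ignored).  To be counted as observed,
    an allele must be carried by at least ``min_allele_individuals`` samples
    (defaults to ``min_minor_individuals``), which suppresses spurious
    third alleles from sequencing errors; positions with more than two
    observed alleles are discarded.  A sample is hom if only one allele's
    tags are seen, het if both, missing if none.
    """
    if min_allele_individuals is None:
        min_allele_individuals = min_minor_individuals
    if samples is None:
        samples = matrix.samples
    sample_idx = [matrix.samples.index(s) for s in samples]
    loci = group_loci(aligned)

    recs: list[dict] = []
    for locus_id, locus in enumerate(loci):
        members = locus.members
        seqs = [matrix.tags[at.tag_index].sequence for at in members]
        effs = np.array(
            [matrix.tags[at.tag_index].effective_length for at in members]
        )
        counts = matrix.counts[[at.tag_index for at in members]][:, sample_idx]
        ref_seq = next((at.ref_seq for at in members if at.ref_seq), None)
        width = int(effs.max())
        arr = np.frombuffer(
            "".join(s[:width].ljust(width, PAD) for s in seqs).encode(), dtype="S1"
        ).reshape(len(members), width)

        locus_sites: list[dict] = []
        for p in range(width):
            col = arr[:, p]
            valid = (effs > p) & (col != b".") & (col != b"N")
            if not valid.any():
                continue
            bases = sorted(set(col[valid]))
            if len(bases) < 2:
                continue
            # per-allele sample depths and carrier counts
            depth_by_base = {}
            carriers_by_base = {}
            for b in bases:
                rows = valid & (col == b)
                d = counts[rows].sum(axis=0)
                depth_by_base[b] = d
                carriers_by_base[b] = int((d > 0).sum())
            observed = [
                b for b in bases if carriers_by_base[b] >= min_allele_individuals
            ]
            if len(observed) != 2:
                continue  # monomorphic after support threshold, or >2 alleles
            b1, b2 = observed
            if ref_seq is not None and p < len(ref_seq):
                ref_base = ref_seq[p].encode()
            else:
                # no reference available: call the deeper allele "ref"
                ref_base = max(
                    observed, key=lambda b: int(depth_by_base[b].sum())
                )
            if ref_base == b1:
                rb, ab = b1, b2
            elif ref_base == b2:
                rb, ab = b2, b1
            else:
                continue  # neither allele matches the reference base
            dr = depth_by_base[rb].astype(np.int32)
            da = depth_by_base[ab].astype(np.int32)
            gt = np.full(len(samples), MISSING, dtype=np.int8)
            gt[(dr > 0) & (da == 0)] = 0
            gt[(dr > 0) & (da > 0)] = 1
            gt[(dr == 0) & (da > 0)] = 2
            # minor allele = fewer carrying individuals (ties: fewer copies)
            n_rb, n_ab = carriers_by_base[rb], carriers_by_base[ab]
            minor_individuals = min(n_rb, n_ab)
            if minor_individuals < min_minor_individuals:
                continue
            if locus.strand == "+":
                gpos = locus.pos + p
                ref_a, alt_a = rb.decode(), ab.decode()
            else:
                gpos = locus.pos - 1 - p
                ref_a = reverse_complement(rb.decode())
                alt_a = reverse_complement(ab.decode())
            locus_sites.append(
                dict(
                    chrom=locus.chrom,
                    pos=gpos,
                    ref=ref_a,
                    alt=alt_a,
                    offset=p,
                    strand=locus.strand,
                    locus_id=locus_id,
                    gt=gt,
                    ad_ref=dr,
                    ad_alt=da,
                )
            )
        linked = len(locus_sites) > 1
        for rec in locus_sites:
            rec["tightly_linked"] = linked
        recs.extend(locus_sites)

    if not recs:
        return _empty_table(list(samples))
    recs.sort(key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]))
    table = SNPTable(
        samples=list(samples),
        chrom=[r["chrom"] for r in recs],
        pos=np.array([r["pos"] for r in recs], dtype=np.int64),
        ref=[r["ref"] for r in recs],
        alt=[r["alt"] for r in recs],
        offset=np.array([r["offset"] for r in recs], dtype=np.int64),
        strand=[r["strand"] for r in recs],
        locus_id=np.array([r["locus_id"] for r in recs], dtype=np.int64),
        tightly_linked=np.array([r["tightly_linked"] for r in recs], dtype=bool),
        gt=np.stack([r["gt"] for r in recs]),
        ad_ref=np.stack([r["ad_ref"] for r in recs]),
        ad_alt=np.stack([r["ad_alt"] for r in recs]),
    )
    return site_statistics(table)


def site_statistics(table: SNPTable) -> SNPTable:
    """Fill per-site MAF, Ho, He, F and call rate (over non-missing calls).

    MAF = minor-allele count / (2 x called diploids); Ho = het fraction among
    called; He = 2p(1-p); F = 1 - Ho/He where He > 0, else NaN.
    """
    gt = table.gt
    called = gt != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_count = np.where(called, gt, 0).sum(axis=1)
        p_alt = alt_count / (2.0 * n_called)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        ho = (gt == 1).sum(axis=1) / n_called
        he = 2.0 * p_alt * (1.0 - p_alt)
        f = np.where(he > 0, 1.0 - ho / he, np.nan)
        call_rate = n_called / max(table.n_samples, 1)
    table.maf = np.where(n_called > 0, maf, np.nan)
    table.ho = np.where(n_called > 0, ho, np.nan)
    table.he = np.where(n_called > 0, he, np.nan)
    table.f = f
    table.call_rate = call_rate.astype(float)
    return table


def _minor_individual_counts(table: SNPTable) -> np.ndarray:
    gt = table.gt
    called = gt != MISSING
    alt_count = np.where(called, gt, 0).sum(axis=1)
    n_called = called.sum(axis=1)
    minor_is_alt = alt_count <= (2 * n_called - alt_count)
    carriers_alt = ((gt == 1) | (gt == 2)).sum(axis=1)
    carriers_ref = ((gt == 1) | (gt == 0)).sum(axis=1)
    return np.where(minor_is_alt, carriers_alt, carriers_ref)


def filter_sites(
    table: SNPTable, config: FilterConfig
) -> tuple[SNPTable, dict[str, int]]:
    """Apply the site filter cascade; returns (kept table, removal ledger).

    A site is kept iff MAF >= mnMAF, F >= mnF, the minor allele is carried by
    at least ``min_minor_individuals`` samples and the call rate is at least
    ``min_site_call_rate``.  The ledger counts, for every filter, how many
    sites fail it (a site failing several filters is counted under each).
    """
    table = site_statistics(table)
    fails = {
        "maf": ~(table.maf >= config.mnMAF),
        "f": ~(table.f >= config.mnF),
        "minor_individuals": _minor_individual_counts(table)
        < config.min_minor_individuals,
        "call_rate": ~(table.call_rate >= config.min_site_call_rate),
    }
    ledger = {name: int(mask.sum()) for name, mask in fails.items()}
    keep = np.ones(table.n_sites, dtype=bool)
    for mask in fails.values():
        keep &= ~mask
    ledger["input"] = table.n_sites
    ledger["kept"] = int(keep.sum())
    return table.take(keep), ledger


@dataclass
class SampleExclusionReport:
    call_rates: dict[str, float]
    excluded: list[str]
    threshold: float


def exclude_samples(
    table: SNPTable, min_individual_call_rate: float
) -> tuple[SNPTable, SampleExclusionReport]:
    """Drop samples whose per-sample call rate is below threshold and
    recompute site statistics on the retained panel."""
    rates = table.sample_call_rates()
    call_rates = {s: float(r) for s, r in zip(table.samples, rates)}
    excluded = [s for s, r in call_rates.items() if r < min_individual_call_rate]
    report = SampleExclusionReport(
        call_rates=call_rates, excluded=excluded, threshold=min_individual_call_rate
    )
    if excluded:
        table = site_statistics(table.drop_samples(excluded))
    else:
        table = site_statistics(table)
    return table, report


def select_unlinked(table: SNPTable) -> SNPTable:
    """Keep one SNP per tag span: highest call rate, ties broken by the lower
    coordinate.  (The tightly-linked flag itself never removes sites.)"""
    best: dict[int, int] = {}
    for i in range(table.n_sites):
        lid = int(table.locus_id[i])
        if lid not in best:
            best[lid] = i
            continue
        j = best[lid]
        if (table.call_rate[i], -table.pos[i]) > (table.call_rate[j], -table.pos[j]):
            best[lid] = i
    idx = np.array(sorted(best.values()), dtype=np.int64)
    return table.take(idx)
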