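"""Synthetic GBS experiment generator.

Produces a fully specified experiment — random genome with a controllable
cut-site density, a multi-breed diploid population with hierarchically drawn
allele frequencies (Balding–Nichols style), planted SNPs, collapsed-paralog
loci and a polymorphic copy-gain region, and barcoded single-end FASTQ reads
— together with ground-truth tables, so every downstream stage can be tested
without any external data.

All randomness flows from one root seed via named SeedSequence children
(genome, population, sites, reads), so a scenario is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .demux_tagger import ADAPTER_READTHROUGH, BarcodeKey
from .restriction_digest import (
    CHROM_START,
    Fragment,
    RestrictionEnzyme,
    digest,
    get_enzyme,
    size_select,
)

__all__ = [
    "BreedSpec",
    "PopulationSpec",
    "ReadSimConfig",
    "CNVRegion",
    "TruthSite",
    "TruthSet",
    "SimSpec",
    "GBSSimulation",
    "simulate_genome",
    "simulate_population",
    "plant_sites",
    "simulate_reads",
    "simulate_experiment",
    "accrual_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class BreedSpec:
    name: str
    n: int
    fst: float

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError(f"{self.name}: F_ST must be in [0, 1)")
        if self.n < 1:
            raise ValueError(f"{self.name}: need >= 1 individual")


@dataclass
class PopulationSpec:
    """Hierarchical allele-frequency model for a multi-breed panel.

    Ancestral alternate-allele frequencies are uniform on ``maf_range``;
    breed frequencies drift around them with Balding–Nichols variance
    F_ST * p * (1-p); genotypes are drawn per individual with an optional
    within-breed inbreeding coefficient.
    """

    breeds: list[BreedSpec]
    n_sites: int
    maf_range: tuple[float, float] = (0.1, 0.5)
    inbreeding: float = 0.0
    seed: int | None = None

    @property
    def n_individuals(self) -> int:
        return sum(b.n for b in self.breeds)


@dataclass
class ReadSimConfig:
    read_length: int = 100
    mean_reads_per_sample: int = 20_000
    cv_reads: float = 0.39
    error_rate: float = 0.0
    include_blank: bool = True
    contamination: float = 0.0
    depth_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass
class CNVRegion:
    chrom: str
    start: int
    end: int
    copy_gain: int
    carriers: list[str]

    def __post_init__(self) -> None:
        if self.copy_gain < 1:
            raise ValueError("copy_gain must be >= 1")


@dataclass
class TruthSite:
    chrom: str
    pos: int  # 0-based genome coordinate
    ref: str
    alt: str
    frag_index: int  # index into the retained-fragment list
    offset: int  # offset from the fragment start (tag coordinate)
    recoverable: bool
    paralog: bool


@dataclass
class TruthSet:
    """Ground truth: planted sites, breed frequencies, genotypes, CNV."""

    samples: list[str]
    breeds: list[str]
    breed_names: list[str]
    sites: list[TruthSite]
    breed_freqs: np.ndarray  # (n_sites, n_breeds) alt-allele frequency
    genotypes: np.ndarray  # (n_samples, n_sites) int8 alt dosage
    cnv: CNVRegion | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def recoverable(self) -> list[TruthSite]:
        return [s for s in self.sites if s.recoverable and not s.paralog]

    def filter_survivors(
        self,
        mnmaf: float = 0.05,
        mnf: float = 0.05,
        min_minor_individuals: int = 3,
    ) -> list[TruthSite]:
        """Recoverable sites whose *true* genotype distribution passes the
        filter cascade.

        Realized allele frequencies drift, so some planted sites truly fail
        the MAF/F/minor-carrier thresholds in the sampled panel; an oracle
        caller with perfect genotypes would drop exactly those, so recall is
        meaningful only against this set.
        """
        out = []
        g = self.genotypes
        for i, site in enumerate(self.sites):
            if not site.recoverable or site.paralog:
                continue
            col = g[:, i]
            p = col.mean() / 2.0
            maf = min(p, 1 - p)
            he = 2 * p * (1 - p)
            ho = (col == 1).mean()
            f = 1 - ho / he if he > 0 else float("nan")
            carriers_alt = int(((col == 1) | (col == 2)).sum())
            carriers_ref = int(((col == 1) | (col == 0)).sum())
            minor = min(carriers_alt, carriers_ref)
            if maf >= mnmaf and f >= mnf and minor >= min_minor_individuals:
                out.append(site)
        return out

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\toffset\trecoverable\tparalog\n")
            for s in self.sites:
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.offset}\t"
                    f"{int(s.recoverable)}\t{int(s.paralog)}\n"
                )

    def write_breed_freqs(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\t" + "\t".join(self.breed_names) + "\n")
            for i, s in enumerate(self.sites):
                row = "\t".join(f"{f:.6g}" for f in self.breed_freqs[i])
                fh.write(f"{s.chrom}\t{s.pos}\t{row}\n")

    def to_snp_table(self):
        """Truth genotypes as a SNPTable (for VCF output / comparisons)."""
        from .snp_caller import SNPTable, site_statistics

        order = sorted(range(self.n_sites),
                       key=lambda i: (self.sites[i].chrom, self.sites[i].pos))
        sites = [self.sites[i] for i in order]
        n = len(sites)
        table = SNPTable(
            samples=list(self.samples),
            chrom=[s.chrom for s in sites],
            pos=np.array([s.pos for s in sites], dtype=np.int64),
            ref=[s.ref for s in sites],
            alt=[s.alt for s in sites],
            offset=np.array([s.offset for s in sites], dtype=np.int64),
            strand=["+"] * n,
            locus_id=np.array([s.frag_index for s in sites], dtype=np.int64),
            tightly_linked=np.zeros(n, dtype=bool),
            gt=self.genotypes[:, order].T.copy(),
            ad_ref=np.zeros((n, len(self.samples)), dtype=np.int32),
            ad_alt=np.zeros((n, len(self.samples)), dtype=np.int32),
        )
        return site_statistics(table)


def simulate_genome(
    chrom_sizes: Mapping[str, int],
    enzyme: RestrictionEnzyme,
    mean_site_spacing: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Random A/C/G/T genome with recognition sites injected at roughly
    exponentially spaced intervals (background sites also occur by chance)."""
    genome: dict[str, str] = {}
    site_len = len(enzyme.recognition)
    expansions = _expand(enzyme.recognition)
    for chrom in chrom_sizes:
        n = int(chrom_sizes[chrom])
        arr = _BASES[rng.integers(0, 4, n)]
        pos = 0
        while True:
            pos += max(site_len + 1, int(rng.exponential(mean_site_spacing)))
            if pos + site_len >= n:
                break
            site = expansions[rng.integers(0, len(expansions))]
            arr[pos : pos + site_len] = np.frombuffer(site.encode(), dtype=np.uint8)
        genome[chrom] = arr.tobytes().decode()
    return genome


def _expand(pattern: str) -> list[str]:
    from .restriction_digest import IUPAC

    seqs = [""]
    for ch in pattern:
        seqs = [s + b for s in seqs for b in IUPAC[ch]]
    return seqs


def simulate_population(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw breed frequencies and individual genotypes.

    Returns (genotypes (n_ind, n_sites) int8 alt dosage,
    breed_freqs (n_sites, n_breeds), breed index per individual).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    p_anc = rng.uniform(lo, hi, spec.n_sites)
    n_breeds = len(spec.breeds)
    freqs = np.empty((spec.n_sites, n_breeds))
    for b, breed in enumerate(spec.breeds):
        if breed.fst <= 0:
            freqs[:, b] = p_anc
        else:
            a = p_anc * (1 - breed.fst) / breed.fst
            bb = (1 - p_anc) * (1 - breed.fst) / breed.fst
            freqs[:, b] = rng.beta(a, bb)
    fis = spec.inbreeding
    genotypes = np.empty((spec.n_individuals, spec.n_sites), dtype=np.int8)
    breed_index = np.empty(spec.n_individuals, dtype=np.int64)
    row = 0
    for b, breed in enumerate(spec.breeds):
        p = freqs[:, b]
        q = 1 - p
        p_hom_ref = q * q + fis * p * q
        p_het = 2 * p * q * (1 - fis)
        u = rng.random((breed.n, spec.n_sites))
        g = (u > p_hom_ref).astype(np.int8) + (u > p_hom_ref + p_het).astype(np.int8)
        genotypes[row : row + breed.n] = g
        breed_index[row : row + breed.n] = b
        row += breed.n
    return genotypes, freqs, breed_index


def plant_sites(
    retained: Sequence[Fragment],
    n_sites: int,
    enzyme: RestrictionEnzyme,
    rng: np.random.Generator,
    tag_length: int = 64,
    n_paralog: int = 0,
    n_unrecoverable: int = 0,
    max_per_fragment: int = 2,
) -> list[TruthSite]:
    """Choose SNP positions inside retained fragment tag spans.

    The alternate allele is rejected if it would create a new recognition
    site (which would silently truncate tags); positions within 6 bp of the
    fragment end are avoided so the downstream cut survives.  Unrecoverable
    sites are planted beyond the 64-nt tag span (but within read reach) and
    flagged.
    """
    rl = len(enzyme.remnant)
    site_len = len(enzyme.recognition)
    pool: list[tuple[int, int]] = []
    beyond: list[tuple[int, int]] = []
    for fi, frag in enumerate(retained):
        hi = min(tag_length, frag.size - site_len)
        for off in range(rl, hi):
            pool.append((fi, off))
        for off in range(tag_length, min(frag.size - site_len, 85)):
            beyond.append((fi, off))
    rng.shuffle(pool)
    rng.shuffle(beyond)

    def try_place(cands, want, recoverable, paralog, used_frags, taken):
        placed = []
        per_frag: dict[int, int] = {}
        for fi, off in cands:
            if len(placed) == want:
                break
            if paralog and (fi in used_frags or fi in per_frag):
                continue
            if per_frag.get(fi, 0) >= max_per_fragment:
                continue
            frag = retained[fi]
            pos = frag.start + off
            if (frag.chrom, pos) in taken:
                continue
            ref = frag.sequence[off]
            if ref not in "ACGT":
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[rng.integers(0, 3)]
            window_lo = max(0, off - site_len + 1)
            window = (
                frag.sequence[window_lo:off] + alt
                + frag.sequence[off + 1 : off + site_len]
            )
            if enzyme.site_regex.search(window):
                continue
            placed.append(
                TruthSite(
                    chrom=frag.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    frag_index=fi,
                    offset=off,
                    recoverable=recoverable,
                    paralog=paralog,
                )
            )
            taken.add((frag.chrom, pos))
            per_frag[fi] = per_frag.get(fi, 0) + 1
        return placed

    taken: set[tuple[str, int]] = set()
    sites = try_place(pool, n_sites, True, False, set(), taken)
    if len(sites) < n_sites:
        raise ValueError(
            f"cannot plant {n_sites} sites: capacity {len(sites)} on "
            f"{len(retained)} retained fragments"
        )
    used = {s.frag_index for s in sites}
    sites += try_place(pool, n_paralog, True, True, used, taken)
    sites += try_place(beyond, n_unrecoverable, False, False, set(), taken)
    return sites


def simulate_reads(
    genome: Mapping[str, str],
    retained: Sequence[Fragment],
    truth: TruthSet,
    key: BarcodeKey,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
    out_path=None,
) -> tuple[dict[str, int], list[tuple[str, str, str]] | None]:
    """Emit barcoded single-end reads for every sample in the key.

    Per-sample totals are Gamma-distributed with the configured mean and CV
    (times any per-sample depth multiplier); reads carry planted alleles per
    the individual's genotype (heterozygous alleles 50/50, collapsed-paralog
    loci 50/50 for everyone); CNV-carrier fragments are emitted at
    copy_gain x the baseline rate; substitution errors hit any read
    position, barcode and remnant included.  The blank emits nothing unless
    ``contamination`` > 0.

    Returns (reads per sample, records) — records is None when ``out_path``
    is given (reads are streamed to the file instead).
    """
    barcode_of = key.barcode_of()
    max_bc = max(len(b) for b in barcode_of.values())
    min_bc = min(len(b) for b in barcode_of.values())
    tpl_len = cfg.read_length - min_bc
    if cfg.read_length < max_bc + 6:
        raise ValueError("read_length too short for longest barcode + remnant")

    # per-fragment read templates (fragment sequence + adapter fill)
    fill = ADAPTER_READTHROUGH * (tpl_len // len(ADAPTER_READTHROUGH) + 2)
    templates = [
        (f.sequence[:tpl_len] + fill)[:tpl_len].encode() for f in retained
    ]
    sites_by_frag: dict[int, list[int]] = {}
    for si, s in enumerate(truth.sites):
        sites_by_frag.setdefault(s.frag_index, []).append(si)
    paralog_frags = {s.frag_index for s in truth.sites if s.paralog}

    n_frag = len(retained)
    base_w = np.ones(n_frag)
    for fi in paralog_frags:
        base_w[fi] = 2.0
    cnv_frag = np.zeros(n_frag, dtype=bool)
    if truth.cnv is not None:
        c = truth.cnv
        for fi, f in enumerate(retained):
            if f.chrom == c.chrom and f.start >= c.start and f.end <= c.end:
                cnv_frag[fi] = True

    ind_of = {s: i for i, s in enumerate(truth.samples)}
    shape = None
    if cfg.cv_reads > 0:
        shape = 1.0 / (cfg.cv_reads**2)

    fh = open(out_path, "w") if out_path is not None else None
    records: list[tuple[str, str, str]] | None = [] if fh is None else None
    qual = "I" * cfg.read_length
    totals: dict[str, int] = {}
    serial = 0
    for entry in key.entries:
        sample = entry.sample
        if entry.blank:
            if not cfg.include_blank:
                continue
            n_reads = (
                int(rng.poisson(cfg.contamination * cfg.mean_reads_per_sample))
                if cfg.contamination > 0
                else 0
            )
            gt_row = None
        else:
            mult = cfg.depth_multipliers.get(sample, 1.0)
            mean = cfg.mean_reads_per_sample * mult
            if shape is None:
                n_reads = int(round(mean))
            else:
                n_reads = int(round(rng.gamma(shape, mean / shape)))
            gt_row = truth.genotypes[ind_of[sample]]
        totals[sample] = n_reads
        if n_reads == 0:
            continue
        w = base_w.copy()
        if truth.cnv is not None and sample in truth.cnv.carriers:
            w[cnv_frag] *= truth.cnv.copy_gain
        counts = rng.multinomial(n_reads, w / w.sum())
        bc = barcode_of[sample].encode()
        read_len = cfg.read_length
        for fi in np.flatnonzero(counts):
            c = int(counts[fi])
            base = (bc + templates[fi])[:read_len]
            arr = np.frombuffer(base * c, dtype=np.uint8).reshape(c, read_len).copy()
            for si in sites_by_frag.get(fi, ()):
                s = truth.sites[si]
                q = len(bc) + s.offset
                if q >= read_len:
                    continue
                if s.paralog or gt_row is None:
                    mask = rng.random(c) < 0.5
                elif gt_row[si] == 2:
                    mask = np.ones(c, dtype=bool)
                elif gt_row[si] == 1:
                    mask = rng.random(c) < 0.5
                else:
                    continue
                arr[mask, q] = ord(s.alt)
            if cfg.error_rate > 0:
                n_err = rng.binomial(c * read_len, cfg.error_rate)
                if n_err:
                    flat = rng.integers(0, c * read_len, n_err)
                    shift = rng.integers(1, 4, n_err).astype(np.uint8)
                    view = arr.reshape(-1)
                    view[flat] = _BASES[(_BASE_INDEX[view[flat]] + shift) % 4]
            for r in range(c):
                seq = arr[r].tobytes().decode()
                name = f"sim|{sample}|{fi}|{serial}"
                serial += 1
                if fh is not None:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
                else:
                    records.append((name, seq, qual))
    if fh is not None:
        fh.close()
    return totals, records


@dataclass
class SimSpec:
    """Complete scenario description (see configs/demo.yaml)."""

    chrom_sizes: dict[str, int]
    enzyme: str = "PstI"
    mean_site_spacing: float = 2000.0
    size_window: tuple[int, int] = (400, 1500)
    n_sites: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    fst: float | dict[str, float] = 0.15
    inbreeding: float = 0.0
    n_paralog_loci: int = 0
    n_unrecoverable: int = 0
    cnv: dict | None = None
    read_length: int = 100
    mean_reads_per_sample: int = 20_000
    cv_reads: float = 0.39
    error_rate: float = 0.0
    contamination: float = 0.0
    depth_multipliers: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict, enzyme: str | None = None) -> "SimSpec":
        d = dict(d)
        if "size_window" in d:
            d["size_window"] = tuple(d["size_window"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if enzyme is not None:
            d.setdefault("enzyme", enzyme)
        return cls(**d)

    def read_config(self) -> ReadSimConfig:
        return ReadSimConfig(
            read_length=self.read_length,
            mean_reads_per_sample=self.mean_reads_per_sample,
            cv_reads=self.cv_reads,
            error_rate=self.error_rate,
            contamination=self.contamination,
            depth_multipliers=dict(self.depth_multipliers),
        )


@dataclass
class GBSSimulation:
    genome: dict[str, str]
    fragments: list[Fragment]
    retained: list[Fragment]
    truth: TruthSet
    key: BarcodeKey
    reads_per_sample: dict[str, int]
    records: list[tuple[str, str, str]] | None = None


def _population_from_key(spec: SimSpec, key: BarcodeKey) -> PopulationSpec:
    order: list[str] = []
    counts: dict[str, int] = {}
    for e in key.entries:
        if e.blank:
            continue
        if e.breed not in counts:
            order.append(e.breed)
        counts[e.breed] = counts.get(e.breed, 0) + 1
    breeds = []
    for name in order:
        fst = spec.fst[name] if isinstance(spec.fst, dict) else spec.fst
        breeds.append(BreedSpec(name=name, n=counts[name], fst=float(fst)))
    return PopulationSpec(
        breeds=breeds,
        n_sites=spec.n_sites,
        maf_range=spec.maf_range,
        inbreeding=spec.inbreeding,
    )


def build_truth(
    spec: SimSpec,
    key: BarcodeKey,
    retained: Sequence[Fragment],
    rng_sites: np.random.Generator,
    rng_pop: np.random.Generator,
) -> TruthSet:
    enzyme = get_enzyme(spec.enzyme)
    sites = plant_sites(
        retained,
        spec.n_sites,
        enzyme,
        rng_sites,
        n_paralog=spec.n_paralog_loci,
        n_unrecoverable=spec.n_unrecoverable,
    )
    pop = _population_from_key(spec, key)
    pop = PopulationSpec(
        breeds=pop.breeds,
        n_sites=len(sites),
        maf_range=spec.maf_range,
        inbreeding=spec.inbreeding,
    )
    genotypes, freqs, _ = simulate_population(pop, rng_pop)
    # individuals are keyed in key order grouped by breed order
    samples, breeds = [], []
    for b in pop.breeds:
        for e in key.entries:
            if not e.blank and e.breed == b.name:
                samples.append(e.sample)
                breeds.append(e.breed)
    cnv = None
    if spec.cnv is not None:
        c = dict(spec.cnv)
        carriers = c.get("carriers")
        if carriers is None:
            carrier_breeds = set(c.get("carrier_breeds", []))
            carriers = [
                e.sample
                for e in key.entries
                if not e.blank and e.breed in carrier_breeds
            ]
        cnv = CNVRegion(
            chrom=c["chrom"],
            start=int(c["start"]),
            end=int(c["end"]),
            copy_gain=int(c.get("copy_gain", 2)),
            carriers=list(carriers),
        )
    return TruthSet(
        samples=samples,
        breeds=breeds,
        breed_names=[b.name for b in pop.breeds],
        sites=sites,
        breed_freqs=freqs,
        genotypes=genotypes,
        cnv=cnv,
    )


def retained_fragments(
    fragments: Sequence[Fragment], size_window: tuple[int, int]
) -> list[Fragment]:
    """Fragments that can produce reads: inside the size-selection window
    and starting at a cut (chromosome-start fragments have no ligation
    site)."""
    kept = size_select(list(fragments), *size_window)
    return [f for f in kept if f.left_enzyme != CHROM_START]


def simulate_experiment(
    spec: SimSpec,
    key: BarcodeKey,
    seed: int,
    outdir=None,
    keep_records: bool = False,
) -> GBSSimulation:
    """Run the full generator; optionally write FASTA/FASTQ/truth files."""
    from . import cli_io

    enzyme = get_enzyme(spec.enzyme)
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_pop, rng_sites, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    genome = simulate_genome(spec.chrom_sizes, enzyme, spec.mean_site_spacing,
                             rng_genome)
    fragments = digest(genome, enzyme)
    retained = retained_fragments(fragments, spec.size_window)
    truth = build_truth(spec, key, retained, rng_sites, rng_pop)
    out_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cli_io.write_fasta(genome, outdir / "reference.fa")
        out_path = outdir / "reads.fastq"
    totals, records = simulate_reads(
        genome, retained, truth, key, spec.read_config(), rng_reads,
        out_path=out_path if not keep_records else None,
    )
    if keep_records and outdir is not None:
        cli_io.write_fastq(records, outdir / "reads.fastq")
    if outdir is not None:
        truth.write_tsv(outdir / "truth_sites.tsv")
        truth.write_breed_freqs(outdir / "truth_breed_freqs.tsv")
        contigs = {c: len(s) for c, s in genome.items()}
        cli_io.write_vcf(truth.to_snp_table(), outdir / "truth_genotypes.vcf",
                         contigs=contigs)
        if truth.cnv is not None:
            with open(outdir / "truth_cnv.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tcopy_gain\tcarriers\n")
                c = truth.cnv
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_gain}\t"
                         + ",".join(c.carriers) + "\n")
    return GBSSimulation(
        genome=genome,
        fragments=fragments,
        retained=retained,
        truth=truth,
        key=key,
        reads_per_sample=totals,
        records=records,
    )


def accrual_experiment(
    sim: GBSSimulation,
    spec: SimSpec,
    n_runs: int,
    reads_per_run: int,
    seed: int,
    filter_config=None,
) -> list[int]:
    """Cumulative unique kept-SNP counts over repeated sequencing runs.

    Each run draws fresh reads at ``reads_per_run`` mean depth from the same
    library; runs are pooled cumulatively and the caller + filter cascade is
    re-run on the pooled tag counts.  The count at run r is the number of
    distinct sites kept in any analysis up to r, hence non-decreasing.
    """
    from .demux_tagger import TagCountMatrix, demultiplex_and_count
    from .snp_caller import (
        FilterConfig,
        ReferenceAnchorIndex,
        anchor_tags,
        discover_and_genotype,
        filter_sites,
    )

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if filter_config is None:
        filter_config = FilterConfig()
    enzyme = get_enzyme(spec.enzyme)
    cfg = spec.read_config()
    cfg.mean_reads_per_sample = reads_per_run
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    index = ReferenceAnchorIndex(sim.genome, enzyme)
    pooled: TagCountMatrix | None = None
    discovered: set[tuple[str, int]] = set()
    curve: list[int] = []
    for _run in range(n_runs):
        _totals, records = simulate_reads(
            sim.genome, sim.retained, sim.truth, sim.key, cfg, rng, out_path=None
        )
        matrix, _ = demultiplex_and_count(records, sim.key, enzyme)
        pooled = matrix if pooled is None else TagCountMatrix.merge([pooled, matrix])
        aligned = anchor_tags(pooled.tags, index=index)
        table = discover_and_genotype(
            pooled, aligned,
            min_minor_individuals=filter_config.min_minor_individuals,
            samples=sim.key.dna_samples,
        )
        kept, _ledger = filter_sites(table, filter_config)
        discovered.update(kept.site_keys())
        curve.append(len(discovered))
    return curve
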