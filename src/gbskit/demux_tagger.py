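"""Barcode demultiplexing, 64-nt tag extraction and tag counting.

A read is assigned to a sample iff it begins with that sample's barcode
followed immediately by the enzyme's cut-site remnant; the longest matching
barcode wins.  Exact matching only (no mismatch rescue) by default.  The tag
canonical sequence *includes* the remnant, is truncated at read-through into
the common adapter or at an internal full recognition site, and short tags
are padded with a reserved pad character so every tag is stored at a fixed
width with an honest ``effective_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .restriction_digest import RestrictionEnzyme

__all__ = [
    "PAD",
    "ADAPTER_READTHROUGH",
    "KeyEntry",
    "BarcodeKey",
    "KeyValidationReport",
    "Tag",
    "TagCountMatrix",
    "DemuxSummary",
    "load_key",
    "validate_key",
    "Demultiplexer",
    "extract_tag",
    "count_tags",
    "demultiplex_and_count",
]

PAD = "."

# Start of the common adapter as it appears when sequencing reads through a
# short insert.
ADAPTER_READTHROUGH = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"

DEFAULT_TAG_LENGTH = 64


class KeyError_(ValueError):
    """Fatal barcode-key problem (duplicates, ambiguity, schema)."""


@dataclass(frozen=True)
class KeyEntry:
    sample: str
    barcode: str
    breed: str
    blank: bool


@dataclass
class BarcodeKey:
    """Sample -> barcode registry, including blank/negative-control rows."""

    entries: list[KeyEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise KeyError_("empty barcode key")

    @property
    def samples(self) -> list[str]:
        return [e.sample for e in self.entries]

    @property
    def blank_samples(self) -> list[str]:
        return [e.sample for e in self.entries if e.blank]

    @property
    def dna_samples(self) -> list[str]:
        return [e.sample for e in self.entries if not e.blank]

    def breed_of(self) -> dict[str, str]:
        return {e.sample: e.breed for e in self.entries}

    def barcode_of(self) -> dict[str, str]:
        return {e.sample: e.barcode for e in self.entries}


def load_key(path) -> BarcodeKey:
    """Read a key TSV with required header ``sample barcode breed blank``."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise KeyError_(f"{path}: empty key file")
    header = lines[0].split("\t")
    required = ["sample", "barcode", "breed", "blank"]
    missing = [c for c in required if c not in header]
    if missing:
        raise KeyError_(f"{path}: key file missing column(s) {missing}")
    idx = {c: header.index(c) for c in required}
    entries = []
    for ln_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < len(header):
            raise KeyError_(f"{path}:{ln_no}: expected {len(header)} columns")
        entries.append(
            KeyEntry(
                sample=fields[idx["sample"]],
                barcode=fields[idx["barcode"]].upper(),
                breed=fields[idx["breed"]],
                blank=fields[idx["blank"]] in ("1", "true", "True", "yes"),
            )
        )
    return BarcodeKey(entries)


@dataclass
class KeyValidationReport:
    duplicates: list[str] = field(default_factory=list)
    ambiguities: list[tuple[str, str]] = field(default_factory=list)
    site_in_barcode: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.duplicates and not self.ambiguities


def validate_key(
    key: BarcodeKey, enzyme: RestrictionEnzyme, strict: bool = True
) -> KeyValidationReport:
    """Check a key for duplicate barcodes and prefix ambiguities.

    An ambiguity exists when one barcode followed by the remnant could be
    parsed as a (different) longer barcode's read prefix, i.e. barcode B2 is a
    proper prefix of B1 + remnant.  Barcodes that recreate the recognition
    site next to the remnant are reported as a warning only.
    """
    report = KeyValidationReport()
    seen: dict[str, str] = {}
    for e in key.entries:
        if e.barcode in seen:
            report.duplicates.append(e.barcode)
        seen[e.barcode] = e.sample

    barcodes = sorted({e.barcode for e in key.entries})
    remnants = enzyme.remnant_expansions()
    for b1 in barcodes:
        for rem in remnants:
            ext = b1 + rem
            for b2 in barcodes:
                if b2 != b1 and ext.startswith(b2):
                    report.ambiguities.append((b1, b2))
    for b in barcodes:
        for rem in remnants:
            if enzyme.site_regex.search(b + rem[: len(enzyme.recognition) - 1]):
                report.site_in_barcode.append(b)
                break
    if strict and not report.ok:
        raise KeyError_(
            f"invalid barcode key: duplicates={report.duplicates} "
            f"ambiguities={report.ambiguities}"
        )
    return report


@dataclass(frozen=True)
class Tag:
    """A fixed-width, cut-site-anchored sequence tag.

    ``sequence`` is padded to the tag length with the reserved pad character;
    ``effective_length`` is the pre-padding length.
    """

    sequence: str
    effective_length: int

    def __post_init__(self) -> None:
        if self.effective_length > len(self.sequence):
            raise ValueError("effective_length exceeds stored width")


def extract_tag(
    read_seq: str,
    barcode: str,
    enzyme: RestrictionEnzyme,
    tag_length: int = DEFAULT_TAG_LENGTH,
) -> Tag | None:
    """Extract the tag from an assigned read.

    The barcode is removed; the tag begins at the remnant and is truncated at
    the first of: ``tag_length`` reached, an internal full recognition site
    (the 5' portion is kept), or the start of the common adapter.  Tags with
    an N in the effective span are dropped (returns None).
    """
    t = read_seq[len(barcode):]
    eff = min(tag_length, len(t))
    m = enzyme.site_regex.search(t, 1, eff + len(enzyme.recognition) - 1)
    if m and m.start() < eff:
        eff = m.start()
    # adapter read-through: match a 13-nt adapter prefix (or whatever is left
    # of the read if shorter)
    probe = ADAPTER_READTHROUGH[:13]
    a = t.find(probe, 0, eff + len(probe) - 1)
    if a == -1 and len(t) < len(barcode) + tag_length + 13:
        # near the end of the read a shorter adapter prefix may remain
        for k in range(min(12, eff), 3, -1):
            if t.endswith(ADAPTER_READTHROUGH[:k]):
                a = len(t) - k
                break
    if a != -1 and a < eff:
        eff = a
    if eff <= 0:
        return None
    core = t[:eff]
    if "N" in core:
        return None
    return Tag(sequence=core + PAD * (tag_length - eff), effective_length=eff)


@dataclass
class DemuxSummary:
    """Read-assignment accounting; classes partition the input reads."""

    assigned: dict[str, int] = field(default_factory=dict)
    no_barcode: int = 0
    barcode_no_remnant: int = 0
    dropped_tags: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def total(self) -> int:
        return self.total_assigned + self.no_barcode + self.barcode_no_remnant

    def blank_counts(self, key: BarcodeKey) -> dict[str, int]:
        return {s: self.assigned.get(s, 0) for s in key.blank_samples}


class Demultiplexer:
    """Assign reads to samples by exact barcode + remnant match."""

    def __init__(self, key: BarcodeKey, enzyme: RestrictionEnzyme):
        validate_key(key, enzyme, strict=True)
        self.key = key
        self.enzyme = enzyme
        self._by_barcode = {e.barcode: e.sample for e in key.entries}
        self._lengths = sorted({len(e.barcode) for e in key.entries}, reverse=True)
        self._remnants = set(enzyme.remnant_expansions())
        self._rl = len(enzyme.remnant)

    def assign(self, seq: str) -> tuple[str | None, str]:
        """Return (sample, class) where class is one of assigned /
        no_barcode / barcode_no_remnant."""
        saw_barcode = False
        for L in self._lengths:
            sample = self._by_barcode.get(seq[:L])
            if sample is not None:
                saw_barcode = True
                if seq[L : L + self._rl] in self._remnants:
                    return sample, "assigned"
        return None, ("barcode_no_remnant" if saw_barcode else "no_barcode")


@dataclass
class TagCountMatrix:
    """Unique tags x samples read-count matrix (the pipeline's central
    object).  Tags are ordered lexicographically by padded sequence."""

    tags: list[Tag]
    samples: list[str]
    counts: np.ndarray  # (n_tags, n_samples) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.tags), len(self.samples)):
            raise ValueError("counts shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.sum())

    def depth_fraction(self, min_count: int = 10) -> float:
        """Fraction of tags whose maximum per-sample count exceeds
        ``min_count`` (depth-adequacy summary)."""
        if not self.tags:
            return 0.0
        return float(np.mean(self.counts.max(axis=1) > min_count))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\teffective_length\t" + "\t".join(self.samples) + "\n")
            for i, tag in enumerate(self.tags):
                row = "\t".join(str(c) for c in self.counts[i])
                fh.write(f"{tag.sequence}\t{tag.effective_length}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "TagCountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["tag", "effective_length"]:
                raise ValueError(f"{path}: not a tag-count matrix")
            samples = header[2:]
            tags, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                tags.append(Tag(sequence=fields[0], effective_length=int(fields[1])))
                rows.append([int(x) for x in fields[2:]])
        counts = np.array(rows, dtype=np.int64) if rows else np.zeros(
            (0, len(samples)), dtype=np.int64
        )
        return cls(tags=tags, samples=samples, counts=counts)

    @staticmethod
    def merge(matrices: list["TagCountMatrix"]) -> "TagCountMatrix":
        """Sum several matrices over the same sample panel (run pooling)."""
        if not matrices:
            raise ValueError("nothing to merge")
        samples = matrices[0].samples
        for m in matrices[1:]:
            if m.samples != samples:
                raise ValueError("sample panels differ")
        acc: dict[str, list] = {}
        for m in matrices:
            for i, tag in enumerate(m.tags):
                row = acc.get(tag.sequence)
                if row is None:
                    acc[tag.sequence] = [tag.effective_length,
                                         m.counts[i].tolist()]
                else:
                    row[1] = [a + b for a, b in zip(row[1], m.counts[i])]
        return _finalize(acc, samples)

    def to_fasta(self, path) -> None:
        """Write unpadded tag sequences for external alignment; the record id
        is the row index."""
        with open(path, "w") as fh:
            for i, tag in enumerate(self.tags):
                fh.write(f">tag{i:07d}\n{tag.sequence[:tag.effective_length]}\n")


def _accumulate(
    acc: dict[str, list], sample_index: dict[str, int], n_samples: int,
    tag: Tag, sample: str,
) -> None:
    row = acc.get(tag.sequence)
    if row is None:
        acc[tag.sequence] = row = [tag.effective_length, [0] * n_samples]
    row[1][sample_index[sample]] += 1


def _finalize(acc: dict, samples: list[str]) -> TagCountMatrix:
    tags, rows = [], []
    for seq in sorted(acc):
        eff, counts = acc[seq]
        tags.append(Tag(sequence=seq, effective_length=eff))
        rows.append(counts)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros(
        (0, len(samples)), dtype=np.int64
    )
    return TagCountMatrix(tags=tags, samples=samples, counts=counts)


def count_tags(
    streams: dict[str, Iterable[Tag]], samples: list[str] | None = None
) -> TagCountMatrix:
    """Collapse per-sample tag streams into a TagCountMatrix."""
    if samples is None:
        samples = sorted(streams)
    sample_index = {s: i for i, s in enumerate(samples)}
    acc: dict[str, list] = {}
    for sample, stream in streams.items():
        for tag in stream:
            _accumulate(acc, sample_index, len(samples), tag, sample)
    return _finalize(acc, samples)


def demultiplex_and_count(
    reads: Iterable[tuple[str, str, str]] | Iterator,
    key: BarcodeKey,
    enzyme: RestrictionEnzyme,
    tag_length: int = DEFAULT_TAG_LENGTH,
) -> tuple[TagCountMatrix, DemuxSummary]:
    """Single-pass demultiplex + tag extraction + counting.

    ``reads`` yields (name, sequence, quality) triples, e.g. from
    :func:`gbskit.cli_io.read_fastq`.
    """
    demux = Demultiplexer(key, enzyme)
    barcode_of = key.barcode_of()
    samples = key.samples
    sample_index = {s: i for i, s in enumerate(samples)}
    summary = DemuxSummary(assigned={s: 0 for s in samples})
    acc: dict[str, list] = {}
    for _name, seq, _qual in reads:
        seq = seq.upper()
        sample, cls = demux.assign(seq)
        if sample is None:
            if cls == "no_barcode":
                summary.no_barcode += 1
            else:
                summary.barcode_no_remnant += 1
            continue
        summary.assigned[sample] += 1
        tag = extract_tag(seq, barcode_of[sample], enzyme, tag_length)
        if tag is None:
            summary.dropped_tags += 1
            continue
        _accumulate(acc, sample_index, len(samples), tag, sample)
    return _finalize(acc, samples), summary
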