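"""In-silico restriction digestion and fragment-size diagnostics.

Coordinates are 0-based, half-open throughout.  A cut made by an enzyme at a
recognition site starting at ``s`` is placed at ``s + cut_offset``, the point
where the sequenced end of the downstream fragment begins (i.e. the start of
the cut-site remnant that shows up at the 5' end of a read after the barcode).
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RestrictionEnzyme",
    "Fragment",
    "FragmentSizeProfile",
    "CHROM_START",
    "CHROM_END",
    "load_enzymes",
    "get_enzyme",
    "find_sites",
    "cut_positions",
    "digest",
    "size_select",
    "fragment_profile",
]

# IUPAC nucleotide codes.  N in a *sequence* never matches anything (the
# conservative choice for assembly gaps), which is why the expansion of a
# pattern letter never includes N itself.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN.", "TGCAYRSWMKVHDBN.")

CHROM_START = "chrom_start"
CHROM_END = "chrom_end"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class EnzymeConfigError(ValueError):
    """Raised for an invalid enzyme definition."""


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        try:
            exp = IUPAC[ch]
        except KeyError:
            raise EnzymeConfigError(f"invalid IUPAC code {ch!r} in {pattern!r}")
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    # Lookahead so overlapping occurrences are all reported.
    return re.compile("(?=" + "".join(parts) + ")")


def _is_palindromic(recognition: str) -> bool:
    rc = reverse_complement(recognition)
    return all(set(IUPAC[a]) == set(IUPAC[b]) for a, b in zip(recognition, rc))


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme recognition/cut model.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"PstI"``.
    recognition : str
        IUPAC recognition sequence (must be palindromic; the enzymes this
        toolkit models all are, so top-strand scanning suffices).
    cut_offset : int
        Offset within the recognition site at which the sequenced end of the
        downstream fragment begins (start of the remnant).
    remnant : str
        Cut-site residue expected at the start of a read after the barcode.
    methylation_sensitive : bool
        Metadata flag only; no methylation mask is applied by default.
    """

    name: str
    recognition: str
    cut_offset: int
    remnant: str
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        for ch in self.recognition:
            if ch not in IUPAC:
                raise EnzymeConfigError(
                    f"{self.name}: invalid IUPAC code {ch!r} in recognition"
                )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeConfigError(f"{self.name}: cut_offset out of range")
        if not _is_palindromic(self.recognition):
            raise EnzymeConfigError(
                f"{self.name}: non-palindromic recognition site "
                f"{self.recognition!r} is not supported"
            )
        expected = self.recognition[self.cut_offset:]
        if len(self.remnant) != len(expected) or any(
            set(IUPAC[a]) != set(IUPAC[b]) for a, b in zip(self.remnant, expected)
        ):
            raise EnzymeConfigError(
                f"{self.name}: remnant {self.remnant!r} is inconsistent with "
                f"recognition {self.recognition!r} cut at {self.cut_offset}"
            )

    @property
    def site_regex(self) -> re.Pattern:
        return _iupac_regex(self.recognition)

    def remnant_expansions(self) -> list[str]:
        """All concrete (A/C/G/T) sequences matching the remnant."""
        seqs = [""]
        for ch in self.remnant:
            seqs = [s + b for s in seqs for b in IUPAC[ch]]
        return seqs


def load_enzymes(path=None) -> dict[str, RestrictionEnzyme]:
    """Load the enzyme registry (packaged TSV by default)."""
    if path is None:
        src = resources.files("gbskit.data").joinpath("enzymes.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = ["name", "recognition", "cut_offset", "remnant", "methylation_sensitive"]
    if header != expected:
        raise EnzymeConfigError(f"enzyme registry header {header} != {expected}")
    registry = {}
    for line in lines[1:]:
        name, rec, off, rem, meth = line.split("\t")
        registry[name] = RestrictionEnzyme(
            name=name,
            recognition=rec,
            cut_offset=int(off),
            remnant=rem,
            methylation_sensitive=bool(int(meth)),
        )
    return registry


_REGISTRY: dict[str, RestrictionEnzyme] | None = None


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up an enzyme by name in the packaged registry."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_enzymes()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise EnzymeConfigError(
            f"unknown enzyme {name!r}; registry has {sorted(_REGISTRY)}"
        )


@dataclass
class Fragment:
    """A genomic restriction fragment (0-based, half-open coordinates)."""

    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length != end - start")

    @property
    def size(self) -> int:
        return self.end - self.start


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Return 0-based start positions of all recognition-site matches.

    Overlapping matches are all reported; positions are strictly increasing.
    N bases never match.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return [m.start() for m in enzyme.site_regex.finditer(sequence.upper())]


def cut_positions(
    sequence: str, enzymes: Sequence[RestrictionEnzyme]
) -> list[tuple[int, str]]:
    """Sorted (cut position, enzyme name) pairs interior to the sequence.

    For a double digest the cut set is the union over both enzymes; a
    position cut by both is labelled with the joined names.
    """
    cuts: dict[int, list[str]] = {}
    for enz in enzymes:
        for s in find_sites(sequence, enz):
            pos = s + enz.cut_offset
            if 0 < pos < len(sequence):
                cuts.setdefault(pos, []).append(enz.name)
    return [(pos, "|".join(sorted(set(names)))) for pos, names in sorted(cuts.items())]


def digest(
    genome: Mapping[str, str] | Iterable[tuple[str, str]],
    enzymes: RestrictionEnzyme | Sequence[RestrictionEnzyme],
) -> list[Fragment]:
    """Digest a genome with one or two enzymes into tiling fragments."""
    if isinstance(enzymes, RestrictionEnzyme):
        enzymes = [enzymes]
    if not 1 <= len(enzymes) <= 2:
        raise ValueError("digest takes one or two enzymes")
    items = genome.items() if hasattr(genome, "items") else list(genome)
    items = list(items)
    if not items:
        raise ValueError("empty genome")
    fragments: list[Fragment] = []
    for chrom, seq in items:
        seq = seq.upper()
        cuts = cut_positions(seq, enzymes)
        bounds = [(0, CHROM_START)] + cuts + [(len(seq), CHROM_END)]
        for (start, left), (end, right) in zip(bounds[:-1], bounds[1:]):
            fragments.append(
                Fragment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    left_enzyme=left,
                    right_enzyme=right,
                    sequence=seq[start:end],
                )
            )
    return fragments


def size_select(
    fragments: Iterable[Fragment], min_bp: int, max_bp: int
) -> list[Fragment]:
    """Keep fragments with min_bp <= size <= max_bp."""
    if not 0 <= min_bp <= max_bp:
        raise ValueError("need 0 <= min_bp <= max_bp")
    return [f for f in fragments if min_bp <= f.size <= max_bp]


@dataclass
class FragmentSizeProfile:
    """Fragment-size histogram plus over-representation diagnostics."""

    histogram: dict[int, int]
    repeat_peaks: list[tuple[int, int, str]]
    window_yield: float | None = None
    binned: dict[int, int] = field(default_factory=dict)
    bin_bp: int = 1

    @property
    def total(self) -> int:
        return sum(self.histogram.values())


def fragment_profile(
    fragments: Sequence[Fragment],
    bin_bp: int = 25,
    repeat_threshold: int = 10,
    bin_factor: float = 5.0,
    window: tuple[int, int] | None = None,
) -> FragmentSizeProfile:
    """Profile fragment sizes and flag repeat-like over-representation.

    Two diagnostics mirror the "discrete peak" symptom of repetitive DNA in a
    library trace: (a) identical fragment sequences occurring at least
    ``repeat_threshold`` times, and (b) size bins whose count exceeds
    ``bin_factor`` times the median non-empty bin count.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    histogram: dict[int, int] = {}
    seq_counts: dict[str, int] = {}
    for f in fragments:
        histogram[f.size] = histogram.get(f.size, 0) + 1
        seq_counts[f.sequence] = seq_counts.get(f.sequence, 0) + 1

    peaks = [
        (len(seq), count, seq)
        for seq, count in seq_counts.items()
        if count >= repeat_threshold
    ]
    peaks.sort(key=lambda t: (-t[1], t[0], t[2]))

    binned: dict[int, int] = {}
    for size, count in histogram.items():
        b = size // bin_bp
        binned[b] = binned.get(b, 0) + count
    if binned:
        med = statistics.median(binned.values())
        hot_bins = {b for b, c in binned.items() if med > 0 and c > bin_factor * med}
        for b in sorted(hot_bins):
            # report the most common sequence in the hot bin as the example
            members = [
                (c, s) for s, c in seq_counts.items() if (len(s) // bin_bp) == b
            ]
            if members:
                c, s = max(members, key=lambda t: (t[0], t[1]))
                if (len(s), c, s) not in peaks:
                    peaks.append((len(s), c, s))

    window_yield = None
    if window is not None and fragments:
        lo, hi = window
        window_yield = sum(1 for f in fragments if lo <= f.size <= hi) / len(fragments)

    return FragmentSizeProfile(
        histogram=histogram,
        repeat_peaks=peaks,
        window_yield=window_yield,
        binned=binned,
        bin_bp=bin_bp,
    )
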