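"""Read-depth CNV scanning over genomic windows.

Copy-number gains show up as polymorphic elevations of library-size
normalized tag counts.  Non-unique tags participate here (duplications make
tags multi-map) even though they are excluded from SNP calling.  Losses are
never called: a window with zero depth in one sample produces no call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .demux_tagger import TagCountMatrix
from .snp_caller import AlignedTag

__all__ = ["DepthProfile", "CNVCall", "depth_profile", "call_gains"]


@dataclass
class DepthProfile:
    """Per-window, per-sample normalized depth aggregates.

    Normalization multiplies each sample's raw counts by
    (panel median library size / sample library size), which preserves rank
    order within a sample.
    """

    samples: list[str]
    windows: list[tuple[str, int, int]]
    aggregates: np.ndarray  # (n_windows, n_samples) float
    tags_per_window: np.ndarray
    loci_per_window: np.ndarray  # distinct anchor positions
    norm_factors: np.ndarray
    window_bp: int


@dataclass
class CNVCall:
    chrom: str
    start: int
    end: int
    carriers: list[str]
    folds: dict[str, float]
    polymorphic: bool


def depth_profile(
    matrix: TagCountMatrix,
    aligned: Sequence[AlignedTag],
    window_bp: int = 50_000,
    chrom_sizes: Mapping[str, int] | None = None,
    samples: Sequence[str] | None = None,
) -> DepthProfile:
    """Aggregate normalized tag depths into fixed-width windows.

    All anchored tags contribute, including non-unique ones (at their best
    location).  Samples with a zero library size (e.g. the blank) are
    excluded unless listed explicitly in ``samples``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    totals = matrix.sample_totals()
    if samples is None:
        keep = [i for i, t in enumerate(totals) if t > 0]
    else:
        keep = [matrix.samples.index(s) for s in samples]
    names = [matrix.samples[i] for i in keep]
    lib = totals[keep].astype(float)
    med = float(np.median(lib))
    factors = np.where(lib > 0, med / np.where(lib > 0, lib, 1.0), 0.0)

    # covered extent per chromosome
    extent: dict[str, int] = dict(chrom_sizes or {})
    for at in aligned:
        extent[at.chrom] = max(extent.get(at.chrom, 0), at.pos + 1)
    windows: list[tuple[str, int, int]] = []
    win_index: dict[tuple[str, int], int] = {}
    for chrom in sorted(extent):
        n_win = (int(extent[chrom]) + window_bp - 1) // window_bp
        for w in range(n_win):
            win_index[(chrom, w)] = len(windows)
            windows.append((chrom, w * window_bp, (w + 1) * window_bp))

    agg = np.zeros((len(windows), len(names)))
    ntags = np.zeros(len(windows), dtype=np.int64)
    anchor_sets: list[set[tuple[int, str]]] = [set() for _ in windows]
    for at in aligned:
        wi = win_index[(at.chrom, at.pos // window_bp)]
        agg[wi] += matrix.counts[at.tag_index][keep] * factors
        ntags[wi] += 1
        anchor_sets[wi].add((at.pos, at.strand))
    return DepthProfile(
        samples=names,
        windows=windows,
        aggregates=agg,
        tags_per_window=ntags,
        loci_per_window=np.array([len(s) for s in anchor_sets], dtype=np.int64),
        norm_factors=factors,
        window_bp=window_bp,
    )


def call_gains(
    profile: DepthProfile,
    fold_threshold: float = 1.75,
    min_tags: int = 3,
    min_loci: int = 3,
) -> list[CNVCall]:
    """Call polymorphic copy-gain windows.

    A sample is a carrier in a window if its normalized aggregate is at
    least ``fold_threshold`` times the cross-sample median and the window
    holds at least ``min_tags`` anchored tags at ``min_loci`` distinct
    anchor positions (sequencing-error tags multiply tag counts without
    adding loci, so the locus guard is what keeps sparse windows out); a
    window is a polymorphic call when it has at least one carrier and at
    least one baseline sample.
    """
    if fold_threshold <= 1.0:
        raise ValueError(
            f"fold_threshold={fold_threshold} is degenerate (every sample "
            "would be a carrier); use a value > 1"
        )
    calls: list[CNVCall] = []
    for wi, (chrom, start, end) in enumerate(profile.windows):
        if profile.tags_per_window[wi] < min_tags:
            continue
        if profile.loci_per_window[wi] < min_loci:
            continue
        row = profile.aggregates[wi]
        med = float(np.median(row))
        if med <= 0:
            continue  # losses / empty windows are never called
        elevated = row >= fold_threshold * med
        if elevated.any() and (~elevated).any():
            carriers = [s for s, e in zip(profile.samples, elevated) if e]
            folds = {
                s: float(row[k] / med)
                for k, s in enumerate(profile.samples)
                if elevated[k]
            }
            calls.append(
                CNVCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    carriers=carriers,
                    folds=folds,
                    polymorphic=True,
                )
            )
    return calls
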