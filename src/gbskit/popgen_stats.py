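"""Downstream analytics: MAF spectra, heterozygosity, allele-sharing
distances, neighbor-joining trees, per-chromosome density and gap
statistics, and whole-genome density extrapolation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .snp_caller import MISSING, SNPTable

__all__ = [
    "GenotypeMatrix",
    "DistanceMatrix",
    "Tree",
    "DensityTable",
    "GapDistribution",
    "load_bovine_annotation",
    "maf_spectrum",
    "heterozygosity",
    "pairwise_distances",
    "neighbor_joining",
    "is_monophyletic",
    "chromosome_density",
    "gap_statistics",
    "density_extrapolation",
]

MAF_BINS = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5]


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix; calls coded 0/1/2 (alternate-allele
    dosage) with -1 for missing.  Allele-sharing quantities are invariant to
    which allele carries the dosage."""

    samples: list[str]
    breeds: list[str]
    chrom: list[str]
    pos: np.ndarray
    dosage: np.ndarray  # (n_samples, n_sites) int8

    @classmethod
    def from_snp_table(cls, table: SNPTable, breed_of: Mapping[str, str] | None = None):
        breeds = [
            (breed_of or {}).get(s, "unknown") for s in table.samples
        ]
        return cls(
            samples=list(table.samples),
            breeds=breeds,
            chrom=list(table.chrom),
            pos=np.asarray(table.pos),
            dosage=table.gt.T.copy(),
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]


def _site_maf(dosage: np.ndarray) -> np.ndarray:
    called = dosage != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dosage, 0).sum(axis=0) / (2.0 * n)
    maf = np.minimum(p, 1 - p)
    return np.where(n > 0, maf, np.nan)


def maf_spectrum(
    gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]] | None = None
) -> tuple[pd.DataFrame, float]:
    """Binned MAF fractions per group plus the overall mean MAF.

    Bins: [0.05, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, 0.5].
    Group spectra use group-restricted allele frequencies.  Returns
    (spectrum DataFrame indexed by bin label, overall mean MAF).
    """
    if groups is None:
        groups = {"all": gm.samples}
    labels = [
        f"[{lo},{hi})" if hi < 0.5 else f"[{lo},{hi}]"
        for lo, hi in zip(MAF_BINS[:-1], MAF_BINS[1:])
    ]
    out = {}
    for name, members in groups.items():
        idx = [gm.samples.index(s) for s in members]
        maf = _site_maf(gm.dosage[idx])
        maf = maf[~np.isnan(maf)]
        maf = maf[maf >= MAF_BINS[0]]
        counts, _ = np.histogram(maf, bins=MAF_BINS)
        frac = counts / counts.sum() if counts.sum() else np.zeros(len(counts))
        out[name] = frac
    overall = _site_maf(gm.dosage)
    mean_maf = float(np.nanmean(overall)) if gm.n_sites else float("nan")
    return pd.DataFrame(out, index=labels), mean_maf


def heterozygosity(
    gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-individual and per-group observed heterozygosity.

    Individual Ho = het calls / called sites; group Ho = mean over members.
    """
    called = gm.dosage != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = (gm.dosage == 1).sum(axis=1) / called.sum(axis=1)
    per_ind = pd.Series(ho, index=gm.samples, name="Ho")
    if groups is None:
        groups = {}
        for s, b in zip(gm.samples, gm.breeds):
            groups.setdefault(b, []).append(s)
    per_group = pd.Series(
        {name: float(per_ind[list(members)].mean()) for name, members in groups.items()},
        name="Ho",
    )
    return per_ind, per_group


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distances with breed-level aggregates."""

    samples: list[str]
    breeds: list[str]
    values: np.ndarray
    within_breed: dict[str, float] = field(default_factory=dict)
    between_breed: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        assert v.shape == (len(self.samples),) * 2
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix not symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def pairwise_distances(gm: GenotypeMatrix, min_overlap: int = 100) -> DistanceMatrix:
    """Allele-sharing distance 1 - (shared alleles / 2), averaged over sites
    co-called in both samples; pairs with fewer than ``min_overlap`` shared
    sites get NaN."""
    n = gm.n_samples
    d = np.zeros((n, n))
    dose = gm.dosage.astype(np.int16)
    called = dose != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            k = int(both.sum())
            if k < min_overlap:
                d[i, j] = d[j, i] = np.nan
                continue
            dij = np.abs(dose[i, both] - dose[j, both]).sum() / (2.0 * k)
            d[i, j] = d[j, i] = dij
    dm = DistanceMatrix(samples=list(gm.samples), breeds=list(gm.breeds), values=d)
    by_breed: dict[str, list[int]] = {}
    for idx, b in enumerate(gm.breeds):
        by_breed.setdefault(b, []).append(idx)
    def _mean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    for b, idxs in by_breed.items():
        dm.within_breed[b] = _mean(
            [d[i, j] for a, i in enumerate(idxs) for j in idxs[a + 1:]]
        )
    names = sorted(by_breed)
    for a, b1 in enumerate(names):
        for b2 in names[a + 1:]:
            dm.between_breed[(b1, b2)] = _mean(
                [d[i, j] for i in by_breed[b1] for j in by_breed[b2]]
            )
    return dm


class Tree:
    """Minimal unrooted tree for NJ output (root is a trifurcation)."""

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length
        self.children: list[Tree] = []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label or ""]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: Tree, top: bool) -> str:
            if node.children:
                inner = ",".join(fmt(c, False) for c in node.children)
                s = f"({inner})"
            else:
                s = _sanitize_label(node.label or "")
            if not top:
                s += f":{node.length:.{digits}g}"
            return s

        return fmt(self, True) + ";"

    def splits(self) -> list[frozenset[str]]:
        """Leaf sets of all clades below the (arbitrary) root."""
        out = []

        def walk(node: Tree) -> frozenset[str]:
            if not node.children:
                return frozenset([node.label or ""])
            acc: frozenset[str] = frozenset()
            for c in node.children:
                acc |= walk(c)
            out.append(acc)
            return acc

        walk(self)
        return out


def _sanitize_label(label: str) -> str:
    for ch in " ();:,[]'":
        label = label.replace(ch, "_")
    return label


def neighbor_joining(
    dm: DistanceMatrix | np.ndarray, labels: Sequence[str] | None = None
) -> Tree:
    """Classic neighbor joining (Q-criterion, standard branch lengths).

    Ties in Q are broken by the lexicographically smallest pair of node
    labels (a node is labelled by its smallest member leaf), so the result
    is deterministic.  Negative branch lengths are clamped to zero and the
    clamped total recorded on the tree as ``negative_deficit``.
    """
    if isinstance(dm, DistanceMatrix):
        labels = dm.samples
        d = dm.values.copy().astype(float)
    else:
        d = np.asarray(dm, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing pairs")

    nodes = [Tree(label=lab) for lab in labels]
    names = [lab for lab in labels]  # lexicographic tie-break handles
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((names[i], names[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        vj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        parent = Tree()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.children = [nodes[i], nodes[j]]
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # close with the 3-point formulas at the trifurcating root
    root = Tree()
    (a, b, c) = nodes
    a.length = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    b.length = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    c.length = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    root.children = [a, b, c]
    root.negative_deficit = deficit  # type: ignore[attr-defined]
    return root


def is_monophyletic(tree: Tree, group: Sequence[str]) -> bool:
    """True iff the group forms a clade on the unrooted tree (either side of
    some branch equals the group)."""
    target = frozenset(group)
    all_leaves = frozenset(tree.leaves())
    if not target <= all_leaves:
        raise ValueError("group contains unknown leaves")
    if len(target) <= 1:
        return True
    for split in tree.splits():
        if split == target or (all_leaves - split) == target:
            return True
    return False


def load_bovine_annotation() -> pd.DataFrame:
    """Packaged per-chromosome table: sizes, gene counts and published SNP
    counts (GBS and BeadChip)."""
    src = resources.files("gbskit.data").joinpath("bos_umd31.tsv")
    with src.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df


@dataclass
class DensityTable:
    """Per-chromosome counts and densities plus a totals row."""

    table: pd.DataFrame
    totals: pd.Series
    unmapped: int
    correlations: dict[str, float]


def chromosome_density(
    annotation: pd.DataFrame,
    snp_counts: Mapping[str, int] | None = None,
    snp_count_column: str = "gbs_snps",
) -> DensityTable:
    """Compute per-chromosome SNP/gene densities and their correlations.

    ``snp_counts`` (chrom -> count, 'unmapped' allowed) overrides the
    annotation's ``snp_count_column``.  Densities are count / size (N/Mbp).
    Pearson correlations are computed over autosomes only (numeric
    chromosome names); reported:

    - ``size_vs_snp_density``: autosome size vs SNP density,
    - ``size_vs_mean_spacing``: autosome size vs mean inter-SNP spacing
      (size/count, kb per SNP) -- the magnitude usually quoted for the
      density-size relationship,
    - ``gene_density_vs_snp_density``.
    """
    df = annotation.copy()
    if snp_counts is not None:
        df["snps"] = [snp_counts.get(str(c), 0) for c in df["chrom"]]
        if "unmapped" not in set(df["chrom"]):
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        [{"chrom": "unmapped", "snps": snp_counts.get("unmapped", 0)}]
                    ),
                ],
                ignore_index=True,
            )
    else:
        df["snps"] = df[snp_count_column]
    mapped = df[df["chrom"] != "unmapped"].copy()
    unmapped = int(df.loc[df["chrom"] == "unmapped", "snps"].fillna(0).sum())
    mapped["size_mbp"] = mapped["size_mbp"].astype(float)
    if "genes" in mapped:
        mapped["gene_density"] = mapped["genes"].astype(float) / mapped["size_mbp"]
    mapped["snp_density"] = mapped["snps"].astype(float) / mapped["size_mbp"]
    mapped["mean_spacing_kb"] = np.where(
        mapped["snps"] > 0, mapped["size_mbp"] * 1000.0 / mapped["snps"], np.nan
    )

    totals = pd.Series(
        {
            "size_mbp": mapped["size_mbp"].sum(),
            "snps": mapped["snps"].sum() + unmapped,
            "mapped_snps": mapped["snps"].sum(),
            "mapped_snp_density": mapped["snps"].sum() / mapped["size_mbp"].sum(),
        }
    )
    if "genes" in mapped:
        totals["genes"] = mapped["genes"].sum()

    is_auto = mapped["chrom"].str.fullmatch(r"\d+")
    auto = mapped[is_auto]
    correlations: dict[str, float] = {}

    def _corr(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 3 or np.nanstd(x) == 0 or np.nanstd(y) == 0:
            warnings.warn("degenerate input: correlation undefined")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    if len(auto):
        correlations["size_vs_snp_density"] = _corr(
            auto["size_mbp"], auto["snp_density"]
        )
        correlations["size_vs_mean_spacing"] = _corr(
            auto["size_mbp"], auto["mean_spacing_kb"]
        )
        if "gene_density" in auto:
            correlations["gene_density_vs_snp_density"] = _corr(
                auto["gene_density"], auto["snp_density"]
            )
        x_rows = mapped[mapped["chrom"] == "X"]
        if len(x_rows):
            correlations["x_snp_density"] = float(x_rows["snp_density"].iloc[0])
    return DensityTable(
        table=mapped.reset_index(drop=True),
        totals=totals,
        unmapped=unmapped,
        correlations=correlations,
    )


@dataclass
class GapDistribution:
    gaps_by_chrom: dict[str, np.ndarray]
    binned_fractions: dict[str, float]
    regional_means: pd.DataFrame  # chrom x (first, middle, last)


def gap_statistics(
    chrom: Sequence[str],
    pos: Sequence[int],
    chrom_sizes: Mapping[str, float] | None = None,
) -> GapDistribution:
    """Adjacent-SNP gap statistics within chromosomes.

    Gaps never span chromosomes.  Binned fractions use <50, 50-100, 100-150
    and >150 kb classes.  When ``chrom_sizes`` (bp) is given, each gap is
    assigned to the chromosome third containing its midpoint and per-region
    mean gaps are reported.
    """
    by_chrom: dict[str, list[int]] = {}
    for c, p in zip(chrom, pos):
        by_chrom.setdefault(c, []).append(int(p))
    gaps_by_chrom = {}
    regional_rows = {}
    all_gaps = []
    for c, positions in sorted(by_chrom.items()):
        positions = np.sort(np.asarray(positions))
        gaps = np.diff(positions)
        gaps_by_chrom[c] = gaps
        all_gaps.append(gaps)
        if chrom_sizes is not None and c in chrom_sizes and len(gaps):
            L = float(chrom_sizes[c])
            mids = (positions[:-1] + positions[1:]) / 2.0
            region = np.minimum((mids / (L / 3.0)).astype(int), 2)
            regional_rows[c] = [
                float(gaps[region == r].mean()) if (region == r).any() else float("nan")
                for r in range(3)
            ]
    gaps = np.concatenate(all_gaps) if all_gaps else np.zeros(0, dtype=int)
    kb = gaps / 1000.0
    total = len(kb)
    if total:
        fractions = {
            "<50kb": float((kb < 50).mean()),
            "50-100kb": float(((kb >= 50) & (kb < 100)).mean()),
            "100-150kb": float(((kb >= 100) & (kb < 150)).mean()),
            ">150kb": float((kb >= 150).mean()),
        }
    else:
        fractions = {"<50kb": 0.0, "50-100kb": 0.0, "100-150kb": 0.0, ">150kb": 0.0}
    regional = pd.DataFrame(
        regional_rows, index=["first_third", "middle_third", "last_third"]
    ).T
    return GapDistribution(
        gaps_by_chrom=gaps_by_chrom,
        binned_fractions=fractions,
        regional_means=regional,
    )


def density_extrapolation(
    total_snps: int, total_tag_bp: float, genome_bp: float
) -> tuple[float, float]:
    """SNP density per kb of tag sequence and its genome-wide extrapolation.

    Returns (snps_per_kb, projected genome-wide SNP count).
    """
    if total_tag_bp <= 0 or genome_bp <= 0:
        raise ValueError("tag and genome sizes must be positive")
    snps_per_kb = total_snps / (total_tag_bp / 1000.0)
    genome_total = snps_per_kb * genome_bp / 1000.0
    return snps_per_kb, genome_total
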