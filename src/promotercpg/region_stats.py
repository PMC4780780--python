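"""Region-wise CpG frequencies and rank-based group comparisons.

Promoter windows are partitioned into four regions (+500..0, 0..-500,
-500..-1000 and -1000..-3000 relative to the TSS, half-open with the TSS
base in the first exon region) and a per-gene motif frequency is computed
from raw, unsmoothed dinucleotide counts in each region: smoothing across
region boundaries would leak signal between regions.

Group comparisons follow the standard rank-statistics toolkit: a
Kruskal-Wallis test across KEGG classes per region (Bonferroni-corrected
over regions), Dunn's post-hoc pairwise z tests when the omnibus test
rejects, and a Wilcoxon rank-sum test of a focal gene set against the
remaining genes. Ties are handled by mid-ranks with the standard tie
corrections throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _seq
from .genome_io import PromoterWindow

logger = logging.getLogger(__name__)

__all__ = [
    "RegionPartition",
    "DEFAULT_PARTITION",
    "TestResult",
    "region_frequency_table",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
    "bonferroni_adjust",
    "class_region_analysis",
    "set_region_analysis",
    "ClassRegionResult",
    "SetRegionResult",
]


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint half-open relative-position intervals covering the window."""

    regions: tuple = (
        ("R1", 0, 500),
        ("R2", -500, 0),
        ("R3", -1000, -500),
        ("R4", -3000, -1000),
    )

    def __post_init__(self):
        ivals = sorted((lo, hi) for _, lo, hi in self.regions)
        if any(lo >= hi for lo, hi in ivals):
            raise ValueError("each region must be a non-empty half-open interval")
        for (l0, h0), (l1, h1) in zip(ivals, ivals[1:]):
            if l1 < h0:
                raise ValueError("regions must be disjoint")
            if l1 != h0:
                raise ValueError("regions must tile the window without gaps")

    @property
    def labels(self) -> tuple:
        return tuple(label for label, _, _ in self.regions)

    def span(self) -> tuple:
        los = [lo for _, lo, _ in self.regions]
        his = [hi for _, _, hi in self.regions]
        return min(los), max(his)


DEFAULT_PARTITION = RegionPartition()


@dataclass
class TestResult:
    """Outcome of one rank test (omnibus, pairwise or two-sample)."""

    test: str
    statistic: float
    pvalue: float
    p_adjusted: float = None
    groups: tuple = None
    n: tuple = None


def region_frequency_table(
    windows: Iterable[PromoterWindow],
    partition: RegionPartition = DEFAULT_PARTITION,
    motif: str = "CG",
) -> pd.DataFrame:
    """Per-gene, per-region motif frequency from raw dinucleotide counts.

    The frequency is (# motif starts whose first base lies in the region) /
    (# dinucleotide start positions in the region with both bases
    unambiguous). Genes covering no position of a region get no row there.
    """
    m0, m1 = _seq.encode(motif)
    rows = []
    for w in windows:
        codes = _seq.encode(w.seq)
        first, second = codes[:-1], codes[1:]
        hit = (first == m0) & (second == m1)
        valid = (first != _seq.N) & (second != _seq.N)
        # dinucleotide start at string index i has relative position i - offset
        for label, lo, hi in partition.regions:
            a = max(0, lo + w.offset_of_tss)
            b = min(len(codes) - 1, hi + w.offset_of_tss)
            if b <= a:
                continue
            n_pos = int(valid[a:b].sum())
            if n_pos == 0:
                continue
            rows.append((w.gene_id, label, int(hit[a:b].sum()) / n_pos, n_pos))
    return pd.DataFrame(rows, columns=["gene_id", "region", "cpg_freq", "n_positions"])


def _as_groups(groups: Sequence, labels: Sequence[str] = None):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(arrays)))
    return arrays, tuple(labels)


def kruskal_wallis(groups: Sequence, labels: Sequence[str] = None) -> TestResult:
    """Kruskal-Wallis H with mid-ranks, tie correction and chi-square p.

    All pooled values identical gives H = 0, p = 1 (no evidence of
    difference, not an error).
    """
    arrays, labels = _as_groups(groups, labels)
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    if np.unique(np.concatenate(arrays)).size == 1:
        # all pooled values identical: no rank information, H = 0 by convention
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return TestResult(
        test="kruskal-wallis",
        statistic=float(h),
        pvalue=float(p),
        groups=labels,
        n=tuple(a.size for a in arrays),
    )


def dunn_posthoc(
    groups: Sequence,
    labels: Sequence[str] = None,
    adjust: str = "none",
) -> list:
    """Dunn's pairwise mean-rank z tests after Kruskal-Wallis.

    z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))
    with mid-ranks, tie term T = sum(t^3 - t), and two-sided normal p.
    ``adjust``: 'none' (default) or 'bonferroni' over the k(k-1)/2 pairs.
    """
    arrays, labels = _as_groups(groups, labels)
    if len(arrays) < 2:
        raise ValueError("dunn_posthoc needs at least 2 groups")
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    results = []
    pairs = list(combinations(range(len(arrays)), 2))
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            TestResult(
                test="dunn",
                statistic=float(z),
                pvalue=float(min(p, 1.0)),
                groups=(labels[i], labels[j]),
                n=(sizes[i], sizes[j]),
            )
        )
    if adjust == "bonferroni":
        adj = bonferroni_adjust([r.pvalue for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


def wilcoxon_rank_sum(
    x: Sequence,
    y: Sequence,
    labels: tuple = ("x", "y"),
    exact_max_n: int = 20,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    The reported statistic is the mid-rank sum of ``x``. The p-value is
    exact (full enumeration) when n_x + n_y <= ``exact_max_n`` and the
    pooled data carry no ties, otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least 1 value")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_stat = float(ranks[: x.size].sum())
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= exact_max_n) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        test=f"wilcoxon-rank-sum ({method})",
        statistic=w_stat,
        pvalue=float(min(res.pvalue, 1.0)),
        groups=labels,
        n=(x.size, y.size),
    )


def bonferroni_adjust(pvals: Sequence[float], m: int = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the number of p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if m is None:
        m = pvals.size
    if m < pvals.size:
        raise ValueError("family size m must cover all tests in the family")
    return np.minimum(1.0, m * pvals)


def _compact_letters(labels: Sequence[str], mean_ranks: Mapping[str, float], sig_pairs: set) -> dict:
    """Compact letter display: groups share a letter iff not significantly different."""
    order = sorted(labels, key=lambda g: -mean_ranks[g])
    letter_sets: list = []
    for g in order:
        placed = False
        for members in letter_sets:
            if all(frozenset((g, m)) not in sig_pairs for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    letters = {g: "" for g in labels}
    for i, members in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in members:
            letters[g] += ch
    return letters


@dataclass
class ClassRegionResult:
    """Per-region outcome of the KEGG-class comparison."""

    region: str
    kruskal: TestResult
    significant: bool
    dunn: list = field(default_factory=list)
    letters: dict = None


@dataclass
class SetRegionResult:
    """Per-region outcome of the focal-set vs background comparison."""

    region: str
    wilcoxon: TestResult
    significant: bool
    direction: int  # +1 focal higher, -1 focal lower, 0 no difference


def _region_values(table: pd.DataFrame, region: str) -> pd.Series:
    sub = table[table["region"] == region]
    return pd.Series(sub["cpg_freq"].values, index=sub["gene_id"].values)


def class_region_analysis(
    table: pd.DataFrame,
    class_sets: Mapping[str, Sequence[str]],
    partition: RegionPartition = DEFAULT_PARTITION,
    alpha: float = 0.05,
    family: int = None,
    dunn_adjust: str = "none",
) -> list:
    """Kruskal-Wallis across classes per region, Dunn post-hoc where it rejects.

    The omnibus p is Bonferroni-corrected over the regions (``family``
    defaults to the number of regions). Dunn pairs and compact letter codes
    are reported only for regions whose adjusted omnibus p is below
    ``alpha``. Regions with fewer than two populated classes are skipped
    with a warning.
    """
    usable = {c: list(g) for c, g in class_sets.items() if len(g) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 classes with at least 2 genes each")
    if family is None:
        family = len(partition.regions)

    results = []
    for label in partition.labels:
        vals = _region_values(table, label)
        groups, names = [], []
        for cls, genes in usable.items():
            g = vals.reindex(genes).dropna().values
            if g.size >= 1:
                groups.append(g)
                names.append(cls)
        if len(groups) < 2:
            logger.warning("region %s: fewer than 2 populated classes, skipped", label)
            continue
        kw = kruskal_wallis(groups, names)
        kw.p_adjusted = float(bonferroni_adjust([kw.pvalue], m=family)[0])
        significant = kw.p_adjusted < alpha
        res = ClassRegionResult(region=label, kruskal=kw, significant=significant)
        if significant:
            res.dunn = dunn_posthoc(groups, names, adjust=dunn_adjust)
            pooled = np.concatenate(groups)
            ranks = sps.rankdata(pooled)
            mean_ranks, start = {}, 0
            for name, g in zip(names, groups):
                mean_ranks[name] = ranks[start : start + g.size].mean()
                start += g.size
            sig_pairs = {
                frozenset(r.groups)
                for r in res.dunn
                if (r.p_adjusted if r.p_adjusted is not None else r.pvalue) < alpha
            }
            res.letters = _compact_letters(names, mean_ranks, sig_pairs)
        results.append(res)
    return results


def set_region_analysis(
    table: pd.DataFrame,
    focal_set: Iterable[str],
    partition: RegionPartition = DEFAULT_PARTITION,
    alpha: float = 0.05,
    family: int = None,
) -> list:
    """Wilcoxon rank-sum of a focal gene set against all remaining genes, per region.

    Significance is flagged at ``alpha`` after Bonferroni correction over
    the regions; the sign of the mean-rank difference gives the direction.
    """
    focal = set(focal_set)
    all_genes = set(table["gene_id"].unique())
    if not focal & all_genes:
        raise ValueError("focal set shares no genes with the frequency table")
    if not all_genes - focal:
        raise ValueError("focal set covers every gene: empty complement")
    if family is None:
        family = len(partition.regions)

    results = []
    for label in partition.labels:
        vals = _region_values(table, label)
        in_focal = np.array([g in focal for g in vals.index])
        x, y = vals.values[in_focal], vals.values[~in_focal]
        if x.size < 1 or y.size < 1:
            logger.warning("region %s: focal or complement empty, skipped", label)
            continue
        wt = wilcoxon_rank_sum(x, y, labels=("focal", "background"))
        wt.p_adjusted = float(bonferroni_adjust([wt.pvalue], m=family)[0])
        expected = x.size * (x.size + y.size + 1) / 2.0
        direction = int(np.sign(wt.statistic - expected))
        results.append(
            SetRegionResult(
                region=label,
                wilcoxon=wt,
                significant=wt.p_adjusted < alpha,
                direction=direction,
            )
        )
    return results


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten analysis results into a stats table (one row per test)."""
    rows = []
    for r in results:
        if isinstance(r, ClassRegionResult):
            k = r.kruskal
            rows.append(
                (r.region, k.test, "|".join(k.groups), k.statistic, k.pvalue, k.p_adjusted, r.significant)
            )
            for d in r.dunn:
                rows.append(
                    (r.region, d.test, "|".join(d.groups), d.statistic, d.pvalue, d.p_adjusted, None)
                )
        elif isinstance(r, SetRegionResult):
            w = r.wilcoxon
            rows.append(
                (r.region, w.test, "|".join(w.groups), w.statistic, w.pvalue, w.p_adjusted, r.significant)
            )
    return pd.DataFrame(
        rows, columns=["region", "test", "groups", "statistic", "p", "p_adj", "significant"]
    )
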