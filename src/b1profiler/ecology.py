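"""Amplicon-table community ecology.

Relative abundance, Shannon diversity, Bray–Curtis dissimilarity with
average-linkage (UPGMA) clustering, grouped rank tests, depth-layer
assignment, and Dufrêne–Legendre indicator species analysis (IndVal) with
seeded permutation p-values.

The IndVal statistic for taxon *i* and group *j* is the product of
specificity ``A = mean abundance in j / sum of group mean abundances`` and
fidelity ``B = fraction of samples in j where the taxon occurs``; the
reported group is the argmax over groups and significance comes from random
relabelling of samples with fixed group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.stats import kruskal as _sp_kruskal
from scipy.stats import mannwhitneyu as _sp_mannwhitneyu

from .errors import ConfigurationError, ConsistencyError

LAYERS = ("epipelagic", "mesopelagic", "bathypelagic")
EPIPELAGIC_MAX_M = 200.0
MESOPELAGIC_MAX_M = 1000.0

_TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def assign_depth_layer(depth_m: float) -> str:
    """Water-column layer: epipelagic (<=200 m), mesopelagic (200–1000 m],
    bathypelagic below. Boundary depths belong to the shallower layer."""
    if depth_m < 0:
        raise ConfigurationError(f"negative depth {depth_m}")
    if depth_m <= EPIPELAGIC_MAX_M:
        return "epipelagic"
    if depth_m <= MESOPELAGIC_MAX_M:
        return "mesopelagic"
    return "bathypelagic"


def drop_chloroplasts(counts: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Remove ASVs classified as chloroplasts (taxonomy substring match,
    case-insensitive)."""
    tax = taxonomy.reindex(counts.index).fillna("")
    keep = ~tax.str.contains("chloroplast", case=False)
    return counts.loc[keep]


def relative_abundance(
    counts: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    collapse_rank: str | None = None,
) -> pd.DataFrame:
    """Per-sample proportions, optionally collapsing taxa at a taxonomy rank.

    Each sample column of the result sums to 1. With ``collapse_rank``,
    counts sharing the same taxonomy prefix down to that rank are summed
    before normalizing.
    """
    if (counts.to_numpy() < 0).any():
        raise ConsistencyError("negative counts")
    if collapse_rank is not None:
        if taxonomy is None:
            raise ConfigurationError("collapse_rank requires a taxonomy series")
        if collapse_rank not in _TAXONOMY_RANKS:
            raise ConfigurationError(f"unknown rank {collapse_rank!r}")
        depth = _TAXONOMY_RANKS.index(collapse_rank) + 1
        tax = taxonomy.reindex(counts.index).fillna("unclassified")
        labels = tax.map(lambda t: ";".join(p.strip() for p in t.split(";")[:depth]))
        counts = counts.groupby(labels).sum()
    sums = counts.sum(axis=0)
    zero = sorted(sums.index[sums == 0])
    if zero:
        raise ConsistencyError(f"all-zero samples: {zero}")
    return counts / sums


def shannon_index(proportions: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p (natural log by default)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ConsistencyError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConsistencyError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity BC = 1 - 2 sum(min(x,y)) / sum(x+y) in [0,1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ConsistencyError("vectors differ in length")
    if (xa < 0).any() or (ya < 0).any():
        raise ConsistencyError("negative abundances")
    if xa.sum() == 0 and ya.sum() == 0:
        raise ConsistencyError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(xa, ya))


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis between sample columns of an abundance table."""
    samples = list(table.columns)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bray_curtis(table.iloc[:, i], table.iloc[:, j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two merged clusters (member labels) and
    the mean inter-cluster dissimilarity at which they fused."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float


class Dendrogram:
    """Average-linkage merge tree over labelled samples."""

    def __init__(self, labels: Sequence[str], merges: list[Merge]):
        self.labels = list(labels)
        self.merges = merges

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaves sit at height 0 and each internal
        node at half its merge height, so branch lengths are height/2
        differences."""
        node: dict[tuple[str, ...], str] = {(l,): l for l in self.labels}
        height: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.labels}
        key = None
        for m in self.merges:
            lh, rh = height[m.left], height[m.right]
            bl_l = m.height / 2.0 - lh / 2.0
            bl_r = m.height / 2.0 - rh / 2.0
            key = tuple(sorted(m.left + m.right))
            node[key] = f"({node[m.left]}:{bl_l:.10g},{node[m.right]}:{bl_r:.10g})"
            height[key] = m.height
        if key is None:  # single leaf
            return f"{self.labels[0]};"
        return node[key] + ";"


def average_linkage(dissimilarity: pd.DataFrame | np.ndarray,
                    labels: Sequence[str] | None = None) -> Dendrogram:
    """UPGMA agglomeration on a square dissimilarity matrix.

    Repeatedly merges the pair of clusters with the smallest arithmetic-mean
    inter-cluster dissimilarity (mean over all original member pairs). Ties
    are broken by the lexicographically smallest combined member-label tuple.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in dissimilarity.columns]
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        if labels is None:
            labels = [f"S{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n):
        raise ConsistencyError("dissimilarity matrix must be square")
    if np.abs(d - d.T).max(initial=0.0) > 1e-9:
        raise ConsistencyError("dissimilarity matrix is asymmetric beyond 1e-9")
    if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
        raise ConsistencyError("dissimilarity matrix diagonal must be zero")
    if (d < 0).any():
        raise ConsistencyError("negative dissimilarities")

    idx = {label: i for i, label in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    merges: list[Merge] = []

    def mean_link(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(np.mean([d[idx[x], idx[y]] for x in a for y in b]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = mean_link(clusters[i], clusters[j])
                tie_key = tuple(sorted(clusters[i] + clusters[j]))
                cand = (h, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        h, _, i, j = best
        left, right = clusters[i], clusters[j]
        merges.append(Merge(left=left, right=right, height=h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(left + right)))
    return Dendrogram(labels, merges)


def grouped_rank_test(
    values: Sequence[float],
    groups: Sequence[str],
    test: str = "kruskal_wallis",
) -> tuple[float, float]:
    """Kruskal–Wallis or two-group Wilcoxon rank-sum test.

    Mid-rank tie correction, two-sided asymptotic p-value. Degenerate input
    where every value is identical returns (0.0, 1.0).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape[0] != g.shape[0]:
        raise ConsistencyError("values and groups differ in length")
    uniq = sorted(set(g.tolist()))
    arrays = [v[g == u] for u in uniq]
    if any(len(a) == 0 for a in arrays):
        raise ConsistencyError("every group needs at least one observation")
    if test == "kruskal_wallis":
        if len(arrays) < 2:
            raise ConfigurationError("kruskal_wallis needs >= 2 groups")
        if np.all(v == v[0]):
            return 0.0, 1.0
        stat, p = _sp_kruskal(*arrays)
        return float(stat), float(p)
    if test == "wilcoxon_rank_sum":
        if len(arrays) != 2:
            raise ConfigurationError("wilcoxon_rank_sum needs exactly 2 groups")
        if np.all(v == v[0]):
            return 0.0, 1.0
        res = _sp_mannwhitneyu(arrays[0], arrays[1], alternative="two-sided",
                               use_continuity=False, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ConfigurationError(f"unknown test {test!r}")


def indval(
    table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Indicator species analysis (single-group Dufrêne–Legendre IndVal).

    Parameters
    ----------
    table:
        Taxa x samples count (or abundance) table.
    groups:
        sample_id -> group label; >= 2 groups each with >= 1 sample.
    n_permutations:
        Number of random sample relabelings (>= 99 for p resolution).
    seed:
        Seed for the permutation RNG; same seed gives bit-identical output.

    Returns one row per taxon: the best group, the observed statistic, and
    the permutation p-value ``(1 + #{perm >= obs}) / (1 + n_permutations)``.
    """
    if n_permutations < 99:
        raise ConfigurationError("n_permutations must be >= 99")
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    g = g.reindex(table.columns)
    if g.isna().any():
        raise ConsistencyError(
            f"samples without group label: {sorted(table.columns[g.isna()])}"
        )
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ConfigurationError("indval needs >= 2 groups")

    x = table.to_numpy(dtype=float)          # taxa x samples
    member = np.stack([(g == lab).to_numpy() for lab in labels], axis=1)  # s x g
    sizes = member.sum(axis=0).astype(float)

    def stats_for(m: np.ndarray) -> np.ndarray:
        means = x @ m / sizes                # taxa x groups
        tot = means.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(tot > 0, means / tot, 0.0)
        b = (x > 0).astype(float) @ m / sizes
        return a * b

    obs = stats_for(member)
    best_idx = obs.argmax(axis=1)
    best_stat = obs.max(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0], dtype=int)
    s = x.shape[1]
    for _ in range(n_permutations):
        perm = rng.permutation(s)
        perm_stat = stats_for(member[perm]).max(axis=1)
        exceed += perm_stat >= best_stat
    pvals = (1 + exceed) / (1 + n_permutations)

    return pd.DataFrame({
        "taxon": list(table.index),
        "group": [labels[i] for i in best_idx],
        "stat": best_stat,
        "p_value": pvals,
        "n_permutations": n_permutations,
    })


def prototroph_share(
    rel_abundance: pd.DataFrame,
    genotype_map: Mapping[str, str],
) -> pd.Series:
    """Per-sample summed relative abundance of taxa mapped to PROTOTROPH.

    Taxa absent from the map count toward the denominator (which is fixed at
    1 for proportion columns) but never the numerator.
    """
    proto = [t for t in rel_abundance.index
             if genotype_map.get(t) == "PROTOTROPH"]
    if not proto:
        return pd.Series(0.0, index=rel_abundance.columns, name="prototroph_share")
    share = rel_abundance.loc[proto].sum(axis=0)
    share.name = "prototroph_share"
    return share
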