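"""Population-structure and diversity statistics.

Identity-by-state and Kimura two-parameter distances, principal-coordinate
(classical MDS) decomposition, BIONJ tree reconstruction, linkage
disequilibrium decay, windowed nucleotide diversity, method-of-moments
inbreeding coefficients, and windowed Weir-Cockerham Fst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from soyepi.datatypes import GenotypeMatrix

__all__ = [
    "DistanceMatrix", "LDDecayCurve", "WindowStat",
    "ibs_matrix", "k2p_distance", "pca_from_distance", "bionj_tree",
    "ld_decay", "pi_windows", "inbreeding_f", "fst_windows",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)


@dataclass
class LDDecayCurve:
    """Mean r-squared per physical-distance bin, with pair counts."""
    bin_edges: np.ndarray          # (n_bins + 1,), half-open [lo, hi)
    mean_r2: np.ndarray            # (n_bins,), nan where no pairs
    pair_counts: np.ndarray        # (n_bins,)
    mean_r2_within_100kb: float = float("nan")
    mean_r2_within_500kb: float = float("nan")
    n_skipped_monomorphic: int = 0


@dataclass
class WindowStat:
    chromosome: str
    start: int
    end: int
    value: float
    n_sites: int
    truncated: bool = False


# ---------------------------------------------------------------------------
# identity-by-state
# ---------------------------------------------------------------------------

def ibs_matrix(genotypes: GenotypeMatrix) -> tuple[np.ndarray, DistanceMatrix]:
    """Pairwise IBS similarity and the 1-IBS distance matrix.

    IBS(i,j) = mean over markers of (2 - |g_i - g_j|) / 2, i.e. the average
    fraction of shared alleles.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if genotypes.n_markers == 0:
        raise ValueError("need at least 1 marker")
    manhattan = _pairwise_abs_diff_sum(genotypes.dosages)
    ibs = 1.0 - manhattan / (2.0 * genotypes.n_markers)
    np.fill_diagonal(ibs, 1.0)
    dist = DistanceMatrix(list(genotypes.sample_ids), 1.0 - ibs)
    return ibs, dist


def _pairwise_abs_diff_sum(dosages: np.ndarray) -> np.ndarray:
    """sum_m |g_i - g_j| via dosage-indicator cross-products (avoids an
    n^2 x p broadcast)."""
    ind = [(dosages == v).astype(np.float64) for v in (0, 1, 2)]
    total = np.zeros((dosages.shape[0],) * 2)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            total += abs(a - b) * (ind[a] @ ind[b].T)
    return total


# ---------------------------------------------------------------------------
# Kimura two-parameter distance
# ---------------------------------------------------------------------------

def k2p_distance(
    genotypes: GenotypeMatrix, saturation_cap: float = 5.0
) -> DistanceMatrix:
    """Kimura two-parameter distance between samples.

    Pairs are compared only at sites where both samples are homozygous
    (each call treated as a haploid base; the panel is ~97% homozygous, so
    heterozygote substitution-type ambiguity is avoided).  With P the
    transition and Q the transversion difference fractions,

        d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)).

    Saturated pairs (log argument <= 0) are set to ``saturation_cap`` and a
    warning is emitted.
    """
    dos = genotypes.dosages
    transition = np.array([m.is_transition for m in genotypes.markers], dtype=np.float64)
    hom_ref = (dos == 0).astype(np.float64)
    hom_alt = (dos == 2).astype(np.float64)
    hom = hom_ref + hom_alt

    compared = hom @ hom.T
    diff_ts = hom_ref @ (hom_alt * transition).T
    diff_ts = diff_ts + diff_ts.T
    diff_tv = hom_ref @ (hom_alt * (1.0 - transition)).T
    diff_tv = diff_tv + diff_tv.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(compared > 0, diff_ts / compared, 0.0)
        Q = np.where(compared > 0, diff_tv / compared, 0.0)
        arg = (1.0 - 2.0 * P - Q) * np.sqrt(np.clip(1.0 - 2.0 * Q, 0.0, None))
        d = np.where(arg > 0, -0.5 * np.log(np.where(arg > 0, arg, 1.0)), np.inf)

    n_saturated = int(np.isinf(d).sum() // 2)
    if n_saturated:
        warnings.warn(
            f"k2p_distance: {n_saturated} saturated pairs capped at {saturation_cap}"
        )
        d = np.where(np.isinf(d), saturation_cap, d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(genotypes.sample_ids), d)


# ---------------------------------------------------------------------------
# classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

def pca_from_distance(
    distance: DistanceMatrix, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Classical multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt eigenvalue) plus the proportion of positive
    eigenvalue mass explained per returned axis.
    """
    D = distance.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(1e-10, 1e-12 * abs(evals[0]))
    n_pos = int(positive.sum())
    if n_components > n_pos:
        warnings.warn(
            f"pca_from_distance: only {n_pos} positive eigenvalues; "
            f"truncating from {n_components}"
        )
        n_components = n_pos
    coords = evecs[:, :n_components] * np.sqrt(evals[:n_components])
    explained = evals[:n_components] / evals[:n_pos].sum() if n_pos else np.zeros(0)
    return coords, explained


# ---------------------------------------------------------------------------
# BIONJ
# ---------------------------------------------------------------------------

def bionj_tree(distance: DistanceMatrix, clamp_negative: bool = True) -> str:
    """Reconstruct an unrooted tree with the variance-weighted
    neighbor-joining agglomeration (BIONJ) and return it as Newick text.

    At each step the closest pair under the standard NJ criterion is joined;
    the reduced distance to the new node is the variance-optimal convex
    combination of the two old distances, and the variance matrix is updated
    alongside.  Negative branch lengths are clamped to zero with the deficit
    moved to the adjacent edge (standard practice; toggleable).
    """
    n = len(distance.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = distance.values.astype(float).copy()
    v = d.copy()  # variance estimates initialized to the distances
    nodes: list[str] = [_quote(s) for s in distance.sample_ids]
    active = list(range(n))

    while len(active) > 3:
        N = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (N - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if aj < ai:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (N - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, clamp_negative)

        others = [k for k in active if k not in (i, j)]
        if v[i, j] > 0:
            lam = 0.5 + (v[j, others].sum() - v[i, others].sum()) / (
                2.0 * (N - 2) * v[i, j]
            )
        else:
            lam = 0.5
        lam = min(1.0, max(0.0, lam))

        new_d = lam * (d[i, others] - li) + (1.0 - lam) * (d[j, others] - lj)
        new_v = lam * v[i, others] + (1.0 - lam) * v[j, others] - lam * (1.0 - lam) * v[i, j]

        u = i  # reuse slot i for the merged node
        d[u, others] = new_d
        d[others, u] = new_d
        v[u, others] = np.maximum(new_v, 0.0)
        v[others, u] = v[u, others]
        d[u, u] = 0.0
        nodes[u] = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        active.remove(j)

    # resolve the final three nodes with the exact three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    if clamp_negative:
        la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    return (
        f"({nodes[a]}:{_fmt(la)},{nodes[b]}:{_fmt(lb)},{nodes[c]}:{_fmt(lc)});"
    )


def _clamp_pair(li: float, lj: float, clamp: bool) -> tuple[float, float]:
    if not clamp:
        return li, lj
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _quote(name: str) -> str:
    if any(ch in name for ch in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# linkage disequilibrium decay
# ---------------------------------------------------------------------------

def ld_decay(
    genotypes: GenotypeMatrix,
    max_distance: int = 500_000,
    bin_width: int = 10_000,
) -> LDDecayCurve:
    """Genotype-correlation r^2 for every intra-chromosomal marker pair up
    to ``max_distance`` bp apart, binned by distance.

    Pairs involving a monomorphic marker are skipped and counted.  Also
    reports the overall (pair-weighted) mean r^2 within 100 kb and 500 kb.
    """
    dos = genotypes.dosages.astype(float)
    n = dos.shape[0]
    sd = dos.std(axis=0)
    poly = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(poly, (dos - dos.mean(axis=0)) / np.where(poly, sd, 1.0), 0.0)

    n_bins = int(np.ceil(max_distance / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    edges[-1] = max(edges[-1], max_distance)
    r2_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    sum_100, cnt_100 = 0.0, 0
    sum_500, cnt_500 = 0.0, 0
    n_skipped = 0

    chroms = genotypes.chromosomes
    positions = genotypes.positions
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        for a in range(len(idx) - 1):
            hi = np.searchsorted(pos, pos[a] + max_distance, side="right")
            if hi <= a + 1:
                continue
            partners = idx[a + 1: hi]
            dists = pos[a + 1: hi] - pos[a]
            ja = idx[a]
            if not poly[ja]:
                n_skipped += len(partners)
                continue
            ok = poly[partners]
            n_skipped += int((~ok).sum())
            if not ok.any():
                continue
            r = z[:, partners[ok]].T @ z[:, ja] / n
            r2 = r ** 2
            dd = dists[ok]
            bins = np.minimum(dd // bin_width, n_bins - 1).astype(int)
            np.add.at(r2_sum, bins, r2)
            np.add.at(counts, bins, 1)
            m100 = dd <= 100_000
            sum_100 += float(r2[m100].sum()); cnt_100 += int(m100.sum())
            m500 = dd <= 500_000
            sum_500 += float(r2[m500].sum()); cnt_500 += int(m500.sum())

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, r2_sum / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=mean_r2,
        pair_counts=counts,
        mean_r2_within_100kb=sum_100 / cnt_100 if cnt_100 else float("nan"),
        mean_r2_within_500kb=sum_500 / cnt_500 if cnt_500 else float("nan"),
        n_skipped_monomorphic=n_skipped,
    )


# ---------------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------------

def _iter_windows(length: int, window_size: int, window_step: int):
    start = 1
    while start <= length:
        end = start + window_size - 1
        yield start, min(end, length), end > length
        if end >= length:
            break
        start += window_step


def pi_windows(
    genotypes: GenotypeMatrix,
    window_size: int = 100_000,
    window_step: int = 10_000,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity per bp.

    Per segregating site, pi = c_ref * c_alt / C(2n, 2) over the 2n sampled
    chromosomes; a window's value is the sum over its sites divided by the
    window length in bp.  Windows start at position 1 and slide by
    ``window_step``; trailing truncated windows are emitted with a flag and
    normalized by their actual length.
    """
    n2 = 2 * genotypes.n_samples
    alt = genotypes.dosages.sum(axis=0)
    ref = n2 - alt
    pairs = n2 * (n2 - 1) / 2.0
    site_pi = ref * alt / pairs

    chroms = genotypes.chromosomes
    positions = genotypes.positions
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        length = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos.max())
        )
        csum = np.concatenate([[0.0], np.cumsum(site_pi[idx])])
        for start, end, truncated in _iter_windows(length, window_size, window_step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            value = (csum[hi] - csum[lo]) / (end - start + 1)
            out.append(WindowStat(chrom, start, end, float(value), int(hi - lo), truncated))
    return out


# ---------------------------------------------------------------------------
# inbreeding coefficient (method of moments)
# ---------------------------------------------------------------------------

def inbreeding_f(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-sample method-of-moments inbreeding coefficient.

    F = (O_hom - E_hom) / (L - E_hom) with E_hom = sum over sites of
    1 - 2 p (1-p) * 2n / (2n - 1), using the sample allele frequency with
    the small-sample correction.  Degenerate samples (L == E_hom) are
    reported as nan.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate frequencies")
    p = genotypes.alt_freq()
    n2 = 2 * genotypes.n_samples
    e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * n2 / (n2 - 1)
    e_hom = e_hom_site.sum()
    o_hom = (genotypes.dosages != 1).sum(axis=1).astype(float)
    L = float(genotypes.n_markers)
    denom = L - e_hom
    if abs(denom) < 1e-12:
        return np.full(genotypes.n_samples, np.nan)
    return (o_hom - e_hom) / denom


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(
    dosages: np.ndarray, group_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c for two
    groups, and a mask of usable (overall-polymorphic) sites."""
    r = 2
    g1 = dosages[group_index == 0]
    g2 = dosages[group_index == 1]
    n_i = np.array([g1.shape[0], g2.shape[0]], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("each group needs at least 2 samples")
    p_i = np.vstack([g1.mean(axis=0) / 2.0, g2.mean(axis=0) / 2.0])
    h_i = np.vstack([(g1 == 1).mean(axis=0), (g2 == 1).mean(axis=0)])

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    usable = (p_bar > 0) & (p_bar < 1)
    return a, b, c, usable


def fst_windows(
    genotypes: GenotypeMatrix,
    groups: np.ndarray,
    window_size: int = 100_000,
    window_step: int = 10_000,
    chromosome_lengths: dict[str, int] | None = None,
) -> tuple[list[WindowStat], float]:
    """Windowed and genome-wide Weir-Cockerham Fst for exactly two groups.

    ``groups`` is a per-sample label array with exactly two distinct values.
    Window and genome-wide values are ratios of summed components
    sum(a) / sum(a+b+c), not means of per-site ratios; sites monomorphic
    over the combined sample are skipped.
    """
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("fst_windows requires exactly two groups")
    gidx = (labels == uniq[1]).astype(int)
    a, b, c, usable = _wc_components(genotypes.dosages.astype(float), gidx)
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + np.where(usable, b, 0.0) + np.where(usable, c, 0.0), 0.0)
    # recompute cleanly to avoid double-masking confusion
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    abc = a + b + c

    genome_wide = float(a.sum() / abc.sum()) if abc.sum() != 0 else float("nan")

    chroms = genotypes.chromosomes
    positions = genotypes.positions
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        length = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos.max())
        )
        ca = np.concatenate([[0.0], np.cumsum(a[idx])])
        cabc = np.concatenate([[0.0], np.cumsum(abc[idx])])
        cn = np.concatenate([[0], np.cumsum(usable[idx].astype(int))])
        for start, end, truncated in _iter_windows(length, window_size, window_step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            denom = cabc[hi] - cabc[lo]
            value = (ca[hi] - ca[lo]) / denom if denom != 0 else float("nan")
            out.append(
                WindowStat(chrom, start, end, float(value), int(cn[hi] - cn[lo]), truncated)
            )
    return out, genome_wide
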