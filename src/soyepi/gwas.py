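"""Mixed-linear-model association on a quantitative trait.

The association model is

    y = mu + PCs * gamma + g * beta + u + e,   u ~ N(0, sigma_g^2 K),
                                               e ~ N(0, sigma_e^2 I)

with K a VanRaden genomic kinship matrix.  Variance components are
estimated once by REML under the null model on the spectral decomposition
of K (P3D), then every marker is tested by generalized least squares with a
Wald t test.  Optional compression replaces K by the group-averaged kinship
over clusters obtained by average-linkage clustering of the kinship-derived
distance; compression with as many groups as samples reproduces the
uncompressed model exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from soyepi.datatypes import GeneAnnotation, GenotypeMatrix, PhenotypeVector
from soyepi.markerset import snp_to_gene

log = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("kinship shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        evals = np.linalg.eigvalsh((v + v.T) / 2.0)
        if evals.min() < -1e-6 * max(1.0, evals.max()):
            raise ValueError("kinship must be positive semi-definite")
        self.values = (v + v.T) / 2.0


@dataclass
class AssociationResult:
    marker_id: str
    chromosome: str
    position: int
    effect: float
    se: float
    p_value: float
    neglog10_p: float
    maf: float
    significant: bool = False


# ---------------------------------------------------------------------------
# marker filtering
# ---------------------------------------------------------------------------

def maf_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.05
) -> tuple[GenotypeMatrix, list[tuple[str, float]]]:
    """Keep markers with MAF strictly greater than ``threshold``.

    Returns the filtered matrix and a report of removed (marker_id, maf).
    """
    maf = genotypes.maf()
    keep = maf > threshold
    removed = [
        (m.marker_id, float(f))
        for m, f, k in zip(genotypes.markers, maf, keep)
        if not k
    ]
    return genotypes.subset_markers(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_vanraden(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix: centered dosage cross-product
    scaled by 2 sum p(1-p)."""
    p = genotypes.alt_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship requires at least one polymorphic marker")
    M = genotypes.dosages[:, poly].astype(float) - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return KinshipMatrix(list(genotypes.sample_ids), M @ M.T / denom)


def compress_kinship(kinship: KinshipMatrix, n_groups: int) -> KinshipMatrix:
    """Average-linkage compression of the kinship matrix.

    Samples are clustered on the kinship-induced distance
    d_ij = K_ii + K_jj - 2 K_ij; the returned matrix replaces every entry by
    the mean kinship between the two samples' clusters.
    """
    K = kinship.values
    n = K.shape[0]
    if not (1 <= n_groups <= n):
        raise ValueError("n_groups must lie in [1, n_samples]")
    if n_groups == n:
        return kinship
    diag = np.diag(K)
    dist = np.sqrt(np.clip(diag[:, None] + diag[None, :] - 2.0 * K, 0.0, None))
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    n_found = labels.max() + 1
    group_means = np.zeros((n_found, n_found))
    counts = np.zeros((n_found, n_found))
    np.add.at(group_means, (labels[:, None], labels[None, :]), K)
    np.add.at(counts, (labels[:, None], labels[None, :]), 1.0)
    group_means /= counts
    return KinshipMatrix(list(kinship.sample_ids), group_means[labels][:, labels])


# ---------------------------------------------------------------------------
# REML / P3D machinery
# ---------------------------------------------------------------------------

def _reml_neg_loglik(log_lambda: float, s: np.ndarray, Uty: np.ndarray,
                     UtX: np.ndarray) -> float:
    """Negative restricted log-likelihood at variance ratio
    lambda = sigma_g^2 / sigma_e^2, on the eigenbasis of K."""
    lam = np.exp(log_lambda)
    w = lam * s + 1.0
    n, k = UtX.shape
    Xw = UtX / np.sqrt(w[:, None])
    yw = Uty / np.sqrt(w)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * (
        np.log(w).sum() + logdet_XtX + (n - k) * np.log(rss)
    )


def cmlm_assoc(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    kinship: KinshipMatrix | None = None,
    n_pcs: int = 3,
    compression_groups: int | None = None,
    variance_ratio: float | None = None,
    method: str = "p3d",
) -> list[AssociationResult]:
    """Compressed mixed-linear-model association scan.

    Parameters
    ----------
    n_pcs : number of principal-component covariates (from the kinship
        eigenvectors); 0 disables structure covariates.
    compression_groups : cluster count for kinship compression; ``None`` or
        ``n_samples`` leaves the model uncompressed.
    variance_ratio : fix lambda = sigma_g^2/sigma_e^2 instead of estimating
        it by REML (0.0 reduces the scan to ordinary least squares when K
        has orthonormal eigenvectors, e.g. K = I).
    method : "p3d" estimates variance components once under the null;
        "exact" re-estimates them for every marker model (slow).
    """
    if method not in ("p3d", "exact"):
        raise ValueError("method must be 'p3d' or 'exact'")
    y_aligned = phenotypes.align_to(genotypes)
    if y_aligned.sample_ids != genotypes.sample_ids:
        genotypes = genotypes.subset_samples(y_aligned.sample_ids)
    y = y_aligned.values
    n = len(y)

    if kinship is None:
        kinship = kinship_vanraden(genotypes)
    if kinship.sample_ids != genotypes.sample_ids:
        pos = {s: i for i, s in enumerate(kinship.sample_ids)}
        idx = np.array([pos[s] for s in genotypes.sample_ids])
        kinship = KinshipMatrix(
            list(genotypes.sample_ids), kinship.values[np.ix_(idx, idx)]
        )
    if compression_groups is not None:
        kinship = compress_kinship(kinship, compression_groups)

    s, U = np.linalg.eigh(kinship.values)
    s = np.clip(s, 0.0, None)

    # structure covariates: top kinship eigenvectors
    covariates = [np.ones(n)]
    if n_pcs > 0:
        covariates.extend(U[:, -(i + 1)] for i in range(min(n_pcs, n - 1)))
    X0 = np.column_stack(covariates)

    Uty = U.T @ y
    UtX0 = U.T @ X0

    if variance_ratio is not None:
        lam = float(variance_ratio)
    else:
        res = minimize_scalar(
            _reml_neg_loglik, bounds=(-12.0, 12.0), args=(s, Uty, UtX0),
            method="bounded", options={"xatol": 1e-6},
        )
        lam = float(np.exp(res.x))
        # compare against the boundary lambda -> 0 (pure OLS)
        if _reml_neg_loglik(-30.0, s, Uty, UtX0) < res.fun:
            lam = 0.0
    log.info("cmlm_assoc: REML variance ratio lambda = %.6g", lam)

    maf = genotypes.maf()
    results: list[AssociationResult] = []

    if method == "p3d":
        w = np.sqrt(lam * s + 1.0)
        yw = Uty / w
        Xw = UtX0 / w[:, None]
        Gw = (U.T @ genotypes.dosages.astype(float)) / w[:, None]
        Q, _ = np.linalg.qr(Xw)
        y_r = yw - Q @ (Q.T @ yw)
        G_r = Gw - Q @ (Q.T @ Gw)
        gss = (G_r ** 2).sum(axis=0)
        df = n - X0.shape[1] - 1
        yss = float(y_r @ y_r)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (G_r.T @ y_r) / gss
            rss = np.maximum(yss - beta ** 2 * gss, 0.0)
            se = np.sqrt(rss / df / gss)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        degenerate = gss <= 1e-12
        p = np.where(degenerate, np.nan, p)
        for j, m in enumerate(genotypes.markers):
            if degenerate[j]:
                continue
            pj = max(float(p[j]), 1e-300)
            results.append(
                AssociationResult(
                    m.marker_id, m.chromosome, m.position,
                    float(beta[j]), float(se[j]), pj,
                    float(-np.log10(pj)), float(maf[j]),
                )
            )
    else:  # exact per-marker REML
        for j, m in enumerate(genotypes.markers):
            g = genotypes.dosages[:, j].astype(float)
            if g.std() == 0:
                continue
            X = np.column_stack([X0, g])
            UtX = U.T @ X
            res = minimize_scalar(
                _reml_neg_loglik, bounds=(-12.0, 12.0), args=(s, Uty, UtX),
                method="bounded", options={"xatol": 1e-6},
            )
            lam_j = float(np.exp(res.x))
            w = np.sqrt(lam_j * s + 1.0)
            Xw = UtX / w[:, None]
            yw = Uty / w
            XtX = Xw.T @ Xw
            beta_all = np.linalg.solve(XtX, Xw.T @ yw)
            resid = yw - Xw @ beta_all
            df = n - X.shape[1]
            sigma2 = float(resid @ resid) / df
            cov = sigma2 * np.linalg.inv(XtX)
            beta_j, se_j = beta_all[-1], np.sqrt(cov[-1, -1])
            pj = max(float(2.0 * stats.t.sf(abs(beta_j) / se_j, df)), 1e-300)
            results.append(
                AssociationResult(
                    m.marker_id, m.chromosome, m.position,
                    float(beta_j), float(se_j), pj,
                    float(-np.log10(pj)), float(maf[j]),
                )
            )
    return results


# ---------------------------------------------------------------------------
# significance calls
# ---------------------------------------------------------------------------

def bonferroni_neglog(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected genome-wide threshold on the -log10 scale."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / n_tests))


def call_significant(
    results: list[AssociationResult],
    threshold_neglogp: float = 7.0,
    annotation: list[GeneAnnotation] | None = None,
) -> tuple[list[AssociationResult], dict[str, list[str]]]:
    """Flag markers above the -log10 p cut-off (strict '>') and, given an
    annotation, return the genic subset as gene_id -> significant marker ids."""
    for r in results:
        r.significant = r.neglog10_p > threshold_neglogp
    significant = [r for r in results if r.significant]
    genic: dict[str, list[str]] = {}
    if annotation is not None and significant:
        genic = snp_to_gene(
            [(r.marker_id, r.chromosome, r.position) for r in significant],
            annotation,
        )
    return significant, genic
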