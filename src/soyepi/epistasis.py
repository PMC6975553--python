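"""Bayesian multilocus interaction search with two-locus verification.

The model partitions candidate markers into three kinds of block:

* the *phenotype-associated* block (``I = 1``): its joint genotype defines
  cells over which the trait is modeled with a conjugate
  Normal-Inverse-Gamma likelihood (continuous trait) or a
  Dirichlet-multinomial over binned values (discrete mode);
* zero or more *genotype-dependency* blocks (``I = h``, ``h >= 2``): the
  joint genotype counts of each block get a Dirichlet-multinomial marginal;
* the *independent background* (``I = 0``): every marker contributes its own
  single-marker Dirichlet-multinomial term.

Every marker's genotypes are always modeled (the associated block also
carries a Dirichlet-multinomial term for its joint counts), so scores are
comparable across partitions.  The posterior over partitions is explored by
Metropolis-Hastings with relocate / pair / swap moves; marker sets that form
a block in at least a threshold fraction of retained (post burn-in) samples
are reported as interaction groups, then verified pairwise with a fixed
two-locus linear regression.

A dependency block of one marker is indistinguishable from background, so
the sampler's state space contains only blocks of two or more markers.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from soyepi.datatypes import GenotypeMatrix, PhenotypeVector

log = logging.getLogger(__name__)

__all__ = [
    "DirichletPrior", "GaussianCellPrior", "PartitionState", "InteractionGroup",
    "TwoLocusResult", "dm_log_marginal", "gaussian_log_marginal",
    "partition_log_score", "enumerate_partition_states", "mcmc_search",
    "two_locus_test", "pairwise_p_range", "PartitionScorer",
]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirichletPrior:
    """Symmetric Dirichlet concentration per category (joint-genotype cell)."""
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")


@dataclass(frozen=True)
class GaussianCellPrior:
    """Normal-Inverse-Gamma prior for the per-cell trait distribution."""
    mu0: float
    kappa0: float = 1.0
    alpha0: float = 2.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa0 <= 0 or self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("kappa0, alpha0, beta0 must all be positive")

    @classmethod
    def from_phenotype(cls, y: np.ndarray) -> "GaussianCellPrior":
        """Empirical default: prior mean at the sample mean, prior scale at
        the sample variance, weight of one pseudo-observation."""
        y = np.asarray(y, dtype=float)
        var = float(y.var(ddof=1)) if len(y) > 1 else 1.0
        return cls(mu0=float(y.mean()), kappa0=1.0, alpha0=2.0, beta0=max(var, 1e-12))


# ---------------------------------------------------------------------------
# marginal likelihoods
# ---------------------------------------------------------------------------

def dm_log_marginal(category_counts, prior: DirichletPrior | float = 1.0) -> float:
    """Log Dirichlet-multinomial marginal of an *ordered* categorical sample.

    log Gamma(A) - log Gamma(A + n) + sum_k [log Gamma(a_k + c_k) - log Gamma(a_k)],
    A = sum a_k.  (No multinomial coefficient: the sample is a particular
    sequence, so exponentiating and summing over all ordered sequences of a
    fixed length gives exactly 1.)
    """
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one count must be positive")
    alpha = prior.concentration if isinstance(prior, DirichletPrior) else float(prior)
    if alpha <= 0:
        raise ValueError("concentration must be positive")
    A = alpha * counts.size
    return float(
        gammaln(A) - gammaln(A + n)
        + np.sum(gammaln(alpha + counts)) - counts.size * gammaln(alpha)
    )


def _gaussian_cells_from_suffstats(
    n: np.ndarray, ssum: np.ndarray, ssq: np.ndarray, prior: GaussianCellPrior
) -> float:
    """Sum of per-cell Normal-Inverse-Gamma log marginals from sufficient
    statistics (count, sum, sum of squares); empty cells contribute 0."""
    n = np.asarray(n, dtype=float)
    mask = n > 0
    if not mask.any():
        return 0.0
    n = n[mask]
    mean = ssum[mask] / n
    m2 = ssq[mask] - n * mean ** 2  # within-cell sum of squared deviations
    m2 = np.clip(m2, 0.0, None)
    kap_n = prior.kappa0 + n
    alp_n = prior.alpha0 + n / 2.0
    bet_n = (
        prior.beta0
        + 0.5 * m2
        + prior.kappa0 * n * (mean - prior.mu0) ** 2 / (2.0 * kap_n)
    )
    terms = (
        gammaln(alp_n) - gammaln(prior.alpha0)
        + prior.alpha0 * np.log(prior.beta0) - alp_n * np.log(bet_n)
        + 0.5 * (np.log(prior.kappa0) - np.log(kap_n))
        - (n / 2.0) * np.log(2.0 * np.pi)
    )
    return float(terms.sum())


def gaussian_log_marginal(values_by_cell, prior: GaussianCellPrior) -> float:
    """Log marginal likelihood of trait values partitioned into cells.

    Cells are independent given the partition; each cell integrates a
    Normal likelihood over its Normal-Inverse-Gamma prior (the marginal is a
    multivariate Student-t)."""
    cells = [np.asarray(c, dtype=float) for c in values_by_cell]
    n = np.array([len(c) for c in cells], dtype=float)
    ssum = np.array([c.sum() for c in cells])
    ssq = np.array([(c ** 2).sum() for c in cells])
    return _gaussian_cells_from_suffstats(n, ssum, ssq, prior)


# ---------------------------------------------------------------------------
# partition states and scoring
# ---------------------------------------------------------------------------

@dataclass
class PartitionState:
    """Assignment of each candidate marker to a block.

    ``assignment[i]`` is 0 (background), 1 (phenotype-associated) or h >= 2
    (genotype-dependency block h).  Dependency labels are arbitrary: scores
    are invariant to relabeling, and a dependency block with a single member
    is equivalent to background.
    """
    assignment: np.ndarray
    log_score: float = float("nan")

    def blocks(self) -> tuple[tuple[int, ...], list[tuple[int, ...]], tuple[int, ...]]:
        """Canonical (associated, dependency blocks, background) index tuples."""
        a = np.asarray(self.assignment)
        assoc = tuple(np.flatnonzero(a == 1).tolist())
        bg = list(np.flatnonzero(a == 0).tolist())
        deps = []
        for label in sorted(set(a.tolist()) - {0, 1}):
            members = tuple(np.flatnonzero(a == label).tolist())
            if len(members) == 1:
                bg.extend(members)
            else:
                deps.append(members)
        deps.sort()
        return assoc, deps, tuple(sorted(bg))


class PartitionScorer:
    """Caches block-level marginal likelihoods for fast state scoring."""

    def __init__(
        self,
        dosages: np.ndarray,
        y: np.ndarray,
        dm_prior: DirichletPrior | float = 1.0,
        cell_prior: GaussianCellPrior | None = None,
        phenotype_mode: str = "gaussian",
        n_phenotype_bins: int = 3,
    ) -> None:
        self.G = np.asarray(dosages, dtype=np.int64)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.G.shape
        self.alpha = (
            dm_prior.concentration if isinstance(dm_prior, DirichletPrior) else float(dm_prior)
        )
        if cell_prior is None:
            cell_prior = GaussianCellPrior.from_phenotype(self.y)
        self.cell_prior = cell_prior
        if phenotype_mode not in ("gaussian", "discrete"):
            raise ValueError("phenotype_mode must be 'gaussian' or 'discrete'")
        self.phenotype_mode = phenotype_mode
        if phenotype_mode == "discrete":
            edges = np.quantile(self.y, np.linspace(0, 1, n_phenotype_bins + 1)[1:-1])
            self.y_bins = np.searchsorted(edges, self.y, side="right")
            self.n_bins = n_phenotype_bins
        self._dm_cache: dict[tuple[int, ...], float] = {}
        self._assoc_cache: dict[tuple[int, ...], float] = {}
        self.single_dm = np.array([
            dm_log_marginal(np.bincount(self.G[:, j], minlength=3), self.alpha)
            for j in range(self.p)
        ])

    def _codes(self, block: tuple[int, ...]) -> np.ndarray:
        code = np.zeros(self.n, dtype=np.int64)
        for i, m in enumerate(block):
            code += self.G[:, m] * 3 ** i
        return code

    def dm_block(self, block: tuple[int, ...]) -> float:
        """Dirichlet-multinomial marginal of the block's joint genotype."""
        if len(block) == 1:
            return float(self.single_dm[block[0]])
        key = tuple(sorted(block))
        hit = self._dm_cache.get(key)
        if hit is None:
            counts = np.bincount(self._codes(key), minlength=3 ** len(key))
            hit = dm_log_marginal(counts, self.alpha)
            self._dm_cache[key] = hit
        return hit

    def assoc_block(self, block: tuple[int, ...]) -> float:
        """Joint-genotype DM term plus the phenotype marginal over the
        block's genotype cells (a single cell when the block is empty)."""
        key = tuple(sorted(block))
        hit = self._assoc_cache.get(key)
        if hit is None:
            if key:
                codes = self._codes(key)
                ncells = 3 ** len(key)
                genotype_term = dm_log_marginal(
                    np.bincount(codes, minlength=ncells), self.alpha
                )
            else:
                codes = np.zeros(self.n, dtype=np.int64)
                ncells = 1
                genotype_term = 0.0
            if self.phenotype_mode == "gaussian":
                ns = np.bincount(codes, minlength=ncells).astype(float)
                ssum = np.bincount(codes, weights=self.y, minlength=ncells)
                ssq = np.bincount(codes, weights=self.y ** 2, minlength=ncells)
                pheno_term = _gaussian_cells_from_suffstats(ns, ssum, ssq, self.cell_prior)
            else:
                joint = np.bincount(
                    codes * self.n_bins + self.y_bins,
                    minlength=ncells * self.n_bins,
                ).reshape(ncells, self.n_bins)
                pheno_term = sum(
                    dm_log_marginal(row, self.alpha) for row in joint if row.sum() > 0
                )
            hit = genotype_term + pheno_term
            self._assoc_cache[key] = hit
        return hit

    def state_score(
        self,
        assoc: tuple[int, ...],
        deps: list[tuple[int, ...]],
        bg: tuple[int, ...],
    ) -> float:
        score = self.assoc_block(tuple(sorted(assoc)))
        for block in deps:
            score += self.dm_block(block)
        score += float(self.single_dm[list(bg)].sum()) if bg else 0.0
        return score


def partition_log_score(
    state: PartitionState | np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    phenotypes: PhenotypeVector | np.ndarray,
    dm_prior: DirichletPrior | float = 1.0,
    cell_prior: GaussianCellPrior | None = None,
    phenotype_mode: str = "gaussian",
) -> float:
    """Log posterior score of one partition (uniform partition prior).

    Convenience wrapper around :class:`PartitionScorer` for single states;
    use the scorer directly when scoring many states.
    """
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    y = phenotypes.values if isinstance(phenotypes, PhenotypeVector) else phenotypes
    if not isinstance(state, PartitionState):
        state = PartitionState(np.asarray(state))
    if len(state.assignment) != np.asarray(dosages).shape[1]:
        raise ValueError("assignment length must equal the candidate marker count")
    if len(state.assignment) == 0:
        raise ValueError("empty candidate set")
    scorer = PartitionScorer(dosages, y, dm_prior, cell_prior, phenotype_mode)
    assoc, deps, bg = state.blocks()
    score = scorer.state_score(assoc, deps, bg)
    state.log_score = score
    return score


def enumerate_partition_states(n_markers: int, max_block: int = 5):
    """Yield every canonical partition (assoc tuple, dep-blocks tuple) of
    ``n_markers`` candidates; dependency blocks have 2..max_block members,
    the associated block 0..max_block.  Intended for small n."""

    def recurse(i, assoc, deps, bg):
        if i == n_markers:
            if all(len(b) >= 2 for b in deps):
                yield (
                    tuple(assoc),
                    tuple(tuple(b) for b in deps),
                    tuple(bg),
                )
            return
        bg.append(i)
        yield from recurse(i + 1, assoc, deps, bg)
        bg.pop()
        if len(assoc) < max_block:
            assoc.append(i)
            yield from recurse(i + 1, assoc, deps, bg)
            assoc.pop()
        for b in deps:
            if len(b) < max_block:
                b.append(i)
                yield from recurse(i + 1, assoc, deps, bg)
                b.pop()
        deps.append([i])
        yield from recurse(i + 1, assoc, deps, bg)
        deps.pop()

    yield from recurse(0, [], [], [])


# ---------------------------------------------------------------------------
# two-locus verification
# ---------------------------------------------------------------------------

@dataclass
class TwoLocusResult:
    coefficient: float
    se: float
    p_value: float
    df: int
    degenerate: bool = False


def _resolve_marker(genotypes: GenotypeMatrix, marker) -> int:
    if isinstance(marker, (int, np.integer)):
        return int(marker)
    try:
        return genotypes.marker_ids.index(marker)
    except ValueError as exc:
        raise KeyError(f"marker {marker!r} not found") from exc


def two_locus_test(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector | np.ndarray,
    marker_a,
    marker_b,
) -> TwoLocusResult:
    """Fixed linear-regression epistasis test for one marker pair.

    Ordinary least squares of y on [1, g_a, g_b, g_a * g_b]; the reported
    p-value is the two-sided t test on the product-term coefficient.
    Collinear designs (e.g. g_a identical to g_b) are flagged degenerate.
    """
    ia = _resolve_marker(genotypes, marker_a)
    ib = _resolve_marker(genotypes, marker_b)
    y = phenotypes.values if isinstance(phenotypes, PhenotypeVector) else np.asarray(phenotypes, float)
    ga = genotypes.dosages[:, ia].astype(float)
    gb = genotypes.dosages[:, ib].astype(float)
    n = len(y)
    if n <= 5:
        raise ValueError("two_locus_test needs more than 5 samples")
    if ga.std() == 0 or gb.std() == 0:
        raise ValueError("both markers must be polymorphic")
    X = np.column_stack([np.ones(n), ga, gb, ga * gb])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        return TwoLocusResult(float("nan"), float("nan"), float("nan"), n - 4, degenerate=True)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 4
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        # perfect fit (e.g. constant y): no evidence against the null
        return TwoLocusResult(float(beta[3]), 0.0, 1.0, df, degenerate=True)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[3, 3]))
    tstat = beta[3] / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return TwoLocusResult(float(beta[3]), se, p, df)


def pairwise_p_range(
    marker_indices,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector | np.ndarray,
) -> tuple[float, float, list[TwoLocusResult]]:
    """Two-locus p-value range over all C(k,2) pairs of a group.

    Degenerate pairs are excluded with a warning; returns (min, max,
    per-pair results)."""
    idx = [_resolve_marker(genotypes, m) for m in marker_indices]
    if len(idx) < 2:
        raise ValueError("need a group of at least 2 markers")
    tests: list[TwoLocusResult] = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            tests.append(two_locus_test(genotypes, phenotypes, idx[a], idx[b]))
    valid = [t.p_value for t in tests if not t.degenerate and np.isfinite(t.p_value)]
    if len(valid) < len(tests):
        warnings.warn("pairwise_p_range: degenerate pairs excluded")
    if not valid:
        return float("nan"), float("nan"), tests
    return min(valid), max(valid), tests


# ---------------------------------------------------------------------------
# MCMC search
# ---------------------------------------------------------------------------

@dataclass
class InteractionGroup:
    marker_indices: tuple[int, ...]
    marker_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    kind: str                       # "phenotype" or "dependency"
    posterior: float
    p_min: float = float("nan")
    p_max: float = float("nan")
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class EpistasisResult:
    groups: list[InteractionGroup]
    block_posteriors: dict           # (kind, frozenset) -> posterior prob
    assoc_counts: Counter            # assoc tuple -> visits (post burn-in)
    n_retained: int
    acceptance_rate: float
    final_state: PartitionState
    #: canonical (assoc, dep-blocks) -> visits; filled when track_states=True
    state_counts: Counter | None = None


class _Chain:
    """Mutable partition with incremental bookkeeping for the sampler."""

    def __init__(self, scorer: PartitionScorer, max_block: int):
        self.sc = scorer
        self.p = scorer.p
        self.max_block = max_block
        self.assoc: set[int] = set()
        self.deps: dict[int, set[int]] = {}
        self.where: list = [("bg",)] * self.p   # per-marker location tag
        self.bg: set[int] = set(range(self.p))
        self.next_label = 2
        self.bg_sum = float(scorer.single_dm.sum())
        self.assoc_score = scorer.assoc_block(())
        self.dep_scores: dict[int, float] = {}

    # -- score of the current state --------------------------------------
    @property
    def score(self) -> float:
        return self.assoc_score + self.bg_sum + sum(self.dep_scores.values())

    def n_destinations(self, i: int) -> int:
        loc = self.where[i]
        n = 0
        if loc[0] != "bg":
            n += 1
        if loc[0] != "assoc" and len(self.assoc) < self.max_block:
            n += 1
        for label, members in self.deps.items():
            if loc != ("dep", label) and len(members) < self.max_block:
                n += 1
        n += len(self.bg) - (1 if loc[0] == "bg" else 0)  # pair partners
        return n

    def destinations(self, i: int) -> list:
        loc = self.where[i]
        dests: list = []
        if loc[0] != "bg":
            dests.append(("bg",))
        if loc[0] != "assoc" and len(self.assoc) < self.max_block:
            dests.append(("assoc",))
        for label, members in self.deps.items():
            if loc != ("dep", label) and len(members) < self.max_block:
                dests.append(("dep", label))
        for j in self.bg:
            if j != i:
                dests.append(("pair", j))
        return dests

    # -- structural edits -------------------------------------------------
    def _detach(self, i: int) -> int | None:
        """Remove marker i from its container; returns the partner stranded
        by a dissolved pair block (now background), else None."""
        loc = self.where[i]
        if loc[0] == "bg":
            self.bg.discard(i)
            self.bg_sum -= self.sc.single_dm[i]
        elif loc[0] == "assoc":
            self.assoc.discard(i)
            self.assoc_score = self.sc.assoc_block(tuple(sorted(self.assoc)))
        else:
            label = loc[1]
            members = self.deps[label]
            members.discard(i)
            if len(members) == 1:
                (partner,) = members
                del self.deps[label]
                del self.dep_scores[label]
                self.bg.add(partner)
                self.bg_sum += self.sc.single_dm[partner]
                self.where[partner] = ("bg",)
                self.where[i] = ("detached",)
                return partner
            self.dep_scores[label] = self.sc.dm_block(tuple(sorted(members)))
        self.where[i] = ("detached",)
        return None

    def _attach(self, i: int, dest: tuple) -> None:
        if dest[0] == "bg":
            self.bg.add(i)
            self.bg_sum += self.sc.single_dm[i]
            self.where[i] = ("bg",)
        elif dest[0] == "assoc":
            self.assoc.add(i)
            self.assoc_score = self.sc.assoc_block(tuple(sorted(self.assoc)))
            self.where[i] = ("assoc",)
        elif dest[0] == "dep":
            label = dest[1]
            self.deps[label].add(i)
            self.dep_scores[label] = self.sc.dm_block(tuple(sorted(self.deps[label])))
            self.where[i] = ("dep", label)
        else:  # ("pair", j): j must be background
            j = dest[1]
            self.bg.discard(j)
            self.bg_sum -= self.sc.single_dm[j]
            label = self.next_label
            self.next_label += 1
            self.deps[label] = {i, j}
            self.dep_scores[label] = self.sc.dm_block(tuple(sorted((i, j))))
            self.where[i] = ("dep", label)
            self.where[j] = ("dep", label)

    def assignment(self) -> np.ndarray:
        a = np.zeros(self.p, dtype=int)
        for i in self.assoc:
            a[i] = 1
        for k, (label, members) in enumerate(sorted(self.deps.items()), start=2):
            for i in members:
                a[i] = k
        return a


def mcmc_search(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    iterations: int = 1_000_000,
    burnin: int = 990_000,
    posterior_threshold: float = 0.5,
    max_block: int = 5,
    dm_prior: DirichletPrior | float = 1.0,
    cell_prior: GaussianCellPrior | None = None,
    phenotype_mode: str = "gaussian",
    seed: int | np.random.Generator = 0,
    min_group_size: int = 2,
    relocate_prob: float = 0.85,
    max_candidates: int = 10_000,
    track_states: bool = False,
) -> EpistasisResult:
    """Metropolis-Hastings search over marker partitions.

    Retained (post burn-in) samples vote: the posterior probability of a
    marker set is the fraction of retained samples in which exactly that set
    forms a block, tracked separately for the phenotype-associated block and
    genotype-dependency blocks.  Groups of at least ``min_group_size``
    markers reaching ``posterior_threshold`` are reported, each with its
    pairwise two-locus p-value range.
    """
    if genotypes.n_markers < 2:
        raise ValueError("need at least 2 candidate markers")
    if genotypes.n_markers > max_candidates:
        raise ValueError("candidate set larger than max_candidates")
    if burnin >= iterations:
        raise ValueError("burn-in must be smaller than the iteration count")
    y_aligned = phenotypes.align_to(genotypes)
    if y_aligned.sample_ids != genotypes.sample_ids:
        genotypes = genotypes.subset_samples(y_aligned.sample_ids)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scorer = PartitionScorer(
        genotypes.dosages, y_aligned.values, dm_prior, cell_prior, phenotype_mode
    )
    chain = _Chain(scorer, max_block)
    p = chain.p

    block_counts: Counter = Counter()
    assoc_counts: Counter = Counter()
    state_counts: Counter | None = Counter() if track_states else None
    n_retained = 0
    n_accept = 0

    for it in range(iterations):
        if rng.random() < relocate_prob:
            i = int(rng.integers(p))
            dests = chain.destinations(i)
            if dests:
                dest = dests[int(rng.integers(len(dests)))]
                n_fwd = len(dests)
                loc = chain.where[i]
                # forward multiplicity: pair dissolution to bg, or pair
                # formation between two background markers
                mult_fwd = 1
                if dest[0] == "bg" and loc[0] == "dep" and len(chain.deps[loc[1]]) == 2:
                    mult_fwd = 2
                elif dest[0] == "pair" and loc[0] == "bg":
                    mult_fwd = 2
                old_score = chain.score
                partner = chain._detach(i)
                chain._attach(i, dest)
                new_score = chain.score
                # reverse proposal: move i back to where it came from
                if loc[0] == "dep" and partner is not None:
                    rev = ("pair", partner)
                else:
                    rev = loc
                mult_rev = 1
                if rev[0] == "bg" and chain.where[i][0] == "dep" \
                        and len(chain.deps[chain.where[i][1]]) == 2:
                    mult_rev = 2
                elif rev[0] == "pair" and dest[0] == "bg":
                    mult_rev = 2
                n_rev = chain.n_destinations(i)
                log_ratio = (
                    new_score - old_score
                    + np.log(mult_rev) - np.log(mult_fwd)
                    + np.log(n_fwd) - np.log(n_rev)
                )
                if np.log(rng.random()) < log_ratio:
                    n_accept += 1
                else:  # undo
                    partner2 = chain._detach(i)
                    if rev[0] == "dep" and rev[1] not in chain.deps:
                        # original block dissolved on detach; partner went bg
                        chain._attach(i, ("pair", partner2))
                    else:
                        chain._attach(i, rev)
        else:  # swap two markers between blocks (symmetric)
            i, j = rng.choice(p, size=2, replace=False)
            i, j = int(i), int(j)
            li, lj = chain.where[i], chain.where[j]
            if li != lj:
                old_score = chain.score
                _swap(chain, i, j)
                new_score = chain.score
                if np.log(rng.random()) < new_score - old_score:
                    n_accept += 1
                else:
                    _swap(chain, j, i)

        if it >= burnin:
            n_retained += 1
            if len(chain.assoc) >= min_group_size:
                block_counts[("phenotype", frozenset(chain.assoc))] += 1
            for members in chain.deps.values():
                block_counts[("dependency", frozenset(members))] += 1
            assoc_counts[tuple(sorted(chain.assoc))] += 1
            if state_counts is not None:
                state_counts[
                    (
                        tuple(sorted(chain.assoc)),
                        tuple(sorted(tuple(sorted(m)) for m in chain.deps.values())),
                    )
                ] += 1

    posteriors = {k: v / n_retained for k, v in block_counts.items()}
    groups: list[InteractionGroup] = []
    for (kind, members), post in sorted(
        posteriors.items(), key=lambda kv: -kv[1]
    ):
        if post < posterior_threshold or len(members) < min_group_size:
            continue
        idx = tuple(sorted(members))
        p_min, p_max, _ = pairwise_p_range(idx, genotypes, y_aligned)
        groups.append(
            InteractionGroup(
                marker_indices=idx,
                marker_ids=[genotypes.markers[k].marker_id for k in idx],
                chromosomes=[genotypes.markers[k].chromosome for k in idx],
                positions=[genotypes.markers[k].position for k in idx],
                kind=kind,
                posterior=post,
                p_min=p_min,
                p_max=p_max,
                gene_ids=[""] * len(idx),
            )
        )
    final = PartitionState(chain.assignment())
    final.log_score = chain.score
    log.info(
        "mcmc_search: %d candidates, %d iterations, acceptance %.3f, %d groups",
        p, iterations, n_accept / iterations, len(groups),
    )
    return EpistasisResult(
        groups=groups,
        block_posteriors=posteriors,
        assoc_counts=assoc_counts,
        n_retained=n_retained,
        acceptance_rate=n_accept / iterations,
        final_state=final,
        state_counts=state_counts,
    )


def _swap(chain: _Chain, i: int, j: int) -> None:
    """Exchange the block membership of markers i and j (block sizes are
    preserved, so no dissolution can occur)."""
    li, lj = chain.where[i], chain.where[j]
    sc = chain.sc
    for marker, src, dst in ((i, li, lj), (j, lj, li)):
        if src[0] == "bg":
            chain.bg.discard(marker)
            chain.bg_sum -= sc.single_dm[marker]
        elif src[0] == "assoc":
            chain.assoc.discard(marker)
        else:
            chain.deps[src[1]].discard(marker)
    for marker, src, dst in ((i, li, lj), (j, lj, li)):
        if dst[0] == "bg":
            chain.bg.add(marker)
            chain.bg_sum += sc.single_dm[marker]
            chain.where[marker] = ("bg",)
        elif dst[0] == "assoc":
            chain.assoc.add(marker)
            chain.where[marker] = ("assoc",)
        else:
            chain.deps[dst[1]].add(marker)
            chain.where[marker] = ("dep", dst[1])
    chain.assoc_score = sc.assoc_block(tuple(sorted(chain.assoc)))
    for label, members in chain.deps.items():
        chain.dep_scores[label] = sc.dm_block(tuple(sorted(members)))
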