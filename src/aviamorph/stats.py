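"""Distance-based phylogenetic MANOVA (RRPP), evolutionary-rate comparison,
two-block PLS, and PCA.

These are the inferential engines for high-dimensional shape data, where
the trait count (3L) routinely exceeds the sample size. All tests are
distance-based (Goodall-style sums of squares over all trait columns), so
no covariance inversion in trait space is ever required, and all operate
on phylogenetically whitened data: with ``P = C^{-1/2}`` from
:class:`~aviamorph.phylo.PhyloCovariance`, responses and design matrices
are premultiplied by ``P`` so that residual rows are exchangeable under
Brownian motion and permutation inference is valid. Passing ``cov=None``
gives the ordinary (non-phylogenetic) test — identical to using a star
tree with unit branch lengths.

Each engine is a small model class whose ``fit`` returns a frozen result
object with estimates, permutation diagnostics and a ``summary()`` table;
module-level functions (``manova_rrpp``, ``compare_rates``, ``phylo_pls``,
``pca``, ``sigma_mult``) are one-call conveniences over the classes.

Permutation p-values use the inclusive convention
``p = (#{extreme} + 1) / (m + 1)``: the observed statistic counts as one
realisation of its own null, so p is never exactly zero and has
resolution 1/(m+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from aviamorph.phylo import PhyloCovariance, phylo_transform

_PERM_CHUNK = 250


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _as_matrix(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def _group_index(groups: Sequence[str]) -> tuple[list[str], np.ndarray]:
    labels = [str(g) for g in groups]
    names = sorted(set(labels))
    codes = np.array([names.index(g) for g in labels])
    return names, codes


# ===========================================================================
# phylogenetic np-MANOVA with RRPP
# ===========================================================================

@dataclass(frozen=True)
class ManovaResult:
    """One-factor distance-based (phylogenetic) MANOVA with RRPP inference."""

    SS_model: float
    SS_residual: float
    SS_total: float
    df_model: int
    df_residual: int
    R2: float
    F: float
    Z: float
    p: float
    iterations: int
    seed: int | None
    group_names: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_model, self.df_residual, self.df_model + self.df_residual],
                "SS": [self.SS_model, self.SS_residual, self.SS_total],
                "R2": [self.R2, np.nan, np.nan],
                "F": [self.F, np.nan, np.nan],
                "Z": [self.Z, np.nan, np.nan],
                "p": [self.p, np.nan, np.nan],
            },
            index=["groups", "residual", "total"],
        )


class PhylogeneticMANOVA:
    """Distance-based one-factor MANOVA of a trait matrix on group labels.

    The response ``Y`` (N x t) and the dummy-coded design are whitened by
    ``P`` when a phylogenetic covariance is supplied. Sums of squares are
    summed squared entries (valid for t >> N); the null distribution of F
    comes from the residual-randomization permutation procedure: rows of
    the reduced-model (intercept-only) residuals are permuted, reduced
    fitted values added back, and F recomputed.
    """

    def __init__(
        self,
        Y: np.ndarray,
        groups: Sequence[str],
        cov: PhyloCovariance | None = None,
    ) -> None:
        self.Y = _as_matrix(Y)
        n = self.Y.shape[0]
        if len(groups) != n:
            raise ValueError(f"{len(groups)} group labels for {n} rows of Y")
        self.group_names, self._codes = _group_index(groups)
        if len(self.group_names) < 2:
            raise ValueError("need at least 2 groups (a single group has no effect to test)")
        if cov is not None and cov.n_taxa != n:
            raise ValueError(f"covariance is for {cov.n_taxa} taxa, Y has {n} rows")
        self.cov = cov

    def _design(self) -> np.ndarray:
        n, g = len(self._codes), len(self.group_names)
        X = np.zeros((n, g))
        X[:, 0] = 1.0
        for j in range(1, g):                # treatment coding
            X[self._codes == j, j] = 1.0
        return X

    def fit(self, iterations: int = 999, seed: int | None = None) -> ManovaResult:
        if iterations < 99:
            raise ValueError("need at least 99 RRPP iterations")
        P = self.cov.P if self.cov is not None else None
        X = self._design()
        Yt = P @ self.Y if P is not None else self.Y
        Xt = P @ X if P is not None else X

        # orthonormal bases: Q_red spans the whitened intercept, Q_m the
        # group contrasts orthogonal to it
        Q_red, _ = np.linalg.qr(Xt[:, :1])
        M = Xt[:, 1:] - Q_red @ (Q_red.T @ Xt[:, 1:])
        Qm_full, Rm = np.linalg.qr(M)
        keep = np.abs(np.diag(Rm)) > 1e-10 * max(1.0, np.abs(np.diag(Rm)).max())
        Q_m = Qm_full[:, keep]
        df_model = Q_m.shape[1]
        n = Yt.shape[0]
        df_res = n - df_model - 1

        E = Yt - Q_red @ (Q_red.T @ Yt)      # reduced-model residuals
        G = E @ E.T                          # Gram matrix: cost independent of t
        SS_total = float(np.trace(G))
        if SS_total <= 1e-12 * n:
            raise ValueError("degenerate data: total sum of squares is zero")
        B = Q_m.T @ E
        SS_model = float((B ** 2).sum())
        SS_res = SS_total - SS_model
        F_obs = (SS_model / df_model) / (SS_res / df_res)

        # RRPP: permuting residual rows of E is equivalent to gathering the
        # rows of [Q_red, Q_m]; SS terms come from diag(Q' G Q)
        rng = _rng(seed)
        Q_all = np.hstack([Q_red, Q_m])      # (n, df_model + 1)
        F_perm = np.empty(iterations)
        done = 0
        while done < iterations:
            m = min(_PERM_CHUNK, iterations - done)
            perms = np.argsort(rng.random((m, n)), axis=1)
            Qp = Q_all[perms]                # (m, n, k)
            GQ = np.einsum("ij,pjk->pik", G, Qp)
            ss = np.einsum("pik,pik->pk", Qp, GQ)
            ss_red = ss[:, 0]
            ss_mod = ss[:, 1:].sum(axis=1)
            ss_res = SS_total - ss_red - ss_mod
            F_perm[done : done + m] = (ss_mod / df_model) / np.maximum(ss_res, 1e-300) * df_res
            done += m

        p = (np.count_nonzero(F_perm >= F_obs) + 1) / (iterations + 1)
        logF = np.log(np.maximum(F_perm, 1e-300))
        sd = logF.std(ddof=1)
        Z = (np.log(F_obs) - logF.mean()) / sd if sd > 0 else np.inf

        return ManovaResult(
            SS_model=SS_model,
            SS_residual=SS_res,
            SS_total=SS_total,
            df_model=df_model,
            df_residual=df_res,
            R2=SS_model / SS_total,
            F=F_obs,
            Z=float(Z),
            p=float(p),
            iterations=iterations,
            seed=seed if not isinstance(seed, np.random.Generator) else None,
            group_names=tuple(self.group_names),
        )


def manova_rrpp(
    Y: np.ndarray,
    groups: Sequence[str],
    cov: PhyloCovariance | None = None,
    iterations: int = 999,
    seed: int | None = None,
) -> ManovaResult:
    """One-call phylogenetic np-MANOVA (see :class:`PhylogeneticMANOVA`)."""
    return PhylogeneticMANOVA(Y, groups, cov).fit(iterations=iterations, seed=seed)


# ===========================================================================
# multivariate evolutionary rate (sigma^2_mult) and group comparison
# ===========================================================================

def sigma_mult(Y: np.ndarray, cov: PhyloCovariance) -> float:
    """Multivariate BM rate: mean squared whitened distance from the root.

    sigma^2_mult = sum_i d_i^2 / N, where d_i is the Euclidean norm of the
    i-th row of U = P (Y - 1a) and a is the GLS root estimate. In the
    univariate case this equals the quadratic form
    (y - a 1)' C^-1 (y - a 1) / N.
    """
    Y = _as_matrix(Y)
    if Y.shape[0] != cov.n_taxa:
        raise ValueError(f"Y has {Y.shape[0]} rows but covariance is for {cov.n_taxa} taxa")
    td = phylo_transform(Y, cov)
    return float((td.d ** 2).sum() / Y.shape[0])


@dataclass(frozen=True)
class RateComparisonResult:
    """Per-group multivariate rates and the simulation test of their ratio."""

    sigma2_by_group: dict[str, float]
    sigma2_overall: float
    observed_ratio: float                    # max / min over groups
    p: float
    pairwise_ratios: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    nsim: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "sigma2_mult": s, "ratio_max_min": self.observed_ratio, "p": self.p}
            for g, s in self.sigma2_by_group.items()
        ]
        return pd.DataFrame(rows).set_index("group")


class EvolutionaryRateComparison:
    """Compare sigma^2_mult among groups of tips sharing one phylogeny.

    Group rates are subgroup means of the squared whitened distances from
    the full-tree transformation (distances are NOT recomputed on pruned
    trees: groups are compared on the common phylogenetic scale). The test
    statistic is the max/min rate ratio; its null distribution comes from
    simulating BM on the full tree with a single common rate and re-scoring
    each replicate with the observed group labels. The ratio is scale-free,
    so the common simulation rate is irrelevant (unit rate used).
    """

    def __init__(self, Y: np.ndarray, groups: Sequence[str], cov: PhyloCovariance) -> None:
        self.Y = _as_matrix(Y)
        n = self.Y.shape[0]
        if n != cov.n_taxa:
            raise ValueError(f"Y has {n} rows but covariance is for {cov.n_taxa} taxa")
        if len(groups) != n:
            raise ValueError(f"{len(groups)} group labels for {n} taxa")
        self.group_names, self._codes = _group_index(groups)
        if len(self.group_names) < 2:
            raise ValueError("need at least 2 groups")
        sizes = np.bincount(self._codes, minlength=len(self.group_names))
        small = [g for g, s in zip(self.group_names, sizes) if s < 2]
        if small:
            raise ValueError(f"groups with fewer than 2 members (rate undefined): {small}")
        self.cov = cov
        self._sizes = sizes

    def _group_rates(self, d2: np.ndarray) -> np.ndarray:
        sums = np.bincount(self._codes, weights=d2, minlength=len(self.group_names))
        return sums / self._sizes

    def fit(self, nsim: int = 999, seed: int | None = None, rate: float = 1.0) -> RateComparisonResult:
        if nsim < 99:
            raise ValueError("need at least 99 null simulations")
        if rate <= 0:
            raise ValueError("common simulation rate must be positive")
        n, t = self.Y.shape
        td = phylo_transform(self.Y, self.cov)
        d2 = td.d ** 2
        obs_rates = self._group_rates(d2)
        obs_ratio = float(obs_rates.max() / obs_rates.min())

        # Null: tip data L Z (Cholesky factor of C) — BM with one common
        # rate; whitening and root-centering are folded into W L.
        L = np.linalg.cholesky(self.cov.C)
        cho = linalg.cho_factor(self.cov.C)
        ones = np.ones(n)
        Ci1 = linalg.cho_solve(cho, ones)
        s_row = Ci1 / (ones @ Ci1)           # a = s_row @ Y
        W = self.cov.P @ (np.eye(n) - np.outer(ones, s_row))
        B = (W @ L) * np.sqrt(rate)

        rng = _rng(seed)
        names = self.group_names
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
        pair_idx = [(names.index(a), names.index(b)) for a, b in pairs]
        obs_pair_ratio = {
            pr: float(max(obs_rates[i], obs_rates[j]) / min(obs_rates[i], obs_rates[j]))
            for pr, (i, j) in zip(pairs, pair_idx)
        }
        count = 0
        pair_counts = dict.fromkeys(pairs, 0)
        done = 0
        while done < nsim:
            m = min(_PERM_CHUNK, nsim - done)
            Zr = rng.standard_normal((m, n, t))
            U = np.einsum("ij,pjt->pit", B, Zr)
            d2_sim = (U ** 2).sum(axis=2)    # (m, n)
            for k in range(m):
                rates_sim = self._group_rates(d2_sim[k])
                if rates_sim.max() / rates_sim.min() >= obs_ratio:
                    count += 1
                for pr, (i, j) in zip(pairs, pair_idx):
                    rsim = max(rates_sim[i], rates_sim[j]) / min(rates_sim[i], rates_sim[j])
                    if rsim >= obs_pair_ratio[pr]:
                        pair_counts[pr] += 1
            done += m

        sigma2_by_group = {g: float(r) for g, r in zip(names, obs_rates)}
        return RateComparisonResult(
            sigma2_by_group=sigma2_by_group,
            sigma2_overall=float(d2.sum() / n),
            observed_ratio=obs_ratio,
            p=float((count + 1) / (nsim + 1)),
            pairwise_ratios=obs_pair_ratio,
            pairwise_p={pr: float((c + 1) / (nsim + 1)) for pr, c in pair_counts.items()},
            nsim=nsim,
            seed=seed if not isinstance(seed, np.random.Generator) else None,
        )


def compare_rates(
    Y: np.ndarray,
    groups: Sequence[str],
    cov: PhyloCovariance,
    nsim: int = 999,
    seed: int | None = None,
) -> RateComparisonResult:
    """One-call rate comparison (see :class:`EvolutionaryRateComparison`)."""
    return EvolutionaryRateComparison(Y, groups, cov).fit(nsim=nsim, seed=seed)


# ===========================================================================
# phylogenetic two-block PLS
# ===========================================================================

@dataclass(frozen=True)
class PlsResult:
    """Two-block PLS axes: score correlations, covariation shares, loadings."""

    r_pls: np.ndarray                        # per-axis correlation of block scores
    covariation_fraction: np.ndarray         # per-axis s_k^2 / sum s^2
    p: float                                 # permutation p for axis 1
    loadings1: np.ndarray                    # (t1, k)
    loadings2: np.ndarray                    # (t2, k)
    scores1: np.ndarray                      # (N, k)
    scores2: np.ndarray                      # (N, k)
    iterations: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "r_pls": self.r_pls,
                "covariation_fraction": self.covariation_fraction,
            },
            index=[f"axis{k + 1}" for k in range(len(self.r_pls))],
        )
        df["p"] = np.nan
        df.loc["axis1", "p"] = self.p
        return df


class PhylogeneticPLS:
    """Two-block partial least squares between whitened trait blocks.

    Both blocks are premultiplied by ``P`` and column-centred; the SVD of
    their cross-covariance yields paired axes of maximal covariation.
    ``r_pls`` is the correlation of paired axis scores (axis signs chosen
    to make it non-negative); significance for axis 1 comes from permuting
    the rows of the whitened second block.
    """

    def __init__(self, Y1: np.ndarray, Y2: np.ndarray, cov: PhyloCovariance | None = None) -> None:
        self.Y1, self.Y2 = _as_matrix(Y1), _as_matrix(Y2)
        n = self.Y1.shape[0]
        if self.Y2.shape[0] != n:
            raise ValueError("blocks must share taxa (row counts differ)")
        if n < 3:
            raise ValueError("need at least 3 taxa for PLS")
        if cov is not None and cov.n_taxa != n:
            raise ValueError(f"covariance is for {cov.n_taxa} taxa, blocks have {n} rows")
        self.cov = cov

    @staticmethod
    def _axis1_r(Z1: np.ndarray, Z2: np.ndarray) -> float:
        R12 = Z1.T @ Z2
        U, s, Vt = np.linalg.svd(R12, full_matrices=False)
        s1, s2 = Z1 @ U[:, 0], Z2 @ Vt[0]
        denom = s1.std() * s2.std()
        if denom == 0:
            return 0.0
        return abs(float(np.corrcoef(s1, s2)[0, 1]))

    def fit(self, iterations: int = 999, seed: int | None = None) -> PlsResult:
        if iterations < 99:
            raise ValueError("need at least 99 permutations")
        P = self.cov.P if self.cov is not None else None
        Z1 = P @ self.Y1 if P is not None else self.Y1.copy()
        Z2 = P @ self.Y2 if P is not None else self.Y2.copy()
        Z1 = Z1 - Z1.mean(axis=0)
        Z2 = Z2 - Z2.mean(axis=0)
        n = Z1.shape[0]
        if not (np.any(Z1.std(axis=0) > 0) and np.any(Z2.std(axis=0) > 0)):
            raise ValueError("degenerate input: a block is constant after centering")

        R12 = Z1.T @ Z2 / (n - 1)
        U, s, Vt = np.linalg.svd(R12, full_matrices=False)
        k = int(np.count_nonzero(s > max(1e-12, 1e-12 * s[0]))) or 1
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        S1, S2 = Z1 @ U, Z2 @ Vt.T
        r = np.empty(k)
        for j in range(k):
            sd = S1[:, j].std() * S2[:, j].std()
            rj = float(np.corrcoef(S1[:, j], S2[:, j])[0, 1]) if sd > 0 else 0.0
            if rj < 0:                       # sign convention: non-negative r
                Vt[j] *= -1
                S2[:, j] *= -1
                rj = -rj
            r[j] = rj
        frac = s ** 2 / (s ** 2).sum()

        rng = _rng(seed)
        r_obs = r[0]
        count = 0
        for _ in range(iterations):
            perm = rng.permutation(n)
            if self._axis1_r(Z1, Z2[perm]) >= r_obs:
                count += 1
        return PlsResult(
            r_pls=r,
            covariation_fraction=frac,
            p=float((count + 1) / (iterations + 1)),
            loadings1=U,
            loadings2=Vt.T,
            scores1=S1,
            scores2=S2,
            iterations=iterations,
            seed=seed if not isinstance(seed, np.random.Generator) else None,
        )


def phylo_pls(
    Y1: np.ndarray,
    Y2: np.ndarray,
    cov: PhyloCovariance | None = None,
    iterations: int = 999,
    seed: int | None = None,
) -> PlsResult:
    """One-call phylogenetic two-block PLS (see :class:`PhylogeneticPLS`)."""
    return PhylogeneticPLS(Y1, Y2, cov).fit(iterations=iterations, seed=seed)


# ===========================================================================
# PCA (morphospace ordination)
# ===========================================================================

@dataclass(frozen=True)
class PcaResult:
    """Ordinary PCA of a trait matrix (no phylogenetic correction)."""

    scores: np.ndarray                       # (N, k)
    variance_fraction: np.ndarray            # (k,)
    components: np.ndarray                   # (k, t)
    mean: np.ndarray                         # (t,)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variance_fraction": self.variance_fraction,
                "cumulative": np.cumsum(self.variance_fraction),
            },
            index=[f"PC{k + 1}" for k in range(len(self.variance_fraction))],
        )


def pca(Y: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Principal components of column-centred Y, via SVD.

    Non-phylogenetic by design: this is the morphospace ordination, not an
    evolutionary model. Retains min(N - 1, t) axes (or ``n_components``).
    """
    Y = _as_matrix(Y)
    n, t = Y.shape
    if n < 2:
        raise ValueError("need at least 2 specimens for PCA")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    k = min(n - 1, t)
    if n_components is not None:
        k = min(k, n_components)
    var = s[:k] ** 2
    total = (s ** 2).sum()
    if total == 0:
        raise ValueError("degenerate input: zero variance")
    return PcaResult(
        scores=U[:, :k] * s[:k],
        variance_fraction=var / total,
        components=Vt[:k],
        mean=mean,
    )
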