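"""ACE twin-model heritability: ML variance components, LRT, FDR, rG.

The classical twin design decomposes a phenotype's variance into additive
genetic (A), common-environment (C) and unique-environment (E) components
from the differing cross-twin covariance of MZ (genetic correlation 1) and
DZ/full-sibling (0.5) pairs.  Heritability is h2 = A / (A + C + E).

Estimation is full maximum likelihood on the bivariate-normal pair
likelihood, written on sufficient statistics so a voxelwise map of fits is
cheap: for each zygosity group only the pair count, the sum of squared
member deviations and the sum of within-pair cross-products enter the
likelihood.  Optimization runs over standard deviations (nonnegativity is
structural) from three deterministic starts — a Falconer/method-of-moments
point and two fixed interior points.  Significance of A uses the
likelihood-ratio test against the A = 0 null with the boundary-corrected
50:50 chi-square mixture reference; voxelwise p-values are
Benjamini-Hochberg corrected.

Bivariate fits use Cholesky-parameterized 2x2 A, C, E blocks; the genetic
correlation is rG = h_xy / sqrt(h2_x * h2_y) with h_xy the genetic
covariance of the standardized traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from subgrad.simulate import PhenotypeMaps, TwinCohort

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# univariate ACE


@dataclass
class ACEFit:
    """Single-voxel ACE fit: variances, proportions, LRT."""

    var_a: float
    var_c: float
    var_e: float
    h2: float
    c2: float
    e2: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    p_lrt: float
    q_fdr: float = np.nan


def lrt_pvalue(loglik_full: float, loglik_null: float) -> float:
    """Boundary-corrected LRT p-value for the A = 0 null.

    T = max(0, 2 (ll_full - ll_null)); under the null T follows a 50:50
    mixture of a point mass at 0 and chi-square(1), so p = 1 at T = 0 and
    0.5 * Pr(chi2_1 >= T) otherwise.
    """
    t = max(0.0, 2.0 * (loglik_full - loglik_null))
    if t == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(t, df=1))


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance flags, q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


class _PairStats:
    """Cohort structure plus per-voxel sufficient statistics."""

    def __init__(
        self,
        cohort: TwinCohort,
        include_sib: bool = True,
        include_singletons: bool = True,
    ):
        self.mz = cohort.pairs("MZ")
        dz = [cohort.pairs("DZ")]
        if include_sib:
            dz.append(cohort.pairs("SIB"))
        self.dz = np.vstack([d for d in dz if d.size]) if any(
            d.size for d in dz
        ) else np.empty((0, 2), dtype=int)
        self.singles = cohort.singletons() if include_singletons else np.array([], int)
        self.n_obs = 2 * (len(self.mz) + len(self.dz)) + len(self.singles)

    def suffstats(self, y: np.ndarray) -> dict:
        used = np.concatenate(
            [self.mz.ravel(), self.dz.ravel(), self.singles]
        ).astype(int)
        mu = y[used].mean()
        d = y - mu
        out = {"mu": mu}
        for name, pairs in (("mz", self.mz), ("dz", self.dz)):
            if len(pairs):
                d1, d2 = d[pairs[:, 0]], d[pairs[:, 1]]
                out[name] = (len(pairs), float(np.sum(d1**2 + d2**2)),
                             float(np.sum(d1 * d2)))
            else:
                out[name] = (0, 0.0, 0.0)
        out["single"] = (len(self.singles), float(np.sum(d[self.singles] ** 2)))
        return out


def _neg2_loglik(va: float, vc: float, ve: float, ss: dict) -> float:
    """-2 log-likelihood of the pair model at variances (va, vc, ve)."""
    v = va + vc + ve
    if v <= 0:
        return np.inf
    total = 0.0
    for name, rho in (("mz", 1.0), ("dz", 0.5)):
        n_g, s1, s2 = ss[name]
        if n_g == 0:
            continue
        c = rho * va + vc
        det = v * v - c * c
        if det <= 0:
            return np.inf
        total += n_g * np.log(det) + (v * s1 - 2.0 * c * s2) / det
        total += 2.0 * n_g * _LOG2PI
    n_s, s_sq = ss["single"]
    if n_s:
        total += n_s * (np.log(v) + _LOG2PI) + s_sq / v
    return total


class ACEModel(BaseEstimator):
    """Voxelwise maximum-likelihood ACE fit on a twin cohort.

    Parameters
    ----------
    include_sib : pool full-sibling pairs with DZ pairs (rho = 0.5).
    include_singletons : let singletons contribute univariate terms.
    min_pairs : floor on MZ and on DZ/SIB pair counts.
    n_starts : deterministic optimizer starts (method-of-moments plus
        fixed interior points).

    Fitted attributes are per-voxel arrays: ``var_a_``, ``var_c_``,
    ``var_e_``, ``h2_``, ``c2_``, ``e2_``, ``loglik_full_``,
    ``loglik_null_``, ``lrt_stat_``, ``p_lrt_``, ``q_fdr_``.
    """

    def __init__(
        self,
        include_sib: bool = True,
        include_singletons: bool = True,
        min_pairs: int = 20,
        n_starts: int = 3,
        tol: float = 1e-8,
    ):
        self.include_sib = include_sib
        self.include_singletons = include_singletons
        self.min_pairs = min_pairs
        self.n_starts = n_starts
        self.tol = tol

    def _check_floors(self, ps: _PairStats) -> None:
        if len(ps.mz) < self.min_pairs or len(ps.dz) < self.min_pairs:
            raise ValueError(
                f"need >= {self.min_pairs} MZ and DZ/SIB pairs "
                f"(got {len(ps.mz)} MZ, {len(ps.dz)} DZ/SIB)"
            )

    def fit(self, Y: np.ndarray | PhenotypeMaps, cohort: TwinCohort):
        if isinstance(Y, PhenotypeMaps):
            Y = Y.values
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != cohort.n_subjects:
            raise ValueError("one row per cohort subject required")
        ps = _PairStats(cohort, self.include_sib, self.include_singletons)
        self._check_floors(ps)

        n_vox = Y.shape[1]
        fields = (
            "var_a_", "var_c_", "var_e_", "h2_", "c2_", "e2_",
            "loglik_full_", "loglik_null_", "lrt_stat_", "p_lrt_",
        )
        for f in fields:
            setattr(self, f, np.full(n_vox, np.nan))

        for j in range(n_vox):
            y = Y[:, j]
            if y.std() == 0:
                raise ValueError(f"zero phenotypic variance at voxel {j}")
            ss = ps.suffstats(y)
            va, vc, ve, llf = self._optimize(ss, null=False)
            _, vcn, ven, lln = self._optimize(ss, null=True)
            tot = va + vc + ve
            self.var_a_[j], self.var_c_[j], self.var_e_[j] = va, vc, ve
            self.h2_[j] = va / tot
            self.c2_[j] = vc / tot
            self.e2_[j] = ve / tot
            self.loglik_full_[j] = llf
            self.loglik_null_[j] = lln
            self.lrt_stat_[j] = max(0.0, 2.0 * (llf - lln))
            self.p_lrt_[j] = lrt_pvalue(llf, lln)
        _, self.q_fdr_ = fdr_bh(self.p_lrt_)
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _moment_start(ss: dict) -> tuple[float, float, float]:
        """Falconer-style method-of-moments start (clipped to the interior)."""
        n_mz, s1_mz, s2_mz = ss["mz"]
        n_dz, s1_dz, s2_dz = ss["dz"]
        n_s, s_sq = ss["single"]
        denom = s1_mz + s1_dz + s_sq
        nobs = 2 * (n_mz + n_dz) + n_s
        v_hat = denom / max(nobs, 1)
        r_mz = s2_mz / (0.5 * s1_mz) if s1_mz > 0 else 0.0
        r_dz = s2_dz / (0.5 * s1_dz) if s1_dz > 0 else 0.0
        a2 = np.clip(2.0 * (r_mz - r_dz), 0.05, 0.9)
        c2 = np.clip(2.0 * r_dz - r_mz, 0.0, 0.9 - a2)
        e2 = max(1.0 - a2 - c2, 0.05)
        total = a2 + c2 + e2
        return (a2 / total * v_hat, c2 / total * v_hat, e2 / total * v_hat)

    def _optimize(self, ss: dict, null: bool):
        v_scale = self._moment_start(ss)
        v_hat = sum(v_scale)
        starts = [
            v_scale,
            (v_hat / 3.0, v_hat / 3.0, v_hat / 3.0),
            (0.1 * v_hat, 0.1 * v_hat, 0.8 * v_hat),
        ][: self.n_starts]
        ub = 4.0 * np.sqrt(v_hat)

        best = (np.inf, None)
        for va0, vc0, ve0 in starts:
            if null:
                x0 = np.sqrt([max(vc0 + va0 / 2, 1e-8), max(ve0, 1e-8)])

                def obj(x):
                    return _neg2_loglik(0.0, x[0] ** 2, x[1] ** 2, ss)

                bounds = [(0.0, ub), (1e-6, ub)]
            else:
                x0 = np.sqrt([max(va0, 1e-8), max(vc0, 1e-8), max(ve0, 1e-8)])

                def obj(x):
                    return _neg2_loglik(x[0] ** 2, x[1] ** 2, x[2] ** 2, ss)

                bounds = [(0.0, ub), (0.0, ub), (1e-6, ub)]
            res = optimize.minimize(
                obj, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "maxiter": 500},
            )
            if res.fun < best[0]:
                best = (res.fun, res.x)
        x = best[1]
        if null:
            va, vc, ve = 0.0, x[0] ** 2, x[1] ** 2
        else:
            va, vc, ve = x[0] ** 2, x[1] ** 2, x[2] ** 2
        loglik = -0.5 * best[0]
        return va, vc, ve, loglik


def fit_ace(pheno_voxel: np.ndarray, cohort: TwinCohort, **kwargs) -> ACEFit:
    """Single-voxel convenience wrapper returning an :class:`ACEFit`."""
    model = ACEModel(**kwargs).fit(np.asarray(pheno_voxel, float), cohort)
    return ACEFit(
        var_a=model.var_a_[0],
        var_c=model.var_c_[0],
        var_e=model.var_e_[0],
        h2=model.h2_[0],
        c2=model.c2_[0],
        e2=model.e2_[0],
        loglik_full=model.loglik_full_[0],
        loglik_null=model.loglik_null_[0],
        lrt_stat=model.lrt_stat_[0],
        p_lrt=model.p_lrt_[0],
        q_fdr=model.q_fdr_[0],
    )


# ---------------------------------------------------------------------------
# nuisance covariates


def build_covariates(
    cohort: TwinCohort,
    terms: tuple[str, ...] = ("age", "sex", "age_x_sex", "age2", "age2_x_sex"),
    include_motion: bool = False,
    center_age: bool = True,
) -> pd.DataFrame:
    """Design matrix with intercept: age, sex, agexsex, age2, age2xsex.

    Age is centered before powers are formed (numerical conditioning only;
    the residual space is unchanged).
    """
    t = cohort.table
    age = t["age"].to_numpy(float)
    if center_age:
        age = age - age.mean()
    sex = t["sex"].to_numpy(float)
    cols = {"intercept": np.ones(len(t))}
    available = {
        "age": age,
        "sex": sex,
        "age_x_sex": age * sex,
        "age2": age**2,
        "age2_x_sex": age**2 * sex,
    }
    for term in terms:
        if term not in available:
            raise ValueError(f"unknown covariate term {term!r}")
        cols[term] = available[term]
    if include_motion:
        cols["motion"] = t["motion"].to_numpy(float)
    design = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        X = design.to_numpy()
        for i, name in enumerate(design.columns):
            Xi = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(Xi) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return design


def residualize_nuisance(
    pheno: PhenotypeMaps | np.ndarray, cov: pd.DataFrame | np.ndarray
) -> PhenotypeMaps | np.ndarray:
    """OLS residuals of every voxel column on the covariate design."""
    X = cov.to_numpy(float) if isinstance(cov, pd.DataFrame) else np.asarray(cov, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain missing or non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    is_maps = isinstance(pheno, PhenotypeMaps)
    Y = pheno.values if is_maps else np.asarray(pheno, float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if is_maps:
        return PhenotypeMaps(resid, trait_name=pheno.trait_name)
    return resid[:, 0] if squeeze else resid


# ---------------------------------------------------------------------------
# family-subsample ("bootstrap") network distributions


def family_subsample_distribution(
    pheno: PhenotypeMaps | np.ndarray,
    cohort: TwinCohort,
    parc,
    n_reps: int = 1000,
    seed: int = 0,
    min_pairs: int = 20,
    n_networks: int = 7,
    **model_kwargs,
) -> np.ndarray:
    """Half-of-families subsample distribution of network-mean h2.

    Each replicate draws floor(F/2) families without replacement, refits the
    ACE model per voxel on their members and averages h2 per network;
    replicates violating the pair floor are flagged and redrawn.
    Returns an (n_reps, n_networks) matrix.
    """
    from subgrad.parcellation import network_summary

    Y = pheno.values if isinstance(pheno, PhenotypeMaps) else np.asarray(pheno, float)
    rng = np.random.default_rng(seed)
    fams = cohort.table["family_id"].unique()
    if len(fams) < 4:
        raise ValueError("need at least 4 families to subsample halves")
    half = len(fams) // 2
    out = np.full((n_reps, n_networks), np.nan)
    tab = cohort.table.reset_index(drop=True)
    for rep in range(n_reps):
        for attempt in range(100):
            chosen = rng.choice(fams, size=half, replace=False)
            mask = tab["family_id"].isin(chosen).to_numpy()
            sub = TwinCohort(tab.loc[mask].reset_index(drop=True))
            try:
                model = ACEModel(min_pairs=min_pairs, **model_kwargs).fit(
                    Y[mask], sub
                )
            except ValueError:
                continue  # pair floor violated: redraw
            out[rep] = network_summary(model.h2_, parc, stat="mean",
                                       n_networks=n_networks)
            break
        else:
            raise ValueError("could not draw a replicate satisfying pair floors")
    return out


def network_contrast(
    boot: np.ndarray,
    unimodal_ids: np.ndarray,
    transmodal_ids: np.ndarray,
) -> dict:
    """ANOVA across network columns; t-test unimodal vs transmodal means.

    ``boot`` is the replicates x networks matrix from
    :func:`family_subsample_distribution`.  The two-sample two-tailed
    t-statistic compares per-replicate transmodal means against unimodal
    means (positive t = transmodal higher).
    """
    boot = np.asarray(boot, dtype=float)
    uni = np.asarray(unimodal_ids, int) - 1
    trans = np.asarray(transmodal_ids, int) - 1
    if len(uni) < 2 or len(trans) < 2:
        raise ValueError("need at least 2 networks per side")
    cols = [boot[:, j] for j in range(boot.shape[1]) if not np.isnan(boot[:, j]).all()]
    if boot.std() <= 1e-12 * max(1.0, abs(float(boot.mean()))):
        # fully constant input: no between- or within-column variation
        return {"F_stat": 0.0, "p_anova": 1.0, "t_stat": 0.0, "p_t": 1.0}
    if any(np.nanstd(c) == 0 for c in cols):
        raise ValueError("degenerate (zero-variance) network column")
    f_stat, p_anova = stats.f_oneway(*cols)
    uni_means = boot[:, uni].mean(axis=1)
    trans_means = boot[:, trans].mean(axis=1)
    t_stat, p_t = stats.ttest_ind(trans_means, uni_means)
    return {
        "F_stat": float(f_stat),
        "p_anova": float(p_anova),
        "t_stat": float(t_stat),
        "p_t": float(p_t),
    }


# ---------------------------------------------------------------------------
# bivariate ACE and genetic correlation


def genetic_correlation(h_xy: float, h2_x: float, h2_y: float) -> float:
    """rG = h_xy / sqrt(h2_x * h2_y)."""
    denom = np.sqrt(h2_x * h2_y)
    if denom == 0:
        raise ValueError("genetic correlation undefined at zero heritability")
    return float(h_xy / denom)


@dataclass
class BivariateACEFit:
    """Bivariate ACE fit: 2x2 covariance blocks, coheritability, rG."""

    genetic_cov: np.ndarray
    common_cov: np.ndarray
    unique_cov: np.ndarray
    h2_x: float
    h2_y: float
    h_xy: float
    rg: float
    loglik: float


def _chol_from_params(p: np.ndarray) -> np.ndarray:
    L = np.array([[p[0], 0.0], [p[1], p[2]]])
    return L @ L.T


class BivariateACEModel(BaseEstimator):
    """Cholesky-parameterized bivariate ACE model for two traits.

    Both traits are z-scored internally.  The pair covariance stacks 2x2
    blocks [[A+C+E, rho A + C], [rho A + C, A+C+E]] with rho = 1 (MZ) or
    0.5 (DZ/SIB); each of A, C, E is L L' for a lower-triangular L, so
    positive semi-definiteness is structural.
    """

    def __init__(
        self,
        include_sib: bool = True,
        include_singletons: bool = True,
        min_pairs: int = 20,
        tol: float = 1e-8,
    ):
        self.include_sib = include_sib
        self.include_singletons = include_singletons
        self.min_pairs = min_pairs
        self.tol = tol

    def fit(self, x: np.ndarray, y: np.ndarray, cohort: TwinCohort):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != cohort.n_subjects or y.shape[0] != cohort.n_subjects:
            raise ValueError("one value per cohort subject required")
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero phenotypic variance")
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()

        ps = _PairStats(cohort, self.include_sib, self.include_singletons)
        if len(ps.mz) < self.min_pairs or len(ps.dz) < self.min_pairs:
            raise ValueError(
                f"need >= {self.min_pairs} MZ and DZ/SIB pairs "
                f"(got {len(ps.mz)} MZ, {len(ps.dz)} DZ/SIB)"
            )

        # degenerate case: collinear traits make the joint likelihood
        # unbounded at the boundary; the genetic correlation is the sign of
        # the collinearity and the blocks duplicate the univariate fit
        if np.allclose(x, y) or np.allclose(x, -y):
            sign = 1.0 if np.allclose(x, y) else -1.0
            uni = ACEModel(
                include_sib=self.include_sib,
                include_singletons=self.include_singletons,
                min_pairs=self.min_pairs,
            ).fit(x, cohort)
            tot = uni.var_a_[0] + uni.var_c_[0] + uni.var_e_[0]

            def block(v):
                return np.array([[v, sign * v], [sign * v, v]])

            self.genetic_cov_ = block(uni.var_a_[0])
            self.common_cov_ = block(uni.var_c_[0])
            self.unique_cov_ = block(uni.var_e_[0])
            self.h2_x_ = self.h2_y_ = float(uni.h2_[0])
            self.h_xy_ = float(sign * uni.h2_[0])
            self.rg_ = sign
            self.loglik_ = np.inf
            return self

        Z = np.c_[x, y]
        groups = []
        for pairs, rho in ((ps.mz, 1.0), (ps.dz, 0.5)):
            if not len(pairs):
                continue
            zz = np.hstack([Z[pairs[:, 0]], Z[pairs[:, 1]]])     # (n_g, 4)
            S = zz.T @ zz
            groups.append((rho, len(pairs), S))
        singles = None
        if len(ps.singles):
            zs = Z[ps.singles]
            singles = (len(ps.singles), zs.T @ zs)

        def nll(p):
            A = _chol_from_params(p[0:3])
            C = _chol_from_params(p[3:6])
            E = _chol_from_params(p[6:9])
            W = A + C + E
            total = 0.0
            for rho, n_g, S in groups:
                X = rho * A + C
                sigma = np.block([[W, X], [X, W]])
                sign, logdet = np.linalg.slogdet(sigma)
                if sign <= 0:
                    return 1e12
                try:
                    inv = np.linalg.inv(sigma)
                except np.linalg.LinAlgError:
                    return 1e12
                total += n_g * (logdet + 4.0 * _LOG2PI) + np.sum(inv * S)
            if singles is not None:
                n_s, Ss = singles
                sign, logdet = np.linalg.slogdet(W)
                if sign <= 0:
                    return 1e12
                total += n_s * (logdet + 2.0 * _LOG2PI) + np.sum(np.linalg.inv(W) * Ss)
            return 0.5 * total

        # deterministic starts: the phenotypic correlation seeds the cross
        # terms of every block, plus fixed interior/negative alternatives
        r_p = float(np.clip(np.corrcoef(x, y)[0, 1], -0.999, 0.999))
        starts = []
        for rg0, cross_env in ((r_p, True), (0.5, False), (0.0, False), (-0.5, False)):
            sa = np.sqrt(0.4)
            se = np.sqrt(0.5)
            sc = np.sqrt(0.1)
            re0 = rg0 if cross_env else 0.0
            starts.append(
                np.array([
                    sa, rg0 * sa, sa * np.sqrt(max(1e-8, 1 - rg0**2)),
                    sc, rg0 * sc if cross_env else 0.0,
                    sc * np.sqrt(max(1e-8, 1 - rg0**2)) if cross_env else sc,
                    se, re0 * se, se * np.sqrt(max(1e-8, 1 - re0**2)),
                ])
            )
        best = (np.inf, None)
        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                options={"ftol": self.tol, "maxiter": 1000},
            )
            if res.fun < best[0]:
                best = (res.fun, res.x)
        p = best[1]
        A = _chol_from_params(p[0:3])
        C = _chol_from_params(p[3:6])
        E = _chol_from_params(p[6:9])
        W = A + C + E
        self.genetic_cov_ = A
        self.common_cov_ = C
        self.unique_cov_ = E
        self.h2_x_ = float(A[0, 0] / W[0, 0])
        self.h2_y_ = float(A[1, 1] / W[1, 1])
        self.h_xy_ = float(A[0, 1] / np.sqrt(W[0, 0] * W[1, 1]))
        denom = np.sqrt(A[0, 0] * A[1, 1])
        self.rg_ = float(A[0, 1] / denom) if denom > 0 else np.nan
        self.loglik_ = -best[0]
        return self


def fit_bivariate_ace(
    x_voxel: np.ndarray, y_voxel: np.ndarray, cohort: TwinCohort, **kwargs
) -> BivariateACEFit:
    """Functional wrapper over :class:`BivariateACEModel`."""
    m = BivariateACEModel(**kwargs).fit(x_voxel, y_voxel, cohort)
    return BivariateACEFit(
        genetic_cov=m.genetic_cov_,
        common_cov=m.common_cov_,
        unique_cov=m.unique_cov_,
        h2_x=m.h2_x_,
        h2_y=m.h2_y_,
        h_xy=m.h_xy_,
        rg=m.rg_,
        loglik=m.loglik_,
    )
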