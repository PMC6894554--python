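"""Hierarchical resource selection probability function (RSPF).

The model is a binomial GLMM on used(1)/unused(0) points:

    logit P(y=1) = X beta + u_year + sum_j b_{pack,j} x_j

with fixed effects ``beta`` (habitat covariates, regional wolf density, and
covariate-by-density interactions), iid Gaussian year intercepts, and
independent Gaussian pack-level coefficient deviations ("random slopes").
Because non-used points are true absences the inverse-logit of the linear
predictor is a genuine probability of use — an RSPF rather than an RSF.

Estimation maximizes a Laplace-approximated marginal likelihood: an inner
penalized IRLS finds the joint mode of (beta, u) given the variances, and an
outer EM-type fixed point updates each variance from the posterior mean of
the squared deviations.  Posterior summaries (mean, sd, percentiles, mode)
come from the approximate Gaussian posterior, under which mode = mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

DEFAULT_PRIOR_SD = 31.6227766  # precision 0.001: a flat prior at logit scale


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """What enters the RSPF: fixed effects, interactions and random terms."""

    fixed: list[str]
    density: str | None = "wolf_density"
    interactions: list[str] = field(default_factory=list)
    year_factor: str | None = "year"
    pack_factor: str | None = "pack_id"
    random_slopes: list[str] | None = None  # None -> all fixed covariates
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self) -> None:
        unknown = set(self.interactions) - set(self.fixed)
        if unknown:
            raise ValueError(f"interaction covariates not in fixed set: {unknown}")

    def slope_covariates(self) -> list[str]:
        return list(self.fixed) if self.random_slopes is None else list(self.random_slopes)


@dataclass
class RandomBlock:
    name: str
    levels: list
    sl: slice          # columns of the joint design
    variance: float


@dataclass
class RSPFFit:
    spec: ModelSpec
    fixed_names: list[str]
    coef: np.ndarray           # joint posterior mode/mean (fixed + random)
    coef_sd: np.ndarray
    blocks: list[RandomBlock]
    n_fixed: int
    fitted: np.ndarray         # P(use) per row of the training table
    y: np.ndarray
    marginal_loglik: float
    hessian_inv: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Posterior marginal table: mean, s.e., 2.5th/97.5th, mode, mean/s.e."""
        mean = self.coef[: self.n_fixed]
        sd = self.coef_sd[: self.n_fixed]
        z = stats.norm.ppf(0.975)
        df = pd.DataFrame({
            "parameter": self.fixed_names,
            "mean": mean,
            "s.e.": sd,
            "2.5th percentile": mean - z * sd,
            "97.5th percentile": mean + z * sd,
            "mode": mean,  # Gaussian approximation: mode coincides with mean
        })
        df["mean/s.e."] = df["mean"] / df["s.e."]
        return df.set_index("parameter")

    def random_effect_variances(self) -> dict[str, float]:
        return {b.name: b.variance for b in self.blocks}

    def pack_deviations(self, covariate: str) -> pd.Series:
        """Per-pack deviation from the population coefficient of ``covariate``."""
        for b in self.blocks:
            if b.name == f"pack:{covariate}":
                return pd.Series(self.coef[b.sl], index=b.levels, name=covariate)
        raise KeyError(f"no pack random slope on {covariate!r}")

    def pack_coefficients(self, covariate: str) -> pd.Series:
        fixed = dict(zip(self.fixed_names, self.coef[: self.n_fixed]))
        return self.pack_deviations(covariate) + fixed[covariate]


# ---------------------------------------------------------------------------
# design construction


def _fixed_design(table: pd.DataFrame, spec: ModelSpec):
    names = ["intercept"] + list(spec.fixed)
    cols = [np.ones(len(table))] + [table[c].to_numpy(float) for c in spec.fixed]
    if spec.density is not None:
        names.append(spec.density)
        cols.append(table[spec.density].to_numpy(float))
        for c in spec.interactions:
            names.append(f"{c}:{spec.density}")
            cols.append(table[c].to_numpy(float) * table[spec.density].to_numpy(float))
    return names, np.column_stack(cols)


def _random_design(table: pd.DataFrame, spec: ModelSpec, offset: int):
    blocks: list[RandomBlock] = []
    cols: list[np.ndarray] = []
    pos = offset

    n = len(table)

    def add_block(name, factor_vals, weight):
        nonlocal pos
        levels = sorted(pd.unique(factor_vals))
        idx = pd.Categorical(factor_vals, categories=levels).codes
        w = np.broadcast_to(np.asarray(weight, float), (n,))
        z = sparse.csr_matrix((w, (np.arange(n), idx)), shape=(n, len(levels)))
        blocks.append(RandomBlock(name=name, levels=levels,
                                  sl=slice(pos, pos + len(levels)), variance=1.0))
        cols.append(z)
        pos += len(levels)

    if spec.year_factor is not None:
        add_block("year", table[spec.year_factor].to_numpy(), 1.0)
    if spec.pack_factor is not None:
        packs = table[spec.pack_factor].to_numpy()
        for cov in spec.slope_covariates():
            add_block(f"pack:{cov}", packs, table[cov].to_numpy(float))
    if cols:
        return blocks, sparse.hstack(cols, format="csr")
    return blocks, sparse.csr_matrix((n, 0))


# ---------------------------------------------------------------------------
# fitting


def _penalized_irls(X, y, prior_prec, start=None, max_iter=60, tol=1e-9):
    """Newton/IRLS for Bernoulli-logit with Gaussian (ridge) prior.

    Returns (theta, H) where H = X'WX + P is the negative joint Hessian.
    Step-halving keeps the penalized deviance monotone.
    """
    n, p = X.shape
    theta = np.zeros(p) if start is None else start.copy()
    is_sparse = sparse.issparse(X)

    def hessian(w):
        if is_sparse:
            Hm = (X.T @ sparse.diags(w) @ X).toarray()
        else:
            Hm = (X.T * w) @ X
        Hm[np.diag_indices_from(Hm)] += prior_prec
        return Hm

    def objective(th):
        eta = np.clip(X @ th, -30, 30)
        return (np.logaddexp(0, eta).sum() - y @ eta
                + 0.5 * (prior_prec * th ** 2).sum())

    obj = objective(theta)
    for _ in range(max_iter):
        eta = np.clip(X @ theta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (mu - y) + prior_prec * theta
        H = hessian(w)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-6
            step = np.linalg.solve(H, grad)
        lam = 1.0
        for _ in range(30):
            new = theta - lam * step
            new_obj = objective(new)
            if new_obj <= obj + 1e-12:
                break
            lam *= 0.5
        moved = abs(obj - new_obj)
        theta, obj = new, new_obj
        if moved < tol * (abs(obj) + 1.0):
            break
    eta = np.clip(X @ theta, -30, 30)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    return theta, hessian(w)


def _marginal_loglik(X, y, theta, prior_prec, H) -> float:
    eta = np.clip(X @ theta, -30, 30)
    loglik = float(y @ eta - np.logaddexp(0, eta).sum())
    pen = 0.5 * float((prior_prec * theta ** 2).sum())
    sign, logdet_h = np.linalg.slogdet(H)
    logdet_p = float(np.log(prior_prec).sum())
    return loglik - pen + 0.5 * logdet_p - 0.5 * logdet_h


def fit_rspf(table: pd.DataFrame, spec: ModelSpec,
             constrain_variances: dict[str, float] | None = None,
             max_outer: int = 40, outer_tol: float = 2e-2,
             min_variance: float = 1e-8) -> RSPFFit:
    """Fit the hierarchical RSPF by Laplace-approximated marginal likelihood.

    ``constrain_variances`` pins named random-effect variances (e.g.
    ``{"year": 0.0}``); a variance of (effectively) zero removes that block's
    influence, and with every variance pinned at zero the fit reduces to
    ordinary logistic regression.
    """
    y = table["y"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("table needs both used and unused rows")
    fixed_names, Xf = _fixed_design(table, spec)
    blocks, Z = _random_design(table, spec, offset=Xf.shape[1])
    # sparse joint design when random blocks exist (one-hot columns)
    X = sparse.hstack([sparse.csr_matrix(Xf), Z], format="csr") if Z.shape[1] else Xf
    n_fixed = Xf.shape[1]
    p = X.shape[1]
    constrain_variances = constrain_variances or {}

    for b in blocks:
        if b.name in constrain_variances:
            b.variance = max(float(constrain_variances[b.name]), min_variance)
        else:
            b.variance = 0.25  # starting value; updated by the outer loop

    prior_prec = np.full(p, 1.0 / spec.prior_sd ** 2)
    flags: list[str] = []
    theta = None
    converged = False
    free = [b for b in blocks if b.name not in constrain_variances]
    for outer in range(max_outer if free else 1):
        for b in blocks:
            prior_prec[b.sl] = 1.0 / max(b.variance, min_variance)
        theta, H = _penalized_irls(X, y, prior_prec, start=theta)
        if not free:
            converged = True
            break
        Hinv_diag = np.diag(np.linalg.inv(H))
        max_rel = 0.0
        for b in free:
            u = theta[b.sl]
            q = u.size
            new_var = float((u @ u + Hinv_diag[b.sl].sum()) / q)
            new_var = max(new_var, min_variance)
            if abs(new_var - b.variance) > 1e-5:  # collapsed variances count as settled
                max_rel = max(max_rel, abs(math.log(new_var / max(b.variance, min_variance))))
            b.variance = new_var
        if max_rel < outer_tol:
            converged = True
            break
    for b in blocks:
        prior_prec[b.sl] = 1.0 / max(b.variance, min_variance)
    theta, H = _penalized_irls(X, y, prior_prec, start=theta)
    if not converged and free:
        flags.append("variance fixed point did not fully converge")

    Hinv = np.linalg.inv(H)
    coef_sd = np.sqrt(np.clip(np.diag(Hinv), 0, None))
    if np.any(np.abs(theta[:n_fixed]) > 15):
        flags.append("possible complete separation: very large coefficients")
    fitted = expit(np.clip(X @ theta, -30, 30))
    return RSPFFit(
        spec=spec, fixed_names=fixed_names, coef=theta, coef_sd=coef_sd,
        blocks=blocks, n_fixed=n_fixed, fitted=fitted, y=y,
        marginal_loglik=_marginal_loglik(X, y, theta, prior_prec, H),
        hessian_inv=Hinv, converged=converged, flags=flags,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_rspf(fit: RSPFFit, x: dict[str, float], density: float = 0.0,
                 level: str = "population", pack_id=None, year=None) -> float:
    """Inverse-logit RSPF at standardized covariates ``x`` and density.

    ``level='population'`` uses the posterior-mean fixed effects conditioned
    on the supplied (standardized) density; ``level='pack'`` adds the pack's
    coefficient deviations (and the year intercept if given).
    """
    spec = fit.spec
    coef = dict(zip(fit.fixed_names, fit.coef[: fit.n_fixed]))
    eta = coef["intercept"]
    for c in spec.fixed:
        eta += coef[c] * x.get(c, 0.0)
    if spec.density is not None:
        eta += coef[spec.density] * density
        for c in spec.interactions:
            eta += coef[f"{c}:{spec.density}"] * x.get(c, 0.0) * density
    if level == "pack":
        if pack_id is None:
            raise ValueError("pack level prediction needs a pack_id")
        for b in fit.blocks:
            if not b.name.startswith("pack:"):
                continue
            cov = b.name.split(":", 1)[1]
            if pack_id not in b.levels:
                raise KeyError(f"unknown pack id {pack_id!r}")
            eta += fit.coef[b.sl][b.levels.index(pack_id)] * x.get(cov, 0.0)
        if year is not None:
            for b in fit.blocks:
                if b.name == "year" and year in b.levels:
                    eta += fit.coef[b.sl][b.levels.index(year)]
    elif level != "population":
        raise ValueError("level must be 'population' or 'pack'")
    return float(expit(eta))


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DiagnosticsReport:
    pearson_r: float
    auc: float
    waic: float
    p_waic: float
    mean_log_cpo: float
    flags: list[str] = field(default_factory=list)


def auc_rank(y: np.ndarray, score: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties share ranks)."""
    y = np.asarray(y, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined for a single-class sample")
    ranks = stats.rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def diagnostics(fit: RSPFFit, table: pd.DataFrame | None = None,
                n_draws: int = 1000, seed: int = 0,
                chunk: int = 100) -> DiagnosticsReport:
    """Fit diagnostics: Pearson r, AUC, WAIC and a pointwise LOO score.

    WAIC and the conditional predictive ordinate (CPO, reported as the mean
    log CPO over rows) are computed from draws of the approximate Gaussian
    posterior over all coefficients; draws are streamed in chunks.
    """
    y = fit.y
    p_hat = fit.fitted
    flags = list(fit.flags)
    if np.std(p_hat) < 1e-12:
        pearson = 0.0
        flags.append("constant fitted values: Pearson r undefined, reported 0")
    else:
        pearson = float(np.corrcoef(p_hat, y)[0, 1])
    auc = auc_rank(y, p_hat)

    # posterior draws: theta_s = mode + L eps, L from the joint covariance
    rng = np.random.default_rng(seed)
    if table is not None:
        fixed_names, Xf = _fixed_design(table, fit.spec)
        blocks, Z = _random_design(table, fit.spec, offset=Xf.shape[1])
        X = sparse.hstack([sparse.csr_matrix(Xf), Z], format="csr") if Z.shape[1] else Xf
    else:
        X = None
    if X is None:
        raise ValueError("diagnostics needs the design table")
    jitter = 1e-10 * np.eye(fit.hessian_inv.shape[0])
    L = np.linalg.cholesky(fit.hessian_inv + jitter)
    n = len(y)
    sum_lik = np.zeros(n)      # sum over draws of p(y_i | theta_s)
    sum_ll = np.zeros(n)
    sum_ll2 = np.zeros(n)
    sum_inv_lik = np.zeros(n)  # for the harmonic-mean CPO
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        eps = rng.standard_normal((fit.coef.size, m))
        thetas = fit.coef[:, None] + L @ eps
        eta = np.clip(X @ thetas, -30, 30)
        ll = y[:, None] * eta - np.logaddexp(0, eta)  # log p(y_i | theta_s)
        sum_lik += np.exp(ll).sum(axis=1)
        sum_ll += ll.sum(axis=1)
        sum_ll2 += (ll ** 2).sum(axis=1)
        sum_inv_lik += np.exp(np.clip(-ll, None, 700)).sum(axis=1)
        done += m
    lppd_i = np.log(np.clip(sum_lik / n_draws, 1e-300, None))
    var_ll = sum_ll2 / n_draws - (sum_ll / n_draws) ** 2
    p_waic = float(var_ll.sum())
    waic = float(-2 * (lppd_i.sum() - p_waic))
    cpo_i = n_draws / np.clip(sum_inv_lik, 1e-300, None)
    mean_log_cpo = float(np.log(np.clip(cpo_i, 1e-300, None)).mean())
    return DiagnosticsReport(pearson_r=pearson, auc=auc, waic=waic,
                             p_waic=p_waic, mean_log_cpo=mean_log_cpo, flags=flags)


# ---------------------------------------------------------------------------
# variable pre-reduction


def reduce_variables(table: pd.DataFrame, candidates: list[str],
                     penalty_grid: np.ndarray | None = None,
                     cv: int = 5, seed: int = 0) -> tuple[list[str], pd.DataFrame]:
    """Lasso-penalized logistic pre-screen of candidate covariates.

    Fits an L1-penalized logistic regression over a grid of penalty
    strengths, scores each penalty by cross-validated predictive deviance
    (log loss), and applies the one-standard-error rule: the strongest
    penalty whose CV score is within one SE of the best is selected, and
    covariates with zero coefficient there are dropped.  Returns the
    retained names and the full coefficient path.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate covariates")
    y = table["y"].to_numpy(int)
    if y.min() == y.max():
        raise ValueError("table needs both classes")
    # perfectly collinear candidates make the lasso solution non-unique:
    # keep only the first of any (near-)duplicated pair
    corr = np.corrcoef(table[candidates].to_numpy(float), rowvar=False)
    keep: list[str] = []
    for i, c in enumerate(candidates):
        if all(abs(corr[i, candidates.index(k)]) < 0.999 for k in keep):
            keep.append(c)
    candidates = keep
    X = table[candidates].to_numpy(float)
    if penalty_grid is None:
        penalty_grid = np.logspace(-4, 2, 13)  # C = 1/penalty, sklearn convention
    penalty_grid = np.sort(np.asarray(penalty_grid, float))  # strongest first
    rows = []
    means, ses = [], []
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    for C in penalty_grid:
        model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000)
        fold_scores = cross_val_score(model, X, y, cv=skf, scoring="neg_log_loss")
        model.fit(X, y)
        coefs = model.coef_.ravel()
        if np.any(np.abs(coefs) > 50):
            raise SeparationError("complete separation along the penalty path")
        means.append(fold_scores.mean())
        ses.append(fold_scores.std(ddof=1) / math.sqrt(cv))
        rows.append(dict(zip(candidates, coefs), C=C,
                         cv_neg_log_loss=fold_scores.mean()))
    path = pd.DataFrame(rows)
    best = int(np.argmax(means))
    threshold = means[best] - ses[best]
    chosen = next(i for i in range(len(penalty_grid)) if means[i] >= threshold)
    chosen_coefs = path.loc[chosen, candidates].to_numpy(float)
    retained = [c for c, b in zip(candidates, chosen_coefs) if b != 0.0]
    return retained, path


# ---------------------------------------------------------------------------
# density-response curves (habitat functional response)


def density_response_curves(fit: RSPFFit, covariate: str,
                            density_grid: np.ndarray,
                            baseline_prob: float = 0.5,
                            z_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Probability-of-use curves for one covariate at several densities.

    At standardized density d the effective slope is beta_x + beta_{x*d} d;
    each curve is logit^-1(logit(baseline_prob) + slope * z) over the
    covariate z range, conditioning occurrence on an initial probability of
    ``baseline_prob``.  The returned frame carries the effective slope per
    density and (in attrs) the density at which the slope changes sign.
    """
    coef = dict(zip(fit.fixed_names, fit.coef[: fit.n_fixed]))
    if covariate not in coef:
        raise KeyError(f"{covariate!r} not a fixed effect")
    b_x = coef[covariate]
    inter_name = f"{covariate}:{fit.spec.density}"
    if inter_name in coef:
        b_xd = coef[inter_name]
    else:
        warnings.warn(f"{covariate!r} has no density interaction: curves are identical")
        b_xd = 0.0
    if z_grid is None:
        z_grid = np.linspace(-3, 3, 121)
    base_logit = math.log(baseline_prob / (1 - baseline_prob))
    frames = []
    for d in np.asarray(density_grid, float):
        slope = b_x + b_xd * d
        frames.append(pd.DataFrame({
            "density": d, "z": z_grid,
            "probability": expit(base_logit + slope * z_grid),
            "effective_slope": slope,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["sign_switch_density"] = (-b_x / b_xd) if b_xd != 0 else None
    return out


# ---------------------------------------------------------------------------
# pack-level heterogeneity (post-hoc)


@dataclass
class PackComparison:
    covariate: str
    strong_packs: list
    weak_packs: list
    strong_mean_size: float
    weak_mean_size: float
    t_statistic: float
    t_pvalue: float
    rank_sum_u: float
    rank_sum_pvalue: float


def pack_heterogeneity_test(fit: RSPFFit, pack_sizes: pd.Series,
                            covariate: str) -> PackComparison:
    """Compare pack sizes between strong- and weak-selection packs.

    Packs above the 75th percentile of the pack-level coefficient for
    ``covariate`` form the strong group, below the 25th the weak group;
    group mean sizes, Welch's t and the Mann-Whitney rank-sum statistic are
    reported.
    """
    coefs = fit.pack_coefficients(covariate)
    coefs = coefs[coefs.index.isin(pack_sizes.index)]
    if len(coefs) < 8:
        raise ValueError("need at least 8 packs with coefficients and sizes")
    lo, hi = np.percentile(coefs, [25, 75])
    weak = coefs.index[coefs < lo].tolist()
    strong = coefs.index[coefs > hi].tolist()
    s_sizes = pack_sizes.loc[strong].to_numpy(float)
    w_sizes = pack_sizes.loc[weak].to_numpy(float)
    if len(s_sizes) < 2 or len(w_sizes) < 2:
        raise ValueError("percentile split left a group with < 2 packs")
    t_stat, t_p = stats.ttest_ind(s_sizes, w_sizes, equal_var=False)
    if np.ptp(np.concatenate([s_sizes, w_sizes])) == 0:
        u_stat, u_p = len(s_sizes) * len(w_sizes) / 2.0, 1.0
        t_stat, t_p = 0.0, 1.0
    else:
        u_stat, u_p = stats.mannwhitneyu(s_sizes, w_sizes, alternative="two-sided")
    return PackComparison(
        covariate=covariate, strong_packs=strong, weak_packs=weak,
        strong_mean_size=float(s_sizes.mean()), weak_mean_size=float(w_sizes.mean()),
        t_statistic=float(t_stat), t_pvalue=float(t_p),
        rank_sum_u=float(u_stat), rank_sum_pvalue=float(u_p),
    )
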