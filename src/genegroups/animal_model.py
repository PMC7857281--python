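"""Bayesian genetic-groups animal model for binary traits.

The model is a logit-link animal model on the latent scale:

    l_i = x_i' beta + a_{animal(i)} + b_{brood(i)} + c_{year(i)} + e_i
    y_i ~ Bernoulli(logit^-1(l_i)),   e_i ~ N(0, 1)

with fixed effects [intercept, immigrant-group coefficient q, inbreeding
coefficient f, natal year (continuous, centred), clutch date (centred),
sex (M vs F contrast)], random additive genetic effects a with covariance
V_A * A (pedigree relatedness), random brood and cohort-year effects, and
the latent residual variance fixed to 1 by convention so the scale is
identified. The coefficient on q is the immigrant genetic-group effect g.

Fitting is by collapsed Gibbs sampling with Polya-Gamma data augmentation:
the PG weights turn the likelihood into weighted Gaussian pseudo-data with
the unit latent residual integrated out, all location effects are drawn
jointly from one sparse factorised Gaussian (the dense fixed-effect
columns enter via a Schur complement, the additive-genetic prior through
its exact square root A^-1 = T' D^-1 T), and each variance component is
slice-sampled from its marginal likelihood with its own effects integrated
out before those effects are redrawn. Variance-component standard
deviations carry proper half-Cauchy priors with configurable scale
(default 1). See docs/methods.md for the full scheme and its validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from ._polyagamma import random_polyagamma
from ._sparsechol import PatternCholesky
from .pedigree import Pedigree, a_inverse

OBS_COLUMNS = ("id", "survival", "sex", "clutch_date", "brood_id", "cohort", "q", "f")
FIXED_EFFECTS = ("intercept", "q", "f", "year", "clutch_date", "sex")


class ModelError(ValueError):
    """Raised when a model cannot be built or estimated from the given data."""


@dataclass
class ModelSpec:
    """Structure of the genetic-groups animal model (see module docstring)."""

    include_group_effect: bool = True
    link: str = "logit"


@dataclass
class PriorSpec:
    """Diffuse-normal fixed effects; half-Cauchy(sd_scale) on component SDs."""

    fixed_effect_variance: float = 1e10
    sd_scale: float = 1.0

    def __post_init__(self):
        if self.fixed_effect_variance <= 0 or self.sd_scale <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


@dataclass
class ChainConfig:
    """MCMC run lengths; `iterations` counts post-burn-in sweeps before thinning."""

    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("chain lengths must be positive and thin >= 1")

    @property
    def retained(self) -> int:
        return self.iterations // self.thin


@dataclass
class DesignBundle:
    """Assembled model matrices shared by all fitting variants."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    animal_idx: np.ndarray       # obs -> pedigree position
    brood_idx: np.ndarray
    brood_levels: list
    year_idx: np.ndarray
    year_levels: list
    ped_ids: list[str]
    a_inv: sparse.csr_matrix
    t_factor: sparse.csr_matrix  # T = I - P with A^-1 = T' D^-1 T
    d_mendel: np.ndarray
    centers: dict[str, float]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_ped(self) -> int:
        return len(self.ped_ids)

    def drop_fixed_effect(self, name: str) -> "DesignBundle":
        if name not in self.columns:
            raise ModelError(f"no fixed effect named {name!r} in design")
        keep = [k for k, c in enumerate(self.columns) if c != name]
        return replace(
            self, X=self.X[:, keep], columns=[self.columns[k] for k in keep]
        )


def validate_observations(obs: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    missing_cols = set(OBS_COLUMNS) - set(obs.columns)
    if missing_cols:
        raise ModelError(f"observation table lacks columns: {sorted(missing_cols)}")
    obs = obs.copy()
    obs["id"] = obs["id"].astype(str)
    absent = [i for i in obs["id"] if i not in ped.index]
    if absent:
        raise ModelError(f"observed ids missing from pedigree: {absent[:5]}")
    bad = obs[list(OBS_COLUMNS[1:])].isna().any(axis=1)
    if bad.any():
        raise ModelError(
            "missing covariates for ids: " + ", ".join(obs.loc[bad, "id"].head(5))
        )
    return obs


def build_design(obs: pd.DataFrame, ped: Pedigree,
                 spec: ModelSpec | None = None) -> DesignBundle:
    """Assemble fixed-effect matrix and random-effect incidence maps.

    Year and clutch date are centred; sex enters as a single M-vs-F
    indicator. Broods must be nested in cohorts (a natal brood belongs to
    one year).
    """
    spec = spec or ModelSpec()
    obs = validate_observations(obs, ped)

    mixed = obs.groupby("brood_id")["cohort"].nunique()
    if (mixed > 1).any():
        raise ModelError(
            f"broods spanning multiple cohorts: {list(mixed[mixed > 1].index[:5])}"
        )

    year = obs["cohort"].to_numpy(dtype=float)
    clutch = obs["clutch_date"].to_numpy(dtype=float)
    centers = {"year": float(year.mean()), "clutch_date": float(clutch.mean())}
    sex_m = (obs["sex"].astype(str).str.upper().isin(["M", "MALE", "1"])).to_numpy(float)

    cols = {
        "intercept": np.ones(len(obs)),
        "q": obs["q"].to_numpy(dtype=float),
        "f": obs["f"].to_numpy(dtype=float),
        "year": year - centers["year"],
        "clutch_date": clutch - centers["clutch_date"],
        "sex": sex_m,
    }
    names = [c for c in FIXED_EFFECTS if spec.include_group_effect or c != "q"]
    X = np.column_stack([cols[c] for c in names])

    brood_levels = sorted(obs["brood_id"].astype(str).unique())
    brood_map = {b: k for k, b in enumerate(brood_levels)}
    year_levels = sorted(obs["cohort"].unique())
    year_map = {y: k for k, y in enumerate(year_levels)}

    rs = a_inverse(ped)
    t_factor = _parent_average_factor(ped)

    return DesignBundle(
        X=X,
        columns=names,
        y=obs["survival"].to_numpy(dtype=float),
        animal_idx=np.array([ped.index[i] for i in obs["id"]], dtype=np.int64),
        brood_idx=np.array([brood_map[str(b)] for b in obs["brood_id"]], dtype=np.int64),
        brood_levels=brood_levels,
        year_idx=np.array([year_map[y] for y in obs["cohort"]], dtype=np.int64),
        year_levels=list(year_levels),
        ped_ids=ped.ids,
        a_inv=rs.a_inv,
        t_factor=t_factor,
        d_mendel=rs.d,
        centers=centers,
    )


def _parent_average_factor(ped: Pedigree) -> sparse.csr_matrix:
    """T = I - P where P averages the known parents; A^-1 = T' D^-1 T."""
    n = len(ped)
    rows = list(range(n))
    cols = list(range(n))
    vals = [1.0] * n
    for k in range(n):
        for p in (ped.sire_idx[k], ped.dam_idx[k]):
            if p >= 0:
                rows.append(k)
                cols.append(int(p))
                vals.append(-0.5)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class PosteriorSamples:
    """Retained MCMC draws from an animal-model fit."""

    v_a: np.ndarray
    v_brood: np.ndarray
    v_year: np.ndarray
    beta: np.ndarray                  # (S, p)
    beta_columns: list[str]
    a: np.ndarray                     # (S, n_ped); pedigree order, ancestors included
    ped_ids: list[str]
    year_levels: list
    thin: int = 1
    seed: int = 0
    autocorr: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # e.g. residual variance (Gaussian fit)

    def __len__(self) -> int:
        return len(self.v_a)

    @property
    def g(self) -> np.ndarray:
        """Posterior draws of the immigrant genetic-group effect."""
        if "q" not in self.beta_columns:
            raise ModelError("model was fitted without a group effect (no q column)")
        return self.beta[:, self.beta_columns.index("q")]

    def fixed_effect(self, name: str) -> np.ndarray:
        return self.beta[:, self.beta_columns.index(name)]

    def thin_by(self, k: int) -> "PosteriorSamples":
        return replace(
            self,
            v_a=self.v_a[::k], v_brood=self.v_brood[::k], v_year=self.v_year[::k],
            beta=self.beta[::k], a=self.a[::k], thin=self.thin * k,
            autocorr=_chain_autocorr(self.v_a[::k], self.beta[::k],
                                     self.beta_columns),
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, mode, 95% HPD and prop<0 per reported scalar."""
        rows = []
        named = [("V_A", self.v_a), ("V_brood", self.v_brood),
                 ("V_year", self.v_year), ("heritability", heritability(self))]
        named += [(c, self.beta[:, k]) for k, c in enumerate(self.beta_columns)]
        for name, draws in named:
            lo, hi = hpd_interval(draws)
            rows.append({
                "parameter": name,
                "posterior_mean": draws.mean(),
                "posterior_mode": posterior_mode(draws),
                "hpd_lower": lo,
                "hpd_upper": hi,
                "prop_negative": float((draws < 0).mean()),
            })
        return pd.DataFrame(rows)

    def to_long_frame(self, include_breeding_values: bool = False) -> pd.DataFrame:
        frames = []
        S = len(self)
        for name, draws in [("V_A", self.v_a), ("V_brood", self.v_brood),
                            ("V_year", self.v_year)]:
            frames.append(pd.DataFrame(
                {"draw": np.arange(S), "parameter": name, "value": draws}))
        for k, c in enumerate(self.beta_columns):
            frames.append(pd.DataFrame(
                {"draw": np.arange(S), "parameter": f"beta:{c}",
                 "value": self.beta[:, k]}))
        if include_breeding_values:
            for j, pid in enumerate(self.ped_ids):
                frames.append(pd.DataFrame(
                    {"draw": np.arange(S), "parameter": f"a:{pid}",
                     "value": self.a[:, j]}))
        return pd.concat(frames, ignore_index=True)

    def save(self, path) -> None:
        """Compact binary cache of the draws (numpy .npz)."""
        np.savez_compressed(
            path, v_a=self.v_a, v_brood=self.v_brood, v_year=self.v_year,
            beta=self.beta, a=self.a,
            beta_columns=np.array(self.beta_columns),
            ped_ids=np.array(self.ped_ids),
            year_levels=np.array(self.year_levels),
            thin=self.thin, seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            samples = cls(
                v_a=z["v_a"], v_brood=z["v_brood"], v_year=z["v_year"],
                beta=z["beta"], beta_columns=[str(c) for c in z["beta_columns"]],
                a=z["a"], ped_ids=[str(i) for i in z["ped_ids"]],
                year_levels=list(z["year_levels"]),
                thin=int(z["thin"]), seed=int(z["seed"]),
            )
        samples.autocorr = _chain_autocorr(samples.v_a, samples.beta,
                                           samples.beta_columns)
        return samples


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `prob` of the draws."""
    x = np.sort(np.asarray(draws))
    n = len(x)
    k = max(1, int(np.floor(prob * n)))
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_mode(draws: np.ndarray) -> float:
    """Kernel-density mode estimate on a grid over the sample range."""
    from scipy.stats import gaussian_kde

    x = np.asarray(draws, dtype=float)
    if np.ptp(x) < 1e-12:
        return float(x[0])
    grid = np.linspace(x.min(), x.max(), 512)
    dens = gaussian_kde(x)(grid)
    return float(grid[int(np.argmax(dens))])


def _lag1(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.std(x) < 1e-14:
        return 0.0
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def _chain_autocorr(v_a, beta, beta_columns) -> dict[str, float]:
    out = {"V_A": _lag1(v_a)}
    for k, c in enumerate(beta_columns):
        out[c] = _lag1(beta[:, k])
    return out


def _sample_inverse_gamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


# ---------------------------------------------------------------------------
# Gibbs samplers
# ---------------------------------------------------------------------------

def fit(design: DesignBundle, priors: PriorSpec | None = None,
        chain: ChainConfig | None = None,
        autocorr_warn: float = 0.05) -> PosteriorSamples:
    """Fit the binary-trait genetic-groups animal model; exact given seed.

    Reports lag-1 autocorrelation for V_A and every fixed effect and warns
    if any exceeds `autocorr_warn` (increase `chain.thin` in that case).
    """
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    y = design.y
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("phenotype must be binary 0/1")
    if "q" in design.columns:
        qcol = design.X[:, design.columns.index("q")]
        if np.ptp(qcol) < 1e-12:
            raise ModelError(
                "immigrant effect inestimable: zero variance in q across "
                "phenotyped individuals"
            )
    return _gibbs(design, priors, chain, binary=True,
                  autocorr_warn=autocorr_warn)


def fit_no_groups_variant(design: DesignBundle, priors: PriorSpec | None = None,
                          chain: ChainConfig | None = None,
                          autocorr_warn: float = 0.05) -> PosteriorSamples:
    """Fit the same model without the q regression (no explicit immigrant effect).

    This variant assumes one unstructured base population; with a genuine
    group difference and trending q it inflates the apparent V_A.
    """
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    if not np.isin(design.y, (0.0, 1.0)).all():
        raise ModelError("phenotype must be binary 0/1")
    reduced = design.drop_fixed_effect("q") if "q" in design.columns else design
    return _gibbs(reduced, priors, chain, binary=True,
                  autocorr_warn=autocorr_warn)


def fit_gaussian(design: DesignBundle, priors: PriorSpec | None = None,
                 chain: ChainConfig | None = None,
                 fixed_variances: dict[str, float] | None = None) -> PosteriorSamples:
    """Gaussian-response variant (identity link) of the same mixed model.

    Used for cross-checks against directly solved mixed-model equations;
    `fixed_variances` may pin any of V_A, V_brood, V_year, V_residual
    (unpinned components are sampled, residual included).
    """
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    return _gibbs(design, priors, chain, binary=False,
                  fixed_variances=fixed_variances or {}, autocorr_warn=np.inf)


def _slice_sample_log(logf, x0: float, rng, width: float = 1.2,
                      max_steps: int = 30) -> float:
    """Univariate slice sampler (stepping out + shrinkage) on an unbounded axis."""
    level = logf(x0) + np.log(rng.random())
    left = x0 - width * rng.random()
    right = left + width
    for _ in range(max_steps):
        if logf(left) <= level:
            break
        left -= width
    for _ in range(max_steps):
        if logf(right) <= level:
            break
        right += width
    for _ in range(100):
        x1 = left + (right - left) * rng.random()
        if logf(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _log_prior_sd_logv(t: float, scale: float) -> float:
    """log prior density of t = log V when the SD sqrt(V) is half-Cauchy(scale)."""
    return 0.5 * t - np.log1p(np.exp(t) / scale**2)


def _gibbs(design: DesignBundle, priors: PriorSpec, chain: ChainConfig,
           binary: bool, fixed_variances: dict[str, float] | None = None,
           autocorr_warn: float = 0.05) -> PosteriorSamples:
    """Collapsed Gibbs sampler shared by the binary and Gaussian variants.

    For the binary model, Polya-Gamma weights turn the likelihood into
    weighted Gaussian pseudo-data z = (y - 1/2)/omega with per-observation
    variance 1/omega + 1 (the fixed unit latent residual is integrated out
    rather than kept in the state). Location effects are drawn jointly via
    one sparse factorisation (fixed effects folded in by a Schur
    complement); each variance component is slice-sampled from its marginal
    likelihood with its own effects integrated out, then the effects are
    redrawn from their exact conditional - so variance draws decorrelate at
    the speed of the weights, not of the breeding values.
    """
    fixed_variances = fixed_variances or {}
    rng = np.random.default_rng(chain.seed)

    X, y = design.X, design.y
    n, p = X.shape
    n_ped = design.n_ped
    n_brood = len(design.brood_levels)
    n_year = len(design.year_levels)

    animal, brood, yearf = design.animal_idx, design.brood_idx, design.year_idx

    a_inv = design.a_inv.tocsr()
    t_factor = design.t_factor.tocsr()
    dinv_sqrt = 1.0 / np.sqrt(design.d_mendel)
    l_factor = (t_factor.T @ sparse.diags(dinv_sqrt)).tocsr()  # A^-1 = L L'
    scale = priors.sd_scale

    rows = np.arange(n)
    ones = np.ones(n)
    z_a = sparse.csr_matrix((ones, (rows, animal)), shape=(n, n_ped))
    z_b = sparse.csr_matrix((ones, (rows, brood)), shape=(n, n_brood))
    z_c = sparse.csr_matrix((ones, (rows, yearf)), shape=(n, n_year))
    Z = sparse.hstack([z_a, z_b, z_c]).tocsr()
    Zt = Z.T.tocsr()
    m_r = n_ped + n_brood + n_year
    sl_a = slice(0, n_ped)
    sl_b = slice(n_ped, n_ped + n_brood)
    sl_c = slice(n_ped + n_brood, m_r)
    prior_prec_beta = np.eye(p) / priors.fixed_effect_variance

    # precision-matrix patterns are fixed across sweeps: factor symbolically
    # once, then each sweep only runs the numeric Cholesky kernels
    ai_coo = a_inv.tocoo()
    bcol = brood + n_ped
    ccol = yearf + n_ped + n_brood
    qrr_rows = np.concatenate([animal, animal, animal, bcol, bcol, bcol,
                               ccol, ccol, ccol, ai_coo.row,
                               np.arange(n_ped, m_r)])
    qrr_cols = np.concatenate([animal, bcol, ccol, animal, bcol, ccol,
                               animal, bcol, ccol, ai_coo.col,
                               np.arange(n_ped, m_r)])
    chol_qrr = PatternCholesky(qrr_rows, qrr_cols, m_r)
    qa_rows = np.concatenate([np.arange(n_ped), ai_coo.row])
    qa_cols = np.concatenate([np.arange(n_ped), ai_coo.col])
    chol_qa = PatternCholesky(qa_rows, qa_cols, n_ped)

    beta = np.zeros(p)
    u = np.zeros(m_r)
    a = u[sl_a]
    b = u[sl_b]
    c = u[sl_c]
    e_lat = np.zeros(n)  # unit-variance latent residual (binary model only)
    v_a = fixed_variances.get("V_A", 1.0)
    v_b = fixed_variances.get("V_brood", 1.0)
    v_c = fixed_variances.get("V_year", 1.0)
    v_e = fixed_variances.get("V_residual", 1.0) if not binary else 1.0
    xi_e = 1.0
    kappa = y - 0.5

    S = chain.retained
    out_va = np.empty(S)
    out_vb = np.empty(S)
    out_vc = np.empty(S)
    out_ve = np.empty(S)
    out_beta = np.empty((S, p))
    out_a = np.empty((S, n_ped))
    kept = 0

    def _grouped_logmarg(t, sw, swr):
        """Marginal log-likelihood of log-variance t for an i.i.d. grouped
        factor, effects integrated out; sw/swr are groupwise sums of the
        weights and of weight*residual."""
        v = np.exp(t)
        return -0.5 * float(np.sum(np.log1p(v * sw) - v * swr**2 / (1 + v * sw))) \
            + _log_prior_sd_logv(t, scale)

    for it in range(chain.burn_in + chain.iterations):
        eta = X @ beta + Z @ u

        if binary:
            omega = random_polyagamma(eta + e_lat, rng)
            z = kappa / omega
            w = omega / (1.0 + omega)
        else:
            z = y.astype(float)
            w = np.full(n, 1.0 / v_e)

        # joint draw of all location effects given the weights: the random
        # blocks use one sparse factorisation; the p dense fixed-effect
        # columns are folded in via a Schur complement so the factorised
        # matrix keeps its pedigree sparsity
        Xw = X * w[:, None]
        ZtWX = np.asarray(Zt @ Xw)
        w9 = np.tile(w, 9)
        qrr_vals = np.concatenate([
            w9, ai_coo.data / v_a,
            np.full(n_brood, 1.0 / v_b), np.full(n_year, 1.0 / v_c)])
        fac_rr = chol_qrr.factor(qrr_vals)
        sqw_eps = np.sqrt(w) * rng.standard_normal(n)
        rhs_r = Zt @ (w * z + sqw_eps)
        rhs_r[sl_a] += l_factor @ rng.standard_normal(n_ped) / np.sqrt(v_a)
        rhs_r[sl_b] += rng.standard_normal(n_brood) / np.sqrt(v_b)
        rhs_r[sl_c] += rng.standard_normal(n_year) / np.sqrt(v_c)
        rhs_b = X.T @ (w * z + sqw_eps) \
            + rng.standard_normal(p) / np.sqrt(priors.fixed_effect_variance)

        sol = fac_rr.solve(np.column_stack([ZtWX, rhs_r]))
        G, y0 = sol[:, :p], sol[:, p]
        schur = X.T @ Xw + prior_prec_beta - ZtWX.T @ G
        beta = np.linalg.solve(schur, rhs_b - ZtWX.T @ y0)
        u = y0 - G @ beta
        a = u[sl_a]
        b = u[sl_b]
        c = u[sl_c]

        # record the mutually consistent state (effects drawn under the
        # variances that generated them) before the variance blocks move
        k = it - chain.burn_in
        if k >= 0 and k % chain.thin == 0 and kept < S:
            out_va[kept] = v_a
            out_vb[kept] = v_b
            out_vc[kept] = v_c
            out_ve[kept] = v_e
            out_beta[kept] = beta
            out_a[kept] = a
            kept += 1

        if not binary and "V_residual" not in fixed_variances:
            r = z - X @ beta - Z @ u
            v_e = _sample_inverse_gamma(
                rng, (n + 1) / 2, float(r @ r) / 2 + 1 / xi_e)
            xi_e = _sample_inverse_gamma(rng, 1.0, 1 / v_e + 1 / scale**2)
            w = np.full(n, 1.0 / v_e)

        # each variance block: slice-sample log V from the marginal
        # likelihood with its own effects (and the latent residual)
        # integrated out, then redraw the effects under the new variance
        xb = X @ beta
        if "V_brood" not in fixed_variances:
            r = z - xb - a[animal] - c[yearf]
            sw = np.bincount(brood, weights=w, minlength=n_brood)
            swr = np.bincount(brood, weights=w * r, minlength=n_brood)
            v_b = np.exp(_slice_sample_log(
                lambda t: _grouped_logmarg(t, sw, swr), np.log(v_b), rng))
            prec = sw + 1.0 / v_b
            b = swr / prec + rng.standard_normal(n_brood) / np.sqrt(prec)
        if "V_year" not in fixed_variances:
            r = z - xb - a[animal] - b[brood]
            sw = np.bincount(yearf, weights=w, minlength=n_year)
            swr = np.bincount(yearf, weights=w * r, minlength=n_year)
            v_c = np.exp(_slice_sample_log(
                lambda t: _grouped_logmarg(t, sw, swr), np.log(v_c), rng))
            prec = sw + 1.0 / v_c
            c = swr / prec + rng.standard_normal(n_year) / np.sqrt(prec)
        if "V_A" not in fixed_variances:
            r = z - xb - b[brood] - c[yearf]
            cw = np.bincount(animal, weights=w, minlength=n_ped)
            h = np.bincount(animal, weights=w * r, minlength=n_ped)
            fac_cache: dict[float, object] = {}

            def _qa_factor(t: float):
                if t not in fac_cache:
                    fac_cache[t] = chol_qa.factor(
                        np.concatenate([cw, ai_coo.data * np.exp(-t)]))
                return fac_cache[t]

            def _va_logmarg(t: float) -> float:
                fac_t = _qa_factor(t)
                logdet = n_ped * t + fac_t.logdet()
                quad = float(h @ fac_t.solve(h))
                return -0.5 * (logdet - quad) + _log_prior_sd_logv(t, scale)

            t_new = _slice_sample_log(_va_logmarg, np.log(v_a), rng)
            v_a = np.exp(t_new)
            pert = np.bincount(animal,
                               weights=np.sqrt(w) * rng.standard_normal(n),
                               minlength=n_ped) \
                + l_factor @ rng.standard_normal(n_ped) / np.sqrt(v_a)
            a = _qa_factor(t_new).solve(h + pert)
        u = np.concatenate([a, b, c])

        if binary:
            # refresh the latent residual for the next Polya-Gamma draw
            eta = xb + Z @ u
            e_lat = w * (z - eta) + rng.standard_normal(n) / np.sqrt(1.0 + omega)

    samples = PosteriorSamples(
        v_a=out_va[:kept], v_brood=out_vb[:kept], v_year=out_vc[:kept],
        beta=out_beta[:kept], beta_columns=list(design.columns),
        a=out_a[:kept], ped_ids=list(design.ped_ids),
        year_levels=list(design.year_levels),
        thin=chain.thin, seed=chain.seed,
        extra={} if binary else {"v_residual": out_ve[:kept]},
    )
    samples.autocorr = _chain_autocorr(samples.v_a, samples.beta,
                                       samples.beta_columns)
    worst = max(samples.autocorr.values())
    if worst > autocorr_warn:
        slow = [k for k, v in samples.autocorr.items() if v > autocorr_warn]
        warnings.warn(
            f"lag-1 autocorrelation above {autocorr_warn} for {slow}; "
            "increase chain.thin or chain.iterations", RuntimeWarning,
        )
    return samples


def fit_with_target_autocorr(design: DesignBundle, priors: PriorSpec | None = None,
                             chain: ChainConfig | None = None,
                             target: float = 0.05,
                             max_rounds: int = 3) -> PosteriorSamples:
    """Refit with doubled thinning (same retained count) until the lag-1
    autocorrelation of V_A and all fixed effects drops below `target`."""
    chain = chain or ChainConfig()
    for _ in range(max_rounds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            samples = fit(design, priors, chain, autocorr_warn=np.inf)
        if max(samples.autocorr.values()) <= target:
            return samples
        chain = replace(chain, thin=chain.thin * 2,
                        iterations=chain.iterations * 2)
    warnings.warn(
        f"autocorrelation target {target} not reached after {max_rounds} "
        "thinning rounds", RuntimeWarning,
    )
    return samples


def heritability(samples: PosteriorSamples) -> np.ndarray:
    """Latent-scale h^2 per draw: V_A over the sum of all variance components.

    The residual contributes its fixed value 1 (or its sampled value for the
    Gaussian variant); no logit-link variance term is added.
    """
    v_e = samples.extra.get("v_residual", 1.0)
    return samples.v_a / (samples.v_a + samples.v_brood + samples.v_year + v_e)
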