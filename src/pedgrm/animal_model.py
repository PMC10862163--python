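"""Bayesian animal model: variance decomposition under a relatedness matrix.

The model for repeated measurements y of a quantitative trait is

    y = X b + Z a + Z p + (Z_year u) + e,
    a ~ N(0, sigma2_a K),   p ~ N(0, sigma2_pe I),
    u ~ N(0, sigma2_year I),   e ~ N(0, sigma2_e I),

where K is any positive-definite relatedness matrix (pedigree A or genomic
G), a are additive genetic effects ("breeding values"), p are
permanent-environment effects of the individuals, and the optional u are
year effects.  Fixed effects b (intercept plus measurer contrasts by
default) carry an improper flat prior.  Random-effect standard deviations
carry half-t(3, sd(y)) priors by default, realised exactly through
parameter expansion (each component is ``alpha * eta`` with a Gaussian
scalar ``alpha`` and a scaled component ``eta``), so the whole model still
admits an exact blocked Gibbs sampler:

* b from its Gaussian full conditional;
* the individual-effect block jointly: eta_a is drawn from its conditional
  with p analytically marginalised (precision
  ``K^{-1}/vtilde_a + alpha_a^2 diag(w)`` with
  ``w_i = n_i / (sigma2_e + n_i * sigma2_pe)``), then alpha_a, then p
  given a — a joint draw of the strongly anti-correlated block, which
  together with the rescaling alpha moves is what makes the Va/Vpe split
  mix well;
* each scale variance from its scaled-inverse-chi-square full
  conditional (the plain conjugate prior, without expansion, is available
  via ``ModelSpec(prior="inv_chisq")``).

Heritability is computed per draw as Va over the sum of all fitted
variance components (mean of ratios), and the additive genetic coefficient
as Va divided by the trait mean.  Convergence is monitored with the split
potential scale reduction factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import (
    CoverageError,
    DecompositionError,
    InsufficientChainsError,
    InvalidConfigError,
)
from .relatedness import RelatednessMatrix

logger = logging.getLogger(__name__)

_JITTER_STEPS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


@dataclass
class ModelSpec:
    """Model structure, priors and MCMC settings.

    ``relatedness`` supplies K for the additive genetic term; the
    permanent-environment term is always an identity over individuals, and
    a year random effect can be switched on.  The default prior on each
    random-effect SD is half-t(``half_t_df``, ``half_t_scale``), with the
    scale defaulting to the sample phenotypic SD; ``prior="inv_chisq"``
    switches to a plain scaled-inverse-chi-square prior on the variances
    (df ``prior_df``, scale ``prior_scale``).  The residual variance
    always uses the scaled-inverse-chi-square prior with tiny df.  The
    MCMC defaults (20,000 iterations, 4,000 burn-in, 4 chains) suit a
    final analysis; simulation studies in the test-suite use shorter
    chains.
    """

    relatedness: RelatednessMatrix | None = None
    fixed_effects: tuple = ("measurer",)
    include_year: bool = False
    n_iter: int = 20000
    n_burnin: int = 4000
    n_chains: int = 4
    thin: int = 1
    seed: int = 0
    prior: str = "half_t"
    half_t_df: float = 3.0
    half_t_scale: float | None = None
    prior_df: float = 1e-3
    prior_scale: float | None = None

    def validate(self) -> None:
        if self.relatedness is None:
            raise InvalidConfigError("ModelSpec.relatedness (K) is required")
        if not 0 <= self.n_burnin < self.n_iter:
            raise InvalidConfigError("need 0 <= n_burnin < n_iter")
        if self.n_chains < 1:
            raise InvalidConfigError("need at least one chain")
        if self.thin < 1:
            raise InvalidConfigError("thin must be >= 1")
        if self.prior not in ("half_t", "inv_chisq"):
            raise InvalidConfigError("prior must be 'half_t' or 'inv_chisq'")
        if self.prior_df <= 0 or self.half_t_df <= 0:
            raise InvalidConfigError("prior degrees of freedom must be positive")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws from all chains.

    ``draws`` has one row per retained draw with columns ``chain``,
    ``draw``, ``mu``, one column per fixed-effect contrast, the variance
    components (``Va``, ``Vpe``, ``Vres``, optionally ``Vyear``) and the
    per-draw heritability ``h2``.
    """

    draws: pd.DataFrame
    fixed_names: list
    n_obs: int
    n_individuals: int
    meta: dict = field(default_factory=dict)

    @property
    def variance_components(self) -> list:
        return [c for c in ("Va", "Vpe", "Vyear", "Vres") if c in self.draws.columns]

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())

    def by_chain(self, column: str) -> np.ndarray:
        """(n_chains, n_draws) array for one parameter."""
        groups = [g[column].to_numpy() for _, g in self.draws.groupby("chain", sort=True)]
        n = min(len(g) for g in groups)
        return np.vstack([g[:n] for g in groups])


@dataclass
class PosteriorSummary:
    quantity: str
    mean: float
    lower: float
    upper: float
    rhat: float | None = None
    extras: dict = field(default_factory=dict)

    def round(self, ndigits: int = 2) -> tuple:
        return (round(self.mean, ndigits), round(self.lower, ndigits),
                round(self.upper, ndigits))


def _repair_to_pd(K: np.ndarray) -> tuple[np.ndarray, float]:
    """PSD repair: escalate a diagonal jitter up to 1e-4·(trace/n).

    A genomic K is often numerically singular (the centred GRM has a
    near-null direction along the all-ones vector), so the accepted jitter
    must leave the smallest eigenvalue clearly positive, not merely let a
    Cholesky squeak through.
    """
    scale = float(np.trace(K)) / len(K)
    eigmin = float(np.linalg.eigvalsh(K).min())
    for eps in _JITTER_STEPS:
        if eigmin + eps * scale > 1e-9 * scale:
            if eps > 0:
                logger.info("relatedness matrix jittered with %.1e * trace/n", eps)
            return K + eps * scale * np.eye(len(K)), eps
    raise DecompositionError(
        "relatedness matrix is not positive definite even after 1e-4*(trace/n) jitter")


def _design_matrix(phen: pd.DataFrame, fixed_effects) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(phen))]
    names: list[str] = []
    for name in fixed_effects:
        if name not in phen.columns:
            raise InvalidConfigError(f"fixed effect {name!r} absent from phenotype table")
        col = phen[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}{lev}")
    return np.column_stack(cols), names


def fit_animal_model(phenotypes: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Gibbs-sample the variance components of the animal model.

    ``phenotypes`` is a long table with columns ``id`` and ``value`` plus
    any fixed-effect covariates named in the spec (and ``year`` if the
    year random effect is on).  Every phenotyped individual must appear in
    the relatedness matrix.  Rows are canonically sorted internally, so
    row order does not affect results for a fixed seed.
    """
    spec.validate()
    K_mat = spec.relatedness
    sort_cols = [c for c in ("id", "year", "measurer", "value") if c in phenotypes.columns]
    phen = phenotypes.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    phen["id"] = phen["id"].map(str)
    y = phen["value"].to_numpy(dtype=float)
    n_obs = len(y)
    ind_ids = sorted(phen["id"].unique())
    missing = [i for i in ind_ids if i not in set(K_mat.labels)]
    if missing:
        raise CoverageError(f"phenotyped individuals absent from K: {missing[:5]}")
    K = K_mat.reorder(ind_ids).values
    n_ind = len(ind_ids)
    obs_ind = pd.Categorical(phen["id"], categories=ind_ids).codes.astype(int)
    n_per_ind = np.bincount(obs_ind, minlength=n_ind).astype(float)
    if (n_per_ind.max() if n_ind else 0) <= 1:
        warnings.warn(
            "no repeated measurements: permanent-environment and additive "
            "variance are separately non-identified (their sum is)", stacklevel=2)

    X, fixed_names = _design_matrix(phen, spec.fixed_effects)
    XtX = X.T @ X
    xtx_fac = cho_factor(XtX + 1e-10 * np.eye(X.shape[1]))

    if spec.include_year:
        if "year" not in phen.columns:
            raise InvalidConfigError("include_year=True needs a 'year' column")
        years = sorted(phen["year"].unique())
        obs_year = pd.Categorical(phen["year"], categories=years).codes.astype(int)
        n_per_year = np.bincount(obs_year, minlength=len(years)).astype(float)

    K_pd, jitter = _repair_to_pd(K)
    k_fac = cho_factor(K_pd, lower=True)
    Kinv = cho_solve(k_fac, np.eye(n_ind))
    Kinv = 0.5 * (Kinv + Kinv.T)

    var_y = float(np.var(y, ddof=1)) if n_obs > 1 else 1.0
    nu0 = float(spec.prior_df)
    s0 = float(spec.prior_scale) if spec.prior_scale is not None else var_y
    nu_s0 = nu0 * s0
    half_t = spec.prior == "half_t"
    nu_t = float(spec.half_t_df)
    A_scale = (float(spec.half_t_scale) if spec.half_t_scale is not None
               else float(np.sqrt(var_y)))
    A2 = A_scale * A_scale

    records = []
    for chain in range(spec.n_chains):
        rng = np.random.default_rng([int(spec.seed), 100 + chain])
        # parameter-expanded state: component variance = alpha^2 * vtilde;
        # under the conjugate prior alpha is pinned at 1
        vt_a = vt_pe = vt_year = 1.0 if half_t else max(var_y / 3.0, 1e-8)
        al_a = al_pe = al_year = np.sqrt(var_y / 3.0) if half_t else 1.0
        vare = max(var_y / 3.0, 1e-8)
        b = cho_solve(xtx_fac, X.T @ y)
        eta_a = np.zeros(n_ind)
        eta_p = np.zeros(n_ind)
        eta_y = np.zeros(len(years)) if spec.include_year else None
        for it in range(spec.n_iter):
            a = al_a * eta_a
            p = al_pe * eta_p
            year_part = al_year * eta_y[obs_year] if spec.include_year else 0.0
            varpe = al_pe * al_pe * vt_pe
            # fixed effects
            resid_loc = y - a[obs_ind] - p[obs_ind] - year_part
            b_mean = cho_solve(xtx_fac, X.T @ resid_loc)
            z = rng.standard_normal(X.shape[1])
            b = b_mean + np.sqrt(vare) * solve_triangular(xtx_fac[0], z, lower=xtx_fac[1])
            # additive block: eta_a with p marginalised, then alpha_a, then p
            r = y - X @ b - year_part
            s_ind = np.bincount(obs_ind, weights=r, minlength=n_ind)
            w = n_per_ind / (vare + n_per_ind * varpe)
            wbar = w * (s_ind / n_per_ind)       # w_i * mean residual of i
            P = Kinv / vt_a
            P[np.diag_indices_from(P)] += (al_a * al_a) * w
            p_fac = cho_factor(P, lower=False)
            eta_mean = cho_solve(p_fac, al_a * wbar)
            z = rng.standard_normal(n_ind)
            eta_a = eta_mean + solve_triangular(p_fac[0], z, lower=False)
            if half_t:
                prec_al = float(w @ (eta_a * eta_a)) + 1.0 / A2
                mean_al = float(wbar @ eta_a) / prec_al
                al_a = mean_al + rng.standard_normal() / np.sqrt(prec_al)
            a = al_a * eta_a
            # permanent environment: eta_p | a, then alpha_pe
            s2 = s_ind - n_per_ind * a
            prec = (al_pe * al_pe) * n_per_ind / vare + 1.0 / vt_pe
            eta_p = (al_pe * s2 / vare) / prec + rng.standard_normal(n_ind) / np.sqrt(prec)
            if half_t:
                prec_al = float(n_per_ind @ (eta_p * eta_p)) / vare + 1.0 / A2
                mean_al = float(s2 @ eta_p) / vare / prec_al
                al_pe = mean_al + rng.standard_normal() / np.sqrt(prec_al)
            p = al_pe * eta_p
            # year effects
            if spec.include_year:
                r3 = r - a[obs_ind] - p[obs_ind]
                s_year = np.bincount(obs_year, weights=r3, minlength=len(years))
                prec_y = (al_year * al_year) * n_per_year / vare + 1.0 / vt_year
                eta_y = (al_year * s_year / vare) / prec_y \
                    + rng.standard_normal(len(years)) / np.sqrt(prec_y)
                if half_t:
                    prec_al = float(n_per_year @ (eta_y * eta_y)) / vare + 1.0 / A2
                    mean_al = float(s_year @ eta_y) / vare / prec_al
                    al_year = mean_al + rng.standard_normal() / np.sqrt(prec_al)
                year_part = al_year * eta_y[obs_year]
            # scale variances
            if half_t:
                vt_a = (nu_t + eta_a @ (Kinv @ eta_a)) / rng.chisquare(nu_t + n_ind)
                vt_pe = (nu_t + eta_p @ eta_p) / rng.chisquare(nu_t + n_ind)
                if spec.include_year:
                    vt_year = (nu_t + eta_y @ eta_y) / rng.chisquare(nu_t + len(years))
            else:  # conjugate scaled-inverse-chi-square; alphas stay at 1
                vt_a = (nu_s0 + a @ (Kinv @ a)) / rng.chisquare(nu0 + n_ind)
                vt_pe = (nu_s0 + p @ p) / rng.chisquare(nu0 + n_ind)
                eta_a, eta_p = a, p
                if spec.include_year:
                    vt_year = (nu_s0 + eta_y @ eta_y) / rng.chisquare(nu0 + len(years))
            vara = al_a * al_a * vt_a
            varpe = al_pe * al_pe * vt_pe
            varyear = al_year * al_year * vt_year
            e = r - a[obs_ind] - p[obs_ind] \
                - (year_part if spec.include_year else 0.0)
            vare = (nu_s0 + e @ e) / rng.chisquare(nu0 + n_obs)
            if it < spec.n_burnin or (it - spec.n_burnin) % spec.thin:
                continue
            total = vara + varpe + vare + (varyear if spec.include_year else 0.0)
            rec = {"chain": chain, "draw": it, "mu": b[0]}
            rec.update(dict(zip(fixed_names, b[1:])))
            rec.update(Va=vara, Vpe=varpe, Vres=vare, h2=vara / total)
            if spec.include_year:
                rec["Vyear"] = varyear
            records.append(rec)
    draws = pd.DataFrame.from_records(records)
    return PosteriorDraws(
        draws=draws, fixed_names=fixed_names, n_obs=n_obs, n_individuals=n_ind,
        meta={"jitter": jitter, "sample_phenotypic_variance": var_y,
              "prior": spec.prior, "prior_df": nu0, "prior_scale": s0,
              "half_t_df": nu_t, "half_t_scale": A_scale,
              "include_year": spec.include_year, "n_chains": spec.n_chains},
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _summary(name: str, values: np.ndarray, rhat: float | None = None,
             **extras) -> PosteriorSummary:
    lower, upper = np.percentile(values, [2.5, 97.5])
    return PosteriorSummary(quantity=name, mean=float(np.mean(values)),
                            lower=float(lower), upper=float(upper),
                            rhat=rhat, extras=extras)


def summarize_heritability(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean and equal-tailed 95% CrI of the per-draw h2 ratio.

    The denominator contains every variance component present in the fit
    (fixed-effect variance excluded).  The alternative ratio-of-means
    estimate is reported in ``extras`` for transparency.
    """
    if draws.draws.empty:
        raise ValueError("no posterior draws")
    comps = draws.draws[draws.variance_components]
    h2 = draws.draws["h2"].to_numpy()
    ratio_of_means = float(comps["Va"].mean() / comps.sum(axis=1).mean())
    return _summary("h2", h2, ratio_of_means=ratio_of_means)


def genetic_coefficient(draws: PosteriorDraws, trait_mean: float) -> PosteriorSummary:
    """Evolvability-style summary: per-draw Va divided by the trait mean.

    ``trait_mean`` must be on the same measurement scale as the variance
    components (a trait recorded in 0.1 mm units needs its mean in 0.1 mm).
    """
    if not trait_mean > 0:
        raise InvalidConfigError("trait mean must be positive")
    values = draws.draws["Va"].to_numpy() / float(trait_mean)
    return _summary("genetic_coefficient", values)


def gelman_rubin_rhat(chains) -> float | dict:
    """Split potential scale reduction factor.

    ``chains`` may be a 2-D array (n_chains, n_draws) for one parameter, or
    a :class:`PosteriorDraws`, in which case a dict of per-parameter values
    is returned.  Each chain is split in half; Rhat is
    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B the between-chain variance of the split-chain means.
    """
    if isinstance(chains, PosteriorDraws):
        params = ["mu", *chains.fixed_names, *chains.variance_components, "h2"]
        return {p: gelman_rubin_rhat(chains.by_chain(p)) for p in params}
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientChainsError("need >= 2 chains of equal length")
    m, n = arr.shape
    if n < 4:
        raise InsufficientChainsError("need >= 4 draws per chain for split Rhat")
    half = n // 2
    split = np.vstack([arr[:, :half], arr[:, half:2 * half]])
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def summarize_model(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, 95% CrI and split-Rhat for every model parameter."""
    params = ["mu", *draws.fixed_names, *draws.variance_components, "h2"]
    multi = draws.n_chains >= 2
    rows = []
    for par in params:
        values = draws.draws[par].to_numpy()
        rhat = gelman_rubin_rhat(draws.by_chain(par)) if multi else float("nan")
        s = _summary(par, values, rhat=rhat)
        rows.append(dict(parameter=par, mean=s.mean, lower=s.lower,
                         upper=s.upper, rhat=rhat))
    return pd.DataFrame(rows)
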