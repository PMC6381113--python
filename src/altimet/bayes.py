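"""Robust Bayesian hierarchical regression of feature abundance on altitude.

For one feature, each subject's repeated measurements follow a straight
line in standardized altitude with t-distributed residuals::

    y_si ~ t(nu) * sigma + beta0_s + beta1_s * x_si
    beta0_s ~ Normal(mu0, sigma0)      beta1_s ~ Normal(mu1, sigma1)

The residual scale sigma and normality parameter nu are shared across
subjects (estimated once per feature).  Priors are non-informative:
Normal(M=0, S=10) on the group means, Uniform(L=1e-3, H=1e3) on all
scale parameters, and a shifted exponential (minimum 1, mean 30) on nu.
The group-level slope mu1 is the quantity of interest: a feature is a
"changer" when the 95% highest-density interval of its mu1 posterior
excludes zero.

Sampling is Metropolis-within-Gibbs with the t residual expressed as a
normal scale mixture: the latent per-observation weights and all
location parameters have conjugate conditional updates, while the scale
parameters (on log scale) and nu (on log(nu-1)) take adaptive
random-walk Metropolis steps whose proposal scales are tuned during
burn-in only.  Two extra moves speed up mixing without changing the
target: an ancillarity (ASIS) rescaling of each group SD that moves the
subject lines together with their scale, and a joint update of
(sigma, nu) with the latent weights integrated out (valid because the
weights are redrawn from their full conditional before next use).  All
chains are advanced simultaneously (vectorized over a leading chain
axis).
"""
from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "TransformRecord",
    "PosteriorSummary",
    "ztransform",
    "sample_priors",
    "fit_robust_hier",
    "fit_feature",
    "hdi",
    "back_transform_slope",
    "decide_changers",
]


@dataclass(frozen=True)
class PriorSpec:
    """Non-informative priors for the hierarchical model."""

    mu_location: float = 0.0   # M
    mu_scale: float = 10.0     # S
    sigma_low: float = 1e-3    # L
    sigma_high: float = 1e3    # H
    nu_min: float = 1.0
    nu_mean: float = 30.0

    def __post_init__(self) -> None:
        if not (self.sigma_low < self.sigma_high and self.mu_scale > 0
                and self.nu_mean > self.nu_min):
            raise ValueError("invalid prior specification")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout.  Proposal adaptation runs during burn-in only."""

    n_chains: int = 3
    n_draws: int = 10_000
    n_burn: int = 2_000
    thin: int = 1
    adapt_interval: int = 50
    mh_substeps: int = 3   # Metropolis refreshes per sweep for scales and nu
    rhat_threshold: float = 1.1
    hdi_mass: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class TransformRecord:
    """Means/SDs used for z-transformation, for exact back-transformation."""

    y_mean: float
    y_sd: float
    x_mean: float
    x_sd: float


def ztransform(y: np.ndarray, x: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, TransformRecord]:
    """Standardize both response and altitude to mean 0, SD 1 (ddof=1).

    Reduces the posterior correlation between slopes and intercepts; the
    returned record makes the transformation exactly reversible.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ysd, xsd = y.std(ddof=1), x.std(ddof=1)
    if ysd == 0 or xsd == 0:
        raise ValueError("zero-variance input cannot be z-transformed")
    rec = TransformRecord(float(y.mean()), float(ysd), float(x.mean()), float(xsd))
    return (y - rec.y_mean) / rec.y_sd, (x - rec.x_mean) / rec.x_sd, rec


def sample_priors(spec: PriorSpec = PriorSpec(), n_draws: int = 1000,
                  seed: int = 0) -> dict[str, np.ndarray]:
    """Draw from the three prior families (for prior predictive checks)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    return {
        "mu": rng.normal(spec.mu_location, spec.mu_scale, size=n_draws),
        "sigma": rng.uniform(spec.sigma_low, spec.sigma_high, size=n_draws),
        "nu": spec.nu_min + rng.exponential(spec.nu_mean - spec.nu_min,
                                            size=n_draws),
    }


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n < 100:
        raise ValueError("HDI needs at least 100 draws")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = draws[k - 1:] - draws[: n - k + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k - 1])


def back_transform_slope(mu1_draws: np.ndarray, record: TransformRecord
                         ) -> np.ndarray:
    """Convert z-scale slope draws to original units (AU per km)."""
    return np.asarray(mu1_draws, dtype=float) * record.y_sd / record.x_sd


@dataclass
class PosteriorSummary:
    """Posterior draws, HDI decision and diagnostics for one feature."""

    feature: str
    draws: dict[str, np.ndarray]            # param -> (chains, kept draws)
    hdi_low: float
    hdi_high: float
    changer: bool
    direction: str                          # "Increasing" / "Decreasing"
    mu1_median: float
    slope_au_per_km: float                  # posterior median, original units
    slope_hdi_au: tuple[float, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    n_subjects: int
    transform: TransformRecord
    subject_slope_means: pd.Series          # posterior mean beta1_s (z scale)
    subject_slope_ols: pd.Series            # per-subject OLS slopes (z scale)

    def flat(self, param: str) -> np.ndarray:
        return self.draws[param].ravel()


def _subject_ols_slopes(ys, xs, starts) -> np.ndarray:
    n = np.diff(np.append(starts, ys.size))
    sx = np.add.reduceat(xs, starts)
    sy = np.add.reduceat(ys, starts)
    sxx = np.add.reduceat(xs * xs, starts)
    sxy = np.add.reduceat(xs * ys, starts)
    denom = sxx - sx * sx / n
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (sxy - sx * sy / n) / denom, 0.0)


def fit_robust_hier(y: np.ndarray, x: np.ndarray, subjects: np.ndarray,
                    priors: PriorSpec = PriorSpec(),
                    mcmc: MCMCConfig = MCMCConfig(),
                    feature: str = "feature") -> PosteriorSummary:
    """Fit the robust hierarchical model to one feature by MCMC.

    ``y`` are raw abundances, ``x`` raw altitudes (km) and ``subjects``
    the per-observation subject labels; both variables are z-transformed
    internally and the record kept for back-transformation.  Individual
    and group regressions are estimated simultaneously, so each
    subject's line is shrunk toward the group line.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    subjects = np.asarray(subjects)
    uniq, counts = np.unique(subjects, return_counts=True)
    if uniq.size < 3 or np.sort(counts)[-3] < 2:
        raise ValueError("need at least 3 subjects with >= 2 observations each")

    yz, xz, rec = ztransform(y, x)
    # sort observations by subject so per-subject sums are reduceat segments
    codes = pd.Categorical(subjects, categories=uniq).codes
    order = np.argsort(codes, kind="stable")
    ys, xs, cs = yz[order], xz[order], codes[order]
    starts = np.searchsorted(cs, np.arange(uniq.size))
    S, N, C = uniq.size, ys.size, mcmc.n_chains

    rng = np.random.default_rng(mcmc.seed)
    L, H = priors.sigma_low, priors.sigma_high
    logL, logH = np.log(L), np.log(H)
    M, Sp = priors.mu_location, priors.mu_scale
    nu_rate = 1.0 / (priors.nu_mean - priors.nu_min)

    ols = _subject_ols_slopes(ys, xs, starts)
    n_per = np.diff(np.append(starts, N)).astype(float)
    b0 = np.tile(np.add.reduceat(ys, starts) / n_per, (C, 1))
    b1 = np.tile(ols, (C, 1)) + rng.normal(0, 0.05, size=(C, S))
    mu0 = b0.mean(axis=1)
    mu1 = b1.mean(axis=1)
    log_s0 = np.log(np.clip(b0.std(axis=1), 10 * L, None))
    log_s1 = np.log(np.clip(b1.std(axis=1), 10 * L, None))
    log_sig = np.full(C, np.log(0.5))
    log_nu1 = np.full(C, np.log(9.0))  # nu = 10 initially

    # adaptive random-walk scales for (sigma0, sigma1, sigma, nu)
    step = {k: np.full(C, 0.3) for k in ("s0", "s1", "sig", "nu")}
    acc = {k: np.zeros(C) for k in step}

    n_kept = mcmc.n_draws // mcmc.thin
    keep = {k: np.empty((C, n_kept)) for k in
            ("mu0", "mu1", "sigma0", "sigma1", "sigma", "nu")}
    b1_sum = np.zeros((C, S))
    b0_sum = np.zeros((C, S))

    r = ys[None, :] - b0[:, cs] - b1[:, cs] * xs[None, :]
    kept = 0
    total = mcmc.n_burn + mcmc.n_draws
    for it in range(total):
        in_burn = it < mcmc.n_burn
        sigma = np.exp(log_sig)
        nu = 1.0 + np.exp(log_nu1)

        # --- latent t-mixture weights (conjugate gamma) ---
        shape = (nu[:, None] + 1.0) / 2.0
        rate = (nu[:, None] + (r / sigma[:, None]) ** 2) / 2.0
        w = rng.gamma(np.broadcast_to(shape, (C, N)), 1.0 / rate)

        # --- per-subject lines (conjugate bivariate normal) ---
        inv_s2 = 1.0 / sigma**2
        wx = w * xs[None, :]
        Sw = np.add.reduceat(w, starts, axis=1)
        Swx = np.add.reduceat(wx, starts, axis=1)
        Swxx = np.add.reduceat(wx * xs[None, :], starts, axis=1)
        Swy = np.add.reduceat(w * ys[None, :], starts, axis=1)
        Swxy = np.add.reduceat(wx * ys[None, :], starts, axis=1)
        s0_2 = np.exp(2 * log_s0)[:, None]
        s1_2 = np.exp(2 * log_s1)[:, None]
        P00 = Sw * inv_s2[:, None] + 1.0 / s0_2
        P01 = Swx * inv_s2[:, None]
        P11 = Swxx * inv_s2[:, None] + 1.0 / s1_2
        rhs0 = Swy * inv_s2[:, None] + mu0[:, None] / s0_2
        rhs1 = Swxy * inv_s2[:, None] + mu1[:, None] / s1_2
        det = P00 * P11 - P01 * P01
        m0 = (P11 * rhs0 - P01 * rhs1) / det
        m1 = (P00 * rhs1 - P01 * rhs0) / det
        c00 = P11 / det
        c01 = -P01 / det
        c11 = P00 / det
        l00 = np.sqrt(c00)
        l10 = c01 / l00
        l11 = np.sqrt(np.clip(c11 - l10 * l10, 1e-300, None))
        z0 = rng.standard_normal((C, S))
        z1 = rng.standard_normal((C, S))
        b0 = m0 + l00 * z0
        b1 = m1 + l10 * z0 + l11 * z1

        # --- group means (conjugate normal) ---
        prec0 = S / s0_2[:, 0] + 1.0 / Sp**2
        mean0 = (b0.sum(axis=1) / s0_2[:, 0] + M / Sp**2) / prec0
        mu0 = mean0 + rng.standard_normal(C) / np.sqrt(prec0)
        prec1 = S / s1_2[:, 0] + 1.0 / Sp**2
        mean1 = (b1.sum(axis=1) / s1_2[:, 0] + M / Sp**2) / prec1
        mu1 = mean1 + rng.standard_normal(C) / np.sqrt(prec1)

        # --- group SDs (random-walk Metropolis on log scale) ---
        ss0 = ((b0 - mu0[:, None]) ** 2).sum(axis=1)
        ss1 = ((b1 - mu1[:, None]) ** 2).sum(axis=1)
        r = ys[None, :] - b0[:, cs] - b1[:, cs] * xs[None, :]

        for _ in range(mcmc.mh_substeps):
            # conditional update given the subject lines:
            # log posterior -(S - 1) log sigma - ss/(2 sigma^2) inside (L,H)
            for key, cur, ss in (("s0", log_s0, ss0), ("s1", log_s1, ss1)):
                prop = cur + step[key] * rng.standard_normal(C)
                ok = (prop > logL) & (prop < logH)
                lp_cur = -(S - 1) * cur - ss / (2 * np.exp(2 * cur))
                lp_prop = np.where(ok, -(S - 1) * prop
                                   - ss / (2 * np.exp(2 * prop)), -np.inf)
                accept = np.log(rng.random(C)) < lp_prop - lp_cur
                cur[accept] = prop[accept]
                acc[key] += accept

        # --- ancillarity rescaling of the group SDs (ASIS): rewrite the
        #     subject lines as b = mu + sigma_g * eta with eta held fixed
        #     and update sigma_g against the data likelihood, which breaks
        #     the funnel-shaped coupling between sigma_g and the b's ---
        sigma2 = np.exp(2 * log_sig)
        for key, lcur, mu_g, bmat, mult in (("s1", log_s1, mu1, b1, xs),
                                            ("s0", log_s0, mu0, b0, None)):
            eta = (bmat - mu_g[:, None]) / np.exp(lcur)[:, None]
            prop = lcur + step[key] * rng.standard_normal(C)
            ok = (prop > logL) & (prop < logH)
            bprop = mu_g[:, None] + np.exp(prop)[:, None] * eta
            shift = (bprop - bmat)[:, cs]
            if mult is not None:
                shift = shift * mult[None, :]
            r_prop = r - shift
            lp_cur_a = -(w * r * r).sum(axis=1) / (2 * sigma2) + lcur
            lp_prop_a = np.where(
                ok, -(w * r_prop * r_prop).sum(axis=1) / (2 * sigma2) + prop,
                -np.inf)
            accept = np.log(rng.random(C)) < lp_prop_a - lp_cur_a
            lcur[accept] = prop[accept]
            bmat[accept] = bprop[accept]
            r[accept] = r_prop[accept]

        # --- residual scale and normality parameter, latent weights
        #     integrated out (partially collapsed: w is redrawn from its
        #     full conditional at the top of the next sweep) ---
        r2 = r * r  # r reflects any accepted rescaling moves

        def _marginal_logpost(lsig: np.ndarray, lnu1: np.ndarray) -> np.ndarray:
            nu_ = 1.0 + np.exp(lnu1)
            inside = (lsig > logL) & (lsig < logH)
            sig2 = np.exp(2 * lsig)
            ll = N * (gammaln((nu_ + 1) / 2) - gammaln(nu_ / 2)
                      - 0.5 * np.log(np.pi * nu_) - lsig) \
                - (nu_ + 1) / 2 * np.log1p(r2 / (nu_[:, None] * sig2[:, None])
                                           ).sum(axis=1)
            # uniform prior on sigma (+ Jacobian), shifted-exp prior on nu
            return np.where(inside,
                            ll + lsig - nu_rate * (nu_ - 1.0) + lnu1, -np.inf)

        lp_cur = _marginal_logpost(log_sig, log_nu1)
        for _ in range(mcmc.mh_substeps):
            p_sig = log_sig + step["sig"] * rng.standard_normal(C)
            p_nu = log_nu1 + step["nu"] * rng.standard_normal(C)
            lp_prop = _marginal_logpost(p_sig, p_nu)
            accept = np.log(rng.random(C)) < lp_prop - lp_cur
            log_sig[accept] = p_sig[accept]
            log_nu1[accept] = p_nu[accept]
            lp_cur = np.where(accept, lp_prop, lp_cur)
            acc["sig"] += accept
            acc["nu"] += accept

        if in_burn and (it + 1) % mcmc.adapt_interval == 0:
            for key in step:
                rate_ = acc[key] / (mcmc.adapt_interval * mcmc.mh_substeps)
                step[key] *= np.exp(np.clip(rate_ - 0.44, -0.5, 0.5))
                step[key] = np.clip(step[key], 1e-3, 5.0)
                acc[key][:] = 0.0

        if not in_burn:
            j = it - mcmc.n_burn
            if j % mcmc.thin == 0 and kept < n_kept:
                keep["mu0"][:, kept] = mu0
                keep["mu1"][:, kept] = mu1
                keep["sigma0"][:, kept] = np.exp(log_s0)
                keep["sigma1"][:, kept] = np.exp(log_s1)
                keep["sigma"][:, kept] = np.exp(log_sig)
                keep["nu"][:, kept] = 1.0 + np.exp(log_nu1)
                kept += 1
            b0_sum += b0
            b1_sum += b1

    ds = az.convert_to_dataset({k: v for k, v in keep.items()})
    rhat_ds, ess_ds = az.rhat(ds), az.ess(ds)
    rhat = {k: float(rhat_ds[k].values) for k in keep}
    ess = {k: float(ess_ds[k].values) for k in keep}
    converged = all(np.isfinite(v) and v <= mcmc.rhat_threshold
                    for v in rhat.values())

    mu1_flat = keep["mu1"].ravel()
    lo, hi = hdi(mu1_flat, mcmc.hdi_mass)
    med = float(np.median(mu1_flat))
    slope_draws = back_transform_slope(mu1_flat, rec)
    slope_lo, slope_hi = hdi(slope_draws, mcmc.hdi_mass)
    return PosteriorSummary(
        feature=feature,
        draws=keep,
        hdi_low=lo,
        hdi_high=hi,
        changer=not (lo <= 0.0 <= hi),
        direction="Increasing" if med > 0 else "Decreasing",
        mu1_median=med,
        slope_au_per_km=float(np.median(slope_draws)),
        slope_hdi_au=(slope_lo, slope_hi),
        rhat=rhat,
        ess=ess,
        converged=converged,
        n_subjects=S,
        transform=rec,
        subject_slope_means=pd.Series(b1_sum.sum(axis=0) / (C * mcmc.n_draws),
                                      index=uniq),
        subject_slope_ols=pd.Series(ols, index=uniq),
    )


def fit_feature(data, feature: str, priors: PriorSpec = PriorSpec(),
                mcmc: MCMCConfig = MCMCConfig()) -> PosteriorSummary:
    """Convenience wrapper: fit one feature of a :class:`LongitudinalDataset`."""
    y, x, subj = data.feature_arrays(feature)
    return fit_robust_hier(y, x, subj, priors, mcmc, feature=feature)


def decide_changers(summaries: list[PosteriorSummary]) -> pd.DataFrame:
    """Assemble the per-feature changer decision table.

    A converged feature is a changer iff zero lies outside the 95% HDI of
    mu1; the direction is the sign of the posterior median.  Decisions
    for unconverged features are withheld (``changer`` is NA) and
    reported via the ``converged`` column.
    """
    rows = []
    for s in summaries:
        rows.append({
            "feature": s.feature,
            "mu1_median": s.mu1_median,
            "hdi_low": s.hdi_low,
            "hdi_high": s.hdi_high,
            "changer": bool(s.changer) if s.converged else pd.NA,
            "direction": s.direction if s.converged else pd.NA,
            "slope_au_per_km": s.slope_au_per_km,
            "converged": s.converged,
        })
    return pd.DataFrame(rows)
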