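"""Dose-response (causal) test with marginalization over direct effects.

Each trans-QTL of a gene is a genetic instrument j with an effect x_j on the
gene's expression and an effect y_j (SE s_yj) on disease.  Under a causal
effect theta with no pleiotropy, y_j ~ N(theta * x_j, s_yj^2).  Direct
(pleiotropic) instrument effects alpha_j on disease are modelled with a
spike-and-slab mixture: with probability pi the instrument carries a direct
effect of scale tau, inflating its outcome variance to s_yj^2 + tau^2.  The
likelihood of theta marginalizes over (pi, tau) on a grid with a uniform
prior on pi and half-normal weights on tau:

    L(theta) = sum_{pi,tau} prior(pi,tau) *
               prod_j [ (1-pi) N(y_j; theta x_j, s_yj^2)
                        + pi N(y_j; theta x_j, s_yj^2 + tau^2) ].

The maximum-likelihood theta is read off a grid of the profile curve and the
P-value comes from the chi-square(1) approximation to the likelihood ratio
against theta = 0.  The exposure-side error s_xj is recorded but not
propagated (fixed-x approximation, standard in two-sample MR with a large
QTL study); a warning is logged when it is non-negligible.

The analysis is restricted to genes with at least ``mr_min_instruments``
trans-QTLs (default 10), because the power of the dose-response test depends
critically on the number of instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .association import ScoreTestResult, score_test
from .gate_scores import locus_score
from .io_formats import CohortData, PipelineConfig
from .qtl_loci import QtlLocus

logger = logging.getLogger("gatescores")


@dataclass
class InstrumentSet:
    """Per-trans-QTL exposure and outcome effects for one gene."""

    gene_id: str
    x: np.ndarray     # effect on exposure (expression), per SD of locus score
    s_x: np.ndarray   # exposure SE (recorded, not used in the likelihood)
    y: np.ndarray     # one-step log OR of the locus score on disease, per SD
    s_y: np.ndarray   # its SE

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.s_x = np.asarray(self.s_x, float)
        self.y = np.asarray(self.y, float)
        self.s_y = np.asarray(self.s_y, float)
        if not (len(self.x) == len(self.y) == len(self.s_y) == len(self.s_x)):
            raise ValueError("instrument arrays must have equal length")
        if np.any(self.s_y <= 0):
            raise ValueError("all outcome SEs must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.x)


@dataclass
class MrModelConfig:
    """Grids and priors for the marginal-likelihood causal-effect model."""

    n_theta: int = 401
    theta_span: float = 5.0   # grid half-width in units of ratio-estimate spread
    pi_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 1.0, 0.1))
    n_tau: int = 8
    tau_min: float = 0.01     # smallest direct-effect scale on the grid
    tau_max_sd_mult: float = 2.0  # largest scale as a multiple of SD(y)

    def __post_init__(self) -> None:
        self.pi_grid = np.asarray(self.pi_grid, float)
        if self.n_theta < 3 or self.n_tau < 1 or self.pi_grid.size == 0:
            raise ValueError("grids must be nonempty")
        if self.tau_min <= 0:
            raise ValueError("tau grid must be positive")


@dataclass
class MrResult:
    """Marginal-likelihood inference on the causal effect of one gene."""

    gene_id: str
    theta_mle: float | None
    theta_grid: np.ndarray
    loglik_curve: np.ndarray
    lr_stat: float | None
    pval: float | None
    n_instruments: int
    testable: bool = True


def build_instruments(gene_id: str,
                      loci: list[QtlLocus],
                      locus_tests: list[ScoreTestResult],
                      cohort: CohortData,
                      config: PipelineConfig) -> InstrumentSet | None:
    """Assemble the instrument set of a gene from its trans loci.

    x_j is the locus effect on expression per SD of the locus score
    (Cov(score, expression implied by the summary betas) / SD(score)), which
    is invariant to rescaling of the raw weight vector.  y_j is the one-step
    log OR of the locus score on disease per SD of the score, with SE
    SD / sqrt(V).  Genes with fewer than ``mr_min_instruments`` trans loci
    are skipped with a logged reason.
    """
    trans = [(l, t) for l, t in zip(loci, locus_tests)
             if l.locus_class == "trans" and t.testable]
    if len(trans) < config.mr_min_instruments:
        logger.info("gene %s skipped for MR: %d trans-QTLs (< %d required)",
                    gene_id, len(trans), config.mr_min_instruments)
        return None
    xs, sxs, ys, sys_ = [], [], [], []
    for locus, test in trans:
        ls = locus_score(cohort, locus)
        sd = ls.sd
        if sd <= 0:
            continue
        x = ls.expression_covariance / sd
        # crude exposure SE from the per-SNP summary SEs (ignoring LD)
        s_x = float(np.sqrt(np.sum(
            (ls.used_weights * ls.dose_variances * ls.used_ses) ** 2))) / sd
        xs.append(x)
        sxs.append(s_x)
        ys.append(test.beta_std)
        sys_.append(test.score_sd / np.sqrt(test.V))
    instr = InstrumentSet(gene_id=gene_id, x=np.array(xs), s_x=np.array(sxs),
                          y=np.array(ys), s_y=np.array(sys_))
    rel = np.max(np.abs(instr.s_x) / np.maximum(np.abs(instr.x), 1e-12))
    if rel > 0.2:
        logger.warning("gene %s: exposure-side SE up to %.0f%% of the effect; "
                       "fixed-x approximation may be optimistic", gene_id, 100 * rel)
    return instr


def ivw_estimate(instr: InstrumentSet) -> tuple[float, float]:
    """Closed-form inverse-variance-weighted ratio estimate and its SE."""
    w = instr.x ** 2 / instr.s_y ** 2
    denom = w.sum()
    if denom <= 0:
        raise ValueError("IVW estimate undefined: all instruments have zero effect")
    theta = float((instr.x * instr.y / instr.s_y ** 2).sum() / denom)
    return theta, float(1.0 / np.sqrt(denom))


def _log_marginal(theta: np.ndarray, instr: InstrumentSet,
                  pi_grid: np.ndarray, tau_grid: np.ndarray,
                  log_prior: np.ndarray) -> np.ndarray:
    """log L(theta) for each theta, marginalized over the (pi, tau) grid.

    ``log_prior`` has shape (n_pi, n_tau) and sums to 1 in probability.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    resid = instr.y[None, :] - theta[:, None] * instr.x[None, :]   # (T, J)
    log_spike = stats.norm.logpdf(resid, scale=instr.s_y[None, :])  # (T, J)
    sd_slab = np.sqrt(instr.s_y[None, None, :] ** 2 + tau_grid[:, None, None] ** 2)
    log_slab = stats.norm.logpdf(resid[None, :, :], scale=sd_slab)  # (K, T, J)

    out = np.empty((len(pi_grid), len(tau_grid), len(theta)))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_grid)
        log_1mpi = np.log1p(-pi_grid)
    for i, pi in enumerate(pi_grid):
        if pi == 0.0:
            per_j = log_spike[None, :, :]          # slab weight zero
        else:
            per_j = np.logaddexp(log_1mpi[i] + log_spike[None, :, :],
                                 log_pi[i] + log_slab)
        out[i] = per_j.sum(axis=2)                 # (K, T)
    return logsumexp(out + log_prior[:, :, None], axis=(0, 1))


def marginal_likelihood(instr: InstrumentSet,
                        cfg: MrModelConfig | None = None) -> MrResult:
    """Profile the marginal likelihood of the causal effect over a theta grid.

    Returns the grid MLE (parabolically refined), the likelihood-ratio
    statistic against theta = 0 and its chi-square(1) P-value.  An instrument
    set whose exposure effects are all (numerically) zero is untestable.
    """
    cfg = cfg or MrModelConfig()
    x_scale = float(np.max(np.abs(instr.x)))
    if not np.isfinite(x_scale) or x_scale < 1e-10:
        logger.info("gene %s untestable by MR: exposure effects all ~0", instr.gene_id)
        return MrResult(instr.gene_id, None, np.empty(0), np.empty(0),
                        None, None, instr.n_instruments, testable=False)

    # theta grid centered on the IVW estimate, spanning theta_span x the
    # ratio-estimate spread, always covering 0
    ivw, ivw_se = ivw_estimate(instr)
    nz = np.abs(instr.x) > 1e-8 * x_scale
    ratios = instr.y[nz] / instr.x[nz]
    spread = max(float(np.std(ratios)) if nz.sum() > 1 else 0.0, ivw_se, 1e-6)
    half = max(cfg.theta_span * spread, 1.2 * abs(ivw))
    grid = np.linspace(ivw - half, ivw + half, cfg.n_theta)

    sd_y = float(np.std(instr.y, ddof=1)) if instr.n_instruments > 1 else abs(instr.y[0])
    tau_hi = max(cfg.tau_max_sd_mult * sd_y, 2 * cfg.tau_min)
    tau_grid = np.geomspace(cfg.tau_min, tau_hi, cfg.n_tau)
    # uniform prior over pi values, half-normal weights over tau values
    half_normal = np.exp(-0.5 * (tau_grid / sd_y) ** 2) if sd_y > 0 else np.ones_like(tau_grid)
    tau_w = half_normal / half_normal.sum()
    log_prior = (np.log(tau_w)[None, :] - np.log(len(cfg.pi_grid))) * np.ones((len(cfg.pi_grid), 1))

    ll = _log_marginal(grid, instr, cfg.pi_grid, tau_grid, log_prior)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite marginal likelihood")
    i = int(np.argmax(ll))
    theta_hat = grid[i]
    # parabolic refinement through the three points around the grid maximum
    if 0 < i < len(grid) - 1:
        y0, y1, y2 = ll[i - 1], ll[i], ll[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            theta_hat = grid[i] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0])
    ll_hat = float(_log_marginal(np.array([theta_hat]), instr,
                                 cfg.pi_grid, tau_grid, log_prior)[0])
    ll_null = float(_log_marginal(np.array([0.0]), instr,
                                  cfg.pi_grid, tau_grid, log_prior)[0])
    lr = max(2.0 * (ll_hat - ll_null), 0.0)
    pval = float(stats.chi2.sf(lr, df=1))
    return MrResult(gene_id=instr.gene_id, theta_mle=float(theta_hat),
                    theta_grid=grid, loglik_curve=ll, lr_stat=lr, pval=pval,
                    n_instruments=instr.n_instruments)
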