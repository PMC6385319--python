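"""Log-normal mixture decomposition of speed distributions.

Direction-resolved speed histograms of axonal endosome movement are well
described by a small number of log-normal components (a slow, oscillatory
population and one or more fast, processive populations).  This module fits
such mixtures to binned speed data by Poisson-weighted least squares and
selects the number of components with an approximate Bayesian model
evidence (Occam-razor) criterion, then summarises each component by its
median-scale parameter ``mu``, shape ``sigma``, event-fraction weight and
mean speed ``<v> = mu * exp(sigma**2 / 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "lognormal_mean",
    "LogNormalComponent",
    "MixtureFit",
    "LogNormalMixture",
    "fit_mixture",
    "IntensityBinProfile",
    "intensity_binned_analysis",
]

DEFAULT_FIT_RANGE = (0.07, 10.0)

# broad uniform prior widths (in the internal log-parameter space) used by
# the Laplace evidence; they set the Occam penalty per extra component
_SIGMA_BOUNDS = (0.02, 2.5)
_LOG_AMP_SPAN = 25.0


def lognormal_mean(mu: float, sigma: float) -> float:
    """Mean of a log-normal speed component, ``mu * exp(sigma**2 / 2)``.

    Parameters
    ----------
    mu : float
        Median-scale parameter of the component (same units as the speeds,
        here µm/s).  Must be positive.
    sigma : float
        Dimensionless shape parameter (standard deviation of ``ln v``).
        Must be non-negative.

    Returns
    -------
    float
        The component mean speed ``<v>``.
    """
    if not np.isfinite(mu) or mu <= 0:
        raise ValueError(f"mu must be positive and finite, got {mu!r}")
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError(f"sigma must be non-negative and finite, got {sigma!r}")
    return float(mu * math.exp(0.5 * sigma**2))


@dataclass
class LogNormalComponent:
    """One log-normal component of a speed mixture."""

    mu: float
    sigma: float
    weight: float
    mean_speed: float
    mu_se: float = float("nan")
    sigma_se: float = float("nan")
    weight_se: float = float("nan")


@dataclass
class MixtureFit:
    """Result of a mixture decomposition of a binned speed histogram."""

    components: list[LogNormalComponent]
    k: int
    fit_range: tuple[float, float]
    log_evidence: float
    goodness: float
    n_events: int
    log_evidences: dict[int, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


def _lognorm_bin_mass(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Probability mass of LogNormal(ln mu, sigma) in each histogram bin."""
    z = (np.log(edges) - math.log(mu)) / sigma
    cdf = special.ndtr(z)
    return np.diff(cdf)


class LogNormalMixture(BaseEstimator):
    """Log-normal mixture fit to a binned speed histogram.

    The speed samples are histogrammed on log-spaced bins inside
    ``fit_range`` and the bin counts are fit, for each candidate number of
    components ``k = 1..k_max``, by a sum of log-normal bin masses with free
    per-component amplitudes, using Poisson-weighted least squares.  The
    returned ``k`` maximises an approximate log model evidence: by default
    the Bayesian information criterion over the total event count (an
    Occam-razor penalised likelihood); a Laplace approximation around the
    optimum with broad uniform priors is also available.  Component
    weights are the fractions of movement events attributed to each
    component, renormalised over the fitted components.

    Parameters
    ----------
    k_max : int
        Largest number of components considered.
    fit_range : (float, float)
        Speeds outside this interval (µm/s) are excluded from the fit.
    n_bins : int
        Number of log-spaced histogram bins across ``fit_range``.
    criterion : {"laplace", "bic"}
        Model-selection criterion.
    n_restarts : int
        Extra random restarts of the optimiser per ``k``.
    random_state : int or None
        Seed for the restart jitter.

    Attributes
    ----------
    k_ : int
        Selected number of components.
    mu_, sigma_, weights_, mean_speeds_ : ndarray of shape (k_,)
        Component parameters sorted by increasing mean speed.
    log_evidence_ : float
        Approximate log evidence of the selected model.
    result_ : MixtureFit
        Full structured result.
    """

    def __init__(
        self,
        k_max: int = 3,
        fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
        n_bins: int = 40,
        criterion: str = "bic",
        n_restarts: int = 2,
        random_state: int | None = 0,
    ):
        self.k_max = k_max
        self.fit_range = fit_range
        self.n_bins = n_bins
        self.criterion = criterion
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _pack(self, log_a, log_mu, log_sigma):
        return np.concatenate([log_a, log_mu, log_sigma])

    def _unpack(self, theta, k):
        return theta[:k], theta[k : 2 * k], theta[2 * k :]

    def _model_counts(self, theta, k, edges):
        log_a, log_mu, log_sigma = self._unpack(theta, k)
        m = np.zeros(len(edges) - 1)
        for j in range(k):
            m += np.exp(log_a[j]) * _lognorm_bin_mass(
                edges, math.exp(log_mu[j]), math.exp(log_sigma[j])
            )
        return m

    def _residuals(self, theta, k, edges, counts):
        m = self._model_counts(theta, k, edges)
        return (counts - m) / np.sqrt(m + 1.0)

    def _poisson_loglik(self, m, counts):
        m = np.clip(m, 1e-12, None)
        return float(np.sum(counts * np.log(m) - m - special.gammaln(counts + 1.0)))

    def _initial_guesses(self, log_v, k, rng):
        """Quantile split of the log-speeds into k groups, plus jitter."""
        qs = np.quantile(log_v, np.linspace(0, 1, k + 1))
        inits = []
        base_a, base_mu, base_s = [], [], []
        for j in range(k):
            sel = (log_v >= qs[j]) & (log_v <= qs[j + 1])
            grp = log_v[sel] if sel.sum() >= 5 else log_v
            base_a.append(math.log(max(sel.sum(), 5)))
            base_mu.append(float(np.median(grp)))
            base_s.append(float(np.clip(grp.std(), 0.1, 2.0)))
        base = self._pack(np.array(base_a), np.array(base_mu), np.log(base_s))
        inits.append(base)
        for _ in range(self.n_restarts):
            jitter = rng.normal(0, 0.3, size=base.size)
            inits.append(base + jitter)
        return inits

    def _fit_k(self, k, edges, counts, log_v, rng):
        n_total = max(counts.sum(), 1)
        lo = np.concatenate(
            [
                np.full(k, -5.0),
                np.full(k, np.log(self.fit_range[0])),
                np.full(k, np.log(_SIGMA_BOUNDS[0])),
            ]
        )
        hi = np.concatenate(
            [
                np.full(k, np.log(2.0 * n_total) + 2.0),
                np.full(k, np.log(self.fit_range[1])),
                np.full(k, np.log(_SIGMA_BOUNDS[1])),
            ]
        )
        best = None
        for theta0 in self._initial_guesses(log_v, k, rng):
            theta0 = np.clip(theta0, lo + 1e-6, hi - 1e-6)
            try:
                res = optimize.least_squares(
                    self._residuals,
                    theta0,
                    args=(k, edges, counts),
                    bounds=(lo, hi),
                    method="trf",
                    max_nfev=4000,
                )
            except Exception:  # pragma: no cover - optimiser hiccup
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best

    def _log_evidence(self, res, k, edges, counts):
        m = self._model_counts(res.x, k, edges)
        loglik = self._poisson_loglik(m, counts)
        p = res.x.size
        # the observations are the binned movement events, so the sample
        # size entering the Occam penalty is the total count
        n = int(counts.sum())
        if self.criterion == "bic":
            return loglik - 0.5 * p * math.log(max(n, 2))
        # Laplace: logE = logL + p/2 ln 2pi - 1/2 ln det H - sum(ln prior width)
        # H approximated by the Gauss-Newton Hessian J^T J of the weighted fit
        H = res.jac.T @ res.jac
        sign, logdet = np.linalg.slogdet(H + 1e-9 * np.eye(p))
        if sign <= 0:
            return loglik - 0.5 * p * math.log(max(n, 2))
        prior_widths = (
            k * math.log(_LOG_AMP_SPAN)
            + k * math.log(math.log(self.fit_range[1] / self.fit_range[0]))
            + k * math.log(math.log(_SIGMA_BOUNDS[1] / _SIGMA_BOUNDS[0]))
        )
        # k! permutation symmetry of component labels
        return (
            loglik
            + 0.5 * p * math.log(2 * math.pi)
            - 0.5 * logdet
            - prior_widths
            + special.gammaln(k + 1)
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the mixture to 1-D speed samples (µm/s)."""
        v = np.asarray(X, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("speeds must be finite")
        vmin, vmax = self.fit_range
        v = v[(v >= vmin) & (v <= vmax)]
        if v.size == 0:
            raise ValueError("no speed samples inside fit_range")
        if v.size < 50:
            raise ValueError(
                f"need at least 50 speed samples inside fit_range, got {v.size}"
            )
        edges = np.geomspace(vmin, vmax, self.n_bins + 1)
        counts, _ = np.histogram(v, bins=edges)
        log_v = np.log(v)
        rng = np.random.default_rng(self.random_state)

        evidences: dict[int, float] = {}
        fits = {}
        for k in range(1, self.k_max + 1):
            res = self._fit_k(k, edges, counts, log_v, rng)
            if res is None:
                continue
            fits[k] = res
            evidences[k] = self._log_evidence(res, k, edges, counts)
        if not fits:
            raise RuntimeError("mixture fit failed for every k")
        k_best = max(evidences, key=evidences.get)
        res = fits[k_best]
        converged = bool(res.success)

        log_a, log_mu, log_sigma = self._unpack(res.x, k_best)
        a = np.exp(log_a)
        w = a / a.sum()
        mu = np.exp(log_mu)
        sigma = np.exp(log_sigma)
        means = mu * np.exp(0.5 * sigma**2)

        # standard errors via the Gauss-Newton covariance, delta method
        p = res.x.size
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac + 1e-9 * np.eye(p))
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(p, np.nan)
        se_log_a, se_log_mu, se_log_sigma = self._unpack(se, k_best)
        mu_se = mu * se_log_mu
        sigma_se = sigma * se_log_sigma
        # weight_j = a_j / sum(a); delta method on the log-amplitudes,
        # d w_j / d ln a_i = a_i * d w_j / d a_i
        w_se = np.empty(k_best)
        for j in range(k_best):
            grad = -a[j] * a / a.sum() ** 2  # d w_j / d a_i for i != j
            grad[j] += a[j] / a.sum()
            w_se[j] = math.sqrt(float(np.sum((grad * a * se_log_a) ** 2)))

        order = np.argsort(means)
        comps = [
            LogNormalComponent(
                mu=float(mu[j]),
                sigma=float(sigma[j]),
                weight=float(w[j]),
                mean_speed=float(means[j]),
                mu_se=float(mu_se[j]),
                sigma_se=float(sigma_se[j]),
                weight_se=float(w_se[j]),
            )
            for j in order
        ]
        m_best = self._model_counts(res.x, k_best, edges)
        goodness = float(np.sum((counts - m_best) ** 2 / (m_best + 1.0)))

        self.k_ = k_best
        self.mu_ = np.array([c.mu for c in comps])
        self.sigma_ = np.array([c.sigma for c in comps])
        self.weights_ = np.array([c.weight for c in comps])
        self.mean_speeds_ = np.array([c.mean_speed for c in comps])
        self.log_evidence_ = float(evidences[k_best])
        self.bin_edges_ = edges
        self.counts_ = counts
        self.result_ = MixtureFit(
            components=comps,
            k=k_best,
            fit_range=(float(vmin), float(vmax)),
            log_evidence=float(evidences[k_best]),
            goodness=goodness,
            n_events=int(v.size),
            log_evidences={k: float(e) for k, e in evidences.items()},
            converged=converged,
        )
        return self

    def pdf(self, v):
        """Mixture density of the fitted model at speeds ``v``."""
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        for mu, sig, w in zip(self.mu_, self.sigma_, self.weights_):
            out += w * stats.lognorm.pdf(v, s=sig, scale=mu)
        return out


def fit_mixture(
    speeds,
    k_max: int = 3,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    n_bins: int = 40,
    **kwargs,
) -> MixtureFit:
    """Decompose a speed sample into log-normal components.

    Thin functional wrapper around :class:`LogNormalMixture`.
    """
    est = LogNormalMixture(
        k_max=k_max, fit_range=fit_range, n_bins=n_bins, **kwargs
    ).fit(speeds)
    return est.result_


@dataclass
class IntensityBinProfile:
    """Per-intensity-bin two-component summaries for one direction."""

    direction: str
    bin_edges: np.ndarray
    slow_mean_speed: np.ndarray
    slow_mean_speed_se: np.ndarray
    fast_mean_speed: np.ndarray
    fast_mean_speed_se: np.ndarray
    fast_fraction: np.ndarray
    fast_fraction_se: np.ndarray
    n_events: np.ndarray


def _fit_two_components_fixed_init(speeds, fit_range, n_bins, init):
    """k=2 fit seeded from a global fit (no model selection)."""
    est = LogNormalMixture(k_max=2, fit_range=fit_range, n_bins=n_bins, n_restarts=1)
    v = np.asarray(speeds, dtype=float)
    v = v[(v >= fit_range[0]) & (v <= fit_range[1])]
    edges = np.geomspace(fit_range[0], fit_range[1], n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    rng = np.random.default_rng(0)

    def guesses(log_v, k, _rng):
        mus, sigmas, ws = init
        n = max(counts.sum(), 1)
        theta = est._pack(
            np.log(np.maximum(ws * n, 1.0)), np.log(mus), np.log(sigmas)
        )
        return [theta]

    est._initial_guesses = guesses  # seed from the global decomposition
    res = est._fit_k(2, edges, counts, np.log(v), rng)
    if res is None:
        return None
    log_a, log_mu, log_sigma = est._unpack(res.x, 2)
    a, mu, sig = np.exp(log_a), np.exp(log_mu), np.exp(log_sigma)
    w = a / a.sum()
    means = mu * np.exp(0.5 * sig**2)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac + 1e-9 * np.eye(6))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(6, np.nan)
    se_log_a, se_log_mu, se_log_sigma = est._unpack(se, 2)
    mean_se = means * np.sqrt(se_log_mu**2 + (sig**2 * se_log_sigma) ** 2)
    # se of the fast-event fraction w_f = a_f / (a_s + a_f), delta method on ln a
    dw = np.array([-(a[0] * a[1]), a[0] * a[1]]) / a.sum() ** 2  # d w_1 / d ln a_i
    w_se_val = math.sqrt(float(np.sum((dw * se_log_a) ** 2)))
    order = np.argsort(means)
    return {
        "means": means[order],
        "mean_se": mean_se[order],
        "fast_fraction": float(w[order][1]),
        "fast_fraction_se": w_se_val,
    }


def intensity_binned_analysis(
    segments,
    n_bins: int = 5,
    binning: str = "log",
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    hist_bins: int = 30,
    min_events: int = 30,
) -> dict[str, IntensityBinProfile]:
    """Two-component speed analysis as a function of binned endosome intensity.

    Movement events (frame-to-frame steps inside processive segments) are
    grouped by the mean integral intensity of their segment, and the
    two-component decomposition is repeated per intensity bin and per
    direction, yielding per-bin slow/fast component mean speeds and the
    fraction of movement events in the fast component.

    Parameters
    ----------
    segments : sequence of ProcessiveSegment
        Segments carrying ``step_speeds`` and ``mean_intensity``.
    n_bins : int
        Number of intensity bins.
    binning : {"log", "quantile"}
        Log-spaced bins across the observed intensity range, or
        equal-count quantile bins.
    min_events : int
        Bins with fewer movement events are reported empty (NaN).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 intensity bins")
    segs = [s for s in segments if np.isfinite(s.mean_intensity)]
    if not segs:
        raise ValueError("no segments with finite mean_intensity")
    intens = np.array([s.mean_intensity for s in segs])
    if binning == "log":
        pos = intens[intens > 0]
        edges = np.geomspace(pos.min(), pos.max() * (1 + 1e-9), n_bins + 1)
    elif binning == "quantile":
        edges = np.quantile(intens, np.linspace(0, 1, n_bins + 1))
        edges[-1] *= 1 + 1e-9
    else:
        raise ValueError(f"unknown binning {binning!r}")

    profiles: dict[str, IntensityBinProfile] = {}
    for direction in ("retrograde", "anterograde"):
        dir_segs = [s for s in segs if s.direction == direction]
        if not dir_segs:
            continue
        all_speeds = np.concatenate([s.step_speeds for s in dir_segs])
        glob = None
        try:
            fit = fit_mixture(all_speeds, k_max=2, fit_range=fit_range, n_bins=hist_bins)
            if fit.k == 2:
                glob = (
                    np.array([c.mu for c in fit.components]),
                    np.array([c.sigma for c in fit.components]),
                    np.array([c.weight for c in fit.components]),
                )
        except (ValueError, RuntimeError):
            pass
        if glob is None:
            med = np.median(all_speeds)
            glob = (
                np.array([med / 2, med * 2]),
                np.array([0.8, 0.5]),
                np.array([0.6, 0.4]),
            )

        shape = n_bins
        out = {
            name: np.full(shape, np.nan)
            for name in (
                "slow_mean",
                "slow_se",
                "fast_mean",
                "fast_se",
                "frac",
                "frac_se",
            )
        }
        n_ev = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = [
                s
                for s in dir_segs
                if edges[b] <= s.mean_intensity < edges[b + 1]
            ]
            if not sel:
                continue
            speeds = np.concatenate([s.step_speeds for s in sel])
            speeds = speeds[(speeds >= fit_range[0]) & (speeds <= fit_range[1])]
            n_ev[b] = speeds.size
            if speeds.size < min_events:
                continue
            r = _fit_two_components_fixed_init(speeds, fit_range, hist_bins, glob)
            if r is None:
                continue
            out["slow_mean"][b], out["fast_mean"][b] = r["means"]
            out["slow_se"][b], out["fast_se"][b] = r["mean_se"]
            out["frac"][b] = r["fast_fraction"]
            out["frac_se"][b] = r["fast_fraction_se"]
        profiles[direction] = IntensityBinProfile(
            direction=direction,
            bin_edges=edges,
            slow_mean_speed=out["slow_mean"],
            slow_mean_speed_se=out["slow_se"],
            fast_mean_speed=out["fast_mean"],
            fast_mean_speed_se=out["fast_se"],
            fast_fraction=out["frac"],
            fast_fraction_se=out["frac_se"],
            n_events=n_ev,
        )
    return profiles
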