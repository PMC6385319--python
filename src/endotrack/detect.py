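"""Sub-pixel endosome detection by squared-Lorentzian model fitting.

Endosomes are diffraction-limited, so each appears as a radially symmetric
peak.  The intensity model is a squared Lorentzian

    I(x, y) = A / (1 + r^2 / w^2)^2,      r^2 = (x - x0)^2 + (y - y0)^2,

whose integral over the plane is finite and analytic, A * pi * w^2 — this
integral is the spot's *integral intensity*, the per-endosome marker
amount used throughout the downstream analysis.  Candidate maxima of the
significance image (differential / differential_sd) are grouped into
clusters and each cluster is fit by a sum of such models with
sd-weighted least squares; a detection is kept only if the probability of
its amplitude arising from noise is below ``alpha`` (probabilistic
thresholding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "SpotModel",
    "squared_lorentzian",
    "integral_intensity",
    "fit_cluster",
    "SpotDetector",
    "detect_spots",
]


@dataclass
class SpotModel:
    """Parameters of one squared-Lorentzian spot."""

    x0: float
    y0: float
    w: float
    A: float

    @property
    def integral_intensity(self) -> float:
        return integral_intensity(self.A, self.w)


def squared_lorentzian(xx, yy, x0, y0, w, A):
    """Evaluate A / (1 + r^2/w^2)^2 on the coordinate grids xx, yy."""
    r2 = (xx - x0) ** 2 + (yy - y0) ** 2
    return A / (1.0 + r2 / (w * w)) ** 2


def integral_intensity(A: float, w: float) -> float:
    """Analytic integral of the squared Lorentzian: A * pi * w^2."""
    return float(A * math.pi * w * w)


def _model_sum(params, xx, yy, k):
    out = np.zeros_like(xx, dtype=float)
    for j in range(k):
        x0, y0, w, A = params[4 * j : 4 * j + 4]
        out += squared_lorentzian(xx, yy, x0, y0, w, A)
    return out


def fit_cluster(
    patch: np.ndarray,
    k: int | None = None,
    sd: np.ndarray | None = None,
    init: list[SpotModel] | None = None,
    k_max: int = 3,
    w0: float = 2.0,
    max_restarts: int = 2,
    max_nfev_per_spot: int = 100,
    ftol: float = 1e-8,
    xtol: float = 1e-8,
):
    """Least-squares fit of k superposed squared-Lorentzians to a patch.

    When ``k`` is not supplied it is chosen among 1..k_max by a penalised
    likelihood (the same Occam-razor logic used for the speed-mixture
    model selection, in its BIC form).  Returns ``(models, cov)`` where
    ``cov`` is the parameter covariance of the weighted fit, or
    ``(None, None)`` when no restart converges (the cluster is reported
    unfit, not fabricated).
    """
    patch = np.asarray(patch, dtype=float)
    H, W = patch.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    if sd is None:
        sd = np.ones_like(patch)
    wgt = 1.0 / np.maximum(sd, 1e-12)

    def run_fit(k, p0):
        lo = np.tile([-1.0, -1.0, 0.5, 0.0], k)
        hi = np.tile([W, H, max(H, W) / 1.5 + 1.0, np.inf], k)
        lo[0::4] = -1.0
        lo[1::4] = -1.0
        hi[0::4] = W
        hi[1::4] = H

        def resid(p):
            return ((_model_sum(p, xx, yy, k) - patch) * wgt).ravel()

        def jac(p):
            J = np.empty((patch.size, 4 * k))
            for j in range(k):
                x0, y0, ww, A = p[4 * j : 4 * j + 4]
                dx, dy = xx - x0, yy - y0
                r2 = dx * dx + dy * dy
                u = 1.0 + r2 / (ww * ww)
                u3 = u**-3
                J[:, 4 * j] = (4.0 * A * dx / (ww * ww) * u3 * wgt).ravel()
                J[:, 4 * j + 1] = (4.0 * A * dy / (ww * ww) * u3 * wgt).ravel()
                J[:, 4 * j + 2] = (4.0 * A * r2 / ww**3 * u3 * wgt).ravel()
                J[:, 4 * j + 3] = (u**-2 * wgt).ravel()
            return J

        try:
            return optimize.least_squares(
                resid, np.clip(p0, lo + 1e-9, hi - 1e-9), bounds=(lo, hi),
                jac=jac, method="trf", max_nfev=max_nfev_per_spot * k,
                x_scale="jac", ftol=ftol, xtol=xtol,
            )
        except Exception:
            return None

    def initial(k, rng=None):
        if init is not None and len(init) == k:
            p0 = []
            for m in init:
                p0 += [m.x0, m.y0, m.w, m.A]
            return np.array(p0)
        # seed from the k strongest separated local maxima
        sm = ndimage.gaussian_filter(patch, 1.0)
        flat = np.argsort(sm.ravel())[::-1]
        seeds = []
        for idx in flat:
            y, x = divmod(idx, W)
            if all((y - sy) ** 2 + (x - sx) ** 2 > w0**2 for sy, sx in seeds):
                seeds.append((y, x))
            if len(seeds) == k:
                break
        p0 = []
        for y, x in seeds:
            p0 += [float(x), float(y), w0, max(patch[y, x], 1e-3)]
        while len(p0) < 4 * k:
            p0 += [W / 2, H / 2, w0, max(patch.max(), 1e-3)]
        return np.array(p0)

    rng = np.random.default_rng(0)

    def best_for_k(k):
        # restarts are a fallback for non-convergence, not a search
        p0 = initial(k)
        for r in range(max_restarts):
            p_try = p0 if r == 0 else p0 * rng.uniform(0.8, 1.2, size=p0.size)
            res = run_fit(k, p_try)
            if res is not None and res.success:
                return res
        return None

    if k is not None:
        best, k_sel = best_for_k(k), k
    else:
        best, k_sel, best_score = None, 0, -np.inf
        n = patch.size
        for kk in range(1, k_max + 1):
            res = best_for_k(kk)
            if res is None:
                continue
            # Gaussian log-lik of the weighted residuals, BIC penalty
            score = -res.cost - 0.5 * 4 * kk * math.log(n)
            if score > best_score:
                best, k_sel, best_score = res, kk, score
    if best is None:
        return None, None
    p = best.x
    models = [
        SpotModel(x0=p[4 * j], y0=p[4 * j + 1], w=p[4 * j + 2], A=p[4 * j + 3])
        for j in range(k_sel)
    ]
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac + 1e-12 * np.eye(p.size))
    except np.linalg.LinAlgError:
        cov = None
    return models, cov


class SpotDetector(BaseEstimator):
    """Per-frame sub-pixel spot detection on differential images.

    Candidate pixels are 3x3 local maxima of the significance image
    ``differential / differential_sd`` above ``seed_z``; candidates within
    ``cluster_radius_factor * w0`` of each other are fit jointly.  A
    detection is kept iff the probability that its fitted amplitude arises
    from noise (Gaussian, with the amplitude standard error from the
    weighted fit, Bonferroni-corrected for the number of resolution
    elements searched in the cluster patch) is below ``alpha``.

    Parameters
    ----------
    alpha : float
        Significance level of the probabilistic threshold, in (0, 1).
    w0 : float
        Expected spot width (px), used for seeding and patch sizes.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        w0: float = 2.0,
        seed_z: float = 2.0,
        cluster_radius_factor: float = 3.0,
        patch_pad_factor: float = 4.0,
        max_per_cluster: int = 4,
    ):
        self.alpha = alpha
        self.w0 = w0
        self.seed_z = seed_z
        self.cluster_radius_factor = cluster_radius_factor
        self.patch_pad_factor = patch_pad_factor
        self.max_per_cluster = max_per_cluster

    # -- internals ----------------------------------------------------------

    def _linear_screen(self, diff, sd, ys, xs):
        """Matched-filter amplitude significance at fixed position over a
        small set of widths (w0 and 2*w0, for spots broadened by motion
        within the temporal de-noising window): with the model A * L(r; w),
        the weighted least-squares amplitude is linear in the data,
        A = sum(L y / sd^2) / sum(L^2 / sd^2), with standard error
        1 / sqrt(sum(L^2 / sd^2)).  Candidates whose amplitude is
        consistent with noise at level alpha at every scale are dropped
        before any nonlinear fitting; the best-matching width is kept as
        the fit seed."""
        H, W = diff.shape
        scales = (self.w0, 2.0 * self.w0)
        r = int(math.ceil(2.5 * max(scales)))
        keep = []
        best_w = []
        for y, x in zip(ys, xs):
            y0, y1 = max(0, y - r), min(H, y + r + 1)
            x0, x1 = max(0, x - r), min(W, x + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            r2 = (xx - x) ** 2 + (yy - y) ** 2
            w2 = 1.0 / np.maximum(sd[y0:y1, x0:x1], 1e-12) ** 2
            patch = diff[y0:y1, x0:x1]
            p_best, z_best, w_sel = 1.0, -np.inf, scales[0]
            for wsc in scales:
                L = 1.0 / (1.0 + r2 / (wsc * wsc)) ** 2
                denom = float((L * L * w2).sum())
                A = float((L * patch * w2).sum()) / max(denom, 1e-12)
                zval = A * math.sqrt(max(denom, 1e-12))
                if zval > z_best:
                    z_best, w_sel = zval, wsc
                p_best = min(p_best, float(special.ndtr(-zval)))
            keep.append(p_best < self.alpha)
            best_w.append(w_sel)
        keep = np.asarray(keep, dtype=bool)
        return ys[keep], xs[keep], np.asarray(best_w)[keep]

    def _candidates(self, z):
        footprint = np.ones((3, 3), bool)
        mx = ndimage.maximum_filter(z, footprint=footprint, mode="nearest")
        cand = (z >= mx) & (z > self.seed_z)
        ys, xs = np.nonzero(cand)
        # deterministic ordering; coincident plateau maxima collapse to the
        # brightest (first in (y, x) order on ties)
        order = np.lexsort((xs, ys))
        return ys[order], xs[order]

    def _clusters(self, ys, xs):
        n = len(ys)
        r2 = (self.cluster_radius_factor * self.w0) ** 2
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (ys[i] - ys[j]) ** 2 + (xs[i] - xs[j]) ** 2 <= r2:
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[pj] = pi
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        return list(groups.values())

    def _split_cluster(self, group, ys, xs, z):
        """Break a transitively chained cluster into compact subgroups:
        brightest remaining candidate seeds a subgroup of everything
        within the cluster radius."""
        remaining = sorted(group, key=lambda i: -z[ys[i], xs[i]])
        r2 = (self.cluster_radius_factor * self.w0) ** 2
        subgroups = []
        while remaining:
            seed = remaining[0]
            sub = [
                i
                for i in remaining
                if (ys[i] - ys[seed]) ** 2 + (xs[i] - xs[seed]) ** 2 <= r2
            ]
            subgroups.append(sub)
            remaining = [i for i in remaining if i not in sub]
        return subgroups

    # -- API ---------------------------------------------------------------

    def detect_frame(
        self, differential: np.ndarray, differential_sd: np.ndarray, frame: int = 0
    ) -> pd.DataFrame:
        """Detect spots in one differential frame.

        Returns a DataFrame with columns frame, x, y, w, amplitude,
        integral_intensity, significance (probability the structure is
        noise); coordinates are 0-based pixel centers, x rightward,
        y downward.
        """
        diff = np.asarray(differential, dtype=float)
        sd = np.asarray(differential_sd, dtype=float)
        if diff.shape != sd.shape:
            raise ValueError("differential and differential_sd shapes differ")
        bad = ~np.isfinite(diff) | ~np.isfinite(sd)
        if bad.any():
            y, x = np.argwhere(bad)[0]
            raise ValueError(f"non-finite pixel at (y={y}, x={x})")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        H, W = diff.shape
        z = diff / np.maximum(sd, 1e-12)
        ys, xs = self._candidates(z)
        ws = np.full(len(ys), self.w0)
        if len(ys):
            ys, xs, ws = self._linear_screen(diff, sd, ys, xs)
        rows = []
        if len(ys):
            pad = int(math.ceil(self.patch_pad_factor * self.w0))
            groups = []
            for group in self._clusters(ys, xs):
                if len(group) > self.max_per_cluster:
                    groups.extend(self._split_cluster(group, ys, xs, z))
                else:
                    groups.append(group)
            for group in groups:
                # seed only the strongest candidates of the subgroup
                group = sorted(group, key=lambda i: -z[ys[i], xs[i]])
                group = group[: self.max_per_cluster]
                gy, gx, gw = ys[group], xs[group], ws[group]
                y0, y1 = max(0, gy.min() - pad), min(H, gy.max() + pad + 1)
                x0, x1 = max(0, gx.min() - pad), min(W, gx.max() + pad + 1)
                patch = diff[y0:y1, x0:x1]
                sd_patch = sd[y0:y1, x0:x1]
                # number of spots in the cluster chosen by the penalised
                # likelihood inside fit_cluster (multiple candidate maxima
                # often belong to one spot)
                models, cov = fit_cluster(
                    patch, k=None, k_max=len(group), sd=sd_patch,
                    w0=float(np.mean(gw)),
                    max_nfev_per_spot=150, ftol=1e-5, xtol=1e-5,
                )
                if models is None:
                    continue
                n_res = max(patch.size / (math.pi * self.w0**2), 1.0)
                r_keep = self.cluster_radius_factor * self.w0
                for j, m in enumerate(models):
                    if m.A <= 0 or not (0 <= m.x0 < patch.shape[1]) or not (
                        0 <= m.y0 < patch.shape[0]
                    ):
                        continue
                    # discard fits that wandered away from this subgroup's
                    # own seeds (they describe a neighbouring cluster)
                    d2 = (gy - (m.y0 + y0)) ** 2 + (gx - (m.x0 + x0)) ** 2
                    if d2.min() > r_keep**2:
                        continue
                    if cov is not None:
                        se_A = math.sqrt(max(cov[4 * j + 3, 4 * j + 3], 0.0))
                    else:
                        se_A = float(np.median(sd_patch))
                    se_A = max(se_A, 1e-12)
                    p_noise = min(1.0, n_res * float(special.ndtr(-m.A / se_A)))
                    if p_noise < self.alpha:
                        rows.append(
                            (
                                frame,
                                m.x0 + x0,
                                m.y0 + y0,
                                m.w,
                                m.A,
                                integral_intensity(m.A, m.w),
                                p_noise,
                            )
                        )
        df = pd.DataFrame(
            rows,
            columns=[
                "frame", "x", "y", "w", "amplitude",
                "integral_intensity", "significance",
            ],
        )
        # coincident fits from adjacent subgroups: keep the brighter
        df = df.sort_values("amplitude", ascending=False, kind="stable")
        keep = []
        kept_xy: list[tuple[float, float]] = []
        for row in df.itertuples():
            if all(
                (row.x - px_) ** 2 + (row.y - py_) ** 2 > self.w0**2
                for px_, py_ in kept_xy
            ):
                keep.append(row.Index)
                kept_xy.append((row.x, row.y))
        df = df.loc[keep]
        return df.sort_values(["frame", "y", "x"], kind="stable").reset_index(drop=True)

    def detect_movie(self, restored) -> pd.DataFrame:
        """Detect spots in every frame of a RestoredMovie."""
        frames = [
            self.detect_frame(
                restored.differential[t], restored.differential_sd[t], frame=t
            )
            for t in range(restored.differential.shape[0])
        ]
        return pd.concat(frames, ignore_index=True)


def detect_spots(
    differential: np.ndarray,
    differential_sd: np.ndarray,
    alpha: float = 0.01,
    frame: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Detect spots in one differential frame; see :class:`SpotDetector`."""
    return SpotDetector(alpha=alpha, **kwargs).detect_frame(
        differential, differential_sd, frame=frame
    )
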