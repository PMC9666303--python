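"""Fixed points and stability of BCM learning with a mean-field threshold.

With slow time constants the sliding threshold can be replaced by its
stimulus average theta(w) = (1/K) sum_k y_k^2, which turns learning into
an N-dimensional dynamical system in the effective weights w.  This
module locates its fixed points:

* standard-BCM points w = K X^{-1} e_m, where the neuron responds with
  y = K to one pattern and 0 to the rest (winner-take-all),
* the weight-dependent points unique to the soft-bound rule, found by a
  determinant-line reduction to a one-dimensional root problem,
* the unselective pinned point w = (-u, ..., -u) that appears under
  feed-forward excitation (u < 0),

and classifies their stability through piecewise Jacobians: at points
where the modification function switches branch the Jacobian of each
adjoining branch must be stable.

The critical inhibition levels bracketing the weight-dependent regime
are available in closed form for two stimuli: above u* the
winner-take-all points are stable and the soft bound is irrelevant;
at and below u** (< 0) the weights pin at the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .dynamics import PlasticityConfig, Rule, mean_field_theta
from .stimuli import StimulusEnsemble

#: eigenvalue real parts within this band of zero are inconclusive
STABILITY_TOL = 1e-8
#: relative finite-difference step for Jacobians
FD_STEP = 1e-6


class SingularStimulusError(ValueError):
    """The stimulus matrix is singular or too ill-conditioned to invert."""


class Classification(str, Enum):
    STANDARD_BCM = "standard_bcm"
    WEIGHT_DEPENDENT = "weight_dependent"
    PINNED_AT_BOUND = "pinned_at_bound"
    SYMMETRIC_UNSTABLE = "symmetric_unstable"


@dataclass
class FixedPointReport:
    """A located fixed point with its stability verdict."""

    w_star: np.ndarray
    theta_star: float
    responses: np.ndarray
    stable: bool
    classification: Classification
    accessible: bool
    eigenvalues: list = field(default_factory=list)
    inconclusive: bool = False

    def to_dict(self) -> dict:
        return {
            "w_star": np.asarray(self.w_star).tolist(),
            "theta_star": self.theta_star,
            "responses": np.asarray(self.responses).tolist(),
            "stable": bool(self.stable),
            "classification": self.classification.value,
            "accessible": bool(self.accessible),
            "eigenvalues": [
                [complex(ev).real for ev in branch] for branch in self.eigenvalues
            ],
            "inconclusive": bool(self.inconclusive),
        }


def _stimulus_matrix(ensemble: StimulusEnsemble | np.ndarray) -> np.ndarray:
    if isinstance(ensemble, StimulusEnsemble):
        return ensemble.patterns
    return np.asarray(ensemble, dtype=float)


def _checked_inverse(X: np.ndarray, cond_max: float = 1e8) -> np.ndarray:
    if X.shape[0] != X.shape[1]:
        raise SingularStimulusError("need K = N (square stimulus matrix)")
    if np.linalg.cond(X) > cond_max:
        raise SingularStimulusError(
            "stimulus matrix is singular or near-singular "
            "(e.g. parallel stimuli, phi = pi/4)"
        )
    return np.linalg.inv(X)


def mean_update(
    w: np.ndarray,
    ensemble: StimulusEnsemble | np.ndarray,
    cfg: PlasticityConfig,
    sigma_y: float = 0.0,
    branches: np.ndarray | None = None,
) -> np.ndarray:
    """Stimulus-averaged weight change (in units of 1/tau_w), linear neuron.

    Computes (1/K) sum_k g_k x^(k) [y_k (y_k - theta) + sigma_y^2] with
    the mean-field threshold theta = (1/K) sum y_k^2 + sigma_y^2, where
    g_k = w + u elementwise on a depression branch of the
    weight-dependent rule and 1 otherwise.

    ``branches`` optionally forces the branch per pattern (+1
    potentiation, -1 depression) instead of reading it off the sign of
    the drive — needed for one-sided Jacobians at non-smooth points.
    """
    X = _stimulus_matrix(ensemble)
    w = np.asarray(w, dtype=float)
    y = X @ w
    theta = mean_field_theta(y, sigma_y)
    drive = y * (y - theta) + sigma_y**2
    if branches is None:
        depressing = drive < 0
    else:
        depressing = np.asarray(branches) < 0
    K = X.shape[0]
    out = np.zeros_like(w)
    for k in range(K):
        g = (w + cfg.u) if (cfg.rule is Rule.WEIGHT_DEPENDENT and depressing[k]) else 1.0
        out += g * X[k] * drive[k]
    return out / K


def standard_fixed_points(
    ensemble: StimulusEnsemble | np.ndarray,
) -> list[FixedPointReport]:
    """Winner-take-all fixed points w = K (X^{-1})_{:,m} of standard BCM.

    Requires K = N linearly independent patterns.  Each candidate m
    responds with y = K to pattern m and 0 to all others, with
    theta = K.  The origin and the fully symmetric point (all responses
    equal to theta = 1) are appended, flagged symmetric-unstable.
    Stability is *not* assessed here; see :func:`stability`.
    """
    X = _stimulus_matrix(ensemble)
    Xi = _checked_inverse(X)
    K = X.shape[0]
    reports = []
    for m in range(K):
        w = K * Xi[:, m]
        responses = np.zeros(K)
        responses[m] = K
        reports.append(
            FixedPointReport(
                w_star=w,
                theta_star=float(K),
                responses=responses,
                stable=False,
                classification=Classification.STANDARD_BCM,
                accessible=True,
            )
        )
    # origin: y = 0 for every pattern
    reports.append(
        FixedPointReport(
            w_star=np.zeros(K),
            theta_star=0.0,
            responses=np.zeros(K),
            stable=False,
            classification=Classification.SYMMETRIC_UNSTABLE,
            accessible=True,
        )
    )
    # symmetric point: y_k = theta for all k forces theta = 1
    w_sym = Xi @ np.ones(K)
    reports.append(
        FixedPointReport(
            w_star=w_sym,
            theta_star=1.0,
            responses=np.ones(K),
            stable=False,
            classification=Classification.SYMMETRIC_UNSTABLE,
            accessible=True,
        )
    )
    return reports


def _finalize(report: FixedPointReport, ensemble, cfg) -> FixedPointReport:
    """Fill in accessibility and the stability verdict."""
    report.accessible = bool(np.all(report.w_star + cfg.u >= -1e-12))
    verdict = stability(report, ensemble, cfg)
    report.stable = verdict["stable"]
    report.eigenvalues = verdict["eigenvalues"]
    report.inconclusive = verdict["inconclusive"]
    return report


def wd_fixed_points_2d(
    ensemble: StimulusEnsemble | np.ndarray,
    cfg: PlasticityConfig,
    w_max: float | None = None,
    eps: float = 1e-6,
    n_scan: int = 2000,
) -> list[FixedPointReport]:
    """Fixed points unique to the weight-dependent rule, two stimuli.

    A fixed point with nonzero drive on both patterns requires one
    pattern to depress and the other to potentiate; setting the
    determinant of the resulting 2x2 system to zero confines candidates
    to a line through (-u, -u) in the (w1, w2) plane:

        x1^(1) x2^(2) (w1 + u) = x1^(2) x2^(1) (w2 + u)

    for the case where pattern 1 depresses (and the mirrored line for
    the swapped case).  The residual along the line is scanned for sign
    changes over w1 in [-u + eps, w_max] and each bracket is resolved by
    Brent's method; roots are kept only if the assumed depression /
    potentiation assignment actually holds there.  An empty list means
    the merged (strong-inhibition) regime.
    """
    X = _stimulus_matrix(ensemble)
    if X.shape != (2, 2):
        raise ValueError("the determinant-line reduction is two-dimensional only")
    if cfg.rule is not Rule.WEIGHT_DEPENDENT:
        raise ValueError("weight-dependent rule required")
    u = cfg.u
    if w_max is None:
        Xi = _checked_inverse(X)
        w_max = 3.0 * float(np.max(np.abs(2.0 * Xi)))

    reports: list[FixedPointReport] = []
    # case index d = pattern that depresses (0 or 1)
    for d in (0, 1):
        p = 1 - d
        # line: X[d,0]*X[p,1]*(w1+u) = X[p,0]*X[d,1]*(w2+u) for d=0
        # (and the mirrored relation for d=1); both pass through (-u,-u)
        a = X[d, 0] * X[p, 1]
        b = X[p, 0] * X[d, 1]

        def w2_of_w1(w1):
            return (a / b) * (w1 + u) - u

        def residual(w1):
            w = np.array([w1, w2_of_w1(w1)])
            y = X @ w
            theta = mean_field_theta(y)
            drive = y * (y - theta)
            # first row of the singular system:
            # [x1^(d)(w1+u)] F_d + [x1^(p)] F_p = 0
            return X[d, 0] * (w1 + u) * drive[d] + X[p, 0] * drive[p]

        grid = np.linspace(-u + eps, w_max, n_scan)
        vals = np.array([residual(g) for g in grid])
        sign = np.sign(vals)
        for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
            root = brentq(residual, grid[i], grid[i + 1], xtol=1e-14)
            w = np.array([root, w2_of_w1(root)])
            y = X @ w
            theta = mean_field_theta(y)
            drive = y * (y - theta)
            # discard the standard points (zero drive) and wrong-case roots
            if abs(drive[d]) < 1e-8 or abs(drive[p]) < 1e-8:
                continue
            if not (drive[d] < 0 and drive[p] > 0):
                continue
            report = FixedPointReport(
                w_star=w,
                theta_star=float(theta),
                responses=y,
                stable=False,
                classification=Classification.WEIGHT_DEPENDENT,
                accessible=True,
            )
            if not any(
                np.allclose(report.w_star, r.w_star, atol=1e-8) for r in reports
            ):
                reports.append(_finalize(report, ensemble, cfg))
    return reports


def all_fixed_points_2d(
    ensemble: StimulusEnsemble | np.ndarray, cfg: PlasticityConfig
) -> list[FixedPointReport]:
    """Standard, symmetric, weight-dependent and pinned points, with stability."""
    reports = [
        _finalize(r, ensemble, cfg) for r in standard_fixed_points(ensemble)
    ]
    if cfg.rule is Rule.WEIGHT_DEPENDENT:
        reports.extend(wd_fixed_points_2d(ensemble, cfg))
        if cfg.u < 0:
            X = _stimulus_matrix(ensemble)
            w = -cfg.u * np.ones(X.shape[1])
            y = X @ w
            reports.append(
                FixedPointReport(
                    w_star=w,
                    theta_star=mean_field_theta(y),
                    responses=y,
                    stable=cfg.u <= critical_inhibition_lower(ensemble),
                    classification=Classification.PINNED_AT_BOUND,
                    accessible=True,
                )
            )
    return reports


def _jacobian(w, ensemble, cfg, branches) -> np.ndarray:
    """Central finite-difference Jacobian of mean_update, fixed branches."""
    w = np.asarray(w, dtype=float)
    n = w.size
    J = np.empty((n, n))
    for j in range(n):
        h = FD_STEP * (1.0 + abs(w[j]))
        wp, wm = w.copy(), w.copy()
        wp[j] += h
        wm[j] -= h
        fp = mean_update(wp, ensemble, cfg, branches=branches)
        fm = mean_update(wm, ensemble, cfg, branches=branches)
        J[:, j] = (fp - fm) / (2.0 * h)
    return J


def stability(
    fp: FixedPointReport,
    ensemble: StimulusEnsemble | np.ndarray,
    cfg: PlasticityConfig,
    tol: float = STABILITY_TOL,
) -> dict:
    """Piecewise-Jacobian stability of a fixed point.

    Patterns whose drive vanishes at the point (the winner-take-all
    points of standard BCM sit exactly on the branch switch of the
    weight-dependent rule) are evaluated under *both* branch
    assignments; the point is stable only if every branch Jacobian has
    all eigenvalue real parts below -tol.

    Where the linearisation is entirely marginal (the origin, whose
    drive is quadratic), a direct nonlinear probe checks for outward
    drive on a small circle of perturbations.
    """
    X = _stimulus_matrix(ensemble)
    w = np.asarray(fp.w_star, dtype=float)
    y = X @ w
    theta = mean_field_theta(y)
    drive = y * (y - theta)
    K = X.shape[0]

    ambiguous = np.abs(drive) < 1e-7
    fixed_branch = np.where(drive < 0, -1, 1)
    n_amb = int(ambiguous.sum())
    if cfg.rule is not Rule.WEIGHT_DEPENDENT:
        assignments = [fixed_branch]
    else:
        assignments = []
        amb_idx = np.nonzero(ambiguous)[0]
        for bits in range(2**n_amb):
            br = fixed_branch.copy()
            for j, idx in enumerate(amb_idx):
                br[idx] = -1 if (bits >> j) & 1 else 1
            assignments.append(br)

    eigs, max_re = [], -np.inf
    for br in assignments:
        ev = np.linalg.eigvals(_jacobian(w, ensemble, cfg, br))
        eigs.append(ev)
        max_re = max(max_re, float(np.max(ev.real)))

    if max_re < -tol:
        return {"stable": True, "inconclusive": False, "eigenvalues": eigs}
    if max_re > tol:
        return {"stable": False, "inconclusive": False, "eigenvalues": eigs}
    # marginal linearisation: probe the nonlinear drive on a small circle
    delta = 1e-4 * (1.0 + float(np.max(np.abs(w))))
    outward = False
    for angle in np.linspace(0.0, 2.0 * np.pi, 17)[:-1] if K == 2 else []:
        d = np.array([np.cos(angle), np.sin(angle)])
        m = mean_update(w + delta * d, ensemble, cfg)
        if float(m @ d) > 1e-12:
            outward = True
            break
    if K != 2:
        rng = np.random.default_rng(0)
        for _ in range(64):
            d = rng.standard_normal(w.size)
            d /= np.linalg.norm(d)
            m = mean_update(w + delta * d, ensemble, cfg)
            if float(m @ d) > 1e-12:
                outward = True
                break
    if outward:
        return {"stable": False, "inconclusive": False, "eigenvalues": eigs}
    return {"stable": False, "inconclusive": True, "eigenvalues": eigs}


def nullclines_2d(
    ensemble: StimulusEnsemble | np.ndarray,
    cfg: PlasticityConfig,
    w_range: tuple[float, float] | None = None,
    n_grid: int = 400,
) -> dict:
    """Zero contours of the two components of the averaged update.

    Returns the sampled grids, the update components on the grid, the
    extracted zero-level polylines of each component (in weight
    coordinates), and the mask of the restricted region w_i < -u where
    an excitatory weight would be negative.
    """
    from skimage import measure

    X = _stimulus_matrix(ensemble)
    if X.shape != (2, 2):
        raise ValueError("null-cline extraction is two-dimensional only")
    if w_range is None:
        Xi = _checked_inverse(X)
        hi = 1.6 * float(np.max(np.abs(2.0 * Xi)))
        w_range = (-cfg.u + 1e-9, hi)
    lo, hi = w_range
    axis = np.linspace(lo, hi, n_grid)
    W1, W2 = np.meshgrid(axis, axis, indexing="ij")
    # vectorized mean_update over the whole grid
    Y = np.stack([X[k, 0] * W1 + X[k, 1] * W2 for k in range(2)])
    theta = 0.5 * (Y[0] ** 2 + Y[1] ** 2)
    drive = Y * (Y - theta)
    W = np.stack([W1, W2])
    comp = np.zeros((2, n_grid, n_grid))
    wd = cfg.rule is Rule.WEIGHT_DEPENDENT
    for k in range(2):
        for i in range(2):
            g = np.where(drive[k] < 0, W[i] + cfg.u, 1.0) if wd else 1.0
            comp[i] += 0.5 * g * X[k, i] * drive[k]

    def to_coords(contour):
        out = np.empty_like(contour)
        out[:, 0] = lo + contour[:, 0] * (hi - lo) / (n_grid - 1)
        out[:, 1] = lo + contour[:, 1] * (hi - lo) / (n_grid - 1)
        return out

    curves1 = [to_coords(c) for c in measure.find_contours(comp[0], 0.0)]
    curves2 = [to_coords(c) for c in measure.find_contours(comp[1], 0.0)]
    mask = (W1 < -cfg.u) | (W2 < -cfg.u)
    return {
        "axis": axis,
        "dw1": comp[0],
        "dw2": comp[1],
        "curves_dw1": curves1,
        "curves_dw2": curves2,
        "restricted_mask": mask,
    }


def count_nullcline_crossings(
    nc: dict,
    ensemble: StimulusEnsemble | np.ndarray | None = None,
    cfg: PlasticityConfig | None = None,
    dedupe_radius: float = 0.05,
    residual_tol: float = 1e-9,
) -> list[np.ndarray]:
    """Intersection points of the two null-clines on the sampled grid.

    Scans the grid for cells in which *both* components of the averaged
    update change sign; when ``ensemble`` and ``cfg`` are supplied each
    candidate cell is refined by a two-dimensional root solve and kept
    only if the residual vanishes (robust where the null-clines meet at
    a branch corner of the piecewise rule, as they do at the
    winner-take-all points).  Crossings closer than ``dedupe_radius``
    are merged.  The origin never appears: the drive is quadratic there
    and produces no sign change.
    """
    from scipy.optimize import root

    axis = nc["axis"]
    dw1, dw2 = nc["dw1"], nc["dw2"]

    def sign_change(f):
        s = np.sign(f)
        return (
            (s[:-1, :-1] * s[1:, :-1] <= 0)
            | (s[:-1, :-1] * s[:-1, 1:] <= 0)
            | (s[:-1, :-1] * s[1:, 1:] <= 0)
        )

    cells = np.nonzero(sign_change(dw1) & sign_change(dw2))
    points: list[np.ndarray] = []
    for i, j in zip(*cells):
        guess = np.array(
            [0.5 * (axis[i] + axis[i + 1]), 0.5 * (axis[j] + axis[j + 1])]
        )
        if ensemble is None or cfg is None:
            points.append(guess)
            continue
        sol = root(lambda w: mean_update(w, ensemble, cfg), guess, method="hybr")
        resid = np.max(np.abs(mean_update(sol.x, ensemble, cfg)))
        if resid < residual_tol:
            points.append(sol.x)
    merged: list[np.ndarray] = []
    for pt in points:
        if not any(np.linalg.norm(pt - m) < dedupe_radius for m in merged):
            merged.append(pt)
    return merged


def critical_inhibition_upper(ensemble: StimulusEnsemble | np.ndarray) -> np.ndarray:
    """Critical inhibition u* above which winner-take-all points are stable.

    For each of the two winner-take-all points m the transition happens
    when the point falls on the determinant line; for the point
    selective to pattern 2,

        u* = 2 x1^(1) x2^(1) [x1^(2) + x2^(2)] / det(X)^2

    and the superscripts swap for the other.  For the mirrored
    parametrization both values coincide.
    """
    X = _stimulus_matrix(ensemble)
    if X.shape != (2, 2):
        raise ValueError("closed form available for two stimuli only")
    det = np.linalg.det(X)
    if abs(det) < 1e-12:
        raise SingularStimulusError("stimulus matrix is singular")
    # u*_m for the point selective to pattern m (0-based): the *other*
    # pattern's components appear in the product
    u0 = 2.0 * X[1, 0] * X[1, 1] * (X[0, 0] + X[0, 1]) / det**2
    u1 = 2.0 * X[0, 0] * X[0, 1] * (X[1, 0] + X[1, 1]) / det**2
    return np.array([u0, u1])


def critical_inhibition_upper_closed_form(phi: float) -> float:
    """u*(phi) = 2 sin 2phi / (cos phi + cos 3phi + sin phi - sin 3phi)."""
    return (
        2.0
        * np.sin(2.0 * phi)
        / (np.cos(phi) + np.cos(3.0 * phi) + np.sin(phi) - np.sin(3.0 * phi))
    )


def critical_inhibition_lower(ensemble: StimulusEnsemble | np.ndarray) -> float:
    """Feed-forward excitation level u** at which weights pin at (-u, -u).

    u** = -2 [x1^(2) + x2^(2)] / ([x1^(1) + x2^(1)]^2 + [x1^(2) + x2^(2)]^2);
    at and below this (negative) value the equilibrium is the fully
    unselective pinned state.
    """
    X = _stimulus_matrix(ensemble)
    if X.shape != (2, 2):
        raise ValueError("closed form available for two stimuli only")
    s1 = X[0, 0] + X[0, 1]
    s2 = X[1, 0] + X[1, 1]
    return float(-2.0 * s2 / (s1**2 + s2**2))


def critical_inhibition_lower_closed_form(phi: float) -> float:
    """u**(phi) = -1 / (sqrt(2) sin(phi + pi/4))."""
    return float(-1.0 / (np.sqrt(2.0) * np.sin(phi + np.pi / 4.0)))


def noise_fixed_points(sigma_y: float) -> dict:
    """Analytic noisy equilibrium for the mirrored unit-norm pair.

    With Gaussian output noise of s.d. sigma_y, standard BCM on two
    mirrored unit vectors has responses y = 1 +/- sqrt(1 - sigma_y^2)
    and theta = 2 while sigma_y < 1; above that the selective points
    collapse onto the symmetric one, y1 = y2 = 1, theta = 1 + sigma_y^2.
    """
    if sigma_y < 0:
        raise ValueError("sigma_y must be non-negative")
    if sigma_y < 1.0:
        root = np.sqrt(1.0 - sigma_y**2)
        return {
            "responses": np.array([1.0 + root, 1.0 - root]),
            "theta": 2.0,
            "collapsed": False,
        }
    return {
        "responses": np.array([1.0, 1.0]),
        "theta": 1.0 + sigma_y**2,
        "collapsed": True,
    }
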