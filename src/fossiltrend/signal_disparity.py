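"""Phylogenetic signal and disparity-through-time statistics.

Pagel's lambda rescales the off-diagonal shared paths of the BM covariance
and is estimated by ML jointly with the rate and root state; Blomberg's K
compares the observed ratio of non-phylogenetic to phylogenetic mean squared
error against its BM expectation. Disparity through time (DTT) tracks mean
relative subclade disparity against node age, compared against a BM
simulation envelope; the morphological disparity index (MDI) is the signed
area between the observed curve and the simulation median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .phylo_core import TimeTree
from .size_data import TraitDataset
from .trait_models import _gls_profile, _gls_profile_scale, fit_model

__all__ = [
    "LambdaFit",
    "KResult",
    "DttCurve",
    "pagel_lambda",
    "blomberg_k",
    "dtt_mdi",
    "bm_envelope",
]


# ======================================================================
# Pagel's lambda
# ======================================================================


@dataclass
class LambdaFit:
    lambda_: float
    sigma2: float
    theta: float
    lnl: float
    lnl_lambda0: float
    lrt_stat: float
    p_value: float


def _lambda_cov(S: np.ndarray, lam: float) -> np.ndarray:
    V = lam * S
    np.fill_diagonal(V, np.diag(S))
    return V


def pagel_lambda(
    tree: TimeTree, dataset: TraitDataset, *, use_se: bool = True
) -> LambdaFit:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0.

    Lambda multiplies the off-diagonal shared paths only; it is optimised
    over [0, 1] jointly with sigma2 (theta profiled by GLS). The test
    statistic 2 dlnL against the lambda=0 (diagonal-covariance, i.e.
    non-phylogenetic) fit is referred to chi-square with 1 df.
    """
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    y, se = dataset.align(tree.tip_labels)
    if not use_se:
        se = np.zeros_like(se)
    S = tree.shared_path_matrix()
    n = tree.n_tips
    ones = np.ones((n, 1))
    D = np.diag(se**2)
    no_se = bool(np.all(se == 0.0))

    def profile(lam: float) -> tuple[float, float, float]:
        C = _lambda_cov(S, lam)
        if no_se:
            lnl, beta, s2 = _gls_profile_scale(y, ones, C)
            return lnl, float(beta[0]), s2
        res = optimize.minimize_scalar(
            lambda ls2: -_gls_profile(y, ones, np.exp(ls2) * C + D)[0],
            bounds=(np.log(1e-10), np.log(1e4)),
            method="bounded",
            options={"xatol": 1e-9},
        )
        s2 = float(np.exp(res.x))
        lnl, beta = _gls_profile(y, ones, s2 * C + D)
        return lnl, float(beta[0]), s2

    res = optimize.minimize_scalar(
        lambda lam: -profile(lam)[0], bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-7},
    )
    lam_hat = float(res.x)
    lnl, theta, s2 = profile(lam_hat)
    lnl0, _, _ = profile(0.0)
    # the bounded optimiser never probes the exact endpoints
    for cand in (0.0, 1.0):
        lc, tc, sc = profile(cand)
        if lc > lnl:
            lam_hat, lnl, theta, s2 = cand, lc, tc, sc
    stat = max(0.0, 2.0 * (lnl - lnl0))
    return LambdaFit(
        lambda_=lam_hat,
        sigma2=s2,
        theta=theta,
        lnl=lnl,
        lnl_lambda0=lnl0,
        lrt_stat=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
    )


# ======================================================================
# Blomberg's K
# ======================================================================


@dataclass
class KResult:
    k: float
    p_value: float
    n_perm: int


def _k_ratio(y: np.ndarray, Sinv_cho, ones: np.ndarray) -> float:
    """Observed MSE0/MSE for trait vector y given a factorised covariance."""
    Vi1 = cho_solve(Sinv_cho, ones[:, 0], check_finite=False)
    a = float((Vi1 @ y) / Vi1.sum())
    r = y - a
    mse0 = float(r @ r)
    mse = float(r @ cho_solve(Sinv_cho, r, check_finite=False))
    return mse0 / mse


def blomberg_k(
    tree: TimeTree,
    dataset: TraitDataset,
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K with a tip-label permutation test.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected-under-BM, where MSE0 uses
    the phylogenetically corrected mean and MSE the BM covariance; the
    expectation is (tr V - n / sum(V^-1)) / (n - 1). Measurement error is
    not folded into the covariance (standard formulation). The permutation
    p-value is the proportion of tip shuffles whose variance ratio is at
    least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    y, _ = dataset.align(tree.tip_labels)
    n = tree.n_tips
    S = tree.shared_path_matrix()
    cho = cho_factor(S, lower=True, check_finite=False)
    ones = np.ones((n, 1))
    Vi1 = cho_solve(cho, ones[:, 0], check_finite=False)
    expected = (float(np.trace(S)) - n / float(Vi1.sum())) / (n - 1)
    obs = _k_ratio(y, cho, ones)
    k = obs / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _k_ratio(rng.permutation(y), cho, ones) >= obs:
            hits += 1
    return KResult(k=k, p_value=(hits + 1) / (n_perm + 1), n_perm=n_perm)


# ======================================================================
# disparity through time
# ======================================================================


@dataclass
class DttCurve:
    """Relative subclade disparity against relative time (root = 0).

    ``times`` are relative node ages in [0, 1] scaled root -> youngest tip,
    starting at 0 where the observed value is 1 (whole-clade disparity,
    normalized). ``sims`` holds one BM-simulated curve per row on the same
    grid; ``median`` is their pointwise median.
    """

    times: np.ndarray
    observed: np.ndarray
    sims: np.ndarray
    median: np.ndarray

    def envelope(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(self.sims, (1 - level) / 2, axis=0)
        hi = np.quantile(self.sims, 1 - (1 - level) / 2, axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.envelope()
        return pd.DataFrame(
            {
                "rel_time": self.times,
                "observed": self.observed,
                "sim_median": self.median,
                "sim_q05": lo,
                "sim_q95": hi,
            }
        )


def _disparity(x: np.ndarray) -> float:
    """Average squared pairwise distance, each unordered pair counted once.

    For a 1-D trait this equals twice the sample variance.
    """
    n = len(x)
    if n < 2:
        return 0.0
    return 2.0 * float(np.var(x, ddof=1))


def _subclade_disparities(tree: TimeTree, values: dict[str, float]):
    """Disparity of the clade under every node, plus node depths."""
    t = tree._tree
    stats_: dict = {}
    disp: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            v = values[node.taxon.label]
            stats_[node] = (1, v, v * v)
            disp[node] = 0.0
        else:
            cnt = s = ss = 0.0
            for ch in node.child_nodes():
                c, s1, ss1 = stats_.pop(ch)
                cnt += c
                s += s1
                ss += ss1
            stats_[node] = (cnt, s, ss)
            if cnt > 1:
                var = (ss - s * s / cnt) / (cnt - 1)
                disp[node] = 2.0 * max(var, 0.0)
            else:
                disp[node] = 0.0
    return disp


def _dtt_grid(tree: TimeTree):
    """Precompute the DTT evaluation grid for a tree.

    Returns (relative times, crossing node lists): one entry per retained
    internal-node depth (root first), where each crossing list holds the
    nodes whose stem edge spans just below that depth. Reused across the
    many simulated datasets evaluated on the same tree.
    """
    t = tree._tree
    depths = tree._depths
    span = max(depths[lf] for lf in t.leaf_node_iter())
    internals = sorted(
        (nd for nd in t.preorder_node_iter() if not nd.is_leaf()),
        key=lambda nd: depths[nd],
    )
    non_root = [nd for nd in t.preorder_node_iter() if nd.parent_node is not None]
    eps = 1e-12
    times = [0.0]
    crossing_lists: list[list] = [[t.seed_node]]
    for nd in internals[1:]:
        h = depths[nd]
        if abs(h / span - times[-1]) < 1e-12:  # coincident node ages
            continue
        crossing_lists.append(
            [w for w in non_root if depths[w.parent_node] <= h + eps < depths[w]]
        )
        times.append(h / span)
    return np.asarray(times), crossing_lists


def dtt_curve_values(tree: TimeTree, values: dict[str, float], grid=None):
    """Observed relative-disparity step curve on the internal-node age grid.

    Returns (relative times, values). The first point is (0, 1); each later
    point sits at an internal node's depth and holds the mean disparity of
    the subclades whose stem crosses just below that node, divided by total
    disparity. ``grid`` accepts a precomputed :func:`_dtt_grid` result.
    """
    if grid is None:
        grid = _dtt_grid(tree)
    times, crossing_lists = grid
    disp = _subclade_disparities(tree, values)
    total = disp[tree._tree.seed_node]
    vals = np.empty(len(times))
    vals[0] = 1.0
    for i in range(1, len(times)):
        crossing = crossing_lists[i]
        if total > 0 and crossing:
            vals[i] = float(np.mean([disp[w] for w in crossing])) / total
        else:
            vals[i] = 0.0
    return times, vals


def _step_integral(times: np.ndarray, vals: np.ndarray, lo: float, hi: float) -> float:
    """Integral of the left-continuous step function over [lo, hi] in [0,1]."""
    edges = np.concatenate([times, [1.0]])
    total = 0.0
    for k in range(len(vals)):
        a, b = max(edges[k], lo), min(edges[k + 1], hi)
        if b > a:
            total += vals[k] * (b - a)
    return total


def dtt_mdi(
    tree: TimeTree,
    dataset: TraitDataset,
    *,
    nsim: int = 1000,
    window: tuple[float, float] | None = None,
    seed: int = 0,
    two_sided: bool = False,
) -> tuple[DttCurve, float, float]:
    """Disparity through time with the MDI statistic and a simulation test.

    BM parameters are first estimated from the data (with the dataset's SE
    structure); ``nsim`` BM datasets are then simulated on the same tree
    (with matching measurement noise) and their DTT curves form the null
    envelope. MDI is the signed area between the observed curve and the
    simulation median — over the whole curve, or over an age ``window``
    (Ma, (younger, older)) mapped to relative time. The p-value is the
    proportion of simulated curves whose (windowed) MDI is at least the
    observed one (one-sided, excess disparity), doubled and capped at 1
    when ``two_sided``.
    """
    from .synthetic_data import sim_traits  # deferred: avoids an import cycle

    if nsim < 2:
        raise ValueError("nsim must be >= 2")
    span = tree.root_age - min(tree.tip_ages.values())
    if window is not None:
        young, old = sorted(float(w) for w in window)
        if old > tree.root_age + 1e-9 or young < min(tree.tip_ages.values()) - 1e-9:
            raise ValueError("window outside the tree's age span")
        # ages -> relative root-to-present time
        lo_rel = (tree.root_age - old) / span
        hi_rel = (tree.root_age - young) / span
    else:
        lo_rel, hi_rel = 0.0, 1.0

    y, se = dataset.align(tree.tip_labels)
    grid = _dtt_grid(tree)
    times, observed = dtt_curve_values(tree, dict(zip(tree.tip_labels, y)), grid)
    if _disparity(y) == 0.0:
        # no trait variation at all: every subclade disparity is zero
        warnings.warn("observed disparity is zero; MDI is trivially 0")
        curve = DttCurve(times=times, observed=observed,
                         sims=np.zeros((nsim, len(times))),
                         median=np.zeros(len(times)))
        return curve, 0.0, 1.0

    fit = fit_model(tree, dataset, "BM", seed=seed, diagnostics=False)
    rng = np.random.default_rng(seed)
    sims = np.empty((nsim, len(times)))
    for b in range(nsim):
        yb = sim_traits(
            tree,
            "BM",
            {"sigma2": fit.sigma2, "theta": fit.theta},
            seed=int(rng.integers(2**31 - 1)),
        ).to_numpy()
        yb = yb + rng.normal(0.0, se)
        _, sims[b] = dtt_curve_values(tree, dict(zip(tree.tip_labels, yb)), grid)
    med = np.median(sims, axis=0)

    mdi = _step_integral(times, observed - med, lo_rel, hi_rel)
    sim_mdi = np.array(
        [_step_integral(times, sims[b] - med, lo_rel, hi_rel) for b in range(nsim)]
    )
    p = float(np.mean(sim_mdi >= mdi))
    if two_sided:
        p = min(1.0, 2.0 * min(p, float(np.mean(sim_mdi <= mdi))))
    curve = DttCurve(times=times, observed=observed, sims=sims, median=med)
    return curve, float(mdi), p


# ======================================================================
# BM quantile envelope (tip values vs tip age)
# ======================================================================


def bm_envelope(
    tree: TimeTree,
    theta: float,
    sigma2: float,
    *,
    nsim: int = 1000,
    quantiles: tuple[float, ...] = (0.80, 0.90, 0.95),
    seed: int = 0,
) -> pd.DataFrame:
    """Central quantile bands of BM-simulated tip values, per tip.

    Simulates trait values at every tip ``nsim`` times under BM(theta,
    sigma2) and reports, for each tip (indexed by its occurrence age), the
    central bands at the requested coverage levels — the construction behind
    fossil-versus-simulation body-size envelopes.
    """
    from .synthetic_data import sim_traits

    if nsim < 2:
        raise ValueError("nsim must be >= 2")
    rng = np.random.default_rng(seed)
    draws = np.empty((nsim, tree.n_tips))
    for b in range(nsim):
        draws[b] = sim_traits(
            tree, "BM", {"sigma2": sigma2, "theta": theta},
            seed=int(rng.integers(2**31 - 1)),
        ).to_numpy()
    out = {
        "species": list(tree.tip_labels),
        "age_Ma": tree.tip_age_array(),
    }
    for q in quantiles:
        lo, hi = (1 - q) / 2, 1 - (1 - q) / 2
        out[f"q{int(round(q * 100))}_lo"] = np.quantile(draws, lo, axis=0)
        out[f"q{int(round(q * 100))}_hi"] = np.quantile(draws, hi, axis=0)
    return pd.DataFrame(out)
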