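"""Presence-only species distribution modelling.

A maximum-entropy-style penalized log-linear model relates presence records
to environmental covariates against a background sample of the landscape.
The model density over background cells is p(i) ∝ exp(β·f_i); β maximizes

    mean_presence(β·f) − log Σ_background exp(β·f) − λ‖β‖₁

which is the standard presence/background (inhomogeneous-Poisson) maxent
objective. Sampling bias in the occurrence records is handled by weighting
the background sample with a quartic-kernel density of the occurrences, so
the fitted ratio cancels the observation effort.

Feature classes are linear + quadratic (optionally pairwise products) on
background-standardized variables; the exact hinge/threshold feature set of
MaxEnt 3.3.3 and its path-dependent percent-contribution bookkeeping are
deliberately not reproduced (permutation importance is the documented
substitute).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid import Grid, RasterLayer
from .io import OccurrenceSet
from .synthetic import EnvStack, quartic_kernel_weights

log = logging.getLogger("stepwise_impact")

__all__ = [
    "BiasGrid",
    "SDMModel",
    "SDMEnsemble",
    "SuitabilityResult",
    "build_bias_grid",
    "sample_background",
    "FeatureBuilder",
    "fit_maxent",
    "compute_auc",
    "mtp_threshold",
    "run_ensemble",
    "predict_and_binarize",
    "variable_importance",
]


# --------------------------------------------------------------------------- bias

@dataclass
class BiasGrid:
    """Relative sampling-effort surface in (0, 1], max exactly 1."""

    layer: RasterLayer
    bandwidth: float
    floor_eps: float = 1e-3


def default_bandwidth(occ: OccurrenceSet) -> float:
    """2× mean nearest-neighbour distance among occurrences."""
    pts = occ.points
    if len(pts) < 2:
        raise ValueError("need >= 2 occurrences for the default bandwidth")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    return 2.0 * float(np.sqrt(d2.min(axis=1)).mean())


def build_bias_grid(occ: OccurrenceSet, grid: Grid, bandwidth: float | None = None,
                    floor_eps: float = 1e-3) -> BiasGrid:
    """Quartic (biweight) kernel density of the occurrences, rescaled to a
    maximum of 1 and floored at ``floor_eps``."""
    if len(occ) < 1:
        raise ValueError("need at least one occurrence")
    if bandwidth is None:
        bandwidth = default_bandwidth(occ)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    dens = quartic_kernel_weights(grid, [tuple(p) for p in occ.points], bandwidth)
    m = dens.max()
    if m > 0:
        dens = dens / m
    vals = np.maximum(dens, floor_eps)
    layer = RasterLayer(grid=grid, values=vals, name="bias", units="relative effort")
    return BiasGrid(layer=layer, bandwidth=bandwidth, floor_eps=floor_eps)


def sample_background(grid: Grid, bias: BiasGrid | None, n: int, seed: int,
                      valid_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw `n` background cells without replacement, probability ∝ bias.

    Returns (rows, cols). A None bias means uniform sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.ones(grid.shape) if bias is None else bias.layer.values.copy()
    if valid_mask is not None:
        w = w * valid_mask
    valid_n = int((w > 0).sum())
    if n > valid_n:
        raise ValueError(f"requested {n} background cells but only {valid_n} valid cells")
    rng = np.random.default_rng(seed)
    flat = w.ravel()
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    return np.unravel_index(idx, grid.shape)


# --------------------------------------------------------------------------- features

class FeatureBuilder:
    """Build standardized linear/quadratic/product features.

    Standardization constants (mean, sd) are computed on the background cells
    only; quadratic and product columns are formed from the standardized
    linear columns. Zero-variance variables are dropped with a warning.
    """

    def __init__(self, env: EnvStack, background_cells: tuple[np.ndarray, np.ndarray],
                 quadratic: bool = True, products: bool = False,
                 variables: tuple[str, ...] | None = None):
        self.env = env
        self.variables = tuple(variables) if variables is not None else tuple(env.layers)
        bg = np.stack([env[v].values[background_cells] for v in self.variables], axis=1)
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0)
        keep = sd > 0
        for v, k in zip(self.variables, keep):
            if not k:
                log.warning("FeatureBuilder: dropping zero-variance variable %r", v)
        self.variables = tuple(v for v, k in zip(self.variables, keep) if k)
        self.mu = mu[keep]
        self.sd = sd[keep]
        self.quadratic = quadratic
        self.products = products
        self.feature_names: list[str] = list(self.variables)
        if quadratic:
            self.feature_names += [f"{v}^2" for v in self.variables]
        if products:
            for i in range(len(self.variables)):
                for j in range(i + 1, len(self.variables)):
                    self.feature_names.append(f"{self.variables[i]}*{self.variables[j]}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, cells: tuple[np.ndarray, np.ndarray],
                  override_values: dict[str, np.ndarray] | None = None) -> np.ndarray:
        cols = []
        for v in self.variables:
            if override_values is not None and v in override_values:
                raw = override_values[v]
            else:
                raw = self.env[v].values[cells]
            cols.append(raw)
        z = (np.stack(cols, axis=1) - self.mu) / self.sd
        feats = [z]
        if self.quadratic:
            feats.append(z**2)
        if self.products:
            prods = [z[:, i] * z[:, j]
                     for i in range(z.shape[1]) for j in range(i + 1, z.shape[1])]
            if prods:
                feats.append(np.stack(prods, axis=1))
        return np.concatenate(feats, axis=1)


# --------------------------------------------------------------------------- model

@dataclass
class SDMModel:
    beta: np.ndarray
    feature_names: list[str]
    reg_lambda: float
    entropy_H: float
    log_z: float          # log Σ_background exp(β·f), for raw-output normalization
    converged: bool = True
    n_iter: int = 0

    def raw(self, features: np.ndarray) -> np.ndarray:
        """Raw maxent output exp(β·f)/Z; sums to 1 over the background."""
        return np.exp(features @ self.beta - self.log_z)

    def logistic(self, features: np.ndarray) -> np.ndarray:
        """Logistic output in (0, 1): e^H·raw/(1 + e^H·raw)."""
        s = np.exp(self.entropy_H + features @ self.beta - self.log_z)
        return s / (1.0 + s)


class ConvergenceError(RuntimeError):
    pass


def fit_maxent(presence_features: np.ndarray, background_features: np.ndarray,
               reg_lambda: float = 0.01, feature_names: list[str] | None = None,
               max_iter: int = 500, tol: float = 1e-8) -> SDMModel:
    """Fit the L1-penalized presence/background log-linear model.

    The non-smooth ‖β‖₁ penalty is handled exactly by the split
    β = u − v (u, v ≥ 0), which turns the objective into a smooth bound-
    constrained problem solved with L-BFGS-B.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    n_p, k = P.shape
    if n_p < 5:
        raise ValueError(f"need >= 5 presences (got {n_p})")
    if B.shape[0] < 10 * n_p:
        log.info("fit_maxent: background (%d) is < 10x presences (%d)", B.shape[0], n_p)
    pbar = P.mean(axis=0)

    def objective(uv: np.ndarray) -> tuple[float, np.ndarray]:
        beta = uv[:k] - uv[k:]
        eta = B @ beta
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        # negative penalized log-likelihood
        nll = -(pbar @ beta) + lz + reg_lambda * uv.sum()
        g_beta = -pbar + B.T @ w
        grad = np.concatenate([g_beta + reg_lambda, -g_beta + reg_lambda])
        return nll, grad

    x0 = np.zeros(2 * k)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * k),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise ConvergenceError(f"maxent fit failed: {res.message}")
    beta = res.x[:k] - res.x[k:]
    eta_b = B @ beta
    log_z = float(logsumexp(eta_b))
    p_bg = np.exp(eta_b - log_z)
    entropy_H = float(-(p_bg * np.log(np.clip(p_bg, 1e-300, None))).sum())
    return SDMModel(
        beta=beta,
        feature_names=feature_names or [f"f{i}" for i in range(k)],
        reg_lambda=reg_lambda,
        entropy_H=entropy_H,
        log_z=log_z,
        converged=bool(res.success or res.status == 1),
        n_iter=int(res.nit),
    )


def compute_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Mann–Whitney AUC: P(presence score > background score), ties ½."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    from scipy.stats import rankdata

    combined = np.concatenate([sp, sb])
    ranks = rankdata(combined)
    r_p = ranks[: sp.size].sum()
    u = r_p - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def mtp_threshold(training_presence_scores: np.ndarray, percentile: float = 10.0) -> float:
    """Nearest-rank minimum-training-presence percentile threshold.

    Returns the ⌈(percentile/100)·n⌉-th smallest training presence score.
    """
    s = np.sort(np.asarray(training_presence_scores, dtype=float))
    if s.size == 0:
        raise ValueError("need at least one training presence score")
    rank = int(np.ceil(percentile / 100.0 * s.size))
    rank = max(rank, 1)
    return float(s[rank - 1])


# --------------------------------------------------------------------------- ensemble

@dataclass
class SDMRun:
    model: SDMModel
    train_indices: np.ndarray
    test_indices: np.ndarray
    test_auc: float
    mtp10_threshold: float


@dataclass
class SDMEnsemble:
    runs: list[SDMRun]
    features: FeatureBuilder
    background_cells: tuple[np.ndarray, np.ndarray]
    n_runs: int
    train_fraction: float
    failed_runs: int = 0
    reg_lambda: float = 0.01

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([r.test_auc for r in self.runs]))

    @property
    def sd_test_auc(self) -> float:
        return float(np.std([r.test_auc for r in self.runs], ddof=1)) if len(self.runs) > 1 else 0.0

    @property
    def mean_threshold(self) -> float:
        return float(np.mean([r.mtp10_threshold for r in self.runs]))

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "train_fraction": self.train_fraction,
            "reg_lambda": self.reg_lambda,
            "failed_runs": self.failed_runs,
            "mean_test_auc": self.mean_test_auc,
            "sd_test_auc": self.sd_test_auc,
            "mean_threshold": self.mean_threshold,
            "feature_names": self.features.feature_names,
            "runs": [
                {
                    "test_auc": r.test_auc,
                    "mtp10_threshold": r.mtp10_threshold,
                    "beta": r.model.beta.tolist(),
                }
                for r in self.runs
            ],
        }


def run_ensemble(occ: OccurrenceSet, env: EnvStack, bias: BiasGrid | None,
                 n_runs: int = 50, train_fraction: float = 0.75, seed: int = 0,
                 reg_lambda: float = 0.01, background_size: int = 10_000,
                 quadratic: bool = True) -> SDMEnsemble:
    """Replicate train/test maxent fits on random subsamples.

    Each run trains on round(train_fraction·n) occurrences and tests on the
    remainder against a fixed bias-weighted background evaluation sample;
    per-run test AUC and the 10% minimum-training-presence threshold are
    recorded. Non-convergent runs are flagged, logged and excluded from the
    ensemble means.
    """
    n = len(occ)
    if n < 8:
        raise ValueError(f"need >= 8 occurrences (got {n})")
    grid = env.grid
    valid = env.valid_mask()
    n_bg = min(background_size, int(valid.sum()))
    rng = np.random.default_rng(seed)
    bg_cells = sample_background(grid, bias, n_bg, seed=int(rng.integers(2**31)),
                                 valid_mask=valid)
    fb = FeatureBuilder(env, bg_cells, quadratic=quadratic)
    B = fb.transform(bg_cells)
    occ_cells = occ.cells(grid)
    F_occ = fb.transform(occ_cells)

    n_train = int(round(train_fraction * n))
    runs: list[SDMRun] = []
    failed = 0
    for _ in range(n_runs):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        try:
            model = fit_maxent(F_occ[tr], B, reg_lambda=reg_lambda,
                               feature_names=fb.feature_names)
        except (ConvergenceError, ValueError) as exc:
            failed += 1
            log.warning("run_ensemble: run excluded (%s)", exc)
            continue
        test_scores = model.logistic(F_occ[te])
        bg_scores = model.logistic(B)
        auc = compute_auc(test_scores, bg_scores) if te.size else np.nan
        thr = mtp_threshold(model.logistic(F_occ[tr]))
        runs.append(SDMRun(model, tr, te, auc, thr))
    if not runs:
        raise ConvergenceError("all ensemble runs failed")
    return SDMEnsemble(runs=runs, features=fb, background_cells=bg_cells,
                       n_runs=n_runs, train_fraction=train_fraction,
                       failed_runs=failed, reg_lambda=reg_lambda)


@dataclass
class SuitabilityResult:
    suitability: RasterLayer
    suitable_mask: RasterLayer
    threshold_used: float


def predict_and_binarize(ensemble: SDMEnsemble, env: EnvStack,
                         threshold: float | None = None) -> SuitabilityResult:
    """Mean logistic suitability across runs, thresholded at the ensemble's
    mean 10% minimum-training-presence value (suitability ≥ threshold ⇒
    suitable; closed lower bound)."""
    if not ensemble.runs:
        raise ValueError("ensemble has no converged runs")
    grid = env.grid
    rows, cols = np.indices(grid.shape)
    cells = (rows.ravel(), cols.ravel())
    F = ensemble.features.transform(cells)
    acc = np.zeros(F.shape[0])
    for r in ensemble.runs:
        acc += r.model.logistic(F)
    suit = (acc / len(ensemble.runs)).reshape(grid.shape)
    nodata = ~env.valid_mask()
    suit_layer = RasterLayer(grid=grid, values=np.where(nodata, 0.0, suit),
                             nodata_mask=nodata, name="suitability", units="logistic")
    thr = ensemble.mean_threshold if threshold is None else threshold
    mask_vals = ((suit >= thr) & ~nodata).astype(float)
    mask_layer = RasterLayer(grid=grid, values=mask_vals, nodata_mask=nodata,
                             name="suitable_mask", units="boolean")
    return SuitabilityResult(suit_layer, mask_layer, thr)


# --------------------------------------------------------------------------- importance

def _training_gain(model: SDMModel, P: np.ndarray, B: np.ndarray) -> float:
    """Unregularized training gain over the uniform-background null model."""
    eta_p = P @ model.beta
    return float(eta_p.mean() - logsumexp(B @ model.beta) + np.log(B.shape[0]))


def variable_importance(ensemble: SDMEnsemble, occ: OccurrenceSet, env: EnvStack,
                        bias: BiasGrid | None, seed: int = 0,
                        n_permutations: int = 5):
    """Jackknife gains and permutation percent contributions per variable.

    gain_alone refits the model with each variable's features only;
    gain_without refits with all other variables. Percent contribution is
    permutation importance: the drop in training gain when a variable's raw
    values are permuted across presence+background cells, normalized to sum
    to 100%.
    """
    import pandas as pd

    fb = ensemble.features
    grid = env.grid
    bg_cells = ensemble.background_cells
    occ_cells = occ.cells(grid)
    B = fb.transform(bg_cells)
    P = fb.transform(occ_cells)
    full = fit_maxent(P, B, reg_lambda=ensemble.reg_lambda, feature_names=fb.feature_names)
    full_gain = _training_gain(full, P, B)

    variables = fb.variables
    rng = np.random.default_rng(seed)
    rows = []
    drops = []
    for v in variables:
        # jackknife: only-this-variable and all-but-this-variable models
        fb_alone = FeatureBuilder(env, bg_cells, quadratic=fb.quadratic, variables=(v,))
        m_alone = fit_maxent(fb_alone.transform(occ_cells), fb_alone.transform(bg_cells),
                             reg_lambda=ensemble.reg_lambda)
        gain_alone = _training_gain(m_alone, fb_alone.transform(occ_cells),
                                    fb_alone.transform(bg_cells))
        others = tuple(u for u in variables if u != v)
        if others:
            fb_wo = FeatureBuilder(env, bg_cells, quadratic=fb.quadratic, variables=others)
            m_wo = fit_maxent(fb_wo.transform(occ_cells), fb_wo.transform(bg_cells),
                              reg_lambda=ensemble.reg_lambda)
            gain_without = _training_gain(m_wo, fb_wo.transform(occ_cells),
                                          fb_wo.transform(bg_cells))
        else:
            gain_without = np.nan

        # permutation importance on the full model
        raw_p = env[v].values[occ_cells]
        raw_b = env[v].values[bg_cells]
        pooled = np.concatenate([raw_p, raw_b])
        drop_reps = []
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            P_perm = fb.transform(occ_cells, override_values={v: perm[: raw_p.size]})
            B_perm = fb.transform(bg_cells, override_values={v: perm[raw_p.size:]})
            drop_reps.append(full_gain - _training_gain(full, P_perm, B_perm))
        drop = max(float(np.mean(drop_reps)), 0.0)
        drops.append(drop)
        rows.append({"variable": v, "gain_alone": gain_alone, "gain_without": gain_without})

    total = sum(drops)
    for row, d in zip(rows, drops):
        row["percent_contribution"] = 100.0 * d / total if total > 0 else 100.0 / len(rows)
    return pd.DataFrame(rows)
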