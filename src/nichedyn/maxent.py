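"""Regularized maximum-entropy presence/background species distribution model.

The model estimates a Gibbs distribution q(x) ∝ exp(λ·f(x)) over the cells
of a study region, where f are feature transforms of the climate variables
(linear and quadratic by default, pairwise products optional) scaled to
[0, 1] over the background sample. The coefficients maximise the penalized
log-likelihood of the presence sample

    L(λ) = Σ_presences λ·f(x) − m · log Σ_background exp(λ·f(x))
           − β Σ_j s_j |λ_j|

with m the presence count and s_j the feature's standard deviation over the
presences; the single multiplier β trades goodness of fit against model
complexity (larger β, smoother model). The objective is concave, so any
local optimum is global. Reported suitability is the classic logistic
output with prevalence 0.5: with all coefficients at zero every background
cell scores exactly 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .geo import BackgroundRegion, OccurrenceSet
from .raster import ClimateStack, GridGeometry, SuitabilityMap

__all__ = [
    "FeatureSpec",
    "SDMModel",
    "EvaluationResult",
    "BinaryRangeComparison",
    "fit_maxent",
    "evaluate",
    "auc_score",
    "threshold_at_percentile",
    "project",
    "project_mean",
    "compare_binary_ranges",
    "cell_areas_km2",
]

# spherical-degree cell dimensions (km per degree)
_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320


@dataclass
class FeatureSpec:
    """Feature transforms plus the normalization fitted on training background.

    Each term is ("linear", i), ("quadratic", i) or ("product", i, j) over
    variable indices; ``lo``/``hi`` are the raw term ranges over the training
    background used to scale every feature into [0, 1].
    """

    variable_names: list[str]
    terms: list[tuple]
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def build(
        cls,
        variable_names: list[str],
        env_background: np.ndarray,
        quadratic: bool = True,
        products: bool = False,
    ) -> "FeatureSpec":
        n_vars = env_background.shape[1]
        terms: list[tuple] = [("linear", i) for i in range(n_vars)]
        if quadratic:
            terms += [("quadratic", i) for i in range(n_vars)]
        if products:
            terms += [
                ("product", i, j) for i in range(n_vars) for j in range(i + 1, n_vars)
            ]
        raw = cls._raw_terms(env_background, terms)
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        degenerate = np.flatnonzero(hi <= lo)
        if degenerate.size:
            dropped = [terms[i] for i in degenerate]
            warnings.warn(f"dropping degenerate features {dropped}")
            keep = [i for i in range(len(terms)) if i not in set(degenerate)]
            terms = [terms[i] for i in keep]
            lo, hi = lo[keep], hi[keep]
        if not terms:
            raise ValueError("no non-degenerate features")
        return cls(variable_names=list(variable_names), terms=terms, lo=lo, hi=hi)

    @staticmethod
    def _raw_terms(env: np.ndarray, terms: list[tuple]) -> np.ndarray:
        cols = []
        for t in terms:
            if t[0] == "linear":
                cols.append(env[:, t[1]])
            elif t[0] == "quadratic":
                cols.append(env[:, t[1]] ** 2)
            elif t[0] == "product":
                cols.append(env[:, t[1]] * env[:, t[2]])
            else:
                raise ValueError(f"unknown feature kind {t[0]!r}")
        return np.column_stack(cols)

    def transform(self, env: np.ndarray) -> np.ndarray:
        """Scaled feature matrix; training normalization, no clamping."""
        raw = self._raw_terms(np.asarray(env, dtype=float), self.terms)
        return (raw - self.lo) / (self.hi - self.lo)

    @property
    def n_features(self) -> int:
        return len(self.terms)


@dataclass
class SDMModel:
    """A fitted maxent model plus everything needed to project it."""

    feature_spec: FeatureSpec
    lambdas: np.ndarray
    beta: float
    log_partition: float      # log sum over training background of exp(λ·f)
    entropy: float            # entropy of the Gibbs distribution on that background
    env_range_lo: np.ndarray  # per-variable training background range
    env_range_hi: np.ndarray
    seed: int | None = None
    train_fraction: float = 0.75
    n_replicates: int = 1
    auc_train: float | None = None
    auc_test: float | None = None
    threshold: float | None = None
    converged: bool = True
    objective: float = field(default=np.nan)

    def gibbs_log_density(self, env: np.ndarray) -> np.ndarray:
        """log q(x) relative to the training background partition function."""
        f = self.feature_spec.transform(env)
        return f @ self.lambdas - self.log_partition

    def suitability(self, env: np.ndarray) -> np.ndarray:
        """Logistic output in (0, 1); 0.5 at a typical background cell."""
        log_q = self.gibbs_log_density(env)
        # logistic = q e^H / (1 + q e^H); computed in log space for stability
        x = log_q + self.entropy
        return 1.0 / (1.0 + np.exp(-x))


def fit_maxent(
    stack: ClimateStack,
    bg: BackgroundRegion,
    occ: OccurrenceSet,
    beta: float = 1.0,
    seed: int | None = None,
    quadratic: bool = True,
    products: bool = False,
    x0: np.ndarray | None = None,
    grad_tol: float = 1e-6,
    max_iter: int = 5000,
) -> SDMModel:
    """Fit the penalized maxent model on a region's presences and background.

    The L1 term is handled by splitting each coefficient into a positive and
    a negative part, giving a smooth bound-constrained concave problem solved
    with L-BFGS-B to projected-gradient tolerance ``grad_tol``. ``x0`` sets
    the optimizer start (zeros by default) — any start must reach the same
    objective, the problem being concave.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if len(occ) < 10:
        raise ValueError("need at least 10 presences")
    env_bg = stack.env_at_points(bg.lon, bg.lat)
    env_pres = stack.env_at_points(occ.lon, occ.lat)
    spec = FeatureSpec.build(
        stack.layer_names, env_bg, quadratic=quadratic, products=products
    )
    f_bg = spec.transform(env_bg)
    f_pres = spec.transform(env_pres)
    m, n_feat = f_pres.shape

    s = f_pres.std(axis=0)
    s = np.maximum(s, 1e-3)  # keep every feature regularized
    pres_sum = f_pres.sum(axis=0)

    def neg_obj_grad(uv: np.ndarray):
        lam = uv[:n_feat] - uv[n_feat:]
        eta = f_bg @ lam
        log_z = logsumexp(eta)
        ll = float(pres_sum @ lam) - m * log_z
        penalty = beta * float(s @ (uv[:n_feat] + uv[n_feat:]))
        q = np.exp(eta - log_z)
        g_lam = pres_sum - m * (f_bg.T @ q)
        grad = np.concatenate([-g_lam + beta * s, g_lam + beta * s])
        return -(ll - penalty), grad

    if x0 is None:
        uv0 = np.zeros(2 * n_feat)
    else:
        x0 = np.asarray(x0, dtype=float)
        uv0 = np.concatenate([np.clip(x0, 0, None), np.clip(-x0, 0, None)])
    bounds = [(0, None)] * (2 * n_feat)
    res = None
    for _ in range(4):  # L-BFGS-B occasionally stalls on rounding; continue from x
        res = minimize(
            neg_obj_grad,
            uv0 if res is None else res.x,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": grad_tol},
        )
        if res.success:
            break
    if not res.success:
        # accept a stalled solve only if it satisfies the first-order conditions
        _, grad = neg_obj_grad(res.x)
        projected = np.where(res.x > 0, grad, np.minimum(grad, 0.0))
        if np.abs(projected).max() > max(1e-4, 100 * grad_tol):
            raise RuntimeError(
                f"maxent optimizer failed: {res.message} after {res.nit} iterations; "
                f"projected gradient {np.abs(projected).max():.3g}"
            )
    lam = res.x[:n_feat] - res.x[n_feat:]

    eta_bg = f_bg @ lam
    log_z = float(logsumexp(eta_bg))
    q = np.exp(eta_bg - log_z)
    entropy = float(-(q * (eta_bg - log_z)).sum())
    return SDMModel(
        feature_spec=spec,
        lambdas=lam,
        beta=beta,
        log_partition=log_z,
        entropy=entropy,
        env_range_lo=env_bg.min(axis=0),
        env_range_hi=env_bg.max(axis=0),
        seed=seed,
        converged=bool(res.success),
        objective=-float(res.fun),
    )


def auc_score(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Probability a random positive outranks a random negative; ties count 1/2.

    Rank (Mann-Whitney) formulation of the area under the ROC curve.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    r_pos = ranks[: scores_pos.size].sum()
    n_pos, n_neg = scores_pos.size, scores_neg.size
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationResult:
    auc_train: float
    auc_test: float
    models: list[SDMModel]
    train_fraction: float
    n_replicates: int
    seed: int | None


def evaluate(
    stack: ClimateStack,
    bg: BackgroundRegion,
    occ: OccurrenceSet,
    beta: float = 1.0,
    train_fraction: float = 0.75,
    n_replicates: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> EvaluationResult:
    """Replicated split-sample evaluation.

    Each replicate draws a random 75/25 (by default) presence split, refits
    on the training part, and scores AUC of training and held-out presences
    against the background points. Returns the replicate mean AUCs along
    with the fitted replicate models (their mean projection is the ensemble
    map).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(occ)
    n_train = int(round(train_fraction * n))
    n_test = n - n_train
    if n_test < 3:
        raise ValueError("test split needs at least 3 presences")
    rng = np.random.default_rng(seed)
    env_bg = stack.env_at_points(bg.lon, bg.lat)
    auc_tr, auc_te, models = [], [], []
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        df = occ.records.iloc[perm].reset_index(drop=True)
        train = OccurrenceSet(records=df.iloc[:n_train], region_id=occ.region_id)
        test = OccurrenceSet(records=df.iloc[n_train:], region_id=occ.region_id)
        model = fit_maxent(stack, bg, train, beta=beta, **fit_kwargs)
        bg_scores = model.suitability(env_bg)
        tr_scores = model.suitability(stack.env_at_points(train.lon, train.lat))
        te_scores = model.suitability(stack.env_at_points(test.lon, test.lat))
        auc_tr.append(auc_score(tr_scores, bg_scores))
        auc_te.append(auc_score(te_scores, bg_scores))
        models.append(model)
    return EvaluationResult(
        auc_train=float(np.mean(auc_tr)),
        auc_test=float(np.mean(auc_te)),
        models=models,
        train_fraction=train_fraction,
        n_replicates=n_replicates,
        seed=seed,
    )


def threshold_at_percentile(suit_at_presences, percentile: float = 10.0) -> float:
    """Nearest-rank presence-percentile threshold.

    The value at sorted position ceil(p/100 * n): the suitability below which
    the lowest ``percentile`` percent of presence records fall. Background
    scores play no role.
    """
    vals = np.sort(np.asarray(suit_at_presences, dtype=float))
    if vals.size == 0:
        raise ValueError("need at least one presence suitability")
    k = int(np.ceil(percentile / 100.0 * vals.size))
    k = max(k, 1)
    return float(vals[k - 1])


def project(model: SDMModel, stack_target: ClimateStack) -> SuitabilityMap:
    """Score every valid cell of a (possibly different) region.

    Features use the training normalization; no re-scaling and no clamping on
    the target. Cells whose raw environment falls outside the training
    background range on any variable are flagged in the extrapolation mask
    but scored like any other.
    """
    missing = [v for v in model.feature_spec.variable_names if v not in stack_target.layers]
    if missing:
        raise ValueError(f"target stack is missing variables {missing}")
    target = stack_target.subset(model.feature_spec.variable_names)
    valid = target.valid_mask
    env = target.env_table()
    suit = np.full(target.geometry.shape, np.nan)
    suit[valid] = model.suitability(env)
    extrap = np.zeros(target.geometry.shape, dtype=bool)
    outside = (env < model.env_range_lo).any(axis=1) | (env > model.env_range_hi).any(axis=1)
    extrap[valid] = outside
    return SuitabilityMap(
        geometry=target.geometry,
        values=suit,
        nodata_mask=~valid,
        provenance="maxent projection",
        extrapolation_mask=extrap,
    )


def project_mean(models: list[SDMModel], stack_target: ClimateStack) -> SuitabilityMap:
    """Ensemble map: mean suitability across replicate fits."""
    if not models:
        raise ValueError("no models to average")
    maps = [project(m, stack_target) for m in models]
    # all replicate maps share the target's nodata cells, so a plain mean
    # keeps NaN exactly there
    vals = np.mean([m.values for m in maps], axis=0)
    extrap = np.zeros_like(maps[0].extrapolation_mask)
    for m in maps:
        extrap |= m.extrapolation_mask
    return SuitabilityMap(
        geometry=maps[0].geometry,
        values=vals,
        nodata_mask=maps[0].nodata_mask,
        provenance=f"mean of {len(models)} maxent replicates",
        extrapolation_mask=extrap,
    )


def cell_areas_km2(geometry: GridGeometry) -> np.ndarray:
    """Latitude-dependent spherical cell areas, km^2, one value per row.

    cell = (111.320 cos(lat) dlon) * (110.574 dlat) km^2 at the cell-center
    latitude.
    """
    rows = np.arange(geometry.n_rows)
    lat = geometry.origin_lat - (rows + 0.5) * geometry.cell_size
    width = _KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat)) * geometry.cell_size
    height = _KM_PER_DEG_LAT * geometry.cell_size
    return width * height


@dataclass
class BinaryRangeComparison:
    """Overlap accounting of two thresholded suitability maps (areas in km^2)."""

    area_map1_km2: float
    area_map2_km2: float
    frac_1_in_2: float
    frac_2_in_1: float
    area_only1_km2: float
    area_only2_km2: float
    area_both_km2: float


def compare_binary_ranges(
    map1: SuitabilityMap,
    map2: SuitabilityMap,
    thr1: float,
    thr2: float,
) -> BinaryRangeComparison:
    """Binarize each map at its threshold and partition the predicted ranges."""
    if not map1.geometry.approx_equal(map2.geometry):
        raise ValueError("suitability maps must share geometry")
    pres1 = (map1.values >= thr1) & ~map1.nodata_mask
    pres2 = (map2.values >= thr2) & ~map2.nodata_mask
    areas = cell_areas_km2(map1.geometry)[:, None] * np.ones(map1.geometry.shape)
    a1 = float(areas[pres1].sum())
    a2 = float(areas[pres2].sum())
    both = float(areas[pres1 & pres2].sum())
    only1 = float(areas[pres1 & ~pres2].sum())
    only2 = float(areas[pres2 & ~pres1].sum())
    return BinaryRangeComparison(
        area_map1_km2=a1,
        area_map2_km2=a2,
        frac_1_in_2=both / a1 if a1 > 0 else np.nan,
        frac_2_in_1=both / a2 if a2 > 0 else np.nan,
        area_only1_km2=only1,
        area_only2_km2=only2,
        area_both_km2=both,
    )
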