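"""Two-stage offset-corrected dementia risk models.

Stage 1 regresses dementia status on demographics alone (age, sex,
ancestry-specific PCs) by unpenalized logistic regression; its fitted linear
predictor becomes a GLM *offset* — a term entering the stage-2 linear
predictor with coefficient fixed at one — so that stage 2 measures genetic
signal net of demographics and population structure:

    yhat_i = g^-1(beta_0 + sum_j beta_j x_ij + offset_i),   g = logit.

Stage 2 is either an unpenalized logistic fit (APOE-count and PRS predictor
sets) or an elastic-net-penalized logistic regression over SNP dosages with
the offset unpenalized. The elastic-net solver is a glmnet-style IRLS +
coordinate-descent path with warm starts (numba-compiled); hyperparameters
(alpha mixing, lambda strength) are chosen by stratified k-fold
cross-validated deviance over a grid, and performance is reported on pooled
hold-out predictions. Bootstrap stability selection refits the whole
two-stage procedure on resampled subjects and retains SNPs selected in at
least a fixed fraction of iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

#: Stage-1 coefficients are capped at this magnitude under perfect separation
#: so offsets stay bounded.
STAGE1_COEF_CAP = 15.0

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))

PREDICTOR_SETS = ("apoe", "ad_prs", "multi_prs", "elasticnet_snps")


class ModelError(ValueError):
    pass


class TransferError(ModelError):
    """New-cohort features do not cover the model's nonzero coefficients."""


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean -2 log-likelihood of Bernoulli outcomes."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

@dataclass
class OffsetVector:
    """Stage-1 linear predictor per sample, with the coefficients behind it."""

    offset: np.ndarray
    stage1_coefficients: dict       # name -> beta (includes "intercept")
    covariate_names: list
    separation_flagged: bool = False


def fit_stage1(labels: np.ndarray, covariates: pd.DataFrame) -> OffsetVector:
    """Unpenalized logistic regression of case status on demographics.

    Returns the fitted linear predictor as the offset for stage 2. Under
    (quasi-)perfect separation, coefficients are capped at +/-15 with a
    warning and the offset recomputed from the capped coefficients.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ModelError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ModelError("need at least one case and one control")
    X = covariates.to_numpy(dtype=float)
    if X.size and not np.all(np.isfinite(X)):
        raise ModelError("covariates must be finite and complete")
    # constant columns are collinear with the intercept; they get beta 0
    varying = X.std(axis=0) > 0 if X.size else np.zeros(0, dtype=bool)
    Xc = sm.add_constant(X[:, varying], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, tol=1e-10)
            params = np.asarray(res.params, dtype=float)
        except Exception:  # statsmodels raises on perfect separation
            params = np.full(Xc.shape[1], np.nan)
    flagged = False
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > STAGE1_COEF_CAP):
        flagged = True
        warnings.warn("stage-1 logistic shows (near-)perfect separation; "
                      f"coefficients capped at |beta| <= {STAGE1_COEF_CAP}",
                      stacklevel=2)
        if not np.all(np.isfinite(params)):
            # refit with a small ridge to get a finite direction, then cap
            res = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1e-3, L1_wt=0.0)
            params = np.asarray(res.params, dtype=float)
        params = np.clip(params, -STAGE1_COEF_CAP, STAGE1_COEF_CAP)
    offset = Xc @ params
    full = np.zeros(X.shape[1] + 1 if X.size else 1)
    full[0] = params[0]
    if X.size:
        full[1:][varying] = params[1:]
    names = ["intercept"] + list(covariates.columns)
    return OffsetVector(offset, dict(zip(names, full)),
                        list(covariates.columns), flagged)


# ---------------------------------------------------------------------------
# Elastic-net path solver (IRLS + coordinate descent, warm starts)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_path(X, Xsq, y, off, alpha, lambdas, max_irls, max_cd, tol):  # pragma: no cover
    n, p = X.shape
    b = np.zeros(p)
    b0 = 0.0
    nl = lambdas.shape[0]
    out_b = np.zeros((nl, p))
    out_b0 = np.zeros(nl)
    for il in range(nl):
        lam = lambdas[il]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_irls):
            # working weights/response at current coefficients
            eta = b0 + X @ b + off
            pr = 1.0 / (1.0 + np.exp(-eta))
            w = pr * (1.0 - pr)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            z = (eta - off) + (y - pr) / w
            v = (w @ Xsq) / n
            r = z - b0 - X @ b
            sw = w.sum()
            b_prev = b.copy()
            b0_prev = b0
            for _ in range(max_cd):
                maxdel = 0.0
                d0 = (w @ r) / sw
                b0 += d0
                r -= d0
                if abs(d0) > maxdel:
                    maxdel = abs(d0)
                for j in range(p):
                    g = (w * X[:, j]) @ r / n + v[j] * b[j]
                    if g > l1:
                        bj = (g - l1) / (v[j] + l2)
                    elif g < -l1:
                        bj = (g + l1) / (v[j] + l2)
                    else:
                        bj = 0.0
                    d = bj - b[j]
                    if d != 0.0:
                        r -= X[:, j] * d
                        b[j] = bj
                        if abs(d) > maxdel:
                            maxdel = abs(d)
                if maxdel < tol:
                    break
            chg = abs(b0 - b0_prev)
            for j in range(p):
                if abs(b[j] - b_prev[j]) > chg:
                    chg = abs(b[j] - b_prev[j])
            if chg < 10.0 * tol:
                break
        out_b[il] = b
        out_b0[il] = b0
    return out_b0, out_b


class _EnetPath:
    """Standardizing wrapper around the compiled path solver."""

    def __init__(self, X: np.ndarray, y: np.ndarray, offset: np.ndarray):
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0, ddof=0)
        self.sd[self.sd == 0] = 1.0
        self.Xs = (X - self.mu) / self.sd
        self.Xsq = self.Xs ** 2
        self.y = np.asarray(y, dtype=float)
        self.offset = np.asarray(offset, dtype=float)

    def lambda_max(self, alpha: float) -> float:
        # gradient at the intercept-only fit with offset
        b0 = _intercept_only(self.y, self.offset)
        p0 = _sigmoid(b0 + self.offset)
        g = np.abs(self.Xs.T @ (self.y - p0)) / len(self.y)
        return float(g.max() / max(alpha, 1e-3))

    def lambdas(self, alpha: float, n_lambda: int,
                lambda_min_ratio: float) -> np.ndarray:
        lmax = self.lambda_max(alpha)
        if lmax <= 0:
            lmax = 1e-3
        return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    def fit(self, alpha: float, lambdas: np.ndarray,
            tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient path on the ORIGINAL feature scale.

        Returns (intercepts, coefs) with shapes (L,), (L, p).
        """
        b0s, bs = _cd_path(self.Xs, self.Xsq, self.y, self.offset,
                           float(alpha), np.asarray(lambdas, dtype=float),
                           100, 200, tol)
        coefs = bs / self.sd
        intercepts = b0s - coefs @ self.mu
        return intercepts, coefs


def _intercept_only(y: np.ndarray, offset: np.ndarray) -> float:
    b0 = 0.0
    for _ in range(50):
        p = _sigmoid(b0 + offset)
        g = np.sum(y - p)
        h = np.sum(p * (1 - p))
        step = g / max(h, 1e-12)
        b0 += step
        if abs(step) < 1e-12:
            break
    return b0


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------

@dataclass
class FittedRiskModel:
    predictor_set: str
    coefficients: dict              # name -> beta, includes "intercept"
    alpha: float | None
    lambda_: float | None
    feature_names: list
    link: str = "logit"
    training_metadata: dict = field(default_factory=dict)
    cv_predictions: np.ndarray | None = None   # pooled hold-out yhat
    cv_fold: np.ndarray | None = None
    cv_results: pd.DataFrame | None = None     # alpha, lambda, mean deviance

    def __post_init__(self):
        vals = np.array(list(self.coefficients.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ModelError("coefficients must be finite")
        if self.alpha is not None and not 0 <= self.alpha <= 1:
            raise ModelError("alpha must lie in [0, 1]")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ModelError("lambda must be nonnegative")

    @property
    def nonzero_features(self) -> list:
        return [n for n in self.feature_names if self.coefficients[n] != 0.0]

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.nonzero_features if n not in features.columns]
        if missing:
            raise TransferError(f"missing required features: {missing}")
        eta = np.full(len(features), self.coefficients["intercept"])
        for name in self.feature_names:
            if name in features.columns and self.coefficients[name] != 0.0:
                eta = eta + self.coefficients[name] * \
                    features[name].to_numpy(dtype=float)
        return eta

    def predict_proba(self, features: pd.DataFrame,
                      offset: np.ndarray) -> np.ndarray:
        return _sigmoid(self.linear_predictor(features) + np.asarray(offset))


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment balanced by case status, deterministic under seed."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _prepare_features(genetic_features: pd.DataFrame):
    X = genetic_features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ModelError("genetic features must be finite")
    names = list(genetic_features.columns)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping all-constant feature columns: {dropped}",
                      stacklevel=3)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names


def _irls_unpenalized(X, y, offset) -> tuple[float, np.ndarray]:
    """Maximum-likelihood logistic fit with offset (lambda = 0 limit)."""
    path = _EnetPath(X, y, offset)
    b0s, bs = path.fit(1.0, np.array([1e-10]), tol=1e-10)
    return float(b0s[0]), bs[0]


def _grid_cv(X, y, off, fold, alpha_grid, n_lambda, lambda_min_ratio,
             n_folds):
    """k-fold CV deviance over the (alpha, lambda) grid.

    Returns the minimizing alpha and lambda (ties: larger lambda, then
    larger alpha), the warm-start path truncated at the chosen lambda, and
    the full grid of mean deviances.
    """
    full = _EnetPath(X, y, off)
    cv_rows = []
    best = None
    for a in alpha_grid:
        lambdas = full.lambdas(a, n_lambda, lambda_min_ratio)
        dev = np.zeros(len(lambdas))
        for f in range(n_folds):
            tr, te = fold != f, fold == f
            p_tr = _EnetPath(X[tr], y[tr], off[tr])
            b0s, bs = p_tr.fit(a, lambdas)
            eta = b0s[:, None] + bs @ X[te].T + off[te][None, :]
            pr = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
            dev += -2.0 * np.mean(y[te] * np.log(pr)
                                  + (1 - y[te]) * np.log(1 - pr), axis=1)
        dev /= n_folds
        for l_, d in zip(lambdas, dev):
            cv_rows.append((a, l_, d))
        j = int(np.argmin(dev))  # first (= largest lambda) at ties
        if best is None or dev[j] < best[0] - 1e-12 or \
           (abs(dev[j] - best[0]) <= 1e-12 and a > best[1]):
            best = (dev[j], a, lambdas[j], lambdas)
    _, alpha, lam, chosen = best
    path_to_lam = chosen[chosen >= lam * (1 - 1e-12)]
    return alpha, lam, path_to_lam, cv_rows


def fit_stage2(labels: np.ndarray, genetic_features: pd.DataFrame,
               offset: OffsetVector, predictor_set: str = "elasticnet_snps",
               alpha_grid=DEFAULT_ALPHA_GRID, n_folds: int = 5,
               n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
               penalize: bool | None = None, seed: int = 0) -> FittedRiskModel:
    """Fit the stage-2 genetic model on top of the demographic offset.

    For penalized fits, (alpha, lambda) are chosen by stratified
    ``n_folds``-fold cross-validated deviance over ``alpha_grid`` x a
    log-spaced lambda path (ties: larger lambda, then larger alpha); final
    coefficients are refit on all samples at the chosen pair. Pooled
    hold-out predictions (one per sample, from the fold in which it was held
    out, refit at the chosen hyperparameters) are stored for evaluation.
    Deterministic under fixed seed.
    """
    if predictor_set not in PREDICTOR_SETS:
        raise ModelError(f"unknown predictor set {predictor_set!r}")
    if penalize is None:
        penalize = predictor_set == "elasticnet_snps"
    y = np.asarray(labels, dtype=float)
    off = np.asarray(offset.offset, dtype=float)
    if len(y) != len(genetic_features) or len(y) != len(off):
        raise ModelError("labels, features and offset must be aligned")
    X, names = _prepare_features(genetic_features)
    fold = stratified_folds(y, n_folds, seed)

    alpha = lam = None
    cv_rows = []
    if penalize:
        # full-sample CV picks the reported hyperparameters and coefficients
        alpha, lam, path_to_lam, cv_rows = _grid_cv(
            X, y, off, fold, alpha_grid, n_lambda, lambda_min_ratio, n_folds)
        b0s, bs = _EnetPath(X, y, off).fit(alpha, path_to_lam)
        b0, b = float(b0s[-1]), bs[-1]
    else:
        b0, b = _irls_unpenalized(X, y, off)

    # pooled hold-out predictions; hyperparameters re-chosen by inner CV on
    # the training folds only, so hold-out samples never inform selection
    yhat = np.empty(len(y))
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if penalize:
            inner_fold = stratified_folds(y[tr], n_folds, seed + 1 + f)
            fa, _, fpath, _ = _grid_cv(X[tr], y[tr], off[tr], inner_fold,
                                       alpha_grid, n_lambda,
                                       lambda_min_ratio, n_folds)
            fb0s, fbs = _EnetPath(X[tr], y[tr], off[tr]).fit(fa, fpath)
            fb0, fb = float(fb0s[-1]), fbs[-1]
        else:
            fb0, fb = _irls_unpenalized(X[tr], y[tr], off[tr])
        yhat[te] = _sigmoid(fb0 + X[te] @ fb + off[te])

    coefs = {"intercept": b0}
    coefs.update({n: float(v) for n, v in zip(names, b)})
    cv_results = pd.DataFrame(cv_rows, columns=["alpha", "lambda",
                                                "mean_deviance"]) \
        if cv_rows else None
    return FittedRiskModel(
        predictor_set=predictor_set, coefficients=coefs, alpha=alpha,
        lambda_=lam, feature_names=names,
        training_metadata={"n_folds": n_folds, "seed": seed,
                           "n": len(y), "penalized": penalize},
        cv_predictions=yhat, cv_fold=fold, cv_results=cv_results)


# ---------------------------------------------------------------------------
# Importance and bootstrap stability selection
# ---------------------------------------------------------------------------

def importance(model: FittedRiskModel, feature_sds: dict) -> dict:
    """|beta_j| * sd_j normalized to sum 1 over nonzero features.

    Scale-invariant: rescaling a feature rescales its coefficient inversely
    at refit, leaving the product unchanged. Returns {} when all
    coefficients are zero.
    """
    raw = {n: abs(model.coefficients[n]) * float(feature_sds[n])
           for n in model.nonzero_features}
    total = sum(raw.values())
    if total == 0:
        return {}
    return {n: v / total for n, v in raw.items()}


@dataclass
class StabilityReport:
    """Per-SNP bootstrap selection frequencies and importance CIs."""

    table: pd.DataFrame     # feature, selection_frequency, importance, lo, hi, retained
    n_boot: int
    retention: float
    n_redrawn: int = 0

    @property
    def retained(self) -> list:
        return self.table.loc[self.table.retained, "feature"].tolist()


def bootstrap_stability(labels: np.ndarray, genetic_features: pd.DataFrame,
                        covariates: pd.DataFrame, n_boot: int = 1000,
                        retention: float = 0.95, seed: int = 0,
                        alpha: float = 0.5, lambda_: float | None = None,
                        refit_hyperparams: str = "lambda",
                        n_folds: int = 5, n_lambda: int = 50,
                        lambda_min_ratio: float = 1e-3) -> StabilityReport:
    """Bootstrap stability selection over the full two-stage procedure.

    Each iteration resamples subjects with replacement (single-class
    resamples are redrawn and logged), refits stage 1 on the resampled
    demographics and an elastic-net stage 2 on the resampled SNPs, and
    records the nonzero-coefficient set and normalized importances.
    ``refit_hyperparams`` is ``"lambda"`` (re-choose lambda by CV each
    iteration, alpha frozen — the default) or ``"none"`` (reuse the supplied
    ``lambda_``). Features selected in at least ``retention`` of iterations
    are retained; their reported importances are renormalized to sum to 1.
    CIs are 2.5/97.5 percentiles of per-iteration importances.
    """
    if n_boot < 1:
        raise ModelError("n_boot must be >= 1")
    if refit_hyperparams not in ("lambda", "none"):
        raise ModelError("refit_hyperparams must be 'lambda' or 'none'")
    if refit_hyperparams == "none" and lambda_ is None:
        raise ModelError("lambda_ required when refit_hyperparams='none'")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    feat_names = list(genetic_features.columns)
    sel = np.zeros((n_boot, len(feat_names)))
    imp = np.zeros((n_boot, len(feat_names)))
    n_redrawn = 0
    for it in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
            n_redrawn += 1
            logger.info("bootstrap iteration %d: single-class resample redrawn",
                        it)
        yb = y[idx]
        off = fit_stage1(yb, covariates.iloc[idx])
        gb = genetic_features.iloc[idx].reset_index(drop=True)
        if refit_hyperparams == "lambda":
            model = fit_stage2(yb, gb, off, alpha_grid=(alpha,),
                               n_folds=n_folds, n_lambda=n_lambda,
                               lambda_min_ratio=lambda_min_ratio,
                               seed=int(rng.integers(0, 2**31 - 1)))
        else:
            Xb, names_b = _prepare_features(gb)
            pth = _EnetPath(Xb, yb, off.offset)
            lambdas = pth.lambdas(alpha, n_lambda, lambda_min_ratio)
            lambdas = np.append(lambdas[lambdas > lambda_], lambda_)
            b0s, bs = pth.fit(alpha, lambdas)
            coefs = {"intercept": float(b0s[-1])}
            coefs.update({nm: float(v) for nm, v in zip(names_b, bs[-1])})
            model = FittedRiskModel("elasticnet_snps", coefs, alpha,
                                    float(lambda_), names_b)
        sds = {nm: gb[nm].std(ddof=0) for nm in model.feature_names}
        imps = importance(model, sds)
        for j, nm in enumerate(feat_names):
            if nm in imps:
                sel[it, j] = 1.0
                imp[it, j] = imps[nm]
    freq = sel.mean(axis=0)
    retained = freq >= retention
    mean_imp = imp.mean(axis=0)
    norm = mean_imp[retained].sum()
    rep_imp = np.where(retained & (norm > 0), mean_imp / (norm if norm else 1.0),
                       mean_imp)
    lo = np.percentile(imp, 2.5, axis=0)
    hi = np.percentile(imp, 97.5, axis=0)
    table = pd.DataFrame({"feature": feat_names, "selection_frequency": freq,
                          "importance": rep_imp, "ci_lo": lo, "ci_hi": hi,
                          "retained": retained})
    return StabilityReport(table, n_boot, retention, n_redrawn)


# ---------------------------------------------------------------------------
# Frozen-weight transfer
# ---------------------------------------------------------------------------

def apply_model(model: FittedRiskModel, new_labels: np.ndarray,
                new_covariates: pd.DataFrame,
                new_geno_features: pd.DataFrame) -> tuple[np.ndarray, OffsetVector]:
    """Apply frozen stage-2 genetic weights to a new cohort.

    Stage 1 is refit on the new cohort's demographics (the validation
    protocol: demographic effects are always estimated in-cohort), then the
    trained genetic coefficients are applied on top of the new offsets.
    Returns (predicted probabilities, new-cohort offset).
    """
    missing = [n for n in model.nonzero_features
               if n not in new_geno_features.columns]
    if missing:
        raise TransferError(f"missing required features: {missing}")
    stage1 = fit_stage1(new_labels, new_covariates)
    probs = model.predict_proba(new_geno_features, stage1.offset)
    return probs, stage1
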