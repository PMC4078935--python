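"""Calibration-set selection, PLS regression and validation statistics.

Implements the chemometric workflow behind NIRS trait calibration:

* representative calibration-sample selection by Kennard-Stone on PCA
  scores of the preprocessed spectra,
* centered PLS1 regression (NIPALS with deflation),
* five-group cross-validation with SECV-based choice of the number of
  latent variables,
* external validation on held-out samples (bias-corrected SEP).

Statistic conventions (the standard chemometrics usage):

* SEC  = sqrt(SSE / (n - k - 1)) on the calibration fit, k latent variables
* SECV = uncorrected root-mean-square of cross-validation residuals
* SEP  = standard deviation of external residuals about their mean
         (n - 1 denominator); the mean residual is reported as bias
* R^2  = squared Pearson correlation of fitted vs. observed on the
         calibration set
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import PreprocessRecipe


@dataclass
class CalibrationModel:
    """A fitted PLS calibration: preprocessing recipe + regression vector."""

    recipe: PreprocessRecipe
    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # trait units per absorbance, in processed-spectrum space
    training_ids: np.ndarray
    stats: "ValidationStats | None" = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.coef

    def to_dict(self) -> dict:
        return {
            "recipe": self.recipe.describe(),
            "n_latent": int(self.n_latent),
            "y_mean": float(self.y_mean),
            "x_mean": self.x_mean.tolist(),
            "coef": self.coef.tolist(),
            "training_ids": [str(t) for t in self.training_ids],
        }


@dataclass
class ValidationStats:
    """Summary statistics of a calibration or validation set."""

    n: int
    mean: float
    sd: float
    sec: float = np.nan
    secv: float = np.nan
    sep: float = np.nan
    bias: float = np.nan
    r2: float = np.nan

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n, "mean": self.mean, "sd": self.sd, "SEC": self.sec,
                "SECV": self.secv, "SEP": self.sep, "bias": self.bias, "R2": self.r2,
            }
        )


def pca_scores(X: np.ndarray, min_explained: float = 0.99) -> np.ndarray:
    """Scores on the leading principal components explaining >= min_explained
    of the variance (centered PCA via SVD)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return np.zeros((X.shape[0], 1))
    k = int(np.searchsorted(np.cumsum(var) / total, min_explained) + 1)
    return U[:, :k] * s[:k]


def kennard_stone(scores: np.ndarray, n_select: int) -> np.ndarray:
    """Kennard-Stone selection: start from the pair of most distant points,
    then repeatedly add the point farthest from the selected set (max-min).
    Deterministic; ties broken by lowest index."""
    n = scores.shape[0]
    if n_select >= n:
        return np.arange(n)
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    d2 = np.sum((scores[:, None, :] - scores[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j)]
    if n_select > 1:
        selected.append(max(i, j))
    mind = np.minimum(d2[selected[0]], d2[selected[-1]])
    while len(selected) < n_select:
        nxt = int(np.argmax(mind))
        if mind[nxt] == 0:
            # remaining candidates all duplicate a selected point
            remaining = np.setdiff1d(np.arange(n), selected)
            nxt = int(remaining[0])
        selected.append(nxt)
        mind = np.minimum(mind, d2[nxt])
    return np.array(sorted(selected))


def select_calibration_set(
    X: np.ndarray, sample_ids: np.ndarray, n_select: int, seed: int | None = None
) -> np.ndarray:
    """Select a representative calibration subset via PCA + Kennard-Stone.

    Falls back to seeded random selection (with a warning) when the spectra
    are rank-deficient to the point of carrying no variance.
    """
    sample_ids = np.asarray(sample_ids)
    if n_select >= len(sample_ids):
        return sample_ids.copy()
    scores = pca_scores(X)
    if np.allclose(scores, 0):
        import warnings

        warnings.warn("degenerate spectra: falling back to random selection")
        rng = np.random.default_rng(seed)
        return sample_ids[np.sort(rng.choice(len(sample_ids), n_select, replace=False))]
    return sample_ids[kennard_stone(scores, n_select)]


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_latent: int):
    """Centered PLS1 by NIPALS deflation; returns W, P, q (loadings)."""
    n, m = Xc.shape
    W = np.empty((m, n_latent))
    P = np.empty((m, n_latent))
    q = np.empty(n_latent)
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_latent):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"latent variable {a + 1} exceeds the informative rank of X"
            )
        w /= norm
        t = X @ w
        tt = t @ t
        p = X.T @ t / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    return W, P, q


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int,
    recipe: PreprocessRecipe | None = None,
    sample_ids=None,
) -> CalibrationModel:
    """Fit a centered PLS1 model and return the regression vector in the
    original processed-spectrum space: coef = W (P'W)^-1 q."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of samples")
    if X.shape[0] < n_latent + 2:
        raise ValueError("too few samples for the requested latent variables")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_latent)
    coef = W @ np.linalg.solve(P.T @ W, q)
    ids = np.arange(len(y)) if sample_ids is None else np.asarray(sample_ids)
    model = CalibrationModel(
        recipe=recipe or PreprocessRecipe(),
        n_latent=n_latent,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        training_ids=ids,
    )
    fitted = model.predict(X)
    resid = y - fitted
    dof = max(len(y) - n_latent - 1, 1)
    sec = float(np.sqrt(np.sum(resid**2) / dof))
    r2 = _r2(fitted, y)
    model.stats = ValidationStats(
        n=len(y), mean=float(y_mean), sd=float(np.std(y, ddof=1)), sec=sec, r2=r2
    )
    return model


def _r2(pred, obs) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_latent_grid,
    n_groups: int = 5,
    seed: int | None = 0,
    parsimony: bool = True,
):
    """Grouped cross-validation over a grid of latent-variable counts.

    Samples are shuffled once (seeded) and split into ``n_groups``
    contiguous blocks; each block is predicted from a model fitted on the
    others. Returns ``(best_n_latent, secv_best, table)`` where the table
    maps each candidate to its SECV. The winner minimizes SECV, with a
    one-standard-error parsimony rule favouring fewer latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_groups:
        raise ValueError("fewer samples than cross-validation groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_groups)
    if min(len(f) for f in folds) < 1:
        raise ValueError("cross-validation group with no samples")
    grid = sorted(set(int(k) for k in np.atleast_1d(n_latent_grid)))
    table = {}
    se_table = {}
    for k in grid:
        sq = np.empty(n)
        ok = True
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            if mask.sum() < k + 2:
                ok = False
                break
            try:
                model = pls_fit(X[mask], y[mask], k)
            except ValueError:
                ok = False
                break
            sq[fold] = (y[fold] - model.predict(X[fold])) ** 2
        if not ok:
            continue
        table[k] = float(np.sqrt(sq.mean()))
        se_table[k] = float(np.std(sq, ddof=1) / np.sqrt(n) / (2 * table[k] + 1e-300))
    if not table:
        raise ValueError("no latent-variable count could be cross-validated")
    best = min(table, key=table.get)
    if parsimony:
        threshold = table[best] + se_table[best]
        best = min(k for k, v in table.items() if v <= threshold)
    return best, table[best], table


def validate_external(
    model: CalibrationModel, X_ext: np.ndarray, y_ext: np.ndarray, ext_ids=None
) -> ValidationStats:
    """External validation: bias-corrected SEP on samples disjoint from the
    training set."""
    if ext_ids is not None:
        overlap = np.intersect1d(np.asarray(ext_ids), model.training_ids)
        if overlap.size:
            raise ValueError(f"validation ids overlap training set: {overlap[:5]}")
    y_ext = np.asarray(y_ext, dtype=float)
    resid = y_ext - model.predict(X_ext)
    bias = float(resid.mean())
    sep = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    return ValidationStats(
        n=len(y_ext),
        mean=float(y_ext.mean()),
        sd=float(np.std(y_ext, ddof=1)) if len(y_ext) > 1 else 0.0,
        sep=sep,
        bias=bias,
        r2=_r2(model.predict(X_ext), y_ext),
    )


def default_recipe_grid() -> list[PreprocessRecipe]:
    """The screening grid: derivative orders 0/1/2 x gap-and-smoothing
    points 0/5/10/15/20 x scatter treatments (none, SNV, detrend, MSC)."""
    recipes = []
    for order in (0, 1, 2):
        points = [1] if order == 0 else [1, 5, 10, 15, 20]
        for gap in points:
            for smooth in (1, 5):
                for norm in ("none", "snv", "detrend", "msc"):
                    recipes.append(
                        PreprocessRecipe(
                            derivative_order=order,
                            derivative_gap=gap,
                            smooth_window=smooth,
                            normalization=norm,
                        )
                    )
    return recipes


def grid_search_recipes(
    recipes,
    raw_spectra,
    y_by_sample: dict,
    n_latent_grid=range(1, 11),
    n_groups: int = 5,
    seed: int = 0,
):
    """Evaluate each preprocessing recipe by SECV and return the winner.

    ``raw_spectra`` is a replicate-averaged SpectraSet; y_by_sample maps
    sample id -> trait value. Returns (best_recipe, report DataFrame).
    """
    from .spectra import apply_recipe

    rows = []
    best = None
    for recipe in recipes:
        try:
            processed = apply_recipe(raw_spectra, recipe)
        except ValueError:
            continue
        ids = processed.sample_ids
        y = np.array([y_by_sample[s] for s in ids])
        try:
            k, secv, _ = cross_validate(
                processed.values, y, n_latent_grid, n_groups=n_groups, seed=seed
            )
        except ValueError:
            continue
        rows.append(
            {"recipe": recipe.describe(), "n_latent": k, "SECV": secv}
        )
        if best is None or secv < best[1]:
            best = (recipe, secv, k)
    if best is None:
        raise ValueError("no recipe could be evaluated")
    report = pd.DataFrame(rows).sort_values("SECV").reset_index(drop=True)
    return best[0], report
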