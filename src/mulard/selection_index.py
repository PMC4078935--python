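"""Selection-index accuracy of predicting a target breeding value.

Classic index theory: given the phenotypic covariance matrix P of the
predictor traits and the vector g of covariances between each predictor
phenotype and the target breeding value, the optimal linear index uses
weights b = P^-1 g and its accuracy (correlation with the target breeding
value) is sqrt(b' g / sigma2_A) where sigma2_A is the target's additive
variance.

With a single predictor equal to the target trait's own phenotype,
g = h^2 sigma2_P and P = sigma2_P, so the accuracy reduces to h — the
square root of the heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IndexProblem:
    """Inputs of one selection-index evaluation (squared trait units)."""

    P: np.ndarray
    g: np.ndarray
    sigma2_A_target: float
    predictor_names: tuple = ()

    def __post_init__(self):
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        if self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("P must be symmetric")
        if len(self.g) != self.P.shape[0]:
            raise ValueError("g length must match P dimension")
        if self.sigma2_A_target <= 0:
            raise ValueError("target additive variance must be positive")
        if np.linalg.eigvalsh(self.P).min() <= 0:
            raise ValueError("P must be positive definite")


@dataclass
class IndexResult:
    weights: np.ndarray
    accuracy: float
    predictor_names: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        names = self.predictor_names or tuple(
            f"predictor_{i + 1}" for i in range(len(self.weights))
        )
        df = pd.DataFrame({"predictor": names, "weight": self.weights})
        df["accuracy"] = self.accuracy
        return df


def index_accuracy(problem: IndexProblem, tolerance: float = 1e-8) -> IndexResult:
    """Optimal index weights and accuracy for one :class:`IndexProblem`.

    Raises if P is singular or if the implied accuracy exceeds 1 (which
    signals inconsistent covariance inputs).
    """
    try:
        b = np.linalg.solve(problem.P, problem.g)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phenotypic covariance matrix") from exc
    quad = float(b @ problem.g)
    if quad < 0:
        raise ValueError("negative index variance: inconsistent P and g")
    acc2 = quad / problem.sigma2_A_target
    if acc2 > 1 + tolerance:
        raise ValueError(
            f"accuracy {np.sqrt(acc2):.4f} exceeds 1: inconsistent inputs"
        )
    return IndexResult(
        weights=b,
        accuracy=float(np.sqrt(min(acc2, 1.0))),
        predictor_names=problem.predictor_names,
    )


def problem_from_components(
    G_line: np.ndarray,
    R: np.ndarray,
    G_other: np.ndarray,
    target: int,
    predictors,
    use: str = "phenotypic",
) -> IndexProblem:
    """Build an index problem from crossbred model component matrices.

    The target breeding value is the ``target`` trait's transmitted effect
    of the line whose covariance matrix is ``G_line``. Predictor phenotypic
    covariances are G_line + G_other + R (``use='phenotypic'``) or G_line
    alone (``use='genetic'``, treating predictors as noise-free genetic
    values). The covariance between a predictor phenotype and the target
    effect comes from G_line in both cases.
    """
    G_line = np.atleast_2d(np.asarray(G_line, dtype=float))
    predictors = list(predictors)
    if use == "phenotypic":
        P_full = G_line + np.atleast_2d(G_other) + np.atleast_2d(R)
    elif use == "genetic":
        P_full = G_line
    else:
        raise ValueError("use must be 'phenotypic' or 'genetic'")
    idx = np.asarray(predictors, dtype=int)
    return IndexProblem(
        P=P_full[np.ix_(idx, idx)],
        g=G_line[idx, target],
        sigma2_A_target=float(G_line[target, target]),
    )


def read_triplet_matrix(path, dim: int | None = None) -> np.ndarray:
    """Read a symmetric matrix stored as row,col,value triplets (0-based)."""
    df = pd.read_csv(path)
    size = dim or int(max(df["row"].max(), df["col"].max()) + 1)
    M = np.zeros((size, size))
    for _, r in df.iterrows():
        M[int(r["row"]), int(r["col"])] = r["value"]
        M[int(r["col"]), int(r["row"])] = r["value"]
    return M
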