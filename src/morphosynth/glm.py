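"""Mass-univariate general linear model across modalities and subjects.

Observations are (subject, modality) pairs; the design can hold modality
indicator columns (cell-means coding, one column per image type),
mean-centred age, a mean-centred quadratic age term (the square of centred
age, itself re-centred), sex, modality-by-age interactions, and sum-to-zero
subject effects for paired modality contrasts. Responses are fitted
site-by-site with ordinary least squares, one-tailed t-tests per contrast
vector, and Bonferroni control of the family-wise error over sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignMatrix", "GlmResult", "build_design", "fit_glm", "correct_multiple"]


@dataclass(frozen=True)
class DesignMatrix:
    """Design with named columns; full column rank by construction."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.matrix, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.columns):
            raise ValueError("matrix/column-name mismatch")
        object.__setattr__(self, "matrix", x)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def contrast(self, weights: Mapping[str, float]) -> np.ndarray:
        """Contrast vector from a {column name: weight} mapping."""
        c = np.zeros(len(self.columns))
        for name, w in weights.items():
            c[self.column_index(name)] = w
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns whose removal restores full rank."""
    full = np.linalg.matrix_rank(x)
    bad = []
    for j in range(x.shape[1]):
        rest = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(rest) == full:
            bad.append(names[j])
    return bad


def build_design(
    metadata: pd.DataFrame,
    terms: Sequence[str] = ("modality",),
) -> DesignMatrix:
    """Assemble a design matrix from per-observation metadata.

    ``metadata`` needs one row per observation with columns drawn from
    ``modality``, ``age``, ``sex`` and ``subject_id`` as the terms require.
    Supported terms:

    - ``"modality"``: one indicator column per image type (row sums 1).
    - ``"age"``: age minus the mean age (centring over observations).
    - ``"age2"``: square of centred age, re-centred to zero mean.
    - ``"sex"``: indicator of the second sex level (sorted order).
    - ``"modality:age"``: centred age within each modality column except
      the first (the interaction contrasts against the reference type).
    - ``"subject"``: sum-to-zero subject deviations (one column per
      subject but the last), for paired modality contrasts.

    Raises a rank-deficiency error naming the collinear columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(metadata)

    def centred_age() -> np.ndarray:
        age = metadata["age"].to_numpy(dtype=float)
        return age - age.mean()

    for term in terms:
        if term == "modality":
            levels = sorted(metadata["modality"].unique())
            for lv in levels:
                cols.append((metadata["modality"] == lv).to_numpy(dtype=float))
                names.append(f"modality[{lv}]")
        elif term == "age":
            cols.append(centred_age())
            names.append("age_c")
        elif term == "age2":
            sq = centred_age() ** 2
            cols.append(sq - sq.mean())
            names.append("age_c2")
        elif term == "sex":
            levels = sorted(metadata["sex"].unique())
            if len(levels) > 2:
                raise ValueError("sex must have at most two levels")
            cols.append((metadata["sex"] == levels[-1]).to_numpy(dtype=float))
            names.append(f"sex[{levels[-1]}]")
        elif term == "modality:age":
            levels = sorted(metadata["modality"].unique())
            ac = centred_age()
            for lv in levels[1:]:
                ind = (metadata["modality"] == lv).to_numpy(dtype=float)
                cols.append(ind * ac)
                names.append(f"modality[{lv}]:age_c")
        elif term == "subject":
            subjects = sorted(metadata["subject_id"].unique())
            for s in subjects[:-1]:
                col = (metadata["subject_id"] == s).to_numpy(dtype=float)
                col -= (metadata["subject_id"] == subjects[-1]).to_numpy(dtype=float)
                cols.append(col)
                names.append(f"subject[{s}]")
        else:
            raise ValueError(f"unknown design term {term!r}")

    x = np.column_stack(cols) if cols else np.empty((n, 0))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=x, columns=tuple(names))


@dataclass
class GlmResult:
    """Per-site OLS estimates and a one-tailed test of one contrast."""

    beta: np.ndarray  # (n_sites, p)
    sigma2: np.ndarray  # (n_sites,)
    dof: int
    contrast: np.ndarray
    t: np.ndarray
    p_one_tailed: np.ndarray
    infinite_t: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "p": self.p_one_tailed, "sigma2": self.sigma2})


def fit_glm(
    design: DesignMatrix,
    response: np.ndarray,
    contrast: np.ndarray | Mapping[str, float],
) -> GlmResult:
    """Site-wise OLS with a one-tailed t-test of ``contrast``.

    ``response`` has shape (n_sites, n_observations) (a single site may be
    passed as a 1-D vector). The t statistic is
    ``c' beta / sqrt(sigma2 * c' (X'X)^-1 c)`` with ``n - rank`` degrees of
    freedom and ``p = P(T > t)`` (direction is supplied by the contrast
    sign). Sites with zero residual variance report an infinite-t sentinel
    and are flagged in ``infinite_t``.
    """
    x = design.matrix
    y = np.atleast_2d(np.asarray(response, dtype=float))
    if y.shape[1] != design.n:
        raise ValueError("response columns must match design rows")
    if isinstance(contrast, Mapping):
        c = design.contrast(contrast)
    else:
        c = np.asarray(contrast, dtype=float)
    rank = design.rank
    dof = design.n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv  # (sites, p)
    resid = y - beta @ x.T
    sigma2 = (resid**2).sum(axis=1) / dof
    cvar = float(c @ xtx_inv @ c)
    effect = beta @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * cvar)
        t = effect / se
    infinite = (sigma2 == 0.0) & (effect != 0.0)
    t = np.where(infinite, np.where(effect > 0, np.inf, -np.inf), t)
    t = np.where((sigma2 == 0.0) & (effect == 0.0), 0.0, t)
    p = stats.t.sf(t, dof)
    return GlmResult(beta=beta, sigma2=sigma2, dof=dof, contrast=c, t=t,
                     p_one_tailed=p, infinite_t=infinite)


def correct_multiple(
    p_values: np.ndarray, method: str = "bonferroni", alpha: float = 0.05
) -> np.ndarray:
    """Bonferroni familywise control: reject site i iff p_i <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bonferroni":
        raise ValueError(f"unsupported correction method {method!r}")
    return p <= alpha / p.size
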