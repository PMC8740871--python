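"""Statistical inference on shape: permutational MANOVA and friends.

The workhorse is a sequential (Type I) permutational multivariate analysis
of variance on Euclidean distances — the adonis-style decomposition: each
term's sum of squares is the incremental explained SS given all earlier
terms, R^2 = SS / SS_total, pseudo-F uses the residual mean square of the
full model, and p-values come from permutations of the raw observation
rows.  For a Euclidean response this is computed directly from orthogonal
projections of the (centered) response matrix, which is exactly equivalent
to the distance-matrix formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import ProcrustesResult

__all__ = [
    "PermanovaTable",
    "RepeatabilityEstimate",
    "permanova",
    "repeatability",
    "allometry_test",
    "group_mean_shapes",
    "exaggerate",
]


@dataclass(frozen=True)
class PermanovaTable:
    """Sequential variance decomposition of a multivariate response."""

    terms: tuple[str, ...]
    df: tuple[int, ...]
    ss: tuple[float, ...]
    r2: tuple[float, ...]
    pseudo_f: tuple[float, ...]
    p: tuple[float, ...]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "df": self.df[i],
            "ss": self.ss[i],
            "r2": self.r2[i],
            "pseudo_f": self.pseudo_f[i],
            "p": self.p[i],
        }

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": d,
                "ss": s,
                "r2": r,
                "pseudo_f": f,
                "p": p,
            }
            for t, d, s, r, f, p in zip(
                self.terms, self.df, self.ss, self.r2, self.pseudo_f, self.p
            )
        ]
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "ss": self.residual_ss,
                "r2": self.residual_r2,
                "pseudo_f": np.nan,
                "p": np.nan,
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": self.residual_df + sum(self.df),
                "ss": self.total_ss,
                "r2": 1.0,
                "pseudo_f": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _term_columns(values) -> np.ndarray:
    """Design columns for one predictor: dummies (drop first) or the column."""
    v = np.asarray(values)
    if v.dtype.kind in "OUSb" or isinstance(values, pd.Categorical):
        levels, codes = np.unique(v, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("constant categorical predictor")
        cols = np.zeros((len(v), len(levels) - 1))
        for j in range(1, len(levels)):
            cols[codes == j, j - 1] = 1.0
        return cols
    v = v.astype(float)
    if np.ptp(v) == 0:
        raise ValueError("constant predictor")
    return v[:, None]


def permanova(
    shape_matrix: np.ndarray,
    predictors: dict | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaTable:
    """Sequential Euclidean PERMANOVA of a multivariate response.

    Parameters
    ----------
    shape_matrix
        (n, p) response; rows are observations (e.g. flattened aligned
        coordinates, p = 2k).
    predictors
        Ordered mapping of term name -> values.  Order matters: sums of
        squares are sequential.  String/categorical values are expanded to
        dummy columns; numeric values enter as single columns.
    n_perm
        Number of random row permutations for the p-values (default
        10 000).  ``n_perm=0`` skips the permutation test entirely and
        reports NaN p-values (useful in replicate loops that only need the
        R^2 decomposition).
    seed
        Seed or Generator for the permutations (mandatory for reproducible
        p-values).
    permutations
        Optional explicit (m, n) array of row-permutation index vectors to
        use instead of random draws — e.g. an exhaustive enumeration of
        relabelings for small n.
    """
    y = np.asarray(shape_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if isinstance(predictors, pd.DataFrame):
        items = [(c, predictors[c].to_numpy()) for c in predictors.columns]
    else:
        items = list(predictors.items())
    if permutations is not None:
        permutations = np.asarray(permutations, dtype=int)
        n_perm = permutations.shape[0]
    elif 0 < n_perm < 99:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")
    rng = np.random.default_rng(seed)

    yc = y - y.mean(axis=0)
    total_ss = float(np.sum(yc**2))

    # orthonormal bases of the sequential increments
    basis = np.ones((n, 1)) / np.sqrt(n)
    qs: list[np.ndarray] = []
    dfs: list[int] = []
    names: list[str] = []
    for name, values in items:
        if len(values) != n:
            raise ValueError(f"predictor {name!r} has wrong length")
        cols = _term_columns(values)
        resid = cols - basis @ (basis.T @ cols)
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        q = q[:, keep]
        if q.shape[1] == 0:
            raise ValueError(f"predictor {name!r} adds no degrees of freedom")
        qs.append(q)
        dfs.append(q.shape[1])
        names.append(str(name))
        basis = np.hstack([basis, q])

    ss_terms = np.array([float(np.sum((q.T @ yc) ** 2)) for q in qs])
    residual_ss = total_ss - float(ss_terms.sum())
    residual_df = n - 1 - sum(dfs)
    if residual_df <= 0:
        raise ValueError("model saturates the data; no residual degrees of freedom")
    ms_res = residual_ss / residual_df
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    if n_perm == 0:
        pvals = np.full(len(qs), np.nan)
    else:
        qall = np.hstack(qs)
        splits = np.cumsum(dfs)[:-1]
        exceed = np.zeros(len(qs))
        for b in range(n_perm):
            idx = permutations[b] if permutations is not None else rng.permutation(n)
            proj = qall.T @ yc[idx]
            ss_p = np.add.reduceat(np.sum(proj**2, axis=1), np.r_[0, splits])
            res_p = total_ss - ss_p.sum()
            f_p = (ss_p / np.array(dfs)) / (res_p / residual_df)
            # tiny slack so exact ties (e.g. complementary relabelings)
            # count as exceedances despite float round-off
            exceed += f_p >= f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))
        pvals = (exceed + 1.0) / (n_perm + 1.0)

    return PermanovaTable(
        terms=tuple(names),
        df=tuple(dfs),
        ss=tuple(ss_terms),
        r2=tuple(ss_terms / total_ss),
        pseudo_f=tuple(f_obs),
        p=tuple(pvals),
        residual_df=residual_df,
        residual_ss=residual_ss,
        total_ss=total_ss,
        n_perm=n_perm,
    )


@dataclass(frozen=True)
class RepeatabilityEstimate:
    """Among-individual / (among-individual + error) variance ratio."""

    r: float
    among_individual_variance: float
    error_variance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("repeatability must lie in [0, 1]")


def repeatability(
    shape_matrix: np.ndarray,
    individual_ids,
    observer_ids=None,
) -> RepeatabilityEstimate:
    """Digitization repeatability from replicate (multi-observer) shapes.

    One-way multivariate variance decomposition over individual identity on
    jointly superimposed coordinates: the among-individual variance
    component is extracted from the individual-identity mean squares, the
    error component is the residual (observer/measurement) mean square, and
    r = among / (among + error).  Requires a balanced design of k >= 2
    replicates per individual.
    """
    y = np.asarray(shape_matrix, dtype=float)
    ids = np.asarray(individual_ids)
    if observer_ids is not None and len(np.unique(np.asarray(observer_ids))) < 2:
        raise ValueError("repeatability requires at least two observers")
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two individuals")
    if counts.min() < 2:
        raise ValueError("every individual needs at least two digitizations")
    if counts.min() != counts.max():
        raise ValueError("replicate design must be balanced")
    k = int(counts[0])

    yc = y - y.mean(axis=0)
    total_ss = float(np.sum(yc**2))
    among_ss = 0.0
    for g in uniq:
        rows = yc[ids == g]
        among_ss += len(rows) * float(np.sum(rows.mean(axis=0) ** 2))
    within_ss = total_ss - among_ss
    df_among = len(uniq) - 1
    df_within = len(ids) - len(uniq)
    ms_among = among_ss / df_among
    ms_within = within_ss / df_within
    s2_among = max((ms_among - ms_within) / k, 0.0)
    s2_error = ms_within
    r = s2_among / (s2_among + s2_error) if (s2_among + s2_error) > 0 else 0.0
    return RepeatabilityEstimate(
        r=float(r),
        among_individual_variance=float(s2_among),
        error_variance=float(s2_error),
    )


def allometry_test(
    proc_result: ProcrustesResult,
    size_measure,
    covariate=None,
    covariate_name: str = "bmi",
    size_name: str = "size",
    n_perm: int = 10_000,
    seed=None,
) -> PermanovaTable:
    """Shape-on-size regression test (static allometry), adonis-style.

    ``size_measure`` is typically log centroid size or body height, one
    value per subject of ``proc_result``.  An optional covariate (BMI in the
    source design) is entered first, so the size term is its incremental
    contribution.
    """
    size = np.asarray(size_measure, dtype=float)
    if size.shape[0] != proc_result.aligned.shape[0]:
        raise ValueError("size measure does not match the superimposed subjects")
    predictors: dict = {}
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape[0] != size.shape[0]:
            raise ValueError("covariate does not match the superimposed subjects")
        predictors[covariate_name] = cov
    predictors[size_name] = size
    return permanova(proc_result.flat, predictors, n_perm=n_perm, seed=seed)


def group_mean_shapes(proc_result: ProcrustesResult, labels) -> dict:
    """Arithmetic mean of aligned coordinates per group, re-centered."""
    labels = np.asarray(labels)
    if labels.shape[0] != proc_result.aligned.shape[0]:
        raise ValueError("labels do not match the superimposed subjects")
    out = {}
    for g in np.unique(labels):
        members = proc_result.aligned[labels == g]
        if members.shape[0] == 0:
            raise ValueError(f"empty group {g!r}")
        mean = members.mean(axis=0)
        out[g] = mean - mean.mean(axis=0)
    return out


def exaggerate(reference: np.ndarray, target: np.ndarray, k: float) -> np.ndarray:
    """Shape difference amplified for display: reference + k (target - reference)."""
    if k < 0:
        raise ValueError("exaggeration factor must be >= 0")
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must have the same shape")
    return ref + k * (tgt - ref)
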