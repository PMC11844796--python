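"""Two-block behavioural PLS by SVD of the cross-block correlation matrix.

Given a z-scored cognition block X (n x p_x) and brain block Y (n x p_y),
the cross-block correlation matrix R = X'Y/(n-1) is decomposed as

    R = U diag(d) V'

Each latent variable (LV) pairs a cognition salience u_k with a brain
salience v_k; d_k**2 / sum(d**2) is the fraction of cross-block covariance
explained, used as the LV's effect size.  Inference follows the standard
behavioural-PLS recipe: LV significance by permuting the rows of one block
and comparing singular values rank-to-rank, and variable reliability by
bootstrap ratios (original salience weight over its bootstrap standard
error), thresholded at the normal 95% confidence criterion.  Subjects are
expressed on an LV by projecting their rows on the saliences
(score_x = X u_k, score_y = Y v_k); the sample covariance of the paired
scores of LV k equals d_k under the (n-1) convention, which ties the
decomposition, the effect sizes and the projections together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CrossBlockMatrix", "LatentVariableSet", "SubjectScores",
    "cross_block_correlation", "svd_latent_variables", "permutation_pvalues",
    "bootstrap_ratios", "threshold_bsr", "project_scores", "pls_fit",
]


@dataclass
class CrossBlockMatrix:
    """Cross-block Pearson correlation matrix with provenance."""

    R: np.ndarray
    n: int
    row_names: list[str]
    col_names: list[str]


@dataclass
class LatentVariableSet:
    """Saliences, singular values and inference results of a PLS fit."""

    U: np.ndarray                    # p_x x K
    V: np.ndarray                    # p_y x K
    d: np.ndarray                    # K singular values, descending
    covexp: np.ndarray               # fractions of cross-block covariance, full rank
    x_names: list[str]
    y_names: list[str]
    n: int
    perm_p: np.ndarray | None = None
    bsr_x: np.ndarray | None = None
    bsr_y: np.ndarray | None = None
    se_x: np.ndarray | None = None
    se_y: np.ndarray | None = None
    sig_mask_x: np.ndarray | None = None
    sig_mask_y: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return self.U.shape[1]

    def n_significant(self, alpha: float = 0.05) -> int:
        """Number of LVs retained at the permutation threshold (unadjusted)."""
        if self.perm_p is None:
            raise ValueError("permutation p-values not computed")
        return int(np.sum(self.perm_p[: self.n_lv] < alpha))

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "LV": [f"LV{k + 1}" for k in range(self.n_lv)],
            "singular_value": self.d[: self.n_lv],
            "covexp": self.covexp[: self.n_lv],
        })
        if self.perm_p is not None:
            out["perm_p"] = self.perm_p[: self.n_lv]
        return out


@dataclass
class SubjectScores:
    """Per-subject projection scores, one column per LV and block."""

    score_x: pd.DataFrame   # n x K, cognition-block projections on U
    score_y: pd.DataFrame   # n x K, brain-block projections on V

    @property
    def lv_names(self) -> list[str]:
        return list(self.score_x.columns)


# ---------------------------------------------------------------------------

def _as_matrix(block) -> tuple[np.ndarray, list[str]]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    arr = np.asarray(block, dtype=float)
    return arr, [f"v{j + 1}" for j in range(arr.shape[1])]


def cross_block_correlation(Xz, Yz) -> CrossBlockMatrix:
    """R = X'Y/(n-1) for z-scored blocks; entries are Pearson correlations."""
    X, xn = _as_matrix(Xz)
    Y, yn = _as_matrix(Yz)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row-count mismatch: {X.shape[0]} vs {Y.shape[0]}")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    R = X.T @ Y / (n - 1)
    return CrossBlockMatrix(R=R, n=n, row_names=xn, col_names=yn)


def svd_latent_variables(R: CrossBlockMatrix | np.ndarray,
                         K: int | None = None) -> LatentVariableSet:
    """SVD of the cross-block matrix; covariance explained over full rank.

    ``covexp`` is always computed on the full spectrum before any
    truncation to K columns, so retained-LV effect sizes do not depend on K.
    """
    if isinstance(R, CrossBlockMatrix):
        mat, xn, yn, n = R.R, R.row_names, R.col_names, R.n
    else:
        mat = np.asarray(R, dtype=float)
        xn = [f"x{j + 1}" for j in range(mat.shape[0])]
        yn = [f"y{j + 1}" for j in range(mat.shape[1])]
        n = 0
    if not np.all(np.isfinite(mat)):
        raise ValueError("cross-block matrix contains non-finite entries")
    U, d, Vt = np.linalg.svd(mat, full_matrices=False)
    covexp = d ** 2 / np.sum(d ** 2)
    if K is not None:
        U, Vt = U[:, :K], Vt[:K]
        d_keep = d[:K]
    else:
        d_keep = d
    return LatentVariableSet(U=U, V=Vt.T, d=d_keep, covexp=covexp,
                             x_names=xn, y_names=yn, n=n)


def _singular_values(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return np.linalg.svd(X.T @ Y / (n - 1), compute_uv=False)


def permutation_pvalues(Xz, Yz, n_perm: int = 500, seed: int | None = None,
                        statistic: str = "singular_value") -> np.ndarray:
    """Permutation p-values per LV, comparing rank-k to rank-k.

    The rows of X are permuted ``n_perm`` times, breaking the subject-level
    pairing while preserving each block's internal structure; the singular
    values (or, with ``statistic='covexp'``, covariance-explained fractions)
    of the re-decomposed cross-block matrix form the null.  P-values use
    add-one smoothing, p = (1 + #{d_perm >= d_obs}) / (n_perm + 1), so a
    finite test never certifies p = 0.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if statistic not in ("singular_value", "covexp"):
        raise ValueError(f"unknown permutation statistic: {statistic!r}")
    X, _ = _as_matrix(Xz)
    Y, _ = _as_matrix(Yz)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row-count mismatch between blocks")
    rng = np.random.default_rng(seed)
    d_obs = _singular_values(X, Y)
    if statistic == "covexp":
        d_obs = d_obs ** 2 / np.sum(d_obs ** 2)
    exceed = np.zeros_like(d_obs)
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        d_p = _singular_values(X[perm], Y)
        if statistic == "covexp":
            d_p = d_p ** 2 / np.sum(d_p ** 2)
        exceed += d_p >= d_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def _zscore_np(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise FloatingPointError("zero-variance column in resample")
    return (M - M.mean(axis=0)) / sd


def bootstrap_ratios(Xz, Yz, lvset: LatentVariableSet, n_boot: int = 500,
                     seed: int | None = None, groups: Sequence | None = None,
                     max_retries: int = 100,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap ratios (salience weight / bootstrap SE) per variable and LV.

    Subjects are resampled with replacement jointly across both blocks
    (stratified within ``groups`` if given), blocks re-standardized within
    each resample, and the SVD recomputed.  Each resample's LVs are
    sign-aligned to the original fit by the sign of the dot product of the
    concatenated saliences [u; v] with the original pair; no Procrustes
    rotation is applied.  Resamples producing a zero-variance column are
    redrawn (bounded retries).

    Returns ``(bsr_x, bsr_y, se_x, se_y)``.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    X, _ = _as_matrix(Xz)
    Y, _ = _as_matrix(Yz)
    n, K = X.shape[0], lvset.n_lv
    rng = np.random.default_rng(seed)
    if groups is not None:
        groups = np.asarray(groups)
        strata = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    def draw() -> np.ndarray:
        if groups is None:
            return rng.integers(0, n, n)
        return np.concatenate([s[rng.integers(0, len(s), len(s))] for s in strata])

    Us = np.empty((n_boot, X.shape[1], K))
    Vs = np.empty((n_boot, Y.shape[1], K))
    ref = np.vstack([lvset.U[:, :K], lvset.V[:, :K]])
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = draw()
            try:
                Xb = _zscore_np(X[idx])
                Yb = _zscore_np(Y[idx])
            except FloatingPointError:
                if attempt == max_retries:
                    raise RuntimeError(
                        "could not draw a bootstrap resample without a "
                        f"zero-variance column in {max_retries} retries")
                continue
            break
        Ub, db, Vbt = np.linalg.svd(Xb.T @ Yb / (len(idx) - 1), full_matrices=False)
        Ub, Vb = Ub[:, :K], Vbt[:K].T
        signs = np.sign(np.einsum("jk,jk->k", np.vstack([Ub, Vb]), ref))
        signs[signs == 0] = 1.0
        Us[b] = Ub * signs
        Vs[b] = Vb * signs
    se_x = Us.std(axis=0, ddof=1)
    se_y = Vs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_x = np.where(se_x > 0, lvset.U[:, :K] / se_x, np.inf * np.sign(lvset.U[:, :K]))
        bsr_y = np.where(se_y > 0, lvset.V[:, :K] / se_y, np.inf * np.sign(lvset.V[:, :K]))
    return bsr_x, bsr_y, se_x, se_y


def threshold_bsr(bsr: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Significance mask |BSR| >= z_{1-alpha/2} (1.96 at the 95% criterion)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    bsr = np.asarray(bsr, dtype=float)
    if not np.all(np.isfinite(bsr) | np.isinf(bsr)):
        raise ValueError("BSR contains NaN")
    return np.abs(bsr) >= sps.norm.ppf(1 - alpha / 2)


def project_scores(X_rows, Y_rows, lvset: LatentVariableSet,
                   index=None) -> SubjectScores:
    """Project data rows on the saliences: score_x = X U, score_y = Y V.

    Rows must be standardized compatibly with the blocks that produced
    ``lvset`` (follow-up rows via baseline-referenced z-scoring).  Works
    identically for baseline and follow-up data.
    """
    X, xn = _as_matrix(X_rows)
    Y, yn = _as_matrix(Y_rows)
    if xn != list(lvset.x_names) or yn != list(lvset.y_names):
        if X.shape[1] != lvset.U.shape[0] or Y.shape[1] != lvset.V.shape[0]:
            raise ValueError("column mismatch with the fitted latent variable set")
        if isinstance(X_rows, pd.DataFrame) or isinstance(Y_rows, pd.DataFrame):
            raise ValueError("column names do not match the fitted latent variable set")
    if index is None:
        index = X_rows.index if isinstance(X_rows, pd.DataFrame) else pd.RangeIndex(len(X))
    lv = [f"LV{k + 1}" for k in range(lvset.n_lv)]
    return SubjectScores(
        score_x=pd.DataFrame(X @ lvset.U, columns=lv, index=index),
        score_y=pd.DataFrame(Y @ lvset.V, columns=lv, index=index),
    )


def pls_fit(Xz, Yz, n_perm: int = 500, n_boot: int = 500, alpha: float = 0.05,
            seed: int | None = None, K: int | None = None,
            statistic: str = "singular_value",
            groups: Sequence | None = None) -> LatentVariableSet:
    """Full behavioural-PLS fit: SVD + permutation test + bootstrap ratios."""
    R = cross_block_correlation(Xz, Yz)
    lvset = svd_latent_variables(R, K=K)
    lvset.perm_p = permutation_pvalues(Xz, Yz, n_perm=n_perm, seed=seed,
                                       statistic=statistic)
    bsr_x, bsr_y, se_x, se_y = bootstrap_ratios(
        Xz, Yz, lvset, n_boot=n_boot,
        seed=None if seed is None else seed + 1, groups=groups)
    lvset.bsr_x, lvset.bsr_y, lvset.se_x, lvset.se_y = bsr_x, bsr_y, se_x, se_y
    lvset.sig_mask_x = threshold_bsr(bsr_x, alpha)
    lvset.sig_mask_y = threshold_bsr(bsr_y, alpha)
    lvset.n_perm, lvset.n_boot, lvset.seed = n_perm, n_boot, seed
    return lvset


def write_lv_outputs(lvset: LatentVariableSet, scores: SubjectScores | None,
                     outdir: str | Path) -> list[Path]:
    """Write the standard TSV artifacts of a PLS fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    lv = [f"LV{k + 1}" for k in range(lvset.n_lv)]

    def _w(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", **kw)
        written.append(p)

    _w("lv_summary.tsv", lvset.summary(), index=False)
    _w("saliences_x.tsv", pd.DataFrame(lvset.U, index=lvset.x_names, columns=lv))
    _w("saliences_y.tsv", pd.DataFrame(lvset.V, index=lvset.y_names, columns=lv))
    if lvset.bsr_x is not None:
        _w("bootstrap_ratios_x.tsv", pd.DataFrame(lvset.bsr_x, index=lvset.x_names, columns=lv))
        _w("bootstrap_ratios_y.tsv", pd.DataFrame(lvset.bsr_y, index=lvset.y_names, columns=lv))
    if scores is not None:
        sx = scores.score_x.add_prefix("score_x_")
        sy = scores.score_y.add_prefix("score_y_")
        _w("scores.tsv", pd.concat([sx, sy], axis=1))
    return written
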