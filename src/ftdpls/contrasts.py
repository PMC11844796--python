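"""Group-difference regressions on latent-variable scores.

For a retained LV the cognition-side score of each patient is regressed on
the brain-side score with diagnostic variant as a moderator:

    cognition_score ~ brain_score + variant + brain_score:variant

The interaction term asks whether the atrophy pattern's impact on the
cognitive profile differs between the three FTD variants; the variant main
effect asks whether groups express the cognitive pattern to different
degrees at the same atrophy level.  All three pairwise intercept and slope
contrasts are extracted as linear contrasts of the fitted coefficients (so
the results do not depend on which group is the dummy-coding reference) and
corrected with Benjamini-Hochberg FDR within the LV's six-contrast family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["ContrastResult", "interaction_regression", "fdr_bh", "contrasts_table"]


@dataclass
class ContrastResult:
    """One pairwise intercept or slope difference between two variants."""

    lv: str
    contrast: str          # e.g. "bvFTD vs svPPA"
    term: str              # "intercept" or "slope"
    estimate: float
    tstat: float
    p_raw: float
    p_fdr: float | None
    adj_r2: float
    n: int


def interaction_regression(cog_scores, brain_scores, groups,
                           lv: str = "LV1") -> tuple[object, list[ContrastResult]]:
    """Fit the moderated regression and extract all pairwise contrasts.

    Parameters
    ----------
    cog_scores, brain_scores:
        Per-subject scalar scores for one LV (cognition block response,
        brain block predictor).
    groups:
        Diagnostic labels; exactly three levels, each with >= 3 members.

    Returns the fitted statsmodels OLS results object and the six
    ContrastResults (3 pairs x {intercept, slope}) with BH-FDR adjusted
    p-values over that family.
    """
    y = np.asarray(cog_scores, dtype=float)
    x = np.asarray(brain_scores, dtype=float)
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    levels = sorted(g.unique())
    if len(levels) != 3:
        raise ValueError(f"exactly 3 group levels required, got {levels}")
    counts = g.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"groups with < 3 members: {small.to_dict()}")
    if np.ptp(x) == 0:
        raise ValueError("brain score is constant")

    # design: intercept, dummies for levels[1:], slope, slope interactions
    d1 = (g == levels[1]).to_numpy(dtype=float)
    d2 = (g == levels[2]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), d1, d2, x, x * d1, x * d2])
    names = ["Intercept", f"grp[{levels[1]}]", f"grp[{levels[2]}]",
             "brain", f"brain:grp[{levels[1]}]", f"brain:grp[{levels[2]}]"]
    model = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()

    # per-level coefficient vectors in the fitted parameter space
    icpt = {levels[0]: np.array([1, 0, 0, 0, 0, 0.0]),
            levels[1]: np.array([1, 1, 0, 0, 0, 0.0]),
            levels[2]: np.array([1, 0, 1, 0, 0, 0.0])}
    slope = {levels[0]: np.array([0, 0, 0, 1, 0, 0.0]),
             levels[1]: np.array([0, 0, 0, 1, 1, 0.0]),
             levels[2]: np.array([0, 0, 0, 1, 0, 1.0])}

    results: list[ContrastResult] = []
    for a, b in itertools.combinations(levels, 2):
        for term, vecs in (("intercept", icpt), ("slope", slope)):
            tt = model.t_test(vecs[a] - vecs[b])
            results.append(ContrastResult(
                lv=lv, contrast=f"{a} vs {b}", term=term,
                estimate=float(np.squeeze(tt.effect)),
                tstat=float(np.squeeze(tt.tvalue)),
                p_raw=float(np.squeeze(tt.pvalue)),
                p_fdr=None, adj_r2=float(model.rsquared_adj), n=len(y)))
    adj = fdr_bh([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_fdr = float(p)
    return model, results


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrasts_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Flatten ContrastResults into the tabular report layout."""
    return pd.DataFrame([{
        "LV": r.lv, "contrast": r.contrast, "term": r.term,
        "estimate": r.estimate, "tStat": r.tstat,
        "p_raw": r.p_raw, "p_fdr": r.p_fdr, "adj_r2": r.adj_r2, "n": r.n,
    } for r in results])
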