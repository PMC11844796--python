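"""Synthetic frontotemporal-dementia cohorts with planted latent structure.

Real multi-site FTD cohort data (diagnostic labels, neuropsychology and
regional deformation-based morphometry values) are access-restricted, so
every downstream stage of this package is exercised on generated cohorts
with a *known* ground truth: a low-rank cross-block correlation between a
cognition block and a brain block, group-specific shifts of the latent
scores, demographic confounds, a matched control group, optional additive
site effects, and roughly one-year follow-up visits with group-specific
latent drift.

Generative model (per patient, per latent variable k):

    (t_x, t_y) ~ N((m_gk, m_gk), [[1, rho_k], [rho_k, 1]])
    X = T_x @ U_true' + demographic effects + N(0, noise_sd^2)
    Y = T_y @ V_true' + demographic effects + N(0, noise_sd^2)

where U_true / V_true are unit-norm, mutually orthogonal sparse saliences
and m_gk is the planted per-group shift.  Controls carry demographic
effects and noise only.  The scale is therefore "latent SD = 1"; noise_sd
is the residual SD of each observed column on that scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["SimConfig", "SyntheticTruth", "generate_cohort", "generate_null_cohort",
           "generate_followup", "PATIENT_GROUPS", "DEFAULT_COG_NAMES"]

PATIENT_GROUPS = ("bvFTD", "svPPA", "nfvPPA")

#: default cognition-column names, echoing a standard FTD neuropsychology
#: battery; the names are labels only and carry no simulated semantics.
DEFAULT_COG_NAMES = [
    "CDR_sumboxes", "CDR_language", "CDR_behaviour", "MMSE",
    "CVLT_learning", "CVLT_recall_30s", "CVLT_recall_10min", "CVLT_recognition",
    "digit_span_forward", "digit_span_backward",
    "MTMT_correct_lines", "MTMT_time",
    "fluency_phonological", "fluency_semantic", "BNT", "PPVT",
]


def _default_counts() -> dict[str, int]:
    return {"bvFTD": 70, "svPPA": 36, "nfvPPA": 30, "control": 50}


def _default_shift() -> dict[str, tuple[float, ...]]:
    return {"bvFTD": (1.2, -1.0), "svPPA": (-1.5, 0.6), "nfvPPA": (0.6, 1.4)}


def _default_drift() -> dict[str, tuple[float, ...]]:
    # yearly latent-score drift; the semantic variant declines fastest on
    # LV-1, echoing the steeper language/naming trajectory of svPPA
    return {"bvFTD": (-0.35, -0.15), "svPPA": (-0.80, -0.25), "nfvPPA": (-0.25, -0.45)}


def _default_ages() -> dict[str, tuple[float, float]]:
    return {"bvFTD": (61.5, 6.4), "svPPA": (63.0, 6.3), "nfvPPA": (68.1, 7.9),
            "control": (64.0, 7.0)}


def _default_followup_fraction() -> dict[str, float]:
    return {"bvFTD": 38 / 70, "svPPA": 24 / 36, "nfvPPA": 15 / 30}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study conditions this package is modelled on:
    70/36/30 patients across bvFTD/svPPA/nfvPPA plus 50 demographically
    matched controls, a 12-column cognition block, a 102-region brain
    block, two planted latent variables with cross-block correlations
    0.7/0.5, and ~1.03 (SD 0.44) year follow-up intervals.
    """

    n_per_group: Mapping[str, int] = field(default_factory=_default_counts)
    p_cog: int = 12
    p_brain: int = 102
    n_latent: int = 2
    rho: Sequence[float] = (0.7, 0.5)
    salience_sparsity: float = 0.5
    group_shift: Mapping[str, Sequence[float]] = field(default_factory=_default_shift)
    demo_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.30, "education": -0.03})
    noise_sd: float = 0.2
    sex_p_male: float = 0.55
    age_mean_sd: Mapping[str, tuple[float, float]] = field(default_factory=_default_ages)
    education_mean_sd: tuple[float, float] = (16.0, 3.0)
    education_min: float = 8.0
    site_labels: Sequence[str] | None = None
    site_offsets: Sequence[float] | None = None
    followup_interval_mean_sd: tuple[float, float] = (1.03, 0.44)
    followup_fraction: Mapping[str, float] = field(default_factory=_default_followup_fraction)
    drift_per_group: Mapping[str, Sequence[float]] = field(default_factory=_default_drift)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1, got {n}")
        if self.p_cog < 1 or self.p_brain < 1 or self.n_latent < 1:
            raise ValueError("p_cog, p_brain and n_latent must be >= 1")
        rho = np.asarray(self.rho, dtype=float)
        if len(rho) != self.n_latent:
            raise ValueError(f"rho must have n_latent={self.n_latent} entries, got {len(rho)}")
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("rho entries must lie in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.salience_sparsity < 1:
            raise ValueError("salience_sparsity must lie in [0, 1)")
        for p, name in ((self.p_cog, "p_cog"), (self.p_brain, "p_brain")):
            nnz = _support_size(p, self.salience_sparsity)
            if nnz * self.n_latent > p:
                raise ValueError(
                    f"salience_sparsity={self.salience_sparsity} leaves {nnz} non-zero "
                    f"loadings per LV; {self.n_latent} orthogonal LVs do not fit in "
                    f"{name}={p} columns")
        for g, s in self.group_shift.items():
            if len(s) != self.n_latent:
                raise ValueError(f"group_shift[{g!r}] must have {self.n_latent} entries")
        if (self.site_labels is None) != (self.site_offsets is None):
            raise ValueError("site_labels and site_offsets must be given together")
        if self.site_labels is not None and len(self.site_labels) != len(self.site_offsets):
            raise ValueError("site_labels and site_offsets must have equal length")

    def cog_names(self) -> list[str]:
        names = DEFAULT_COG_NAMES[: self.p_cog]
        names += [f"cog_{i:02d}" for i in range(len(names) + 1, self.p_cog + 1)]
        return names

    def brain_names(self) -> list[str]:
        return [f"region_{i:03d}" for i in range(1, self.p_brain + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort (patients only)."""

    U_true: np.ndarray            # p_cog x K
    V_true: np.ndarray            # p_brain x K
    latent_x: np.ndarray          # n_patients x K
    latent_y: np.ndarray          # n_patients x K
    rho: np.ndarray               # planted per-LV correlations
    rho_realized: np.ndarray      # empirical corr(latent_x_k, latent_y_k)
    group_assignments: pd.Series  # subject_id -> group (patients)

    def write(self, prefix: str | Path) -> None:
        """Write saliences/latents as TSV plus a JSON summary sidecar."""
        prefix = str(Path(prefix))
        K = self.U_true.shape[1]
        lv = [f"LV{k + 1}" for k in range(K)]
        pd.DataFrame(self.U_true, columns=lv).to_csv(
            prefix + ".U_true.tsv", sep="\t", index=False)
        pd.DataFrame(self.V_true, columns=lv).to_csv(
            prefix + ".V_true.tsv", sep="\t", index=False)
        lat = pd.DataFrame(
            np.hstack([self.latent_x, self.latent_y]),
            columns=[f"latent_x_{v}" for v in lv] + [f"latent_y_{v}" for v in lv])
        lat.insert(0, "subject_id", self.group_assignments.index)
        lat.to_csv(prefix + ".latents.tsv", sep="\t", index=False)
        Path(prefix + ".truth.json").write_text(json.dumps({
            "rho": self.rho.tolist(),
            "rho_realized": self.rho_realized.tolist(),
            "groups": self.group_assignments.to_dict(),
        }, indent=1))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _support_size(p: int, sparsity: float) -> int:
    return max(1, int(round(p * (1.0 - sparsity))))


def _sparse_orthonormal(p: int, K: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm columns with disjoint random supports (hence orthogonal).

    Non-zero loadings have equal magnitude 1/sqrt(nnz) with random signs;
    together with the variance-equalizing residuals this keeps the planted
    saliences identifiable on the correlation scale (no column dominates
    the variance budget of its block).
    """
    nnz = _support_size(p, sparsity)
    perm = rng.permutation(p)
    M = np.zeros((p, K))
    for k in range(K):
        rows = perm[k * nnz: (k + 1) * nnz]
        signs = rng.choice([-1.0, 1.0], size=nnz)
        M[rows, k] = signs / np.sqrt(nnz)
    return M


def _demographics(group: str, n: int, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    age_m, age_s = cfg.age_mean_sd[group]
    age = rng.normal(age_m, age_s, n)
    sex = np.where(rng.random(n) < cfg.sex_p_male, "M", "F")
    edu_m, edu_s = cfg.education_mean_sd
    edu = rng.normal(edu_m, edu_s, n)
    while np.any(edu < cfg.education_min):  # truncated normal, >= 8 years
        bad = edu < cfg.education_min
        edu[bad] = rng.normal(edu_m, edu_s, bad.sum())
    return pd.DataFrame({"age": age, "sex": sex, "education": np.round(edu, 1)})


#: centering constants for demographic effects (kept fixed so the same
#: coefficient means the same thing across groups and configs)
_DEMO_CENTER = {"age": 65.0, "sex": 0.5, "education": 16.0}


def _demo_contribution(demo: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    out = np.zeros(len(demo))
    for cov, coef in cfg.demo_effects.items():
        if cov == "sex":
            x = (demo["sex"] == "M").to_numpy(dtype=float)
        else:
            x = demo[cov].to_numpy(dtype=float)
        out = out + coef * (x - _DEMO_CENTER[cov])
    return out


def _assign_sites(n: int, cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if cfg.site_labels is None:
        return np.full(n, "site1"), np.zeros(n)
    idx = rng.integers(0, len(cfg.site_labels), n)
    return np.asarray(cfg.site_labels)[idx], np.asarray(cfg.site_offsets, dtype=float)[idx]


def _column_noise_sd(saliences: np.ndarray, noise_sd: float,
                     with_latent: bool) -> np.ndarray:
    """Per-column residual SDs that equalize total column variance.

    Columns loading weakly on the planted latents receive extra
    pattern-unrelated variance so that every column of a block has the same
    total variance (max_j sum_k s_jk^2 + noise_sd^2).  Z-scoring is then a
    uniform rescaling and the planted saliences remain identifiable on the
    correlation scale instead of being warped column-by-column.  Rows
    without latent signal (controls) get the full column variance as noise,
    so their marginals match the patients' up to group shifts.
    """
    load2 = (saliences ** 2).sum(axis=1)
    total = load2.max() + noise_sd ** 2
    return np.sqrt(total - (load2 if with_latent else 0.0))


def _observe(latent: np.ndarray | None, saliences: np.ndarray, demo_shift: np.ndarray,
             site_offset: np.ndarray, noise_sd: float, rng: np.random.Generator,
             site_applies: bool) -> np.ndarray:
    n, p = len(demo_shift), saliences.shape[0]
    signal = latent @ saliences.T if latent is not None else 0.0
    col_sd = _column_noise_sd(saliences, noise_sd, with_latent=latent is not None)
    out = signal + demo_shift[:, None] + col_sd * rng.standard_normal((n, p))
    if site_applies:
        out = out + site_offset[:, None]
    return out


def _whitened_normals(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """iid-normal draw with the empirical mean/covariance fixed to 0/I.

    A variance-reduction device: whitening makes the realized second
    moments of the latent scores equal their population values at any n,
    so planted cross-block correlations are reproduced exactly rather than
    up to O(1/sqrt(n)) sampling error.  Falls back to a raw draw when n is
    too small to whiten.
    """
    Z = rng.standard_normal((n, m))
    if n <= m + 1:
        return Z
    Z = Z - Z.mean(axis=0)
    L = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=1))
    return Z @ np.linalg.inv(L).T


def _build(config: SimConfig, null: bool) -> tuple[CohortTable, SyntheticTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_latent
    rho = np.zeros(K) if null else np.asarray(config.rho, dtype=float)
    U = _sparse_orthonormal(config.p_cog, K, config.salience_sparsity, rng)
    V = _sparse_orthonormal(config.p_brain, K, config.salience_sparsity, rng)

    n_pat = sum(config.n_per_group.get(g, 0) for g in PATIENT_GROUPS)
    # planted cohorts fix the latents' empirical second moments so realized
    # structure equals the planted structure; null cohorts must stay honest
    # samples (fixing cross-moments to zero would make the observed pairing
    # atypically decoupled and bias permutation calibration)
    Z = (_whitened_normals(n_pat, 2 * K, rng) if not null
         else rng.standard_normal((n_pat, 2 * K)))
    TX = np.empty((n_pat, K))
    TY = np.empty((n_pat, K))
    for k in range(K):
        TX[:, k] = Z[:, 2 * k]
        TY[:, k] = rho[k] * Z[:, 2 * k] + np.sqrt(1 - rho[k] ** 2) * Z[:, 2 * k + 1]

    frames, lat_x, lat_y, subj, grp = [], [], [], [], []
    counter = 0
    pat_offset = 0
    for group in list(PATIENT_GROUPS) + ["control"]:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        demo = _demographics(group, n, config, rng)
        sites, offs = _assign_sites(n, config, rng)
        shift = _demo_contribution(demo, config)
        if group == "control":
            tx = ty = None
        else:
            mean = np.asarray(config.group_shift.get(group, np.zeros(K)), dtype=float)
            tx = TX[pat_offset: pat_offset + n] + mean
            ty = TY[pat_offset: pat_offset + n] + mean
            pat_offset += n
        X = _observe(tx, U, shift, offs, config.noise_sd, rng, site_applies=False)
        Y = _observe(ty, V, shift, offs, config.noise_sd, rng, site_applies=True)
        ids = [f"sub-{i:04d}" for i in range(counter + 1, counter + n + 1)]
        counter += n
        df = pd.DataFrame({"subject_id": ids, "visit": "baseline",
                           "years_since_baseline": 0.0, "group": group, "site": sites})
        df = pd.concat([df, demo,
                        pd.DataFrame(X, columns=config.cog_names()),
                        pd.DataFrame(Y, columns=config.brain_names())], axis=1)
        frames.append(df)
        if group != "control":
            lat_x.append(tx)
            lat_y.append(ty)
            subj.extend(ids)
            grp.extend([group] * n)

    data = pd.concat(frames, ignore_index=True)
    latent_x = np.vstack(lat_x)
    latent_y = np.vstack(lat_y)
    # rho is a within-group correlation: remove planted group means first,
    # otherwise shared shifts inflate the pooled estimate
    garr = np.asarray(grp)
    cx, cy = latent_x.copy(), latent_y.copy()
    for group in np.unique(garr):
        m = garr == group
        cx[m] -= cx[m].mean(axis=0)
        cy[m] -= cy[m].mean(axis=0)
    realized = np.array([np.corrcoef(cx[:, k], cy[:, k])[0, 1] for k in range(K)])
    truth = SyntheticTruth(U_true=U, V_true=V, latent_x=latent_x, latent_y=latent_y,
                           rho=rho, rho_realized=realized,
                           group_assignments=pd.Series(grp, index=subj, name="group"))
    cohort = CohortTable(data, config.cog_names(), config.brain_names())
    return cohort, truth


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a baseline cohort with planted brain-cognition structure.

    Deterministic given ``config.seed``; returns the cohort table (patients
    plus controls) and the planted ground truth for recovery testing.
    """
    return _build(config, null=False)


def generate_null_cohort(config: SimConfig) -> CohortTable:
    """Generate a cohort whose two blocks are statistically independent.

    Serves as the null model for calibrating the permutation test.  The
    config must not plant any cross-block structure: ``rho`` entries and
    ``group_shift`` entries must all be zero (shared group means would
    couple the blocks through the group structure).  Marginal distributions
    match :func:`generate_cohort` under the same (zeroed) settings.
    """
    config.validate()
    rho = np.asarray(config.rho, dtype=float)
    if np.any(rho != 0):
        raise ValueError("null cohort requested but config.rho plants cross-block "
                         "correlation; set rho to zeros")
    for g, s in config.group_shift.items():
        if np.any(np.asarray(s, dtype=float) != 0):
            raise ValueError("null cohort requested but config.group_shift plants shared "
                             f"group means (group {g!r}); set group_shift to zeros")
    cohort, _ = _build(config, null=True)
    return cohort


def generate_followup(cohort: CohortTable, truth: SyntheticTruth,
                      config: SimConfig) -> CohortTable:
    """Append one follow-up visit per selected patient.

    Follow-up intervals are drawn from the configured normal distribution
    (resampled until positive); latent scores advance by the group's yearly
    drift times the interval before the observed blocks are regenerated with
    fresh noise.  Age advances by the interval; sex/education are carried
    over.  Deterministic given ``config.seed``.
    """
    config.validate()
    base = cohort.data[cohort.data["visit"] == "baseline"]
    if base.empty:
        raise ValueError("cohort has no baseline rows")
    rng = np.random.default_rng([config.seed, 0x0F11])  # independent stream
    K = config.n_latent
    mu, sd = config.followup_interval_mean_sd

    subj_index = {s: i for i, s in enumerate(truth.group_assignments.index)}
    rows = []
    for group in PATIENT_GROUPS:
        gb = base[base["group"] == group]
        if gb.empty:
            continue
        frac = config.followup_fraction.get(group, 0.0) if not isinstance(
            config.followup_fraction, (int, float)) else float(config.followup_fraction)
        n_fu = int(round(frac * len(gb)))
        if n_fu == 0:
            continue
        chosen = gb.iloc[np.sort(rng.choice(len(gb), size=n_fu, replace=False))]
        drift = np.asarray(config.drift_per_group.get(group, np.zeros(K)), dtype=float)
        for _, row in chosen.iterrows():
            sid = row["subject_id"]
            if sid not in subj_index:
                raise ValueError(f"subject {sid} missing from truth")
            interval = rng.normal(mu, sd)
            while interval <= 0:
                interval = rng.normal(mu, sd)
            i = subj_index[sid]
            tx = truth.latent_x[i] + drift * interval
            ty = truth.latent_y[i] + drift * interval
            demo = pd.DataFrame({"age": [row["age"] + interval], "sex": [row["sex"]],
                                 "education": [row["education"]]})
            shift = _demo_contribution(demo, config)
            off = np.zeros(1) if config.site_labels is None else np.asarray(
                [dict(zip(config.site_labels, config.site_offsets)).get(row.get("site"), 0.0)])
            X = _observe(tx[None, :], truth.U_true, shift, off, config.noise_sd, rng, False)
            Y = _observe(ty[None, :], truth.V_true, shift, off, config.noise_sd, rng, True)
            rec = {"subject_id": sid, "visit": "followup",
                   "years_since_baseline": float(interval), "group": group,
                   "site": row.get("site", "site1"), "age": row["age"] + interval,
                   "sex": row["sex"], "education": row["education"]}
            rec.update(dict(zip(cohort.cognition_cols, X.ravel())))
            rec.update(dict(zip(cohort.brain_cols, Y.ravel())))
            rows.append(rec)
    if not rows:
        return cohort
    out = pd.concat([cohort.data, pd.DataFrame(rows)], ignore_index=True)
    return dc_replace(cohort, data=out)
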