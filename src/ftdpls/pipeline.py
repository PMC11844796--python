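"""End-to-end orchestration: simulate → preprocess → PLS → contrasts →
classify → longitudinal, from a single config with one master seed.

Each stage writes plain-text artifacts into the run directory and consumes
only the serialized artifacts of earlier stages, so stages can be re-run
individually; ``run_pipeline`` sequences them and emits a manifest with
per-stage seeds, timings and output checksums.  All randomness flows from
the master seed through fixed per-stage offsets, so re-running an identical
config reproduces identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import contrasts as ctr
from . import longitudinal as lng
from . import pls as plsm
from .cohort import (CohortTable, complete_case_filter, impute_group_mean,
                     read_cohort, select_followup_closest_to, write_cohort,
                     wscore_adjust, zscore_columns, StandardizationStats)
from .simulate import SimConfig, generate_cohort, generate_followup

__all__ = ["RunConfig", "run_pipeline", "cv_repeated_nested"]

# fixed per-stage seed offsets off the master seed (kept < 2**31 total)
_STAGE_OFFSET = {"simulate": 0, "pls": 101, "classify": 202, "longitudinal": 303}


def _stage_seed(master: int, stage: str) -> int:
    return int((master + _STAGE_OFFSET[stage]) % (2 ** 31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML or JSON."""

    outdir: str = "ftdpls_run"
    seed: int = 0
    # input: either a simulation config or a cohort file + column schema
    sim: SimConfig | None = None
    input_path: str | None = None
    schema: Mapping[str, Sequence[str]] | None = None
    simulate_followup: bool = True
    # preprocessing
    impute_columns: tuple[str, ...] = ("education",)
    use_wscore: bool = False
    followup_target_years: float = 1.0
    # PLS
    n_perm: int = 500
    n_boot: int = 500
    alpha: float = 0.05
    perm_statistic: str = "singular_value"
    # classifier
    feature_sets: tuple[str, ...] = ("maximal", "minimal", "brain_only", "cognition_only")
    minimal_cognition: tuple[str, ...] = ("CDR_sumboxes", "CDR_language",
                                          "CDR_behaviour", "BNT")
    cv_k: int = 10
    cv_repeats: int = 100
    n_learners: int = 100
    nested: bool = False
    # longitudinal
    run_longitudinal: bool = True

    def validate(self) -> None:
        if self.sim is None and (self.input_path is None or self.schema is None):
            raise ValueError("either 'sim' or both 'input_path' and 'schema' are required")
        if self.schema is not None:
            for role in ("cognition", "brain"):
                if role not in self.schema:
                    raise ValueError(f"schema must declare {role!r} columns")
        if self.n_perm < 1 or self.n_boot < 2:
            raise ValueError("n_perm must be >= 1 and n_boot >= 2")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None and not isinstance(d["sim"], SimConfig):
            d["sim"] = SimConfig(**d["sim"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and a remediation hint."""

    def __init__(self, stage: str, err: Exception, hint: str = ""):
        super().__init__(f"stage '{stage}' failed: {err}" + (f" ({hint})" if hint else ""))
        self.stage = stage


# ---------------------------------------------------------------------------
# stages: each reads/writes only serialized artifacts in `outdir`
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    sim = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, "simulate"))
    cohort, truth = generate_cohort(sim)
    if config.simulate_followup:
        cohort = generate_followup(cohort, truth, sim)
    write_cohort(cohort, outdir / "cohort.tsv", with_schema=True)
    truth.write(outdir / "truth")
    return sorted(outdir.glob("cohort.tsv*")) + sorted(outdir.glob("truth.*"))


def _load_cohort(config: RunConfig, outdir: Path) -> CohortTable:
    if (outdir / "cohort.tsv").exists():
        return read_cohort(outdir / "cohort.tsv")
    if config.input_path is None:
        raise FileNotFoundError("no cohort.tsv in run directory and no input_path")
    return read_cohort(config.input_path, config.schema)


def stage_preprocess(config: RunConfig, outdir: Path) -> list[Path]:
    cohort = _load_cohort(config, outdir)
    cohort = impute_group_mean(cohort, config.impute_columns)
    required = cohort.cognition_cols + cohort.covariate_cols
    cohort, report = complete_case_filter(cohort, required)
    cohort = select_followup_closest_to(cohort, config.followup_target_years)

    patients = cohort.patients()
    base = patients.baseline()
    fu_df = patients.data[patients.data["visit"] == "followup"]

    Xraw = base.cognition()
    Yraw = base.brain()
    fu_X = fu_df[cohort.cognition_cols].astype(float)
    fu_Y = fu_df[cohort.brain_cols].astype(float)
    if config.use_wscore:
        controls = cohort.controls().baseline()
        if len(controls) == 0:
            raise ValueError("w-scoring requested but the cohort has no controls")
        cdata = controls.data
        Xraw = wscore_adjust(base.data, cdata, cohort.cognition_cols)
        Yraw = wscore_adjust(base.data, cdata, cohort.brain_cols)
        fu_X = wscore_adjust(fu_df, cdata, cohort.cognition_cols)
        fu_Y = wscore_adjust(fu_df, cdata, cohort.brain_cols)

    Xz, xstats = zscore_columns(Xraw)
    Yz, ystats = zscore_columns(Yraw)
    # follow-up visits standardized against *baseline* statistics
    fu_Xz, _ = zscore_columns(fu_X, xstats)
    fu_Yz, _ = zscore_columns(fu_Y, ystats)

    written = []

    def _w(name: str, df: pd.DataFrame, index=False) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    meta = base.data[["subject_id", "group", "age", "sex", "education"]]
    _w("patients_baseline_meta.tsv", meta)
    _w("Xz_baseline.tsv", pd.concat([base.data[["subject_id"]], Xz], axis=1))
    _w("Yz_baseline.tsv", pd.concat([base.data[["subject_id"]], Yz], axis=1))
    if len(fu_df):
        fumeta = fu_df[["subject_id", "group", "years_since_baseline"]].reset_index(drop=True)
        _w("followup_meta.tsv", fumeta)
        _w("Xz_followup.tsv", pd.concat([fumeta[["subject_id"]],
                                         fu_Xz.reset_index(drop=True)], axis=1))
        _w("Yz_followup.tsv", pd.concat([fumeta[["subject_id"]],
                                         fu_Yz.reset_index(drop=True)], axis=1))
    stats = pd.concat([xstats.to_frame().assign(block="cognition"),
                       ystats.to_frame().assign(block="brain")])
    stats.index.name = "column"
    _w("standardization_stats.tsv", stats, index=True)
    (outdir / "exclusions.json").write_text(json.dumps({
        "n_input": report.n_input, "n_retained": report.n_retained,
        "removed_per_group": report.removed_per_group,
        "removed_per_column": report.removed_per_column,
        "orphaned_followups": report.orphaned_followups}, indent=1))
    written.append(outdir / "exclusions.json")
    return written


def _read_block(path: Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t")
    subj = df.pop("subject_id")
    return df, subj


def stage_pls(config: RunConfig, outdir: Path) -> list[Path]:
    Xz, subj = _read_block(outdir / "Xz_baseline.tsv")
    Yz, _ = _read_block(outdir / "Yz_baseline.tsv")
    seed = _stage_seed(config.seed, "pls")
    lvset = plsm.pls_fit(Xz, Yz, n_perm=config.n_perm, n_boot=config.n_boot,
                         alpha=config.alpha, seed=seed,
                         statistic=config.perm_statistic)
    scores = plsm.project_scores(Xz, Yz, lvset, index=subj)
    written = plsm.write_lv_outputs(lvset, scores, outdir)
    fu_path = outdir / "Xz_followup.tsv"
    if fu_path.exists():
        fXz, fsubj = _read_block(fu_path)
        fYz, _ = _read_block(outdir / "Yz_followup.tsv")
        fscores = plsm.project_scores(fXz, fYz, lvset, index=fsubj)
        sx = fscores.score_x.add_prefix("score_x_")
        sy = fscores.score_y.add_prefix("score_y_")
        p = outdir / "scores_followup.tsv"
        pd.concat([sx, sy], axis=1).to_csv(p, sep="\t", index=True, index_label="subject_id")
        written.append(p)
    return written


def _read_scores(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _retained_lvs(outdir: Path, alpha: float) -> list[str]:
    summary = pd.read_csv(outdir / "lv_summary.tsv", sep="\t")
    sig = summary.loc[summary["perm_p"] < alpha, "LV"].tolist()
    return sig if sig else [summary.iloc[0]["LV"]]


def stage_contrasts(config: RunConfig, outdir: Path) -> list[Path]:
    scores = _read_scores(outdir / "scores.tsv")
    meta = pd.read_csv(outdir / "patients_baseline_meta.tsv", sep="\t")
    groups = meta.set_index("subject_id").loc[scores.index, "group"]
    rows = []
    for lv in _retained_lvs(outdir, config.alpha):
        _, results = ctr.interaction_regression(
            scores[f"score_x_{lv}"], scores[f"score_y_{lv}"], groups, lv=lv)
        rows.append(ctr.contrasts_table(results))
    table = pd.concat(rows, ignore_index=True)
    path = outdir / "contrasts.tsv"
    table.to_csv(path, sep="\t", index=False)
    return [path]


def _feature_table(outdir: Path, config: RunConfig, feature_set: str,
                   followup: bool = False):
    """Load scores (+ covariates) for one feature set; refits PLS on the
    minimal cognition battery when needed."""
    lv_keep = _retained_lvs(outdir, config.alpha)
    if feature_set == "minimal":
        scores, fu_scores = _minimal_scores(outdir, config)
    else:
        scores = _read_scores(outdir / "scores.tsv")
        fu_scores = (_read_scores(outdir / "scores_followup.tsv")
                     if (outdir / "scores_followup.tsv").exists() else None)
    spec = cls.FeatureSpec.preset(feature_set)
    keep = []
    if spec.use_x:
        keep += [f"score_x_{lv}" for lv in lv_keep]
    if spec.use_y:
        keep += [f"score_y_{lv}" for lv in lv_keep]
    meta = pd.read_csv(outdir / "patients_baseline_meta.tsv", sep="\t").set_index("subject_id")
    src = scores if not followup else fu_scores
    if src is None:
        return None, None, None
    feats = src[keep].copy()
    for cov in spec.covariates:
        col = meta.loc[feats.index, cov] if not followup else meta.loc[feats.index, cov]
        if cov == "sex":
            col = col.map({"F": 0.0, "M": 1.0})
        feats[cov] = col.astype(float).to_numpy()
    labels = meta.loc[feats.index, "group"].to_numpy()
    return feats, labels, feats.index.to_numpy()


def _minimal_scores(outdir: Path, config: RunConfig):
    Xz, subj = _read_block(outdir / "Xz_baseline.tsv")
    Yz, _ = _read_block(outdir / "Yz_baseline.tsv")
    cols = [c for c in config.minimal_cognition if c in Xz.columns]
    if not cols:
        raise ValueError("none of the minimal cognition columns are present; "
                         f"wanted {config.minimal_cognition}")
    seed = _stage_seed(config.seed, "pls") + 7
    lvset = plsm.pls_fit(Xz[cols], Yz, n_perm=config.n_perm, n_boot=config.n_boot,
                         alpha=config.alpha, seed=seed)
    scores = plsm.project_scores(Xz[cols], Yz, lvset, index=subj)
    out = pd.concat([scores.score_x.add_prefix("score_x_"),
                     scores.score_y.add_prefix("score_y_")], axis=1)
    out.index = pd.Index(subj, name="subject_id")
    fu = None
    if (outdir / "Xz_followup.tsv").exists():
        fXz, fsubj = _read_block(outdir / "Xz_followup.tsv")
        fYz, _ = _read_block(outdir / "Yz_followup.tsv")
        fs = plsm.project_scores(fXz[cols], fYz, lvset, index=fsubj)
        fu = pd.concat([fs.score_x.add_prefix("score_x_"),
                        fs.score_y.add_prefix("score_y_")], axis=1)
        fu.index = pd.Index(fsubj, name="subject_id")
    # the minimal fit retains its own LV count; reuse only as many LVs as
    # the maximal fit retained, capped by availability
    return out, fu


def stage_classify(config: RunConfig, outdir: Path) -> list[Path]:
    seed = _stage_seed(config.seed, "classify")
    metrics: dict = {}
    written = []
    for i, fs in enumerate(config.feature_sets):
        feats, labels, _ = _feature_table(outdir, config, fs)
        report = cls.cv_repeated(feats, labels, k=config.cv_k,
                                 n_repeats=config.cv_repeats,
                                 B=config.n_learners, seed=seed + i)
        metrics[fs] = report.summary()
        cm = pd.DataFrame(report.confusion_total, index=report.classes,
                          columns=report.classes)
        p = outdir / f"confusion_{fs}.tsv"
        cm.to_csv(p, sep="\t")
        written.append(p)
    # longitudinal hold-out on the maximal feature set, if follow-up exists
    if (outdir / "scores_followup.tsv").exists() and "maximal" in config.feature_sets:
        bf, bl, bs = _feature_table(outdir, config, "maximal")
        ff, fl, fsub = _feature_table(outdir, config, "maximal", followup=True)
        report = cls.longitudinal_validate(bf, bl, bs, ff, fl, fsub,
                                           k=config.cv_k, n_repeats=config.cv_repeats,
                                           B=config.n_learners, seed=seed + 50)
        metrics["maximal_longitudinal"] = report.summary()
    path = outdir / "metrics.json"
    path.write_text(json.dumps(metrics, indent=1))
    return written + [path]


def stage_longitudinal(config: RunConfig, outdir: Path) -> list[Path]:
    fu_path = outdir / "scores_followup.tsv"
    if not fu_path.exists():
        return []
    base = _read_scores(outdir / "scores.tsv")
    fu = _read_scores(fu_path)
    fumeta = pd.read_csv(outdir / "followup_meta.tsv", sep="\t").set_index("subject_id")
    meta = pd.read_csv(outdir / "patients_baseline_meta.tsv", sep="\t").set_index("subject_id")
    lv_keep = _retained_lvs(outdir, config.alpha)
    cols = [f"{blk}_{lv}" for lv in lv_keep for blk in ("score_x", "score_y")]
    rates = lng.rate_table(base[cols], fu[cols], fumeta["years_since_baseline"])
    rates["group"] = meta.loc[rates["subject_id"], "group"].to_numpy()
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    rows = []
    for col in cols:
        sub = rates[rates["score"] == col]
        pt = lng.paired_change_test(sub["baseline"], sub["followup"])
        rows.append({"score": col, "test": "paired_t", "contrast": "followup vs baseline",
                     "tStat": pt.t, "p": pt.p, "n": pt.n})
        if sub["group"].nunique() >= 2 and (sub["group"].value_counts() >= 2).all():
            gc = lng.group_rate_contrasts(sub["rate"], sub["group"])
            for _, r in gc.iterrows():
                rows.append({"score": col, "test": "tukey_rate", "contrast": r["contrast"],
                             "tStat": r["tStat"], "p": r["p_tukey"],
                             "n": int(r["n_a"] + r["n_b"])})
    tests = pd.DataFrame(rows)
    # raw + BH-adjusted p for the paired family (multiplicity unstated upstream)
    paired = tests["test"] == "paired_t"
    tests.loc[paired, "p_fdr"] = ctr.fdr_bh(tests.loc[paired, "p"].to_numpy())
    tests.to_csv(outdir / "longitudinal_tests.tsv", sep="\t", index=False)
    return [outdir / "rates.tsv", outdir / "longitudinal_tests.tsv"]


_STAGES = [("simulate", stage_simulate), ("preprocess", stage_preprocess),
           ("pls", stage_pls), ("contrasts", stage_contrasts),
           ("classify", stage_classify), ("longitudinal", stage_longitudinal)]

_HINTS = {"simulate": "check the sim config fields named in the error",
          "preprocess": "check schema/column roles and missing-data settings",
          "pls": "check block sizes and n_perm/n_boot",
          "contrasts": "needs 3 diagnostic groups with >= 3 members each",
          "classify": "reduce cv_k or check class sizes",
          "longitudinal": "needs follow-up visits with valid intervals"}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    Returns the manifest dict (stage seeds, timings, artifact checksums).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    for name, fn in _STAGES:
        if name == "simulate" and config.sim is None:
            continue
        if name == "longitudinal" and not config.run_longitudinal:
            continue
        t0 = time.perf_counter()
        try:
            paths = fn(config, outdir)
        except Exception as err:
            raise PipelineError(name, err, _HINTS.get(name, "")) from err
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": _stage_seed(config.seed, name) if name in _STAGE_OFFSET else None,
            "outputs": [p.name for p in paths],
        }
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(Path(p))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# nested-CV variant: PLS refit inside each training fold
# ---------------------------------------------------------------------------

def cv_repeated_nested(X_cog: pd.DataFrame, Y_brain: pd.DataFrame, labels,
                       covariates: pd.DataFrame | None = None,
                       K: int = 2, k: int = 10, n_repeats: int = 10,
                       B: int = 100, seed: int | None = None) -> cls.ClassifierReport:
    """Repeated CV where standardization and PLS are refit per training fold.

    The default protocol fits PLS once on all baseline patients (labels
    unused) before cross-validating the scores; although that step is
    unsupervised, test subjects still participate in it.  This variant
    removes even that by estimating z-scoring statistics and saliences on
    each training fold only and projecting held-out rows.
    """
    from sklearn.model_selection import StratifiedKFold
    y = np.asarray(labels)
    classes = np.unique(y)
    Xc = X_cog.reset_index(drop=True)
    Yb = Y_brain.reset_index(drop=True)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    rng = np.random.default_rng(seed)
    n = len(y)
    acc = np.empty(n_repeats)
    sens = np.empty((n_repeats, len(classes)))
    spec = np.empty((n_repeats, len(classes)))
    cm_total = np.zeros((len(classes), len(classes)), dtype=int)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        y_pred = np.empty(n, dtype=y.dtype)
        for train, test in skf.split(Xc, y):
            Xz_tr, xs = zscore_columns(Xc.iloc[train])
            Yz_tr, ys = zscore_columns(Yb.iloc[train])
            lvset = plsm.svd_latent_variables(
                plsm.cross_block_correlation(Xz_tr, Yz_tr), K=K)
            tr_scores = plsm.project_scores(Xz_tr, Yz_tr, lvset)
            Xz_te, _ = zscore_columns(Xc.iloc[test], xs)
            Yz_te, _ = zscore_columns(Yb.iloc[test], ys)
            te_scores = plsm.project_scores(Xz_te, Yz_te, lvset)
            Ftr = np.hstack([tr_scores.score_x.to_numpy(), tr_scores.score_y.to_numpy()])
            Fte = np.hstack([te_scores.score_x.to_numpy(), te_scores.score_y.to_numpy()])
            if cov is not None:
                Ftr = np.hstack([Ftr, cov.iloc[train].to_numpy(dtype=float)])
                Fte = np.hstack([Fte, cov.iloc[test].to_numpy(dtype=float)])
            model = cls.fit_ensemble(Ftr, y[train], B=B,
                                     seed=int(rng.integers(2 ** 31)))
            y_pred[test] = cls.predict_majority(model, Fte)
        cm = cls._confusion(y, y_pred, classes)
        cm_total += cm
        acc[r] = 100.0 * np.trace(cm) / n
        sens[r], spec[r] = cls._per_class_rates(cm)
    return cls.ClassifierReport(classes=list(classes), accuracy_per_repeat=acc,
                                sensitivity=sens, specificity=spec,
                                confusion_total=cm_total,
                                protocol=f"nested stratified {k}-fold x {n_repeats} "
                                         f"repeats, B={B}, PLS per fold", seed=seed)
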