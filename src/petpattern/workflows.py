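"""End-to-end experiment workflows.

Two arms mirror the study design:

* *direct* — classify patient group A versus patient group B on preprocessed
  voxel vectors, with nested CV per classifier, a final pattern trained on
  all data, and pairwise Pearson correlations between the classifiers'
  subject scores.
* *disease-specific* — derive an A-specific pattern (A vs controls) and a
  B-specific pattern (B vs controls); project every subject onto both to get
  (s_A, s_B) expression-score pairs, averaged over CV repeats; then classify
  A vs B in the 2D score plane with a linear SVM (the second stage), and
  compare score-pair sets across classifiers with the RV coefficient.

Fold bookkeeping for expression scores: subjects inside a pattern's training
cohort are scored only by the pattern from the outer fold that held them
out; subjects outside the cohort are scored by every fold's pattern,
averaged. No subject is ever scored by a pattern trained on itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    FoldScheme,
    nested_cv,
    pearson,
    roc_auc,
    rv_coefficient,
)
from .glm_classify import (
    ClassifierSpec,
    LabeledFeatures,
    _fit_for,
    fit_pca,
    pca_transform,
    tune_hyperparameters,
)
from .patterns import Pattern, ScorePair, extract_pattern, expression_scores

log = logging.getLogger("petpattern")

DEFAULT_CLASSIFIERS = ("pca_lr", "pca_svm", "svm")


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    manifest: str | None = None
    mask: str | None = None
    experiment: str = "direct"        # direct | disease_specific
    classifiers: tuple = DEFAULT_CLASSIFIERS
    fwhm_mm: float = 6.0
    outer_k: int = 10
    inner_k: int = 10
    n_repeats: int = 10
    seed: int = 0
    outdir: str = "results"

    def validate(self):
        if self.experiment not in ("direct", "disease_specific"):
            raise ValueError(f"unknown experiment: {self.experiment}")
        for m in self.classifiers:
            if m not in ("svm", "pca_svm", "pca_lr"):
                raise ValueError(f"unknown classifier: {m}")

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d, "config_hash": hashlib.sha1(blob.encode()).hexdigest()[:12],
                "version": __version__}


def fit_full_model(X, t, spec: ClassifierSpec, inner_k: int, seed: int,
                   mask_id: str, kind: str = "discriminative") -> tuple[Pattern, dict]:
    """Tune on all data via inner CV, refit on all data, return the pattern."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=int)
    pca = fit_pca(X) if spec.uses_pca else None
    Xf = pca_transform(pca, X) if pca is not None else X
    grid = spec.build_grid(Xf, t)
    params = tune_hyperparameters(LabeledFeatures(X, t), spec.method, grid,
                                  inner_k=inner_k, seed=seed)
    model = _fit_for(spec.method, LabeledFeatures(Xf, t), params)
    pattern = extract_pattern(pca, model, mask_id=mask_id, kind=kind,
                              provenance={"method": spec.method, "hyperparams": params})
    return pattern, params


# ---------------------------------------------------------------------------
# direct classification arm

def run_direct(X, labels, mask_id: str, config: RunConfig) -> dict:
    """A-vs-B nested CV per classifier + all-data patterns + score Pearsons.

    ``labels`` are group strings; group "A" maps to +1 (the positive class),
    "B" to -1. Controls, if present in the input, are excluded.
    """
    config.validate()
    labels = np.asarray(labels)
    sel = np.isin(labels, ["A", "B"])
    if len(np.unique(labels[sel])) < 2:
        raise ValueError("direct classification needs both patient groups A and B")
    X = np.asarray(X, dtype=float)[sel]
    t = np.where(labels[sel] == "A", 1, -1)

    results, patterns_out = {}, {}
    for method in config.classifiers:
        spec = ClassifierSpec(method=method, inner_k=config.inner_k)
        scheme = FoldScheme(outer_k=config.outer_k, inner_k=config.inner_k,
                            n_repeats=config.n_repeats, seed=config.seed).materialize(t)
        cv = nested_cv(X, t, spec, scheme)
        log.info("direct %s: %s", method, cv.summary)
        results[method] = cv
        pattern, params = fit_full_model(
            X, t, spec, config.inner_k, config.seed, mask_id, kind="discriminative")
        log.info("direct %s full-data hyperparams: %s", method, params)
        patterns_out[method] = pattern

    corr = {}
    methods = list(config.classifiers)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            corr[f"{a}|{b}"] = pearson(results[a].mean_scores, results[b].mean_scores)
    return {"cv": results, "patterns": patterns_out, "score_pearson": corr,
            "labels": t, "subject_index": np.flatnonzero(sel)}


# ---------------------------------------------------------------------------
# disease-specific arm

def pattern_expression_cv(X, in_cohort: np.ndarray, t_cohort: np.ndarray,
                          spec: ClassifierSpec, scheme: FoldScheme,
                          mask_id: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-repeat expression scores of *all* subjects on a cohort pattern.

    The cohort (e.g. patients A + controls) is split by the scheme; for each
    repeat and outer fold a pattern is trained on the training folds. Cohort
    subjects receive the score from their held-out fold's pattern;
    out-of-cohort subjects receive the fold-average. Returns an
    (N_all, n_repeats) score matrix and per-repeat cohort AUC rows.
    """
    X = np.asarray(X, dtype=float)
    n_all = X.shape[0]
    cohort_idx = np.flatnonzero(in_cohort)
    outside_idx = np.flatnonzero(~in_cohort)
    Xc = X[cohort_idx]
    if not scheme.assignments:
        scheme.materialize(t_cohort)
    scores = np.zeros((n_all, scheme.n_repeats))
    rows = []
    for r, assignment in enumerate(scheme.assignments):
        n_folds = assignment.max() + 1
        outside_acc = np.zeros(outside_idx.size)
        for fold in range(n_folds):
            tr = assignment != fold
            te = assignment == fold
            Xtr, ttr = Xc[tr], t_cohort[tr]
            pca = fit_pca(Xtr) if spec.uses_pca else None
            Xf = pca_transform(pca, Xtr) if pca is not None else Xtr
            grid = spec.build_grid(Xf, ttr)
            params = tune_hyperparameters(
                LabeledFeatures(Xtr, ttr), spec.method, grid,
                inner_k=scheme.inner_k, seed=scheme.seed + 7919 * r + fold)
            model = _fit_for(spec.method, LabeledFeatures(Xf, ttr), params)
            pattern = extract_pattern(pca, model, mask_id=mask_id,
                                      kind="disease_specific")
            s_all = expression_scores(pattern, X)  # projection, no intercept
            scores[cohort_idx[te], r] = s_all[cohort_idx[te]]
            outside_acc += s_all[outside_idx] / n_folds
        scores[outside_idx, r] = outside_acc
        _, auc = roc_auc(scores[cohort_idx, r], t_cohort)
        rows.append({"repeat": r, "auc": auc})
    return scores, pd.DataFrame(rows)


def run_disease_specific(X, labels, mask_id: str, config: RunConfig,
                         second_stage_method: str = "pca_svm") -> dict:
    """Disease-specific patterns, score pairs, and second-stage SVM.

    For each classifier: derive A-vs-HC and B-vs-HC patterns under repeated
    CV, collect repeat-averaged (s_A, s_B) pairs for every subject, and fit
    all-data patterns for reporting. The second stage classifies A vs B from
    the score pairs of ``second_stage_method`` with a linear SVM under the
    same repeated-CV scheme (C tuned by inner CV, kernel scale fixed at 1).
    """
    config.validate()
    labels = np.asarray(labels)
    if "HC" not in labels:
        raise ValueError("disease-specific experiment requires an HC group in the manifest")
    if not (("A" in labels) and ("B" in labels)):
        raise ValueError("disease-specific experiment requires patient groups A and B")
    X = np.asarray(X, dtype=float)
    n = labels.size

    per_method: dict[str, dict] = {}
    for method in config.classifiers:
        spec = ClassifierSpec(method=method, inner_k=config.inner_k)
        pair_scores = {}
        per_repeat = {}
        for grp, tag in (("A", "s_A"), ("B", "s_B")):
            in_cohort = np.isin(labels, [grp, "HC"])
            t_cohort = np.where(labels[in_cohort] == grp, 1, -1)
            scheme = FoldScheme(outer_k=config.outer_k, inner_k=config.inner_k,
                                n_repeats=config.n_repeats,
                                seed=config.seed + (17 if grp == "B" else 0))
            s, rep = pattern_expression_cv(X, in_cohort, t_cohort, spec, scheme, mask_id)
            pair_scores[tag] = s
            per_repeat[tag] = rep
            log.info("disease-specific %s %s-vs-HC mean AUC %.3f",
                     method, grp, rep["auc"].mean())
        pairs = [
            ScorePair(subject_id=str(i), s_A=float(pair_scores["s_A"][i].mean()),
                      s_B=float(pair_scores["s_B"][i].mean()),
                      n_repeats_averaged=config.n_repeats)
            for i in range(n)
        ]
        per_method[method] = {"pairs": pairs, "scores_long": pair_scores,
                              "per_repeat": per_repeat}

    # all-data disease-specific patterns, per classifier and group
    patterns_out: dict[str, dict[str, Pattern]] = {}
    for method in config.classifiers:
        spec = ClassifierSpec(method=method, inner_k=config.inner_k)
        patterns_out[method] = {}
        for grp in ("A", "B"):
            in_cohort = np.isin(labels, [grp, "HC"])
            t_cohort = np.where(labels[in_cohort] == grp, 1, -1)
            pattern, _ = fit_full_model(X[in_cohort], t_cohort, spec,
                                        config.inner_k, config.seed, mask_id,
                                        kind="disease_specific")
            patterns_out[method][grp] = pattern

    # RV coefficients between classifiers' (s_A, s_B) pair sets
    rv = {}
    methods = list(config.classifiers)
    def _pair_matrix(m):
        return np.array([[p.s_A, p.s_B] for p in per_method[m]["pairs"]])
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            rv[f"{a}|{b}"] = rv_coefficient(_pair_matrix(a), _pair_matrix(b))

    # second stage: A vs B in the score plane of one classifier
    if second_stage_method not in per_method:
        second_stage_method = methods[0]
    sel = np.isin(labels, ["A", "B"])
    S = _pair_matrix(second_stage_method)[sel]
    t2 = np.where(labels[sel] == "A", 1, -1)
    grid = [{"C": float(c), "scale": 1.0} for c in np.logspace(-3, 3, 7)]
    spec2 = ClassifierSpec(method="svm", grid=grid, inner_k=config.inner_k)
    scheme2 = FoldScheme(outer_k=config.outer_k, inner_k=config.inner_k,
                         n_repeats=config.n_repeats, seed=config.seed + 99)
    second_cv = nested_cv(S, t2, spec2, scheme2)
    log.info("second-stage (%s scores): %s", second_stage_method, second_cv.summary)

    return {"per_method": per_method, "patterns": patterns_out, "rv": rv,
            "second_stage": second_cv, "second_stage_method": second_stage_method,
            "second_stage_labels": t2}


# ---------------------------------------------------------------------------
# persistence + report

def save_direct_results(res: dict, outdir, config: RunConfig,
                        mask=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = {m: cv.summary for m, cv in res["cv"].items()}
    payload = {"experiment": "direct", "metrics": metrics,
               "score_pearson": res["score_pearson"],
               "provenance": config.provenance()}
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    rows = []
    for m, cv in res["cv"].items():
        for i, s in enumerate(cv.mean_scores):
            rows.append({"classifier": m, "subject": i, "label": int(cv.labels[i]),
                         "mean_score": float(s)})
    pd.DataFrame(rows).to_csv(outdir / "scores.csv", index=False)
    for m, cv in res["cv"].items():
        curve, _ = cv.pooled_roc()
        curve.to_csv(outdir / f"roc_{m}.csv", index=False)
    if mask is not None:
        from .patterns import save_pattern
        for m, pat in res["patterns"].items():
            save_pattern(pat, mask, outdir / f"pattern_direct_{m}.nii.gz")


def save_disease_specific_results(res: dict, outdir, config: RunConfig,
                                  mask=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "experiment": "disease_specific",
        "rv": res["rv"],
        "second_stage_method": res["second_stage_method"],
        "second_stage": res["second_stage"].summary,
        "provenance": config.provenance(),
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    rows = []
    for m, d in res["per_method"].items():
        for p in d["pairs"]:
            rows.append({"classifier": m, "subject_id": p.subject_id,
                         "s_A": p.s_A, "s_B": p.s_B,
                         "n_repeats_averaged": p.n_repeats_averaged})
    pd.DataFrame(rows).to_csv(outdir / "score_pairs.csv", index=False)
    if mask is not None:
        from .patterns import save_pattern
        for m, pats in res["patterns"].items():
            for grp, pat in pats.items():
                save_pattern(pat, mask, outdir / f"pattern_{grp}_vs_HC_{m}.nii.gz")


def report(results_dir) -> str:
    """Render a markdown summary of a completed run directory."""
    results_dir = Path(results_dir)
    metrics_path = results_dir / "metrics.json"
    if not metrics_path.exists():
        raise FileNotFoundError(f"no metrics.json in {results_dir}; run an experiment first")
    meta = json.loads(metrics_path.read_text())
    lines = [f"# Run report ({meta['experiment']})", ""]
    if meta["experiment"] == "direct":
        lines += ["| classifier | AUC | sensitivity | specificity |",
                  "|---|---|---|---|"]
        for m, s in meta["metrics"].items():
            lines.append(
                f"| {m} | {s['auc']:.3f} ± {s['auc_sd']:.3f} "
                f"| {s['sensitivity']:.3f} ± {s['sensitivity_sd']:.3f} "
                f"| {s['specificity']:.3f} ± {s['specificity_sd']:.3f} |")
        lines += ["", "## Pearson r between classifiers' subject scores", ""]
        for k, v in meta["score_pearson"].items():
            lines.append(f"- {k}: r = {v:.3f}")
    else:
        s = meta["second_stage"]
        lines += [
            f"Second stage ({meta['second_stage_method']} score pairs): "
            f"AUC {s['auc']:.3f} ± {s['auc_sd']:.3f}, "
            f"sens {s['sensitivity']:.3f}, spec {s['specificity']:.3f}", "",
            "## RV coefficients between score-pair sets", ""]
        for k, v in meta["rv"].items():
            lines.append(f"- {k}: RV = {v:.3f}")
        pairs_csv = results_dir / "score_pairs.csv"
        if pairs_csv.exists():
            _plot_score_plane(results_dir, meta)
    text = "\n".join(lines) + "\n"
    (results_dir / "report.md").write_text(text)
    return text


def _plot_score_plane(results_dir: Path, meta: dict) -> None:
    """Scatter of (s_A, s_B) score pairs for the second-stage classifier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(results_dir / "score_pairs.csv")
    df = df[df.classifier == meta["second_stage_method"]]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df.s_A, df.s_B, s=12)
    ax.set_xlabel("A-pattern expression score")
    ax.set_ylabel("B-pattern expression score")
    ax.set_title(f"Score plane ({meta['second_stage_method']})")
    fig.savefig(results_dir / "score_plane.png", dpi=100)
    plt.close(fig)
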