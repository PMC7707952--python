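"""End-to-end orchestration: simulate → extract → train → evaluate.

The flow mirrors the two-stage architecture: an RBF network classifies every
measured structure, per-case tallies of benign-classified structures feed the
numeric and percent case classifiers (thresholds optimized on training cases
only), and the metrics module scores both levels on the train, test and
combined splits.

Nucleus-level training labels are the case's histological diagnosis
propagated to its structures — exactly the supervision available in practice,
where a malignant slide also contains normal-looking cells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as cio
from .cases import CaseTally, CaseThreshold, case_score, classify_case, \
    optimize_threshold, tally_case
from .metrics import ConfusionMatrix, auc_ci, auc_ci_and_compare, confusion, \
    delong_auc_variance, performance_indices, two_proportion_test
from .morphometry import FEATURE_NAMES, ImagePatch, MorphometryError, \
    NucleusBoundary, extract_features
from .rbf import BENIGN, MALIGNANT, RBFConfig, RBFModel, fit_rbf
from .synthetic import CohortConfig, cohort_frames, simulate_cohort, \
    split_train_test

logger = logging.getLogger(__name__)

MODES = ("numeric", "percent")
SPLITS = ("train", "test", "combined")


# --------------------------------------------------------------------------
# stage: simulate

def cmd_simulate(
    config: CohortConfig | str | Path | None,
    out_dir: str | Path,
    train_fraction: float = 0.5,
) -> dict[str, Path]:
    """Generate a synthetic cohort, split it by case, and write CSVs + manifest."""
    cfg = _load_cohort_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    train, test = split_train_test(cohort, train_fraction=train_fraction,
                                   seed=cfg.seed)
    split = {c.case_id: "train" for c in train}
    split.update({c.case_id: "test" for c in test})
    cases_df, features_df = cohort_frames(cohort, split=split)
    paths = {"cases": out / "cases.csv", "features": out / "features.csv"}
    cases_df.to_csv(paths["cases"], index=False)
    cio.write_feature_table(features_df, paths["features"])
    paths["manifest"] = cio.write_manifest(
        out, cfg, {"cohort": cfg.seed, "split": cfg.seed}, list(paths.values())
    )
    logger.info("simulate: %d cases, %d structures -> %s",
                len(cohort), len(features_df), out)
    return paths


def _load_cohort_config(config) -> CohortConfig:
    if config is None:
        return CohortConfig()
    if isinstance(config, CohortConfig):
        return config
    raw = json.loads(Path(config).read_text())
    raw = raw.get("cohort", raw)
    if "strong_features" in raw:
        raw["strong_features"] = tuple(raw["strong_features"])
    return CohortConfig(**raw)


# --------------------------------------------------------------------------
# stage: extract

def cmd_extract(
    images_dir: str | Path,
    boundaries_csv: str | Path,
    out_csv: str | Path,
    blank_field: str | Path | None = None,
) -> pd.DataFrame:
    """Measure every delineated structure listed in the boundary CSV.

    Structures whose boundary fails validation (degenerate polygon, outside
    the image, ...) are skipped and logged; at least one structure must
    succeed.  Images are located by the boundary CSV's ``image`` column, or
    as ``<case_id>.png`` / ``.tif(f)`` under ``images_dir``.
    """
    images_dir = Path(images_dir)
    bdf = cio.read_boundaries(boundaries_csv)
    blank = cio.read_image(blank_field) if blank_field else None
    rows, skipped = [], 0
    image_cache: dict[str, np.ndarray] = {}
    for case_id, structure_id, image_name, verts in cio.boundaries_from_frame(bdf):
        try:
            pixels = _load_structure_image(images_dir, case_id, image_name,
                                           image_cache)
            patch = ImagePatch(pixels, blank_field=blank)
            fv = extract_features(patch, NucleusBoundary(verts))
        except (MorphometryError, FileNotFoundError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping %s/%s: %s", case_id, structure_id, exc)
            continue
        rows.append({"case_id": case_id, "structure_id": structure_id,
                     **fv.as_dict()})
    logger.info("extract: %d measured, %d skipped", len(rows), skipped)
    if not rows:
        raise RuntimeError("no structure could be measured")
    df = pd.DataFrame(rows)
    cio.write_feature_table(df, out_csv)
    return df


def _load_structure_image(images_dir, case_id, image_name, cache):
    if image_name is not None and not (isinstance(image_name, float)
                                       and np.isnan(image_name)):
        candidates = [images_dir / str(image_name)]
    else:
        candidates = [images_dir / f"{case_id}{ext}"
                      for ext in (".png", ".tif", ".tiff")]
    for cand in candidates:
        if cand.exists():
            key = str(cand)
            if key not in cache:
                cache[key] = cio.read_image(cand)
            return cache[key]
    raise FileNotFoundError(f"no image found for case {case_id!r}")


# --------------------------------------------------------------------------
# stage: train

@dataclass
class TrainResult:
    model: RBFModel
    thresholds: dict[str, CaseThreshold]  # mode -> threshold
    train_tallies: list[CaseTally]
    train_truth: list[str]


def nucleus_labels(features_df: pd.DataFrame, cases_df: pd.DataFrame) -> pd.Series:
    """Histology of the parent case, propagated to every structure."""
    lookup = cases_df.set_index("case_id")["histology"]
    return features_df["case_id"].map(lookup)


def predict_structures(model: RBFModel, features_df: pd.DataFrame) -> np.ndarray:
    return model.predict(features_df[list(FEATURE_NAMES)].to_numpy(float))


def tally_frame(
    case_ids: pd.Series, predicted: np.ndarray
) -> tuple[list[CaseTally], list[str]]:
    """Per-case tallies (sorted by case_id) from structure-level predictions."""
    df = pd.DataFrame({"case_id": case_ids.to_numpy(), "pred": predicted})
    tallies = [
        tally_case(str(cid), grp["pred"].tolist())
        for cid, grp in df.groupby("case_id", sort=True)
    ]
    return tallies, [t.case_id for t in tallies]


def train_stage(
    features_df: pd.DataFrame,
    cases_df: pd.DataFrame,
    rbf_config: RBFConfig | None = None,
) -> TrainResult:
    """Fit the RBF on training-split structures and optimize both thresholds."""
    if "split" not in cases_df.columns:
        raise ValueError("cases table has no 'split' column; run the split first")
    train_cases = cases_df[cases_df["split"] == "train"]
    feats = features_df[features_df["case_id"].isin(train_cases["case_id"])]
    labels = nucleus_labels(feats, cases_df)
    model = fit_rbf(
        feats[list(FEATURE_NAMES)].to_numpy(float),
        labels.to_numpy(),
        config=rbf_config,
        feature_names=list(FEATURE_NAMES),
    )
    predicted = predict_structures(model, feats)
    tallies, order = tally_frame(feats["case_id"], predicted)
    truth = train_cases.set_index("case_id")["histology"].loc[order].tolist()
    thresholds = {mode: optimize_threshold(tallies, truth, mode) for mode in MODES}
    return TrainResult(model=model, thresholds=thresholds,
                       train_tallies=tallies, train_truth=truth)


def cmd_train(
    features_csv: str | Path,
    cases_csv: str | Path,
    config: RBFConfig | str | Path | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """File-based wrapper around :func:`train_stage`; writes model + thresholds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features_df = cio.read_feature_table(features_csv)
    cases_df = pd.read_csv(cases_csv)
    cfg = _load_rbf_config(config)
    result = train_stage(features_df, cases_df, cfg)
    paths = {"model": out / "model.json"}
    result.model.to_json(paths["model"])
    for mode in MODES:
        paths[f"threshold_{mode}"] = out / f"threshold_{mode}.json"
        result.thresholds[mode].to_json(paths[f"threshold_{mode}"])
    report = _training_report(result)
    paths["training_report"] = out / "training_report.json"
    paths["training_report"].write_text(json.dumps(report, indent=1))
    paths["manifest"] = cio.write_manifest(
        out, cfg, {"rbf": cfg.seed if cfg else 0}, list(paths.values())
    )
    return paths


def _load_rbf_config(config) -> RBFConfig:
    if config is None:
        return RBFConfig()
    if isinstance(config, RBFConfig):
        return config
    raw = json.loads(Path(config).read_text())
    raw = raw.get("rbf", raw)
    if "k_grid" in raw:
        raw["k_grid"] = tuple(raw["k_grid"])
    return RBFConfig(**raw)


def _training_report(result: TrainResult) -> dict:
    report: dict = {"thresholds": {m: result.thresholds[m].value for m in MODES},
                    "case_indices": {}}
    for mode in MODES:
        pred = [classify_case(t, result.thresholds[mode])
                for t in result.train_tallies]
        cm = confusion(result.train_truth, pred)
        report["case_indices"][mode] = {
            "confusion": dataclasses.asdict(cm),
            "indices": performance_indices(cm).as_dict(rounded=True),
        }
    return report


# --------------------------------------------------------------------------
# stage: evaluate

def _index_block(cm: ConfusionMatrix) -> dict:
    return {"confusion": dataclasses.asdict(cm),
            "indices": performance_indices(cm).as_dict()}


def _split_masks(features_df, cases_df) -> dict[str, pd.Series]:
    split_of = cases_df.set_index("case_id")["split"]
    col = features_df["case_id"].map(split_of)
    return {"train": col == "train", "test": col == "test",
            "combined": col.isin(["train", "test"])}


def _ztests(cm_train: ConfusionMatrix, cm_test: ConfusionMatrix) -> dict:
    pairs = {
        "sensitivity": ((cm_train.tp, cm_train.tp + cm_train.fn),
                        (cm_test.tp, cm_test.tp + cm_test.fn)),
        "specificity": ((cm_train.tn, cm_train.tn + cm_train.fp),
                        (cm_test.tn, cm_test.tn + cm_test.fp)),
        "oa": ((cm_train.tp + cm_train.tn, cm_train.total),
               (cm_test.tp + cm_test.tn, cm_test.total)),
    }
    out = {}
    for name, ((x1, n1), (x2, n2)) in pairs.items():
        out[name] = dataclasses.asdict(two_proportion_test(x1, n1, x2, n2))
    return out


def evaluate_stage(
    model: RBFModel,
    thresholds: dict[str, CaseThreshold],
    features_df: pd.DataFrame,
    cases_df: pd.DataFrame,
) -> dict:
    """Score the fitted system at both levels on train, test and combined sets.

    Returns a nested report: nucleus- and case-level confusion matrices and
    index panels per split, train-vs-test z-tests, ROC/AUC with DeLong CIs
    per classifier, the unpaired train-vs-test AUC comparison, and the paired
    numeric-vs-percent comparison per split.
    """
    truth_nuc = nucleus_labels(features_df, cases_df).to_numpy()
    predicted = predict_structures(model, features_df)
    masks = _split_masks(features_df, cases_df)

    report: dict = {"nucleus": {}, "cases": {m: {} for m in MODES},
                    "z_tests": {}, "roc": {m: {} for m in MODES},
                    "auc_comparisons": {}}
    nuc_cm = {}
    for split, mask in masks.items():
        cm = confusion(truth_nuc[mask.to_numpy()], predicted[mask.to_numpy()])
        nuc_cm[split] = cm
        report["nucleus"][split] = _index_block(cm)
    report["z_tests"]["nucleus"] = _ztests(nuc_cm["train"], nuc_cm["test"])

    hist = cases_df.set_index("case_id")["histology"]
    case_cm: dict[str, dict[str, ConfusionMatrix]] = {m: {} for m in MODES}
    scores: dict[str, dict[str, np.ndarray]] = {m: {} for m in MODES}
    auc_se: dict[str, dict[str, float]] = {m: {} for m in MODES}
    auc_val: dict[str, dict[str, float]] = {m: {} for m in MODES}
    case_truth: dict[str, list[str]] = {}
    for split, mask in masks.items():
        sub = features_df[mask.to_numpy()]
        tallies, order = tally_frame(sub["case_id"], predicted[mask.to_numpy()])
        truth = hist.loc[order].tolist()
        case_truth[split] = truth
        for mode in MODES:
            pred = [classify_case(t, thresholds[mode]) for t in tallies]
            cm = confusion(truth, pred)
            case_cm[mode][split] = cm
            report["cases"][mode][split] = _index_block(cm)
            scores[mode][split] = np.array([case_score(t, mode) for t in tallies])
            curve = auc_ci(scores[mode][split], truth)
            aucs, cov = delong_auc_variance(scores[mode][split][None, :], truth)
            auc_val[mode][split] = 100.0 * float(aucs[0])
            auc_se[mode][split] = 100.0 * float(np.sqrt(max(cov[0, 0], 0.0)))
            report["roc"][mode][split] = {
                "auc": curve.auc,
                "ci": [curve.auc_ci_low, curve.auc_ci_high],
                "fpr": curve.fpr.tolist(),
                "tpr": curve.tpr.tolist(),
                "thresholds": curve.thresholds.tolist(),
            }
    for mode in MODES:
        report["z_tests"][mode] = _ztests(case_cm[mode]["train"],
                                          case_cm[mode]["test"])
        # train and test hold different cases: unpaired z on DeLong variances
        diff = auc_val[mode]["train"] - auc_val[mode]["test"]
        s = math.hypot(auc_se[mode]["train"], auc_se[mode]["test"])
        z = 0.0 if s == 0 else diff / s
        report["auc_comparisons"][f"{mode}_train_vs_test"] = {
            "difference": diff, "z": z,
            "p_value": float(2 * stats.norm.sf(abs(z))),
        }
    for split in SPLITS:
        comp = auc_ci_and_compare(scores["numeric"][split],
                                  scores["percent"][split], case_truth[split])
        report["auc_comparisons"][f"numeric_vs_percent_{split}"] = \
            dataclasses.asdict(comp)
    return report


def cmd_evaluate(
    model_json: str | Path,
    threshold_jsons: dict[str, str | Path],
    features_csv: str | Path,
    cases_csv: str | Path,
    out_dir: str | Path,
) -> dict[str, Path]:
    """File-based wrapper around :func:`evaluate_stage`; writes report + ROC CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = RBFModel.from_json(Path(model_json))
    thresholds = {m: CaseThreshold.from_json(Path(p))
                  for m, p in threshold_jsons.items()}
    features_df = cio.read_feature_table(features_csv)
    cases_df = pd.read_csv(cases_csv)
    report = evaluate_stage(model, thresholds, features_df, cases_df)

    paths = {"report": out / "evaluation_report.json"}
    paths["report"].write_text(json.dumps(report, indent=1, default=float))
    rows = []
    for level, blocks in (("nucleus", report["nucleus"]),):
        for split, blk in blocks.items():
            rows.append({"level": level, "classifier": "rbf", "split": split,
                         **blk["indices"]})
    for mode in MODES:
        for split, blk in report["cases"][mode].items():
            rows.append({"level": "case", "classifier": mode, "split": split,
                         **blk["indices"]})
    paths["indices"] = out / "performance_indices.csv"
    pd.DataFrame(rows).to_csv(paths["indices"], index=False)
    for mode in MODES:
        for split in SPLITS:
            blk = report["roc"][mode][split]
            roc_path = out / f"roc_{mode}_{split}.csv"
            pd.DataFrame({
                "threshold": blk["thresholds"],
                "fpr": blk["fpr"], "tpr": blk["tpr"],
            }).to_csv(roc_path, index=False)
            paths[f"roc_{mode}_{split}"] = roc_path
    paths["manifest"] = cio.write_manifest(out, None, {}, list(paths.values()))
    return paths


# --------------------------------------------------------------------------
# one-call convenience

def run_pipeline(
    cohort_config: CohortConfig | None = None,
    rbf_config: RBFConfig | None = None,
    train_fraction: float = 0.5,
) -> dict:
    """simulate → split → train → evaluate, entirely in memory.

    Returns ``{"model", "thresholds", "report", "features_df", "cases_df"}``.
    """
    cfg = cohort_config or CohortConfig()
    cohort = simulate_cohort(cfg)
    train, test = split_train_test(cohort, train_fraction=train_fraction,
                                   seed=cfg.seed)
    split = {c.case_id: "train" for c in train}
    split.update({c.case_id: "test" for c in test})
    cases_df, features_df = cohort_frames(cohort, split=split)
    result = train_stage(features_df, cases_df, rbf_config)
    report = evaluate_stage(result.model, result.thresholds,
                            features_df, cases_df)
    return {
        "model": result.model,
        "thresholds": result.thresholds,
        "report": report,
        "features_df": features_df,
        "cases_df": cases_df,
    }
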