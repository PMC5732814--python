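"""End-to-end study orchestration.

``run_extract`` turns a directory of image/mask pairs into the per-patient
feature table; ``run_study`` runs the three analyses — correlation screen,
median-split Kaplan-Meier/log-rank, and paired TNM-vs-Combined random-forest
prediction with permutation importance — over the configured grouping
variables and writes a report bundle (CSV/JSON plus a manifest).

Complement groups (e.g. non-LCC, non-T2) are first-class group specifiers:
a prediction target ``(grouping, level)`` is always evaluated alongside its
complement so subgroup-specific effects can be contrasted against the rest
of the cohort.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .features import FEATURE_NAMES, extract_features
from .forest import CVReport, compare_feature_sets, encode_clinical, make_labels, oob_importance
from .imaging import read_mask, read_volume
from .survival import km_report_table, load_cohort, screen_group

__all__ = ["run_extract", "run_study", "select_group", "StudyReport"]

log = logging.getLogger("radsurv")

DEFAULT_GROUPINGS = ("subtype", "T", "N", "M", "stage")


def _find_pairs(image_dir: str, mask_dir: str) -> list[tuple[str, str, str]]:
    """Match image and mask files by patient id.

    An image file ``<id>_image.<ext>`` (or ``<id>.<ext>``) pairs with
    ``<id>_mask.<ext>`` (or ``<id>.<ext>``) in the mask directory.
    """
    exts = (".nii", ".nii.gz", ".nrrd")

    def stem(fname: str) -> str:
        for ext in exts:
            if fname.endswith(ext):
                return fname[: -len(ext)]
        return ""

    masks: dict[str, str] = {}
    for fname in sorted(os.listdir(mask_dir)):
        s = stem(fname)
        if s:
            masks[s.removesuffix("_mask")] = os.path.join(mask_dir, fname)
    pairs = []
    for fname in sorted(os.listdir(image_dir)):
        s = stem(fname)
        if not s:
            continue
        pid = s.removesuffix("_image")
        if pid in masks:
            pairs.append((pid, os.path.join(image_dir, fname), masks[pid]))
        else:
            log.warning("no mask found for patient %s; skipped", pid)
    return pairs


def run_extract(
    image_dir: str,
    mask_dir: str,
    out_csv: str | None = None,
    n_levels: int = 32,
) -> pd.DataFrame:
    """Extract the 24-feature vector for every image/mask pair.

    Per-patient failures are logged and the run continues; the result has
    one row per successful patient.  A run with zero successes is an error.
    """
    rows = []
    for pid, img_path, mask_path in _find_pairs(image_dir, mask_dir):
        try:
            vol = read_volume(img_path)
            mask = read_mask(mask_path)
            feats = extract_features(vol, mask, n_levels=n_levels)
        except Exception as exc:  # noqa: BLE001 - per-patient isolation is the contract
            log.warning("feature extraction failed for %s: %s", pid, exc)
            continue
        rows.append({"id": pid, **feats})
    if not rows:
        raise ValueError("feature extraction succeeded for zero patients")
    table = pd.DataFrame(rows)[["id", *FEATURE_NAMES]]
    if out_csv:
        table.to_csv(out_csv, index=False, float_format="%.10g")
    return table


def select_group(
    cohort: pd.DataFrame, grouping: str, level, complement: bool = False
) -> pd.DataFrame:
    """Rows of one group level, or of its complement (``non-<level>``)."""
    member = cohort[grouping] == level
    return cohort[~member if complement else member]


@dataclass
class StudyReport:
    """Bundle of the three analyses plus the run manifest."""

    screens: dict[str, pd.DataFrame]
    km: dict[str, pd.DataFrame]
    cv: dict[str, dict[str, CVReport]]
    importance: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, frames in (("screen", self.screens), ("km", self.km)):
            for grouping, frame in frames.items():
                frame.to_csv(os.path.join(out_dir, f"{name}_{grouping}.csv"), index=False)
        cv_json = {
            label: {
                fs: {"mean_auc": rep.mean_auc, "fold_aucs": rep.fold_aucs, "n": rep.n,
                     "excluded_folds": rep.n_excluded_folds}
                for fs, rep in reports.items()
            }
            for label, reports in self.cv.items()
        }
        with open(os.path.join(out_dir, "cv.json"), "w") as fh:
            json.dump(cv_json, fh, indent=2)
        for label, frame in self.importance.items():
            frame.to_csv(os.path.join(out_dir, f"importance_{label}.csv"), index=False)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _default_predict_groups(cohort: pd.DataFrame, groupings) -> list[tuple[str, object]]:
    """One headline prediction target per grouping: its largest level."""
    targets = []
    for grouping in groupings:
        counts = cohort[grouping].value_counts()
        if len(counts):
            targets.append((grouping, counts.index[0]))
    return targets


def run_study(
    cohort: pd.DataFrame | None = None,
    feature_csv: str | None = None,
    clinical_csv: str | None = None,
    groupings=DEFAULT_GROUPINGS,
    predict_groups: list[tuple[str, object]] | None = None,
    n_trees: int = 500,
    n_folds: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    importance: bool = True,
    min_predict: int = 20,
    out_dir: str | None = None,
) -> StudyReport:
    """Run the full three-stage study on a cohort table.

    Per grouping variable: the Holm-corrected Spearman screen and the
    median-split KM/log-rank table.  Per prediction target ``(grouping,
    level)`` — default: the largest level of each grouping — the paired
    TNM-vs-Combined cross-validation is run on the group *and* on its
    complement, and OOB permutation importance is computed for the combined
    feature set on the group.  Groups too small for a stage are reported as
    skipped, never silently dropped.
    """
    if cohort is None:
        if feature_csv is None or clinical_csv is None:
            raise ValueError("pass either a cohort table or feature_csv + clinical_csv")
        cohort = load_cohort(feature_csv, clinical_csv)
    missing = [f for f in FEATURE_NAMES if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks feature columns: {missing[:3]}...")

    screens: dict[str, pd.DataFrame] = {}
    km: dict[str, pd.DataFrame] = {}
    skipped: list[dict] = []
    for grouping in groupings:
        screens[grouping] = screen_group(cohort, grouping, alpha=alpha)
        km[grouping] = km_report_table(cohort, grouping, alpha=alpha)

    if predict_groups is None:
        predict_groups = _default_predict_groups(cohort, groupings)

    cv: dict[str, dict[str, CVReport]] = {}
    imp: dict[str, pd.DataFrame] = {}
    for grouping, level in predict_groups:
        for complement in (False, True):
            label = f"{'non-' if complement else ''}{level}"
            sub = select_group(cohort, grouping, level, complement=complement)
            if len(sub) < min_predict:
                skipped.append({"stage": "predict", "grouping": grouping,
                                "group": label, "n": len(sub)})
                log.warning("prediction group %s too small (n=%d); skipped", label, len(sub))
                continue
            cv[label] = compare_feature_sets(
                sub, list(FEATURE_NAMES), n_trees=n_trees, n_folds=n_folds, seed=seed
            )
            if importance and not complement:
                clin = encode_clinical(sub)
                keep = clin.notna().all(axis=1)
                sub_k, clin_k = sub.loc[keep], clin.loc[keep]
                y, _ = make_labels(sub_k)
                X = np.hstack([clin_k.to_numpy(float),
                               sub_k[list(FEATURE_NAMES)].to_numpy(float)])
                names = list(clin_k.columns) + list(FEATURE_NAMES)
                imp[label] = oob_importance(
                    X, y, feature_names=names, n_trees=n_trees, n_folds=n_folds, seed=seed
                )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "n_trees": n_trees,
        "n_folds": n_folds,
        "alpha": alpha,
        "groupings": list(groupings),
        "predict_groups": [list(pg) for pg in predict_groups],
        "family_sizes": {g: int(frame["family_size"].iloc[0]) for g, frame in screens.items()},
        "n_patients": int(len(cohort)),
        "skipped": skipped,
    }
    report = StudyReport(screens=screens, km=km, cv=cv, importance=imp, manifest=manifest)
    if out_dir:
        report.save(out_dir)
    return report


def plot_km(report_row: pd.Series, group: pd.DataFrame, path: str) -> None:
    """Save the two-arm Kaplan-Meier plot for one median-split report row."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import median_split_km

    rep = median_split_km(group, report_row["feature"])
    fig, ax = plt.subplots(figsize=(5, 4))
    rep.below.plot_survival_function(ax=ax, label=f"< median (n={rep.n_below})")
    rep.above.plot_survival_function(ax=ax, label=f">= median (n={rep.n_above})")
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_title(f"{report_row['feature']} in {report_row['group']}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
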