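"""Segmentation overlap metrics, T-stage classification metrics, and agreement.

Per-case overlap is measured with the Dice similarity coefficient
DSC = 2|X∩Y| / (|X|+|Y|) and the intersection-over-union IOU = |X∩Y| / |X∪Y|
(related by DSC = 2·IOU/(1+IOU)). Staging performance is summarized with a
3x3 confusion matrix and one-vs-rest precision/recall(sensitivity)/
specificity/F1 per class plus macro and support-weighted averages.
Measurement agreement between two raters (e.g. predicted vs ground-truth
geometry) uses the two-way random-effects, absolute-agreement, single-measure
intraclass correlation ICC(2,1), with the conventional concordance bands
(excellent above 0.95, good above 0.80).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from sklearn.metrics import confusion_matrix

from .io import CohortManifest, read_mask
from .quantify import StagingRules, classify_t_stage, compute_geometry, largest_component
from .volume import Mask3D

__all__ = [
    "SegMetrics",
    "ClassificationReport",
    "AgreementEntry",
    "AgreementReport",
    "dsc",
    "iou",
    "classification_metrics",
    "icc_agreement",
    "evaluate_cohort",
]

STAGES = ("T1", "T2", "T3")


def _check_pair(x: Mask3D, y: Mask3D) -> tuple[np.ndarray, np.ndarray]:
    if x.shape != y.shape:
        raise ValueError(f"mask shape mismatch: {x.shape} vs {y.shape}")
    return x.labels > 0, y.labels > 0


def dsc(x: Mask3D, y: Mask3D) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|).

    Both masks empty returns 1 with a warning (nothing to find, nothing
    found); exactly one empty returns 0.
    """
    a, b = _check_pair(x, y)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("dsc: both masks empty, returning 1.0 by convention", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def iou(x: Mask3D, y: Mask3D) -> float:
    """Intersection over union |X∩Y| / |X∪Y| with the same empty conventions."""
    a, b = _check_pair(x, y)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("iou: both masks empty, returning 1.0 by convention", stacklevel=2)
        return 1.0
    return int((a & b).sum()) / union


@dataclass
class SegMetrics:
    """Per-case DSC/IOU table with cohort mean and SD."""

    per_case: pd.DataFrame  # columns: case_id, dsc, iou

    @property
    def mean_dsc(self) -> float:
        return float(self.per_case["dsc"].mean())

    @property
    def sd_dsc(self) -> float:
        return float(self.per_case["dsc"].std())

    @property
    def mean_iou(self) -> float:
        return float(self.per_case["iou"].mean())

    @property
    def sd_iou(self) -> float:
        return float(self.per_case["iou"].std())

    def summary(self) -> str:
        return (
            f"DSC {self.mean_dsc:.3f} +/- {self.sd_dsc:.3f}, "
            f"IOU {self.mean_iou:.3f} +/- {self.sd_iou:.3f} "
            f"(n={len(self.per_case)})"
        )


@dataclass
class ClassificationReport:
    """Confusion matrix and one-vs-rest metrics over the T categories."""

    confusion: np.ndarray  # 3x3, rows = truth, cols = prediction
    per_class: pd.DataFrame  # precision, recall, specificity, f1, support per stage
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    n: int

    def summary(self) -> str:
        lines = [f"accuracy {self.accuracy:.3f} (n={self.n})", str(self.per_class.round(3))]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "labels": list(STAGES),
            "per_class": self.per_class.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "n": self.n,
        }


def classification_metrics(true_stages, predicted_stages) -> ClassificationReport:
    """One-vs-rest staging metrics from paired label lists.

    A class absent from the truth has undefined recall/F1; those entries are
    reported as NaN with a warning and macro averages are taken over the
    defined classes only.
    """
    t = list(true_stages)
    p = list(predicted_stages)
    if len(t) == 0 or len(t) != len(p):
        raise ValueError("need equal-length, non-empty label lists")
    bad = set(t) | set(p) - set(STAGES)
    if not set(t) | set(p) <= set(STAGES):
        raise ValueError(f"labels outside {STAGES}: {sorted(bad - set(STAGES))}")
    cm = confusion_matrix(t, p, labels=list(STAGES))
    n = cm.sum()
    rows = {}
    for i, stage in enumerate(STAGES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        support = int(cm[i].sum())
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if support else np.nan
        specificity = tn / (tn + fp) if tn + fp else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if support and tp + fp and (precision + recall) > 0
            else (0.0 if support else np.nan)
        )
        if not support:
            warnings.warn(f"class {stage} absent from truth; recall/F1 undefined", stacklevel=2)
        rows[stage] = {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
            "support": support,
        }
    per_class = pd.DataFrame(rows).T
    defined = per_class.dropna(subset=["recall"])
    macro = {
        k: float(defined[k].mean()) for k in ("precision", "recall", "specificity", "f1")
    }
    weights = per_class["support"] / n
    weighted = {
        k: float(np.nansum(per_class[k] * weights)) for k in ("precision", "recall", "specificity", "f1")
    }
    return ClassificationReport(
        confusion=cm,
        per_class=per_class,
        accuracy=float(np.trace(cm) / n),
        macro_avg=macro,
        weighted_avg=weighted,
        n=int(n),
    )


def _band(icc: float) -> str:
    if icc > 0.95:
        return "excellent"
    if icc > 0.80:
        return "good"
    return "poor"


@dataclass
class AgreementEntry:
    feature: str
    icc: float
    band: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class AgreementReport:
    entries: list[AgreementEntry]
    model: str = "ICC2 (two-way random, absolute agreement, single measure)"

    def summary(self) -> str:
        lines = [self.model]
        for e in self.entries:
            lines.append(
                f"  {e.feature}: ICC {e.icc:.3f} ({e.band}); "
                f"A {e.mean_a:.1f} +/- {e.sd_a:.1f}, B {e.mean_b:.1f} +/- {e.sd_b:.1f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"model": self.model, "entries": [e.to_dict() for e in self.entries]}


def icc_agreement(values_a, values_b, feature: str = "value") -> AgreementEntry:
    """ICC(2,1) agreement between two paired measurement series.

    Absolute agreement penalizes systematic offsets between the raters, the
    appropriate behaviour when comparing an automatic measurement against a
    reference one.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D series with n >= 3")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate: zero total variance")
    n = len(a)
    long = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["A", "B"], n),
            "ratings": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="ratings"
        )
    # two-way random, absolute agreement, single measure: labelled ICC2 in
    # older pingouin releases and ICC(A,1) in newer ones
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    icc = float(table.loc[sel, "ICC"].iloc[0])
    return AgreementEntry(
        feature=feature,
        icc=icc,
        band=_band(icc),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n=n,
    )


def evaluate_cohort(
    manifest: CohortManifest,
    predictions_dir: str | Path,
    out_dir: str | Path | None = None,
    staging: StagingRules | None = None,
    staging_feature: str = "maximal_diameter_mm",
) -> tuple[SegMetrics, ClassificationReport, AgreementReport]:
    """Full cohort evaluation of predicted against ground-truth masks.

    Expects ``<case_id>_pred.nii.gz`` in ``predictions_dir`` for every
    manifest case; missing predictions are flagged, excluded, and counted.
    Produces per-case DSC/IOU, geometry of both masks, staging of both
    (on ``staging_feature``), classification metrics of predicted vs true
    stage, and ICC agreement of volume and diameters. Writes
    ``segmetrics.csv``, ``classification.json`` and ``agreement.json`` when
    ``out_dir`` is given.
    """
    staging = staging or StagingRules()
    predictions_dir = Path(predictions_dir)
    rows, skipped = [], []
    for row in manifest:
        pred_path = predictions_dir / f"{row['case_id']}_pred.nii.gz"
        if not pred_path.exists():
            skipped.append(str(row["case_id"]))
            continue
        gt = read_mask(row["mask_path"])
        pred = read_mask(pred_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            case_dsc, case_iou = dsc(pred, gt), iou(pred, gt)
            geo_gt = compute_geometry(largest_component(gt))
            geo_pred = compute_geometry(largest_component(pred))
        rows.append(
            {
                "case_id": row["case_id"],
                "dsc": case_dsc,
                "iou": case_iou,
                "stage_true": classify_t_stage(getattr(geo_gt, staging_feature), staging),
                "stage_pred": classify_t_stage(getattr(geo_pred, staging_feature), staging),
                **{f"gt_{k}": v for k, v in geo_gt.as_dict().items()},
                **{f"pred_{k}": v for k, v in geo_pred.as_dict().items()},
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} case(s) without predictions excluded: {skipped}",
                      stacklevel=2)
    if not rows:
        raise ValueError("no evaluable cases: every manifest case lacks a prediction")
    table = pd.DataFrame(rows)
    seg = SegMetrics(per_case=table[["case_id", "dsc", "iou"]].copy())
    clf = classification_metrics(table["stage_true"], table["stage_pred"])
    agreement = AgreementReport(
        entries=[
            icc_agreement(table["pred_voxel_volume_mm3"], table["gt_voxel_volume_mm3"], "volume_mm3"),
            icc_agreement(
                table["pred_maximal_diameter_mm"], table["gt_maximal_diameter_mm"], "maximal_diameter_mm"
            ),
            icc_agreement(
                table["pred_minimal_diameter_mm"], table["gt_minimal_diameter_mm"], "minimal_diameter_mm"
            ),
        ]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "segmetrics.csv", index=False)
        payload = clf.to_dict()
        payload["excluded_cases"] = skipped
        (out_dir / "classification.json").write_text(json.dumps(payload, indent=2))
        (out_dir / "agreement.json").write_text(json.dumps(agreement.to_dict(), indent=2))
    return seg, clf, agreement
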