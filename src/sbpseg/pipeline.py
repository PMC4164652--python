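"""End-to-end cohort pipeline: segment -> quantify -> compare -> classify.

``run_pipeline`` ties all stages together for a cohort of subjects (either
synthetic, generated on the fly, or loaded from per-subject CSVs): per-subject
KS segmentation, patch statistics and spectral ``A_max``; cohort-level pooled
length distributions, two-sample KS group comparisons, Pearson correlations of
each quantifier with AHI, per-feature ROC analyses, and the combined
(``<L>``, ``A_max``) rule.  Per-subject failures are isolated and logged; the
cohort stages run on the surviving subjects.  Everything is reproducible from
the root seed, and the report records all effective parameters plus a
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .classify import DecisionRule2D, roc_curve, rule2d_evaluate
from .patch_stats import (
    SubjectFeatures,
    ks_two_sample,
    length_ccdf,
    pearson,
    pooled_ccdf,
    quartiles,
    subject_features,
)
from .segmentation import SegmentationConfig, segment
from .spectral import DEFAULT_BAND, WelchParams, amax_from_series
from .synthetic import DEFAULT_AHI_RANGES, DEFAULT_GROUP_SIZES, gen_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

FEATURES_ANALYZED = ("mean_L", "mean_var", "a_max")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with the analysis defaults."""

    alpha: float = 0.01
    l0: int = 33
    welch: WelchParams = field(default_factory=WelchParams)
    band: tuple[float, float] = DEFAULT_BAND
    seed: int = 0
    n_beats: int = 14400
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    ahi_ranges: dict = field(default_factory=lambda: dict(DEFAULT_AHI_RANGES))
    input_dir: str | None = None  # if set, read subjects from CSVs instead
    metadata_csv: str | None = None  # subject_id, group, ahi for input_dir mode
    out_dir: str | None = None
    rule: str = "and_negative"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        welch = WelchParams(**raw.pop("welch", {}))
        band = tuple(raw.pop("band", DEFAULT_BAND))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(welch=welch, band=band, **known)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "alpha": self.alpha, "l0": self.l0, "band": list(self.band),
                "welch": [self.welch.window, self.welch.nperseg,
                          self.welch.resolved_noverlap()],
                "seed": self.seed, "n_beats": self.n_beats,
                "group_sizes": self.group_sizes, "ahi_ranges": self.ahi_ranges,
                "rule": self.rule,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_subjects(config: PipelineConfig):
    """Either synthesize the cohort or read (series, metadata) from disk."""
    if config.input_dir is None:
        cohort = gen_cohort(
            group_sizes=config.group_sizes,
            ahi_ranges=config.ahi_ranges,
            seed=config.seed,
            n_beats=config.n_beats,
        )
        return [(s.subject_id, s.spec.group, s.spec.ahi, s.series) for s in cohort]
    if config.metadata_csv is None:
        raise ValueError("input_dir mode requires metadata_csv (subject_id, group, ahi)")
    import pandas as pd

    meta = pd.read_csv(config.metadata_csv)
    required = {"subject_id", "group", "ahi"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata CSV needs columns {sorted(required)}")
    out = []
    for row in meta.itertuples():
        series = sio.read_beat_series(Path(config.input_dir) / f"{row.subject_id}.csv")
        out.append((str(row.subject_id), str(row.group), float(row.ahi), series))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the cohort report."""
    seg_config = SegmentationConfig(alpha=config.alpha, l0=config.l0)
    seg_config.resolve_curve()  # fail fast & reuse across subjects
    subjects = _load_subjects(config)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "subjects").mkdir(parents=True, exist_ok=True)

    features: list[SubjectFeatures] = []
    lengths_by_group: dict[str, list[np.ndarray]] = {}
    failures: list[dict] = []
    for sid, group, ahi, series in subjects:
        try:
            seg = segment(series, seg_config)
            amax = amax_from_series(series, seg, config.welch, config.band)
            feats = subject_features(seg, a_max=amax.a_max, subject_id=sid,
                                     group=group, ahi=ahi)
        except Exception as exc:  # isolate per-subject failures
            logger.exception("subject %s failed; excluded from cohort stages", sid)
            failures.append({"subject_id": sid, "error": str(exc)})
            continue
        features.append(feats)
        lengths_by_group.setdefault(group, []).append(seg.lengths)
        if out_dir:
            sio.write_beat_series(series, out_dir / "subjects" / f"{sid}.csv")
            sio.write_segments(seg, out_dir / "subjects" / f"{sid}.segments.csv")

    if not features:
        raise RuntimeError("no subject survived the per-subject stages")

    report: dict = {
        "config": {
            "alpha": config.alpha, "l0": config.l0,
            "welch": {"window": config.welch.window, "nperseg": config.welch.nperseg,
                      "noverlap": config.welch.resolved_noverlap()},
            "band": list(config.band), "seed": config.seed,
            "n_beats": config.n_beats, "rule": config.rule,
            "hash": config.config_hash(),
        },
        "n_subjects": len(features),
        "failures": failures,
    }

    # --- cohort-level distributions and tests -----------------------------
    groups_present = sorted(lengths_by_group)
    report["group_ccdf"] = {
        g: {
            "lengths": pooled_ccdf(lengths_by_group[g]).lengths,
            "ccdf": pooled_ccdf(lengths_by_group[g]).ccdf,
        }
        for g in groups_present
    }
    ks_tests = {}
    if "C" in lengths_by_group:
        pooled_c = np.concatenate(lengths_by_group["C"])
        for g in groups_present:
            if g == "C":
                continue
            d, p = ks_two_sample(np.concatenate(lengths_by_group[g]), pooled_c)
            ks_tests[f"pooled_lengths_{g}_vs_C"] = {"D": d, "p": p}
        for feat in FEATURES_ANALYZED:
            vals_c = [getattr(f, feat) for f in features if f.group == "C"]
            for g in groups_present:
                if g == "C":
                    continue
                vals_g = [getattr(f, feat) for f in features if f.group == g]
                if len(vals_c) >= 2 and len(vals_g) >= 2:
                    d, p = ks_two_sample(vals_g, vals_c)
                    ks_tests[f"{feat}_{g}_vs_C"] = {"D": d, "p": p}
    report["ks_tests"] = ks_tests

    ahi = np.array([f.ahi for f in features])
    report["correlations_with_ahi"] = {}
    for feat in FEATURES_ANALYZED:
        vals = np.array([getattr(f, feat) for f in features])
        if np.std(vals) > 0 and np.std(ahi) > 0:
            report["correlations_with_ahi"][feat] = pearson(vals, ahi)
    report["quartiles"] = {
        feat: {
            g: quartiles([getattr(f, feat) for f in features if f.group == g])
            for g in groups_present
            if sum(f.group == g for f in features) >= 1
        }
        for feat in ("mean_var", "mean_mu")
    }

    # --- classification ----------------------------------------------------
    labels = np.array([f.is_apneic for f in features])
    if labels.any() and not labels.all():
        rocs = {}
        for feat in FEATURES_ANALYZED:
            vals = np.array([getattr(f, feat) for f in features])
            roc = roc_curve(vals, labels)
            rocs[feat] = {
                "auc": roc.auc,
                "optimal_threshold": roc.optimal_threshold,
                "accuracy": roc.accuracy,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        report["roc"] = rocs
        rule = DecisionRule2D(
            threshold_L=rocs["mean_L"]["optimal_threshold"],
            threshold_A=rocs["a_max"]["optimal_threshold"],
            rule=config.rule,
        )
        mean_L = np.array([f.mean_L for f in features])
        a_max = np.array([f.a_max for f in features])
        r2d = rule2d_evaluate(mean_L, a_max, labels, rule)
        report["rule2d"] = {
            "threshold_L": rule.threshold_L, "threshold_A": rule.threshold_A,
            "rule": rule.rule,
            **{k: v for k, v in r2d.items() if k != "predictions"},
        }
    else:
        logger.warning("single-class cohort: classification stages skipped")
        report["roc"] = None
        report["rule2d"] = None

    report["features"] = [
        {k: getattr(f, k) for k in ("subject_id", "group", "ahi", "mean_L",
                                    "mean_var", "mean_mu", "a_max",
                                    "n_segments", "n_beats")}
        for f in features
    ]

    if out_dir:
        sio.write_features(features, out_dir / "features.csv")
        sio.write_json(report, out_dir / "report.json")
    return report
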