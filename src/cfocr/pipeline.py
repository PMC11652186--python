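"""End-to-end three-stage pipeline on synthetic cfDNA data.

Stage 1 — *training-set filtering*: binary-labeled 20-kb sample
segments (with label noise) are laid out on one synthetic chromosome;
the pooled 200-bp window features are fit with the MRCD robust chart,
per-segment T² sequences go through the run rules, and candidates are
overlap-filtered: open-labeled samples must overlap a called open
region, closed-labeled samples must not.

Stage 2 — *sensitized chart*: the MEWMA model and bootstrap BD are
calibrated on the filtered closed samples' summary vectors, the binary
pC classifier is trained on the filtered labels, partially open samples
are synthesized by tau-mixing filtered open/closed feature matrices,
and the fused ST² statistic with its bootstrap control limit assigns
three-class labels.

Stage 3 — *confident learning refinement*: cross-validated class
probabilities estimate the confident joint of the chart labels, likely
mislabeled samples are pruned, classes reweighted, and two peer
networks are co-taught; their averaged prediction is the final call.

Metrics are computed on a fresh held-out synthetic test set for both
the chart-only labels and the final model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import confident as cl
from .classifier import train_classifier
from .config import PipelineConfig, save_config
from .features import IntervalFeatureMatrix, matrix_to_features, summarize_std
from .io import write_bed
from .metrics import compute_metrics
from .mewma import bootstrap_bd, fit_mewma, mewma_t2
from .robust_chart import (apply_run_rules, calibrate_limits, filter_training_set,
                           fit_mrcd, t2_statistic)
from .sensitized import SensitizedChart, calibrate_cl, classify_region
from .simulate import (CCR, OCR, POCR, SimParams, make_dataset,
                       simulate_pocr_features)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineResult:
    config: PipelineConfig
    metrics_final: dict
    metrics_chart: dict
    calls_stage1: list
    n_filtered: int
    n_candidates: int
    chart: SensitizedChart
    models: cl.CoTeachModels
    test_true: np.ndarray
    test_pred_final: np.ndarray
    test_pred_chart: np.ndarray
    outdir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                t0 = time.perf_counter()
                out = fn(*args, **kwargs)
                logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
                return out
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


@_stage("filter-train")
def stage_filter(config: PipelineConfig, seed: int):
    """Simulate the noisy binary training set and chart-filter it."""
    ss = np.random.SeedSequence(seed)
    s_data, s_calib, s_balance = (int(c.generate_state(1)[0] % 2**31)
                                  for c in ss.spawn(3))
    data = make_dataset(
        n_per_class=1,  # overridden per class below
        n_ocr=config.n_ocr, n_ccr=config.n_ccr, n_pocr=0,
        tau=config.tau, noise_rate=config.noise_rate, params=config.sim,
        seed=s_data, segment_bp=config.segment_bp, window_bp=config.window_bp,
        wps_w=config.wps_w,
    )
    n = len(data)
    # contiguous layout on one synthetic chromosome, in generated order
    intervals = np.stack([np.arange(n) * config.segment_bp,
                          (np.arange(n) + 1) * config.segment_bp], axis=1)

    pooled = np.concatenate([f.values for f in data.features], axis=0)
    model = fit_mrcd(pooled, alpha_trim=config.alpha_trim)
    calib = calibrate_limits(p=4, n=config.calib_n, alpha=config.alpha,
                             n_mc=config.n_mc, seed=s_calib,
                             alpha_trim=config.alpha_trim)
    calls = []
    for i, feat in enumerate(data.features):
        t2 = t2_statistic(model, feat.values)
        calls.extend(apply_run_rules(t2, calib.ucl, window_bp=config.window_bp,
                                     seg_start=int(intervals[i, 0])))

    # the labeled candidate region is gene-region scale, not the whole
    # monitored interval: the planted open span where one exists, else
    # the central candidate_bp of the segment. A short false alarm
    # elsewhere in the segment must not veto a closed candidate.
    pad = (config.segment_bp - min(config.candidate_bp, config.segment_bp)) // 2
    starts, ends = [], []
    for i in range(n):
        span = data.spans[i]
        if span is not None:
            starts.append(intervals[i, 0] + span[0])
            ends.append(intervals[i, 0] + span[1])
        else:
            starts.append(intervals[i, 0] + pad)
            ends.append(intervals[i, 1] - pad)
    candidates = pd.DataFrame({
        "sample": np.arange(n),
        "start": starts,
        "end": ends,
        "label": data.observed,
    })
    filtered = filter_training_set(candidates, calls, balance=False)
    # classifier training additionally uses a class-balanced subset; the
    # chart calibration keeps every filtered in-control sample
    balanced = filter_training_set(candidates, calls,
                                   balance=config.balance_filtered,
                                   seed=s_balance)
    return data, candidates, filtered, balanced, calls, model, calib


@_stage("sensitized-chart")
def stage_charts(config: PipelineConfig, seed: int, data, filtered, balanced):
    """Calibrate the MEWMA + classifier fusion and assign 3-class labels."""
    ss = np.random.SeedSequence(seed)
    s_bd, s_clf, s_mix, s_cl = (int(c.generate_state(1)[0] % 2**31)
                                for c in ss.spawn(4))
    idx = filtered["sample"].to_numpy()
    lab = filtered["label"].to_numpy()
    oc_idx = idx[lab == 1]
    ic_idx = idx[lab == 0]
    if oc_idx.size == 0 or ic_idx.size == 0:
        raise ValueError("filtering removed an entire class")

    feats = data.features
    sv = np.stack([summarize_std(feats[i]) for i in idx])
    sv_ic = np.stack([summarize_std(feats[i]) for i in ic_idx])
    mewma = fit_mewma(sv_ic, lam=config.lam, alpha=config.alpha, B=config.B)
    mewma.bd = bootstrap_bd(mewma_t2(sv_ic, mewma), alpha=config.alpha,
                            B=config.B, seed=s_bd)

    kind = config.classifier.feature_kind
    bal_idx = balanced["sample"].to_numpy()
    bal_lab = balanced["label"].to_numpy()
    Xb = np.stack([matrix_to_features(feats[i], kind) for i in bal_idx])
    clf = train_classifier(Xb, bal_lab, config.classifier, seed=s_clf)

    chart = SensitizedChart(mewma=mewma, classifier=clf, eta=config.eta)

    rng = np.random.default_rng(s_mix)
    pocr_feats: list[IntervalFeatureMatrix] = []
    for _ in range(config.n_pocr):
        fo = feats[oc_idx[rng.integers(oc_idx.size)]]
        fc = feats[ic_idx[rng.integers(ic_idx.size)]]
        pocr_feats.append(simulate_pocr_features(fo, fc, config.tau))

    pool_feats = [feats[i] for i in idx] + pocr_feats
    pool_sv = np.concatenate([sv, np.stack([summarize_std(f) for f in pocr_feats])]) \
        if pocr_feats else sv
    pool_X = np.stack([matrix_to_features(f, kind) for f in pool_feats])

    ic_st2 = chart.statistic(sv_ic, np.stack(
        [matrix_to_features(feats[i], kind) for i in ic_idx]))
    calibrate_cl(ic_st2, chart, alpha=config.alpha, B=config.B,
                 tau=config.tau, seed=s_cl)

    pool_st2 = chart.statistic(pool_sv, pool_X)
    chart_labels = classify_region(pool_st2, chart)
    return chart, pool_feats, pool_X, pool_st2, np.asarray(chart_labels)


@_stage("confident-coteach")
def stage_refine(config: PipelineConfig, seed: int, pool_X, chart_labels):
    """Confident-joint pruning, reweighting and co-teaching."""
    ss = np.random.SeedSequence(seed)
    s_cv, s_ct = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    probs = cl.cross_val_probs(pool_X, chart_labels, n_classes=3,
                               config=config.classifier, seed=s_cv)
    joint = cl.estimate_confident_joint(probs, chart_labels)
    keep, weights = cl.prune_and_reweight(pool_X, chart_labels, joint)
    models = cl.coteach_train(pool_X[keep], chart_labels[keep],
                              config=config.classifier, seed=s_ct,
                              class_weights=weights,
                              noise_estimate=joint.noise_estimate())
    return models, joint, keep


@_stage("evaluate")
def stage_evaluate(config: PipelineConfig, seed: int, chart: SensitizedChart,
                   models: cl.CoTeachModels):
    """Fresh held-out synthetic test set; chart-only and final metrics."""
    ss = np.random.SeedSequence(seed)
    s_test = int(ss.generate_state(1)[0] % 2**31)
    test = make_dataset(
        n_per_class=config.n_test_per_class, tau=config.tau, noise_rate=0.0,
        params=config.sim, seed=s_test, segment_bp=config.segment_bp,
        window_bp=config.window_bp, wps_w=config.wps_w,
    )
    kind = config.classifier.feature_kind
    sv = np.stack([summarize_std(f) for f in test.features])
    X = np.stack([matrix_to_features(f, kind) for f in test.features])
    st2 = chart.statistic(sv, X)
    pred_chart = np.asarray(classify_region(st2, chart))
    pred_final = cl.predict_final(models, X)
    scores = models.predict_proba(X)
    metrics_chart = compute_metrics(test.true, pred_chart)
    metrics_final = compute_metrics(test.true, pred_final, scores=scores)
    return test, st2, pred_chart, pred_final, metrics_chart, metrics_final


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the three stages and (optionally) persist artifacts."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    logger.info("pipeline seed=%d config=%s", config.seed, config.config_hash())

    data, candidates, filtered, balanced, calls, mrcd, calib = stage_filter(
        config, seeds[0])
    logger.info("stage 1: %d/%d candidates retained (%d balanced); %d open "
                "calls; UCL=%.3f (alpha=%.3g)", len(filtered), len(candidates),
                len(balanced), len(calls), calib.ucl, calib.alpha)
    chart, pool_feats, pool_X, pool_st2, chart_labels = stage_charts(
        config, seeds[1], data, filtered, balanced)
    logger.info("stage 2: eta=%.2f lam=%.2f tau=%.2f CL=%.3f CL_adj=%.3f; "
                "chart labels: %s", config.eta, config.lam, config.tau,
                chart.cl, chart.cl_adjusted,
                dict(zip(*np.unique(chart_labels, return_counts=True))))
    models, joint, keep = stage_refine(config, seeds[2], pool_X, chart_labels)
    logger.info("stage 3: noise estimate %.3f; pruned %d of %d",
                joint.noise_estimate(), int((~keep).sum()), keep.size)
    test, st2, pred_chart, pred_final, m_chart, m_final = stage_evaluate(
        config, seeds[3], chart, models)

    result = PipelineResult(
        config=config, metrics_final=m_final, metrics_chart=m_chart,
        calls_stage1=calls, n_filtered=len(filtered), n_candidates=len(candidates),
        chart=chart, models=models, test_true=test.true,
        test_pred_final=pred_final, test_pred_chart=pred_chart,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(config, outdir / "config.yaml")
        calib.to_json(outdir / "ucl_calibration.json")
        (outdir / "sensitized_calibration.json").write_text(json.dumps({
            "eta": config.eta, "lam": config.lam, "tau": config.tau,
            "bd": chart.mewma.bd, "cl": chart.cl, "cl_adjusted": chart.cl_adjusted,
            "alpha": config.alpha, "B": config.B, "seed": config.seed,
        }, indent=2, sort_keys=True))
        write_bed(outdir / "stage1_calls.bed", "chrS",
                  [c.interval for c in calls],
                  names=["rule" + "+".join(map(str, sorted(c.rules))) for c in calls])
        n_test = len(test.true)
        test_iv = np.stack([np.arange(n_test) * config.segment_bp,
                            (np.arange(n_test) + 1) * config.segment_bp], axis=1)
        write_bed(outdir / "final_calls.bed", "chrT", test_iv,
                  names=pred_final, scores=np.round(1000 * st2).astype(int))
        (outdir / "metrics.json").write_text(json.dumps({
            "seed": config.seed, "config_hash": config.config_hash(),
            "chart_only": m_chart, "final": m_final,
        }, indent=2, sort_keys=True))
        result.outdir = outdir
    return result
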