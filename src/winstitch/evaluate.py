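"""Benchmark protocol: class-wise SSIM, region-split Dice, paired tests.

Stitching artefacts live on a small fraction of pixels (the former tile
boundaries), so raw scores barely move; the protocol therefore

* scores each method's reconstruction against ground truth with the mean
  per-class SSIM and with micro/macro Dice,
* splits the Dice scores between an *edge-vicinity* region (pixels within
  ``half_width`` of a non-overlapping tile boundary) and the remaining
  patch-centre region, isolating where windowing can act, and
* reports every score *adjusted*, i.e. minus the no-overlap baseline's
  score on the same image, so predictor quality cancels and only the
  recombination effect remains.

Method comparisons across a set of scenes use a paired t-test on the
per-image score differences and an exact (binomial) sign test.
"""

from __future__ import annotations

import itertools
import math
from collections import namedtuple
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .reconstruct import METHODS, reconstruct
from .simulate import ArtefactProfile, SceneSpec, generate_scene, noisy_edge_predictor
from .tiling import plan_grid

__all__ = [
    "ssim_classwise",
    "make_grid_mask",
    "dice_scores",
    "adjusted_scores",
    "paired_t_test",
    "exact_sign_test",
    "run_benchmark",
    "BenchmarkResult",
    "TTestResult",
]

TTestResult = namedtuple("TTestResult", ["statistic", "df", "pvalue"])


def ssim_classwise(
    pred: np.ndarray,
    truth: np.ndarray,
    *,
    win_size: int = 7,
    data_range: float = 1.0,
) -> float:
    """Mean over class channels of the per-channel structural similarity.

    Uses the conventional SSIM defaults (7-pixel uniform window, standard
    stabilising constants) with a data range of 1.0 for probability maps;
    the stabilising constants keep constant (zero-variance) channels well
    defined.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.ndim == 2:
        pred = pred[..., None]
    if truth.ndim == 2:
        truth = truth[..., None]
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    scores = [
        structural_similarity(
            pred[..., c], truth[..., c], win_size=win_size, data_range=data_range
        )
        for c in range(pred.shape[2])
    ]
    return float(np.mean(scores))


def make_grid_mask(
    height: int, width: int, patch: int, half_width: int = 5
) -> np.ndarray:
    """Boolean edge-vicinity mask: True within ``half_width`` pixels of any
    interior tile boundary of the non-overlapping ``patch`` tiling.

    Boundaries sit between pixel rows/columns at multiples of ``patch``;
    each contributes a band of ``2 * half_width`` pixels.  ``half_width``
    must stay below ``patch / 2`` so the centre region cannot vanish.
    """
    if not 0 <= half_width < patch // 2:
        raise ValueError(
            f"half_width must satisfy 0 <= half_width < patch/2; got "
            f"{half_width} for patch {patch}"
        )

    def near(extent: int) -> np.ndarray:
        pos = np.arange(extent)
        hit = np.zeros(extent, dtype=bool)
        for line in range(patch, extent, patch):
            dist = np.where(pos >= line, pos - line, line - 1 - pos)
            hit |= dist < half_width
        return hit

    return near(height)[:, None] | near(width)[None, :]


def _region_dice(
    pred: np.ndarray, truth: np.ndarray, n_classes: int, absent: str
) -> tuple[float, float]:
    if pred.size == 0:
        return float("nan"), float("nan")
    conf = np.bincount(
        truth.astype(np.int64) * n_classes + pred.astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    tp = np.diag(conf).astype(np.float64)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    micro = 2.0 * tp.sum() / (2.0 * tp.sum() + fp.sum() + fn.sum())
    denom = 2.0 * tp + fp + fn
    present = denom > 0
    per_class = np.ones(n_classes, dtype=np.float64)
    per_class[present] = 2.0 * tp[present] / denom[present]
    if absent == "one":
        macro = float(per_class.mean())
    elif absent == "skip":
        macro = float(per_class[present].mean()) if present.any() else float("nan")
    else:
        raise ValueError(f"absent must be 'one' or 'skip'; got {absent!r}")
    return float(micro), macro


def dice_scores(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    n_classes: int | None = None,
    absent: str = "one",
) -> pd.DataFrame:
    """Micro and macro Dice, optionally split by an edge-vicinity mask.

    Micro pools true/false positives and negatives over classes before the
    ratio ``2*TP / (2*TP + FP + FN)``; macro averages the per-class ratios.
    A class absent from both prediction and truth inside a region scores 1
    by default (``absent='one'``) or is dropped (``absent='skip'``).

    Returns a DataFrame indexed by region (``all``, or ``centre`` and
    ``edge_vicinity`` when a mask is given) with columns micro/macro.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError(
            f"label shape mismatch: {pred_labels.shape} vs {truth_labels.shape}"
        )
    if n_classes is None:
        n_classes = int(max(pred_labels.max(initial=0), truth_labels.max(initial=0))) + 1
    if mask is None:
        regions = {"all": np.ones(pred_labels.shape, dtype=bool)}
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred_labels.shape:
            raise ValueError(f"mask shape {mask.shape} does not match labels")
        regions = {"centre": ~mask, "edge_vicinity": mask}
    rows = {}
    for name, sel in regions.items():
        rows[name] = _region_dice(
            pred_labels[sel], truth_labels[sel], n_classes, absent
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=["micro", "macro"])


def adjusted_scores(table: pd.DataFrame, baseline: str = "no_overlap") -> pd.DataFrame:
    """Add an ``adjusted`` column: raw score minus the baseline method's raw
    score on the same (image_id, metric, region)."""
    required = {"image_id", "method", "metric", "region", "raw"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"score table is missing columns {sorted(missing)}")
    ref = table.loc[table["method"] == baseline, ["image_id", "metric", "region", "raw"]]
    if ref.empty:
        raise ValueError(f"baseline method {baseline!r} not present in the table")
    ref = ref.rename(columns={"raw": "_baseline"})
    out = table.merge(
        ref, on=["image_id", "metric", "region"], how="left", validate="many_to_one"
    )
    out["adjusted"] = out["raw"] - out.pop("_baseline")
    return out


def paired_t_test(differences: np.ndarray) -> TTestResult:
    """One-sample t-test on paired per-image differences (two-sided).

    Reports ``df = n - 1``.  Zero-variance differences are degenerate, not
    NaN: all-zero gives ``(0, n-1, 1)``, a non-zero constant gives an
    infinite statistic with p = 0.
    """
    d = np.asarray(differences, dtype=np.float64).ravel()
    if d.size < 2:
        raise ValueError("the paired t-test needs at least two differences")
    df = d.size - 1
    if d.std(ddof=1) == 0.0:
        if d.mean() == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, d.mean()), df, 0.0)
    res = stats.ttest_1samp(d, 0.0)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def exact_sign_test(differences: np.ndarray) -> float:
    """Two-sided exact binomial test on the signs of paired differences.

    Ties (zero differences) are dropped; if every difference is a tie the
    test is undefined and a ``ValueError`` is raised.
    """
    d = np.asarray(differences, dtype=np.float64).ravel()
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    if pos + neg == 0:
        raise ValueError("all differences are ties; the sign test is undefined")
    return float(min(1.0, stats.binomtest(pos, pos + neg, 0.5).pvalue))


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-image scores, pairwise p-value matrices, and the run settings."""

    scores: pd.DataFrame
    test_matrices: dict[str, pd.DataFrame]
    config: dict


def run_benchmark(
    seeds: int | list[int] = 14,
    *,
    height: int = 512,
    width: int = 512,
    patch: int = 128,
    n_blobs: int = 30,
    radius_range: tuple[float, float] = (8.0, 18.0),
    edge_band: int = 2,
    profile: ArtefactProfile | None = None,
    mask_half_width: int = 5,
    methods: tuple[str, ...] = METHODS,
    base_seed: int = 0,
    baseline: str = "no_overlap",
) -> BenchmarkResult:
    """Simulate scenes, reconstruct with every method, score and test.

    For each scene seed: generate a synthetic scene, build the
    border-noise predictor, reconstruct with all requested methods, and
    record SSIM (whole image) plus micro/macro Dice split into patch-centre
    and edge-vicinity regions — raw and baseline-adjusted.  Afterwards each
    (metric, region) gets a methods-by-methods matrix of paired-t p-values
    on the per-image raw scores.

    ``seeds`` is either an explicit list of scene seeds or a count
    (``base_seed .. base_seed + seeds - 1``).  Noise streams derive from the
    scene seed so every scene is an independent replicate.
    """
    seed_list = (
        [base_seed + i for i in range(seeds)] if isinstance(seeds, int) else list(seeds)
    )
    base_profile = profile if profile is not None else ArtefactProfile()
    grid = plan_grid(height, width, patch)
    mask = make_grid_mask(height, width, patch, mask_half_width)
    rows = []
    for s in seed_list:
        spec = SceneSpec(
            height=height,
            width=width,
            n_blobs=n_blobs,
            radius_range=radius_range,
            edge_band=edge_band,
            seed=s,
        )
        image, gt = generate_scene(spec)
        gt_labels = gt.argmax(axis=2)
        predictor = noisy_edge_predictor(
            gt, grid, replace(base_profile, seed=base_profile.seed + s)
        )
        for method in methods:
            recon = reconstruct(image, predictor, method, patch)
            rows.append((s, method, "ssim", "all", ssim_classwise(recon, gt)))
            dd = dice_scores(recon.argmax(axis=2), gt_labels, mask)
            for region in ("centre", "edge_vicinity"):
                rows.append((s, method, "dice_micro", region, dd.loc[region, "micro"]))
                rows.append((s, method, "dice_macro", region, dd.loc[region, "macro"]))
    table = pd.DataFrame(
        rows, columns=["image_id", "method", "metric", "region", "raw"]
    )
    table = adjusted_scores(table, baseline)
    matrices: dict[str, pd.DataFrame] = {}
    for (metric, region), sub in table.groupby(["metric", "region"]):
        wide = sub.pivot(index="image_id", columns="method", values="raw")
        pv = pd.DataFrame(np.nan, index=list(methods), columns=list(methods))
        for a, b in itertools.combinations(methods, 2):
            p = paired_t_test((wide[a] - wide[b]).to_numpy()).pvalue
            pv.loc[a, b] = pv.loc[b, a] = p
        matrices[f"{metric}:{region}"] = pv
    config = {
        "seeds": seed_list,
        "height": height,
        "width": width,
        "patch": patch,
        "n_blobs": n_blobs,
        "radius_range": list(radius_range),
        "edge_band": edge_band,
        "base_noise": base_profile.base_noise,
        "edge_noise": base_profile.edge_noise,
        "mask_half_width": mask_half_width,
        "methods": list(methods),
        "baseline": baseline,
    }
    return BenchmarkResult(scores=table, test_matrices=matrices, config=config)
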