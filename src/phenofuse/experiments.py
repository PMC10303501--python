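"""Pre-registered synthetic study designs.

Each function runs one property study at a fixed, documented configuration
and returns the raw per-seed measurements; callers (tests, the results
script) apply their own summaries. The configurations are the package's
stand-ins for conditions observable only on the original field data:

* ``fusion_gap_study`` — classes arranged in complementary pairs (half of
  the pairs distinguishable only by seeds, half only by pods), so a
  single-organ classifier has a structural accuracy ceiling that pod+seed
  fusion can exceed. This emulates the fused-vs-single-branch accuracy gap.
* ``sibling_confusability_study`` — one near-duplicate class pair (small
  phenotype delta in both organs) among otherwise well-separated classes;
  sibling classes should show the lowest recall and merge first in the
  class dendrogram, emulating the known confusable mutant-line pairs.
* ``segmentation_recovery_study`` — object-count recovery of the
  segmentation stage against generator ground truth.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .segmentation import SegmentationParams, segment_scan
from .synthetic import generate_phenotypes, render_scan


def _study_config(seed: int, out_root, K: int, n_sibling_pairs: int,
                  complementarity: float, per_class_scans: int = 6,
                  objects_per_scan: int = 8) -> PipelineConfig:
    cfg = PipelineConfig(rng_seed=seed, out_root=str(out_root))
    cfg.synth.K = K
    cfg.synth.per_class_scans = per_class_scans
    cfg.synth.objects_per_scan = objects_per_scan
    cfg.synth.n_sibling_pairs = n_sibling_pairs
    cfg.synth.complementarity = complementarity
    cfg.augmentation.enabled = False          # SVM on fixed features needs no balancing
    cfg.analysis.enabled = False
    return cfg


def fusion_gap_study(seeds, K: int = 8, complementarity: float = 0.5,
                     out_root=None) -> dict:
    """Fused vs single-organ test accuracy per seed.

    Returns ``{"fused": [...], "pod_only": [...], "seed_only": [...]}``
    (test accuracies, one per seed).
    """
    out = {"fused": [], "pod_only": [], "seed_only": []}
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(out_root) if out_root else Path(tmp)
        for seed in seeds:
            cfg = _study_config(seed, root / f"gap{seed}", K=K,
                                n_sibling_pairs=0, complementarity=complementarity)
            report = run_pipeline(cfg)
            for k in out:
                out[k].append(report["metrics"][k]["test"]["accuracy"])
    return out


def sibling_confusability_study(seeds, K: int = 8, sibling_delta: float = 0.01,
                                out_root=None) -> dict:
    """Per-seed sibling diagnostics.

    For each seed: whether the lowest-recall class is a sibling, whether
    the class tree's first merge is the sibling pair, and the sibling
    recalls themselves.
    """
    results = {"lowest_recall_is_sibling": [], "first_merge_is_sibling": [],
               "sibling_recall": [], "nonsibling_recall": []}
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(out_root) if out_root else Path(tmp)
        for seed in seeds:
            cfg = _study_config(seed, root / f"sib{seed}", K=K,
                                n_sibling_pairs=1, complementarity=0.0,
                                per_class_scans=8)
            cfg.synth.sibling_delta = sibling_delta
            cfg.analysis.enabled = True
            cfg.analysis.gradcam = False
            report = run_pipeline(cfg)
            siblings = set(report["sibling_pairs"][0])
            per_class = report["metrics"]["fused"]["test"]["per_class"]
            recalls = {c: per_class[c]["recall"] for c in per_class}
            # strict: the worst sibling must be below every non-sibling class
            worst_sibling = min(recalls[c] for c in siblings)
            best_floor = min(recalls[c] for c in recalls if c not in siblings)
            results["lowest_recall_is_sibling"].append(worst_sibling < best_floor)
            results["sibling_recall"].append(
                float(np.mean([recalls[c] for c in siblings])))
            results["nonsibling_recall"].append(
                float(np.mean([recalls[c] for c in recalls if c not in siblings])))
            first = set(report["analysis"]["first_merge"])
            results["first_merge_is_sibling"].append(first == siblings)
    return results


def sibling_delta_sweep(deltas, seeds, K: int = 6) -> list[float]:
    """Mean sibling recall at each phenotype delta (difficulty knob check)."""
    means = []
    for delta in deltas:
        res = sibling_confusability_study(seeds, K=K, sibling_delta=delta)
        means.append(float(np.mean(res["sibling_recall"])))
    return means


def segmentation_recovery_study(n_scans: int = 50, objects_per_scan: int = 10,
                                K: int = 5, rng_seed: int = 0) -> dict:
    """Fraction of synthetic scans whose object count is recovered exactly."""
    phenos, _ = generate_phenotypes(K, rng_seed=rng_seed)
    master = np.random.default_rng(rng_seed)
    exact = 0
    params = SegmentationParams()
    for i in range(n_scans):
        pheno = phenos[i % K]
        organ = "seed" if i % 2 == 0 else "pod"
        scan, truth = render_scan(pheno, organ, objects_per_scan,
                                  rng_seed=int(master.integers(2 ** 31)),
                                  scan_id=f"rec{i}")
        exact += int(len(segment_scan(scan, params)) == truth.count)
    return {"n_scans": n_scans, "exact_count_scans": exact,
            "recovery_rate": exact / n_scans}
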