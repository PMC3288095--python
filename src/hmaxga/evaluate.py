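"""Experimental protocol: splits, linear classifier, equilibrium-point error,
ROC/EER/AUC, run aggregation, significance tests and selection analyses.

The headline experiment mirrors the model-comparison protocol: per seeded
run, split the data three ways (train / evaluation / test), extract a random
patch pool from the training images, compute the full C2 matrix once, let the
GA pick P patches using the evaluation split, then measure test performance
of (i) the selected P patches, (ii) P random patches and (iii) the full pool,
aggregating mean and standard deviation over runs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.stats import ks_2samp, ranksums
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .c1 import C1Config, compute_c1, default_c1_config
from .ga import GAConfig, make_wrapper_fitness, run_ga
from .io import LabeledDataset
from .patches import PatchDictionary, extract_patches
from .s1 import FilterBank, build_filter_bank
from .s2c2 import S2Config, batch_c2
from .synthetic import patch_on_motif

logger = logging.getLogger(__name__)

SPLIT_PROTOCOLS = {
    "graz01": {"train": 100, "test": 50},
    "graz02": {"train": 150, "test": 75},
}


@dataclass
class SplitSpec:
    """Disjoint id lists for the three-way (or train/test) protocol."""

    train_ids: list
    eval_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.eval_ids), set(self.test_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split subsets must be pairwise disjoint")


def split_three_way(ds: LabeledDataset, seed: int) -> SplitSpec:
    """Per-class shuffled equal thirds; remainder images are dropped."""
    rng = np.random.default_rng(seed)
    train, evaluation, test = [], [], []
    for label in sorted(np.unique(ds.labels)):
        ids = [i for i, y in zip(ds.ids, ds.labels) if y == label]
        if len(ids) < 3:
            raise ValueError(f"class {label} has fewer than 3 images")
        perm = rng.permutation(len(ids))
        k = len(ids) // 3
        dropped = len(ids) - 3 * k
        if dropped:
            logger.info("three-way split: dropping %d remainder image(s) of "
                        "class %+d", dropped, label)
        shuffled = [ids[p] for p in perm]
        train += shuffled[:k]
        evaluation += shuffled[k:2 * k]
        test += shuffled[2 * k:3 * k]
    return SplitSpec(train_ids=train, eval_ids=evaluation, test_ids=test,
                     seed=int(seed))


def split_counts(ds: LabeledDataset, protocol: str, seed: int) -> SplitSpec:
    """Named fixed-count protocols with exact per-class train/test sizes."""
    if protocol not in SPLIT_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; "
                         f"choose from {sorted(SPLIT_PROTOCOLS)}")
    counts = SPLIT_PROTOCOLS[protocol]
    need = counts["train"] + counts["test"]
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(np.unique(ds.labels)):
        ids = [i for i, y in zip(ds.ids, ds.labels) if y == label]
        if len(ids) < need:
            raise ValueError(
                f"protocol {protocol} needs {need} images of class {label:+d}, "
                f"got {len(ids)} (short by {need - len(ids)})"
            )
        perm = rng.permutation(len(ids))
        shuffled = [ids[p] for p in perm]
        train += shuffled[:counts["train"]]
        test += shuffled[counts["train"]:need]
    return SplitSpec(train_ids=train, eval_ids=[], test_ids=test, seed=int(seed))


def train_linear_classifier(X: np.ndarray, y: np.ndarray, c: float = 1.0):
    """Fit a linear SVM; returns a deterministic real-valued scorer
    (higher = more target-like)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=c)
    clf.fit(X, y)

    def scorer(X_new: np.ndarray) -> np.ndarray:
        return clf.decision_function(np.asarray(X_new, dtype=float))

    scorer.classifier = clf
    return scorer


def _validate_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    return scores, labels


def equilibrium_error(scores, labels) -> float:
    """Error rate at the equilibrium point of the ROC, where the false
    positive rate equals the false negative rate (linear interpolation
    between adjacent operating points when there is no exact crossing)."""
    scores, labels = _validate_scores(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1,
                            drop_intermediate=False)
    fnr = 1.0 - tpr
    diff = fpr - fnr  # -1 at the strictest threshold, +1 at the loosest
    i = int(np.argmax(diff >= 0))
    if diff[i] == 0:
        return float(fpr[i])
    t = -diff[i - 1] / (diff[i] - diff[i - 1])
    return float(fpr[i - 1] + t * (fpr[i] - fpr[i - 1]))


def eer_performance(scores, labels) -> float:
    """Detection rate at the equal-error point: 1 - equilibrium error."""
    return 1.0 - equilibrium_error(scores, labels)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (the rank statistic: probability a random
    positive outscores a random negative, ties counted half)."""
    scores, labels = _validate_scores(scores, labels)
    return float(roc_auc_score(labels == 1, scores))


def compare_runs(perf_a, perf_b) -> tuple:
    """Two-sided (Wilcoxon rank-sum p, two-sample Kolmogorov-Smirnov p)."""
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    return (float(ranksums(a, b).pvalue), float(ks_2samp(a, b).pvalue))


def selection_percentage(best: np.ndarray, pdict: PatchDictionary) -> dict:
    """Share of the selected patches contributed by each patch size, in
    percent; the values sum to 100."""
    bits = np.asarray(best).astype(bool)
    if bits.shape != (len(pdict),):
        raise ValueError("chromosome length must match the dictionary size")
    total = int(bits.sum())
    if total == 0:
        raise ValueError("empty selection")
    out = {n: 0.0 for n in pdict.sizes}
    for patch, bit in zip(pdict.patches, bits):
        if bit:
            out[patch.size_n] += 1.0
    return {n: 100.0 * v / total for n, v in out.items()}


def population_matrix(pop: np.ndarray) -> tuple:
    """Population as a binary matrix (rows = chromosomes, columns = patches)
    plus per-column selection frequency."""
    mat = np.asarray(pop, dtype=np.uint8)
    if mat.ndim != 2:
        raise ValueError("population must be a 2-D binary matrix")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("population entries must be 0 or 1")
    return mat, mat.mean(axis=0)


@dataclass
class ExperimentConfig:
    """Conditions of the selected-vs-random patch experiment."""

    n_runs: int = 10
    seed: int = 0
    sizes: tuple = (4, 8, 12, 16)
    count_per_size: int = 50
    ga: GAConfig = field(default_factory=lambda: GAConfig(
        init_density=0.2, max_generations=60, stagnation_patience=15))
    s2: S2Config = field(default_factory=S2Config)
    svm_c: float = 1.0
    pool_from_targets_only: bool = True


@dataclass
class RunRecord:
    seed: int
    n_selected: int
    n_generations: int
    eer_selected: float
    eer_random: float
    eer_full: float
    auc_selected: float
    auc_random: float
    auc_full: float
    selection_pct: dict
    n_pool_on_motif: int | None = None
    n_selected_on_motif: int | None = None


@dataclass
class ExperimentReport:
    runs: list
    summary: dict
    config: dict
    seeds: list

    def to_dict(self) -> dict:
        return {"runs": [asdict(r) for r in self.runs],
                "summary": self.summary, "config": self.config,
                "seeds": self.seeds}


def _metrics(mask, c2_train, y_train, c2_test, y_test, svm_c):
    scorer = train_linear_classifier(c2_train[mask].T, y_train, c=svm_c)
    scores = scorer(c2_test[mask].T)
    return equilibrium_error(scores, y_test), roc_auc(scores, y_test)


def single_selection_run(
    ds: LabeledDataset,
    c1_by_id: dict,
    cfg: ExperimentConfig,
    run_seed: int,
    boxes: dict | None = None,
    baseline_seed: int | None = None,
):
    """One seeded run of the protocol; returns (RunRecord, PatchDictionary,
    GAResult)."""
    split = split_three_way(ds, run_seed)
    if cfg.pool_from_targets_only:
        pool_ids = [i for i in split.train_ids if ds.label_of(i) == 1]
    else:
        pool_ids = list(split.train_ids)
    pdict = extract_patches([c1_by_id[i] for i in pool_ids], cfg.sizes,
                            cfg.count_per_size, seed=run_seed)

    mats, ys = {}, {}
    for name, ids in (("train", split.train_ids), ("eval", split.eval_ids),
                      ("test", split.test_ids)):
        mats[name] = batch_c2([c1_by_id[i] for i in ids], pdict, cfg=cfg.s2,
                              image_ids=ids).values
        ys[name] = np.array([ds.label_of(i) for i in ids])

    fitness = make_wrapper_fitness(mats["train"], ys["train"], mats["eval"],
                                   ys["eval"], svm_c=cfg.svm_c)
    result = run_ga(len(pdict), fitness, replace(cfg.ga, seed=run_seed))
    bits = result.best_chromosome.astype(bool)
    n_selected = int(bits.sum())

    eer_sel, auc_sel = _metrics(bits, mats["train"], ys["train"],
                                mats["test"], ys["test"], cfg.svm_c)
    rng = np.random.default_rng(
        baseline_seed if baseline_seed is not None else run_seed + 500_000)
    random_mask = np.zeros(len(pdict), dtype=bool)
    random_mask[rng.choice(len(pdict), size=n_selected, replace=False)] = True
    eer_rand, auc_rand = _metrics(random_mask, mats["train"], ys["train"],
                                  mats["test"], ys["test"], cfg.svm_c)
    full_mask = np.ones(len(pdict), dtype=bool)
    eer_full, auc_full = _metrics(full_mask, mats["train"], ys["train"],
                                  mats["test"], ys["test"], cfg.svm_c)

    n_pool_on = n_sel_on = None
    if boxes is not None:
        on = np.array([patch_on_motif(p, boxes) for p in pdict.patches])
        n_pool_on = int(on.sum())
        n_sel_on = int(on[bits].sum())

    record = RunRecord(
        seed=int(run_seed), n_selected=n_selected,
        n_generations=result.n_generations,
        eer_selected=eer_sel, eer_random=eer_rand, eer_full=eer_full,
        auc_selected=auc_sel, auc_random=auc_rand, auc_full=auc_full,
        selection_pct=selection_percentage(bits, pdict),
        n_pool_on_motif=n_pool_on, n_selected_on_motif=n_sel_on,
    )
    return record, pdict, result


def run_experiment(
    ds: LabeledDataset,
    cfg: ExperimentConfig | None = None,
    boxes: dict | None = None,
    bank: FilterBank | None = None,
    c1_cfg: C1Config | None = None,
) -> ExperimentReport:
    """The full multi-run protocol; run r uses seed ``cfg.seed + r``."""
    cfg = cfg if cfg is not None else ExperimentConfig()
    bank = bank if bank is not None else build_filter_bank()
    c1_cfg = c1_cfg if c1_cfg is not None else default_c1_config()

    c1_by_id = {
        img_id: compute_c1(img, bank=bank, cfg=c1_cfg, source_id=img_id)
        for img, img_id in zip(ds.images, ds.ids)
    }

    runs = []
    seeds = [cfg.seed + r for r in range(cfg.n_runs)]
    for r, run_seed in enumerate(seeds):
        try:
            record, _, _ = single_selection_run(ds, c1_by_id, cfg, run_seed,
                                                boxes=boxes)
        except Exception as exc:
            raise RuntimeError(f"experiment run {r} (seed {run_seed}) "
                               f"failed: {exc}") from exc
        runs.append(record)
        logger.info("run %d: P=%d, EER selected/random/full = %.3f/%.3f/%.3f",
                    r, record.n_selected, record.eer_selected,
                    record.eer_random, record.eer_full)

    summary = {}
    for name in ("eer_selected", "eer_random", "eer_full", "auc_selected",
                 "auc_random", "auc_full"):
        vals = np.array([getattr(rec, name) for rec in runs])
        summary[f"mean_{name}"] = float(vals.mean())
        summary[f"std_{name}"] = float(vals.std(ddof=0))
    summary["mean_n_selected"] = float(np.mean([rec.n_selected for rec in runs]))
    if boxes is not None:
        total_sel = sum(rec.n_selected for rec in runs)
        total_sel_on = sum(rec.n_selected_on_motif for rec in runs)
        total_pool = cfg.count_per_size * len(cfg.sizes) * cfg.n_runs
        total_pool_on = sum(rec.n_pool_on_motif for rec in runs)
        summary["selected_on_motif_rate"] = total_sel_on / total_sel
        summary["pool_on_motif_rate"] = total_pool_on / total_pool

    config_snapshot = {
        "n_runs": cfg.n_runs, "seed": cfg.seed, "sizes": list(cfg.sizes),
        "count_per_size": cfg.count_per_size, "ga": asdict(cfg.ga),
        "s2": asdict(cfg.s2), "svm_c": cfg.svm_c,
        "pool_from_targets_only": cfg.pool_from_targets_only,
    }
    return ExperimentReport(runs=runs, summary=summary,
                            config=config_snapshot, seeds=seeds)
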