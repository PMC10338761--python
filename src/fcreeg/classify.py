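"""Subject-aware five-fold cross-validation and classification metrics.

Subjects (never individual epochs) are dealt into five class-stratified
parts, so all images of one subject live in exactly one part and no
subject identity leaks between training, validation and test sets.  In
fold f, part f is the test set, part (f+1) mod 5 the validation set and
the remaining three parts the training set — the 0.6 / 0.2 / 0.2 split,
with every part serving as the test set exactly once across the folds.

With the reference cohort (45 SZ / 39 HC subjects, 6 images each) each
test fold holds exactly 54 SZ images; subject-pure HC parts hold 42 or
48 images (multiples of 6 are the only sizes a leak-free split allows).

The SZ class is "positive": TP/FN count patient images, TN/FP controls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .imaging import FCRDataset
from .nn import build_resnet, count_parameters  # re-exported for convenience
from .nn.train import TrainConfig, evaluate, fit, predict_proba

__all__ = ["FoldPlan", "make_folds", "Metrics", "compute_metrics",
           "cross_validate", "CVResult", "TrainConfig", "build_resnet",
           "count_parameters"]


@dataclass
class FoldPlan:
    """Assignment of subjects to k parts plus the rotating fold roles."""

    k: int
    assignment: dict[str, int]  # subject_id -> part index

    def part_subjects(self, part: int) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == part)

    def roles(self, fold: int) -> tuple[list[int], int, int]:
        """(train part indices, validation part, test part) for one fold."""
        test = fold % self.k
        val = (fold + 1) % self.k
        train = [p for p in range(self.k) if p not in (test, val)]
        return train, val, test

    def validate(self) -> None:
        parts = [set(self.part_subjects(p)) for p in range(self.k)]
        for i in range(self.k):
            for j in range(i + 1, self.k):
                inter = parts[i] & parts[j]
                if inter:
                    raise AssertionError(f"subject leakage between parts "
                                         f"{i} and {j}: {sorted(inter)}")


def make_folds(subjects: list[tuple[str, str]], k: int = 5,
               seed: int = 0) -> FoldPlan:
    """Class-stratified subject-level partition into k parts.

    Within each class, subjects are shuffled (deterministically by seed)
    and dealt round-robin, so part sizes differ by at most one subject
    per class.
    """
    by_class: dict[str, list[str]] = {}
    for sid, group in subjects:
        by_class.setdefault(group, []).append(sid)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for group in sorted(by_class):
        ids = sorted(by_class[group])
        if len(ids) < k:
            raise ValueError(
                f"class {group} has {len(ids)} subjects, fewer than k={k}")
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            if sid in assignment:
                raise ValueError(f"duplicate subject id {sid!r}")
            assignment[sid] = i % k
    plan = FoldPlan(k=k, assignment=assignment)
    plan.validate()
    return plan


@dataclass
class Metrics:
    """Confusion counts and the derived rates, as percentages."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.tp, self.tn, self.fp, self.fn
        if min(tp, tn, fp, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        self.accuracy = _rate(tp + tn, tp + fp + tn + fn, "accuracy")
        self.sensitivity = _rate(tp, tp + fn, "sensitivity")
        self.specificity = _rate(tn, tn + fp, "specificity")
        self.precision = _rate(tp, tp + fp, "precision")
        if np.isnan(self.precision) or np.isnan(self.sensitivity) or \
                (self.precision + self.sensitivity) == 0:
            warnings.warn("F1 undefined (zero precision + recall)")
            self.f1 = float("nan")
        else:
            self.f1 = (2 * self.precision * self.sensitivity
                       / (self.precision + self.sensitivity))


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return float("nan")
    return 100.0 * num / den


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Accuracy, sensitivity (recall), specificity, precision and F1.

    accuracy = (TP+TN)/(TP+FP+TN+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP),
    F1 = 2 * precision * recall / (precision + recall); all percentages.
    """
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class CVResult:
    per_fold: list[Metrics]
    histories: list[dict]
    fold_test_sizes: list[int]

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(m, metric) for m in self.per_fold])
        return float(vals.mean()), float(vals.std(ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: self.mean_sd(m) for m in
                ("accuracy", "sensitivity", "specificity", "precision", "f1")}


def _dataset_arrays(dataset: FCRDataset, input_size: int | None):
    """Images -> (X in NCHW float32 scaled to [0,1], y, subject ids)."""
    xs, ys, sids = [], [], []
    for im in dataset.images:
        px = im.pixels
        if input_size is not None and input_size != im.size:
            px = np.asarray(Image.fromarray(px).resize(
                (input_size, input_size), Image.Resampling.BILINEAR))
        xs.append(px.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(1 if im.label == "SZ" else 0)
        sids.append(im.subject_id)
    return np.stack(xs), np.array(ys, dtype=np.int64), np.array(sids)


def cross_validate(dataset: FCRDataset, plan: FoldPlan,
                   cfg: TrainConfig | None = None, variant: str = "tiny",
                   input_size: int | None = None,
                   labels: dict[str, str] | None = None) -> CVResult:
    """Train one fresh model per fold and aggregate test metrics.

    Images are standardized per channel by the training part's mean/SD
    only (no test-set contamination).  ``labels`` optionally overrides
    the subject -> class labels (used by permutation-null experiments).
    Fully seeded: fold f's model uses cfg.seed * 100 + f.
    """
    cfg = cfg or TrainConfig()
    x, y, sids = _dataset_arrays(dataset, input_size)
    if labels is not None:
        y = np.array([1 if labels[s] == "SZ" else 0 for s in sids],
                     dtype=np.int64)
    ds_subjects = {s for s, _ in dataset.subjects}
    if ds_subjects != set(plan.assignment):
        raise ValueError("fold plan and dataset cover different subjects")
    part_of = np.array([plan.assignment[s] for s in sids])
    per_fold, histories, test_sizes = [], [], []
    for fold in range(plan.k):
        train_parts, val_part, test_part = plan.roles(fold)
        tr = np.isin(part_of, train_parts)
        va = part_of == val_part
        te = part_of == test_part
        if not tr.any():
            raise ValueError(f"fold {fold}: empty training part")
        # leakage guard: subject sets of the three roles must be disjoint
        s_tr, s_va, s_te = (set(sids[m]) for m in (tr, va, te))
        assert not (s_tr & s_va or s_tr & s_te or s_va & s_te), \
            "subject leakage across fold roles"
        mean = x[tr].mean(axis=(0, 2, 3), keepdims=True)
        sd = x[tr].std(axis=(0, 2, 3), keepdims=True) + 1e-8
        xn = (x - mean) / sd
        model = build_resnet(variant, n_classes=2, seed=cfg.seed * 100 + fold,
                             input_size=x.shape[-1])
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed * 100 + fold})
        hist = fit(model, xn[tr], y[tr], xn[va], y[va], fold_cfg)
        proba = predict_proba(model, xn[te])
        pred = proba.argmax(axis=1)
        yt = y[te]
        tp = int(((pred == 1) & (yt == 1)).sum())
        tn = int(((pred == 0) & (yt == 0)).sum())
        fp = int(((pred == 1) & (yt == 0)).sum())
        fn = int(((pred == 0) & (yt == 1)).sum())
        m = compute_metrics(tp, tn, fp, fn)
        _check_accuracy_identity(m)
        per_fold.append(m)
        histories.append(hist)
        test_sizes.append(int(te.sum()))
    return CVResult(per_fold=per_fold, histories=histories,
                    fold_test_sizes=test_sizes)


def _check_accuracy_identity(m: Metrics) -> None:
    """Accuracy must equal prevalence-weighted sensitivity/specificity."""
    n_pos, n_neg = m.tp + m.fn, m.tn + m.fp
    if n_pos == 0 or n_neg == 0:
        return
    prev = n_pos / (n_pos + n_neg)
    expected = m.sensitivity * prev + m.specificity * (1 - prev)
    assert abs(m.accuracy - expected) < 1e-9, \
        f"accuracy identity violated: {m.accuracy} vs {expected}"
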