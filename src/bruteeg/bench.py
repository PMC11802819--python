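"""Splitting protocols, accuracy, and the model x preprocessing benchmark grid.

Two evaluation regimes are supported:

subject-dependent
    train/dev/test drawn from one subject's trials, stratified by class so
    the class proportions agree within one trial;
subject-independent
    the test split is *all* trials of a held-out subject set — no subject is
    common between train and test — and the development split is a stratified
    fraction of the remaining trials.

Model selection (the seed search) sees the development split only; feature
pipelines and the normaliser are fitted on the training split only.  Grid
cells that raise are flagged failed and the grid is still returned.
Accuracy is the plain fraction of correct predictions.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brute_tree import BruteResult, TreeParams, brute_fit, budget, fit_tree, predict
from .epochs import N_CLASSES, EpochDataset, FeatureMatrix
from .exceptions import ValidationError
from .features import FeaturePipeline, Normalizer

CSV_COLUMNS = ["axis1", "axis2", "train_acc", "test_acc", "status", "seed"]


# -- splits ----------------------------------------------------------------

@dataclass
class SplitSpec:
    """Disjoint train/dev/test trial-index lists plus provenance."""

    train: np.ndarray
    dev: np.ndarray
    test: np.ndarray
    mode: str
    detail: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.dev = np.asarray(self.dev, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        allidx = np.concatenate([self.train, self.dev, self.test])
        if len(np.unique(allidx)) != len(allidx):
            raise ValidationError("indices: train/dev/test must be pairwise disjoint")

    def to_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "dev": self.dev.tolist(),
            "test": self.test.tolist(),
            "mode": self.mode,
            "detail": self.detail,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(
            train=d["train"], dev=d["dev"], test=d["test"],
            mode=d["mode"], detail=d.get("detail", {}), seed=d.get("seed", 0),
        )


def _stratified_take(
    idx: np.ndarray, labels: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``idx`` into (taken, rest): per class, round(frac * n_c) trials."""
    taken, rest = [], []
    for c in np.unique(labels[idx]):
        cls_idx = idx[labels[idx] == c]
        cls_idx = cls_idx[rng.permutation(cls_idx.size)]
        n_take = int(round(frac * cls_idx.size))
        taken.append(cls_idx[:n_take])
        rest.append(cls_idx[n_take:])
    return np.sort(np.concatenate(taken)), np.sort(np.concatenate(rest))


def split_subject_dependent(
    ds: EpochDataset,
    subject: int,
    test_frac: float = 0.2,
    dev_frac: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Stratified within-subject split; dev_frac is a fraction of the train rows."""
    mask = ds.subjects == subject
    if not mask.any():
        raise ValidationError(f"subject: {subject} absent from dataset")
    idx = np.flatnonzero(mask)
    for c in np.unique(ds.labels[idx]):
        if (ds.labels[idx] == c).sum() < 2:
            raise ValidationError(f"labels: class {c} has fewer than 2 trials for subject {subject}")
    rng = np.random.default_rng(seed)
    test, remaining = _stratified_take(idx, ds.labels, test_frac, rng)
    dev, train = _stratified_take(remaining, ds.labels, dev_frac, rng)
    return SplitSpec(
        train=train, dev=dev, test=test,
        mode="subject_dependent", detail={"subject": int(subject)}, seed=seed,
    )


def split_subject_independent(
    ds: EpochDataset,
    test_subjects,
    dev_frac: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Held-out-subject split: test gets every trial of ``test_subjects``.

    The subject sets of train+dev and test are disjoint by construction;
    dev is a stratified ``dev_frac`` of the remaining trials.
    """
    test_subjects = set(int(s) for s in test_subjects)
    present = set(int(s) for s in np.unique(ds.subjects))
    if not test_subjects:
        raise ValidationError("test_subjects: must be non-empty")
    if not test_subjects < present:
        raise ValidationError("test_subjects: must be a proper subset of the dataset's subjects")
    test = np.flatnonzero(np.isin(ds.subjects, sorted(test_subjects)))
    remaining = np.flatnonzero(~np.isin(ds.subjects, sorted(test_subjects)))
    rng = np.random.default_rng(seed)
    dev, train = _stratified_take(remaining, ds.labels, dev_frac, rng)
    return SplitSpec(
        train=train, dev=dev, test=test,
        mode="subject_independent",
        detail={"test_subjects": sorted(test_subjects)}, seed=seed,
    )


# -- accuracy --------------------------------------------------------------

def accuracy(pred, truth) -> float:
    """Fraction of correct predictions, in [0, 1]."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValidationError("pred/truth: need equal non-zero lengths")
    return float(np.mean(pred == truth))


# -- model adapters --------------------------------------------------------

class MajorityClassModel:
    """Baseline: always predict the most frequent training class."""

    def fit(self, x_tr, y_tr, x_dev=None, y_dev=None):
        self.label_ = int(np.argmax(np.bincount(np.asarray(y_tr), minlength=N_CLASSES)))
        return self

    def predict(self, x):
        return np.full(np.asarray(x).shape[0], self.label_, dtype=np.int64)


class SingleTreeModel:
    """One extremely randomized tree with a fixed seed (no seed search)."""

    def __init__(self, params: TreeParams | None = None):
        self.params = params or TreeParams()

    def fit(self, x_tr, y_tr, x_dev=None, y_dev=None):
        self.tree_ = fit_tree(np.asarray(x_tr), np.asarray(y_tr), self.params)
        return self

    def predict(self, x):
        return predict(self.tree_, np.asarray(x))


class BruteExtraTreeModel:
    """The seed-search classifier behind a plain fit/predict interface.

    ``m='auto'`` applies the training-size budget rule; an integer ``m``
    overrides it (used to scale experiments down).
    """

    def __init__(self, m="auto", seed0: int = 0, params: TreeParams | None = None):
        self.m = m
        self.seed0 = seed0
        self.params = params or TreeParams()
        self.result_: BruteResult | None = None

    def fit(self, x_tr, y_tr, x_dev=None, y_dev=None):
        if x_dev is None or len(x_dev) == 0:
            raise ValidationError("dev: the seed search requires a development split")
        m = budget(len(x_tr)) if self.m == "auto" else int(self.m)
        self.result_ = brute_fit(
            (np.asarray(x_tr), np.asarray(y_tr)),
            (np.asarray(x_dev), np.asarray(y_dev)),
            params=self.params, m=m, seed0=self.seed0, record_trail=False,
        )
        return self

    def predict(self, x):
        return predict(self.result_.best_model, np.asarray(x))


# -- benchmark grid --------------------------------------------------------

@dataclass
class BenchConfig:
    """Protocol for one benchmark grid."""

    mode: str = "subject_dependent"  # or "subject_independent"
    test_frac: float = 0.2
    dev_frac: float = 0.2
    test_subjects: tuple = ()
    n_keep: int = 4
    seed: int = 0


@dataclass
class ResultsGrid:
    """Model x preprocessing accuracy table plus reproducibility metadata."""

    table: pd.DataFrame
    metadata: dict

    def to_csv(self, path=None) -> str | None:
        buf = io.StringIO()
        df = self.table[CSV_COLUMNS]
        df.to_csv(buf, index=False, float_format="%.10g", lineterminator="\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as f:
            f.write(text)
        return None


def dataset_hash(ds: EpochDataset) -> str:
    h = hashlib.sha256()
    h.update(ds.data.tobytes())
    h.update(ds.labels.tobytes())
    h.update(ds.subjects.tobytes())
    return h.hexdigest()[:16]


def _run_cell(
    ds: EpochDataset, split: SplitSpec, model, method: str, n_keep: int
) -> tuple[float, float]:
    """split -> featurize (fit on train) -> normalize (fit on train) -> train -> eval."""
    pipe = FeaturePipeline(method, n_keep=n_keep).fit(ds.select(split.train))
    fm_train = pipe.transform(ds.select(split.train))
    fm_dev = pipe.transform(ds.select(split.dev))
    fm_test = pipe.transform(ds.select(split.test))
    nz = Normalizer().fit(fm_train)
    x_tr = nz.apply(fm_train).values
    x_dev = nz.apply(fm_dev).values
    x_te = nz.apply(fm_test).values
    model.fit(x_tr, fm_train.labels, x_dev, fm_dev.labels)
    train_acc = accuracy(model.predict(x_tr), fm_train.labels)
    test_acc = accuracy(model.predict(x_te), fm_test.labels)
    return train_acc, test_acc


def run_benchmark(
    ds: EpochDataset,
    models: dict,
    methods: list[str],
    config: BenchConfig | None = None,
) -> ResultsGrid:
    """Run every (model, method) cell of the grid under one protocol.

    ``models`` maps a model name to a zero-argument factory returning a fresh
    fit/predict object.  In subject-dependent mode each cell is the
    unweighted mean over subjects of the per-subject accuracies; in
    subject-independent mode it is a single held-out-subject run.  Cells that
    raise are flagged ``failed:<message>`` and the grid is still returned.
    """
    if not models or not methods:
        raise ValidationError("models/methods: need at least one of each")
    config = config or BenchConfig()
    rows = []
    for method in methods:
        for name, factory in models.items():
            try:
                if config.mode == "subject_dependent":
                    tr_accs, te_accs = [], []
                    for subject in np.unique(ds.subjects):
                        split = split_subject_dependent(
                            ds, int(subject), config.test_frac, config.dev_frac,
                            seed=config.seed,
                        )
                        tr, te = _run_cell(ds, split, factory(), method, config.n_keep)
                        tr_accs.append(tr)
                        te_accs.append(te)
                    train_acc, test_acc = float(np.mean(tr_accs)), float(np.mean(te_accs))
                elif config.mode == "subject_independent":
                    split = split_subject_independent(
                        ds, config.test_subjects, config.dev_frac, seed=config.seed
                    )
                    train_acc, test_acc = _run_cell(ds, split, factory(), method, config.n_keep)
                else:
                    raise ValidationError(f"mode: unknown value {config.mode!r}")
                rows.append((name, method, train_acc, test_acc, "ok", config.seed))
            except ValidationError:
                raise
            except Exception as exc:  # flag and continue: one cell must not kill the grid
                rows.append((name, method, np.nan, np.nan, f"failed:{exc}", config.seed))
    table = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return ResultsGrid(
        table=table,
        metadata={
            "dataset_hash": dataset_hash(ds),
            "mode": config.mode,
            "seed": config.seed,
            "test_frac": config.test_frac,
            "dev_frac": config.dev_frac,
            "test_subjects": list(config.test_subjects),
        },
    )


def plot_heatmap(table: pd.DataFrame, out_path) -> None:
    """Render the grid's test accuracies as a heatmap (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="axis1", columns="axis2", values="test_acc")
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 3, 0.6 * len(pivot) + 2))
    im = ax.imshow(pivot.values, cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = pivot.values[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="test accuracy")
    ax.set_xlabel("preprocessing")
    ax.set_ylabel("model")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
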