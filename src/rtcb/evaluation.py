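"""Confusion tables and the five per-class evaluation metrics.

Each class is scored one-vs-rest: precision TP/(TP+FP), sensitivity
(recall) TP/(TP+FN), specificity TN/(TN+FP), F1 = 2PR/(P+R), per-class
accuracy (TP+TN)/total, plus the overall accuracy trace/total. Metrics
whose denominator is zero (e.g. precision of a never-predicted class) are
flagged NaN and excluded from macro averages with a warning rather than
silently reported as 0. Percentages are rounded half-up to two decimals
for reporting. A Pearson correlation matrix across (model x metric)
tables supports metric-synergy heat maps, and an optional radar/heat-map
renderer writes PNGs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

METRIC_NAMES = ("precision", "sensitivity", "specificity", "f1", "accuracy")


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionTable:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @staticmethod
    def from_class_counts(totals: dict[str, int], correct: dict[str, int],
                          ) -> "ConfusionTable":
        """Build a table from per-class total/correct counts only (as
        published summaries report them); off-diagonal errors are lumped
        into a single wrong column per row, which preserves every
        one-vs-rest TP/FN and the overall accuracy."""
        classes = tuple(totals)
        k = len(classes)
        counts = np.zeros((k, k), dtype=np.int64)
        for i, c in enumerate(classes):
            if correct[c] > totals[c]:
                raise ValueError(f"class {c!r}: correct exceeds total")
            counts[i, i] = correct[c]
            counts[i, (i + 1) % k] += totals[c] - correct[c]
        return ConfusionTable(counts, classes)


def confusion(preds, labels, classes: tuple[str, ...] | int) -> ConfusionTable:
    """Tally a K x K confusion table from parallel label/prediction streams."""
    if isinstance(classes, int):
        classes = tuple(str(i) for i in range(classes))
    k = len(classes)
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    if preds.size and (preds.min() < 0 or preds.max() >= k
                       or labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"class indices must lie in [0, {k})")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (labels, preds), 1)
    return ConfusionTable(counts, classes)


def overall_accuracy(ct: ConfusionTable) -> float:
    """trace / grand total."""
    if ct.grand_total == 0:
        raise ValueError("empty confusion table")
    return float(np.trace(ct.counts)) / ct.grand_total


@dataclass
class MetricsTable:
    classes: tuple[str, ...]
    per_class: dict[str, dict[str, float]]  # class -> metric -> value (NaN = undefined)
    overall_accuracy: float
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def macro(self, metric: str) -> float:
        vals = [self.per_class[c][metric] for c in self.classes
                if not np.isnan(self.per_class[c][metric])]
        return float(np.mean(vals)) if vals else float("nan")

    def matrix(self) -> np.ndarray:
        return np.array([[self.per_class[c][m] for m in METRIC_NAMES]
                         for c in self.classes])


def per_class_metrics(ct: ConfusionTable) -> MetricsTable:
    """One-vs-rest metric table; zero-denominator cells are NaN-flagged."""
    if len(ct.classes) < 2:
        raise ValueError("need at least 2 classes")
    total = ct.grand_total
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[tuple[str, str]] = []

    def ratio(num, den, cls, name):
        if den == 0:
            undefined.append((cls, name))
            return float("nan")
        return num / den

    for i, c in enumerate(ct.classes):
        tp = int(ct.counts[i, i])
        fp = int(ct.counts[:, i].sum()) - tp
        fn = int(ct.counts[i, :].sum()) - tp
        tn = total - tp - fp - fn
        p = ratio(tp, tp + fp, c, "precision")
        r = ratio(tp, tp + fn, c, "sensitivity")
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            undefined.append((c, "f1"))
            f1 = float("nan")
        else:
            f1 = 2 * p * r / (p + r)
        per_class[c] = {
            "precision": p,
            "sensitivity": r,
            "specificity": ratio(tn, tn + fp, c, "specificity"),
            "f1": f1,
            "accuracy": ratio(tp + tn, total, c, "accuracy"),
        }
    if undefined:
        warnings.warn(f"undefined metrics (zero denominator): {undefined}",
                      RuntimeWarning, stacklevel=2)
    return MetricsTable(ct.classes, per_class, overall_accuracy(ct), undefined)


def accuracy_delta(a: float, b: float) -> float:
    """Percentage-point difference (a - b) * 100, rounded half-up to 2 dp."""
    for v in (a, b):
        if not 0 <= v <= 1:
            raise ValueError("accuracies must lie in [0, 1]")
    return round_half_up((a - b) * 100.0, 2)


def metric_correlation(matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation between the columns of a (models x metrics)
    matrix. Zero-variance columns yield NaN rows/columns with a warning."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    stds = m.std(axis=0)
    degenerate = np.where(stds == 0)[0]
    if degenerate.size:
        warnings.warn(f"zero-variance metric columns {degenerate.tolist()}: "
                      "correlations undefined (NaN)", RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    corr[np.diag_indices_from(corr)] = np.where(
        np.isin(np.arange(corr.shape[0]), degenerate), np.nan, 1.0)
    return corr


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------

def report(ct: ConfusionTable, metrics: MetricsTable, out_dir: str | Path,
           corr: np.ndarray | None = None, plots: bool = False) -> dict[str, Path]:
    """Write counts/metrics/correlation CSVs (and optional PNG plots).

    `counts.csv` follows the Tot/Cor/Inc summary layout; `confusion.csv`
    keeps the full table; `metrics.csv` has one row per class plus a macro
    row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = out_dir / "counts.csv"
    with open(paths["counts"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "Tot", "Cor", "Inc"])
        for i, c in enumerate(ct.classes):
            tot = int(ct.counts[i].sum())
            cor = int(ct.counts[i, i])
            w.writerow([c, tot, cor, tot - cor])

    paths["confusion"] = out_dir / "confusion.csv"
    with open(paths["confusion"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["true\\pred", *ct.classes])
        for i, c in enumerate(ct.classes):
            w.writerow([c, *ct.counts[i].tolist()])

    paths["metrics"] = out_dir / "metrics.csv"
    with open(paths["metrics"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", *METRIC_NAMES])
        for c in metrics.classes:
            w.writerow([c] + [f"{metrics.per_class[c][m]:.4f}"
                              for m in METRIC_NAMES])
        w.writerow(["macro"] + [f"{metrics.macro(m):.4f}" for m in METRIC_NAMES])
        w.writerow(["overall_accuracy",
                    f"{metrics.overall_accuracy:.4f}", "", "", "", ""])

    if corr is not None:
        paths["correlation"] = out_dir / "correlation.csv"
        with open(paths["correlation"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["", *METRIC_NAMES])
            for name, row in zip(METRIC_NAMES, corr):
                w.writerow([name, *[f"{v:.6f}" for v in row]])

    if plots:
        paths.update(_render_plots(metrics, corr, out_dir))
    return paths


def read_counts_csv(path: str | Path) -> tuple[dict[str, int], dict[str, int]]:
    """Re-parse a counts.csv back into (totals, correct) dictionaries."""
    totals, correct = {}, {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            totals[row["class"]] = int(row["Tot"])
            correct[row["class"]] = int(row["Cor"])
    return totals, correct


def _render_plots(metrics: MetricsTable, corr: np.ndarray | None,
                  out_dir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    # radar of macro metrics
    angles = np.linspace(0, 2 * np.pi, len(METRIC_NAMES), endpoint=False)
    vals = [metrics.macro(m) for m in METRIC_NAMES]
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]])
    ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(METRIC_NAMES, fontsize=7)
    paths["radar"] = out_dir / "radar.png"
    fig.savefig(paths["radar"], dpi=100)
    plt.close(fig)

    if corr is not None:
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(corr, vmin=-1, vmax=1, cmap="coolwarm")
        ax.set_xticks(range(len(METRIC_NAMES)))
        ax.set_yticks(range(len(METRIC_NAMES)))
        ax.set_xticklabels(METRIC_NAMES, rotation=45, fontsize=7)
        ax.set_yticklabels(METRIC_NAMES, fontsize=7)
        fig.colorbar(im)
        fig.tight_layout()
        paths["heatmap"] = out_dir / "correlation.png"
        fig.savefig(paths["heatmap"], dpi=100)
        plt.close(fig)
    return paths
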