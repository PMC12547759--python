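"""Descriptive statistics and results persistence.

Word-count descriptives mirror the study protocol: per-patient word counts
over messages sent before the day limit, with the top 5 % of patients
removed before computing mean and SD because the log-normal-like right tail
dominates them otherwise. Trimming convention: patients at or above the
empirical (1 - trim) quantile (linear-interpolation quantile) are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import MessageStream
from .study import StudyResults

__all__ = ["WordCountSummary", "describe_wordcounts", "write_results", "plot_pooled"]


@dataclass(frozen=True)
class WordCountSummary:
    mean: float
    sd: float
    n_patients: int
    n_trimmed: int
    histogram_counts: tuple[int, ...]
    histogram_edges: tuple[float, ...]


def describe_wordcounts(stream: MessageStream, day_limit: int = 29,
                        trim_top_fraction: float = 0.05,
                        n_bins: int = 30) -> WordCountSummary:
    """Trimmed mean/SD and histogram of per-patient early word counts."""
    if stream.n_messages == 0:
        raise ValueError("empty message stream")
    if not (0.0 <= trim_top_fraction < 1.0):
        raise ValueError("trim_top_fraction must lie in [0, 1)")
    frame = stream.frame
    kept = frame[frame["day"] < day_limit]
    counts = kept.groupby("patient_id")["text"].apply(
        lambda s: int(sum(len(t.split()) for t in s)))
    values = counts.to_numpy(float)
    if trim_top_fraction > 0:
        q = np.quantile(values, 1.0 - trim_top_fraction)
        keep = values < q
    else:
        keep = np.ones(len(values), dtype=bool)
    trimmed = values[keep]
    if len(trimmed) == 0:
        raise ValueError("no patients remain after trimming")
    hist, edges = np.histogram(trimmed, bins=n_bins)
    return WordCountSummary(mean=float(trimmed.mean()),
                            sd=float(trimmed.std(ddof=1)) if len(trimmed) > 1 else 0.0,
                            n_patients=len(trimmed),
                            n_trimmed=int((~keep).sum()),
                            histogram_counts=tuple(int(c) for c in hist),
                            histogram_edges=tuple(float(e) for e in edges))


def write_results(results: StudyResults, out_dir) -> dict[str, str]:
    """Persist the tidy results tables and a manifest; returns paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    fold = results.fold_table()
    fold["hyperparameters"] = fold["hyperparameters"].map(json.dumps)
    for name, frame in (("fold_metrics", fold),
                        ("pooled", results.pooled_table()),
                        ("comparisons", results.comparison_table())):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    manifest = {"seeds": results.seeds, "families": list(results.families)}
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(mp)
    sp = out / "summary.txt"
    sp.write_text(results.summary() + "\n")
    paths["summary"] = str(sp)
    return paths


def plot_pooled(results: StudyResults, metric: str, path) -> None:
    """Forest-style plot of pooled means with CIs (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [pe for pe in results.pooled if pe.metric == metric]
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(rows) + 1.5))
    y = np.arange(len(rows))
    means = [pe.mean for pe in rows]
    err = np.array([[pe.mean - pe.ci_low for pe in rows],
                    [pe.ci_high - pe.mean for pe in rows]])
    ax.errorbar(means, y, xerr=err, fmt="o", capsize=4)
    ax.set_yticks(y)
    ax.set_yticklabels([pe.model_id for pe in rows])
    ax.set_xlabel(metric)
    ax.set_title(f"Pooled {metric} with 95% CI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
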