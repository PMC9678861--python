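"""Experimental protocol: per-tumor-type runs, replicates, reporting.

The experimental protocol splits a multi-tumor cohort into independent per-tumor
optimization problems, repeats each as several seeded replicates (the
evolutionary search is stochastic), picks the maximum-search-F1 solution
from each Pareto front, re-evaluates it on the held-out test split, and
compares selected-vs-all-features metrics across replicates with the
Wilcoxon signed-rank test. Leave-one-out retrieval on a cohort from an
institution absent from training serves as external validation.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .io import FeatureTable, subset_by_tumor_type
from .moo import Individual, ParetoArchive, run_nsga3
from .objectives import MOOConfig, precision_recall_f1, search_f1, site_accuracy

logger = logging.getLogger("debiasfs")


@dataclass
class RunResult:
    """One (tumor type, replicate) optimization outcome."""

    tumor_type: str
    replicate: int
    seed: int
    archive: list[Individual]
    chosen: Individual
    test_search_f1: float
    test_site_accuracy: float
    n_selected: int
    baseline_test_search_f1: float
    baseline_test_site_accuracy: float
    wall_seconds: float = 0.0  # in-memory only, never serialized


@dataclass(frozen=True)
class ExperimentConfig:
    moo: MOOConfig
    n_replicates: int = 31
    output_dir: str | Path = "runs"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# Solution picking and evaluation
# ---------------------------------------------------------------------------


def pick_max_f1_solution(front: list[Individual] | ParetoArchive) -> Individual:
    """The front member with maximal validation search F1 (minimal f1_loss).

    Ties break by smaller feature ratio, then smaller site accuracy, then
    lexicographically smallest mask, so the pick is deterministic.
    """
    members = front.members if isinstance(front, ParetoArchive) else list(front)
    if not members:
        raise ValueError("empty Pareto front")
    return min(
        members,
        key=lambda ind: (
            ind.objectives.f1_loss,
            ind.objectives.f2_ratio,
            ind.objectives.f3_site_acc,
            tuple(ind.mask.tolist()),
        ),
    )


def evaluate_on_test(
    individual: Individual, table: FeatureTable, config: MOOConfig
) -> tuple[float, float, int]:
    """Held-out metrics: (search macro-F1 test-vs-train, site accuracy, n selected)."""
    f1 = search_f1(
        individual.mask, table,
        query_split="test", reference_split="train", k=config.k_neighbors,
    )
    acc = site_accuracy(
        individual.mask, table,
        train_split="train", eval_split="test", C=config.svm_C,
    )
    return f1, acc, int(np.count_nonzero(individual.mask))


def external_validation(mask, external_table: FeatureTable, k: int = 3) -> dict:
    """Leave-one-out retrieval within an unseen-institution cohort.

    Every sample is a query against all remaining samples on the masked
    features; k-NN classification, per-diagnosis F1 and their unweighted
    average. Classes with <= k samples are scored but flagged.
    """
    m = np.asarray(mask).astype(bool)
    X = external_table.X[:, m]
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"external cohort needs at least k+1={k + 1} samples")
    diag = np.asarray(external_table.diagnosis)
    for cls in sorted(set(diag.tolist())):
        if int(np.sum(diag == cls)) <= k:
            warnings.warn(
                f"diagnosis {cls!r} has <= k={k} external samples; its F1 is unstable"
            )
    preds = np.empty(n, dtype=diag.dtype)
    dist = cdist(X, X)
    for i in range(n):
        rest = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = rest[np.argsort(dist[i, rest], kind="stable")[:k]]
        # reuse the shared k-NN tie rules on the precomputed neighbour order
        neigh = diag[order]
        counts: dict = {}
        for lab in neigh.tolist():
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        for lab in neigh.tolist():
            if counts[lab] == best:
                preds[i] = lab
                break
    metrics = precision_recall_f1(diag, preds)
    return {
        "per_class_f1": dict(zip(metrics.classes, metrics.f1.tolist())),
        "average_f1": metrics.macro_f1,
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(w_small: float, ranks: np.ndarray) -> float:
    """Two-sided exact p via subset-sum counting over the observed ranks.

    Works on doubled ranks so midranks (multiples of 0.5) stay integral;
    the null distribution is the conditional permutation distribution of
    the positive-rank sum over all 2^n sign assignments.
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled positive-rank sum s
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    cdf = counts.cumsum() / 2.0 ** len(r2)
    p = 2.0 * cdf[int(round(2.0 * w_small))]
    return min(1.0, float(p))


def wilcoxon_compare(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences get midranks.
    The statistic is min(W+, W-). The p-value is exact (the conditional
    sign-permutation distribution, computed by subset-sum counting) for
    n <= 25 nonzero differences, and a normal approximation with tie and
    continuity corrections above. A single nonzero difference yields
    p = 1 by convention.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("need equal-length 1-D paired vectors with n >= 5")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    abs_sorted = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs_sorted[j + 1] == abs_sorted[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # midrank
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if n <= 25:
        return statistic, _exact_signed_rank_p(statistic, ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return statistic, 1.0
    # continuity correction pulls the statistic half a step toward the mean
    z = (statistic - mean + 0.5) / np.sqrt(var)
    return statistic, float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _archive_frame(archive: list[Individual]) -> pd.DataFrame:
    rows = [
        {
            "mask": "".join(map(str, ind.mask.tolist())),
            "f1_loss": ind.objectives.f1_loss,
            "f2_ratio": ind.objectives.f2_ratio,
            "f3_site_acc": ind.objectives.f3_site_acc,
        }
        for ind in archive
    ]
    df = pd.DataFrame(rows, columns=["mask", "f1_loss", "f2_ratio", "f3_site_acc"])
    return df.sort_values(["f1_loss", "f2_ratio", "f3_site_acc", "mask"]).reset_index(drop=True)


def load_archive(path: str | Path) -> list[Individual]:
    from .objectives import ObjectiveVector

    df = pd.read_csv(path, dtype={"mask": str})
    return [
        Individual(
            mask=np.array([int(c) for c in row["mask"]], dtype=np.uint8),
            objectives=ObjectiveVector(
                float(row["f1_loss"]), float(row["f2_ratio"]), float(row["f3_site_acc"])
            ),
        )
        for _, row in df.iterrows()
    ]


def run_experiment(table: FeatureTable, config: ExperimentConfig) -> list[RunResult]:
    """Run every (tumor type, replicate) optimization and persist results.

    Tumor types with a single diagnosis are skipped with a warning (no
    retrieval problem to optimize). Completed (tumor, replicate) pairs
    found in the output directory are loaded, not recomputed, so an
    interrupted experiment resumes where it stopped. Replicate r uses seed
    ``base_seed + r``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: list[RunResult] = []
    for tumor in sorted(set(table.tumor_type)):
        sub = subset_by_tumor_type(table, tumor)
        train_diags = {sub.diagnosis[i] for i in sub.split_indices("train")}
        if len(train_diags) < 2:
            logger.warning(
                "skipping tumor type %r: only %d diagnosis class(es)", tumor, len(train_diags)
            )
            continue
        D = sub.n_features
        ones = Individual(np.ones(D, dtype=np.uint8))
        base_f1, base_acc, _ = evaluate_on_test(ones, sub, config.moo)
        for rep in range(config.n_replicates):
            seed = config.moo.seed + rep
            stem = out / f"{tumor}_rep{rep:03d}"
            result_path = stem.with_suffix(".json")
            archive_path = Path(f"{stem}_archive.csv")
            if result_path.exists() and archive_path.exists():
                results.append(
                    _load_result(tumor, rep, seed, result_path, archive_path)
                )
                logger.info("reusing completed run %s", stem.name)
                continue
            t0 = time.perf_counter()
            moo_cfg = replace(config.moo, seed=seed)
            _, archive, history = run_nsga3(sub, moo_cfg)
            chosen = pick_max_f1_solution(archive)
            f1, acc, n_sel = evaluate_on_test(chosen, sub, moo_cfg)
            res = RunResult(
                tumor_type=tumor,
                replicate=rep,
                seed=seed,
                archive=archive.members,
                chosen=chosen,
                test_search_f1=f1,
                test_site_accuracy=acc,
                n_selected=n_sel,
                baseline_test_search_f1=base_f1,
                baseline_test_site_accuracy=base_acc,
                wall_seconds=time.perf_counter() - t0,
            )
            _archive_frame(archive.members).to_csv(archive_path, index=False)
            pd.DataFrame(history).to_csv(f"{stem}_history.csv", index=False)
            result_path.write_text(json.dumps(_result_payload(res), indent=2, sort_keys=True))
            results.append(res)
            logger.info(
                "tumor=%s rep=%d seed=%d front=%d picked %d features "
                "(test F1 %.4f, site acc %.4f)",
                tumor, rep, seed, len(archive), n_sel, f1, acc,
            )
    return results


def _result_payload(res: RunResult) -> dict:
    return {
        "tumor_type": res.tumor_type,
        "replicate": res.replicate,
        "seed": res.seed,
        "selected_indices": np.flatnonzero(res.chosen.mask).tolist(),
        "D": int(res.chosen.mask.size),
        "validation_objectives": {
            "f1_loss": res.chosen.objectives.f1_loss,
            "f2_ratio": res.chosen.objectives.f2_ratio,
            "f3_site_acc": res.chosen.objectives.f3_site_acc,
        },
        "test_search_f1": res.test_search_f1,
        "test_site_accuracy": res.test_site_accuracy,
        "n_selected": res.n_selected,
        "baseline_test_search_f1": res.baseline_test_search_f1,
        "baseline_test_site_accuracy": res.baseline_test_site_accuracy,
    }


def _load_result(
    tumor: str, rep: int, seed: int, result_path: Path, archive_path: Path
) -> RunResult:
    payload = json.loads(result_path.read_text())
    archive = load_archive(archive_path)
    mask = np.zeros(payload["D"], dtype=np.uint8)
    mask[payload["selected_indices"]] = 1
    from .objectives import ObjectiveVector

    chosen = Individual(
        mask,
        ObjectiveVector(
            payload["validation_objectives"]["f1_loss"],
            payload["validation_objectives"]["f2_ratio"],
            payload["validation_objectives"]["f3_site_acc"],
        ),
    )
    return RunResult(
        tumor_type=tumor,
        replicate=rep,
        seed=seed,
        archive=archive,
        chosen=chosen,
        test_search_f1=payload["test_search_f1"],
        test_site_accuracy=payload["test_site_accuracy"],
        n_selected=payload["n_selected"],
        baseline_test_search_f1=payload["baseline_test_search_f1"],
        baseline_test_site_accuracy=payload["baseline_test_site_accuracy"],
    )


def render_report(results: list[RunResult], output_dir: str | Path) -> pd.DataFrame:
    """Per-tumor-type comparison of all-features vs selected-features metrics.

    Means over replicates, with Wilcoxon significance flags (two-sided
    p < 0.05) when at least 5 replicates are available. Writes
    ``report.csv`` and a human-readable ``report.txt``; returns the table.
    """
    if not results:
        raise ValueError("no results to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tumor in sorted({r.tumor_type for r in results}):
        rs = sorted(
            (r for r in results if r.tumor_type == tumor), key=lambda r: r.replicate
        )
        sel_f1 = np.array([r.test_search_f1 for r in rs])
        sel_acc = np.array([r.test_site_accuracy for r in rs])
        base_f1 = np.array([r.baseline_test_search_f1 for r in rs])
        base_acc = np.array([r.baseline_test_site_accuracy for r in rs])

        def p_or_nan(a: np.ndarray, b: np.ndarray) -> float:
            if len(a) < 5 or np.all(a == b):
                return float("nan")
            return wilcoxon_compare(a, b)[1]

        p_f1 = p_or_nan(sel_f1, base_f1)
        p_acc = p_or_nan(sel_acc, base_acc)
        rows.append(
            {
                "tumor_type": tumor,
                "n_replicates": len(rs),
                "all_features_site_accuracy": base_acc.mean(),
                "selected_site_accuracy": sel_acc.mean(),
                "site_accuracy_p": p_acc,
                "site_accuracy_significant": bool(p_acc < 0.05) if np.isfinite(p_acc) else False,
                "all_features_search_f1": base_f1.mean(),
                "selected_search_f1": sel_f1.mean(),
                "search_f1_p": p_f1,
                "search_f1_significant": bool(p_f1 < 0.05) if np.isfinite(p_f1) else False,
                "mean_n_selected": float(np.mean([r.n_selected for r in rs])),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "report.csv", index=False, float_format="%.6f")
    lines = ["Selected-features vs all-features, test split (means over replicates)", ""]
    for _, r in df.iterrows():
        lines.append(
            f"{r['tumor_type']}: site accuracy {r['all_features_site_accuracy']:.3f} -> "
            f"{r['selected_site_accuracy']:.3f}"
            f"{' *' if r['site_accuracy_significant'] else ''}; "
            f"search F1 {r['all_features_search_f1']:.3f} -> {r['selected_search_f1']:.3f}"
            f"{' *' if r['search_f1_significant'] else ''}; "
            f"{r['mean_n_selected']:.1f} features on average over {int(r['n_replicates'])} replicates"
        )
    lines.append("")
    lines.append("* two-sided Wilcoxon signed-rank p < 0.05 across replicates")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return df
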