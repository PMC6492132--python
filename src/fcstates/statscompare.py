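"""Statistical comparison of states and of classification pipelines.

* edge-wise paired t-tests between two states across subjects (on Fisher-z
  connectivity values) with Benjamini-Hochberg FDR;
* McNemar's test on the discordant error counts of two classifiers evaluated
  on identical samples (exact binomial for small discordant counts,
  continuity-corrected chi-square otherwise);
* Wilcoxon signed-rank for paired accuracy lists across conditions.

Degenerate cases (zero-variance differences, no discordant pairs, all-zero
differences) report p = 1 with a flag rather than NaN: conservative and safe
inside automated pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .discrimination import CVResult

#: discordant-count threshold switching McNemar from exact binomial to chi2
MCNEMAR_EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class MultipleTestingConfig:
    """Benjamini-Hochberg FDR level."""

    q: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")


@dataclass(frozen=True)
class PairedOutcome:
    """Discordant counts of two classifiers on the same samples.

    b = A correct while B wrong; c = A wrong while B correct.
    """

    b: int
    c: int
    n: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0 or self.b + self.c > self.n:
            raise ValueError("invalid discordant counts")

    @classmethod
    def from_correctness(cls, a: np.ndarray, b: np.ndarray) -> "PairedOutcome":
        a = np.asarray(a, dtype=bool)
        b = np.asarray(b, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("correctness vectors must align")
        return cls(int(np.sum(a & ~b)), int(np.sum(~a & b)), int(a.size))


def paired_edgewise_ttests(
    netmats_a: np.ndarray, netmats_b: np.ndarray
) -> pd.DataFrame:
    """Per-edge paired two-sided t-tests between two states.

    Inputs are per-subject edge-value arrays (n_subjects, n_edges), or
    (n_subjects, n_nodes, n_nodes) symmetric stacks which are vectorized to
    their strict upper triangles.  Edges with zero-variance differences get
    t = 0, p = 1 and a flag (conservative).
    """
    a = _to_edges(netmats_a)
    b = _to_edges(netmats_b)
    if a.shape != b.shape:
        raise ValueError("state A and B must cover the same subjects and edges")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    diff = a - b
    degenerate = diff.std(axis=0, ddof=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_rel(a, b, axis=0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"edge": np.arange(a.shape[1]), "t": t, "p": p,
                         "degenerate": degenerate})


def state_contrast_table(
    netmats_a: np.ndarray,
    netmats_b: np.ndarray,
    n_nodes: int,
    config: MultipleTestingConfig = MultipleTestingConfig(),
) -> pd.DataFrame:
    """Edge-list state contrast: (node_i, node_j, t, p, fdr_reject).

    Runs the paired edge-wise t-tests and appends the BH-FDR decision at
    level q, keeping the uncorrected p as well so either presentation can be
    reported.  Node indices are 0-based and follow the upper-triangle order.
    """
    res = paired_edgewise_ttests(netmats_a, netmats_b)
    iu = np.triu_indices(n_nodes, k=1)
    if len(res) != iu[0].size:
        raise ValueError("edge count does not match n_nodes")
    res = res.assign(node_i=iu[0], node_j=iu[1], fdr_reject=bh_fdr(res["p"], config))
    return res[["node_i", "node_j", "t", "p", "fdr_reject", "degenerate"]]


def _to_edges(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        iu = np.triu_indices(x.shape[1], k=1)
        return x[:, iu[0], iu[1]]
    if x.ndim != 2:
        raise ValueError("expected (subjects, edges) or (subjects, nodes, nodes)")
    return x


def bh_fdr(pvalues: Sequence[float], config: MultipleTestingConfig = MultipleTestingConfig()) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=config.q, method="fdr_bh")
    return reject


def mcnemar_test(outcome: PairedOutcome, variant: str = "auto") -> tuple[float, float]:
    """McNemar's test on discordant counts (statistic, two-sided p).

    variant "auto": exact binomial when b + c < 25, else chi-square with
    continuity correction (|b-c|-1)^2/(b+c) on 1 df.  "exact" / "chi2" force
    a path.  b + c = 0 -> p = 1.
    """
    b, c = outcome.b, outcome.c
    n_disc = b + c
    if n_disc == 0:
        return 0.0, 1.0
    if variant == "auto":
        variant = "exact" if n_disc < MCNEMAR_EXACT_THRESHOLD else "chi2"
    if variant == "exact":
        k = min(b, c)
        p = 2.0 * stats.binom.cdf(k, n_disc, 0.5)
        # the symmetric center term must not be double-counted
        if b == c:
            p = 1.0
        return float(k), float(min(p, 1.0))
    if variant == "chi2":
        statistic = (abs(b - c) - 1) ** 2 / n_disc
        return float(statistic), float(stats.chi2.sf(statistic, df=1))
    raise ValueError(f"unknown variant {variant!r}")


def wilcoxon_signed_rank(
    accuracies_a: Sequence[float], accuracies_b: Sequence[float]
) -> tuple[float, float, bool]:
    """Wilcoxon signed-rank on paired condition-wise scores.

    Returns (W, two-sided p, degenerate flag).  W is the smaller signed-rank
    sum; zero differences are excluded; exact null for n <= 25 without ties,
    tie-corrected normal approximation otherwise.  All-zero differences give
    p = 1 with the flag set.
    """
    a = np.asarray(list(accuracies_a), dtype=float)
    b = np.asarray(list(accuracies_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return w, float(res.pvalue), False


def compare_pipelines(
    results: Mapping[str, CVResult],
    baseline: str,
    config: MultipleTestingConfig = MultipleTestingConfig(),
) -> pd.DataFrame:
    """McNemar comparison of every pipeline against a baseline, BH-FDR corrected.

    All CVResults must cover the identical samples (same true labels in the
    same order), which holds when cells of one benchmark share the sample set
    and fold plan.  Returns a table with accuracies, discordant counts, raw p
    and the FDR decision at level q.
    """
    if baseline not in results:
        raise ValueError(f"baseline {baseline!r} not among results")
    ref = results[baseline]
    ref_truth = np.asarray(ref.y_true)
    rows = []
    others = [k for k in results if k != baseline]
    for name in others:
        res = results[name]
        if not np.array_equal(np.asarray(res.y_true), ref_truth):
            raise ValueError(f"pipeline {name!r} was evaluated on different samples")
        outcome = PairedOutcome.from_correctness(res.correct, ref.correct)
        stat, p = mcnemar_test(outcome)
        rows.append({
            "pipeline": name,
            "accuracy_pct": res.accuracy,
            "baseline_accuracy_pct": ref.accuracy,
            "b": outcome.b,
            "c": outcome.c,
            "p_raw": p,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table[f"significant_q{config.q}"] = bh_fdr(table["p_raw"], config)
        table["beats_baseline"] = table[f"significant_q{config.q}"] & (
            table["accuracy_pct"] > table["baseline_accuracy_pct"]
        )
        table["q"] = config.q
    return table
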