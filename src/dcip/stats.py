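"""Group-comparison statistics and the ddCt relative-expression stage.

All comparisons operate on replicate-level (per-plant) summaries, never on
pooled nuclei — pooling thousands of nuclei from a handful of plants would
pseudo-replicate.  The omnibus test is the tie-corrected Kruskal-Wallis H
(chi-squared reference distribution, or exact permutation for small samples),
followed by Dunn's pairwise z-tests on the pooled ranks, two-sided and
unadjusted by default.  Normalized single-condition comparisons use a
one-sample t-test against 1.0.  Families of t-tests are adjusted with the
step-down Holm-Sidak procedure.

Relative expression follows the Livak ddCt convention: technical replicates
are averaged to one Ct per (sample, gene); dCt = Ct(gene) - Ct(reference
gene) per sample; ddCt = dCt - mean control dCt; fold change = 2^(-ddCt).
Per-sample ddCt values are retained so fold changes can be tested.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    df: int
    method: str
    n_total: int


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


@dataclass
class ExpressionResult:
    """Per-gene fold changes plus the per-sample ddCt values behind them."""

    summary: pd.DataFrame      # gene, dct_control_mean, dct_treated_mean, ddct, fold_change
    per_sample: pd.DataFrame   # sample, group, gene, dct, ddct, fold_change
    reference_gene: str
    control_group: str


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    else:
        out = {str(i): np.asarray(v, dtype=np.float64) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in out.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if not np.isfinite(vals).all():
            raise ValueError(f"group {name!r} contains non-finite values")
    return out


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def _h_statistic(samples: list[np.ndarray]) -> tuple[float, bool]:
    """Tie-corrected Kruskal-Wallis H; second value is True when all pooled
    observations are identical (H defined as 0 by convention)."""
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0, True  # every observation tied: no rank information
    return h / correction, False


def kruskal_wallis(groups, method: str = "chi2") -> KruskalResult:
    """Kruskal-Wallis rank ANOVA across >= 2 groups.

    ``method="chi2"`` refers H to a chi-squared distribution with k-1 df
    (flagged in the log as unreliable for total n < 8); ``"permutation"``
    enumerates every assignment of the pooled observations to the group
    sizes (total n <= 12) and reports the exact tail probability.
    """
    g = _as_groups(groups)
    samples = list(g.values())
    n_total = sum(s.size for s in samples)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    h, degenerate = _h_statistic(samples)
    df = len(samples) - 1
    if degenerate:
        return KruskalResult(0.0, 1.0, df, method, n_total)
    if method == "chi2":
        if n_total < 8:
            logger.info("chi-squared approximation is unreliable for total n=%d < 8", n_total)
        p = float(sps.chi2.sf(h, df))
        return KruskalResult(float(h), p, df, "chi2", n_total)
    if method == "permutation":
        if n_total > 12:
            raise ValueError("exact permutation supported only for total n <= 12")
        pooled = np.concatenate(samples)
        sizes = [s.size for s in samples]
        count = 0
        total = 0
        idx_all = frozenset(range(n_total))
        for parts in _partitions(idx_all, sizes):
            perm = [pooled[list(p)] for p in parts]
            h_perm, _ = _h_statistic(perm)
            if h_perm >= h - 1e-12:
                count += 1
            total += 1
        return KruskalResult(float(h), count / total, df, "permutation", n_total)
    raise ValueError("method must be 'chi2' or 'permutation'")


def _partitions(indices: frozenset, sizes: list[int]):
    """Yield every distinct split of ``indices`` into consecutive groups of
    the requested sizes."""
    if len(sizes) == 1:
        yield (tuple(sorted(indices)),)
        return
    first = sizes[0]
    for combo in itertools.combinations(sorted(indices), first):
        rest = indices.difference(combo)
        for tail in _partitions(rest, sizes[1:]):
            yield (combo,) + tail


def dunn_pairwise(groups, p_adjust: str | None = None) -> pd.DataFrame:
    """Dunn's pairwise z-tests on the pooled ranks of all groups.

    Two-sided p-values, tie-corrected pooled variance, and no multiplicity
    adjustment by default; pass ``p_adjust="holm-sidak"`` to append an
    adjusted column.  Returns one row per unordered pair.
    """
    g = _as_groups(groups)
    names = list(g.keys())
    samples = [g[k] for k in names]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, s in zip(names, samples):
        mean_ranks[name] = ranks[start:start + s.size].mean()
        start += s.size
    a = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = g[g1].size, g[g2].size
        se = math.sqrt(a * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            z = 0.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append((g1, g2, z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "pvalue"])
    if p_adjust is not None:
        if p_adjust != "holm-sidak":
            raise ValueError("only 'holm-sidak' adjustment is supported")
        out["pvalue_adjusted"] = holm_sidak(out["pvalue"].to_numpy())
    return out


def one_sample_t_vs_one(values) -> TTestResult:
    """Two-sided one-sample t-test of the mean against the ideal value 1.0
    (used for normalized efficiencies/intensities, where 1.0 means 'equal to
    the reference treatment')."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    df = v.size - 1
    if sd == 0:
        warnings.warn("zero variance in one-sample t-test; degenerate result",
                      UserWarning, stacklevel=2)
        if v.mean() == 1.0:
            return TTestResult(0.0, 1.0, df, degenerate=True)
        t = math.inf if v.mean() > 1.0 else -math.inf
        return TTestResult(t, 0.0, df, degenerate=True)
    res = sps.ttest_1samp(v, popmean=1.0)
    return TTestResult(float(res.statistic), float(res.pvalue), df)


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values.

    Sort ascending; adjusted_(i) = max_{j <= i} 1 - (1 - p_(j))^(m - j + 1),
    clipped to 1; returned in the original order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_group: str = "control",
) -> ExpressionResult:
    """Livak ddCt relative expression from a long-format Ct table.

    ``ct_table`` needs columns ``sample``, ``group``, ``gene``, ``ct`` (and
    optionally ``tech_rep``; technical replicates are averaged first).  The
    reference gene must be measured in every sample and the control group
    must be non-empty.  The reference gene's fold change is exactly 1 and all
    fold changes are invariant to per-sample global Ct shifts.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required.difference(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    mean_ct = (
        ct_table.groupby(["sample", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    groups = mean_ct["group"].unique().tolist()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present in the table")

    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["ct"]
    for sample in mean_ct["sample"].unique():
        if sample not in ref.index:
            raise ValueError(f"sample {sample!r} has no Ct for reference gene {reference_gene!r}")

    mean_ct["dct"] = mean_ct["ct"] - mean_ct["sample"].map(ref)
    baseline = (
        mean_ct[mean_ct["group"] == control_group]
        .groupby("gene")["dct"]
        .mean()
    )
    unknown = set(mean_ct["gene"]).difference(baseline.index)
    if unknown:
        raise ValueError(f"genes absent from the control group: {sorted(unknown)}")
    mean_ct["ddct"] = mean_ct["dct"] - mean_ct["gene"].map(baseline)
    mean_ct["fold_change"] = 2.0 ** (-mean_ct["ddct"])

    treated = mean_ct[mean_ct["group"] != control_group]
    rows = []
    for gene in sorted(mean_ct["gene"].unique()):
        dct_c = float(baseline[gene])
        t = treated[treated["gene"] == gene]
        dct_t = float(t["dct"].mean()) if len(t) else float("nan")
        dd = dct_t - dct_c if len(t) else float("nan")
        fold = 2.0 ** (-dd) if len(t) else float("nan")
        rows.append((gene, dct_c, dct_t, dd, fold))
    summary = pd.DataFrame(
        rows, columns=["gene", "dct_control_mean", "dct_treated_mean", "ddct", "fold_change"]
    )
    per_sample = mean_ct[["sample", "group", "gene", "dct", "ddct", "fold_change"]].copy()
    logger.info(
        "ddct: reference=%s control=%s genes=%d samples=%d",
        reference_gene, control_group, summary.shape[0], mean_ct["sample"].nunique(),
    )
    return ExpressionResult(summary, per_sample, reference_gene, control_group)
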