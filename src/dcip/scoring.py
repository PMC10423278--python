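"""Headline delivery statistics: the control-calibrated positivity threshold,
percent GFP-positive nuclei, and reference-normalized efficiency/intensity.

The positivity cutoff is a one-tailed bound at confidence ``level`` (default
0.99) above the mean green/red ratio of the negative-control nuclei:

    threshold = control_mean + z(level) * control_sd        (default mode)

i.e. a bound on the per-nucleus ratio *distribution* under normality.  The
alternative reading — a bound on the *mean*, ``control_mean +
z * control_sd / sqrt(n)`` — is selectable with ``mode="sem"``; at typical
control sample sizes it collapses onto the control mean and flags nearly
every nucleus, which is why the distribution bound is the default.  The
chosen interpretation is always logged.  A nucleus is GFP-positive iff its
ratio is strictly greater than the threshold (ties are negative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class ControlThreshold:
    """Positivity cutoff derived from the negative-control ratio sample."""

    control_mean: float
    control_sd: float
    n_control: int
    level: float
    quantile: float
    threshold: float
    mode: str = "distribution"

    def to_dict(self) -> dict:
        return {
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "n_control": self.n_control,
            "level": self.level,
            "quantile": self.quantile,
            "threshold": self.threshold,
            "mode": self.mode,
        }


def control_threshold(
    control_ratios: np.ndarray,
    level: float = 0.99,
    mode: str = "distribution",
    use_t: bool = False,
) -> ControlThreshold:
    """Derive the GFP-positivity threshold from control nuclei ratios.

    Parameters
    ----------
    control_ratios
        Green/red ratios of the control group's valid nuclei.
    level
        One-tailed confidence level of the bound (default 0.99).
    mode
        ``"distribution"`` (default): ``mean + q * sd``;
        ``"sem"``: ``mean + q * sd / sqrt(n)``.
    use_t
        Use the Student-t quantile with n-1 df instead of the normal quantile.
    """
    r = np.asarray(control_ratios, dtype=np.float64)
    r = r[np.isfinite(r)]
    n = r.size
    if n == 0:
        raise ValueError("no control nuclei")
    if n < 2:
        raise ValueError("need at least 2 control nuclei (sd undefined)")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if mode not in ("distribution", "sem"):
        raise ValueError("mode must be 'distribution' or 'sem'")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    q = float(sps.t.ppf(level, n - 1)) if use_t else float(sps.norm.ppf(level))
    spread = sd if mode == "distribution" else sd / np.sqrt(n)
    thr = mean + q * spread
    logger.info(
        "control threshold: mode=%s level=%g quantile=%.6f mean=%.6g sd=%.6g n=%d -> %.6g",
        mode, level, q, mean, sd, n, thr,
    )
    return ControlThreshold(mean, sd, n, level, q, thr, mode)


def classify_positive(ratios: np.ndarray, threshold: ControlThreshold | float) -> np.ndarray:
    """GFP-positivity flags: strictly greater than the threshold."""
    thr = threshold.threshold if isinstance(threshold, ControlThreshold) else float(threshold)
    return np.asarray(ratios, dtype=np.float64) > thr


def percent_positive(n_positive: int, n_total: int) -> float:
    """Percent GFP-positive: 100 * positives / total counted nuclei.

    A replicate with no nuclei is undefined: returns NaN with a warning so
    the caller can exclude it.
    """
    if n_total <= 0:
        warnings.warn("percent positive undefined for zero nuclei; replicate excluded",
                      UserWarning, stacklevel=2)
        return float("nan")
    if n_positive > n_total:
        raise ValueError("n_positive cannot exceed n_total")
    return 100.0 * n_positive / n_total


def delivery_efficiency(pct_positive: float, reference_pct: float) -> float:
    """Percent positive normalized to the reference treatment of the same
    experiment/replicate; the reference itself maps to 1.0."""
    if not reference_pct > 0:
        warnings.warn("reference percent positive is zero; efficiency undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    return pct_positive / reference_pct


def delivery_intensity(mean_ratio: float, reference_mean_ratio: float) -> float:
    """Mean green/red ratio normalized to the reference treatment's mean."""
    if not reference_mean_ratio > 0:
        warnings.warn("reference mean ratio is zero; intensity undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    return mean_ratio / reference_mean_ratio


def normalize_to_reference_mean(values: np.ndarray, reference_group_values: np.ndarray) -> np.ndarray:
    """Divide each value by the mean of the reference group (e.g. dot-blot
    intensities normalized to the 0 h group); the reference group's
    normalized mean is 1 by construction."""
    ref = np.asarray(reference_group_values, dtype=np.float64)
    if ref.size == 0:
        raise ValueError("reference group is empty")
    ref_mean = ref.mean()
    if not ref_mean > 0:
        raise ValueError("reference group mean must be positive")
    return np.asarray(values, dtype=np.float64) / ref_mean


@dataclass
class ScoreResult:
    """Per-replicate treatment summaries plus the threshold that produced them."""

    summary: pd.DataFrame
    threshold: ControlThreshold
    measurements: pd.DataFrame  # input rows with a 'positive' flag appended


SUMMARY_COLUMNS = (
    "treatment",
    "plant",
    "n_nuclei",
    "n_positive",
    "percent_positive",
    "mean_ratio",
)


def score_experiment(
    measurements: pd.DataFrame,
    control: str,
    reference: str | None = None,
    level: float = 0.99,
    mode: str = "distribution",
    use_t: bool = False,
) -> ScoreResult:
    """Score a whole experiment's measurement table.

    All valid control nuclei of the experiment calibrate one threshold; each
    (treatment, plant) replicate pools its fields of view before counting.
    If ``reference`` is given, normalized efficiency and intensity columns
    are added, computed within-plant against that plant's reference
    replicate; without a reference the columns are absent.
    """
    df = measurements.copy()
    if "valid" in df.columns:
        valid = df[df["valid"].astype(bool)].copy()
    else:
        valid = df.copy()
    treatments = valid["treatment"].unique().tolist()
    if control not in treatments:
        raise ValueError(f"control treatment {control!r} has no valid nuclei in the table")
    if reference is not None and reference not in treatments:
        raise ValueError(f"reference treatment {reference!r} has no valid nuclei in the table")

    thr = control_threshold(
        valid.loc[valid["treatment"] == control, "green_red_ratio"].to_numpy(),
        level=level,
        mode=mode,
        use_t=use_t,
    )
    valid["positive"] = classify_positive(valid["green_red_ratio"].to_numpy(), thr)

    rows = []
    for (treatment, plant), grp in valid.groupby(["treatment", "plant"], sort=True):
        n = len(grp)
        n_pos = int(grp["positive"].sum())
        rows.append(
            (
                treatment,
                plant,
                n,
                n_pos,
                percent_positive(n_pos, n),
                float(grp["green_red_ratio"].mean()),
            )
        )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    if reference is not None:
        ref_rows = summary[summary["treatment"] == reference].set_index("plant")
        eff, inten = [], []
        for _, row in summary.iterrows():
            if row["plant"] in ref_rows.index:
                ref = ref_rows.loc[row["plant"]]
                eff.append(delivery_efficiency(row["percent_positive"], ref["percent_positive"]))
                inten.append(delivery_intensity(row["mean_ratio"], ref["mean_ratio"]))
            else:
                warnings.warn(
                    f"plant {row['plant']!r} has no reference replicate; efficiency undefined",
                    UserWarning,
                    stacklevel=2,
                )
                eff.append(float("nan"))
                inten.append(float("nan"))
        summary["normalized_efficiency"] = eff
        summary["normalized_intensity"] = inten

    return ScoreResult(summary=summary, threshold=thr, measurements=valid)
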