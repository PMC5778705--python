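"""Agreement statistics for paired A-value measurements.

Given per-specimen A-values from a method under test and a gold standard
(high-resolution micro-CT measurements in the clinical setting), this
module computes the standard agreement battery: absolute percentage
difference, a Shapiro-Wilk normality gate, the Wilcoxon matched-pairs
signed-rank test, Spearman rank correlation, and Bland-Altman limits of
agreement with a clinical acceptance band (default ±1.05 mm of A-value
error, the threshold derived from revised CDL equations).

Wilcoxon uses exact enumeration of all 2^n sign patterns for n <= 12 and
the normal approximation with continuity and tie corrections otherwise;
Spearman uses an exact rank-permutation p for n <= 8 and the
t-approximation otherwise.  Zero differences are dropped by default
(Wilcoxon's original procedure) or retained with Pratt's method.

The model-style surface is :class:`AgreementModel` /
:class:`AgreementResults`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementModel",
    "AgreementResults",
    "abs_pct_diff",
    "wilcoxon_matched_pairs",
    "spearman",
    "shapiro_wilk",
    "bland_altman",
    "improvement",
]


@dataclass
class PairedMeasurements:
    """Per-specimen method vs gold-standard values (mm)."""

    ids: list[str]
    method_values: np.ndarray
    gold_values: np.ndarray

    def __post_init__(self):
        self.method_values = np.asarray(self.method_values, dtype=float)
        self.gold_values = np.asarray(self.gold_values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.method_values.shape != (n,) or self.gold_values.shape != (n,):
            raise ValueError("ids, method_values and gold_values must have equal length")
        if n < 3:
            raise ValueError("need at least 3 paired measurements")
        if np.any(self.gold_values <= 0):
            raise ValueError("gold-standard values must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedMeasurements":
        """Build from a dataframe with columns id, method_mm, gold_mm."""
        return cls(
            ids=df["id"].tolist(),
            method_values=df["method_mm"].to_numpy(),
            gold_values=df["gold_mm"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str) -> "PairedMeasurements":
        return cls.from_dataframe(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.ids)


def abs_pct_diff(method: float, gold: float) -> float:
    """100 * |method - gold| / gold; scale-invariant accuracy measure."""
    method = np.asarray(method, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if np.any(gold <= 0):
        raise ValueError("gold value must be positive")
    out = 100.0 * np.abs(method - gold) / gold
    return float(out) if out.ndim == 0 else out


def improvement(manual_mean_pct: float, automated_mean_pct: float) -> float:
    """Accuracy gain (percentage points): manual error minus automated error."""
    if manual_mean_pct < 0 or automated_mean_pct < 0:
        raise ValueError("mean percentage differences must be non-negative")
    return float(manual_mean_pct - automated_mean_pct)


# -- Wilcoxon matched pairs ----------------------------------------------


def _signed_ranks(d: np.ndarray, zero_method: str):
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks = stats.rankdata(np.abs(d))
        ranks = ranks[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    return d, ranks


def wilcoxon_matched_pairs(
    method: np.ndarray,
    gold: np.ndarray,
    zero_method: str = "wilcox",
    exact_threshold: int = 12,
):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W_plus, p)``.  Exact null enumeration of the 2^n sign
    patterns (ties mid-ranked) for n <= ``exact_threshold``; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction.  Zero differences dropped ('wilcox', default) or ranked
    then dropped ('pratt').
    """
    d = np.asarray(method, dtype=float) - np.asarray(gold, dtype=float)
    d, ranks = _signed_ranks(d, zero_method)
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= exact_threshold:
        p = _wilcoxon_exact_p(w_plus, ranks)
    else:
        p = _wilcoxon_approx_p(w_plus, ranks)
    return w_plus, p

def _wilcoxon_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided p by full enumeration of sign patterns over the ranks."""
    n = ranks.size
    total = 1 << n
    # distribution of W+ over all sign assignments
    ws = np.zeros(1, dtype=float)
    for r in ranks:  # convolution over ± contributions
        ws = np.concatenate([ws, ws + r])
    ge = np.count_nonzero(ws >= w_plus - 1e-12)
    le = np.count_nonzero(ws <= w_plus + 1e-12)
    p = 2.0 * min(ge, le) / total
    return min(1.0, p)


def _wilcoxon_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    n = ranks.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the ranks of |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed ranks")
    delta = abs(w_plus - mu)
    z = (delta - 0.5) / math.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# -- Spearman correlation -------------------------------------------------


def spearman(method: np.ndarray, gold: np.ndarray, exact_threshold: int = 8):
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns ``(r, p)`` with a two-sided p from exact permutation of the
    rank vector for n <= ``exact_threshold`` and from the t-approximation
    ``t = r sqrt((n-2)/(1-r^2))`` otherwise.
    """
    x = np.asarray(method, dtype=float)
    y = np.asarray(gold, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_threshold:
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
        observed = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(rx_c @ ry_c[list(perm)])
            if stat >= observed - 1e-12 * denom:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


def shapiro_wilk(values: np.ndarray):
    """Shapiro-Wilk W and p; the normality gate before the nonparametric
    comparisons.  Valid for 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# -- Bland-Altman ---------------------------------------------------------


def bland_altman(method: np.ndarray, gold: np.ndarray, clinical_bound: float = 1.05):
    """Limits-of-agreement summary of the differences d = method - gold.

    Sample (n-1) SD; limits of agreement mean ± 1.96 SD;
    ``frac_outside_clinical`` is the proportion with |d| > clinical_bound.
    """
    m = np.asarray(method, dtype=float)
    g = np.asarray(gold, dtype=float)
    if m.size < 3:
        raise ValueError("need at least 3 pairs")
    d = m - g
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
        "clinical_bound": float(clinical_bound),
        "frac_outside_clinical": float(np.mean(np.abs(d) > clinical_bound)),
    }


def _significance_label(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# -- model objects --------------------------------------------------------


@dataclass
class AgreementResults:
    """Fitted agreement battery with a printable summary."""

    n: int
    abs_pct_diff_mean: float
    abs_pct_diff_sd: float
    shapiro_w: float
    shapiro_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    spearman_r: float
    spearman_p: float
    bland_altman: dict
    per_specimen: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        ba = self.bland_altman
        lines = [
            f"Agreement vs gold standard (n = {self.n})",
            "=" * 52,
            f"{'abs % difference (mean ± SD)':<34}"
            f"{self.abs_pct_diff_mean:.1f} ± {self.abs_pct_diff_sd:.1f}%",
            f"{'Shapiro-Wilk W (p)':<34}{self.shapiro_w:.3f} "
            f"(p = {self.shapiro_p:.3g})",
            f"{'Wilcoxon matched pairs p':<34}{self.wilcoxon_p:.3g} "
            f"({_significance_label(self.wilcoxon_p)})",
            f"{'Spearman r (p)':<34}{self.spearman_r:.2f} "
            f"(p = {self.spearman_p:.3g}, "
            f"{_significance_label(self.spearman_p)})",
            "-" * 52,
            f"{'Bland-Altman mean diff (mm)':<34}{ba['mean_diff']:+.2f}",
            f"{'Limits of agreement (mm)':<34}"
            f"[{ba['loa_low']:+.2f}, {ba['loa_high']:+.2f}]",
            f"{'Outside ±' + format(ba['clinical_bound'], '.2f') + ' mm band':<34}"
            f"{100 * ba['frac_outside_clinical']:.0f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "abs_pct_diff_mean": self.abs_pct_diff_mean,
            "abs_pct_diff_sd": self.abs_pct_diff_sd,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
            "wilcoxon_stat": self.wilcoxon_stat,
            "wilcoxon_p": self.wilcoxon_p,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "bland_altman": self.bland_altman,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_bland_altman(self, ax=None):
        """Bland-Altman scatter with limits of agreement and the clinical
        acceptance band (dotted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        df = self.per_specimen
        means = (df["method_mm"] + df["gold_mm"]) / 2.0
        diffs = df["method_mm"] - df["gold_mm"]
        ba = self.bland_altman
        ax.scatter(means, diffs, s=18, color="tab:blue")
        ax.axhline(ba["mean_diff"], color="k", lw=1)
        for y in (ba["loa_low"], ba["loa_high"]):
            ax.axhline(y, color="gray", lw=1, ls="--")
        for y in (ba["clinical_bound"], -ba["clinical_bound"]):
            ax.axhline(y, color="red", lw=1, ls=":")
        ax.set_xlabel("mean of methods (mm)")
        ax.set_ylabel("method - gold (mm)")
        ax.set_title("Bland-Altman")
        return ax


class AgreementModel:
    """Agreement analysis of paired A-value measurements.

    ``fit()`` computes the full battery and returns
    :class:`AgreementResults`.
    """

    def __init__(
        self,
        data: PairedMeasurements,
        clinical_bound: float = 1.05,
        zero_method: str = "wilcox",
    ):
        self.data = data
        self.clinical_bound = clinical_bound
        self.zero_method = zero_method

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AgreementModel":
        return cls(PairedMeasurements.from_dataframe(df), **kwargs)

    def fit(self) -> AgreementResults:
        m, g = self.data.method_values, self.data.gold_values
        pct = abs_pct_diff(m, g)
        w, shapiro_p = shapiro_wilk(m - g)
        stat, wilcoxon_p = wilcoxon_matched_pairs(m, g, zero_method=self.zero_method)
        r, spearman_p = spearman(m, g)
        ba = bland_altman(m, g, self.clinical_bound)
        per = pd.DataFrame(
            {
                "id": self.data.ids,
                "method_mm": m,
                "gold_mm": g,
                "diff_mm": m - g,
                "abs_pct_diff": pct,
            }
        )
        return AgreementResults(
            n=len(self.data),
            abs_pct_diff_mean=float(np.mean(pct)),
            abs_pct_diff_sd=float(np.std(pct, ddof=1)),
            shapiro_w=w,
            shapiro_p=shapiro_p,
            wilcoxon_stat=stat,
            wilcoxon_p=wilcoxon_p,
            spearman_r=r,
            spearman_p=spearman_p,
            bland_altman=ba,
            per_specimen=per,
        )
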