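"""Relative quantification of qPCR Ct tables and ANOVA/Tukey comparison.

Expression of a target gene is quantified relative to an internal reference
(e.g. Gapdh) by the comparative-Ct method: per sample,
``dCt = Ct(gene) - Ct(reference)`` and ``fold = 2**-dCt``; optionally a
calibrator group gives ``ddCt = dCt - mean dCt(calibrator)`` and
``fold = 2**-ddCt``.  Technical replicates are collapsed by the arithmetic
mean of Ct before any difference is formed; fold changes are averaged across
biological samples with an SEM.  Differences among genes are tested by
one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "ct")


@dataclass
class CtTable:
    """Long-format Ct records plus the reference-gene name.

    ``data`` columns: sample_id, group, gene, ct and optionally
    technical_replicate (absent means one replicate per record).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_group: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if not np.all(np.isfinite(self.data["ct"])):
            raise ValueError("non-finite Ct values")
        samples = set(self.data["sample_id"])
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample_id"])
        if samples - with_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing for samples "
                f"{sorted(samples - with_ref)}"
            )

    @classmethod
    def from_csv(cls, path: str | Path, reference_gene: str,
                 calibrator_group: str | None = None) -> "CtTable":
        return cls(pd.read_csv(path), reference_gene, calibrator_group)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def collapsed(self) -> pd.DataFrame:
        """Mean Ct per (sample, group, gene) across technical replicates."""
        return (
            self.data.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
        )


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per-sample dCt and 2**-dCt relative to the reference gene."""
    wide = table.collapsed()
    ref = wide[wide["gene"] == table.reference_gene][["sample_id", "ct"]].rename(
        columns={"ct": "ct_ref"}
    )
    out = wide.merge(ref, on="sample_id")
    out["delta_ct"] = out["ct"] - out["ct_ref"]
    out["fold"] = 2.0 ** -out["delta_ct"]
    return out


def relative_expression(table: CtTable, mode: str = "delta_ct") -> pd.DataFrame:
    """Fold change per (gene, group): mean and SEM over biological samples.

    mode ``delta_ct``: fold = mean over samples of 2**-dCt (per-sample
    transform first, then average).  mode ``delta_delta_ct``: per sample
    ddCt = dCt - mean dCt of the calibrator group (same gene), fold =
    2**-ddCt, then averaged the same way.
    """
    per_sample = delta_ct(table)
    if mode == "delta_ct":
        value_col = "fold"
    elif mode == "delta_delta_ct":
        if table.calibrator_group is None:
            raise ValueError("delta_delta_ct requires a calibrator_group")
        calib = per_sample[per_sample["group"] == table.calibrator_group]
        if calib.empty:
            raise ValueError(f"empty calibrator group {table.calibrator_group!r}")
        base = calib.groupby("gene")["delta_ct"].mean().rename("dct_calib")
        per_sample = per_sample.join(base, on="gene")
        per_sample["fold_ddct"] = 2.0 ** -(per_sample["delta_ct"] - per_sample["dct_calib"])
        value_col = "fold_ddct"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    g = per_sample.groupby(["gene", "group"])[value_col]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    out = out.rename(columns={"mean": "fold", "sem": "sem_fold", "count": "n"})
    out["mode"] = mode
    return out[["gene", "group", "mode", "fold", "sem_fold", "n"]]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame = field(repr=False)
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = {self.F:.4g}, "
            f"p = {self.p_value:.4g}" + ("  [degenerate: zero within-group variance]"
                                         if self.degenerate else ""),
            "Tukey HSD:",
        ]
        for _, r in self.tukey.iterrows():
            lines.append(
                f"  {r['group_i']} vs {r['group_j']}: diff = {r['mean_diff']:+.4g}, "
                f"q = {r['q_statistic']:.4g}, p_adj = {r['adjusted_p']:.4g}"
            )
        return "\n".join(lines)


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD over named groups of observations.

    F is computed from the standard sums-of-squares decomposition; for each
    pair, q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)) with the
    adjusted p from the studentized-range distribution at (k, df_within).
    Zero within-group variance with unequal means is reported as p = 0 with a
    degeneracy flag rather than an infinite F.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    ns = np.array([len(a) for a in arrays])
    if np.any(ns < 2):
        raise ValueError("every group needs >= 2 observations")
    k = len(arrays)
    big_n = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    df_between, df_within = k - 1, big_n - k
    ms_within = ss_within / df_within
    degenerate = ms_within == 0.0
    if degenerate:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if degenerate:
                q = np.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(np.clip(stats.studentized_range.sf(q, k, df_within), 0.0, 1.0))
            rows.append(
                {
                    "group_i": names[i],
                    "group_j": names[j],
                    "mean_diff": float(diff),
                    "q_statistic": float(q),
                    "adjusted_p": p_adj,
                }
            )
    return AnovaResult(
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        tukey=pd.DataFrame(rows),
        degenerate=degenerate,
    )


def anova_by_gene(
    table: CtTable,
    genes: Sequence[str] | None = None,
    mode: str = "delta_ct",
) -> AnovaResult:
    """ANOVA/Tukey across genes on per-sample fold values (reference excluded)."""
    per_sample = delta_ct(table)
    per_sample = per_sample[per_sample["gene"] != table.reference_gene]
    if genes is not None:
        per_sample = per_sample[per_sample["gene"].isin(genes)]
    grouped = {g: d["fold"].to_numpy() for g, d in per_sample.groupby("gene")}
    return anova_tukey(grouped)
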