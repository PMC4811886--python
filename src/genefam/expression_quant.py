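"""qPCR relative expression by the reference-normalized ΔΔCt method.

ΔCt = Ct(target) − Ct(reference) within a sample; ΔΔCt = ΔCt(treated) −
ΔCt(control); fold change = 2^(−ΔΔCt), i.e. amplification efficiency is
fixed at 2.0 (no efficiency correction).  Replicate spread is carried on
the ΔCt scale and reported as a fold-change range; significance is a
two-sided two-sample t-test on replicate ΔCt values, starred at
P < 0.05 (*) and P < 0.01 (**).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


@dataclass
class CtTable:
    """Long-format Ct measurements with a designated reference gene."""

    data: pd.DataFrame  # columns: gene, sample, replicate, ct
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ExpressionError(f"Ct table must have columns {sorted(required)}")
        if (self.data["ct"] <= 0).any():
            raise ExpressionError("Ct values must be positive")
        for sample, sub in self.data.groupby("sample"):
            if self.reference_gene not in set(sub["gene"]):
                raise ExpressionError(
                    f"reference gene {self.reference_gene!r} missing in sample "
                    f"{sample!r}"
                )

    @classmethod
    def read_tsv(cls, path: str | Path, reference_gene: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene)

    def delta_ct(self, gene: str, sample: str) -> np.ndarray:
        """Per-replicate ΔCt; replicates paired by replicate id, falling
        back to the reference-mean when replicate structures differ."""
        sub = self.data[self.data["sample"] == sample]
        tgt = sub[sub["gene"] == gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == self.reference_gene].set_index("replicate")["ct"]
        if len(tgt) == 0:
            raise ExpressionError(f"gene {gene!r} not measured in sample {sample!r}")
        common = tgt.index.intersection(ref.index)
        if len(common) == len(tgt):
            return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)
        return (tgt - ref.mean()).to_numpy(dtype=float)


@dataclass
class RelativeExpression:
    gene: str
    treated: str
    control: str
    fold_change: float
    ddct: float
    sd_dct: float
    fold_range: tuple[float, float]
    p_value: float
    stars: str
    replicate_dct: dict[str, list[float]] = field(default_factory=dict)


def significance(
    treated_reps: Sequence[float],
    control_reps: Sequence[float],
    welch: bool = False,
) -> tuple[float, str]:
    """Two-sided two-sample t-test on replicate ΔCt values.

    Returns (p, stars); with fewer than 2 replicates on a side the p is
    undefined (NaN) and no stars are given.  Identical degenerate sets
    (zero variance, equal means) are not significant (p = 1).
    """
    t, c = np.asarray(treated_reps, float), np.asarray(control_reps, float)
    if len(t) < 2 or len(c) < 2:
        return math.nan, ""
    if np.var(t) == 0 and np.var(c) == 0:
        p = 1.0 if np.mean(t) == np.mean(c) else 0.0
    else:
        p = float(stats.ttest_ind(t, c, equal_var=not welch).pvalue)
    if p < 0.01:
        return p, "**"
    if p < 0.05:
        return p, "*"
    return p, ""


def delta_delta_ct(
    table: CtTable,
    gene: str,
    treated: str,
    control: str,
    welch: bool = False,
) -> RelativeExpression:
    """Relative expression of ``gene`` in ``treated`` vs ``control``.

    ΔΔCt uses replicate-mean ΔCt per sample; the replicate ΔCt spread
    (pooled sd of both samples) gives the fold-change range
    [2^(−ΔΔCt−sd), 2^(−ΔΔCt+sd)] reported low-to-high.
    """
    dct_t = table.delta_ct(gene, treated)
    dct_c = table.delta_ct(gene, control)
    ddct = float(np.mean(dct_t) - np.mean(dct_c))
    fold = 2.0 ** (-ddct)
    n_t, n_c = len(dct_t), len(dct_c)
    if n_t >= 2 or n_c >= 2:
        pooled_var = (
            (np.var(dct_t, ddof=1) if n_t >= 2 else 0.0) * max(n_t - 1, 0)
            + (np.var(dct_c, ddof=1) if n_c >= 2 else 0.0) * max(n_c - 1, 0)
        ) / max(n_t + n_c - 2, 1)
        sd = float(np.sqrt(pooled_var))
    else:
        sd = 0.0
    p, stars = significance(dct_t, dct_c, welch=welch)
    lo, hi = 2.0 ** (-ddct - sd), 2.0 ** (-ddct + sd)
    return RelativeExpression(
        gene=gene,
        treated=treated,
        control=control,
        fold_change=fold,
        ddct=ddct,
        sd_dct=sd,
        fold_range=(min(lo, hi), max(lo, hi)),
        p_value=p,
        stars=stars,
        replicate_dct={"treated": list(map(float, dct_t)), "control": list(map(float, dct_c))},
    )


def expression_table(
    table: CtTable, genes: Sequence[str], treated: str, control: str
) -> pd.DataFrame:
    rows = []
    for g in genes:
        r = delta_delta_ct(table, g, treated, control)
        rows.append(
            {
                "gene": g,
                "treated": treated,
                "control": control,
                "fold_change": r.fold_change,
                "ddct": r.ddct,
                "sd_dct": r.sd_dct,
                "p_value": r.p_value,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)
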