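"""Response-gene screening by Spearman rank correlation, and its power.

A *response gene* is one whose expression correlates with a continuous
measure of treatment response (here, tumor lesion size) across patients.
Genes are retained when the two-sided Spearman test is significant at
``p_threshold`` AND the absolute correlation exceeds ``r_threshold``
(defaults 0.05 and 0.3).  No multiple-testing correction is applied at
this stage: the screen is a deliberately permissive pre-filter and the raw
p-value cutoff is part of the procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix

EXACT_PERMUTATION_MAX_N = 10


@dataclass
class ScreenParams:
    p_threshold: float = 0.05
    r_threshold: float = 0.3
    method: str = "t"  # 't' approximation, or 'exact' permutation for n <= 10

    def validate(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if not 0 <= self.r_threshold < 1:
            raise ValueError("r_threshold must be in [0,1)")
        if self.method not in ("t", "exact"):
            raise ValueError("method must be 't' or 'exact'")


@dataclass
class ResponseGeneSet:
    """Retained genes with their Spearman rho and p-value.

    ``table`` is indexed by gene_id with columns ``rho`` and ``p_value``;
    every row satisfies both screening thresholds.  ``n_skipped_constant``
    counts zero-variance genes for which the correlation is undefined.
    """

    table: pd.DataFrame
    n_tested: int
    n_skipped_constant: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ResponseGeneSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
        return cls(table=df, n_tested=len(df), n_skipped_constant=0)


def _spearman_batch(values: np.ndarray, lesion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and two-sided t-approximation p per row."""
    n = values.shape[1]
    gr = stats.rankdata(values, axis=1)
    lr = stats.rankdata(lesion)
    gr_c = gr - gr.mean(axis=1, keepdims=True)
    lr_c = lr - lr.mean()
    denom = np.sqrt((gr_c ** 2).sum(axis=1) * (lr_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr_c @ lr_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def _spearman_exact_p(gene_ranks: np.ndarray, lesion_ranks: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value by full enumeration of lesion orderings."""
    n = len(lesion_ranks)
    gc = gene_ranks - gene_ranks.mean()
    lc = lesion_ranks - lesion_ranks.mean()
    denom = math.sqrt((gc ** 2).sum() * (lc ** 2).sum())
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in permutations(lc):
        r = float(np.dot(gc, perm)) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def screen_response_genes(
    expr: ExpressionMatrix,
    lesion: pd.Series,
    params: ScreenParams | None = None,
) -> ResponseGeneSet:
    """Screen genes correlated with the continuous response measure.

    Parameters
    ----------
    expr : expression matrix; columns must cover ``lesion``'s index.
    lesion : per-sample continuous response measure; NA entries (and their
        samples) are dropped before testing.
    params : thresholds and p-value method.

    Ties are handled by average ranks.  With ``method='exact'`` (n <= 10)
    the p-value is a full permutation enumeration instead of the t
    approximation.
    """
    params = params or ScreenParams()
    params.validate()
    lesion = lesion.dropna()
    usable = [s for s in lesion.index if s in expr.data.columns]
    if len(usable) != len(lesion):
        missing = sorted(set(lesion.index) - set(expr.data.columns))
        raise ValueError(f"lesion samples absent from expression matrix: {missing[:5]}")
    if len(usable) < 4:
        raise ValueError(f"need >=4 samples with lesion values, got {len(usable)}")
    if params.method == "exact" and len(usable) > EXACT_PERMUTATION_MAX_N:
        raise ValueError(f"exact permutation limited to n <= {EXACT_PERMUTATION_MAX_N}")

    sub = expr.data.loc[:, usable]
    values = sub.to_numpy()
    lesion_v = lesion.loc[usable].to_numpy(dtype=float)

    constant = values.std(axis=1) == 0
    rho, p = _spearman_batch(values, lesion_v)

    if params.method == "exact":
        lr = stats.rankdata(lesion_v)
        grs = stats.rankdata(values, axis=1)
        for i in np.flatnonzero(~constant):
            p[i] = _spearman_exact_p(grs[i], lr, rho[i])

    keep = (~constant) & (p < params.p_threshold) & (np.abs(rho) > params.r_threshold)
    table = pd.DataFrame(
        {"rho": rho[keep], "p_value": p[keep]},
        index=pd.Index(np.asarray(sub.index)[keep], name="gene_id"),
    )
    return ResponseGeneSet(
        table=table,
        n_tested=int((~constant).sum()),
        n_skipped_constant=int(constant.sum()),
    )


def power_spearman(n: int, r: float, alpha: float = 0.05) -> float:
    """Power of the two-sided correlation test (critical-r construction).

    The critical correlation is derived from the t distribution with n-2
    degrees of freedom; power is then computed on the Fisher-z (atanh)
    scale with standard deviation 1/sqrt(n-3) and the small-sample mean
    correction r/(2(n-1)).  This is the construction used by standard
    power calculators for correlation tests.

    Parameters
    ----------
    n : sample count (>= 4).
    r : assumed population correlation, |r| < 1 (sign is irrelevant).
    alpha : two-sided significance level.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    r = abs(float(r))
    if r >= 1:
        raise ValueError("|r| must be < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    r_crit = math.sqrt(t_crit ** 2 / (t_crit ** 2 + n - 2))
    zr = math.atanh(r) + r / (2.0 * (n - 1))
    zrc = math.atanh(r_crit)
    s = math.sqrt(n - 3)
    return float(stats.norm.cdf((zr - zrc) * s) + stats.norm.cdf((-zr - zrc) * s))
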