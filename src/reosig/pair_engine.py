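"""Candidate gene-pair construction, orientation and screening.

A gene pair (i, j) carries a *relative expression ordering* (REO) signal
when the within-sample ordering E_i > E_j occurs preferentially in one
response group.  The pair engine:

1. enumerates all unordered pairs containing at least one response gene
   (:func:`enumerate_pairs` / :func:`count_candidate_pairs`);
2. orients each pair by its expression difference statistic

       ED_ij = mean_{responders}(E_i - E_j) - mean_{non-responders}(E_i - E_j)

   keeping the orientation with ED > 0 and discarding ED = 0 pairs;
3. screens pairs whose per-sample differences separate the response groups
   (two-sided Wilcoxon rank-sum, p < 0.01 by default);
4. keeps pairs whose vote accuracy beats the no-information rate by a
   one-sided exact binomial test (alpha 0.05 by default).

A sample's *vote* for a pair is the strict comparison E_i > E_j (ties vote
non-responder); votes, confusion counts, accuracy and the binomial p-value
are therefore invariant to any strictly increasing within-sample transform.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from math import comb
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, ResponseLabels

EXACT_WILCOXON_MAX_N = 25

PAIR_TABLE_COLUMNS = [
    "gene_i", "gene_j", "ed", "wilcoxon_p", "binomial_p",
    "tp", "tn", "fp", "fn", "f_score",
]


@dataclass
class PairScreenParams:
    wilcoxon_p_threshold: float = 0.01
    binomial_alpha: float = 0.05
    binomial_null_p: float | None = None  # default: majority-class proportion

    def validate(self) -> None:
        if not 0 < self.wilcoxon_p_threshold < 1:
            raise ValueError("wilcoxon_p_threshold must be in (0,1)")
        if not 0 < self.binomial_alpha < 1:
            raise ValueError("binomial_alpha must be in (0,1)")
        if self.binomial_null_p is not None and not 0 < self.binomial_null_p <= 1:
            raise ValueError("binomial_null_p must be in (0,1]")


@dataclass
class GenePairRecord:
    """One oriented candidate pair.

    Orientation contract: E(gene_i) > E(gene_j) is the responder-indicating
    ordering, and ``ed`` (the ED statistic in that orientation) is > 0 for
    every retained record.  Confusion counts come from voting each labeled
    sample responder iff E_i > E_j.
    """

    gene_i: str
    gene_j: str
    ed: float
    tp: int
    tn: int
    fp: int
    fn: int
    f_score: float
    wilcoxon_p: float = float("nan")
    binomial_p: float = float("nan")

    @property
    def n_labeled(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def sort_key(self) -> tuple:
        return (-self.f_score, self.wilcoxon_p, self.gene_i, self.gene_j)


# ---------------------------------------------------------------------------
# enumeration

def count_candidate_pairs(n_marked: int, n_total: int) -> int:
    """Number of unordered pairs containing at least one marked gene.

    C(n_marked, 2) pairs within the marked set plus n_marked * (n_total -
    n_marked) pairs bridging to the rest of the universe.
    """
    if n_marked < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    if n_marked > n_total:
        raise ValueError("n_marked cannot exceed n_total")
    return comb(n_marked, 2) + n_marked * (n_total - n_marked)


def enumerate_pairs(
    marked_genes: Iterable[str], all_genes: Sequence[str]
) -> Iterator[tuple[str, str]]:
    """Yield every unordered pair with >= 1 marked gene, exactly once.

    Pairs come out in lexicographic order with the smaller id first.
    """
    universe = sorted(set(all_genes))
    marked = sorted(set(marked_genes))
    missing = [m for m in marked if m not in set(universe)]
    if missing:
        raise ValueError(f"marked genes not in universe: {missing[:5]}")
    marked_set = set(marked)
    for idx, a in enumerate(universe):
        if a in marked_set:
            for b in universe[idx + 1:]:
                yield (a, b)
        else:
            # only pairs whose second member is marked and sorts after a
            for b in marked[bisect_right(marked, a):]:
                yield (a, b)


# ---------------------------------------------------------------------------
# single-pair statistics

def _pair_diffs(
    pair: tuple[str, str], expr: ExpressionMatrix, labels: ResponseLabels
) -> tuple[np.ndarray, np.ndarray]:
    gi, gj = pair
    for g in (gi, gj):
        if g not in expr.data.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    d = (expr.data.loc[gi, labels.sample_ids] - expr.data.loc[gj, labels.sample_ids]).to_numpy()
    resp = labels.as_bool()
    if resp.all() or not resp.any():
        raise ValueError("both label groups must be non-empty")
    return d[resp], d[~resp]


def compute_ed(
    pair: tuple[str, str], expr: ExpressionMatrix, labels: ResponseLabels
) -> float:
    """ED statistic: responder mean of (E_i - E_j) minus non-responder mean."""
    d_resp, d_non = _pair_diffs(pair, expr, labels)
    return float(d_resp.mean() - d_non.mean())


def wilcoxon_reo_test(
    pair: tuple[str, str], expr: ExpressionMatrix, labels: ResponseLabels
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing (E_i - E_j) between groups.

    Exact null distribution when the combined group size is <= 25 and the
    differences are tie-free; normal approximation with tie correction
    otherwise.
    """
    d_resp, d_non = _pair_diffs(pair, expr, labels)
    return _wilcoxon_p(d_resp, d_non)


def _wilcoxon_p(d_resp: np.ndarray, d_non: np.ndarray) -> float:
    n = len(d_resp) + len(d_non)
    combined = np.concatenate([d_resp, d_non])
    no_ties = len(np.unique(combined)) == n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(d_resp, d_non, alternative="two-sided", method=method)
    return float(res.pvalue)


def orient_pair(
    pair: tuple[str, str], expr: ExpressionMatrix, labels: ResponseLabels
) -> GenePairRecord | None:
    """Orient a pair by ED and populate its vote confusion counts.

    Returns the record with ed > 0 (swapping the genes if the canonical
    orientation has ED < 0) or ``None`` when ED = 0, in which case the pair
    carries no orientation signal and is excluded.
    """
    ed = compute_ed(pair, expr, labels)
    if ed == 0:
        return None
    gi, gj = pair if ed > 0 else (pair[1], pair[0])
    d_resp, d_non = _pair_diffs((gi, gj), expr, labels)
    tp = int((d_resp > 0).sum())
    fn = len(d_resp) - tp
    fp = int((d_non > 0).sum())
    tn = len(d_non) - fp
    rec = GenePairRecord(
        gene_i=gi, gene_j=gj, ed=abs(ed),
        tp=tp, tn=tn, fp=fp, fn=fn,
        f_score=(tp + tn) / (tp + tn + fp + fn),
    )
    return rec


def pair_f_score(record: GenePairRecord) -> float:
    """Vote accuracy (TP+TN)/(TP+FN+TN+FP) of a pair's strict-ordering vote."""
    n = record.n_labeled
    if n == 0:
        raise ValueError("confusion counts are empty")
    return (record.tp + record.tn) / n


def binomial_filter(
    record: GenePairRecord, params: PairScreenParams | None = None
) -> tuple[bool, float]:
    """One-sided exact binomial test of vote accuracy against a null rate.

    The null success probability defaults to the majority-class proportion
    of the labeled samples (the no-information rate); the p-value is the
    exact upper tail P(X >= correct) for X ~ Binomial(n, p0).
    """
    params = params or PairScreenParams()
    params.validate()
    n = record.n_labeled
    if n == 0:
        raise ValueError("confusion counts are empty")
    p0 = params.binomial_null_p
    if p0 is None:
        n_pos = record.tp + record.fn
        p0 = max(n_pos, n - n_pos) / n
    correct = record.tp + record.tn
    p = float(stats.binom.sf(correct - 1, n, p0))
    return p < params.binomial_alpha, p


# ---------------------------------------------------------------------------
# batch screening

def pair_votes(
    pairs: Sequence[tuple[str, str]], expr: ExpressionMatrix, sample_ids: Sequence[str]
) -> np.ndarray:
    """Boolean vote matrix (pairs x samples): True where E_i > E_j strictly."""
    gene_pos = {g: k for k, g in enumerate(expr.data.index)}
    try:
        i_rows = np.array([gene_pos[gi] for gi, _ in pairs], dtype=int)
        j_rows = np.array([gene_pos[gj] for _, gj in pairs], dtype=int)
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} absent from expression matrix") from None
    cols = [expr.data.columns.get_loc(s) for s in sample_ids]
    X = expr.values[:, cols]
    return X[i_rows] > X[j_rows]


def screen_pairs(
    pairs: Iterable[tuple[str, str]],
    expr: ExpressionMatrix,
    labels: ResponseLabels,
    params: PairScreenParams | None = None,
    chunk_size: int = 100_000,
) -> tuple[list[GenePairRecord], dict[str, int]]:
    """Run the full pair screen (ED orientation -> Wilcoxon -> binomial).

    Returns the retained, fully populated records sorted by
    (-f_score, wilcoxon_p, gene_i, gene_j), together with a funnel of
    counts at each filtering step.  Pairs are processed in chunks with
    vectorized statistics, so the input may be a lazy stream.
    """
    params = params or PairScreenParams()
    params.validate()
    resp = labels.as_bool()
    if resp.all() or not resp.any():
        raise ValueError("both label groups must be non-empty")
    n1, n2 = int(resp.sum()), int((~resp).sum())
    n = n1 + n2
    p0 = params.binomial_null_p if params.binomial_null_p is not None else max(n1, n2) / n

    gene_pos = {g: k for k, g in enumerate(expr.data.index)}
    cols = [expr.data.columns.get_loc(s) for s in labels.sample_ids]
    X = expr.values[:, cols]

    funnel = {"input": 0, "ed_positive": 0, "wilcoxon_pass": 0, "binomial_pass": 0}
    kept: list[GenePairRecord] = []

    pair_iter = iter(pairs)
    while True:
        chunk = []
        for pair in pair_iter:
            chunk.append(pair)
            if len(chunk) >= chunk_size:
                break
        if not chunk:
            break
        funnel["input"] += len(chunk)
        i_rows = np.array([gene_pos[gi] for gi, _ in chunk], dtype=int)
        j_rows = np.array([gene_pos[gj] for _, gj in chunk], dtype=int)
        D = X[i_rows] - X[j_rows]  # pairs x labeled samples
        ed = D[:, resp].mean(axis=1) - D[:, ~resp].mean(axis=1)

        # orient: negate differences where the canonical ED is negative
        flip = ed < 0
        D[flip] *= -1.0
        nonzero = ed != 0
        funnel["ed_positive"] += int(nonzero.sum())

        votes = D > 0
        tp = votes[:, resp].sum(axis=1)
        fp = votes[:, ~resp].sum(axis=1)
        fn = n1 - tp
        tn = n2 - fp
        correct = tp + tn
        binom_p = stats.binom.sf(correct - 1, n, p0)

        if n > EXACT_WILCOXON_MAX_N:
            wilc_p = np.asarray(
                stats.mannwhitneyu(
                    D[:, resp], D[:, ~resp], alternative="two-sided",
                    method="asymptotic", axis=1,
                ).pvalue
            )
        else:
            wilc_p = np.array([_wilcoxon_p(D[k, resp], D[k, ~resp]) for k in range(len(chunk))])

        wilc_ok = nonzero & (wilc_p < params.wilcoxon_p_threshold)
        funnel["wilcoxon_pass"] += int(wilc_ok.sum())
        keep = wilc_ok & (binom_p < params.binomial_alpha)
        funnel["binomial_pass"] += int(keep.sum())

        for k in np.flatnonzero(keep):
            gi, gj = chunk[k]
            if flip[k]:
                gi, gj = gj, gi
            kept.append(GenePairRecord(
                gene_i=gi, gene_j=gj, ed=float(abs(ed[k])),
                tp=int(tp[k]), tn=int(tn[k]), fp=int(fp[k]), fn=int(fn[k]),
                f_score=float(correct[k] / n),
                wilcoxon_p=float(wilc_p[k]), binomial_p=float(binom_p[k]),
            ))

    kept.sort(key=GenePairRecord.sort_key)
    return kept, funnel


# ---------------------------------------------------------------------------
# pair table IO

def records_to_frame(records: Sequence[GenePairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.gene_i, r.gene_j, r.ed, r.wilcoxon_p, r.binomial_p,
          r.tp, r.tn, r.fp, r.fn, r.f_score] for r in records],
        columns=PAIR_TABLE_COLUMNS,
    )


def write_pair_table(path: str | Path, records: Sequence[GenePairRecord]) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[GenePairRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    return [
        GenePairRecord(
            gene_i=row.gene_i, gene_j=row.gene_j, ed=row.ed,
            tp=int(row.tp), tn=int(row.tn), fp=int(row.fp), fn=int(row.fn),
            f_score=row.f_score, wilcoxon_p=row.wilcoxon_p, binomial_p=row.binomial_p,
        )
        for row in df.itertuples()
    ]
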