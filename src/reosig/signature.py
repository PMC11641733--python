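"""Gene-pair signatures: majority-vote scoring and greedy forward selection.

A signature is an ordered set of oriented gene pairs plus a vote threshold.
A sample's score is the number of signature pairs whose responder-indicating
ordering E_i > E_j holds in that sample; the sample is called a responder
when the score reaches the threshold (2 of 3 for a three-pair signature).
Scoring needs only the sample's own column, so a signature applies to a
single sample with no cohort normalization.

Selection is a seeded greedy forward search maximizing classification
accuracy (the pair "F-score"): the top ``n_seeds`` candidate pairs by
accuracy each seed a signature that grows by the single pair giving the
largest strict accuracy increase, until no addition improves; the best of
the seeded signatures wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, ResponseLabels, RESPONDER, NON_RESPONDER
from .pair_engine import GenePairRecord, pair_votes


def default_threshold(k: int) -> int:
    """Strict-majority vote threshold for a k-pair signature: floor(k/2)+1."""
    if k < 1:
        raise ValueError("signature size must be >= 1")
    return k // 2 + 1


DEFAULT_CALL_THRESHOLD = 2
"""Score needed to call a responder during forward selection.

The responder call is a fixed score cutoff, not a size-adaptive majority:
a sample is a responder when at least this many signature pairs show their
responder-indicating ordering, whatever the current signature size.  See
the methods note for why the search needs the cutoff to be fixed."""


@dataclass
class Signature:
    """Oriented gene pairs plus the vote threshold for calling a responder."""

    pairs: list[tuple[str, str]]
    vote_threshold: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.vote_threshold <= len(self.pairs):
            raise ValueError("vote_threshold must be in [1, number of pairs]")
        seen = set()
        for gi, gj in self.pairs:
            if gi == gj:
                raise ValueError(f"degenerate pair ({gi}, {gj})")
            key = frozenset((gi, gj))
            if key in seen:
                raise ValueError(f"pair {{{gi}, {gj}}} appears more than once")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScoreResult:
    """Per-sample integer scores and the resulting responder calls."""

    table: pd.DataFrame  # index sample_id; columns: score, predicted

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoreResult":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
        return cls(table=df)


def score_samples(sig: Signature, expr: ExpressionMatrix) -> ScoreResult:
    """Score every sample of ``expr`` against the signature.

    Raises ``KeyError`` naming the first signature gene missing from the
    matrix.
    """
    votes = pair_votes(sig.pairs, expr, expr.sample_ids)
    scores = votes.sum(axis=0)
    predicted = np.where(scores >= sig.vote_threshold, RESPONDER, NON_RESPONDER)
    table = pd.DataFrame(
        {"score": scores, "predicted": predicted},
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )
    return ScoreResult(table=table)


def forward_select(
    candidates: Sequence[GenePairRecord],
    expr: ExpressionMatrix,
    labels: ResponseLabels,
    n_seeds: int = 20,
    max_pairs: int = 11,
    candidate_cap: int = 10_000,
    call_threshold: int = DEFAULT_CALL_THRESHOLD,
) -> Signature:
    """Seeded greedy forward selection of the highest-accuracy signature.

    Candidates are ordered by (-f_score, wilcoxon_p, gene_i, gene_j) and
    capped at ``candidate_cap``.  Each of the top ``n_seeds`` pairs seeds a
    greedy growth: at every step all remaining candidates are scanned and
    the one whose addition yields the largest strict increase in signature
    accuracy is added; growth stops when no addition strictly improves
    accuracy or ``max_pairs`` is reached.  Throughout the search a sample
    is called a responder when its score reaches the fixed
    ``call_threshold`` (default 2), whatever the current signature size.
    The best seeded signature wins (highest accuracy, then fewer pairs,
    then seed order); its vote threshold is ``min(call_threshold, size)``.
    The provenance dict records each seed's trajectory.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if call_threshold < 1:
        raise ValueError("call_threshold must be >= 1")
    ordered = sorted(candidates, key=GenePairRecord.sort_key)[:candidate_cap]
    y = labels.as_bool()
    n = len(y)
    votes = pair_votes(
        [(r.gene_i, r.gene_j) for r in ordered], expr, labels.sample_ids
    ).astype(np.int16)

    best: tuple[int, int, int, list[int], list[float]] | None = None
    seed_logs = []
    for seed_idx in range(min(n_seeds, len(ordered))):
        chosen = [seed_idx]
        score_vec = votes[seed_idx].copy()
        correct = int(((score_vec >= call_threshold) == y).sum())
        trajectory = [correct / n]
        while len(chosen) < max_pairs:
            remaining = np.setdiff1d(np.arange(len(ordered)), chosen, assume_unique=False)
            if remaining.size == 0:
                break
            cand_scores = score_vec[None, :] + votes[remaining]
            cand_correct = ((cand_scores >= call_threshold) == y).sum(axis=1)
            pick = int(np.argmax(cand_correct))  # first index wins ties
            if int(cand_correct[pick]) <= correct:
                break
            chosen.append(int(remaining[pick]))
            score_vec += votes[remaining[pick]]
            correct = int(cand_correct[pick])
            trajectory.append(correct / n)
        seed_logs.append({
            "seed_pair": [ordered[seed_idx].gene_i, ordered[seed_idx].gene_j],
            "pairs": [[ordered[c].gene_i, ordered[c].gene_j] for c in chosen],
            "f_score_trajectory": trajectory,
        })
        key = (correct, -len(chosen), -seed_idx)
        if best is None or key > best[:3]:
            best = (correct, -len(chosen), -seed_idx, chosen, trajectory)

    assert best is not None
    correct, _, neg_seed, chosen, trajectory = best
    pairs = [(ordered[c].gene_i, ordered[c].gene_j) for c in chosen]
    final_threshold = min(call_threshold, len(pairs))
    # accuracy of the returned signature under its final threshold
    final_scores = votes[chosen].sum(axis=0)
    final_correct = int(((final_scores >= final_threshold) == y).sum())
    return Signature(
        pairs=pairs,
        vote_threshold=final_threshold,
        provenance={
            "n_candidates": len(ordered),
            "n_seeds": min(n_seeds, len(ordered)),
            "winning_seed": -neg_seed,
            "call_threshold": call_threshold,
            "training_f_score": final_correct / n,
            "f_score_trajectory": trajectory,
            "seeds": seed_logs,
        },
    )
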