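"""Binary pathway-pair features and the prevalence filter.

Within each sample, every unordered pair of pathways is reduced to one bit:
1 if the first pathway (in canonical catalog order) scores strictly higher
than the second, 0 otherwise (ties give 0). Because the bit depends only on
the within-sample ordering of pathway scores, the pair matrix is invariant
to any strictly increasing per-sample distortion of the underlying
expression — which is what makes pair signatures portable across
sequencing platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_set_scoring import PathwayScores

__all__ = ["PairMatrix", "build_pair_matrix", "filter_pairs", "pair_values_for", "pair_id"]


def pair_id(a: str, b: str) -> str:
    return f"{a}|{b}"


@dataclass
class PairMatrix:
    """Pairs x samples binary matrix with pair identities.

    `pairs` lists (pathway_a, pathway_b) tuples; row index of `values` is
    the "a|b" pair ID. Orientation matters: value 1 means pathway_a scored
    strictly higher than pathway_b in that sample.
    """

    pairs: list[tuple[str, str]]
    values: pd.DataFrame

    def __post_init__(self):
        if len(self.pairs) != self.values.shape[0]:
            raise ValueError("pair list and value matrix disagree on the number of pairs")
        ids = [pair_id(a, b) for a, b in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair identities")
        v = self.values.to_numpy()
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("pair matrix values must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b in self.pairs]

    @property
    def prevalence(self) -> pd.Series:
        """Per-pair fraction of ones across samples."""
        return self.values.mean(axis=1)

    def subset(self, pair_list: list[tuple[str, str]]) -> "PairMatrix":
        ids = [pair_id(a, b) for a, b in pair_list]
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"pairs not present in matrix: {missing}")
        return PairMatrix(pairs=list(pair_list), values=self.values.loc[ids])


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, PathwayScores):
        return scores.scores
    return scores


def build_pair_matrix(scores) -> PairMatrix:
    """All K(K-1)/2 canonical pathway pairs as binary within-sample comparisons.

    Canonical orientation: pathway_a is the one earlier in the score-matrix
    (catalog) row order. value[a|b, s] = 1 iff score(a, s) > score(b, s).
    """
    frame = _scores_frame(scores)
    pathways = list(frame.index)
    if len(pathways) < 2:
        raise ValueError(f"need at least 2 pathways to build pairs, got {len(pathways)}")
    mat = frame.to_numpy(dtype=float)
    ia, ib = np.triu_indices(len(pathways), k=1)
    values = (mat[ia] > mat[ib]).astype(np.int8)
    pairs = [(pathways[i], pathways[j]) for i, j in zip(ia, ib)]
    frame_out = pd.DataFrame(values, index=[pair_id(a, b) for a, b in pairs], columns=frame.columns)
    return PairMatrix(pairs=pairs, values=frame_out)


def filter_pairs(pm: PairMatrix, low: float = 0.2, high: float = 0.8) -> PairMatrix:
    """Keep pairs whose prevalence (fraction of ones) lies in [low, high].

    Pairs that are 1 in more than `high` or less than `low` of the samples
    are nearly constant and carry no discriminative information; both
    boundaries are inclusive. Computed on the training cohort only —
    validation cohorts inherit the trained pair list unchanged.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"require 0 <= low < high <= 1, got low={low}, high={high}")
    prev = pm.prevalence.to_numpy()
    keep = (prev >= low) & (prev <= high)
    if not keep.any():
        raise ValueError(
            f"prevalence filter [{low}, {high}] removed all {len(pm.pairs)} pairs; "
            "widen the bounds or use a larger cohort"
        )
    pairs = [p for p, k in zip(pm.pairs, keep) if k]
    return PairMatrix(pairs=pairs, values=pm.values.loc[keep])


def pair_values_for(pairs: list[tuple[str, str]], scores) -> PairMatrix:
    """Evaluate a fixed list of (oriented) pairs on a new cohort's scores.

    Applies the same strict-> rule with no prevalence filter; used to carry
    a trained signature onto validation cohorts. Pathways named in `pairs`
    must all be present in `scores`.
    """
    frame = _scores_frame(scores)
    needed = {p for ab in pairs for p in ab}
    missing = sorted(needed - set(frame.index))
    if missing:
        raise KeyError(f"pathways missing from score matrix: {missing}")
    if not pairs:
        return PairMatrix(pairs=[], values=pd.DataFrame(index=pd.Index([]), columns=frame.columns, dtype=np.int8))
    rows = np.stack(
        [
            (frame.loc[a].to_numpy(float) > frame.loc[b].to_numpy(float)).astype(np.int8)
            for a, b in pairs
        ]
    )
    values = pd.DataFrame(rows, index=[pair_id(a, b) for a, b in pairs], columns=frame.columns)
    return PairMatrix(pairs=list(pairs), values=values)
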