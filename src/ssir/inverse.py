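"""Inverse SAR: enumerate, filter, score and merge untested analogues.

The fitted rule model scores any code of the full combinatorial space, so
the complement of the training set (all ``M - a`` not-yet-synthesized
analogues) can be ranked directly.  A chemical-space neighbor filter keeps
candidates within a bounded number of substitution differences of enough
training compounds, and multi-property rankings are merged by summing
per-property votes linearly rescaled onto [-1, +1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import AnalogueCode, LibrarySpec, enumerate_full_library
from .model import SSIRVoting

__all__ = [
    "CandidateSet",
    "enumerate_candidates",
    "neighbor_filter",
    "predict_candidates",
    "scale_votes",
    "consensus_rank",
    "positive_in_all",
]


@dataclass
class CandidateSet:
    """Untested analogues with per-property votes and consensus scores."""

    spec: LibrarySpec
    codes: list[AnalogueCode]
    votes: dict[str, np.ndarray] = field(default_factory=dict)
    scaled: dict[str, np.ndarray] = field(default_factory=dict)
    consensus: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"code": ["".join(c) for c in self.codes]})
        for name, v in self.votes.items():
            df[f"votes_{name}"] = v
        for name, v in self.scaled.items():
            df[f"scaled_{name}"] = v
        if self.consensus is not None:
            df["consensus"] = self.consensus
        return df


def enumerate_candidates(
    spec: LibrarySpec, training_codes: Sequence[AnalogueCode]
) -> CandidateSet:
    """All ``M - a`` analogues of the full library not in the training set,
    in the deterministic full-enumeration order."""
    training = {spec.validate_code(c) for c in training_codes}
    codes = [c for c in enumerate_full_library(spec) if c not in training]
    return CandidateSet(spec=spec, codes=codes)


def neighbor_filter(
    candidates: CandidateSet,
    training_codes: Sequence[AnalogueCode],
    max_diff: int = 1,
    min_neighbors: int = 3,
) -> CandidateSet:
    """Keep candidates within *max_diff* substitution differences (site-wise
    Hamming distance) of at least *min_neighbors* training compounds."""
    if max_diff < 1 or min_neighbors < 1:
        raise ValueError("max_diff and min_neighbors must be >= 1")
    spec = candidates.spec
    cand_idx = spec.encode(candidates.codes)
    train_idx = spec.encode([spec.validate_code(c) for c in training_codes])
    keep = np.zeros(len(candidates), dtype=bool)
    for start in range(0, cand_idx.shape[0], 2048):
        chunk = cand_idx[start : start + 2048]
        dist = (chunk[:, None, :] != train_idx[None, :, :]).sum(axis=2)
        keep[start : start + 2048] = (dist <= max_diff).sum(axis=1) >= min_neighbors
    kept = np.flatnonzero(keep)
    return CandidateSet(
        spec=spec,
        codes=[candidates.codes[i] for i in kept],
        votes={k: v[kept] for k, v in candidates.votes.items()},
    )


def predict_candidates(
    models: Mapping[str, SSIRVoting] | SSIRVoting,
    candidates: CandidateSet,
) -> CandidateSet:
    """Attach per-model integer votes to the candidate set.

    *models* maps property names to fitted models; a bare model is stored
    under the name ``"votes"``.
    """
    if isinstance(models, SSIRVoting):
        models = {"votes": models}
    for name, model in models.items():
        candidates.votes[name] = model.decision_function(candidates.codes)
    return candidates


def scale_votes(votes: Sequence[int]) -> np.ndarray:
    """Rescale integer votes onto [-1, +1], preserving sign and rank order.

    Positive votes are divided by the maximum positive vote (onto (0, +1]),
    negative votes by the magnitude of the minimum vote (onto [-1, 0));
    exactly-zero votes stay exactly 0.
    """
    v = np.asarray(votes, dtype=float)
    if v.size == 0:
        raise ValueError("no votes to scale")
    out = np.zeros_like(v)
    pos, neg = v > 0, v < 0
    if pos.any():
        out[pos] = v[pos] / v[pos].max()
    if neg.any():
        out[neg] = v[neg] / abs(v[neg].min())
    return out


def consensus_rank(candidates: CandidateSet) -> CandidateSet:
    """Merge the per-property vote lists into one consensus ranking.

    Each property's votes are rescaled by :func:`scale_votes` and summed;
    the sum is the consensus score.  Candidates are reordered by descending
    consensus, ties broken by the canonical candidate order.
    """
    if len(candidates.votes) < 1:
        raise ValueError("consensus needs at least one vote vector")
    lengths = {v.shape[0] for v in candidates.votes.values()}
    if lengths != {len(candidates)}:
        raise ValueError("vote vectors are not aligned with the candidate set")
    candidates.scaled = {k: scale_votes(v) for k, v in candidates.votes.items()}
    consensus = np.sum(list(candidates.scaled.values()), axis=0)
    order = np.argsort(-consensus, kind="stable")
    return CandidateSet(
        spec=candidates.spec,
        codes=[candidates.codes[i] for i in order],
        votes={k: v[order] for k, v in candidates.votes.items()},
        scaled={k: v[order] for k, v in candidates.scaled.items()},
        consensus=consensus[order],
    )


def positive_in_all(candidates: CandidateSet) -> np.ndarray:
    """Mask of candidates with strictly positive votes for every property.

    Membership is scale-invariant: raw and rescaled votes give the same set.
    """
    if not candidates.votes:
        raise ValueError("candidate set carries no votes")
    mask = np.ones(len(candidates), dtype=bool)
    for v in candidates.votes.values():
        mask &= v > 0
    return mask
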