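"""k-NN similarity-search benchmark scored by AUC ROC.

Protocol: per trial, 100 actives are sampled from a class; 10 become the
reference set and the remaining 90 are potential hits spiked into a background
database of decoys. Every database compound is scored against the references
— the maximum Tanimoto coefficient for 1-NN, or the mean of the top-k values
for k-NN — and the ranking of hits versus background is summarized as the
area under the ROC curve. Trials are averaged (20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["SearchTrial", "knn_score", "knn_scores", "auc_roc", "run_trials"]


@dataclass
class SearchTrial:
    """One similarity-search trial: reference/hit split, scores, and AUC."""

    trial: int
    k: int
    seed: int
    reference_ids: tuple[str, ...]
    hit_ids: tuple[str, ...]
    hit_scores: np.ndarray = field(repr=False)
    background_scores: np.ndarray = field(repr=False)
    auc: float = float("nan")


def _pairwise_tanimoto(db: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """(n_db, n_ref) Tanimoto matrix for binary fingerprint matrices."""
    db = np.asarray(db, dtype=np.float64)
    refs = np.asarray(refs, dtype=np.float64)
    inter = db @ refs.T
    union = db.sum(axis=1)[:, None] + refs.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / union, 0.0)
    return tc


def knn_score(db_fp: np.ndarray, ref_fps: np.ndarray, k: int) -> float:
    """Final similarity score of one database compound against the references.

    Maximum Tanimoto for ``k=1``; mean of the ``k`` largest Tanimoto values
    otherwise.
    """
    ref_fps = np.atleast_2d(ref_fps)
    if not 1 <= k <= len(ref_fps):
        raise ValueError(f"k={k} out of range for {len(ref_fps)} references")
    tcs = _pairwise_tanimoto(np.atleast_2d(db_fp), ref_fps)[0]
    if k == 1:
        return float(tcs.max())
    return float(np.sort(tcs)[-k:].mean())


def knn_scores(db_fps: np.ndarray, ref_fps: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`knn_score` over a database fingerprint matrix."""
    if not 1 <= k <= len(ref_fps):
        raise ValueError(f"k={k} out of range for {len(ref_fps)} references")
    tc = _pairwise_tanimoto(db_fps, ref_fps)
    if k == 1:
        return tc.max(axis=1)
    return np.sort(tc, axis=1)[:, -k:].mean(axis=1)


def auc_roc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2).

    Mann-Whitney formulation of the area under the ROC curve.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def run_trials(
    actives: Sequence,
    background: Sequence,
    fp_fn: Callable[[Sequence], np.ndarray],
    k: int,
    n_trials: int = 20,
    n_sample: int = 100,
    n_ref: int = 10,
    seed: int = 0,
    class_name: str = "",
) -> tuple[list[SearchTrial], float]:
    """Run the benchmark for one activity class and one k.

    ``actives``/``background`` are molecule records (or SMILES); ``fp_fn``
    maps a molecule list to a fingerprint matrix. The background is fixed
    across trials; references and hits are resampled per trial with seeds
    derived from the master seed. Returns the per-trial results and their
    mean AUC.
    """
    if len(actives) < n_sample:
        raise ValueError(
            f"class {class_name or '<unnamed>'}: {len(actives)} actives < "
            f"n_sample={n_sample}"
        )
    ids = [getattr(a, "id", str(i)) for i, a in enumerate(actives)]
    active_fps = np.asarray(fp_fn(list(actives)))
    background_fps = np.asarray(fp_fn(list(background)))

    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    results = []
    for t in range(n_trials):
        rng = np.random.default_rng(int(trial_seeds[t]))
        chosen = rng.choice(len(actives), size=n_sample, replace=False)
        refs, hits = chosen[:n_ref], chosen[n_ref:]
        hit_scores = knn_scores(active_fps[hits], active_fps[refs], k)
        bg_scores = knn_scores(background_fps, active_fps[refs], k)
        results.append(
            SearchTrial(
                trial=t,
                k=k,
                seed=int(trial_seeds[t]),
                reference_ids=tuple(ids[i] for i in refs),
                hit_ids=tuple(ids[i] for i in hits),
                hit_scores=hit_scores,
                background_scores=bg_scores,
                auc=auc_roc(hit_scores, bg_scores),
            )
        )
    return results, float(np.mean([r.auc for r in results]))
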