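"""Scoring ranked edge predictions and running ensemble benchmarks.

A prediction over N genes ranks all N(N-1) ordered pairs; the gold
standard marks each pair as a true edge or a non-edge.  Two summary areas
are reported, as in the DREAM network challenges:

* AUC(ROC) — the probability that a uniformly random true edge outranks a
  uniformly random non-edge.  Computed in closed Mann–Whitney form with
  midrank tie handling, which sidesteps curve-interpolation ambiguity.
* AUC(PvsR) — the area under the precision-versus-recall walk of the
  ranking, accumulated as sum(precision * delta-recall) over distinct
  score levels.  A tie group contributes its pooled precision, so a
  constant ranking scores the positive prevalence and a perfect ranking
  scores 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .confidence import CONFIDENCE_METHODS, confidence_matrix
from .datasets import EdgeRanking, GeneNetwork
from .downrank import downrank
from .errors import EvaluationError, ValidationError
from .simulate import SimulationConfig, generate_er_network, simulate_knockout_compendium

__all__ = [
    "EvaluationResult",
    "evaluate_ranking",
    "evaluate_scores",
    "simulate_replicate",
    "benchmark_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    auc_roc: float
    auc_pvsr: float
    n_positives: int
    n_candidates: int

    def to_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_pvsr": self.auc_pvsr,
            "n_positives": self.n_positives,
            "n_candidates": self.n_candidates,
        }


def _auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with midranks for ties."""
    pos = int(labels.sum())
    neg = labels.size - pos
    ranks = rankdata(scores)  # average ranks, ascending
    rank_sum = ranks[labels].sum()
    return float((rank_sum - pos * (pos + 1) / 2) / (pos * neg))


def _auc_pvsr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall walk over distinct score levels."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    # boundaries after each distinct score level
    boundary = np.nonzero(np.diff(s))[0]
    cuts = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[cuts]
    k = cuts + 1.0  # predictions made at each level
    precision = tp / k
    pos = y.sum()
    recall = tp / pos
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * d_recall))


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> EvaluationResult:
    """Score a flat array of candidate scores against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    pos = int(labels.sum())
    if pos == 0:
        raise EvaluationError("gold standard has no edges: AUCs are undefined")
    if pos == labels.size:
        raise EvaluationError("gold standard has no non-edges: AUC(ROC) is undefined")
    return EvaluationResult(
        auc_roc=_auc_roc(scores, labels),
        auc_pvsr=_auc_pvsr(scores, labels),
        n_positives=pos,
        n_candidates=labels.size,
    )


def evaluate_ranking(ranking: EdgeRanking, truth: GeneNetwork) -> EvaluationResult:
    """Score a full edge ranking against a gold-standard network."""
    if ranking.n_genes != truth.n_genes:
        raise ValidationError(
            f"ranking covers {ranking.n_genes} genes but gold standard has "
            f"{truth.n_genes}"
        )
    edges = truth.edges
    labels = np.array([(i, j) in edges for i, j in ranking.pairs])
    return evaluate_scores(ranking.scores, labels)


# ---------------------------------------------------------------------------
# ensemble benchmark
# ---------------------------------------------------------------------------


def simulate_replicate(
    cfg: SimulationConfig, seed: int | np.random.SeedSequence
):
    """One benchmark replicate: a random network and its knockout compendium.

    The seed fully determines both; a truth with zero edges is redrawn
    (and logged) since no metric is defined for it.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    net = generate_er_network(cfg.n_genes, cfg.avg_degree, rng)
    while net.n_edges == 0:
        logger.info("redrawing replicate network: truth had zero edges")
        net = generate_er_network(cfg.n_genes, cfg.avg_degree, rng)
    data = simulate_knockout_compendium(net, cfg, rng=rng)
    return net, data


def benchmark_ensemble(
    cfg: SimulationConfig,
    n_networks: int,
    methods: list[str] | tuple[str, ...] = ("D", "ND", "ZD", "ZR"),
    thresholds: list[float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Mean AUCs of confidence methods over an ensemble of random networks.

    For each replicate a network and compendium are simulated, every
    requested confidence matrix is computed, optionally down-ranked at
    each threshold, and both AUCs are scored against the simulated truth.
    Returns one row per (method, threshold) cell with per-cell means and
    standard errors; ``threshold`` is NaN for the no-down-ranking baseline.
    A fixed seed makes the whole table reproducible, and replicate r can
    be regenerated in isolation from child seed r.
    """
    if n_networks < 1:
        raise ValidationError("n_networks must be >= 1")
    unknown = set(methods) - set(CONFIDENCE_METHODS)
    if unknown:
        raise ValidationError(f"unknown method tags: {sorted(unknown)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_networks)

    cells: dict[tuple[str, float], dict[str, list[float]]] = {}
    for r in range(n_networks):
        net, data = simulate_replicate(cfg, children[r])
        edges = net.edges
        for method in methods:
            # simulated compendia can hold a fully repressed gene at
            # wild-type 0; floor it for ND instead of aborting the replicate
            kwargs = {"zero_wildtype": "floor"} if method == "ND" else {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = confidence_matrix(data, method, **kwargs)
            variants: list[tuple[float | None, EdgeRanking]] = [
                (None, EdgeRanking.from_confidence(w))
            ]
            for t in thresholds or []:
                variants.append((t, EdgeRanking.from_confidence(downrank(w, t))))
            for t, ranking in variants:
                lab = np.array([(i, j) in edges for i, j in ranking.pairs])
                res = evaluate_scores(ranking.scores, lab)
                cell = cells.setdefault(
                    (method, t), {"auc_roc": [], "auc_pvsr": []}
                )
                cell["auc_roc"].append(res.auc_roc)
                cell["auc_pvsr"].append(res.auc_pvsr)

    rows = []
    for (method, t), vals in cells.items():
        roc = np.array(vals["auc_roc"])
        pr = np.array(vals["auc_pvsr"])
        rows.append(
            {
                "method": method,
                "threshold": float("nan") if t is None else t,
                "auc_roc_mean": roc.mean(),
                "auc_roc_sem": roc.std(ddof=1) / np.sqrt(len(roc)) if len(roc) > 1 else 0.0,
                "auc_pvsr_mean": pr.mean(),
                "auc_pvsr_sem": pr.std(ddof=1) / np.sqrt(len(pr)) if len(pr) > 1 else 0.0,
                "n_networks": len(roc),
            }
        )
    return pd.DataFrame(rows)
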