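"""Small built-in example datasets and a fixture writer.

``DEMO_WILDTYPE`` / ``DEMO_KNOCKOUT`` is a 5-gene knockout compendium in
which knocking out G2 visibly moves G1 (0.14 -> 0.68) while most other
responses sit at noise level — handy for working through every
confidence matrix by hand.

The graph examples are the two canonical down-ranking cases: a
feed-forward loop (A -> B -> C plus the shortcut A -> C, whose influence
the indirect path explains) and a graph with a 2-gene cycle, whose
within-cycle edges must never be demoted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .datasets import (
    ConfidenceMatrix,
    ExpressionDataset,
    GeneNetwork,
    default_gene_names,
    write_expression_files,
    write_gold_standard,
)
from .simulate import SimulationConfig, generate_er_network, simulate_knockout_compendium

__all__ = [
    "DEMO_WILDTYPE",
    "DEMO_KNOCKOUT",
    "demo_dataset",
    "ffl_network",
    "ffl_confidence",
    "scc_network",
    "scc_confidence",
    "make_fixtures",
]

# 5-gene demo compendium: row i = steady state after deleting gene i
DEMO_WILDTYPE = (0.14, 0.89, 0.01, 0.87, 0.14)
DEMO_KNOCKOUT = (
    (0.00, 0.96, 0.00, 0.86, 0.06),
    (0.68, 0.00, 0.04, 0.90, 0.05),
    (0.17, 0.86, 0.00, 0.88, 0.02),
    (0.13, 0.86, 0.08, 0.00, 0.09),
    (0.12, 0.78, 0.09, 0.91, 0.00),
)


def demo_dataset() -> ExpressionDataset:
    """The bundled 5-gene knockout compendium."""
    return ExpressionDataset(
        gene_names=default_gene_names(5),
        wildtype=np.array(DEMO_WILDTYPE),
        knockout=np.array(DEMO_KNOCKOUT),
    )


def ffl_network() -> GeneNetwork:
    """Feed-forward loop: G1 -> G2 -> G3 with shortcut G1 -> G3."""
    return GeneNetwork.from_edges(3, [(0, 1), (1, 2), (0, 2)])


def ffl_confidence() -> ConfidenceMatrix:
    """Hand-set confidences for the feed-forward loop; the shortcut edge
    scores between the two chain edges, so only down-ranking moves it."""
    scores = np.zeros((3, 3))
    scores[0, 1] = 5.0
    scores[1, 2] = 4.0
    scores[0, 2] = 4.5
    return ConfidenceMatrix(scores=scores, method_tag="D")


def scc_network() -> GeneNetwork:
    """A 2-gene cycle G1 <-> G2 feeding a chain G2 -> G3 -> G4, plus the
    shortcut G2 -> G4 that down-ranking demotes.  The cycle edges sit in
    one strongly connected component and are exempt."""
    return GeneNetwork.from_edges(
        4, [(0, 1), (1, 0), (1, 2), (2, 3), (1, 3)]
    )


def scc_confidence() -> ConfidenceMatrix:
    scores = np.zeros((4, 4))
    for (i, j), v in {
        (0, 1): 6.0,
        (1, 0): 5.5,
        (1, 2): 5.0,
        (2, 3): 4.0,
        (1, 3): 4.5,
    }.items():
        scores[i, j] = v
    return ConfidenceMatrix(scores=scores, method_tag="D")


def _write_confidence(w: ConfidenceMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(w.gene_names) + "\n")
        for row in w.scores:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def make_fixtures(out_dir: str | Path, seed: int = 0) -> None:
    """Write the bundled examples plus one small simulated compendium.

    Produces the 5-gene demo expression files, gold standards and hand-set
    confidence matrices for the feed-forward-loop and cycle examples, and
    a simulated 10-gene, mean-degree-2 compendium with its gold standard
    for integration tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    demo = demo_dataset()
    write_expression_files(
        demo, out / "demo5_wildtype.tsv", out / "demo5_knockouts.tsv"
    )

    write_gold_standard(ffl_network(), out / "ffl_gold.tsv")
    _write_confidence(ffl_confidence(), out / "ffl_confidence.tsv")
    write_gold_standard(scc_network(), out / "scc_gold.tsv")
    _write_confidence(scc_confidence(), out / "scc_confidence.tsv")

    cfg = SimulationConfig(n_genes=10, avg_degree=2.0, seed=seed)
    rng = np.random.default_rng(seed)
    net = generate_er_network(cfg.n_genes, cfg.avg_degree, rng)
    while net.n_edges == 0:
        net = generate_er_network(cfg.n_genes, cfg.avg_degree, rng)
    data = simulate_knockout_compendium(net, cfg, rng=rng)
    write_expression_files(
        data, out / "sim10_wildtype.tsv", out / "sim10_knockouts.tsv"
    )
    write_gold_standard(net, out / "sim10_gold.tsv")
    with open(out / "sim10_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
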