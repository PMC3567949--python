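"""Seeded tree generators and the two simulation studies.

Random topologies use sequential uniform random-edge insertion: starting
from a single leaf, each next leaf is grafted onto an edge drawn uniformly
(the root edge included).  Over n leaves this produces every rooted binary
labelled topology with equal probability, since a tree with k leaves has
2k-1 insertion points and (2n-3)!! labelled topologies exist.  Gene-tree
leaf labels are drawn uniformly with replacement from the genome set.

Two studies mirror the package's evaluation protocol:

* **optimality** — measure how far the correction heuristic is from the
  exhaustive optimum on the hard instances (an AD vertex above a NAD
  vertex, where exactness is not guaranteed).
* **detection** — plant errors by inserting random leaves into trees that
  are MD-consistent by construction, and measure what fraction of the
  planted leaves the correction recovers (N / NbAdded, with NbAdded =
  size/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correct import correct_tree, exact_min_removals, satisfies_constraint_c
from .errors import ResourceError, TreeDomainError
from .reconcile import is_md_consistent
from .treeio import Tree

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "random_species_tree",
    "random_gene_tree",
    "random_md_tree",
    "perturb_with_leaves",
    "run_optimality_experiment",
    "run_detection_experiment",
]


def _random_topology(payloads: Sequence[str], rng: np.random.Generator) -> Tree:
    t = Tree.leaf(payloads[0])
    for lbl in payloads[1:]:
        nodes = t.nodes()
        at = nodes[rng.integers(len(nodes))]
        t, _ = t.graft_leaf(at, lbl)
    return t


def random_species_tree(G: Sequence[str], seed: int) -> Tree:
    """Uniform random rooted binary species tree on the genome set G."""
    labels = sorted(set(G))
    if len(labels) < 2:
        raise TreeDomainError("a species tree needs at least two species")
    return _random_topology(labels, np.random.default_rng(seed))


def random_gene_tree(size: int, G: Sequence[str], seed: int) -> Tree:
    """Uniform random topology with labels drawn uniformly (with replacement)."""
    if size < 2:
        raise TreeDomainError("a random gene tree needs at least two leaves")
    rng = np.random.default_rng(seed)
    pool = sorted(set(G))
    labels = [pool[rng.integers(len(pool))] for _ in range(size)]
    return _random_topology(labels, rng)


def random_md_tree(S: Tree, size: int, seed: int) -> Tree:
    """A random tree MD-consistent with S, grown by random leaf duplications.

    Starts from S itself and repeatedly replaces a uniform leaf by a cherry
    of two copies of its label; each step adds one apparent duplication, so
    the output is MD-consistent with S by construction.
    """
    if size < S.size:
        raise TreeDomainError(f"size {size} smaller than the species tree ({S.size})")
    rng = np.random.default_rng(seed)
    t = S
    for _ in range(size - S.size):
        leaves = t.leaves()
        t = t.duplicate_leaf(leaves[rng.integers(len(leaves))])
    return t


def perturb_with_leaves(T: Tree, k: int, G: Sequence[str], seed: int) -> Tree:
    """Insert k leaves at uniform edges (root edge included), uniform labels."""
    if k < 1:
        raise TreeDomainError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pool = sorted(set(G))
    t = T
    for _ in range(k):
        nodes = t.nodes()
        at = nodes[rng.integers(len(nodes))]
        t, _ = t.graft_leaf(at, pool[rng.integers(len(pool))])
    return t


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    mode: str  # "optimality" | "detection"
    genome_size: int
    tree_sizes: list[int]
    trees_per_size: int
    seed: int
    oracle_cap: int = 2_000_000

    def genomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.genome_size)]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    rows: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    def to_csv(self) -> str:
        header = sorted({k for r in self.rows for k in r})
        lines = ["# " + ", ".join(f"{k}={v}" for k, v in sorted(self.aggregates.items()))]
        lines.append(",".join(header))
        for r in self.rows:
            lines.append(",".join(str(r.get(k, "")) for k in header))
        return "\n".join(lines) + "\n"


def _has_ad_above_nad(T: Tree, S: Tree) -> bool:
    return not satisfies_constraint_c(T, S) and not is_md_consistent(T, S)


def run_optimality_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Heuristic vs exhaustive optimum on AD-above-NAD instances.

    Per size: generate ``trees_per_size`` (species tree, gene tree) pairs,
    retain those with an AD vertex above a NAD vertex, and compare the
    heuristic removal count N with the exhaustive optimum N_opt.
    Aggregates: overall exact-match percentage, per-size mean error rate
    (N-N_opt)/N and its maximum across sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.genomes()
    result = ExperimentResult(cfg)
    per_size_err: dict[int, list[float]] = {}
    exact = total = skipped = 0
    for size in cfg.tree_sizes:
        for _ in range(cfg.trees_per_size):
            s_seed = int(rng.integers(2**31 - 1))
            t_seed = int(rng.integers(2**31 - 1))
            S = random_species_tree(G, s_seed)
            T = random_gene_tree(size, G, t_seed)
            if not _has_ad_above_nad(T, S):
                continue
            n = correct_tree(T, S).removals
            try:
                n_opt, _ = exact_min_removals(T, S, cap=cfg.oracle_cap)
            except ResourceError:
                skipped += 1
                continue
            err = (n - n_opt) / n if n else 0.0
            per_size_err.setdefault(size, []).append(err)
            total += 1
            exact += n == n_opt
            result.rows.append(
                {"size": size, "N": n, "N_opt": n_opt, "error_rate": round(err, 6)}
            )
    mean_err = {s: float(np.mean(v)) for s, v in per_size_err.items()}
    result.aggregates = {
        "retained": total,
        "skipped": skipped,
        "exact_match_pct": 100.0 * exact / total if total else float("nan"),
        "max_mean_error_rate": max(mean_err.values()) if mean_err else float("nan"),
        "mean_error_rate_by_size": {s: round(v, 4) for s, v in sorted(mean_err.items())},
        "model": "uniform random-edge insertion, uniform labels",
    }
    return result


def run_detection_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Recovery of planted leaves: N / NbAdded with NbAdded = size/10.

    Per size s: random species tree, random MD-consistent tree of size s,
    s/10 random leaf insertions, then correction.  Trials whose perturbed
    tree is still MD-consistent need no removal (detection 0 by
    construction) and are flagged; the headline average excludes them.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.genomes()
    result = ExperimentResult(cfg)
    det_all: list[float] = []
    det_excl: list[float] = []
    for size in cfg.tree_sizes:
        nb_added = max(1, size // 10)
        for _ in range(cfg.trees_per_size):
            s_seed = int(rng.integers(2**31 - 1))
            m_seed = int(rng.integers(2**31 - 1))
            p_seed = int(rng.integers(2**31 - 1))
            S = random_species_tree(G, s_seed)
            T = random_md_tree(S, size, m_seed)
            P = perturb_with_leaves(T, nb_added, G, p_seed)
            still_md = is_md_consistent(P, S)
            n = 0 if still_md else correct_tree(P, S).removals
            detection = 100.0 * n / nb_added
            det_all.append(detection)
            if not still_md:
                det_excl.append(detection)
            result.rows.append(
                {
                    "size": size,
                    "NbAdded": nb_added,
                    "N": n,
                    "md_consistent": still_md,
                    "detection_pct": round(detection, 4),
                }
            )
    result.aggregates = {
        "trials": len(det_all),
        "md_consistent_trials": len(det_all) - len(det_excl),
        "avg_detection_pct_incl": float(np.mean(det_all)) if det_all else float("nan"),
        "avg_detection_pct_excl": float(np.mean(det_excl)) if det_excl else float("nan"),
        "model": "uniform random-edge insertion, uniform labels",
    }
    return result
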