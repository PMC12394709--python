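"""Mk / Mkv log-likelihood for binary morphological characters.

The model is the symmetric 2-state Markov process with stationary
frequencies (1/2, 1/2) and total leaving rate 1 per unit branch length, so

    P(same state | t)   = (1 + exp(-2 t)) / 2
    P(change state | t) = (1 - exp(-2 t)) / 2.

Likelihoods are computed by Felsenstein pruning, vectorised over
characters.  Missing entries contribute a flat partial (1, 1) at the tip.
The Mkv variant corrects for the ascertainment bias of morphological
matrices (constant characters are never scored) by conditioning every
character's likelihood on being variable: dividing by one minus the summed
likelihood of the two constant patterns.  By reversibility the score does
not depend on where the tree is rooted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from cephalon.cladistics.matrix import MISSING, CharacterMatrix
from cephalon.cladistics.tree import Tree

__all__ = ["MkLikelihoodSpec", "mk_loglik", "optimize_branch_lengths"]


@dataclass(frozen=True)
class MkLikelihoodSpec:
    """Settings of the Mk likelihood kernel.

    conditioning: ``"none"`` scores the plain Mk model; ``"variable"``
    applies the Mkv ascertainment correction.
    """

    k_states: int = 2
    conditioning: str = "none"

    def __post_init__(self) -> None:
        if self.k_states != 2:
            raise ValueError("only the binary (2-state) model is implemented")
        if self.conditioning not in ("none", "variable"):
            raise ValueError("conditioning must be 'none' or 'variable'")


def _transition(t: float) -> np.ndarray:
    if t < 0:
        raise ValueError("negative branch length")
    same = 0.5 * (1.0 + np.exp(-2.0 * t))
    diff = 0.5 * (1.0 - np.exp(-2.0 * t))
    return np.array([[same, diff], [diff, same]])


def _site_likelihoods(
    tree: Tree, tips: dict[str, np.ndarray], n_chars: int, root: int | None = None
) -> np.ndarray:
    """Per-character likelihoods by pruning; ``tips`` maps taxon -> (n,2) partials."""
    partials: dict[int, np.ndarray] = {}
    order = tree.postorder(root)
    for u, p in order:
        if u in tree.names:
            part = tips[tree.names[u]]
        else:
            part = np.ones((n_chars, 2))
            for c in tree.adj[u]:
                if c == p:
                    continue
                t = tree.adj[u][c]
                if t is None:
                    raise ValueError("likelihood requires branch lengths everywhere")
                part = part * (partials[c] @ _transition(t).T)
            # a rooted tree's root edge (if any) is folded in by the parent
        partials[u] = part
        top = u
    if top in tree.names:  # degenerate: rooting at a leaf
        raise ValueError("root the pruning at an internal node")
    return 0.5 * partials[top].sum(axis=1)


def _tip_partials(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    tips = {}
    for i, taxon in enumerate(matrix.taxa):
        row = matrix.chars[i]
        part = np.ones((matrix.n_chars, 2))
        part[row == 0] = [1.0, 0.0]
        part[row == 1] = [0.0, 1.0]
        tips[taxon] = part
    return tips


def _constant_pattern_likelihood(tree: Tree, root: int | None = None) -> float:
    """Summed likelihood of the two all-same fully observed patterns."""
    taxa = tree.taxa
    total = 0.0
    for state in (0, 1):
        part = np.zeros((1, 2))
        part[0, state] = 1.0
        tips = {t: part for t in taxa}
        total += float(_site_likelihoods(tree, tips, 1, root)[0])
    return total


def mk_loglik(
    tree: Tree,
    matrix: CharacterMatrix,
    spec: MkLikelihoodSpec = MkLikelihoodSpec(),
    root: int | None = None,
) -> float:
    """Total log-likelihood of the matrix on a fixed tree with branch lengths.

    Character weights act as multiplicities (integer weights arise from
    bootstrap resampling).  Under ``conditioning="variable"`` each
    character's likelihood is divided by ``1 - L(constant)``.
    """
    if sorted(tree.names.values()) != sorted(matrix.taxa):
        raise ValueError("tree leaves must biject with matrix taxa")
    site = _site_likelihoods(tree, _tip_partials(matrix), matrix.n_chars, root)
    if np.any(site <= 0):
        return -np.inf
    ll = np.log(site)
    if spec.conditioning == "variable":
        ll = ll - np.log1p(-_constant_pattern_likelihood(tree, root))
    return float(np.dot(matrix.weights, ll))


def optimize_branch_lengths(
    tree: Tree,
    matrix: CharacterMatrix,
    spec: MkLikelihoodSpec = MkLikelihoodSpec(),
    n_sweeps: int = 3,
    max_length: float = 10.0,
) -> tuple[Tree, float]:
    """Coarse branch-length fit: bounded 1-D line search per branch.

    Sweeps the branches in a fixed order ``n_sweeps`` times, optimising each
    length with a bounded scalar search while the others are held fixed.
    Intended for scoring fixed topologies, not as a tree search.
    """
    out = tree.copy()
    edges = sorted({(min(u, v), max(u, v)) for u in out.adj for v in out.adj[u]})
    for u in out.adj:
        for v in out.adj[u]:
            if out.adj[u][v] is None:
                out.adj[u][v] = 0.1
    for _ in range(n_sweeps):
        for u, v in edges:

            def nll(t: float) -> float:
                out.adj[u][v] = out.adj[v][u] = t
                return -mk_loglik(out, matrix, spec)

            res = minimize_scalar(
                nll, bounds=(1e-8, max_length), method="bounded",
                options={"xatol": 1e-6},
            )
            out.adj[u][v] = out.adj[v][u] = float(res.x)
    return out, mk_loglik(out, matrix, spec)
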