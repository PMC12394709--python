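"""Fitch parsimony with random-addition + TBR heuristic search.

The scorer packs all binary characters of a matrix into two Python integers
per node (one bit per character for "state set contains 0" / "contains 1"),
so a full Fitch pass over a tree costs a handful of bitwise operations per
internal node regardless of character count.  Missing entries (``?``) are
the full state set at the leaf.  Weighted lengths (successive reweighting,
bootstrap multiplicities) group characters by distinct weight and score
each group's bitmask separately.

The heuristic search mirrors the classic protocol: random stepwise-addition
starting trees followed by tree-bisection-reconnection (TBR) hill climbing
with first-improvement acceptance, keeping every distinct topology at the
best length found and closing the set under equal-length TBR moves so tree
islands are reported completely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cephalon.cladistics.matrix import MISSING, CharacterMatrix
from cephalon.cladistics.tree import Tree, strict_consensus

__all__ = [
    "ParsimonyResult",
    "SupportTable",
    "fitch_length",
    "char_bounds",
    "ci_ri",
    "heuristic_search",
    "exhaustive_search",
    "bootstrap",
    "successive_reweight",
]

_WEIGHT_SCALE = 10**6  # fixed-point scale for non-integer character weights


# ---------------------------------------------------------------------------
# encoding and scoring
# ---------------------------------------------------------------------------


def _leaf_codes(matrix: CharacterMatrix) -> tuple[list[int], list[int]]:
    """Per-taxon bitmasks: bit j of s0 set iff char j's state set contains 0."""
    s0, s1 = [], []
    for row in matrix.chars:
        b0 = b1 = 0
        for j, st in enumerate(row):
            if st == 0:
                b0 |= 1 << j
            elif st == 1:
                b1 |= 1 << j
            else:  # missing: full state set
                b0 |= 1 << j
                b1 |= 1 << j
        s0.append(b0)
        s1.append(b1)
    return s0, s1


def _weight_groups(weights: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Group characters by weight into (int_weight, char_bitmask); drop zeros."""
    w = np.asarray(weights, dtype=np.float64)
    if np.allclose(w, np.rint(w)):
        scale = 1
        wi = np.rint(w).astype(np.int64)
    else:
        scale = _WEIGHT_SCALE
        wi = np.rint(w * scale).astype(np.int64)
    groups: dict[int, int] = {}
    for j, iw in enumerate(wi):
        if iw > 0:
            groups[int(iw)] = groups.get(int(iw), 0) | (1 << j)
    return sorted(groups.items()), scale


def _postorder(adj: dict, root: int) -> list[tuple[int, int]]:
    order = []
    stack = [(root, -1)]
    while stack:
        u, p = stack.pop()
        order.append((u, p))
        for w in adj[u]:
            if w != p:
                stack.append((w, u))
    order.reverse()
    return order


def _score_adj(
    adj: dict,
    n_taxa: int,
    leaf0: list[int],
    leaf1: list[int],
    groups: list[tuple[int, int]],
) -> int:
    """Weighted Fitch length (in fixed-point units) of an unrooted tree."""
    root = next(u for u in adj if u >= n_taxa) if len(adj) > 2 else next(iter(adj))
    steps = 0
    v0: dict[int, int] = {}
    v1: dict[int, int] = {}
    for u, p in _postorder(adj, root):
        if u < n_taxa:
            v0[u] = leaf0[u]
            v1[u] = leaf1[u]
            continue
        a0 = a1 = -1  # sentinel: all-ones
        for c in adj[u]:
            if c == p:
                continue
            if a0 == -1:
                a0, a1 = v0[c], v1[c]
                continue
            i0 = a0 & v0[c]
            i1 = a1 & v1[c]
            empty = ~(i0 | i1)
            if empty:
                u0 = a0 | v0[c]
                u1 = a1 | v1[c]
                a0 = i0 | (empty & u0)
                a1 = i1 | (empty & u1)
                for w, m in groups:
                    e = empty & m
                    if e:
                        steps += w * e.bit_count()
            else:
                a0, a1 = i0, i1
        v0[u], v1[u] = a0, a1
    return steps


def _steps_per_char(
    adj: dict, n_taxa: int, n_chars: int, leaf0: list[int], leaf1: list[int]
) -> np.ndarray:
    """Unweighted Fitch step count for each character separately."""
    root = next(u for u in adj if u >= n_taxa) if len(adj) > 2 else next(iter(adj))
    steps = np.zeros(n_chars, dtype=np.int64)
    v0: dict[int, int] = {}
    v1: dict[int, int] = {}
    mask_all = (1 << n_chars) - 1
    for u, p in _postorder(adj, root):
        if u < n_taxa:
            v0[u], v1[u] = leaf0[u], leaf1[u]
            continue
        a0 = a1 = -1
        for c in adj[u]:
            if c == p:
                continue
            if a0 == -1:
                a0, a1 = v0[c], v1[c]
                continue
            i0, i1 = a0 & v0[c], a1 & v1[c]
            empty = ~(i0 | i1) & mask_all
            if empty:
                a0 = i0 | (empty & (a0 | v0[c]))
                a1 = i1 | (empty & (a1 | v1[c]))
                e = empty
                while e:
                    j = (e & -e).bit_length() - 1
                    steps[j] += 1
                    e &= e - 1
            else:
                a0, a1 = i0, i1
        v0[u], v1[u] = a0, a1
    return steps


# ---------------------------------------------------------------------------
# Tree <-> internal adjacency
# ---------------------------------------------------------------------------


def _tree_to_adj(tree: Tree, taxa: list[str]) -> dict:
    if sorted(tree.names.values()) != sorted(taxa):
        raise ValueError("tree leaves must biject with matrix taxa")
    index = {name: i for i, name in enumerate(taxa)}
    n = len(taxa)
    relabel: dict[int, int] = {}
    nxt = n
    for node in tree.adj:
        if node in tree.names:
            relabel[node] = index[tree.names[node]]
        else:
            relabel[node] = nxt
            nxt += 1
    return {relabel[u]: {relabel[v] for v in nbrs} for u, nbrs in tree.adj.items()}


def _adj_to_tree(adj: dict, taxa: list[str]) -> Tree:
    n = len(taxa)
    names = {i: taxa[i] for i in range(n)}
    return Tree({u: {v: None for v in nbrs} for u, nbrs in adj.items()}, names)


def _splits_key(adj: dict, n_taxa: int) -> frozenset[int]:
    """Canonical unrooted-topology key over taxon indices 0..n-1."""
    root = next(u for u in adj if u >= n_taxa)
    full = (1 << n_taxa) - 1
    masks: dict[int, int] = {}
    out = set()
    for u, p in _postorder(adj, root):
        masks[u] = (
            1 << u if u < n_taxa else sum(masks[c] for c in adj[u] if c != p)
        )
        if p != -1:
            m = masks[u]
            if m & 1:
                m = full ^ m
            if 2 <= m.bit_count() <= n_taxa - 2:
                out.add(m)
    return frozenset(out)


# ---------------------------------------------------------------------------
# public scoring API
# ---------------------------------------------------------------------------


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> tuple[float, np.ndarray]:
    """Weighted Fitch length and per-character step counts on ``tree``."""
    adj = _tree_to_adj(tree, matrix.taxa)
    leaf0, leaf1 = _leaf_codes(matrix)
    steps = _steps_per_char(adj, matrix.n_taxa, matrix.n_chars, leaf0, leaf1)
    return float(np.dot(matrix.weights, steps)), steps


def char_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (m_i, g_i): minimum and maximum steps over all trees.

    For a binary character, m_i is 1 if both states are observed (else 0)
    and g_i is the count of the rarer observed state: the worst tree
    interleaves the two states so every rarer-state leaf changes separately.
    """
    minima = np.zeros(matrix.n_chars, dtype=np.int64)
    maxima = np.zeros(matrix.n_chars, dtype=np.int64)
    for j in range(matrix.n_chars):
        col = matrix.chars[:, j]
        c0 = int((col == 0).sum())
        c1 = int((col == 1).sum())
        minima[j] = 1 if (c0 > 0 and c1 > 0) else 0
        maxima[j] = min(c0, c1)
    return minima, maxima


def _rc_per_char(
    steps: np.ndarray, minima: np.ndarray, maxima: np.ndarray
) -> np.ndarray:
    """Rescaled consistency index per character; 1 for uninformative chars."""
    rc = np.ones(len(steps), dtype=np.float64)
    for j in range(len(steps)):
        s, m, g = int(steps[j]), int(minima[j]), int(maxima[j])
        if g > m and s > 0:
            rc[j] = (m / s) * ((g - s) / (g - m))
    return rc


def ci_ri(
    steps: np.ndarray,
    minima: np.ndarray,
    maxima: np.ndarray,
    weights: np.ndarray | None = None,
    informative: np.ndarray | None = None,
) -> dict:
    """Ensemble consistency and retention indices, plus per-character RC.

    Both the all-characters and informative-only conventions are returned,
    since published values can follow either.  ``ci`` is flagged undefined
    (reported as 1.0) when the tree requires no steps at all.
    """
    w = np.ones(len(steps)) if weights is None else np.asarray(weights, float)

    def ensemble(mask: np.ndarray) -> tuple[float, float]:
        S = float(np.dot(w[mask], steps[mask]))
        M = float(np.dot(w[mask], minima[mask]))
        G = float(np.dot(w[mask], maxima[mask]))
        ci = M / S if S > 0 else 1.0
        ri = (G - S) / (G - M) if G > M else 1.0
        return ci, ri

    every = np.ones(len(steps), dtype=bool)
    info = every if informative is None else informative
    ci_all, ri_all = ensemble(every)
    ci_inf, ri_inf = ensemble(info)
    return {
        "ci": ci_all,
        "ri": ri_all,
        "ci_informative": ci_inf,
        "ri_informative": ri_inf,
        "ci_undefined": bool(np.dot(w, steps) == 0),
        "rc": _rc_per_char(steps, minima, maxima),
    }


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


@dataclass
class ParsimonyResult:
    """Optimal length, the MPT set, per-character fit and homoplasy indices."""

    best_length: float
    trees: list[Tree]
    steps: np.ndarray  # per-character steps on trees[0]
    minima: np.ndarray
    maxima: np.ndarray
    ci: float
    ri: float
    ci_informative: float
    ri_informative: float
    rc_best_fit: np.ndarray  # per-character max RC over the MPT set
    rc_mean: np.ndarray = None  # per-character mean RC over the MPT set
    search_log: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


class _Searcher:
    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.n = matrix.n_taxa
        self.leaf0, self.leaf1 = _leaf_codes(matrix)
        self.groups, self.scale = _weight_groups(matrix.weights)

    def score(self, adj: dict) -> int:
        return _score_adj(adj, self.n, self.leaf0, self.leaf1, self.groups)

    # -- stepwise addition -------------------------------------------------

    def stepwise(self, rng: np.random.Generator) -> dict:
        n = self.n
        order = list(rng.permutation(n))
        a, b, c = order[:3]
        hub = n
        adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        nxt = n + 1
        for leaf in order[3:]:
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            rng.shuffle(edges)
            best_sc, best_edge = None, None
            for u, v in edges:
                self._insert(adj, leaf, u, v, nxt)
                sc = self.score(adj)
                self._remove(adj, leaf, u, v, nxt)
                if best_sc is None or sc < best_sc:
                    best_sc, best_edge = sc, (u, v)
            u, v = best_edge
            self._insert(adj, leaf, u, v, nxt)
            nxt += 1
        return adj

    @staticmethod
    def _insert(adj: dict, leaf: int, u: int, v: int, mid: int) -> None:
        adj[u].discard(v)
        adj[v].discard(u)
        adj[mid] = {u, v, leaf}
        adj[u].add(mid)
        adj[v].add(mid)
        adj[leaf] = {mid}

    @staticmethod
    def _remove(adj: dict, leaf: int, u: int, v: int, mid: int) -> None:
        del adj[mid], adj[leaf]
        adj[u].discard(mid)
        adj[v].discard(mid)
        adj[u].add(v)
        adj[v].add(u)

    # -- TBR ---------------------------------------------------------------

    def _tbr_moves(self, adj: dict, rng: np.random.Generator | None):
        """Yield (new_adjacency, score) for every TBR rearrangement."""
        n = self.n
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        if rng is not None:
            rng.shuffle(edges)
        for u, v in edges:
            adj2 = {x: set(nb) for x, nb in adj.items()}
            adj2[u].discard(v)
            adj2[v].discard(u)
            junctions = []
            for w in (u, v):
                if len(adj2[w]) == 2:  # internal node left with degree 2
                    x, y = adj2[w]
                    adj2[x].discard(w)
                    adj2[y].discard(w)
                    adj2[x].add(y)
                    adj2[y].add(x)
                    del adj2[w]
                    junctions.append(w)
                else:
                    junctions.append(None)
            ju, jv = junctions
            if ju is None:  # u survived (it is a leaf on its own side)
                side_u = self._component(adj2, u)
            else:  # u was suppressed; its side holds its non-v neighbors
                side_u = self._component_containing(adj2, adj, u, exclude=v)
            side_v = set(adj2) - side_u
            edges_u = [(x, y) for x in side_u for y in adj2[x] if x < y and y in side_u]
            edges_v = [(x, y) for x in side_v for y in adj2[x] if x < y and y in side_v]
            attach_u = [None] if not edges_u else edges_u
            attach_v = [None] if not edges_v else edges_v
            if rng is not None:
                rng.shuffle(attach_u)
                rng.shuffle(attach_v)
            for ea in attach_u:
                for eb in attach_v:
                    adj3 = {x: set(nb) for x, nb in adj2.items()}
                    pa = self._attach(adj3, ea, u, ju)
                    pb = self._attach(adj3, eb, v, jv)
                    adj3[pa].add(pb)
                    adj3[pb].add(pa)
                    yield adj3

    @staticmethod
    def _attach(adj3: dict, edge, endpoint: int, junction: int | None) -> int:
        """Subdivide ``edge`` with ``junction`` or return the lone leaf."""
        if edge is None:
            return endpoint  # single-leaf component attaches directly
        x, y = edge
        adj3[x].discard(y)
        adj3[y].discard(x)
        adj3[junction] = {x, y}
        adj3[x].add(junction)
        adj3[y].add(junction)
        return junction

    @staticmethod
    def _component(adj2: dict, start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj2[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    def _component_containing(
        self, adj2: dict, adj: dict, removed: int, exclude: int
    ) -> set[int]:
        """Component of adj2 holding the suppressed node's own-side neighbors."""
        for nb in adj[removed]:
            if nb != exclude and nb in adj2:
                return self._component(adj2, nb)
        raise RuntimeError("suppressed node had no surviving neighbor")

    def hillclimb(
        self, adj: dict, rng: np.random.Generator, max_rounds: int = 200
    ) -> tuple[dict, int, int]:
        """First-improvement TBR to a local optimum; returns (tree, score, moves tried)."""
        cur = self.score(adj)
        tried = 0
        for _ in range(max_rounds):
            improved = False
            for cand in self._tbr_moves(adj, rng):
                tried += 1
                sc = self.score(cand)
                if sc < cur:
                    adj, cur = cand, sc
                    improved = True
                    break
            if not improved:
                break
        return adj, cur, tried


def heuristic_search(
    matrix: CharacterMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    max_trees: int = 100,
    closure: bool = True,
) -> ParsimonyResult:
    """Random-addition + TBR parsimony search keeping all optimal topologies.

    Each replicate builds a stepwise-addition starting tree from a random
    taxon order and TBR-swaps it to a local optimum.  All distinct
    topologies at the overall best length are retained and, when
    ``closure`` is set, the set is closed under equal-length TBR moves
    (capped at ``max_trees``) so complete tree islands are reported.
    Deterministic given ``seed``.
    """
    if matrix.n_taxa < 4:
        raise ValueError("search needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    s = _Searcher(matrix)
    best_len: int | None = None
    best: dict[frozenset, dict] = {}
    tried_total = 0
    for _ in range(n_replicates):
        adj = s.stepwise(rng)
        adj, sc, tried = s.hillclimb(adj, rng)
        tried_total += tried
        if best_len is None or sc < best_len:
            best_len = sc
            best = {_splits_key(adj, s.n): adj}
        elif sc == best_len and len(best) < max_trees:
            best.setdefault(_splits_key(adj, s.n), adj)
    truncated = False
    if closure:
        queue = list(best.values())
        while queue:
            adj = queue.pop()
            for cand in s._tbr_moves(adj, None):
                sc = s.score(cand)
                if sc < best_len:  # equal-length plateau led downhill
                    cand, sc, tried = s.hillclimb(cand, rng)
                    tried_total += tried
                    best_len = sc
                    best = {_splits_key(cand, s.n): cand}
                    queue = [cand]
                    break
                if sc == best_len:
                    key = _splits_key(cand, s.n)
                    if key not in best:
                        if len(best) >= max_trees:
                            truncated = True
                            continue
                        best[key] = cand
                        queue.append(cand)
    return _assemble(matrix, s, best_len, list(best.values()), {
        "replicates": n_replicates,
        "seed": seed,
        "rearrangements_tried": tried_total,
        "mpt_set_truncated": truncated,
        "method": "random-addition + TBR",
    })


def exhaustive_search(matrix: CharacterMatrix) -> ParsimonyResult:
    """Exact optimum by enumerating every unrooted binary topology (n <= 9)."""
    n = matrix.n_taxa
    if n > 9:
        raise ValueError("exhaustive search refuses more than 9 taxa")
    if n < 4:
        raise ValueError("search needs >= 4 taxa")
    s = _Searcher(matrix)
    best_len = None
    best: dict[frozenset, dict] = {}
    count = 0

    def rec(adj: dict, nxt: int, k: int) -> None:
        nonlocal best_len, best, count
        if k == n:
            count += 1
            sc = s.score(adj)
            if best_len is None or sc < best_len:
                best_len = sc
                best = {_splits_key(adj, n): {x: set(nb) for x, nb in adj.items()}}
            elif sc == best_len:
                best.setdefault(
                    _splits_key(adj, n), {x: set(nb) for x, nb in adj.items()}
                )
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            _Searcher._insert(adj, k, u, v, nxt)
            rec(adj, nxt + 1, k + 1)
            _Searcher._remove(adj, k, u, v, nxt)

    hub = n
    adj0 = {0: {hub}, 1: {hub}, 2: {hub}, hub: {0, 1, 2}}
    rec(adj0, n + 1, 3)
    return _assemble(
        matrix, s, best_len, list(best.values()), {"method": "exhaustive", "trees_scored": count}
    )


def _assemble(
    matrix: CharacterMatrix,
    s: _Searcher,
    best_len: int,
    adjs: list[dict],
    log: dict,
) -> ParsimonyResult:
    minima, maxima = char_bounds(matrix)
    steps_sets = [
        _steps_per_char(a, matrix.n_taxa, matrix.n_chars, s.leaf0, s.leaf1)
        for a in adjs
    ]
    rc_sets = [_rc_per_char(st, minima, maxima) for st in steps_sets]
    rc_best = np.max(rc_sets, axis=0)
    rc_mean = np.mean(rc_sets, axis=0)
    indices = ci_ri(
        steps_sets[0], minima, maxima, matrix.weights, matrix.informative_mask()
    )
    trees = [_adj_to_tree(a, matrix.taxa) for a in adjs]
    return ParsimonyResult(
        best_length=best_len / s.scale,
        trees=trees,
        steps=steps_sets[0],
        minima=minima,
        maxima=maxima,
        ci=indices["ci"],
        ri=indices["ri"],
        ci_informative=indices["ci_informative"],
        ri_informative=indices["ri_informative"],
        rc_best_fit=rc_best,
        rc_mean=rc_mean,
        search_log=log,
    )


# ---------------------------------------------------------------------------
# bootstrap and successive reweighting
# ---------------------------------------------------------------------------


@dataclass
class SupportTable:
    """Bipartition -> bootstrap percentage over B replicates."""

    taxon_order: list[str]
    frequencies: dict[int, float]  # split bitmask -> percent
    n_replicates: int

    def named(self) -> list[tuple[tuple[str, ...], float]]:
        out = []
        for mask, pct in sorted(self.frequencies.items(), key=lambda kv: -kv[1]):
            group = tuple(
                t for i, t in enumerate(self.taxon_order) if mask >> i & 1
            )
            out.append((group, pct))
        return out


def bootstrap(
    matrix: CharacterMatrix,
    B: int = 1000,
    seed: int = 0,
    n_replicates: int = 2,
    max_trees: int = 16,
) -> SupportTable:
    """Nonparametric character bootstrap with a reduced search per replicate.

    Characters are resampled with replacement (respecting prior weights);
    each pseudo-matrix gets a random-addition + TBR search with
    ``n_replicates`` addition replicates, and the splits of the strict
    consensus of that replicate's optimal trees are tallied.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = matrix.taxa
    tally: dict[int, int] = {}
    for b in range(B):
        pseudo = matrix.resample(rng)
        res = heuristic_search(
            pseudo,
            n_replicates=n_replicates,
            seed=int(rng.integers(2**31)),
            max_trees=max_trees,
            closure=False,
        )
        cons = strict_consensus(res.trees)
        for split in cons.splits(taxa):
            tally[split] = tally.get(split, 0) + 1
    freqs = {m: 100.0 * c / B for m, c in tally.items()}
    return SupportTable(taxa, freqs, B)


def successive_reweight(
    matrix: CharacterMatrix,
    seed: int = 0,
    n_replicates: int = 10,
    max_rounds: int = 10,
    convention: str = "max",
) -> dict:
    """Successive character reweighting by the rescaled consistency index.

    Starting from an equal-weights search, each round sets every weight to
    the character's RC on the current optimal trees (``max`` over MPTs by
    default, ``mean`` optionally) and re-searches, until the weight vector
    stops changing (tolerance 1e-9) or ``max_rounds`` is hit.  Returns the
    weight trajectory, the number of completed rounds at stabilization, the
    final search result, and a convergence flag.
    """
    if convention not in ("max", "mean"):
        raise ValueError("convention must be 'max' or 'mean'")
    rng = np.random.default_rng(seed)
    current = matrix.with_weights(np.ones(matrix.n_chars))
    result = heuristic_search(
        current, n_replicates=n_replicates, seed=int(rng.integers(2**31))
    )
    trajectory = [np.ones(matrix.n_chars)]
    rounds = 0
    converged = False
    while rounds < max_rounds:
        rounds += 1
        new_w = _round_weights(result, convention)
        trajectory.append(new_w)
        if np.max(np.abs(new_w - trajectory[-2])) < 1e-9:
            converged = True
            break
        current = matrix.with_weights(new_w)
        result = heuristic_search(
            current, n_replicates=n_replicates, seed=int(rng.integers(2**31))
        )
    return {
        "weights_trajectory": trajectory,
        "rounds_to_stable": rounds,
        "converged": converged,
        "final_result": result,
    }


def _round_weights(result: ParsimonyResult, convention: str) -> np.ndarray:
    rc = result.rc_best_fit if convention == "max" else result.rc_mean
    return np.round(rc, 6)
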