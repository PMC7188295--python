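"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are connected by edges weighted with mutational steps — the
minimum number of substitutions plus contiguous indel runs separating two
sequences (one indel run counts as one step, since a single mutational
event can insert or delete several bases).  Pairs are connectable only up
to a parsimony limit derived from the sequence length at a given
confidence; edges are added in ascending step order, keeping equal-step
alternatives, so each connected component carries a minimum-step spanning
structure.  No median (inferred intermediate) vectors are added: multi-step
edges carry their step count instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

# combined DP value = score * _K - steps: maximizing it maximizes the
# affine alignment score first and minimizes the step count among
# score-optimal alignments second.  _K must exceed any possible step count.
_K = 1 << 13
_NEG = -(1 << 60)
_MATCH = 1 * _K
_MISMATCH = -2 * _K - 1
_OPEN = -4 * _K - 1   # first gap column of a run: one step
_EXTEND = -1 * _K     # run continuation: no extra step


@lru_cache(maxsize=100_000)
def _steps_dp(a: str, b: str) -> int:
    """Three-state (match / gap-in-b / gap-in-a) global affine DP."""
    n, m = len(a), len(b)
    mrow = [_NEG] * (m + 1)
    xrow = [_NEG] * (m + 1)
    yrow = [_NEG] * (m + 1)
    mrow[0] = 0
    if m:
        yrow[1] = _OPEN
        for j in range(2, m + 1):
            yrow[j] = yrow[j - 1] + _EXTEND
    for i in range(1, n + 1):
        pm, px, py = mrow, xrow, yrow
        mrow = [_NEG] * (m + 1)
        xrow = [_NEG] * (m + 1)
        yrow = [_NEG] * (m + 1)
        xrow[0] = _OPEN if i == 1 else px[0] + _EXTEND
        ca = a[i - 1]
        for j in range(1, m + 1):
            diag = pm[j - 1]
            if px[j - 1] > diag:
                diag = px[j - 1]
            if py[j - 1] > diag:
                diag = py[j - 1]
            mrow[j] = diag + (_MATCH if ca == b[j - 1] else _MISMATCH)
            up = pm[j] + _OPEN
            if px[j] + _EXTEND > up:
                up = px[j] + _EXTEND
            if py[j] + _OPEN > up:
                up = py[j] + _OPEN
            xrow[j] = up
            left = mrow[j - 1] + _OPEN
            if xrow[j - 1] + _OPEN > left:
                left = xrow[j - 1] + _OPEN
            if yrow[j - 1] + _EXTEND > left:
                left = yrow[j - 1] + _EXTEND
            yrow[j] = left
    best = max(mrow[m], xrow[m], yrow[m])
    q, r = divmod(best, _K)
    return 0 if r == 0 else _K - r


def mutational_steps(a: str, b: str) -> int:
    """Substitutions + indel runs separating two sequences.

    Counted on the optimal global alignment under the package's standard
    affine scoring (match +1, mismatch -2, gap open -4, extend -1); among
    score-optimal alignments the one with the fewest steps is used, so the
    count is deterministic.  A contiguous indel run counts as one step,
    since one mutational event can add or remove several bases.
    """
    if a == b:
        return 0
    if len(a) == len(b):
        # for <=3 mismatches the gapless diagonal alignment is uniquely
        # optimal (any gap pair costs more than three mismatches)
        hamming = sum(x != y for x, y in zip(a, b))
        if hamming <= 3:
            return hamming
    if a > b:  # symmetric; canonical order for the cache
        a, b = b, a
    return _steps_dp(a, b)


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that ``steps`` observed differences are parsimonious.

    Multiple-hit model in the spirit of the statistical-parsimony
    estimator: mutations strike the ``seq_length`` sites independently and
    uniformly; the observed differences reflect the true mutations iff no
    site is struck twice, giving P_j = prod_{i=1}^{j-1} (1 - i/m).
    """
    if steps < 1:
        return 1.0
    p = 1.0
    for i in range(1, steps):
        p *= max(0.0, 1.0 - i / seq_length)
    return p


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability still meets ``confidence``."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    limit = 1
    for j in range(2, seq_length + 1):
        if parsimony_probability(j, seq_length) >= confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class ParsimonyNetwork:
    """Frequency-annotated haplotype graph under a connection limit."""

    graph: nx.Graph
    connection_limit: int

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_network(sequences: dict[str, str],
                  frequencies: dict[str, float] | None = None,
                  labels: dict[str, str] | None = None,
                  limit: int | None = None,
                  confidence: float = 0.95) -> ParsimonyNetwork:
    """Build the parsimony network over named haplotype sequences.

    Edges are considered in ascending step order (ties: higher joint node
    frequency first, then lexicographic name pair).  Within one step tier,
    every edge joining nodes that were in different components at the start
    of the tier is kept — so score-tied alternative connections survive as
    reticulations — while edges internal to a component connected at an
    earlier (smaller-step) tier are skipped.  Pairs beyond the connection
    limit are never joined.
    """
    names = sorted(sequences)
    frequencies = frequencies or {}
    labels = labels or {}
    if limit is None:
        mean_len = max(1, round(sum(len(s) for s in sequences.values())
                                / max(1, len(sequences))))
        limit = connection_limit(mean_len, confidence)

    g = nx.Graph()
    for n in names:
        g.add_node(n, frequency=float(frequencies.get(n, 0.0)),
                   label=labels.get(n, ""))

    candidates = []
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            steps = mutational_steps(sequences[u], sequences[v])
            if 0 < steps <= limit:
                joint = frequencies.get(u, 0.0) + frequencies.get(v, 0.0)
                candidates.append((steps, -joint, (u, v)))
    candidates.sort()

    from itertools import groupby

    comp: dict[str, int] = {n: i for i, n in enumerate(names)}
    for steps, tier in groupby(candidates, key=lambda e: e[0]):
        tier = list(tier)
        start_comp = dict(comp)  # components as of the start of this tier
        added = []
        for _, _, (u, v) in tier:
            if start_comp[u] != start_comp[v]:
                g.add_edge(u, v, steps=int(steps))
                added.append((u, v))
        for u, v in added:  # merge components for the next tier
            cu, cv = comp[u], comp[v]
            if cu != cv:
                for n in names:
                    if comp[n] == cv:
                        comp[n] = cu
    return ParsimonyNetwork(g, limit)


def export_network(net: ParsimonyNetwork, path) -> None:
    """Write the network as GraphML (node frequency/label, edge steps)."""
    g = net.graph.copy()
    g.graph["connection_limit"] = net.connection_limit
    nx.write_graphml(g, path)


def import_network(path) -> ParsimonyNetwork:
    g = nx.read_graphml(path)
    limit = int(g.graph.get("connection_limit", 0))
    g = nx.relabel_nodes(g, str)
    for _, _, d in g.edges(data=True):
        d["steps"] = int(d["steps"])
    return ParsimonyNetwork(g, limit)
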