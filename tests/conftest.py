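"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive each quantity by brute force
(all-window scans, exhaustive run enumeration, leftmost-recursion structure
enumeration, networkx shortest paths) so they stay independent of the package
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from bp3scan import IntronRecord

TOY_INTRON_SEQ = "GUAAGUUUUCUAACUUUUUUUAG"  # 23 nt, CUAAC at 10, branch A at 13


@pytest.fixture
def toy_intron() -> IntronRecord:
    return IntronRecord(
        intron_id="toy.1", gene_id="toy", intron_index=1, contig_id="chrT",
        start=1, end=len(TOY_INTRON_SEQ), strand="+", sequence=TOY_INTRON_SEQ,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_scan(sequence: str, pentamers: set[str]) -> list[tuple[str, int]]:
    """All-windows pentamer scan: (motif, 1-based start) in ascending order."""
    out = []
    for start in range(1, len(sequence) - 4 + 1):
        window = sequence[start - 1:start + 4]
        if window in pentamers:
            out.append((window, start))
    return out


def naive_ppt(sequence: str, region_start: int, region_end: int,
              min_length: int = 6, min_u: int = 3) -> list[tuple[int, int, int]]:
    """Exhaustive maximal-run enumeration: (start, end, u_count) tuples.

    Walks every position, grows the longest non-A/non-N run starting there,
    and keeps it only if nothing extends it on either side within the region.
    """
    region = sequence[region_start - 1:region_end]
    runs = []
    for i in range(len(region)):
        if region[i] not in "CGU":
            continue
        if i > 0 and region[i - 1] in "CGU":
            continue  # not maximal on the left
        j = i
        while j + 1 < len(region) and region[j + 1] in "CGU":
            j += 1
        run = region[i:j + 1]
        if len(run) >= min_length and run.count("U") >= min_u:
            runs.append((region_start + i, region_start + j, run.count("U")))
    return runs


def brute_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum pair count by exhaustive recursion over nested structures.

    Leftmost decomposition without memoisation: position i is either unpaired
    or paired with some j > i + min_loop; exponential, fine for length <= 12.
    """
    allowed = {"AU", "UA", "GC", "CG", "GU", "UG"}

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if sequence[i - 1] + sequence[k - 1] in allowed:
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(1, len(sequence))


def bfs_distance_oracle(pair_table: tuple[int, ...], i: int, j: int) -> int:
    """Independent shortest path via networkx over backbone + pair edges."""
    import networkx as nx

    n = len(pair_table) - 1
    graph = nx.Graph()
    graph.add_nodes_from(range(1, n + 1))
    graph.add_edges_from((k, k + 1) for k in range(1, n))
    graph.add_edges_from((k, pair_table[k]) for k in range(1, n + 1)
                         if pair_table[k])
    return nx.shortest_path_length(graph, i, j)
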