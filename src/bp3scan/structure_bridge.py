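"""RNA secondary structure of the BP-3'ss segment and effective distances.

A structured segment between the branchpoint and the 3' splice site can bring
the acceptor physically closer to the branch adenosine than the linear
nucleotide count suggests.  This module represents nested secondary structures
(dot-bracket notation), folds segments with a deterministic base-pair
maximisation (Nussinov) dynamic program as a stand-in for an external
thermodynamic folder, and defines the *effective distance* between two intron
positions as the unit-weight shortest path in the graph whose edges are the
backbone bonds (k, k+1) and the base pairs (k, partner(k)).

An unpaired segment therefore has effective distance equal to the linear
spacing, and every base pair can only shorten paths.  The module also proposes
compensatory (complementary) mutations that restore pairing after a
substitution disrupts a stem, preferring Watson-Crick restorations over G-U
wobbles.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

from .io_annotations import IntronRecord
from .signal_scan import DistanceConvention, SpliceSignalAnnotation, bp_distances

DEFAULT_ALLOWED_PAIRS = frozenset(
    {"AU", "UA", "GC", "CG", "GU", "UG"}
)
WATSON_CRICK = {"A": "U", "U": "A", "G": "C", "C": "G"}


class StructureError(ValueError):
    """Raised for invalid dot-bracket input."""


@dataclass(frozen=True)
class FoldConfig:
    min_loop: int = 3  # minimum unpaired bases closing a hairpin
    allowed_pairs: frozenset[str] = DEFAULT_ALLOWED_PAIRS

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def can_pair(self, x: str, y: str) -> bool:
        return x + y in self.allowed_pairs


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure: sequence, dot-bracket and pair table.

    ``pair_table[i]`` (1-based; index 0 unused) is the partner of position i,
    or 0 when unpaired.  The table is symmetric by construction.
    """

    sequence: str
    dotbracket: str
    pair_table: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple((i, j) for i, j in enumerate(self.pair_table)
                     if j > i > 0)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def parse_dotbracket(sequence: str, dotbracket: str,
                     config: FoldConfig = FoldConfig()) -> SecondaryStructure:
    """Validate a dot-bracket string against a sequence and build the pair table.

    Checks bracket balance, pair chemistry (AU/GC/GU by default) and the
    minimum hairpin-loop length; errors name the offending position.
    """
    if len(sequence) != len(dotbracket):
        raise StructureError(
            f"sequence length {len(sequence)} != structure length {len(dotbracket)}"
        )
    pair_table = [0] * (len(sequence) + 1)
    stack: list[int] = []
    for pos, char in enumerate(dotbracket, start=1):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            open_pos = stack.pop()
            x, y = sequence[open_pos - 1], sequence[pos - 1]
            if not config.can_pair(x, y):
                raise StructureError(
                    f"disallowed pair {x}-{y} at positions ({open_pos}, {pos})"
                )
            if pos - open_pos - 1 < config.min_loop and _is_hairpin(
                    dotbracket, open_pos, pos):
                raise StructureError(
                    f"hairpin loop shorter than {config.min_loop} at "
                    f"positions ({open_pos}, {pos})"
                )
            pair_table[open_pos] = pos
            pair_table[pos] = open_pos
        elif char != ".":
            raise StructureError(f"invalid character {char!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(sequence, dotbracket, tuple(pair_table))


def _is_hairpin(dotbracket: str, open_pos: int, close_pos: int) -> bool:
    return all(c == "." for c in dotbracket[open_pos:close_pos - 1])


def read_vienna(path: str) -> tuple[str, str]:
    """Read a Vienna-style file: sequence line then dot-bracket line.

    A leading FASTA-style header line is tolerated.
    """
    lines = [line.strip() for line in open(path) if line.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError(f"{path}: expected sequence and structure lines")
    sequence = lines[0].upper().replace("T", "U")
    dotbracket = lines[1].split()[0]  # drop trailing energy annotation if any
    return sequence, dotbracket


# ---------------------------------------------------------------------------
# Base-pair maximisation fold
# ---------------------------------------------------------------------------

def nussinov_fold(sequence: str,
                  config: FoldConfig = FoldConfig()) -> SecondaryStructure:
    """Maximum-base-pair nested structure under the loop constraint.

    Deterministic traceback: within an interval, closing the 3' end with the
    pairing whose 5' partner is smallest is preferred over leaving it
    unpaired, so repeated runs yield byte-identical dot-brackets.  'N' never
    pairs.  This is a geometric stand-in for thermodynamic folding: it
    maximises pair count, not stability.
    """
    n = len(sequence)
    min_loop = config.min_loop
    # dp[i][j]: max pairs in 1-based interval [i, j]
    dp = [[0] * (n + 2) for _ in range(n + 2)]
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if config.can_pair(sequence[k - 1], sequence[j - 1]):
                    cand = dp[i][k - 1] + 1 + dp[k + 1][j - 1]
                    if cand > best:
                        best = cand
            dp[i][j] = best

    structure = ["."] * n
    intervals = [(1, n)]
    while intervals:
        i, j = intervals.pop()
        if j - i <= min_loop:
            continue
        target = dp[i][j]
        paired = False
        for k in range(i, j - min_loop):
            if config.can_pair(sequence[k - 1], sequence[j - 1]) and \
                    dp[i][k - 1] + 1 + dp[k + 1][j - 1] == target:
                structure[k - 1] = "("
                structure[j - 1] = ")"
                intervals.append((i, k - 1))
                intervals.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            intervals.append((i, j - 1))
    return parse_dotbracket(sequence, "".join(structure), config)


def effective_distance(structure: SecondaryStructure, i: int, j: int) -> int:
    """Shortest path between positions i and j over backbone + pair edges.

    Backbone bonds (k, k+1) and base pairs (k, partner(k)) each count 1.
    Breadth-first search; the backbone keeps the graph connected.
    """
    n = len(structure)
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"positions ({i}, {j}) outside structure of length {n}")
    if i == j:
        return 0
    table = structure.pair_table
    dist = [-1] * (n + 1)
    dist[i] = 0
    queue = deque([i])
    while queue:
        node = queue.popleft()
        neighbours = []
        if node > 1:
            neighbours.append(node - 1)
        if node < n:
            neighbours.append(node + 1)
        if table[node]:
            neighbours.append(table[node])
        for nb in neighbours:
            if dist[nb] < 0:
                dist[nb] = dist[node] + 1
                if nb == j:
                    return dist[nb]
                queue.append(nb)
    raise AssertionError("backbone graph is connected")  # pragma: no cover


# ---------------------------------------------------------------------------
# Compensatory mutations
# ---------------------------------------------------------------------------

def compensatory_mutations(structure: SecondaryStructure,
                           proposed_substitutions: Mapping[int, str],
                           config: FoldConfig = FoldConfig()) -> dict[int, str]:
    """Partner substitutions restoring pairs broken by the proposals.

    For each substituted position that is paired in ``structure``, the
    partner's Watson-Crick complement of the new base is proposed unless the
    post-substitution pair is already Watson-Crick.  A substitution that
    leaves only a G-U wobble still draws a proposal: wobbles are accepted in
    structures but disfavoured as restorations, so the WC pairing is
    re-established.  Substitutions at unpaired positions yield no proposal,
    and a base without a WC complement (N) cannot be restored.
    """
    proposals: dict[int, str] = {}
    n = len(structure)
    for pos, new_base in proposed_substitutions.items():
        if not 1 <= pos <= n:
            raise ValueError(f"substitution position {pos} outside structure")
        new_base = new_base.upper().replace("T", "U")
        partner = structure.pair_table[pos]
        if partner == 0:
            continue
        partner_base = proposed_substitutions.get(partner,
                                                  structure.sequence[partner - 1])
        partner_base = partner_base.upper().replace("T", "U")
        restoration = WATSON_CRICK.get(new_base)
        if restoration is None or restoration == partner_base:
            continue  # already WC-complementary, or no restoration exists
        proposals[partner] = restoration
    return proposals


def apply_substitutions(sequence: str, substitutions: Mapping[int, str]) -> str:
    """Return ``sequence`` with 1-based point substitutions applied."""
    out = list(sequence)
    for pos, base in substitutions.items():
        out[pos - 1] = base.upper().replace("T", "U")
    return "".join(out)


# ---------------------------------------------------------------------------
# Fold-and-measure on annotated introns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldReport:
    """Linear vs effective BP-3'ss spacing through a fold of one intron."""

    intron_id: str
    segment_start: int  # intron-local position of the branch adenosine
    segment_end: int    # intron length (segment runs to the 3' end)
    linear_d3: int
    effective_d3: int
    n_pairs: int
    dotbracket: str


def fold_and_measure(intron: IntronRecord,
                     annotation: SpliceSignalAnnotation,
                     structure_source: str = "internal-fold",
                     dotbracket: str | None = None,
                     convention: DistanceConvention = DistanceConvention(),
                     config: FoldConfig = FoldConfig()) -> FoldReport:
    """Fold the BP-3'ss segment and measure the effective spacing.

    The segment runs from the branch adenosine to the intron's 3' end.  With
    ``structure_source='internal-fold'`` the max-pairing fold is used; with
    ``'dotbracket-file'`` a caller-supplied dot-bracket for the segment (e.g.
    from an external thermodynamic folder) is parsed instead.  The effective
    spacing is the graph distance from the branch adenosine to the 3'ss
    position implied by the active d3 convention, so an unpaired segment
    reproduces the linear count exactly.
    """
    if not annotation.has_bp:
        raise ValueError(f"{intron.intron_id}: no selected branchpoint to fold from")
    branch_pos = annotation.selected_bp.branch_pos
    _, linear_d3 = bp_distances(intron.sequence, annotation.selected_bp, convention)
    segment = intron.sequence[branch_pos - 1:]
    if structure_source == "internal-fold":
        structure = nussinov_fold(segment, config)
    elif structure_source == "dotbracket-file":
        if dotbracket is None:
            raise ValueError("structure_source='dotbracket-file' needs a dotbracket")
        structure = parse_dotbracket(segment, dotbracket, config)
    else:
        raise ValueError(f"unknown structure source {structure_source!r}")
    # Segment-local node 1 is the branch adenosine; the 3'ss node sits
    # linear_d3 backbone bonds downstream under every convention.
    effective = effective_distance(structure, 1, linear_d3 + 1)
    return FoldReport(
        intron_id=intron.intron_id,
        segment_start=branch_pos,
        segment_end=len(intron.sequence),
        linear_d3=linear_d3,
        effective_d3=effective,
        n_pairs=structure.n_pairs,
        dotbracket=structure.dotbracket,
    )
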