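"""Splicing-signal scanning: branchpoint pentamers, spacings, polypyrimidine tracts.

The branchpoint (BP) catalogue is the set of CURAY-like pentamers observed at
fission-yeast branchpoints; each pentamer carries the branch adenosine at
position 4.  When several catalogue pentamers occur in one intron, the hit
closest to the 3' splice site (the NAG acceptor) is selected, because the
spliceosome uses the 3'-most functional branchpoint.

Distances between the selected branch adenosine and the two splice sites are
the module's central quantities:

* ``d3`` (default): bases strictly between the branch adenosine and the
  terminal AG dinucleotide, ``d3 = L - branch_pos - 2``;
* ``d5`` (default): bases 5' of the branch adenosine,
  ``d5 = branch_pos - 1``.

Alternative counting conventions are exposed because "bases in between" is
ambiguous by a couple of nucleotides across annotation releases.

A polypyrimidine tract (PPT) is a run of at least six consecutive non-adenine
nucleotides containing no fewer than three uridines.  The default mode counts
maximal such runs; a sliding-window mode counts every 6-nt window satisfying
the rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io_annotations import IntronRecord

# Branchpoint pentamer catalogue (printed order; duplicates removed on load).
CATALOGUE_PENTAMERS: tuple[str, ...] = (
    "CCAAC", "CUAAC", "UUAAC", "UCAAC",
    "CCGAC", "CUGAC", "UUGAC", "UCGAC",
    "CCAAU", "CUAAU", "UUAAU", "UCAAU",
    "CCGAU", "CUGAU", "UUGAU", "UCGAU",
    "GUAAC", "CUCAC", "AUAAC", "UUGAC",
    "CUGAU", "CUAAA", "CUUAC", "CUAAG",
)

BRANCH_OFFSET = 3  # branch adenosine is pentamer position 4 (0-based offset 3)
PENTAMER_LENGTH = 5


class DegenerateIntronError(ValueError):
    """Branch adenosine too close to the 3' end for the active d3 convention."""


@dataclass(frozen=True)
class BranchpointCatalogue:
    """De-duplicated, order-preserving set of branchpoint pentamers."""

    pentamers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for raw in self.pentamers:
            pentamer = raw.upper().replace("T", "U")
            if len(pentamer) != PENTAMER_LENGTH:
                raise ValueError(f"pentamer {raw!r} is not 5 nt long")
            if pentamer[BRANCH_OFFSET] != "A":
                raise ValueError(
                    f"pentamer {raw!r} lacks the branch adenosine at position 4"
                )
            seen.setdefault(pentamer, None)
        object.__setattr__(self, "pentamers", tuple(seen))

    def __len__(self) -> int:
        return len(self.pentamers)

    def __contains__(self, pentamer: str) -> bool:
        return pentamer in set(self.pentamers)


def default_catalogue() -> BranchpointCatalogue:
    """The standard fission-yeast branchpoint catalogue (22 unique pentamers)."""
    return BranchpointCatalogue(CATALOGUE_PENTAMERS)


@dataclass(frozen=True)
class BranchpointHit:
    """A catalogue pentamer occurrence; positions are 1-based intron-local."""

    motif: str
    pent_start: int

    @property
    def branch_pos(self) -> int:
        return self.pent_start + BRANCH_OFFSET

    @property
    def pent_end(self) -> int:
        return self.pent_start + PENTAMER_LENGTH - 1


class D3Mode(str, Enum):
    """How d3 counts nucleotides between the branch A and the 3' splice site."""

    BETWEEN_AG = "between-AG"          # bases strictly between branch A and terminal AG
    TO_JUNCTION = "to-junction"        # bases from branch A to the exon junction (L - branch_pos)
    TO_TERMINAL_G = "to-terminal-G"    # bases strictly between branch A and the terminal G


class D5Mode(str, Enum):
    """How d5 counts nucleotides between the 5' splice site and the branch A."""

    FROM_BRANCH_A = "from-branch-A"               # bases 5' of the branch adenosine
    HEXAMER_TO_PENTAMER = "hexamer-to-pentamer"   # bases between 5'ss hexamer and pentamer


@dataclass(frozen=True)
class DistanceConvention:
    d3_mode: D3Mode = D3Mode.BETWEEN_AG
    d5_mode: D5Mode = D5Mode.FROM_BRANCH_A


def bp_distances(intron: IntronRecord | str, hit: BranchpointHit,
                 convention: DistanceConvention = DistanceConvention()) -> tuple[int, int]:
    """Return ``(d5, d3)`` for the selected branchpoint under a convention.

    Raises :class:`DegenerateIntronError` when the branch adenosine sits so
    close to the 3' end that the convention's count would be negative.
    """
    sequence = intron.sequence if isinstance(intron, IntronRecord) else intron
    length = len(sequence)
    branch = hit.branch_pos
    if hit.pent_start < 1 or hit.pent_end > length:
        raise ValueError("branchpoint hit outside the intron")
    if sequence[hit.pent_start - 1:hit.pent_end] != hit.motif:
        raise ValueError("branchpoint hit inconsistent with the intron sequence")

    if convention.d5_mode is D5Mode.FROM_BRANCH_A:
        d5 = branch - 1
    else:
        d5 = max(hit.pent_start - 7, 0)

    if convention.d3_mode is D3Mode.BETWEEN_AG:
        d3 = length - branch - 2
    elif convention.d3_mode is D3Mode.TO_JUNCTION:
        d3 = length - branch
    else:
        d3 = length - branch - 1
    if d3 < 0:
        raise DegenerateIntronError(
            f"branch adenosine at {branch} is within the 3'-terminal bases "
            f"required by d3 mode {convention.d3_mode.value!r} (intron length {length})"
        )
    return d5, d3


def scan_branchpoints(sequence: str,
                      catalogue: BranchpointCatalogue | None = None) -> list[BranchpointHit]:
    """All catalogue pentamer occurrences in ``sequence``, ascending by position.

    Overlapping hits are all reported; 'N' never matches.  Sequences shorter
    than a pentamer yield an empty list.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    members = set(catalogue.pentamers)
    hits: list[BranchpointHit] = []
    for start in range(len(sequence) - PENTAMER_LENGTH + 1):
        window = sequence[start:start + PENTAMER_LENGTH]
        if window in members:
            hits.append(BranchpointHit(motif=window, pent_start=start + 1))
    return hits


def select_branchpoint(hits: Sequence[BranchpointHit]) -> BranchpointHit | None:
    """The hit closest to the 3' splice site (largest position), or None."""
    if not hits:
        return None
    return max(hits, key=lambda hit: hit.pent_start)


@dataclass(frozen=True)
class PolypyrimidineTract:
    """A maximal run (or 6-nt window) of non-A bases with >= 3 uridines."""

    start: int
    end: int
    u_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PPTConfig:
    mode: str = "maximal"        # "maximal" runs or sliding "window" counting
    min_length: int = 6
    min_u: int = 3
    exclude_5ss_hexamer: bool = False  # drop positions 1..6 from the 5'ss-BP region

    def __post_init__(self) -> None:
        if self.mode not in {"maximal", "window"}:
            raise ValueError(f"unknown PPT mode {self.mode!r}")
        if self.min_length < 1 or self.min_u < 0:
            raise ValueError("PPT thresholds must be positive")


def find_ppt(sequence: str, region_start: int, region_end: int,
             config: PPTConfig = PPTConfig()) -> list[PolypyrimidineTract]:
    """Polypyrimidine tracts within ``[region_start, region_end]`` (1-based incl.).

    The region is clipped to the sequence before testing.  In ``maximal`` mode
    tracts are maximal runs of non-A (and non-N) bases of length >=
    ``min_length`` containing >= ``min_u`` uridines; tracts are disjoint.  In
    ``window`` mode every ``min_length``-nt window satisfying the rule is
    returned (overlaps allowed).
    """
    if region_start > region_end:
        raise ValueError(
            f"inverted region [{region_start}, {region_end}]"
        )
    if region_start < 1 or region_end > len(sequence):
        raise ValueError(
            f"region [{region_start}, {region_end}] outside sequence of "
            f"length {len(sequence)}"
        )
    region = sequence[region_start - 1:region_end]
    tracts: list[PolypyrimidineTract] = []
    if config.mode == "window":
        width = config.min_length
        for offset in range(len(region) - width + 1):
            window = region[offset:offset + width]
            if _is_non_a_run(window) and window.count("U") >= config.min_u:
                start = region_start + offset
                tracts.append(PolypyrimidineTract(start, start + width - 1,
                                                  window.count("U")))
        return tracts
    run_start: int | None = None
    for offset, char in enumerate(region + "A"):  # sentinel terminates last run
        if char in "CGU":
            if run_start is None:
                run_start = offset
        elif run_start is not None:
            run = region[run_start:offset]
            if len(run) >= config.min_length and run.count("U") >= config.min_u:
                start = region_start + run_start
                tracts.append(PolypyrimidineTract(start, start + len(run) - 1,
                                                  run.count("U")))
            run_start = None
    return tracts


def _is_non_a_run(window: str) -> bool:
    return all(char in "CGU" for char in window)


@dataclass(frozen=True)
class SpliceSignalAnnotation:
    """Full splicing-signal annotation of one intron.

    ``d5``/``d3`` follow the :class:`DistanceConvention` active at annotation
    time; ``ppt_5bp`` are tracts in the 5'ss-to-branchpoint region and
    ``ppt_bp3`` tracts in the branchpoint-to-3'ss region.  Anomalies are
    recorded as flags, never as errors.
    """

    intron_id: str
    five_ss: str
    three_ss: str
    selected_bp: BranchpointHit | None
    d5: int | None
    d3: int | None
    ppt_5bp: tuple[PolypyrimidineTract, ...]
    ppt_bp3: tuple[PolypyrimidineTract, ...]
    flags: frozenset[str]

    @property
    def has_bp(self) -> bool:
        return self.selected_bp is not None


FLAG_NO_BP = "no-bp-found"
FLAG_NONCANONICAL_5SS = "noncanonical-5ss"
FLAG_NONCANONICAL_3SS = "noncanonical-3ss"


def annotate_intron(intron: IntronRecord,
                    catalogue: BranchpointCatalogue | None = None,
                    convention: DistanceConvention = DistanceConvention(),
                    ppt_config: PPTConfig = PPTConfig()) -> SpliceSignalAnnotation:
    """Annotate one intron: selected branchpoint, spacings, PPTs, flags.

    The branchpoint is the catalogue hit closest to the 3' splice site.  When
    the selected branch adenosine is degenerate under the active d3 convention
    (within the terminal bases the convention excludes), the next hit toward
    the 5' end is tried, and ``no-bp-found`` is flagged if none remains.
    """
    sequence = intron.sequence
    if len(sequence) < 10:
        raise ValueError(f"{intron.intron_id}: intron shorter than 10 nt")
    if catalogue is None:
        catalogue = default_catalogue()

    flags: set[str] = set()
    if not sequence.startswith("GU"):
        flags.add(FLAG_NONCANONICAL_5SS)
    if not sequence.endswith("AG"):
        flags.add(FLAG_NONCANONICAL_3SS)

    hits = scan_branchpoints(sequence, catalogue)
    selected: BranchpointHit | None = None
    d5 = d3 = None
    for hit in sorted(hits, key=lambda h: -h.pent_start):
        try:
            d5, d3 = bp_distances(sequence, hit, convention)
        except DegenerateIntronError:
            continue
        selected = hit
        break
    if selected is None:
        flags.add(FLAG_NO_BP)
        ppt_5bp: tuple[PolypyrimidineTract, ...] = ()
        ppt_bp3: tuple[PolypyrimidineTract, ...] = ()
        d5 = d3 = None
    else:
        five_region_start = 7 if ppt_config.exclude_5ss_hexamer else 1
        five_region_end = selected.pent_start - 1
        if five_region_end >= five_region_start:
            ppt_5bp = tuple(find_ppt(sequence, five_region_start,
                                     five_region_end, ppt_config))
        else:
            ppt_5bp = ()
        if selected.pent_end + 1 <= len(sequence):
            ppt_bp3 = tuple(find_ppt(sequence, selected.pent_end + 1,
                                     len(sequence), ppt_config))
        else:
            ppt_bp3 = ()

    return SpliceSignalAnnotation(
        intron_id=intron.intron_id,
        five_ss=sequence[:6],
        three_ss=sequence[-3:],
        selected_bp=selected,
        d5=d5,
        d3=d3,
        ppt_5bp=ppt_5bp,
        ppt_bp3=ppt_bp3,
        flags=frozenset(flags),
    )


ANNOTATION_COLUMNS = (
    "intron_id", "five_ss", "bp_motif", "pent_start", "branch_pos",
    "d5", "d3", "n_ppt_5bp", "n_ppt_bp3", "three_ss", "flags",
)


def annotation_row(annotation: SpliceSignalAnnotation) -> dict[str, object]:
    """Flatten an annotation into the TSV output schema."""
    bp = annotation.selected_bp
    return {
        "intron_id": annotation.intron_id,
        "five_ss": annotation.five_ss,
        "bp_motif": bp.motif if bp else "",
        "pent_start": bp.pent_start if bp else "",
        "branch_pos": bp.branch_pos if bp else "",
        "d5": annotation.d5 if annotation.d5 is not None else "",
        "d3": annotation.d3 if annotation.d3 is not None else "",
        "n_ppt_5bp": len(annotation.ppt_5bp),
        "n_ppt_bp3": len(annotation.ppt_bp3),
        "three_ss": annotation.three_ss,
        "flags": ",".join(sorted(annotation.flags)),
    }
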