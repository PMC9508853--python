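"""Retention-ratio classification and comparative group statistics.

Introns are called factor-dependent when their log2(mutant/wt) intron-retention
ratio at 30 degrees C reaches a cutoff (default 0.5, about a 1.4-fold retention
increase); the rest are independent, and introns without a measurement are
unclassified.  Group summaries collect the spacing histograms, polypyrimidine
tract averages and position frequency matrices used to compare dependent and
independent introns, plus a two-sample Kolmogorov-Smirnov comparison of the
spacing distributions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_annotations import IntronRecord, RetentionMeasure
from .signal_scan import SpliceSignalAnnotation

BASES = ("A", "C", "G", "U")

LABEL_DEPENDENT = "dependent"
LABEL_INDEPENDENT = "independent"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierConfig:
    """Cutoff rule for dependency calls (log2 units at 30 degrees C)."""

    cutoff: float = 0.5
    temperature_key: str = "30C"
    inclusive: bool = True  # dependent iff ratio >= cutoff (> when False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass(frozen=True)
class DependencyLabel:
    intron_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in {LABEL_DEPENDENT, LABEL_INDEPENDENT, LABEL_UNCLASSIFIED}:
            raise ValueError(f"unknown label {self.label!r}")


def classify_dependency(measures: Sequence[RetentionMeasure],
                        config: ClassifierConfig = ClassifierConfig()
                        ) -> list[DependencyLabel]:
    """Call each intron dependent/independent/unclassified; order preserved."""
    labels: list[DependencyLabel] = []
    for measure in measures:
        ratio = measure.log2_ratio_30c
        if ratio is None:
            label = LABEL_UNCLASSIFIED
        elif (ratio >= config.cutoff) if config.inclusive else (ratio > config.cutoff):
            label = LABEL_DEPENDENT
        else:
            label = LABEL_INDEPENDENT
        labels.append(DependencyLabel(measure.intron_id, label))
    return labels


@dataclass(frozen=True)
class GroupSummary:
    """Per-group spacing histograms and polypyrimidine-tract averages.

    Histograms run over the group's introns that carry a selected branchpoint;
    ``n_no_bp`` counts the members without one (reported, never silently
    dropped).  ``d3_mode``/``d5_mode`` are the histogram peaks (smallest value
    on ties).
    """

    group: str
    n: int
    n_no_bp: int
    mean_ppt_5bp: float
    mean_ppt_bp3: float
    d3_histogram: Mapping[int, int]
    d5_histogram: Mapping[int, int]
    d3_mode: int | None
    d5_mode: int | None


def _histogram_mode(histogram: Mapping[int, int]) -> int | None:
    if not histogram:
        return None
    return min(histogram, key=lambda value: (-histogram[value], value))


def summarize_group(annotations: Sequence[SpliceSignalAnnotation],
                    labels: Sequence[DependencyLabel],
                    group: str,
                    include_no_bp_in_means: bool = False) -> GroupSummary:
    """Summarise one dependency group.

    Tract means are taken over the group's branchpoint-bearing introns by
    default; ``include_no_bp_in_means`` adds branchpoint-less introns as zero
    tracts instead of excluding them.
    """
    member_ids = {lab.intron_id for lab in labels if lab.label == group}
    members = [ann for ann in annotations if ann.intron_id in member_ids]
    if not members:
        raise ValueError(f"group {group!r} is empty")
    with_bp = [ann for ann in members if ann.has_bp]
    d3_hist = Counter(ann.d3 for ann in with_bp)
    d5_hist = Counter(ann.d5 for ann in with_bp)
    pool = members if include_no_bp_in_means else with_bp
    if pool:
        mean_5bp = float(np.mean([len(ann.ppt_5bp) for ann in pool]))
        mean_bp3 = float(np.mean([len(ann.ppt_bp3) for ann in pool]))
    else:
        mean_5bp = mean_bp3 = float("nan")
    return GroupSummary(
        group=group,
        n=len(members),
        n_no_bp=len(members) - len(with_bp),
        mean_ppt_5bp=mean_5bp,
        mean_ppt_bp3=mean_bp3,
        d3_histogram=dict(sorted(d3_hist.items())),
        d5_histogram=dict(sorted(d5_hist.items())),
        d3_mode=_histogram_mode(d3_hist),
        d5_mode=_histogram_mode(d5_hist),
    )


def count_spacing_tail(annotations: Sequence[SpliceSignalAnnotation],
                       threshold_nt: int) -> int:
    """Number of introns whose BP-3'ss spacing is >= ``threshold_nt``."""
    if threshold_nt < 0:
        raise ValueError("threshold must be non-negative")
    return sum(1 for ann in annotations
               if ann.d3 is not None and ann.d3 >= threshold_nt)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base frequencies at offsets around a splicing-signal anchor.

    ``anchor`` is one of ``5ss`` (offset 0 = first intron base), ``BP``
    (offset 0 = branch adenosine) or ``3ss`` (offset 0 = last intron base).
    ``freq`` is 4 x n_offsets over (A, C, G, U); ``counts`` gives the number
    of introns contributing to each column.  Columns with no data carry NaN
    frequencies and appear in ``empty_offsets``; populated columns sum to 1.
    """

    anchor: str
    offsets: tuple[int, ...]
    freq: np.ndarray
    counts: tuple[int, ...]

    @property
    def empty_offsets(self) -> tuple[int, ...]:
        return tuple(off for off, n in zip(self.offsets, self.counts) if n == 0)


DEFAULT_LOGO_WINDOWS: dict[str, tuple[int, int]] = {
    # 5'ss: two exonic positions (flagged empty on intron-only input) plus the
    # donor region through +6, covering the A enrichment at +3/+4.
    "5ss": (-2, 6),
    # BP: the pentamer (branch A at 0 spans -3..+1) plus 2 nt on each side.
    "BP": (-5, 3),
    # 3ss: the acceptor NAG and the four preceding bases.
    "3ss": (-6, 0),
}


def _anchor_position(anchor: str, annotation: SpliceSignalAnnotation,
                     length: int) -> int | None:
    if anchor == "5ss":
        return 1
    if anchor == "3ss":
        return length
    if anchor == "BP":
        return annotation.selected_bp.branch_pos if annotation.has_bp else None
    raise ValueError(f"unknown anchor {anchor!r}")


def build_pfm(annotations: Sequence[SpliceSignalAnnotation],
              sequences: Mapping[str, str],
              anchor: str,
              offsets: Sequence[int] | None = None) -> PositionFrequencyMatrix:
    """Position frequency matrix around an anchor over the given introns.

    Each column is normalised over the introns for which the offset resolves
    to a position inside the intron; the per-column n is retained so sparse
    columns can be judged (and empty ones flagged rather than emitted as
    zeros).  Raises if no offset resolves for any intron.
    """
    if offsets is None:
        lo, hi = DEFAULT_LOGO_WINDOWS[anchor]
        offsets = range(lo, hi + 1)
    offsets = tuple(offsets)
    counts = np.zeros((4, len(offsets)), dtype=float)
    base_index = {base: i for i, base in enumerate(BASES)}
    for annotation in annotations:
        sequence = sequences.get(annotation.intron_id)
        if sequence is None:
            continue
        pos0 = _anchor_position(anchor, annotation, len(sequence))
        if pos0 is None:
            continue
        for col, offset in enumerate(offsets):
            pos = pos0 + offset
            if 1 <= pos <= len(sequence):
                base = sequence[pos - 1]
                if base in base_index:
                    counts[base_index[base], col] += 1
    col_n = counts.sum(axis=0)
    if not col_n.any():
        raise ValueError(f"no intron resolves any offset for anchor {anchor!r}")
    with np.errstate(invalid="ignore"):
        freq = counts / col_n
    return PositionFrequencyMatrix(
        anchor=anchor,
        offsets=offsets,
        freq=freq,
        counts=tuple(int(n) for n in col_n),
    )


def compare_distributions(group_a: Sequence[float],
                          group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of spacing distributions.

    Returns ``(D, p)`` with D in [0, 1] and the asymptotic p-value.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    result = stats.ks_2samp(np.asarray(group_a, dtype=float),
                            np.asarray(group_b, dtype=float),
                            method="asymp")
    return float(result.statistic), float(result.pvalue)
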