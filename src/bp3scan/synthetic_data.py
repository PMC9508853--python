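"""Synthetic intron datasets with planted splicing signals and ground truth.

Each simulated intron is assembled as

    GUAAGU + 5' spacer + BP pentamer + 3' spacer + UAG

so the donor hexamer, branchpoint and acceptor are known by construction.
Spacer lengths are drawn so that the branchpoint-to-3'ss spacing (d3, default
convention: bases strictly between the branch adenosine and the terminal AG)
and the 5' spacing hit group-specific truncated-normal targets.  Rejection
sampling removes any accidental catalogue pentamer 3' of the planted one, so
the closest-to-3'ss selection rule recovers the planted branchpoint exactly;
decoy suppression can be disabled to stress that rule deliberately.

The two dependency groups emulate the structure of a splicing-sensitive
microarray experiment: factor-dependent introns carry long BP-3'ss spacings
and high log2 retention ratios, independent introns short spacings and ratios
around zero, with Gaussian overlap across the 0.5 log2 classification cutoff.
Defaults: d3 dependent ~ N(25, 8), independent ~ N(12, 4), both truncated to
[4, 60] nt (bracketing the 12-nt genome-wide average spacing and the ~21-nt
threshold above which splicing needs the regulators); ratios N(1.0, 0.3) vs
N(0.0, 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .io_annotations import (
    GenomeSequence,
    IntronRecord,
    RetentionMeasure,
    reverse_complement,
    write_fasta,
    write_gff3_introns,
    write_retention_table,
)
from .signal_scan import (
    BranchpointCatalogue,
    default_catalogue,
    scan_branchpoints,
)

DONOR_HEXAMER = "GUAAGU"
ACCEPTOR = "UAG"
PPT_MOTIF = "UUCUUU"

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal over integers (draws are rounded to the nearest nt)."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.minimum >= self.maximum:
            raise ValueError("minimum must be < maximum")

    def sample(self, rng: np.random.Generator) -> int:
        for _ in range(_MAX_REJECTIONS):
            value = rng.normal(self.mean, self.sd)
            if self.minimum <= value <= self.maximum:
                return int(round(value))
        raise RuntimeError("truncated-normal rejection sampling failed")

    def cdf(self, x: float) -> float:
        """CDF of the continuous truncated normal (before rounding)."""
        a = (self.minimum - self.mean) / self.sd
        b = (self.maximum - self.mean) / self.sd
        return float(stats.truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd))

    def rounded_cdf(self, k: float) -> float:
        """P(round(X) <= k): the correct reference for integer draws."""
        return self.cdf(np.floor(k) + 0.5)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic dataset.

    The d3 targets are interpreted under the default distance convention
    (bases strictly between branch A and the terminal AG), so the minimum of
    4 nt leaves room for the construction's two fixed bases.
    """

    n_dependent: int = 100
    n_independent: int = 100
    d3_dependent_dist: TruncNormal = TruncNormal(25.0, 8.0, 4.0, 60.0)
    d3_independent_dist: TruncNormal = TruncNormal(12.0, 4.0, 4.0, 60.0)
    d5_dist: TruncNormal = TruncNormal(30.0, 10.0, 10.0, 80.0)
    bp_motif_weights: Mapping[str, float] = field(default_factory=lambda: {
        "CUAAC": 0.70, "UUAAC": 0.08, "CUGAC": 0.07,
        "UCAAC": 0.05, "CCAAC": 0.05, "CUAAU": 0.05,
    })
    ratio_dependent_mean: float = 1.0
    ratio_dependent_sd: float = 0.3
    ratio_independent_mean: float = 0.0
    ratio_independent_sd: float = 0.2
    spacer_base_weights: Mapping[str, float] = field(default_factory=lambda: {
        "A": 0.35, "U": 0.35, "C": 0.15, "G": 0.15,
    })
    ppt_insertion_prob: float = 0.5
    reject_decoys: bool = True
    exon_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dependent < 0 or self.n_independent < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.ppt_insertion_prob <= 1.0:
            raise ValueError("ppt_insertion_prob must lie in [0, 1]")
        for name in ("bp_motif_weights", "spacer_base_weights"):
            weights = getattr(self, name)
            total = float(sum(weights.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one simulated intron."""

    intron_id: str
    group: str
    planted_branch_pos: int
    planted_d3: int
    planted_ratio: float
    planted_ppt_positions: tuple[int, ...]


def _draw_spacer(rng: np.random.Generator, length: int,
                 weights: Mapping[str, float]) -> str:
    if length <= 0:
        return ""
    bases = list(weights)
    probs = np.array([weights[b] for b in bases], dtype=float)
    return "".join(rng.choice(bases, size=length, p=probs))


def _draw_motif(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    motifs = list(weights)
    probs = np.array([weights[m] for m in motifs], dtype=float)
    return str(rng.choice(motifs, p=probs))


def sample_intron(params: SimulationParams,
                  rng: np.random.Generator,
                  group: str = "dependent",
                  intron_id: str = "sim_intron",
                  catalogue: BranchpointCatalogue | None = None
                  ) -> tuple[IntronRecord, SyntheticTruth]:
    """Sample one intron sequence with a recoverable planted branchpoint.

    The returned :class:`IntronRecord` carries standalone plus-strand
    coordinates on a virtual contig; :func:`simulate_dataset` re-embeds the
    same sequences into genomic context.  Rejection sampling (up to 1000
    attempts) discards sequences where a catalogue pentamer lands 3' of the
    planted one, unless ``reject_decoys`` is off.  The spacing targets d5 and
    d3 are drawn once, before the rejection loop, and only the spacer content
    is resampled: decoy suppression therefore never distorts the planted
    spacing distributions.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    d3_dist = (params.d3_dependent_dist if group == "dependent"
               else params.d3_independent_dist)
    d5 = params.d5_dist.sample(rng)
    d3 = d3_dist.sample(rng)
    motif = _draw_motif(rng, params.bp_motif_weights)
    for _ in range(_MAX_REJECTIONS):
        # d5 = len(hexamer) + spacer5 + 3 pentamer bases before the branch A
        spacer5 = _draw_spacer(rng, d5 - len(DONOR_HEXAMER) - 3,
                               params.spacer_base_weights)
        # d3 = trailing pentamer base + spacer3 + the U of the terminal UAG
        spacer3 = _draw_spacer(rng, d3 - 2, params.spacer_base_weights)
        ppt_positions: list[int] = []
        spacer5, spacer3, ppt_positions = _insert_ppts(
            rng, params, spacer5, spacer3, d5_prefix=len(DONOR_HEXAMER))
        sequence = DONOR_HEXAMER + spacer5 + motif + spacer3 + ACCEPTOR
        branch_pos = len(DONOR_HEXAMER) + len(spacer5) + 4
        if params.reject_decoys:
            hits = scan_branchpoints(sequence, catalogue)
            planted_start = branch_pos - 3
            if not hits or hits[-1].pent_start != planted_start:
                continue
        record = IntronRecord(
            intron_id=intron_id, gene_id=intron_id, intron_index=1,
            contig_id="synthetic", start=1, end=len(sequence), strand="+",
            sequence=sequence,
        )
        truth = SyntheticTruth(
            intron_id=intron_id, group=group,
            planted_branch_pos=branch_pos, planted_d3=d3,
            planted_ratio=float("nan"),
            planted_ppt_positions=tuple(ppt_positions),
        )
        return record, truth
    raise RuntimeError(
        f"{intron_id}: could not place a decoy-free intron in "
        f"{_MAX_REJECTIONS} attempts (pathological parameters?)"
    )


def _insert_ppts(rng: np.random.Generator, params: SimulationParams,
                 spacer5: str, spacer3: str,
                 d5_prefix: int) -> tuple[str, str, list[int]]:
    """Overwrite a window of each spacer with the PPT motif (length-preserving)."""
    positions: list[int] = []
    motif = PPT_MOTIF
    if len(spacer5) >= len(motif) and rng.random() < params.ppt_insertion_prob:
        offset = int(rng.integers(0, len(spacer5) - len(motif) + 1))
        spacer5 = spacer5[:offset] + motif + spacer5[offset + len(motif):]
        positions.append(d5_prefix + offset + 1)
    if len(spacer3) >= len(motif) and rng.random() < params.ppt_insertion_prob:
        offset = int(rng.integers(0, len(spacer3) - len(motif) + 1))
        spacer3 = spacer3[:offset] + motif + spacer3[offset + len(motif):]
        # intron-local position filled in by caller knowledge is not needed
        # for truth checks; record spacer3-local offset relative to 3' spacer.
        positions.append(-(offset + 1))
    return spacer5, spacer3, positions


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory simulated dataset plus its ground truth."""

    genome: dict[str, GenomeSequence]
    introns: list[IntronRecord]
    measures: list[RetentionMeasure]
    truths: list[SyntheticTruth]


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Simulate a full dataset: genome, embedded introns, ratios, truth.

    Introns are concatenated into one synthetic contig separated by fixed
    GC-balanced exon spacers; alternating introns are placed on the minus
    strand (their genomic slice is the reverse complement of the transcript
    sequence) so strand handling is exercised end to end.
    """
    rng = np.random.default_rng(params.seed)
    exon_weights = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    plan = ([("dependent", i) for i in range(params.n_dependent)]
            + [("independent", i) for i in range(params.n_independent)])

    chunks: list[str] = []
    cursor = 0
    introns: list[IntronRecord] = []
    measures: list[RetentionMeasure] = []
    truths: list[SyntheticTruth] = []
    for ordinal, (group, index) in enumerate(plan):
        intron_id = f"{group[:3]}_{index + 1:04d}.1"
        gene_id = f"gene_{ordinal + 1:04d}"
        record, truth = sample_intron(params, rng, group, intron_id)
        strand = "+" if ordinal % 2 == 0 else "-"
        exon = _draw_spacer(rng, params.exon_length, exon_weights)
        chunks.append(exon)
        cursor += len(exon)
        start = cursor + 1
        end = cursor + len(record.sequence)
        genomic = (record.sequence if strand == "+"
                   else reverse_complement(record.sequence))
        chunks.append(genomic)
        cursor = end
        introns.append(IntronRecord(
            intron_id=intron_id, gene_id=gene_id, intron_index=1,
            contig_id="sim_contig_1", start=start, end=end, strand=strand,
            sequence=record.sequence,
        ))
        if group == "dependent":
            ratio = rng.normal(params.ratio_dependent_mean,
                               params.ratio_dependent_sd)
        else:
            ratio = rng.normal(params.ratio_independent_mean,
                               params.ratio_independent_sd)
        measures.append(RetentionMeasure(intron_id, float(ratio)))
        truths.append(replace(truth, planted_ratio=float(ratio)))
    chunks.append(_draw_spacer(rng, params.exon_length, exon_weights))
    contig = GenomeSequence("sim_contig_1", "".join(chunks))
    return SyntheticDataset(
        genome={contig.contig_id: contig},
        introns=introns,
        measures=measures,
        truths=truths,
    )


def sample_dataset(params: SimulationParams,
                   out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write genome FASTA, intron GFF3, retention TSV, truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(params)
    paths = {
        "genome": out_dir / "genome.fa",
        "introns": out_dir / "introns.gff3",
        "retention": out_dir / "retention.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_gff3_introns(dataset.introns, paths["introns"], source="bp3scan_sim")
    write_retention_table(dataset.measures, paths["retention"])
    with open(paths["truth"], "w") as handle:
        handle.write("intron_id\tgroup\tbranch_pos\td3\tratio\n")
        for truth in dataset.truths:
            handle.write(
                f"{truth.intron_id}\t{truth.group}\t{truth.planted_branch_pos}"
                f"\t{truth.planted_d3}\t{truth.planted_ratio!r}\n"
            )
    return paths


def analytic_recall(mean: float, sd: float, cutoff: float) -> float:
    """Expected dependent-call fraction for Gaussian ratios: Phi((mu - c)/sd)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(stats.norm.cdf((mean - cutoff) / sd))
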