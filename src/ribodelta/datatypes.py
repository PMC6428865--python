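"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open and transcript-oriented: position 0 of
a per-nucleotide profile is the first transcribed nucleotide of the 5'UTR,
and the first nucleotide of the start codon sits at offset ``utr5_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ASSAYS = ("mRNA", "RPF")
CONDITIONS = ("t0", "t30")

#: The seven behavioral classes. "activated" means the gene depends on the
#: exonuclease for its translation, so its translational efficiency drops
#: upon knock-down (delta_te < 0); "repressed" is the opposite. The mRNA
#: suffix records what happened to transcript abundance: buffered (within
#: the +/-0.433 log2 band), decreased, or increased.
CLASS_LABELS = (
    "activated_buffered",
    "activated_decreased",
    "activated_increased",
    "repressed_buffered",
    "repressed_decreased",
    "repressed_increased",
    "not_regulated",
)

SRP_CLASSES = ("dependent", "independent", "unknown")


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: which assay, condition, and replicate."""

    sample_id: str
    assay: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r} for sample {self.sample_id}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r} for sample {self.sample_id}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


class CountTable:
    """Gene x sample matrix of raw counts with sample metadata.

    Rows are genes, columns are samples in the order of ``samples``. Entries
    must be non-negative integers; validation happens at construction.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ) -> None:
        gene_ids = list(gene_ids)
        samples = list(samples)
        counts = np.asarray(counts)
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        triples = [(s.assay, s.condition, s.replicate) for s in samples]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (assay, condition, replicate) triples in samples")
        if counts.shape != (len(gene_ids), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count {counts[g, s]} at gene {gene_ids[g]!r}, "
                f"sample {samples[s].sample_id!r}"
            )
        self.gene_ids = gene_ids
        self.samples = samples
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountTable({len(self.gene_ids)} genes x {len(self.samples)} samples)"


@dataclass
class GeneAnnotation:
    """Region lengths (nt) of one transcript plus functional labels."""

    gene_id: str
    utr5_length: int
    cds_length: int
    utr3_length: int
    is_membrane: bool = False
    srp_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.utr5_length < 0 or self.utr3_length < 0:
            raise ValueError(f"{self.gene_id}: UTR lengths must be >= 0")
        if self.cds_length < 3 or self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: cds_length must be a positive multiple of 3, "
                f"got {self.cds_length}"
            )
        if self.srp_class not in SRP_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown srp_class {self.srp_class!r}")

    @property
    def total_length(self) -> int:
        return self.utr5_length + self.cds_length + self.utr3_length

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3


@dataclass
class PARSProfile:
    """Per-nucleotide structure scores over utr5+cds+utr3; NaN marks missing."""

    gene_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"{self.gene_id}: scores must be a non-empty 1-D vector")


@dataclass
class CodonCoverage:
    """Ribosome footprint counts per codon for one gene in one library."""

    gene_id: str
    sample_id: str
    counts_per_codon: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts_per_codon)
        if arr.ndim != 1:
            raise ValueError("counts_per_codon must be 1-D")
        if arr.size and (np.any(arr < 0) or np.any(np.mod(arr, 1) != 0)):
            raise ValueError(f"{self.gene_id}/{self.sample_id}: counts must be non-negative integers")
        self.counts_per_codon = arr.astype(np.int64)


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_class: str
    true_log2fc_mrna: float
    true_log2fc_te: float
    base_mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.true_class not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be > 0")
        if self.true_class == "not_regulated":
            if self.true_log2fc_te != 0:
                raise ValueError("not_regulated genes must have true_log2fc_te == 0")
        else:
            if self.true_log2fc_te == 0:
                raise ValueError("regulated genes must have true_log2fc_te != 0")
            if self.true_class.startswith("activated") and self.true_log2fc_te >= 0:
                raise ValueError("activated classes require true_log2fc_te < 0")
            if self.true_class.startswith("repressed") and self.true_log2fc_te <= 0:
                raise ValueError("repressed classes require true_log2fc_te > 0")


@dataclass
class TEResult:
    """Per-gene outcome of the translational-efficiency interaction test.

    ``delta_te`` is the interaction effect on the log2 scale: the RPF fold
    change not explained by the mRNA fold change.
    """

    gene_id: str
    log2fc_mrna: float
    log2fc_rpf: float
    delta_te: float
    wald_z: float
    p: float
    fdr: float
    class_label: str = "not_regulated"


@dataclass
class GlmFit:
    """Negative-binomial GLM fit summary (natural-log scale coefficients)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    dispersion_used: float


@dataclass
class RateRecord:
    """Transcription/decay bookkeeping for one gene in one condition.

    SR = nTR / cell_volume and HL = RA / SR, all in arbitrary units.
    """

    gene_id: str
    condition: str
    nTR: float
    cell_volume: float
    SR: float
    RA: float
    HL: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")


@dataclass
class MetageneProfile:
    """Averaged positional signal for a gene group in one condition."""

    axis: str  # "codon_bins" or "nt_relative_to_TIS"
    positions: np.ndarray
    values: np.ndarray
    n_genes: np.ndarray
    group_label: str
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        self.n_genes = np.asarray(self.n_genes, dtype=int)
        if not (len(self.positions) == len(self.values) == len(self.n_genes)):
            raise ValueError("positions, values, n_genes must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
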