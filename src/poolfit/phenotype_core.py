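"""Normalization, control averaging, per-mutant phenotype ratios, phenotype
binning, and the gene dropout tally.

A *screen* compares pooled mutant abundances after growth under a treatment
against a control. The *phenotype* of a mutant is the ratio

    Phi = treatment_normalized_reads / control_normalized_reads,

defined only where the (averaged) control has a raw read count above a floor
(default 50) so that the denominator is reliably measured. Phi < 1 means a
growth defect under the treatment, Phi > 1 enrichment. Phenotypes are
discretized into bins at powers of two around neutrality for the exact-test
framework: [0, 0.0625), [0.0625, 0.125), [0.125, 0.25), [0.25, 0.5),
[0.5, 2), [2, 4), [4, 8), [8, 16), plus an overflow bin for Phi >= 16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolfit.screen_io import CountTable, InsertionAnnotation

NORMALIZATION_TOTAL = 1e8
MIN_CONTROL_RAW = 50
DISRUPTIVE_FEATURES = frozenset({"5UTR", "CDS", "intron"})


@dataclass(frozen=True)
class BinScheme:
    """Phenotype bin boundaries (left-closed, right-open).

    The default 8 bins span Phi in [0, 16); ``overflow`` adds a 9th bin for
    Phi >= 16 so extreme enrichment is kept rather than silently dropped.
    With ``overflow=False`` such alleles raise instead (strict reading).
    """

    boundaries: tuple[float, ...] = (0.0625, 0.125, 0.25, 0.5, 2.0, 4.0, 8.0, 16.0)
    overflow: bool = True

    def __post_init__(self):
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + (1 if self.overflow else 0)


@dataclass
class Screen:
    """One treatment-vs-control comparison; both samples share a round."""

    screen_id: str
    treatment: CountTable
    control: CountTable
    round_id: str = ""


@dataclass
class ScreenPhenotypes:
    """Per-barcode phenotypes Phi for one screen. Barcodes whose control raw
    count fails the floor are absent from ``phi`` (undefined phenotype)."""

    screen_id: str
    phi: dict[str, float] = field(default_factory=dict)
    control_raw: dict[str, int] = field(default_factory=dict)
    treatment_raw: dict[str, int] = field(default_factory=dict)


def normalize(table: CountTable, target_total: float = NORMALIZATION_TOTAL) -> CountTable:
    """Scale raw counts so they sum to ``target_total`` (default 1e8).

    Returns a new CountTable; raw counts are untouched.
    """
    total = table.total_raw
    if total <= 0:
        raise ValueError(f"cannot normalize {table.sample_id}: total raw count is 0")
    factor = target_total / total
    return CountTable(
        sample_id=table.sample_id,
        counts=dict(table.counts),
        normalized={b: c * factor for b, c in table.counts.items()},
    )


def average_controls(
    controls: list[CountTable],
    sample_id: str | None = None,
    rounds: list[str] | None = None,
) -> CountTable:
    """Average replicate controls from the same screening round.

    Normalized reads are averaged per barcode (a barcode absent from a
    replicate contributes 0 to its mean); raw counts are summed, so the
    control-read floor applied downstream sees the pooled depth. When the
    replicates' round ids are supplied they must all match.
    """
    if not controls:
        raise ValueError("need at least one control")
    if rounds is not None and len(set(rounds)) > 1:
        raise ValueError(f"cannot average controls across rounds {sorted(set(rounds))}")
    for c in controls:
        if c.normalized is None:
            raise ValueError(f"control {c.sample_id} is not normalized")
    k = len(controls)
    raw: dict[str, int] = {}
    norm: dict[str, float] = {}
    for c in controls:
        for b, v in c.counts.items():
            raw[b] = raw.get(b, 0) + v
        for b, v in c.normalized.items():
            norm[b] = norm.get(b, 0.0) + v
    norm = {b: v / k for b, v in norm.items()}
    sid = sample_id or (controls[0].sample_id + "_average" if k > 1 else controls[0].sample_id)
    return CountTable(sample_id=sid, counts=raw, normalized=norm)


def compute_phenotypes(screen: Screen, min_control_raw: int = MIN_CONTROL_RAW) -> ScreenPhenotypes:
    """Compute Phi for every barcode whose control raw count exceeds the floor.

    A barcode observed in the control but absent from the treatment gets
    Phi = 0 — absence after growth is the informative dropout signal, not
    missing data.
    """
    if screen.control.normalized is None or screen.treatment.normalized is None:
        raise ValueError("both count tables must be normalized first")
    out = ScreenPhenotypes(screen_id=screen.screen_id)
    tnorm = screen.treatment.normalized
    for b, craw in screen.control.counts.items():
        out.control_raw[b] = craw
        out.treatment_raw[b] = screen.treatment.counts.get(b, 0)
        if craw > min_control_raw:
            out.phi[b] = tnorm.get(b, 0.0) / screen.control.normalized[b]
    return out


def bin_phenotype(phi: float, scheme: BinScheme | None = None) -> int:
    """Map a phenotype ratio to its bin index (0-based, left-closed bins)."""
    scheme = scheme or BinScheme()
    if phi < 0 or math.isnan(phi):
        raise ValueError(f"phenotype must be >= 0, got {phi}")
    for i, b in enumerate(scheme.boundaries):
        if phi < b:
            return i
    if scheme.overflow:
        return len(scheme.boundaries)
    raise ValueError(f"phenotype {phi} >= {scheme.boundaries[-1]} with no overflow bin")


def log2_matrix(
    phenos: list[ScreenPhenotypes], clip: float = 7.0
) -> pd.DataFrame:
    """Barcode x screen matrix of log2(Phi), for visualization and clustering.

    Phi is clipped into [2**-clip, 2**clip] before the log so dropouts
    (Phi = 0) map to a finite floor below the smallest bin boundary.
    Undefined phenotypes become NaN.
    """
    barcodes = sorted({b for p in phenos for b in p.phi})
    mat = pd.DataFrame(
        np.nan, index=barcodes, columns=[p.screen_id for p in phenos], dtype=float
    )
    lo, hi = 2.0 ** -clip, 2.0 ** clip
    for p in phenos:
        col = p.screen_id
        for b, phi in p.phi.items():
            mat.at[b, col] = math.log2(min(max(phi, lo), hi))
    return mat


def tally_dropout_genes(
    phenos: list[ScreenPhenotypes],
    annotations: list[InsertionAnnotation],
    features: frozenset[str] = DISRUPTIVE_FEATURES,
    min_control_raw: int = MIN_CONTROL_RAW,
) -> set[str]:
    """Genes with >=1 disruptive-feature insertion that dropped out of >=1
    screen: control raw reads above the floor but zero treatment reads
    (abundance below the detection limit)."""
    eligible = {
        a.barcode: a.gene_id
        for a in annotations
        if a.gene_id and a.feature in features
    }
    genes: set[str] = set()
    for p in phenos:
        for b, gene in eligible.items():
            if gene in genes:
                continue
            if (
                p.control_raw.get(b, 0) > min_control_raw
                and p.treatment_raw.get(b, 0) == 0
                and b in p.phi
            ):
                genes.add(gene)
    return genes
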