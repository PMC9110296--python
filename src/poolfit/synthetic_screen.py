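"""Ground-truth synthetic pooled screens.

The generator emulates the structure of a genome-scale barcoded mutant
library grown competitively: each gene carries a small number of independent
insertion alleles; each allele is tagged by a unique barcode; insertion
features and mapping confidences follow the library-wide frequencies
(intron 25%, 3'UTR 23%, CDS 19%, not mapped 14%, intergenic 6%, 5'UTR 5%,
multiple/other 8%); clonal abundances in the starting pool are log-normal.

Competitive growth is deterministic exponential in expectation: a clone with
relative fitness effect s under a condition multiplies its abundance by
2^(d(1+s)) over d doublings of the neutral pool, so s = 0 is neutral and
s = -1 freezes the clone at its inoculum abundance — after the paper-scale
seven doublings such a clone's expected phenotype is 2^-7, below the lowest
phenotype bin boundary. Sequencing is multinomial sampling of R reads from
the final abundance distribution (optionally Dirichlet-overdispersed), done
independently for each control replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poolfit.screen_io import CountTable, InsertionAnnotation

FEATURE_PROBS = {
    "intron": 0.25,
    "3UTR": 0.23,
    "CDS": 0.19,
    "not_mapped": 0.14,
    "intergenic": 0.06,
    "5UTR": 0.05,
    "multiple_other": 0.08,
}

# mapping confidence 1 (best) .. 6; most insertions map confidently
CONFIDENCE_PROBS = {1: 0.40, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.10, 6: 0.05}

# experimental design constants of the emulated screens
INOCULATION_DENSITY = 2e4  # cells/ml
CULTURE_VOLUME_ML = 2000.0  # standard 2-liter vessel
N_MUTANTS = 58_101
FINAL_DENSITY = 2e6  # cells/ml at harvest
INSERTIONS_PER_MUTANT = 1.2


def design_constants(
    inoculation_density: float = INOCULATION_DENSITY,
    volume_ml: float = CULTURE_VOLUME_ML,
    n_mutants: int = N_MUTANTS,
    final_density: float = FINAL_DENSITY,
) -> dict[str, float]:
    """Derived quantities of the competitive-growth design: total inoculated
    cells, cells per mutant at inoculation, and the number of pool doublings
    between inoculation and harvest."""
    total = inoculation_density * volume_ml
    return {
        "total_cells": total,
        "cells_per_mutant": total / n_mutants,
        "doublings": float(np.log2(final_density / inoculation_density)),
    }


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-screen parameters; defaults are the emulated study's scale
    where it states one (see module docstring)."""

    n_genes: int = 200
    alleles_per_gene_mean: float = 3.0  # 1 + Poisson(mean - 1), so min 1
    insertions_per_mutant_mean: float = INSERTIONS_PER_MUTANT
    feature_probs: dict[str, float] = field(default_factory=lambda: dict(FEATURE_PROBS))
    confidence_probs: dict[int, float] = field(default_factory=lambda: dict(CONFIDENCE_PROBS))
    abundance_sigma: float = 1.0  # log-normal spread of clonal inoculum sizes
    doublings: float = 7.0
    depth: int = 10_000_000  # reads per sample
    n_control_replicates: int = 2
    barcode_length: int = 22
    dispersion: float | None = None  # Dirichlet overdispersion; None = pure multinomial
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.feature_probs.values()) - 1.0) > 1e-9:
            raise ValueError("feature_probs must sum to 1")
        if abs(sum(self.confidence_probs.values()) - 1.0) > 1e-9:
            raise ValueError("confidence_probs must sum to 1")
        if self.doublings <= 0 or self.depth <= 0:
            raise ValueError("doublings and depth must be positive")


@dataclass
class SimTruth:
    """Ground-truth fitness effects: (gene_id, condition) -> s. Genes absent
    from the map are neutral (s = 0); alleles inherit their gene's s."""

    s: dict[tuple[str, str], float] = field(default_factory=dict)

    def effect(self, gene_id: str | None, condition: str) -> float:
        if gene_id is None:
            return 0.0
        return self.s.get((gene_id, condition), 0.0)

    def hit_genes(self, condition: str) -> set[str]:
        return {g for (g, c), v in self.s.items() if c == condition and v != 0.0}


@dataclass
class SimLibrary:
    """A simulated mutant pool: insertion annotations, true clonal inoculum
    abundances per barcode, and the sequenced initial sample."""

    annotations: list[InsertionAnnotation]
    abundance: dict[str, float]
    initial: CountTable

    def gene_ids(self) -> list[str]:
        return sorted({a.gene_id for a in self.annotations if a.gene_id})


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        b = "".join(bases[rng.integers(0, 4, size=length)])
        if b not in seen:
            seen.add(b)
            out.append(b)
    return out


def simulate_library(config: SimConfig, rng: np.random.Generator | None = None) -> SimLibrary:
    """Draw a mutant library: genes, alleles, features, confidences, barcodes
    and log-normal inoculum abundances, plus a multinomial initial sample."""
    rng = rng or np.random.default_rng(config.seed)
    n_alleles_per_gene = 1 + rng.poisson(max(config.alleles_per_gene_mean - 1, 0), size=config.n_genes)
    total_alleles = int(n_alleles_per_gene.sum())
    barcodes = _random_barcodes(total_alleles, config.barcode_length, rng)

    features = list(config.feature_probs)
    fprobs = np.array([config.feature_probs[f] for f in features])
    confs = sorted(config.confidence_probs)
    cprobs = np.array([config.confidence_probs[c] for c in confs])

    annotations: list[InsertionAnnotation] = []
    i = 0
    for g in range(config.n_genes):
        gene_id = f"Cre{g % 17 + 1:02d}.g{100100 + g * 100:06d}"
        for _ in range(n_alleles_per_gene[g]):
            feature = features[rng.choice(len(features), p=fprobs)]
            conf = confs[rng.choice(len(confs), p=cprobs)]
            genic = feature not in ("intergenic", "not_mapped")
            annotations.append(
                InsertionAnnotation(
                    barcode=barcodes[i],
                    side="5prime",
                    mutant_id=f"M{i:06d}",
                    plate=f"P{i // 384 + 1:03d}",
                    well=f"W{i % 384 + 1:03d}",
                    gene_id=gene_id if genic else None,
                    feature=feature,
                    confidence=int(conf),
                )
            )
            i += 1

    abundance = {
        b: float(a)
        for b, a in zip(barcodes, rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=total_alleles))
    }
    initial = _sequence_sample("initial", abundance, config, rng)
    return SimLibrary(annotations=annotations, abundance=abundance, initial=initial)


def _sequence_sample(
    sample_id: str,
    abundance: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> CountTable:
    barcodes = list(abundance)
    weights = np.array([abundance[b] for b in barcodes], dtype=float)
    if config.dispersion:
        weights = weights * rng.gamma(1.0 / config.dispersion, config.dispersion, size=len(weights))
    p = weights / weights.sum()
    counts = rng.multinomial(config.depth, p)
    return CountTable(
        sample_id=sample_id,
        counts={b: int(c) for b, c in zip(barcodes, counts) if c > 0},
    )


def grown_abundance(
    library: SimLibrary, truth: SimTruth, condition: str, doublings: float
) -> dict[str, float]:
    """Expected clonal abundance after competitive growth: a0 * 2^(d(1+s))."""
    gene_of = {a.barcode: a.gene_id for a in library.annotations}
    out = {}
    for b, a0 in library.abundance.items():
        s = truth.effect(gene_of.get(b), condition)
        if s < -1:
            raise ValueError(f"fitness effect s={s} < -1 for barcode {b}")
        out[b] = a0 * 2.0 ** (doublings * (1.0 + s))
    return out


def simulate_screen(
    library: SimLibrary,
    truth: SimTruth,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[CountTable], CountTable]:
    """Sequence one treatment sample and ``n_control_replicates`` control
    replicates after competitive growth; returns (controls, treatment)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    control_ab = grown_abundance(library, SimTruth(), condition, config.doublings)
    treat_ab = grown_abundance(library, truth, condition, config.doublings)
    controls = [
        _sequence_sample(f"{condition}_control_{r + 1}", control_ab, config, rng)
        for r in range(config.n_control_replicates)
    ]
    treatment = _sequence_sample(f"{condition}_treatment", treat_ab, config, rng)
    return controls, treatment


def choose_hit_genes(
    library: SimLibrary,
    n_hits: int,
    rng: np.random.Generator,
    min_passing_alleles: int = 3,
    max_confidence: int = 4,
    features: frozenset[str] = frozenset({"5UTR", "CDS", "intron"}),
) -> list[str]:
    """Pick hit genes among those with enough statistically admissible
    alleles (disruptive feature, confidence within bound) to be testable."""
    counts: dict[str, int] = {}
    for a in library.annotations:
        if a.gene_id and a.feature in features and a.confidence <= max_confidence:
            counts[a.gene_id] = counts.get(a.gene_id, 0) + 1
    eligible = sorted(g for g, c in counts.items() if c >= min_passing_alleles)
    if len(eligible) < n_hits:
        raise ValueError(f"only {len(eligible)} genes have >= {min_passing_alleles} admissible alleles")
    return sorted(rng.choice(eligible, size=n_hits, replace=False).tolist())


def make_truth(hit_genes, condition: str, s: float = -1.0) -> SimTruth:
    return SimTruth({(g, condition): s for g in hit_genes})


def export_truth(truth: SimTruth, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": g, "condition": c, "s": v} for (g, c), v in sorted(truth.s.items())],
        columns=["gene_id", "condition", "s"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str, "s": float})
    return SimTruth({(r.gene_id, r.condition): float(r.s) for r in df.itertuples(index=False)})


# ---------------------------------------------------------------------------
# synthetic raw reads (for exercising the barcode-extraction front end)


def screened_barcodes(
    n: int, length: int, adapter: str, rng: np.random.Generator, min_mismatch: int = 3
) -> list[str]:
    """Random barcodes screened so no window of barcode+adapter starting
    before the true adapter position comes within ``min_mismatch``
    substitutions of the adapter — planted reads then trim back to exactly
    the planted barcode."""
    out: list[str] = []
    seen: set[str] = set()
    bases = np.array(list("ACGT"))
    while len(out) < n:
        b = "".join(bases[rng.integers(0, 4, size=length)])
        if b in seen:
            continue
        composite = b + adapter
        ok = True
        for i in range(0, length):
            window = composite[i : i + len(adapter)]
            mm = sum(x != y for x, y in zip(window, adapter))
            if mm < min_mismatch:
                ok = False
                break
        if ok:
            seen.add(b)
            out.append(b)
    return out


def write_synthetic_fastq(
    path: str | Path,
    counts: dict[str, int],
    adapter: str,
    rng: np.random.Generator,
    read_length: int = 50,
    adapter_error_prob: float = 0.0,
) -> None:
    """Write planted reads barcode+adapter+random filler, one FASTQ record
    per read; with probability ``adapter_error_prob`` a read's adapter
    carries one random substitution (within the single-error tolerance of
    the default trim spec)."""
    bases = "ACGT"
    reads = []
    for barcode, n in counts.items():
        for _ in range(n):
            ad = adapter
            if adapter_error_prob and rng.random() < adapter_error_prob:
                pos = int(rng.integers(0, len(adapter)))
                sub = bases[(bases.index(adapter[pos]) + 1 + int(rng.integers(0, 3))) % 4]
                ad = adapter[:pos] + sub + adapter[pos + 1 :]
            body = barcode + ad
            filler_len = max(read_length - len(body), 0)
            filler = "".join(bases[int(x)] for x in rng.integers(0, 4, size=filler_len))
            reads.append(body + filler)
    order = rng.permutation(len(reads))
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"@read{i}\n{reads[i]}\n+\n{'I' * len(reads[i])}\n")
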