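"""End-to-end simulation studies: operating characteristics of the
exact-test framework on synthetic screens with known ground truth.

These drive both the test suite and the reproduction script: a null study
(all genes neutral) checks type-I control of the conditional test, and a
hit-recovery study (a handful of genes with complete growth arrest, s = -1)
measures sensitivity and the realized false-discovery proportion at the
FDR < 0.3 working threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from poolfit.allele_stats import gene_screen_results, high_confidence_relationships
from poolfit.phenotype_core import Screen, average_controls, compute_phenotypes, normalize
from poolfit.synthetic_screen import (
    SimConfig,
    SimTruth,
    choose_hit_genes,
    make_truth,
    simulate_library,
    simulate_screen,
)


def run_simulated_screen(
    config: SimConfig,
    n_hits: int = 0,
    s: float = -1.0,
    condition: str = "condA",
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one library + one screen and run the full phenotype and
    gene-statistics pipeline on it. Returns (gene results, ground truth)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    library = simulate_library(config, rng)
    if n_hits > 0:
        truth = make_truth(choose_hit_genes(library, n_hits, rng), condition, s)
    else:
        truth = SimTruth()
    controls, treatment = simulate_screen(library, truth, condition, config, rng)
    control = average_controls([normalize(c) for c in controls])
    screen = Screen(
        screen_id=condition,
        treatment=normalize(treatment),
        control=control,
        round_id="R1",
    )
    phenos = compute_phenotypes(screen)
    results = gene_screen_results(
        [phenos], library.annotations, seed=int(rng.integers(2**31))
    )
    return results, truth


def null_pvalue_fractions(
    config: SimConfig, seeds: list[int], alpha: float = 0.05
) -> list[float]:
    """Fraction of genes with p < alpha in all-neutral screens, one entry
    per seed. Under the (conservative, discrete) exact null these should
    scatter at or below alpha."""
    fractions = []
    for seed in seeds:
        results, _ = run_simulated_screen(config, n_hits=0, seed=seed)
        fractions.append(float((results["p"] < alpha).mean()))
    return fractions


def hit_recovery(
    config: SimConfig,
    seeds: list[int],
    n_hits: int = 10,
    s: float = -1.0,
    fdr_threshold: float = 0.3,
) -> dict[str, float]:
    """Sensitivity and realized false-discovery proportion over seeds.

    Returns recovery (fraction of planted hit genes reported at
    fdr < threshold, pooled over seeds), false_discovery_fraction (fraction
    of reported relationships whose gene is not a planted hit), and the
    discovery count.
    """
    n_recovered = n_planted = n_reported = n_false = 0
    for seed in seeds:
        results, truth = run_simulated_screen(config, n_hits=n_hits, s=s, seed=seed)
        hits = truth.hit_genes("condA")
        reported = set(high_confidence_relationships(results, fdr_threshold)["gene_id"])
        n_planted += len(hits)
        n_recovered += len(hits & reported)
        n_reported += len(reported)
        n_false += len(reported - hits)
    return {
        "recovery": n_recovered / n_planted if n_planted else float("nan"),
        "false_discovery_fraction": n_false / n_reported if n_reported else 0.0,
        "n_reported": float(n_reported),
        "n_planted": float(n_planted),
    }
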