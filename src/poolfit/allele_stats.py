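"""Multi-allele gene-phenotype statistics.

The test at the core of the pipeline asks, for each gene in a screen: do the
binned phenotypes of this gene's insertion alleles look like a random draw
from the binned phenotypes of *all* insertions in the screen? Conditioning on
both margins, the gene's bin-count vector is multivariate hypergeometric over
the column totals, and the two-sided p-value sums the probabilities of every
gene-row table at most as probable as the observed one (the Freeman-Halton
probability-mass ordering, the r x c generalization of Fisher's exact test).
Small gene rows are enumerated exactly; large ones fall back to a seeded
Monte Carlo estimate. Benjamini-Hochberg FDR is then applied to genes with
more than two alleles, the paper-trail threshold for calling a relationship
"high confidence".

Alleles enter the test only if their insertion is disruptive (5'UTR, CDS or
intron), mapped with confidence level <= 4, and measured with > 50 control
reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from poolfit.phenotype_core import BinScheme, ScreenPhenotypes, bin_phenotype
from poolfit.screen_io import InsertionAnnotation

_REL_TOL = 1e-12  # relative slack when comparing table probabilities
_LOG_TOL = math.log1p(_REL_TOL)


@dataclass(frozen=True)
class AlleleFilter:
    """Which insertion alleles are admissible for the statistical framework."""

    max_confidence: int = 4
    allowed_features: frozenset[str] = frozenset({"5UTR", "CDS", "intron"})
    min_control_raw: int = 50

    def passes(self, a: InsertionAnnotation) -> bool:
        return (
            a.gene_id is not None
            and a.confidence <= self.max_confidence
            and a.feature in self.allowed_features
        )


@dataclass
class ContingencyTable2xK:
    """Gene-vs-background binned phenotype counts for one screen.

    ``background_row`` holds the bin counts of all admissible insertions in
    the screen; by the literal background definition it includes the gene's
    own alleles (``exclude_self`` in the builders subtracts them).
    """

    gene_row: np.ndarray
    background_row: np.ndarray

    def __post_init__(self):
        self.gene_row = np.asarray(self.gene_row, dtype=np.int64)
        self.background_row = np.asarray(self.background_row, dtype=np.int64)
        if self.gene_row.shape != self.background_row.shape or self.gene_row.ndim != 1:
            raise ValueError("rows must be 1-D and of equal length")
        if (self.gene_row < 0).any() or (self.background_row < 0).any():
            raise ValueError("negative cell counts")

    @property
    def n(self) -> int:
        return int(self.gene_row.sum())

    @property
    def column_totals(self) -> np.ndarray:
        return self.gene_row + self.background_row


# ---------------------------------------------------------------------------
# exact 2 x k test


def _log_table_prob(x: np.ndarray, c: np.ndarray, log_denom: float) -> float:
    """log P(gene row = x | margins) under the multivariate hypergeometric."""
    return float(
        (gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)).sum() - log_denom
    )


def _enumerate_p(c: np.ndarray, n: int, logp_obs: float) -> float:
    """Sum the null probability of every feasible gene row whose probability
    is <= the observed one (up to relative tolerance), by depth-first
    enumeration of compositions of n bounded by the column totals."""
    k = len(c)
    suffix = np.concatenate([np.cumsum(c[::-1])[::-1], [0]])
    log_denom = float(gammaln(suffix[0] + 1) - gammaln(n + 1) - gammaln(suffix[0] - n + 1))
    logc_terms = gammaln(c + 1)
    threshold = logp_obs + _LOG_TOL
    total = 0.0

    x = np.zeros(k, dtype=np.int64)

    def rec(j: int, remaining: int, logp: float) -> None:
        nonlocal total
        if j == k - 1:
            lp = logp + float(logc_terms[j] - gammaln(remaining + 1) - gammaln(c[j] - remaining + 1))
            if lp - log_denom <= threshold:
                total += math.exp(lp - log_denom)
            return
        lo = max(0, remaining - int(suffix[j + 1]))
        hi = min(remaining, int(c[j]))
        for v in range(lo, hi + 1):
            rec(
                j + 1,
                remaining - v,
                logp + float(logc_terms[j] - gammaln(v + 1) - gammaln(c[j] - v + 1)),
            )

    rec(0, n, 0.0)
    return min(total, 1.0)


def exact_test_2xk(
    table: ContingencyTable2xK,
    mc_threshold: int = 30,
    n_mc: int = 100_000,
    seed: int | np.random.Generator = 0,
    full: bool = False,
):
    """Two-sided exact test of a gene's binned phenotypes against the screen
    background.

    Exact enumeration when the gene row total n <= ``mc_threshold``;
    otherwise a Monte Carlo estimate from ``n_mc`` multivariate
    hypergeometric null draws with the given seed. With ``full=True``
    returns ``(p, method, se)`` where se is the binomial standard error
    (0.0 for enumeration).
    """
    c = table.column_totals
    n = table.n
    if len(c) < 2:
        raise ValueError("need at least 2 phenotype bins")
    if n == 0:
        raise ValueError("gene row is empty")
    N = int(c.sum())
    log_denom = float(gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    logp_obs = _log_table_prob(table.gene_row, c, log_denom)

    if n <= mc_threshold:
        p = _enumerate_p(c, n, logp_obs)
        return (p, "enumeration", 0.0) if full else p

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(c, n, size=n_mc).astype(np.int64)
    logps = (
        gammaln(c + 1) - gammaln(draws + 1) - gammaln(c - draws + 1)
    ).sum(axis=1) - log_denom
    hits = int((logps <= logp_obs + _LOG_TOL).sum())
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return (p, "monte_carlo", se) if full else p


# ---------------------------------------------------------------------------
# BH-FDR


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-screen gene statistics


def _binned_alleles(
    screen: ScreenPhenotypes,
    annotations: list[InsertionAnnotation],
    allele_filter: AlleleFilter,
    scheme: BinScheme,
) -> dict[str, list[tuple[str, float, int]]]:
    """Admissible alleles per gene: (barcode, phi, bin) triplets. The control
    read floor is enforced here (phi may have been computed with a different
    floor upstream)."""
    per_gene: dict[str, list[tuple[str, float, int]]] = {}
    for a in annotations:
        if not allele_filter.passes(a):
            continue
        phi = screen.phi.get(a.barcode)
        if phi is None:
            continue
        if screen.control_raw.get(a.barcode, 0) <= allele_filter.min_control_raw:
            continue
        per_gene.setdefault(a.gene_id, []).append((a.barcode, phi, bin_phenotype(phi, scheme)))
    return per_gene


def build_gene_table(
    gene_id: str,
    screen: ScreenPhenotypes,
    annotations: list[InsertionAnnotation],
    allele_filter: AlleleFilter | None = None,
    scheme: BinScheme | None = None,
    exclude_self: bool = False,
) -> ContingencyTable2xK | None:
    """Contingency table for one gene in one screen, or None if the gene has
    no admissible allele."""
    allele_filter = allele_filter or AlleleFilter()
    scheme = scheme or BinScheme()
    per_gene = _binned_alleles(screen, annotations, allele_filter, scheme)
    if gene_id not in per_gene:
        return None
    k = scheme.n_bins
    background = np.zeros(k, dtype=np.int64)
    for alleles in per_gene.values():
        for _, _, b in alleles:
            background[b] += 1
    gene_row = np.zeros(k, dtype=np.int64)
    for _, _, b in per_gene[gene_id]:
        gene_row[b] += 1
    if exclude_self:
        background = background - gene_row
    return ContingencyTable2xK(gene_row=gene_row, background_row=background)


def median_gene_phenotype(phis) -> float:
    """Median Phi over a gene's tested alleles (mean of the central pair for
    even counts)."""
    phis = list(phis)
    if not phis:
        raise ValueError("no tested alleles")
    return float(np.median(phis))


def gene_screen_results(
    screens: list[ScreenPhenotypes],
    annotations: list[InsertionAnnotation],
    allele_filter: AlleleFilter | None = None,
    scheme: BinScheme | None = None,
    fdr_scope: str = "per_screen",
    exclude_self: bool = False,
    min_alleles_for_fdr: int = 3,
    mc_threshold: int = 30,
    n_mc: int = 100_000,
    seed: int = 0,
    log2_clip: float = 7.0,
) -> pd.DataFrame:
    """Exact-test p, BH-FDR and median phenotype for every gene in every
    screen.

    FDR is computed over genes with at least ``min_alleles_for_fdr`` alleles
    (default: more than two), per screen by default or pooled across screens
    with ``fdr_scope="global"``. Returns a DataFrame with one row per
    (gene, screen) pair; the ``fdr`` column is NaN for genes with too few
    alleles.
    """
    if fdr_scope not in ("per_screen", "global"):
        raise ValueError("fdr_scope must be 'per_screen' or 'global'")
    allele_filter = allele_filter or AlleleFilter()
    scheme = scheme or BinScheme()
    k = scheme.n_bins

    rows = []
    ss = np.random.SeedSequence(seed)
    for screen, child in zip(screens, ss.spawn(max(len(screens), 1))):
        per_gene = _binned_alleles(screen, annotations, allele_filter, scheme)
        if not per_gene:
            continue
        background = np.zeros(k, dtype=np.int64)
        for alleles in per_gene.values():
            for _, _, b in alleles:
                background[b] += 1
        rng = np.random.default_rng(child)
        for gene in sorted(per_gene):
            alleles = per_gene[gene]
            gene_row = np.zeros(k, dtype=np.int64)
            for _, _, b in alleles:
                gene_row[b] += 1
            bg = background - gene_row if exclude_self else background
            p = exact_test_2xk(
                ContingencyTable2xK(gene_row, bg),
                mc_threshold=mc_threshold,
                n_mc=n_mc,
                seed=rng,
            )
            med = median_gene_phenotype([phi for _, phi, _ in alleles])
            lo, hi = 2.0 ** -log2_clip, 2.0 ** log2_clip
            rows.append(
                {
                    "gene_id": gene,
                    "screen_id": screen.screen_id,
                    "n_alleles": len(alleles),
                    "bins": ",".join(str(int(v)) for v in gene_row),
                    "p": p,
                    "fdr": np.nan,
                    "median_phenotype": med,
                    "log2_median": math.log2(min(max(med, lo), hi)),
                }
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "screen_id", "n_alleles", "bins", "p", "fdr",
            "median_phenotype", "log2_median",
        ],
    )
    if df.empty:
        return df
    eligible = df["n_alleles"] >= min_alleles_for_fdr
    if fdr_scope == "global":
        if eligible.any():
            df.loc[eligible, "fdr"] = bh_fdr(df.loc[eligible, "p"].to_numpy())
    else:
        for _, idx in df[eligible].groupby("screen_id").groups.items():
            df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "p"].to_numpy())
    return df


def high_confidence_relationships(results: pd.DataFrame, fdr_threshold: float = 0.3) -> pd.DataFrame:
    """(gene, screen) pairs passing the FDR threshold (default 0.3)."""
    return results[results["fdr"] < fdr_threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# set + GO enrichment


def set_enrichment_2x2(hits: set, annotated: set, universe: set) -> float:
    """One-sided hypergeometric p for over-representation of ``annotated``
    among ``hits`` within ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not annotated <= universe:
        raise ValueError("hits and annotated must be subsets of the universe")
    overlap = len(hits & annotated)
    return float(hypergeom.sf(overlap - 1, len(universe), len(annotated), len(hits)))


def go_enrichment(
    screens: list[ScreenPhenotypes],
    annotations: list[InsertionAnnotation],
    gene2go: dict[str, list[str]],
    allele_filter: AlleleFilter | None = None,
    scheme: BinScheme | None = None,
    mc_threshold: int = 30,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-screen GO-term phenotype enrichment.

    Each term's contingency row pools the binned phenotypes of all admissible
    insertions in genes carrying the term; a multi-annotated gene's alleles
    are counted once per term, and the background row pools all term rows
    (duplicates included). When a term's row is the entire background (the
    degenerate single-term case) there is no contrast and p := 1. BH-FDR is
    applied over all terms within each screen.
    """
    allele_filter = allele_filter or AlleleFilter()
    scheme = scheme or BinScheme()
    k = scheme.n_bins

    rows = []
    ss = np.random.SeedSequence(seed)
    for screen, child in zip(screens, ss.spawn(max(len(screens), 1))):
        per_gene = _binned_alleles(screen, annotations, allele_filter, scheme)
        term_rows: dict[str, np.ndarray] = {}
        for gene, alleles in per_gene.items():
            for term in gene2go.get(gene, []):
                row = term_rows.setdefault(term, np.zeros(k, dtype=np.int64))
                for _, _, b in alleles:
                    row[b] += 1
        if not term_rows:
            continue
        background = np.zeros(k, dtype=np.int64)
        for row in term_rows.values():
            background += row
        rng = np.random.default_rng(child)
        screen_rows = []
        for term in sorted(term_rows):
            row = term_rows[term]
            if (row == background).all():
                p = 1.0
            else:
                p = exact_test_2xk(
                    ContingencyTable2xK(row, background),
                    mc_threshold=mc_threshold,
                    n_mc=n_mc,
                    seed=rng,
                )
            screen_rows.append(
                {
                    "go_term": term,
                    "screen_id": screen.screen_id,
                    "n_insertions": int(row.sum()),
                    "p": p,
                    "fdr": np.nan,
                }
            )
        sub = pd.DataFrame(screen_rows)
        sub["fdr"] = bh_fdr(sub["p"].to_numpy())
        rows.append(sub)

    if not rows:
        return pd.DataFrame(columns=["go_term", "screen_id", "n_insertions", "p", "fdr"])
    return pd.concat(rows, ignore_index=True)
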