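"""Tabular I/O for pooled-screen data: count tables, insertion annotations,
sample manifests, gene->GO maps, fingerprints, and a flat config format.

Column naming follows the deposited-table conventions: per-sample columns are
``<sample>_read_count``, ``<sample>_normalized_reads`` and, for averaged
controls, ``<sample>_average_read_count`` / ``<sample>_average_normalized_reads``.
All files are UTF-8, tab-separated, ``.`` decimal. A barcode absent from a
sample's table means "not observed" and is distinct from an observed zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("poolfit")

FEATURES = ("5UTR", "CDS", "intron", "3UTR", "intergenic", "not_mapped", "multiple_other")
ROLES = ("initial", "control", "treatment")

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class CountTable:
    """Barcode read counts for one sample.

    ``counts`` holds raw (integer) reads; ``normalized`` is populated by
    :func:`poolfit.phenotype_core.normalize` and sums to the normalization
    target (1e8 by default). Missing barcodes are absent, not zero.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    normalized: dict[str, float] | None = None

    @property
    def total_raw(self) -> int:
        return sum(self.counts.values())

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.counts


@dataclass(frozen=True)
class InsertionAnnotation:
    """One insertion allele: its barcode, physical library location, and the
    gene-level mapping (gene id, genic feature hit, mapping confidence)."""

    barcode: str
    side: str = "5prime"
    mutant_id: str = ""
    plate: str = ""
    well: str = ""
    gene_id: str | None = None
    feature: str = "not_mapped"
    confidence: int = 1

    def __post_init__(self):
        if not self.barcode or set(self.barcode) - _BASES:
            raise ValueError(f"barcode must be uppercase ACGT, got {self.barcode!r}")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.confidence < 1:
            raise ValueError("confidence must be >= 1")


@dataclass(frozen=True)
class Sample:
    """One manifest row. ``control_ref`` names the control (or averaged
    control) a treatment sample is compared against."""

    sample_id: str
    round_id: str
    role: str
    condition_label: str = ""
    control_ref: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


# ---------------------------------------------------------------------------
# count tables


def read_count_table(
    path: str | Path,
    sample_id: str | None = None,
    barcode_col: str = "barcode",
    column_suffix: str = "_read_count",
) -> CountTable:
    """Read one sample's counts from a TSV with a barcode column and
    ``<sample>_read_count`` (and optionally ``<sample>_normalized_reads``)
    columns.

    Parameters
    ----------
    sample_id
        Which sample's columns to read. If None the file must contain exactly
        one ``*_read_count`` column.
    barcode_col
        Name of the barcode column (deposited tables vary).
    column_suffix
        Raw-count column suffix; ``_average_read_count`` selects averaged
        control columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if barcode_col not in df.columns:
        raise ParseError(f"{path}: no barcode column {barcode_col!r}")
    count_cols = [c for c in df.columns if c.endswith(column_suffix)]
    if sample_id is not None:
        count_cols = [c for c in count_cols if c == f"{sample_id}{column_suffix}"]
    if len(count_cols) != 1:
        raise ParseError(
            f"{path}: expected exactly one {column_suffix!r} column"
            + (f" for sample {sample_id!r}" if sample_id else "")
            + f", found {count_cols}"
        )
    col = count_cols[0]
    sid = col[: -len(column_suffix)]

    dup = df[barcode_col].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate barcode row(s): {df[barcode_col][dup].iloc[0]}")

    counts: dict[str, int] = {}
    for i, (bc, raw) in enumerate(zip(df[barcode_col], df[col]), start=2):
        try:
            v = int(raw)
            if v < 0:
                raise ValueError
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {i}: malformed count {raw!r} for {bc}") from None
        counts[bc] = v

    table = CountTable(sample_id=sid, counts=counts)
    norm_suffix = column_suffix.replace("_read_count", "_normalized_reads")
    norm_col = f"{sid}{norm_suffix}"
    if norm_col in df.columns:
        table.normalized = {bc: float(v) for bc, v in zip(df[barcode_col], df[norm_col])}
    return table


def write_count_table(table: CountTable, path: str | Path, barcode_col: str = "barcode") -> None:
    """Write a CountTable to TSV; round-trips through :func:`read_count_table`."""
    cols: dict[str, list] = {barcode_col: list(table.counts)}
    cols[f"{table.sample_id}_read_count"] = [table.counts[b] for b in table.counts]
    if table.normalized is not None:
        cols[f"{table.sample_id}_normalized_reads"] = [
            table.normalized.get(b, 0.0) for b in table.counts
        ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[InsertionAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"barcode", "feature", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            InsertionAnnotation(
                barcode=d["barcode"],
                side=d.get("side", "5prime") or "5prime",
                mutant_id=d.get("mutant_id", ""),
                plate=d.get("plate", ""),
                well=d.get("well", ""),
                gene_id=d.get("gene_id") or None,
                feature=d["feature"],
                confidence=int(d["confidence"]),
            )
        )
    return out


def write_annotations(annotations: Iterable[InsertionAnnotation], path: str | Path) -> None:
    rows = [
        {
            "barcode": a.barcode,
            "side": a.side,
            "mutant_id": a.mutant_id,
            "plate": a.plate,
            "well": a.well,
            "gene_id": a.gene_id or "",
            "feature": a.feature,
            "confidence": a.confidence,
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=["barcode", "side", "mutant_id", "plate", "well", "gene_id", "feature", "confidence"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        Sample(
            sample_id=r.sample_id,
            round_id=r.round_id,
            role=r.role,
            condition_label=getattr(r, "condition_label", ""),
            control_ref=getattr(r, "control_ref", "") or None,
        )
        for r in df.itertuples(index=False)
    ]


def write_manifest(samples: Iterable[Sample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "round_id": s.round_id,
                "role": s.role,
                "condition_label": s.condition_label,
                "control_ref": s.control_ref or "",
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def validate_manifest(samples: list[Sample]) -> list[str]:
    """Validate a sample manifest; returns a list of violation messages
    (empty iff valid). Checks, in a fixed order independent of input order:

    - every treatment names exactly one existing control reference;
    - duplicated sample ids;
    - controls grouped for averaging (same ``control_ref`` target naming
      several controls) come from a single screening round.
    """
    violations: list[str] = []
    by_id: dict[str, list[Sample]] = {}
    for s in samples:
        by_id.setdefault(s.sample_id, []).append(s)
    for sid in sorted(by_id):
        if len(by_id[sid]) > 1:
            roles = {s.role for s in by_id[sid]}
            tag = "role conflict" if len(roles) > 1 else "duplicate sample id"
            violations.append(f"{tag}: {sid}")

    # averaged-control ids are control_refs that are not themselves samples
    # but are named as the average target by >=1 control rows
    avg_groups: dict[str, list[Sample]] = {}
    for s in samples:
        if s.role == "control" and s.control_ref:
            avg_groups.setdefault(s.control_ref, []).append(s)

    for s in sorted(samples, key=lambda x: x.sample_id):
        if s.role == "treatment":
            ref = s.control_ref
            if not ref:
                violations.append(f"treatment without control reference: {s.sample_id}")
            elif ref not in by_id and ref not in avg_groups:
                violations.append(f"dangling control reference: {s.sample_id} -> {ref}")

    for avg_id in sorted(avg_groups):
        rounds = {c.round_id for c in avg_groups[avg_id]}
        if len(rounds) > 1:
            violations.append(
                f"averaging group {avg_id} spans rounds {sorted(rounds)}"
            )
    return violations


# ---------------------------------------------------------------------------
# misc tables


def read_gene2go(path: str | Path) -> dict[str, list[str]]:
    """Read a gene->GO map (one ``gene_id<TAB>go_id`` pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, list[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(gene, [])
        if term not in mapping[gene]:
            mapping[gene].append(term)
    return mapping


def read_fingerprints(path: str | Path) -> dict[str, frozenset[int]]:
    """Read fingerprints: ``compound_id<TAB>comma-separated bit indices``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for cid, bits in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[cid] = frozenset(int(b) for b in str(bits).split(",") if b != "")
    return out


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result DataFrame as TSV with its column order preserved."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: bad config line {line!r}")
        k, v = line.split("=", 1)
        cfg[k.strip()] = v.strip()
    return cfg
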