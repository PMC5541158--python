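"""Strain-to-genome linking via 16S similarity and KO matrix assembly.

Strains are linked to sequenced genomes by matching their 16S rRNA gene
against a genome-derived 16S reference at strict identity and coverage
thresholds (defaults: identity > 0.99 and coverage > 0.95).  The sequence
comparison itself is external: this module consumes a precomputed tabular
hit file (query, subject, percent identity, alignment length, query
length); coverage is the aligned fraction of the query 16S.  Each linked
strain contributes one row to a strains x KEGG-ortholog presence/absence
matrix built from a genome annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SequenceMatch",
    "load_hit_table",
    "filter_matches",
    "build_ko_matrix",
    "load_annotation_table",
    "summarize_linkage",
    "percent_round_half_up",
]


@dataclass(frozen=True)
class SequenceMatch:
    """One 16S-vs-genome hit; identity and coverage are fractions in [0,1]."""

    strain_id: str
    genome_id: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        for fld in ("identity", "coverage"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fld} must be in [0,1], got {v}")


def load_hit_table(path, sep: str = "\t") -> list[SequenceMatch]:
    """Read a hit file with columns query_id, subject_id, pct_identity,
    alignment_length, query_length [, coverage].

    Percent identity is on the 0-100 scale (as aligners report it);
    coverage, when not given, is alignment_length / query_length, capped
    at 1.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"query_id", "subject_id", "pct_identity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if hasattr(row, "coverage") and not pd.isna(row.coverage):
            cov = float(row.coverage)
        else:
            cov = min(float(row.alignment_length) / float(row.query_length), 1.0)
        out.append(
            SequenceMatch(
                strain_id=str(row.query_id),
                genome_id=str(row.subject_id),
                identity=float(row.pct_identity) / 100.0,
                coverage=cov,
            )
        )
    return out


def filter_matches(
    matches: Iterable[SequenceMatch],
    min_identity: float = 0.99,
    min_coverage: float = 0.95,
) -> list[SequenceMatch]:
    """Keep hits passing both thresholds strictly, then resolve one best
    hit per strain.

    Thresholds are strict inequalities (identity > min_identity AND
    coverage > min_coverage).  Among a strain's passing hits the highest
    identity wins; ties break by higher coverage, then lexicographic
    genome id, so the result is deterministic.
    """
    for thr in (min_identity, min_coverage):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must be fractions in [0,1]")
    passing = [
        m for m in matches
        if m.identity > min_identity and m.coverage > min_coverage
    ]
    best: dict[str, SequenceMatch] = {}
    for m in passing:
        cur = best.get(m.strain_id)
        if cur is None or (
            (-m.identity, -m.coverage, m.genome_id)
            < (-cur.identity, -cur.coverage, cur.genome_id)
        ):
            best[m.strain_id] = m
    return [best[k] for k in sorted(best)]


def load_annotation_table(path, sep: str = "\t") -> dict[str, set]:
    """Genome annotations, one (genome_id, ko_id) pair per row."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.genome_id), set()).add(str(row.ko_id))
    return out


def build_ko_matrix(
    links: Iterable[SequenceMatch], annotations: Mapping[str, set]
) -> pd.DataFrame:
    """Strains x KOs presence/absence matrix over the linked genomes.

    Columns are the union of KO ids over linked genomes, sorted; a cell is
    1 iff the KO is annotated in the strain's linked genome.  A linked
    genome absent from the annotation table is an error.
    """
    links = list(links)
    missing = sorted({m.genome_id for m in links} - set(annotations))
    if missing:
        raise KeyError(f"linked genomes missing from annotations: {missing}")
    if not links:
        return pd.DataFrame(dtype=np.int8)
    kos = sorted(set().union(*(annotations[m.genome_id] for m in links)))
    ko_idx = {k: j for j, k in enumerate(kos)}
    strains = [m.strain_id for m in links]
    mat = np.zeros((len(links), len(kos)), dtype=np.int8)
    for i, m in enumerate(links):
        for k in annotations[m.genome_id]:
            mat[i, ko_idx[k]] = 1
    return pd.DataFrame(mat, index=strains, columns=kos)


def percent_round_half_up(numerator: float, denominator: float) -> int:
    """Integer percentage, .5 rounding up (67 for 503/754)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


def summarize_linkage(
    n_linked: int, n_with_optimum: Mapping[str, int]
) -> pd.DataFrame:
    """Per-trait coverage among genome-linked strains.

    ``n_with_optimum`` maps a trait name to the number of linked strains
    reporting an optimum for it; the table gives counts and integer
    percentages of ``n_linked``.
    """
    rows = [
        {
            "trait": trait,
            "n_linked": n_linked,
            "n_with_optimum": n,
            "pct_with_optimum": percent_round_half_up(n, n_linked),
        }
        for trait, n in n_with_optimum.items()
    ]
    return pd.DataFrame(rows)
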