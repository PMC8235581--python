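"""Transposase census and insertion-sequence (IS) family assignment.

Transposases are identified from annotation product strings; family
membership is assigned by best hit against a user-supplied labelled protein
library (any FASTA with a ``family=`` header tag — a synthetic library ships
with the simulator for testing; a curated IS database export can be dropped
in for real genomes). Draft assemblies underestimate transposable-element
counts because IS copies collapse or break at contig ends, so a warning is
attached for non-complete assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .genome_io import GeneFeature, ProteinRecord
from .orthology import _make_aligner, align_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransposaseRecord:
    locus_tag: str
    genome_id: str
    family: str | None
    identity: float | None
    coverage: float | None


def transposase_census(features: list[GeneFeature], assembly_level: str = "complete") -> dict:
    """Count transposase CDS and their percent of all CDS (one decimal).

    A CDS is a transposase when its product contains "transposase"
    (case-insensitive).
    """
    cds = [f for f in features if f.kind == "CDS"]
    if not cds:
        raise ValueError("no CDS features; transposase fraction undefined")
    tps = [f for f in cds if "transposase" in (f.product or "").lower()]
    if assembly_level != "complete":
        logger.warning(
            "assembly level %r: transposable-element counts are likely "
            "underestimated on fragmented assemblies", assembly_level,
        )
    return {
        "count": len(tps),
        "cds_count": len(cds),
        "fraction_of_cds": transposase_fraction(len(tps), len(cds)),
        "locus_tags": [f.locus_tag for f in tps],
    }


def transposase_fraction(n_transposase: int, n_cds: int) -> float:
    """Percent of coding sequences that are transposases, one decimal
    (e.g. 78 of 3504 CDS -> 2.2)."""
    if n_cds <= 0:
        raise ValueError("CDS count must be positive")
    return round(100.0 * n_transposase / n_cds, 1)


def read_family_library(path) -> list[tuple[str, str]]:
    """Read a labelled protein library: FASTA with ``family=`` header tags."""
    library = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = None
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        library.append((family or rec.id, str(rec.seq).upper()))
    return library


def assign_is_family(
    transposase_protein: ProteinRecord,
    reference_library: list[tuple[str, str]],
    min_identity: float = 25.0,
    min_coverage: float = 0.6,
) -> TransposaseRecord:
    """Family of the highest-scoring library hit passing the thresholds;
    score ties break by identity, then library label order."""
    if not reference_library:
        raise ValueError("empty IS reference library")
    aligner = _make_aligner()
    best = None  # (score, identity, family, coverage)
    for family, seq in reference_library:
        ref = ProteinRecord(f"lib|{family}", family, "library", seq)
        res = align_pair(aligner, transposase_protein, ref)
        if res is None:
            continue
        identity, cov_q, _cov_r, score = res
        if identity < min_identity or cov_q < min_coverage:
            continue
        key = (score, identity)
        if best is None or key > (best[0], best[1]):
            best = (score, identity, family, cov_q)
    if best is None:
        return TransposaseRecord(
            transposase_protein.locus_tag, transposase_protein.genome_id, None, None, None
        )
    return TransposaseRecord(
        transposase_protein.locus_tag,
        transposase_protein.genome_id,
        best[2],
        round(best[1], 2),
        round(best[3], 3),
    )


def is_family_matrix(
    assignments: dict[str, list[TransposaseRecord]]
) -> pd.DataFrame:
    """Family-by-genome count matrix (assigned transposases only); an
    ``unassigned`` row keeps column sums equal to per-genome census counts."""
    genome_ids = sorted(assignments)
    families = sorted(
        {r.family for recs in assignments.values() for r in recs if r.family}
    )
    mat = pd.DataFrame(0, index=families + ["unassigned"], columns=genome_ids)
    for gid, recs in assignments.items():
        for r in recs:
            mat.loc[r.family if r.family else "unassigned", gid] += 1
    mat.index.name = "is_family"
    return mat
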