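"""Multiheme c-type cytochrome detection by heme-binding motif counting.

c-type cytochromes bind heme covalently through a CXXCH (or the less common
CXXXCH) motif; chains carrying several such motifs ("multiheme") are the
workhorses of extracellular electron transport in metal-reducing bacteria.
Two pattern modes are provided:

* ``canonical`` — C-X-X-C-H and C-X-X-X-C-H (the biochemical heme c motif);
* ``literal``   — C-X-X-H and C-X-X-X-H (a strictly more permissive variant
  kept for compatibility with looser published pattern notations).

Scanning is left-to-right, greedily taking the shortest match at each
position and resuming after the matched histidine, so tandem motifs are not
double-counted; an ``overlapping`` switch restores position-by-position
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# (pattern length, check) pairs, shortest first
_MODES = {
    "canonical": (
        (5, lambda s, i: s[i] == "C" and s[i + 3] == "C" and s[i + 4] == "H"),
        (6, lambda s, i: s[i] == "C" and s[i + 4] == "C" and s[i + 5] == "H"),
    ),
    "literal": (
        (4, lambda s, i: s[i] == "C" and s[i + 3] == "H"),
        (5, lambda s, i: s[i] == "C" and s[i + 4] == "H"),
    ),
}

MULTIHEME_THRESHOLD = 4  # "more than 3" motifs


@dataclass(frozen=True)
class HemeScanResult:
    protein_id: str
    motif_positions: tuple[int, ...]
    pattern_mode: str
    threshold: int = MULTIHEME_THRESHOLD

    @property
    def motif_count(self) -> int:
        return len(self.motif_positions)

    @property
    def is_multiheme(self) -> bool:
        return self.motif_count >= self.threshold


def scan_heme_motifs(
    protein, pattern_mode: str = "canonical", overlapping: bool = False
) -> HemeScanResult:
    """Count heme-binding motifs in one protein.

    ``protein`` is a ProteinRecord or a (protein_id, sequence)-like object;
    a bare string is accepted and labelled by itself.
    """
    if isinstance(protein, str):
        pid, seq = protein, protein
    else:
        pid, seq = protein.protein_id, protein.sequence
    seq = seq.upper()
    extra = set(seq) - AA_ALPHABET
    if extra:
        raise ValueError(f"protein {pid}: non-amino-acid characters {sorted(extra)}")
    if pattern_mode not in _MODES:
        raise ValueError(f"unknown pattern_mode {pattern_mode!r}")
    patterns = _MODES[pattern_mode]
    positions = []
    i, n = 0, len(seq)
    while i < n:
        hit = None
        for plen, check in patterns:  # shortest match wins
            if i + plen <= n and check(seq, i):
                hit = plen
                break
        if hit is None:
            i += 1
        else:
            positions.append(i)
            i = i + 1 if overlapping else i + hit
    return HemeScanResult(pid, tuple(positions), pattern_mode)


def classify_multiheme(scan: HemeScanResult, threshold: int = MULTIHEME_THRESHOLD) -> bool:
    """Multiheme call: motif count >= threshold (default 4, i.e. ">3")."""
    return scan.motif_count >= threshold


def with_threshold(scan: HemeScanResult, threshold: int) -> HemeScanResult:
    return replace(scan, threshold=threshold)


def ogc_profile(
    multiheme_ids: set[str],
    ogset,
    genome_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Orthologous-group-of-cytochromes (OGC) count matrix.

    Rows are OGs containing at least one multiheme protein (singleton
    multiheme proteins are appended as single-member rows); entries count the
    multiheme members per genome.
    """
    genome_ids = list(genome_ids or ogset.genome_ids)
    rows = {}
    for og_id in sorted(ogset.groups):
        counts = {g: 0 for g in genome_ids}
        hit = False
        for gid, members in ogset.groups[og_id].items():
            n = sum(1 for m in members if m in multiheme_ids)
            if n:
                hit = True
            if gid in counts:
                counts[gid] += n
        if hit:
            rows[og_id] = counts
    for singleton in sorted(ogset.singletons):
        if singleton in multiheme_ids:
            gid = singleton.split("|", 1)[0]
            counts = {g: 0 for g in genome_ids}
            if gid in counts:
                counts[gid] = 1
            rows[f"singleton:{singleton}"] = counts
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=genome_ids)
    mat = mat.astype(int) if len(mat) else pd.DataFrame(columns=genome_ids, dtype=int)
    mat.index.name = "ogc_id"
    return mat
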