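"""Chemotaxis gene catalog, cluster detection and typing, MCP heptad
classes, and the flagellar-cluster census.

Bacterial chemotaxis genes (cheA..cheY and the chemoreceptor mcp genes) are
identified from annotation product strings (optionally overridden by a
user-supplied locus->kind table), grouped into genomic clusters, and each
cluster is assigned one of the architecture types described for
Deltaproteobacteria: E. coli-like (type 2), Frz-like (carrying the cheA-cheY
fusion), Dif-like (44H chemoreceptor plus cheA/C/D/W/Y), the
Deltaproteobacteria-specific beta group (cheA/B/R/W without a receptor), and
a beta variant additionally carrying cheC/cheD/cheX.

Methyl-accepting chemotaxis proteins (MCPs) are classified by the number of
7-residue heptad repeats (H) in their cytoplasmic signalling domain; valid
classes are 24H, 28H, 34H, 36H, 38H, 40H, 44H and 64H. The cytoplasmic
domain is taken C-terminal of the last transmembrane helix detected by
Kyte-Doolittle hydropathy (window 19, mean >= 1.6, overlapping windows
merged).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import GeneFeature, ProteinRecord

CHE_KINDS = (
    "cheA", "cheAY", "cheB", "cheC", "cheD", "cheR", "cheV", "cheW",
    "cheX", "cheY", "mcp",
)

MCP_CLASSES = (24, 28, 34, 36, 38, 40, 44, 64)
MCP_CLASS_TOLERANCE = 2

CLUSTER_TYPES = (
    "EcoliLikeType2", "FrzLike", "DifLike", "BetaGroup", "BetaCDX", "Unclassified",
)

# Kyte-Doolittle hydropathy scale
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

TM_WINDOW = 19
TM_THRESHOLD = 1.6

_FUSION_RE = re.compile(r"chea[-/ _]?chey|chea/y|\bcheay\b", re.I)
_CHE_RE = re.compile(r"\bche([ABCDRVWXY])\b", re.I)
_FLAG_GENE_RE = re.compile(r"\b(?:flg|flh|fli|mot)[A-Z]\b")


@dataclass(frozen=True)
class CheGene:
    locus_tag: str
    kind: str
    evidence: str = "keyword"

    def __post_init__(self):
        if self.kind not in CHE_KINDS:
            raise ValueError(f"unknown chemotaxis gene kind {self.kind!r}")


@dataclass(frozen=True)
class Operon:
    replicon_id: str
    strand: str
    locus_tags: tuple[str, ...]
    start: int
    end: int


@dataclass(frozen=True)
class CheCluster:
    replicon_id: str
    start: int
    end: int
    che_genes: tuple[CheGene, ...]
    all_locus_tags: tuple[str, ...]
    n_intervening: int
    type_label: str = "Unclassified"

    @property
    def kinds(self) -> set[str]:
        return {g.kind for g in self.che_genes}


@dataclass(frozen=True)
class McpClass:
    protein_id: str
    heptad_count: int
    mcp_class: int | None
    cytoplasmic_span: tuple[int, int]
    reason: str = ""


def catalog_che_genes(
    features: list[GeneFeature],
    keyword_table: dict[str, str] | None = None,
) -> list[CheGene]:
    """Identify chemotaxis genes from product strings.

    ``keyword_table`` maps locus_tag -> kind (a dict or an iterable of
    (locus_tag, kind) pairs) and overrides the product-string rules
    (evidence recorded as ``user_table``); conflicting entries for one locus
    are an error. The CheA-CheY fusion is recorded as the single kind
    ``cheAY``.
    """
    pairs = (
        list(keyword_table.items())
        if isinstance(keyword_table, dict)
        else list(keyword_table or [])
    )
    keyword_table = {}
    conflicts = []
    for tag, kind in pairs:
        if kind not in CHE_KINDS:
            raise ValueError(f"user table: unknown kind {kind!r} for locus {tag}")
        if tag in keyword_table and keyword_table[tag] != kind:
            conflicts.append(tag)
        keyword_table[tag] = kind
    if conflicts:
        raise ValueError(
            "conflicting user-table entries for loci: " + ", ".join(sorted(set(conflicts)))
        )
    out = []
    for f in features:
        if f.kind != "CDS":
            continue
        if f.locus_tag in keyword_table:
            out.append(CheGene(f.locus_tag, keyword_table[f.locus_tag], "user_table"))
            continue
        product = f.product or ""
        if _FUSION_RE.search(product):
            out.append(CheGene(f.locus_tag, "cheAY"))
        elif re.search(r"methyl[- ]accepting", product, re.I):
            out.append(CheGene(f.locus_tag, "mcp"))
        elif m := _CHE_RE.search(product):
            out.append(CheGene(f.locus_tag, "che" + m.group(1).upper()))
        elif re.search(r"\bchev\b", product, re.I):
            out.append(CheGene(f.locus_tag, "cheV"))
    return out


def call_operons(features: list[GeneFeature], max_gap_bp: int = 200) -> list[Operon]:
    """Maximal runs of same-strand consecutive genes with intergenic gaps
    <= ``max_gap_bp``. A strand flip always breaks the run."""
    cds = [f for f in features if f.kind == "CDS"]
    cds.sort(key=lambda f: (f.replicon_id, f.start))
    operons, run = [], []
    for f in cds:
        if run and (
            f.replicon_id != run[-1].replicon_id
            or f.strand != run[-1].strand
            or f.start - run[-1].end > max_gap_bp
        ):
            operons.append(_finish_operon(run))
            run = []
        run.append(f)
    if run:
        operons.append(_finish_operon(run))
    return operons


def _finish_operon(run: list[GeneFeature]) -> Operon:
    return Operon(
        replicon_id=run[0].replicon_id,
        strand=run[0].strand,
        locus_tags=tuple(f.locus_tag for f in run),
        start=run[0].start,
        end=run[-1].end,
    )


def detect_che_clusters(
    che_genes: list[CheGene],
    features: list[GeneFeature],
    max_intervening: int = 2,
    min_che: int = 3,
) -> tuple[list[CheCluster], list[CheGene]]:
    """Group chemotaxis genes into genomic clusters.

    A cluster is a maximal window in which consecutive che genes are
    separated by at most ``max_intervening`` non-che genes; windows with
    fewer than ``min_che`` che genes are dropped. Returns (clusters,
    dispersed mcp genes outside any kept cluster) — chemoreceptors scattered
    around the chromosome are a documented feature of these genomes.
    """
    by_tag = {g.locus_tag: g for g in che_genes}
    cds = sorted(
        (f for f in features if f.kind == "CDS"),
        key=lambda f: (f.replicon_id, f.start),
    )
    clusters: list[CheCluster] = []
    i = 0
    while i < len(cds):
        if cds[i].locus_tag not in by_tag:
            i += 1
            continue
        # extend a window from this che gene
        window = [i]
        j = i + 1
        gap = 0
        while j < len(cds) and cds[j].replicon_id == cds[i].replicon_id:
            if cds[j].locus_tag in by_tag:
                window.append(j)
                gap = 0
            else:
                gap += 1
                if gap > max_intervening:
                    break
            j += 1
        lo, hi = window[0], window[-1]
        members = tuple(by_tag[cds[k].locus_tag] for k in window)
        if len(members) >= min_che:
            clusters.append(
                CheCluster(
                    replicon_id=cds[lo].replicon_id,
                    start=cds[lo].start,
                    end=cds[hi].end,
                    che_genes=members,
                    all_locus_tags=tuple(f.locus_tag for f in cds[lo : hi + 1]),
                    n_intervening=(hi - lo + 1) - len(members),
                )
            )
        i = hi + 1
    clustered = {g.locus_tag for c in clusters for g in c.che_genes}
    dispersed = [g for g in che_genes if g.kind == "mcp" and g.locus_tag not in clustered]
    return clusters, dispersed


def detect_tm_helices(
    sequence: str, window: int = TM_WINDOW, threshold: float = TM_THRESHOLD
) -> list[tuple[int, int]]:
    """Transmembrane helix spans by Kyte-Doolittle sliding-window hydropathy;
    overlapping qualifying windows are merged."""
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return []
    vals = [KD_SCALE.get(a, 0.0) for a in seq]
    total = sum(vals[:window])
    spans = []
    for s in range(0, n - window + 1):
        if s > 0:
            total += vals[s + window - 1] - vals[s - 1]
        if total / window >= threshold:
            if spans and s <= spans[-1][1]:
                spans[-1] = (spans[-1][0], s + window)
            else:
                spans.append((s, s + window))
    return spans


def classify_mcp(protein: ProteinRecord) -> McpClass:
    """Assign an MCP heptad class from the cytoplasmic-domain length.

    H = round(domain length / 7); the class is the nearest valid class if
    within +-2 heptads (distance ties broken toward the larger class), else
    unclassified. Proteins with no detected TM helix are unclassified, with
    H computed on the full length and flagged.
    """
    seq = protein.sequence
    pid = protein.protein_id
    if len(seq) < 50:
        return McpClass(pid, 0, None, (0, len(seq)), reason="too_short")
    helices = detect_tm_helices(seq)
    if not helices:
        h = round(len(seq) / 7)
        return McpClass(pid, h, None, (0, len(seq)), reason="no_tm_helix")
    cyto_start = helices[-1][1]
    domain = seq[cyto_start:]
    h = round(len(domain) / 7)
    best = min(MCP_CLASSES, key=lambda c: (abs(h - c), -c))
    if abs(h - best) <= MCP_CLASS_TOLERANCE:
        return McpClass(pid, h, best, (cyto_start, len(seq)))
    return McpClass(pid, h, None, (cyto_start, len(seq)), reason="no_class_within_2")


def type_cluster(cluster: CheCluster, mcp_classes: dict[str, McpClass]) -> str:
    """Rule cascade assigning the architecture type of a chemotaxis cluster.

    ``mcp_classes`` maps locus_tag -> McpClass for the cluster's mcp genes.
    The first matching rule wins: Frz-like (cheAY fusion present); Dif-like
    (44H receptor plus cheA/C/D/W/Y); beta group (cheA/B/R/W, no receptor),
    refined to the cheC/D/X-carrying variant; E. coli-like type 2 (>=2
    receptors plus interleaved non-che genes).
    """
    kinds = cluster.kinds
    mcp_tags = [g.locus_tag for g in cluster.che_genes if g.kind == "mcp"]
    if "cheAY" in kinds:
        return "FrzLike"
    has_44h = any(
        (m := mcp_classes.get(t)) is not None and m.mcp_class == 44 for t in mcp_tags
    )
    if has_44h and {"cheA", "cheC", "cheD", "cheW", "cheY"} <= kinds:
        return "DifLike"
    if {"cheA", "cheB", "cheR", "cheW"} <= kinds and not mcp_tags:
        if {"cheC", "cheD", "cheX"} <= kinds:
            return "BetaCDX"
        return "BetaGroup"
    if len(mcp_tags) >= 2 and cluster.n_intervening >= 1:
        return "EcoliLikeType2"
    return "Unclassified"


def flagellar_census(features: list[GeneFeature], max_intervening: int = 2) -> dict:
    """Census of flagellar biosynthesis genes (flg/flh/fli/mot gene names or
    'flagell*' products); ``complete`` means the largest locus carries at
    least 25 flagellar genes, the scale of a full biosynthesis cluster."""
    cds = sorted(
        (f for f in features if f.kind == "CDS"),
        key=lambda f: (f.replicon_id, f.start),
    )
    is_flag = [
        bool(
            re.search(r"flagell", f.product, re.I) or _FLAG_GENE_RE.search(f.product or "")
        )
        for f in cds
    ]
    n_genes = sum(is_flag)
    loci = []
    i = 0
    while i < len(cds):
        if not is_flag[i]:
            i += 1
            continue
        members = [i]
        j, gap = i + 1, 0
        while j < len(cds) and cds[j].replicon_id == cds[i].replicon_id:
            if is_flag[j]:
                members.append(j)
                gap = 0
            else:
                gap += 1
                if gap > max_intervening:
                    break
            j += 1
        loci.append([cds[k].locus_tag for k in members])
        i = members[-1] + 1
    largest = max((len(l) for l in loci), default=0)
    return {
        "n_flagellar_genes": n_genes,
        "n_loci": len(loci),
        "largest_locus": largest,
        "complete": largest >= 25,
    }


def che_summary(che_genes: list[CheGene], mcp_classes: dict[str, McpClass]) -> dict:
    """Per-genome count table by che kind and MCP class (Table-3 style)."""
    counts = {k: 0 for k in CHE_KINDS}
    for g in che_genes:
        counts[g.kind] += 1
    class_counts: dict[str, int] = {}
    for g in che_genes:
        if g.kind != "mcp":
            continue
        m = mcp_classes.get(g.locus_tag)
        key = f"{m.mcp_class}H" if m and m.mcp_class else "unclassified"
        class_counts[key] = class_counts.get(key, 0) + 1
    counts["mcp_classes"] = dict(sorted(class_counts.items()))
    counts["total"] = sum(v for k, v in counts.items() if isinstance(v, int))
    return counts
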