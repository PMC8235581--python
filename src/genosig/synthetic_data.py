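"""Synthetic annotated bacterial genomes with planted signature features.

The generator emulates the statistical structure the comparative pipeline
assumes: a set of genomes descended from a common ancestor along a two-cluster
phylogeny, with controlled per-branch nucleotide divergence, and planted
feature content — multiheme cytochromes with a chosen heme-motif count,
chemoreceptors (MCPs) of a chosen heptad class, chemotaxis operons of each
named architecture type, transposase copies with insertion-sequence family
labels, and an optional flagellar gene cluster. Every run also produces a
machine-readable truth table recording what was planted where and the
expected pairwise nucleotide identities, which downstream recovery tests use
as their oracle.

Substitutions are per-site Bernoulli draws (the new base uniform over the
three alternatives), so the realized mismatch fraction on one branch equals
the branch rate; saturation (multiple hits) appears between genomes on
different branches, and the truth table's expected identities apply the
exact two-channel correction q = p1 + p2 - 4/3 p1 p2 (Jukes-Cantor-style).
Indels (length 1-10, geometric) fall in intergenic DNA only, so annotations
remain exact; planted (non-neutral) genes are additionally protected from
substitutions by default so that their role parameters survive — pass
``mutate_planted=True`` to stress-test recovery under divergence.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import GeneFeature, GenomeRecord, write_genome_fasta, write_gff3

# ----------------------------------------------------------------- constants

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_TABLE11.stop_codons)
_AA2CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _AA2CODONS.setdefault(aa, []).append(codon)
for aa in _AA2CODONS:
    _AA2CODONS[aa].sort()

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CH = "ADEFGIKLMNPQRSTVWY"  # background alphabet for planted cytochromes

# MCP construction blocks: a hydrophilic N-terminal segment, two 20-residue
# TM helices whose Kyte-Doolittle profile ends the detected helix exactly at
# the helix/tail boundary, a short periplasmic loop, and a hydrophilic
# cytoplasmic tail of exactly 7*H residues.
MCP_NTERM = "MNTSQDKTLSEQARDSLNQTSDKQS"
MCP_TM = "AASAVAASAVAASAVAASAV"
MCP_LOOP = "DQSKTNDRQS"
# one tail permutation per heptad class (same hydrophilic composition, so
# hydropathy is class-independent, but classes are distinct sequence
# families rather than nested prefixes of each other)
MCP_TAIL_UNITS = {
    24: "DKSEQTNR", 28: "KDQSENRT", 34: "EQDKRSTN", 36: "RNEKDQTS",
    38: "DSKRQENT", 40: "KTEDNRQS", 44: "ENRQKDST", 64: "RQNTKESD",
}

CHE_TYPES = ("EcoliLikeType2", "FrzLike", "DifLike", "BetaGroup", "BetaCDX")

# gene order (kind, mcp heptad class or None) per chemotaxis cluster type;
# "other" marks an interleaved non-chemotaxis gene
CHE_TYPE_LAYOUT: dict[str, tuple] = {
    "EcoliLikeType2": (
        ("cheA", None), ("cheW", None), ("mcp", 36), ("other", None),
        ("mcp", 40), ("cheR", None), ("cheB", None), ("cheY", None),
    ),
    "FrzLike": (("cheAY", None), ("cheW", None), ("mcp", 40), ("cheB", None), ("cheR", None)),
    "DifLike": (
        ("cheA", None), ("cheC", None), ("cheD", None), ("cheW", None),
        ("cheY", None), ("mcp", 44),
    ),
    "BetaGroup": (("cheA", None), ("cheB", None), ("cheR", None), ("cheW", None), ("cheY", None)),
    "BetaCDX": (
        ("cheA", None), ("cheB", None), ("cheR", None), ("cheW", None),
        ("cheC", None), ("cheD", None), ("cheX", None), ("cheY", None),
    ),
}

CHE_PRODUCTS = {
    "cheA": "chemotaxis histidine kinase CheA",
    "cheAY": "chemotaxis protein CheA-CheY fusion",
    "cheB": "chemotaxis response regulator methylesterase CheB",
    "cheC": "chemotaxis phosphatase CheC",
    "cheD": "chemoreceptor glutamine deamidase CheD",
    "cheR": "chemotaxis methyltransferase CheR",
    "cheV": "chemotaxis coupling protein CheV",
    "cheW": "chemotaxis scaffold protein CheW",
    "cheX": "chemotaxis phosphatase CheX",
    "cheY": "chemotaxis response regulator CheY",
    "mcp": "methyl-accepting chemotaxis protein",
}

IS_FAMILIES = ("IS3", "IS4", "IS21", "IS110", "IS200/IS605", "IS256", "IS1595")

_FLAG_NAMES = (
    "FlgB", "FlgC", "FlgD", "FlgE", "FlgF", "FlgG", "FlgH", "FlgI", "FlgJ",
    "FlgK", "FlgL", "FlhA", "FlhB", "FlhF", "FliC", "FliD", "FliE", "FliF",
    "FliG", "FliH", "FliI", "FliJ", "FliK", "FliL", "FliM", "FliN", "FliO",
    "FliP", "FliQ", "FliR", "FliS", "MotA", "MotB",
)

INTERGENIC_GAP = 300  # bp between independent genes
OPERON_GAP = 30       # bp between genes of one planted operon/cluster


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class PlantSpec:
    """One planted feature (or block of features).

    role: cytochrome | mcp | che_operon | transposase | flagellar_cluster | neutral
    params: role parameters (k_motifs, class_h, che_type, family, copies, n_genes)
    genomes: target genome ids, or None for all genomes.
    """

    role: str
    params: dict = field(default_factory=dict)
    genomes: tuple[str, ...] | None = None

    def __post_init__(self):
        valid = {"cytochrome", "mcp", "che_operon", "transposase", "flagellar_cluster", "neutral"}
        if self.role not in valid:
            raise ValueError(f"unknown plant role {self.role!r}")
        if self.role == "cytochrome" and self.params.get("k_motifs", 4) < 0:
            raise ValueError("k_motifs must be >= 0")
        if self.role == "mcp" and self.params.get("class_h", 40) not in (24, 28, 34, 36, 38, 40, 44, 64):
            raise ValueError("class_h must be a valid MCP class")
        if self.role == "che_operon" and self.params.get("che_type", "BetaGroup") not in CHE_TYPES:
            raise ValueError("che_type must be one of " + ", ".join(CHE_TYPES))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate five closely related strains: two flagellated,
    chemotaxis- and cytochrome-rich genomes versus three transposon-expanded
    ones, diverged to pairwise nucleotide identities of roughly 70-73%.
    """

    seed: int = 0
    n_genomes: int = 5
    genome_length_bp: int = 120_000
    gene_count: int = 150
    gc_target: float = 0.58
    substitution_rate: float = 0.20
    indel_rate: float = 0.0002
    feature_plan: list[PlantSpec] | None = None
    genome_ids: tuple[str, ...] | None = None
    mutate_planted: bool = False

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate <= 0.75):
            raise ValueError("substitution_rate must be in [0, 0.75]")
        if self.genome_ids is None:
            self.genome_ids = tuple(f"G{i + 1}" for i in range(self.n_genomes))
        if len(self.genome_ids) != self.n_genomes:
            raise ValueError("genome_ids length must equal n_genomes")
        if self.feature_plan is None:
            self.feature_plan = default_feature_plan(self.genome_ids)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        plan = data.pop("feature_plan", None)
        cfg = cls(**data)
        if plan is not None:
            cfg.feature_plan = [
                PlantSpec(p["role"], p.get("params", {}),
                          tuple(p["genomes"]) if p.get("genomes") else None)
                for p in plan
            ]
        return cfg


@dataclass(frozen=True)
class TruthGene:
    genome_id: str
    locus_tag: str
    family_id: str
    role: str
    params: dict


@dataclass
class TruthTable:
    """Record of everything planted, plus expected pairwise identities."""

    genes: list[TruthGene] = field(default_factory=list)
    expected_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    branch_p: dict[str, float] = field(default_factory=dict)
    library: list[tuple[str, str]] = field(default_factory=list)  # (IS family, protein)

    def pair_identity(self, a: str, b: str) -> float:
        return self.expected_identity[tuple(sorted((a, b)))]

    def genes_of(self, genome_id: str, role: str | None = None) -> list[TruthGene]:
        return [
            g for g in self.genes
            if g.genome_id == genome_id and (role is None or g.role == role)
        ]

    def to_json(self, path) -> None:
        data = {
            "genes": [asdict(g) for g in self.genes],
            "expected_identity": {f"{a}|{b}": v for (a, b), v in self.expected_identity.items()},
            "branch_p": self.branch_p,
            "library": [{"family": f, "sequence": s} for f, s in self.library],
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        data = json.loads(Path(path).read_text())
        t = cls()
        t.genes = [TruthGene(**g) for g in data["genes"]]
        t.expected_identity = {
            tuple(k.split("|")): v for k, v in data["expected_identity"].items()
        }
        t.branch_p = data["branch_p"]
        t.library = [(d["family"], d["sequence"]) for d in data["library"]]
        return t

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tlocus_tag\tfamily_id\trole\tparams\n")
            for g in self.genes:
                fh.write(
                    f"{g.genome_id}\t{g.locus_tag}\t{g.family_id}\t{g.role}\t"
                    + json.dumps(g.params, sort_keys=True) + "\n"
                )


# ---------------------------------------------------------- default study plan

def default_feature_plan(genome_ids: tuple[str, ...]) -> list[PlantSpec]:
    """Two-cluster signature plan: the first two genomes carry the flagellar
    cluster, the Frz-like and cheC/D/X chemotaxis clusters and extra
    cytochromes; the remaining genomes carry the transposon expansion."""
    ga = list(genome_ids[:2])
    gb = list(genome_ids[2:]) or ga
    plan = [
        PlantSpec("flagellar_cluster", {"n_genes": 28}, tuple(ga)),
        PlantSpec("che_operon", {"che_type": "EcoliLikeType2"}),
        PlantSpec("che_operon", {"che_type": "DifLike"}),
        PlantSpec("che_operon", {"che_type": "BetaGroup"}),
        PlantSpec("che_operon", {"che_type": "FrzLike"}, tuple(ga)),
        PlantSpec("che_operon", {"che_type": "BetaCDX"}, tuple(ga)),
        PlantSpec("cytochrome", {"k_motifs": 4}),
        PlantSpec("cytochrome", {"k_motifs": 6}),
        PlantSpec("cytochrome", {"k_motifs": 8}),
        PlantSpec("cytochrome", {"k_motifs": 10}),
        PlantSpec("cytochrome", {"k_motifs": 5}, tuple(ga)),
        PlantSpec("cytochrome", {"k_motifs": 7}, tuple(ga)),
        PlantSpec("cytochrome", {"k_motifs": 5}, tuple(gb)),
        PlantSpec("cytochrome", {"k_motifs": 9}, tuple(gb)),
        PlantSpec("mcp", {"class_h": 40}),
        PlantSpec("mcp", {"class_h": 34}),
        PlantSpec("mcp", {"class_h": 36}, tuple(ga)),
        PlantSpec("mcp", {"class_h": 64}, tuple(ga)),
        PlantSpec("mcp", {"class_h": 24}, tuple(gb)),
        PlantSpec("mcp", {"class_h": 44}, tuple(gb)),
        PlantSpec("transposase", {"family": "IS3", "copies": 3}, tuple(gb)),
        PlantSpec("transposase", {"family": "IS256", "copies": 2}, tuple(gb)),
        PlantSpec("transposase", {"family": "IS1595", "copies": 2}, tuple(gb)),
        PlantSpec("transposase", {"family": "IS4", "copies": 1}),
    ]
    return plan


# ------------------------------------------------------------- construction

def _random_protein(rng, length: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def make_cytochrome_protein(k_motifs: int, rng, length: int = 160) -> str:
    """Background protein free of C and H with exactly ``k_motifs``
    non-overlapping C-X-X-C-H motifs planted at spaced positions."""
    need = k_motifs * 5
    length = max(length, need + 10 * (k_motifs + 1))
    aa = list(_random_protein(rng, length, AA_NO_CH))
    if k_motifs:
        stride = length // k_motifs
        for i in range(k_motifs):
            pos = i * stride + int(rng.integers(0, max(1, stride - 6)))
            aa[pos:pos + 5] = ["C", aa[pos + 1], aa[pos + 2], "C", "H"]
    return "M" + "".join(aa)


def make_mcp_protein(class_h: int) -> str:
    """Deterministic chemoreceptor: N-term + TM + loop + TM + 7*H tail."""
    unit = MCP_TAIL_UNITS[class_h]
    tail = (unit * (7 * class_h))[: 7 * class_h]
    return MCP_NTERM + MCP_TM + MCP_LOOP + MCP_TM + tail


def make_transposase_library(rng, families: tuple[str, ...] = IS_FAMILIES,
                             length: int = 240) -> list[tuple[str, str]]:
    """One prototype protein per insertion-sequence family."""
    return [(fam, "M" + _random_protein(rng, length - 1)) for fam in families]


def mutate_protein(sequence: str, p_aa: float, rng) -> str:
    """Substitute each residue with probability ``p_aa`` (testing aid)."""
    aa = list(sequence)
    for i in range(len(aa)):
        if rng.random() < p_aa:
            choices = [c for c in AA20 if c != aa[i]]
            aa[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(aa)


def _reverse_translate(protein: str, rng, base_p: np.ndarray) -> str:
    """Protein -> stop-free CDS; synonymous codons weighted toward the
    base-composition target."""
    codons = []
    for aa in protein:
        opts = _AA2CODONS[aa]
        w = np.array([np.prod([base_p[_B2I[b]] for b in c]) for c in opts])
        w = w / w.sum()
        codons.append(opts[int(rng.choice(len(opts), p=w))])
    return "".join(codons)


def _random_cds(rng, n_codons: int, base_p: np.ndarray) -> str:
    """Random stop-free coding sequence at the target base composition."""
    out = ["ATG"]
    while len(out) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.choice(4, size=3, p=base_p))
        if c not in _STOPS:
            out.append(c)
    out.append("TAA")
    return "".join(out)


# ------------------------------------------------------------- the generator

@dataclass
class _GenePlan:
    role: str
    product: str
    params: dict
    family_id: str
    protein: str | None  # None -> random CDS
    n_codons: int
    block: int | None    # genes sharing a block id stay contiguous, same strand
    genomes: tuple[str, ...] | None


def _expand_plan(config: SimulationConfig, rng) -> list[_GenePlan]:
    plans: list[_GenePlan] = []
    block = 0
    fam = 0

    def next_fam(prefix):
        nonlocal fam
        fam += 1
        return f"{prefix}{fam:04d}"

    library = dict(make_transposase_library(np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])))
    for spec in config.feature_plan:
        if spec.role == "flagellar_cluster":
            block += 1
            n = spec.params.get("n_genes", 28)
            for i in range(n):
                name = _FLAG_NAMES[i % len(_FLAG_NAMES)]
                plans.append(_GenePlan(
                    "flagellar", f"flagellar biosynthesis protein {name}",
                    {"gene": name}, next_fam("flg"), None, 110, block, spec.genomes))
        elif spec.role == "che_operon":
            block += 1
            ctype = spec.params.get("che_type", "BetaGroup")
            for kind, class_h in CHE_TYPE_LAYOUT[ctype]:
                if kind == "other":
                    plans.append(_GenePlan(
                        "neutral", "hypothetical protein", {"in_che_cluster": ctype},
                        next_fam("fam"), None, 110, block, spec.genomes))
                elif kind == "mcp":
                    # same-class receptors share one deterministic scaffold,
                    # hence one sequence family
                    plans.append(_GenePlan(
                        "che_gene", CHE_PRODUCTS["mcp"],
                        {"che_type": ctype, "che_kind": "mcp", "class_h": class_h},
                        f"mcp{class_h}H", make_mcp_protein(class_h), 0, block, spec.genomes))
                else:
                    plans.append(_GenePlan(
                        "che_gene", CHE_PRODUCTS[kind],
                        {"che_type": ctype, "che_kind": kind},
                        next_fam("che"), None, 150, block, spec.genomes))
        elif spec.role == "cytochrome":
            k = spec.params.get("k_motifs", 4)
            plans.append(_GenePlan(
                "cytochrome", "multiheme c-type cytochrome",
                {"k_motifs": k}, next_fam("cyt"),
                make_cytochrome_protein(k, rng), 0, None, spec.genomes))
        elif spec.role == "mcp":
            h = spec.params.get("class_h", 40)
            plans.append(_GenePlan(
                "mcp", CHE_PRODUCTS["mcp"], {"class_h": h}, f"mcp{h}H",
                make_mcp_protein(h), 0, None, spec.genomes))
        elif spec.role == "transposase":
            family = spec.params.get("family", "IS3")
            if family not in library:
                library[family] = "M" + _random_protein(rng, 239)
            # all copies of one IS family are one sequence family
            for _ in range(spec.params.get("copies", 1)):
                plans.append(_GenePlan(
                    "transposase", f"{family} family transposase",
                    {"family": family}, "tps" + family.replace("/", "_"),
                    library[family], 0, None, spec.genomes))
        elif spec.role == "neutral":
            for _ in range(spec.params.get("copies", 1)):
                plans.append(_GenePlan(
                    "neutral", "hypothetical protein", {}, next_fam("fam"),
                    None, 120, None, spec.genomes))
    # neutral filler; gene_count is a floor — enough neutrals are always
    # generated to keep planted blocks separated by >=3 intervening genes
    n_blocks = len({p.block for p in plans if p.block is not None})
    # standalone receptors must stay dispersed (>=3 intervening genes)
    min_separators = 3 * n_blocks + sum(
        3 if p.role == "mcp" else 1
        for p in plans if p.block is None and p.role != "neutral"
    )
    n_neutral = max(config.gene_count - len(plans), min_separators)
    for _ in range(n_neutral):
        plans.append(_GenePlan(
            "neutral", "hypothetical protein", {}, next_fam("fam"),
            None, int(rng.integers(90, 160)), None, None))
    # interleave: blocks separated by >=3 neutral singles
    blocks: dict[int, list[_GenePlan]] = {}
    singles: list[_GenePlan] = []
    neutrals: list[_GenePlan] = []
    for p in plans:
        if p.block is not None:
            blocks.setdefault(p.block, []).append(p)
        elif p.role == "neutral":
            neutrals.append(p)
        else:
            singles.append(p)
    ordered: list[_GenePlan] = []
    for b in sorted(blocks):
        ordered.extend(blocks[b])
        for _ in range(3):
            if neutrals:
                ordered.append(neutrals.pop(0))
    for s in singles:
        ordered.append(s)
        for _ in range(3 if s.role == "mcp" else 1):
            if neutrals:
                ordered.append(neutrals.pop(0))
    ordered.extend(neutrals)
    return ordered, [(f, s) for f, s in library.items()]


def simulate_ancestor(
    config: SimulationConfig,
) -> tuple[GenomeRecord, list[GeneFeature], TruthTable]:
    """Build the ancestral annotated genome with every planted feature.

    Deterministic given ``config.seed``; raises before any output if the
    feature plan cannot fit in ``genome_length_bp``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gc = config.gc_target
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ordered, library = _expand_plan(config, rng)

    # materialize nucleotide sequences
    cds_list = []
    for p in ordered:
        if p.protein is not None:
            nt = _reverse_translate(p.protein, rng, base_p) + "TAA"
        else:
            nt = _random_cds(rng, p.n_codons, base_p)
        cds_list.append(nt)
    total = sum(len(c) for c in cds_list) + sum(
        OPERON_GAP if (p.block is not None and i and ordered[i - 1].block == p.block)
        else INTERGENIC_GAP
        for i, p in enumerate(ordered)
    ) + INTERGENIC_GAP
    if total > config.genome_length_bp:
        raise ValueError(
            f"feature plan needs {total} bp but genome_length_bp is {config.genome_length_bp}"
        )

    def intergenic(n):
        return "".join(_BASES[i] for i in rng.choice(4, size=n, p=base_p))

    pieces = []
    features = []
    truth = TruthTable(library=library)
    pos = 0
    prev_block = None
    block_strand = "+"
    for i, (p, nt) in enumerate(zip(ordered, cds_list)):
        gap = OPERON_GAP if (p.block is not None and p.block == prev_block) else INTERGENIC_GAP
        pieces.append(intergenic(gap))
        pos += gap
        if p.block is None:
            strand = "+" if rng.random() < 0.5 else "-"
        elif p.block != prev_block:
            block_strand = "+" if rng.random() < 0.5 else "-"
            strand = block_strand
        else:
            strand = block_strand
        placed = nt if strand == "+" else str(Seq(nt).reverse_complement())
        tag = f"ANC_{i + 1:04d}"
        features.append(GeneFeature(
            feature_id=tag, replicon_id="chr", start=pos, end=pos + len(nt),
            strand=strand, kind="CDS", product=p.product, locus_tag=tag))
        truth.genes.append(TruthGene("ancestor", tag, p.family_id, p.role, dict(p.params)))
        pieces.append(placed)
        pos += len(nt)
        prev_block = p.block
    pieces.append(intergenic(config.genome_length_bp - pos))
    genome = GenomeRecord("ancestor", "synthetic ancestor", (("chr", "".join(pieces)),))
    truth.branch_p["ancestor"] = 0.0
    # stash plan metadata for the dataset driver
    truth._plan = {f"ANC_{i + 1:04d}": p for i, p in enumerate(ordered)}  # type: ignore[attr-defined]
    return genome, features, truth


def evolve_genome(
    parent: GenomeRecord,
    features: list[GeneFeature],
    p: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    genome_id: str | None = None,
    protected_tags: frozenset[str] = frozenset(),
    drop_tags: frozenset[str] = frozenset(),
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """One branch of evolution: substitutions, intergenic indels, gene loss.

    Substitutions hit each unprotected site independently with probability
    ``p``; indels (geometric length, max 10) fall only outside coding
    regions, so feature coordinates stay exact; features in ``drop_tags``
    are excised with their whole span.
    """
    if not (0.0 <= p <= 0.75):
        raise ValueError("substitution rate must be in [0, 0.75]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    gid = genome_id or f"{parent.genome_id}_child"
    new_reps = []
    new_features = []
    for rid, seq in parent.replicons:
        feats = sorted(
            (f for f in features if f.replicon_id == rid), key=lambda f: f.start
        )
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.int8)
        for b, i in _B2I.items():
            lut[ord(b)] = i
        idx = lut[arr]
        L = len(arr)
        # substitution mask, sparing protected gene spans
        sub = rng.random(L) < p
        for f in feats:
            if f.locus_tag in protected_tags:
                sub[f.start:f.end] = False
        shift = 1 + rng.integers(0, 3, size=int(sub.sum()))
        idx[sub] = (idx[sub] + shift) % 4
        rev = np.frombuffer(b"ACGT", dtype=np.uint8)
        arr = rev[idx]
        # indel + drop events (positions strictly outside retained CDS spans)
        coding = np.zeros(L, dtype=bool)
        for f in feats:
            if f.locus_tag not in drop_tags:
                coding[f.start:f.end] = True
        events = []  # (pos, delta, kind, payload)
        for f in feats:
            if f.locus_tag in drop_tags:
                events.append((f.start, "del", f.end - f.start))
        if indel_rate > 0:
            cand = np.nonzero((rng.random(L) < indel_rate) & ~coding)[0]
            starts = np.array([f.start for f in feats], dtype=int)
            for posn in cand:
                posn = int(posn)
                length = int(min(rng.geometric(0.5), 10))
                if rng.random() < 0.5:
                    ins = rev[rng.choice(4, size=length)]
                    events.append((posn, "ins", ins))
                else:
                    nxt = starts[bisect_right(list(starts), posn):]
                    limit = int(nxt[0]) if len(nxt) else L
                    length = min(length, limit - posn)
                    if length > 0:
                        events.append((posn, "del", length))
        events.sort(key=lambda e: e[0])
        pieces = []
        breakpoints = []  # (orig_pos, cumulative delta)
        cur = delta = 0
        for posn, kind, payload in events:
            if posn < cur:
                continue  # swallowed by an earlier deletion
            pieces.append(arr[cur:posn])
            if kind == "ins":
                pieces.append(payload)
                delta += len(payload)
                cur = posn
            else:
                cur = posn + payload
                delta -= payload
            breakpoints.append((posn, delta))
        pieces.append(arr[cur:])
        child_seq = b"".join(piece.tobytes() for piece in pieces).decode()
        bp_pos = [b[0] for b in breakpoints]
        bp_delta = [b[1] for b in breakpoints]

        def new_coord(x: int) -> int:
            k = bisect_right(bp_pos, x)
            return x + (bp_delta[k - 1] if k else 0)

        for f in feats:
            if f.locus_tag in drop_tags:
                continue
            ns = new_coord(f.start)
            new_features.append(GeneFeature(
                feature_id=f.feature_id, replicon_id=rid, start=ns,
                end=ns + (f.end - f.start), strand=f.strand, kind=f.kind,
                product=f.product, locus_tag=f.locus_tag, partial=f.partial))
        new_reps.append((rid, child_seq))
    child = GenomeRecord(gid, f"synthetic strain {gid}", tuple(new_reps),
                         parent.assembly_level)
    return child, new_features


def combine_branch_p(p1: float, p2: float) -> float:
    """Expected mismatch after two successive uniform-substitution channels."""
    return p1 + p2 - (4.0 / 3.0) * p1 * p2


def _default_topology(ids: tuple[str, ...]):
    """Two-cluster topology (branch lengths as fractions of the configured
    per-branch substitution rate)."""
    ids = list(ids)
    if len(ids) == 1:
        return [(1.0, ids[0])]
    if len(ids) == 2:
        return [(1.0, ids[0]), (1.0, ids[1])]

    def inner(sub, leaf):
        if len(sub) == 1:
            return (leaf + 0.05, sub[0])
        if len(sub) == 2:
            return (0.05, [(leaf, sub[0]), (leaf, sub[1])])
        return (0.05, [(leaf, sub[0]), inner(sub[1:], leaf - 0.05)])

    half = max(2, len(ids) // 2) if len(ids) > 3 else 1
    return [inner(ids[:half], 0.95), inner(ids[half:], 0.95)]


def simulate_dataset(
    config: SimulationConfig, topology=None
) -> tuple[dict[str, tuple[GenomeRecord, list[GeneFeature]]], TruthTable]:
    """Ancestor plus evolved leaf genomes along a (default two-cluster)
    topology, with the truth table of planted genes and expected identities.

    ``topology`` is a list of nodes, each ``(branch_fraction, leaf_id)`` or
    ``(branch_fraction, [child nodes...])``; fractions scale
    ``config.substitution_rate``.
    """
    ancestor, anc_features, truth = simulate_ancestor(config)
    plan = truth._plan  # type: ignore[attr-defined]
    topology = topology if topology is not None else _default_topology(config.genome_ids)
    protected = frozenset(
        tag for tag, p in plan.items() if p.role != "neutral"
    ) if not config.mutate_planted else frozenset()

    genomes: dict[str, tuple[GenomeRecord, list[GeneFeature]]] = {}
    leaf_paths: dict[str, list[tuple[int, float]]] = {}
    leaf_drops: dict[str, frozenset[str]] = {}
    seed_counter = [0]
    branch_counter = [0]

    def next_seed():
        seed_counter[0] += 1
        return int(np.random.SeedSequence([config.seed, 5, seed_counter[0]]).generate_state(1)[0] % (2**31))

    def walk(parent_g, parent_f, nodes, path):
        for frac, payload in nodes:
            branch_counter[0] += 1
            bid = branch_counter[0]
            p_branch = frac * config.substitution_rate
            is_leaf = isinstance(payload, str)
            drop = frozenset()
            gid = payload if is_leaf else f"node{bid}"
            if is_leaf:
                drop = frozenset(
                    tag for tag, pl in plan.items()
                    if pl.genomes is not None and payload not in pl.genomes
                )
            child, child_f = evolve_genome(
                parent_g, parent_f, p_branch, config.indel_rate * frac,
                seed=next_seed(), genome_id=gid,
                protected_tags=protected, drop_tags=drop,
            )
            new_path = path + [(bid, p_branch)]
            if is_leaf:
                # rename locus tags to the leaf genome
                renamed = []
                for f in child_f:
                    tag = f"{payload}_{f.locus_tag.split('_')[-1]}"
                    renamed.append(GeneFeature(
                        feature_id=tag, replicon_id=f.replicon_id, start=f.start,
                        end=f.end, strand=f.strand, kind=f.kind,
                        product=f.product, locus_tag=tag, partial=f.partial))
                    anc_tag = f.locus_tag
                    pl = plan[anc_tag]
                    truth.genes.append(TruthGene(
                        payload, tag, pl.family_id, pl.role, dict(pl.params)))
                genomes[payload] = (
                    GenomeRecord(payload, child.strain_name, child.replicons,
                                 child.assembly_level),
                    renamed,
                )
                leaf_paths[payload] = new_path
                leaf_drops[payload] = drop
                truth.branch_p[payload] = sum(p for _, p in new_path)
            else:
                walk(child, child_f, payload, new_path)

    walk(ancestor, anc_features, topology, [])
    leaves = sorted(genomes)
    span_len = {f.locus_tag: f.end - f.start for f in anc_features}
    total_bp = ancestor.length_bp
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            sa = {bid: pb for bid, pb in leaf_paths[a]}
            sb = {bid: pb for bid, pb in leaf_paths[b]}
            shared = set(sa) & set(sb)
            q = 0.0
            for bid, pb in list(sa.items()) + list(sb.items()):
                if bid not in shared:
                    q = combine_branch_p(q, pb)
            # substitution-protected planted spans present in both leaves are
            # identical by construction; the expectation covers shared content
            dropped = leaf_drops[a] | leaf_drops[b]
            shared_bp = total_bp - sum(span_len[t] for t in dropped)
            frozen_bp = sum(
                span_len[t] for t in protected if t not in dropped
            )
            u = 1.0 - frozen_bp / shared_bp if shared_bp else 1.0
            truth.expected_identity[(a, b)] = round(100.0 * (1.0 - q * u), 3)
    return genomes, truth


def emit_dataset(
    genomes: dict[str, tuple[GenomeRecord, list[GeneFeature]]],
    truth: TruthTable,
    out_dir,
) -> dict[str, Path]:
    """Write per-genome FASTA + GFF3, the truth table (JSON and TSV) and the
    insertion-sequence reference library; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for gid, (genome, feats) in sorted(genomes.items()):
        fna = out / f"{gid}.fna"
        gff = out / f"{gid}.gff3"
        write_genome_fasta(genome, fna)
        write_gff3(genome, feats, gff)
        paths[f"{gid}.fna"] = fna
        paths[f"{gid}.gff3"] = gff
    tj = out / "truth.json"
    truth.to_json(tj)
    paths["truth.json"] = tj
    tt = out / "truth.tsv"
    truth.to_tsv(tt)
    paths["truth.tsv"] = tt
    lib = out / "is_library.faa"
    with open(lib, "w") as fh:
        for fam, seq in truth.library:
            fh.write(f">{fam.replace('/', '_')} family={fam}\n{seq}\n")
    paths["is_library.faa"] = lib
    return paths
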