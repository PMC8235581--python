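"""Annotated-genome I/O, proteome derivation and basic genome statistics.

Coordinates are 0-based half-open internally; GFF3 input/output uses the
standard 1-based inclusive convention. Annotation can be supplied either as
GFF3 or as a 7-column tab-separated feature table
(replicon, start, end, strand, kind, product, locus_tag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
FEATURE_KINDS = ("CDS", "pseudogene", "other")


@dataclass(frozen=True)
class GenomeRecord:
    """One strain: ordered replicons plus bookkeeping labels."""

    genome_id: str
    strain_name: str
    replicons: tuple[tuple[str, str], ...]
    assembly_level: str = "complete"

    def __post_init__(self):
        ids = [rid for rid, _ in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicon ids in genome {self.genome_id}")
        for rid, seq in self.replicons:
            if not seq:
                raise ValueError(f"empty replicon {rid} in genome {self.genome_id}")
            extra = set(seq.upper()) - NUCLEOTIDES
            if extra:
                raise ValueError(
                    f"replicon {rid} of {self.genome_id} has non-ACGTN characters: {sorted(extra)}"
                )

    @property
    def length_bp(self) -> int:
        return sum(len(seq) for _, seq in self.replicons)

    def sequence(self, replicon_id: str) -> str:
        for rid, seq in self.replicons:
            if rid == replicon_id:
                return seq
        raise KeyError(f"no replicon {replicon_id} in genome {self.genome_id}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene feature on one replicon; start/end are 0-based half-open."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str
    product: str = ""
    locus_tag: str = ""
    partial: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.feature_id}: invalid span {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    locus_tag: str
    genome_id: str
    sequence: str
    disrupted: bool = False
    partial: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty protein {self.protein_id}")


def _check_features(genome: GenomeRecord, features: list[GeneFeature]) -> None:
    lengths = {rid: len(seq) for rid, seq in genome.replicons}
    tags = set()
    for f in features:
        if f.replicon_id not in lengths:
            raise ValueError(f"feature {f.feature_id} references unknown replicon {f.replicon_id}")
        if f.end > lengths[f.replicon_id]:
            raise ValueError(
                f"feature {f.feature_id} coordinate {f.end} exceeds replicon "
                f"{f.replicon_id} length {lengths[f.replicon_id]}"
            )
        if f.locus_tag:
            if f.locus_tag in tags:
                raise ValueError(f"duplicate locus_tag {f.locus_tag}")
            tags.add(f.locus_tag)


def _parse_gff3(path: Path) -> list[GeneFeature]:
    features = []
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attributes = {}
            for item in attrs.split(";"):
                if not item or "=" not in item:
                    continue
                key, _, val = item.partition("=")
                attributes[key.strip()] = unquote(val.strip())
            n += 1
            kind = ftype if ftype in FEATURE_KINDS else "other"
            features.append(
                GeneFeature(
                    feature_id=attributes.get("ID", f"feature{n:05d}"),
                    replicon_id=unquote(seqid),
                    start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    kind=kind,
                    product=attributes.get("product", ""),
                    locus_tag=attributes.get("locus_tag", ""),
                    partial=attributes.get("partial", "") in ("true", "1"),
                )
            )
    return features


def _parse_feature_table(path: Path) -> list[GeneFeature]:
    features = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise ValueError(f"{path} line {i + 1}: expected 7 columns, got {len(cols)}")
            replicon, start, end, strand, kind, product, locus_tag = cols
            features.append(
                GeneFeature(
                    feature_id=locus_tag or f"feature{i + 1:05d}",
                    replicon_id=replicon,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    kind=kind if kind in FEATURE_KINDS else "other",
                    product=product,
                    locus_tag=locus_tag,
                )
            )
    return features


def read_annotated_genome(
    fasta_path,
    annotation_path,
    genome_id: str | None = None,
    strain_name: str = "",
    assembly_level: str = "complete",
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a genome FASTA plus its annotation (GFF3 or 7-column TSV).

    Features are returned sorted by (replicon, start); coordinates outside a
    replicon and duplicate locus tags are hard errors.
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    replicons = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")
    )
    if not replicons:
        raise ValueError(f"no sequences in {fasta_path}")
    genome = GenomeRecord(
        genome_id=genome_id or fasta_path.stem,
        strain_name=strain_name,
        replicons=replicons,
        assembly_level=assembly_level,
    )
    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        features = _parse_gff3(annotation_path)
    else:
        features = _parse_feature_table(annotation_path)
    _check_features(genome, features)
    order = {rid: i for i, (rid, _) in enumerate(replicons)}
    features.sort(key=lambda f: (order[f.replicon_id], f.start, f.feature_id))
    return genome, features


def write_genome_fasta(genome: GenomeRecord, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in genome.replicons:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genome: GenomeRecord, features: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, seq in genome.replicons:
            fh.write(f"##sequence-region {rid} 1 {len(seq)}\n")
        for f in features:
            attrs = [f"ID={quote(f.feature_id)}"]
            if f.locus_tag:
                attrs.append(f"locus_tag={quote(f.locus_tag)}")
            if f.product:
                attrs.append(f"product={quote(f.product, safe=' ')}")
            if f.partial:
                attrs.append("partial=true")
            fh.write(
                "\t".join(
                    [
                        f.replicon_id,
                        "genosig",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def derive_proteome(
    genome: GenomeRecord,
    features: list[GeneFeature],
    force_met_start: bool = False,
) -> list[ProteinRecord]:
    """Translate CDS features (table 11) into protein records.

    Minus-strand CDS are reverse-complemented first; a trailing stop codon is
    removed. A CDS with an internal stop is returned flagged ``disrupted``;
    downstream protein analyses drop those via :func:`usable_proteins`.
    A CDS whose length is not divisible by 3 is flagged partial and translated
    on its longest in-frame prefix.
    """
    proteins = []
    for f in features:
        if f.kind != "CDS":
            continue
        nt = genome.sequence(f.replicon_id)[f.start : f.end]
        if f.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        partial = f.partial
        if len(nt) % 3 != 0:
            partial = True
            logger.warning(
                "CDS %s length %d not divisible by 3; translating longest in-frame prefix",
                f.feature_id,
                len(nt),
            )
            nt = nt[: len(nt) - len(nt) % 3]
        aa = str(Seq(nt).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        disrupted = "*" in aa
        if disrupted:
            aa = aa.replace("*", "X")
        if force_met_start and aa:
            aa = "M" + aa[1:]
        if not aa:
            continue
        rec = ProteinRecord(
            protein_id=f"{genome.genome_id}|{f.locus_tag or f.feature_id}",
            locus_tag=f.locus_tag or f.feature_id,
            genome_id=genome.genome_id,
            sequence=aa,
            disrupted=disrupted,
            partial=partial,
        )
        proteins.append(rec)  # disrupted records stay flagged; see usable_proteins
    n_bad = sum(1 for p in proteins if p.disrupted)
    if n_bad:
        logger.info("%d disrupted CDS flagged in %s", n_bad, genome.genome_id)
    return proteins


def usable_proteins(proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Proteins eligible for downstream analyses (intact, non-disrupted)."""
    return [p for p in proteins if not p.disrupted]


def write_proteome_fasta(proteins: list[ProteinRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.genome_id}|{p.locus_tag}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_proteome_fasta(path, genome_id: str | None = None) -> list[ProteinRecord]:
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid, _, tag = rec.id.partition("|")
        if not tag:
            tag, gid = gid, genome_id or Path(path).stem
        proteins.append(
            ProteinRecord(
                protein_id=f"{gid}|{tag}",
                locus_tag=tag,
                genome_id=gid,
                sequence=str(rec.seq).upper(),
            )
        )
    return proteins


def genome_stats(genome: GenomeRecord, features: list[GeneFeature]) -> dict:
    """Length, GC%% (Ns excluded from both numerator and denominator, one
    decimal) and CDS count."""
    gc = at = 0
    for _, seq in genome.replicons:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    denom = gc + at
    return {
        "length_bp": genome.length_bp,
        "gc_percent": round(100.0 * gc / denom, 1) if denom else None,
        "cds_count": sum(1 for f in features if f.kind == "CDS"),
    }


def reverse_complement_genome(
    genome: GenomeRecord, features: list[GeneFeature]
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Replicon-wise reverse complement with strands flipped (testing aid)."""
    lengths = {rid: len(seq) for rid, seq in genome.replicons}
    new_reps = tuple(
        (rid, str(Seq(seq).reverse_complement())) for rid, seq in genome.replicons
    )
    new_feats = [
        replace(
            f,
            start=lengths[f.replicon_id] - f.end,
            end=lengths[f.replicon_id] - f.start,
            strand="-" if f.strand == "+" else "+",
        )
        for f in features
    ]
    return (
        GenomeRecord(genome.genome_id, genome.strain_name, new_reps, genome.assembly_level),
        new_feats,
    )
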