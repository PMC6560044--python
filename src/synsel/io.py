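"""Readers and writers for the formats the pipeline consumes and emits.

FASTA via Biopython; gene annotations as GFF3 (gffutils) or a 6-column
BED-like TSV with a companion CDS FASTA; Kazusa-style codon usage tables;
gene-set lists (one id per line, ``#`` comments); TSV outputs with
``#``-prefixed metadata headers; FASTA/relaxed-PHYLIP alignment export.

Sequences are uppercased on read; RNA ``U`` is normalised to ``T`` with a
warning; records containing ambiguity codes (``N`` etc.) are dropped whole,
with a warning — conservative for conservation counting.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import CodonAlignment
from .codon_usage import CodonUsageProfile, profile_from_counts
from .genetic_code import SENSE_CODONS, STOP_CODONS
from .records import GeneRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "write_gene_list",
    "read_codon_table",
    "write_codon_table",
    "read_bed_genes",
    "write_bed_genes",
    "read_gff3_genes",
    "write_gff3",
    "write_codon_alignment_fasta",
    "write_phylip",
    "write_tsv",
]

_VALID = set("ACGT")


def _clean_sequence(seq: str, name: str) -> str | None:
    s = seq.upper()
    if "U" in s:
        warnings.warn(f"{name}: RNA alphabet normalised (U -> T)", stacklevel=3)
        s = s.replace("U", "T")
    if set(s) - _VALID:
        warnings.warn(
            f"{name}: dropped (contains ambiguity codes "
            f"{sorted(set(s) - _VALID)})",
            stacklevel=3,
        )
        return None
    return s


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an ordered ``{id: sequence}`` mapping.

    Records with ambiguity codes are dropped with a warning; ``U`` is
    normalised to ``T``.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id)
        if seq is not None:
            out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for gid in ids:
            fh.write(f"{gid}\n")


# Kazusa-style table: "AUU 17.6 (714298)" triplets, wrapped arbitrarily.
_KAZUSA_ENTRY = re.compile(
    r"([ACGTU]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+)\s*\)"
)


def read_codon_table(path: str | Path, metric: str = "aa_specific") -> CodonUsageProfile:
    """Parse a Kazusa-layout codon usage table into a genome-wide profile.

    The layout is whitespace-separated ``codon per-mille (count)`` triplets;
    both RNA (``U``) and DNA (``T``) spellings are accepted. All 64 codons
    must be present; a truncated table raises an error naming the missing
    codons. Stop-codon counts are parsed but excluded from the profile.
    """
    text = Path(path).read_text()
    counts: dict[str, int] = {}
    for codon, _freq, count in _KAZUSA_ENTRY.findall(text):
        counts[codon.replace("U", "T")] = int(count)
    missing = sorted((SENSE_CODONS | STOP_CODONS) - set(counts))
    if missing:
        raise ValueError(
            f"codon table {path} is missing {len(missing)} codons: {missing}"
        )
    sense_counts = {c: n for c, n in counts.items() if c in SENSE_CODONS}
    return profile_from_counts(sense_counts, metric, source="genome-wide")


def write_codon_table(counts: Mapping[str, int], path: str | Path) -> None:
    """Write counts in Kazusa layout (frequency per mille derived)."""
    full = {c: int(counts.get(c, 0)) for c in sorted(SENSE_CODONS | STOP_CODONS)}
    total = sum(full.values()) or 1
    entries = [
        f"{c.replace('T', 'U')} {1000.0 * n / total:.1f} ({n})"
        for c, n in full.items()
    ]
    with open(path, "w") as fh:
        for i in range(0, len(entries), 4):
            fh.write("  ".join(entries[i : i + 4]) + "\n")


def write_bed_genes(genes: Sequence[GeneRecord], bed_path: str | Path,
                    fasta_path: str | Path | None = None) -> None:
    """Write a 6-column BED-like TSV (chrom, start0, end, gene_id, score,
    strand) and, optionally, a companion CDS FASTA keyed by gene id."""
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )
    if fasta_path is not None:
        write_fasta({g.gene_id: g.cds for g in genes}, fasta_path)


def read_bed_genes(bed_path: str | Path, fasta_path: str | Path,
                   species: str = "") -> list[GeneRecord]:
    """Read the BED-like TSV + companion CDS FASTA back into GeneRecords."""
    cds = read_fasta(fasta_path)
    genes = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start0, end, gene_id, _score, strand = line.split("\t")[:6]
        if gene_id not in cds:
            warnings.warn(f"{gene_id}: no CDS in FASTA; record dropped",
                          stacklevel=2)
            continue
        genes.append(
            GeneRecord(
                gene_id=gene_id, species=species, chrom=chrom,
                start=int(start0) + 1, end=int(end), strand=strand,
                cds=cds[gene_id],
            )
        )
    return genes


def read_gff3_genes(gff_path: str | Path, genome_fasta: str | Path,
                    species: str = "") -> list[GeneRecord]:
    """Extract genes with stitched CDSs from a GFF3 and its genome FASTA.

    CDS segments of each gene are concatenated in coordinate order and
    reverse-complemented for minus-strand genes.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    genes = []
    for gene in db.features_of_type("gene"):
        segments = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: f.start
        )
        if not segments:
            continue
        chrom_seq = genome.get(gene.seqid)
        if chrom_seq is None:
            warnings.warn(f"{gene.id}: chromosome {gene.seqid!r} not in FASTA",
                          stacklevel=2)
            continue
        cds = "".join(chrom_seq[f.start - 1 : f.end] for f in segments)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        cleaned = _clean_sequence(cds, gene.id)
        if cleaned is None:
            continue
        genes.append(
            GeneRecord(
                gene_id=gene.id, species=species,
                symbol=gene.attributes.get("Name", [""])[0],
                chrom=gene.seqid, start=gene.start, end=gene.end,
                strand=gene.strand or "+", cds=cleaned,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene/mRNA/CDS features (one unspliced CDS per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.symbol:
                attrs += f";Name={g.symbol}"
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def write_codon_alignment_fasta(aln: CodonAlignment, path: str | Path) -> None:
    write_fasta(dict(zip(aln.ids, aln.rows)), path)


def write_phylip(aln: CodonAlignment, path: str | Path) -> None:
    """Relaxed sequential PHYLIP (for external tree-building tools)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {aln.length}\n")
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f"{name}  {row}\n")


def write_tsv(df: pd.DataFrame, path: str | Path,
              metadata: Mapping[str, object] | None = None) -> None:
    """Write a TSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
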