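"""Reference sequences and gene models for circular organelle genomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A single-transcript gene with one or more CDS segments.

    CDS segments are 0-based half-open genomic intervals stored in genomic
    order; ``phase`` applies to the first coding segment in transcription
    order, as in GFF3.
    """

    gene_id: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]] = field(default_factory=list)
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for start, end in self.cds:
            if end <= start:
                raise ValueError(f"degenerate CDS segment ({start}, {end})")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (0-based half-open) covering all CDS segments."""
        return min(s for s, _ in self.cds), max(e for _, e in self.cds)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def coding_sequence(self, genome_seq: str) -> str:
        """Spliced CDS in transcription order, phase-trimmed, 5'->3'."""
        parts = [genome_seq[s:e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq[self.phase :]


@dataclass
class GenomeRef:
    """An organelle reference sequence with circularity flag and gene models."""

    name: str
    seq: str
    circular: bool = True
    genes: list[GeneModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def genes_overlapping(self, start: int, end: int) -> list[GeneModel]:
        """Genes whose CDS footprint intersects [start, end) (0-based)."""
        out = []
        for g in self.genes:
            gs, ge = g.span
            if gs < end and start < ge:
                out.append(g)
        return out


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome.seq), width):
            fh.write(genome.seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into a name -> sequence dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA record before header")
                seqs[name].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_gff3(genome: GenomeRef, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive, CDS with phase)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome.seq)}\n")
        for g in genome.genes:
            gs, ge = g.span
            fh.write(
                "\t".join(
                    [genome.name, "organellotype", "gene", str(gs + 1), str(ge),
                     ".", g.strand, ".", f"ID={g.gene_id}"]
                )
                + "\n"
            )
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            phase = g.phase
            rows = []
            for s, e in segs:
                rows.append((s, e, phase))
                phase = (3 - ((e - s - phase) % 3)) % 3
            for s, e, ph in sorted(rows):
                fh.write(
                    "\t".join(
                        [genome.name, "organellotype", "CDS", str(s + 1), str(e),
                         ".", g.strand, str(ph), f"ID=cds-{g.gene_id};Parent={g.gene_id}"]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse CDS features from a GFF3 file into gene models.

    Only the gene/CDS subset written by :func:`write_gff3` is supported;
    CDS rows are grouped by their Parent attribute.
    """
    by_gene: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("Parent") or attrs.get("ID") or "unknown"
            start, end = int(fields[3]) - 1, int(fields[4])
            phase = int(fields[7]) if fields[7] in "012" else 0
            if gene_id not in by_gene:
                by_gene[gene_id] = GeneModel(gene_id=gene_id, strand=fields[6])
                order.append(gene_id)
            by_gene[gene_id].cds.append((start, end))
    genes = []
    for gid in order:
        g = by_gene[gid]
        g.cds.sort()
        first = g.cds[-1] if g.strand == "-" else g.cds[0]
        # recover phase of the first coding segment in transcription order
        g.phase = _segment_phase(path, gid, first)
        genes.append(g)
    return genes


def _segment_phase(path: str | Path, gene_id: str, seg: tuple[int, int]) -> int:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            if f"Parent={gene_id}" not in fields[8]:
                continue
            if int(fields[3]) - 1 == seg[0] and int(fields[4]) == seg[1]:
                return int(fields[7]) if fields[7] in "012" else 0
    return 0
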