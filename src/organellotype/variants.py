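"""Variant sites and VCF input/output.

VCF reading is delegated to pysam; writing emits plain uncompressed VCF v4.2
with haploid GT calls (organelle genomes) plus per-allele AD counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

_VALID = set("ACGT")

MISSING = -1


@dataclass
class VariantSite:
    """One polymorphic site with per-accession calls and allele depths.

    ``genotypes`` holds one allele index per accession (0 = REF, 1.. = ALTs,
    -1 = missing); ``allele_depths`` is an (accessions x alleles) read-count
    matrix aligned with [REF] + ALTs, or None when AD is unavailable.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray | None = None
    allele_depths: np.ndarray | None = None
    n_heteroplasmic: int = 0  # accessions with a mixed (diploid-style) GT call

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if not self.ref or set(self.ref) - _VALID:
            raise ValueError(f"invalid REF allele {self.ref!r} at pos {self.pos}")
        if not self.alts:
            raise ValueError(f"site at pos {self.pos} has no ALT allele")
        if len(set(self.alts)) != len(self.alts) or self.ref in self.alts:
            raise ValueError(f"ALT alleles not distinct from REF at pos {self.pos}")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
            if self.genotypes.max(initial=MISSING) >= 1 + len(self.alts):
                raise ValueError(f"genotype index out of range at pos {self.pos}")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def label(self) -> str:
        """Positional rendering, e.g. ``p.457333 (T > C)``."""
        return f"p.{self.pos} ({self.ref} > {','.join(self.alts)})"

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantSite]]:
    """Read a VCF into accession ids and VariantSite records.

    Heteroplasmic diploid-style GT calls (e.g. 0/1) are collapsed to the
    majority allele by AD; AD ties or absent AD yield a missing call.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    sites: list[VariantSite] = []
    for rec in vf:
        alts = tuple(rec.alts or ())
        if not alts:
            continue
        n_all = 1 + len(alts)
        gts = np.full(len(samples), MISSING, dtype=np.int16)
        ads = np.zeros((len(samples), n_all), dtype=np.int64)
        n_het = 0
        for i, name in enumerate(samples):
            call = rec.samples[name]
            ad = call.get("AD")
            if ad is not None:
                for j, d in enumerate(ad[:n_all]):
                    ads[i, j] = d or 0
            alleles = [a for a in (call.get("GT") or ()) if a is not None]
            if not alleles:
                continue
            if len(set(alleles)) == 1:
                gts[i] = alleles[0]
            else:
                # heteroplasmy: collapse to majority allele by AD, tie -> missing
                n_het += 1
                if ad is None:
                    continue
                row = ads[i]
                best = int(np.argmax(row))
                if (row == row[best]).sum() == 1:
                    gts[i] = best
        sites.append(
            VariantSite(
                contig=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                genotypes=gts,
                allele_depths=ads,
                n_heteroplasmic=n_het,
            )
        )
    vf.close()
    return samples, sites


def write_vcf(
    path: str | Path,
    accessions: list[str],
    sites: list[VariantSite],
    contigs: dict[str, int],
    het_genotypes: dict[tuple[int, int], tuple[int, int]] | None = None,
) -> None:
    """Write sites to an uncompressed, sorted VCF v4.2 with GT and AD.

    ``het_genotypes`` optionally maps (site_index, accession_index) to a
    diploid-style genotype pair rendered as "a/b" (heteroplasmic calls).
    """
    het_genotypes = het_genotypes or {}
    order = sorted(range(len(sites)), key=lambda i: (sites[i].contig, sites[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=organellotype\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        for si in order:
            s = sites[si]
            cols = [s.contig, str(s.pos), ".", s.ref, ",".join(s.alts),
                    ".", "PASS", ".", "GT:AD"]
            for ai in range(len(accessions)):
                het = het_genotypes.get((si, ai))
                if het is not None:
                    gt = f"{het[0]}/{het[1]}"
                elif s.genotypes is None or s.genotypes[ai] == MISSING:
                    gt = "."
                else:
                    gt = str(int(s.genotypes[ai]))
                if s.allele_depths is not None:
                    ad = ",".join(str(int(d)) for d in s.allele_depths[ai])
                else:
                    ad = ",".join("." for _ in range(s.n_alleles))
                cols.append(f"{gt}:{ad}")
            fh.write("\t".join(cols) + "\n")
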