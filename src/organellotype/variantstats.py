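"""Variant classification, Ts/Tv statistics and coding-effect annotation.

A minimal, self-contained effect predictor: each alt allele is substituted
into the spliced CDS of every overlapping gene, the affected codons are
translated, and the protein change is mapped onto a small effect vocabulary
with a fixed impact ladder (frameshift/nonsense -> high, missense/inframe ->
moderate, synonymous -> low, everything else -> modifier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from organellotype.genome import GeneModel, GenomeRef, revcomp
from organellotype.variants import VariantSite

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})

IMPACT_OF = {
    "frameshift": "high",
    "nonsense": "high",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "synonymous": "low",
    "non_coding": "modifier",
    "intergenic": "modifier",
}

# NCBI translation tables: 1 = standard (plant mitochondria), 11 = bacterial/
# plastid. Both share codon->aa assignments; they differ only in start codons,
# which this predictor does not use beyond the annotated ATG.
_CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_AA):
    _CODON_TABLE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _a


def translate(cds: str) -> str:
    """Translate a CDS (no stop trimming; unknown codons -> 'X')."""
    return "".join(
        _CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


class AnnotationError(ValueError):
    """CDS of a gene is inconsistent (length/phase) at a variant."""


@dataclass(frozen=True)
class SiteClass:
    kind: str  # SNP | InDel | MNP | mixed
    allelism: str  # biallelic | multiallelic


@dataclass(frozen=True)
class EffectCall:
    gene: str | None
    effect: str
    impact: str
    alt: str

    def __post_init__(self) -> None:
        if IMPACT_OF[self.effect] != self.impact:
            raise ValueError(f"impact {self.impact} inconsistent with {self.effect}")


def _alt_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "InDel"


def classify_site(v: VariantSite) -> SiteClass:
    """Classify a site as SNP/InDel/MNP (or mixed) and bi/multi-allelic."""
    kinds = {_alt_kind(v.ref, a) for a in v.alts}
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    allelism = "biallelic" if len(v.alts) == 1 else "multiallelic"
    return SiteClass(kind=kind, allelism=allelism)


def ts_tv_ratio(variants: list[VariantSite]) -> float:
    """Transitions over transversions among biallelic SNPs.

    Returns 0.0 when there are transversions but no transitions, and NaN
    when no biallelic SNP contributes a transversion or transition at all
    (including the all-transition case, where the ratio is unbounded).
    """
    ts = tv = 0
    for v in variants:
        cls = classify_site(v)
        if cls.kind != "SNP" or cls.allelism != "biallelic":
            continue
        if frozenset((v.ref, v.alts[0])) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return math.nan
    return ts / tv


def _cds_index(gene: GeneModel, gpos: int) -> int | None:
    """Map genomic 0-based position to phase-trimmed CDS coordinate, or None."""
    segs = sorted(gene.cds)
    offset = 0
    idx = None
    for s, e in segs:
        if s <= gpos < e:
            idx = offset + (gpos - s)
            break
        offset += e - s
    if idx is None:
        return None
    total = gene.cds_length()
    if gene.strand == "-":
        idx = total - 1 - idx
    idx -= gene.phase
    return idx if idx >= 0 else None


def _classify_substitution(cds: str, cds_alt: str) -> str:
    """Effect of an equal-length CDS substitution from the changed codons."""
    prot_ref = translate(cds)
    prot_alt = translate(cds_alt)
    if prot_alt == prot_ref:
        return "synonymous"
    for i, (a, b) in enumerate(zip(prot_ref, prot_alt)):
        if a == b:
            continue
        if b == "*" or a == "*":
            return "nonsense"  # stop gain / stop loss
        if i == 0 and a == "M":
            return "nonsense"  # start loss, folded into high impact
    return "missense"


def annotate_effect(
    v: VariantSite, genes: list[GeneModel], genome: GenomeRef
) -> list[EffectCall]:
    """One EffectCall per (overlapping gene, alt allele).

    Variants outside every gene footprint yield a single intergenic call per
    alt; inside a gene but outside its CDS yields non_coding. A gene whose
    CDS length (after phase trim) is not a codon multiple raises
    AnnotationError for that gene; other genes are still annotated.
    """
    start = v.pos - 1
    end = start + len(v.ref)
    calls: list[EffectCall] = []
    errors: list[AnnotationError] = []
    hit_genes = [g for g in genes if g.span[0] < end and start < g.span[1]]
    if not hit_genes:
        return [
            EffectCall(gene=None, effect="intergenic", impact="modifier", alt=a)
            for a in v.alts
        ]
    for g in hit_genes:
        in_cds = any(s < end and start < e for s, e in g.cds)
        for alt in v.alts:
            if not in_cds:
                calls.append(EffectCall(gene=g.gene_id, effect="non_coding",
                                        impact="modifier", alt=alt))
                continue
            if (g.cds_length() - g.phase) % 3 != 0:
                errors.append(AnnotationError(
                    f"gene {g.gene_id}: CDS length not a codon multiple"))
                continue
            delta = len(alt) - len(v.ref)
            if delta != 0:
                effect = "frameshift" if delta % 3 else "inframe_indel"
            else:
                effect = _substitution_effect(v, alt, g, genome)
            calls.append(EffectCall(gene=g.gene_id, effect=effect,
                                    impact=IMPACT_OF[effect], alt=alt))
    if errors and not calls:
        raise errors[0]
    return calls


def _substitution_effect(
    v: VariantSite, alt: str, gene: GeneModel, genome: GenomeRef
) -> str:
    """Effect of an equal-length substitution, computed codon-locally."""
    cds = gene.coding_sequence(genome.seq)
    # map every substituted genomic base into CDS space
    edits: dict[int, str] = {}
    for off in range(len(v.ref)):
        gpos = v.pos - 1 + off
        idx = _cds_index(gene, gpos)
        if idx is None:
            continue
        base = alt[off]
        edits[idx] = base if gene.strand == "+" else revcomp(base)
    if not edits:
        return "non_coding"
    # classify on the affected codons only, keeping position for start loss
    prot_changed = False
    for c in sorted({idx // 3 for idx in edits}):
        codon = cds[c * 3 : c * 3 + 3]
        if len(codon) < 3:
            continue
        mutated = list(codon)
        for idx, b in edits.items():
            if idx // 3 == c:
                mutated[idx % 3] = b
        a = _CODON_TABLE.get(codon, "X")
        b = _CODON_TABLE.get("".join(mutated), "X")
        if a == b:
            continue
        prot_changed = True
        if b == "*" or a == "*":
            return "nonsense"
        if c == 0 and a == "M":
            return "nonsense"
    return "missense" if prot_changed else "synonymous"


def annotate_variants(
    variants: list[VariantSite], genes: list[GeneModel], genome: GenomeRef
) -> list[list[EffectCall]]:
    """Annotate every variant; annotation errors degrade to non_coding."""
    out = []
    for v in variants:
        try:
            out.append(annotate_effect(v, genes, genome))
        except AnnotationError:
            out.append(
                [EffectCall(gene=None, effect="non_coding", impact="modifier", alt=a)
                 for a in v.alts]
            )
    return out


_IMPACT_RANK = {"high": 3, "moderate": 2, "low": 1, "modifier": 0}


def site_impact(calls: list[EffectCall]) -> str:
    """Highest impact among a site's per-(gene, alt) calls."""
    return max(calls, key=lambda c: _IMPACT_RANK[c.impact]).impact


@dataclass
class VariantSummary:
    totals: pd.Series
    per_gene: pd.DataFrame


def summarize(
    variants: list[VariantSite], effects: list[list[EffectCall]] | None = None
) -> VariantSummary:
    """Count sites by class, allelism, gene membership and impact per gene."""
    n_snp = n_indel = n_other = n_bi = n_multi = 0
    for v in variants:
        cls = classify_site(v)
        if cls.kind == "SNP":
            n_snp += 1
        elif cls.kind == "InDel":
            n_indel += 1
        else:
            n_other += 1
        if cls.allelism == "biallelic":
            n_bi += 1
        else:
            n_multi += 1
    totals = pd.Series(
        {
            "total_sites": len(variants),
            "snp_sites": n_snp,
            "indel_sites": n_indel,
            "other_sites": n_other,
            "biallelic_sites": n_bi,
            "multiallelic_sites": n_multi,
            "genic_sites": 0,
            "high_impact_sites": 0,
            "moderate_impact_sites": 0,
        },
        dtype=int,
    )
    gene_rows: dict[str, dict[str, int]] = {}
    if effects is not None:
        for calls in effects:
            genic = {c.gene for c in calls if c.gene is not None}
            if genic:
                totals["genic_sites"] += 1
            imp = site_impact(calls) if calls else "modifier"
            if imp == "high":
                totals["high_impact_sites"] += 1
            elif imp == "moderate":
                totals["moderate_impact_sites"] += 1
            # one increment per (gene, site): highest impact among the
            # site's calls for that gene
            best: dict[str, str] = {}
            for c in calls:
                if c.gene is None:
                    continue
                prev = best.get(c.gene)
                if prev is None or _IMPACT_RANK[c.impact] > _IMPACT_RANK[prev]:
                    best[c.gene] = c.impact
            for gene, imp in best.items():
                if imp in ("high", "moderate"):
                    row = gene_rows.setdefault(gene, {"high": 0, "moderate": 0})
                    row[imp] += 1
    per_gene = (
        pd.DataFrame.from_dict(gene_rows, orient="index")
        .rename_axis("gene")
        .sort_index()
        if gene_rows
        else pd.DataFrame(columns=["high", "moderate"]).rename_axis("gene")
    )
    return VariantSummary(totals=totals, per_gene=per_gene)
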