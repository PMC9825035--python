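"""Synthetic organelle references, accession panels and VCFs with known truth.

Every downstream stage is testable against the planted truth produced here:
references carry planted repeat pairs and gene models, panels draw accession
haplotypes i.i.d. from a skewed frequency vector with species-partitioned
haplotype sharing, and VCF emission models per-site read depths (Poisson),
sequencing error and designated heteroplasmic sites whose reference-allele
depth is binomial around a target RAF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from organellotype.genome import GeneModel, GenomeRef
from organellotype.variants import MISSING, VariantSite, write_vcf

DEFAULT_ERROR_RATE = 0.002

_STOPS = {"TAA", "TAG", "TGA"}


class PlacementError(RuntimeError):
    """Planted features cannot be placed without overlap."""


class CoordinateError(ValueError):
    """A position falls outside the genome."""


@dataclass
class RepeatSpec:
    """Planted repeat structure of a synthetic genome."""

    n_pairs: int = 0
    unit_length: int = 1000
    identity: float = 1.0
    inverted_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pairs and self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if not 0.0 <= self.inverted_fraction <= 1.0:
            raise ValueError("inverted_fraction must be in [0, 1]")

    def total_length(self) -> int:
        return 2 * self.n_pairs * self.unit_length


@dataclass
class PlantedRepeat:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    inverted: bool


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    sizes: list[int],
    occupied: list[tuple[int, int]],
    retries: int = 1000,
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals of the given sizes, or raise."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for idx, size in enumerate(sizes):
        ok = False
        for _ in range(retries):
            start = int(rng.integers(0, max(1, length - size)))
            iv = (start, start + size)
            if all(iv[1] <= s or e <= iv[0] for s, e in taken):
                taken.append(iv)
                placed.append(iv)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place interval {idx + 1}/{len(sizes)} of size {size}"
            )
    return placed


def _clean_cds(rng: np.random.Generator, length: int) -> str:
    """A CDS of the given length (multiple of 3): ATG ... internal sense
    codons ... stop."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    for _ in range(length // 3 - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def generate_reference(
    length: int,
    repeat_spec: RepeatSpec | None = None,
    gene_density: float = 0.1,
    seed: int = 0,
    name: str = "organelle",
    circular: bool = True,
) -> tuple[GenomeRef, list[PlantedRepeat]]:
    """Generate a reference with planted repeat pairs and gene models.

    ``gene_density`` is genes per kb. Returns the genome and the exact
    planted repeat coordinates (0-based half-open). Deterministic per seed.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    repeat_spec = repeat_spec or RepeatSpec()
    if repeat_spec.total_length() > length:
        raise ValueError("planted repeats exceed genome length")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))

    n_genes = int(round(gene_density * length / 1000))
    gene_sizes = [int(rng.integers(100, 301)) * 3 for _ in range(n_genes)]
    gene_ivs = _place_intervals(rng, length, gene_sizes, [])
    genes: list[GeneModel] = []
    for i, (s, e) in enumerate(gene_ivs):
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _clean_cds(rng, e - s)
        if strand == "-":
            from organellotype.genome import revcomp

            cds = revcomp(cds)
        seq[s:e] = list(cds)
        genes.append(GeneModel(gene_id=f"gene{i + 1}", strand=strand,
                               cds=[(s, e)], phase=0))

    sizes = [repeat_spec.unit_length] * (2 * repeat_spec.n_pairs)
    try:
        repeat_ivs = _place_intervals(rng, length, sizes, gene_ivs)
    except PlacementError as exc:
        raise PlacementError(f"repeat placement failed: {exc}") from exc
    planted: list[PlantedRepeat] = []
    for i in range(repeat_spec.n_pairs):
        a, b = repeat_ivs[2 * i], repeat_ivs[2 * i + 1]
        if a > b:
            a, b = b, a
        inverted = rng.random() < repeat_spec.inverted_fraction
        unit = "".join(seq[a[0] : a[1]])
        copy = unit
        if repeat_spec.identity < 1.0:
            copy = list(copy)
            n_mut = int(round((1.0 - repeat_spec.identity) * len(copy)))
            for p in rng.choice(len(copy), size=n_mut, replace=False):
                copy[p] = rng.choice([c for c in "ACGT" if c != copy[p]])
            copy = "".join(copy)
        if inverted:
            from organellotype.genome import revcomp

            copy = revcomp(copy)
        seq[b[0] : b[1]] = list(copy)
        planted.append(PlantedRepeat(interval_a=a, interval_b=b, inverted=inverted))
    genome = GenomeRef(name=name, seq="".join(seq), circular=circular, genes=genes)
    return genome, planted


@dataclass
class SiteDef:
    """Allele definitions of one polymorphic site (index 0 = REF)."""

    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + tuple(self.alts)


def design_sites(
    genome: GenomeRef,
    n_sites: int,
    seed: int = 0,
    p_indel: float = 0.15,
    p_multi: float = 0.1,
    min_spacing: int = 12,
    positions: list[int] | None = None,
) -> list[SiteDef]:
    """Choose positions and allele sets for polymorphic sites.

    Indel REF spans stay short (<= 7 bp) and positions keep min_spacing so
    reference spans never overlap.
    """
    rng = np.random.default_rng(seed)
    n = len(genome.seq)
    if positions is None:
        lo, hi = 10, n - 10
        grid = np.arange(lo, hi, min_spacing)
        if len(grid) < n_sites:
            raise ValueError("genome too short for requested site count")
        positions = sorted(rng.choice(grid, size=n_sites, replace=False).tolist())
    sites: list[SiteDef] = []
    for pos in positions:
        if not 1 <= pos <= n:
            raise CoordinateError(f"site position {pos} outside genome of length {n}")
        base = genome.seq[pos - 1]
        r = rng.random()
        if r < p_indel:
            if rng.random() < 0.5:  # deletion
                span = int(rng.integers(2, 8))
                ref = genome.seq[pos - 1 : pos - 1 + span]
                alts = (base,)
            else:  # insertion
                ins = _random_seq(rng, int(rng.integers(1, 7)))
                ref = base
                alts = (base + ins,)
        elif r < p_indel + p_multi:
            others = [c for c in "ACGT" if c != base]
            k = int(rng.integers(2, 4))
            alts = tuple(rng.choice(others, size=k, replace=False).tolist())
            ref = base
        else:
            ref = base
            alts = (str(rng.choice([c for c in "ACGT" if c != base])),)
        sites.append(SiteDef(pos=int(pos), ref=ref, alts=alts))
    return sites


@dataclass
class HetSiteSpec:
    """A designated heteroplasmic site: binomial AD around target_raf."""

    site_index: int
    target_raf: float
    depth: float | None = None  # mean depth; None = panel mean_depth
    alt_index: int = 1  # allele index receiving the non-reference reads

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_raf <= 1.0:
            raise ValueError("target RAF must be in [0, 1]")


DEFAULT_GEOGRAPHY = {
    # (country, region, province) rows with sampling weights, keyed by species
    "cultivated": [
        (("China", "NE", "Heilongjiang"), 0.25),
        (("China", "NE", "Jilin"), 0.15),
        (("China", "HS", "Shandong"), 0.15),
        (("China", "HS", "Henan"), 0.11),
        (("USA", "other", "NA"), 0.08),
        (("Japan", "other", "NA"), 0.05),
        (("South Korea", "other", "NA"), 0.03),
        (("Russia", "other", "NA"), 0.02),
        (("unknown", "unknown", "NA"), 0.16),
    ],
    "wild": [
        (("China", "NE", "Heilongjiang"), 0.45),
        (("China", "HS", "Shandong"), 0.25),
        (("South Korea", "other", "NA"), 0.15),
        (("Japan", "other", "NA"), 0.1),
        (("Russia", "other", "NA"), 0.05),
    ],
}


@dataclass
class PanelSpec:
    """Specification of a synthetic accession panel."""

    n_accessions: int
    haplotype_allele_matrix: np.ndarray  # (n_haplotypes, n_sites) allele indices
    haplotype_freqs: np.ndarray
    species_of_haplotype: list[str]  # 'wild' | 'cultivated' | 'shared'
    het_sites: list[HetSiteSpec] = field(default_factory=list)
    mean_depth: float = 60.0
    missing_rate: float = 0.0
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0
    geography: dict | None = None
    shared_cultivated_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.haplotype_allele_matrix = np.asarray(self.haplotype_allele_matrix,
                                                  dtype=np.int16)
        self.haplotype_freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if abs(self.haplotype_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype_freqs must sum to 1")
        if len(self.haplotype_freqs) != self.haplotype_allele_matrix.shape[0]:
            raise ValueError("freqs/matrix haplotype count mismatch")
        if len(self.species_of_haplotype) != self.haplotype_allele_matrix.shape[0]:
            raise ValueError("species labels/matrix haplotype count mismatch")
        for h in self.het_sites:
            if not 0 <= h.site_index < self.haplotype_allele_matrix.shape[1]:
                raise ValueError(f"het site index {h.site_index} out of range")


@dataclass
class PanelTruth:
    """Fully known ground truth of a simulated panel (JSON-serializable)."""

    accessions: list[str]
    haplotype_of: list[int]  # haplotype index per accession
    species: list[str]
    status: list[str]
    country: list[str]
    region: list[str]
    province: list[str]
    sites: list[SiteDef]
    haplotype_allele_matrix: np.ndarray
    het_sites: list[HetSiteSpec]
    het_raf: dict[int, list[float]]  # site_index -> per-accession target RAF
    missing_rate: float
    error_rate: float
    mean_depth: float
    contig: str
    contig_length: int

    def true_calls(self) -> np.ndarray:
        """(accessions x sites) planted allele indices."""
        return self.haplotype_allele_matrix[np.asarray(self.haplotype_of)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accessions": self.accessions,
            "haplotype_of": list(map(int, self.haplotype_of)),
            "species": self.species,
            "status": self.status,
            "country": self.country,
            "region": self.region,
            "province": self.province,
            "sites": [
                {"pos": s.pos, "ref": s.ref, "alts": list(s.alts)}
                for s in self.sites
            ],
            "haplotype_allele_matrix": self.haplotype_allele_matrix.tolist(),
            "het_sites": [asdict(h) for h in self.het_sites],
            "het_raf": {str(k): v for k, v in self.het_raf.items()},
            "missing_rate": self.missing_rate,
            "error_rate": self.error_rate,
            "mean_depth": self.mean_depth,
            "contig": self.contig,
            "contig_length": self.contig_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            accessions=d["accessions"],
            haplotype_of=d["haplotype_of"],
            species=d["species"],
            status=d["status"],
            country=d["country"],
            region=d["region"],
            province=d["province"],
            sites=[SiteDef(pos=s["pos"], ref=s["ref"], alts=tuple(s["alts"]))
                   for s in d["sites"]],
            haplotype_allele_matrix=np.asarray(d["haplotype_allele_matrix"],
                                               dtype=np.int16),
            het_sites=[HetSiteSpec(**h) for h in d["het_sites"]],
            het_raf={int(k): v for k, v in d["het_raf"].items()},
            missing_rate=d["missing_rate"],
            error_rate=d["error_rate"],
            mean_depth=d["mean_depth"],
            contig=d["contig"],
            contig_length=d["contig_length"],
        )


def simulate_panel(
    panel_spec: PanelSpec,
    sites: list[SiteDef],
    ref_genome: GenomeRef,
    accession_prefix: str = "acc",
) -> PanelTruth:
    """Draw a panel: haplotypes i.i.d. from haplotype_freqs, metadata per
    species, per-accession target RAFs at designated heteroplasmic sites."""
    n_sites = panel_spec.haplotype_allele_matrix.shape[1]
    if len(sites) != n_sites:
        raise ValueError("site list length does not match allele matrix")
    glen = len(ref_genome.seq)
    for s in sites:
        if not 1 <= s.pos <= glen or s.pos - 1 + len(s.ref) > glen:
            raise CoordinateError(f"site at pos {s.pos} outside genome ({glen} bp)")
        if ref_genome.seq[s.pos - 1 : s.pos - 1 + len(s.ref)] != s.ref:
            raise ValueError(f"REF mismatch at pos {s.pos}")
    if panel_spec.haplotype_allele_matrix.max(initial=0) >= min(
        len(s.alleles) for s in sites
    ):
        for j, s in enumerate(sites):
            col_max = int(panel_spec.haplotype_allele_matrix[:, j].max())
            if col_max >= len(s.alleles):
                raise ValueError(
                    f"allele index {col_max} invalid for site p.{s.pos} "
                    f"({len(s.alleles)} alleles)"
                )
    rng = np.random.default_rng(panel_spec.seed)
    n = panel_spec.n_accessions
    hap_of = rng.choice(len(panel_spec.haplotype_freqs), size=n,
                        p=panel_spec.haplotype_freqs)
    geography = panel_spec.geography or DEFAULT_GEOGRAPHY
    species, status, country, region, province = [], [], [], [], []
    for h in hap_of:
        label = panel_spec.species_of_haplotype[h]
        if label == "shared":
            label = ("cultivated"
                     if rng.random() < panel_spec.shared_cultivated_fraction
                     else "wild")
        species.append(label)
        if label == "cultivated":
            status.append("landrace" if rng.random() < 0.6 else "elite")
        else:
            status.append("wild")
        rows = geography[label]
        weights = np.array([w for _, w in rows], dtype=float)
        weights /= weights.sum()
        c, rgn, prov = rows[int(rng.choice(len(rows), p=weights))][0]
        country.append(c)
        region.append(rgn)
        province.append(prov)
    het_raf = {
        h.site_index: [float(h.target_raf)] * n for h in panel_spec.het_sites
    }
    width = len(str(n))
    return PanelTruth(
        accessions=[f"{accession_prefix}{i + 1:0{width}d}" for i in range(n)],
        haplotype_of=[int(h) for h in hap_of],
        species=species,
        status=status,
        country=country,
        region=region,
        province=province,
        sites=list(sites),
        haplotype_allele_matrix=panel_spec.haplotype_allele_matrix.copy(),
        het_sites=list(panel_spec.het_sites),
        het_raf=het_raf,
        missing_rate=panel_spec.missing_rate,
        error_rate=panel_spec.error_rate,
        mean_depth=panel_spec.mean_depth,
        contig=ref_genome.name,
        contig_length=glen,
    )


def emit_vcf(
    truth: PanelTruth,
    path: str | Path,
    mean_depth: float | None = None,
    seed: int = 0,
) -> None:
    """Write the panel as a sorted multi-sample VCF v4.2 with GT and AD.

    Homozygous calls concentrate AD on the true allele (Poisson total depth,
    small per-read error rate); designated heteroplasmic sites draw
    AD_ref ~ Binomial(depth, target RAF) and are emitted as 0/a het calls.
    """
    mean_depth = mean_depth if mean_depth is not None else truth.mean_depth
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(truth.accessions)
    calls = truth.true_calls()
    het_by_site = {h.site_index: h for h in truth.het_sites}
    sites_out: list[VariantSite] = []
    het_genotypes: dict[tuple[int, int], tuple[int, int]] = {}
    for j, sd in enumerate(truth.sites):
        n_alleles = len(sd.alleles)
        gts = np.full(n, MISSING, dtype=np.int16)
        ads = np.zeros((n, n_alleles), dtype=np.int64)
        het = het_by_site.get(j)
        depth_mean = (het.depth if het and het.depth else mean_depth)
        depths = rng.poisson(depth_mean, size=n)
        missing_draw = rng.random(n) < truth.missing_rate
        for i in range(n):
            if missing_draw[i]:
                continue
            depth = int(depths[i])
            if het is not None:
                raf = truth.het_raf[j][i]
                ad_ref = int(rng.binomial(depth, raf))
                ads[i, 0] = ad_ref
                ads[i, het.alt_index] = depth - ad_ref
                het_genotypes[(j, i)] = (0, het.alt_index)
                # GT for haplotyping collapses to majority allele downstream
                gts[i] = 0 if ad_ref * 2 > depth else het.alt_index
            else:
                t = int(calls[i, j])
                n_err = (int(rng.binomial(depth, truth.error_rate))
                         if truth.error_rate > 0 else 0)
                n_err = min(n_err, depth)
                ads[i, t] = depth - n_err
                if n_err and n_alleles > 1:
                    others = [a for a in range(n_alleles) if a != t]
                    spread = rng.multinomial(n_err, [1 / len(others)] * len(others))
                    for a, c in zip(others, spread):
                        ads[i, a] += int(c)
                gts[i] = t
        sites_out.append(
            VariantSite(contig=truth.contig, pos=sd.pos, ref=sd.ref,
                        alts=sd.alts, genotypes=gts, allele_depths=ads)
        )
    write_vcf(
        path,
        truth.accessions,
        sites_out,
        contigs={truth.contig: truth.contig_length},
        het_genotypes=het_genotypes,
    )


def write_metadata_tsv(truth: PanelTruth, path: str | Path) -> None:
    """Accession metadata table (TSV) matching the panel truth."""
    with open(path, "w") as fh:
        fh.write("accession\tspecies\tstatus\tcountry\tregion\tprovince\n")
        for i, acc in enumerate(truth.accessions):
            fh.write(
                f"{acc}\t{truth.species[i]}\t{truth.status[i]}\t"
                f"{truth.country[i]}\t{truth.region[i]}\t{truth.province[i]}\n"
            )


def paper_like_panel_spec(
    n_accessions: int = 1000,
    n_sites: int = 30,
    n_haplotypes: int = 12,
    seed: int = 0,
    **kwargs,
) -> PanelSpec:
    """A panel with strongly skewed haplotype frequencies and
    species-partitioned sharing, shaped like real resequencing panels.

    The top two haplotypes take ~72% and ~18% of the cultivated pool; a few
    haplotypes are wild-only and a couple are shared across species.
    """
    rng = np.random.default_rng(seed)
    # heteroplasmy is orthogonal to haplotype: designated het sites stay
    # monomorphic in the haplotype matrix (mixed AD only)
    frozen = {h.site_index for h in (kwargs.get("het_sites") or [])}
    free = [j for j in range(n_sites) if j not in frozen]
    if len(free) < 2:
        raise ValueError("too few non-heteroplasmic sites for distinct haplotypes")
    # distinct haplotype vectors: mutate a backbone progressively
    matrix = np.zeros((n_haplotypes, n_sites), dtype=np.int16)
    for h in range(1, n_haplotypes):
        matrix[h] = matrix[h - 1]
        n_flip = int(rng.integers(1, 4))
        flips = rng.choice(free, size=min(n_flip, len(free)), replace=False)
        for f in flips:
            matrix[h, f] = 1 - matrix[h, f]
        while np.any(np.all(matrix[:h] == matrix[h], axis=1)):
            extra = int(rng.choice(free))
            matrix[h, extra] = 1 - matrix[h, extra]
    # skewed frequencies: two dominant cultivated, tail shared/wild
    raw = np.array([0.717, 0.181] + [1.0] * (n_haplotypes - 2))
    tail = 1.0 - raw[0] - raw[1]
    raw[2:] = tail * (rng.dirichlet([1.5] * (n_haplotypes - 2)))
    raw /= raw.sum()
    species = ["cultivated", "cultivated"]
    for h in range(2, n_haplotypes):
        species.append("shared" if h < 4 else ("wild" if h % 2 else "cultivated"))
    return PanelSpec(
        n_accessions=n_accessions,
        haplotype_allele_matrix=matrix,
        haplotype_freqs=raw,
        species_of_haplotype=species,
        seed=seed,
        **kwargs,
    )
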