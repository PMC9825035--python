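"""Reference-allele-frequency (RAF) analysis of allele depths.

At designated sites, each accession's RAF is ad_ref/(ad_ref + ad_alt) when
the combined depth reaches min_depth; intermediate RAFs flag
heteroplasmy-like mixed signal. Strata are compared with a two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median

import pandas as pd
from scipy.stats import mannwhitneyu

from organellotype.variants import VariantSite, read_vcf

DEFAULT_MIN_DEPTH = 10
DEFAULT_HET_BAND = (0.05, 0.95)


@dataclass(frozen=True)
class SiteQuery:
    """One requested site: position, REF, the designated ALT, and a label."""

    pos: int
    ref: str
    alt: str
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label or f"p.{self.pos} ({self.ref} > {self.alt})"


@dataclass
class RAFRecord:
    accession: str
    site: str
    ad_ref: int
    ad_alt: int
    raf: float | None  # None when depth < min_depth

    def __post_init__(self) -> None:
        if self.raf is not None and not 0.0 <= self.raf <= 1.0:
            raise ValueError(f"RAF {self.raf} out of [0, 1]")


@dataclass
class SiteHetProfile:
    site: str
    median_raf: float
    fraction_heterozygous: float
    n_defined: int


class SiteLookupError(KeyError):
    """Requested sites absent from the VCF."""


def raf_from_site(
    site: VariantSite, alt: str, accessions: list[str], site_name: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[RAFRecord]:
    """RAF records for one VariantSite against one designated alt allele."""
    if site.allele_depths is None:
        raise ValueError(f"site {site_name} has no AD field")
    try:
        alt_idx = site.alleles.index(alt)
    except ValueError:
        raise SiteLookupError(f"alt {alt!r} not among alleles at {site_name}")
    records = []
    for i, acc in enumerate(accessions):
        ad_ref = int(site.allele_depths[i, 0])
        ad_alt = int(site.allele_depths[i, alt_idx])
        depth = ad_ref + ad_alt
        raf = ad_ref / depth if depth >= min_depth else None
        records.append(RAFRecord(accession=acc, site=site_name,
                                 ad_ref=ad_ref, ad_alt=ad_alt, raf=raf))
    return records


def compute_raf(
    vcf_path: str | Path,
    sites: list[SiteQuery],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[RAFRecord]:
    """One RAFRecord per (accession, requested site) from a VCF with AD."""
    accessions, vcf_sites = read_vcf(vcf_path)
    by_pos = {(s.pos, s.ref): s for s in vcf_sites}
    missing = [q.name for q in sites if (q.pos, q.ref) not in by_pos]
    if missing:
        raise SiteLookupError(f"sites absent from VCF: {', '.join(missing)}")
    records: list[RAFRecord] = []
    for q in sites:
        site = by_pos[(q.pos, q.ref)]
        records.extend(raf_from_site(site, q.alt, accessions, q.name, min_depth))
    return records


def site_profile(
    records: list[RAFRecord],
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> SiteHetProfile:
    """Median RAF and heterozygous fraction over defined records of one site."""
    sites = {r.site for r in records}
    if len(sites) != 1:
        raise ValueError(f"records span {len(sites)} sites; expected one")
    defined = [r.raf for r in records if r.raf is not None]
    lo, hi = het_band
    if not defined:
        return SiteHetProfile(site=sites.pop(), median_raf=float("nan"),
                              fraction_heterozygous=0.0, n_defined=0)
    frac_het = sum(1 for r in defined if lo < r < hi) / len(defined)
    return SiteHetProfile(
        site=sites.pop(),
        median_raf=float(median(defined)),
        fraction_heterozygous=frac_het,
        n_defined=len(defined),
    )


@dataclass
class StrataComparison:
    site: str
    n: dict[str, int]
    medians: dict[str, float]
    statistic: float | None
    p_value: float | None
    flagged: list[str]  # strata too small to test (n < 3)


def compare_strata(
    records: list[RAFRecord],
    grouping: dict[str, str],
    min_n: int = 3,
) -> StrataComparison:
    """Two-sided Wilcoxon rank-sum comparison of defined RAFs across strata.

    ``grouping`` maps accession -> stratum label. The test runs when exactly
    two strata reach min_n defined records; smaller strata are flagged and
    excluded. Medians are reported for every stratum regardless.
    """
    sites = {r.site for r in records}
    if len(sites) != 1:
        raise ValueError("compare_strata expects records from a single site")
    by_stratum: dict[str, list[float]] = {}
    for r in records:
        stratum = grouping.get(r.accession)
        if stratum is None or r.raf is None:
            continue
        by_stratum.setdefault(stratum, []).append(r.raf)
    n = {s: len(v) for s, v in by_stratum.items()}
    medians = {s: float(median(v)) if v else float("nan")
               for s, v in by_stratum.items()}
    flagged = sorted(s for s, c in n.items() if c < min_n)
    testable = sorted(s for s, c in n.items() if c >= min_n)
    statistic = p_value = None
    if len(testable) == 2:
        res = mannwhitneyu(
            by_stratum[testable[0]], by_stratum[testable[1]],
            alternative="two-sided",
        )
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return StrataComparison(site=sites.pop(), n=n, medians=medians,
                            statistic=statistic, p_value=p_value, flagged=flagged)


def read_sites_tsv(path: str | Path) -> list[SiteQuery]:
    """Sites file: TSV with columns pos, ref, alt and optional label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"sites file must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(SiteQuery(pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                             label=row.get("label") if "label" in df.columns else None))
    return out


def write_raf_tsv(records: list[RAFRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tsite\tad_ref\tad_alt\traf\n")
        for r in records:
            raf = f"{r.raf:.6g}" if r.raf is not None else "NA"
            fh.write(f"{r.accession}\t{r.site}\t{r.ad_ref}\t{r.ad_alt}\t{raf}\n")


def write_profiles_tsv(profiles: list[SiteHetProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tmedian_raf\tfraction_heterozygous\tn_defined\n")
        for p in profiles:
            fh.write(
                f"{p.site}\t{p.median_raf:.6g}\t"
                f"{p.fraction_heterozygous:.6g}\t{p.n_defined}\n"
            )
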