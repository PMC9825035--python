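"""Joint cytoplasm typing and geographic/diversity summaries.

Combines chloroplast (CT) and mitochondrial (MT) haplotype assignments into
joint cytoplasm types ("CT1/MT1"), tabulates their distribution across
metadata strata with half-up percentage rounding, and summarizes haplotype
sharing between wild and cultivated accessions and per-category diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from organellotype.haplotyper import GroupAssignment, HaplotypeTable

METADATA_KEYS = ("species", "status", "country", "region", "province")

UNKNOWN = "unknown"


@dataclass
class CytoplasmAssignment:
    accession: str
    ct: str
    mt: str
    ctg: str | None = None
    mtg: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def joint(self) -> str:
        return f"{self.ct}/{self.mt}"

    @property
    def joint_group(self) -> str:
        return f"{self.ctg}/{self.mtg}"


@dataclass
class JoinResult:
    assignments: list[CytoplasmAssignment]
    n_excluded_ct: int
    n_excluded_mt: int

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_ct + self.n_excluded_mt


def join_assignments(
    ct_table: HaplotypeTable,
    mt_table: HaplotypeTable,
    meta: pd.DataFrame | None = None,
    ct_groups: GroupAssignment | None = None,
    mt_groups: GroupAssignment | None = None,
) -> JoinResult:
    """Inner-join CT and MT assignments on accession id.

    ``meta`` is indexed by accession with columns from METADATA_KEYS; missing
    metadata becomes the explicit "unknown" category. Accessions unassigned
    in either organelle are excluded and counted per organelle (an accession
    missing from both tables counts toward CT).
    """
    universe = sorted(
        set(ct_table.assignment) | set(ct_table.unassigned)
        | set(mt_table.assignment) | set(mt_table.unassigned)
    )
    if meta is not None and meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate accession ids in metadata: {dup[:5]}")
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate accession ids")
    out: list[CytoplasmAssignment] = []
    n_ct = n_mt = 0
    for acc in universe:
        ct = ct_table.assignment.get(acc)
        mt = mt_table.assignment.get(acc)
        if ct is None:
            n_ct += 1
            continue
        if mt is None:
            n_mt += 1
            continue
        md = {}
        for key in METADATA_KEYS:
            if meta is not None and acc in meta.index and key in meta.columns:
                val = meta.at[acc, key]
                md[key] = UNKNOWN if pd.isna(val) or val == "" else str(val)
            else:
                md[key] = UNKNOWN
        out.append(
            CytoplasmAssignment(
                accession=acc,
                ct=ct,
                mt=mt,
                ctg=ct_groups.group_of_haplotype.get(ct) if ct_groups else None,
                mtg=mt_groups.group_of_haplotype.get(mt) if mt_groups else None,
                metadata=md,
            )
        )
    return JoinResult(assignments=out, n_excluded_ct=n_ct, n_excluded_mt=n_mt)


def round_percent(count: int, total: int) -> float:
    """Percentage count/total rounded half-up to one decimal (69.2-style)."""
    if total == 0:
        return float("nan")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _type_of(a: CytoplasmAssignment, level: str, organelle: str = "CT") -> str:
    if level == "joint":
        return a.joint
    if level == "group":
        return a.joint_group
    if level == "haplotype":
        return a.ct if organelle == "CT" else a.mt
    raise ValueError(f"unknown level {level!r}")


@dataclass
class DistributionTable:
    counts: pd.DataFrame  # categories x types, with a "total" row and column
    percent: pd.DataFrame  # same shape minus the total column


def distribution_table(
    assignments: list[CytoplasmAssignment],
    by: str | None = None,
    level: str = "joint",
    organelle: str = "CT",
) -> DistributionTable:
    """Counts and half-up-rounded percentages of cytoplasm types per category.

    ``by`` is a metadata key (None = one "all" category); ``level`` selects
    joint types (CTx/MTy), group combinations (CTGx/MTGy) or single-organelle
    haplotypes. Percentages are per category row; a totals row is appended.
    """
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        cat = a.metadata.get(by, UNKNOWN) if by else "all"
        typ = _type_of(a, level, organelle)
        rows.setdefault(cat, {})
        rows[cat][typ] = rows[cat].get(typ, 0) + 1
    types = sorted({t for r in rows.values() for t in r})
    cats = sorted(rows)
    counts = pd.DataFrame(
        [[rows[c].get(t, 0) for t in types] for c in cats],
        index=pd.Index(cats, name=by or "category"),
        columns=types,
        dtype=int,
    )
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)
    percent = pd.DataFrame(index=counts.index, columns=types, dtype=float)
    for cat in counts.index:
        tot = int(counts.at[cat, "total"])
        for t in types:
            percent.at[cat, t] = round_percent(int(counts.at[cat, t]), tot)
    return DistributionTable(counts=counts, percent=percent)


@dataclass
class SharedHaplotypes:
    organelle: str
    shared: set[str]
    n_cultivated_carriers: int
    n_wild_carriers: int


def shared_haplotypes(
    assignments: list[CytoplasmAssignment], organelle: str = "CT"
) -> SharedHaplotypes:
    """Haplotypes observed in both wild and cultivated accessions, with the
    number of carriers of any shared haplotype in each species class."""
    key = "ct" if organelle == "CT" else "mt"
    by_species: dict[str, set[str]] = {"cultivated": set(), "wild": set()}
    for a in assignments:
        sp = a.metadata.get("species", UNKNOWN)
        if sp in by_species:
            by_species[sp].add(getattr(a, key))
    shared = by_species["cultivated"] & by_species["wild"]
    n_cult = sum(
        1 for a in assignments
        if a.metadata.get("species") == "cultivated" and getattr(a, key) in shared
    )
    n_wild = sum(
        1 for a in assignments
        if a.metadata.get("species") == "wild" and getattr(a, key) in shared
    )
    return SharedHaplotypes(
        organelle=organelle,
        shared=shared,
        n_cultivated_carriers=n_cult,
        n_wild_carriers=n_wild,
    )


def haplotype_diversity(freq_counts: list[int]) -> float:
    """Unbiased haplotype diversity H = n/(n-1) * (1 - sum p_i^2).

    Defined as 0 for n < 2 (a single observation carries no diversity).
    """
    n = sum(freq_counts)
    if n < 2:
        return 0.0
    s = sum((c / n) ** 2 for c in freq_counts)
    return n / (n - 1) * (1.0 - s)


def diversity_summary(
    assignments: list[CytoplasmAssignment],
    by: str | None = None,
    level: str = "haplotype",
    organelle: str = "CT",
) -> pd.DataFrame:
    """Per-category distinct-haplotype counts and haplotype diversity H."""
    groups: dict[str, list[str]] = {}
    for a in assignments:
        cat = a.metadata.get(by, UNKNOWN) if by else "all"
        groups.setdefault(cat, []).append(_type_of(a, level, organelle))
    records = []
    for cat in sorted(groups):
        types = groups[cat]
        counts = pd.Series(types).value_counts()
        records.append(
            {
                (by or "category"): cat,
                "n": len(types),
                "n_haplotypes": len(counts),
                "diversity": haplotype_diversity(counts.tolist()),
            }
        )
    return pd.DataFrame.from_records(records).set_index(by or "category")


def contingency_test(
    assignments: list[CytoplasmAssignment],
    by: str,
    types: list[str],
    level: str = "haplotype",
    organelle: str = "CT",
) -> tuple[float, float]:
    """Chi-square contingency test of type composition across categories.

    Utility only; returns (statistic, p-value).
    """
    from scipy.stats import chi2_contingency

    table: dict[str, dict[str, int]] = {}
    for a in assignments:
        typ = _type_of(a, level, organelle)
        if typ not in types:
            continue
        cat = a.metadata.get(by, UNKNOWN)
        table.setdefault(cat, {t: 0 for t in types})
        table[cat][typ] += 1
    df = pd.DataFrame(table).T
    res = chi2_contingency(df.values)
    return float(res.statistic), float(res.pvalue)
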