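"""Rare-allele sharing ancestry analysis.

A low-coverage sample is screened at a panel of rare variants (total
allele count 1..9 in a modern reference panel).  A carrier call requires
at least `min_support` reads of the rare allele and is always treated as
heterozygous.  Sharing counts with each reference population, stratified
by panel allele count, yield ratio curves, the NED/(NED+IBS)-style
projection over low-count strata, and ancestry fractions anchored at two
group means (0% = indigenous anchor, 100% = immigrant anchor, no
clipping).  Errors propagate from square-root counting statistics,
treating numerator and denominator as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PanelSite",
    "CarrierCalls",
    "SharingTable",
    "ProjectionResult",
    "call_carriers",
    "build_sharing",
    "ratio_curve",
    "projection",
    "ancestry_fraction",
    "ancestry_fraction_se",
    "group_summary",
    "resample_haploid",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_counts_tsv",
    "write_read_counts_tsv",
    "sharing_table_tsv",
]

MAX_PANEL_COUNT = 9


@dataclass(frozen=True)
class PanelSite:
    chrom: str
    pos: int  # 1-based position
    ref: str
    alt: str  # the rare allele
    counts: tuple  # per-population rare-allele counts, panel population order
    total: int

    def __post_init__(self):
        if self.total != sum(self.counts):
            raise ValueError("total != sum of per-population counts")
        if not 1 <= self.total <= MAX_PANEL_COUNT:
            raise ValueError(f"panel allele count {self.total} outside 1..9")

    @property
    def key(self):
        return (self.chrom, self.pos)


@dataclass
class Panel:
    populations: tuple
    sites: dict  # key -> PanelSite

    def __len__(self):
        return len(self.sites)


def make_panel(populations, sites) -> Panel:
    return Panel(tuple(populations), {s.key: s for s in sites})


@dataclass
class CarrierCalls:
    sample_id: str
    sites: set  # keys of panel sites where the rare allele was called
    ignored: int = 0  # read-count records at non-panel sites


@dataclass
class SharingTable:
    """Shared-allele counts: population x panel allele count (1..9).

    `moments[p, q, s-1]` accumulates the per-site cross products
    `sum_i c_p,i * c_q,i` over called sites in stratum s; they feed the
    site-clustered error propagation in :func:`projection` (alleles at
    one called site enter together, so the sampling unit is the site,
    not the allele).
    """

    sample_id: str
    populations: tuple
    counts: np.ndarray  # (n_pops, 9); column s-1 is stratum s
    moments: np.ndarray | None = None

    def stratum(self, pop: str, s: int) -> int:
        return int(self.counts[self.populations.index(pop), s - 1])


@dataclass
class ProjectionResult:
    sample_id: str
    f: float
    se: float
    ancestry_pct: float | None = None
    ancestry_se: float | None = None


def call_carriers(read_counts: dict, panel: Panel, min_support: int = 2,
                  sample_id: str = "sample") -> CarrierCalls:
    """Carrier at a panel site iff >= min_support reads show the rare allele."""
    sites = set()
    ignored = 0
    for key, (rare, total) in read_counts.items():
        if rare < 0 or total < 0 or rare > total:
            raise ValueError(f"invalid read counts {rare}/{total} at {key}")
        if key not in panel.sites:
            ignored += 1
            continue
        if rare >= min_support:
            sites.add(key)
    return CarrierCalls(sample_id=sample_id, sites=sites, ignored=ignored)


def build_sharing(calls: CarrierCalls, panel: Panel) -> SharingTable:
    """Accumulate panel per-population allele counts over called sites,
    stratified by the site's total panel allele count."""
    P = len(panel.populations)
    counts = np.zeros((P, MAX_PANEL_COUNT), dtype=np.int64)
    moments = np.zeros((P, P, MAX_PANEL_COUNT), dtype=np.int64)
    for key in calls.sites:
        site = panel.sites.get(key)
        if site is None:
            raise ValueError(f"called site {key} not in panel")
        c = np.asarray(site.counts, dtype=np.int64)
        counts[:, site.total - 1] += c
        moments[:, :, site.total - 1] += np.outer(c, c)
    return SharingTable(calls.sample_id, panel.populations, counts, moments)


def ratio_curve(t: SharingTable, num_pop: str, den_pop: str):
    """Per-stratum sharing ratio num/den with sqrt-count error propagation.

    Returns a list of dicts; strata with a zero denominator are omitted
    and flagged.
    """
    ni = t.populations.index(num_pop)
    di = t.populations.index(den_pop)
    out = []
    for s in range(1, MAX_PANEL_COUNT + 1):
        a = float(t.counts[ni, s - 1])
        b = float(t.counts[di, s - 1])
        if b == 0:
            out.append({"stratum": s, "omitted": True})
            continue
        r = a / b
        se = r * math.sqrt(1.0 / a + 1.0 / b) if a > 0 else float("nan")
        out.append({"stratum": s, "ratio": r, "se": se, "omitted": False})
    return out


def projection(
    t: SharingTable, num_pop: str, den_pop: str, max_stratum: int = 5
) -> ProjectionResult:
    """f = NED/(NED+IBS)-style projection over strata 1..max_stratum.

    The standard error treats the called *site* as the sampling unit
    (its alleles enter the counts together):
    ``var(f) = sum_i (a_i - f T_i)^2 / (sum_i T_i)^2`` with
    ``a_i`` the numerator alleles and ``T_i`` the numerator+denominator
    alleles at called site i, computed from the table's cross moments.
    For sites carrying a single shared allele this reduces exactly to
    the binomial rule ``sqrt(f (1-f) / (NED+IBS))``, which is also the
    fallback when the moments are unavailable.
    """
    ni = t.populations.index(num_pop)
    di = t.populations.index(den_pop)
    ned = float(t.counts[ni, :max_stratum].sum())
    ibs = float(t.counts[di, :max_stratum].sum())
    tot = ned + ibs
    if tot <= 0:
        raise ValueError("zero total sharing count in projection")
    f = ned / tot
    if t.moments is not None:
        m = t.moments[:, :, :max_stratum].sum(axis=2)
        sum_a2 = float(m[ni, ni])
        sum_aT = float(m[ni, ni] + m[ni, di])
        sum_T2 = float(m[ni, ni] + 2 * m[ni, di] + m[di, di])
        var = max(sum_a2 - 2 * f * sum_aT + f * f * sum_T2, 0.0) / tot**2
        se = math.sqrt(var)
    else:
        se = math.sqrt(max(f * (1.0 - f), 0.0) / tot)
    return ProjectionResult(t.sample_id, f, se)


def ancestry_fraction(f: float, iron_mean: float, saxon_mean: float) -> float:
    """Percentage position on the anchor axis: 0% at the indigenous (Iron
    Age) anchor mean, 100% at the immigrant (Anglo-Saxon era) anchor mean.
    Values are not clipped."""
    if saxon_mean == iron_mean:
        raise ValueError("anchor means are equal; fraction undefined")
    return 100.0 * (f - iron_mean) / (saxon_mean - iron_mean)


def ancestry_fraction_se(
    f: float,
    se_f: float,
    iron_mean: float,
    se_iron: float,
    saxon_mean: float,
    se_saxon: float,
) -> float:
    """Propagated s.e. of the ancestry percentage (independent errors)."""
    d = saxon_mean - iron_mean
    if d == 0:
        raise ValueError("anchor means are equal")
    w_iron = (saxon_mean - f) / d
    w_saxon = (f - iron_mean) / d
    var = (se_f**2 + (w_iron * se_iron) ** 2 + (w_saxon * se_saxon) ** 2) / d**2
    return 100.0 * math.sqrt(var)


def group_summary(fractions: dict, exclusions=()) -> dict:
    """Mean and min-max spread of per-sample fractions, minus exclusions."""
    excl = set(exclusions)
    included = {s: v for s, v in fractions.items() if s not in excl}
    if not included:
        raise ValueError("no samples left after exclusions")
    vals = np.asarray(list(included.values()), dtype=float)
    return {
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": len(included),
        "excluded": sorted(excl & set(fractions)),
        "per_sample": dict(included),
    }


def resample_haploid(frequencies: dict, seed: int, sample_id: str = "pseudo") -> CarrierCalls:
    """Pseudo-haploid individual: carrier at each site with probability equal
    to the population's rare-allele frequency (sampling with replacement)."""
    rng = np.random.default_rng(seed)
    sites = set()
    for key in sorted(frequencies):
        fr = frequencies[key]
        if not 0.0 <= fr <= 1.0:
            raise ValueError(f"frequency {fr} outside [0, 1] at {key}")
        if rng.random() < fr:
            sites.add(key)
    return CarrierCalls(sample_id=sample_id, sites=sites)


def panel_frequencies(panel: Panel, pop: str, pop_size: int) -> dict:
    """Per-site rare-allele frequency of `pop` given its haploid panel size."""
    i = panel.populations.index(pop)
    return {k: s.counts[i] / pop_size for k, s in panel.sites.items()}


def estimate_ancestry(
    panel: Panel,
    read_counts: dict,
    groups: dict,
    num_pop: str,
    den_pop: str,
    indigenous_group: str,
    immigrant_group: str,
    min_support: int = 2,
    max_stratum: int = 5,
    exclusions=(),
) -> dict:
    """Full sharing pipeline: carrier calls -> sharing tables -> projection
    -> ancestry fractions anchored at two group means.

    `read_counts` maps sample -> {site: (rare_reads, total_reads)};
    `groups` assigns each sample to a group; the anchor groups' mean
    projections define 0% and 100%.  Anchor means carry the standard
    error of the mean over their samples (empirical spread).  Returns per
    sample ProjectionResult plus anchor statistics.
    """
    projections = {}
    for sample, rc in read_counts.items():
        calls = call_carriers(rc, panel, min_support, sample_id=sample)
        table = build_sharing(calls, panel)
        projections[sample] = projection(table, num_pop, den_pop, max_stratum)

    def anchor(group):
        fs = [
            p.f
            for s, p in projections.items()
            if groups.get(s) == group and s not in set(exclusions)
        ]
        if not fs:
            raise ValueError(f"no samples in anchor group {group!r}")
        fs = np.asarray(fs)
        se = fs.std(ddof=1) / math.sqrt(len(fs)) if len(fs) > 1 else 0.0
        return float(fs.mean()), float(se)

    iron_mean, iron_se = anchor(indigenous_group)
    saxon_mean, saxon_se = anchor(immigrant_group)
    for p in projections.values():
        p.ancestry_pct = ancestry_fraction(p.f, iron_mean, saxon_mean)
        p.ancestry_se = ancestry_fraction_se(
            p.f, p.se, iron_mean, iron_se, saxon_mean, saxon_se
        )
    return {
        "projections": projections,
        "anchors": {
            indigenous_group: (iron_mean, iron_se),
            immigrant_group: (saxon_mean, saxon_se),
        },
    }


# ----------------------------------------------------------------------
# TSV formats


def write_panel_tsv(panel: Panel) -> str:
    header = ["chrom", "pos", "ref", "alt"] + list(panel.populations) + ["total"]
    lines = ["\t".join(header)]
    for key in sorted(panel.sites):
        s = panel.sites[key]
        lines.append(
            "\t".join(
                [s.chrom, str(s.pos), s.ref, s.alt]
                + [str(c) for c in s.counts]
                + [str(s.total)]
            )
        )
    return "\n".join(lines) + "\n"


def read_panel_tsv(text: str) -> Panel:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    pops = tuple(header[4:-1])
    sites = []
    for ln in lines[1:]:
        f = ln.split("\t")
        counts = tuple(int(c) for c in f[4 : 4 + len(pops)])
        sites.append(PanelSite(f[0], int(f[1]), f[2], f[3], counts, int(f[-1])))
    return make_panel(pops, sites)


def write_read_counts_tsv(read_counts: dict) -> str:
    lines = ["\t".join(["chrom", "pos", "rare_reads", "total_reads"])]
    for (chrom, pos) in sorted(read_counts):
        rare, total = read_counts[(chrom, pos)]
        lines.append(f"{chrom}\t{pos}\t{rare}\t{total}")
    return "\n".join(lines) + "\n"


def read_counts_tsv(text: str) -> dict:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = {}
    for ln in lines[1:]:
        chrom, pos, rare, total = ln.split("\t")
        out[(chrom, int(pos))] = (int(rare), int(total))
    return out


def sharing_table_tsv(tables) -> str:
    """Long-format TSV (sample, population, stratum, count)."""
    lines = ["\t".join(["sample", "population", "stratum", "count"])]
    for t in tables:
        for pi, pop in enumerate(t.populations):
            for s in range(1, MAX_PANEL_COUNT + 1):
                lines.append(f"{t.sample_id}\t{pop}\t{s}\t{t.counts[pi, s - 1]}")
    return "\n".join(lines) + "\n"
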