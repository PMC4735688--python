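"""Joint rare-allele site-pattern histograms.

A *site pattern* is the vector of derived-allele counts per population at
one genomic site.  A :class:`PatternHistogram` counts how many sites show
each tracked pattern (total derived count between 1 and ``max_m``), plus a
monomorphic class, an overflow class (total derived count above ``max_m``)
and the callable genome length ``total_sites``.  The class-conservation
invariant ``monomorphic + overflow + sum(tracked) == total_sites`` holds
after every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleConfig",
    "PatternHistogram",
    "vcf_to_histogram",
    "read_histogram",
    "write_histogram",
    "restrict_to_shared",
    "merge_histograms",
    "read_mask_bed",
]

# A site pattern is represented as a tuple of per-population derived counts.
SitePattern = tuple


@dataclass(frozen=True)
class SampleConfig:
    """Fixed population order and per-population haploid sample sizes."""

    populations: tuple
    sizes: tuple

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        if len(self.populations) != len(self.sizes):
            raise ValueError("populations and sizes must have equal length")
        if any(n < 1 for n in self.sizes):
            raise ValueError("haploid sizes must be >= 1")

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass
class PatternHistogram:
    config: SampleConfig
    max_m: int = 4
    counts: dict = field(default_factory=dict)
    monomorphic: int = 0
    overflow: int = 0
    total_sites: int = 0
    meta: dict = field(default_factory=dict)

    def check(self) -> None:
        """Raise if the class-conservation invariant is violated."""
        tracked = sum(self.counts.values())
        if self.monomorphic < 0 or self.overflow < 0 or any(
            c < 0 for c in self.counts.values()
        ):
            raise ValueError("negative class count")
        if self.monomorphic + self.overflow + tracked != self.total_sites:
            raise ValueError(
                "class conservation violated: "
                f"{self.monomorphic} + {self.overflow} + {tracked} != "
                f"{self.total_sites}"
            )
        K = self.config.n_pops
        for pat in self.counts:
            if len(pat) != K:
                raise ValueError(f"pattern {pat} has wrong arity (expected {K})")
            if any(m < 0 or m > n for m, n in zip(pat, self.config.sizes)):
                raise ValueError(f"pattern {pat} exceeds sample sizes")
            if not 1 <= sum(pat) <= self.max_m:
                raise ValueError(f"pattern {pat} outside tracked range")

    def add_pattern(self, pattern, count: int = 1) -> None:
        """Tally `count` sites with the given derived-count vector.

        Monomorphic and overflowing patterns are routed to their classes;
        total_sites grows by `count`.
        """
        pattern = tuple(int(m) for m in pattern)
        s = sum(pattern)
        if s == 0:
            self.monomorphic += count
        elif s > self.max_m:
            self.overflow += count
        else:
            self.counts[pattern] = self.counts.get(pattern, 0) + count
        self.total_sites += count

    @classmethod
    def from_patterns(cls, config, max_m, patterns, total_sites) -> "PatternHistogram":
        """Build from an iterable of variant-site patterns.

        Sites not listed are monomorphic: the monomorphic class absorbs
        ``total_sites`` minus the number of listed variant sites.
        """
        h = cls(config=config, max_m=max_m)
        for pat in patterns:
            h.add_pattern(pat)
        if h.total_sites > total_sites:
            raise ValueError("more variant sites than total_sites")
        h.monomorphic += total_sites - h.total_sites
        h.total_sites = total_sites
        return h


# ----------------------------------------------------------------------
# Text format


def write_histogram(h: PatternHistogram) -> str:
    lines = [
        "POPS=" + ",".join(h.config.populations),
        "N=" + ",".join(str(n) for n in h.config.sizes),
        f"MAX_M={h.max_m}",
        f"TOTAL_SITES={h.total_sites}",
        f"MONOMORPHIC {h.monomorphic}",
        f"OVERFLOW {h.overflow}",
    ]
    for pat in sorted(h.counts):
        lines.append(",".join(str(m) for m in pat) + f" {h.counts[pat]}")
    return "\n".join(lines) + "\n"


def read_histogram(text: str) -> PatternHistogram:
    pops = None
    sizes = None
    max_m = None
    total = None
    mono = 0
    over = 0
    counts: dict = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("POPS="):
            pops = tuple(line[5:].split(","))
        elif line.startswith("N="):
            sizes = tuple(int(x) for x in line[2:].split(","))
        elif line.startswith("MAX_M="):
            max_m = int(line[6:])
        elif line.startswith("TOTAL_SITES="):
            total = int(line[12:])
        elif line.startswith("MONOMORPHIC"):
            mono = int(line.split()[1])
        elif line.startswith("OVERFLOW"):
            over = int(line.split()[1])
        else:
            try:
                pat_s, count_s = line.split()
                pat = tuple(int(x) for x in pat_s.split(","))
                count = int(count_s)
            except ValueError as e:
                raise ValueError(f"line {line_no}: malformed line {raw!r}") from e
            if sizes is None:
                raise ValueError(f"line {line_no}: body before N= header")
            if len(pat) != len(sizes):
                raise ValueError(
                    f"line {line_no}: pattern arity {len(pat)} != header {len(sizes)}"
                )
            counts[pat] = counts.get(pat, 0) + count
    if sizes is None or max_m is None or total is None:
        raise ValueError("missing N=, MAX_M= or TOTAL_SITES= header")
    if pops is None:
        pops = tuple(f"pop{i + 1}" for i in range(len(sizes)))
    h = PatternHistogram(
        config=SampleConfig(pops, sizes),
        max_m=max_m,
        counts=counts,
        monomorphic=mono,
        overflow=over,
        total_sites=total,
    )
    h.check()
    return h


# ----------------------------------------------------------------------
# Histogram algebra


def restrict_to_shared(h: PatternHistogram, query_pop: str) -> PatternHistogram:
    """Keep only patterns shared between the query population and the rest.

    Tracked patterns survive iff the query carries at least one derived
    copy AND at least one other population does too; query-private variants
    (high false-positive rate in low-coverage samples) and variants absent
    from the query are dropped, as are the monomorphic and overflow classes.
    """
    qi = h.config.index(query_pop)
    kept = {
        pat: c
        for pat, c in h.counts.items()
        if pat[qi] >= 1 and sum(pat) - pat[qi] >= 1
    }
    out = PatternHistogram(
        config=h.config,
        max_m=h.max_m,
        counts=kept,
        monomorphic=0,
        overflow=0,
        total_sites=sum(kept.values()),
        meta=dict(
            h.meta, restricted_to=query_pop, original_total_sites=h.total_sites
        ),
    )
    out.check()
    return out


def merge_histograms(histograms) -> PatternHistogram:
    """Add histograms classwise (e.g. per-chromosome builds)."""
    histograms = list(histograms)
    if not histograms:
        raise ValueError("no histograms to merge")
    first = histograms[0]
    out = PatternHistogram(
        config=first.config,
        max_m=first.max_m,
        counts=dict(first.counts),
        monomorphic=first.monomorphic,
        overflow=first.overflow,
        total_sites=first.total_sites,
    )
    for h in histograms[1:]:
        if h.config != first.config or h.max_m != first.max_m:
            raise ValueError("histogram configuration mismatch")
        out.monomorphic += h.monomorphic
        out.overflow += h.overflow
        out.total_sites += h.total_sites
        for pat, c in h.counts.items():
            out.counts[pat] = out.counts.get(pat, 0) + c
    out.check()
    return out


# ----------------------------------------------------------------------
# VCF ingestion


def read_mask_bed(path_or_text: str) -> dict:
    """Read a BED mappability mask into {chrom: Nx2 array} (0-based half-open).

    Intervals must be sorted and non-overlapping per chromosome.
    """
    if "\n" in path_or_text or "\t" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    raw: dict = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split()[:3]
        raw.setdefault(chrom, []).append((int(start), int(end)))
    mask = {}
    for chrom, ivs in raw.items():
        arr = np.asarray(ivs, dtype=np.int64)
        if np.any(arr[1:, 0] < arr[:-1, 1]) or np.any(np.diff(arr[:, 0]) < 0):
            raise ValueError(f"mask intervals unsorted or overlapping on {chrom}")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError(f"empty or inverted mask interval on {chrom}")
        mask[chrom] = arr
    return mask


def _in_mask(mask: dict, chrom: str, pos0: int) -> bool:
    arr = mask.get(chrom)
    if arr is None:
        return False
    i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
    return i >= 0 and pos0 < arr[i, 1]


def mask_length(mask: dict) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in mask.values()))


def vcf_to_histogram(
    vcf_path: str,
    pop_assignments: dict,
    mask,
    max_m: int = 4,
    polarize: str = "reference",
    pop_order=None,
) -> PatternHistogram:
    """Build a pattern histogram from a VCF, population table and BED mask.

    Only biallelic SNPs inside the mask are counted; sites inside the mask
    but absent from the VCF are monomorphic.  ``polarize='reference'``
    treats ALT as derived; ``polarize='ancestral-tag'`` uses the INFO/AA
    tag (sites lacking a usable tag are skipped and removed from
    total_sites, as are sites with missing genotypes, indels and
    multi-allelic records; all skips are tallied in ``meta``).
    """
    from cyvcf2 import VCF

    if polarize not in ("reference", "ancestral-tag"):
        raise ValueError("polarize must be 'reference' or 'ancestral-tag'")
    if isinstance(mask, (str,)):
        mask = read_mask_bed(mask)

    if pop_order is None:
        pop_order = list(dict.fromkeys(pop_assignments.values()))
    pop_index = {p: i for i, p in enumerate(pop_order)}
    K = len(pop_order)

    vcf = VCF(vcf_path)
    vcf_samples = list(vcf.samples)
    missing = set(pop_assignments) - set(vcf_samples)
    if missing:
        raise ValueError(f"samples missing from VCF: {sorted(missing)}")
    # column -> population index, -1 for samples not in the panel
    col_pop = np.full(len(vcf_samples), -1, dtype=np.int64)
    for col, s in enumerate(vcf_samples):
        if s in pop_assignments:
            col_pop[col] = pop_index[pop_assignments[s]]
    used = col_pop >= 0

    sizes = np.zeros(K, dtype=np.int64)
    tallies = {
        "non_snp_skipped": 0,
        "missing_gt_skipped": 0,
        "no_ancestral_tag_skipped": 0,
        "outside_mask": 0,
    }
    counts: dict = {}
    overflow = 0
    n_variant = 0
    removed = 0
    sizes_known = False

    for v in vcf:
        pos0 = v.POS - 1  # VCF is 1-based; internal arithmetic 0-based
        if not _in_mask(mask, v.CHROM, pos0):
            tallies["outside_mask"] += 1
            continue
        is_snp = (
            len(v.REF) == 1 and len(v.ALT) == 1 and len(v.ALT[0]) == 1
            and v.REF in "ACGT" and v.ALT[0] in "ACGT"
        )
        if not is_snp:
            tallies["non_snp_skipped"] += 1
            removed += 1
            continue
        gt = np.asarray(v.genotype.array())  # (n_samples, ploidy+1); last col phase
        alleles = gt[:, :-1]
        panel_alleles = alleles[used]
        if np.any(panel_alleles < 0):
            tallies["missing_gt_skipped"] += 1
            removed += 1
            continue
        if not sizes_known:
            ploidies = (alleles >= 0).sum(axis=1)
            for col in np.nonzero(used)[0]:
                sizes[col_pop[col]] += ploidies[col]
            sizes_known = True
        alt_per_sample = (alleles == 1).sum(axis=1)
        alt_counts = np.bincount(
            col_pop[used], weights=alt_per_sample[used], minlength=K
        ).astype(np.int64)
        if polarize == "ancestral-tag":
            aa = v.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) else None
            if aa == v.REF:
                derived = alt_counts
            elif aa == v.ALT[0]:
                derived = sizes - alt_counts
            else:
                tallies["no_ancestral_tag_skipped"] += 1
                removed += 1
                continue
        else:
            derived = alt_counts
        s = int(derived.sum())
        n_variant += 1
        if s == 0:
            continue  # monomorphic in the panel
        if s > max_m:
            overflow += 1
        else:
            pat = tuple(int(x) for x in derived)
            counts[pat] = counts.get(pat, 0) + 1

    if not sizes_known:
        # No usable variant seen; infer haploid sizes is impossible, assume
        # diploid panel members.
        for col in np.nonzero(used)[0]:
            sizes[col_pop[col]] += 2

    total_sites = mask_length(mask) - removed
    tracked = sum(counts.values())
    h = PatternHistogram(
        config=SampleConfig(tuple(pop_order), tuple(int(n) for n in sizes)),
        max_m=max_m,
        counts=counts,
        monomorphic=total_sites - tracked - overflow,
        overflow=overflow,
        total_sites=total_sites,
        meta={"tallies": tallies, "polarize": polarize, "source": str(vcf_path)},
    )
    h.check()
    return h
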