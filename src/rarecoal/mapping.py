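"""Placing a single query genome onto a fitted population tree.

The query (typically an ancient, low-coverage individual) enters the model
as an extra two-haploid branch, heterozygous at every called site.  For
every branch and a grid of merge times the composite likelihood of the
shared rare-allele patterns is evaluated; the resulting surface locates
the query's closest ancestry on the tree.  A positive sample age freezes
the query branch between the present and the age: its lineage is inert on
[0, age) and merge points younger than the age are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corecoal import histogram_loglikelihood
from .model import Branch, DemographyModel, JoinEvent, UnitScale
from .patterns import PatternHistogram, restrict_to_shared

__all__ = ["MergeScan", "ScanEntry", "merge_scan", "best_merge", "surface_export"]


@dataclass(frozen=True)
class ScanEntry:
    branch: str
    time: float
    loglik: float


@dataclass
class MergeScan:
    entries: list  # ScanEntry, sorted by loglik descending
    query_pop: str
    query_age: float
    normalization: float  # max log-likelihood

    def __iter__(self):
        return iter(self.entries)


def merge_scan(
    tree: DemographyModel,
    h: PatternHistogram,
    query_pop: str,
    query_age: float = 0.0,
    grid_density: int = 20,
    u: UnitScale | None = None,
    conditional: bool = False,
    root_extension: float = 2.0,
) -> MergeScan:
    """Scan merge points (branch, time) for the query branch.

    The histogram must contain a query column (2 haploids, derived count 1
    at carrier sites); it is restricted to shared variants (query-private
    patterns have high false-positive rates and are excluded).  Scan times
    on each branch run geometrically from max(query age, branch start) to
    the branch's terminal join; the surviving root branch is scanned up to
    ``root_extension`` times the root join time.
    """
    h_shared = restrict_to_shared(h, query_pop)
    if not h_shared.counts:
        raise ValueError("no patterns shared between query and reference panel")
    n_query = h.config.sizes[h.config.index(query_pop)]
    root_time = tree.root_time()
    scan_max = max(root_time, 0.005) * root_extension
    if query_age >= scan_max:
        raise ValueError(
            f"query age {query_age} is not below the scan ceiling {scan_max}"
        )

    entries = []
    for b in tree.branches:
        terminal = tree.terminal_join_time(b.name)
        end = terminal if math.isfinite(terminal) else scan_max
        # one grid per branch segment (between joins absorbed by b)
        cuts = sorted(
            {0.0, end}
            | {j.time for j in tree.joins if j.into == b.name and j.time < end}
        )
        times = []
        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            hi = s1 * (1 - 1e-9)
            lo = max(query_age * (1 + 1e-6) + 1e-7, s0, hi * 1e-3)
            if lo >= hi:
                continue
            times.extend(np.geomspace(lo, hi, grid_density))
        for t in times:
            model2 = tree.copy()
            model2.branches.append(
                Branch(
                    query_pop,
                    tree.lambda_at(b.name, t),
                    n_query,
                    sample_age=query_age,
                )
            )
            model2.joins.append(JoinEvent(float(t), b.name, query_pop))
            ll = histogram_loglikelihood(
                model2, h_shared, u, conditional=conditional
            )
            entries.append(ScanEntry(b.name, float(t), ll))
    if not entries:
        raise ValueError("empty merge scan (no admissible merge points)")
    entries.sort(key=lambda e: (-e.loglik, -e.time))
    return MergeScan(
        entries=entries,
        query_pop=query_pop,
        query_age=query_age,
        normalization=entries[0].loglik,
    )


def best_merge(s: MergeScan, tie_tol: float = 1e-9):
    """Arg-max merge point; ties are broken toward the older time.

    Returns (branch, time, loglik, tied) where `tied` flags multiple
    maxima within `tie_tol` log-units.
    """
    if not s.entries:
        raise ValueError("empty scan")
    top = [e for e in s.entries if s.normalization - e.loglik <= tie_tol]
    best = max(top, key=lambda e: e.time)
    return best.branch, best.time, best.loglik, len(top) > 1


def surface_export(s: MergeScan) -> list:
    """Relative-likelihood table: exp(logL - max logL) per entry."""
    return [
        {
            "branch": e.branch,
            "time": e.time,
            "loglik": e.loglik,
            "rel_lik": math.exp(e.loglik - s.normalization),
        }
        for e in s.entries
    ]
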