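"""Monte-Carlo structured-coalescent simulation under a DemographyModel.

Backed by msprime/tskit, this module is the brute-force oracle for the
likelihood engine and the synthetic-data generator for the inference,
mapping and sharing pipelines.  Sites are either truly unlinked
(independent genealogies, one per site; exact but slow) or simulated as a
recombining sequence with a realistic per-bp recombination rate (fast;
rare-allele pattern frequencies depend only on marginal genealogies, and
the composite likelihood treats sites independently anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from .model import Branch, DemographyModel, JoinEvent, UnitScale, validate_model
from .patterns import PatternHistogram, SampleConfig
from .sharing import Panel, PanelSite, make_panel

__all__ = [
    "SimConfig",
    "to_msprime_demography",
    "simulate_genealogy",
    "genealogy_summary",
    "oracle_pattern_length",
    "oracle_pattern_lengths",
    "simulate_histogram",
    "export_vcf",
    "SharingFixture",
    "simulate_sharing_fixture",
    "random_tree_model",
]


@dataclass
class SimConfig:
    """Configuration of a histogram simulation.

    num_sites is the callable genome length; theta per site is
    ``2 * n_ref * mu`` from the unit scale.  mode='linked' simulates a
    recombining sequence; mode='unlinked' simulates one genealogy per
    site.
    """

    model: DemographyModel
    num_sites: int
    u: UnitScale = field(default_factory=UnitScale)
    recombination_rate: float = 1e-8
    mode: str = "unlinked"
    sites_per_genealogy: int = 10
    max_m: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.num_sites <= 0:
            raise ValueError("num_sites must be positive")
        if self.mode not in ("linked", "unlinked"):
            raise ValueError("mode must be 'linked' or 'unlinked'")


def to_msprime_demography(m: DemographyModel, u: UnitScale):
    """Translate a model into an msprime Demography (sizes in diploids,
    times in generations; joins become complete mass migrations)."""
    errs = validate_model(m)
    if errs:
        raise ValueError("invalid model: " + "; ".join(errs))
    dem = msprime.Demography()
    for b in m.branches:
        dem.add_population(name=b.name, initial_size=b.lam * u.n_ref)
    for j in m.sorted_joins():
        t_gen = j.time * 2.0 * u.n_ref
        dem.add_mass_migration(
            time=t_gen, source=j.from_, dest=j.into, proportion=1.0
        )
        if j.lambda_after is not None:
            dem.add_population_parameters_change(
                time=t_gen, population=j.into, initial_size=j.lambda_after * u.n_ref
            )
    dem.sort_events()
    return dem


def _sample_sets(m: DemographyModel, u: UnitScale):
    return [
        msprime.SampleSet(
            b.sample_size,
            population=b.name,
            time=b.sample_age * 2.0 * u.n_ref,
            ploidy=1,
        )
        for b in m.branches
        if b.sample_size > 0
    ]


def _sample_populations(ts, m: DemographyModel):
    """Map each sample node to the model branch index."""
    name_to_idx = {b.name: i for i, b in enumerate(m.branches)}
    pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
    nodes = ts.samples()
    return np.asarray(
        [name_to_idx[pop_names[ts.node(n).population]] for n in nodes]
    ), nodes


def simulate_genealogy(m: DemographyModel, seed: int, u: UnitScale | None = None):
    """One exact genealogy of the model's samples (single, non-recombining
    locus).  Returns a tskit TreeSequence; see genealogy_summary."""
    u = u or m.scale or UnitScale()
    return msprime.sim_ancestry(
        samples=_sample_sets(m, u),
        demography=to_msprime_demography(m, u),
        ploidy=2,
        random_seed=max(int(seed) % (2**31 - 1), 1),
    )


def _node_pop_counts(tree, sample_pops, sample_nodes, K):
    order = tree.postorder()
    counts = np.zeros((tree.tree_sequence.num_nodes, K), dtype=np.int64)
    for n, p in zip(sample_nodes, sample_pops):
        counts[n, p] = 1
    for v in order:
        p = tree.parent(v)
        if p != -1:
            counts[p] += counts[v]
    return counts


def genealogy_summary(ts, m: DemographyModel, u: UnitScale | None = None):
    """Per-branch subtended leaf-count vectors and branch lengths (scaled).

    Returns a list of (counts_tuple, scaled_length) over all non-root
    genealogy branches of the first (only) tree.
    """
    u = u or m.scale or UnitScale()
    K = len(m.branches)
    sample_pops, sample_nodes = _sample_populations(ts, m)
    tree = ts.first()
    counts = _node_pop_counts(tree, sample_pops, sample_nodes, K)
    out = []
    scale = 2.0 * u.n_ref
    for v in tree.nodes():
        if tree.parent(v) != -1:
            out.append((tuple(int(c) for c in counts[v]), tree.branch_length(v) / scale))
    return out


def oracle_pattern_lengths(
    m: DemographyModel,
    max_m: int,
    reps: int,
    seed: int,
    u: UnitScale | None = None,
) -> dict:
    """Monte-Carlo expected genealogy length subtending each tracked pattern.

    For each replicate genealogy, sums the (scaled) lengths of all branches
    whose subtended leaf-count vector equals the pattern; returns
    {pattern: (mean, standard_error)} over replicates.  The likelihood
    engine's per-site pattern probability equals theta_scaled * mean.
    """
    u = u or m.scale or UnitScale()
    K = len(m.branches)
    n_tot = sum(b.sample_size for b in m.branches)
    reps_iter = msprime.sim_ancestry(
        samples=_sample_sets(m, u),
        demography=to_msprime_demography(m, u),
        ploidy=2,
        random_seed=max(int(seed) % (2**31 - 1), 1),
        num_replicates=reps,
    )
    sums: dict = {}
    sumsqs: dict = {}
    scale = 2.0 * u.n_ref
    first = True
    for ts in reps_iter:
        if first:
            sample_pops, sample_nodes = _sample_populations(ts, m)
            first = False
        tree = ts.first()
        counts = _node_pop_counts(tree, sample_pops, sample_nodes, K)
        local: dict = {}
        for v in tree.nodes():
            p = tree.parent(v)
            if p == -1:
                continue
            tot = int(counts[v].sum())
            if 1 <= tot <= max_m and tot < n_tot:
                key = tuple(int(c) for c in counts[v])
                local[key] = local.get(key, 0.0) + tree.branch_length(v) / scale
        for key, val in local.items():
            sums[key] = sums.get(key, 0.0) + val
            sumsqs[key] = sumsqs.get(key, 0.0) + val * val
    out = {}
    for key, s in sums.items():
        mean = s / reps
        var = max(sumsqs[key] / reps - mean * mean, 0.0)
        out[key] = (mean, math.sqrt(var / reps))
    return out


def oracle_pattern_length(m, pattern, reps, seed, u=None):
    pattern = tuple(int(x) for x in pattern)
    all_lengths = oracle_pattern_lengths(m, sum(pattern), reps, seed, u)
    return all_lengths.get(pattern, (0.0, 0.0))


# ----------------------------------------------------------------------
# Histogram simulation


def _config_of(m: DemographyModel) -> SampleConfig:
    sampled = [b for b in m.branches if b.sample_size > 0]
    return SampleConfig(
        tuple(b.name for b in sampled), tuple(b.sample_size for b in sampled)
    )


def simulate_histogram(cfg: SimConfig):
    """Simulate a pattern histogram (and return the mutated tree sequence
    in linked mode for optional VCF export).

    Returns (histogram, tree_sequence_or_None).
    """
    m, u = cfg.model, cfg.u
    rng = np.random.default_rng(cfg.seed)
    seed1 = int(rng.integers(1, 2**31 - 1))
    seed2 = int(rng.integers(1, 2**31 - 1))
    config = _config_of(m)
    K_sampled = config.n_pops
    sampled_idx = {b.name: i for i, b in enumerate(m.branches) if b.sample_size > 0}

    if cfg.mode == "linked":
        ts = msprime.sim_ancestry(
            samples=_sample_sets(m, u),
            demography=to_msprime_demography(m, u),
            ploidy=2,
            sequence_length=cfg.num_sites,
            recombination_rate=cfg.recombination_rate,
            random_seed=seed1,
        )
        mts = msprime.sim_mutations(
            ts, rate=u.mu, random_seed=seed2, model=msprime.BinaryMutationModel()
        )
        sample_pops, _ = _sample_populations(mts, m)
        col = np.asarray(
            [list(sampled_idx).index(m.branches[p].name) for p in sample_pops]
        )
        patterns = []
        for v in mts.variants():
            if "1" not in v.alleles:
                continue
            derived_idx = v.alleles.index("1")
            mask = v.genotypes == derived_idx
            cnt = np.bincount(col[mask], minlength=K_sampled)
            patterns.append(tuple(int(c) for c in cnt))
        h = PatternHistogram.from_patterns(config, cfg.max_m, patterns, cfg.num_sites)
        h.meta.update(seed=cfg.seed, mode="linked")
        return h, mts

    # unlinked: independent genealogies, `sites_per_genealogy` iid sites each
    theta = u.scaled_theta
    block = max(int(cfg.sites_per_genealogy), 1)
    n_reps = int(math.ceil(cfg.num_sites / block))
    total_sites = n_reps * block
    reps_iter = msprime.sim_ancestry(
        samples=_sample_sets(m, u),
        demography=to_msprime_demography(m, u),
        ploidy=2,
        random_seed=seed1,
        num_replicates=n_reps,
    )
    K = len(m.branches)
    sampled_cols = [i for i, b in enumerate(m.branches) if b.sample_size > 0]
    scale = 2.0 * u.n_ref
    patterns = []
    first = True
    for ts in reps_iter:
        if first:
            sample_pops, sample_nodes = _sample_populations(ts, m)
            first = False
        tree = ts.first()
        p_var = -np.expm1(-theta * tree.total_branch_length / scale)
        k = rng.binomial(block, p_var)
        if k < 1:
            continue
        nodes = [v for v in tree.nodes() if tree.parent(v) != -1]
        lengths = np.asarray([tree.branch_length(v) for v in nodes])
        cum = np.cumsum(lengths)
        counts = _node_pop_counts(tree, sample_pops, sample_nodes, K)
        for _ in range(k):
            pick = int(np.searchsorted(cum, rng.random() * cum[-1]))
            full = counts[nodes[min(pick, len(nodes) - 1)]]
            pat = tuple(int(full[i]) for i in sampled_cols)
            if 0 < sum(pat) < sum(config.sizes):
                patterns.append(pat)
    h = PatternHistogram.from_patterns(config, cfg.max_m, patterns, total_sites)
    h.meta.update(seed=cfg.seed, mode="unlinked")
    return h, None


def export_vcf(ts, m: DemographyModel, vcf_path: str):
    """Write the mutated tree sequence as a haploid VCF plus a population
    assignment table {sample_name: population}.

    Binary mutation states are relabelled A (ancestral) / C (derived) and
    positions shifted to the 1-based VCF convention.
    """
    tables = ts.dump_tables()
    tables.sites.packset_ancestral_state(
        ["A" if s.ancestral_state == "0" else "C" for s in ts.sites()]
    )
    tables.mutations.packset_derived_state(
        ["A" if mu.derived_state == "0" else "C" for mu in ts.mutations()]
    )
    ts = tables.tree_sequence()
    sample_pops, sample_nodes = _sample_populations(ts, m)
    node_to_name = {}
    assignments = {}
    per_pop_counter: dict = {}
    names = []
    for ind in ts.individuals():
        node = ind.nodes[0]
        pop = m.branches[sample_pops[list(sample_nodes).index(node)]].name
        i = per_pop_counter.get(pop, 0)
        per_pop_counter[pop] = i + 1
        name = f"{pop}_{i}"
        names.append(name)
        assignments[name] = pop
        node_to_name[node] = name
    with open(vcf_path, "w") as fh:
        ts.write_vcf(
            fh,
            individual_names=names,
            contig_id="1",
            position_transform=lambda x: np.round(np.asarray(x)) + 1,
        )
    return assignments


# ----------------------------------------------------------------------
# Sharing-analysis fixture


@dataclass
class SharingFixture:
    """Synthetic inputs for the allele-sharing pipeline.

    Two source populations A and B split at t_split; query individuals are
    pure A, pure B, or admixed with B-fraction alpha (admixture at
    t_admix).  Panel sites are derived variants with total panel allele
    count 1..9; read counts mimic shotgun coverage with symmetric
    per-read error.
    """

    panel: Panel
    pop_sizes: dict
    read_counts: dict  # sample -> {site_key: (rare_reads, total_reads)}
    genotypes: dict  # sample -> {site_key: dosage}
    groups: dict  # sample -> 'pureA' | 'pureB' | 'admixed'
    truth: dict  # sample -> true B-ancestry fraction
    alpha: float
    seed: int

    def write(self, directory: str) -> None:
        import os

        from .sharing import write_panel_tsv, write_read_counts_tsv

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "panel.tsv"), "w") as fh:
            fh.write(write_panel_tsv(self.panel))
        for sample, rc in self.read_counts.items():
            with open(os.path.join(directory, f"reads_{sample}.tsv"), "w") as fh:
                fh.write(write_read_counts_tsv(rc))
        with open(os.path.join(directory, "truth.tsv"), "w") as fh:
            fh.write("sample\tgroup\ttrue_b_fraction\n")
            for sample in sorted(self.truth):
                fh.write(
                    f"{sample}\t{self.groups[sample]}\t{self.truth[sample]}\n"
                )


def _sharing_demography(alpha, t_split, t_admix, lam, u):
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=lam[0] * u.n_ref)
    dem.add_population(name="B", initial_size=lam[1] * u.n_ref)
    dem.add_population(name="ANC", initial_size=lam[2] * u.n_ref)
    dem.add_population(name="Q", initial_size=u.n_ref)
    t_adm_g = t_admix * 2 * u.n_ref
    if alpha <= 0.0:
        dem.add_admixture(time=t_adm_g, derived="Q", ancestral=["A"], proportions=[1.0])
    elif alpha >= 1.0:
        dem.add_admixture(time=t_adm_g, derived="Q", ancestral=["B"], proportions=[1.0])
    else:
        dem.add_admixture(
            time=t_adm_g, derived="Q", ancestral=["A", "B"],
            proportions=[1 - alpha, alpha],
        )
    dem.add_population_split(
        time=t_split * 2 * u.n_ref, derived=["A", "B"], ancestral="ANC"
    )
    dem.sort_events()
    return dem


def simulate_sharing_fixture(
    alpha: float = 0.4,
    n_panel: tuple = (60, 60),
    n_anchor_each: int = 5,
    n_query_each: int = 4,
    t_split: float = 0.02,
    t_admix: float = 0.0008,
    coverage: float = 6.0,
    error: float = 1e-3,
    num_sites: int = 600_000,
    sites_per_genealogy: int = 10,
    lam: tuple = (1.0, 1.0, 1.0),
    u: UnitScale | None = None,
    seed: int = 0,
) -> SharingFixture:
    """Simulate panel + read-count inputs for the sharing pipeline.

    Sites are unlinked (independent genealogies carrying blocks of
    `sites_per_genealogy` iid sites).  Panel sites keep derived variants
    with total panel allele count 1..9; every query sample receives read
    counts at every panel site (Poisson depth, symmetric per-read error).

    Query groups: `anchorA`/`anchorB` define the 0% / 100% anchors;
    held-out `testA` (true fraction 0), `testB` (1) and `admixed`
    (alpha) individuals are the recovery targets.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    u = u or UnitScale()
    rng = np.random.default_rng(seed)
    dem = _sharing_demography(alpha, t_split, t_admix, lam, u)
    n_hapA, n_hapB = n_panel
    groups = {}
    truth = {}
    sample_names = []
    group_plan = [
        ("anchorA", "A", n_anchor_each, 0.0),
        ("anchorB", "B", n_anchor_each, 1.0),
        ("testA", "A", n_query_each, 0.0),
        ("testB", "B", n_query_each, 1.0),
        ("admixed", "Q", n_query_each, alpha),
    ]
    for grp, _, n, tr in group_plan:
        for i in range(n):
            name = f"{grp}_{i}"
            sample_names.append(name)
            groups[name] = grp
            truth[name] = tr
    n_q = len(sample_names)
    samples = [
        msprime.SampleSet(n_hapA, population="A", ploidy=1),
        msprime.SampleSet(n_hapB, population="B", ploidy=1),
    ] + [
        msprime.SampleSet(n, population=pop, ploidy=2)
        for _, pop, n, _ in group_plan
    ]
    # column group per sample node: 0 = panel A, 1 = panel B, 2+i = query i
    group_of = np.concatenate(
        [
            np.zeros(n_hapA, dtype=np.int64),
            np.ones(n_hapB, dtype=np.int64),
            2 + np.repeat(np.arange(n_q), 2),
        ]
    )
    K = 2 + n_q
    block = max(int(sites_per_genealogy), 1)
    n_reps = int(math.ceil(num_sites / block))
    theta = u.scaled_theta
    scale = 2.0 * u.n_ref
    reps_iter = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        num_replicates=n_reps,
    )
    sites = []
    genotypes: dict = {name: {} for name in sample_names}
    pos = 0
    for ts in reps_iter:
        tree = ts.first()
        p_var = -np.expm1(-theta * tree.total_branch_length / scale)
        k = rng.binomial(block, p_var)
        if k < 1:
            continue
        nodes = [v for v in tree.nodes() if tree.parent(v) != -1]
        lengths = np.asarray([tree.branch_length(v) for v in nodes])
        cum = np.cumsum(lengths)
        counts = _node_pop_counts_grouped(tree, ts.samples(), group_of, K)
        for _ in range(k):
            pick = int(np.searchsorted(cum, rng.random() * cum[-1]))
            vec = counts[nodes[min(pick, len(nodes) - 1)]]
            cA, cB = int(vec[0]), int(vec[1])
            total = cA + cB
            if not 1 <= total <= 9:
                continue
            pos += 1
            key = ("1", pos)
            sites.append(PanelSite("1", pos, "A", "C", (cA, cB), total))
            for qi, name in enumerate(sample_names):
                genotypes[name][key] = int(vec[2 + qi])
    panel = make_panel(("A", "B"), sites)

    read_counts: dict = {}
    for name in sample_names:
        rc = {}
        for key, dosage in genotypes[name].items():
            depth = int(rng.poisson(coverage))
            if depth == 0:
                rc[key] = (0, 0)
                continue
            p = (dosage / 2.0) * (1 - error) + (1 - dosage / 2.0) * error
            rare = int(rng.binomial(depth, p))
            rc[key] = (rare, depth)
        read_counts[name] = rc

    return SharingFixture(
        panel=panel,
        pop_sizes={"A": n_hapA, "B": n_hapB},
        read_counts=read_counts,
        genotypes=genotypes,
        groups=groups,
        truth=truth,
        alpha=alpha,
        seed=seed,
    )


def _node_pop_counts_grouped(tree, sample_nodes, group_of, K):
    counts = np.zeros((tree.tree_sequence.num_nodes, K), dtype=np.int64)
    for n, g in zip(sample_nodes, group_of):
        counts[n, g] = 1
    for v in tree.postorder():
        p = tree.parent(v)
        if p != -1:
            counts[p] += counts[v]
    return counts


# ----------------------------------------------------------------------
# Random valid models (property tests)


def random_tree_model(
    n_pops: int,
    seed: int = 0,
    sample_size: int = 4,
    with_ancient: bool = False,
) -> DemographyModel:
    """A random valid population tree with n_pops sampled tips."""
    rng = np.random.default_rng(seed)
    names = [f"P{i}" for i in range(n_pops)]
    branches = [
        Branch(n, float(rng.uniform(0.3, 3.0)), sample_size) for n in names
    ]
    if with_ancient and n_pops >= 2:
        branches[-1].sample_age = float(rng.uniform(1e-4, 5e-4))
    alive = list(names)
    joins = []
    t = 1e-3
    while len(alive) > 1:
        t += float(rng.uniform(5e-4, 5e-3))
        i, j = rng.choice(len(alive), size=2, replace=False)
        into, frm = alive[i], alive[j]
        lam_after = float(rng.uniform(0.3, 3.0)) if rng.random() < 0.5 else None
        joins.append(JoinEvent(t, into, frm, lam_after))
        alive.remove(frm)
    m = DemographyModel(branches=branches, joins=joins)
    errs = validate_model(m)
    if errs:
        raise AssertionError(f"random model invalid: {errs}")
    return m
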