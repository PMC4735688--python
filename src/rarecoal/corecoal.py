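"""The rare-variant coalescent likelihood engine.

For a site pattern (derived-allele counts per population) the engine
propagates, backward in time through a population tree, the distribution
of derived and non-derived ancestral lineage counts.  Because branches of
the tree evolve independently between joins, the state factorizes into
one small (derived, non-derived) count distribution per branch; factors
are convolved at joins and finished with a closed-form recursion in the
root branch.  The per-site probability of a pattern is::

    p(pattern) = theta_scaled * multiplicity * E[singleton time]

where ``theta_scaled = 2 * n_ref * mu`` is the per-site mutation rate per
scaled time unit, the multiplicity ``prod_k C(n_k, m_k)`` counts carrier
labelings consistent with the observed counts, and the singleton time is
the expected length of the genealogy branch subtending exactly the
carriers: time accrued while a single derived ancestral lineage remains,
ending when it coalesces with a non-derived lineage.  Configurations in
which a derived lineage meets a non-derived lineage before the derived
lineages have fully coalesced are absorbed as inconsistent.

The monomorphic class is handled through the expected total tree length
(exact, from per-branch lineage-count distributions) and the overflow
class (total derived count above ``max_m``) by complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .model import DemographyModel, UnitScale, validate_model
from .patterns import PatternHistogram

__all__ = [
    "LineageStateDistribution",
    "initial_state",
    "step",
    "apply_join",
    "activate_branch",
    "pattern_probability",
    "pattern_probabilities",
    "total_tree_length",
    "histogram_loglikelihood",
]


def _tip_factor(m: int, n_samples: int) -> np.ndarray:
    F = np.zeros((m + 1, n_samples - m + 1))
    F[m, n_samples - m] = 1.0
    return F


# ----------------------------------------------------------------------
# Public state object (single pattern)


@dataclass
class LineageStateDistribution:
    """Lineage-count state for one tracked site pattern.

    Holds one (derived, non-derived) count distribution per active,
    activated branch; frozen branches (ancient samples not yet born,
    looking backward) carry their derived counts inertly until activated.
    ``acc`` is the accumulated expected singleton time; ``inconsistent``
    the probability mass absorbed from multi-derived states;
    ``singleton_absorbed`` the mass absorbed after the singleton formed.
    """

    branch_names: list
    factors: dict  # branch name -> F[a, n] (absent while frozen)
    lam: dict  # branch name -> scaled size
    pending: dict  # frozen branch name -> (m, n_samples)
    acc: float = 0.0
    inconsistent: float = 0.0
    singleton_absorbed: float = 0.0
    tol: float = 1e-12

    # -- views ----------------------------------------------------------

    @property
    def probs(self) -> dict:
        """Joint distribution over derived configurations (product of the
        per-branch marginals; exact by branch independence)."""
        margs = []
        for name in self.branch_names:
            if name in self.factors:
                margs.append(self.factors[name].sum(axis=1))
            else:
                m = self.pending[name][0]
                d = np.zeros(m + 1)
                d[m] = 1.0
                margs.append(d)
        out: dict = {}
        for combo in product(*(range(len(mg)) for mg in margs)):
            p = 1.0
            for c, mg in zip(combo, margs):
                p *= mg[c]
            if p > 0:
                out[combo] = p
        return out

    @property
    def nbar(self) -> np.ndarray:
        """Expected non-derived lineage count per branch (0 while frozen)."""
        out = np.zeros(len(self.branch_names))
        for i, name in enumerate(self.branch_names):
            F = self.factors.get(name)
            if F is None:
                continue
            mass = F.sum()
            if mass > 0:
                out[i] = (F.sum(axis=0) * np.arange(F.shape[1])).sum() / mass
        return out

    def total_mass(self) -> float:
        mass = 1.0
        for name in self.branch_names:
            if name in self.factors:
                mass *= self.factors[name].sum()
        return mass

    def check_mass(self, tol: float = 1e-8) -> None:
        total = self.total_mass() + self.inconsistent + self.singleton_absorbed
        if not -tol <= total <= 1.0 + tol:
            raise ValueError(f"probability mass {total} outside [0, 1]")

    def _carriers(self):
        active = [
            n for n in self.branch_names
            if n in self.factors and self.factors[n].shape[0] > 1
        ]
        frozen = [n for n, (m, _) in self.pending.items() if m > 0]
        return active, frozen


def initial_state(pattern, m: DemographyModel) -> LineageStateDistribution:
    """State at time 0: the observed configuration with probability one."""
    pattern = tuple(int(x) for x in pattern)
    if len(pattern) != len(m.branches):
        raise ValueError("pattern arity does not match branch count")
    if sum(pattern) < 1:
        raise ValueError("monomorphic pattern: handled by the total-length path")
    factors = {}
    pending = {}
    for mk, b in zip(pattern, m.branches):
        if mk < 0 or mk > b.sample_size:
            raise ValueError(
                f"pattern count {mk} exceeds sample size of branch {b.name}"
            )
        if b.sample_age > 0:
            pending[b.name] = (mk, b.sample_size)
        else:
            factors[b.name] = _tip_factor(mk, b.sample_size)
    return LineageStateDistribution(
        branch_names=list(m.branch_names),
        factors=factors,
        lam={b.name: b.lam for b in m.branches},
        pending=pending,
    )


def step(state: LineageStateDistribution, dt: float) -> LineageStateDistribution:
    """Propagate the state by dt scaled time units (no demographic events)."""
    from ._factor import evolve_factor, trim_factor

    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state
    active, frozen = state._carriers()
    new_factors = {}
    acc = state.acc
    inc = state.inconsistent
    sab = state.singleton_absorbed
    sole = len(active) == 1 and not frozen
    alive_before = state.total_mass()
    sing_kill = 0.0
    for name, F in state.factors.items():
        Fend, i1, ks, km = evolve_factor(F, state.lam[name], dt, state.tol)
        new_factors[name] = trim_factor(Fend)
        if sole and name == active[0]:
            acc += i1
            sing_kill = ks
    alive_after = 1.0
    for F in new_factors.values():
        alive_after *= F.sum()
    killed = max(alive_before - alive_after, 0.0)
    # with a single carrier branch the other factors never absorb, so the
    # per-factor singleton/multi split is exact; otherwise every
    # configuration still has >= 2 derived lineages and all kills are
    # inconsistencies
    sab += sing_kill if sole else 0.0
    inc += killed - (sing_kill if sole else 0.0)
    out = LineageStateDistribution(
        branch_names=list(state.branch_names),
        factors=new_factors,
        lam=dict(state.lam),
        pending=dict(state.pending),
        acc=acc,
        inconsistent=inc,
        singleton_absorbed=sab,
        tol=state.tol,
    )
    out.check_mass()
    return out


def activate_branch(state: LineageStateDistribution, name: str):
    """Unfreeze an ancient branch: its sampled lineages enter the state."""
    if name not in state.pending:
        raise ValueError(f"branch {name} is not frozen")
    mk, n = state.pending[name]
    factors = dict(state.factors)
    factors[name] = _tip_factor(mk, n)
    pending = {k: v for k, v in state.pending.items() if k != name}
    from dataclasses import replace

    return replace(state, factors=factors, pending=pending)


def apply_join(
    state: LineageStateDistribution, into: str, from_: str, lambda_after=None
) -> LineageStateDistribution:
    """Merge branch `from_` into `into`: lineage counts add (convolution)."""
    from ._factor import convolve_factors, trim_factor

    if into in state.pending or from_ in state.pending:
        raise ValueError("cannot join a frozen branch")
    if into not in state.factors or from_ not in state.factors:
        raise ValueError("joining an inactive branch")
    factors = dict(state.factors)
    Ff = factors.pop(from_)
    factors[into] = trim_factor(convolve_factors(factors[into], Ff))
    lam = dict(state.lam)
    lam.pop(from_, None)
    if lambda_after is not None:
        lam[into] = lambda_after
    from dataclasses import replace

    return replace(
        state,
        branch_names=[n for n in state.branch_names if n != from_],
        factors=factors,
        lam=lam,
    )


# ----------------------------------------------------------------------
# Batched engine


class _Engine:
    """Propagates many patterns through the same model, sharing the
    per-branch factors that patterns with equal sub-patterns induce."""

    def __init__(self, m: DemographyModel, patterns, tol: float = 1e-12):
        errs = validate_model(m)
        if errs:
            raise ValueError("invalid model: " + "; ".join(errs))
        self.m = m
        self.tol = tol
        self.patterns = [tuple(int(x) for x in p) for p in patterns]
        for p in self.patterns:
            if len(p) != len(m.branches):
                raise ValueError("pattern arity does not match branch count")
            if sum(p) < 1:
                raise ValueError("monomorphic pattern passed to the engine")
            for mk, b in zip(p, m.branches):
                if mk > b.sample_size or mk < 0:
                    raise ValueError(
                        f"pattern count {mk} invalid for branch {b.name} "
                        f"(n = {b.sample_size})"
                    )

    def run(self) -> dict:
        from ._factor import (
            convolve_factors,
            evolve_factor,
            root_tail_acc,
            trim_factor,
        )

        m = self.m
        B = len(self.patterns)
        acc = np.zeros(B)
        sab = np.zeros(B)
        inc_sole = np.zeros(B)

        store: dict = {}  # key -> current factor matrix
        lam: dict = {b.name: b.lam for b in m.branches}

        # per-pattern bookkeeping
        key_of = [dict() for _ in range(B)]  # branch name -> factor key
        m_under = [dict() for _ in range(B)]  # branch name -> derived under it
        frozen_m = [dict() for _ in range(B)]  # frozen branch -> derived count

        for bi, p in enumerate(self.patterns):
            for k, b in enumerate(m.branches):
                if b.sample_age > 0:
                    frozen_m[bi][b.name] = p[k]
                else:
                    key = ("t", k, p[k])
                    key_of[bi][b.name] = key
                    m_under[bi][b.name] = p[k]
                    if key not in store:
                        store[key] = _tip_factor(p[k], b.sample_size)

        events: list = []
        for k, b in enumerate(m.branches):
            if b.sample_age > 0:
                events.append((b.sample_age, "activate", b.name))
        for ji, j in enumerate(m.sorted_joins()):
            events.append((j.time, "join", (ji, j)))
        events.sort(key=lambda e: (e[0], 0 if e[1] == "activate" else 1))

        key_branch = {}  # key -> branch name (for lam lookup)
        for bi in range(B):
            for name, key in key_of[bi].items():
                key_branch[key] = name

        t = 0.0
        for ev_time, kind, payload in events:
            dt = ev_time - t
            if dt > 0:
                epoch = {}
                for key, F in store.items():
                    Fend, i1, ks, km = evolve_factor(
                        F, lam[key_branch[key]], dt, self.tol
                    )
                    store[key] = trim_factor(Fend)
                    epoch[key] = (i1, ks, km)
                for bi in range(B):
                    carriers = [n for n, mu in m_under[bi].items() if mu > 0]
                    has_frozen = any(v > 0 for v in frozen_m[bi].values())
                    if len(carriers) == 1 and not has_frozen:
                        i1, ks, km = epoch[key_of[bi][carriers[0]]]
                        acc[bi] += i1
                        sab[bi] += ks
                        inc_sole[bi] += km
                t = ev_time
            if kind == "activate":
                name = payload
                k = m.branch_index(name)
                b = m.branch(name)
                for bi in range(B):
                    mk = frozen_m[bi].pop(name)
                    key = ("t", k, mk)
                    key_of[bi][name] = key
                    m_under[bi][name] = mk
                    if key not in store:
                        store[key] = _tip_factor(mk, b.sample_size)
                    key_branch[key] = name
            else:
                ji, j = payload
                if j.lambda_after is not None:
                    lam[j.into] = j.lambda_after
                new_store_keys = {}
                for bi in range(B):
                    ki = key_of[bi].pop(j.into)
                    kf = key_of[bi].pop(j.from_)
                    nk = ("j", ji, ki, kf)
                    key_of[bi][j.into] = nk
                    m_under[bi][j.into] = m_under[bi].pop(j.into) + m_under[
                        bi
                    ].pop(j.from_)
                    new_store_keys[nk] = (ki, kf)
                    key_branch[nk] = j.into
                old_store = store
                store = {}
                # keep factors still referenced by some pattern
                live = {key for bi in range(B) for key in key_of[bi].values()}
                for nk, (ki, kf) in new_store_keys.items():
                    store[nk] = trim_factor(
                        convolve_factors(old_store[ki], old_store[kf])
                    )
                for key in live - set(store):
                    store[key] = old_store[key]

        # final open-ended epoch: every pattern sits in a single root branch
        from ._factor import root_tail_table

        residual = np.zeros(B)
        tail_tables: dict = {}
        for bi in range(B):
            carriers = [n for n, mu in m_under[bi].items() if mu > 0]
            if len(carriers) != 1 or frozen_m[bi]:
                raise RuntimeError("model left multiple unjoined carrier branches")
            root = carriers[0]
            q = store[key_of[bi][root]]
            tkey = (root, q.shape[0] >= 2)
            table = tail_tables.get(tkey)
            if table is None or table.shape[0] < q.shape[0] or table.shape[1] < q.shape[1]:
                na = max(q.shape[0], 5)
                nn = max(
                    (store[key_of[b2][root]].shape[1]
                     for b2 in range(B) if root in key_of[b2]),
                    default=q.shape[1],
                )
                table = root_tail_table(na, max(nn, q.shape[1]), lam[root])
                tail_tables[tkey] = table
            mass = q.sum()
            acc[bi] += root_tail_acc(q, lam[root], table)
            sab[bi] += mass
        inconsistent = 1.0 - sab  # everything is eventually absorbed
        return {
            "acc": acc,
            "inconsistent": inconsistent,
            "singleton_absorbed": sab,
            "residual": residual,
        }


def _multiplicity(m: DemographyModel, pattern) -> float:
    mult = 1.0
    for mk, b in zip(pattern, m.branches):
        mult *= math.comb(b.sample_size, int(mk))
    return mult


def pattern_probabilities(
    m: DemographyModel,
    patterns,
    u: UnitScale | None = None,
) -> np.ndarray:
    """Per-site probabilities for a batch of tracked patterns."""
    u = u or m.scale or UnitScale()
    patterns = [tuple(int(x) for x in p) for p in patterns]
    if not patterns:
        return np.zeros(0)
    out = _Engine(m, patterns).run()
    mult = np.asarray([_multiplicity(m, p) for p in patterns])
    return u.scaled_theta * mult * out["acc"]


def pattern_probability(
    m: DemographyModel,
    pattern,
    u: UnitScale | None = None,
) -> float:
    """Per-site probability of observing the given site pattern."""
    return float(pattern_probabilities(m, [pattern], u)[0])


# ----------------------------------------------------------------------
# Expected total tree length (monomorphic class)


def _pure_death_epoch(p: np.ndarray, lam: float, dt: float):
    """Evolve a lineage-count distribution over an epoch of length dt.

    Returns (p_end, m) where m[k] = integral of P(count == k) over the
    epoch.  The generator moves k -> k-1 at rate k (k - 1) / (2 lam).
    """
    from ._factor import pure_death_marginal

    n = len(p) - 1
    if n < 2 or dt <= 0:
        return p.copy(), p * dt
    return pure_death_marginal(
        np.ascontiguousarray(p, dtype=np.float64), float(lam), float(dt), 1e-12
    )


def total_tree_length(m: DemographyModel, u: UnitScale | None = None) -> float:
    """Expected total genealogy length (scaled units) for the model's samples.

    Exact: per-branch lineage-count distributions follow pure-death
    chains, independent across branches, convolved at joins; after the
    last event the closed form E[L | k lineages] = 2 lam H_{k-1} finishes
    the root epoch.  Uses E[L] = int (E[N_tot] - 1) dt + E[TMRCA].
    """
    errs = validate_model(m)
    if errs:
        raise ValueError("invalid model: " + "; ".join(errs))
    lam = {b.name: b.lam for b in m.branches}
    dists: dict = {}
    for b in m.branches:
        if b.sample_age == 0:
            p = np.zeros(b.sample_size + 1)
            p[b.sample_size] = 1.0
            dists[b.name] = p

    events: list = []
    for b in m.branches:
        if b.sample_age > 0:
            events.append((b.sample_age, "activate", b.name))
    for j in m.sorted_joins():
        events.append((j.time, "join", j))
    events.sort(key=lambda e: (e[0], 0 if e[1] == "activate" else 1))

    L = 0.0
    t = 0.0
    for ev_time, kind, payload in events:
        dt = ev_time - t
        if dt > 0:
            carrying = [n for n, p in dists.items() if p[1:].sum() > 1e-15]
            ge2 = 0.0  # integral of P(N_tot >= 2)
            for n in list(dists):
                p_end, mm = _pure_death_epoch(dists[n], lam[n], dt)
                dists[n] = p_end
                ks = np.arange(len(mm))
                L += float((ks * mm).sum())  # integral of E[N_branch]
                if len(carrying) == 1 and n == carrying[0]:
                    ge2 = float(mm[2:].sum())
            if len(carrying) >= 2:
                ge2 = dt
            L += ge2 - dt  # -1 from E[N_tot] - 1; + P(N_tot >= 2) for TMRCA
            t = ev_time
        if kind == "activate":
            b = m.branch(payload)
            p = np.zeros(b.sample_size + 1)
            p[b.sample_size] = 1.0
            dists[payload] = (
                np.convolve(dists[payload], p) if payload in dists else p
            )
        else:
            j = payload
            pi = dists.pop(j.into, np.asarray([1.0]))
            pf = dists.pop(j.from_, np.asarray([1.0]))
            dists[j.into] = np.convolve(pi, pf)
            if j.lambda_after is not None:
                lam[j.into] = j.lambda_after

    (root_name,) = dists.keys()
    q = dists[root_name]
    lam_root = lam[root_name]
    harm = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, len(q)))])
    # E[L from k lineages] = 2 lam H_{k-1}
    L += float(sum(q[k] * 2.0 * lam_root * harm[k - 1] for k in range(2, len(q))))
    return L


# ----------------------------------------------------------------------
# Composite likelihood


def _all_tracked_patterns(sizes, max_m):
    return [
        p
        for p in product(*(range(min(n, max_m) + 1) for n in sizes))
        if 1 <= sum(p) <= max_m
    ]


def _align_histogram(m: DemographyModel, h: PatternHistogram):
    """Column permutation mapping histogram populations onto model branches."""
    sampled = [b.name for b in m.branches if b.sample_size > 0]
    if set(h.config.populations) != set(sampled):
        raise ValueError(
            f"histogram populations {h.config.populations} do not match "
            f"sampled model branches {sampled}"
        )
    for b in m.branches:
        if b.sample_size > 0:
            hn = h.config.sizes[h.config.index(b.name)]
            if hn != b.sample_size:
                raise ValueError(
                    f"sample size mismatch for {b.name}: histogram {hn}, "
                    f"model {b.sample_size}"
                )
    return [h.config.index(b.name) for b in m.branches if b.sample_size > 0]


def histogram_loglikelihood(
    m: DemographyModel,
    h: PatternHistogram,
    u: UnitScale | None = None,
    conditional: bool = False,
    floor: float = 1e-12,
) -> float:
    """Composite multinomial log-likelihood of a pattern histogram.

    Site classes are the tracked patterns, the monomorphic class
    ``p0 = 1 - theta * E[total tree length]`` and the overflow class by
    complement.  For a restricted histogram (monomorphic and overflow
    zeroed, e.g. after restrict_to_shared) only the retained pattern terms
    contribute; with ``conditional=True`` they are renormalized over the
    retained classes instead.
    """
    u = u or m.scale or UnitScale()
    perm = _align_histogram(m, h)
    sampled_idx = [k for k, b in enumerate(m.branches) if b.sample_size > 0]
    K = len(m.branches)

    def to_model_order(pat):
        full = [0] * K
        for k, col in zip(sampled_idx, perm):
            full[k] = pat[col]
        return tuple(full)

    restricted = h.monomorphic == 0 and h.overflow == 0
    if restricted and h.meta.get("restricted_to") is not None:
        qcol = h.config.index(h.meta["restricted_to"])
        pats = [
            p
            for p in _all_tracked_patterns(h.config.sizes, h.max_m)
            if p[qcol] >= 1 and sum(p) - p[qcol] >= 1
        ]
    elif restricted:
        pats = sorted(h.counts)
    else:
        pats = _all_tracked_patterns(h.config.sizes, h.max_m)
    if not pats:
        raise ValueError("empty histogram: no tracked patterns")

    probs = pattern_probabilities(m, [to_model_order(p) for p in pats], u)
    probs = np.maximum(probs, floor)
    counts = np.asarray([h.counts.get(p, 0) for p in pats], dtype=float)
    if conditional:
        probs = probs / probs.sum()
    ll = float(counts @ np.log(probs))
    if restricted and not conditional:
        # complement class keeps the information in the rate of shared
        # sites when the callable total is known
        orig = h.meta.get("original_total_sites")
        if orig is not None and orig > h.total_sites:
            p_rest = max(1.0 - float(probs.sum()), floor)
            ll += (orig - h.total_sites) * math.log(p_rest)
    if not restricted and not conditional:
        L = total_tree_length(m, u)
        p0 = 1.0 - u.scaled_theta * L
        if p0 <= 0:
            raise ValueError("monomorphic probability <= 0: model inconsistent")
        p_over = max(1.0 - p0 - float(probs.sum()), floor)
        ll += h.monomorphic * math.log(p0) + h.overflow * math.log(p_over)
    return ll
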