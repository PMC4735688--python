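"""Demographic models: population trees with constant per-branch sizes.

A model is a rooted population tree.  Each branch is a population with a
scaled diploid size ``lambda = N_b / n_ref`` and contributes a fixed number
of haploid samples at the tips (optionally at a positive *sample age* for
ancient samples).  Join events merge one branch into another backward in
time; the surviving branch may change size at the join.  All times are in
coalescent-scaled units of ``2 * n_ref`` generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "UnitScale",
    "Branch",
    "JoinEvent",
    "DemographyModel",
    "ParameterMap",
    "ModelSyntaxError",
    "parse_model_file",
    "write_model_file",
    "validate_model",
    "to_real",
]


@dataclass(frozen=True)
class UnitScale:
    """Constants linking scaled coalescent units to real units.

    n_ref is the reference diploid size used for internal scaling; mu is the
    per-generation per-site mutation rate; gen_years is years per generation.
    The per-site mutation rate per scaled time unit is
    ``scaled_theta = 2 * n_ref * mu``.
    """

    n_ref: float = 20_000.0
    mu: float = 1.25e-8
    gen_years: float = 29.0

    def __post_init__(self) -> None:
        if self.n_ref <= 0 or self.mu <= 0 or self.gen_years <= 0:
            raise ValueError("UnitScale fields must be strictly positive")

    @property
    def scaled_theta(self) -> float:
        return 2.0 * self.n_ref * self.mu

    def scaled_to_years(self, t: float) -> float:
        return t * 2.0 * self.n_ref * self.gen_years

    def years_to_scaled(self, years: float) -> float:
        return years / (2.0 * self.n_ref * self.gen_years)

    def lambda_to_diploids(self, lam: float) -> float:
        return lam * self.n_ref

    def diploids_to_lambda(self, n: float) -> float:
        return n / self.n_ref

    def generations_to_scaled(self, gens: float) -> float:
        return gens / (2.0 * self.n_ref)


@dataclass
class Branch:
    name: str
    lam: float
    sample_size: int = 0
    sample_age: float = 0.0


@dataclass
class JoinEvent:
    time: float
    into: str
    from_: str
    lambda_after: float | None = None


@dataclass
class DemographyModel:
    branches: list[Branch] = field(default_factory=list)
    joins: list[JoinEvent] = field(default_factory=list)
    scale: UnitScale | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def branch_names(self) -> list[str]:
        return [b.name for b in self.branches]

    def branch(self, name: str) -> Branch:
        for b in self.branches:
            if b.name == name:
                return b
        raise KeyError(f"unknown branch {name!r}")

    def branch_index(self, name: str) -> int:
        for i, b in enumerate(self.branches):
            if b.name == name:
                return i
        raise KeyError(f"unknown branch {name!r}")

    def sorted_joins(self) -> list[JoinEvent]:
        """Joins in time order; ties keep file order (stable sort)."""
        return sorted(self.joins, key=lambda j: j.time)

    def terminal_join_time(self, name: str) -> float:
        """Time at which branch `name` merges into another (inf for the root)."""
        for j in self.sorted_joins():
            if j.from_ == name:
                return j.time
        return math.inf

    def root_name(self) -> str:
        dead = {j.from_ for j in self.joins}
        alive = [b.name for b in self.branches if b.name not in dead]
        if len(alive) != 1:
            raise ValueError("model is not a rooted tree")
        return alive[0]

    def root_time(self) -> float:
        return max((j.time for j in self.joins), default=0.0)

    def copy(self) -> "DemographyModel":
        return DemographyModel(
            branches=[replace(b) for b in self.branches],
            joins=[replace(j) for j in self.joins],
            scale=self.scale,
        )

    def lambda_at(self, name: str, time: float) -> float:
        """Size of branch `name` at scaled time `time` (piecewise constant)."""
        lam = self.branch(name).lam
        for j in self.sorted_joins():
            if j.into == name and j.time <= time and j.lambda_after is not None:
                lam = j.lambda_after
        return lam

    def sample_sizes(self) -> dict[str, int]:
        return {b.name: b.sample_size for b in self.branches}


def validate_model(m: DemographyModel) -> list[str]:
    """Return a list of invariant violations; an empty list means valid."""
    errs: list[str] = []
    names = [b.name for b in m.branches]
    if len(set(names)) != len(names):
        errs.append("duplicate branch names")
    if not m.branches:
        errs.append("model has no branches")
        return errs
    for b in m.branches:
        if not b.lam > 0:
            errs.append(f"branch {b.name}: lambda must be > 0")
        if b.sample_size < 0:
            errs.append(f"branch {b.name}: sample_size must be >= 0")
        if b.sample_age < 0:
            errs.append(f"branch {b.name}: sample_age must be >= 0")
    if len(m.joins) != len(m.branches) - 1:
        errs.append(
            f"not a rooted tree: {len(m.branches)} branches require "
            f"{len(m.branches) - 1} joins, got {len(m.joins)}"
        )
    froms = [j.from_ for j in m.joins]
    if len(set(froms)) != len(froms):
        errs.append("a branch is 'from' in more than one join")
    nameset = set(names)
    for j in m.joins:
        if not j.time > 0:
            errs.append(f"join {j.into}<-{j.from_}: time > 0 required")
        if j.into == j.from_:
            errs.append(f"join {j.into}<-{j.from_}: into == from")
        for lbl in (j.into, j.from_):
            if lbl not in nameset:
                errs.append(f"join references unknown branch {lbl!r}")
        if j.lambda_after is not None and not j.lambda_after > 0:
            errs.append(f"join {j.into}<-{j.from_}: lambda_after must be > 0")
    if errs:
        return errs
    # Process joins in time order and check the tree is consistent: both
    # partners must still be alive when they merge.
    alive = set(nameset)
    for j in m.sorted_joins():
        if j.into not in alive or j.from_ not in alive:
            errs.append(
                f"join {j.into}<-{j.from_} at t={j.time}: branch already merged "
                "(cyclic or out-of-order joins)"
            )
            return errs
        alive.discard(j.from_)
    if len(alive) != 1:
        errs.append("not a rooted tree: more than one branch survives all joins")
    # Ancient samples must predate the first join involving their branch.
    for b in m.branches:
        if b.sample_age > 0:
            t_first = min(
                (j.time for j in m.joins if b.name in (j.into, j.from_)),
                default=math.inf,
            )
            if not b.sample_age < t_first:
                errs.append(
                    f"branch {b.name}: sample_age {b.sample_age} not earlier than "
                    f"its first join at {t_first}"
                )
    return errs


def to_real(m: DemographyModel, u: UnitScale | None = None) -> dict:
    """Convert scaled model quantities to years and diploid sizes.

    years = scaled_time * 2 * n_ref * gen_years;
    diploids = lambda * n_ref.
    """
    u = u or m.scale or UnitScale()
    report = {
        "n_ref": u.n_ref,
        "mu": u.mu,
        "gen_years": u.gen_years,
        "branches": [
            {
                "name": b.name,
                "diploid_size": u.lambda_to_diploids(b.lam),
                "sample_size": b.sample_size,
                "sample_age_years": u.scaled_to_years(b.sample_age),
            }
            for b in m.branches
        ],
        "joins": [
            {
                "into": j.into,
                "from": j.from_,
                "time_years": u.scaled_to_years(j.time),
                "diploid_size_after": (
                    u.lambda_to_diploids(j.lambda_after)
                    if j.lambda_after is not None
                    else None
                ),
            }
            for j in m.sorted_joins()
        ],
    }
    return report


# ----------------------------------------------------------------------
# Model text format


class ModelSyntaxError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def parse_model_file(text: str) -> DemographyModel:
    """Parse the model text format.

    One directive per line, '#' starts a comment::

        branch <name> <lambda> <sample_size> [<sample_age>]
        join <time> <into> <from> [<lambda_after>]
        scale <n_ref> <mu> <gen_years>
    """
    m = DemographyModel()
    seen_scale = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0]
        try:
            if kind == "branch":
                if len(tok) not in (4, 5):
                    raise ValueError("expected: branch <name> <lambda> <n> [<age>]")
                name = tok[1]
                if name in {b.name for b in m.branches}:
                    raise ValueError(f"duplicate branch {name!r}")
                age = float(tok[4]) if len(tok) == 5 else 0.0
                m.branches.append(Branch(name, float(tok[2]), int(tok[3]), age))
            elif kind == "join":
                if len(tok) not in (4, 5):
                    raise ValueError(
                        "expected: join <time> <into> <from> [<lambda_after>]"
                    )
                lam_after = float(tok[4]) if len(tok) == 5 else None
                m.joins.append(JoinEvent(float(tok[1]), tok[2], tok[3], lam_after))
            elif kind == "scale":
                if len(tok) != 4:
                    raise ValueError("expected: scale <n_ref> <mu> <gen_years>")
                if seen_scale:
                    raise ValueError("duplicate scale directive")
                seen_scale = True
                m.scale = UnitScale(float(tok[1]), float(tok[2]), float(tok[3]))
            else:
                raise ValueError(f"unknown directive {kind!r}")
        except ModelSyntaxError:
            raise
        except ValueError as e:
            raise ModelSyntaxError(line_no, str(e)) from e
    errs = validate_model(m)
    if errs:
        raise ValueError("invalid model: " + "; ".join(errs))
    return m


def write_model_file(m: DemographyModel) -> str:
    lines = []
    if m.scale is not None:
        lines.append(f"scale {m.scale.n_ref:g} {m.scale.mu:g} {m.scale.gen_years:g}")
    for b in m.branches:
        base = f"branch {b.name} {b.lam!r} {b.sample_size}"
        lines.append(base + (f" {b.sample_age!r}" if b.sample_age > 0 else ""))
    for j in m.sorted_joins():
        base = f"join {j.time!r} {j.into} {j.from_}"
        lines.append(
            base + (f" {j.lambda_after!r}" if j.lambda_after is not None else "")
        )
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# Free-parameter vectorization


_LOG_LAMBDA_BOUNDS = (math.log(1e-3), math.log(1e3))
_INCREMENT_BOUNDS = (1e-8, 2.0)


class ParameterMap:
    """Maps named free parameters onto model slots.

    Sizes are optimized on log scale; join times are parameterized as
    positive increments relative to the latest event on either child
    lineage, which keeps any parameter vector within bounds consistent
    with the tree ordering.

    Recognized names: ``lambda_<branch>`` (tip size),
    ``lambda_<into>_after_<from>`` (ancestral segment size after a join),
    ``t_<into>_<from>`` (join time).
    """

    def __init__(self, template: DemographyModel, names: list[str]):
        errs = validate_model(template)
        if errs:
            raise ValueError("invalid template model: " + "; ".join(errs))
        self.template = template
        self.names = list(names)
        self._slots: list[tuple[str, int]] = []
        self.bounds: list[tuple[float, float]] = []
        sorted_joins = template.sorted_joins()
        for name in self.names:
            slot = self._resolve(template, sorted_joins, name)
            self._slots.append(slot)
            kind = slot[0]
            self.bounds.append(
                _INCREMENT_BOUNDS if kind == "time" else _LOG_LAMBDA_BOUNDS
            )

    @staticmethod
    def _resolve(m, sorted_joins, name: str) -> tuple[str, int]:
        if name.startswith("t_"):
            rest = name[2:]
            for i, j in enumerate(sorted_joins):
                if f"{j.into}_{j.from_}" == rest:
                    return ("time", i)
            raise ValueError(f"parameter {name!r} matches no join")
        if name.startswith("lambda_"):
            rest = name[7:]
            if "_after_" in rest:
                into, frm = rest.split("_after_", 1)
                for i, j in enumerate(sorted_joins):
                    if j.into == into and j.from_ == frm:
                        return ("lambda_after", i)
                raise ValueError(f"parameter {name!r} matches no join")
            for i, b in enumerate(m.branches):
                if b.name == rest:
                    return ("lambda_tip", i)
            raise ValueError(f"parameter {name!r} matches no branch")
        raise ValueError(f"unrecognized parameter name {name!r}")

    @classmethod
    def free_all(cls, template: DemographyModel) -> "ParameterMap":
        """All join times, tip sizes (of sampled branches) and ancestral sizes."""
        names = []
        for j in template.sorted_joins():
            names.append(f"t_{j.into}_{j.from_}")
        for b in template.branches:
            if b.sample_size > 0:
                names.append(f"lambda_{b.name}")
        for j in template.sorted_joins():
            if j.lambda_after is not None:
                names.append(f"lambda_{j.into}_after_{j.from_}")
        return cls(template, names)

    # -- increment bookkeeping -------------------------------------------

    def _join_bases(self, m: DemographyModel) -> list[float]:
        """Base time for each sorted join: latest event on either child lineage."""
        last: dict[str, float] = {b.name: b.sample_age for b in m.branches}
        bases = []
        for j in m.sorted_joins():
            base = max(last.get(j.into, 0.0), last.get(j.from_, 0.0))
            bases.append(base)
            last[j.into] = j.time
        return bases

    def pack(self, m: DemographyModel | None = None):
        """Transformed parameter vector for model `m` (default: template)."""
        import numpy as np

        m = m or self.template
        sorted_joins = m.sorted_joins()
        bases = self._join_bases(m)
        x = []
        for kind, idx in self._slots:
            if kind == "time":
                x.append(sorted_joins[idx].time - bases[idx])
            elif kind == "lambda_tip":
                x.append(math.log(m.branches[idx].lam))
            else:
                x.append(math.log(sorted_joins[idx].lambda_after))
        return np.asarray(x, dtype=float)

    def unpack(self, x) -> DemographyModel:
        """Model with free slots set from transformed vector `x`.

        Join times are reconstructed in time order of the template so that
        each free join sits `increment` above the latest event on its child
        lineages.
        """
        m = self.template.copy()
        sorted_joins = m.sorted_joins()  # same objects as in m.joins
        incr: dict[int, float] = {}
        for (kind, idx), v in zip(self._slots, x):
            if kind == "time":
                incr[idx] = float(v)
            elif kind == "lambda_tip":
                m.branches[idx].lam = math.exp(float(v))
            else:
                sorted_joins[idx].lambda_after = math.exp(float(v))
        if incr:
            last: dict[str, float] = {b.name: b.sample_age for b in m.branches}
            for i, j in enumerate(sorted_joins):
                base = max(last.get(j.into, 0.0), last.get(j.from_, 0.0))
                if i in incr:
                    j.time = base + incr[i]
                last[j.into] = j.time
        return m

    def in_bounds(self, x) -> bool:
        return all(lo <= v <= hi for v, (lo, hi) in zip(x, self.bounds))

    def __len__(self) -> int:
        return len(self.names)
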