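"""Experimental design generation for the media-optimization campaign.

All designs are two-level (or nested two-level) plans over a
:class:`FactorSpace` whose bounds are expressed in xRef units (multiples of
the reference medium concentration). Coded levels live in ``[-1, +1]`` with
``-1`` mapping affinely to the lower bound and ``+1`` to the upper bound.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorSpace",
    "DesignMatrix",
    "SnapResult",
    "ROLES",
    "reduce_components",
    "full_factorial",
    "fractional_factorial",
    "nested_round3_design",
    "add_reference_replicates",
    "plates_required",
    "snap_to_pipetting_grid",
]

ROLES = ("factorial", "center", "space_filling", "ei_proposed", "random_uniform", "reference")

PLATE_ROW_LABELS = "ABCDEF"
PLATE_N_COLS = 8
DEFAULT_CAPACITY = 48


@dataclass(frozen=True)
class Factor:
    """One free input variable with bounds in xRef units."""

    name: str
    lower: float
    upper: float
    reference_concentration: float | None = None

    def __post_init__(self):
        if self.lower < 0:
            raise ValueError(f"factor {self.name}: lower bound must be >= 0")
        if not self.upper > self.lower:
            raise ValueError(f"factor {self.name}: need lower < upper")


@dataclass
class FactorSpace:
    """Named free variables plus clustering/tying/fixing metadata.

    ``tied_groups`` maps a representative (free) variable name to the set of
    component names co-varied with it; ``fixed`` holds components held at a
    constant xRef level. ``require_reference_inside`` enforces that the
    reference composition (1.0 xRef) is inside every factor's bounds.
    """

    factors: list[Factor]
    tied_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    fixed: list[tuple[str, float]] = field(default_factory=list)
    require_reference_inside: bool = True

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        for rep in self.tied_groups:
            if rep not in names:
                raise ValueError(f"tie representative {rep!r} is not a free variable")
        if self.require_reference_inside:
            for f in self.factors:
                if not (f.lower <= 1.0 <= f.upper):
                    raise ValueError(
                        f"factor {f.name}: reference level 1.0 xRef outside [{f.lower}, {f.upper}]"
                    )

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def lower(self) -> np.ndarray:
        return np.array([f.lower for f in self.factors], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([f.upper for f in self.factors], dtype=float)

    def code(self, natural: np.ndarray) -> np.ndarray:
        """Map natural xRef levels to coded [-1, +1] levels (affine)."""
        natural = np.asarray(natural, dtype=float)
        return 2.0 * (natural - self.lower) / (self.upper - self.lower) - 1.0

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`code`."""
        coded = np.asarray(coded, dtype=float)
        return self.lower + (coded + 1.0) / 2.0 * (self.upper - self.lower)

    def subset(self, names, bounds: dict[str, tuple[float, float]] | None = None,
               fix_level: float = 1.0, require_reference_inside: bool | None = None) -> "FactorSpace":
        """Restrict to ``names``; remaining free variables become fixed at
        ``fix_level``. ``bounds`` optionally overrides per-factor bounds."""
        names = list(names)
        unknown = set(names) - set(self.names)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        bounds = bounds or {}
        kept = []
        for f in self.factors:
            if f.name in names:
                lo, hi = bounds.get(f.name, (f.lower, f.upper))
                kept.append(Factor(f.name, lo, hi, f.reference_concentration))
        kept.sort(key=lambda f: names.index(f.name))
        fixed = list(self.fixed) + [(f.name, fix_level) for f in self.factors if f.name not in names]
        tied = {rep: members for rep, members in self.tied_groups.items() if rep in names}
        rri = self.require_reference_inside if require_reference_inside is None else require_reference_inside
        return FactorSpace(kept, tied, fixed, require_reference_inside=rri)

    def with_bounds(self, bounds: dict[str, tuple[float, float]],
                    require_reference_inside: bool | None = None) -> "FactorSpace":
        new = [replace(f, lower=bounds[f.name][0], upper=bounds[f.name][1]) if f.name in bounds else f
               for f in self.factors]
        rri = self.require_reference_inside if require_reference_inside is None else require_reference_inside
        return FactorSpace(new, dict(self.tied_groups), list(self.fixed), require_reference_inside=rri)


def _well_label(index_on_plate: int) -> str:
    row = PLATE_ROW_LABELS[index_on_plate // PLATE_N_COLS]
    return f"{row}{index_on_plate % PLATE_N_COLS + 1}"


@dataclass
class DesignMatrix:
    """Planned runs in coded units, bound to a :class:`FactorSpace`.

    The frame holds columns ``run_id``, ``role`` plus one coded column per
    free variable. Natural (xRef) levels are derived on demand so the
    coded<->natural relation cannot drift out of sync.
    """

    space: FactorSpace
    round_id: int
    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = ["run_id", "role"] + self.space.names
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design frame missing columns {missing}")
        bad = set(self.frame["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_coded(cls, space: FactorSpace, coded: np.ndarray, roles, round_id: int,
                   meta: dict | None = None, start_index: int = 1) -> "DesignMatrix":
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        if coded.shape[1] != space.k:
            coded = coded.reshape(-1, space.k)
        n = coded.shape[0]
        if isinstance(roles, str):
            roles = [roles] * n
        frame = pd.DataFrame(coded, columns=space.names)
        frame.insert(0, "role", list(roles))
        frame.insert(0, "run_id", [f"R{round_id}-{start_index + i:02d}" for i in range(n)])
        return cls(space, round_id, frame, meta or {})

    @classmethod
    def from_natural(cls, space: FactorSpace, natural: np.ndarray, roles, round_id: int,
                     meta: dict | None = None, start_index: int = 1) -> "DesignMatrix":
        natural = np.atleast_2d(np.asarray(natural, dtype=float))
        if natural.size == 0:
            natural = natural.reshape(0, space.k)
        return cls.from_coded(space, space.code(natural), roles, round_id, meta, start_index)

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def roles(self) -> pd.Series:
        return self.frame["role"]

    def coded(self) -> np.ndarray:
        return self.frame[self.space.names].to_numpy(dtype=float)

    def natural(self) -> np.ndarray:
        return self.space.decode(self.coded())

    def natural_frame(self) -> pd.DataFrame:
        out = self.frame[["run_id", "role"]].copy()
        nat = self.natural()
        for j, name in enumerate(self.space.names):
            out[name] = nat[:, j] if len(self) else np.array([])
        return out

    def append(self, other: "DesignMatrix") -> "DesignMatrix":
        if other.space.names != self.space.names:
            raise ValueError("factor mismatch between designs")
        frame = pd.concat([self.frame, other.frame], ignore_index=True)
        return DesignMatrix(self.space, self.round_id, frame, dict(self.meta))

    # -- serialization ------------------------------------------------------

    def to_frame(self, capacity: int = DEFAULT_CAPACITY, coded: bool = False) -> pd.DataFrame:
        """Tabular export: run_id, round, role, plate, well, then xRef levels."""
        nat = self.natural_frame()
        out = pd.DataFrame({
            "run_id": nat["run_id"],
            "round": self.round_id,
            "role": nat["role"],
            "plate": [i // capacity + 1 for i in range(len(self))],
            "well": [_well_label(i % capacity) for i in range(len(self))],
        })
        for name in self.space.names:
            out[name] = nat[name]
        if coded:
            for name in self.space.names:
                out[f"coded_{name}"] = self.frame[name]
        return out

    def to_csv(self, path, capacity: int = DEFAULT_CAPACITY, coded: bool = False) -> None:
        self.to_frame(capacity=capacity, coded=coded).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: FactorSpace) -> "DesignMatrix":
        raw = pd.read_csv(path)
        round_id = int(raw["round"].iloc[0]) if len(raw) else 0
        natural = raw[space.names].to_numpy(dtype=float) if len(raw) else np.zeros((0, space.k))
        frame = pd.DataFrame(space.code(natural), columns=space.names)
        frame.insert(0, "role", raw["role"].tolist())
        frame.insert(0, "run_id", raw["run_id"].tolist())
        return cls(space, round_id, frame)


# ---------------------------------------------------------------------------
# component reduction
# ---------------------------------------------------------------------------

_DECISION_ALIASES = {
    "vary": "vary", "fix": "fix",
    "cluster": "cluster", "cluster-with": "cluster",
    "tie": "tie", "tie-with": "tie",
}


def reduce_components(component_table, bounds: dict[str, tuple[float, float]] | None = None,
                      default_bounds: tuple[float, float] = (0.2, 1.7),
                      reference_concentrations: dict[str, float] | None = None) -> FactorSpace:
    """Collapse a component table with variation decisions into a FactorSpace.

    Each record needs ``name`` and ``decision`` (vary / fix / cluster / tie);
    cluster and tie records carry the partner under ``with``. The number of
    free variables equals the varied components minus cluster merges minus
    ties. Bounds default to ``default_bounds`` and may be overridden per
    variable through ``bounds``.
    """
    bounds = bounds or {}
    refc = reference_concentrations or {}
    varied: list[str] = []
    clusters: dict[str, list[str]] = {}
    cluster_position: dict[str, int] = {}
    ties: list[tuple[str, str]] = []
    fixed: list[tuple[str, float]] = []
    seen: set[str] = set()

    for pos, record in enumerate(component_table):
        name = record["name"]
        if name in seen:
            raise ValueError(f"duplicate component {name!r}")
        seen.add(name)
        decision = _DECISION_ALIASES.get(str(record["decision"]).lower())
        if decision is None:
            raise ValueError(f"unknown decision {record['decision']!r} for component {name!r}")
        if decision == "vary":
            varied.append(name)
        elif decision == "fix":
            fixed.append((name, float(record.get("level", 1.0))))
        elif decision == "cluster":
            group = record.get("with")
            if not group:
                raise ValueError(f"component {name!r}: cluster decision needs a group name")
            clusters.setdefault(group, []).append(name)
            cluster_position.setdefault(group, pos)
        else:  # tie
            target = record.get("with")
            if not target:
                raise ValueError(f"component {name!r}: tie decision needs a target")
            ties.append((name, target))

    varied_names = set(varied)
    for name, target in ties:
        if target not in varied_names:
            raise ValueError(
                f"component {name!r} is tied to {target!r}, which is not a varied component"
            )

    # free variables in table order; a cluster variable appears at the
    # position of its first member
    ordered: list[tuple[int, str]] = []
    for pos, record in enumerate(component_table):
        if record["name"] in varied_names:
            ordered.append((pos, record["name"]))
    for group, pos in cluster_position.items():
        if group in varied_names:
            raise ValueError(f"cluster group {group!r} collides with a varied component name")
        ordered.append((pos, group))
    ordered.sort()

    factors = []
    for _, name in ordered:
        lo, hi = bounds.get(name, default_bounds)
        factors.append(Factor(name, lo, hi, refc.get(name)))

    tied_groups: dict[str, tuple[str, ...]] = {}
    for name, target in ties:
        tied_groups[target] = tuple(sorted(set(tied_groups.get(target, ())) | {name}))
    for group, members in clusters.items():
        tied_groups[group] = tuple(sorted(members))

    return FactorSpace(factors, tied_groups, fixed)


# ---------------------------------------------------------------------------
# factorial generators
# ---------------------------------------------------------------------------

def _two_level_grid(k: int) -> np.ndarray:
    """All 2^k combinations of -1/+1, first factor slowest."""
    if k == 0:
        return np.zeros((1, 0))
    return np.array(list(itertools.product((-1.0, 1.0), repeat=k)))


def full_factorial(space: FactorSpace, round_id: int = 2) -> DesignMatrix:
    """Complete two-level factorial: 2^k rows, every corner once."""
    coded = _two_level_grid(space.k)
    return DesignMatrix.from_coded(space, coded, "factorial", round_id,
                                   meta={"generator": "full_factorial"})


def _word_name(mask: int, names: list[str]) -> str:
    return "*".join(names[i] for i in range(len(names)) if mask >> i & 1)


def fractional_factorial(space: FactorSpace, focus_factor: str, round_id: int = 1,
                         capacity: int | None = None, reserve: int = 0) -> DesignMatrix:
    """Smallest regular two-level fraction estimating all main effects and
    every two-factor interaction involving ``focus_factor`` free of mutual
    aliasing.

    Regular 2^(k-p) fractions are built from ``b`` basis factors plus
    generator words; generator sets are searched in lexicographic order and
    the first satisfying the estimability requirement wins, so the result is
    reproducible. The defining generators are recorded in ``meta``.
    """
    k = space.k
    if focus_factor not in space.names:
        raise ValueError(f"focus factor {focus_factor!r} not in factor space")
    focus = space.names.index(focus_factor)

    n_terms = 2 * k  # intercept + k mains + (k-1) focus interactions
    b_min = max(1, math.ceil(math.log2(max(n_terms, 2))))

    solution = None
    for b in range(min(b_min, k), k + 1):
        if b == k:
            solution = (b, [])
            break
        base_masks = [1 << i for i in range(b)]
        words = [m for m in range(2 ** b) if bin(m).count("1") >= 2]
        p = k - b
        for combo in itertools.combinations(words, p):
            masks = base_masks + list(combo)
            terms = list(masks) + [masks[focus] ^ masks[j] for j in range(k) if j != focus]
            if 0 not in terms and len(set(terms)) == 2 * k - 1:
                solution = (b, list(combo))
                break
        if solution is not None:
            break

    b, generators = solution
    n = 2 ** b
    if capacity is not None and n + reserve > capacity:
        raise ValueError(
            f"smallest regular fraction needs {n} runs (+{reserve} references), "
            f"exceeding plate capacity {capacity} by {n + reserve - capacity}"
        )

    base = _two_level_grid(b)
    cols = [base[:, i] for i in range(b)]
    for mask in generators:
        col = np.ones(n)
        for i in range(b):
            if mask >> i & 1:
                col = col * base[:, i]
        cols.append(col)
    coded = np.column_stack(cols) if cols else np.zeros((1, 0))

    meta = {"generator": "fractional_factorial", "focus": focus_factor, "n_basis": b}
    if generators:
        defining = [f"{space.names[b + j]}={_word_name(m, space.names)}"
                    for j, m in enumerate(generators)]
        meta["defining_relation"] = ";".join(defining)
    else:
        meta["generator"] = "full_factorial"  # fraction degenerates to the full plan
    return DesignMatrix.from_coded(space, coded, "factorial", round_id, meta=meta)


# ---------------------------------------------------------------------------
# nested round-3 design
# ---------------------------------------------------------------------------

def _greedy_maximin(candidates: np.ndarray, existing: np.ndarray, n_pick: int) -> list[int]:
    """Deterministic farthest-point selection; ties broken by candidate order."""
    if n_pick == 0:
        return []
    chosen: list[int] = []
    ref = existing.copy()
    mindist = np.full(len(candidates), np.inf)
    if len(ref):
        d = np.linalg.norm(candidates[:, None, :] - ref[None, :, :], axis=2)
        mindist = d.min(axis=1)
    for _ in range(n_pick):
        idx = int(np.argmax(mindist))  # argmax takes the first max -> deterministic
        chosen.append(idx)
        d_new = np.linalg.norm(candidates - candidates[idx], axis=1)
        mindist = np.minimum(mindist, d_new)
    return chosen


def nested_round3_design(space: FactorSpace, mg_levels, inner_half_range: bool = True,
                         n_centers: int = 2, n_edge: int = 9, seed: int = 0,
                         mg_factor: str | None = None, round_id: int = 3) -> DesignMatrix:
    """Stacked 2^3 factorial cubes over three magnesium levels plus center
    and space-filling edge points.

    ``space`` must have exactly four free variables: the magnesium factor
    plus the three cube variables. Levels between the first and the last use
    half ranges (coded +-0.5) when ``inner_half_range`` is set; all rows are
    expressed in a single coding frame. Edge points are chosen by a
    deterministic maximin spread over the cube edges (``seed`` reserved for
    future stochastic placement strategies).
    """
    if space.k != 4:
        raise ValueError(f"nested design needs exactly 4 free variables, got {space.k}")
    mg_name = mg_factor or ("MgSO4" if "MgSO4" in space.names else space.names[0])
    if mg_name not in space.names:
        raise ValueError(f"magnesium factor {mg_name!r} not in factor space")
    mg_idx = space.names.index(mg_name)
    cube_idx = [i for i in range(4) if i != mg_idx]

    mg_levels = [float(v) for v in mg_levels]
    if len(mg_levels) < 1:
        raise ValueError("need at least one magnesium level")
    if any(b <= a for a, b in zip(mg_levels, mg_levels[1:])):
        raise ValueError(f"mg_levels must be strictly increasing, got {mg_levels}")
    mg_lo, mg_hi = space.factors[mg_idx].lower, space.factors[mg_idx].upper
    for v in mg_levels:
        if not (mg_lo <= v <= mg_hi):
            raise ValueError(f"magnesium level {v} outside bounds [{mg_lo}, {mg_hi}]")

    def mg_coded(value: float) -> float:
        return 2.0 * (value - mg_lo) / (mg_hi - mg_lo) - 1.0

    halfwidth = []
    for i in range(len(mg_levels)):
        inner = inner_half_range and 0 < i < len(mg_levels) - 1
        halfwidth.append(0.5 if inner else 1.0)

    rows, roles = [], []
    corners = _two_level_grid(3)
    for i, level in enumerate(mg_levels):
        for corner in corners:
            x = np.zeros(4)
            x[mg_idx] = mg_coded(level)
            for c, j in zip(corner, cube_idx):
                x[j] = c * halfwidth[i]
            rows.append(x)
            roles.append("factorial")

    # center points cycle through the cubes starting with the innermost level
    order = sorted(range(len(mg_levels)),
                   key=lambda i: (abs(i - (len(mg_levels) - 1) / 2), i))
    for c in range(n_centers):
        i = order[c % len(mg_levels)]
        x = np.zeros(4)
        x[mg_idx] = mg_coded(mg_levels[i])
        rows.append(x)
        roles.append("center")

    # space-filling candidates on cube edges: two cube coordinates at the
    # cube's bounds, the third strictly inside
    candidates = []
    for i, level in enumerate(mg_levels):
        h = halfwidth[i]
        for free_dim in range(3):
            bound_dims = [d for d in range(3) if d != free_dim]
            for signs in itertools.product((-1.0, 1.0), repeat=2):
                for t in (-0.5, 0.0, 0.5):
                    x = np.zeros(4)
                    x[mg_idx] = mg_coded(level)
                    for s, d in zip(signs, bound_dims):
                        x[cube_idx[d]] = s * h
                    x[cube_idx[free_dim]] = t * h
                    candidates.append(x)
    candidates = np.array(candidates)
    existing = np.array(rows)
    picked = _greedy_maximin(candidates, existing, n_edge)
    for idx in picked:
        rows.append(candidates[idx])
        roles.append("space_filling")

    meta = {"generator": "nested_round3", "mg_factor": mg_name,
            "mg_levels": tuple(mg_levels), "inner_half_range": inner_half_range,
            "n_centers": n_centers, "n_edge": n_edge, "seed": seed}
    return DesignMatrix.from_coded(space, np.array(rows), roles, round_id, meta=meta)


# ---------------------------------------------------------------------------
# plate bookkeeping
# ---------------------------------------------------------------------------

def add_reference_replicates(design: DesignMatrix, n_ref: int,
                             capacity: int = DEFAULT_CAPACITY) -> DesignMatrix:
    """Append ``n_ref`` wells at the unmodified reference medium (1.0 xRef)."""
    if n_ref < 0:
        raise ValueError("n_ref must be >= 0")
    if n_ref == 0:
        return design
    total = len(design) + n_ref
    if total > capacity:
        raise ValueError(
            f"design of {len(design)} rows plus {n_ref} references exceeds "
            f"capacity {capacity} by {total - capacity}"
        )
    natural = np.ones((n_ref, design.space.k))
    refs = DesignMatrix.from_natural(design.space, natural, "reference",
                                     design.round_id, start_index=len(design) + 1)
    return design.append(refs)


def plates_required(n_runs: int, capacity: int = DEFAULT_CAPACITY) -> int:
    """Smallest number of plates covering ``n_runs`` wells."""
    if n_runs < 0:
        raise ValueError("n_runs must be >= 0")
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    return -(-n_runs // capacity)


# ---------------------------------------------------------------------------
# pipetting-grid snapping
# ---------------------------------------------------------------------------

@dataclass
class SnapResult:
    design: DesignMatrix
    errors: pd.DataFrame          # relative snap error per run and factor
    increments: dict[str, float]  # xRef level per minimum aliquot

    @property
    def max_abs_error(self) -> float:
        cols = [c for c in self.errors.columns if c.startswith("abs_")]
        return float(self.errors[cols].to_numpy().max()) if len(self.errors) else 0.0


def snap_to_pipetting_grid(design: DesignMatrix, well_volume: float = 2500.0,
                           min_pipette: float = 10.0,
                           stock_concentrations: dict[str, float] | None = None,
                           default_stock: float = 0.002) -> SnapResult:
    """Round natural levels to what the liquid handler can actually dose.

    Stock concentrations are given in xRef-equivalents contributed per uL of
    stock pipetted into one well; achievable levels are integer multiples of
    ``min_pipette * stock``. Levels below half a minimum aliquot snap to 0.
    Snapping is advisory: the result reports the per-row relative error and
    never raises.
    """
    if min_pipette <= 0 or well_volume <= 0:
        raise ValueError("volumes must be positive")
    stock_concentrations = stock_concentrations or {}
    space = design.space
    natural = design.natural()
    snapped = natural.copy()
    increments = {}
    err_abs = np.zeros_like(natural)
    err_rel = np.zeros_like(natural)
    for j, name in enumerate(space.names):
        conc = float(stock_concentrations.get(name, default_stock))
        if conc <= 0:
            raise ValueError(f"stock concentration for {name!r} must be positive")
        step = min_pipette * conc
        increments[name] = step
        n_aliquots = np.floor(natural[:, j] / step + 0.5)  # half-up, deterministic
        max_aliquots = np.floor(well_volume / min_pipette)
        n_aliquots = np.clip(n_aliquots, 0, max_aliquots)
        snapped[:, j] = n_aliquots * step
        err_abs[:, j] = np.abs(snapped[:, j] - natural[:, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(natural[:, j] > 0, err_abs[:, j] / natural[:, j], 0.0)
        err_rel[:, j] = rel

    new = DesignMatrix.from_coded(space, space.code(snapped), design.roles.tolist(),
                                  design.round_id, meta={**design.meta, "snapped": True})
    new.frame["run_id"] = design.frame["run_id"].to_numpy()
    errors = pd.DataFrame({"run_id": design.frame["run_id"]})
    for j, name in enumerate(space.names):
        errors[f"rel_{name}"] = err_rel[:, j]
        errors[f"abs_{name}"] = err_abs[:, j]
    return SnapResult(new, errors, increments)
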