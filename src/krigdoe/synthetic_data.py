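"""Synthetic ground-truth response surface and in-silico cultivation oracle.

The surface stands in for the micro-photobioreactor: additive per-factor
quadratics plus bilinear interactions on xRef coordinates, an interior
optimum for the four key components, and seeded multiplicative measurement
noise. Every pipeline stage is testable against it without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import presets
from ._flattext import dumps, loads, parse_floats, parse_list
from .designs import DesignMatrix
from .effects import ObservationSet

__all__ = ["GroundTruthSurface", "default_surface", "evaluate", "make_fixture_campaign"]

# Stated location of the interior optimum of the four key components (xRef)
# and the productivity gain factor at that optimum relative to the reference.
CORE_OPTIMUM = {"MgSO4": 3.25, "CaCl2": 1.25, "trace": 2.5, "NaNO3": 0.45}
BASELINE_PRODUCTIVITY = 73.0   # mg/L/d at the all-reference composition
OPTIMUM_GAIN_FACTOR = 3.03     # optimum / baseline productivity ratio

# Shape constants before global rescaling: per-factor curvature (negative ->
# concave) and marginal optimum location; bilinear interaction coefficients.
_SHAPE_CURVATURE = {
    "MES": -2.0, "phosphate": -1.0, "NaNO3": -105.0, "MgSO4": -22.0,
    "NaCl": -0.8, "CaCl2": -75.0, "trace": -20.0, "FeSO4": -1.5, "Na2EDTA": -2.0,
}
_SHAPE_MARGINAL_OPT = {
    "MES": 0.7, "phosphate": 1.05, "NaCl": 1.0, "FeSO4": 1.1, "Na2EDTA": 0.7,
}
_SHAPE_INTERACTIONS = {("MgSO4", "NaNO3"): -22.0, ("CaCl2", "trace"): -4.0}

_DEFAULT_BOX = {name: (0.0, 4.0) for name in _SHAPE_CURVATURE}


@dataclass
class GroundTruthSurface:
    """Parametric medium -> productivity surface with a noise model.

    ``value`` is the noiseless response; per-factor terms and interactions
    vanish at the all-reference composition, so the reference productivity is
    ``baseline`` exactly. Negative raw values are physically meaningless and
    are floored at zero by :func:`evaluate`.
    """

    baseline: float
    factor_names: tuple[str, ...]
    curvature: dict[str, float]            # kappa_j < 0 for an interior optimum
    optimum_location: dict[str, float]     # m_j, marginal optimum in xRef
    interactions: dict[tuple[str, str], float]
    noise_type: str = "lognormal_cv"       # or "additive_sd"
    noise_value: float = 0.07
    box: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.noise_value < 0:
            raise ValueError("noise value must be >= 0")
        if self.noise_type not in ("lognormal_cv", "additive_sd"):
            raise ValueError(f"unknown noise type {self.noise_type!r}")
        self.factor_names = tuple(self.factor_names)
        if not self.box:
            self.box = {n: (0.0, 4.0) for n in self.factor_names}

    # -- evaluation ----------------------------------------------------------

    def value(self, composition) -> np.ndarray:
        """Noiseless surface value; composition is a mapping/DataFrame of
        xRef levels (missing factors default to the reference level 1.0)."""
        if isinstance(composition, pd.DataFrame):
            comp = {c: composition[c].to_numpy(dtype=float) for c in composition.columns}
        else:
            comp = {k: np.asarray(v, dtype=float) for k, v in dict(composition).items()}
        n = max((np.size(v) for v in comp.values()), default=1)
        out = np.full(n, self.baseline, dtype=float)
        for name in self.factor_names:
            x = comp.get(name, 1.0)
            k = self.curvature[name]
            m = self.optimum_location[name]
            out = out + k * ((x - m) ** 2 - (1.0 - m) ** 2)
        for (a, b), c in self.interactions.items():
            xa, xb = comp.get(a, 1.0), comp.get(b, 1.0)
            out = out + c * (xa - 1.0) * (xb - 1.0)
        return out

    def _value_vector(self, x: np.ndarray, names) -> float:
        return float(self.value({n: x[i] for i, n in enumerate(names)}))

    def argmax(self, free=None, fixed: dict[str, float] | None = None,
               resolution: int = 21, polish: bool = True) -> tuple[dict[str, float], float]:
        """Box-constrained maximizer of the noiseless surface.

        Dense grid over the ``free`` factors (the rest held at ``fixed``
        levels, default reference) followed by a local L-BFGS-B refinement.
        """
        free = list(free) if free is not None else list(self.factor_names)
        fixed = dict(fixed or {})
        for n in self.factor_names:
            if n not in free and n not in fixed:
                fixed[n] = 1.0
        lower = np.array([self.box[n][0] for n in free])
        upper = np.array([self.box[n][1] for n in free])

        d = len(free)
        if resolution ** d <= 2 * 10 ** 5:
            grids = [np.linspace(lower[i], upper[i], resolution) for i in range(d)]
            mesh = np.meshgrid(*grids, indexing="ij")
            Q = np.column_stack([m.ravel() for m in mesh])
        else:
            rng = np.random.default_rng(self.seed)
            Q = rng.uniform(lower, upper, size=(8192, d))
        comp = {n: Q[:, i] for i, n in enumerate(free)}
        comp.update({n: np.full(len(Q), v) for n, v in fixed.items()})
        vals = self.value(comp)
        x0 = Q[int(np.argmax(vals))]
        best_x, best_f = x0, float(np.max(vals))

        if polish:
            def neg(x):
                c = {n: x[i] for i, n in enumerate(free)}
                c.update(fixed)
                return -float(self.value(c)[0])

            res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                    bounds=list(zip(lower, upper)))
            if -res.fun >= best_f:
                best_x, best_f = res.x, float(-res.fun)
        return {n: float(best_x[i]) for i, n in enumerate(free)}, best_f

    # -- serialization -------------------------------------------------------

    def to_text(self) -> str:
        names = list(self.factor_names)
        pairs = sorted(self.interactions)
        scalars = {
            "type": "ground_truth_surface",
            "baseline": self.baseline,
            "factor_names": ",".join(names),
            "noise_type": self.noise_type,
            "noise_value": self.noise_value,
            "seed": self.seed,
            "interaction_pairs": ",".join(f"{a}*{b}" for a, b in pairs),
        }
        arrays = {
            "curvature": [self.curvature[n] for n in names],
            "optimum_location": [self.optimum_location[n] for n in names],
            "interaction_coefficients": [self.interactions[p] for p in pairs] or [0.0],
            "box_lower": [self.box[n][0] for n in names],
            "box_upper": [self.box[n][1] for n in names],
        }
        return dumps(scalars, arrays, header="krigdoe ground-truth surface v1")

    @classmethod
    def from_text(cls, text: str) -> "GroundTruthSurface":
        scalars, arrays = loads(text)
        if scalars.get("type") != "ground_truth_surface":
            raise ValueError("not a serialized surface")
        names = parse_list(scalars["factor_names"])
        pairs = [tuple(p.split("*")) for p in parse_list(scalars.get("interaction_pairs", ""))]
        coeffs = arrays["interaction_coefficients"].ravel()
        interactions = {tuple(p): float(c) for p, c in zip(pairs, coeffs)}
        return cls(
            baseline=float(scalars["baseline"]),
            factor_names=tuple(names),
            curvature=dict(zip(names, arrays["curvature"].ravel())),
            optimum_location=dict(zip(names, arrays["optimum_location"].ravel())),
            interactions=interactions,
            noise_type=scalars["noise_type"],
            noise_value=float(scalars["noise_value"]),
            box={n: (float(lo), float(hi)) for n, lo, hi in
                 zip(names, arrays["box_lower"].ravel(), arrays["box_upper"].ravel())},
            seed=int(scalars["seed"]),
        )


def default_surface(noise_cv: float = 0.07, baseline: float = BASELINE_PRODUCTIVITY,
                    gain_factor: float = OPTIMUM_GAIN_FACTOR, seed: int = 0) -> GroundTruthSurface:
    """The packaged default surface.

    Construction: marginal optima of the four key factors are placed so that
    the joint stationary point of the concave quadratic-plus-bilinear form
    sits exactly at :data:`CORE_OPTIMUM`; all curvatures and interaction
    coefficients are then rescaled so the optimum exceeds the baseline by
    ``gain_factor``. Both steps are exact, so the surface's maximizer and
    optimum value are known analytically.
    """
    names = tuple(_SHAPE_CURVATURE)
    kappa = dict(_SHAPE_CURVATURE)
    inter = dict(_SHAPE_INTERACTIONS)

    # marginal optima of the core factors from stationarity at CORE_OPTIMUM:
    #   2 kappa_p (x*_p - m_p) + sum_q c_pq (x*_q - 1) = 0
    m = dict(_SHAPE_MARGINAL_OPT)
    for p in CORE_OPTIMUM:
        shift = 0.0
        for (a, b), c in inter.items():
            if p == a:
                shift += c * (CORE_OPTIMUM[b] - 1.0)
            elif p == b:
                shift += c * (CORE_OPTIMUM[a] - 1.0)
        m[p] = CORE_OPTIMUM[p] + shift / (2.0 * kappa[p])

    raw = GroundTruthSurface(baseline, names, kappa, m, inter,
                             noise_value=0.0, box=dict(_DEFAULT_BOX), seed=seed)
    gain = float(raw.value(CORE_OPTIMUM)[0]) - baseline
    scale = (gain_factor - 1.0) * baseline / gain
    kappa = {k: v * scale for k, v in kappa.items()}
    inter = {k: v * scale for k, v in inter.items()}
    return GroundTruthSurface(baseline, names, kappa, m, inter,
                              noise_type="lognormal_cv", noise_value=noise_cv,
                              box=dict(_DEFAULT_BOX), seed=seed)


def evaluate(surface: GroundTruthSurface, design: DesignMatrix, seed: int = 0,
             capacity: int = 48) -> ObservationSet:
    """In-silico cultivation: noiseless surface value per run plus seeded
    measurement noise, floored at zero.

    Factors absent from the design are taken from the design space's fixed
    levels (reference 1.0 otherwise). Compositions outside the surface's
    declared box are clipped with a warning.
    """
    frame = design.natural_frame()
    fixed = dict(design.space.fixed)
    comp = {}
    clipped = False
    for name in surface.factor_names:
        if name in frame.columns:
            x = frame[name].to_numpy(dtype=float)
        else:
            x = np.full(len(frame), fixed.get(name, 1.0))
        lo, hi = surface.box.get(name, (-np.inf, np.inf))
        clip = np.clip(x, lo, hi)
        if np.any(clip != x):
            clipped = True
        comp[name] = clip
    if clipped:
        warnings.warn("design leaves the surface box; compositions clipped for evaluation",
                      RuntimeWarning, stacklevel=2)

    truth = surface.value(comp)
    rng = np.random.default_rng(seed)
    if surface.noise_value == 0:
        y = np.maximum(truth, 0.0)
    elif surface.noise_type == "lognormal_cv":
        cv = surface.noise_value
        s2 = np.log1p(cv ** 2)
        mult = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=len(truth))
        y = np.maximum(truth, 0.0) * mult
    else:  # additive_sd
        y = truth + rng.normal(0.0, surface.noise_value, size=len(truth))
        if np.any(y < 0):
            warnings.warn("negative raw draws clipped to 0", RuntimeWarning, stacklevel=2)
        y = np.maximum(y, 0.0)

    obs = ObservationSet.from_design(design, y)
    plates = [f"R{design.round_id}-P{i // capacity + 1}" for i in range(len(frame))]
    obs.frame["plate_id"] = plates
    return obs


def make_fixture_campaign(seed: int = 0, out_dir=None, noise_cv: float = 0.07):
    """Run the packaged four-round campaign and return per-round fixtures.

    Returns a dict ``round -> (DesignMatrix, ObservationSet)`` with the
    published plate loadings (37, 37, 39, 39 wells); when ``out_dir`` is
    given, design and observation CSVs are written there (deterministic and
    byte-identical for equal seeds).
    """
    from .campaign import default_config, run_campaign  # local import: avoid cycle

    surface = default_surface(noise_cv=noise_cv, seed=seed)
    state = run_campaign(config=default_config(), seed=seed, surface=surface)
    bundle = {r: (d, o) for r, d, o in state.round_artifacts}
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "surface.txt").write_text(surface.to_text())
        for r, (design, obs) in bundle.items():
            design.to_csv(out / f"round{r}_design.csv")
            obs.to_csv(out / f"round{r}_observations.csv")
    return bundle
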