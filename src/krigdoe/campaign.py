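"""Closed-loop orchestration of the four-round optimization strategy.

Round 1 screens all free variables with a regular two-level fraction, round 2
confirms the retained factors with a full factorial, round 3 brackets the
optimum with nested factorial cubes over three magnesium levels, and round 4
refines it with Expected-Improvement proposals plus uniform space filling.
Observations accumulate across rounds; the Kriging surrogate is refit on all
data available after each round.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets
from .designs import (DesignMatrix, FactorSpace, add_reference_replicates,
                      fractional_factorial, full_factorial, nested_round3_design,
                      reduce_components)
from .effects import (ObservationSet, effects_table, estimate_effects,
                      normalize_to_reference, screen_components)
from .ei_design import MCMCConfig, dram_sample, incumbent, select_batch, uniform_space_filling
from .kriging import KrigingModel, argmax_mean, fit, grid_evaluate

__all__ = ["RoundSpec", "CampaignConfig", "CampaignState", "default_config",
           "run_round", "run_campaign", "predict_improvement_factor", "report"]


@dataclass
class RoundSpec:
    round_id: int
    generator: str                      # fractional | full | nested | ei_uniform
    factors: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_ref: int = 5
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.generator not in ("fractional", "full", "nested", "ei_uniform"):
            raise ValueError(f"unknown generator {self.generator!r}")


@dataclass
class CampaignConfig:
    base_space: FactorSpace
    rounds: list[RoundSpec]
    capacity: int = presets.PLATE_CAPACITY
    alpha: float = presets.SIGNIFICANCE_LEVEL
    kriging_starts: int = 8
    kernel: str = "sq_exp"
    grid_resolution: int = 21
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    # "all": refit on every cumulative observation; "box": only on
    # observations whose current-factor levels lie inside the round's factor
    # box (10% margin) -- screening wells far outside the refinement region
    # otherwise distort the local surrogate
    fit_scope: str = "box"
    fit_margin: float = 0.1


def default_config() -> CampaignConfig:
    """The packaged campaign preset mirroring the published trajectory."""
    base = reduce_components(presets.COMPONENT_TABLE, bounds=presets.ROUND12_BOUNDS,
                             reference_concentrations=presets.REFERENCE_CONCENTRATIONS)
    rounds = [
        RoundSpec(1, "fractional", tuple(base.names), dict(presets.ROUND12_BOUNDS),
                  n_ref=presets.N_REF_ROUND12, params={"focus": "MgSO4"}),
        RoundSpec(2, "full", presets.ROUND2_FACTORS,
                  {k: presets.ROUND12_BOUNDS[k] for k in presets.ROUND2_FACTORS},
                  n_ref=presets.N_REF_ROUND12),
        RoundSpec(3, "nested", presets.ROUND34_FACTORS, dict(presets.ROUND34_BOUNDS),
                  n_ref=presets.N_REF_ROUND34,
                  params={"mg_levels": presets.ROUND3_MG_LEVELS, "n_centers": 2, "n_edge": 9}),
        RoundSpec(4, "ei_uniform", presets.ROUND34_FACTORS, dict(presets.ROUND34_BOUNDS),
                  n_ref=presets.N_REF_ROUND34,
                  params={"n_batch": presets.N_EI_PROPOSALS,
                          "n_uniform": presets.N_UNIFORM_ROUND4}),
    ]
    return CampaignConfig(base, rounds)


@dataclass
class CampaignState:
    config: CampaignConfig
    seed: int
    round_index: int = 0
    space: FactorSpace | None = None
    observations: ObservationSet | None = None
    model: KrigingModel | None = None
    history: list[dict] = field(default_factory=list)
    effects: dict[int, pd.DataFrame] = field(default_factory=dict)
    screening: dict[int, dict] = field(default_factory=dict)
    round_artifacts: list[tuple] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def digest(self) -> str:
        """Deterministic content hash of the campaign trajectory."""
        payload = {
            "round_index": self.round_index,
            "history": [
                {k: (dict(sorted((kk, round(vv, 10)) for kk, vv in v.items()))
                     if isinstance(v, dict) else (round(v, 10) if isinstance(v, float) else v))
                 for k, v in h.items()}
                for h in self.history
            ],
        }
        if self.observations is not None:
            obs = self.observations.frame.copy()
            num = obs.select_dtypes("number").round(10)
            payload["observations"] = [
                obs["run_id"].tolist(),
                [num[c].tolist() for c in num.columns],
            ]
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _round_seed(seed: int, round_id: int, purpose: int) -> int:
    return int(np.random.SeedSequence([seed, round_id, purpose]).generate_state(1)[0])


def _build_design(state: CampaignState, spec: RoundSpec) -> tuple[FactorSpace, DesignMatrix]:
    cfg = state.config
    space = cfg.base_space.subset(spec.factors, bounds=spec.bounds,
                                  require_reference_inside=False)
    p = spec.params
    if spec.generator == "fractional":
        design = fractional_factorial(space, p.get("focus", space.names[0]),
                                      round_id=spec.round_id, capacity=cfg.capacity,
                                      reserve=spec.n_ref)
    elif spec.generator == "full":
        design = full_factorial(space, round_id=spec.round_id)
    elif spec.generator == "nested":
        design = nested_round3_design(space, p.get("mg_levels", presets.ROUND3_MG_LEVELS),
                                      inner_half_range=p.get("inner_half_range", True),
                                      n_centers=p.get("n_centers", 2),
                                      n_edge=p.get("n_edge", 9),
                                      seed=_round_seed(state.seed, spec.round_id, 0),
                                      round_id=spec.round_id)
    else:  # ei_uniform
        if state.model is None:
            raise ValueError("EI round requires a fitted model from a previous round")
        mcmc = replace(cfg.mcmc, seed=_round_seed(state.seed, spec.round_id, 1))
        f_best = incumbent(state.model, state.observations)
        chain = dram_sample(state.model, f_best, space, mcmc)
        proposals = select_batch(chain, p.get("n_batch", 12), round_id=spec.round_id)
        filler = uniform_space_filling(space, p.get("n_uniform", 23),
                                       seed=_round_seed(state.seed, spec.round_id, 2),
                                       round_id=spec.round_id,
                                       start_index=len(proposals) + 1)
        # proposals were built on a standalone space; rebind onto this round's
        proposals = DesignMatrix.from_natural(space, proposals.natural(),
                                              "ei_proposed", spec.round_id,
                                              meta=proposals.meta)
        design = proposals.append(filler)
        design.meta["acceptance_rate"] = chain.acceptance_rate
        design.meta["f_best"] = f_best
    design = add_reference_replicates(design, spec.n_ref, capacity=cfg.capacity)
    if len(design) > cfg.capacity:
        raise ValueError(f"round {spec.round_id} design exceeds one plate")
    return space, design


def _match_user_data(design: DesignMatrix, data: ObservationSet, tol: float = 1e-6) -> ObservationSet:
    """Validate user-supplied results against the planned compositions."""
    names = design.space.names
    planned = design.natural_frame().set_index("run_id")
    got = data.frame.set_index("run_id")
    missing = [r for r in planned.index if r not in got.index]
    if missing:
        raise ValueError(f"results missing runs {missing}")
    mismatches = []
    for rid in planned.index:
        a = planned.loc[rid, names].to_numpy(dtype=float)
        b = got.loc[rid, names].to_numpy(dtype=float)
        if np.any(np.abs(a - b) > tol):
            mismatches.append(rid)
    if mismatches:
        raise ValueError(f"compositions differ from the design for runs {mismatches}")
    frame = got.loc[planned.index].reset_index()
    return ObservationSet(frame, tuple(names))


def run_round(state: CampaignState, spec: RoundSpec, oracle=None,
              data: ObservationSet | None = None) -> CampaignState:
    """Execute one campaign round: design, evaluate (or match supplied data),
    merge, refit, relocate the optimum. Returns a new state."""
    cfg = state.config
    if spec.generator == "ei_uniform" and len(spec.factors) == 0:
        raise ValueError("EI round needs free factors")

    # a round with no new runs only advances the round counter
    if spec.params.get("n_runs", None) == 0 and spec.n_ref == 0:
        new = replace(state, round_index=spec.round_id)
        new.log = state.log + [f"round {spec.round_id}: no new points, state carried over"]
        return new

    space, design = _build_design(state, spec)

    if data is not None:
        obs = _match_user_data(design, data)
    elif oracle is not None:
        from .synthetic_data import evaluate

        obs = evaluate(oracle, design, seed=_round_seed(state.seed, spec.round_id, 3),
                       capacity=cfg.capacity)
    else:
        raise ValueError("run_round needs either an oracle surface or user data")

    merged = obs if state.observations is None else state.observations.merge(obs)

    log = list(state.log)
    for name, (lo, hi) in spec.bounds.items():
        prev = next((f for f in cfg.base_space.factors if f.name == name), None)
        if prev and (prev.lower, prev.upper) != (lo, hi):
            log.append(f"round {spec.round_id}: {name} bounds {prev.lower}->{lo}, "
                       f"{prev.upper}->{hi} xRef")

    effects = dict(state.effects)
    screening = dict(state.screening)
    if spec.generator in ("fractional", "full"):
        focus = spec.params.get("focus")
        if focus:
            inter = [(focus, n) for n in space.names if n != focus]
        else:
            inter = [(a, b) for i, a in enumerate(space.names)
                     for b in space.names[i + 1:]]
        try:
            normed = normalize_to_reference(obs)
            ests = estimate_effects(normed, design, interaction_terms=inter, alpha=cfg.alpha)
            effects[spec.round_id] = effects_table(ests)
            part = screen_components(ests, alpha=cfg.alpha)
            screening[spec.round_id] = {k: sorted(v) for k, v in part.items()}
            log.append(f"round {spec.round_id}: screening keeps {sorted(part['keep'])}")
        except ValueError as exc:  # effects are diagnostics; never abort the loop
            log.append(f"round {spec.round_id}: effect estimation skipped ({exc})")

    fit_obs = merged
    if cfg.fit_scope == "box":
        X = merged.inputs(space.names)
        margin = cfg.fit_margin * (space.upper - space.lower)
        inside = np.all((X >= space.lower - margin) & (X <= space.upper + margin), axis=1)
        if inside.sum() >= max(10, space.k + 2):
            fit_obs = ObservationSet(merged.frame[inside], merged.factor_names)
    model = fit(fit_obs, factor_names=space.names, space=space, kernel=cfg.kernel,
                n_starts=cfg.kriging_starts, seed=_round_seed(state.seed, spec.round_id, 4))
    x_opt, _ = argmax_mean(model, box=(space.lower, space.upper),
                           resolution=cfg.grid_resolution,
                           seed=_round_seed(state.seed, spec.round_id, 5))
    pred = model.predict(x_opt)
    entry = {
        "round": spec.round_id,
        "optimum": {n: float(v) for n, v in zip(space.names, x_opt)},
        "predicted_mean": float(pred.mean),
        "predicted_sd": float(pred.sd),
        "n_runs": len(design),
    }
    log.append(f"round {spec.round_id}: {len(design)} wells, optimum "
               f"{entry['optimum']}, mean {entry['predicted_mean']:.2f}")

    return replace(state, round_index=spec.round_id, space=space, observations=merged,
                   model=model, history=state.history + [entry], effects=effects,
                   screening=screening,
                   round_artifacts=state.round_artifacts + [(spec.round_id, design, obs)],
                   log=log)


def run_campaign(config: CampaignConfig | None = None, seed: int = 0,
                 surface=None) -> CampaignState:
    """Run the full in-silico campaign against a ground-truth surface."""
    if surface is None:
        from .synthetic_data import default_surface

        surface = default_surface(seed=seed)
    config = config or default_config()
    state = CampaignState(config=config, seed=seed)
    for spec in config.rounds:
        state = run_round(state, spec, oracle=surface)
    return state


def predict_improvement_factor(model: KrigingModel, reference_obs: ObservationSet | None = None,
                               x_opt=None, box=None, resolution: int = 21,
                               seed: int = 0) -> dict[str, float]:
    """Predicted productivity gain of the located optimum over the reference.

    ``factor = mu(x_opt) / mu(x_ref)``; the uncertainty combines the two
    predictive SDs by first-order propagation assuming independence.
    """
    if reference_obs is not None and len(reference_obs.references()) < 1:
        raise ValueError("need at least one reference observation")
    if x_opt is None:
        x_opt, _ = argmax_mean(model, box=box, resolution=resolution, seed=seed)
    x_ref = np.ones(len(model.factor_names))
    po = model.predict(np.asarray(x_opt, dtype=float))
    pr = model.predict(x_ref)
    mu_o, s_o = float(po.mean), float(po.sd)
    mu_r, s_r = float(pr.mean), float(pr.sd)
    if mu_r <= 0:
        raise ValueError(f"reference prediction {mu_r} is not positive")
    factor = mu_o / mu_r
    sd = float(np.sqrt((s_o / mu_r) ** 2 + (mu_o * s_r / mu_r ** 2) ** 2))
    return {"factor": factor, "sd": sd}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(state: CampaignState, out_dir, slice_pairs=None, resolution: int = 41,
           plots: bool = False) -> dict:
    """Write effect tables, contour grids, the optimum trajectory and a
    machine-readable summary. Regenerating from the same state is
    byte-identical."""
    if not state.history:
        raise ValueError("report requires at least one completed round")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for rid, table in sorted(state.effects.items()):
        table.to_csv(out / f"effects_round{rid}.csv", index=False)

    traj = pd.DataFrame([
        {"round": h["round"], "predicted_mean": h["predicted_mean"],
         "predicted_sd": h["predicted_sd"], "n_runs": h["n_runs"],
         **{f"opt_{k}": v for k, v in h["optimum"].items()}}
        for h in state.history
    ])
    traj.to_csv(out / "optimum_trajectory.csv", index=False)

    captions = {}
    if state.model is not None:
        names = list(state.model.factor_names)
        if slice_pairs is None:
            slice_pairs = [(names[i], names[j]) for i in range(len(names))
                           for j in range(i + 1, len(names))][:3]
        opt = state.history[-1]["optimum"]
        for a, b in slice_pairs:
            fixed = {n: opt.get(n, 1.0) for n in names if n not in (a, b)}
            grid = grid_evaluate(state.model, (a, b), fixed, resolution=resolution)
            fname = f"grid_{a}_{b}.csv"
            grid.to_frame().to_csv(out / fname, index=False)
            captions[fname] = {"axes": [a, b], "fixed": fixed}
            if plots:
                _contour_png(grid, out / f"grid_{a}_{b}.png")
    (out / "grid_captions.json").write_text(json.dumps(captions, sort_keys=True, indent=1))

    summary = {
        "seed": state.seed,
        "rounds_completed": state.round_index,
        "history": state.history,
        "screening": state.screening,
        "digest": state.digest(),
        "log": state.log,
    }
    if state.model is not None and state.observations is not None:
        summary["improvement"] = predict_improvement_factor(
            state.model, x_opt=np.array([state.history[-1]["optimum"][n]
                                         for n in state.model.factor_names]))
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary


def _contour_png(grid, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    X, Y = np.meshgrid(grid.coords[0], grid.coords[1], indexing="ij")
    cs = ax.contourf(X, Y, grid.mean, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="predicted productivity")
    ax.set_xlabel(f"{grid.axes[0]} (xRef)")
    ax.set_ylabel(f"{grid.axes[1]} (xRef)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
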