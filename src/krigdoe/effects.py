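"""Main-effect and interaction estimation from two-level designs.

Effects are reported as the expected response change between the minimal and
maximal level of a factor (twice the coded regression coefficient). The error
model pools the regression residual variance with the replicate variance of
the reference wells, and each term gets a two-sided t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "ObservationSet",
    "EffectEstimate",
    "normalize_to_reference",
    "estimate_effects",
    "screen_components",
]

_META_COLUMNS = ("run_id", "round", "role", "plate", "well", "plate_id", "response")


@dataclass
class ObservationSet:
    """Run compositions (xRef) with measured responses.

    The frame carries ``run_id``, ``role``, ``plate_id``, one column per
    factor, and ``response`` (volumetric lipid productivity, mg/L/d, or a
    fold-of-reference value after normalization).
    """

    frame: pd.DataFrame
    factor_names: tuple[str, ...]

    def __post_init__(self):
        self.factor_names = tuple(self.factor_names)
        needed = {"run_id", "role", "plate_id", "response", *self.factor_names}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"observation frame missing columns {sorted(missing)}")
        if (self.frame["response"] < 0).any():
            raise ValueError("responses must be non-negative")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_design(cls, design: DesignMatrix, responses, plate_id: str = "P1") -> "ObservationSet":
        responses = np.asarray(responses, dtype=float)
        if len(responses) != len(design):
            raise ValueError("one response per design row required")
        frame = design.natural_frame()
        frame["plate_id"] = plate_id
        frame["response"] = responses
        return cls(frame, tuple(design.space.names))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def responses(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=float)

    def inputs(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else list(self.factor_names)
        return self.frame[names].to_numpy(dtype=float)

    def references(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "reference"]

    def merge(self, other: "ObservationSet") -> "ObservationSet":
        cols = sorted(set(self.factor_names) | set(other.factor_names))
        a, b = self.frame.copy(), other.frame.copy()
        for c in cols:  # factors absent from one set were held at reference
            if c not in a.columns:
                a[c] = 1.0
            if c not in b.columns:
                b[c] = 1.0
        frame = pd.concat([a, b], ignore_index=True, sort=False)
        return ObservationSet(frame, tuple(cols))

    def to_csv(self, path) -> None:
        cols = ["run_id", "role", "plate_id", *self.factor_names, "response"]
        extra = [c for c in self.frame.columns if c not in cols]
        self.frame[cols + extra].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factor_names=None) -> "ObservationSet":
        frame = pd.read_csv(path)
        if factor_names is None:
            skip = set(_META_COLUMNS)
            factor_names = tuple(c for c in frame.columns if c not in skip)
        if "plate_id" not in frame.columns:
            frame["plate_id"] = frame["plate"].astype(str) if "plate" in frame.columns else "P1"
        return cls(frame, tuple(factor_names))


@dataclass(frozen=True)
class EffectEstimate:
    """Expected response change between minimal and maximal factor level."""

    term: str | tuple[str, str]
    effect: float
    se: float
    t: float
    p_value: float
    significant: bool
    df: int

    @property
    def is_interaction(self) -> bool:
        return isinstance(self.term, tuple)

    @property
    def label(self) -> str:
        return ":".join(self.term) if self.is_interaction else self.term


def normalize_to_reference(obs: ObservationSet) -> ObservationSet:
    """Divide every response by the mean reference response of its plate."""
    frame = obs.frame.copy()
    refs = frame[frame["role"] == "reference"]
    if refs.empty:
        raise ValueError("normalization requires at least one reference row")
    means = refs.groupby("plate_id")["response"].mean()
    for plate, sub in frame.groupby("plate_id"):
        if plate not in means.index:
            raise ValueError(f"plate {plate!r} has no reference rows")
        m = means.loc[plate]
        if m <= 0:
            raise ValueError(f"plate {plate!r}: reference mean {m} is not positive")
        frame.loc[sub.index, "response"] = sub["response"] / m
    return ObservationSet(frame, obs.factor_names)


def _reference_variance(obs: ObservationSet) -> tuple[float, int]:
    """Pooled within-plate sum of squares of reference replicates, with df."""
    refs = obs.references()
    ss, df = 0.0, 0
    for _, sub in refs.groupby("plate_id"):
        if len(sub) >= 2:
            y = sub["response"].to_numpy(dtype=float)
            ss += float(np.sum((y - y.mean()) ** 2))
            df += len(sub) - 1
    return ss, df


def _model_matrix(coded: np.ndarray, names: list[str], interactions) -> tuple[np.ndarray, list]:
    terms: list = []
    cols = [np.ones(len(coded))]
    for j, name in enumerate(names):
        terms.append(name)
        cols.append(coded[:, j])
    for a, b in interactions:
        ia, ib = names.index(a), names.index(b)
        terms.append(tuple(sorted((a, b))))
        cols.append(coded[:, ia] * coded[:, ib])
    return np.column_stack(cols), terms


def _alias_pairs(X: np.ndarray, terms: list) -> list[tuple]:
    """Pairs of effect columns that are confounded (|cosine| ~ 1)."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    G = (X / norms).T @ (X / norms)
    pairs = []
    labels = ["intercept"] + [":".join(t) if isinstance(t, tuple) else t for t in terms]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if abs(G[i, j]) > 1 - 1e-8:
                pairs.append((labels[i], labels[j]))
    return pairs


def estimate_effects(obs: ObservationSet, design: DesignMatrix,
                     interaction_terms=None, alpha: float = 0.1) -> list[EffectEstimate]:
    """Least-squares effect estimation on a two-level design.

    Fits response on intercept + coded main effects + the requested coded
    two-factor interactions using the non-reference rows, then tests each
    term two-sided against zero. The error variance pools the fit residuals
    with the reference-replicate scatter (all the pure-error information the
    design carries).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    interactions = [tuple(t) for t in (interaction_terms or [])]
    names = list(design.space.names)
    for a, b in interactions:
        if a not in names or b not in names:
            raise ValueError(f"interaction ({a},{b}) references unknown factors")

    merged = obs.frame.merge(design.frame[["run_id", *names]], on="run_id",
                             suffixes=("", "_coded"))
    if len(merged) != len(obs.frame):
        raise ValueError("observations do not match the design run_ids")
    run_mask = merged["role"] != "reference"
    coded = merged.loc[run_mask, [f"{n}_coded" if f"{n}_coded" in merged else n
                                  for n in names]].to_numpy(dtype=float)
    y = merged.loc[run_mask, "response"].to_numpy(dtype=float)

    X, terms = _model_matrix(coded, names, interactions)
    n, p = X.shape
    aliases = _alias_pairs(X, terms)
    if aliases:
        raise ValueError(f"requested terms are aliased: {aliases}")
    if n < p:
        raise ValueError(f"saturated model: {n} runs for {p} terms")

    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    df_res = n - p

    ss_ref, df_ref = _reference_variance(obs)
    df_total = df_res + df_ref
    if df_total <= 0:
        raise ValueError("no degrees of freedom for error (saturated model, no replicates)")
    s2 = (ss_res + ss_ref) / df_total

    cov_diag = s2 * np.diag(np.linalg.inv(XtX))
    estimates = []
    for i, term in enumerate(terms, start=1):
        effect = 2.0 * coef[i]
        se = 2.0 * float(np.sqrt(cov_diag[i]))
        if se > 0:
            t = effect / se
            pval = 2.0 * float(stats.t.sf(abs(t), df_total))
        else:
            t, pval = 0.0, 1.0
        estimates.append(EffectEstimate(term, float(effect), se, float(t), pval,
                                        bool(pval < alpha), df_total))
    return estimates


def screen_components(estimates, alpha: float = 0.1) -> dict[str, set[str]]:
    """Partition free variables into keep/drop after screening.

    A variable is kept if its main effect is significant at ``alpha`` or if
    it participates in a significant two-factor interaction.
    """
    mains = [e for e in estimates if not e.is_interaction]
    keep: set[str] = set()
    for e in estimates:
        if e.p_value < alpha:
            if e.is_interaction:
                keep.update(e.term)
            else:
                keep.add(e.term)
    drop = {e.term for e in mains} - keep
    return {"keep": keep, "drop": drop}


def effects_table(estimates) -> pd.DataFrame:
    rows = [{"term": e.label, "effect": e.effect, "se": e.se, "t": e.t,
             "p": e.p_value, "significant": e.significant} for e in estimates]
    return pd.DataFrame(rows)
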