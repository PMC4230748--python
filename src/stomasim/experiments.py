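"""Scenario library: light/CO2/ABA conditions, perturbation presets,
in-silico knockout screens, osmotica accounting, rule-modification runs.

Conditions are expressed as signal settings (light quality = levels of
the blue/red signals; CO2 level 0 free / 1 ambient / 2 elevated; ABA
present/absent) plus clamps.  Pharmacological treatments are named
clamp presets: DCMU holds photophosphorylation at 0, fusicoccin holds
the 14-3-3-bound H+-ATPase at its maximal activation level, sucrose
depletion holds sucrose at 0; a knockout holds any one node at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import rules as R
from .engine import EnsembleResult, ExperimentConfig, SummaryStats, run_ensemble, summarize
from .model import EdgeSpec, ModelSpec

__all__ = [
    "LIGHTS", "condition_signals", "preset_clamps",
    "OsmoticaComposition", "osmotica_composition",
    "ConditionResult", "run_condition",
    "knockout_screen", "screen_histogram", "SCREEN_BINS",
    "apply_modification", "aba_response_table",
]

LIGHTS: dict[str, tuple[int, int]] = {
    "dual": (1, 1), "blue": (1, 0), "red": (0, 1), "dark": (0, 0),
}

#: clamp presets for pharmacological / depletion treatments
_PRESETS = {
    "dcmu": {"photophosphorylation": 0},
    "fusicoccin": {"H_ATPase_complex": 9},
    "sucrose_depletion": {"sucrose": 0},
}


def condition_signals(light: str, co2: int = 1, aba: int = 0) -> dict[str, float]:
    """Signal levels for a named light quality + CO2 + ABA condition."""
    if light not in LIGHTS:
        raise ValueError(f"unknown light condition {light!r}; "
                         f"choose from {sorted(LIGHTS)}")
    if co2 not in (0, 1, 2):
        raise ValueError(f"CO2 level must be 0, 1 or 2, got {co2}")
    if aba not in (0, 1):
        raise ValueError(f"ABA must be 0 or 1, got {aba}")
    blue, red = LIGHTS[light]
    return {"blue_light": blue, "red_light": red, "CO2": co2, "ABA": aba}


def preset_clamps(*names: str, model: ModelSpec | None = None) -> dict[str, float]:
    """Clamp dict for named treatment presets (combinable)."""
    out: dict[str, float] = {}
    for name in names:
        key = name.lower().replace("-", "_")
        if key not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        out.update(_PRESETS[key])
    return out


# ---------------------------------------------------------------------------
# Osmotica accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OsmoticaComposition:
    """Percent contribution of ionic vs sucrose osmotica to opening.

    Both are ``None`` when the opening level is 0 (no osmoticum
    accumulated, composition undefined).
    """

    ions_percent: float | None
    sucrose_percent: float | None


def _osmotica_terms(model: ModelSpec) -> tuple[list[str], list[str]]:
    meta = (model.metadata or {}).get("osmotica", {})
    ions = list(meta.get("ions", []))
    sucrose = list(meta.get("sucrose", []))
    if not ions or not sucrose:
        raise ValueError(
            "model metadata must declare osmotica term lists "
            "(metadata.osmotica.ions / metadata.osmotica.sucrose)")
    return ions, sucrose


def osmotica_composition(ensemble: EnsembleResult, model: ModelSpec,
                         node: str | None = None) -> OsmoticaComposition:
    """Split the steady-state opening level into ion vs sucrose parts.

    Each osmoticum term (a sub-expression of the opening rule, with the
    same weight it carries there, declared in the model metadata) is
    evaluated per replicate at the step where the mean opening peaks;
    the ensemble-mean term values are normalized to sum to 100%.
    """
    node = node or model.output.name
    ions_terms, sucrose_terms = _osmotica_terms(model)
    mean = ensemble.node_mean(node)
    peak_step = int(mean.argmax())
    if mean[peak_step] == 0:
        return OsmoticaComposition(None, None)

    index = {n: i for i, n in enumerate(ensemble.node_names)}

    def term_mean(texts: list[str]) -> float:
        total = 0.0
        states = ensemble.levels[:, peak_step, :]
        for text in texts:
            expr = R.parse_rule(text, ensemble.node_names)
            fn = R.compile_rule(expr, index, -np.inf, np.inf)
            total += float(np.mean([fn(s) for s in states]))
        return total

    ions = term_mean(ions_terms)
    sucrose = term_mean(sucrose_terms)
    total = ions + sucrose
    if total <= 0:
        return OsmoticaComposition(None, None)
    return OsmoticaComposition(100.0 * ions / total, 100.0 * sucrose / total)


# ---------------------------------------------------------------------------
# Single-condition runs
# ---------------------------------------------------------------------------

@dataclass
class ConditionResult:
    light: str
    co2: int
    aba: int
    clamps: dict[str, float]
    summary: SummaryStats
    osmotica: OsmoticaComposition
    ensemble: EnsembleResult


def run_condition(model: ModelSpec, light: str, co2: int = 1, aba: int = 0,
                  clamps: Mapping[str, float] | None = None,
                  n_steps: int = 18, n_replicates: int = 2000,
                  seed: int = 0) -> ConditionResult:
    """Ensemble simulation of one experimental condition."""
    config = ExperimentConfig(
        n_steps=n_steps, n_replicates=n_replicates, seed=seed,
        signal_levels=condition_signals(light, co2, aba),
        clamps=dict(clamps or {}))
    ens = run_ensemble(model, config)
    out = model.output.name
    return ConditionResult(light=light, co2=co2, aba=aba,
                           clamps=dict(clamps or {}),
                           summary=summarize(ens, out),
                           osmotica=osmotica_composition(ens, model),
                           ensemble=ens)


# ---------------------------------------------------------------------------
# Knockout screen
# ---------------------------------------------------------------------------

#: Table-style percent-of-wild-type bins: [0,5), [5,15), ..., [85,95),
#: [95,100], (100,105], plus an explicit overflow bin above 105%.
SCREEN_BINS: list[str] = (
    ["0-5%", "5-15%", "15-25%", "25-35%", "35-45%", "45-55%", "55-65%",
     "65-75%", "75-85%", "85-95%", "95-100%", "100-105%", ">105%"])

_BIN_LOWER = [0, 5, 15, 25, 35, 45, 55, 65, 75, 85, 95]


def _bin_label(percent: float) -> str:
    if percent > 105:
        return ">105%"
    if percent > 100:
        return "100-105%"
    for lo, hi, label in zip(_BIN_LOWER, _BIN_LOWER[1:] + [100], SCREEN_BINS):
        if lo <= percent < hi:
            return label
    return "95-100%"  # exact 100% counts as wild-type-like


def knockout_screen(model: ModelSpec,
                    lights: Iterable[str] = ("dual", "blue", "red"),
                    co2_levels: Iterable[int] = (1, 0, 2),
                    aba: int = 0,
                    n_replicates: int = 2000,
                    n_steps: int = 18,
                    seed: int = 0,
                    nodes: Iterable[str] | None = None) -> pd.DataFrame:
    """Single-node knockout screen over a light x CO2 condition grid.

    Every internal node is individually clamped at 0; its maximal mean
    opening is expressed as a percentage of the wild-type opening of the
    same condition.  Where the wild type does not open, the percentage
    is undefined (NaN, ``wt_zero`` flagged).
    """
    screened = list(nodes) if nodes is not None else [n.name for n in model.internals]
    out_node = model.output.name
    rows = []
    seeds = _derive_seeds(seed, (len(screened) + 1) * 9)
    k = 0
    for light in lights:
        for co2 in co2_levels:
            wt = run_condition(model, light, co2, aba,
                               n_replicates=n_replicates, n_steps=n_steps,
                               seed=seeds[k])
            k += 1
            wt_max = wt.summary.max_level
            for node in screened:
                res = run_condition(model, light, co2, aba,
                                    clamps={node: 0},
                                    n_replicates=n_replicates, n_steps=n_steps,
                                    seed=seeds[k])
                k += 1
                pct = 100.0 * res.summary.max_level / wt_max if wt_max > 0 else np.nan
                rows.append({
                    "node": node, "light": light, "co2": co2, "aba": aba,
                    "max_opening": res.summary.max_level,
                    "t50": res.summary.t50, "t95": res.summary.t95,
                    "wt_max_opening": wt_max,
                    "percent_of_wt": pct,
                    "wt_zero": wt_max == 0,
                    "bin": _bin_label(pct) if wt_max > 0 else None,
                })
    return pd.DataFrame(rows)


def screen_histogram(screen: pd.DataFrame, light: str, co2: int) -> pd.Series:
    """Knockout counts per percent-of-WT bin for one condition."""
    sub = screen[(screen.light == light) & (screen.co2 == co2)]
    counts = sub["bin"].value_counts()
    return pd.Series([int(counts.get(b, 0)) for b in SCREEN_BINS],
                     index=SCREEN_BINS, name=f"{light}/CO2={co2}")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------------------
# Model modification / ABA table
# ---------------------------------------------------------------------------

def apply_modification(model: ModelSpec, node: str, new_rule: str) -> ModelSpec:
    """Return a copy of the model with one rule replaced.

    Edges are added for any regulator the new rule introduces (negative
    when the new reference appears under ``Not``); the original model is
    untouched.
    """
    expr = R.parse_rule(new_rule, model.node_names)
    old_refs = R.referenced_nodes(model.rules[node])
    new_refs = R.referenced_nodes(expr)
    from .fixtures import _negated_refs  # sign heuristic shared with builder
    negated = _negated_refs(expr)
    extra = [EdgeSpec(src, node, "-" if src in negated else "+")
             for src in sorted(new_refs - old_refs)]
    dropped = old_refs - new_refs
    if dropped:
        raise ValueError(f"modification drops regulators {sorted(dropped)}; "
                         f"remove their edges explicitly via ModelSpec.with_rule")
    return model.with_rule(node, new_rule, extra_edges=extra)


def aba_response_table(model: ModelSpec, co2: int = 1,
                       n_replicates: int = 2000, n_steps: int = 18,
                       seed: int = 0) -> pd.DataFrame:
    """Opening summary for 3 light qualities x ABA absent/present."""
    seeds = _derive_seeds(seed, 6)
    rows = []
    k = 0
    for light in ("dual", "blue", "red"):
        for aba in (0, 1):
            res = run_condition(model, light, co2, aba,
                                n_replicates=n_replicates, n_steps=n_steps,
                                seed=seeds[k])
            k += 1
            rows.append({"light": light, "aba": aba,
                         "max_opening": res.summary.max_level,
                         "t50": res.summary.t50, "t95": res.summary.t95})
    return pd.DataFrame(rows)
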